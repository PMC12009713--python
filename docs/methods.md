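# Methods

## The statistical model

`tsea` performs taxon set enrichment analysis (TSEA): given a ranked taxon
list — one real value per taxon, typically a log2 fold change from a
differential-abundance (DA) comparison, an effect size, or a correlation
coefficient — it asks, for each predefined taxon set, whether the set
members' values are distributed differently from the values of the
remaining input taxa.

For a set with detected members holding values $x_1,\dots,x_m$ and the
other input taxa holding $y_1,\dots,y_n$, the test statistic is the
two-sample Kolmogorov–Smirnov distance

$$D = \sup_x \lvert \hat F_m(x) - \hat G_n(x) \rvert,$$

the largest vertical gap between the two empirical CDFs, with a two-sided
p-value. P-values across all tested sets are adjusted with the
Benjamini–Hochberg (BH) step-up procedure to control the false discovery
rate, and results are ordered by FDR, then p-value, then set id.

Key modelling choices:

* **Members versus non-members.** The reference sample is the *rest* of the
  input, not the full input. Putting every member on both sides would make
  the two samples overlap and invalidate the two-sample null; testing
  against the complement is the standard resolution and changes essentially
  nothing when sets are small relative to the background.
* **Two-sided alternative.** The direction of change is not part of the
  test; it is read off by comparing the set's `median_rank` (median of the
  detected members' values, mean-of-central-pair for even counts) with the
  background median. A set median below the background median indicates
  depletion — e.g. loss of short-chain fatty acid producers in a disease
  cohort — above it, enrichment.
* **Detectability filter.** Before testing, sets are restricted to those
  with at least `min_size` members detected among the input identifiers
  (default 5). Testing sets represented by one or two taxa says nothing
  about the set, and the filter keeps the BH family small and meaningful.
  BH runs across exactly the tested sets.
* **Rank-only dependence.** $D$ and its p-value depend only on how the two
  samples interleave, so every result (statistic, p, FDR, ordering) is
  invariant under any strictly increasing transform of all input values.
  This is the mechanism that makes the method robust to the choice of
  upstream DA tool: different tools rescale effect estimates but largely
  agree on the ranking. The invariance is asserted bit-for-bit in the test
  suite.

## P-value computation

The KS p-value comes from `scipy.stats.ks_2samp`:

* **Exact** permutation-distribution p when $m \cdot n \le 10\,000$ and the
  two samples share no tied value. The exact p is the fraction of the
  $\binom{m+n}{m}$ equally likely interleavings whose $D$ reaches the
  observed one; the test suite re-derives it by brute-force enumeration for
  all splits of up to 8 values.
* **Asymptotic** Kolmogorov distribution otherwise. Cross-sample ties make
  the exact permutation argument invalid, so tied inputs deterministically
  fall back to the asymptotic p and the result row carries a `tie_flag`
  (no jitter, no hidden randomness). The asymptotic tail can underflow to
  zero for extreme separations; p is clamped to the smallest positive
  normal float so downstream BH input stays in (0, 1].

BH itself is delegated to `statsmodels` and is checked in the tests against
a hand-coded step-up formula
$\tilde p_{(i)} = \min_{j \ge i} \, m\, p_{(j)} / j$, capped at 1.

## Input handling

DA tables are read with pandas; a table needs a taxon-name column and one
numeric rank column. Dialect presets supply default column names for LinDA
(`log2FoldChange`), ALDEx2 (`effect`) and fastANCOM (`logFC`); explicit
column flags always override. Rows with missing or non-finite ranks are
dropped (logged); duplicate taxa are an error, since a taxon with two ranks
is ambiguous.

Taxon names are normalised (underscores to spaces, whitespace collapsed,
provisional-genus brackets like `[Ruminococcus]` removed; case and strain
designators preserved) and can be resolved to NCBI taxonomy IDs through a
persistent JSON cache. Entrez is queried only with `--online`, throttled to
3 requests/second and retried with backoff; a failing lookup marks the name
unresolved and never aborts a run. Unresolved names are kept verbatim and
matched by exact normalised-name equality — silently dropping them would
bias the background distribution. Matching is exact by identifier: a
genus-level input does not match species-level set members; cross-rank
behaviour is deliberately undefined. A packaged starter cache of ~40
well-known gut taxa lets examples and tests run fully offline.

Taxon-set databases are read and written as GMT (one set per line:
name, description, members) or as a JSON list of
`{set_id, display_name, category, members[], source?}` objects. Member
lists are deduplicated within each set on read (logged); merging duplicate
sets *across* sources is left to the user, since there is no universally
right answer for reconciling conflicting set definitions.

## The synthetic data generators

Two generators make the package self-contained:

* `generate_fixture_db(n_small, n_medium, n_large, universe_size, seed)`
  draws taxon sets with sizes uniform on [2, 9], [10, 50] and
  [51, min(150, universe_size)] — the small/medium/large size classes — with
  members sampled from a shared pseudo-taxid universe. Sets overlap freely,
  as real metabolite-producer sets do (one species produces many
  metabolites).
* `generate_null_background(config)` draws i.i.d. per-taxon log2 fold
  changes, normal(0, 0.5) by default, emulating what a DA tool reports when
  comparing two random groups of healthy individuals: values centred at
  zero with |log2FC| > 1 uncommon. A Student-t option (df 3, scale 0.5)
  provides heavier tails. Identifiers come from the same pseudo-taxid
  universe so backgrounds and fixture sets intersect by construction.

What the synthetic backgrounds do **not** emulate: the correlation
structure of real communities (co-occurring, cross-feeding taxa violate the
i.i.d. assumption), compositional coupling between taxa, heteroscedastic
per-taxon uncertainty, and DA-tool-specific shrinkage. Tests passing on
synthetic data therefore demonstrate the engine's *statistical
correctness and sensitivity profile*, not its false-discovery behaviour on
any particular real cohort; absolute TPRs at weak effects in particular are
generator-dependent.

## The signal-implantation benchmark

Sensitivity is measured by implanting known signals into certified-null
backgrounds:

1. Draw a background; run the full enrichment on it and *screen* it —
   accept only if no set reaches FDR < 0.05 (redrawing up to a retry
   bound), so every replicate starts enrichment-free.
2. Pick, uniformly at random, one target set whose detected-member count
   falls in the requested size class (small < 10, medium 10–50,
   large > 50).
3. Replace the target members' values with i.i.d. draws from
   Uniform(log2 E / 2, 3 log2 E / 2). The uniform's median is exactly
   log2 E, so "a 2.5× implant" means a median 2.5-fold change; the support
   stays positive for E > 1. Direction `decrease` negates the draws; a
   `shift` mode (add the draw instead of replacing) exists for sensitivity
   analysis, and in that mode E = 1 is an exact no-op, giving the
   false-positive calibration point. The bounds rule is configurable.
4. Re-run the enrichment and score a detection when the target set's FDR
   falls below 0.05 (the same α used for screening; both configurable).

TPR per (size class, effect size) cell is the detection fraction. Each cell
owns an independent, deterministic random stream derived from the master
seed (`SeedSequence(seed, spawn_key=(class, effect))`), so results are
fully reproducible and adding cells never perturbs existing ones.

Default problem sizes — backgrounds of 300 taxa, a 50-set database
(15/20/15 small/medium/large), 200 replicates per cell in the shipped
acceptance checks — were chosen as the smallest configuration at which a
TPR is estimated with a binomial standard error below ~1.5 percentage
points and cell-to-cell comparisons across effect sizes are stable; the
benchmark driver accepts any replicate count.

The qualitative sensitivity profile this produces: TPR rises with effect
size in every class; medium sets (10–50 members) are the sweet spot,
detected > 97 % of the time at a 2.5-fold median effect; very small sets
carry little information per set, and very large sets dilute their own
signal — as a set approaches the size of the background, the complement it
is compared against shrinks and shifts with it, making the two
distributions harder to separate.

## Numerical and degenerate-case choices

* Even-count medians are the mean of the two central values.
* A set whose detected members cover the *entire* input has an empty
  complement; the comparison is degenerate and the set is skipped with a
  warning.
* An input in which no set passes the detectability filter yields an empty
  result table (with a warning), not an error — an honest "nothing
  testable" outcome.
* Result ties in FDR and p are broken by set id, so output ordering is
  total and deterministic; the TSV writers use fixed `%.10g` float
  formatting, making repeated runs byte-identical.
* All randomness flows through explicit seeds (`random.Random` for the
  fixture generator, `numpy` `Generator`/`SeedSequence` elsewhere); nothing
  reads global RNG state.

## Known limitations

* The i.i.d. null ignores taxon co-occurrence; on real data the effective
  number of independent taxa is smaller than the taxon count, and type-I
  behaviour can be less clean than the synthetic calibration suggests.
* Exact KS p-values are unavailable under cross-sample ties; heavy tying
  (e.g. many identical fold changes from a zero-inflated tool) pushes all
  sets onto the asymptotic approximation, which is conservative at small m.
* No weighted (GSEA-style running-sum) scores, per-sample enrichment
  scores, or over-representation tests; this package is deliberately the
  rank-distribution test only.
* Cross-rank identifier matching (genus input vs species members) is not
  attempted.
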