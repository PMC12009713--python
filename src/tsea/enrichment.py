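"""Rank-based taxon set enrichment: the core statistical engine.

The input is a ranked taxon list — one value per taxon, typically a log2
fold change from a differential-abundance (DA) comparison or a correlation
coefficient. For every taxon set with enough detected members the two-sample
Kolmogorov–Smirnov (KS) test asks whether the set members' values are
distributed differently from the values of all the *other* input taxa;
p-values are then Benjamini–Hochberg adjusted across the tested sets.

Because the KS statistic depends only on how the two samples interleave,
the whole analysis is invariant under any strictly increasing transform of
the input values. This is what makes the approach robust to the choice of
upstream DA tool: different tools rescale effect sizes but largely preserve
the ranking, and the ranking is all that matters here.

The testing side is members versus non-members (not members versus the full
input): using all taxa as the reference would put every member in both
samples and invalidate the two-sample null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sets import TaxonSetDatabase, filter_detectable

logger = logging.getLogger(__name__)

#: Exact KS p-values are computed when m*n is at or below this bound (and the
#: samples share no tied values); the asymptotic Kolmogorov distribution is
#: used otherwise.
EXACT_KS_LIMIT = 10_000


class RankedTaxa:
    """A ranked taxon list: unique identifiers mapped to finite values.

    Values are dimensionless reals — log2 fold changes, effect sizes or
    correlation coefficients — and only their ordering matters to the
    enrichment test. At least two entries are required.
    """

    __slots__ = ("_ids", "_values", "_index")

    def __init__(self, entries: Mapping[str, float] | Iterable[tuple[str, float]]) -> None:
        items = list(entries.items()) if isinstance(entries, Mapping) else list(entries)
        ids = [str(k) for k, _ in items]
        values = np.asarray([v for _, v in items], dtype=float)
        if len(ids) < 2:
            raise ValueError("ranked input needs at least 2 taxa")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate taxon identifiers: {dupes[:5]}")
        if not np.all(np.isfinite(values)):
            bad = [ids[i] for i in np.flatnonzero(~np.isfinite(values))[:5]]
            raise ValueError(f"non-finite rank values for: {bad}")
        self._ids: tuple[str, ...] = tuple(ids)
        self._values: np.ndarray = values
        self._values.flags.writeable = False
        self._index: dict[str, int] = {t: i for i, t in enumerate(ids)}

    @classmethod
    def from_series(cls, series: pd.Series) -> "RankedTaxa":
        return cls(zip(series.index.astype(str), series.to_numpy(dtype=float)))

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def values(self) -> np.ndarray:
        return self._values

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def __getitem__(self, taxon: str) -> float:
        return float(self._values[self._index[taxon]])

    def __iter__(self) -> Iterator[str]:
        return iter(self._ids)

    def items(self) -> Iterator[tuple[str, float]]:
        return ((t, float(v)) for t, v in zip(self._ids, self._values))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedTaxa):
            return NotImplemented
        return self._ids == other._ids and np.array_equal(self._values, other._values)

    def subset_values(self, taxa: Sequence[str]) -> np.ndarray:
        """Values for the given taxa, in the given order."""
        return self._values[[self._index[t] for t in taxa]]

    def to_series(self) -> pd.Series:
        return pd.Series(self._values, index=pd.Index(self._ids, name="taxon"), name="rank")

    @property
    def median(self) -> float:
        return float(np.median(self._values))


@dataclass(frozen=True)
class KsOutcome:
    """Two-sample KS comparison: statistic, p-value and how p was obtained."""

    statistic: float
    p_value: float
    exact: bool      # exact permutation-distribution p (vs asymptotic)
    tied: bool       # values shared across the two samples (exact p invalid)


def ks_two_sample(
    member_values: Sequence[float], nonmember_values: Sequence[float]
) -> KsOutcome:
    """Two-sided two-sample KS test of set members against non-members.

    The statistic is ``D = sup_x |ECDF_members(x) - ECDF_nonmembers(x)|``.
    The p-value comes from the exact permutation distribution when
    ``m * n <= 10000`` and the samples share no tied values; otherwise the
    asymptotic Kolmogorov distribution is used. Ties across samples force
    the asymptotic path and are flagged, since the exact null assumes all
    interleavings are distinguishable.
    """
    x = np.asarray(member_values, dtype=float)
    y = np.asarray(nonmember_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("degenerate comparison: both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("rank values must be finite")
    tied = bool(np.intersect1d(x, y).size)
    exact = (x.size * y.size <= EXACT_KS_LIMIT) and not tied
    res = stats.ks_2samp(x, y, alternative="two-sided",
                         method="exact" if exact else "asymp")
    # The asymptotic tail can underflow to 0 for extreme separations; the
    # true p is always positive, so clamp to the smallest normal float.
    p = min(max(float(res.pvalue), np.finfo(float).tiny), 1.0)
    return KsOutcome(
        statistic=float(res.statistic),
        p_value=p,
        exact=exact,
        tied=tied,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, returned in input order.

    Sorted ascending, ``adjusted_(i) = min_{j >= i} m * p_(j) / j`` capped at
    1. Inputs must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested taxon set: detection, effect summary and significance."""

    set_id: str
    category: str
    n_detected: int
    detected_members: tuple[str, ...]
    median_rank: float
    ks_statistic: float
    p_value: float
    fdr: float
    tie_flag: bool


class TaxonSetEnrichment:
    """Enrichment model: a ranked taxon list against a taxon-set database.

    Parameters
    ----------
    ranked
        The ranked taxon list (taxon -> value), e.g. DA log2 fold changes.
    database
        Taxon sets to test.
    min_size
        Minimum number of set members that must be detected among the input
        taxa for the set to be tested (default 5).

    Examples
    --------
    >>> from tsea import RankedTaxa, TaxonSetEnrichment, generate_fixture_db
    >>> db = generate_fixture_db(2, 2, 0, universe_size=100, seed=1)
    >>> ranked = RankedTaxa({t: 0.1 * i for i, t in enumerate(db.universe)})
    >>> results = TaxonSetEnrichment(ranked, db).fit()
    >>> results.frame.columns[:3].tolist()
    ['set_id', 'category', 'n_detected']
    """

    def __init__(
        self,
        ranked: RankedTaxa,
        database: TaxonSetDatabase,
        min_size: int = 5,
    ) -> None:
        if not isinstance(ranked, RankedTaxa):
            ranked = RankedTaxa(ranked)
        self.ranked = ranked
        self.database = database
        self.min_size = int(min_size)
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        database: TaxonSetDatabase,
        taxon_col: str = "taxon",
        rank_col: str = "log2FoldChange",
        min_size: int = 5,
    ) -> "TaxonSetEnrichment":
        """Build the model from a DA-style results table."""
        from .da_io import ranked_from_frame  # local import avoids a cycle

        return cls(ranked_from_frame(frame, taxon_col, rank_col), database, min_size)

    def fit(self) -> "EnrichmentResults":
        """Run the filter, per-set KS tests and BH adjustment.

        Sets whose detected members span the whole input (leaving the
        non-member side empty) cannot be tested and are skipped with a
        warning. An empty result — nothing survives the detectability
        filter — is legal and returned with a warning, not an error.
        """
        tested_db = filter_detectable(self.database, self.ranked, self.min_size)
        if len(tested_db) == 0:
            logger.warning(
                "no taxon set has >= %d members detected among the %d input "
                "taxa; returning an empty result",
                self.min_size, len(self.ranked),
            )
        all_ids = self.ranked.ids
        rows: list[dict] = []
        for s in tested_db:
            detected = tested_db.detected_members[s.set_id]
            member_set = set(detected)
            nonmembers = [t for t in all_ids if t not in member_set]
            if not nonmembers:
                logger.warning(
                    "set %r contains every input taxon; skipping the "
                    "degenerate comparison", s.set_id,
                )
                continue
            member_values = self.ranked.subset_values(detected)
            nonmember_values = self.ranked.subset_values(nonmembers)
            ks = ks_two_sample(member_values, nonmember_values)
            rows.append(
                dict(
                    set_id=s.set_id,
                    category=s.category,
                    n_detected=len(detected),
                    detected_members=detected,
                    median_rank=float(np.median(member_values)),
                    ks_statistic=ks.statistic,
                    p_value=ks.p_value,
                    tie_flag=ks.tied,
                )
            )
        if rows:
            fdrs = bh_adjust([r["p_value"] for r in rows])
            for r, q in zip(rows, fdrs):
                r["fdr"] = float(q)
            rows.sort(key=lambda r: (r["fdr"], r["p_value"], r["set_id"]))
        results = [
            EnrichmentRow(
                set_id=r["set_id"], category=r["category"],
                n_detected=r["n_detected"], detected_members=r["detected_members"],
                median_rank=r["median_rank"], ks_statistic=r["ks_statistic"],
                p_value=r["p_value"], fdr=r["fdr"], tie_flag=r["tie_flag"],
            )
            for r in rows
        ]
        return EnrichmentResults(self, results)


#: Column order of the tabular output.
RESULT_COLUMNS = (
    "set_id", "category", "n_detected", "median_rank", "ks_statistic",
    "p_value", "fdr", "detected_members", "tie_flag",
)


class EnrichmentResults:
    """Fitted enrichment results, ordered by FDR then p-value then set id.

    ``median_rank`` is the median of the detected members' input values
    (mean of the two central values for even counts); compared against the
    background median it gives the direction of change — a set whose
    median sits below the background median is depleted, above it enriched.
    """

    def __init__(self, model: TaxonSetEnrichment, rows: list[EnrichmentRow]) -> None:
        self.model = model
        self.rows = rows
        #: Median of all input rank values; reference point for direction.
        self.background_median = model.ranked.median

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[EnrichmentRow]:
        return iter(self.rows)

    def __getitem__(self, set_id: str) -> EnrichmentRow:
        for r in self.rows:
            if r.set_id == set_id:
                return r
        raise KeyError(set_id)

    def __contains__(self, set_id: str) -> bool:
        return any(r.set_id == set_id for r in self.rows)

    @property
    def frame(self) -> pd.DataFrame:
        """Results as a DataFrame (members comma-joined)."""
        data = [
            {
                "set_id": r.set_id,
                "category": r.category,
                "n_detected": r.n_detected,
                "median_rank": r.median_rank,
                "ks_statistic": r.ks_statistic,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "detected_members": ",".join(r.detected_members),
                "tie_flag": r.tie_flag,
            }
            for r in self.rows
        ]
        return pd.DataFrame(data, columns=list(RESULT_COLUMNS))

    def significant(self, alpha: float = 0.05) -> list[EnrichmentRow]:
        """Rows with FDR below ``alpha``."""
        return [r for r in self.rows if r.fdr < alpha]

    def to_tsv(self, path) -> None:
        """Write the results table as TSV with deterministic formatting."""
        write_results_tsv(self, path)

    def summary(self, alpha: float = 0.05, max_rows: int = 20) -> str:
        """Human-readable summary table."""
        lines = [
            "Taxon set enrichment (two-sample KS, BH-adjusted)",
            f"  input taxa: {len(self.model.ranked)}   "
            f"sets tested: {len(self.rows)} of {len(self.model.database)} "
            f"(min detected = {self.model.min_size})",
            f"  background median rank: {self.background_median:.4g}",
            f"  significant at FDR < {alpha:g}: {len(self.significant(alpha))}",
            "",
            f"  {'set_id':<22}{'n':>4}{'median':>10}{'D':>8}{'p':>12}{'FDR':>12}  dir",
        ]
        for r in self.rows[:max_rows]:
            direction = "up" if r.median_rank > self.background_median else "down"
            lines.append(
                f"  {r.set_id:<22}{r.n_detected:>4}{r.median_rank:>10.3g}"
                f"{r.ks_statistic:>8.3f}{r.p_value:>12.3g}{r.fdr:>12.3g}  {direction}"
            )
        if len(self.rows) > max_rows:
            lines.append(f"  ... {len(self.rows) - max_rows} more rows")
        return "\n".join(lines)


def _fmt(x: float) -> str:
    return format(x, ".10g")


def write_results_tsv(results: EnrichmentResults, path) -> None:
    """Serialise results with a fixed header and stable float formatting."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results.rows:
            fh.write(
                "\t".join(
                    [
                        r.set_id,
                        r.category,
                        str(r.n_detected),
                        _fmt(r.median_rank),
                        _fmt(r.ks_statistic),
                        _fmt(r.p_value),
                        _fmt(r.fdr),
                        ",".join(r.detected_members),
                        str(r.tie_flag),
                    ]
                )
                + "\n"
            )


def run_enrichment(
    ranked: RankedTaxa, database: TaxonSetDatabase, min_size: int = 5
) -> EnrichmentResults:
    """One-call enrichment: filter, test each set, BH-adjust, sort."""
    return TaxonSetEnrichment(ranked, database, min_size).fit()
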