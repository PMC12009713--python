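"""Taxon name normalisation and NCBI taxonomy ID resolution.

DA tools emit taxon names in several near-equivalent spellings
(``Faecalibacterium_prausnitzii``, ``[Ruminococcus] torques``, doubled
whitespace from spreadsheet round-trips). This module canonicalises those
spellings and resolves names to NCBI taxonomy IDs, preferring a persistent
JSON cache so the whole pipeline runs offline; the Entrez taxonomy API is
queried only on explicit request.

Matching downstream is by exact identifier: unresolved names pass through
verbatim so enrichment can still match them against name-keyed set members,
and a genus-level input never silently matches species-level members —
cross-rank behaviour is deliberately undefined.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Mapping

logger = logging.getLogger(__name__)

#: Sentinel stored in the cache for names Entrez could not resolve.
UNRESOLVED = "UNRESOLVED"

_BRACKETED = re.compile(r"\[([^\[\]]+)\]")
_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Canonicalise a taxon name.

    Underscores become single spaces, repeated whitespace collapses,
    surrounding whitespace is stripped, and square brackets around a
    provisionally-placed genus (``[Ruminococcus] torques``) are removed.
    Case and strain designators are preserved. Idempotent.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("taxon name is empty")
    name = str(raw).replace("_", " ")
    name = _BRACKETED.sub(r"\1", name)
    name = _WS.sub(" ", name).strip()
    if not name:
        raise ValueError(f"taxon name {raw!r} is empty after normalisation")
    return name


@dataclass
class TaxidCache:
    """Persistent name -> taxid cache, keyed by normalised names.

    Serialised as human-auditable JSON: one object per name with the taxid
    (a positive decimal string, or the ``UNRESOLVED`` sentinel) and an
    ISO-8601 retrieval timestamp.
    """

    entries: dict[str, dict[str, str]] = field(default_factory=dict)

    def get(self, name: str) -> str | None:
        """Cached taxid for a normalised name; None on a miss.

        The ``UNRESOLVED`` sentinel is returned as such — a recorded miss
        is distinct from a never-queried name.
        """
        rec = self.entries.get(name)
        return rec["taxid"] if rec else None

    def put(self, name: str, taxid: str) -> None:
        if taxid != UNRESOLVED and (not taxid.isdigit() or int(taxid) <= 0):
            raise ValueError(f"taxid must be a positive decimal string, got {taxid!r}")
        self.entries[name] = {
            "taxid": taxid,
            "retrieved_at": datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    @classmethod
    def load(cls, path: str | Path) -> "TaxidCache":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        entries: dict[str, dict[str, str]] = {}
        for name, rec in raw.items():
            if not isinstance(rec, dict) or "taxid" not in rec:
                raise ValueError(f"{path}: malformed cache entry for {name!r}")
            entries[name] = {
                "taxid": str(rec["taxid"]),
                "retrieved_at": str(rec.get("retrieved_at", "")),
            }
        return cls(entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.entries, fh, indent=1, ensure_ascii=False, sort_keys=True)
            fh.write("\n")


def load_starter_cache() -> TaxidCache:
    """The packaged starter cache of well-known gut taxa.

    A small snapshot of name -> NCBI taxid mappings for common gut
    commensals and pathogens, shipped so examples and tests resolve names
    without network access.
    """
    path = Path(__file__).parent / "data" / "starter_cache.json"
    return TaxidCache.load(path)


def _entrez_lookup(name: str) -> str:
    """Single Entrez taxonomy name-search; returns a taxid or UNRESOLVED."""
    from Bio import Entrez

    if not Entrez.email:  # Entrez requires a contact address
        Entrez.email = "tsea@example.org"
    handle = Entrez.esearch(db="taxonomy", term=name)
    record = Entrez.read(handle)
    handle.close()
    ids = record.get("IdList", [])
    return str(ids[0]) if ids else UNRESOLVED


def names_to_taxids(
    names: Iterable[str],
    cache: TaxidCache,
    online: bool = False,
    *,
    max_retries: int = 3,
    _lookup: Callable[[str], str] | None = None,
    _sleep: Callable[[float], None] = time.sleep,
) -> tuple[dict[str, str], list[str]]:
    """Resolve taxon names to NCBI taxids, cache first.

    Parameters
    ----------
    names
        Raw taxon names; duplicates are resolved once.
    cache
        Consulted before any query; with ``online`` true, successful and
        definitively-empty Entrez answers are written back.
    online
        When false no network access occurs and cache misses are simply
        reported unresolved.

    Returns
    -------
    (mapping, unresolved)
        ``mapping`` maps each resolved *normalised* name to its taxid;
        ``unresolved`` lists normalised names without a taxid, which
        callers keep verbatim so downstream matching can fall back to
        name equality.

    Notes
    -----
    Online queries are throttled to at most 3 requests/second (the NCBI
    limit without an API key) and retried with exponential backoff; a name
    that still fails is marked unresolved with a warning — a network
    problem never aborts the run.
    """
    lookup = _lookup or _entrez_lookup
    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    seen: set[str] = set()
    for raw in names:
        name = normalize_name(raw)
        if name in seen:
            continue
        seen.add(name)
        cached = cache.get(name)
        if cached is not None:
            if cached == UNRESOLVED:
                unresolved.append(name)
            else:
                mapping[name] = cached
            continue
        if not online:
            unresolved.append(name)
            continue
        taxid: str | None = None
        for attempt in range(max_retries):
            try:
                taxid = lookup(name)
                break
            except Exception as exc:  # noqa: BLE001 - any transport failure
                wait = 2.0 ** attempt
                logger.warning("Entrez lookup failed for %r (attempt %d/%d): %s",
                               name, attempt + 1, max_retries, exc)
                _sleep(wait)
        if taxid is None:
            logger.warning("giving up on %r after %d attempts; marked unresolved",
                           name, max_retries)
            unresolved.append(name)  # transient failure: do not cache
        else:
            cache.put(name, taxid)
            if taxid == UNRESOLVED:
                unresolved.append(name)
            else:
                mapping[name] = taxid
        _sleep(1.0 / 3.0)  # rate limit
    return mapping, unresolved


def translate_ranked(ranked, mapping: Mapping[str, str]):
    """Re-key a ranked taxon list by taxid where a mapping entry exists.

    Unmapped names stay verbatim. If two input names map to the same taxid
    the input is ambiguous and an error is raised.
    """
    from .enrichment import RankedTaxa

    pairs = []
    for name, value in ranked.items():
        pairs.append((mapping.get(name, name), value))
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(
            f"multiple input taxa map to the same identifier: {dupes[:5]}"
        )
    return RankedTaxa(pairs)
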