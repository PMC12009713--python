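"""Taxon-set databases: the reference objects enrichment is tested against.

A *taxon set* is a named group of microbial taxa sharing a property — a
disease signature, the producers of a metabolite, a previously published
microbiota association.  Collections of such sets play the role that
pathway/gene-set databases play in transcriptomics.  This module defines the
in-memory types, readers/writers for the two interchange formats (GMT and a
JSON schema), the detectability filter applied before testing, and a
deterministic synthetic-database generator used throughout the test and
benchmark machinery.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .enrichment import RankedTaxa

logger = logging.getLogger(__name__)

#: Recognised set categories. ``health_disease`` covers signatures of health
#: and disease states, ``metabolite_producers`` covers producers of a given
#: metabolite (butyrate, propionate, indole-3-propionic acid, ...),
#: ``published_associations`` covers previously reported microbiota
#: associations, and ``custom`` is everything user-supplied.
CATEGORIES = ("health_disease", "metabolite_producers", "published_associations", "custom")


@dataclass(frozen=True)
class TaxonSet:
    """A named, non-redundant set of taxon identifiers.

    Members are canonical NCBI taxonomy IDs rendered as decimal strings
    (e.g. ``"853"`` for *Faecalibacterium prausnitzii*) or verbatim taxon
    names when no ID mapping is available. Member order is preserved for
    reproducible serialisation but equality is order-insensitive.
    """

    set_id: str
    display_name: str
    category: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("set_id must be a non-empty string")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if not self.members:
            raise ValueError(f"taxon set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"taxon set {self.set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonSet):
            return NotImplemented
        return (
            self.set_id == other.set_id
            and self.display_name == other.display_name
            and self.category == other.category
            and frozenset(self.members) == frozenset(other.members)
        )

    def __hash__(self) -> int:
        return hash((self.set_id, frozenset(self.members)))


class TaxonSetDatabase:
    """An ordered collection of :class:`TaxonSet` with unique ``set_id``s.

    ``source_metadata`` carries free-form provenance strings per set (which
    upstream resource a set came from, retrieval dates, ...); it is round-
    tripped by the JSON format and ignored by GMT.
    """

    def __init__(
        self,
        sets: Iterable[TaxonSet],
        source_metadata: Mapping[str, str] | None = None,
    ) -> None:
        self.sets: list[TaxonSet] = list(sets)
        seen: set[str] = set()
        for s in self.sets:
            if s.set_id in seen:
                raise ValueError(f"duplicate set_id {s.set_id!r} in database")
            seen.add(s.set_id)
        self.source_metadata: dict[str, str] = dict(source_metadata or {})
        #: set_id -> tuple of members detected in the ranked input; populated
        #: by :func:`filter_detectable`, empty on a freshly built database.
        self.detected_members: dict[str, tuple[str, ...]] = {}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[TaxonSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> TaxonSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    def __contains__(self, set_id: str) -> bool:
        return any(s.set_id == set_id for s in self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonSetDatabase):
            return NotImplemented
        return self.sets == other.sets and self.source_metadata == other.source_metadata

    def __repr__(self) -> str:
        return f"TaxonSetDatabase({len(self.sets)} sets)"

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member identifiers across sets."""
        return frozenset(m for s in self.sets for m in s.members)


# ---------------------------------------------------------------------------
# Readers / writers


def _dedup(members: Sequence[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for m in members:
        if m not in seen:
            seen.add(m)
            out.append(m)
    return tuple(out)


def _read_gmt(path: Path) -> TaxonSetDatabase:
    sets: list[TaxonSet] = []
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields (name, description, members...), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            unique = _dedup(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s: line %d: set %r has %d duplicate member(s); deduplicated",
                    path, lineno, name, len(members) - len(unique),
                )
            try:
                sets.append(
                    TaxonSet(set_id=name, display_name=description or name,
                             category="custom", members=unique)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if description:
                meta[name] = description
    if not sets:
        raise ValueError(f"{path}: no sets found")
    return TaxonSetDatabase(sets, meta)


def _read_json(path: Path) -> TaxonSetDatabase:
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, list):
        raise ValueError(f"{path}: expected a top-level JSON list of set objects")
    if not payload:
        raise ValueError(f"{path}: no sets found")
    sets: list[TaxonSet] = []
    meta: dict[str, str] = {}
    for i, rec in enumerate(payload):
        where = f"{path}: record {i + 1}"
        if not isinstance(rec, dict) or "set_id" not in rec or "members" not in rec:
            raise ValueError(f"{where}: each record needs 'set_id' and 'members'")
        members = rec["members"]
        if not isinstance(members, list) or not all(isinstance(m, str) for m in members):
            raise ValueError(f"{where}: 'members' must be a list of strings")
        unique = _dedup(members)
        if len(unique) < len(members):
            logger.warning("%s: set %r had duplicate members; deduplicated",
                           where, rec["set_id"])
        try:
            sets.append(
                TaxonSet(
                    set_id=str(rec["set_id"]),
                    display_name=str(rec.get("display_name", rec["set_id"])),
                    category=str(rec.get("category", "custom")),
                    members=unique,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
        if "source" in rec:
            meta[str(rec["set_id"])] = str(rec["source"])
    return TaxonSetDatabase(sets, meta)


def read_taxon_sets(path: str | Path, format: str = "auto") -> TaxonSetDatabase:
    """Read a taxon-set database from a GMT or JSON file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"gmt"``, ``"json"``, or ``"auto"`` (decide from the file suffix,
        falling back to content sniffing).

    Returns
    -------
    TaxonSetDatabase
        Validated database. Duplicate members within a set are silently
        deduplicated with a logged warning; GMT sets default to the
        ``custom`` category since the format carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"taxon set file not found: {path}")
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix == ".gmt":
            format = "gmt"
        elif suffix == ".json":
            format = "json"
        else:
            head = path.read_text(encoding="utf-8", errors="replace").lstrip()[:1]
            format = "json" if head == "[" else "gmt"
    if format == "gmt":
        return _read_gmt(path)
    if format == "json":
        return _read_json(path)
    raise ValueError(f"unknown format {format!r}; expected 'gmt', 'json' or 'auto'")


def write_taxon_sets(db: TaxonSetDatabase, path: str | Path, format: str = "auto") -> None:
    """Write a database to GMT or JSON (UTF-8, deterministic byte output)."""
    path = Path(path)
    if format == "auto":
        format = "json" if path.suffix.lower() == ".json" else "gmt"
    if format == "gmt":
        with open(path, "w", encoding="utf-8") as fh:
            for s in db.sets:
                fh.write("\t".join([s.set_id, s.display_name, *s.members]) + "\n")
    elif format == "json":
        records = []
        for s in db.sets:
            rec: dict[str, object] = {
                "set_id": s.set_id,
                "display_name": s.display_name,
                "category": s.category,
                "members": list(s.members),
            }
            if s.set_id in db.source_metadata:
                rec["source"] = db.source_metadata[s.set_id]
            records.append(rec)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1, ensure_ascii=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Detectability filter


def filter_detectable(
    db: TaxonSetDatabase, ranked: "RankedTaxa", min_size: int = 5
) -> TaxonSetDatabase:
    """Keep only sets with at least ``min_size`` members detected in the input.

    A member is *detected* when its identifier appears among the ranked
    input taxa. The returned database carries the per-set intersection in
    ``detected_members``; an empty result is legal. Default ``min_size`` is
    5, matching the common practice of not testing nearly-empty sets.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    present = set(ranked.ids)
    surviving: list[TaxonSet] = []
    detected: dict[str, tuple[str, ...]] = {}
    for s in db.sets:
        hits = tuple(m for m in s.members if m in present)
        if len(hits) >= min_size:
            surviving.append(s)
            detected[s.set_id] = hits
    out = TaxonSetDatabase(
        surviving, {k: v for k, v in db.source_metadata.items() if k in detected}
    )
    out.detected_members = detected
    return out


# ---------------------------------------------------------------------------
# Synthetic database generator

#: (low, high) inclusive member-count bounds for the three size classes.
SIZE_CLASS_BOUNDS: dict[str, tuple[int, int]] = {
    "small": (2, 9),
    "medium": (10, 50),
    "large": (51, 150),
}


def fixture_universe(universe_size: int, start: int = 100001) -> tuple[str, ...]:
    """Deterministic universe of synthetic pseudo-taxids (decimal strings).

    The identifiers are shaped like NCBI taxids but deliberately start high
    so they cannot be mistaken for curated real IDs.
    """
    return tuple(str(start + i) for i in range(universe_size))


def generate_fixture_db(
    n_small: int,
    n_medium: int,
    n_large: int,
    universe_size: int,
    seed: int,
) -> TaxonSetDatabase:
    """Synthesize a taxon-set database spanning the three size classes.

    Set sizes are drawn uniformly from [2, 9] (small), [10, 50] (medium) and
    [51, min(150, universe_size)] (large); members are sampled without
    replacement from a shared pseudo-taxid universe, so sets overlap freely —
    mirroring real databases where one species belongs to many metabolite-
    producer sets. Deterministic given ``seed``.
    """
    if min(n_small, n_medium, n_large) < 0:
        raise ValueError("set counts must be non-negative")
    rng = random.Random(seed)
    universe = list(fixture_universe(universe_size))
    requested = [
        ("small", n_small, SIZE_CLASS_BOUNDS["small"]),
        ("medium", n_medium, SIZE_CLASS_BOUNDS["medium"]),
        ("large", n_large, (SIZE_CLASS_BOUNDS["large"][0],
                            min(SIZE_CLASS_BOUNDS["large"][1], universe_size))),
    ]
    for cls, count, (lo, hi) in requested:
        if count > 0 and universe_size < lo:
            raise ValueError(
                f"cannot draw a {cls} set (>= {lo} members) from a universe of "
                f"{universe_size} taxa"
            )
    categories = ("metabolite_producers", "health_disease", "published_associations")
    sets: list[TaxonSet] = []
    meta: dict[str, str] = {}
    for cls, count, (lo, hi) in requested:
        for i in range(count):
            size = rng.randint(lo, hi)
            members = tuple(rng.sample(universe, size))
            set_id = f"{cls}_{i + 1:03d}"
            sets.append(
                TaxonSet(
                    set_id=set_id,
                    display_name=f"synthetic {cls} set {i + 1}",
                    category=categories[i % len(categories)],
                    members=members,
                )
            )
            meta[set_id] = "synthetic fixture"
    return TaxonSetDatabase(sets, meta)
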