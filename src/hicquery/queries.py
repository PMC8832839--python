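"""The seven positional query modes over a binned contact map.

Each BED line (or BEDPE line for ``pair``) is one query.  Modes:

``bait``
    Virtual-4C style viewpoint: average contact between the bait bin and a
    window of ``near_bin`` bins on either side (window clipped at the
    chromosome ends; the bait's own diagonal contact is included).
``local``
    Every bin-pair contact (including zeros and the diagonal) inside one
    interval.
``loop``
    Contact between the two terminal bins of an interval — the bin holding
    ``start`` and the bin holding ``end - 1``.
``pair``
    Mean (and sum) of contacts between all bin pairs of two regions, which
    may sit on different chromosomes.
``sites``
    All pairwise contacts among a set of point loci, including each locus's
    diagonal.
``submap``
    The map restricted to pairs with both bins inside the union of the
    query regions.
``TAD``
    Sum and average of all intra-interval contacts, diagonal included —
    the intra-domain contact density of a topologically associating domain.

Point-like anchors (bait, loop ends, sites) resolve to the bin containing
the interval midpoint ``floor((start + end) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

from .errors import ParseError, QueryError
from .io import ContactMap, write_bins_text, write_contacts_text

__all__ = [
    "QueryRecord",
    "PairQueryRecord",
    "ScalarResult",
    "RecordListResult",
    "read_bed",
    "read_bedpe",
    "read_classified_bed",
    "query_bait",
    "query_local",
    "query_loop",
    "query_pair",
    "query_sites",
    "query_submap",
    "query_tad",
    "SCALAR_MODES",
    "MODES",
]

MODES = ("bait", "local", "loop", "pair", "sites", "submap", "TAD")
#: modes whose result is a single frequency, hence permutable
SCALAR_MODES = ("bait", "loop", "pair", "TAD")


@dataclass(frozen=True)
class QueryRecord:
    """One BED interval interpreted under a query mode."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise QueryError(
                f"query {self.name or '<unnamed>'}: start >= end "
                f"({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PairQueryRecord:
    """A pair of regions (BEDPE line); regions may be inter-chromosomal."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    name: str = ""

    def __post_init__(self) -> None:
        for c, s, e in ((self.chrom1, self.start1, self.end1),
                        (self.chrom2, self.start2, self.end2)):
            if s >= e:
                raise QueryError(
                    f"query {self.name or '<unnamed>'}: start >= end ({c}:{s}-{e})"
                )

    def regions(self) -> tuple[QueryRecord, QueryRecord]:
        return (
            QueryRecord(self.chrom1, self.start1, self.end1, self.name),
            QueryRecord(self.chrom2, self.start2, self.end2, self.name),
        )


@dataclass(frozen=True)
class ScalarResult:
    """Per-query scalar summary.

    ``frequency`` is the mode's headline number (mean for bait/pair/TAD,
    the single looked-up contact for loop); ``total`` carries the sum where
    the mode defines one (pair, TAD); ``n_pairs`` counts the bin pairs
    aggregated.
    """

    name: str
    frequency: float
    n_pairs: int
    total: float | None = None
    query: QueryRecord | PairQueryRecord | None = None


@dataclass(frozen=True)
class RecordListResult:
    """Row-list result: ``(bin_i, bin_j, contact)`` with i <= j, sorted."""

    name: str
    rows: tuple[tuple[int, int, float], ...]
    query: QueryRecord | None = None


# ---------------------------------------------------------------------------
# BED / BEDPE parsing
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[QueryRecord]:
    """Read BED3+ queries; column 4 names the query, ``query_<k>`` otherwise.

    Track lines, comments and strand columns are ignored (results are
    strand-free).
    """
    path = Path(path)
    records: list[QueryRecord] = []
    k = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: BED needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            k += 1
            name = fields[3] if len(fields) >= 4 and fields[3] else f"query_{k}"
            try:
                records.append(QueryRecord(fields[0], start, end, name))
            except QueryError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    if not records:
        raise ParseError(f"{path.name}: no query records found")
    return records


def read_bedpe(path: str | Path) -> list[PairQueryRecord]:
    """Read paired-region queries: ``chrom1 start1 end1 chrom2 start2 end2 [name]``."""
    path = Path(path)
    records: list[PairQueryRecord] = []
    k = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path.name}:{lineno}: paired query needs >= 6 fields, "
                    f"got {len(fields)}"
                )
            try:
                s1, e1 = int(fields[1]), int(fields[2])
                s2, e2 = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            k += 1
            name = fields[6] if len(fields) >= 7 and fields[6] else f"query_{k}"
            try:
                records.append(
                    PairQueryRecord(fields[0], s1, e1, fields[3], s2, e2, name)
                )
            except QueryError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    if not records:
        raise ParseError(f"{path.name}: no query records found")
    return records


def read_classified_bed(path: str | Path) -> list[tuple[QueryRecord, str]]:
    """Read a BED whose 4th column is a class label (e.g. epiTAD classes
    active / null / PcG / HP1), returning (record, label) pairs."""
    path = Path(path)
    out: list[tuple[QueryRecord, str]] = []
    k = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path.name}:{lineno}: classified BED needs >= 4 fields"
                )
            try:
                rec = QueryRecord(
                    fields[0], int(fields[1]), int(fields[2]), f"query_{k + 1}"
                )
            except (ValueError, QueryError) as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            k += 1
            out.append((rec, fields[3]))
    if not out:
        raise ParseError(f"{path.name}: no records found")
    return out


# ---------------------------------------------------------------------------
# query modes
# ---------------------------------------------------------------------------

def query_bait(cmap: ContactMap, q: QueryRecord, near_bin: int) -> ScalarResult:
    """Average contact between the bait bin and its +-``near_bin`` window."""
    if near_bin < 0:
        raise QueryError(f"query {q.name}: near_bin must be >= 0, got {near_bin}")
    bait = cmap.bins.bin_of_position(q.chrom, q.midpoint())
    window = cmap.bins.neighborhood(bait, q.chrom, near_bin)
    values = [cmap.lookup(bait, x) for x in window]
    return ScalarResult(
        name=q.name,
        frequency=sum(values) / len(values),
        n_pairs=len(values),
        query=q,
    )


def query_local(cmap: ContactMap, q: QueryRecord) -> RecordListResult:
    """Every intra-interval bin pair, zeros and diagonal included."""
    ids = cmap.bins.bins_of_interval(q.chrom, q.start, q.end)
    rows = tuple(
        (i, j, cmap.lookup(i, j)) for i, j in combinations_with_replacement(ids, 2)
    )
    return RecordListResult(name=q.name, rows=rows, query=q)


def query_loop(cmap: ContactMap, q: QueryRecord) -> ScalarResult:
    """Contact between the interval's two terminal bins (loop anchors)."""
    i = cmap.bins.bin_of_position(q.chrom, q.start)
    j = cmap.bins.bin_of_position(q.chrom, q.end - 1)
    return ScalarResult(
        name=q.name, frequency=cmap.lookup(i, j), n_pairs=1, query=q
    )


def query_pair(cmap: ContactMap, q: PairQueryRecord) -> ScalarResult:
    """Mean and sum of contacts across the two regions' bin cross-product."""
    bins1 = cmap.bins.bins_of_interval(q.chrom1, q.start1, q.end1)
    bins2 = cmap.bins.bins_of_interval(q.chrom2, q.start2, q.end2)
    total = 0.0
    for i in bins1:
        for j in bins2:
            total += cmap.lookup(i, j)
    n = len(bins1) * len(bins2)
    return ScalarResult(
        name=q.name, frequency=total / n, n_pairs=n, total=total, query=q
    )


def query_sites(cmap: ContactMap, qs: list[QueryRecord]) -> RecordListResult:
    """All pairwise contacts (incl. diagonals) among point loci.

    Sites landing in the same bin are deduplicated: n distinct bins yield
    n(n+1)/2 rows.
    """
    if not qs:
        raise QueryError("sites query needs at least one site")
    site_bins = sorted(
        {cmap.bins.bin_of_position(q.chrom, q.midpoint()) for q in qs}
    )
    rows = tuple(
        (i, j, cmap.lookup(i, j))
        for i, j in combinations_with_replacement(site_bins, 2)
    )
    name = qs[0].name if len(qs) == 1 else f"sites_{len(qs)}"
    return RecordListResult(name=name, rows=rows)


def query_submap(
    cmap: ContactMap,
    qs: list[QueryRecord],
    out_contacts: str | Path | None = None,
    out_bins: str | Path | None = None,
) -> ContactMap:
    """Restrict the map to pairs with BOTH bins inside the regions' union.

    The returned map shares the full bin table, so any query whose interval
    lies inside the selected regions gives the same answer on the submap as
    on the original map.  When output paths are given, the submap contacts
    (and the bin table) are written in the text dialects ``read_*`` consume.
    """
    if not qs:
        raise QueryError("submap query needs at least one region")
    keep: set[int] = set()
    for q in qs:
        keep.update(cmap.bins.bins_of_interval(q.chrom, q.start, q.end))
    if not keep:
        raise QueryError("submap regions overlap no bins")
    sub = ContactMap(
        bins=cmap.bins,
        entries={
            k: v for k, v in cmap.entries.items() if k[0] in keep and k[1] in keep
        },
    )
    if out_contacts is not None:
        write_contacts_text(sub, out_contacts)
    if out_bins is not None:
        write_bins_text(cmap.bins, out_bins)
    return sub


def query_tad(cmap: ContactMap, q: QueryRecord) -> ScalarResult:
    """Intra-domain contact density: sum and average over all internal pairs.

    The average divides the sum by all m(m+1)/2 bin pairs of the m-bin
    interval (diagonal included), so domains of different sizes are
    comparable; it is the headline ``frequency``.
    """
    ids = cmap.bins.bins_of_interval(q.chrom, q.start, q.end)
    total = 0.0
    for i, j in combinations_with_replacement(ids, 2):
        total += cmap.lookup(i, j)
    m = len(ids)
    n_pairs = m * (m + 1) // 2
    return ScalarResult(
        name=q.name,
        frequency=total / n_pairs,
        n_pairs=n_pairs,
        total=total,
        query=q,
    )
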