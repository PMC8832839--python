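"""Binned contact-map storage and genomic-coordinate arithmetic.

A Hi-C contact map at resolution *r* assigns one non-negative contact
frequency to every pair of fixed-width genomic bins.  The map is held sparse:
a hash keyed by the unordered bin-id pair ``(i, j)`` with ``i <= j``; any
pair not present reads as 0.0.  This mirrors how binned maps are distributed
as bin-table + bin-pair-contact text files and gives O(1) lookup per query
bin pair.

Coordinates are 0-based, half-open throughout (BED convention): a bin of
size 10 starting at 20 covers positions 20..29 and position 30 belongs to
the next bin.

Text dialects
-------------
Bin table (``read_bins``): tab-separated ``bin_id  chrom  start  end``,
optional single header line (auto-detected).  Bin ids are global integers,
unique across chromosomes; bins within a chromosome are contiguous and
sorted.  All bins share one size except possibly the last bin of each
chromosome.

Contacts (``read_contacts_text``): tab-separated ``bin1  bin2  value``.
Either triangle (or both, if consistent) may be given; keys are
canonicalised to ``i <= j`` on load.

A binary cache (``save_binary``/``load_binary``) stores the same content as
packed numpy arrays behind a magic string and format version, so a large
text map is parsed once and re-loaded without parsing.
"""

from __future__ import annotations

import struct
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, QueryError, ValidationError

__all__ = [
    "GenomeBins",
    "ContactMap",
    "bin_key",
    "read_bins",
    "read_contacts_text",
    "write_bins_text",
    "write_contacts_text",
    "save_binary",
    "load_binary",
]

_MAGIC = b"HICQBIN1"
_VERSION = 1


def bin_key(i: int, j: int) -> tuple[int, int]:
    """Canonical unordered bin-pair key: the sorted tuple ``(min, max)``."""
    return (i, j) if i <= j else (j, i)


@dataclass(frozen=True)
class _ChromIndex:
    """Per-chromosome view: bin ids plus their start/end coordinates, sorted."""

    ids: np.ndarray      # int64, ascending genomic order
    starts: np.ndarray   # int64
    ends: np.ndarray     # int64

    @property
    def length(self) -> int:
        return int(self.ends[-1])


@dataclass(frozen=True)
class GenomeBins:
    """Mapping between genomic coordinates and global integer bin ids.

    Parameters
    ----------
    table
        DataFrame with columns ``bin_id, chrom, start, end`` (one row per
        bin, any row order accepted; validated and re-sorted on
        construction).
    """

    table: pd.DataFrame
    bin_size: int = field(init=False)
    _by_chrom: dict[str, _ChromIndex] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["bin_id", "chrom", "start", "end"]
        if list(t.columns) != required:
            t = t[required]
        t = t.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "table", t)
        if t["bin_id"].duplicated().any():
            dup = int(t["bin_id"][t["bin_id"].duplicated()].iloc[0])
            raise ValidationError(f"duplicate bin_id {dup} in bin table")
        if (t["end"] <= t["start"]).any():
            bad = t[t["end"] <= t["start"]].iloc[0]
            raise ValidationError(
                f"bin {int(bad.bin_id)} has end <= start ({int(bad.end)} <= {int(bad.start)})"
            )
        widths = (t["end"] - t["start"]).to_numpy()
        # modal width = the nominal resolution; terminal bins may be shorter
        vals, counts = np.unique(widths, return_counts=True)
        object.__setattr__(self, "bin_size", int(vals[np.argmax(counts)]))

        by_chrom: dict[str, _ChromIndex] = {}
        for chrom, grp in t.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                k = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise ValidationError(
                    f"bins overlap on {chrom}: "
                    f"[{starts[k]},{ends[k]}) and [{starts[k + 1]},{ends[k + 1]})"
                )
            by_chrom[str(chrom)] = _ChromIndex(
                ids=grp["bin_id"].to_numpy(dtype=np.int64), starts=starts, ends=ends
            )
        object.__setattr__(self, "_by_chrom", by_chrom)

    # -- introspection -----------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    @property
    def n_bins(self) -> int:
        return len(self.table)

    def chrom_length(self, chrom: str) -> int:
        """End coordinate of the last bin of *chrom*."""
        return self._chrom(chrom).length

    def has_bin(self, bin_id: int) -> bool:
        return bin_id in set(self.table["bin_id"].to_numpy().tolist())

    def bin_id_set(self) -> frozenset[int]:
        return frozenset(int(b) for b in self.table["bin_id"])

    def _chrom(self, chrom: str) -> _ChromIndex:
        try:
            return self._by_chrom[chrom]
        except KeyError:
            raise QueryError(
                f"unknown chromosome {chrom!r}; known: {', '.join(self._by_chrom)}"
            ) from None

    # -- coordinate arithmetic --------------------------------------------

    def bin_of_position(self, chrom: str, pos: int) -> int:
        """The bin whose half-open interval [start, end) contains *pos*."""
        ci = self._chrom(chrom)
        if pos < int(ci.starts[0]) or pos >= ci.length:
            raise QueryError(
                f"position {chrom}:{pos} outside binned range "
                f"[{int(ci.starts[0])}, {ci.length})"
            )
        k = bisect_right(ci.starts, pos) - 1
        if pos >= ci.ends[k]:  # gap between bins (contiguity normally forbids this)
            raise QueryError(f"position {chrom}:{pos} falls in an unbinned gap")
        return int(ci.ids[k])

    def bins_of_interval(self, chrom: str, start: int, end: int) -> list[int]:
        """All bin ids overlapping [start, end) on *chrom*, ascending.

        Partial overlaps count; raises :class:`QueryError` when the interval
        misses every bin.
        """
        if start >= end:
            raise QueryError(f"empty interval {chrom}:{start}-{end}")
        ci = self._chrom(chrom)
        lo = bisect_right(ci.ends, start)          # first bin with end > start
        hi = bisect_right(ci.starts, end - 1)      # bins with start < end
        if lo >= hi:
            raise QueryError(
                f"interval {chrom}:{start}-{end} overlaps no bin "
                f"(binned range [{int(ci.starts[0])}, {ci.length}))"
            )
        return [int(b) for b in ci.ids[lo:hi]]

    def neighborhood(self, bin_id_: int, chrom: str, k: int) -> list[int]:
        """Bins within +-*k* positions of *bin_id_* along *chrom*, clipped
        to the chromosome ends."""
        ci = self._chrom(chrom)
        idx = int(np.searchsorted(ci.ids, bin_id_))
        if idx >= len(ci.ids) or ci.ids[idx] != bin_id_:
            raise QueryError(f"bin {bin_id_} is not on chromosome {chrom}")
        lo = max(0, idx - k)
        hi = min(len(ci.ids), idx + k + 1)
        return [int(b) for b in ci.ids[lo:hi]]


@dataclass
class ContactMap:
    """Sparse symmetric contact store keyed by canonical bin pairs.

    ``entries`` maps ``(i, j)`` with ``i <= j`` to a non-negative contact
    frequency; a pair absent from the store reads as 0.0 contact (sparse
    Hi-C semantics, which keeps window averages well defined).
    """

    bins: GenomeBins
    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def lookup(self, i: int, j: int) -> float:
        return self.entries.get(bin_key(i, j), 0.0)

    def set(self, i: int, j: int, value: float) -> None:
        if value < 0:
            raise ValidationError(f"negative contact {value} for pair ({i}, {j})")
        self.entries[bin_key(i, j)] = float(value)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self) -> Iterable[tuple[tuple[int, int], float]]:
        return self.entries.items()


# ---------------------------------------------------------------------------
# text readers / writers
# ---------------------------------------------------------------------------

def _looks_like_header(fields: list[str]) -> bool:
    # a data line starts with an integer bin id
    try:
        int(fields[0])
        return False
    except ValueError:
        return True


def read_bins(path: str | Path) -> GenomeBins:
    """Parse a bin table: TSV ``bin_id  chrom  start  end``.

    One optional header line is detected (first field not an integer) and
    skipped.  Raises :class:`ParseError` naming the offending line, or
    :class:`ValidationError` for overlap/duplicate violations.
    """
    path = Path(path)
    rows: list[tuple[int, str, int, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 4:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 4 tab-separated fields "
                    f"(bin_id, chrom, start, end), got {len(fields)}"
                )
            try:
                rows.append((int(fields[0]), fields[1], int(fields[2]), int(fields[3])))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path.name}: no bin records found")
    table = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])
    return GenomeBins(table)


def read_contacts_text(path: str | Path, bins: GenomeBins) -> ContactMap:
    """Parse a bin-pair contact file: TSV ``bin1  bin2  value``.

    Keys are canonicalised so either (or both) triangles may appear; if both
    orientations of a pair are present with different values that is treated
    as data corruption and raised, never silently resolved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2],
            names=["bin1", "bin2", "value"],
            dtype={"bin1": "int64", "bin2": "int64", "value": "float64"},
            skiprows=_count_header_lines(path),
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path.name}: {exc}") from None

    known = bins.bin_id_set()
    for col in ("bin1", "bin2"):
        unknown = set(df[col].unique().tolist()) - known
        if unknown:
            raise ValidationError(
                f"{path.name}: bin id(s) not in bin table: "
                f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}"
            )
    if (df["value"] < 0).any():
        bad = df[df["value"] < 0].iloc[0]
        raise ValidationError(
            f"{path.name}: negative contact {bad.value} for pair "
            f"({int(bad.bin1)}, {int(bad.bin2)})"
        )
    if df["value"].isna().any():
        raise ParseError(f"{path.name}: non-numeric contact value")

    i = np.minimum(df["bin1"], df["bin2"]).to_numpy()
    j = np.maximum(df["bin1"], df["bin2"]).to_numpy()
    v = df["value"].to_numpy()
    entries: dict[tuple[int, int], float] = {}
    for ii, jj, vv in zip(i.tolist(), j.tolist(), v.tolist()):
        key = (ii, jj)
        prev = entries.get(key)
        if prev is not None and prev != vv:
            raise ValidationError(
                f"{path.name}: inconsistent symmetric duplicate for pair {key}: "
                f"{prev} vs {vv}"
            )
        entries[key] = vv
    return ContactMap(bins=bins, entries=entries)


def _count_header_lines(path: Path) -> int:
    with path.open() as fh:
        first = fh.readline()
    if not first:
        return 0
    fields = first.rstrip("\n").split("\t")
    return 1 if fields and _looks_like_header(fields) else 0


def write_bins_text(bins: GenomeBins, path: str | Path) -> None:
    """Write a bin table in the dialect :func:`read_bins` consumes."""
    bins.table.to_csv(path, sep="\t", index=False, header=False)


def write_contacts_text(cmap: ContactMap, path: str | Path) -> None:
    """Write contacts as TSV ``bin1  bin2  value``, keys sorted."""
    with Path(path).open("w") as fh:
        for (i, j) in sorted(cmap.entries):
            fh.write(f"{i}\t{j}\t{cmap.entries[(i, j)]:g}\n")


# ---------------------------------------------------------------------------
# binary cache
# ---------------------------------------------------------------------------

def save_binary(cmap: ContactMap, path: str | Path) -> None:
    """Serialise map + bin table to a versioned binary cache.

    Layout: magic, uint32 version, then the bin table (chrom-name pool +
    per-bin ``bin_id/chrom_idx/start/end`` arrays) and the contact triples
    as raw little-endian numpy buffers, each array length-prefixed.  Values
    round-trip bit-exactly.
    """
    t = cmap.bins.table
    chroms = list(dict.fromkeys(t["chrom"]))
    chrom_idx = np.array([chroms.index(c) for c in t["chrom"]], dtype="<u4")
    keys = sorted(cmap.entries)
    ii = np.array([k[0] for k in keys], dtype="<i8")
    jj = np.array([k[1] for k in keys], dtype="<i8")
    vv = np.array([cmap.entries[k] for k in keys], dtype="<f8")

    with Path(path).open("wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", _VERSION))
        name_blob = "\x00".join(chroms).encode()
        fh.write(struct.pack("<I", len(name_blob)))
        fh.write(name_blob)
        fh.write(struct.pack("<Q", len(t)))
        fh.write(t["bin_id"].to_numpy(dtype="<i8").tobytes())
        fh.write(chrom_idx.tobytes())
        fh.write(t["start"].to_numpy(dtype="<i8").tobytes())
        fh.write(t["end"].to_numpy(dtype="<i8").tobytes())
        fh.write(struct.pack("<Q", len(keys)))
        fh.write(ii.tobytes())
        fh.write(jj.tobytes())
        fh.write(vv.tobytes())


def load_binary(path: str | Path) -> ContactMap:
    """Load a cache written by :func:`save_binary`.

    Raises :class:`FormatError` on a wrong magic string or version rather
    than returning garbage.
    """
    path = Path(path)
    with path.open("rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise FormatError(
                f"{path.name}: not a hicquery binary cache (bad magic)"
            )
        (version,) = struct.unpack("<I", fh.read(4))
        if version != _VERSION:
            raise FormatError(
                f"{path.name}: unsupported cache version {version} "
                f"(expected {_VERSION})"
            )
        (name_len,) = struct.unpack("<I", fh.read(4))
        chroms = fh.read(name_len).decode().split("\x00")
        (n_bins,) = struct.unpack("<Q", fh.read(8))
        bin_id = np.frombuffer(fh.read(8 * n_bins), dtype="<i8")
        chrom_idx = np.frombuffer(fh.read(4 * n_bins), dtype="<u4")
        start = np.frombuffer(fh.read(8 * n_bins), dtype="<i8")
        end = np.frombuffer(fh.read(8 * n_bins), dtype="<i8")
        (n_entries,) = struct.unpack("<Q", fh.read(8))
        ii = np.frombuffer(fh.read(8 * n_entries), dtype="<i8")
        jj = np.frombuffer(fh.read(8 * n_entries), dtype="<i8")
        vv = np.frombuffer(fh.read(8 * n_entries), dtype="<f8")
        if fh.read(1):
            raise FormatError(f"{path.name}: trailing bytes after cache payload")

    table = pd.DataFrame(
        {
            "bin_id": bin_id.astype("int64"),
            "chrom": [chroms[k] for k in chrom_idx],
            "start": start.astype("int64"),
            "end": end.astype("int64"),
        }
    )
    bins = GenomeBins(table)
    entries = {
        (int(a), int(b)): float(c)
        for a, b, c in zip(ii.tolist(), jj.tolist(), vv.tolist())
    }
    return ContactMap(bins=bins, entries=entries)


def from_matrix(matrix, bins: GenomeBins, bin_ids=None) -> ContactMap:
    """Adapter: build a ContactMap from any dense/sparse symmetric matrix.

    Intended for matrices obtained from external readers (cooler, Juicer
    dumps).  ``bin_ids`` gives the bin id of each matrix row; defaults to
    the bin table's ids in order.  Only the upper triangle (incl. diagonal)
    of nonzero values is stored; asymmetric input raises.
    """
    m = np.asarray(
        matrix.todense() if hasattr(matrix, "todense") else matrix, dtype=float
    )
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {m.shape}")
    if not np.allclose(m, m.T):
        raise ValidationError("matrix is not symmetric")
    ids = (
        bins.table["bin_id"].to_numpy()
        if bin_ids is None
        else np.asarray(bin_ids, dtype=np.int64)
    )
    if len(ids) != m.shape[0]:
        raise ValidationError(
            f"matrix has {m.shape[0]} rows but {len(ids)} bin ids were given"
        )
    cmap = ContactMap(bins=bins)
    r, c = np.nonzero(np.triu(m))
    for a, b in zip(r.tolist(), c.tolist()):
        cmap.set(int(ids[a]), int(ids[b]), float(m[a, b]))
    return cmap
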