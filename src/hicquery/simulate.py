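"""Synthetic binned contact maps for testing and benchmarking.

The generator emulates the two text inputs a binned Hi-C map is shipped as
(bin table + bin-pair contacts) at desk scale.  The intra-chromosomal base
signal follows the canonical power-law distance decay

    mu(i, j) = C * (1 + |i - j|) ** (-alpha)

optionally multiplied by an enrichment factor for pairs falling entirely
inside a "TAD block" (a self-interacting domain), and optionally replaced
by one Poisson draw per entry, Poisson(mu), to mimic count noise.  Maps are
symmetric by construction and fully reproducible from the seed.

Defaults: C = 100 and alpha = 1, the classic contact-probability decay
slope observed in mammalian and fly Hi-C at sub-megabase scales; no blocks;
no noise.  Inter-chromosomal pairs default to 0 (omitted entries); a
constant background can be requested for cross-chromosome tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ContactMap, GenomeBins, write_bins_text, write_contacts_text
from .queries import MODES

__all__ = ["MapSpec", "generate_map", "write_fixture", "generate_queries", "toy5"]


@dataclass(frozen=True)
class MapSpec:
    """Parameters of one synthetic map.

    Attributes
    ----------
    chrom_sizes
        Chromosome name -> length in bp.
    bin_size
        Bin width in bp; the last bin of a chromosome may be shorter.
    decay_scale
        C, the contact level at distance 0 (the diagonal).
    decay_exponent
        alpha >= 0; 0 gives a flat map.
    tad_blocks
        (chrom, start, end, enrichment) with enrichment >= 1; pairs with
        both bins inside a block are multiplied by it.
    noise
        "none" (exact closed form) or "poisson" (one draw per entry).
    inter_level
        Constant contact for inter-chromosomal pairs; 0 omits them.
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    decay_scale: float = 100.0
    decay_exponent: float = 1.0
    tad_blocks: tuple[tuple[str, int, int, float], ...] = ()
    noise: str = "none"
    inter_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValidationError("chrom_sizes must name at least one chromosome")
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if self.decay_scale <= 0:
            raise ValidationError("decay_scale must be > 0")
        if self.decay_exponent < 0:
            raise ValidationError("decay_exponent must be >= 0")
        if self.noise not in ("none", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.inter_level < 0:
            raise ValidationError("inter_level must be >= 0")
        for chrom, start, end, enr in self.tad_blocks:
            if chrom not in self.chrom_sizes:
                raise ValidationError(f"tad_block on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_sizes[chrom]):
                raise ValidationError(
                    f"tad_block [{start},{end}) outside {chrom} "
                    f"(length {self.chrom_sizes[chrom]})"
                )
            if enr < 1:
                raise ValidationError(f"tad_block enrichment must be >= 1, got {enr}")


def _bin_table(spec: MapSpec) -> pd.DataFrame:
    rows = []
    bin_id = 0
    for chrom, size in spec.chrom_sizes.items():
        start = 0
        while start < size:
            rows.append((bin_id, chrom, start, min(start + spec.bin_size, size)))
            bin_id += 1
            start += spec.bin_size
    return pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])


def generate_map(spec: MapSpec) -> tuple[GenomeBins, ContactMap]:
    """Build the bin table and contact map a :class:`MapSpec` describes."""
    bins = GenomeBins(_bin_table(spec))
    rng = np.random.default_rng(spec.seed)
    t = bins.table

    # bin index within its chromosome, and block membership per bin
    entries: dict[tuple[int, int], float] = {}
    for chrom in bins.chromosomes:
        grp = t[t["chrom"] == chrom]
        ids = grp["bin_id"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        in_block = []
        for _, bstart, bend, enr in [b for b in spec.tad_blocks if b[0] == chrom]:
            mask = (starts < bend) & (ends > bstart)
            in_block.append((mask, enr))
        n = len(ids)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        mu = spec.decay_scale * (1.0 + d) ** (-spec.decay_exponent)
        for mask, enr in in_block:
            both = np.outer(mask, mask)
            mu = np.where(both, mu * enr, mu)
        iu, ju = np.triu_indices(n)
        vals = mu[iu, ju]
        if spec.noise == "poisson":
            vals = rng.poisson(vals).astype(float)
        for a, b, v in zip(ids[iu].tolist(), ids[ju].tolist(), vals.tolist()):
            if v > 0:
                entries[(a, b)] = float(v)

    if spec.inter_level > 0 and len(bins.chromosomes) > 1:
        chrom_of = dict(zip(t["bin_id"], t["chrom"]))
        all_ids = t["bin_id"].tolist()
        for a, b in combinations_with_replacement(all_ids, 2):
            if chrom_of[a] != chrom_of[b]:
                v = spec.inter_level
                if spec.noise == "poisson":
                    v = float(rng.poisson(v))
                if v > 0:
                    entries[(a, b)] = v

    return bins, ContactMap(bins=bins, entries=entries)


def write_fixture(
    bins: GenomeBins, cmap: ContactMap, directory: str | Path, stem: str = "fixture"
) -> tuple[Path, Path]:
    """Emit ``<stem>.bins`` and ``<stem>.contacts`` TSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bins_path = directory / f"{stem}.bins"
    contacts_path = directory / f"{stem}.contacts"
    write_bins_text(bins, bins_path)
    write_contacts_text(cmap, contacts_path)
    return bins_path, contacts_path


def generate_queries(
    bins: GenomeBins,
    mode: str,
    n: int,
    seed: int = 0,
    path: str | Path | None = None,
    min_span_bins: int = 1,
    max_span_bins: int = 10,
) -> list:
    """Draw *n* uniformly placed, in-range queries for *mode*.

    Spans are uniform in ``[min_span_bins, max_span_bins]`` bins.  ``pair``
    mode yields paired-region records (7-column lines when written); every
    other mode yields plain BED records.  Deterministic per seed.
    """
    from .queries import PairQueryRecord, QueryRecord

    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = bins.chromosomes
    records = []

    def draw_interval(k: int):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        chrom_len = bins.chrom_length(chrom)
        span_bins = int(rng.integers(min_span_bins, max_span_bins + 1))
        span = min(span_bins * bins.bin_size, chrom_len)
        start = int(rng.integers(0, chrom_len - span + 1))
        return chrom, start, start + span

    for k in range(1, n + 1):
        if mode == "pair":
            c1, s1, e1 = draw_interval(k)
            c2, s2, e2 = draw_interval(k)
            records.append(PairQueryRecord(c1, s1, e1, c2, s2, e2, f"query_{k}"))
        else:
            c, s, e = draw_interval(k)
            records.append(QueryRecord(c, s, e, f"query_{k}"))

    if path is not None:
        with Path(path).open("w") as fh:
            for r in records:
                if mode == "pair":
                    fh.write(
                        f"{r.chrom1}\t{r.start1}\t{r.end1}\t"
                        f"{r.chrom2}\t{r.start2}\t{r.end2}\t{r.name}\n"
                    )
                else:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
    return records


# TOY5: chrT of length 50, bin size 10, bins 0..4, c(i, j) = 10 - |i - j|.
# Shipped as a literal value table so worked examples stay stable.
_TOY5_BINS = [(k, "chrT", 10 * k, 10 * (k + 1)) for k in range(5)]
_TOY5_ENTRIES = {
    (i, j): float(10 - (j - i)) for i, j in combinations_with_replacement(range(5), 2)
}


def toy5() -> tuple[GenomeBins, ContactMap]:
    """The 5-bin worked-example map: one 50 bp chromosome, c = 10 - |i-j|."""
    bins = GenomeBins(
        pd.DataFrame(_TOY5_BINS, columns=["bin_id", "chrom", "start", "end"])
    )
    return bins, ContactMap(bins=bins, entries=dict(_TOY5_ENTRIES))
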