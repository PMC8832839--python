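"""Permutation null for scalar query modes.

The significance of an observed contact frequency is assessed against an
empirical null built by relocating the query uniformly at random within its
own chromosome: the shuffle is a rigid shift that preserves the query's
length (and, for same-chromosome region pairs, the inter-region offset), so
the null holds the query's internal geometry fixed while randomising its
genomic position.  The observed frequency is then ranked among the sampled
frequencies:

* ``ratio``         = observed / mean(samples)
* ``rank_percent``  = 100 * #{samples >= observed} / #samples  ("top X%")

Ties count toward the samples (conservative one-sided exceedance).  Only
the scalar modes (bait, loop, pair, TAD) can be permuted; list-valued modes
have no single frequency to rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import QueryError
from .io import ContactMap, GenomeBins
from .queries import (
    PairQueryRecord,
    QueryRecord,
    SCALAR_MODES,
    query_bait,
    query_loop,
    query_pair,
    query_tad,
)

__all__ = [
    "PermutationConfig",
    "PermutationReport",
    "shuffle_query",
    "run_permutation",
    "rank_percent",
    "ratio",
    "format_ratio",
    "format_rank",
]

DEFAULT_SEED = 20220210


@dataclass(frozen=True)
class PermutationConfig:
    """How to permute: sample count, seed, and the query mode being tested.

    ``n_samples = 0`` disables the test (the report then carries only the
    observed frequency).  ``near_bin`` is consulted for bait mode only.
    """

    mode: str
    n_samples: int = 100
    seed: int = DEFAULT_SEED
    near_bin: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise QueryError(f"n_samples must be >= 0, got {self.n_samples}")
        if self.mode not in SCALAR_MODES:
            raise QueryError(
                f"mode {self.mode!r} has no scalar frequency to permute; "
                f"permutable modes: {', '.join(SCALAR_MODES)}"
            )


@dataclass(frozen=True)
class PermutationReport:
    """Observed frequency versus the shuffle null.

    ``ratio``/``rank_percent`` are NaN when the test is disabled
    (``n_samples == 0``); ``ratio`` is also NaN when the sample mean is 0
    (undefined, flagged rather than crashing).
    """

    name: str
    observed: float
    samples: tuple[float, ...]
    sample_mean: float
    ratio: float
    rank_percent: float

    @property
    def enabled(self) -> bool:
        return len(self.samples) > 0


def rank_percent(observed: float, samples: Sequence[float]) -> float:
    """100 x fraction of samples >= observed ("top X%"); ties favor samples."""
    if len(samples) == 0:
        raise QueryError("rank_percent needs at least one sample")
    n_ge = sum(1 for s in samples if s >= observed)
    return 100.0 * n_ge / len(samples)


def ratio(observed: float, samples: Sequence[float]) -> float:
    """observed / mean(samples); NaN (not a crash) when the mean is zero."""
    if len(samples) == 0:
        raise QueryError("ratio needs at least one sample")
    mean = float(np.mean(samples))
    if mean == 0.0:
        return math.nan
    return observed / mean


def format_ratio(value: float) -> str:
    """Two-decimal display, e.g. 7237.85 / 6363.51 -> '1.14'; NaN -> 'NA'."""
    return "NA" if math.isnan(value) else f"{value:.2f}"


def format_rank(value: float) -> str:
    """'top X%' with X rounded to the nearest integer; NaN -> 'NA'."""
    return "NA" if math.isnan(value) else f"top {round(value):d}%"


def _shift_interval(
    start: int, end: int, chrom_len: int, rng: np.random.Generator, name: str
) -> int:
    span = end - start
    if span > chrom_len:
        raise QueryError(
            f"query {name}: span {span} exceeds chromosome length {chrom_len}"
        )
    return int(rng.integers(0, chrom_len - span + 1))


def shuffle_query(
    q: QueryRecord | PairQueryRecord,
    bins: GenomeBins,
    rng: np.random.Generator,
) -> QueryRecord | PairQueryRecord:
    """One rigid within-chromosome relocation of *q*.

    The new start is uniform over every in-range placement; length,
    chromosome, and (for same-chromosome pairs) the offset between the two
    regions are preserved.  Regions of an inter-chromosomal pair are shifted
    independently on their own chromosomes.
    """
    if isinstance(q, QueryRecord):
        chrom_len = bins.chrom_length(q.chrom)
        new_start = _shift_interval(q.start, q.end, chrom_len, rng, q.name)
        return replace(q, start=new_start, end=new_start + q.span)

    if q.chrom1 == q.chrom2:
        # rigid shift of the envelope holding both regions
        env_start = min(q.start1, q.start2)
        env_end = max(q.end1, q.end2)
        chrom_len = bins.chrom_length(q.chrom1)
        new_env = _shift_interval(env_start, env_end, chrom_len, rng, q.name)
        delta = new_env - env_start
        return replace(
            q,
            start1=q.start1 + delta,
            end1=q.end1 + delta,
            start2=q.start2 + delta,
            end2=q.end2 + delta,
        )

    s1 = _shift_interval(q.start1, q.end1, bins.chrom_length(q.chrom1), rng, q.name)
    s2 = _shift_interval(q.start2, q.end2, bins.chrom_length(q.chrom2), rng, q.name)
    return replace(
        q,
        start1=s1,
        end1=s1 + (q.end1 - q.start1),
        start2=s2,
        end2=s2 + (q.end2 - q.start2),
    )


def _evaluate(cmap: ContactMap, q, config: PermutationConfig) -> float:
    if config.mode == "bait":
        return query_bait(cmap, q, config.near_bin).frequency
    if config.mode == "loop":
        return query_loop(cmap, q).frequency
    if config.mode == "pair":
        return query_pair(cmap, q).frequency
    if config.mode == "TAD":
        return query_tad(cmap, q).frequency
    raise QueryError(f"unsupported scalar mode {config.mode!r}")


def run_permutation(
    cmap: ContactMap,
    q: QueryRecord | PairQueryRecord,
    config: PermutationConfig,
) -> PermutationReport:
    """Observed frequency of *q* plus ``config.n_samples`` shuffled replicas.

    Deterministic for a fixed ``config.seed``: the same seed reproduces the
    identical samples list.
    """
    observed = _evaluate(cmap, q, config)
    if config.n_samples == 0:
        return PermutationReport(
            name=q.name,
            observed=observed,
            samples=(),
            sample_mean=math.nan,
            ratio=math.nan,
            rank_percent=math.nan,
        )
    rng = np.random.default_rng(config.seed)
    samples = []
    for _ in range(config.n_samples):
        samples.append(_evaluate(cmap, shuffle_query(q, cmap.bins, rng), config))
    samples = tuple(samples)
    return PermutationReport(
        name=q.name,
        observed=observed,
        samples=samples,
        sample_mean=float(np.mean(samples)),
        ratio=ratio(observed, samples),
        rank_percent=rank_percent(observed, samples),
    )
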