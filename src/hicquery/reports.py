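"""Result writers and the permutation density plot.

One run emits one results TSV with a row per query.  Scalar modes with
permutation enabled additionally emit one random-sample file per query,
``<stem>_random_<k>.txt`` (k = 1-based query index): line 1 a header,
line 2 the query's own frequency, lines 3.. the sampled frequencies at full
precision.  The TSV renders ratio at two decimals and rank as "top X%";
full precision lives in the sample files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import DataError, ParseError
from .permutation import PermutationReport, format_rank, format_ratio
from .queries import PairQueryRecord, QueryRecord, RecordListResult, ScalarResult

__all__ = [
    "write_results",
    "write_rows",
    "write_random_samples",
    "read_random_samples",
    "plot_permutation",
]

_COLUMNS = [
    "name",
    "coords",
    "frequency",
    "sum",
    "n_pairs",
    "random_mean",
    "ratio",
    "rank",
]


def _coords(q) -> str:
    if isinstance(q, PairQueryRecord):
        return (
            f"{q.chrom1}:{q.start1}-{q.end1}|{q.chrom2}:{q.start2}-{q.end2}"
        )
    if isinstance(q, QueryRecord):
        return f"{q.chrom}:{q.start}-{q.end}"
    return ""


def write_results(
    results: Sequence[ScalarResult],
    reports: Sequence[PermutationReport | None],
    path: str | Path,
) -> None:
    """Main results TSV: one row per query, fixed column order.

    Permutation columns are rendered empty (not dropped) when the test is
    disabled, so downstream parsers see a stable header.
    """
    if not results:
        raise DataError("no results to write")
    if len(reports) != len(results):
        raise DataError(
            f"{len(results)} results but {len(reports)} permutation reports"
        )
    with Path(path).open("w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for res, rep in zip(results, reports):
            total = "" if res.total is None else f"{res.total:g}"
            if rep is not None and rep.enabled:
                extra = [
                    f"{rep.sample_mean:g}",
                    format_ratio(rep.ratio),
                    format_rank(rep.rank_percent),
                ]
            else:
                extra = ["", "", ""]
            fh.write(
                "\t".join(
                    [
                        res.name,
                        _coords(res.query),
                        f"{res.frequency:g}",
                        total,
                        str(res.n_pairs),
                    ]
                    + extra
                )
                + "\n"
            )


def write_rows(result: RecordListResult, path: str | Path) -> None:
    """Row-list output for local/sites: TSV ``bin_i  bin_j  contact``."""
    with Path(path).open("w") as fh:
        fh.write("bin_i\tbin_j\tcontact\n")
        for i, j, v in result.rows:
            fh.write(f"{i}\t{j}\t{v:g}\n")


def write_random_samples(report: PermutationReport, path: str | Path) -> None:
    """Per-query sample file: header, observed frequency, then each sample."""
    with Path(path).open("w") as fh:
        fh.write(f"# permutation samples for {report.name}\n")
        fh.write(f"{report.observed!r}\n")
        for s in report.samples:
            fh.write(f"{s!r}\n")


def read_random_samples(path: str | Path) -> tuple[float, list[float]]:
    """Parse a file written by :func:`write_random_samples`.

    Returns (observed, samples).  Raises :class:`ParseError` naming the
    offending line on malformed input.
    """
    path = Path(path)
    observed: float | None = None
    samples: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                value = float(line)
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: expected a number, got {line!r}"
                ) from None
            if observed is None:
                observed = value
            else:
                samples.append(value)
    if observed is None:
        raise ParseError(f"{path.name}: no frequencies found")
    return observed, samples


def plot_permutation(report_file: str | Path, out_image: str | Path) -> None:
    """Density of the permutation samples with the observed frequency marked.

    The observed value is a vertical line; the x-axis is expanded when it
    falls outside the sample range.  Needs at least two samples for a
    density estimate.
    """
    observed, samples = read_random_samples(report_file)
    if len(samples) < 2:
        raise DataError(
            f"{Path(report_file).name}: need >= 2 samples for a density plot, "
            f"got {len(samples)}"
        )
    arr = np.asarray(samples)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(arr, bins=min(30, max(5, len(arr) // 5)), density=True,
            color="steelblue", alpha=0.6, edgecolor="white")
    if np.ptp(arr) > 0:
        from scipy.stats import gaussian_kde

        grid = np.linspace(arr.min(), arr.max(), 256)
        ax.plot(grid, gaussian_kde(arr)(grid), color="navy", lw=1.5)
    ax.axvline(observed, color="red", lw=2, label=f"query = {observed:g}")
    lo, hi = ax.get_xlim()
    if not (lo <= observed <= hi):
        ax.set_xlim(min(lo, observed), max(hi, observed))
    ax.set_xlabel("contact frequency")
    ax.set_ylabel("density")
    ax.set_title("permutation null vs. observed frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_image)
    plt.close(fig)
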