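"""Independent dense-matrix reference for the query modes.

Deliberately naive: reads the text files with plain Python, builds a full
dense symmetric matrix indexed by bin id, and answers each query mode by
linear scans and explicit double loops.  Shares no code with the package so
it can serve as an oracle.
"""

from __future__ import annotations

import numpy as np


def load_dense(bins_path, contacts_path):
    """Returns (rows, M): rows = [(bin_id, chrom, start, end)...], M dense."""
    rows = []
    with open(bins_path) as fh:
        for line in fh:
            f = line.split("\t")
            if not line.strip():
                continue
            try:
                int(f[0])
            except ValueError:
                continue  # header
            rows.append((int(f[0]), f[1], int(f[2]), int(f[3])))
    n = max(r[0] for r in rows) + 1
    M = np.zeros((n, n))
    with open(contacts_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                i = int(f[0])
            except ValueError:
                continue
            j, v = int(f[1]), float(f[2])
            M[i, j] = v
            M[j, i] = v
    return rows, M


def ref_bin_of(rows, chrom, pos):
    for bin_id, c, s, e in rows:
        if c == chrom and s <= pos < e:
            return bin_id
    raise LookupError(f"{chrom}:{pos} not in any bin")


def ref_bins_in(rows, chrom, start, end):
    hits = [(s, b) for b, c, s, e in rows if c == chrom and s < end and e > start]
    return [b for _, b in sorted(hits)]


def ref_bait(rows, M, chrom, start, end, k):
    bait = ref_bin_of(rows, chrom, (start + end) // 2)
    chrom_bins = [b for _, b in sorted((s, b) for b, c, s, e in rows if c == chrom)]
    idx = chrom_bins.index(bait)
    window = chrom_bins[max(0, idx - k): idx + k + 1]
    return float(np.mean([M[bait, x] for x in window])), len(window)


def ref_local(rows, M, chrom, start, end):
    ids = ref_bins_in(rows, chrom, start, end)
    return [(i, j, float(M[i, j])) for i in ids for j in ids if i <= j]


def ref_loop(rows, M, chrom, start, end):
    return float(M[ref_bin_of(rows, chrom, start), ref_bin_of(rows, chrom, end - 1)])


def ref_pair(rows, M, c1, s1, e1, c2, s2, e2):
    b1 = ref_bins_in(rows, c1, s1, e1)
    b2 = ref_bins_in(rows, c2, s2, e2)
    vals = [float(M[i, j]) for i in b1 for j in b2]
    return float(np.sum(vals)), float(np.mean(vals)), len(vals)


def ref_sites(rows, M, sites):
    bins = sorted({ref_bin_of(rows, c, (s + e) // 2) for c, s, e in sites})
    return [(i, j, float(M[i, j])) for i in bins for j in bins if i <= j]


def ref_submap(rows, M, regions):
    keep = set()
    for c, s, e in regions:
        keep.update(ref_bins_in(rows, c, s, e))
    return {
        (i, j): float(M[i, j])
        for i in keep for j in keep
        if i <= j and M[i, j] != 0.0
    }


def ref_tad(rows, M, chrom, start, end):
    ids = ref_bins_in(rows, chrom, start, end)
    total = float(sum(M[i, j] for i in ids for j in ids if i <= j))
    m = len(ids)
    return total, total / (m * (m + 1) / 2), m * (m + 1) // 2
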