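import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `reference` importable

from hicquery import MapSpec, generate_map, toy5, write_fixture


@pytest.fixture
def toy():
    """The 5-bin worked-example map (chrT, 50 bp, c = 10 - |i-j|)."""
    return toy5()


@pytest.fixture
def toy_paths(tmp_path):
    """TOY5 written out as bin-table + contacts TSVs."""
    bins, cmap = toy5()
    return write_fixture(bins, cmap, tmp_path, "toy5")


def small_map_spec(seed: int, **overrides) -> MapSpec:
    """A two-chromosome noisy map under 100 bins, varied per seed."""
    kwargs = dict(
        chrom_sizes={"chr2L": 55_000, "chr2R": 38_000},
        bin_size=1_000,
        decay_scale=80.0,
        decay_exponent=1.0,
        tad_blocks=(("chr2L", 10_000, 22_000, 3.0),),
        noise="poisson",
        inter_level=2.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return MapSpec(**kwargs)


@pytest.fixture
def noisy_map(tmp_path):
    """One seeded noisy two-chromosome map, in memory and on disk."""
    spec = small_map_spec(seed=7)
    bins, cmap = generate_map(spec)
    paths = write_fixture(bins, cmap, tmp_path, "noisy")
    return bins, cmap, paths
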