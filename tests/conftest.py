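from __future__ import annotations

import numpy as np
import pytest

from varigen import (
    FixtureSpec,
    FragmentProfile,
    FrequencyTable,
    SizeBin,
    SizeDistribution,
    SnvTransitionMatrix,
    VariantClass,
)
from varigen.frequency import DEFAULT_BIN_EDGES


def make_size_dist(
    spec: dict[VariantClass, list[tuple[int, int, float]]] | None = None,
) -> SizeDistribution:
    if spec is None:
        spec = {cls: [(1, 10, 0.96), (11, 100, 0.04)]
                for cls in VariantClass if cls not in (VariantClass.SNV, VariantClass.TRANSLOCATION)}
    return SizeDistribution(
        {cls: [SizeBin(lo, hi, p) for lo, hi, p in bins] for cls, bins in spec.items()}
    )


def make_table(
    chrom_profiles: dict[str, list[FragmentProfile]],
    *,
    fragment_length: int = 1000,
    bin_edges: list[float] | None = None,
    size_dist: SizeDistribution | None = None,
    snv_matrix: SnvTransitionMatrix | None = None,
) -> FrequencyTable:
    """Build a frequency table by binning the given profiles on their GC."""
    edges = bin_edges or DEFAULT_BIN_EDGES
    n_bins = len(edges) - 1
    binned: dict[str, list[list[FragmentProfile]]] = {}
    for chrom, profs in chrom_profiles.items():
        bins: list[list[FragmentProfile]] = [[] for _ in range(n_bins)]
        for p in profs:
            assert p.gc_fraction is not None
            idx = min(int(np.searchsorted(edges, p.gc_fraction, side="right")) - 1, n_bins - 1)
            bins[idx].append(p)
        binned[chrom] = bins
    return FrequencyTable(
        fragment_length=fragment_length,
        bin_edges=list(edges),
        profiles=binned,
        size_dist=size_dist or make_size_dist(),
        snv_matrix=snv_matrix or SnvTransitionMatrix.uniform(),
        provenance="test fixture",
    )


def write_fasta_plain(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec() -> FixtureSpec:
    return FixtureSpec(
        chrom_lengths={"chr1": 60_000, "chr2": 40_000},
        gc_targets={"chr1": 0.41, "chr2": 0.55},
        seed=7,
    )


@pytest.fixture
def small_reference(tmp_path, small_spec):
    """A small two-chromosome synthetic reference on disk + in memory."""
    from varigen import generate_reference
    from varigen.frequency import read_reference

    path = tmp_path / "ref.fa"
    generate_reference(small_spec, path)
    return path, read_reference(path)
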