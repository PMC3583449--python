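"""Shared fixtures: toy genomes and study-scale synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import mutwave as mw


@pytest.fixture(scope="session")
def toy_genome() -> mw.GenomeSpec:
    """100-bp circular genome, OriC at position 1, alternating AT/GC halves."""
    seq = "AT" * 25 + "GC" * 25
    return mw.GenomeSpec(name="toy", length=100, oric=1, sequence=seq)


@pytest.fixture(scope="session")
def wave_genome() -> mw.GenomeSpec:
    """Quarter-scale synthetic chromosome with sequence and repeats."""
    return mw.generate_genome(
        length=1_160_000, n_repeats=8, repeat_length=2_000, seed=11
    )


@pytest.fixture(scope="session")
def wave_intensity(wave_genome) -> mw.WaveIntensityModel:
    L = wave_genome.length
    return mw.WaveIntensityModel(
        baseline=1625 / L, amplitude=0.5, period=L / 4.64
    )


@pytest.fixture(scope="session")
def wave_mutations(wave_genome, wave_intensity) -> mw.MutationSet:
    """1625 mutations from the mirror-symmetric wave intensity."""
    return mw.sample_mutations(
        wave_genome, wave_intensity, n_target=1625, seed=7
    )


def build_gap_fixture() -> tuple[mw.MutationSet, tuple[tuple[int, int], ...]]:
    """Deterministic 1625 positions on a 4,640,000-bp circle.

    44 designated gaps (43 of 8091 bp + 1 of 8087 bp, totalling 356,000 bp)
    each contain one small repeat; the remaining 1581 gaps (1071 of 2710 bp
    + 510 of 2709 bp) total 4,284,000 bp.  Mean gap sizes are therefore
    4640/1625 = 2.86 kb before and 4284/1581 = 2.71 kb after exclusion.
    """
    big = [8091] * 43 + [8087]
    small = [2710] * 1071 + [2709] * 510
    gaps = []
    # distribute the big gaps roughly evenly among the small ones
    stride = len(small) // len(big)
    si = 0
    for b in big:
        gaps.extend(small[si : si + stride])
        si += stride
        gaps.append(b)
    gaps.extend(small[si:])
    assert len(gaps) == 1625 and sum(gaps) == 4_640_000
    positions = np.cumsum([0] + gaps[:-1])
    genome = mw.GenomeSpec(name="fixture", length=4_640_000, oric=3_924_000)
    records = [
        mw.MutationRecord(position=int(p), ref_base="A", alt_base="G",
                          line_id=f"L{(i % 34) + 1:02d}")
        for i, p in enumerate(positions)
    ]
    repeats = []
    start = 0
    for g in gaps:
        if g > 8000:  # a big gap: park a repeat strictly inside it
            repeats.append((start + 100, start + 200))
        start += g
    assert len(repeats) == 44
    return mw.MutationSet(genome, records), tuple(repeats)


@pytest.fixture(scope="session")
def gap_fixture():
    return build_gap_fixture()
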