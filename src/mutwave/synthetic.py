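"""Synthetic genomes, mutation sets, and feature tracks with wave structure.

The generator emulates the statistical structure of a mutation-accumulation
(MA) experiment in a mismatch-repair-deficient bacterium: 34 lines bottle-
necked for 375 generations accumulate ~1625 base-pair substitutions whose
spatial density follows a mirror-symmetric wave over the two replichores
with superimposed asymmetric regional hotspots, an A:T>G:C-dominated
spectrum, repeat intervals where calling is impossible, and per-bin feature
tracks linearly coupled to the density.  Every downstream stage of the
pipeline is thereby testable without any external download.

The intensity along replichore distance d is
``lambda(d) = baseline * (1 + amplitude * cos(2 pi d / period + phase))``,
multiplied by each hotspot's fold over its interval.  The default period of
1000 kb places density peaks near 1000 kb and 2100 kb from the origin, and
the default amplitude of 0.5 reproduces replichore-fold correlations of the
magnitude seen in real MA data (rho ~ 0.7 at n = 1625).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .binning import BinConfig, BinnedTrack
from .genome import (
    SUBSTITUTION_CLASSES,
    GenomeSpec,
    MutationRecord,
    MutationSet,
    clockwise_distance,
    replichore_distance,
)

__all__ = [
    "Hotspot",
    "WaveIntensityModel",
    "SpectrumModel",
    "generate_genome",
    "sample_mutations",
    "generate_feature_tracks",
    "DEFAULT_SPECTRUM",
    "DEFAULT_N_LINES",
    "DEFAULT_GENERATIONS",
    "DEFAULT_N_MUTATIONS",
]

# Study-scale defaults: 34 MA lines propagated 375 generations each,
# accumulating ~1625 base-pair substitutions genome-wide.
DEFAULT_N_LINES = 34
DEFAULT_GENERATIONS = 375
DEFAULT_N_MUTATIONS = 1625

# Relative landmark positions on the E. coli chromosome (fractions of its
# 4,641,652-bp length), used to place OriC/Ter on generated genomes.
_ECOLI_L = 4_641_652
_REL_ORIC = 3_924_000 / _ECOLI_L
_REL_TER = {
    "TerD": 1_279_000 / _ECOLI_L,
    "TerA": 1_340_000 / _ECOLI_L,
    "TerC": 1_607_000 / _ECOLI_L,
    "TerB": 1_682_000 / _ECOLI_L,
}


@dataclass(frozen=True)
class Hotspot:
    """A regional fold-enrichment on one replichore.

    ``replichore`` is 'clockwise' or 'counterclockwise'; the interval is in
    bp of fork-travel distance from OriC.  Tying a hotspot to one replichore
    is what breaks mirror symmetry locally, as regional hotspots do in real
    data.
    """

    replichore: Literal["clockwise", "counterclockwise"]
    start: float
    end: float
    fold: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid hotspot interval [{self.start}, {self.end})")
        if self.fold <= 0:
            raise ValueError("hotspot fold must be positive")


@dataclass
class WaveIntensityModel:
    """Cosine mutation-intensity wave over replichore distance.

    With ``symmetric=True`` the intensity depends only on fork-travel
    distance, making the two replichores mirror images in expectation; with
    ``symmetric=False`` the cosine runs over clockwise position instead (an
    asymmetry control).  ``amplitude=0`` gives spatially uniform intensity.
    ``baseline`` is in mutations/bp but only sets the scale: sampling
    normalises the intensity to the requested mutation count.
    """

    baseline: float = DEFAULT_N_MUTATIONS / _ECOLI_L
    amplitude: float = 0.5
    period: float = 1_000_000.0
    phase: float = 0.0
    hotspots: Sequence[Hotspot] = field(default_factory=tuple)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if not (0.0 <= self.amplitude < 1.0):
            raise ValueError("amplitude must be in [0, 1)")
        if self.period <= 0:
            raise ValueError("period must be positive")

    def intensity(self, positions, genome: GenomeSpec) -> np.ndarray:
        """lambda at internal positions (vectorised), in mutations/bp."""
        pos = np.atleast_1d(np.asarray(positions))
        if self.symmetric:
            d = replichore_distance(pos, genome).astype(float)
        else:
            d = clockwise_distance(pos, genome).astype(float)
        lam = self.baseline * (
            1.0 + self.amplitude * np.cos(2.0 * np.pi * d / self.period + self.phase)
        )
        if self.hotspots:
            cw = clockwise_distance(pos, genome)
            on_cw = 2 * cw < genome.length
            rd = replichore_distance(pos, genome)
            for h in self.hotspots:
                in_interval = (rd >= h.start) & (rd < h.end)
                if h.replichore == "clockwise":
                    lam = np.where(in_interval & on_cw, lam * h.fold, lam)
                else:
                    lam = np.where(in_interval & ~on_cw, lam * h.fold, lam)
        return lam

    def max_intensity(self) -> float:
        max_fold = max((h.fold for h in self.hotspots), default=1.0)
        return self.baseline * (1.0 + self.amplitude) * max(max_fold, 1.0)


def default_hotspots() -> tuple[Hotspot, Hotspot]:
    """Two asymmetric regional hotspots: one 600-700 kb from the origin on
    the clockwise replichore and one just before the terminal region on the
    counterclockwise replichore.  Fold-enrichments are free parameters
    (2.0 here), not estimates."""
    return (
        Hotspot("clockwise", 600_000, 700_000, 2.0),
        Hotspot("counterclockwise", 1_900_000, 2_000_000, 2.0),
    )


@dataclass(frozen=True)
class SpectrumModel:
    """Proportions over the six strand-collapsed substitution classes."""

    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (6,):
            raise ValueError("spectrum needs 6 class proportions")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("proportions must be nonnegative and sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(SUBSTITUTION_CLASSES))


# A mismatch-repair-deficient spectrum dominated by A:T>G:C transitions,
# with G:C>A:T second and transversions rare.
DEFAULT_SPECTRUM = SpectrumModel((0.55, 0.33, 0.04, 0.03, 0.03, 0.02))


def generate_genome(
    length: int = _ECOLI_L,
    gc_content: float = 0.508,
    n_repeats: int = 30,
    repeat_length: int = 5_000,
    seed: int = 0,
    name: str = "synthetic_chr",
    with_sequence: bool = True,
) -> GenomeSpec:
    """Random circular genome with landmarks at study-relative positions.

    The sequence is i.i.d. with expected GC content ``gc_content``;
    ``n_repeats`` non-overlapping intervals of ``repeat_length`` bp emulate
    IS elements and rRNA operons (uncallable territory).  OriC and the four
    Ter sites are placed at the same relative positions they occupy on the
    E. coli chromosome, scaled to ``length``.
    """
    if not (0.0 < gc_content < 1.0):
        raise ValueError("gc_content must be in (0, 1)")
    if n_repeats < 0 or repeat_length <= 0:
        raise ValueError("invalid repeat parameters")
    if n_repeats * repeat_length >= length:
        raise ValueError(
            f"cannot pack {n_repeats} repeats of {repeat_length} bp into "
            f"{length} bp"
        )
    rng = np.random.default_rng(seed)
    sequence = None
    if with_sequence:
        pg = gc_content / 2.0
        pa = (1.0 - gc_content) / 2.0
        bases = rng.choice(
            np.frombuffer(b"ACGT", dtype="S1"), size=length, p=[pa, pg, pg, pa]
        )
        sequence = bases.tobytes().decode("ascii")

    repeats: list[tuple[int, int]] = []
    attempts = 0
    while len(repeats) < n_repeats:
        attempts += 1
        if attempts > 1000 * max(n_repeats, 1):
            raise RuntimeError(
                f"could not place {n_repeats} non-overlapping repeats of "
                f"{repeat_length} bp in {length} bp"
            )
        start = int(rng.integers(0, length - repeat_length))
        end = start + repeat_length
        if all(end <= s or start >= e for s, e in repeats):
            repeats.append((start, end))
    repeats.sort()

    oric = max(1, min(length, int(round(_REL_ORIC * length)) + 1))
    ter = {
        label: max(1, min(length, int(round(rel * length)) + 1))
        for label, rel in _REL_TER.items()
    }
    return GenomeSpec(
        name=name,
        length=length,
        oric=oric,
        ter_sites=ter,
        repeats=tuple(repeats),
        sequence=sequence,
    )


def _class_pair(cls: str) -> str:
    return "AT" if cls.startswith("A:T") else "GC"


def _ref_alt_for_class(cls: str, ref: str) -> tuple[str, str]:
    """Alt base for a class given the actual reference base at the site."""
    top_ref, top_alt = cls.split(">")  # e.g. 'A:T', 'G:C'
    purine_ref, purine_alt = top_ref[0], top_alt[0]
    if ref == purine_ref:
        return ref, purine_alt
    # ref is the complementary pyrimidine; mutate to the alt's pyrimidine
    comp = {"A": "T", "G": "C", "T": "A", "C": "G"}
    return ref, comp[purine_alt]


def sample_mutations(
    genome: GenomeSpec,
    intensity: WaveIntensityModel | None = None,
    spectrum: SpectrumModel | None = None,
    n_target: int = DEFAULT_N_MUTATIONS,
    n_lines: int = DEFAULT_N_LINES,
    seed: int = 0,
) -> MutationSet:
    """Draw mutations from the wave intensity with the requested spectrum.

    Positions are sampled by inhomogeneous thinning of uniform proposals
    over the callable (non-repeat) genome; each mutation's class is drawn
    from the spectrum, and with a sequence present its position is
    constrained (by proposal filtering) to a site whose reference base pair
    matches the class.  Without a sequence, placement is unconstrained and
    class labels are type-only.  Line identifiers are uniform over
    ``n_lines``.  Fixed seed gives byte-identical output.
    """
    intensity = intensity or WaveIntensityModel(hotspots=default_hotspots())
    spectrum = spectrum or DEFAULT_SPECTRUM
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    if n_target == 0:
        return MutationSet(genome, [])
    rng = np.random.default_rng(seed)

    callable_mask = ~genome.repeat_mask()
    if genome.sequence is not None:
        seq = genome.sequence_array()
        is_at = (seq == b"A") | (seq == b"T")
        pools = {
            "AT": np.flatnonzero(callable_mask & is_at),
            "GC": np.flatnonzero(callable_mask & ~is_at),
        }
    else:
        pools = {"any": np.flatnonzero(callable_mask)}
    if all(len(v) == 0 for v in pools.values()):
        raise ValueError("no callable sites to place mutations on")

    classes = rng.choice(
        len(SUBSTITUTION_CLASSES), size=n_target, p=np.asarray(spectrum.proportions)
    )
    lam_max = intensity.max_intensity()
    positions = np.empty(n_target, dtype=np.int64)
    for pair, pool in pools.items():
        if pair == "any":
            which = np.arange(n_target)
        else:
            which = np.flatnonzero(
                [_class_pair(SUBSTITUTION_CLASSES[c]) == pair for c in classes]
            )
        need = len(which)
        if need == 0:
            continue
        if len(pool) == 0:
            raise ValueError(f"spectrum requires {pair} sites but none are callable")
        accepted: list[np.ndarray] = []
        got = 0
        while got < need:
            m = max(2 * (need - got), 64)
            props = pool[rng.integers(0, len(pool), size=m)]
            lam = intensity.intensity(props, genome)
            if np.all(lam <= 0):
                raise ValueError("intensity is zero everywhere on the pool")
            keep = props[rng.random(m) * lam_max < lam]
            accepted.append(keep)
            got += len(keep)
        positions[which] = np.concatenate(accepted)[:need]

    line_ids = rng.integers(1, n_lines + 1, size=n_target)
    records = []
    for pos, cls_i, line in zip(positions, classes, line_ids):
        cls = SUBSTITUTION_CLASSES[cls_i]
        if genome.sequence is not None:
            ref = genome.sequence[pos]
        else:
            ref = "A" if _class_pair(cls) == "AT" else "G"
        ref, alt = _ref_alt_for_class(cls, ref)
        records.append(
            MutationRecord(
                position=int(pos), ref_base=ref, alt_base=alt, line_id=f"L{line:02d}"
            )
        )
    return MutationSet(genome, records)


def generate_feature_tracks(
    genome: GenomeSpec,
    intensity: WaveIntensityModel,
    couplings: Sequence[tuple[str, float, float, str]],
    config: BinConfig | None = None,
    seed: int = 0,
) -> dict[str, BinnedTrack]:
    """Per-bin feature tracks linearly coupled to the mutation intensity.

    Each coupling is (name, slope, noise_sd, aggregation_mode): the track
    value in a bin is slope * (bin-mean relative intensity) + Gaussian
    noise.  ``aggregation_mode`` ('sum' or 'mean') is recorded on the track
    so downstream handling matches the discrete-summed / qualitative-
    averaged convention.  Slope 0 yields pure-noise null features.
    """
    if not couplings:
        raise ValueError("need at least one coupling")
    config = config or BinConfig()
    rng = np.random.default_rng(seed)
    # bin-mean relative intensity from a 1-kb position grid
    grid = np.arange(0, genome.length, 1000, dtype=np.int64)
    lam = intensity.intensity(grid, genome)
    lam = lam / lam.mean()
    from .binning import bin_positions  # local import to avoid cycle at load

    idx = bin_positions(grid, genome, config)
    sums = np.bincount(idx, weights=lam, minlength=config.n_bins)
    counts = np.bincount(idx, minlength=config.n_bins)
    bin_mean = sums / np.maximum(counts, 1)

    tracks: dict[str, BinnedTrack] = {}
    for name, slope, noise_sd, mode in couplings:
        if mode not in ("sum", "mean"):
            raise ValueError(f"aggregation_mode must be 'sum' or 'mean', got {mode!r}")
        values = slope * bin_mean + rng.normal(0.0, noise_sd, size=config.n_bins)
        tracks[name] = BinnedTrack(config, values, mode, genome.length, name)
    return tracks
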