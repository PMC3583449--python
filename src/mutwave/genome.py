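"""Circular-genome coordinate system, replichore geometry, and core domain types.

A circular bacterial chromosome is replicated bidirectionally from a single
origin (OriC).  The two replication forks travel in opposite directions and
meet in the terminus region, which is bracketed by polar fork-trap Ter sites.
Each half of the chromosome replicated by one fork is a *replichore*.  All
spatial analyses in this package are anchored at OriC and expressed either in
clockwise distance from the origin or in replichore coordinates (distance
travelled by the fork that replicates the position).

Coordinate conventions
----------------------
Internal coordinates are 0-based, half-open.  All file I/O converts
explicitly: mutation tables and VCF are 1-based, BED is 0-based half-open.
Landmark attributes on :class:`GenomeSpec` (``oric``, ``ter_sites``) are kept
1-based, matching how positions are printed in the literature; use
:func:`to_internal` to convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoordinateError",
    "GenomeSpec",
    "MutationRecord",
    "MutationSet",
    "Replichore",
    "ReplichoreCoordinate",
    "SUBSTITUTION_CLASSES",
    "substitution_class",
    "clockwise_distance",
    "replichore_of",
    "to_internal",
    "to_one_based",
    "ecoli_genome",
]

BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The six strand-collapsed base-pair substitution classes, in conventional
#: order (transitions first).
SUBSTITUTION_CLASSES = (
    "A:T>G:C",
    "G:C>A:T",
    "A:T>T:A",
    "A:T>C:G",
    "G:C>T:A",
    "G:C>C:G",
)


class CoordinateError(ValueError):
    """A genomic position or interval is outside the chromosome."""


class Replichore(str, Enum):
    """Direction of travel of the replication fork covering a position."""

    CLOCKWISE = "clockwise"
    COUNTERCLOCKWISE = "counterclockwise"


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of a single circular chromosome.

    Parameters
    ----------
    name : str
        Chromosome label, used to validate input tables.
    length : int
        Chromosome length in bp.
    oric : int
        1-based position of the replication origin.
    ter_sites : mapping of str to int
        1-based positions of replication termination (fork trap) sites,
        e.g. TerA-TerD.
    repeats : sequence of (int, int)
        0-based half-open intervals of repeated elements (IS elements,
        rRNA operons) within which variant calling is impossible.
    sequence : str, optional
        Uppercase base string of length ``length``.
    macrodomains : mapping of str to (int, int), optional
        Labelled 0-based half-open intervals (static annotation only).
    """

    name: str
    length: int
    oric: int
    ter_sites: Mapping[str, int] = field(default_factory=dict)
    repeats: Sequence[tuple[int, int]] = ()
    sequence: str | None = None
    macrodomains: Mapping[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        if not (1 <= self.oric <= self.length):
            raise CoordinateError(
                f"oric={self.oric} outside [1, {self.length}]"
            )
        for label, pos in self.ter_sites.items():
            if not (1 <= pos <= self.length):
                raise CoordinateError(f"{label}={pos} outside [1, {self.length}]")
        for start, end in self.repeats:
            if not (0 <= start < end <= self.length):
                raise CoordinateError(
                    f"repeat interval [{start}, {end}) invalid on length "
                    f"{self.length}"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != genome length "
                f"{self.length}"
            )

    @property
    def oric0(self) -> int:
        """0-based internal position of OriC."""
        return self.oric - 1

    def repeat_mask(self) -> np.ndarray:
        """Boolean array of length ``length``, True inside repeat intervals."""
        mask = np.zeros(self.length, dtype=bool)
        for start, end in self.repeats:
            mask[start:end] = True
        return mask

    def sequence_array(self) -> np.ndarray:
        """Sequence as a 1-byte character array; raises if no sequence."""
        if self.sequence is None:
            raise ValueError(f"genome {self.name!r} carries no sequence")
        return np.frombuffer(self.sequence.encode("ascii"), dtype="S1")


def to_internal(position_1based: int, genome: GenomeSpec) -> int:
    """Convert a 1-based position to the internal 0-based coordinate."""
    if not (1 <= position_1based <= genome.length):
        raise CoordinateError(
            f"position {position_1based} outside [1, {genome.length}] on "
            f"genome {genome.name!r}"
        )
    return position_1based - 1


def to_one_based(position: int, genome: GenomeSpec) -> int:
    """Inverse of :func:`to_internal`."""
    if not (0 <= position < genome.length):
        raise CoordinateError(
            f"internal position {position} outside [0, {genome.length}) on "
            f"genome {genome.name!r}"
        )
    return position + 1


def clockwise_distance(position, genome: GenomeSpec):
    """Distance in bp from OriC moving clockwise, in [0, length).

    Accepts a scalar or array of internal (0-based) positions.  The clockwise
    replichore is the one whose fork moves in the direction of increasing
    genomic coordinate from OriC.
    """
    pos = np.asarray(position)
    if np.any(pos < 0) or np.any(pos >= genome.length):
        bad = pos[(pos < 0) | (pos >= genome.length)]
        raise CoordinateError(
            f"position(s) {np.atleast_1d(bad)[:5].tolist()} outside "
            f"[0, {genome.length})"
        )
    d = (pos - genome.oric0) % genome.length
    return d if isinstance(position, np.ndarray) else int(d)


@dataclass(frozen=True)
class ReplichoreCoordinate:
    """Position expressed as fork-travel distance on one replichore."""

    replichore: Replichore
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("replichore distance must be nonnegative")


def replichore_of(position: int, genome: GenomeSpec) -> ReplichoreCoordinate:
    """Assign a position to a replichore and its fork-travel distance.

    Positions strictly closer to OriC clockwise belong to the clockwise
    replichore; the midpoint (exactly length/2 from OriC) is assigned to the
    counterclockwise replichore — an arbitrary but fixed convention.
    """
    d = clockwise_distance(position, genome)
    if 2 * d < genome.length:
        return ReplichoreCoordinate(Replichore.CLOCKWISE, d)
    return ReplichoreCoordinate(Replichore.COUNTERCLOCKWISE, genome.length - d)


def replichore_distance(position, genome: GenomeSpec):
    """Vectorised fork-travel distance (min of the two arc distances).

    The midpoint convention matches :func:`replichore_of`: at exactly
    length/2 the counterclockwise distance (length/2) is returned.
    """
    d = clockwise_distance(np.asarray(position), genome)
    return np.where(2 * d < genome.length, d, genome.length - d)


def substitution_class(ref_base: str, alt_base: str) -> str:
    """Strand-collapsed class of a substitution, e.g. ('T','C') -> 'A:T>G:C'.

    Classes are reported with the purine of the mutated pair as A or G, so a
    T>C change is collapsed to its complement A>G, i.e. class A:T>G:C.
    """
    ref, alt = ref_base.upper(), alt_base.upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid bases {ref_base!r}>{alt_base!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    if ref in "CT":  # collapse pyrimidine-strand mutation to its complement
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    # each side is written purine-first: base then its pairing partner
    return f"{ref}:{ref.translate(_COMPLEMENT)}>{alt}:{alt.translate(_COMPLEMENT)}"


@dataclass(frozen=True)
class MutationRecord:
    """One base-pair substitution call.

    ``position`` is stored 0-based (input tables are 1-based; loaders
    convert).  ``line_id`` identifies the mutation-accumulation line the call
    came from; the spatial analyses pool all lines.
    """

    position: int
    ref_base: str
    alt_base: str
    line_id: str = ""

    def __post_init__(self) -> None:
        # class computation validates the bases
        substitution_class(self.ref_base, self.alt_base)

    @property
    def substitution_class(self) -> str:
        return substitution_class(self.ref_base, self.alt_base)


class MutationSet:
    """A collection of base-pair substitutions on one genome.

    Provides vectorised position access and the derived 6-class
    strand-collapsed mutational spectrum.
    """

    def __init__(self, genome: GenomeSpec, records: Sequence[MutationRecord]):
        self.genome = genome
        self.records = list(records)
        for rec in self.records:
            if not (0 <= rec.position < genome.length):
                raise CoordinateError(
                    f"mutation position {rec.position} outside "
                    f"[0, {genome.length})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def positions(self) -> np.ndarray:
        """Internal 0-based positions, in record order."""
        return np.fromiter(
            (r.position for r in self.records), dtype=np.int64, count=len(self)
        )

    @property
    def spectrum(self) -> pd.Series:
        """Proportion of mutations in each of the six substitution classes.

        Sums to 1 for a nonempty set; all-zero for an empty one.
        """
        counts = pd.Series(0.0, index=list(SUBSTITUTION_CLASSES))
        for rec in self.records:
            counts[rec.substitution_class] += 1
        total = counts.sum()
        return counts / total if total else counts

    def spectrum_counts(self) -> pd.Series:
        counts = pd.Series(0, index=list(SUBSTITUTION_CLASSES), dtype=int)
        for rec in self.records:
            counts[rec.substitution_class] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """1-based tabular view (chrom, pos, ref, alt, line_id)."""
        return pd.DataFrame(
            {
                "chrom": self.genome.name,
                "pos": [r.position + 1 for r in self.records],
                "ref": [r.ref_base for r in self.records],
                "alt": [r.alt_base for r in self.records],
                "line_id": [r.line_id for r in self.records],
            }
        )


# E. coli K-12 MG1655 (NC_000913.2) geometry with kb-rounded landmarks:
# OriC at 3924 kb; fork-trap sites TerD 1279 kb, TerA 1340 kb, TerC 1607 kb,
# TerB 1682 kb.  Clockwise-moving forks halt at TerC/TerB, counterclockwise
# ones at TerA/TerD.
ECOLI_LENGTH = 4_641_652
ECOLI_ORIC = 3_924_000
ECOLI_TER_SITES = {
    "TerD": 1_279_000,
    "TerA": 1_340_000,
    "TerC": 1_607_000,
    "TerB": 1_682_000,
}


def ecoli_genome(
    length: int = ECOLI_LENGTH,
    sequence: str | None = None,
    repeats: Sequence[tuple[int, int]] = (),
) -> GenomeSpec:
    """The packaged E. coli K-12 chromosome geometry.

    ``length`` defaults to the exact NC_000913.2 length; pass 4_640_000 for
    the kb-rounded geometry.  Both yield the same origin-anchored bin
    assignments for the four Ter landmarks under the default 46-bin scheme
    (TerD in bin 20, TerA in bin 21, TerC and TerB in bin 24).
    """
    return GenomeSpec(
        name="NC_000913.2",
        length=length,
        oric=ECOLI_ORIC,
        ter_sites=dict(ECOLI_TER_SITES),
        repeats=tuple(repeats),
        sequence=sequence,
    )
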