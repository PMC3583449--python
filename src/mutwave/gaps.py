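"""Inter-mutation gap statistics and the test against spatial randomness.

If mutations fell uniformly at random on the chromosome, the sizes of the
gaps between adjacent mutations would follow an exponential distribution
with mean = chromosome length / number of mutations.  Because calls inside
large repeated elements (IS elements, rRNA operons) are impossible, every
gap whose interior overlaps such a repeat is removed before testing; the
mean gap is then effective length / retained count.

Duplicate positions (the same site mutated in two lines) produce zero-length
gaps and are kept by default — they are genuine recurrences and contribute
to short-range clustering; pass ``collapse_duplicates=True`` to drop them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import MutationSet

__all__ = [
    "GapSet",
    "ExponentialTest",
    "compute_gaps",
    "exclude_repeat_gaps",
    "exponential_test",
]


class InsufficientDataError(ValueError):
    """Too few mutations or gaps to compute the requested statistic."""


@dataclass
class GapSet:
    """Circular inter-mutation gaps with exclusion bookkeeping.

    ``gaps`` are sorted bp distances between adjacent mutations around the
    circle.  ``gap_starts``/``gap_ends`` give each gap's open interval in
    genome coordinates (the wrap-around gap has end > genome length, taken
    modulo the length).  Before any exclusion the gaps sum to the genome
    length and there is one gap per mutation.
    """

    gaps: np.ndarray
    genome_length: int
    gap_starts: np.ndarray | None = None
    gap_ends: np.ndarray | None = None
    excluded_gaps: int = 0
    excluded_length: int = 0

    def __post_init__(self) -> None:
        self.gaps = np.asarray(self.gaps, dtype=np.int64)
        order = np.argsort(self.gaps, kind="stable")
        self.gaps = self.gaps[order]
        if self.gap_starts is not None:
            self.gap_starts = np.asarray(self.gap_starts, dtype=np.int64)[order]
        if self.gap_ends is not None:
            self.gap_ends = np.asarray(self.gap_ends, dtype=np.int64)[order]

    @property
    def n_retained(self) -> int:
        return len(self.gaps)

    @property
    def effective_length(self) -> int:
        return self.genome_length - self.excluded_length

    @property
    def mean_gap(self) -> float:
        if self.n_retained == 0:
            raise InsufficientDataError("no gaps retained")
        return self.effective_length / self.n_retained


def compute_gaps(mutations: MutationSet, collapse_duplicates: bool = False) -> GapSet:
    """Circular successive differences between sorted mutation positions.

    With n positions on the circle there are n gaps (the last wraps around
    through the origin) summing exactly to the genome length.
    """
    pos = np.sort(mutations.positions)
    if collapse_duplicates:
        pos = np.unique(pos)
    if len(pos) < 2:
        raise InsufficientDataError(
            f"need >= 2 {'distinct ' if collapse_duplicates else ''}positions, "
            f"got {len(pos)}"
        )
    L = mutations.genome.length
    nxt = np.r_[pos[1:], pos[0] + L]
    gaps = nxt - pos
    order = np.argsort(gaps, kind="stable")
    return GapSet(
        gaps=gaps[order],
        genome_length=L,
        gap_starts=pos[order],
        gap_ends=nxt[order],
    )


def exclude_repeat_gaps(
    gapset: GapSet, repeats: Sequence[tuple[int, int]]
) -> GapSet:
    """Drop every gap whose open interior overlaps a repeat interval.

    Repeats are 0-based half-open intervals.  A gap (a, b) — open, because
    the mutations at its ends are real calls — is excluded when a repeat
    [s, e) intersects its interior: s < b and e > a, evaluated on the circle
    (the wrap-around gap is checked on both of its linear segments).
    Boundary touching does not exclude.  The retained count and effective
    length shrink by the excluded gaps.
    """
    if gapset.gap_starts is None or gapset.gap_ends is None:
        raise ValueError("gap intervals unavailable; GapSet was built from raw gaps")
    if len(repeats) == 0:
        return gapset
    L = gapset.genome_length
    starts = np.asarray([s for s, _ in repeats], dtype=np.int64)
    ends = np.asarray([e for _, e in repeats], dtype=np.int64)

    a = gapset.gap_starts
    b = gapset.gap_ends  # may exceed L for the wrap gap
    # direct overlap, plus the same repeats shifted by +L to catch the
    # wrap-around gap whose interval extends past the origin
    hit = np.zeros(len(a), dtype=bool)
    for shift in (0, L):
        s = starts[None, :] + shift
        e = ends[None, :] + shift
        hit |= np.any((s < b[:, None]) & (e > a[:, None]), axis=1)
    excluded = int(hit.sum())
    excluded_len = int(gapset.gaps[hit].sum())
    return GapSet(
        gaps=gapset.gaps[~hit],
        genome_length=L,
        gap_starts=a[~hit],
        gap_ends=b[~hit],
        excluded_gaps=gapset.excluded_gaps + excluded,
        excluded_length=gapset.excluded_length + excluded_len,
    )


@dataclass
class ExponentialTest:
    chi2: float
    df: int
    p_value: float
    n_classes: int
    mean_gap: float
    qq_table: pd.DataFrame
    observed: np.ndarray
    expected: np.ndarray


def exponential_test(gapset: GapSet, n_quantile_bins: int = 20) -> ExponentialTest:
    """Chi-square test of the gaps against the exponential expectation.

    Size classes are the equal-probability quantile intervals of
    Exp(mean = effective length / retained count), so every class has the
    same expected count n/K; the statistic is referred to chi-square with
    K - 1 degrees of freedom (the mean is fixed by the genome length and
    mutation count, not fitted).  A Q-Q summary by quartile accompanies the
    test: under randomness observed and theoretical quantiles agree.
    """
    n = gapset.n_retained
    if n < 20:
        raise InsufficientDataError(f"need >= 20 gaps for the chi-square test, got {n}")
    K = int(n_quantile_bins)
    if n / K < 5:
        K = max(2, n // 5)
    mu = gapset.mean_gap
    inner = -mu * np.log1p(-np.arange(1, K) / K)
    edges = np.r_[0.0, inner, np.inf]
    observed = np.histogram(gapset.gaps, bins=edges)[0].astype(float)
    expected = np.full(K, n / K)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = K - 1
    p = float(stats.chi2.sf(chi2, df))

    gaps = np.sort(gapset.gaps)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = -mu * np.log1p(-probs)
    quartile = np.minimum((probs * 4).astype(int) + 1, 4)
    qq = pd.DataFrame(
        {"quartile": quartile, "observed": gaps, "expected": theo}
    ).groupby("quartile").agg(
        observed_mean=("observed", "mean"),
        expected_mean=("expected", "mean"),
        n=("observed", "size"),
    ).reset_index()
    return ExponentialTest(
        chi2=chi2,
        df=df,
        p_value=p,
        n_classes=K,
        mean_gap=mu,
        qq_table=qq,
        observed=observed,
        expected=expected,
    )
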