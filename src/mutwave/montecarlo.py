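"""Spectrum-preserving Monte Carlo placement null and over-dispersion tests.

The null hypothesis is that mutations fall uniformly at random over the
callable genome.  Each simulated mutation first draws a strand-collapsed
substitution class from the observed spectrum and then a uniformly random
eligible site whose reference base matches that class (an A:T>G:C mutation
may land on an A or a T); sites inside repeat intervals are never eligible,
because calls there were impossible in the real data.  Without a genome
sequence the placement degrades to uniform over the callable territory.

Per-simulation bin-count variances summarise how much spatial structure pure
randomness produces; the observed variance is compared against that ensemble
and against the Poisson expectation (index of dispersion), and individual
simulated bin vectors are compared to the observed one by chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .binning import BinConfig, BinnedTrack, bin_positions
from .genome import GenomeSpec, MutationSet

__all__ = [
    "NullEnsemble",
    "DispersionTest",
    "PatternChi2",
    "simulate_null",
    "dispersion_test",
    "pattern_chi2",
]

logger = logging.getLogger(__name__)


@dataclass
class NullEnsemble:
    """Binned count vectors and their variances for n_sims random placements."""

    counts: np.ndarray  # shape (n_sims, n_bins)
    variances: np.ndarray  # per-sim sample variance of the bin counts
    n_mutations: int
    seed: int

    @property
    def n_sims(self) -> int:
        return self.counts.shape[0]

    def variance_summary(self) -> dict:
        v = self.variances
        return {
            "n_sims": int(self.n_sims),
            "mean_variance": float(v.mean()),
            "min_variance": float(v.min()),
            "max_variance": float(v.max()),
        }


def _eligible_sites(genome: GenomeSpec) -> dict[str, np.ndarray]:
    """Callable site arrays keyed by base pair ('AT', 'GC') or 'any'."""
    callable_mask = ~genome.repeat_mask()
    if genome.sequence is None:
        return {"any": np.flatnonzero(callable_mask)}
    seq = genome.sequence_array()
    is_at = (seq == b"A") | (seq == b"T")
    sites = {
        "AT": np.flatnonzero(callable_mask & is_at),
        "GC": np.flatnonzero(callable_mask & ~is_at),
    }
    return sites


def simulate_null(
    mutations: MutationSet | int,
    genome: GenomeSpec,
    n_sims: int = 1000,
    config: BinConfig | None = None,
    seed: int = 0,
) -> NullEnsemble:
    """Place mutations at random across the callable genome, n_sims times.

    ``mutations`` may be a :class:`MutationSet` (its size and spectrum are
    reproduced) or a plain integer count (uniform placement with no spectrum
    conditioning).  Each simulation conserves the total count exactly and is
    binned under ``config`` (default 46 origin-anchored bins).
    """
    config = config or BinConfig()
    rng = np.random.default_rng(seed)
    if isinstance(mutations, MutationSet):
        n_mut = len(mutations)
        spectrum = mutations.spectrum
    else:
        n_mut = int(mutations)
        spectrum = None
    if n_mut <= 0:
        raise ValueError(f"need a positive mutation count, got {n_mut}")

    sites = _eligible_sites(genome)
    if spectrum is None or "any" in sites:
        if spectrum is not None and "any" in sites:
            logger.info(
                "genome has no sequence: spectrum-conditioned placement "
                "falls back to uniform"
            )
        pool = sites.get("any")
        if pool is None:
            pool = np.sort(np.r_[sites["AT"], sites["GC"]])
        if len(pool) == 0:
            raise ValueError("no eligible sites outside repeat intervals")
        draws = rng.integers(0, len(pool), size=(n_sims, n_mut))
        positions = pool[draws]
    else:
        for pair, arr in sites.items():
            at_mass = spectrum[[c for c in spectrum.index if c.startswith("A:T")]].sum()
            mass = at_mass if pair == "AT" else 1.0 - at_mass
            if len(arr) == 0 and mass > 0:
                raise ValueError(
                    f"no eligible {pair} sites but the spectrum places "
                    f"probability {mass:.3f} on {pair} classes"
                )
        # class only matters through its base pair; draw the number of
        # A:T-pair mutations per sim and fill positions pair-wise
        p_at = float(
            spectrum[[c for c in spectrum.index if c.startswith("A:T")]].sum()
        )
        n_at = rng.binomial(n_mut, p_at, size=n_sims)
        positions = np.empty((n_sims, n_mut), dtype=np.int64)
        for i in range(n_sims):
            k = n_at[i]
            positions[i, :k] = sites["AT"][rng.integers(0, len(sites["AT"]), size=k)]
            positions[i, k:] = sites["GC"][
                rng.integers(0, len(sites["GC"]), size=n_mut - k)
            ]

    idx = bin_positions(positions.ravel(), genome, config).reshape(n_sims, n_mut)
    flat = idx + config.n_bins * np.arange(n_sims)[:, None]
    counts = np.bincount(
        flat.ravel(), minlength=n_sims * config.n_bins
    ).reshape(n_sims, config.n_bins)
    variances = counts.var(axis=1, ddof=1)
    return NullEnsemble(
        counts=counts, variances=variances, n_mutations=n_mut, seed=seed
    )


@dataclass(frozen=True)
class DispersionTest:
    mean: float
    variance: float
    statistic: float
    df: int
    p_value: float


def dispersion_test(track: BinnedTrack) -> DispersionTest:
    """Index-of-dispersion test of binned counts against the Poisson.

    Under uniform random placement the counts are (approximately) Poisson
    with variance equal to the mean, and (n-1) * s^2 / mean follows a
    chi-square with n - 1 degrees of freedom.  The reported p-value is
    two-sided: both over-dispersion (clustering/waves) and under-dispersion
    (regularity) count as departures.
    """
    n = track.n_bins
    if n < 2:
        raise ValueError("dispersion test needs >= 2 bins")
    mean = float(track.values.mean())
    if mean == 0:
        raise ValueError("dispersion undefined: zero mean count")
    variance = float(track.values.var(ddof=1))
    statistic = (n - 1) * variance / mean
    df = n - 1
    upper = stats.chi2.sf(statistic, df)
    lower = stats.chi2.cdf(statistic, df)
    p = float(min(1.0, 2.0 * min(upper, lower)))
    return DispersionTest(mean=mean, variance=variance, statistic=statistic, df=df, p_value=p)


@dataclass(frozen=True)
class PatternChi2:
    chi2: float
    df: int
    p_value: float


def pattern_chi2(simulated: np.ndarray, observed: np.ndarray) -> PatternChi2:
    """Chi-square distance of a simulated bin vector from the observed one.

    Statistic = sum (sim_i - obs_i)^2 / obs_i with df = n_bins - 1 and an
    upper-tail p-value; a simulated random placement that differs
    significantly from the observed pattern is evidence the pattern is not
    itself random.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"shape mismatch: {sim.shape} vs {obs.shape}")
    if np.any(obs <= 0):
        raise ValueError(
            "observed bin(s) with zero count: merge bins before the "
            "chi-square comparison"
        )
    chi2 = float(((sim - obs) ** 2 / obs).sum())
    df = len(obs) - 1
    return PatternChi2(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))
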