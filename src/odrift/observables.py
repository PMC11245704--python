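"""Observables on simulation output and calibration of mu and E_part.

The central observable is the heteroplasmy probability ``P = T_det /
T_total``: the fraction of simulated time (in stem-cell divisions) during
which the focal locus is detectably heteroplasmic in a sequenced tissue
sample.  Multiplying ``P`` by the number of neutral positions screened across
a cohort gives the expected number of observed heteroplasmic sites, which is
the quantity the partitioning-error calibration matches against data.

The substitution-rate observable counts fixations per simulated time and
scales them to a divergence period; because the substitution count is linear
in the mutation rate in the small-mu regime, the mutation rate is fitted by
linear-through-origin inversion of a handful of probe simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .meristem_model import BottleneckRegime, ModelParams, Population
from .simulator import ExperimentResult, run_experiment

__all__ = [
    "SequencingScheme",
    "RateEstimate",
    "tissue_allele_frequency",
    "is_detectable",
    "heteroplasmy_probability",
    "expected_heteroplasmic_sites",
    "substitutions_per_period",
    "fit_mu",
    "calibrate_mu",
    "fit_epart",
    "heteroplasmy_age_cdf",
    "outcome_sem",
    "sweep_parameter",
]

#: divergence time of the Atlantic and Alaskan eelgrass populations (years)
DEFAULT_DIVERGENCE_YEARS = 243_300.0


@dataclass(frozen=True)
class SequencingScheme:
    """Per-stem-cell progeny fractions of the sequenced tissue sample."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)

    @classmethod
    def equal(cls, N: int) -> "SequencingScheme":
        return cls(np.full(N, 1.0 / N))

    @classmethod
    def tunica_corpus_ratio(cls, N: int, ratio: float) -> "SequencingScheme":
        """Tunica : corpus progeny ratio (sweeps use 16 down to 1/16)."""
        half = N // 2
        w = np.empty(N)
        w[:half] = ratio / half
        w[half:] = 1.0 / half
        return cls(w / w.sum())


def tissue_allele_frequency(
    pop: Population, scheme: Optional[SequencingScheme] = None
) -> float:
    """Weighted mean of per-cell mutant frequencies in the sequenced sample.

    During proliferation the weights are renormalised over the live cells.
    """
    freqs = pop.cell_frequencies()
    live = pop.alive
    if scheme is None:
        return float(freqs[live].mean())
    w = scheme.weights
    if w.shape != (pop.params.N,):
        raise ValueError("scheme weights incompatible with the population layout")
    ww = w[live]
    if ww.sum() == 0:
        raise ValueError("all live cells have zero sequencing weight")
    return float((ww * freqs[live]).sum() / ww.sum())


def is_detectable(af: float, L: float) -> bool:
    """True when both alleles reach the detection limit: L <= af <= 1 - L.

    Homoplasmic states (af in {0, 1}) are never detectable heteroplasmy,
    including at L = 0.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError("allele frequency outside [0, 1]")
    return 0.0 < af < 1.0 and L <= af <= 1.0 - L


def heteroplasmy_probability(res: ExperimentResult) -> tuple[float, float]:
    """``(P, sem)``: detectable time fraction and its standard error.

    The SEM is taken over the distribution of per-mutation detectable spans
    (each injected mutation contributes one outcome).
    """
    if res.T_total <= 0:
        raise ValueError("empty experiment: T_total is zero")
    return res.P, res.sem_P


def expected_heteroplasmic_sites(P: float, total_neutral_positions: float) -> float:
    """Expected heteroplasmic-site count over the cohort's neutral positions."""
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be a probability")
    return P * total_neutral_positions


def substitutions_per_period(
    res: ExperimentResult,
    params: Optional[ModelParams] = None,
    years: float = DEFAULT_DIVERGENCE_YEARS,
) -> float:
    """Expected fixations in one locus over ``years`` of simulated time."""
    if res.T_total <= 0:
        raise ValueError("empty experiment: T_total is zero")
    params = params or res.params
    return res.n_fixed * (years * params.divisions_per_year) / res.T_total


def outcome_sem(per_mutation_values: Sequence[float]) -> float:
    """Standard error of the mean of per-mutation outcome values."""
    v = np.asarray(per_mutation_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two outcomes for a SEM")
    return float(v.std(ddof=1) / math.sqrt(v.size))


# ---------------------------------------------------------------------------
# Mutation-rate calibration
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    """Fitted mutation rate from substitution-count probes.

    ``probes`` holds ``(mu, substitutions-per-locus-per-period)`` pairs;
    ``regime_used`` records whether the fit interpolated between bracketing
    probes or extrapolated along the through-origin line.
    """

    mu_hat: float
    target_substitutions: float
    T_divergence: float
    G: float
    probes: list[tuple[float, float]] = field(default_factory=list)
    regime_used: str = "linear-through-origin"
    sem: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mu_hat <= 0:
            raise ValueError("fitted mutation rate must be positive")


def fit_mu(
    target: float, probes: Sequence[tuple[float, float]],
    T_divergence: float = DEFAULT_DIVERGENCE_YEARS, G: float = 40.0,
) -> RateEstimate:
    """Invert the linear mu -> substitution-count response for a target count.

    With a single probe the response is assumed proportional; with several,
    the through-origin slope is fitted by least squares.  The probe sequence
    must be non-decreasing in its response (linearity beyond noise).
    """
    probes = [(float(m), float(s)) for m, s in probes]
    if not probes:
        raise ValueError("at least one probe is required")
    mus = np.array([m for m, _ in probes])
    subs = np.array([s for _, s in probes])
    if (mus <= 0).any():
        raise ValueError("probe mutation rates must be positive")
    order = np.argsort(mus)
    s_sorted = subs[order]
    # tolerate Monte-Carlo jitter of ~50% of the local scale, no more
    if len(probes) > 1:
        drops = np.diff(s_sorted)
        scale = np.maximum(s_sorted[:-1], 1e-300)
        if (drops < -0.5 * scale).any():
            raise ValueError("probe responses are not monotone in mu beyond noise")
    slope = float((mus * subs).sum() / (mus * mus).sum())
    if slope <= 0:
        raise ValueError("no fixations observed in any probe; cannot fit mu")
    mu_hat = target / slope
    lo, hi = float(mus.min()), float(mus.max())
    regime = "interpolated" if lo <= mu_hat <= hi else "extrapolated-through-origin"
    return RateEstimate(
        mu_hat=mu_hat, target_substitutions=target,
        T_divergence=T_divergence, G=G,
        probes=probes, regime_used=regime,
    )


def calibrate_mu(
    params: ModelParams,
    regime: BottleneckRegime,
    target_substitutions: float,
    probe_mus: Sequence[float],
    rng: np.random.Generator,
    n_mutations: Optional[int] = None,
    years: float = DEFAULT_DIVERGENCE_YEARS,
) -> RateEstimate:
    """Run probe simulations at each mu and fit the rate for a target count.

    ``target_substitutions`` is the accumulated-mutation count per locus over
    the divergence period (e.g. 2.3e-4 for the mitochondrial genome).
    """
    probes = []
    sems = []
    for mu in probe_mus:
        res = run_experiment(params.evolve(mu=mu), regime, rng=rng,
                             n_mutations=n_mutations, keep_runs=False)
        s = substitutions_per_period(res, years=years)
        probes.append((mu, s))
        sems.append(s / math.sqrt(max(res.n_fixed, 1)))
    est = fit_mu(target_substitutions, probes, T_divergence=years, G=params.G)
    # Poisson error on the fixation counts propagated through the inversion
    rel = math.sqrt(sum((se / max(s, 1e-300)) ** 2 for (_, s), se in zip(probes, sems)))
    est.sem = est.mu_hat * rel / max(len(probes), 1)
    return est


# ---------------------------------------------------------------------------
# Partitioning-error calibration
# ---------------------------------------------------------------------------

def fit_epart(
    target_P: float,
    params: ModelParams,
    regime: BottleneckRegime,
    rng: np.random.Generator,
    grid: Optional[Sequence[float]] = None,
    n_mutations: int = 20000,
    max_bisect: int = 6,
) -> dict:
    """Find the partitioning-error window whose P brackets ``target_P``.

    P is monotone non-increasing in ``E_part`` (stricter partition keeps
    alleles segregating longer), so the log-spaced grid scan is followed by
    bisection in log space, stopping once the bracket's P values straddle the
    target within the simulation SEM.  Returns the bracketing interval with
    the measured P and SEM at each evaluated point.
    """
    if params.mode != "pt":
        raise ValueError("E_part calibration requires plastid mode")
    if grid is None:
        grid = [0.5, 0.05, 0.005, 0.0005]
    grid = sorted(set(float(g) for g in grid), reverse=True)
    if grid[0] > 0.5 or grid[-1] <= 0:
        raise ValueError("grid must lie in (0, 0.5]")

    evaluated: list[tuple[float, float, float]] = []  # (E, P, sem)

    def measure(e: float) -> tuple[float, float]:
        res = run_experiment(params.evolve(E_part=e), regime, rng=rng,
                             n_mutations=n_mutations, keep_runs=False)
        P, sem = heteroplasmy_probability(res)
        evaluated.append((e, P, sem))
        return P, sem

    p_hi_e, sem_hi = measure(grid[0])  # largest E -> smallest P
    if target_P <= p_hi_e + sem_hi:
        return {"interval": (grid[0], grid[0]), "evaluated": evaluated,
                "note": "target at or below P of the random-partition endpoint"}
    lo_e, hi_e = None, grid[0]
    p_lo = p_hi = p_hi_e
    for e in grid[1:]:
        P, sem = measure(e)
        if P >= target_P:
            lo_e, p_lo = e, P
            break
        hi_e, p_hi = e, P
    if lo_e is None:
        raise ValueError("target_P outside the achievable range of the grid: "
                         f"max P {max(p for _, p, _ in evaluated):.3g} < target {target_P:.3g}")
    for _ in range(max_bisect):
        mid = math.sqrt(lo_e * hi_e)
        P, sem = measure(mid)
        if abs(P - target_P) <= sem:
            lo_e = hi_e = mid
            break
        if P >= target_P:
            lo_e = mid
        else:
            hi_e = mid
    return {"interval": (min(lo_e, hi_e), max(lo_e, hi_e)), "evaluated": evaluated}


# ---------------------------------------------------------------------------
# Heteroplasmy age distribution
# ---------------------------------------------------------------------------

def heteroplasmy_age_cdf(
    res: ExperimentResult,
    params: Optional[ModelParams] = None,
    thresholds_years: Sequence[float] = (36.0, 100.0, 1000.0),
) -> dict[float, float]:
    """Fraction of detectable observations older than each age threshold.

    Every detectable division contributes one observation whose age is its
    offset since injection converted to years (1 year = N G divisions); the
    distribution is therefore length-biased by construction — a site that
    stays detectable longer is observed proportionally more often, exactly as
    it would be when sequencing at a random time point.
    """
    params = params or res.params
    if res.T_det == 0:
        raise ValueError("no detectable observations in this experiment")
    starts = res.det_run_starts
    lengths = res.det_run_lengths
    total = int(lengths.sum())
    out = {}
    per_year = params.divisions_per_year
    ends = starts + lengths  # exclusive
    for thr in thresholds_years:
        # an observation at offset k divisions has age k / (N G) years;
        # "at least thr years old" means k >= thr * N * G
        cutoff = int(math.ceil(thr * per_year))
        older = np.maximum(0, ends - np.maximum(starts, cutoff))
        out[float(thr)] = float(older.sum() / total)
    return out


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def sweep_parameter(
    base_params: ModelParams,
    regimes: Sequence[BottleneckRegime],
    name: str,
    values: Sequence,
    rng: np.random.Generator,
    n_mutations: int = 10000,
) -> pd.DataFrame:
    """P (with SEM) and fixation counts over a grid of one model parameter.

    ``name`` may be any ModelParams field (e.g. ``n``, ``L``, ``P_sym``,
    ``strat_ratio``, ``E_part``); plastid copy-number sweeps that must keep
    ``n = n_pt * n_rep`` consistent should pass explicit params instead.
    """
    rows = []
    for regime in regimes:
        for v in values:
            params = base_params.evolve(**{name: v})
            res = run_experiment(params, regime, rng=rng,
                                 n_mutations=n_mutations, keep_runs=False)
            P, sem = heteroplasmy_probability(res)
            rows.append({
                "regime": regime.name, "param": name, "value": v,
                "P": P, "sem_P": sem, "n_fixed": res.n_fixed,
                "n_mutations": res.n_mutations,
                "T_total": res.T_total, "T_det": res.T_det,
            })
    return pd.DataFrame(rows)
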