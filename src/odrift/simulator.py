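"""Mutation lifecycle engine and the run-until-M_fix experiment loop.

A simulation experiment follows one neutral genome locus through repeated
mutation / segregation cycles.  While the oDNA population is homoplasmic the
time to the next mutation is drawn from a geometric distribution whose success
probability combines the per-division mutational supply with the chance that
the mutant copy stays in the stem-cell niche at an asymmetric division:

    p = (1 - (1 - mu)**n) * (1 - F_asym + F_asym / 2)

    F_asym = (B_sex - N + 1) (B_branch - N/2) (1 - P_sym) / (B_sex B_branch)

with the bottleneck intervals expressed in population cell divisions
(1 year = N * G divisions).  A single mutant copy is then injected into a
uniformly chosen cell (and plastid) and its fate is simulated division by
division until loss or fixation, with sexual (1 surviving corpus cell) and
branching (10 surviving cells: one tunica row plus its aligned corpus row)
bottlenecks firing on deterministic clocks, each followed by proliferation
back to N cells.

Performance note: divisions in which a wild-type cell divides asymmetrically
leave the allele content untouched.  The engine therefore draws the number of
consecutive content-preserving divisions from the corresponding geometric law
and only executes the mechanics of "interesting" divisions (mutant-cell
divisions and symmetric divisions), which is an exact acceleration, not an
approximation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .meristem_model import (
    BottleneckRegime,
    ModelParams,
    Population,
    _apply_division,
    build_population,
    perform_division,
)

__all__ = [
    "MutationOutcome",
    "ExperimentResult",
    "asym_fraction",
    "mutation_probability",
    "draw_waiting_time",
    "apply_sexual_bottleneck",
    "apply_branching_bottleneck",
    "proliferate",
    "simulate_mutation_lifecycle",
    "run_experiment",
    "collect_event_times",
]

# assertion-only guard against non-terminating lifecycles
MAX_LIFECYCLE_DIVISIONS = 10**9


# ---------------------------------------------------------------------------
# Mutation supply
# ---------------------------------------------------------------------------

def asym_fraction(params: ModelParams, regime: BottleneckRegime) -> float:
    """Fraction of asymmetric cell divisions under a bottleneck regime.

    Bottleneck intervals are converted from years to population divisions
    (``years * N * G``); the bracket terms then subtract exactly the N-1
    (sexual) and N/2 (branching) symmetric regrowth divisions per cycle.  A
    disabled bottleneck contributes a factor of 1.
    """
    N = params.N
    f = 1.0 - params.P_sym
    b_sex = regime.sex_divisions(params)
    if b_sex is not None:
        if b_sex <= N - 1:
            raise ValueError("B_sex too short: no room to regrow after a sexual bottleneck")
        f *= (b_sex - N + 1) / b_sex
    b_branch = regime.branch_divisions(params)
    if b_branch is not None:
        if b_branch <= N / 2:
            raise ValueError("B_branch too short: no room to regrow after branching")
        f *= (b_branch - N / 2) / b_branch
    return f


def mutation_probability(params: ModelParams, regime: BottleneckRegime) -> float:
    """Per-division probability that a surviving de novo mutation arises.

    ``1 - (1 - mu)**n`` is the chance of at least one mutant replicon among
    the n copies of the dividing cell; the second factor accounts for the
    1/2 probability that the mutant lands in the differentiating daughter of
    an asymmetric division (so no extra coin is flipped at injection).
    """
    f = asym_fraction(params, regime)
    supply = -math.expm1(params.n * math.log1p(-params.mu)) if params.mu > 0 else 0.0
    return supply * (1.0 - f + f / 2.0)


def draw_waiting_time(p: float, rng: np.random.Generator) -> int:
    """Divisions until the next mutation event (shifted geometric, support >= 1)."""
    if not 0.0 < p <= 1.0:
        raise ValueError("mutation probability must be in (0, 1]; "
                         "p == 0 would wait forever")
    if p >= 1.0:
        return 1
    return int(rng.geometric(p))


# ---------------------------------------------------------------------------
# Bottlenecks and proliferation
# ---------------------------------------------------------------------------

def apply_sexual_bottleneck(pop: Population, rng: np.random.Generator) -> Population:
    """Reduce the population to one uniformly chosen corpus cell (seeding)."""
    corpus_live = [int(s) for s in pop.layout.corpus if pop.alive[s]]
    if not corpus_live:
        raise ValueError("sexual bottleneck on a population with an empty corpus")
    keep = corpus_live[rng.integers(len(corpus_live))]
    mask = np.zeros(pop.params.N, dtype=bool)
    mask[keep] = True
    pop.counts[~mask] = 0
    pop.alive[:] = mask
    pop.n_live = 1
    return pop


def apply_branching_bottleneck(pop: Population, rng: np.random.Generator) -> Population:
    """Keep one tunica row and its vertically aligned corpus row (branching)."""
    pair = pop.layout.row_pairs[rng.integers(2)]
    mask = np.zeros(pop.params.N, dtype=bool)
    mask[pair] = True
    mask &= pop.alive
    pop.counts[~mask] = 0
    pop.alive[:] = mask
    pop.n_live = int(mask.sum())
    return pop


def proliferate(
    pop: Population, params: ModelParams, rng: np.random.Generator
) -> tuple[Population, int]:
    """Regrow the population to N cells by symmetric growth divisions."""
    if pop.n_live >= params.N:
        raise ValueError("proliferate called on a full population")
    used = 0
    while pop.n_live < params.N:
        perform_division(pop, params, rng, phase="proliferation")
        used += 1
    return pop, used


# ---------------------------------------------------------------------------
# Outcome containers
# ---------------------------------------------------------------------------

@dataclass
class MutationOutcome:
    """Fate of one injected mutation.

    ``det_runs`` stores maximal runs of consecutive detectable division
    indices since injection as ``(start, length)`` pairs; index 0 is the
    sequencing snapshot taken at injection, before the first division.
    Event times (``t_*``) are division indices since injection, ``None``
    when the event did not occur before absorption/stop.
    """

    fate: str  # "fixed" | "lost" | "stopped"
    t_segregation: int
    origin_time: int = 0
    det_runs: list[tuple[int, int]] = field(default_factory=list)
    t_first_mutant_cell: Optional[int] = None
    t_first_homoplasmic_plastid: Optional[int] = None
    t_intraplastid_homoplasmy: Optional[int] = None

    @property
    def n_detectable(self) -> int:
        return sum(length for _, length in self.det_runs)

    @property
    def detectable_units(self) -> np.ndarray:
        if not self.det_runs:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.arange(s, s + l) for s, l in self.det_runs])


@dataclass
class ExperimentResult:
    """Aggregate of a run-until-``n N M_fix``-mutations experiment."""

    params: ModelParams
    regime: BottleneckRegime
    n_mutations: int
    n_fixed: int
    T_total: int
    T_det: int
    det_per_mutation: np.ndarray  # detectable divisions contributed by each mutation
    t_seg: np.ndarray  # segregation time of each mutation
    det_run_starts: np.ndarray  # concatenated detectable runs (ages bookkeeping)
    det_run_lengths: np.ndarray

    @property
    def P(self) -> float:
        """Heteroplasmy probability: detectable fraction of simulated time."""
        return self.T_det / self.T_total

    @property
    def sem_P(self) -> float:
        """SEM of P over the per-mutation detectable spans."""
        k = len(self.det_per_mutation)
        if k < 2:
            return float("nan")
        mean_tot = self.T_total / k
        return float(self.det_per_mutation.std(ddof=1) / math.sqrt(k) / mean_tot)

    def to_dict(self) -> dict:
        return {
            "regime": self.regime.name,
            "mode": self.params.mode,
            "n": self.params.n,
            "N": self.params.N,
            "mu": self.params.mu,
            "E_part": self.params.E_part,
            "L": self.params.L,
            "n_mutations": self.n_mutations,
            "n_fixed": self.n_fixed,
            "T_total": int(self.T_total),
            "T_det": int(self.T_det),
            "P": self.P,
            "sem_P": self.sem_P,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Lifecycle engine
# ---------------------------------------------------------------------------

class _Schedule:
    """Deterministic bottleneck clocks in absolute division time.

    Sexual events fire at multiples of the sexual interval; branching events
    are offset by half their interval so that no event ever falls inside the
    regrowth window of the other (the regrowth windows are N-1 and N/2
    divisions, far shorter than half of any interval used here).
    """

    def __init__(self, params: ModelParams, regime: BottleneckRegime) -> None:
        self.sex = regime.sex_divisions(params)
        self.branch = regime.branch_divisions(params)
        self.N = params.N
        if self.sex is not None and self.sex <= params.N - 1:
            raise ValueError("B_sex shorter than the sexual regrowth window")
        if self.branch is not None and self.branch <= params.N // 2:
            raise ValueError("B_branch shorter than the branching regrowth window")
        if self.sex is not None and self.branch is not None:
            # the half-interval offset must keep every event clear of the
            # other event's regrowth window
            if self.branch // 2 <= self.N:
                raise ValueError("B_branch too short to interleave with B_sex")
        self.branch_offset = self.branch // 2 if self.branch is not None else 0

    def next_sex(self, t: int) -> Optional[int]:
        if self.sex is None:
            return None
        return (t // self.sex + 1) * self.sex

    def next_branch(self, t: int) -> Optional[int]:
        if self.branch is None:
            return None
        return ((t - self.branch_offset) // self.branch + 1) * self.branch + self.branch_offset

    def next_event(self, t: int) -> tuple[Optional[int], Optional[str]]:
        """Earliest event strictly after t; sexual wins a (never-occurring) tie."""
        s, b = self.next_sex(t), self.next_branch(t)
        if s is None and b is None:
            return None, None
        if b is None or (s is not None and s <= b):
            return s, "sex"
        return b, "branch"

    def last_event_within(self, t: int, window_sex: int, window_branch: int):
        """Most recent event at or before t if t lies in its regrowth window."""
        if self.sex is not None:
            last = (t // self.sex) * self.sex
            if last > 0 and t - last < window_sex:
                return last, "sex"
        if self.branch is not None:
            last = ((t - self.branch_offset) // self.branch) * self.branch + self.branch_offset
            if last > 0 and t - last < window_branch:
                return last, "branch"
        return None, None

    def period(self) -> int:
        """Joint cycle length of the two clocks (1 when no bottlenecks)."""
        if self.sex is None and self.branch is None:
            return 1
        if self.sex is None:
            return self.branch
        if self.branch is None:
            return self.sex
        return math.lcm(self.sex, self.branch)


def _population_at_phase(
    params: ModelParams,
    schedule: _Schedule,
    t_abs: int,
    rng: np.random.Generator,
) -> Population:
    """Wild-type population state at absolute time ``t_abs``.

    Homoplasmic content is trivial, but the slot occupancy matters when a
    mutation arises during post-bottleneck regrowth: the reconstruction
    applies the most recent bottleneck and replays its regrowth divisions.
    """
    pop = build_population(params)
    last, kind = schedule.last_event_within(t_abs, params.N - 1, params.N // 2)
    if last is None:
        return pop
    if kind == "sex":
        apply_sexual_bottleneck(pop, rng)
    else:
        apply_branching_bottleneck(pop, rng)
    for _ in range(t_abs - last):
        perform_division(pop, params, rng, phase="proliferation")
    return pop


class _Tracker:
    """Incremental allele bookkeeping over the population slots."""

    __slots__ = ("pop", "params", "n", "cap", "tm", "slot_tot", "het",
                 "n_het_plastids", "mutant_set", "saw_mutant_cell",
                 "saw_homoplasmic_plastid")

    def __init__(self, pop: Population) -> None:
        self.pop = pop
        self.params = pop.params
        self.n = self.params.n
        self.cap = self.params.n_rep if pop.mode == "pt" else self.params.n
        self.slot_tot = pop.cell_mutants().astype(np.int64)
        self.tm = int(self.slot_tot.sum())
        if pop.mode == "pt":
            c = pop.counts
            self.het = ((c > 0) & (c < self.params.n_rep)).sum(axis=1).astype(np.int64)
            self.het[~pop.alive] = 0
        else:
            self.het = np.zeros(self.params.N, dtype=np.int64)
        self.n_het_plastids = int(self.het.sum())
        self.mutant_set = set(np.flatnonzero(self.slot_tot > 0).tolist())
        self.saw_mutant_cell = bool((self.slot_tot[pop.alive] == self.n).any())
        if pop.mode == "pt":
            self.saw_homoplasmic_plastid = bool(
                (pop.counts[pop.alive] == self.params.n_rep).any())
        else:
            self.saw_homoplasmic_plastid = self.saw_mutant_cell

    def refresh_slot(self, slot: int) -> None:
        pop = self.pop
        if not pop.alive[slot]:
            new_tot = 0
            new_het = 0
        elif pop.mode == "mt":
            new_tot = int(pop.counts[slot])
            new_het = 0
        else:
            row = pop.counts[slot]
            new_tot = int(row.sum())
            new_het = int(((row > 0) & (row < self.params.n_rep)).sum())
            if new_tot and (row == self.params.n_rep).any():
                self.saw_homoplasmic_plastid = True
        self.tm += new_tot - int(self.slot_tot[slot])
        self.n_het_plastids += new_het - int(self.het[slot])
        self.slot_tot[slot] = new_tot
        self.het[slot] = new_het
        if new_tot:
            self.mutant_set.add(slot)
            if new_tot == self.n:
                self.saw_mutant_cell = True
                if pop.mode == "mt":
                    self.saw_homoplasmic_plastid = True
        else:
            self.mutant_set.discard(slot)

    def refresh_all(self) -> None:
        pop = self.pop
        self.slot_tot = pop.cell_mutants().astype(np.int64)
        self.tm = int(self.slot_tot.sum())
        if pop.mode == "pt":
            c = pop.counts
            self.het = ((c > 0) & (c < self.params.n_rep)).sum(axis=1).astype(np.int64)
            self.het[~pop.alive] = 0
        self.n_het_plastids = int(self.het.sum())
        self.mutant_set = set(np.flatnonzero(self.slot_tot > 0).tolist())
        if (self.slot_tot[pop.alive] == self.n).any():
            self.saw_mutant_cell = True
        if pop.mode == "pt" and (pop.counts[pop.alive] == self.params.n_rep).any():
            self.saw_homoplasmic_plastid = True
        elif pop.mode == "mt" and self.saw_mutant_cell:
            self.saw_homoplasmic_plastid = True

    def tissue_af(self) -> float:
        pop = self.pop
        w = self.params.seq_weights
        if w is None:
            return self.tm / (self.n * pop.n_live)
        live = pop.alive
        ww = w[live]
        return float((ww * self.slot_tot[live] / self.n).sum() / ww.sum())


def _is_detectable(af: float, L: float) -> bool:
    return 0.0 < af < 1.0 and L <= af <= 1.0 - L


def simulate_mutation_lifecycle(
    params: ModelParams,
    schedule: BottleneckRegime,
    rng: np.random.Generator,
    origin_time: int = 0,
    stop_events: frozenset[str] | set[str] = frozenset(),
) -> MutationOutcome:
    """Inject one mutant copy at ``origin_time`` and follow it to absorption.

    The tissue allele frequency is observed after every division (and once at
    injection); runs of detectable observations (both alleles at frequency
    >= L) are recorded.  ``stop_events`` may name tracked events
    ('first_mutant_cell', 'first_homoplasmic_plastid',
    'intraplastid_homoplasmy') at which the lifecycle halts early (used by
    segregation-time studies; the fate is then 'stopped' unless absorption
    happened first).
    """
    sched = _Schedule(params, schedule)
    pop = _population_at_phase(params, sched, origin_time, rng)
    track = _Tracker(pop)

    # inject one mutant copy into a uniformly chosen live cell (and plastid)
    live = pop.live_slots()
    host = int(live[rng.integers(len(live))])
    if pop.mode == "mt":
        pop.counts[host] += 1
    else:
        pop.counts[host, rng.integers(params.n_pt)] += 1
    track.refresh_slot(host)

    out = MutationOutcome(fate="stopped", t_segregation=0, origin_time=origin_time)
    L = params.L
    t = 0  # divisions since injection
    t_abs = origin_time
    run_start = -1  # open detectable run start, -1 when closed

    def observe(af: float, count: int = 1) -> None:
        nonlocal run_start
        if count <= 0:
            return
        if _is_detectable(af, L):
            if run_start < 0:
                run_start = t - count + 1
        elif run_start >= 0:
            out.det_runs.append((run_start, t - count + 1 - run_start))
            run_start = -1

    def note_events() -> bool:
        """Record first-passage events; return True if a stop event fired."""
        hit = False
        if track.saw_mutant_cell and out.t_first_mutant_cell is None:
            out.t_first_mutant_cell = t
            hit |= "first_mutant_cell" in stop_events
        if track.saw_homoplasmic_plastid and out.t_first_homoplasmic_plastid is None:
            out.t_first_homoplasmic_plastid = t
            hit |= "first_homoplasmic_plastid" in stop_events
        if (pop.mode == "pt" and track.n_het_plastids == 0 and track.tm > 0
                and out.t_intraplastid_homoplasmy is None):
            out.t_intraplastid_homoplasmy = t
            hit |= "intraplastid_homoplasmy" in stop_events
        return hit

    def absorbed() -> Optional[str]:
        if track.tm == 0:
            return "lost"
        if track.tm == params.n * pop.n_live:
            return "fixed"
        return None

    observe(track.tissue_af())
    stop = note_events()
    fate = absorbed()

    while fate is None and not stop:
        assert t < MAX_LIFECYCLE_DIVISIONS, "lifecycle exceeded the step cap"
        if pop.n_live < params.N:
            # proliferation: every division is a symmetric growth division
            perform_division(pop, params, rng, phase="proliferation")
            track.refresh_all()
            t += 1
            t_abs += 1
            observe(track.tissue_af())
            stop = note_events()
            fate = absorbed()
            continue

        event_t, event_kind = sched.next_event(t_abs)
        gap = (event_t - t_abs) if event_t is not None else None

        k_m = len(track.mutant_set)
        p_interesting = k_m / params.N + (1.0 - k_m / params.N) * params.P_sym
        # j = index (1-based from now) of the next content-changing division
        j = int(rng.geometric(p_interesting)) if p_interesting < 1.0 else 1

        if gap is not None and j > gap:
            # only content-preserving divisions until the bottleneck fires
            t += gap
            t_abs += gap
            observe(track.tissue_af(), count=gap)
            if event_kind == "sex":
                apply_sexual_bottleneck(pop, rng)
            else:
                apply_branching_bottleneck(pop, rng)
            track.refresh_all()
            fate = absorbed()
            continue

        # j-1 content-preserving divisions, then one interesting division
        if j > 1:
            t += j - 1
            t_abs += j - 1
            observe(track.tissue_af(), count=j - 1)

        # conditional draw of (divider, symmetry) given "interesting"
        pm = k_m / params.N
        ps = params.P_sym
        u = rng.random() * p_interesting
        if u < pm:
            symmetric = u >= pm * (1.0 - ps)
            mutants = tuple(track.mutant_set)
            divider = mutants[rng.integers(k_m)]
        else:
            symmetric = True
            wild = [s for s in range(params.N) if s not in track.mutant_set]
            divider = wild[rng.integers(len(wild))]
        ev = _apply_division(pop, divider, symmetric, rng, "constant")
        track.refresh_slot(ev.dividing_cell)
        if ev.replaced_cell is not None:
            track.refresh_slot(ev.replaced_cell)
        t += 1
        t_abs += 1
        observe(track.tissue_af(), count=1)
        stop = note_events()
        fate = absorbed()

    if run_start >= 0:
        out.det_runs.append((run_start, t + 1 - run_start))
    out.fate = fate if fate is not None else "stopped"
    out.t_segregation = t
    return out


# ---------------------------------------------------------------------------
# Experiment loop
# ---------------------------------------------------------------------------

def run_experiment(
    params: ModelParams,
    schedule: BottleneckRegime,
    rng: Optional[np.random.Generator] = None,
    n_mutations: Optional[int] = None,
    keep_runs: bool = True,
) -> ExperimentResult:
    """Simulate mutation/segregation cycles until ``n N M_fix`` mutations arose.

    ``T_total`` sums the geometric waiting times and the segregation times of
    every mutation; ``T_det`` sums the detectable divisions.  ``n_mutations``
    overrides the M_fix-derived stop criterion (scaled-down runs).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if n_mutations is None:
        if params.M_fix < 1:
            raise ValueError("M_fix must be >= 1")
        n_mutations = int(round(params.n * params.N * params.M_fix))
    p = mutation_probability(params, schedule)
    if p <= 0.0:
        raise ValueError("mutation probability is zero (mu == 0): no mutation "
                         "will ever arise")

    t_abs = 0
    T_total = 0
    T_det = 0
    n_fixed = 0
    det = np.zeros(n_mutations, dtype=np.int64)
    t_seg = np.zeros(n_mutations, dtype=np.int64)
    starts: list[int] = []
    lengths: list[int] = []
    for i in range(n_mutations):
        w = draw_waiting_time(p, rng)
        t_abs += w
        T_total += w
        outcome = simulate_mutation_lifecycle(params, schedule, rng, origin_time=t_abs)
        t_abs += outcome.t_segregation
        T_total += outcome.t_segregation
        det[i] = outcome.n_detectable
        t_seg[i] = outcome.t_segregation
        T_det += outcome.n_detectable
        if outcome.fate == "fixed":
            n_fixed += 1
        if keep_runs:
            for s, l in outcome.det_runs:
                starts.append(s)
                lengths.append(l)
    return ExperimentResult(
        params=params,
        regime=schedule,
        n_mutations=n_mutations,
        n_fixed=n_fixed,
        T_total=T_total,
        T_det=T_det,
        det_per_mutation=det,
        t_seg=t_seg,
        det_run_starts=np.asarray(starts, dtype=np.int64),
        det_run_lengths=np.asarray(lengths, dtype=np.int64),
    )


def collect_event_times(
    params: ModelParams,
    schedule: BottleneckRegime,
    rng: np.random.Generator,
    event: str,
    n_events: int,
    max_mutations: Optional[int] = None,
    conditional: bool = True,
) -> np.ndarray:
    """Division indices at which a tracked segregation event first occurs.

    One mutant copy is injected per replicate at a uniformly random phase of
    the joint bottleneck cycle and simulated until the event or absorption.
    ``conditional=True`` (default) returns times only for replicates in which
    the event occurred — the conditioning used for the segregation-time
    summaries; with ``conditional=False`` lost replicates contribute their
    loss time instead (every replicate then has 'no heteroplasmic plastid
    anywhere' trivially satisfied at loss).

    Events: 'first_mutant_cell' (first cell whose whole oDNA pool is mutant),
    'first_homoplasmic_plastid' (first fully mutant plastid) and
    'intraplastid_homoplasmy' (no plastid internally heteroplasmic while the
    mutant still segregates).
    """
    valid = {"first_mutant_cell", "first_homoplasmic_plastid", "intraplastid_homoplasmy"}
    if event not in valid:
        raise ValueError(f"unknown event {event!r}; choose from {sorted(valid)}")
    period = _Schedule(params, schedule).period()
    times: list[int] = []
    tried = 0
    attr = {
        "first_mutant_cell": "t_first_mutant_cell",
        "first_homoplasmic_plastid": "t_first_homoplasmic_plastid",
        "intraplastid_homoplasmy": "t_intraplastid_homoplasmy",
    }[event]
    while len(times) < n_events:
        if max_mutations is not None and tried >= max_mutations:
            break
        tried += 1
        t0 = int(rng.integers(period)) if period > 1 else 0
        outcome = simulate_mutation_lifecycle(
            params, schedule, rng, origin_time=t0, stop_events={event})
        t_event = getattr(outcome, attr)
        if t_event is not None:
            times.append(t_event)
        elif not conditional:
            times.append(outcome.t_segregation)
    return np.asarray(times, dtype=np.int64)
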