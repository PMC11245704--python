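"""Domain types and single-division mechanics of the meristem stem-cell niche.

The model follows the organisation of a monocot shoot apical meristem: a
constant population of ``N`` stem cells arranged in two meristematic layers
(tunica, L1, and corpus, L2), each layer holding two rows of ``N/4`` cells with
periodic row boundaries.  Every cell carries ``n`` organelle-DNA (oDNA)
replicons.  In *mitochondrial* mode the cell is a single well-mixed pool of
``n`` copies (regular fusion/fission erases any intra-organellar structure);
in *plastid* mode the pool is structured into ``n_pt`` plastids of ``n_rep``
copies each (``n = n_pt * n_rep``).

A cell division doubles every oDNA pool exactly (no relaxed replication) and
splits it into two equal halves by hypergeometric sampling.  In plastid mode
every plastid first divides into two sisters; the 2*n_pt sister plastids are
then partitioned between the daughter cells either at random or by an active
partition mechanism with error probability ``E_part`` (the probability that a
sister pair co-segregates into the same daughter; 0.5 reproduces random
segregation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "BottleneckRegime",
    "REGIMES",
    "MeristemLayout",
    "Population",
    "DivisionEvent",
    "build_population",
    "replicate_and_split_pool",
    "divide_plastid",
    "partition_plastids",
    "symmetric_replacement_target",
    "perform_division",
]

# Calibrated study-condition defaults: copy numbers and structure from Z. marina
# coverage estimates, rates from the fits against observed substitution /
# heteroplasmy counts (midpoints of the fitted windows).
MT_DEFAULTS = dict(n=40, mu=4.5e-11, n_pt=None, n_rep=None, E_part=0.5, M_fix=500)
PT_DEFAULTS = dict(n=216, mu=3.7e-11, n_pt=12, n_rep=18, E_part=0.00065, M_fix=200)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the agent-based stem-cell / oDNA model.

    Attributes
    ----------
    n : int
        oDNA replicons per cell.  In plastid mode must equal ``n_pt * n_rep``.
    N : int
        Number of stem cells (two layers, two rows each; divisible by 4).
    mu : float
        Mutation rate per base pair per replicon per cell division.
    G : float
        Stem-cell divisions per cell per year; one simulated year equals
        ``N * G`` population cell divisions.
    P_sym : float
        Probability that a constant-phase division is symmetric.
    strat_ratio : float
        Anticlinal : periclinal weight for the replacement target of a
        symmetric tunica division (stratification scheme; default 10:1).
    n_pt, n_rep : int or None
        Plastids per cell and ptDNA copies per plastid (plastid mode only).
    E_part : float
        Plastid partitioning error in [0, 0.5]; 0.5 is random segregation.
    L : float
        Heteroplasmy detection limit in [0, 0.5]: an allele frequency ``f`` is
        detectable when ``L <= f <= 1 - L``.
    M_fix : float
        Expected number of fixations per experiment; the experiment stop
        criterion is ``n * N * M_fix`` mutations.
    seq_weights : ndarray or None
        Per-stem-cell progeny weights of the sequenced tissue (sum to 1);
        ``None`` means all equal.
    seed : int or None
        Seed for the experiment-level RNG when none is supplied explicitly.
    """

    n: int = 40
    N: int = 20
    mu: float = 4.5e-11
    G: float = 40.0
    P_sym: float = 0.01
    strat_ratio: float = 10.0
    n_pt: Optional[int] = None
    n_rep: Optional[int] = None
    E_part: float = 0.5
    L: float = 0.05
    M_fix: float = 500.0
    seq_weights: Optional[np.ndarray] = field(default=None, repr=False)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.N < 4 or self.N % 4:
            raise ValueError("N must be a positive multiple of 4 (two layers of two rows)")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if not 0.0 <= self.P_sym <= 1.0:
            raise ValueError("P_sym must be in [0, 1]")
        if not 0.0 <= self.E_part <= 0.5:
            raise ValueError("E_part must be in [0, 0.5]")
        if not 0.0 <= self.L <= 0.5:
            raise ValueError("L must be in [0, 0.5]")
        if self.strat_ratio <= 0:
            raise ValueError("strat_ratio must be positive")
        if (self.n_pt is None) != (self.n_rep is None):
            raise ValueError("n_pt and n_rep must be given together")
        if self.n_pt is not None:
            if self.n_pt < 1 or self.n_rep < 1:
                raise ValueError("n_pt and n_rep must be >= 1")
            if self.n_pt * self.n_rep != self.n:
                raise ValueError("plastid mode requires n == n_pt * n_rep")
        if self.seq_weights is not None:
            w = np.asarray(self.seq_weights, dtype=float)
            if w.shape != (self.N,):
                raise ValueError("seq_weights must have length N")
            if (w < 0).any() or not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
                raise ValueError("seq_weights must be non-negative and sum to 1")
            object.__setattr__(self, "seq_weights", w)

    # -- convenience ------------------------------------------------------

    @property
    def mode(self) -> str:
        """'pt' when the plastid hierarchy is enabled, else 'mt'."""
        return "pt" if self.n_pt is not None else "mt"

    @property
    def divisions_per_year(self) -> float:
        return self.N * self.G

    @classmethod
    def mitochondrial(cls, **overrides) -> "ModelParams":
        """Default mitochondrial parameter set (single well-mixed pool, n=40)."""
        kw = dict(MT_DEFAULTS)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def plastid(cls, **overrides) -> "ModelParams":
        """Default plastid parameter set (12 plastids x 18 copies, active partition)."""
        kw = dict(PT_DEFAULTS)
        kw.update(overrides)
        return cls(**kw)

    def evolve(self, **overrides) -> "ModelParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class BottleneckRegime:
    """Named schedule of sexual (1-cell) and branching (10-cell) bottlenecks.

    ``B_sex`` / ``B_branch`` are the intervals between events in years;
    ``None`` disables that bottleneck type.
    """

    name: str
    B_sex: Optional[float]
    B_branch: Optional[float]

    @classmethod
    def from_name(cls, name: str) -> "BottleneckRegime":
        try:
            return REGIMES[name]
        except KeyError:
            raise ValueError(f"unknown bottleneck regime {name!r}; "
                             f"choose from {sorted(REGIMES)}") from None

    def sex_divisions(self, params: ModelParams) -> Optional[int]:
        if self.B_sex is None:
            return None
        return round(self.B_sex * params.divisions_per_year)

    def branch_divisions(self, params: ModelParams) -> Optional[int]:
        if self.B_branch is None:
            return None
        return round(self.B_branch * params.divisions_per_year)


REGIMES = {
    "strict": BottleneckRegime("strict", 3.0, 0.25),
    "clone": BottleneckRegime("clone", 1000.0, 0.25),
    "relaxed": BottleneckRegime("relaxed", 100.0, 1.0),
    "no": BottleneckRegime("no", None, None),
}


class MeristemLayout:
    """Slot geometry: two layers x two rows x N/4 columns, periodic rows.

    Slot numbering: tunica rows occupy ``0 .. N/2-1`` (row 0 then row 1),
    corpus rows occupy ``N/2 .. N-1``.  Within a layer the neighbours of a
    slot are the two row-adjacent slots (periodic) plus the same-column slot
    of the layer's other row.  The periclinal target of a tunica slot is the
    vertically aligned corpus slot (same row and column).
    """

    def __init__(self, N: int) -> None:
        if N < 4 or N % 4:
            raise ValueError("N must be a positive multiple of 4")
        self.N = N
        self.row_len = N // 4
        self.half = N // 2
        self.tunica = np.arange(0, self.half)
        self.corpus = np.arange(self.half, N)
        self.anticlinal = self._build_neighbours()
        # tunica slot i -> corpus slot i + N/2 (same row, same column)
        self.periclinal_target = np.arange(N) + self.half
        # branching bottleneck survivors: one tunica row with its vertically
        # aligned corpus row
        rl = self.row_len
        self.row_pairs = [
            np.concatenate([np.arange(0, rl), np.arange(self.half, self.half + rl)]),
            np.concatenate([np.arange(rl, 2 * rl), np.arange(self.half + rl, N)]),
        ]

    def _build_neighbours(self) -> list[np.ndarray]:
        rl, half = self.row_len, self.half
        neigh = []
        for slot in range(self.N):
            layer = slot // half
            within = slot - layer * half
            row, col = divmod(within, rl)
            base = layer * half + row * rl
            other_row = layer * half + (1 - row) * rl
            cands = {base + (col - 1) % rl, base + (col + 1) % rl, other_row + col}
            cands.discard(slot)  # degenerate single-column rows
            neigh.append(np.array(sorted(cands), dtype=np.int64))
        return neigh

    def is_tunica(self, slot: int) -> bool:
        return slot < self.half


_LAYOUT_CACHE: dict[int, MeristemLayout] = {}


def get_layout(N: int) -> MeristemLayout:
    if N not in _LAYOUT_CACHE:
        _LAYOUT_CACHE[N] = MeristemLayout(N)
    return _LAYOUT_CACHE[N]


@dataclass
class DivisionEvent:
    """Bookkeeping record of one stem-cell division."""

    dividing_cell: int
    symmetric: bool
    replaced_cell: Optional[int] = None
    replacement_kind: str = "none"  # anticlinal | periclinal | none
    retained_daughter: Optional[int] = None  # asymmetric case: 0 or 1


class Population:
    """State of the stem-cell population and its oDNA content.

    ``counts`` holds mutant copy numbers: shape ``(N,)`` in mitochondrial mode
    (copies per cell, capacity ``n``) or ``(N, n_pt)`` in plastid mode (copies
    per plastid, capacity ``n_rep``).  ``alive`` marks the occupied slots;
    during regrowth after a bottleneck fewer than ``N`` slots are live.
    """

    __slots__ = ("params", "layout", "mode", "counts", "alive", "n_live")

    def __init__(self, params: ModelParams) -> None:
        self.params = params
        self.layout = get_layout(params.N)
        self.mode = params.mode
        if self.mode == "mt":
            self.counts = np.zeros(params.N, dtype=np.int64)
        else:
            self.counts = np.zeros((params.N, params.n_pt), dtype=np.int64)
        self.alive = np.ones(params.N, dtype=bool)
        self.n_live = params.N

    # -- content queries --------------------------------------------------

    def cell_mutants(self) -> np.ndarray:
        """Mutant copies per slot (zero on dead slots)."""
        if self.mode == "mt":
            return np.where(self.alive, self.counts, 0)
        return np.where(self.alive, self.counts.sum(axis=1), 0)

    def total_mutant(self) -> int:
        return int(self.cell_mutants().sum())

    def cell_frequencies(self) -> np.ndarray:
        return self.cell_mutants() / self.params.n

    def live_slots(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def mutant_slots(self) -> np.ndarray:
        return np.flatnonzero(self.cell_mutants() > 0)

    def heteroplasmic_plastids(self) -> int:
        """Number of internally heteroplasmic plastids (plastid mode)."""
        if self.mode != "pt":
            raise ValueError("plastid query on a mitochondrial-mode population")
        c = self.counts[self.alive]
        return int(((c > 0) & (c < self.params.n_rep)).sum())

    def validate(self) -> None:
        """Assert the copy-number invariants (used heavily in tests)."""
        if self.mode == "mt":
            assert ((self.counts >= 0) & (self.counts <= self.params.n)).all()
        else:
            assert ((self.counts >= 0) & (self.counts <= self.params.n_rep)).all()
            assert self.counts.shape == (self.params.N, self.params.n_pt)
        assert self.n_live == int(self.alive.sum())
        assert not self.counts[~self.alive].any(), "dead slots must be empty"

    def copy(self) -> "Population":
        new = Population.__new__(Population)
        new.params = self.params
        new.layout = self.layout
        new.mode = self.mode
        new.counts = self.counts.copy()
        new.alive = self.alive.copy()
        new.n_live = self.n_live
        return new


def build_population(
    params: ModelParams,
    mutant_cell: Optional[int] = None,
    mutant_copies: int = 0,
    mutant_plastid: int = 0,
) -> Population:
    """Construct a constant-phase population, optionally seeding one mutant cell.

    In plastid mode the ``mutant_copies`` are placed inside a single plastid
    (``mutant_plastid``) of ``mutant_cell`` and must not exceed ``n_rep``.
    """
    pop = Population(params)
    if mutant_cell is None:
        if mutant_copies:
            raise ValueError("mutant_copies given without a mutant_cell")
        return pop
    if not 0 <= mutant_cell < params.N:
        raise ValueError(f"mutant_cell {mutant_cell} outside the {params.N}-slot layout")
    if params.mode == "mt":
        if not 0 <= mutant_copies <= params.n:
            raise ValueError("mutant_copies exceeds the per-cell capacity n")
        pop.counts[mutant_cell] = mutant_copies
    else:
        if not 0 <= mutant_copies <= params.n_rep:
            raise ValueError("mutant_copies exceeds the per-plastid capacity n_rep")
        if not 0 <= mutant_plastid < params.n_pt:
            raise ValueError("mutant_plastid outside the plastid set")
        pop.counts[mutant_cell, mutant_plastid] = mutant_copies
    return pop


# ---------------------------------------------------------------------------
# oDNA replication and segregation primitives
# ---------------------------------------------------------------------------

def replicate_and_split_pool(m: int, n: int, rng: np.random.Generator) -> tuple[int, int]:
    """Double an n-copy pool carrying m mutants and split it into two n-pools.

    The 2n replicated copies (2m mutant) are dealt into two pools of exactly n
    copies; the mutant count of the first pool is hypergeometric.  Mutant
    copies are conserved: ``m1 + m2 == 2 m``.
    """
    if not 0 <= m <= n:
        raise ValueError(f"mutant count {m} outside [0, {n}]")
    if m == 0 or m == n:
        return m, m
    m1 = int(rng.hypergeometric(2 * m, 2 * (n - m), n))
    return m1, 2 * m - m1


def divide_plastid(m: int, n_rep: int, rng: np.random.Generator) -> tuple[int, int]:
    """Divide one plastid into two sisters (same mechanics at plastid scale)."""
    return replicate_and_split_pool(m, n_rep, rng)


def _split_plastid_row(row: np.ndarray, n_rep: int, rng: np.random.Generator) -> np.ndarray:
    """Sister-pair formation for all plastids of one cell.

    Returns an ``(n_pt, 2)`` array of sister mutant counts.  Homoplasmic
    plastids split deterministically, so only the (typically few)
    heteroplasmic plastids draw from the hypergeometric law.
    """
    n_pt = row.shape[0]
    out = np.empty((n_pt, 2), dtype=np.int64)
    out[:, 0] = row
    out[:, 1] = row
    for i in range(n_pt):
        m = out[i, 0]
        if 0 < m < n_rep:
            m1 = int(rng.hypergeometric(2 * m, 2 * (n_rep - m), n_rep))
            out[i, 0] = m1
            out[i, 1] = 2 * m - m1
    return out


def partition_plastids(
    sister_pairs: Sequence[Sequence[int]] | np.ndarray,
    e_part: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribute sister-plastid pairs between the two daughter cells.

    Each pair independently co-segregates ("together") with probability
    ``e_part``, otherwise the sisters are split one to each daughter.  Sides
    and orientations are drawn uniformly, and the whole assignment is redrawn
    until both daughters receive exactly ``n_pt`` plastids (rejection
    sampling).  At ``e_part = 0.5`` the accepted assignment is uniform over
    all equal partitions of the ``2 n_pt`` plastids; at ``e_part = 0`` every
    pair is split and each daughter inherits one sister of every pair.
    """
    pairs = np.asarray(sister_pairs, dtype=np.int64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("sister_pairs must be an (n_pt, 2) array")
    k = pairs.shape[0]
    if e_part == 0.5:
        # the conditioned pair-flag draw at E_part = 0.5 is exactly uniform
        # over all equal partitions of the 2k plastids, so sample it directly
        flat = pairs.ravel()
        perm = rng.permutation(2 * k)
        return flat[perm[:k]].copy(), flat[perm[k:]].copy()
    while True:
        together = rng.random(k) < e_part
        side = rng.integers(0, 2, size=k)
        n_tog = int(together.sum())
        if 2 * int(side[together].sum()) == n_tog:
            break
    orient = rng.integers(0, 2, size=k)
    rows = np.arange(k)
    if n_tog == 0:
        return pairs[rows, orient], pairs[rows, 1 - orient]
    split = ~together
    srows = rows[split]
    a = np.concatenate([pairs[srows, orient[split]],
                        pairs[together & (side == 1)].ravel()])
    b = np.concatenate([pairs[srows, 1 - orient[split]],
                        pairs[together & (side == 0)].ravel()])
    return a, b


def symmetric_replacement_target(
    pop: Population,
    dividing_cell: int,
    strat_ratio: Optional[float],
    rng: np.random.Generator,
) -> tuple[int, str]:
    """Pick the cell replaced by the second daughter of a symmetric division.

    A tunica cell replaces a within-layer neighbour (anticlinal, weight
    ``strat_ratio``) or the vertically aligned corpus cell (periclinal,
    weight 1).  A corpus cell only replaces within the corpus; replacement
    never crosses from corpus to tunica.
    """
    layout = pop.layout
    ratio = pop.params.strat_ratio if strat_ratio is None else strat_ratio
    if layout.is_tunica(dividing_cell):
        if rng.random() * (ratio + 1.0) < 1.0:
            return int(layout.periclinal_target[dividing_cell]), "periclinal"
    neigh = layout.anticlinal[dividing_cell]
    return int(neigh[rng.integers(len(neigh))]), "anticlinal"


# ---------------------------------------------------------------------------
# Whole-cell division
# ---------------------------------------------------------------------------

def _divide_cell_contents(pop: Population, slot: int, rng: np.random.Generator):
    """Replicate and segregate the oDNA content of one cell into two daughters."""
    params = pop.params
    if pop.mode == "mt":
        m = int(pop.counts[slot])
        if m == 0:
            return 0, 0
        return replicate_and_split_pool(m, params.n, rng)
    row = pop.counts[slot]
    if not row.any():
        z = np.zeros(params.n_pt, dtype=np.int64)
        return z, z.copy()
    sisters = _split_plastid_row(row, params.n_rep, rng)
    return partition_plastids(sisters, params.E_part, rng)


def _set_slot(pop: Population, slot: int, content) -> None:
    if pop.mode == "mt":
        pop.counts[slot] = content
    else:
        pop.counts[slot, :] = content


def _apply_division(
    pop: Population,
    divider: int,
    symmetric: bool,
    rng: np.random.Generator,
    phase: str,
) -> DivisionEvent:
    """Apply the mechanics of one division with divider and symmetry fixed."""
    a, b = _divide_cell_contents(pop, divider, rng)
    if phase == "proliferation":
        # growth division: the second daughter occupies an empty slot, within
        # the divider's own layer whenever one is free (stem cells divide
        # preferentially within their meristematic layer); cross-layer growth
        # happens only when the own layer is full, which is how the single
        # corpus survivor of a sexual bottleneck reseeds the tunica
        empty = np.flatnonzero(~pop.alive)
        half = pop.layout.half
        own = empty[(empty // half) == (divider // half)]
        pool = own if len(own) else empty
        target = int(pool[rng.integers(len(pool))])
        if rng.integers(2):
            a, b = b, a
        _set_slot(pop, divider, a)
        _set_slot(pop, target, b)
        pop.alive[target] = True
        pop.n_live += 1
        return DivisionEvent(divider, True, target, "growth")
    if symmetric:
        target, kind = symmetric_replacement_target(pop, divider, None, rng)
        if rng.integers(2):
            a, b = b, a
        _set_slot(pop, divider, a)
        _set_slot(pop, target, b)
        return DivisionEvent(divider, True, target, kind)
    keep = int(rng.integers(2))
    _set_slot(pop, divider, (a, b)[keep])
    return DivisionEvent(divider, False, retained_daughter=keep)


def perform_division(
    pop: Population,
    params: ModelParams,
    rng: np.random.Generator,
    phase: str = "constant",
) -> tuple[Population, DivisionEvent]:
    """Run one stochastic stem-cell division (in place).

    Constant phase: a uniformly chosen live cell divides; the division is
    symmetric with probability ``P_sym`` (second daughter replaces a
    stratification-scheme neighbour), otherwise asymmetric (one daughter
    retained uniformly, the other differentiates and leaves the niche).
    Proliferation phase: the division is always symmetric and grows the
    population into an empty slot.
    """
    if phase not in ("constant", "proliferation"):
        raise ValueError(f"unknown phase {phase!r}")
    if phase == "proliferation" and pop.n_live >= params.N:
        raise ValueError("proliferation division requested at full population size")
    live = pop.live_slots()
    divider = int(live[rng.integers(len(live))])
    symmetric = phase == "proliferation" or bool(rng.random() < params.P_sym)
    event = _apply_division(pop, divider, symmetric, rng, phase)
    return pop, event
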