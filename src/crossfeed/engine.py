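"""Gillespie direct-method loop and the eight event executors.

Two implementations coexist:

* pure-Python executors operating on :class:`~crossfeed.model.ColonyState`,
  used as the readable reference and for scripted-RNG unit tests;
* a compiled kernel (:mod:`crossfeed._kernel`) used by
  :func:`run_simulation` for production runs.

Random-number order per iteration: r1 selects the channel, r2 sets the time
increment, and any further draws needed inside the event (cell choice,
thinning acceptance, placement direction, molecule choice) are taken from
the same stream in that order.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .model import (
    EMPTY,
    NEIGHBOR_OFFSETS,
    SPECIES_1,
    SPECIES_2,
    ColonyState,
    ModelParams,
    PropensityVector,
    local_monod_factor,
    propensities,
)

__all__ = [
    "EventOutcome",
    "TimeSeries",
    "Trajectory",
    "BoundaryError",
    "select_event",
    "time_increment",
    "execute_division",
    "execute_excretion",
    "execute_uptake",
    "execute_diffusion",
    "step",
    "run_simulation",
]

CHANNEL_NAMES = (
    "divide_1", "excrete_B", "uptake_A",
    "divide_2", "excrete_A", "uptake_B",
    "diffuse_B", "diffuse_A",
)


class BoundaryError(RuntimeError):
    """A cell reached the outermost lattice ring: the domain was too small."""


class NoReactionError(RuntimeError):
    """All propensities vanished; the system is static."""


@dataclasses.dataclass
class EventOutcome:
    """Record of one realized (or null) reaction channel firing."""

    channel: int
    executed: bool
    site: Optional[tuple] = None
    details: Optional[dict] = None


@dataclasses.dataclass
class TimeSeries:
    """Sampled totals: columns t, rho1, rho2, nA, nB, radius."""

    t: np.ndarray
    rho1: np.ndarray
    rho2: np.ndarray
    nA: np.ndarray
    nB: np.ndarray
    radius: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        for name in ("rho1", "rho2"):
            if np.any(np.diff(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-decreasing")


@dataclasses.dataclass
class Trajectory:
    """One simulation run: parameters, sampled series, snapshots, tallies."""

    params: ModelParams
    samples: TimeSeries
    snapshots: list  # list of (t, ColonyState)
    event_counts: np.ndarray  # (8, 2): executed / null per channel
    stasis: bool = False

    @property
    def final_state(self) -> Optional[ColonyState]:
        return self.snapshots[-1][1] if self.snapshots else None


# ---------------------------------------------------------------------------
# Direct-method primitives
# ---------------------------------------------------------------------------

def select_event(k, r1: float) -> int:
    """Channel j in [1, 8] with sum_{i<j} k_i < k0*r1 <= sum_{i<=j} k_i."""
    kv = k.k if isinstance(k, PropensityVector) else np.asarray(k, dtype=float)
    k0 = kv.sum()
    if k0 <= 0:
        raise NoReactionError("all propensities are zero")
    target = k0 * r1
    cum = 0.0
    for j, kj in enumerate(kv, start=1):
        prev = cum
        cum += kj
        if prev < target <= cum:
            return j
    return int(np.flatnonzero(kv > 0)[-1]) + 1  # guard against rounding


def time_increment(k0: float, r2: float) -> float:
    """Exponential waiting time -ln(r2)/k0."""
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    if not (0.0 < r2 <= 1.0):
        raise ValueError("r2 must lie in (0, 1]")
    return -math.log(r2) / k0


# ---------------------------------------------------------------------------
# Reference event executors (Python path)
# ---------------------------------------------------------------------------

def _cells_of(state: ColonyState, species: int) -> np.ndarray:
    sites = np.argwhere(state.cell_grid == species)
    if len(sites) == 0:
        raise ValueError(f"no cells of species {species}")
    return sites


def _pick_cell(state: ColonyState, species: int, rng) -> tuple:
    sites = _cells_of(state, species)
    idx = int(rng.integers(len(sites)))
    return tuple(sites[idx])


def _in_lattice_neighbors(shape, site):
    n, m = shape
    x, y = site
    return [(x + dx, y + dy) for dx, dy in NEIGHBOR_OFFSETS
            if 0 <= x + dx < n and 0 <= y + dy < m]


def execute_division(state: ColonyState, species: int, rng,
                     params: ModelParams) -> EventOutcome:
    """Attempt one division of a uniformly chosen cell of ``species``.

    In thinning mode the attempt is accepted with probability S/(S+K) on the
    5-site growth neighbourhood; the daughter goes to an empty nearest
    neighbour per ``params.division_site_rule``.  Rejections are null
    events (time was already advanced by the caller).
    """
    channel = 1 if species == SPECIES_1 else 4
    site = _pick_cell(state, species, rng)
    if params.propensity_mode == "thinning":
        accept_p = local_monod_factor(state, site, species, params,
                                      include_center=True)
        if accept_p <= 0.0 or rng.random() >= accept_p:
            return EventOutcome(channel, False, site, {"reason": "monod"})
    neighbors = _in_lattice_neighbors(state.shape, site)
    if params.division_site_rule == "choose-then-reject":
        x, y = site
        dx, dy = NEIGHBOR_OFFSETS[int(rng.integers(4))]
        target = (x + dx, y + dy)
        nx, ny = target
        n, m = state.shape
        if not (0 <= nx < n and 0 <= ny < m) or state.cell_grid[target] != EMPTY:
            return EventOutcome(channel, False, site, {"reason": "occupied"})
    else:
        empties = [p for p in neighbors if state.cell_grid[p] == EMPTY]
        if not empties:
            return EventOutcome(channel, False, site, {"reason": "occupied"})
        target = empties[int(rng.integers(len(empties)))]
    state.cell_grid[target] = species
    return EventOutcome(channel, True, site, {"daughter": target})


def execute_excretion(state: ColonyState, species: int, rng,
                      params: ModelParams = None) -> EventOutcome:
    """A uniformly chosen producer places one product molecule on a n.n. site.

    Species 1 excretes B, species 2 excretes A.  The destination is drawn
    uniformly among the in-lattice nearest neighbours; occupied sites are
    allowed (molecules stack).  Excretion is unconditional.
    """
    channel = 2 if species == SPECIES_1 else 5
    site = _pick_cell(state, species, rng)
    neighbors = _in_lattice_neighbors(state.shape, site)
    target = neighbors[int(rng.integers(len(neighbors)))]
    grid = state.nutrient_B if species == SPECIES_1 else state.nutrient_A
    grid[target] += 1
    return EventOutcome(channel, True, site, {"placed": target})


def execute_uptake(state: ColonyState, species: int, rng,
                   params: ModelParams) -> EventOutcome:
    """A uniformly chosen cell removes one partner molecule from its 4 n.n.

    In thinning mode the attempt is first accepted with probability
    S/(S+K) computed on the 4-neighbour uptake neighbourhood; the molecule
    is then drawn site-proportionally to the neighbour counts.
    """
    channel = 3 if species == SPECIES_1 else 6
    site = _pick_cell(state, species, rng)
    grid = state.nutrient_A if species == SPECIES_1 else state.nutrient_B
    neighbors = _in_lattice_neighbors(state.shape, site)
    counts = np.array([grid[p] for p in neighbors], dtype=np.int64)
    S = int(counts.sum())
    if S == 0:
        return EventOutcome(channel, False, site, {"reason": "no molecule"})
    if params.propensity_mode == "thinning":
        K = params.K_A if species == SPECIES_1 else params.K_B
        if rng.random() >= S / (S + K):
            return EventOutcome(channel, False, site, {"reason": "monod"})
    u = rng.random() * S
    cum = 0
    for p, c in zip(neighbors, counts):
        cum += int(c)
        if u < cum:
            grid[p] -= 1
            return EventOutcome(channel, True, site, {"removed": p})
    raise AssertionError("unreachable")


def execute_diffusion(state: ColonyState, nutrient: str, rng,
                      params: ModelParams = None) -> EventOutcome:
    """Hop one uniformly chosen molecule to a random n.n. site.

    Hops off the lattice are reflected (null event); totals are conserved.
    """
    channel = 8 if nutrient == "A" else 7
    grid = state.nutrient_A if nutrient == "A" else state.nutrient_B
    total = int(grid.sum())
    if total == 0:
        raise ValueError(f"no molecules of nutrient {nutrient}")
    # site chosen with probability proportional to its count
    flat = grid.ravel()
    u = int(rng.integers(total))
    idx = int(np.searchsorted(np.cumsum(flat), u, side="right"))
    site = np.unravel_index(idx, grid.shape)
    dx, dy = NEIGHBOR_OFFSETS[int(rng.integers(4))]
    n, m = grid.shape
    target = (site[0] + dx, site[1] + dy)
    if not (0 <= target[0] < n and 0 <= target[1] < m):
        return EventOutcome(channel, False, tuple(site), {"reason": "reflected"})
    grid[site] -= 1
    grid[target] += 1
    return EventOutcome(channel, True, tuple(site), {"moved_to": target})


_EXECUTORS = {
    1: lambda s, rng, p: execute_division(s, SPECIES_1, rng, p),
    2: lambda s, rng, p: execute_excretion(s, SPECIES_1, rng, p),
    3: lambda s, rng, p: execute_uptake(s, SPECIES_1, rng, p),
    4: lambda s, rng, p: execute_division(s, SPECIES_2, rng, p),
    5: lambda s, rng, p: execute_excretion(s, SPECIES_2, rng, p),
    6: lambda s, rng, p: execute_uptake(s, SPECIES_2, rng, p),
    7: lambda s, rng, p: execute_diffusion(s, "B", rng, p),
    8: lambda s, rng, p: execute_diffusion(s, "A", rng, p),
}


def step(state: ColonyState, params: ModelParams, rng) -> EventOutcome:
    """One full direct-method iteration on the Python path (in place).

    Draws (r1, r2), selects and executes the channel, advances ``state.t``.
    Raises :class:`NoReactionError` when every propensity is zero.
    """
    k = propensities(state, params)
    if k.k0 <= 0:
        raise NoReactionError("all propensities are zero")
    r1 = rng.random()
    while r1 == 0.0:  # r1 must lie in (0, 1)
        r1 = rng.random()
    j = select_event(k, r1)
    r2 = rng.random()
    while r2 == 0.0:
        r2 = rng.random()
    state.t += time_increment(k.k0, r2)
    return _EXECUTORS[j](state, rng, params)


# ---------------------------------------------------------------------------
# Fast path
# ---------------------------------------------------------------------------

def colony_radius_of_grid(cell_grid: np.ndarray, origin) -> float:
    """Mean origin distance of occupied sites with >= 1 empty 4-neighbour."""
    occ = cell_grid != EMPTY
    if not occ.any():
        raise ValueError("no cells")
    empty = ~occ
    frontier = np.zeros_like(occ)
    frontier[:-1] |= empty[1:]
    frontier[1:] |= empty[:-1]
    frontier[:, :-1] |= empty[:, 1:]
    frontier[:, 1:] |= empty[:, :-1]
    frontier[0] = frontier[-1] = frontier[:, 0] = frontier[:, -1] = True
    frontier &= occ
    xs, ys = np.nonzero(frontier)
    return float(np.hypot(xs - origin[0], ys - origin[1]).mean())


def run_simulation(params: ModelParams,
                   sample_interval: Optional[float] = None,
                   snapshot_times: Optional[Sequence[float]] = None,
                   initial_state: Optional[ColonyState] = None) -> Trajectory:
    """Run the compiled KMC loop from the inoculum to ``params.T_max``.

    The initial condition is built from ``params`` (centred L0 x L0 patch,
    optional pre-seeded nutrients) unless ``initial_state`` is given.
    Identical parameters and seed yield a bit-identical trajectory.
    """
    from .scenarios import initial_state as build_initial

    if sample_interval is None:
        sample_interval = params.T_max / 200.0
    snapshot_times = sorted(snapshot_times or [])
    if any(ts > params.T_max for ts in snapshot_times):
        raise ValueError("snapshot times must be <= T_max")

    state = (initial_state.copy() if initial_state is not None
             else build_initial(params))
    N = state.shape[0]
    origin = ((N - 1) / 2.0, (N - 1) / 2.0)

    sim = _kernel.SimState.from_colony(state, params)

    sample_times = np.arange(sample_interval, params.T_max + 1e-12,
                             sample_interval)
    checkpoints = sorted(set(float(x) for x in sample_times)
                         | set(float(x) for x in snapshot_times))

    rec_t = [state.t]
    rec = [(sim.n1, sim.n2, sim.nA, sim.nB,
            colony_radius_of_grid(sim.cell_grid(), origin))]
    snapshots = []
    snap_iter = list(snapshot_times)
    stasis = False

    for t_stop in checkpoints:
        if not stasis:
            status = sim.advance_to(t_stop)
            if status == _kernel.STATUS_BOUNDARY:
                raise BoundaryError(
                    f"colony reached the lattice boundary at t={sim.t:.3f}; "
                    f"increase lattice_size (currently {N})")
            if status == _kernel.STATUS_STASIS:
                stasis = True
                warnings.warn(f"no reactions possible at t={sim.t:.4g}; "
                              "populations frozen", RuntimeWarning)
        t_rec = t_stop
        rec_t.append(t_rec)
        rec.append((sim.n1, sim.n2, sim.nA, sim.nB,
                    colony_radius_of_grid(sim.cell_grid(), origin)))
        if snap_iter and math.isclose(t_stop, snap_iter[0]):
            snap_iter.pop(0)
            snapshots.append((t_stop, sim.to_colony(t_stop)))

    arr = np.asarray(rec, dtype=float)
    samples = TimeSeries(
        t=np.asarray(rec_t, dtype=float),
        rho1=arr[:, 0], rho2=arr[:, 1], nA=arr[:, 2], nB=arr[:, 3],
        radius=arr[:, 4])
    return Trajectory(params=params, samples=samples, snapshots=snapshots,
                      event_counts=sim.event_counts.copy(), stasis=stasis)
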