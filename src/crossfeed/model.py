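"""Model state, parameters and rate laws.

Two species live on a 2-D square lattice.  Each cell of species 1 grows by
consuming nutrient A (excreted by species 2) and excretes nutrient B, and
vice versa.  Growth follows Monod kinetics evaluated on the nutrient counts
at the cell's site and its four nearest neighbours; all other event rates
are mass-action (rate constant times reagent count).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Union

import numpy as np

__all__ = [
    "EMPTY",
    "SPECIES_1",
    "SPECIES_2",
    "ModelParams",
    "ColonyState",
    "PropensityVector",
    "local_growth_rate",
    "propensities",
]

EMPTY = 0
SPECIES_1 = 1
SPECIES_2 = 2

#: 4-neighbour offsets (dx, dy) used for growth, excretion, uptake, diffusion.
NEIGHBOR_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))

DIVISION_SITE_RULES = ("uniform-empty", "choose-then-reject")
PROPENSITY_MODES = ("thinning", "global-monod")
BOUNDARY_MODES = ("reflect",)


class ConfigurationError(ValueError):
    """Raised when parameters violate a model invariant."""


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """All rate constants and geometry for one simulation run.

    Rates are per unit time: ``lambda_max_*`` per cell (maximal division
    rate), ``gamma_*`` per producer cell (excretion), ``D_*`` per molecule
    (hop rate).  Yields ``Y_*`` convert consumed molecules into biomass and
    Monod constants ``K_*`` are in units of molecule counts.
    """

    lambda_max_1: float = 1.0
    lambda_max_2: float = 1.0
    gamma_A: float = 1.0
    gamma_B: float = 1.0
    D_A: float = 1.0
    D_B: float = 1.0
    Y_A: float = 1.0
    Y_B: float = 1.0
    K_A: float = 1.0
    K_B: float = 1.0
    L0: int = 20
    rho0: float = 0.25
    lattice_size: Union[int, str] = "auto"
    T_max: float = 100.0
    seed: int = 0
    preseed_A: int = 0
    preseed_B: int = 0
    division_site_rule: str = "uniform-empty"
    propensity_mode: str = "thinning"
    boundary_mode: str = "reflect"

    def __post_init__(self) -> None:
        for name in ("lambda_max_1", "lambda_max_2", "gamma_A", "gamma_B",
                     "D_A", "D_B", "Y_A", "Y_B", "K_A", "K_B"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.Y_A <= 0 or self.Y_B <= 0:
            raise ConfigurationError("yields must be > 0")
        if not (0.0 < self.rho0 <= 1.0):
            raise ConfigurationError("rho0 must lie in (0, 1]")
        if self.L0 < 1:
            raise ConfigurationError("L0 must be >= 1")
        if self.preseed_A < 0 or self.preseed_B < 0:
            raise ConfigurationError("pre-seeded nutrient counts must be >= 0")
        if self.T_max <= 0:
            raise ConfigurationError("T_max must be > 0")
        if self.division_site_rule not in DIVISION_SITE_RULES:
            raise ConfigurationError(
                f"division_site_rule must be one of {DIVISION_SITE_RULES}")
        if self.propensity_mode not in PROPENSITY_MODES:
            raise ConfigurationError(
                f"propensity_mode must be one of {PROPENSITY_MODES}")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ConfigurationError(
                f"boundary_mode must be one of {BOUNDARY_MODES}")
        if self.lattice_size != "auto":
            if not isinstance(self.lattice_size, (int, np.integer)):
                raise ConfigurationError("lattice_size must be an int or 'auto'")
            if self.lattice_size < self.L0:
                raise ConfigurationError("lattice_size must be >= L0")

    def resolve_lattice_size(self) -> int:
        """Side length actually used for the simulation grid.

        ``"auto"`` sizes the grid so that a colony expanding at up to
        1.5 * max(lambda) lattice units per unit time never feels the
        boundary before ``T_max``.
        """
        if self.lattice_size != "auto":
            return int(self.lattice_size)
        lam = max(self.lambda_max_1, self.lambda_max_2)
        radius = self.L0 / 2 + 1.5 * lam * self.T_max + 10
        return int(2 * math.ceil(radius) + 2)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ColonyState:
    """Lattice snapshot: cell grid, two nutrient count grids and the clock.

    ``cell_grid`` holds {0 empty, 1 species 1, 2 species 2}; a site carries
    at most one cell but arbitrarily many molecules.  Cells never move and
    never die.
    """

    __slots__ = ("cell_grid", "nutrient_A", "nutrient_B", "t")

    def __init__(self, cell_grid: np.ndarray, nutrient_A: np.ndarray,
                 nutrient_B: np.ndarray, t: float = 0.0):
        cell_grid = np.asarray(cell_grid, dtype=np.int8)
        nutrient_A = np.asarray(nutrient_A, dtype=np.int64)
        nutrient_B = np.asarray(nutrient_B, dtype=np.int64)
        if cell_grid.ndim != 2:
            raise ValueError("cell_grid must be 2-D")
        if nutrient_A.shape != cell_grid.shape or nutrient_B.shape != cell_grid.shape:
            raise ValueError("grids must share one shape")
        if (nutrient_A < 0).any() or (nutrient_B < 0).any():
            raise ValueError("nutrient counts must be non-negative")
        self.cell_grid = cell_grid
        self.nutrient_A = nutrient_A
        self.nutrient_B = nutrient_B
        self.t = float(t)

    @classmethod
    def empty(cls, lattice_size: int) -> "ColonyState":
        shape = (lattice_size, lattice_size)
        return cls(np.zeros(shape, dtype=np.int8),
                   np.zeros(shape, dtype=np.int64),
                   np.zeros(shape, dtype=np.int64))

    @property
    def shape(self) -> tuple:
        return self.cell_grid.shape

    @property
    def totals(self) -> tuple:
        """(rho1, rho2, nA, nB) recomputed from the grids."""
        return (int((self.cell_grid == SPECIES_1).sum()),
                int((self.cell_grid == SPECIES_2).sum()),
                int(self.nutrient_A.sum()),
                int(self.nutrient_B.sum()))

    @property
    def rho1(self) -> int:
        return int((self.cell_grid == SPECIES_1).sum())

    @property
    def rho2(self) -> int:
        return int((self.cell_grid == SPECIES_2).sum())

    @property
    def n_A(self) -> int:
        return int(self.nutrient_A.sum())

    @property
    def n_B(self) -> int:
        return int(self.nutrient_B.sum())

    def copy(self) -> "ColonyState":
        return ColonyState(self.cell_grid.copy(), self.nutrient_A.copy(),
                           self.nutrient_B.copy(), self.t)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ColonyState):
            return NotImplemented
        return (self.t == other.t
                and np.array_equal(self.cell_grid, other.cell_grid)
                and np.array_equal(self.nutrient_A, other.nutrient_A)
                and np.array_equal(self.nutrient_B, other.nutrient_B))


@dataclasses.dataclass(frozen=True)
class PropensityVector:
    """The eight channel propensities and their sum.

    Channels (1-based): 1 species-1 division, 2 species-1 excretes B,
    3 species-1 takes up A, 4 species-2 division, 5 species-2 excretes A,
    6 species-2 takes up B, 7 nutrient B hops, 8 nutrient A hops.
    """

    k: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        if k.shape != (8,):
            raise ValueError("expected 8 channel propensities")
        if (k < 0).any():
            raise ValueError("propensities must be non-negative")
        object.__setattr__(self, "k", k)

    @property
    def k0(self) -> float:
        return float(self.k.sum())

    def __getitem__(self, j: int) -> float:
        """1-based channel access, matching the channel numbering."""
        if not 1 <= j <= 8:
            raise IndexError("channel index must be in [1, 8]")
        return float(self.k[j - 1])


def _nutrient_for_species(state: ColonyState, species: int) -> np.ndarray:
    if species == SPECIES_1:
        return state.nutrient_A
    if species == SPECIES_2:
        return state.nutrient_B
    raise ValueError(f"species must be 1 or 2, got {species}")


def neighborhood_sum(grid: np.ndarray, site: tuple, include_center: bool) -> int:
    """Sum of counts over the 4 nearest neighbours (optionally + the site).

    Off-lattice neighbours contribute zero.
    """
    n, m = grid.shape
    x, y = site
    if not (0 <= x < n and 0 <= y < m):
        raise IndexError(f"site {site!r} outside the {n}x{m} lattice")
    total = int(grid[x, y]) if include_center else 0
    for dx, dy in NEIGHBOR_OFFSETS:
        xx, yy = x + dx, y + dy
        if 0 <= xx < n and 0 <= yy < m:
            total += int(grid[xx, yy])
    return total


def local_growth_rate(state: ColonyState, site: tuple, species: int,
                      params: ModelParams) -> float:
    """Instantaneous division rate of a cell of ``species`` at ``site``.

    Monod form lambda* . S / (S + K) where S sums the partner nutrient over
    the site and its four nearest neighbours.
    """
    grid = _nutrient_for_species(state, species)
    S = neighborhood_sum(grid, site, include_center=True)
    if species == SPECIES_1:
        lam, K = params.lambda_max_1, params.K_A
    else:
        lam, K = params.lambda_max_2, params.K_B
    if S == 0:
        return 0.0
    return lam * S / (S + K)


def local_monod_factor(state: ColonyState, site: tuple, species: int,
                       params: ModelParams, include_center: bool = True) -> float:
    """S/(S+K) on the given neighbourhood; the thinning acceptance factor."""
    grid = _nutrient_for_species(state, species)
    S = neighborhood_sum(grid, site, include_center=include_center)
    K = params.K_A if species == SPECIES_1 else params.K_B
    if S == 0:
        return 0.0
    return S / (S + K)


def propensities(state: ColonyState, params: ModelParams) -> PropensityVector:
    """Channel propensities from the system totals.

    In ``thinning`` mode division/uptake channels carry the maximal rate
    and the local Monod factor is applied as a rejection step at execution.
    In ``global-monod`` mode the factor n/(n+K) with system totals is folded
    into the propensity itself.
    """
    rho1, rho2, nA, nB = state.totals
    if params.propensity_mode == "global-monod":
        fA = nA / (nA + params.K_A) if nA > 0 else 0.0
        fB = nB / (nB + params.K_B) if nB > 0 else 0.0
    else:
        fA = fB = 1.0
    k = np.array([
        params.lambda_max_1 * fA * rho1,
        params.gamma_B * rho1,
        params.lambda_max_1 * fA / params.Y_A * rho1,
        params.lambda_max_2 * fB * rho2,
        params.gamma_A * rho2,
        params.lambda_max_2 * fB / params.Y_B * rho2,
        params.D_B * nB,
        params.D_A * nA,
    ])
    return PropensityVector(k)
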