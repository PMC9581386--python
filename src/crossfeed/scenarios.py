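"""Initial conditions and named parameter presets.

Every preset corresponds to one of the characterized growth regimes: nutrient
pre-seeded sectors, high-excretion cross-feeding sectors, engulfment,
diffusion-limited spirals, and the branchy high-diffusion variants.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import (
    SPECIES_1,
    SPECIES_2,
    ColonyState,
    ConfigurationError,
    ModelParams,
)

__all__ = [
    "ScenarioPreset",
    "make_inoculum",
    "preseed_nutrients",
    "preset",
    "preset_names",
    "initial_state",
]


@dataclasses.dataclass(frozen=True)
class ScenarioPreset:
    name: str
    params: ModelParams
    note: str


def make_inoculum(L: int, rho0: float, lattice_size: int, rng) -> ColonyState:
    """Centred L x L patch holding rho0*L^2 cells, half of each species.

    Cells are placed uniformly at random without overlap; all nutrient
    grids start at zero.  ``rho0 * L**2`` must be an even integer so the
    species split is exact.
    """
    n_cells_f = rho0 * L * L
    n_cells = int(round(n_cells_f))
    if abs(n_cells_f - n_cells) > 1e-9 or n_cells % 2 != 0:
        raise ConfigurationError(
            f"rho0*L^2 = {n_cells_f} must be an even integer")
    if n_cells > L * L:
        raise ConfigurationError("inoculum density exceeds 1")
    if lattice_size < L:
        raise ConfigurationError("lattice_size must be >= L")
    state = ColonyState.empty(lattice_size)
    off = (lattice_size - L) // 2
    flat = rng.choice(L * L, size=n_cells, replace=False)
    species = np.concatenate([
        np.full(n_cells // 2, SPECIES_1, dtype=np.int8),
        np.full(n_cells // 2, SPECIES_2, dtype=np.int8)])
    rng.shuffle(species)
    xs, ys = np.divmod(flat, L)
    state.cell_grid[off + xs, off + ys] = species
    return state


def preseed_nutrients(state: ColonyState, a0: int, b0: int) -> ColonyState:
    """Set every site's nutrient counts to (a0, b0), in place."""
    if a0 < 0 or b0 < 0:
        raise ConfigurationError("pre-seeded counts must be >= 0")
    if a0 > 0:
        state.nutrient_A[:] = a0
    if b0 > 0:
        state.nutrient_B[:] = b0
    return state


def initial_state(params: ModelParams, rng=None) -> ColonyState:
    """Build the run's initial ColonyState from its parameters."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = make_inoculum(params.L0, params.rho0,
                          params.resolve_lattice_size(), rng)
    return preseed_nutrients(state, params.preseed_A, params.preseed_B)


def _sym(lam=1.0, gamma=1.0, D=1.0, Y=1.0, **kw) -> ModelParams:
    return ModelParams(lambda_max_1=lam, lambda_max_2=lam,
                       gamma_A=gamma, gamma_B=gamma,
                       D_A=D, D_B=D, Y_A=Y, Y_B=Y, **kw)


def _build_presets() -> dict:
    presets = {
        "sector-preseeded": ScenarioPreset(
            "sector-preseeded",
            _sym(lam=1.0, gamma=1.0, D=1.0, preseed_A=15, preseed_B=15,
                 T_max=600.0),
            "sectors with nutrients placed throughout the lattice "
            "(15 A + 15 B per site)"),
        "sector-crossfeed": ScenarioPreset(
            "sector-crossfeed",
            _sym(lam=1.0, gamma=10.0, D=500.0, T_max=140.0),
            "sectors sustained by cross-feeding: high excretion, "
            "fast diffusion"),
        "engulfment": ScenarioPreset(
            "engulfment",
            _sym(lam=1.0, gamma=1.0, D=500.0, T_max=420.0),
            "fast diffusion with low excretion; interfaces coalesce and "
            "one species engulfs the other"),
        "spiral": ScenarioPreset(
            "spiral",
            _sym(lam=1.0, gamma=1.0, D=1.0, T_max=1000.0),
            "diffusion-limited mutualism; stable two-branch spiral"),
    }
    for lam in (2, 5, 10):
        name = f"spiral-lambda-{lam}"
        presets[name] = ScenarioPreset(
            name, _sym(lam=float(lam), gamma=1.0, D=1.0, T_max=1000.0),
            f"spiral regime at growth rate {lam}")
    for D in (10, 100, 250, 500):
        name = f"branch-D-{D}"
        presets[name] = ScenarioPreset(
            name, _sym(lam=10.0, gamma=1.0, D=float(D), T_max=400.0),
            f"branchy outer edge at growth rate 10, diffusion {D}")
    return presets


_PRESETS = _build_presets()


def preset_names() -> list:
    return sorted(_PRESETS)


def preset(name: str) -> ScenarioPreset:
    """Look up a named preset; raises with the list of valid names."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: "
            f"{', '.join(preset_names())}") from None
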