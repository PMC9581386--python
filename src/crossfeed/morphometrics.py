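"""Colony measurements: radius, roughness, interface traces and their MSD,
power-law fits, spiral branch width, advancing-tip angles and the spiral
growth-bookkeeping check.

Interface convention (fixed by this package, documented here so results are
comparable across runs): unlike-species boundaries are located on rings of
constant rounded radius around the colony origin, chained ring-to-ring by
angular proximity, and reported as lateral displacement increments
y(s+1) - y(s) = r * wrap(theta(s+1) - theta(s)) without any detrending.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .model import EMPTY, SPECIES_1, SPECIES_2, ColonyState

__all__ = [
    "InterfaceTrace",
    "InterfaceSet",
    "MSDCurve",
    "PowerLawFit",
    "SpiralMetrics",
    "colony_radius",
    "roughness",
    "extract_interfaces",
    "interface_msd",
    "average_msd",
    "fit_power_law",
    "branch_width",
    "characteristic_width",
    "tip_angles",
    "nutrient_profile",
    "spiral_growth_check",
]


# ---------------------------------------------------------------------------
# Frontier geometry
# ---------------------------------------------------------------------------

def _frontier_mask(cell_grid: np.ndarray) -> np.ndarray:
    """Occupied sites with at least one empty 4-neighbour (off-lattice
    neighbours count as empty)."""
    occ = cell_grid != EMPTY
    empty = np.pad(~occ, 1, constant_values=True)
    adj_empty = (empty[:-2, 1:-1] | empty[2:, 1:-1]
                 | empty[1:-1, :-2] | empty[1:-1, 2:])
    return occ & adj_empty


def _frontier_distances(state: ColonyState, origin) -> np.ndarray:
    mask = _frontier_mask(state.cell_grid)
    if not mask.any():
        raise ValueError("no cells in the colony")
    xs, ys = np.nonzero(mask)
    return np.hypot(xs - origin[0], ys - origin[1])


def colony_radius(state: ColonyState, origin) -> float:
    """Mean origin distance over all frontier cells."""
    return float(_frontier_distances(state, origin).mean())


def roughness(state: ColonyState, origin) -> float:
    """Standard deviation of frontier-cell distances about the mean radius."""
    return float(_frontier_distances(state, origin).std())


# ---------------------------------------------------------------------------
# Interface traces
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class InterfaceTrace:
    """Lateral meander of one inter-species boundary.

    ``s`` is radial progress (ring index, lattice units, strictly
    increasing); ``y`` the cumulative lateral displacement in lattice units;
    ``theta`` the unwrapped boundary angle at each ring.
    """

    s: np.ndarray
    y: np.ndarray
    theta: np.ndarray

    def __len__(self) -> int:
        return len(self.s)


@dataclasses.dataclass
class InterfaceSet:
    traces: list
    engulfed: bool = False

    def __iter__(self):
        return iter(self.traces)

    def __len__(self):
        return len(self.traces)


def _ring_boundaries(angles: np.ndarray, species: np.ndarray) -> np.ndarray:
    """Angular positions where the species changes along a sorted ring."""
    order = np.argsort(angles)
    a = angles[order]
    sp = species[order]
    nxt = np.roll(sp, -1)
    change = sp != nxt
    if not change.any():
        return np.empty(0)
    a_next = np.roll(a, -1)
    mid = (a + a_next) / 2.0
    # the wrap-around pair straddles +-pi
    mid[-1] = (a[-1] + a_next[-1] + 2 * np.pi) / 2.0
    mid = np.mod(mid + np.pi, 2 * np.pi) - np.pi
    return mid[change]


def _wrap(dtheta):
    return np.mod(dtheta + np.pi, 2 * np.pi) - np.pi


def extract_interfaces(state: ColonyState, origin,
                       r_start: Optional[float] = None,
                       min_length: int = 10) -> InterfaceSet:
    """Chain unlike-species boundaries into radial traces.

    Boundaries are found on rings of rounded radius k and matched to the
    nearest active trace at ring k-1 (subject to a lateral jump cap);
    unmatched boundaries open new traces, unmatched traces close.  If one
    species is absent the set is empty and flagged as engulfed.
    """
    grid = state.cell_grid
    has1 = (grid == SPECIES_1).any()
    has2 = (grid == SPECIES_2).any()
    if not (has1 and has2):
        return InterfaceSet([], engulfed=True)

    xs, ys = np.nonzero(grid != EMPTY)
    sp = grid[xs, ys]
    dist = np.hypot(xs - origin[0], ys - origin[1])
    ang = np.arctan2(ys - origin[1], xs - origin[0])
    ring = np.rint(dist).astype(int)

    if r_start is None:
        r_start = 3
    # only rings dense enough to close around the colony are usable
    max_ring = ring.max()
    counts = np.bincount(ring, minlength=max_ring + 1)
    usable = [k for k in range(int(np.ceil(r_start)), max_ring + 1)
              if counts[k] >= 5.5 * k]
    if not usable:
        return InterfaceSet([], engulfed=False)

    active = []    # dicts: theta (unwrapped), y, records [(s, theta, y)]
    finished = []
    prev_k = None
    for k in usable:
        if prev_k is not None and k != prev_k + 1:
            finished.extend(active)   # radial gap: close everything
            active = []
        prev_k = k
        sel = ring == k
        bounds = _ring_boundaries(ang[sel], sp[sel])
        # greedy nearest matching between active traces and boundaries
        cap = max(0.6, 6.0 / k)     # max angular jump per unit radius
        pairs = []
        for ti, tr in enumerate(active):
            for bi, b in enumerate(bounds):
                d = abs(_wrap(b - tr["theta"]))
                if d <= cap:
                    pairs.append((d, ti, bi))
        pairs.sort(key=lambda p: p[0])
        used_t, used_b = set(), set()
        matches = {}
        for d, ti, bi in pairs:
            if ti in used_t or bi in used_b:
                continue
            used_t.add(ti)
            used_b.add(bi)
            matches[ti] = bi
        new_active = []
        for ti, tr in enumerate(active):
            if ti in matches:
                b = bounds[matches[ti]]
                dth = _wrap(b - tr["theta"])
                tr["theta"] += dth
                tr["y"] += k * dth
                tr["records"].append((k, tr["theta"], tr["y"]))
                new_active.append(tr)
            else:
                finished.append(tr)
        for bi, b in enumerate(bounds):
            if bi not in used_b:
                new_active.append({"theta": float(b), "y": 0.0,
                                   "records": [(k, float(b), 0.0)]})
        active = new_active
    finished.extend(active)

    traces = []
    for tr in finished:
        if len(tr["records"]) < min_length:
            continue
        recs = np.asarray(tr["records"], dtype=float)
        traces.append(InterfaceTrace(s=recs[:, 0], theta=recs[:, 1],
                                     y=recs[:, 2]))
    traces.sort(key=len, reverse=True)
    return InterfaceSet(traces, engulfed=False)


# ---------------------------------------------------------------------------
# MSD and power laws
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MSDCurve:
    x: np.ndarray
    msd: np.ndarray


def interface_msd(trace: InterfaceTrace,
                  windows: Sequence[int]) -> MSDCurve:
    """Sliding-window MSD: mean over start points of (y(s+x) - y(s))^2.

    Windows longer than the trace are omitted with a warning.
    """
    y = np.asarray(trace.y, dtype=float)
    n = len(y)
    xs, vals = [], []
    for x in windows:
        x = int(x)
        if x >= n:
            warnings.warn(f"window {x} exceeds trace length {n}; omitted")
            continue
        if x == 0:
            xs.append(0)
            vals.append(0.0)
            continue
        d = y[x:] - y[:-x]
        xs.append(x)
        vals.append(float(np.mean(d * d)))
    return MSDCurve(np.asarray(xs, dtype=float), np.asarray(vals))


def average_msd(traces: Sequence[InterfaceTrace],
                windows: Sequence[int]) -> MSDCurve:
    """Across-trace mean of the per-trace MSD curves (matching windows)."""
    curves = [interface_msd(tr, windows) for tr in traces]
    if not curves:
        raise ValueError("no traces to average")
    common = sorted(set.intersection(*[set(c.x.tolist()) for c in curves]))
    if not common:
        raise ValueError("no common window sizes across traces")
    out = []
    for x in common:
        out.append(np.mean([c.msd[np.where(c.x == x)[0][0]] for c in curves]))
    return MSDCurve(np.asarray(common, dtype=float), np.asarray(out))


@dataclasses.dataclass
class PowerLawFit:
    exponent: float
    prefactor: float
    stderr: float


def fit_power_law(xs, ys, fit_range=None) -> PowerLawFit:
    """Least-squares line through (log x, log y); slope = exponent."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if fit_range is not None:
        lo, hi = fit_range
        sel = (xs >= lo) & (xs <= hi)
        xs, ys = xs[sel], ys[sel]
    if len(xs) < 3:
        raise ValueError("need at least 3 points to fit")
    if (xs <= 0).any() or (ys <= 0).any():
        raise ValueError("power-law fit requires positive values")
    res = stats.linregress(np.log(xs), np.log(ys))
    return PowerLawFit(exponent=float(res.slope),
                       prefactor=float(np.exp(res.intercept)),
                       stderr=float(res.stderr))


# ---------------------------------------------------------------------------
# Spiral morphometrics
# ---------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _open_space_stretch(grid: np.ndarray, species: int) -> np.ndarray:
    """Largest 8-connected component of ``species`` cells that touch empty
    space; boolean mask (empty if the species has no exposed cells)."""
    mask = grid == species
    # off-lattice does not count as open space (colonies never reach it)
    empty = np.pad(grid == EMPTY, 1, constant_values=False)
    adj_empty = (empty[:-2, 1:-1] | empty[2:, 1:-1]
                 | empty[1:-1, :-2] | empty[1:-1, 2:])
    outer = mask & adj_empty
    if not outer.any():
        return np.zeros_like(mask)
    lab, n = ndimage.label(outer, structure=_STRUCT8)
    sizes = ndimage.sum_labels(outer, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _stretch_components(grid: np.ndarray, species: int,
                        min_size: int = 8) -> int:
    mask = grid == species
    empty = np.pad(grid == EMPTY, 1, constant_values=False)
    adj_empty = (empty[:-2, 1:-1] | empty[2:, 1:-1]
                 | empty[1:-1, :-2] | empty[1:-1, 2:])
    outer = mask & adj_empty
    lab, n = ndimage.label(outer, structure=_STRUCT8)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(outer, lab, index=np.arange(1, n + 1))
    return int((sizes >= min_size).sum())


def branch_width(state: ColonyState, origin=None) -> float:
    """Mean width of the widest open-space frontier stretch.

    For each cell of the stretch the width is 1 + the distance to the
    species' inner edge (cells touching the other species), i.e. the span
    between the outer and inner boundaries of the branch.
    """
    grid = state.cell_grid
    widths = []
    for species, other in ((SPECIES_1, SPECIES_2), (SPECIES_2, SPECIES_1)):
        stretch = _open_space_stretch(grid, species)
        if not stretch.any():
            continue
        mask_other = np.pad(grid == other, 1, constant_values=False)
        adj_other = (mask_other[:-2, 1:-1] | mask_other[2:, 1:-1]
                     | mask_other[1:-1, :-2] | mask_other[1:-1, 2:])
        inner = (grid == species) & adj_other
        if not inner.any():
            continue
        # distance from every site to the nearest inner-edge site
        dist = ndimage.distance_transform_edt(~inner)
        widths.append(float(dist[stretch].mean() + 1.0))
    if not widths:
        raise ValueError("no open-space frontier stretch with an inner edge")
    return float(np.mean(widths))


def characteristic_width(D: float, lambda_max: float) -> float:
    """Dimensional estimate sqrt(2 D / lambda) of the branch width."""
    if lambda_max <= 0:
        raise ValueError("lambda_max must be > 0")
    if D < 0:
        raise ValueError("D must be >= 0")
    return float(np.sqrt(2.0 * D / lambda_max))


def _arc_endpoints(angles: np.ndarray):
    """Endpoints of the circular arc covered by a set of angles.

    Returns (lo, hi) with hi > lo in an unwrapped frame; None when the
    angles cover the whole circle (no usable gap).
    """
    a = np.sort(angles)
    gaps = np.diff(np.concatenate([a, [a[0] + 2 * np.pi]]))
    gi = int(np.argmax(gaps))
    if gaps[gi] < np.deg2rad(15):
        return None
    lo = a[(gi + 1) % len(a)]
    hi = a[gi]
    if hi < lo:
        hi += 2 * np.pi
    return lo, hi


@dataclasses.dataclass
class SpiralMetrics:
    """Per-snapshot spiral measurements (angles relative to t0)."""

    t: np.ndarray
    theta1: np.ndarray      # unwrapped advancing-tip angle, species 1
    theta2: np.ndarray      # unwrapped advancing-tip angle, species 2
    separation: np.ndarray  # |wrapped tip separation| in [0, pi]
    branch_count: np.ndarray
    width: np.ndarray


def tip_angles(snapshots: Sequence, origin, t0: float = None) -> SpiralMetrics:
    """Track the advancing tip of each species across snapshots.

    ``snapshots`` is a sequence of (t, ColonyState).  The tip of a species
    is an endpoint of the angular arc covered by its open-space frontier
    stretch; endpoints are matched across snapshots by angular continuity
    (assumes < pi/2 motion per step, checked at runtime) and the endpoint
    with the larger cumulative drift is reported as the advancing tip.
    Angles are reported relative to the first snapshot at or after ``t0``.
    """
    snaps = sorted(snapshots, key=lambda p: p[0])
    if t0 is not None:
        snaps = [p for p in snaps if p[0] >= t0]
    if not snaps:
        raise ValueError("no snapshots at or after t0")

    ts, widths, counts = [], [], []
    # per species, two endpoint tracks: cumulative unwrapped angles
    tracks = {SPECIES_1: None, SPECIES_2: None}
    series = {SPECIES_1: [], SPECIES_2: []}
    for t, state in snaps:
        ts.append(t)
        try:
            widths.append(branch_width(state))
        except ValueError:
            widths.append(np.nan)
        counts.append(_stretch_components(state.cell_grid, SPECIES_1)
                      + _stretch_components(state.cell_grid, SPECIES_2))
        for species in (SPECIES_1, SPECIES_2):
            stretch = _open_space_stretch(state.cell_grid, species)
            if not stretch.any():
                series[species].append((np.nan, np.nan))
                continue
            xs, ys = np.nonzero(stretch)
            ang = np.arctan2(ys - origin[1], xs - origin[0])
            ends = _arc_endpoints(ang)
            if ends is None:
                series[species].append((np.nan, np.nan))
                continue
            lo, hi = ends
            if tracks[species] is None:
                tracks[species] = [lo, hi]
            else:
                cur = tracks[species]
                d_direct = (abs(_wrap(lo - cur[0])), abs(_wrap(hi - cur[1])))
                d_swap = (abs(_wrap(hi - cur[0])), abs(_wrap(lo - cur[1])))
                if sum(d_swap) < sum(d_direct):
                    lo, hi = hi, lo
                steps = (_wrap(lo - cur[0]), _wrap(hi - cur[1]))
                if max(abs(steps[0]), abs(steps[1])) > np.pi / 2:
                    warnings.warn(
                        "tip moved more than pi/2 between snapshots; "
                        "use a finer snapshot cadence")
                cur[0] += steps[0]
                cur[1] += steps[1]
            series[species].append(tuple(tracks[species]))

    def _advancing(track_pairs):
        """Pick the arc endpoint on the winding side as the advancing tip.

        Both endpoints drift with the spiral; the advancing tip is the
        ccw-start endpoint when the spiral winds clockwise (net drift < 0)
        and the ccw-end endpoint otherwise.
        """
        arr = np.asarray(track_pairs, dtype=float)  # (T, 2) unwrapped
        if np.isnan(arr).all():
            return np.full(len(arr), np.nan), np.full(len(arr), np.nan)
        drift = np.nansum(arr - arr[0], axis=0)
        col = 0 if drift[0] + drift[1] < 0 else 1
        rel = arr[:, col] - arr[0, col]
        return rel, arr[:, col]

    rel1, abs1 = _advancing(series[SPECIES_1])
    rel2, abs2 = _advancing(series[SPECIES_2])
    sep = np.abs(_wrap(abs1 - abs2))
    return SpiralMetrics(
        t=np.asarray(ts, dtype=float),
        theta1=rel1, theta2=rel2, separation=sep,
        branch_count=np.asarray(counts),
        width=np.asarray(widths, dtype=float))


def nutrient_profile(state: ColonyState):
    """Copies of the per-site A and B molecule count grids."""
    return state.nutrient_A.copy(), state.nutrient_B.copy()


def spiral_growth_check(w, r, theta, rho, eps: float = 1e-12) -> np.ndarray:
    """Relative residual of d(rho) against 2 (w r dtheta + pi r dw).

    All inputs are aligned series over the same snapshot times.  Returns
    per-interval relative residuals; their median summarizes how well the
    two-branch bookkeeping identity holds.
    """
    w = np.asarray(w, dtype=float)
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if not (len(w) == len(r) == len(theta) == len(rho)):
        raise ValueError("series must be aligned (equal lengths)")
    if len(w) < 2:
        raise ValueError("need at least 2 samples")
    dw = np.diff(w)
    dth = np.abs(np.diff(theta))  # tip speed; winding direction irrelevant
    drho = np.diff(rho)
    rm = (r[:-1] + r[1:]) / 2.0
    wm = (w[:-1] + w[1:]) / 2.0
    pred = 2.0 * (wm * rm * dth + np.pi * rm * dw)
    denom = np.maximum(np.abs(drho), eps)
    return (drho - pred) / denom
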