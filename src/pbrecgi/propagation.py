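"""Propagating action potentials on the epicardial mesh.

Each mesh vertex carries one cell model; vertices connected by a
triangulation edge exchange a coupling current I = g (V_j - V_i) with
node-to-node conductance g = gbar / d^2, where d is the edge length (mm).
Conduction is isotropic and homogeneous: the same gbar everywhere. A beat is
initiated by injecting a stimulus current at an origin vertex and its 1-ring
neighbours for a couple of milliseconds.

The free parameter gbar only sets the propagation speed; it is calibrated by
bisection so that total activation of the surface takes a prescribed time
(default 60-100 ms), which reproduces the physiological sequence of a
propagating activation front, fully activated ventricles, a recovery wave,
and fully recovered ventricles within a 550-sample beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .cellmodels import CellModel, get_cell_model
from .mesh import TriSurfaceMesh

#: default stimulus amplitude per model (model units of current)
_DEFAULT_STIM_AMPLITUDE = {"fhn": 4.0, "lr92": 20.0}
#: internal integration substeps per output sample, per model
_DEFAULT_SUBSTEPS = {"fhn": 10, "lr92": 50}

VOLTAGE_BOUNDS_MV = (-120.0, 60.0)


class SimulationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class PropagationParams:
    """Parameters of the node-coupling propagation model.

    gbar : coupling strength, model units * mm^2 (g = gbar / d^2 per edge)
    dt : output sampling interval, ms
    n_steps : number of output samples per beat (default 550)
    stim_amplitude : stimulus current, model units (model default if None)
    stim_duration : ms
    stim_start : ms
    n_substeps : internal integration steps per output sample
    """

    gbar: float = 0.0
    dt: float = 1.0
    n_steps: int = 550
    stim_amplitude: float | None = None
    stim_duration: float = 2.0
    stim_start: float = 10.0
    n_substeps: int | None = None

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass
class SimulatedBeat:
    """Per-node voltage time series of one simulated beat.

    phi_H : (n_nodes, n_steps) mV; origin : stimulated vertex id.
    """

    phi_H: np.ndarray
    origin: int
    model: str
    dt: float

    @property
    def n_nodes(self) -> int:
        return self.phi_H.shape[0]

    @property
    def n_steps(self) -> int:
        return self.phi_H.shape[1]

    def activation_times(self, threshold_mv: float = -40.0) -> np.ndarray:
        """First upward crossing of a voltage threshold per node, in ms
        (the simulator's ground-truth activation sequence); NaN where the
        node never activates."""
        above = self.phi_H > threshold_mv
        first = np.argmax(above, axis=1).astype(float) * self.dt
        first[~above.any(axis=1)] = np.nan
        return first


def coupling_matrix(mesh: TriSurfaceMesh) -> sparse.csr_matrix:
    """Graph Laplacian-like operator L with edge weights 1/d^2 such that the
    coupling current vector is ``gbar * (L @ V)``."""
    w = 1.0 / mesh.edge_lengths() ** 2
    adj = mesh.adjacency(w)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (adj - sparse.diags(deg)).tocsr()


def stimulus_vertices(mesh: TriSurfaceMesh, origin: int) -> np.ndarray:
    """The origin vertex and its 1-ring neighbourhood."""
    e = mesh.edges()
    ring = np.unique(np.concatenate([e[e[:, 0] == origin, 1],
                                     e[e[:, 1] == origin, 0]]))
    return np.unique(np.concatenate([[origin], ring]))


def simulate_beat(mesh: TriSurfaceMesh, model: CellModel | str,
                  params: PropagationParams, origin: int = 0) -> SimulatedBeat:
    """Simulate one beat paced from ``origin``; returns voltages in mV.

    All nodes start at the cell model's resting state. Explicit time stepping
    at dt / n_substeps; the run aborts with a SimulationError if voltages
    leave physiological bounds (decrease the step size or gbar).
    """
    if isinstance(model, str):
        model = get_cell_model(model)
    n = mesh.n_vertices
    if not (0 <= origin < n):
        raise ValueError(f"origin vertex {origin} outside mesh")
    amp = params.stim_amplitude
    if amp is None:
        amp = _DEFAULT_STIM_AMPLITUDE[model.name]
    n_sub = params.n_substeps or _DEFAULT_SUBSTEPS[model.name]
    dt_int = params.dt / n_sub

    L = coupling_matrix(mesh)
    stim_idx = stimulus_vertices(mesh, origin)
    state = np.repeat(model.resting_state()[:, None], n, axis=1)
    phi = np.empty((n, params.n_steps))
    phi[:, 0] = model.voltage_mv(state[model.v_index])

    lo, hi = VOLTAGE_BOUNDS_MV
    t = 0.0
    for k in range(1, params.n_steps):
        for _ in range(n_sub):
            i_stim = np.zeros(n)
            if params.stim_start <= t < params.stim_start + params.stim_duration:
                i_stim[stim_idx] = amp
            i_coup = params.gbar * (L @ state[model.v_index])
            state = model.step(state, dt_int, i_stim + i_coup)
            t += dt_int
        v_mv = model.voltage_mv(state[model.v_index])
        if not np.all(np.isfinite(v_mv)) or v_mv.min() < lo or v_mv.max() > hi:
            raise SimulationError(
                f"voltage left [{lo}, {hi}] mV at t={t:.1f} ms; "
                "reduce the integration step (increase n_substeps) or gbar")
        phi[:, k] = v_mv
    return SimulatedBeat(phi_H=phi, origin=int(origin), model=model.name,
                         dt=params.dt)


def _activation_spread(mesh, model, params, origin) -> float:
    """Last-minus-first activation time; +inf if any node never activates."""
    beat = simulate_beat(mesh, model, params, origin=origin)
    act = beat.activation_times()
    if np.any(np.isnan(act)):
        return np.inf
    return float(np.nanmax(act) - np.nanmin(act))


def calibrate_gbar(mesh: TriSurfaceMesh, model: CellModel | str,
                   target_spread_ms: tuple[float, float] = (60.0, 100.0),
                   params: PropagationParams | None = None,
                   origin: int = 0,
                   bracket: tuple[float, float] = (1e-3, 64.0),
                   max_iter: int = 40) -> float:
    """Bisection on gbar so that the total activation spread of a paced beat
    falls inside ``target_spread_ms``. The spread decreases monotonically
    with gbar over the bracket (faster coupling, faster propagation).
    Deterministic.
    """
    if isinstance(model, str):
        model = get_cell_model(model)
    params = params or PropagationParams()
    lo_t, hi_t = target_spread_ms
    g_lo, g_hi = bracket
    if not (0 <= g_lo < g_hi):
        raise CalibrationError("invalid gbar bracket")

    def spread(g):
        p = PropagationParams(gbar=g, dt=params.dt, n_steps=params.n_steps,
                              stim_amplitude=params.stim_amplitude,
                              stim_duration=params.stim_duration,
                              stim_start=params.stim_start,
                              n_substeps=params.n_substeps)
        return _activation_spread(mesh, model, p, origin)

    s_lo, s_hi = spread(g_lo), spread(g_hi)
    if s_hi > hi_t:
        raise CalibrationError(
            f"spread {s_hi:.1f} ms at gbar={g_hi} still above target window; "
            "widen the bracket")
    if s_lo < lo_t:
        raise CalibrationError(
            f"spread {s_lo:.1f} ms at gbar={g_lo} already below target window")
    for _ in range(max_iter):
        g_mid = np.sqrt(g_lo * g_hi)  # bisect in log space
        s = spread(g_mid)
        if lo_t <= s <= hi_t:
            return float(g_mid)
        if s > hi_t:
            g_lo = g_mid
        else:
            g_hi = g_mid
    raise CalibrationError("bisection did not reach the target window")


# ---------------------------------------------------------------------------
# Regions and beat origins
# ---------------------------------------------------------------------------

REGIONS = ("LV", "RV", "BASE_APEX")


@dataclass
class RegionLabels:
    """Per-vertex anatomical region label: LV or RV free wall, or the
    basal/apical caps where no pacing is assumed."""

    labels: np.ndarray  # array of strings from REGIONS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    def vertices(self, region: str) -> np.ndarray:
        """Vertex ids of one region, or every vertex for 'ALL'."""
        if region.upper() == "ALL":
            return np.arange(len(self.labels))
        if region.upper() not in REGIONS:
            raise ValueError(f"unknown region '{region}'")
        return np.flatnonzero(self.labels == region.upper())


def label_regions(mesh: TriSurfaceMesh,
                  axis: np.ndarray = (0.0, 0.0, 1.0),
                  longitude_ref: np.ndarray = (1.0, 0.0, 0.0),
                  base_fraction: float = 0.2,
                  apex_fraction: float = 0.1) -> RegionLabels:
    """Partition a sphere-topology heart surface into LV / RV free walls and
    a BASE_APEX remainder, given the base-to-apex axis.

    The top ``base_fraction`` and bottom ``apex_fraction`` of the axis
    coordinate form BASE_APEX; the remaining band is split into two
    longitudinal sectors (LV at azimuth [0, pi) measured from
    ``longitude_ref`` around the axis).
    """
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    ref = np.asarray(longitude_ref, float)
    e1 = ref - (ref @ ax) * ax
    if np.linalg.norm(e1) < 1e-12:
        raise ValueError("longitude_ref must not be parallel to axis")
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ax, e1)

    t = mesh.vertices @ ax
    t = (t - t.min()) / (t.max() - t.min())
    labels = np.empty(mesh.n_vertices, dtype=object)
    cap = (t >= 1.0 - base_fraction) | (t <= apex_fraction)
    labels[cap] = "BASE_APEX"
    band = ~cap
    az = np.arctan2(mesh.vertices @ e2, mesh.vertices @ e1)
    labels[band & (az >= 0)] = "LV"
    labels[band & (az < 0)] = "RV"
    out = RegionLabels(labels.astype(str))
    for r in REGIONS:
        if len(out.vertices(r)) == 0:
            raise ValueError(f"region {r} is empty")
    return out


def choose_beat_origins(labels: RegionLabels, mesh: TriSurfaceMesh,
                        region: str = "ALL", n: int = 50,
                        min_spacing: float = 8.0, seed: int = 0,
                        exclude: np.ndarray | None = None) -> np.ndarray:
    """Pseudo-random beat origins in one region with a roughly uniform,
    equidistant distribution (rejection sampling on a pairwise minimum
    spacing). Deterministic per seed. If the spacing is infeasible it is
    relaxed geometrically with a warning.
    """
    cand = labels.vertices(region)
    if exclude is not None:
        cand = np.setdiff1d(cand, np.asarray(exclude, int))
    if n > len(cand):
        raise ValueError(
            f"requested {n} origins but region has {len(cand)} vertices")
    rng = np.random.default_rng(seed)
    spacing = float(min_spacing)
    while True:
        order = rng.permutation(cand)
        chosen: list[int] = []
        for v in order:
            p = mesh.vertices[v]
            if all(np.linalg.norm(p - mesh.vertices[c]) >= spacing
                   for c in chosen):
                chosen.append(int(v))
                if len(chosen) == n:
                    return np.array(chosen)
        spacing *= 0.8
        warnings.warn(
            f"min_spacing infeasible, relaxed to {spacing:.2f} mm",
            stacklevel=2)
        if spacing < 1e-3:
            return np.array(chosen + [int(v) for v in order
                                      if int(v) not in chosen][:n - len(chosen)])
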