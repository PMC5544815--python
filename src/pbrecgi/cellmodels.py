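"""Cardiac cell models for the simplified propagation simulator.

Two single-cell action-potential models are provided:

* ``fhn`` — the two-variable FitzHugh–Nagumo excitable system. It is
  dimensionless; an affine output map sends its resting potential to exactly
  -80 mV and its nominal spike peak to +20 mV, so that simulated APs carry
  the physiological resting offset (which becomes the near-constant first
  SVD component of any ensemble built from them). A time-scale constant
  converts model time to milliseconds so that a single AP lasts a few
  hundred ms.

* ``lr92`` — the eight-variable Luo–Rudy 1991 guinea-pig ventricular model
  (fast sodium, slow inward calcium, time-dependent and time-independent
  potassium, plateau and background currents). Voltages are in mV natively.

All right-hand sides are vectorized over cells: states have shape
(n_state, n_cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize


@dataclass
class CellModel:
    """Interface shared by the cell models.

    ``rhs(state, i_stim)`` returns d(state)/dt in model units per ms, with
    ``i_stim`` an external current (model units) added to the voltage
    equation. ``voltage_mv(v)`` applies the affine output map to millivolts.
    """

    name: str
    n_state: int
    v_index: int = 0
    mv_scale: float = 1.0
    mv_offset: float = 0.0

    def rhs(self, state: np.ndarray, i_stim: np.ndarray | float) -> np.ndarray:
        raise NotImplementedError

    def resting_state(self) -> np.ndarray:
        raise NotImplementedError

    def voltage_mv(self, v_model: np.ndarray) -> np.ndarray:
        return self.mv_scale * v_model + self.mv_offset

    def step(self, state: np.ndarray, dt: float,
             i_stim: np.ndarray | float = 0.0) -> np.ndarray:
        """Advance one time step of ``dt`` ms (forward Euler by default)."""
        return state + dt * self.rhs(state, i_stim)

    def resting_voltage_mv(self) -> float:
        return float(self.voltage_mv(self.resting_state()[self.v_index]))


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _fhn_rest(eps: float, beta0: float, gamma: float) -> tuple[float, float]:
    # intersection of the cubic and linear nullclines; unique stable point
    # for the classic parameter set
    coeffs = [1.0 / 3.0, 0.0, 1.0 / gamma - 1.0, beta0 / gamma]
    roots = np.roots(coeffs)
    v = float(np.real(roots[np.isreal(roots)][0]))
    w = (v + beta0) / gamma
    return v, w


@dataclass
class FitzHughNagumo(CellModel):
    """Classic FHN excitable cell,

        dv/dt = (v - v^3/3 - w + I) / tau_v
        dw/dt = eps (v + beta0 - gamma w) / tau_w

    with separate millisecond time constants for the fast excitation
    variable (``tau_v``, sets the upstroke velocity and hence supports a
    realistic conduction speed on coarse meshes) and the slow recovery
    variable (``tau_w``, sets the action-potential duration, a couple of
    hundred ms at the default)."""

    eps: float = 0.08
    beta0: float = 0.7
    gamma: float = 0.8
    tau_v: float = 1.5  # ms
    tau_w: float = 25.0  # ms
    v_peak_model: float = 2.0  # nominal spike peak, maps to +20 mV

    def __init__(self, eps: float = 0.08, beta0: float = 0.7,
                 gamma: float = 0.8, tau_v: float = 1.5, tau_w: float = 25.0,
                 v_peak_model: float = 2.0) -> None:
        self.eps, self.beta0, self.gamma = eps, beta0, gamma
        self.tau_v, self.tau_w = tau_v, tau_w
        self.v_peak_model = v_peak_model
        v_rest, _ = _fhn_rest(eps, beta0, gamma)
        scale = 100.0 / (v_peak_model - v_rest)  # -80 .. +20 mV span
        super().__init__(name="fhn", n_state=2, v_index=0,
                         mv_scale=scale, mv_offset=-80.0 - scale * v_rest)

    def rhs(self, state, i_stim=0.0):
        v, w = state[0], state[1]
        dv = (v - v ** 3 / 3.0 - w + i_stim) / self.tau_v
        dw = self.eps * (v + self.beta0 - self.gamma * w) / self.tau_w
        return np.stack([dv, dw])

    def resting_state(self) -> np.ndarray:
        return np.array(_fhn_rest(self.eps, self.beta0, self.gamma))


# ---------------------------------------------------------------------------
# Luo-Rudy 1991
# ---------------------------------------------------------------------------

_R, _T, _F = 8.3145, 310.0, 96485.0
_RTF = _R * _T / _F * 1000.0  # mV
_KO, _KI, _NAO, _NAI = 5.4, 145.0, 140.0, 18.0
_PR_NAK = 0.01833
_E_NA = _RTF * np.log(_NAO / _NAI)
_E_K = _RTF * np.log((_KO + _PR_NAK * _NAO) / (_KI + _PR_NAK * _NAI))
_E_K1 = _RTF * np.log(_KO / _KI)
_G_K = 0.282 * np.sqrt(_KO / 5.4)
_G_K1 = 0.6047 * np.sqrt(_KO / 5.4)


def _lr92_gate_rates(v: np.ndarray):
    """alpha/beta rate constants (1/ms) of the six LR92 gating variables."""
    v = np.asarray(v, float)
    safe = np.errstate(over="ignore", divide="ignore", invalid="ignore")
    with safe:
        a_m = 0.32 * (v + 47.13) / (1.0 - np.exp(-0.1 * (v + 47.13)))
        a_m = np.where(np.abs(v + 47.13) < 1e-7, 3.2, a_m)
        b_m = 0.08 * np.exp(-v / 11.0)

        lo = v < -40.0
        a_h = np.where(lo, 0.135 * np.exp(-(80.0 + v) / 6.8), 0.0)
        b_h = np.where(lo,
                       3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
                       1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
        a_j = np.where(
            lo,
            (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
            * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))), 0.0)
        b_j = np.where(
            lo,
            0.1212 * np.exp(-0.01052 * v)
            / (1.0 + np.exp(-0.1378 * (v + 40.14))),
            0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))))

        a_d = 0.095 * np.exp(-0.01 * (v - 5.0)) / (
            1.0 + np.exp(-0.072 * (v - 5.0)))
        b_d = 0.07 * np.exp(-0.017 * (v + 44.0)) / (
            1.0 + np.exp(0.05 * (v + 44.0)))
        a_f = 0.012 * np.exp(-0.008 * (v + 28.0)) / (
            1.0 + np.exp(0.15 * (v + 28.0)))
        b_f = 0.0065 * np.exp(-0.02 * (v + 30.0)) / (
            1.0 + np.exp(-0.2 * (v + 30.0)))
        a_x = 0.0005 * np.exp(0.083 * (v + 50.0)) / (
            1.0 + np.exp(0.057 * (v + 50.0)))
        b_x = 0.0013 * np.exp(-0.06 * (v + 20.0)) / (
            1.0 + np.exp(-0.04 * (v + 20.0)))
    return (a_m, b_m, a_h, b_h, a_j, b_j, a_d, b_d, a_f, b_f, a_x, b_x)


def _lr92_currents(v, m, h, j, d, f, x, cai):
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        i_na = 23.0 * m ** 3 * h * j * (v - _E_NA)
        e_si = 7.7 - 13.0287 * np.log(np.maximum(cai, 1e-10))
        i_si = 0.09 * d * f * (v - e_si)
        xi = np.where(
            v > -100.0,
            2.837 * (np.exp(0.04 * (v + 77.0)) - 1.0)
            / ((v + 77.0) * np.exp(0.04 * (v + 35.0))), 1.0)
        xi = np.where(np.abs(v + 77.0) < 1e-7,
                      2.837 * 0.04 / np.exp(0.04 * (v + 35.0)), xi)
        i_k = _G_K * x * xi * (v - _E_K)
        a_k1 = 1.02 / (1.0 + np.exp(0.2385 * (v - _E_K1 - 59.215)))
        b_k1 = ((0.49124 * np.exp(0.08032 * (v - _E_K1 + 5.476))
                 + np.exp(0.06175 * (v - _E_K1 - 594.31)))
                / (1.0 + np.exp(-0.5143 * (v - _E_K1 + 4.753))))
        i_k1 = _G_K1 * a_k1 / (a_k1 + b_k1) * (v - _E_K1)
        kp = 1.0 / (1.0 + np.exp((7.488 - v) / 5.98))
        i_kp = 0.0183 * kp * (v - _E_K1)
        i_b = 0.03921 * (v + 59.87)
    return i_na, i_si, i_k, i_k1, i_kp, i_b


@dataclass
class LuoRudy1991(CellModel):
    """Luo–Rudy 1991 ventricular cell. State: [V, m, h, j, d, f, X, Cai];
    V in mV, Cai in mM, gates dimensionless; time in ms."""

    def __init__(self) -> None:
        super().__init__(name="lr92", n_state=8, v_index=0,
                         mv_scale=1.0, mv_offset=0.0)

    def rhs(self, state, i_stim=0.0):
        v, m, h, j, d, f, x, cai = state
        (a_m, b_m, a_h, b_h, a_j, b_j,
         a_d, b_d, a_f, b_f, a_x, b_x) = _lr92_gate_rates(v)
        i_na, i_si, i_k, i_k1, i_kp, i_b = _lr92_currents(
            v, m, h, j, d, f, x, cai)
        dv = -(i_na + i_si + i_k + i_k1 + i_kp + i_b) + i_stim
        dcai = -1e-4 * i_si + 0.07 * (1e-4 - cai)
        return np.stack([
            dv,
            a_m * (1.0 - m) - b_m * m,
            a_h * (1.0 - h) - b_h * h,
            a_j * (1.0 - j) - b_j * j,
            a_d * (1.0 - d) - b_d * d,
            a_f * (1.0 - f) - b_f * f,
            a_x * (1.0 - x) - b_x * x,
            dcai,
        ])

    def gate_rates(self, v):
        return _lr92_gate_rates(v)

    def step(self, state, dt, i_stim=0.0):
        """Rush–Larsen update for the gates (exact exponential relaxation
        towards their voltage-dependent steady state, stable for stiff gate
        kinetics), forward Euler for V and Cai."""
        v, cai = state[0], state[7]
        rates = _lr92_gate_rates(v)
        i_na, i_si, i_k, i_k1, i_kp, i_b = _lr92_currents(*state)
        dv = -(i_na + i_si + i_k + i_k1 + i_kp + i_b) + i_stim
        new = np.empty_like(state)
        new[0] = v + dt * dv
        for g in range(6):
            a, b = rates[2 * g], rates[2 * g + 1]
            tau = 1.0 / (a + b)
            inf = a * tau
            new[g + 1] = inf + (state[g + 1] - inf) * np.exp(-dt / tau)
        new[7] = cai + dt * (-1e-4 * i_si + 0.07 * (1e-4 - cai))
        return new

    def resting_state(self) -> np.ndarray:
        return _lr92_resting_state()


@lru_cache(maxsize=1)
def _lr92_resting_state() -> np.ndarray:
    """Equilibrium of the unstimulated LR92 cell: settle by integration from
    textbook initial conditions, then polish with a root find."""
    model = LuoRudy1991.__new__(LuoRudy1991)
    CellModel.__init__(model, name="lr92", n_state=8, v_index=0)
    y = np.array([-84.38, 0.0017, 0.983, 0.995, 3e-6, 1.0, 0.0057, 2e-4])
    y = y[:, None]
    dt = 0.05
    for _ in range(int(3000 / dt)):
        y = model.step(y, dt)
    sol = optimize.fsolve(lambda s: model.rhs(s[:, None]).ravel(), y.ravel(),
                          full_output=False, xtol=1e-13)
    return np.asarray(sol, float)


_REGISTRY = {"fhn": FitzHughNagumo, "lr92": LuoRudy1991}


def get_cell_model(name: str, **kwargs) -> CellModel:
    """Instantiate a registered cell model ('fhn' or 'lr92')."""
    try:
        return _REGISTRY[name.lower()](**kwargs)
    except KeyError:
        raise ValueError(f"unknown cell model '{name}'") from None
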