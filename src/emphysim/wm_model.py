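"""Well-mixed kinetic model of inflammation and alveolar tissue remodeling.

The model describes the innate immune response of lung parenchyma to inhaled
particles with two algebraic response functions and thirteen coupled
non-linear ordinary differential equations.  The state tracks three
macrophage pools (undifferentiated, pro-inflammatory M1, anti-inflammatory
M2), five cytokines (IL-10, TNF-alpha, IL-1, TGF-beta, IL-8), fibroblasts,
collagen, matrix metalloproteinases (MMP), neutrophils and elastase.
Activation and inhibition loops are saturating Hill terms; recruitment of
monocytes by TNF-alpha and of fibroblast growth by TGF-beta follow cubic
empirical response curves from the wound-healing literature.

"Well-mixed" means there is no space: one compartment, mixed units as used
throughout the inflammation-modeling literature (cells for cell pools,
pg/ml for cytokines and proteases, ug for collagen).  The spatial
agent-based layer in :mod:`emphysim.abm` reuses these rates per grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Iterable

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "STATE_FIELDS",
    "ImmuneParams",
    "ImmuneState",
    "Trajectory",
    "monocyte_recruitment",
    "fibroblast_growth_factor",
    "hill",
    "derivatives",
    "integrate",
    "steady_state",
]

#: Canonical ordering of the thirteen state variables (also the CSV column
#: order used by trajectory export).
STATE_FIELDS = (
    "Mun", "M1", "M2", "IL10", "Ta", "IL1", "Tb",
    "F", "C", "MMP", "IL8", "N", "El",
)

#: Any state component exceeding this magnitude aborts an integration with a
#: diagnostic instead of silently overflowing to inf.
OVERFLOW_GUARD = 1e12


class IntegrationError(RuntimeError):
    """Raised when a trajectory diverges past the overflow guard."""


class ConvergenceError(RuntimeError):
    """Raised when no steady state is reached within the search horizon."""


def monocyte_recruitment(Ta: float) -> float:
    """Monocyte recruitment rate (cells/day) driven by TNF-alpha.

    Cubic empirical chemotaxis curve; ``Ta`` is the TNF-alpha concentration
    in pg/ml.  The curve is calibrated for the physiological range (roughly
    0-10 pg/ml); outside it the cubic grows without biological meaning, so
    spatial callers clamp their input (see :class:`emphysim.abm.ABConfig`).
    """
    if Ta < 0:
        raise ValueError(f"TNF-alpha concentration must be >= 0, got {Ta}")
    return 0.335 * Ta ** 3 - 6.309 * Ta ** 2 + 32.281 * Ta + 57.302


def fibroblast_growth_factor(Tb: float) -> float:
    """Dimensionless fibroblast proliferation factor driven by TGF-beta (pg/ml)."""
    if Tb < 0:
        raise ValueError(f"TGF-beta concentration must be >= 0, got {Tb}")
    return 0.05 * Tb ** 3 - 0.98 * Tb ** 2 + 6.54 * Tb + 7.11


def hill(x: float | np.ndarray, c: float) -> float | np.ndarray:
    """Saturating Hill activation ``x / (x + c)`` in [0, 1].

    ``c`` is the half-saturation constant (> 0).  The complementary
    inhibition form ``c / (x + c)`` is ``1 - hill(x, c)``.
    """
    if c <= 0:
        raise ValueError(f"Hill constant must be > 0, got {c}")
    return x / (x + c)


@dataclass
class ImmuneParams:
    """Rate constants of the kinetic model.

    Defaults are the literature values of the model's parameter table.
    Constants the source table leaves blank or ambiguous carry documented
    estimates and are listed in :attr:`ESTIMATED`; all are plain config
    entries and can be overridden.

    Units: activation rates ``k2-k4`` ml/pg/day; secretion rates ``k5-k9``,
    ``k12``, ``k13``, ``k15`` pg/cell/day; ``k10`` 1/day (multiplies the
    dimensionless growth factor); ``k11`` ug/cell/day; transition and
    decay rates 1/day; Hill constants ``c*`` pg/ml; ``dFC`` ml/pg/day.
    """

    # macrophage activation / transition
    k2: float = 0.1      # IL-1 driven activation to M1
    k3: float = 1.0      # TNF-alpha driven activation to M1
    k4: float = 0.3      # IL-10 driven activation to M2
    km12: float = 0.075  # M1 -> M2
    km21: float = 0.05   # M2 -> M1
    mu: float = 0.2      # macrophage emigration
    muN: float = 0.2     # neutrophil emigration (estimated; table row blank)
    # secretion
    k5: float = 5e-4     # IL-10 by M2
    k6: float = 7e-4     # TNF-alpha by M1
    k7: float = 5e-4     # IL-1 by M1
    k8: float = 0.07     # TGF-beta by M2
    k9: float = 0.04     # TGF-beta by fibroblasts
    k12: float = 3.0     # MMP by M1
    k13: float = 5e-4    # IL-8 by M2
    k15: float = 3.0     # elastase by neutrophils
    lam: float = 5e-6    # TGF-beta by damaged tissue, pg/cell/day
    # fibroblasts / matrix
    k10: float = 0.924   # fibroblast growth rate
    k11: float = 20.0    # collagen deposition by fibroblasts
    dF: float = 0.12     # fibroblast apoptosis
    dFC: float = 1e-3    # MMP-collagen cleavage coefficient (estimated)
    # Hill constants
    cIL1: float = 10.0   # IL-1 promotion on M1
    cTa: float = 10.0    # TNF-alpha promotion on M1
    cIL10: float = 5.0   # IL-10 promotion on M2
    c1: float = 100.0    # IL-10 self-inhibition
    c: float = 25.0      # IL-10 inhibition on IL-1 / TNF-alpha
    c2: float = 100.0    # IL-8 self-inhibition (estimated, mirrors c1)
    cIL8: float = 8.0    # IL-8 half-saturation of neutrophil recruitment
    # neutrophils
    k14rate: float = 10.0    # max neutrophil recruitment, cells/day (estimated)
    Nmax: float = 1000.0     # neutrophil carrying capacity (estimated)
    # decay
    dIL10: float = 2.5
    dTa: float = 55.0
    dIL1: float = 0.2
    dTb: float = 15.0
    dIL8: float = 2.5    # estimated, mirrors dIL10
    dM: float = 0.875
    dE: float = 1.0      # estimated

    #: Constants not fixed by the source parameter table (estimated here).
    ESTIMATED = frozenset({"muN", "dIL8", "c2", "Nmax", "dE", "dFC", "k14rate"})

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        for name in ("cIL1", "cTa", "cIL10", "c1", "c", "c2", "cIL8"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Hill constant {name} must be > 0")

    def replace(self, **kwargs) -> "ImmuneParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ImmuneParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ImmuneState:
    """The thirteen state variables (cells, pg/ml, ug) of the kinetic model."""

    Mun: float = 0.0
    M1: float = 0.0
    M2: float = 0.0
    IL10: float = 0.0
    Ta: float = 0.0
    IL1: float = 0.0
    Tb: float = 0.0
    F: float = 0.0
    C: float = 0.0
    MMP: float = 0.0
    IL8: float = 0.0
    N: float = 0.0
    El: float = 0.0

    def validate(self) -> None:
        for name in STATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"state component {name} is not finite: {v}")
            if v < 0:
                raise ValueError(f"state component {name} must be >= 0: {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "ImmuneState":
        return cls(**dict(zip(STATE_FIELDS, map(float, y))))

    @classmethod
    def baseline(cls) -> "ImmuneState":
        """Healthy-tissue baseline: resting monocyte pool at its
        recruitment/emigration balance, everything else zero."""
        return cls(Mun=monocyte_recruitment(0.0) / ImmuneParams().mu)


@dataclass
class Trajectory:
    """Time series of states: ``times`` (days) and an (n, 13) array."""

    times: np.ndarray
    values: np.ndarray  # shape (len(times), 13), columns in STATE_FIELDS order
    clamp_events: int = 0  # number of components clipped at zero

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(STATE_FIELDS)):
            raise ValueError("values shape does not match times")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def states(self) -> list[ImmuneState]:
        return [ImmuneState.from_array(row) for row in self.values]

    @property
    def final(self) -> ImmuneState:
        return ImmuneState.from_array(self.values[-1])

    def component(self, name: str) -> np.ndarray:
        return self.values[:, STATE_FIELDS.index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(STATE_FIELDS))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs(y: np.ndarray, p: ImmuneParams) -> np.ndarray:
    """Right-hand side on the raw state vector (STATE_FIELDS order)."""
    Mun, M1, M2, IL10, Ta, IL1, Tb, F, C, MMP, IL8, N, El = y

    a_IL1 = hill(IL1, p.cIL1)
    a_Ta = hill(Ta, p.cTa)
    a_IL10 = hill(IL10, p.cIL10)
    inh_self = p.c1 / (IL10 + p.c1)   # IL-10 self-inhibition
    inh_pro = p.c / (IL10 + p.c)      # IL-10 inhibition on IL-1 / TNF-alpha
    inh_IL8 = p.c2 / (IL8 + p.c2)

    dMun = (monocyte_recruitment(Ta)
            - p.k2 * Mun * a_IL1 - p.k3 * Mun * a_Ta - p.k4 * Mun * a_IL10
            - p.mu * Mun)
    dM1 = (p.k2 * Mun * a_IL1 + p.k3 * Mun * a_Ta
           + p.km21 * M2 - p.km12 * M1 - p.mu * M1)
    dM2 = p.k4 * Mun * a_IL10 - p.km21 * M2 + p.km12 * M1 - p.mu * M2
    dIL10 = p.k5 * M2 * inh_self - p.dIL10 * IL10
    dTa = p.k6 * M1 * inh_pro - p.dTa * Ta
    dIL1 = p.k7 * M1 * inh_pro - p.dIL1 * IL1
    dTb = p.k8 * M2 + p.k9 * F - p.dTb * Tb
    dF = p.k10 * fibroblast_growth_factor(Tb) * F - p.dF * F
    dC = p.k11 * F - p.dFC * MMP * C
    dMMP = p.k12 * M1 - p.dFC * MMP * C - p.dM * MMP
    dIL8 = p.k13 * M2 * inh_IL8 - p.dIL8 * IL8
    dN = p.k14rate * (1.0 - N / p.Nmax) * hill(IL8, p.cIL8) - p.muN * N
    dEl = p.k15 * N - p.dE * El

    return np.array([dMun, dM1, dM2, dIL10, dTa, dIL1, dTb,
                     dF, dC, dMMP, dIL8, dN, dEl])


def derivatives(state: ImmuneState, params: ImmuneParams) -> ImmuneState:
    """Time derivative of every state component (pure function)."""
    state.validate()
    return ImmuneState.from_array(_rhs(state.to_array(), params))


def integrate(
    state0: ImmuneState,
    params: ImmuneParams,
    duration: float,
    dt: float = 0.01,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from ``state0`` over ``duration`` days.

    ``dt`` is the output sampling step and, for ``method='euler'``, the
    fixed integration step.  The default adaptive stiff-capable scheme
    handles the fast TNF-alpha decay and fibroblast growth terms; explicit
    Euler is provided for lock-step consistency with the agent-based layer.
    Components driven marginally below zero by discretization are clamped
    to zero; the number of clamped entries is reported on the trajectory.
    """
    state0.validate()
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    y0 = state0.to_array()
    if duration == 0:
        return Trajectory(np.array([0.0]), y0[None, :])

    n = int(round(duration / dt))
    times = np.linspace(0.0, n * dt, n + 1)

    if method == "euler":
        values = np.empty((n + 1, y0.size))
        values[0] = y0
        clamps = 0
        y = y0.copy()
        for i in range(n):
            y = y + dt * _rhs(y, params)
            neg = y < 0
            clamps += int(neg.sum())
            y[neg] = 0.0
            if np.any(np.abs(y) > OVERFLOW_GUARD):
                bad = STATE_FIELDS[int(np.argmax(np.abs(y)))]
                raise IntegrationError(
                    f"component {bad} exceeded overflow guard at t={times[i+1]:g}")
            values[i + 1] = y
        return Trajectory(times, values, clamp_events=clamps)

    # Adaptive integration on the clipped vector field: evaluating the RHS at
    # max(y, 0) keeps the solver stable when a component grazes zero.
    def f(_t, y):
        return _rhs(np.maximum(y, 0.0), params)

    sol = solve_ivp(f, (0.0, times[-1]), y0, method=method, t_eval=times,
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    values = sol.y.T
    if np.any(np.abs(values) > OVERFLOW_GUARD):
        idx = np.unravel_index(int(np.argmax(np.abs(values))), values.shape)
        raise IntegrationError(
            f"component {STATE_FIELDS[idx[1]]} exceeded overflow guard")
    neg = values < 0
    values = np.where(neg, 0.0, values)
    return Trajectory(times, values, clamp_events=int(neg.sum()))


def steady_state(
    params: ImmuneParams,
    state0: ImmuneState | None = None,
    tol: float = 1e-6,
    horizon: float = 2000.0,
    chunk: float = 50.0,
) -> ImmuneState:
    """Relax the model to a fixed point by long-time integration.

    Integrates in chunks until the infinity norm of the derivative drops
    below ``tol`` (units: per-day rate) or ``horizon`` days elapse.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    state = state0 if state0 is not None else ImmuneState()
    t = 0.0
    norm = np.inf
    while t < horizon:
        traj = integrate(state, params, chunk, dt=chunk / 100)
        state = traj.final
        norm = float(np.max(np.abs(_rhs(state.to_array(), params))))
        if norm < tol:
            return state
        t += chunk
    raise ConvergenceError(
        f"no steady state within {horizon} days; last derivative norm {norm:g}")
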