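"""Grid-based agent model of smoking-driven alveolar inflammation.

Each grid cell represents a small portion of an alveolar unit and carries a
structural-integrity scalar ("tissue life" in [0, 1]), normalized elastin
and collagen content, deposited smoke particles and local cytokine/protease
concentrations.  Discrete cell agents (undifferentiated monocytes, M1/M2
macrophages, neutrophils, fibroblasts) patrol the grid, secrete and respond
to the local concentrations using the same rate constants as the well-mixed
kinetic model (:mod:`emphysim.wm_model`).

A periodic square-wave "smoking" signal deposits particles; resident
particles emit TNF-alpha, which recruits and activates macrophages.  At
sites with high pro-inflammatory load, damage-associated molecular patterns
(DAMPS) erode tissue life; a cell whose tissue life reaches zero is dead and
never recovers.  Damaged tissue secretes TGF-beta to recruit fibroblasts.
Proteases (MMP, elastase) degrade collagen and elastin, which feed the
composition-dependent stiffness of the finite-element layer.

The update is a fixed, documented phase sequence driven by a single seeded
random generator, so runs are bit-reproducible.  In ``deterministic_mode``
all Bernoulli/Poisson draws are replaced by fractional expected-value
updates on per-cell population counts; on a 1x1 grid with diffusion off and
DAMPS off this reduces exactly to an explicit-Euler integration of the
well-mixed equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .wm_model import (
    ImmuneParams,
    fibroblast_growth_factor,
    hill,
    monocyte_recruitment,
)

__all__ = [
    "CellKind",
    "CellAgent",
    "SmokingSignal",
    "ABConfig",
    "ABState",
    "init_grid",
    "deposit_particles",
    "step",
    "damaged_fraction",
    "run",
]

#: Local concentration fields tracked per grid cell (pg/ml).
CONC_FIELDS = ("IL10", "Ta", "IL1", "Tb", "IL8", "MMP", "El")

#: Decay-rate parameter name for each concentration field.
_DECAY_OF = {
    "IL10": "dIL10", "Ta": "dTa", "IL1": "dIL1", "Tb": "dTb",
    "IL8": "dIL8", "MMP": "dM", "El": "dE",
}


class CellKind(str, Enum):
    MONO_UN = "MONO_UN"
    M1 = "M1"
    M2 = "M2"
    NEUTROPHIL = "NEUTROPHIL"
    FIBROBLAST = "FIBROBLAST"


#: Kinds that perform the random-walk / chemotaxis movement phase.
MOBILE_KINDS = (CellKind.MONO_UN, CellKind.M1, CellKind.M2, CellKind.NEUTROPHIL)
#: Kinds that can phagocytose deposited particles.
PHAGOCYTE_KINDS = (CellKind.MONO_UN, CellKind.M1, CellKind.M2)


@dataclass
class CellAgent:
    """A discrete immune/stromal cell on the grid."""

    kind: CellKind
    row: int
    col: int
    age: int = 0


@dataclass
class SmokingSignal:
    """Periodic square-wave exposure signal.

    ``e_s`` particles are deposited at every step of the "on" phase of each
    period, for ``T_s`` steps of total smoking activity; afterwards the
    simulation runs ``post_steps`` further to (re-)equilibrate.  The signal
    frequency of the square wave is ``1 / period``.
    """

    e_s: int = 0
    T_s: int = 0
    period: int = 10
    duty: float = 0.5
    post_steps: int = 20

    def __post_init__(self) -> None:
        if self.e_s < 0 or int(self.e_s) != self.e_s:
            raise ValueError("e_s must be a non-negative integer")
        if self.T_s < 0:
            raise ValueError("T_s must be >= 0")
        if not 0 < self.duty <= 1:
            raise ValueError("duty must be in (0, 1]")
        if self.period < 1:
            raise ValueError("period must be >= 1")

    def active(self, step_index: int) -> bool:
        """True when particles are inhaled at this step."""
        if step_index >= self.T_s:
            return False
        return (step_index % self.period) < self.duty * self.period

    @property
    def total_steps(self) -> int:
        return self.T_s + self.post_steps


@dataclass
class ABConfig:
    """Configuration of the agent grid.

    Constants the biological source material leaves open are gathered here
    with documented defaults; all are plain config entries.

    ``dt`` is in days per step; with the default 0.1 every first-order rate
    of the kinetic parameter table satisfies ``rate * dt < 1`` except the
    fast cytokine decays, which are applied as exact exponential factors.
    ``s_p`` is the TNF-alpha (pg/ml) emitted per resident particle per
    step, and together with ``k_damps`` (tissue-life loss per unit
    inflammation per day) sets the damage timescale; both were calibrated
    once so that sustained medium exposure destroys most of the tissue
    while zero exposure leaves it exactly intact (see the methods note).
    ``ta_influx_cap`` clamps the TNF-alpha value fed to the cubic monocyte
    recruitment curve to its physiologically calibrated range.
    """

    rows: int = 13
    cols: int = 10
    dt: float = 0.1                  # days per step
    D: float = 0.2                   # cytokine diffusion, cell^2/step
    k_damps: float = 3.0             # tissue-life loss / unit inflammation / day
    s_p: float = 1.0e6               # TNF-alpha pg/ml per particle per step
    p_clear: float = 0.02            # per-step phagocytosis probability
    fib_recruit_threshold: float = 1.0  # Tb (pg/ml) above which fibroblasts seed
    k_eldeg: float = 0.05            # elastin degradation by elastase, ml/pg/day
    C0: float = 100.0                # initial per-cell collagen, ug
    mono_density: float = 1.0 / 25.0  # baseline MONO_UN agents per cell
    influx_scale: float = 0.01       # recruitment share routed to each cell
    ta_influx_cap: float = 10.0      # pg/ml clamp on Eq-1 input (inf to disable)
    deterministic_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("p_clear",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.D <= 0.25:
            raise ValueError("D must be in [0, 0.25] for a stable explicit step")


@dataclass
class ABState:
    """Full state of the agent grid.

    Per-cell numpy arrays plus the discrete agent list.  ``counts`` holds
    per-cell population counts per kind; in stochastic mode it is derived
    from the agent list, in deterministic mode it is the authoritative
    (fractional) representation.
    """

    config: ABConfig
    tissue_life: np.ndarray
    alive: np.ndarray
    cel: np.ndarray
    ccl: np.ndarray
    particles: np.ndarray
    C: np.ndarray
    conc: dict[str, np.ndarray]
    counts: dict[CellKind, np.ndarray]
    agents: list[CellAgent] = field(default_factory=list)
    rng: np.random.Generator = None  # type: ignore[assignment]
    step_count: int = 0
    total_deposited: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue_life.shape

    @property
    def n_cells(self) -> int:
        return self.tissue_life.size

    def agent_counts(self) -> dict[CellKind, np.ndarray]:
        """Per-cell population counts of every agent kind."""
        if self.config.deterministic_mode:
            return self.counts
        counts = {k: np.zeros(self.shape) for k in CellKind}
        for a in self.agents:
            counts[a.kind][a.row, a.col] += 1.0
        return counts

    def validate(self) -> None:
        shape = self.shape
        for name, arr in [("alive", self.alive), ("cel", self.cel),
                          ("ccl", self.ccl), ("particles", self.particles),
                          ("C", self.C), *self.conc.items()]:
            if arr.shape != shape:
                raise ValueError(f"array {name} has mismatched shape")
        if np.any(self.tissue_life < 0) or np.any(self.tissue_life > 1):
            raise ValueError("tissue_life out of [0, 1]")
        if np.any(self.tissue_life[~self.alive] != 0):
            raise ValueError("dead cells must have tissue_life == 0")
        for name, arr in self.conc.items():
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"concentration {name} invalid")
        for a in self.agents:
            if not (0 <= a.row < shape[0] and 0 <= a.col < shape[1]):
                raise ValueError("agent outside grid")


def init_grid(config: ABConfig) -> ABState:
    """Fresh healthy grid with patrolling undifferentiated macrophages.

    All cells start alive with full tissue life and full elastin/collagen
    content; ``floor(n_cells * mono_density)`` MONO_UN agents are placed
    uniformly at random.
    """
    shape = (config.rows, config.cols)
    rng = np.random.default_rng(config.seed)
    state = ABState(
        config=config,
        tissue_life=np.ones(shape),
        alive=np.ones(shape, dtype=bool),
        cel=np.ones(shape),
        ccl=np.ones(shape),
        particles=np.zeros(shape),
        C=np.full(shape, config.C0),
        conc={name: np.zeros(shape) for name in CONC_FIELDS},
        counts={k: np.zeros(shape) for k in CellKind},
        rng=rng,
    )
    n_agents = int(config.rows * config.cols * config.mono_density)
    cells = rng.integers(0, state.n_cells, size=n_agents)
    for idx in cells:
        r, c = divmod(int(idx), config.cols)
        state.agents.append(CellAgent(CellKind.MONO_UN, r, c))
        state.counts[CellKind.MONO_UN][r, c] += 1.0
    return state


def deposit_particles(
    state: ABState,
    signal: SmokingSignal,
    step_index: int,
    targets: Sequence[tuple[int, int]] | None = None,
) -> ABState:
    """Deposit ``e_s`` particles at random target cells if the signal is on.

    Outside the smoking window (or in the "off" phase of the square wave)
    the state is returned unchanged.  Each particle independently picks a
    uniform random target cell.
    """
    if not signal.active(step_index) or signal.e_s == 0:
        return state
    if targets is None:
        flat = state.rng.integers(0, state.n_cells, size=signal.e_s)
        rows, cols = np.divmod(flat, state.config.cols)
    else:
        if len(targets) == 0:
            raise ValueError("targets must be non-empty while the signal is active")
        picks = state.rng.integers(0, len(targets), size=signal.e_s)
        rows = np.array([targets[i][0] for i in picks])
        cols = np.array([targets[i][1] for i in picks])
    np.add.at(state.particles, (rows, cols), 1.0)
    state.total_deposited += signal.e_s
    return state


def damaged_fraction(state: ABState) -> float:
    """Fraction of grid cells that are dead, in [0, 1]."""
    return float((~state.alive).sum()) / state.n_cells


def _laplacian(x: np.ndarray) -> np.ndarray:
    """4-neighbor Laplacian with zero-flux (reflecting) boundaries."""
    p = np.pad(x, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]) - 4.0 * x


def _neighbors(r: int, c: int, shape: tuple[int, int]):
    if r > 0:
        yield r - 1, c
    if r < shape[0] - 1:
        yield r + 1, c
    if c > 0:
        yield r, c - 1
    if c < shape[1] - 1:
        yield r, c + 1


def step(state: ABState, params: ImmuneParams, config: ABConfig | None = None) -> ABState:
    """Advance the grid one time step (in place; the state is also returned).

    The update runs in a fixed phase order: particle TNF-alpha emission,
    agent secretion, cytokine diffusion, decay, monocyte influx, movement,
    differentiation/emigration, neutrophil/fibroblast recruitment,
    phagocytosis, matrix turnover, DAMPS damage, and TGF-beta secretion by
    damaged tissue.
    """
    cfg = config or state.config
    if cfg.deterministic_mode:
        return _step_deterministic(state, params, cfg)
    return _step_stochastic(state, params, cfg)


def _step_stochastic(state: ABState, p: ImmuneParams, cfg: ABConfig) -> ABState:
    dt = cfg.dt
    rng = state.rng
    conc = state.conc
    shape = state.shape

    # (1) particle TNF-alpha emission
    if state.particles.any():
        conc["Ta"] += cfg.s_p * state.particles

    # (2) agent secretion at occupied cells, with IL-10 inhibition factors
    counts = state.agent_counts()
    inh_self = p.c1 / (conc["IL10"] + p.c1)
    inh_pro = p.c / (conc["IL10"] + p.c)
    inh_il8 = p.c2 / (conc["IL8"] + p.c2)
    m1, m2 = counts[CellKind.M1], counts[CellKind.M2]
    fib, neut = counts[CellKind.FIBROBLAST], counts[CellKind.NEUTROPHIL]
    conc["IL10"] += p.k5 * m2 * inh_self * dt
    conc["Ta"] += p.k6 * m1 * inh_pro * dt
    conc["IL1"] += p.k7 * m1 * inh_pro * dt
    conc["Tb"] += (p.k8 * m2 + p.k9 * fib) * dt
    conc["IL8"] += p.k13 * m2 * inh_il8 * dt
    conc["MMP"] += p.k12 * m1 * dt
    conc["El"] += p.k15 * neut * dt

    # (3) mass-conserving 4-neighbor diffusion, zero-flux borders
    if cfg.D > 0:
        for name in CONC_FIELDS:
            conc[name] += cfg.D * _laplacian(conc[name])

    # (4) decay (exact exponential factor, stable for the fast decays)
    for name in CONC_FIELDS:
        conc[name] *= math.exp(-getattr(p, _DECAY_OF[name]) * dt)

    # (5) monocyte influx driven by the mean TNF-alpha level
    alive_idx = np.flatnonzero(state.alive.ravel())
    if alive_idx.size:
        mean_ta = min(float(conc["Ta"].mean()), cfg.ta_influx_cap)
        expected = monocyte_recruitment(mean_ta) * dt * cfg.influx_scale * alive_idx.size
        for _ in range(rng.poisson(expected)):
            r, c = divmod(int(alive_idx[rng.integers(alive_idx.size)]), cfg.cols)
            state.agents.append(CellAgent(CellKind.MONO_UN, r, c))

    # (6) movement: random walk, climbing the TNF-alpha gradient when high
    ta = conc["Ta"]
    for a in state.agents:
        a.age += 1
        if a.kind not in MOBILE_KINDS:
            continue
        nbrs = list(_neighbors(a.row, a.col, shape))
        if not nbrs:
            continue
        if ta[a.row, a.col] > p.cTa:
            best = max(nbrs, key=lambda rc: ta[rc])
            if ta[best] > ta[a.row, a.col]:
                a.row, a.col = best
                continue
        a.row, a.col = nbrs[rng.integers(len(nbrs))]

    # (7) differentiation / transition / emigration
    survivors: list[CellAgent] = []
    for a in state.agents:
        u = rng.random()
        here = (a.row, a.col)
        if a.kind is CellKind.MONO_UN:
            p_m1 = (p.k2 * hill(conc["IL1"][here], p.cIL1)
                    + p.k3 * hill(ta[here], p.cTa)) * dt
            p_m2 = p.k4 * hill(conc["IL10"][here], p.cIL10) * dt
            p_out = p.mu * dt
            if u < p_m1:
                a.kind = CellKind.M1
            elif u < p_m1 + p_m2:
                a.kind = CellKind.M2
            elif u < p_m1 + p_m2 + p_out:
                continue  # emigrates
        elif a.kind is CellKind.M1:
            if u < p.km12 * dt:
                a.kind = CellKind.M2
            elif u < (p.km12 + p.mu) * dt:
                continue
        elif a.kind is CellKind.M2:
            if u < p.km21 * dt:
                a.kind = CellKind.M1
            elif u < (p.km21 + p.mu) * dt:
                continue
        elif a.kind is CellKind.NEUTROPHIL:
            if u < p.muN * dt:
                continue
        elif a.kind is CellKind.FIBROBLAST:
            if u < p.dF * dt:
                continue
            if rng.random() < p.k10 * fibroblast_growth_factor(conc["Tb"][here]) * dt:
                survivors.append(CellAgent(CellKind.FIBROBLAST, a.row, a.col))
        survivors.append(a)
    state.agents = survivors

    # (8) neutrophil recruitment (local IL-8, global carrying capacity) and
    # fibroblast seeding where TGF-beta is high
    n_total = sum(1 for a in state.agents if a.kind is CellKind.NEUTROPHIL)
    cap = max(0.0, 1.0 - n_total / p.Nmax)
    if cap > 0:
        expect = p.k14rate * cap * hill(conc["IL8"], p.cIL8) * dt * state.alive
        draws = rng.poisson(expect)
        for r, c in zip(*np.nonzero(draws)):
            for _ in range(int(draws[r, c])):
                state.agents.append(CellAgent(CellKind.NEUTROPHIL, int(r), int(c)))
    fib_cells = {(a.row, a.col) for a in state.agents
                 if a.kind is CellKind.FIBROBLAST}
    seed_mask = (conc["Tb"] > cfg.fib_recruit_threshold) & state.alive
    for r, c in zip(*np.nonzero(seed_mask)):
        if (int(r), int(c)) not in fib_cells:
            state.agents.append(CellAgent(CellKind.FIBROBLAST, int(r), int(c)))

    # (9) phagocytosis: co-located macrophages clear particles
    for a in state.agents:
        if a.kind in PHAGOCYTE_KINDS and state.particles[a.row, a.col] >= 1:
            if rng.random() < cfg.p_clear:
                state.particles[a.row, a.col] -= 1.0

    # (10) matrix turnover: collagen deposition/cleavage, elastin degradation
    counts = state.agent_counts()
    cleaved = p.dFC * conc["MMP"] * state.C * dt
    state.C += p.k11 * counts[CellKind.FIBROBLAST] * dt - cleaved
    np.clip(state.C, 0.0, None, out=state.C)
    conc["MMP"] = np.clip(conc["MMP"] - cleaved, 0.0, None)
    state.ccl = np.clip(state.C / cfg.C0, 0.0, 1.0)
    state.cel *= np.exp(-cfg.k_eldeg * conc["El"] * dt)

    # (11) DAMPS damage: pro-inflammatory load erodes tissue life
    if cfg.k_damps > 0:
        index = 0.5 * (hill(conc["IL1"], p.cIL1) + hill(ta, p.cTa))
        state.tissue_life -= cfg.k_damps * dt * index * state.alive
        np.clip(state.tissue_life, 0.0, 1.0, out=state.tissue_life)
        died = state.alive & (state.tissue_life <= 0.0)
        if died.any():
            state.tissue_life[died] = 0.0
            state.alive[died] = False

    # (12) damaged tissue secretes TGF-beta to recruit wound healing
    conc["Tb"] += p.lam * (1.0 - state.tissue_life) * dt

    state.step_count += 1
    return state


def _step_deterministic(state: ABState, p: ImmuneParams, cfg: ABConfig) -> ABState:
    """Expected-value update on fractional per-cell population counts.

    All stochastic phases are replaced by their means; agents do not move.
    The local kinetics are advanced with one explicit-Euler step of the
    well-mixed equations evaluated at the start-of-step state, so with
    diffusion and DAMPS off a 1x1 grid reproduces the well-mixed Euler
    trajectory exactly.
    """
    dt = cfg.dt
    conc = state.conc
    cnt = state.counts

    # (1) particle TNF-alpha emission
    if state.particles.any():
        conc["Ta"] += cfg.s_p * state.particles

    mean_ta = min(float(conc["Ta"].mean()), cfg.ta_influx_cap)

    # (2-4, 7-8, 10) one Euler step of the local kinetics, influx excluded
    Mun, M1, M2 = cnt[CellKind.MONO_UN], cnt[CellKind.M1], cnt[CellKind.M2]
    N, F = cnt[CellKind.NEUTROPHIL], cnt[CellKind.FIBROBLAST]
    IL10, Ta, IL1 = conc["IL10"], conc["Ta"], conc["IL1"]
    Tb, IL8, MMP, El = conc["Tb"], conc["IL8"], conc["MMP"], conc["El"]
    a_il1, a_ta, a_il10 = hill(IL1, p.cIL1), hill(Ta, p.cTa), hill(IL10, p.cIL10)
    inh_self, inh_pro = p.c1 / (IL10 + p.c1), p.c / (IL10 + p.c)
    inh_il8 = p.c2 / (IL8 + p.c2)
    fg = (0.05 * Tb ** 3 - 0.98 * Tb ** 2 + 6.54 * Tb + 7.11)

    act1, act2 = p.k2 * Mun * a_il1 + p.k3 * Mun * a_ta, p.k4 * Mun * a_il10
    d = {
        "Mun": -act1 - act2 - p.mu * Mun,
        "M1": act1 + p.km21 * M2 - (p.km12 + p.mu) * M1,
        "M2": act2 + p.km12 * M1 - (p.km21 + p.mu) * M2,
        "IL10": p.k5 * M2 * inh_self - p.dIL10 * IL10,
        "Ta": p.k6 * M1 * inh_pro - p.dTa * Ta,
        "IL1": p.k7 * M1 * inh_pro - p.dIL1 * IL1,
        "Tb": p.k8 * M2 + p.k9 * F - p.dTb * Tb,
        "F": p.k10 * fg * F - p.dF * F,
        "C": p.k11 * F - p.dFC * MMP * state.C,
        "MMP": p.k12 * M1 - p.dFC * MMP * state.C - p.dM * MMP,
        "IL8": p.k13 * M2 * inh_il8 - p.dIL8 * IL8,
        "N": p.k14rate * (1.0 - N / p.Nmax) * hill(IL8, p.cIL8) - p.muN * N,
        "El": p.k15 * N - p.dE * El,
    }
    cnt[CellKind.MONO_UN] = np.clip(Mun + dt * d["Mun"], 0.0, None)
    cnt[CellKind.M1] = np.clip(M1 + dt * d["M1"], 0.0, None)
    cnt[CellKind.M2] = np.clip(M2 + dt * d["M2"], 0.0, None)
    cnt[CellKind.NEUTROPHIL] = np.clip(N + dt * d["N"], 0.0, None)
    cnt[CellKind.FIBROBLAST] = np.clip(F + dt * d["F"], 0.0, None)
    state.C = np.clip(state.C + dt * d["C"], 0.0, None)
    for name in CONC_FIELDS:
        conc[name] = np.clip(conc[name] + dt * d[name], 0.0, None)

    # (3) diffusion on the updated concentrations
    if cfg.D > 0:
        for name in CONC_FIELDS:
            conc[name] += cfg.D * _laplacian(conc[name])

    # (5) monocyte influx, distributed uniformly over alive cells
    n_alive = int(state.alive.sum())
    if n_alive:
        total = monocyte_recruitment(mean_ta) * dt * cfg.influx_scale * n_alive
        cnt[CellKind.MONO_UN][state.alive] += total / n_alive

    # (9) expected phagocytosis by resident macrophages
    macs = (cnt[CellKind.MONO_UN] + cnt[CellKind.M1] + cnt[CellKind.M2])
    removed = np.minimum(cfg.p_clear * np.minimum(macs, 1.0), state.particles)
    state.particles -= removed

    # (10) normalized matrix content
    state.ccl = np.clip(state.C / cfg.C0, 0.0, 1.0)
    state.cel *= np.exp(-cfg.k_eldeg * conc["El"] * dt)

    # (11) DAMPS damage
    if cfg.k_damps > 0:
        index = 0.5 * (hill(conc["IL1"], p.cIL1) + hill(conc["Ta"], p.cTa))
        state.tissue_life -= cfg.k_damps * dt * index * state.alive
        np.clip(state.tissue_life, 0.0, 1.0, out=state.tissue_life)
        died = state.alive & (state.tissue_life <= 0.0)
        if died.any():
            state.tissue_life[died] = 0.0
            state.alive[died] = False

    # (12) TGF-beta secretion by damaged tissue
    conc["Tb"] += p.lam * (1.0 - state.tissue_life) * dt

    state.step_count += 1
    return state


def run(
    state: ABState,
    signal: SmokingSignal,
    params: ImmuneParams,
    config: ABConfig | None = None,
    n_steps: int = 0,
) -> tuple[ABState, pd.DataFrame]:
    """Apply deposition + step ``n_steps`` times, recording aggregates.

    The returned frame has one row per executed step with the mean tissue
    life, damaged fraction, and grid-mean concentrations.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    cfg = config or state.config
    records = []
    for _ in range(n_steps):
        deposit_particles(state, signal, state.step_count)
        step(state, params, cfg)
        row = {
            "step": state.step_count,
            "mean_life": float(state.tissue_life.mean()),
            "damaged_frac": damaged_fraction(state),
        }
        for name in CONC_FIELDS:
            row[name] = float(state.conc[name].mean())
        records.append(row)
    columns = ["step", "mean_life", "damaged_frac", *CONC_FIELDS]
    return state, pd.DataFrame(records, columns=columns)
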