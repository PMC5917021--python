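"""Bidirectional coupling between the agent grid and the elastic solver.

A coupled run alternates: (i) a block of agent-model steps that deposit
particles, drive inflammation and degrade the matrix; (ii) a freeze in
which per-cell elastin/collagen content becomes per-element stiffness,
the plane-stress problem is solved under the breathing load, and every
cell whose strain exceeds its composition-weighted tensile limit is
killed.  The cycle repeats until the damaged area passes a stop fraction
(default 80%) or the requested horizon is reached.  A gate skips the
mechanical solve entirely once too little healthy tissue remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import abm
from .abm import ABConfig, ABState, SmokingSignal
from .mechanics import (
    BreathingLoad,
    MaterialField,
    QuadMesh,
    StrainField,
    build_mesh,
    mixture_modulus,
    rupture,
    solve_elasticity,
)
from .wm_model import ImmuneParams

__all__ = [
    "SKIP",
    "CouplingConfig",
    "CoupledHistory",
    "DamageRegion",
    "export_ab_to_fe",
    "apply_fe_to_ab",
    "run_coupled",
    "extract_damage_contours",
]

#: Sentinel returned by :func:`export_ab_to_fe` when the damage gate trips.
SKIP = "SKIP"


@dataclass
class CouplingConfig:
    ab_steps_per_cycle: int = 10      # 1 simulated day at dt = 0.1
    damage_stop_fraction: float = 0.80
    max_cycles: int = 100
    nu: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.damage_stop_fraction <= 1:
            raise ValueError("damage_stop_fraction must be in (0, 1]")
        if self.ab_steps_per_cycle < 1:
            raise ValueError("ab_steps_per_cycle must be >= 1")


@dataclass
class CoupledHistory:
    """Per-cycle records of a coupled run."""

    frame: pd.DataFrame                  # cycle, damaged_frac, mean_life, ...
    series: pd.DataFrame                 # per-step aggregates from the AB runs
    n_fe_solves: int = 0

    @property
    def final_damaged_fraction(self) -> float:
        return float(self.frame["damaged_frac"].iloc[-1]) if len(self.frame) else 0.0


def export_ab_to_fe(
    ab: ABState,
    coupling: CouplingConfig | None = None,
    cell_size: float = 1.0,
):
    """Freeze the agent grid into a mesh + material field, or ``SKIP``.

    Returns ``SKIP`` when the damaged fraction has reached the stop
    fraction (not enough healthy tissue for a meaningful solve); otherwise
    the grid-equivalent quad mesh and the per-element mixture moduli, with
    dead cells at 1 Pa.
    """
    cfg = coupling or CouplingConfig()
    if abm.damaged_fraction(ab) >= cfg.damage_stop_fraction:
        return SKIP
    rows, cols = ab.shape
    mesh = build_mesh(rows, cols, cell_size)
    mat = MaterialField.from_grid(ab.cel, ab.ccl, ab.alive, nu=cfg.nu)
    return mesh, mat


def apply_fe_to_ab(ab: ABState, strains: StrainField) -> ABState:
    """Kill every cell whose strain exceeds its tensile limit.

    Only the ``alive``/``tissue_life`` entries of ruptured cells change;
    everything else in the agent state is preserved.  Applying the same
    strain field twice is idempotent.
    """
    if strains.exx.size != ab.n_cells:
        raise ValueError("strain field does not match the agent grid")
    for r, c in rupture(strains, ab.cel, ab.ccl, ab.alive):
        ab.tissue_life[r, c] = 0.0
        ab.alive[r, c] = False
    return ab


def run_coupled(
    ab0: ABState,
    signal: SmokingSignal,
    params: ImmuneParams | None = None,
    ab_config: ABConfig | None = None,
    coupling: CouplingConfig | None = None,
    load: BreathingLoad | None = None,
) -> tuple[ABState, CoupledHistory]:
    """Run the full AB <-> FE cycle until stop fraction or ``max_cycles``."""
    params = params or ImmuneParams()
    ab_config = ab_config or ab0.config
    coupling = coupling or CouplingConfig()
    load = load or BreathingLoad()

    records = []
    all_series = []
    n_solves = 0
    ab = ab0
    for cycle in range(coupling.max_cycles):
        ab, series = abm.run(ab, signal, params, ab_config,
                             coupling.ab_steps_per_cycle)
        all_series.append(series)

        n_ruptured = 0
        max_strain = np.nan
        exported = export_ab_to_fe(ab, coupling)
        if exported is not SKIP:
            mesh, mat = exported
            _, strains = solve_elasticity(mesh, mat, load)
            n_solves += 1
            max_strain = float(strains.max_principal.max())
            before = int((~ab.alive).sum())
            ab = apply_fe_to_ab(ab, strains)
            n_ruptured = int((~ab.alive).sum()) - before

        records.append({
            "cycle": cycle,
            "damaged_frac": abm.damaged_fraction(ab),
            "mean_life": float(ab.tissue_life.mean()),
            "max_principal_strain": max_strain,
            "n_ruptured": n_ruptured,
        })
        if abm.damaged_fraction(ab) >= coupling.damage_stop_fraction:
            break

    frame = pd.DataFrame(records,
                         columns=["cycle", "damaged_frac", "mean_life",
                                  "max_principal_strain", "n_ruptured"])
    series = (pd.concat(all_series, ignore_index=True)
              if all_series else pd.DataFrame())
    return ab, CoupledHistory(frame=frame, series=series, n_fe_solves=n_solves)


@dataclass
class DamageRegion:
    """A connected patch of destroyed tissue (reporting only)."""

    label: int
    area: int                      # number of dead cells in the region
    cells: list[tuple[int, int]]
    boundary: list[tuple[int, int]]  # region cells adjacent to live tissue


def extract_damage_contours(ab: ABState) -> list[DamageRegion]:
    """Connected components of dead tissue after one morphological closing.

    4-connected labeling on the dead-cell mask; a single binary closing
    pass bridges one-cell gaps, mirroring contour extraction on the
    damaged zone.  Used for reporting/visualization; the mechanical model
    works directly on per-element materials.
    """
    dead = ~ab.alive
    if not dead.any():
        return []
    cross = ndimage.generate_binary_structure(2, 1)
    closed = ndimage.binary_closing(dead, structure=cross)
    # closing never removes actually dead cells
    mask = closed | dead
    labels, n = ndimage.label(mask, structure=cross)
    regions = []
    for lab in range(1, n + 1):
        cells = [tuple(map(int, rc)) for rc in zip(*np.nonzero(labels == lab))]
        boundary = []
        for r, c in cells:
            for rr, cc in abm._neighbors(r, c, ab.shape):
                if labels[rr, cc] != lab:
                    boundary.append((r, c))
                    break
        regions.append(DamageRegion(label=lab, area=len(cells), cells=cells,
                                    boundary=boundary))
    return regions
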