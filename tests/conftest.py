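import numpy as np
import pytest

from emphysim import ABConfig, ImmuneParams, ImmuneState, init_grid
from emphysim.abm import CONC_FIELDS, CellKind


@pytest.fixture
def params():
    return ImmuneParams()


@pytest.fixture
def wm_equiv_setup():
    """1x1 deterministic agent grid loaded with a mixed initial state, plus
    the matching well-mixed initial state (fibroblasts zero to stay clear of
    the exponential growth instability)."""
    cfg = ABConfig(rows=1, cols=1, dt=0.01, D=0.0, k_damps=0.0, s_p=0.0,
                   p_clear=0.0, influx_scale=1.0, mono_density=0.0,
                   deterministic_mode=True, ta_influx_cap=np.inf)
    ab = init_grid(cfg)
    s0 = ImmuneState(Mun=286.51, M1=50.0, M2=50.0, IL10=1.0, Ta=2.0, IL1=1.0,
                     Tb=1.0, F=0.0, C=100.0, MMP=1.0, IL8=1.0, N=10.0, El=1.0)
    ab.counts[CellKind.MONO_UN][0, 0] = s0.Mun
    ab.counts[CellKind.M1][0, 0] = s0.M1
    ab.counts[CellKind.M2][0, 0] = s0.M2
    ab.counts[CellKind.NEUTROPHIL][0, 0] = s0.N
    ab.counts[CellKind.FIBROBLAST][0, 0] = s0.F
    ab.C[0, 0] = s0.C
    for name in CONC_FIELDS:
        ab.conc[name][0, 0] = getattr(s0, name)
    return ab, cfg, s0


def ab_state_vector(ab):
    """13-component aggregate of a 1x1 grid in the canonical field order."""
    return np.array([
        ab.counts[CellKind.MONO_UN][0, 0],
        ab.counts[CellKind.M1][0, 0],
        ab.counts[CellKind.M2][0, 0],
        ab.conc["IL10"][0, 0],
        ab.conc["Ta"][0, 0],
        ab.conc["IL1"][0, 0],
        ab.conc["Tb"][0, 0],
        ab.counts[CellKind.FIBROBLAST][0, 0],
        ab.C[0, 0],
        ab.conc["MMP"][0, 0],
        ab.conc["IL8"][0, 0],
        ab.counts[CellKind.NEUTROPHIL][0, 0],
        ab.conc["El"][0, 0],
    ])
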