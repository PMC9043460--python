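"""Shared fixtures: the expensive forward simulations are session-scoped.

The baseline parameter set is the mid-range cornea (R = 7 mm, CCT = 550 um,
IOP = 20 mmHg, E = 0.4 MPa, a1 = 0.4, lg tau1 = -2.5); trend fixtures vary
one parameter at a time around it.
"""

import numpy as np
import pytest

from orasim.inversion import (SweepRanges, fit_inversion, sample_parameters,
                              run_sweep, validate_inversion)
from orasim.pipeline import SimulationConfig, simulate_ora

BASELINE = dict(R_mm=7.0, CCT_um=550.0, IOP_mmHg=20.0,
                E_MPa=0.4, a1=0.4, tau1_s=10.0 ** -2.5)


def run_case(config=None, **overrides):
    p = {**BASELINE, **overrides}
    return simulate_ora(p["R_mm"], p["CCT_um"], p["IOP_mmHg"],
                        p["E_MPa"], p["a1"], p["tau1_s"],
                        config or SimulationConfig(),
                        return_intermediates=True)


@pytest.fixture(scope="session")
def baseline_run():
    """Features, history and curve of the mid-range cornea (40x4 mesh)."""
    return run_case()


@pytest.fixture(scope="session")
def elastic_run():
    """Same cornea with all Prony moduli zero (pure elastic limit)."""
    cfg = SimulationConfig(a2=0.0, a3=0.0)
    return run_case(cfg, a1=0.0, tau1_s=1.0)


@pytest.fixture(scope="session")
def trend_features(baseline_run):
    """One-at-a-time parameter sweeps around the baseline (40x4 mesh).

    Returns {axis: {value: OraFeatures}} for axis in E_MPa / tau1_s /
    IOP_mmHg; the baseline run is reused where values coincide.
    """
    out = {"E_MPa": {}, "tau1_s": {}, "IOP_mmHg": {}}
    base_feats = baseline_run[0]
    for E in (0.2, 0.4, 0.6):
        out["E_MPa"][E] = base_feats if E == 0.4 else run_case(E_MPa=E)[0]
    for tau in (0.001, 0.01, 0.1):
        out["tau1_s"][tau] = run_case(tau1_s=tau)[0]
    for iop in (10.0, 20.0, 30.0):
        out["IOP_mmHg"][iop] = base_feats if iop == 20.0 else run_case(IOP_mmHg=iop)[0]
    return out


@pytest.fixture(scope="session")
def sweep_fit():
    """50-run scaled-down sweep plus its 70/30 quadratic-regression fit."""
    cfg = SimulationConfig().coarse()
    samples = sample_parameters(SweepRanges(n_samples=50, seed=7))
    table = run_sweep(samples, cfg)
    fit = fit_inversion(table, split=0.7, seed=3)
    metrics = validate_inversion(fit, fit.heldout_predictions)
    return table, fit, metrics
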