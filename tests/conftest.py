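"""Shared fixtures: the packaged column and its heavier simulation products.

Session scope keeps the expensive runs (column build, background settle,
step-drive scans) shared between the property tests and the acceptance
tests.
"""

import numpy as np
import pandas as pd
import pytest

from popcolumn.column import build_column, load_default_config
from popcolumn.experiments import (
    DriveProtocol,
    homogeneity_scan,
    run_drive,
    steady_state_perturbation,
)
from popcolumn.network import RateSignal, run


@pytest.fixture(scope="session")
def column_config():
    return load_default_config()


@pytest.fixture(scope="session")
def column_net(column_config):
    return build_column(column_config)


@pytest.fixture(scope="session")
def bg_traces(column_net):
    """Background-only run: 100 ms settle + 100 ms hold."""
    return run(column_net, 200.0, 0.1)


@pytest.fixture(scope="session")
def bg_rates(bg_traces):
    """Steady background rates (mean over the final 20 ms), per population."""
    return pd.Series(
        {n: bg_traces.window_mean(n, 180.0, 200.0) for n in bg_traces.rates.columns}
    )


def _balanced_step(layer, amplitude=20.0):
    return DriveProtocol(
        layer=layer,
        specificity="balanced",
        signal=RateSignal(kind="step", amplitude=amplitude),
    )


@pytest.fixture(scope="session")
def balanced_step_perturbations(column_net):
    """Balanced 20 Hz step drives: L2/3 alone, L4 alone, and both jointly."""
    out = {}
    for key, layer in (("L2/3", "L2/3"), ("L4", "L4"), ("joint", ["L2/3", "L4"])):
        traces = run_drive(column_net, _balanced_step(layer))
        out[key] = steady_state_perturbation(traces)
    return out


@pytest.fixture(scope="session")
def homogeneity_tables(column_net, bg_rates):
    """5/10 Hz homogeneity scans for L4 and L5 drive, all specificities."""
    tables = {}
    for layer in ("L4", "L5"):
        for spec in ("excitatory", "balanced", "inhibitory"):
            tables[(layer, spec)] = homogeneity_scan(
                column_net, layer, spec, F0=bg_rates
            )
    return tables
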