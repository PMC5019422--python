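"""The 8-population cortical column as a density network.

Builds the 4-layer x 2-cell-type (excitatory/inhibitory) column from the
packaged Potjans-Diesmann-derived constants: 8 internal populations, up to 64
recurrent connections whose in-degrees follow the source tables'
pairwise-Bernoulli synapse-count convention (~ -N_pre ln(1-C)), a single
excitatory voltage jump obtained from the synaptic charge (w tau_s / C_m),
inhibitory jumps -g times that, and one rescaled constant-rate background
drive per population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import List, Optional

import numpy as np
import yaml

from .network import (
    ConfigurationError,
    ConnectionSpec,
    NetworkModel,
    PopulationSpec,
    RateSignal,
    build_network,
    normal_delay_kernel,
)

__all__ = [
    "POPULATIONS",
    "LAYERS",
    "ColumnConfig",
    "load_default_config",
    "weight_from_charge",
    "in_degree",
    "synapse_count_in_degree",
    "rescale_background",
    "build_column",
]

POPULATIONS = ["L2/3e", "L2/3i", "L4e", "L4i", "L5e", "L5i", "L6e", "L6i"]
LAYERS = ["L2/3", "L4", "L5", "L6"]


@dataclass
class ColumnConfig:
    """Connectivity and single-neuron constants of the column model."""

    population_sizes: np.ndarray            # 8 entries
    conn_prob: np.ndarray                   # 8x8, target x source
    syn_current_exc: float                  # pA
    syn_kernel_tau: float                   # ms
    membrane_capacitance: float             # pF
    membrane_tau: float                     # ms
    v_threshold: float                      # mV above reset
    g_inh_ratio: float
    bg_in_degree: np.ndarray                # 8 entries
    bg_rate: float                          # Hz per background source
    bg_rescale: float
    delay_exc: float                        # ms
    delay_inh: float                        # ms
    grid_v_min: float = -5.0
    grid_n_bins: int = 200
    populations: List[str] = field(default_factory=lambda: list(POPULATIONS))

    def validate(self, strict: bool = True) -> None:
        """Range checks; ``strict`` additionally pins the packaged overrides.

        Perturbed configurations (sensitivity analysis) pass ``strict=False``
        since their probability matrix deviates from the packaged one.
        """
        if np.any(self.conn_prob < 0) or np.any(self.conn_prob > 1):
            raise ConfigurationError("conn_prob entries must lie in [0, 1]")
        if np.any(np.asarray(self.population_sizes) <= 0):
            raise ConfigurationError("population_sizes must be positive")
        if self.bg_rescale <= 0:
            raise ConfigurationError("bg_rescale must be positive")
        for name, value in [
            ("syn_current_exc", self.syn_current_exc),
            ("syn_kernel_tau", self.syn_kernel_tau),
            ("membrane_capacitance", self.membrane_capacitance),
            ("membrane_tau", self.membrane_tau),
            ("v_threshold", self.v_threshold),
        ]:
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if strict:
            if not np.isclose(self.conn_prob[0, 2], 0.088):
                raise ConfigurationError(
                    "conn_prob L4e->L2/3e must carry the 0.088 override"
                )
            if self.g_inh_ratio != 4:
                raise ConfigurationError("g_inh_ratio must be 4")

    # -- derived quantities -------------------------------------------------

    @property
    def weight_exc(self) -> float:
        """Excitatory voltage jump (mV) from the synaptic charge."""
        return weight_from_charge(
            self.syn_current_exc, self.syn_kernel_tau, self.membrane_capacitance
        )

    @property
    def weight_inh(self) -> float:
        """Inhibitory voltage jump (mV): -g times the excitatory jump."""
        return -self.g_inh_ratio * self.weight_exc

    def background(self) -> tuple:
        """(rate Hz, weight mV) of the rescaled background drive."""
        return rescale_background(self.bg_rate, self.weight_exc, self.bg_rescale)

    def with_conn_prob(self, conn_prob: np.ndarray) -> "ColumnConfig":
        return replace(self, conn_prob=np.asarray(conn_prob, dtype=float))


def load_default_config() -> ColumnConfig:
    """Load the packaged column constants."""
    text = (
        resources.files("popcolumn") / "data" / "potjans_diesmann_column.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    cfg = ColumnConfig(
        population_sizes=np.asarray(raw["population_sizes"], dtype=float),
        conn_prob=np.asarray(raw["connection_probabilities"], dtype=float),
        syn_current_exc=float(raw["syn_current_exc_pA"]),
        syn_kernel_tau=float(raw["syn_kernel_tau_ms"]),
        membrane_capacitance=float(raw["membrane_capacitance_pF"]),
        membrane_tau=float(raw["membrane_tau_ms"]),
        v_threshold=float(raw["v_threshold_mV"]),
        g_inh_ratio=float(raw["g_inh_ratio"]),
        bg_in_degree=np.asarray(raw["bg_in_degree"], dtype=float),
        bg_rate=float(raw["bg_rate_hz"]),
        bg_rescale=float(raw["bg_rescale"]),
        delay_exc=float(raw["delay_exc_ms"]),
        delay_inh=float(raw["delay_inh_ms"]),
        grid_v_min=float(raw["grid_v_min_mV"]),
        grid_n_bins=int(raw["grid_n_bins"]),
        populations=list(raw["populations"]),
    )
    cfg.validate(strict=True)
    return cfg


def weight_from_charge(current_amplitude: float, tau_s: float, capacitance: float) -> float:
    """Voltage jump (mV) from an exponential synaptic current.

    The jump equals the total delivered charge over the capacitance:
    ``dv = (w / C_m) * integral exp(-t/tau_s) dt = w * tau_s / C_m``
    with w in pA, tau_s in ms and C_m in pF.
    """
    if current_amplitude <= 0 or tau_s <= 0 or capacitance <= 0:
        raise ValueError("current, tau_s and capacitance must be positive")
    return current_amplitude * tau_s / capacitance


def in_degree(conn_prob_entry: float, n_source: float) -> float:
    """Expected inputs per target neuron: probability x source-population size."""
    if not 0 <= conn_prob_entry <= 1:
        raise ValueError("connection probability must lie in [0, 1]")
    if n_source < 0:
        raise ValueError("population size must be >= 0")
    return conn_prob_entry * n_source


def synapse_count_in_degree(
    conn_prob_entry: float, n_source: float, n_target: float
) -> float:
    """In-degree under the pairwise-Bernoulli synapse-count convention.

    The source tables define C as the probability of finding at least one
    synapse between a random pair, with synapses drawn independently; the
    expected synapse count is then K = ln(1-C) / ln(1 - 1/(N_src N_tgt)) and
    the in-degree K / N_tgt ~= -N_src ln(1-C).  This exceeds the linear
    C x N_src (its small-C limit) by up to ~25% for the densest projections,
    which matters for the strongly connected L5 loop.
    """
    if not 0 <= conn_prob_entry < 1:
        raise ValueError("connection probability must lie in [0, 1)")
    if conn_prob_entry == 0:
        return 0.0
    n_pairs = n_source * n_target
    return float(
        np.log1p(-conn_prob_entry) / np.log1p(-1.0 / n_pairs) / n_target
    )


def rescale_background(rate: float, weight: float, factor: float) -> tuple:
    """Trade background rate for weight at fixed mean drive.

    Returns ``(rate / factor, weight * factor)``; the product (mean synaptic
    input) is preserved exactly while the variance of the shot-noise input
    grows by ``factor``.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return rate / factor, weight * factor


def build_column(config: Optional[ColumnConfig] = None, strict: bool = True) -> NetworkModel:
    """Assemble the 8-population column :class:`NetworkModel`.

    One external constant-rate background population drives all 8 internal
    populations with population-specific in-degrees at the rescaled rate and
    weight; recurrent connections carry the excitatory or inhibitory jump and
    the source-type mean delay.
    """
    if config is None:
        config = load_default_config()
    config.validate(strict=strict)

    w_e = config.weight_exc
    w_i = config.weight_inh
    bg_rate, bg_weight = config.background()

    pops = [
        PopulationSpec(
            name=name,
            kind="internal",
            tau_m=config.membrane_tau,
            v_min=config.grid_v_min,
            v_theta=config.v_threshold,
            n_bins=config.grid_n_bins,
        )
        for name in config.populations
    ]
    pops.append(
        PopulationSpec(
            name="bg",
            kind="external",
            rate_signal=RateSignal(kind="constant", baseline=bg_rate),
        )
    )

    conns = []
    for ti, tgt in enumerate(config.populations):
        for si, src in enumerate(config.populations):
            k = synapse_count_in_degree(
                config.conn_prob[ti, si],
                config.population_sizes[si],
                config.population_sizes[ti],
            )
            if k == 0:
                continue
            inhibitory = src.endswith("i")
            d_mean = config.delay_inh if inhibitory else config.delay_exc
            conns.append(
                ConnectionSpec(
                    source=src,
                    target=tgt,
                    in_degree=k,
                    weight=w_i if inhibitory else w_e,
                    delay=d_mean,
                    # source tables: delays normal with sd = mean/2, truncated
                    # at the 0.1 ms resolution; a single mean delay produces a
                    # spurious few-hundred-Hz delay-loop limit cycle
                    delay_kernel=normal_delay_kernel(d_mean, 0.5 * d_mean),
                )
            )
        conns.append(
            ConnectionSpec(
                source="bg",
                target=tgt,
                in_degree=float(config.bg_in_degree[ti]),
                weight=bg_weight,
                delay=0.0,
            )
        )
    return build_network(pops, conns)
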