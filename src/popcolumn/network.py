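"""Recurrently coupled networks of density-simulated LIF populations.

Internal populations are advanced by the finite-volume solver; external
populations are prescribed rate signals.  A connection delivers the (delayed)
source rate, multiplied by its in-degree, to the target's synaptic operator
for the connection's weight.  Recurrent coupling assigns the presynaptic
population's output rate to the postsynaptic input rate; the whole pipeline is
deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .solver import (
    ConfigurationError,
    DensityState,
    FluxOperator,
    SolverError,
    VoltageGrid,
    build_grid,
    gaussian_init,
    leak_operator,
    step_density,
    synaptic_operator,
)

__all__ = [
    "RateSignal",
    "PopulationSpec",
    "ConnectionSpec",
    "normal_delay_kernel",
    "RateTraces",
    "NetworkModel",
    "build_network",
    "run",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateSignal:
    """Prescribed external firing rate (Hz).

    kinds
        ``constant``: baseline for all t.
        ``step``: baseline, then baseline + amplitude from ``onset`` on.
        ``sinusoid``: baseline before onset, then
        ``baseline + amplitude * (1 - cos(2 pi f (t - onset))) / 2`` — a
        raised cosine that starts continuously at baseline, stays
        non-negative, and has peak excess exactly ``amplitude``.
    """

    kind: str = "constant"
    baseline: float = 0.0
    amplitude: float = 0.0
    onset: float = 0.0
    frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step", "sinusoid"):
            raise ConfigurationError(f"unknown signal kind {self.kind!r}")
        if self.baseline < 0 or self.amplitude < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.kind == "sinusoid" and not self.frequency:
            raise ConfigurationError("sinusoid needs a frequency")

    def __call__(self, t) -> np.ndarray:
        """Evaluate the signal (Hz) at time(s) ``t`` in ms."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, float(self.baseline))
        if self.kind == "constant":
            return out
        after = t >= self.onset
        if self.kind == "step":
            out[after] += self.amplitude
        else:
            f_per_ms = self.frequency * 1e-3
            phase = 2.0 * np.pi * f_per_ms * (t[after] - self.onset)
            out[after] += self.amplitude * 0.5 * (1.0 - np.cos(phase))
        return out


@dataclass(frozen=True)
class PopulationSpec:
    """One homogeneous population: density-simulated or a prescribed rate."""

    name: str
    kind: str = "internal"  # "internal" | "external"
    tau_m: float = 10.0
    v_min: float = -5.0
    v_theta: float = 15.0
    n_bins: int = 200
    rate_signal: Optional[RateSignal] = None

    def __post_init__(self) -> None:
        if self.kind not in ("internal", "external"):
            raise ConfigurationError(f"unknown population kind {self.kind!r}")
        if self.kind == "internal" and self.tau_m <= 0:
            raise ConfigurationError("internal populations need tau_m > 0")
        if self.kind == "external" and self.rate_signal is None:
            raise ConfigurationError("external populations need a rate_signal")


@dataclass(frozen=True)
class ConnectionSpec:
    """Rate connection: effective input = in_degree x delayed source rate.

    ``delay`` is a single transmission delay; ``delay_kernel``, when given,
    replaces it with a discretized delay distribution — a tuple of
    ``(delay_ms, fraction)`` pairs whose fractions sum to 1, each carrying
    that fraction of the connection's rate.
    """

    source: str
    target: str
    in_degree: float
    weight: float
    delay: float = 0.0
    delay_kernel: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.in_degree < 0:
            raise ConfigurationError("in_degree must be >= 0")
        if self.delay < 0:
            raise ConfigurationError("delay must be >= 0")
        if self.in_degree > 0 and self.weight == 0:
            raise ConfigurationError("active connection needs nonzero weight")
        if self.delay_kernel is not None:
            ker = tuple(self.delay_kernel)
            if any(d < 0 or w < 0 for d, w in ker):
                raise ConfigurationError("delay kernel entries must be >= 0")
            if abs(sum(w for _, w in ker) - 1.0) > 1e-9:
                raise ConfigurationError("delay kernel fractions must sum to 1")
            object.__setattr__(self, "delay_kernel", ker)

    def delay_terms(self):
        """(delay_ms, fraction) pairs; the scalar delay when no kernel."""
        if self.delay_kernel is not None:
            return self.delay_kernel
        return ((self.delay, 1.0),)


def normal_delay_kernel(mean: float, sd: float, dt: float = 0.1, d_min: float = 0.1) -> tuple:
    """Discretized truncated-normal delay distribution on the dt grid.

    Gaussian weights at multiples of ``dt`` over mean +/- 4 sd, truncated
    below at ``d_min`` and renormalized — the delay-distribution shape of the
    column model's source tables (sd = mean / 2, cut at the resolution).
    """
    lo = max(d_min, mean - 4.0 * sd)
    hi = mean + 4.0 * sd
    ds = np.arange(np.ceil(lo / dt), np.floor(hi / dt) + 1) * dt
    wts = np.exp(-0.5 * ((ds - mean) / sd) ** 2)
    wts /= wts.sum()
    return tuple((float(d), float(w)) for d, w in zip(ds, wts))


@dataclass
class RateTraces:
    """Per-population output firing rates on the simulation time grid."""

    times: np.ndarray                 # ms
    rates: pd.DataFrame               # one column per internal population, Hz
    meta: dict = field(default_factory=dict)

    def population(self, name: str) -> np.ndarray:
        return self.rates[name].to_numpy()

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def window_mean(self, name: str, t_start: float, t_stop: float) -> float:
        sel = (self.times >= t_start) & (self.times < t_stop)
        return float(self.rates[name].to_numpy()[sel].mean())

    def to_csv(self, path, header_meta: Optional[dict] = None) -> None:
        """CSV: time column + one column per population, optional '#' header."""
        with open(path, "w") as fh:
            if header_meta:
                fh.write("# " + json.dumps(header_meta, sort_keys=True) + "\n")
            df = self.rates.copy()
            df.insert(0, "time_ms", self.times)
            df.to_csv(fh, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_ms", data=self.times)
            grp = fh.create_group("rates_hz")
            for name in self.rates.columns:
                grp.create_dataset(name, data=self.rates[name].to_numpy())
            for k, v in self.meta.items():
                try:
                    fh.attrs[k] = v
                except TypeError:
                    fh.attrs[k] = json.dumps(v)


# ---------------------------------------------------------------------------
# network model
# ---------------------------------------------------------------------------

class NetworkModel:
    """Populations + connections, with precomputed per-weight flux operators."""

    def __init__(
        self,
        populations: Sequence[PopulationSpec],
        connections: Sequence[ConnectionSpec],
    ):
        names = [p.name for p in populations]
        if len(set(names)) != len(names):
            raise ConfigurationError("population names must be unique")
        self.populations = list(populations)
        self.connections = list(connections)
        self.by_name: Dict[str, PopulationSpec] = {p.name: p for p in populations}
        self.internal = [p for p in populations if p.kind == "internal"]
        self.external = [p for p in populations if p.kind == "external"]

        for c in connections:
            if c.source not in self.by_name or c.target not in self.by_name:
                raise ConfigurationError(
                    f"connection {c.source}->{c.target} names an undeclared population"
                )
            if self.by_name[c.target].kind != "internal":
                raise ConfigurationError(
                    f"connection target {c.target} must be an internal population"
                )

        # grids and leak operators per internal population
        self.grids: Dict[str, VoltageGrid] = {}
        self.leaks: Dict[str, FluxOperator] = {}
        for p in self.internal:
            grid = build_grid(p.v_min, p.v_theta, p.n_bins)
            self.grids[p.name] = grid
            self.leaks[p.name] = leak_operator(grid, p.tau_m)

        # per-target synaptic operators, one per distinct weight
        self.target_ops: Dict[str, Dict[float, FluxOperator]] = {
            p.name: {} for p in self.internal
        }
        for c in connections:
            if c.in_degree == 0:
                continue
            key = round(c.weight, 12)
            ops = self.target_ops[c.target]
            if key not in ops:
                ops[key] = synaptic_operator(self.grids[c.target], c.weight)

    def extended(self, populations=(), connections=()) -> "NetworkModel":
        """New model with extra populations/connections (e.g. a stimulus)."""
        return NetworkModel(
            list(self.populations) + list(populations),
            list(self.connections) + list(connections),
        )

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for output provenance."""
        blob = json.dumps(
            {
                "populations": [vars(p) | {"rate_signal": vars(p.rate_signal) if p.rate_signal else None} for p in self.populations],
                "connections": [vars(c) for c in self.connections],
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_network(populations, connections) -> NetworkModel:
    """Validate and assemble a :class:`NetworkModel`."""
    return NetworkModel(populations, connections)


# ---------------------------------------------------------------------------
# packing for the compiled engine
# ---------------------------------------------------------------------------

def _pack_ops(grid: VoltageGrid, ops: List[FluxOperator]):
    """Align a list of operators on one union CSR pattern.

    Returns (indptr, indices, data_rows, fire_rows); data row i holds
    operator i's entries at the union pattern's positions.
    """
    import scipy.sparse as sp

    pattern = None
    for op in ops:
        absmat = abs(op.matrix)
        # keep structural zeros alive by using the pattern only
        absmat.data[:] = 1.0
        pattern = absmat if pattern is None else pattern + absmat
    pattern = pattern.tocsr()
    pattern.sum_duplicates()
    pattern.sort_indices()
    nnz = pattern.nnz
    pos = {}
    for i in range(grid.n_bins):
        for q in range(pattern.indptr[i], pattern.indptr[i + 1]):
            pos[(i, pattern.indices[q])] = q
    data_rows = np.zeros((len(ops), nnz))
    fire_rows = np.zeros((len(ops), grid.n_bins))
    for k, op in enumerate(ops):
        coo = op.matrix.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            data_rows[k, pos[(i, j)]] += v
        fire_rows[k, :] = op.firing_row
    return pattern.indptr.astype(np.int64), pattern.indices.astype(np.int64), data_rows, fire_rows


def _delay_steps(delay: float, dt: float) -> int:
    return int(round(delay / dt))


def run(
    network: NetworkModel,
    duration: float,
    dt: float = 0.1,
    initial: Optional[Dict[str, DensityState]] = None,
    engine: str = "numba",
) -> RateTraces:
    """Run the coupled simulation and return the per-population rate traces.

    All populations are advanced synchronously: at each step the delayed
    source rates are read first, then every population takes one density
    step (Jacobi update, order independent).  Delays are rounded to the
    nearest multiple of ``dt``; a zero (or sub-half-step) delay resolves at a
    one-step lag.  Delay buffers are initialized with each source's t = 0
    rate (0 for internal populations, the signal baseline for external ones).

    ``initial`` maps internal population names to densities; unspecified
    populations start from the standard Gaussian (mean 0, sd 5 mV).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    T = int(round(duration / dt))
    internal_names = [p.name for p in network.internal]
    external_names = [p.name for p in network.external]
    int_index = {n: i for i, n in enumerate(internal_names)}
    ext_index = {n: i for i, n in enumerate(external_names)}
    n_pops = len(internal_names)
    if n_pops == 0:
        raise ConfigurationError("network has no internal populations")
    n_bins = {network.grids[n].n_bins for n in internal_names}
    if len(n_bins) != 1:
        raise ConfigurationError("all internal populations must share a grid size")
    n_bins = n_bins.pop()

    # operator tables: index 0 = leak, then sorted distinct weights
    weight_order = {
        n: sorted(network.target_ops[n].keys()) for n in internal_names
    }
    op_index = {
        n: {w: k + 1 for k, w in enumerate(weight_order[n])}
        for n in internal_names
    }

    # connection tables
    c_tgt, c_op, c_srckind, c_src, c_indeg, c_delay = [], [], [], [], [], []
    for c in network.connections:
        if c.in_degree == 0:
            continue
        tgt = int_index[c.target]
        for d_ms, frac in c.delay_terms():
            if frac == 0.0:
                continue
            c_tgt.append(tgt)
            c_op.append(op_index[c.target][round(c.weight, 12)])
            if c.source in int_index:
                c_srckind.append(0)
                c_src.append(int_index[c.source])
            else:
                c_srckind.append(1)
                c_src.append(ext_index[c.source])
            c_indeg.append(float(c.in_degree) * frac)
            c_delay.append(_delay_steps(d_ms, dt))

    times = np.arange(T) * dt
    ext = np.zeros((max(1, len(external_names)), T))
    for n, i in ext_index.items():
        ext[i] = network.by_name[n].rate_signal(times) * 1e-3  # Hz -> /ms

    # initial densities
    P = np.zeros((n_pops, n_bins))
    for n, i in int_index.items():
        if initial and n in initial:
            state = initial[n]
        else:
            state = gaussian_init(network.grids[n], 0.0, 5.0)
        P[i] = np.asarray(state.mass, dtype=float)

    if engine == "numba":
        max_ops = max(len(weight_order[n]) for n in internal_names) + 1
        packed = {
            n: _pack_ops(
                network.grids[n],
                [network.leaks[n]]
                + [network.target_ops[n][w] for w in weight_order[n]],
            )
            for n in internal_names
        }
        max_nnz = max(packed[n][0][-1] for n in internal_names)
        indptr = np.zeros((n_pops, n_bins + 1), dtype=np.int64)
        indices = np.zeros((n_pops, max_nnz), dtype=np.int64)
        nnz = np.zeros(n_pops, dtype=np.int64)
        opdata = np.zeros((n_pops, max_ops, max_nnz))
        fire = np.zeros((n_pops, max_ops, n_bins))
        nops = np.zeros(n_pops, dtype=np.int64)
        leak_maxdiag = np.zeros(n_pops)
        for n, i in int_index.items():
            ip, idx, drows, frows = packed[n]
            indptr[i] = ip
            indices[i, : idx.size] = idx
            nnz[i] = idx.size
            opdata[i, : drows.shape[0], : idx.size] = drows
            fire[i, : frows.shape[0], :] = frows
            nops[i] = drows.shape[0]
            leak_maxdiag[i] = float(
                np.max(-network.leaks[n].matrix.diagonal())
            )
        rates = np.zeros((n_pops, T))
        status, t_fail, p_fail = _engine.run_kernel(
            T,
            float(dt),
            indptr,
            indices,
            nnz,
            opdata,
            fire,
            nops,
            leak_maxdiag,
            np.asarray(c_tgt, dtype=np.int64),
            np.asarray(c_op, dtype=np.int64),
            np.asarray(c_srckind, dtype=np.int64),
            np.asarray(c_src, dtype=np.int64),
            np.asarray(c_indeg, dtype=float),
            np.asarray(c_delay, dtype=np.int64),
            ext,
            P,
            rates,
        )
        if status != _engine.OK:
            msg = {
                _engine.NEGATIVE_MASS: "negative probability mass",
                _engine.MASS_DRIFT: "probability mass drift",
                _engine.SERIES_FAILURE: "propagator series failure",
            }[status]
            raise SolverError(
                f"{msg} in population {internal_names[p_fail]} at step {t_fail}"
            )
        rates_hz = rates.T * 1e3
    elif engine == "python":
        rates_hz = _run_python(
            network, T, dt, P, internal_names, int_index, ext_index, ext,
            c_tgt, c_op, c_srckind, c_src, c_indeg, c_delay, weight_order,
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")

    df = pd.DataFrame(rates_hz, columns=internal_names)
    traces = RateTraces(times=times, rates=df, meta={"dt": dt})
    traces.final_masses = {n: P[i].copy() for n, i in int_index.items()}
    return traces


def _run_python(
    network, T, dt, P, internal_names, int_index, ext_index, ext,
    c_tgt, c_op, c_srckind, c_src, c_indeg, c_delay, weight_order,
):
    """Reference loop built directly on :func:`solver.step_density`."""
    n_pops = len(internal_names)
    rates = np.zeros((n_pops, T))  # events/ms
    states = {
        n: DensityState(mass=P[i].copy(), time=0.0)
        for n, i in int_index.items()
    }
    for t in range(T):
        lam_hz = [dict() for _ in range(n_pops)]
        for c in range(len(c_tgt)):
            d = max(c_delay[c], 1)
            if c_srckind[c] == 0:
                idx = t - d
                r = rates[c_src[c], idx] * 1e3 if idx >= 0 else 0.0
            else:
                r = ext[c_src[c], max(t - c_delay[c], 0)] * 1e3
            lam_hz[c_tgt[c]][c_op[c]] = (
                lam_hz[c_tgt[c]].get(c_op[c], 0.0) + c_indeg[c] * r
            )
        for n, i in int_index.items():
            inputs = [
                (network.target_ops[n][weight_order[n][o - 1]], r)
                for o, r in lam_hz[i].items()
            ]
            states[n], lam_out = step_density(
                states[n], network.leaks[n], inputs, dt
            )
            rates[i, t] = lam_out * 1e-3
        # propagate updated masses back for the caller
    for n, i in int_index.items():
        P[i] = states[n].mass
    return rates.T * 1e3
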