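"""Monte-Carlo spiking LIF ensembles: the brute-force validation oracle.

Simulates populations of individual leaky integrate-and-fire neurons
(tau_m dv/dt = -v + dv_jump * sum_i delta(t - t_i); v >= v_th => v -> 0,
zero refractory period by default) with explicit Poisson background spikes
and realized recurrent connectivity, and averages trial firing rates.  The
density solver must agree with these averages within Monte-Carlo error; the
two implementations share no code paths.

Between input events the voltage decays in closed form (per-step factor
exp(-dt/tau_m)); spikes are applied as instantaneous jumps on the dt grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .column import (
    ColumnConfig,
    load_default_config,
    synapse_count_in_degree,
)
from .network import ConfigurationError, RateTraces

__all__ = [
    "SpikingEnsembleSpec",
    "EnsembleResult",
    "simulate_ensemble",
    "simulate_single_population",
]


@dataclass(frozen=True)
class SpikingEnsembleSpec:
    """Parameters of a spiking realization of the column model.

    ``scale`` multiplies the population sizes; in-degrees are preserved under
    scaling (the density model is parameterized by in-degree), so per-pair
    synapse counts are drawn as Poisson with mean in_degree / n_source_scaled
    — equivalent to the Bernoulli rule in the sparse full-scale limit while
    remaining well defined when the scaled effective probability exceeds 1.
    """

    config: ColumnConfig = None
    scale: float = 1.0
    dt: float = 0.1          # ms
    seed: int = 0
    refractory: float = 0.0  # ms; 0 per the simplified model, 2.0 optional

    def sizes(self) -> np.ndarray:
        cfg = self.config if self.config is not None else load_default_config()
        n = np.round(np.asarray(cfg.population_sizes) * self.scale).astype(int)
        if np.any(n < 1):
            raise ConfigurationError(
                "scale leaves a population with zero neurons"
            )
        return n


@dataclass
class EnsembleResult:
    """Trial-averaged rates plus per-trial traces for error estimation."""

    times: np.ndarray            # bin centers, ms
    populations: List[str]
    per_trial: np.ndarray        # (n_trials, n_pops, n_bins) Hz
    traces: RateTraces = None    # trial mean

    def trial_window_means(self, population: str, t_start: float, t_stop: float):
        """Per-trial mean rate of one population over a time window (Hz)."""
        p = self.populations.index(population)
        sel = (self.times >= t_start) & (self.times < t_stop)
        return self.per_trial[:, p, sel].mean(axis=1)


def _realize_outgoing(rng, n_src: int, in_degrees):
    """Per-source-neuron outgoing target lists for one source population.

    ``in_degrees`` maps (tgt_offset, n_tgt) -> K; synapse counts per target
    neuron are Poisson(K) with sources uniform (multiple synapses allowed).
    """
    chunks = [[] for _ in range(n_src)]
    for (offset, n_tgt), K in in_degrees.items():
        if K <= 0 or n_tgt == 0:
            continue
        counts = rng.poisson(K, size=n_tgt)
        total = int(counts.sum())
        srcs = rng.integers(0, n_src, size=total)
        tgts = np.repeat(np.arange(n_tgt, dtype=np.int64) + offset, counts)
        order = np.argsort(srcs, kind="stable")
        srcs, tgts = srcs[order], tgts[order]
        bounds = np.searchsorted(srcs, np.arange(n_src + 1))
        for s in range(n_src):
            lo, hi = bounds[s], bounds[s + 1]
            if hi > lo:
                chunks[s].append(tgts[lo:hi])
    return [
        np.concatenate(c) if c else np.empty(0, dtype=np.int64) for c in chunks
    ]


def simulate_ensemble(
    spec: SpikingEnsembleSpec,
    stimulus=None,
    duration: float = 200.0,
    n_trials: int = 1,
    bin_width: float = 1.0,
    record_rasters: bool = False,
) -> EnsembleResult:
    """Trial-averaged spiking simulation of the (scaled) column model.

    Per trial, the connectivity realization and the Gaussian initial voltages
    (mean 0, sd 5 mV) are redrawn; background and any stimulus arrive as
    Poisson spike trains at the configured rates.  Population rates are spike
    counts per ``bin_width`` bin divided by (n_neurons x bin width), averaged
    over trials.

    ``stimulus`` is an :class:`experiments.DriveProtocol` (or None); its
    signal is evaluated on the dt grid and delivered as an inhomogeneous
    Poisson train through ``sources_per_neuron`` independent sources.
    """
    cfg = spec.config if spec.config is not None else load_default_config()
    rng = np.random.default_rng(spec.seed)
    dt = spec.dt
    T = int(round(duration / dt))
    sizes = spec.sizes()
    n_pops = len(sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_total = int(offsets[-1])
    names = list(cfg.populations)

    w_e = cfg.weight_exc
    w_i = cfg.weight_inh
    bg_rate, bg_w = cfg.background()
    decay = np.exp(-dt / cfg.membrane_tau)
    v_th = cfg.v_threshold

    # per-synapse delays: truncated normal (sd = mean/2, floor dt), as in the
    # source model; sharp identical delays would artificially synchronize the
    # scaled-down network
    delay_mean = {"e": cfg.delay_exc, "i": cfg.delay_inh}
    max_delay = int(round((cfg.delay_exc * 3.0) / dt)) + 1

    # per-neuron background Poisson intensity (events per step)
    bg_lam = np.concatenate(
        [
            np.full(sizes[p], cfg.bg_in_degree[p] * bg_rate * 1e-3 * dt)
            for p in range(n_pops)
        ]
    )

    # stimulus intensity per neuron per step (events/step), time-varying
    stim_lam = None
    stim_weight = w_e
    if stimulus is not None:
        targets = stimulus.target_populations()
        mask = np.zeros(n_total)
        for tname in targets:
            p = names.index(tname)
            mask[offsets[p]: offsets[p + 1]] = stimulus.sources_per_neuron
        sig_hz = stimulus.signal(np.arange(T) * dt)
        stim_lam = (sig_hz * 1e-3 * dt, mask)

    n_bins = int(round(duration / bin_width))
    per_trial = np.zeros((n_trials, n_pops, n_bins))
    steps_per_bin = int(round(bin_width / dt))
    rasters = [] if record_rasters else None

    pop_of = np.concatenate(
        [np.full(sizes[p], p, dtype=np.int64) for p in range(n_pops)]
    )

    jump_of_src = np.where(
        np.concatenate(
            [np.full(sizes[p], names[p].endswith("i")) for p in range(n_pops)]
        ),
        w_i,
        w_e,
    )

    for trial in range(n_trials):
        trng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        # fresh connectivity realization: per source neuron, outgoing target
        # indices and per-synapse delay steps
        outgoing: List[np.ndarray] = [None] * n_total
        out_delay: List[np.ndarray] = [None] * n_total
        for sp in range(n_pops):
            in_degs = {}
            for tp in range(n_pops):
                K = synapse_count_in_degree(
                    cfg.conn_prob[tp, sp],
                    cfg.population_sizes[sp],
                    cfg.population_sizes[tp],
                )
                in_degs[(int(offsets[tp]), int(sizes[tp]))] = K
            chunks = _realize_outgoing(trng, int(sizes[sp]), in_degs)
            dm = delay_mean["i" if names[sp].endswith("i") else "e"]
            for s, tg in enumerate(chunks):
                outgoing[offsets[sp] + s] = tg.astype(np.int64)
                d = trng.normal(dm, 0.5 * dm, size=tg.size)
                steps = np.clip(np.round(d / dt), 1, max_delay).astype(np.int64)
                out_delay[offsets[sp] + s] = steps

        v = trng.normal(0.0, 5.0, size=n_total)
        v = np.minimum(v, v_th - 1e-9)
        # future synaptic deliveries, indexed by (arrival step % D, neuron)
        D = max_delay + 1
        pending = np.zeros((D, n_total))
        counts = np.zeros((n_pops, n_bins))
        refr_until = np.full(n_total, -1.0)

        for t in range(T):
            slot = t % D
            v *= decay
            v += pending[slot]
            pending[slot] = 0.0
            # background shot noise
            v += trng.poisson(bg_lam) * bg_w
            if stim_lam is not None:
                lam_t, mask = stim_lam
                if lam_t[t] > 0:
                    v += trng.poisson(lam_t[t] * mask) * stim_weight
            if spec.refractory > 0:
                v[refr_until > t * dt] = 0.0
            spiked = v >= v_th
            if spec.refractory > 0:
                spiked &= refr_until <= t * dt
                refr_until[spiked] = t * dt + spec.refractory
            v[spiked] = 0.0
            ids = np.flatnonzero(spiked)
            for s in ids:
                tg = outgoing[s]
                if tg.size:
                    np.add.at(
                        pending, ((t + out_delay[s]) % D, tg), jump_of_src[s]
                    )
            if ids.size:
                b = t // steps_per_bin
                np.add.at(counts[:, b], pop_of[ids], 1)
                if record_rasters:
                    rasters.append(
                        np.column_stack([np.full(ids.size, t * dt), ids])
                    )
        per_trial[trial] = counts / (sizes[:, None] * bin_width * 1e-3)

    times = (np.arange(n_bins) + 0.5) * bin_width
    mean = per_trial.mean(axis=0)
    traces = RateTraces(
        times=times,
        rates=pd.DataFrame(mean.T, columns=names),
        meta={"n_trials": n_trials, "scale": spec.scale, "seed": spec.seed},
    )
    result = EnsembleResult(
        times=times, populations=names, per_trial=per_trial, traces=traces
    )
    if record_rasters:
        result.rasters = (
            np.vstack(rasters) if rasters else np.empty((0, 2))
        )
    return result


def simulate_single_population(
    n_neurons: int,
    inputs: Sequence[Tuple[float, float]],
    duration: float,
    tau_m: float = 10.0,
    v_theta: float = 15.0,
    dt: float = 0.1,
    seed: int = 0,
    n_trials: int = 1,
    init_sd: float = 5.0,
) -> EnsembleResult:
    """Uncoupled LIF ensemble under Poisson shot-noise drive.

    ``inputs`` is a list of (total event rate in Hz, jump in mV) pairs, e.g.
    the background drive as (in_degree x rate, weight).  Used to cross-check
    the density solver's transient and steady-state output rate.
    """
    rng = np.random.default_rng(seed)
    T = int(round(duration / dt))
    decay = np.exp(-dt / tau_m)
    lam = [(r * 1e-3 * dt, w) for r, w in inputs]
    per_trial = np.zeros((n_trials, 1, T))
    for trial in range(n_trials):
        trng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        v = np.minimum(trng.normal(0.0, init_sd, n_neurons), v_theta - 1e-9)
        for t in range(T):
            v *= decay
            for l, w in lam:
                v += trng.poisson(l, n_neurons) * w
            spiked = v >= v_theta
            v[spiked] = 0.0
            per_trial[trial, 0, t] = spiked.sum() / (n_neurons * dt * 1e-3)
    times = np.arange(T) * dt
    traces = RateTraces(
        times=times,
        rates=pd.DataFrame(per_trial.mean(axis=0).T, columns=["pop"]),
        meta={"n_trials": n_trials},
    )
    return EnsembleResult(
        times=times, populations=["pop"], per_trial=per_trial, traces=traces
    )
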