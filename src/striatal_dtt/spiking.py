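"""Conductance-based spiking network of the striatum.

2000 D1 + 2000 D2 medium spiny neurons (MSNs) and 80 fast spiking
interneurons (FSIs), modelled as leaky integrate-and-fire neurons with
alpha-function conductance synapses:

    C dV/dt = -G_rest (V - V_rest) - g_exc (V - V_exc) - g_inh (V - V_inh) + I_ext
    g(t)    = J (t/tau) exp(1 - t/tau)   per presynaptic event (peak J at t = tau)

MSNs inhibit each other (asymmetric probabilities and strengths: D2->D1 is
the strongest projection) and receive feedforward inhibition from FSIs,
which preferentially target D1.  FSIs receive cortical excitation only.
Cortical drive is delivered as 250 afferents per neuron; a per-afferent
rate of 10 Hz reproduces the reference 2500 Hz aggregate background.  In
the multiplicative scenario D1 cortical synapses are stronger (3.6 vs
3.0 nS); in the additive scenario peaks are equal and D1 receives extra
afferent rate.

Integration is exponential-Euler on the membrane with exactly propagated
alpha-kernel states, dt = 0.1 ms by default, compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .dtt import SweepResult, find_dtt

__all__ = [
    "NeuronParams",
    "SynapseSpec",
    "NetworkConfig",
    "Network",
    "SpikeRecord",
    "CorticalDrive",
    "MSN_PARAMS",
    "FSI_PARAMS",
    "DEFAULT_SYNAPSES",
    "build_network",
    "alpha_kernel",
    "simulate",
    "population_rate",
    "delta_msn_spiking",
    "dtt_sweep_spiking",
    "fi_curve",
    "lif_rheobase",
    "lif_rate_closed_form",
]


@dataclass(frozen=True)
class NeuronParams:
    """Passive LIF parameters of one population (mV, pF, nS, ms)."""

    v_rest: float = -80.0
    v_th: float = -45.0
    v_exc: float = 0.0
    v_inh: float = -64.0
    c: float = 200.0
    g_rest: float = 12.5
    tau_exc: float = 0.3
    tau_inh: float = 2.0
    t_ref: float = 2.0

    def __post_init__(self) -> None:
        if not self.v_rest < self.v_th:
            raise ValueError("v_rest must be below v_th")
        for name in ("c", "g_rest", "tau_exc", "tau_inh"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/G_rest (ms)."""
        return self.c / self.g_rest

    @property
    def r_in(self) -> float:
        """Input resistance 1/G_rest in GOhm-compatible mV/pA units."""
        return 1.0 / self.g_rest


MSN_PARAMS = NeuronParams()
FSI_PARAMS = NeuronParams(v_th=-54.0, v_inh=-76.0, c=500.0, g_rest=25.0)


@dataclass(frozen=True)
class SynapseSpec:
    """One projection class: connection probability, peak conductance, delay."""

    source: str
    target: str
    probability: float
    peak_ns: float
    delay_ms: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.peak_ns < 0 or self.delay_ms <= 0:
            raise ValueError("peak_ns must be >= 0 and delay_ms > 0")


#: Striatal inhibitory connectivity (paired-recording probabilities; FSIs
#: receive no striatal inhibition).
DEFAULT_SYNAPSES: tuple[SynapseSpec, ...] = (
    SynapseSpec("d1", "d1", 0.26, 0.5, 2.0),
    SynapseSpec("d1", "d2", 0.07, 1.0, 2.0),
    SynapseSpec("d2", "d2", 0.36, 1.0, 2.0),
    SynapseSpec("d2", "d1", 0.27, 1.2, 2.0),
    SynapseSpec("fsi", "d1", 0.54, 2.5, 1.0),
    SynapseSpec("fsi", "d2", 0.36, 2.5, 1.0),
)

_POPS = ("d1", "d2", "fsi")


@dataclass(frozen=True)
class NetworkConfig:
    """Population sizes, neuron parameters and connectivity of the network."""

    n_d1: int = 2000
    n_d2: int = 2000
    n_fsi: int = 80
    d1_params: NeuronParams = MSN_PARAMS
    d2_params: NeuronParams = MSN_PARAMS
    fsi_params: NeuronParams = FSI_PARAMS
    synapses: tuple[SynapseSpec, ...] = DEFAULT_SYNAPSES

    def __post_init__(self) -> None:
        if min(self.n_d1, self.n_d2, self.n_fsi) <= 0:
            raise ValueError("population sizes must be > 0")
        for s in self.synapses:
            if s.source not in _POPS or s.target not in _POPS:
                raise ValueError(f"unknown population in {s}")
            if s.target == "fsi":
                raise ValueError("FSIs receive no striatal inhibition")

    @property
    def n_total(self) -> int:
        return self.n_d1 + self.n_d2 + self.n_fsi

    def pop_slice(self, pop: str) -> slice:
        starts = {
            "d1": 0,
            "d2": self.n_d1,
            "fsi": self.n_d1 + self.n_d2,
        }
        sizes = {"d1": self.n_d1, "d2": self.n_d2, "fsi": self.n_fsi}
        return slice(starts[pop], starts[pop] + sizes[pop])


@dataclass(frozen=True)
class Network:
    """A realized connectivity: CSR adjacency over global neuron indices."""

    config: NetworkConfig
    indptr: np.ndarray  # (n_total + 1,)
    targets: np.ndarray  # int32, per-synapse postsynaptic index
    peaks: np.ndarray  # float64, nS
    delays: np.ndarray  # float64, ms
    connectivity_seed: int

    @property
    def n_synapses(self) -> int:
        return int(self.targets.size)

    def out_degree(self, i: int) -> int:
        return int(self.indptr[i + 1] - self.indptr[i])

    def in_degree(self, pop_target: str) -> np.ndarray:
        sl = self.config.pop_slice(pop_target)
        counts = np.bincount(self.targets, minlength=self.config.n_total)
        return counts[sl]


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Draw a random connectivity realization.

    Every ordered (source, target) pair covered by a
    :class:`SynapseSpec` row is connected independently with the row's
    probability; no autapses, at most one synapse per ordered pair.
    Deterministic for a given (config, seed).
    """
    rng = np.random.default_rng(seed)
    n = config.n_total
    # accumulate per-source adjacency
    tgt_lists: list[list[np.ndarray]] = [[] for _ in range(n)]
    peak_lists: list[list[float]] = [[] for _ in range(n)]
    delay_lists: list[list[float]] = [[] for _ in range(n)]

    for spec in config.synapses:
        if spec.probability == 0.0 or spec.peak_ns == 0.0:
            continue
        src_sl, tgt_sl = config.pop_slice(spec.source), config.pop_slice(spec.target)
        src_idx = np.arange(src_sl.start, src_sl.stop)
        tgt_idx = np.arange(tgt_sl.start, tgt_sl.stop)
        for si in src_idx:
            mask = rng.random(tgt_idx.size) < spec.probability
            if spec.source == spec.target:
                mask[si - tgt_sl.start] = False  # no autapses
            tt = tgt_idx[mask]
            if tt.size:
                tgt_lists[si].append(tt)
                peak_lists[si].append(spec.peak_ns)
                delay_lists[si].append(spec.delay_ms)

    indptr = np.zeros(n + 1, dtype=np.int64)
    targets, peaks, delays = [], [], []
    for i in range(n):
        cnt = 0
        for tt, pk, dl in zip(tgt_lists[i], peak_lists[i], delay_lists[i]):
            targets.append(tt)
            peaks.append(np.full(tt.size, pk))
            delays.append(np.full(tt.size, dl))
            cnt += tt.size
        indptr[i + 1] = indptr[i] + cnt
    return Network(
        config=config,
        indptr=indptr,
        targets=(
            np.concatenate(targets).astype(np.int32) if targets
            else np.empty(0, np.int32)
        ),
        peaks=np.concatenate(peaks) if peaks else np.empty(0),
        delays=np.concatenate(delays) if delays else np.empty(0),
        connectivity_seed=seed,
    )


def alpha_kernel(peak: float, tau: float, t):
    """Alpha conductance time course J*(t/tau)*exp(1 - t/tau); 0 for t < 0.

    Peaks at exactly *peak* at t = *tau*.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0.0, peak * (t / tau) * np.exp(1.0 - t / tau), 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# drive specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorticalDrive:
    """Cortical excitation per population.

    Rates are per-afferent (Hz); each neuron pools ``n_afferents``
    independent afferents, so the aggregate rate is ``n_afferents * rate``.
    Scenario II uses the default asymmetric peaks (3.6 vs 3.0 nS); for
    scenario I set equal peaks and a positive ``extra_rate_d1``.
    """

    rate: float = 10.0
    extra_rate_d1: float = 0.0
    rate_fsi: float | None = None  # defaults to `rate`
    peak_d1: float = 3.6
    peak_d2: float = 3.0
    peak_fsi: float = 5.0
    n_afferents: int = 250

    def __post_init__(self) -> None:
        if self.rate < 0 or self.extra_rate_d1 < 0:
            raise ValueError("rates must be >= 0")
        if self.n_afferents < 1:
            raise ValueError("n_afferents must be >= 1")

    def with_dopamine(self, alpha: float) -> "CorticalDrive":
        """Scale the cortical peaks by (1 + alpha) for D1 and (1 - alpha) for D2."""
        p1, p2 = self.peak_d1 * (1 + alpha), self.peak_d2 * (1 - alpha)
        if p1 <= 0 or p2 <= 0:
            raise ValueError("dopamine factor drives a cortical peak non-positive")
        return replace(self, peak_d1=p1, peak_d2=p2)

    def aggregate_rates(self, config: NetworkConfig) -> np.ndarray:
        """Per-neuron aggregate Poisson input rate (Hz)."""
        out = np.empty(config.n_total)
        out[config.pop_slice("d1")] = self.n_afferents * (
            self.rate + self.extra_rate_d1
        )
        out[config.pop_slice("d2")] = self.n_afferents * self.rate
        fsi_rate = self.rate if self.rate_fsi is None else self.rate_fsi
        out[config.pop_slice("fsi")] = self.n_afferents * fsi_rate
        return out

    def peaks(self, config: NetworkConfig) -> np.ndarray:
        out = np.empty(config.n_total)
        out[config.pop_slice("d1")] = self.peak_d1
        out[config.pop_slice("d2")] = self.peak_d2
        out[config.pop_slice("fsi")] = self.peak_fsi
        return out


@dataclass(frozen=True)
class SpikeRecord:
    """Spikes of one simulation: parallel (neuron id, time ms) arrays."""

    ids: np.ndarray
    times: np.ndarray
    duration: float
    dt: float
    config: NetworkConfig
    seeds: dict[str, int] = field(default_factory=dict)
    v_traces: np.ndarray | None = None
    v_trace_ids: np.ndarray | None = None

    def population(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        sl = self.config.pop_slice(pop)
        m = (self.ids >= sl.start) & (self.ids < sl.stop)
        return self.ids[m], self.times[m]


# ---------------------------------------------------------------------------
# integration kernel
# ---------------------------------------------------------------------------

_E = math.e


@njit(cache=True)
def _poisson_knuth(lam: float) -> int:
    if lam <= 0.0:
        return 0
    L = math.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= np.random.random()
        if p <= L:
            return k
        k += 1


@njit(cache=True)
def _run_kernel(
    n_steps,
    dt,
    v,
    refr,
    v_rest,
    v_th,
    v_exc,
    v_inh,
    c,
    g_rest,
    tau_exc,
    tau_inh,
    tref_steps,
    ge,
    xe,
    gi,
    xi,
    indptr,
    targets,
    peaks,
    delay_steps,
    inh_buf,
    lam_step,
    in_amp,
    ev_indptr,
    ev_steps,
    ev_amps,
    ev_ptr,
    i_ext,
    g_step_inh,
    onset_step,
    seed,
    out_ids,
    out_times,
    rec_ids,
    rec_v,
):
    np.random.seed(seed)
    n = v.size
    buf_len = inh_buf.shape[1]
    n_spikes = 0
    max_spikes = out_ids.size
    de = np.exp(-dt / tau_exc)
    di = np.exp(-dt / tau_inh)
    for step in range(n_steps):
        slot = step % buf_len
        for i in range(n):
            # deliver delayed inhibitory events
            xi[i] += inh_buf[i, slot]
            inh_buf[i, slot] = 0.0
            # cortical Poisson drive
            if lam_step[i] > 0.0:
                k = _poisson_knuth(lam_step[i])
                if k > 0:
                    xe[i] += k * in_amp[i] * _E
            # precomputed event drive (correlated inputs)
            p = ev_ptr[i]
            while p < ev_indptr[i + 1] and ev_steps[p] == step:
                xe[i] += ev_amps[p] * _E
                p += 1
            ev_ptr[i] = p
            # alpha-kernel states (exact propagation over dt)
            ge_new = (ge[i] + xe[i] * dt / tau_exc[i]) * de[i]
            xe[i] *= de[i]
            ge[i] = ge_new
            gi_new = (gi[i] + xi[i] * dt / tau_inh[i]) * di[i]
            xi[i] *= di[i]
            gi[i] = gi_new
            # membrane
            g_inh_tot = gi[i] + (g_step_inh[i] if step >= onset_step else 0.0)
            gtot = g_rest[i] + ge[i] + g_inh_tot
            v_inf = (
                g_rest[i] * v_rest[i]
                + ge[i] * v_exc[i]
                + g_inh_tot * v_inh[i]
                + i_ext[i]
            ) / gtot
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_rest[i]
            else:
                v[i] = v_inf + (v[i] - v_inf) * math.exp(-dt * gtot / c[i])
                if v[i] >= v_th[i]:
                    if n_spikes >= max_spikes:
                        return -1
                    out_ids[n_spikes] = i
                    out_times[n_spikes] = (step + 1) * dt
                    n_spikes += 1
                    v[i] = v_rest[i]
                    refr[i] = tref_steps[i]
                    for s in range(indptr[i], indptr[i + 1]):
                        tgt = targets[s]
                        dslot = (step + delay_steps[s]) % buf_len
                        inh_buf[tgt, dslot] += peaks[s] * _E
            if not math.isfinite(v[i]):
                return -(1000000 + i)
        for r in range(rec_ids.size):
            rec_v[r, step] = v[rec_ids[r]]
    return n_spikes


def simulate(
    network: Network,
    drive: CorticalDrive,
    T: float = 2500.0,
    dt: float = 0.1,
    seed: int = 0,
    event_times: Sequence[np.ndarray] | None = None,
    event_amps: Sequence[np.ndarray] | None = None,
    i_ext: np.ndarray | None = None,
    fsi_step_inhibition_ns: float = 0.0,
    step_onset: float | None = None,
    record_v_ids: Sequence[int] | None = None,
) -> SpikeRecord:
    """Integrate the network for *T* ms and return the spikes.

    Parameters
    ----------
    drive
        Poisson cortical input per population.  Populations with an entry
        in *event_times* (per-neuron sorted times, ms, with conductance
        amplitudes *event_amps* in nS) are driven by those events instead;
        set the corresponding Poisson rate to 0 via the drive to avoid
        double driving.
    i_ext
        Optional constant injected current per neuron (pA).
    fsi_step_inhibition_ns, step_onset
        Tonic inhibitory conductance (nS) applied to every FSI from
        ``step_onset`` ms onward (from t=0 if onset is None): the
        pallidostriatal (GPe) feedback abstraction.
    seed
        Controls membrane initial conditions and the Poisson input;
        connectivity has its own seed in :func:`build_network`.

    Membrane potentials start uniformly in [v_rest, v_th); spikes reset to
    v_rest with a 2 ms refractory clamp; synaptic events are delivered
    after each projection's delay.
    """
    if dt <= 0 or dt > 0.1 + 1e-12:
        raise ValueError("dt must be positive and <= 0.1 ms")
    cfg = network.config
    n = cfg.n_total
    n_steps = int(round(T / dt))

    par = np.empty((9, n))
    for pop, p in (
        ("d1", cfg.d1_params),
        ("d2", cfg.d2_params),
        ("fsi", cfg.fsi_params),
    ):
        sl = cfg.pop_slice(pop)
        par[:, sl] = np.array(
            [p.v_rest, p.v_th, p.v_exc, p.v_inh, p.c, p.g_rest, p.tau_exc, p.tau_inh,
             p.t_ref]
        )[:, None]
    v_rest, v_th, v_exc, v_inh, c, g_rest, tau_exc, tau_inh, t_ref = par
    tref_steps = np.round(t_ref / dt).astype(np.int64)

    rng = np.random.default_rng(seed)
    v = rng.uniform(v_rest, v_th)
    refr = np.zeros(n, dtype=np.int64)
    ge, xe, gi, xi = (np.zeros(n) for _ in range(4))

    delay_steps = np.maximum(1, np.round(network.delays / dt)).astype(np.int64)
    buf_len = int(delay_steps.max()) + 1 if delay_steps.size else 1
    inh_buf = np.zeros((n, buf_len))

    lam_step = drive.aggregate_rates(cfg) * dt / 1000.0
    in_amp = drive.peaks(cfg)

    if event_times is not None:
        if event_amps is None or len(event_times) != n or len(event_amps) != n:
            raise ValueError("event_times/event_amps must have one entry per neuron")
        lengths = np.array([len(t) for t in event_times], dtype=np.int64)
        ev_indptr = np.concatenate([[0], np.cumsum(lengths)])
        ev_steps = (
            np.concatenate([np.asarray(t) for t in event_times])
            if ev_indptr[-1] else np.empty(0)
        )
        ev_steps = np.minimum((ev_steps / dt).astype(np.int64), n_steps - 1)
        ev_amps = (
            np.concatenate([np.asarray(a, dtype=float) for a in event_amps])
            if ev_indptr[-1] else np.empty(0)
        )
        # neurons with explicit events get no Poisson drive
        lam_step = lam_step.copy()
        lam_step[lengths > 0] = 0.0
    else:
        ev_indptr = np.zeros(n + 1, dtype=np.int64)
        ev_steps = np.empty(0, dtype=np.int64)
        ev_amps = np.empty(0)
    ev_ptr = ev_indptr[:-1].copy()

    i_ext = np.zeros(n) if i_ext is None else np.asarray(i_ext, dtype=float)
    g_step_inh = np.zeros(n)
    if fsi_step_inhibition_ns:
        g_step_inh[cfg.pop_slice("fsi")] = fsi_step_inhibition_ns
    onset_step = 0 if step_onset is None else int(round(step_onset / dt))

    rec_ids = (
        np.asarray(record_v_ids, dtype=np.int64)
        if record_v_ids is not None
        else np.empty(0, dtype=np.int64)
    )
    rec_v = np.empty((rec_ids.size, n_steps))

    max_spikes = int(n * (T / 1000.0) * 350) + 10_000
    out_ids = np.empty(max_spikes, dtype=np.int32)
    out_times = np.empty(max_spikes)

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    res = _run_kernel(
        n_steps, dt, v, refr,
        v_rest, v_th, v_exc, v_inh, c, g_rest, tau_exc, tau_inh, tref_steps,
        ge, xe, gi, xi,
        network.indptr, network.targets, network.peaks, delay_steps, inh_buf,
        lam_step, in_amp,
        ev_indptr, ev_steps.astype(np.int64), ev_amps, ev_ptr,
        i_ext, g_step_inh, onset_step,
        kernel_seed, out_ids, out_times, rec_ids, rec_v,
    )
    if res == -1:
        raise RuntimeError("spike buffer overflow; network is firing implausibly fast")
    if res < 0:
        raise RuntimeError(f"non-finite membrane potential in neuron {-res - 1000000}")
    n_spikes = int(res)
    return SpikeRecord(
        ids=out_ids[:n_spikes].copy(),
        times=out_times[:n_spikes].copy(),
        duration=T,
        dt=dt,
        config=cfg,
        seeds={"connectivity": network.connectivity_seed, "simulation": seed},
        v_traces=rec_v if rec_ids.size else None,
        v_trace_ids=rec_ids if rec_ids.size else None,
    )


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------


def population_rate(
    record: SpikeRecord,
    pop: str,
    window: float = 10.0,
    discard: float = 500.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean population rate (Hz) and PSTH.

    The mean rate is total spikes / (neurons * analysed duration) after
    dropping the first *discard* ms; the PSTH is binned at *window* ms and
    normalized to Hz per neuron.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if discard >= record.duration:
        raise ValueError("discard must be < duration")
    sl = record.config.pop_slice(pop)
    n_neurons = sl.stop - sl.start
    _, times = record.population(pop)
    times = times[times >= discard]
    analysed = (record.duration - discard) / 1000.0
    rate = times.size / (n_neurons * analysed)
    edges = np.arange(discard, record.duration + 1e-9, window)
    hist, _ = np.histogram(times, bins=edges)
    psth = hist / (n_neurons * window / 1000.0)
    return float(rate), psth, edges[:-1]


def _per_neuron_rates(record: SpikeRecord, pop: str, discard: float) -> np.ndarray:
    sl = record.config.pop_slice(pop)
    ids, times = record.population(pop)
    ids = ids[times >= discard] - sl.start
    analysed = (record.duration - discard) / 1000.0
    return np.bincount(ids, minlength=sl.stop - sl.start) / analysed


def delta_msn_spiking(
    record: SpikeRecord,
    discard: float = 500.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Population-mean D1 minus D2 rate, with a bootstrap CI over neurons."""
    r1 = _per_neuron_rates(record, "d1", discard)
    r2 = _per_neuron_rates(record, "d2", discard)
    delta = float(r1.mean() - r2.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        boots[b] = (
            rng.choice(r1, r1.size, replace=True).mean()
            - rng.choice(r2, r2.size, replace=True).mean()
        )
    a = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [a, 1.0 - a])
    return delta, (float(lo), float(hi))


def dtt_sweep_spiking(
    config: NetworkConfig,
    drive_template: CorticalDrive,
    grid: Sequence[float],
    seeds: Sequence[int] = (0, 1, 2),
    T: float = 2500.0,
    dt: float = 0.1,
    discard: float = 500.0,
) -> SweepResult:
    """Delta_MSN versus per-afferent cortical rate, with DTT detection.

    Each grid point is simulated once per seed (independent connectivity
    and input realizations); the DTT is interpolated from the sign change
    of the trial-mean curve.  Per-point trial values and bootstrap CIs are
    kept in ``metadata``.
    """
    grid = np.asarray(grid, dtype=float)
    trials = np.empty((grid.size, len(seeds)))
    cis = []
    for i, rate in enumerate(grid):
        for j, s in enumerate(seeds):
            net = build_network(config, seed=1000 + s)
            rec = simulate(
                net, replace(drive_template, rate=float(rate)), T=T, dt=dt, seed=s
            )
            trials[i, j], ci = delta_msn_spiking(rec, discard=discard, seed=s)
            cis.append((float(rate), s, ci))
    mean_curve = trials.mean(axis=1)
    res = find_dtt(grid, mean_curve)
    meta = {
        "trials": trials,
        "seeds": tuple(seeds),
        "cis": cis,
        "T": T,
        "dt": dt,
        "discard": discard,
    }
    return replace(res, axis="lam_ctx_per_afferent", metadata=meta)


# ---------------------------------------------------------------------------
# single-neuron validation
# ---------------------------------------------------------------------------


def lif_rheobase(params: NeuronParams) -> float:
    """Minimal constant current (pA) that reaches threshold: (V_th - V_rest)*G."""
    return (params.v_th - params.v_rest) * params.g_rest


def lif_rate_closed_form(params: NeuronParams, current: float) -> float:
    """Analytic steady firing rate (Hz) of the LIF at constant *current* (pA)."""
    if current <= lif_rheobase(params):
        return 0.0
    dv = (params.v_th - params.v_rest) / (current / params.g_rest)
    period = params.t_ref - params.tau_m * math.log(1.0 - dv)
    return 1000.0 / period


def fi_curve(
    params: NeuronParams,
    currents: Sequence[float],
    T: float = 2000.0,
    dt: float = 0.01,
) -> np.ndarray:
    """Simulated F-I curve: firing rate (Hz) per injected current (pA).

    Runs one disconnected neuron per current with no synaptic input.
    Supports per-population parameter overrides simply by passing the
    population's :class:`NeuronParams` (e.g. distinct D1/D2 passive
    properties).
    """
    currents = np.asarray(currents, dtype=float)
    if np.any(currents < 0):
        raise ValueError("currents must be >= 0")
    cfg = NetworkConfig(
        n_d1=1, n_d2=1, n_fsi=1,
        d1_params=params, d2_params=params, fsi_params=FSI_PARAMS,
        synapses=(),
    )
    net = build_network(cfg, seed=0)
    rates = np.empty_like(currents)
    quiet = CorticalDrive(rate=0.0, rate_fsi=0.0)
    for k, cur in enumerate(currents):
        i_ext = np.zeros(cfg.n_total)
        i_ext[0] = cur
        rec = simulate(net, quiet, T=T, dt=dt, seed=0, i_ext=i_ext)
        ids, times = rec.ids, rec.times
        rates[k] = (ids == 0).sum() / (T / 1000.0)
    return rates
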