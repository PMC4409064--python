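"""Experiment orchestration: protocols, configuration, and serialization.

Ties the mean-field model, the spiking network and the correlated-input
generator into the study's protocols: scenario sweeps with DTT detection,
B x W correlation grids with W_opt extraction, dopamine scans, the GPe
arbitration step, and the symmetric-FSI comparison.  Also provides TOML
config parsing, CSV/JSON/TSV output with provenance, and deterministic
test-fixture generation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .correlated_inputs import mother_rate_for_afferent_rate
from .dtt import SweepResult, apply_dopamine, apply_gpe, find_dtt, sweep_delta_msn
from .meanfield import (
    EffectiveWeights,
    FsiDriveModel,
    ScenarioInput,
    rate_dynamics,
)
from .spiking import (
    CorticalDrive,
    Network,
    NetworkConfig,
    SpikeRecord,
    build_network,
    delta_msn_spiking,
    dtt_sweep_spiking,
    simulate,
)

__all__ = [
    "CorrelationGridResult",
    "mip_event_input",
    "run_correlation_grid",
    "run_dopamine_scan",
    "run_gpe_arbitration",
    "run_symmetric_fsi",
    "critical_delta_ctx",
    "fixture_generator",
    "load_config",
    "config_hash",
    "write_sweep_csv",
    "write_summary_json",
    "write_spikes_tsv",
]


# ---------------------------------------------------------------------------
# correlated-input drive for the spiking network
# ---------------------------------------------------------------------------


def mip_event_input(
    config: NetworkConfig,
    afferent_rate: float,
    b_prime: float,
    w: float,
    duration: float,
    seed: int,
    peak_d1: float = 3.6,
    peak_d2: float = 3.0,
    n_afferents: int = 250,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Two-layer MIP cortical drive for every MSN, in pooled-event form.

    Each MSN owns a pool of ``n_afferents`` afferents generated from its
    pool-mother (layer 2, copy probability *w*), which is itself thinned
    from a global mother train (layer 1, copy probability *b_prime*).  The
    network only sees the summed conductance of a pool, so each selected
    mother event is delivered once with amplitude ``Binomial(n_afferents,
    w) * peak``: exactly equivalent to materializing the afferents, since
    the per-afferent copies are conditionally independent Bernoulli draws.

    The mother rate is set so each afferent fires at *afferent_rate* Hz.
    FSIs get empty event lists (they keep independent Poisson drive).
    """
    rng = np.random.default_rng(seed)
    r_in = mother_rate_for_afferent_rate(afferent_rate, b_prime, w)
    n_events = rng.poisson(r_in * duration / 1000.0)
    mother = np.sort(rng.uniform(0.0, duration, n_events))

    times: list[np.ndarray] = []
    amps: list[np.ndarray] = []
    for pop, peak in (("d1", peak_d1), ("d2", peak_d2)):
        sl = config.pop_slice(pop)
        for _ in range(sl.stop - sl.start):
            k = rng.binomial(n_events, b_prime)
            idx = np.sort(rng.choice(n_events, size=k, replace=False))
            mult = rng.binomial(n_afferents, w, size=k)
            keep = mult > 0
            times.append(mother[idx[keep]])
            amps.append(mult[keep] * peak)
    for _ in range(config.n_fsi):
        times.append(np.empty(0))
        amps.append(np.empty(0))
    return times, amps


@dataclass(frozen=True)
class CorrelationGridResult:
    """Delta_MSN over a (b_prime, w) or (rate, w) grid, with W_opt."""

    b_prime: np.ndarray
    w: np.ndarray
    rate: float
    delta_mean: np.ndarray  # (n_bprime, n_w)
    delta_ci: np.ndarray  # (n_bprime, n_w, 2)
    labels: np.ndarray  # (n_bprime, n_w) of {"d1", "d2", "conflict"}
    w_opt: np.ndarray  # (n_bprime,) arg-max of delta_mean over w
    metadata: dict[str, Any]


def run_correlation_grid(
    config: NetworkConfig,
    rate: float,
    b_prime_grid: Sequence[float],
    w_grid: Sequence[float],
    seeds: Sequence[int] = (0, 1, 2),
    T: float = 2500.0,
    discard: float = 500.0,
    drive: CorticalDrive | None = None,
    conflict_threshold: float | None = None,
) -> CorrelationGridResult:
    """Delta_MSN across input-correlation space in the spiking network.

    For each (b', w) cell, MIP-correlated cortical input at *rate* Hz per
    afferent drives the MSNs (FSIs keep independent Poisson input at the
    same per-afferent rate), the network is simulated once per seed, and
    the trial-mean D1-minus-D2 rate difference is recorded.

    Cells are labelled ``d1``/``d2`` by sign when the 95% bootstrap CI of
    Delta_MSN excludes 0, else ``conflict`` (region of high conflict); pass
    *conflict_threshold* (Hz) to use |Delta_MSN| < threshold instead.
    ``w_opt`` is the w-grid arg-max of the trial-mean Delta_MSN per b'.
    """
    drive = drive or CorticalDrive()
    bgrid = np.asarray(b_prime_grid, dtype=float)
    wgrid = np.asarray(w_grid, dtype=float)
    delta_mean = np.empty((bgrid.size, wgrid.size))
    delta_ci = np.empty((bgrid.size, wgrid.size, 2))
    labels = np.empty((bgrid.size, wgrid.size), dtype=object)

    for ib, bp in enumerate(bgrid):
        for iw, w in enumerate(wgrid):
            deltas, all_r1, all_r2 = [], [], []
            for s in seeds:
                net = build_network(config, seed=1000 + s)
                ev_seed = int(
                    np.random.SeedSequence([s, ib, iw]).generate_state(1)[0]
                    & 0x7FFFFFFF
                )
                ev_t, ev_a = mip_event_input(
                    config, rate, bp, w, T,
                    seed=ev_seed,
                    peak_d1=drive.peak_d1, peak_d2=drive.peak_d2,
                    n_afferents=drive.n_afferents,
                )
                rec = simulate(
                    net,
                    replace(drive, rate=rate, rate_fsi=rate),
                    T=T, seed=s, event_times=ev_t, event_amps=ev_a,
                )
                d, _ = delta_msn_spiking(rec, discard=discard, seed=s)
                deltas.append(d)
                from .spiking import _per_neuron_rates

                all_r1.append(_per_neuron_rates(rec, "d1", discard))
                all_r2.append(_per_neuron_rates(rec, "d2", discard))
            delta_mean[ib, iw] = np.mean(deltas)
            # bootstrap over pooled per-neuron rates across trials
            r1 = np.concatenate(all_r1)
            r2 = np.concatenate(all_r2)
            rng = np.random.default_rng(7)
            boots = [
                rng.choice(r1, r1.size).mean() - rng.choice(r2, r2.size).mean()
                for _ in range(500)
            ]
            lo, hi = np.quantile(boots, [0.025, 0.975])
            delta_ci[ib, iw] = (lo, hi)
            if conflict_threshold is not None:
                conflict = abs(delta_mean[ib, iw]) < conflict_threshold
            else:
                conflict = lo <= 0.0 <= hi
            labels[ib, iw] = (
                "conflict" if conflict
                else ("d1" if delta_mean[ib, iw] > 0 else "d2")
            )

    w_opt = wgrid[np.argmax(delta_mean, axis=1)]
    return CorrelationGridResult(
        b_prime=bgrid, w=wgrid, rate=rate,
        delta_mean=delta_mean, delta_ci=delta_ci, labels=labels, w_opt=w_opt,
        metadata={"seeds": tuple(seeds), "T": T, "discard": discard},
    )


# ---------------------------------------------------------------------------
# dopamine, GPe and symmetric-FSI protocols
# ---------------------------------------------------------------------------


def run_dopamine_scan(
    alphas: Sequence[float] = (-0.2, -0.1, 0.0, 0.1, 0.2),
    model: str = "meanfield",
    weights: EffectiveWeights | None = None,
    template: ScenarioInput | None = None,
    grid: Sequence[float] | None = None,
    spiking_config: NetworkConfig | None = None,
    spiking_drive: CorticalDrive | None = None,
    spiking_grid: Sequence[float] | None = None,
    seeds: Sequence[int] = (0, 1, 2),
    T: float = 2500.0,
) -> pd.DataFrame:
    """DTT as a function of the dopamine factor alpha.

    Dopamine scales the cortical gains (jc1 up, jc2 down for alpha > 0),
    shifting the DTT up for high dopamine and down for depletion.  Returns
    a DataFrame with columns ``alpha``, ``dtt``, ``n_crossings`` and
    ``dtt_effective``: strong depletion abolishes the D1-dominant regime
    altogether (an all-negative sweep, effective DTT 0), while strong
    dopamine removes the D2-dominant regime within the swept range
    (all-positive, effective DTT +inf); missing crossings are otherwise
    recorded as absent (NaN).
    """

    def effective(res) -> float:
        if res.dtt is not None:
            return float(res.dtt)
        if res.n_crossings == 0:
            if np.all(res.delta_msn <= 0):
                return 0.0
            if np.all(res.delta_msn >= 0):
                return float("inf")
        return float("nan")

    rows = []
    if model == "meanfield":
        weights = weights or EffectiveWeights()
        template = template or ScenarioInput("multiplicative")
        for a in alphas:
            res = sweep_delta_msn(apply_dopamine(weights, a), template, grid=grid)
            rows.append(
                {"alpha": a, "dtt": res.dtt, "n_crossings": res.n_crossings,
                 "dtt_effective": effective(res)}
            )
    elif model == "spiking":
        cfg = spiking_config or NetworkConfig()
        drv = spiking_drive or CorticalDrive()
        sgrid = spiking_grid if spiking_grid is not None else np.arange(5.0, 30.1, 2.5)
        for a in alphas:
            res = dtt_sweep_spiking(cfg, drv.with_dopamine(a), sgrid, seeds=seeds, T=T)
            rows.append(
                {"alpha": a, "dtt": res.dtt, "n_crossings": res.n_crossings,
                 "dtt_effective": effective(res)}
            )
    else:
        raise ValueError("model must be 'meanfield' or 'spiking'")
    return pd.DataFrame(rows)


def run_gpe_arbitration(
    inhibition: float = 10.0,
    onset: float = 400.0,
    dopamine_alpha: float = 0.0,
    lam_ctx: float = 16.0,
    model: str = "meanfield",
    weights: EffectiveWeights | None = None,
    template: ScenarioInput | None = None,
    T: float = 800.0,
    spiking_config: NetworkConfig | None = None,
    spiking_drive: CorticalDrive | None = None,
    spiking_inhibition_ns: float = 20.0,
    seed: int = 0,
) -> dict[str, Any]:
    """GPe arbitration step: constant FSI inhibition switched on at *onset*.

    The operating point (default lam_ctx just above the normal-dopamine
    DTT) starts D2-biased; releasing the MSNs from feedforward inhibition
    favours D1 (which receives more FSI input), so in the normal-dopamine
    state the bias flips to D1 after the step, while under dopamine
    depletion (alpha < 0) the D2 bias is too strong to flip.

    Returns the Delta_MSN time course with pre-/post-onset signs.  For the
    spiking model *inhibition* is replaced by a tonic inhibitory
    conductance (*spiking_inhibition_ns*) onto the FSIs.
    """
    if model == "meanfield":
        weights = apply_dopamine(weights or EffectiveWeights(), dopamine_alpha)
        template = template or ScenarioInput("multiplicative")
        template = replace(template, lam_ctx=lam_ctx)
        template = replace(
            template, fsi_drive=apply_gpe(template.fsi_drive, inhibition, onset=onset)
        )
        traj = rate_dynamics(weights, template, T=T)
        t, delta = traj.t, traj.delta_msn
        # steady-state windows: just before onset, and at the end
        pre = float(delta[np.searchsorted(t, onset) - 1])
        post = float(delta[-1])
    elif model == "spiking":
        cfg = spiking_config or NetworkConfig()
        drv = replace(
            (spiking_drive or CorticalDrive()).with_dopamine(dopamine_alpha),
            rate=lam_ctx,
        )
        net = build_network(cfg, seed=1000 + seed)
        rec = simulate(
            net, drv, T=T, seed=seed,
            fsi_step_inhibition_ns=spiking_inhibition_ns, step_onset=onset,
        )
        from .spiking import population_rate

        _, psth1, edges = population_rate(rec, "d1", window=50.0, discard=0.0)
        _, psth2, _ = population_rate(rec, "d2", window=50.0, discard=0.0)
        delta = psth1 - psth2
        t = edges
        settle = 200.0  # ms discarded after t=0 and after onset
        pre = float(delta[(t >= settle) & (t < onset)].mean())
        post = float(delta[t >= onset + settle].mean())
    else:
        raise ValueError("model must be 'meanfield' or 'spiking'")
    return {
        "t": t,
        "delta_msn": delta,
        "pre_sign": float(np.sign(pre)),
        "post_sign": float(np.sign(post)),
        "pre": pre,
        "post": post,
        "flipped": pre < 0 < post,
        "onset": onset,
        "inhibition": inhibition,
        "dopamine_alpha": dopamine_alpha,
    }


def run_symmetric_fsi(
    scenario: str = "symmetric_multiplicative",
    co_modulated: bool = True,
    jf_sym: float = 0.075,
    weights: EffectiveWeights | None = None,
    clamped_rate: float = 10.0,
    grid: Sequence[float] | None = None,
    mode: str = "linear",
) -> SweepResult:
    """Linear-balance sweep with equal FSI projections to both MSN types.

    With symmetric feedforward inhibition the additive scenario keeps its
    DTT (the MSN-MSN recurrent asymmetry suffices), whether the FSI rate is
    clamped or co-modulated with cortex, while along the co-modulated
    multiplicative diagonal Delta_MSN never crosses from positive to
    negative: the common FSI term is proportional to (J11+J12)-(J21+J22) > 0
    and favours D1.  A clamped-FSI multiplicative crossing exists only when
    the cortical-gain advantage is small, jc1*(J22+J21) < jc2*(J11+J12),
    i.e. jc1/jc2 below 27/26 for the reference recurrent weights.

    The closed-form linear balance is used by default since these are
    statements about the leak-free analysis (the saturating model squashes
    Delta_MSN to 0 from above instead of crossing); pass
    ``mode="nonlinear"`` for the full fixed points.
    """
    weights = replace(weights or EffectiveWeights(), jf_sym=jf_sym)
    if scenario not in ("symmetric_additive", "symmetric_multiplicative"):
        raise ValueError("scenario must be one of the symmetric variants")
    if co_modulated:
        drv = FsiDriveModel(mode="proportional")
    else:
        drv = FsiDriveModel(mode="clamped", clamped_rate=clamped_rate)
    if grid is None:
        grid = np.arange(0.0, 40.0 + 1e-9, 0.1)
    delta_ctx = 1.0 if scenario == "symmetric_additive" else 0.0
    template = ScenarioInput(scenario, delta_ctx=delta_ctx, fsi_drive=drv)
    return sweep_delta_msn(weights, template, grid=grid, mode=mode)


def critical_delta_ctx(
    weights: EffectiveWeights | None = None,
    template: ScenarioInput | None = None,
    dctx_grid: Sequence[float] | None = None,
    grid: Sequence[float] | None = None,
) -> float | None:
    """Smallest Delta_CTX for which D1 stays dominant across the whole sweep.

    Scans Delta_CTX upward; returns the first value whose additive lam_ctx
    sweep shows no sign change with Delta_MSN >= 0 throughout (above it the
    striatum can no longer switch to a D2 bias), or None if every scanned
    value still yields a transition.
    """
    weights = weights or EffectiveWeights()
    template = template or ScenarioInput("additive")
    if dctx_grid is None:
        dctx_grid = np.arange(0.0, 5.0 + 1e-9, 0.1)
    for d in dctx_grid:
        res = sweep_delta_msn(weights, replace(template, delta_ctx=float(d)), grid=grid)
        if res.n_crossings == 0 and np.all(res.delta_msn >= 0.0):
            return float(d)
    return None


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def fixture_generator(kind: str, size: int = 20, seed: int = 0) -> Any:
    """Small deterministic fixtures for the test suite.

    Kinds: ``toy-sweep`` (a Delta_MSN curve with a known single crossing at
    ``size`` Hz on a 0-20 grid), ``mini-network`` (a size+size+2 neuron
    network), ``short-trains`` (a handful of 1 s Poisson trains).
    """
    rng = np.random.default_rng(seed)
    if kind == "toy-sweep":
        grid = np.linspace(0.0, 20.0, 201)
        vals = float(size) - grid  # crosses at exactly `size`
        return grid, vals
    if kind == "mini-network":
        cfg = NetworkConfig(n_d1=size, n_d2=size, n_fsi=2)
        return build_network(cfg, seed=seed)
    if kind == "short-trains":
        from .correlated_inputs import poisson_train

        return [poisson_train(10.0, 1000.0, int(rng.integers(2**31))) for _ in range(size)]
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# config and serialization
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a TOML config into model objects.

    Recognized sections (all optional; defaults reproduce the reference
    parameter set): ``[weights]``, ``[fsi_drive]``, ``[scenario]``,
    ``[sweep]``, ``[noise]``, ``[robustness]``, ``[spiking]``.
    Returns a dict with keys ``weights``, ``fsi_drive``, ``scenario_input``,
    ``sweep``, ``noise``, ``robustness``, ``spiking`` and ``raw``.
    """
    raw = tomllib.loads(Path(path).read_text())
    weights = EffectiveWeights(**raw.get("weights", {}))
    fsi = FsiDriveModel(**raw.get("fsi_drive", {}))
    scen = raw.get("scenario", {})
    scenario_input = ScenarioInput(
        scenario=scen.get("scenario", "multiplicative"),
        lam_ctx=scen.get("lam_ctx", 10.0),
        delta_ctx=scen.get("delta_ctx", 0.0),
        fsi_drive=fsi,
    )
    sweep = raw.get("sweep", {})
    spk = raw.get("spiking", {})
    spiking = {
        "config": NetworkConfig(
            n_d1=spk.get("n_d1", 2000),
            n_d2=spk.get("n_d2", 2000),
            n_fsi=spk.get("n_fsi", 80),
        ),
        "drive": CorticalDrive(
            rate=spk.get("rate", 10.0),
            peak_d1=spk.get("peak_d1", 3.6),
            peak_d2=spk.get("peak_d2", 3.0),
            peak_fsi=spk.get("peak_fsi", 5.0),
            n_afferents=spk.get("n_afferents", 250),
        ),
        "T": spk.get("duration", 2500.0),
        "dt": spk.get("dt", 0.1),
    }
    return {
        "weights": weights,
        "fsi_drive": fsi,
        "scenario_input": scenario_input,
        "sweep": sweep,
        "noise": raw.get("noise", {}),
        "robustness": raw.get("robustness", {}),
        "spiking": spiking,
        "raw": raw,
    }


def config_hash(obj: Any) -> str:
    """Stable short hash of a configuration object (provenance)."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {type(o).__name__: dataclasses.asdict(o)}
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return repr(o)

    blob = json.dumps(obj, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sweep_csv(result: SweepResult, path: str | Path) -> None:
    """Write a sweep as CSV: grid point, Delta_MSN."""
    pd.DataFrame({result.axis or "x": result.grid, "delta_msn": result.delta_msn}).to_csv(
        path, index=False
    )


def write_summary_json(
    result: SweepResult, path: str | Path, seed: int | None = None
) -> None:
    """Write the DTT summary with provenance (config hash, seed, version)."""
    meta = {
        k: v for k, v in result.metadata.items()
        if isinstance(v, (str, int, float, tuple, list))
    }
    payload = {
        "axis": result.axis,
        "dtt": result.dtt,
        "n_crossings": result.n_crossings,
        "direction": result.direction,
        "seed": seed,
        "version": __version__,
        "config_hash": config_hash(
            {"metadata": meta, "grid": [float(result.grid[0]), float(result.grid[-1])]}
        ),
        "metadata": meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def write_spikes_tsv(record: SpikeRecord, out_dir: str | Path) -> None:
    """Write per-population spike TSVs (neuron_id, time_ms) plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pop in ("d1", "d2", "fsi"):
        ids, times = record.population(pop)
        pd.DataFrame({"neuron_id": ids, "time_ms": times}).to_csv(
            out_dir / f"spikes_{pop}.tsv", sep="\t", index=False
        )
    sidecar = {
        "n_d1": record.config.n_d1,
        "n_d2": record.config.n_d2,
        "n_fsi": record.config.n_fsi,
        "duration_ms": record.duration,
        "dt_ms": record.dt,
        "seeds": record.seeds,
        "version": __version__,
        "config_hash": config_hash(record.config),
    }
    (out_dir / "spikes_meta.json").write_text(json.dumps(sidecar, indent=2))


def export_adjacency_csv(network: Network, path: str | Path) -> None:
    """Write the realized connectivity as source,target,weight_ns,delay_ms CSV."""
    n = network.config.n_total
    src = np.repeat(np.arange(n), np.diff(network.indptr))
    pd.DataFrame(
        {
            "source": src,
            "target": network.targets,
            "weight_ns": network.peaks,
            "delay_ms": network.delays,
        }
    ).to_csv(path, index=False)
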