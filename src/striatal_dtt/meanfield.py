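"""Mean-field rate model of the striatal D1/D2/FSI circuit.

The striatum is modelled as two mutually inhibiting populations of medium
spiny neurons (D1 "Go" and D2 "No-Go" MSNs) plus feedforward inhibition from
fast spiking interneurons (FSIs), all driven by cortical excitation.  The
population rates obey first-order dynamics

    d(lam_D1)/dt = -0.01*lam_D1 + S(-J11*lam_D1 - J12*lam_D2 - J1F*lam_FSI + e_D1)
    d(lam_D2)/dt = -0.01*lam_D2 + S(-J21*lam_D1 - J22*lam_D2 - J2F*lam_FSI + e_D2)

with time in milliseconds (leak constant 100 ms), the saturating transfer
function S(z) = z / sqrt(z**2 + 1), and excitatory drives e_D1, e_D2 set by
the input scenario.  All coupling magnitudes are stored unsigned; every
equation applies the sign (inhibition negative, excitation positive)
explicitly.

Two input scenarios give D1 MSNs their competitive edge:

* additive -- equal cortico-striatal gains, D1 receives an extra rate
  Delta_CTX on top of the common cortical rate lambda_CTX;
* multiplicative -- equal rates, D1 has the stronger cortical gain
  (JC1 > JC2).

``symmetric_*`` variants replace the asymmetric FSI projections (J1F > J2F)
by a single common magnitude ``jf_sym``.

Besides forward integration this module provides the closed-form fixed
points of the linearized, leak-free system, the decomposition of the rate
difference Delta_MSN = lam_D1 - lam_D2 into its mechanistic terms, the
Jacobian stability analysis of the nonlinear fixed points, and the
conversion from anatomical connectivity measurements to effective coupling
magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import optimize

__all__ = [
    "EffectiveWeights",
    "FsiDriveModel",
    "ScenarioInput",
    "RateState",
    "RateTrajectory",
    "LinearAnalysisResult",
    "AnatomicalParams",
    "TABLE_ANATOMY",
    "DegenerateWeightsError",
    "IntegrationError",
    "FixedPointError",
    "NotAFixedPointError",
    "transfer",
    "transfer_deriv",
    "rate_dynamics",
    "fixed_point",
    "linear_fixed_points",
    "delta_msn_closed_form",
    "jacobian_stability",
    "effective_weight_from_anatomy",
    "msn_weights_from_anatomy",
]

LEAK = 0.01  # 1/ms; population rates relax with a 100 ms time constant
# steady rates are bounded by S(z) <= 1, i.e. by 1/LEAK = 100 Hz

Scenario = Literal[
    "additive", "multiplicative", "symmetric_additive", "symmetric_multiplicative"
]


class DegenerateWeightsError(ValueError):
    """The 2x2 recurrent weight matrix is singular; closed forms undefined."""


class IntegrationError(RuntimeError):
    """Forward integration produced a non-finite rate."""


class FixedPointError(RuntimeError):
    """No fixed point with acceptable residual was found."""


class NotAFixedPointError(ValueError):
    """A state handed to the stability analysis is not a fixed point."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectiveWeights:
    """Unsigned coupling magnitudes of the striatal microcircuit.

    Index convention: first index is the *target* population.  Defaults are
    the reference parameter set of the model (mutual/recurrent MSN
    inhibition J11..J22, preferential FSI inhibition J1F > J2F, and the
    cortical gains JC1 > JC2 of the multiplicative scenario).

    ``jf_sym`` is the optional common FSI magnitude used by the
    symmetric-FSI variants; it is ignored by the asymmetric scenarios.
    """

    j11: float = 0.06
    j12: float = 0.21
    j21: float = 0.04
    j22: float = 0.22
    j1f: float = 0.09
    j2f: float = 0.06
    jc1: float = 1.06
    jc2: float = 1.0
    jf_sym: float | None = None

    def __post_init__(self) -> None:
        for name in ("j11", "j12", "j21", "j22", "j1f", "j2f", "jc1", "jc2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"weight magnitude {name} must be > 0")
        if self.jf_sym is not None and not self.jf_sym > 0:
            raise ValueError("jf_sym must be > 0 when set")

    @property
    def det(self) -> float:
        """Determinant J22*J11 - J12*J21 of the recurrent weight matrix."""
        return self.j22 * self.j11 - self.j12 * self.j21

    def fsi_weights(self, scenario: str) -> tuple[float, float]:
        """(J1F, J2F) magnitudes effective under *scenario*."""
        if scenario.startswith("symmetric"):
            if self.jf_sym is None:
                raise ValueError("symmetric scenarios require jf_sym to be set")
            return self.jf_sym, self.jf_sym
        return self.j1f, self.j2f


# Calibrated defaults of the proportional FSI drive (see FsiDriveModel).
# The gain is fixed at a round, physiological value; the activation
# threshold was calibrated once by scripts/calibrate_fsi_gain.py so that the
# multiplicative reference sweep crosses at ~13 Hz.  Do not edit by hand.
DEFAULT_FSI_GAIN = 3.0
DEFAULT_FSI_THRESHOLD = 9.4


@dataclass(frozen=True)
class FsiDriveModel:
    """How the FSI population rate follows the cortical rate.

    The circuit data constrain the FSI -> MSN weights but not the
    cortex -> FSI transfer, so three models are provided:

    ``clamped``
        lam_FSI is held at ``clamped_rate`` regardless of cortex.
    ``proportional``
        lam_FSI = gain * max(0, lam_CTX - threshold).  ``threshold`` (Hz)
        is a rheobase-like cortical rate below which FSIs are silent;
        FSIs need substantially more depolarisation than MSNs to fire, so
        their rate is modelled as zero until the cortical drive clears it.
    ``dynamic``
        lam_FSI obeys its own rate equation
        d(lam_FSI)/dt = -0.01*lam_FSI + S(jcf*lam_CTX).

    ``gpe_inhibition`` models pallidostriatal feedback: a non-negative rate
    subtracted from lam_FSI (result floored at 0), either for all times or,
    when ``gpe_onset`` is set, only from that time (ms) onward.
    """

    mode: Literal["clamped", "proportional", "dynamic"] = "proportional"
    clamped_rate: float = 10.0
    gain: float = DEFAULT_FSI_GAIN
    threshold: float = DEFAULT_FSI_THRESHOLD
    jcf: float = 0.01
    gpe_inhibition: float = 0.0
    gpe_onset: float | None = None

    def __post_init__(self) -> None:
        if self.gpe_inhibition < 0:
            raise ValueError("gpe_inhibition must be >= 0")
        if self.clamped_rate < 0 or self.gain < 0 or self.threshold < 0:
            raise ValueError("FSI drive parameters must be non-negative")

    def _gpe(self, t: float | None) -> float:
        if self.gpe_onset is not None and (t is None or t < self.gpe_onset):
            return 0.0
        return self.gpe_inhibition

    def rate(self, lam_ctx: float, t: float | None = None) -> float:
        """Steady-state FSI rate for cortical rate *lam_ctx* at time *t* (ms).

        For the dynamic mode this is the fixed point of the FSI rate
        equation, lam_FSI = 100 * S(jcf * lam_ctx).
        """
        if self.mode == "clamped":
            base = self.clamped_rate
        elif self.mode == "proportional":
            base = self.gain * max(0.0, lam_ctx - self.threshold)
        elif self.mode == "dynamic":
            base = float(transfer(self.jcf * lam_ctx)) / LEAK
        else:  # pragma: no cover - guarded by Literal typing
            raise ValueError(f"unknown FSI drive mode {self.mode!r}")
        return max(0.0, base - self._gpe(t))


@dataclass(frozen=True)
class ScenarioInput:
    """Cortical input configuration for one operating point."""

    scenario: Scenario = "multiplicative"
    lam_ctx: float = 10.0
    delta_ctx: float = 0.0
    fsi_drive: FsiDriveModel = field(default_factory=FsiDriveModel)

    def __post_init__(self) -> None:
        if self.lam_ctx < 0:
            raise ValueError("lam_ctx must be >= 0")
        if self.delta_ctx < 0:
            raise ValueError("delta_ctx must be >= 0")
        if self.scenario not in (
            "additive",
            "multiplicative",
            "symmetric_additive",
            "symmetric_multiplicative",
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def is_additive(self) -> bool:
        return self.scenario.endswith("additive")

    def drives(self, weights: EffectiveWeights) -> tuple[float, float]:
        """Excitatory drives (e_D1, e_D2) in Hz-equivalent units.

        Additive: unit cortical gain to both MSN types, with the extra rate
        Delta_CTX added to D1.  Multiplicative: common rate scaled by the
        asymmetric gains JC1 >= JC2 (delta_ctx unused).
        """
        if self.is_additive:
            return self.lam_ctx + self.delta_ctx, self.lam_ctx
        # Baseline multiplicative scenarios have jc1 >= jc2 (D1 favoured);
        # dopamine-depleted variants legitimately reverse the order, which
        # abolishes the D1-dominant regime rather than being invalid.
        return weights.jc1 * self.lam_ctx, weights.jc2 * self.lam_ctx

    def fsi_rate(self, t: float | None = None) -> float:
        return self.fsi_drive.rate(self.lam_ctx, t)


@dataclass(frozen=True)
class RateState:
    """Population rates (Hz) of the three striatal populations."""

    lam_d1: float
    lam_d2: float
    lam_fsi: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.lam_d1, self.lam_d2, self.lam_fsi):
            if not math.isfinite(v) or v < 0:
                raise ValueError("population rates must be finite and >= 0")

    @property
    def delta_msn(self) -> float:
        return self.lam_d1 - self.lam_d2


@dataclass(frozen=True)
class RateTrajectory:
    """Time course of the population rates from forward integration."""

    t: np.ndarray
    lam_d1: np.ndarray
    lam_d2: np.ndarray
    lam_fsi: np.ndarray

    @property
    def terminal(self) -> RateState:
        return RateState(
            float(self.lam_d1[-1]), float(self.lam_d2[-1]), float(self.lam_fsi[-1])
        )

    @property
    def delta_msn(self) -> np.ndarray:
        return self.lam_d1 - self.lam_d2


@dataclass(frozen=True)
class LinearAnalysisResult:
    """Closed-form fixed point of the linear, leak-free rate balance.

    ``decomposition`` maps term names to values; the terms sum to
    ``delta_msn`` exactly.  For the additive scenarios the terms are
    ``inp_str`` (recurrent striatal shaping of the common input) and
    ``inp_add`` (the extra D1 drive); for the multiplicative ones they are
    ``d1_eff``/``d2_eff`` and, with symmetric FSI projections, the common
    feedforward term ``comm_eff``.
    """

    lam_d1: float
    lam_d2: float
    decomposition: dict[str, float]

    @property
    def delta_msn(self) -> float:
        return self.lam_d1 - self.lam_d2


@dataclass(frozen=True)
class AnatomicalParams:
    """Anatomical quantities behind one effective coupling magnitude.

    The effective inhibition a target neuron feels from a presynaptic
    population is the product of presynaptic count, connection probability,
    unitary IPSC amplitude, target input resistance and synaptic time
    constant.
    """

    n_source: float
    rho: float
    ipsc: float  # pA
    r_in: float  # MOhm
    tau: float  # ms

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        for name in ("n_source", "ipsc", "r_in", "tau"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


#: Measured anatomy of the MSN->MSN and FSI->MSN projections (paired
#: recordings): connection probabilities, IPSC amplitudes, input resistance
#: and synaptic time constants.  Keys are (target, source).
TABLE_ANATOMY: dict[tuple[str, str], AnatomicalParams] = {
    ("d1", "d1"): AnatomicalParams(2000, 0.26, 42.0, 238.0, 12.0),
    ("d2", "d1"): AnatomicalParams(2000, 0.07, 107.0, 238.0, 12.0),
    ("d2", "d2"): AnatomicalParams(2000, 0.36, 107.0, 238.0, 12.0),
    ("d1", "d2"): AnatomicalParams(2000, 0.27, 133.0, 238.0, 12.0),
}


# ---------------------------------------------------------------------------
# transfer function and dynamics
# ---------------------------------------------------------------------------


def transfer(z):
    """Saturating transfer function S(z) = z / sqrt(z**2 + 1).

    Odd, strictly increasing, with S(z) -> +-1 as z -> +-inf.
    """
    z = np.asarray(z, dtype=float)
    out = z / np.sqrt(z * z + 1.0)
    return out if out.ndim else float(out)


def transfer_deriv(z):
    """Analytic derivative S'(z) = (z**2 + 1)**(-3/2) of :func:`transfer`."""
    z = np.asarray(z, dtype=float)
    out = (z * z + 1.0) ** -1.5
    return out if out.ndim else float(out)


def _rhs(
    lam_d1: float,
    lam_d2: float,
    lam_fsi: float,
    e1: float,
    e2: float,
    w: EffectiveWeights,
    j1f: float,
    j2f: float,
) -> tuple[float, float]:
    z1 = -w.j11 * lam_d1 - w.j12 * lam_d2 - j1f * lam_fsi + e1
    z2 = -w.j21 * lam_d1 - w.j22 * lam_d2 - j2f * lam_fsi + e2
    return (
        -LEAK * lam_d1 + transfer(z1),
        -LEAK * lam_d2 + transfer(z2),
    )


def rate_dynamics(
    weights: EffectiveWeights,
    scenario_input: ScenarioInput,
    initial: RateState | None = None,
    T: float = 5000.0,
    dt: float = 0.1,
    record_every: int = 10,
) -> RateTrajectory:
    """Forward-Euler integration of the population rate equations.

    Parameters
    ----------
    T, dt
        Duration and step in ms.  The leak constant is 100 ms, so
        ``T >= 1000`` reaches the fixed point to high accuracy for the
        default parameters.
    record_every
        Keep every n-th sample (the terminal state is always exact).

    Rates are floored at 0 after every step; transiently negative drives are
    allowed (S is odd) so the smooth stability analysis stays valid.
    """
    if dt <= 0 or T <= 0:
        raise ValueError("T and dt must be > 0")
    initial = initial or RateState(0.0, 0.0, 0.0)
    e1, e2 = scenario_input.drives(weights)
    j1f, j2f = weights.fsi_weights(scenario_input.scenario)
    drv = scenario_input.fsi_drive
    dynamic_fsi = drv.mode == "dynamic"

    n_steps = int(round(T / dt))
    d1, d2 = initial.lam_d1, initial.lam_d2
    # fsi_state is the intrinsic FSI rate; the rate felt by the MSNs has any
    # GPe inhibition subtracted (floored at 0).
    fsi_state = initial.lam_fsi if dynamic_fsi else None
    fsi = (
        max(0.0, fsi_state - drv._gpe(0.0)) if dynamic_fsi
        else scenario_input.fsi_rate(t=0.0)
    )

    ts, x1s, x2s, xfs = [0.0], [d1], [d2], [fsi]
    zf = drv.jcf * scenario_input.lam_ctx
    for step in range(1, n_steps + 1):
        t = step * dt
        dd1, dd2 = _rhs(d1, d2, fsi, e1, e2, weights, j1f, j2f)
        d1 = max(0.0, d1 + dt * dd1)
        d2 = max(0.0, d2 + dt * dd2)
        if dynamic_fsi:
            fsi_state = max(
                0.0, fsi_state + dt * (-LEAK * fsi_state + transfer(zf))
            )
            fsi = max(0.0, fsi_state - drv._gpe(t))
        else:
            fsi = scenario_input.fsi_rate(t=t)
        if not (math.isfinite(d1) and math.isfinite(d2) and math.isfinite(fsi)):
            raise IntegrationError(
                f"rate dynamics diverged at step {step} (t = {t:.3f} ms)"
            )
        if step % record_every == 0 or step == n_steps:
            ts.append(t)
            x1s.append(d1)
            x2s.append(d2)
            xfs.append(fsi)
    return RateTrajectory(
        np.asarray(ts), np.asarray(x1s), np.asarray(x2s), np.asarray(xfs)
    )


_FP_TOL = 1e-8
_FP_STARTS = ((0.0, 0.0), (0.0, 100.0), (100.0, 0.0), (100.0, 100.0), (50.0, 50.0))


def projected_residual(
    weights: EffectiveWeights, scenario_input: ScenarioInput, state: RateState
) -> float:
    """Max residual of the rate-floored dynamics at *state*.

    At an interior point this is the raw |d(lam)/dt|; on the boundary
    (a rate pinned at 0 Hz) an inward-pointing negative derivative does not
    count, since the floor absorbs it.
    """
    e1, e2 = scenario_input.drives(weights)
    j1f, j2f = weights.fsi_weights(scenario_input.scenario)
    r = np.asarray(
        _rhs(state.lam_d1, state.lam_d2, state.lam_fsi, e1, e2, weights, j1f, j2f)
    )
    x = np.array([state.lam_d1, state.lam_d2])
    r = np.where((x <= 0.0) & (r < 0.0), 0.0, r)
    return float(np.max(np.abs(r)))


def fixed_point(
    weights: EffectiveWeights,
    scenario_input: ScenarioInput,
    tol: float = _FP_TOL,
) -> RateState:
    """Steady state of the nonlinear rate equations (rates floored at 0).

    Interior roots of the right-hand sides are found with a hybrid Powell
    solver started from the four corners of the admissible rate square
    [0, 100]^2 plus its centre.  When recurrent inhibition pins one
    population at 0 Hz the steady state lies on the boundary; those
    candidates are found by a bracketed scalar solve for the free
    population, accepting the point only if the pinned population's raw
    derivative is non-positive there.  If distinct candidates survive, the
    one closest to the terminal state of a long forward simulation is
    returned, so the result is always the dynamically selected fixed point.
    """
    e1, e2 = scenario_input.drives(weights)
    j1f, j2f = weights.fsi_weights(scenario_input.scenario)
    lam_fsi = scenario_input.fsi_rate(t=None)

    def fun(x):
        return _rhs(x[0], x[1], lam_fsi, e1, e2, weights, j1f, j2f)

    roots: list[np.ndarray] = []

    def add(x: np.ndarray) -> None:
        st = RateState(max(0.0, float(x[0])), max(0.0, float(x[1])), lam_fsi)
        if projected_residual(weights, scenario_input, st) < tol:
            xx = np.array([st.lam_d1, st.lam_d2])
            if not any(np.allclose(xx, r, atol=1e-6) for r in roots):
                roots.append(xx)

    for start in _FP_STARTS:
        sol = optimize.root(fun, np.asarray(start, dtype=float), method="hybr")
        if np.all(sol.x > -1e-9):
            add(sol.x)

    # boundary candidates: one population clamped at 0
    for pinned in (0, 1):
        def f(y: float) -> float:
            x = [0.0, 0.0]
            x[1 - pinned] = y
            return fun(x)[1 - pinned]

        hi = 1.0 / LEAK + 10.0  # f(hi) <= -LEAK*10 + 0 < 0 always
        f0 = f(0.0)
        if f0 <= 0.0:
            add(np.zeros(2))
        elif f(hi) < 0.0:
            y = optimize.brentq(f, 0.0, hi, xtol=1e-12)
            x = np.zeros(2)
            x[1 - pinned] = y
            add(x)

    if not roots:
        raise FixedPointError(
            f"no fixed point with residual < {tol:g} found for {scenario_input}"
        )
    if len(roots) > 1:
        term = rate_dynamics(weights, scenario_input, T=20000.0).terminal
        ref = np.array([term.lam_d1, term.lam_d2])
        roots.sort(key=lambda r: float(np.linalg.norm(r - ref)))
    return RateState(float(roots[0][0]), float(roots[0][1]), lam_fsi)


# ---------------------------------------------------------------------------
# linear (leak-free) closed forms
# ---------------------------------------------------------------------------


def _linear_balance(
    weights: EffectiveWeights, scenario_input: ScenarioInput
) -> tuple[float, float, float]:
    """Solve the 2x2 linear rate balance; returns (lam_d1, lam_d2, lam_fsi)."""
    det = weights.det
    if abs(det) < 1e-12:
        raise DegenerateWeightsError("J22*J11 - J12*J21 is (numerically) zero")
    e1, e2 = scenario_input.drives(weights)
    j1f, j2f = weights.fsi_weights(scenario_input.scenario)
    lam_fsi = scenario_input.fsi_rate(t=None)
    b1 = e1 - j1f * lam_fsi
    b2 = e2 - j2f * lam_fsi
    lam_d1 = (weights.j22 * b1 - weights.j12 * b2) / det
    lam_d2 = (weights.j11 * b2 - weights.j21 * b1) / det
    return lam_d1, lam_d2, lam_fsi


def delta_msn_closed_form(
    weights: EffectiveWeights, scenario_input: ScenarioInput
) -> LinearAnalysisResult:
    """Closed-form Delta_MSN with its mechanistic decomposition.

    Evaluates the printed decompositions of the linearized balance:
    additive -> Inp_str + Inp_add; multiplicative -> D1_eff + D2_eff;
    symmetric multiplicative -> D1_eff + D2_eff + comm_eff.  The terms sum
    to lam_d1 - lam_d2 of :func:`linear_fixed_points` exactly (algebraic
    identity, used as a test invariant).
    """
    w = weights
    det = w.det
    if abs(det) < 1e-12:
        raise DegenerateWeightsError("J22*J11 - J12*J21 is (numerically) zero")
    lam_d1, lam_d2, lam_fsi = _linear_balance(weights, scenario_input)
    lam_ctx = scenario_input.lam_ctx
    j1f, j2f = w.fsi_weights(scenario_input.scenario)

    if scenario_input.scenario == "additive":
        inp_str = (
            lam_ctx * (w.j22 + w.j21 - w.j11 - w.j12)
            + (j2f * (w.j12 + w.j11) - j1f * (w.j21 + w.j22)) * lam_fsi
        ) / det
        inp_add = scenario_input.delta_ctx * (w.j22 + w.j21) / det
        decomp = {"inp_str": inp_str, "inp_add": inp_add}
    elif scenario_input.scenario == "symmetric_additive":
        jf = j1f  # == j2f == jf_sym
        inp_str = (
            (w.j12 + w.j11 - w.j21 - w.j22) * (jf * lam_fsi - lam_ctx)
        ) / det
        inp_add = scenario_input.delta_ctx * (w.j22 + w.j21) / det
        decomp = {"inp_str": inp_str, "inp_add": inp_add}
    elif scenario_input.scenario == "multiplicative":
        d1_eff = (
            lam_ctx * w.jc1 * (w.j22 + w.j21) - lam_fsi * j1f * (w.j22 + w.j21)
        ) / det
        d2_eff = (
            -lam_ctx * w.jc2 * (w.j12 + w.j11) + lam_fsi * j2f * (w.j12 + w.j11)
        ) / det
        decomp = {"d1_eff": d1_eff, "d2_eff": d2_eff}
    else:  # symmetric_multiplicative
        jf = j1f
        d1_eff = lam_ctx * w.jc1 * (w.j22 + w.j21) / det
        d2_eff = -lam_ctx * w.jc2 * (w.j12 + w.j11) / det
        comm_eff = jf * lam_fsi * ((w.j12 + w.j11) - (w.j22 + w.j21)) / det
        decomp = {"d1_eff": d1_eff, "d2_eff": d2_eff, "comm_eff": comm_eff}

    return LinearAnalysisResult(lam_d1, lam_d2, decomp)


def linear_fixed_points(
    weights: EffectiveWeights, scenario_input: ScenarioInput
) -> LinearAnalysisResult:
    """Fixed point rates of the linearized, leak-free dynamics.

    Solves the linear balance J_rec @ (lam_d1, lam_d2) = excitation -
    feedforward inhibition and attaches the scenario's Delta_MSN
    decomposition.
    """
    return delta_msn_closed_form(weights, scenario_input)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------


def jacobian_stability(
    weights: EffectiveWeights,
    scenario_input: ScenarioInput,
    state: RateState,
    residual_tol: float = 1e-6,
) -> np.ndarray:
    """Eigenvalues of the 2x2 Jacobian of the rate dynamics at a fixed point.

    The Jacobian uses the analytic derivative S'(z) = (z**2+1)**(-3/2) of
    the implemented transfer function.  Raises
    :class:`NotAFixedPointError` if *state* does not satisfy the dynamics
    to within ``residual_tol``.
    """
    e1, e2 = scenario_input.drives(weights)
    j1f, j2f = weights.fsi_weights(scenario_input.scenario)
    lam_fsi = state.lam_fsi
    resid = _rhs(state.lam_d1, state.lam_d2, lam_fsi, e1, e2, weights, j1f, j2f)
    if max(abs(resid[0]), abs(resid[1])) > residual_tol:
        raise NotAFixedPointError(
            f"residual {max(map(abs, resid)):.3g} exceeds {residual_tol:g}"
        )
    z1 = -weights.j11 * state.lam_d1 - weights.j12 * state.lam_d2 - j1f * lam_fsi + e1
    z2 = -weights.j21 * state.lam_d1 - weights.j22 * state.lam_d2 - j2f * lam_fsi + e2
    s1, s2 = transfer_deriv(z1), transfer_deriv(z2)
    jac = np.array(
        [
            [-LEAK - s1 * weights.j11, -s1 * weights.j12],
            [-s2 * weights.j21, -LEAK - s2 * weights.j22],
        ]
    )
    return np.sort_complex(np.linalg.eigvals(jac))


# ---------------------------------------------------------------------------
# anatomy -> effective weight
# ---------------------------------------------------------------------------


def effective_weight_from_anatomy(
    anat: AnatomicalParams, normalization: float = 1.0
) -> float:
    """Effective coupling magnitude N * rho * IPSC * R * tau * normalization.

    The product fixes only relative magnitudes; *normalization* carries the
    unit conversion and is conventionally chosen so that the D2->D2 entry
    equals the reference value 0.22 (see :func:`msn_weights_from_anatomy`).
    """
    return anat.n_source * anat.rho * anat.ipsc * anat.r_in * anat.tau * normalization


def msn_weights_from_anatomy(
    table: dict[tuple[str, str], AnatomicalParams] | None = None,
    j22_ref: float = 0.22,
) -> dict[str, float]:
    """MSN->MSN coupling magnitudes from anatomy, normalized to J22 = *j22_ref*.

    Returns a dict with keys ``j11, j12, j21, j22`` (first index = target).
    """
    table = table if table is not None else TABLE_ANATOMY
    raw = {
        f"j{1 if tgt == 'd1' else 2}{1 if src == 'd1' else 2}":
            effective_weight_from_anatomy(anat)
        for (tgt, src), anat in table.items()
    }
    scale = j22_ref / raw["j22"]
    return {k: v * scale for k, v in raw.items()}


def with_dopamine(weights: EffectiveWeights, alpha: float) -> EffectiveWeights:
    """Cortical gains under dopamine modulation; see :func:`striatal_dtt.dtt.apply_dopamine`."""
    jc1 = weights.jc1 * (1.0 + alpha)
    jc2 = weights.jc2 * (1.0 - alpha)
    if jc1 <= 0 or jc2 <= 0:
        raise ValueError("dopamine factor drives a cortical gain non-positive")
    return replace(weights, jc1=jc1, jc2=jc2)
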