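"""Single-neuron leaky integrate-and-fire dynamics.

Two one-step integration schemes for the current-based LIF neuron with
exponentially decaying synaptic currents are provided:

* *exact* -- the analytical solution of the linear subthreshold system
  sampled at the grid spacing ``h`` (membrane and synaptic equations are
  propagated jointly);
* *exponential* -- the synaptic current is decayed exponentially between
  steps but treated as piecewise constant inside the membrane-potential
  update (the two equations are integrated separately).

On top of these, :func:`run_single_neuron` offers four backends: the two
grid schemes in double precision, the exponential scheme in emulated
s16.15 fixed-point state arithmetic with 16-bit quantized weights, and a
*precise* backend that locates threshold crossings off the grid on the
closed-form solution.

Units: time in ms, voltage in mV, current in nA, resistance in MΩ.

Per-step order for the grid backends (fixed so that results are
bit-reproducible and cross-implementations can match):

1. propagate/decay the state over ``h``,
2. add the input due this step to the synaptic current,
3. threshold test (spike iff ``V >= theta``), reset and start of the
   refractory period,
4. record the membrane potential.

During the refractory period the membrane potential is clamped to the
reset value while the synaptic current keeps evolving and accumulating
input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from spikebench.errors import ConfigurationError, InvalidParameterError

__all__ = [
    "NeuronParameters",
    "NeuronState",
    "ExactPropagator",
    "SpikeEvent",
    "VoltageTrace",
    "make_exact_propagator",
    "exponential_input_scale",
    "step_exact",
    "step_exponential",
    "find_precise_crossing",
    "run_single_neuron",
    "BACKENDS",
]

BACKENDS = ("exact-grid", "exponential-grid", "exponential-fixed", "precise")


@dataclass(frozen=True)
class NeuronParameters:
    """Parameters of the current-based LIF neuron.

    Attributes
    ----------
    tau_m : float
        Membrane time constant (ms).
    tau_s : float
        Synaptic time constant (ms).
    tau_ref : float
        Absolute refractory period (ms).
    R_m : float
        Membrane resistance (MΩ).
    E_L : float
        Leak (resting) potential (mV).
    theta : float
        Spike threshold (mV); a spike is emitted when ``V >= theta``.
    V_r : float
        Reset potential (mV), also the clamp level during refractoriness.
    """

    tau_m: float = 10.0
    tau_s: float = 0.5
    tau_ref: float = 2.0
    R_m: float = 40.0
    E_L: float = -65.0
    theta: float = -50.0
    V_r: float = -65.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_s <= 0:
            raise InvalidParameterError("time constants must be positive")
        if self.tau_ref < 0:
            raise InvalidParameterError("tau_ref must be non-negative")
        if self.R_m <= 0:
            raise InvalidParameterError("R_m must be positive")
        if self.V_r > self.theta:
            raise InvalidParameterError("V_r must not exceed theta")


@dataclass
class NeuronState:
    """Dynamic variables of one neuron.

    ``refractory_remaining`` is the time (ms) the neuron still spends
    clamped at ``V_r``; it is zero when the neuron is excitable.
    """

    V: float
    I: float = 0.0
    refractory_remaining: float = 0.0


@dataclass(frozen=True)
class ExactPropagator:
    """One-step map of the linear subthreshold system over a step ``h``.

    ``I' = beta * I`` and ``V' = E_L + (V - E_L) * alpha + I * P21``
    reproduce the analytical solution sampled at ``h``.
    """

    h: float
    alpha: float
    beta: float
    P21: float


class SpikeEvent(NamedTuple):
    """A spike of ``neuron_id`` at ``time`` (ms).

    Grid backends report grid-aligned end-of-step times; the precise
    backend reports continuous times.
    """

    neuron_id: int
    time: float


@dataclass
class VoltageTrace:
    """Membrane potential sampled at the integration steps."""

    times: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def make_exact_propagator(params: NeuronParameters, h: float) -> ExactPropagator:
    """Build the exact one-step propagator for step size ``h`` (ms).

    ``h = 0`` yields the identity map. For the removable singularity
    ``tau_s == tau_m`` the analytic limit ``P21 = R_m * (h/tau_m) * alpha``
    is used.
    """
    if h < 0:
        raise InvalidParameterError("step size h must be non-negative")
    alpha = math.exp(-h / params.tau_m)
    beta = math.exp(-h / params.tau_s)
    if params.tau_s == params.tau_m:
        P21 = params.R_m * (h / params.tau_m) * alpha
    else:
        P21 = params.R_m * params.tau_s * (beta - alpha) / (params.tau_s - params.tau_m)
    return ExactPropagator(h=h, alpha=alpha, beta=beta, P21=P21)


def exponential_input_scale(params: NeuronParameters, h: float,
                            decay_then_add: bool = False) -> float:
    """Input scaling ``q`` of the exponential scheme.

    The default ``q = tau_s * (1 - beta) / h`` makes the discrete charge
    sum of a single synaptic event equal ``J * tau_s`` exactly (geometric
    series ``h * J * q / (1 - beta)``).  With ``decay_then_add=True`` the
    literal decay-before-add rule ``q = beta`` is used instead.
    """
    if h <= 0:
        raise InvalidParameterError("step size h must be positive")
    beta = math.exp(-h / params.tau_s)
    if decay_then_add:
        return beta
    return params.tau_s * (1.0 - beta) / h


def _refractory_steps(params: NeuronParameters, h: float) -> int:
    return int(round(params.tau_ref / h))


def step_exact(state: NeuronState, prop: ExactPropagator,
               params: NeuronParameters, incoming_weight_sum: float,
               I_e: float = 0.0) -> tuple[NeuronState, bool]:
    """Advance one step with the exact propagator.

    ``incoming_weight_sum`` is the signed total (nA) of deliveries due
    this step. Returns ``(new_state, spiked)``; on a spike the caller
    attributes it to the end-of-step grid time.
    """
    h = prop.h
    I_new = prop.beta * state.I + incoming_weight_sum
    if state.refractory_remaining > 0.25 * h:
        r = state.refractory_remaining - h
        return NeuronState(V=params.V_r, I=I_new,
                           refractory_remaining=r if r > 0.25 * h else 0.0), False
    V_new = (params.E_L + (state.V - params.E_L) * prop.alpha
             + state.I * prop.P21
             + params.R_m * I_e * (1.0 - prop.alpha))
    # a state already at threshold spikes regardless of the propagated value
    if V_new >= params.theta or state.V >= params.theta:
        refr = _refractory_steps(params, h) * h if h > 0 else params.tau_ref
        return NeuronState(V=params.V_r, I=I_new, refractory_remaining=refr), True
    return NeuronState(V=V_new, I=I_new, refractory_remaining=0.0), False


def step_exponential(state: NeuronState, params: NeuronParameters, h: float,
                     incoming_weight_sum: float, I_e: float = 0.0,
                     decay_then_add: bool = False) -> tuple[NeuronState, bool]:
    """Advance one step with the separated exponential scheme.

    The synaptic current is first updated, ``I' = beta*I + q*w``, then
    treated as constant in the membrane update
    ``V' = E_L + (V - E_L)*alpha + R_m*I'*(1 - alpha)``.
    """
    if h <= 0:
        raise InvalidParameterError("step size h must be positive")
    alpha = math.exp(-h / params.tau_m)
    beta = math.exp(-h / params.tau_s)
    q = beta if decay_then_add else params.tau_s * (1.0 - beta) / h
    I_new = beta * state.I + q * incoming_weight_sum
    if state.refractory_remaining > 0.25 * h:
        r = state.refractory_remaining - h
        return NeuronState(V=params.V_r, I=I_new,
                           refractory_remaining=r if r > 0.25 * h else 0.0), False
    V_new = (params.E_L + (state.V - params.E_L) * alpha
             + params.R_m * (I_new + I_e) * (1.0 - alpha))
    if V_new >= params.theta or state.V >= params.theta:
        refr = _refractory_steps(params, h) * h
        return NeuronState(V=params.V_r, I=I_new, refractory_remaining=refr), True
    return NeuronState(V=V_new, I=I_new, refractory_remaining=0.0), False


def _closed_form_V(V0: float, I0: float, t: float, params: NeuronParameters,
                   I_e: float = 0.0) -> float:
    """Analytical membrane potential ``t`` ms after state ``(V0, I0)``
    with no further input."""
    a = math.exp(-t / params.tau_m)
    b = math.exp(-t / params.tau_s)
    if params.tau_s == params.tau_m:
        p21 = params.R_m * (t / params.tau_m) * a
    else:
        p21 = params.R_m * params.tau_s * (b - a) / (params.tau_s - params.tau_m)
    return (params.E_L + (V0 - params.E_L) * a + I0 * p21
            + params.R_m * I_e * (1.0 - a))


def find_precise_crossing(state: NeuronState, params: NeuronParameters,
                          h: float, tol: float = 1e-10,
                          I_e: float = 0.0) -> Optional[float]:
    """Earliest ``t* in [0, h]`` with ``V(t*) = theta`` on the closed form.

    Input spikes are grid-constrained, so within a step the membrane
    potential follows the closed-form solution from the step's initial
    state. The crossing is bracketed on a uniform sub-grid and refined by
    bisection to tolerance ``tol`` (ms). Returns ``None`` if the
    trajectory stays below threshold.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be positive")
    if h < 0:
        raise InvalidParameterError("h must be non-negative")
    if state.V >= params.theta:
        return 0.0
    if h == 0:
        return None
    # exact quick reject: V(t) can never exceed max(V0, E_L + R_m * I_+)
    # because dV/dt < 0 whenever V lies above the (decaying) drive level
    bound = params.E_L + params.R_m * (max(state.I, 0.0) + max(I_e, 0.0))
    if max(state.V, bound) < params.theta:
        return None
    n_sub = 64
    f_prev = state.V - params.theta  # < 0
    t_prev = 0.0
    bracket = None
    for j in range(1, n_sub + 1):
        t = h * j / n_sub
        f = _closed_form_V(state.V, state.I, t, params, I_e) - params.theta
        if f >= 0.0:
            bracket = (t_prev, t)
            break
        t_prev, f_prev = t, f
    if bracket is None:
        return None
    lo, hi = bracket
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _closed_form_V(state.V, state.I, mid, params, I_e) >= params.theta:
            hi = mid
        else:
            lo = mid
    return hi


def _as_counts(input_counts: Sequence[int] | np.ndarray, n_steps: int) -> np.ndarray:
    counts = np.asarray(input_counts)
    if counts.ndim != 1:
        raise InvalidParameterError("input counts must be one-dimensional")
    if len(counts) < n_steps:
        raise InvalidParameterError(
            f"need {n_steps} per-step counts, got {len(counts)}")
    return counts[:n_steps]


def run_single_neuron(params: NeuronParameters, backend: str,
                      input_counts: Sequence[int] | np.ndarray | None,
                      h: float, duration: float, seed: int | None = None,
                      weight: float = 0.0878, rate: float | None = None,
                      I_e: float = 0.0, V0: float | None = None,
                      decay_then_add: bool = False,
                      weight_frac_bits: int = 16,
                      crossing_tol: float = 1e-10,
                      ) -> tuple[list[SpikeEvent], VoltageTrace]:
    """Simulate one neuron for ``duration`` ms at step ``h`` ms.

    Parameters
    ----------
    backend : str
        One of ``exact-grid``, ``exponential-grid``, ``exponential-fixed``
        or ``precise``.
    input_counts : array of int, optional
        Per-step counts of grid-constrained input spikes. If ``None``,
        ``rate`` (spikes/s) and ``seed`` are used to draw Poisson counts.
    weight : float
        Synaptic weight J (nA) of each input spike; multiple spikes per
        step are aggregated as ``count * J`` before delivery.
    I_e : float
        Constant current drive (nA) entering the membrane equation.
    weight_frac_bits : int
        Fractional bits of the 16-bit weight format used by the
        ``exponential-fixed`` backend (default: all 16, the single-neuron
        test format).

    Returns
    -------
    (spikes, trace)
        Spike events and the voltage trace recorded at every step.
    """
    if backend not in BACKENDS:
        raise ConfigurationError(
            f"unknown backend {backend!r}; expected one of {BACKENDS}")
    if h <= 0 or duration < 0:
        raise InvalidParameterError("h must be positive and duration non-negative")
    n_steps = int(round(duration / h))
    if input_counts is None:
        from spikebench.workbench.synth import generate_grid_poisson
        if rate is None:
            counts = np.zeros(n_steps, dtype=np.int64)
        else:
            counts = generate_grid_poisson(rate, h, duration, seed)
    else:
        counts = _as_counts(input_counts, n_steps)

    V_init = params.E_L if V0 is None else V0
    times = (np.arange(n_steps) + 1) * h
    values = np.empty(n_steps)
    spikes: list[SpikeEvent] = []

    if backend == "exact-grid":
        _run_exact_grid(params, counts, h, weight, I_e, V_init, values, spikes)
    elif backend == "exponential-grid":
        _run_exponential_grid(params, counts, h, weight, I_e, V_init, values,
                              spikes, decay_then_add)
    elif backend == "exponential-fixed":
        _run_exponential_fixed(params, counts, h, weight, I_e, V_init, values,
                               spikes, decay_then_add, weight_frac_bits)
    else:
        _run_precise(params, counts, h, weight, I_e, V_init, values, spikes,
                     crossing_tol)
    return spikes, VoltageTrace(times=times, values=values)


def _run_exact_grid(params, counts, h, weight, I_e, V_init, values, spikes):
    prop = make_exact_propagator(params, h)
    alpha, beta, P21 = prop.alpha, prop.beta, prop.P21
    E_L, theta, V_r, R_m = params.E_L, params.theta, params.V_r, params.R_m
    dc = R_m * I_e * (1.0 - alpha)
    ref_steps = _refractory_steps(params, h)
    V, I, ref = V_init, 0.0, 0
    for k in range(len(counts)):
        w = counts[k] * weight
        if ref > 0:
            I = beta * I + w
            ref -= 1
            V = V_r
        else:
            V_new = E_L + (V - E_L) * alpha + I * P21 + dc
            I = beta * I + w
            if V_new >= theta:
                spikes.append(SpikeEvent(0, (k + 1) * h))
                V = V_r
                ref = ref_steps
            else:
                V = V_new
        values[k] = V


def _run_exponential_grid(params, counts, h, weight, I_e, V_init, values,
                          spikes, decay_then_add):
    alpha = math.exp(-h / params.tau_m)
    beta = math.exp(-h / params.tau_s)
    q = beta if decay_then_add else params.tau_s * (1.0 - beta) / h
    E_L, theta, V_r, R_m = params.E_L, params.theta, params.V_r, params.R_m
    g = R_m * (1.0 - alpha)
    ref_steps = _refractory_steps(params, h)
    V, I, ref = V_init, 0.0, 0
    for k in range(len(counts)):
        I = beta * I + q * (counts[k] * weight)
        if ref > 0:
            ref -= 1
            V = V_r
        else:
            V_new = E_L + (V - E_L) * alpha + g * (I + I_e)
            if V_new >= theta:
                spikes.append(SpikeEvent(0, (k + 1) * h))
                V = V_r
                ref = ref_steps
            else:
                V = V_new
        values[k] = V


def _run_exponential_fixed(params, counts, h, weight, I_e, V_init, values,
                           spikes, decay_then_add, weight_frac_bits):
    # Emulated s16.15 state arithmetic with the weight quantized in the
    # 16-bit format; mirrors the exponential-grid recurrence.
    from spikebench.fixed_point import S16_15, quantize_truncate

    fx = S16_15
    alpha = math.exp(-h / params.tau_m)
    beta = math.exp(-h / params.tau_s)
    q = beta if decay_then_add else params.tau_s * (1.0 - beta) / h
    w_q = quantize_truncate(weight, weight_frac_bits)

    alpha_fx = fx.from_float(alpha)
    beta_fx = fx.from_float(beta)
    q_fx = fx.from_float(q)
    g_fx = fx.from_float(params.R_m * (1.0 - alpha))
    E_L_fx = fx.from_float(params.E_L)
    theta_fx = fx.from_float(params.theta)
    V_r_fx = fx.from_float(params.V_r)
    I_e_fx = fx.from_float(I_e)
    w_fx = fx.from_float(w_q)

    ref_steps = _refractory_steps(params, h)
    V, I, ref = fx.from_float(V_init), 0, 0
    for k in range(len(counts)):
        w_total = fx.sat(int(counts[k]) * w_fx)
        I = fx.sat(fx.mul(beta_fx, I) + fx.mul(q_fx, w_total))
        if ref > 0:
            ref -= 1
            V = V_r_fx
        else:
            V_new = fx.sat(E_L_fx + fx.mul(fx.sat(V - E_L_fx), alpha_fx)
                           + fx.mul(g_fx, fx.sat(I + I_e_fx)))
            if V_new >= theta_fx:
                spikes.append(SpikeEvent(0, (k + 1) * h))
                V = V_r_fx
                ref = ref_steps
            else:
                V = V_new
        values[k] = fx.to_float(V)


def _run_precise(params, counts, h, weight, I_e, V_init, values, spikes,
                 tol):
    tau_s, tau_m = params.tau_s, params.tau_m
    theta, V_r = params.theta, params.V_r
    V, I = V_init, 0.0
    refr_end = -1.0
    for k in range(len(counts)):
        t0 = k * h
        I += counts[k] * weight  # grid-constrained delivery at the grid point
        s = 0.0
        while s < h - 1e-12:
            t_abs = t0 + s
            if refr_end > t_abs + 1e-12:
                span = min(refr_end - t_abs, h - s)
                I *= math.exp(-span / tau_s)
                V = V_r
                s += span
                continue
            dt = h - s
            tc = find_precise_crossing(NeuronState(V=V, I=I), params, dt, tol,
                                       I_e)
            if tc is None:
                V = _closed_form_V(V, I, dt, params, I_e)
                I *= math.exp(-dt / tau_s)
                s = h
            else:
                spikes.append(SpikeEvent(0, t_abs + tc))
                I *= math.exp(-tc / tau_s)
                V = V_r
                refr_end = t_abs + tc + params.tau_ref
                s += tc
                if tc == 0.0:
                    # V was exactly at threshold at the segment start; the
                    # reset guarantees progress on the next iteration.
                    continue
        values[k] = V if refr_end <= t0 + h else V_r
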