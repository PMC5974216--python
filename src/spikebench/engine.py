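"""Grid-based network propagation with 16-slot delay ring buffers.

The engine iterates a fixed, documented substep order so that runs are
bit-reproducible given ``(network, config, seed)``:

1. deliver the due ring-buffer slot to every neuron,
2. per-neuron backend step (propagate/decay, add delivered input,
   threshold test),
3. collect spikes,
4. route each spike into the target ring buffers at slot
   ``(current + delay)``; delays beyond the 16-slot span go through a
   delay-extension stage (multiples of the ring-buffer span handled by a
   separate scheduler, remainder delivered through the ring buffer),
5. advance the external drive.

Synaptic contributions accumulate in separate unsigned excitatory and
inhibitory buffers (mirroring the 2-bit synapse-type field of the packed
synapse word); signs are applied at delivery. On the fixed-point backend
the buffers are 16-bit accumulators in the population's weight format;
additions saturate and saturations are counted, never raised.

The module also houses the CPU-cycle cost model relating biological time
to wall-clock time on the emulated hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from spikebench.errors import (ConfigurationError, InvalidParameterError,
                               UnsupportedDelayError)
from spikebench.fixed_point import (BitAllocation, RingBufferScalingInputs,
                                    allocate_bits, ring_buffer_max)
from spikebench.lif_core import SpikeEvent
from spikebench.network_model import NetworkInstance, derive_rng

__all__ = [
    "RING_SLOTS",
    "MAX_EXTENSION_MULTIPLES",
    "EngineConfig",
    "DelaySplit",
    "split_delay",
    "encode_synapse_word",
    "decode_synapse_word",
    "RingBufferState",
    "OverflowCounter",
    "CostModelSpec",
    "cycles_per_ms",
    "slowdown_factor",
    "packet_spacing",
    "SpikeRecord",
    "NetworkSimulation",
    "run",
]

#: Number of delay slots in each synaptic-input ring buffer.
RING_SLOTS = 16
#: Maximum number of ring-buffer-span multiples one extension stage holds.
MAX_EXTENSION_MULTIPLES = 8

NETWORK_BACKENDS = ("exact-grid", "exponential-grid", "exponential-fixed")


@dataclass(frozen=True)
class EngineConfig:
    """Run configuration of the network engine.

    ``h_b`` is the biological step (ms); ``h_w`` the wall-clock step used
    only by the cost model. ``transient_discard`` marks the stretch the
    statistics suite drops; the engine records everything.
    """

    backend: str = "exact-grid"
    h_b: float = 0.1
    h_w: float = 0.1
    duration: float = 10000.0
    transient_discard: float = 1000.0
    master_seed: int = 0
    sigma: float = 5.0                 # ring-buffer headroom, in SDs
    expected_rate: float = 30.0        # spikes/s assumed for weight scaling
    record_V_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.h_b <= 0:
            raise InvalidParameterError("h_b must be positive")
        if self.backend not in NETWORK_BACKENDS:
            raise ConfigurationError(
                f"unknown backend {self.backend!r}; expected one of "
                f"{NETWORK_BACKENDS}")


@dataclass(frozen=True)
class DelaySplit:
    """Decomposition of a delay into an extension part (multiple of the
    16-slot span) and a deliverable remainder in ``(0, 16*h_b]``."""

    delay_total: float
    delay_extended: float
    delay_remaining: float


def split_delay(delay_total: float, h_b: float) -> DelaySplit:
    """Split ``delay_total`` into extension multiples of ``16*h_b`` plus a
    remainder deliverable by the ring buffer.

    Delays within the ring-buffer span pass through unchanged. For longer
    delays the extension takes ``ceil(delay/(16*h_b)) - 1`` multiples, so
    exact multiples keep the maximal remainder ``16*h_b`` (a zero
    remainder would be undeliverable). One extension stage supports at
    most 8 multiples; totals above ``(8+1)*16*h_b`` raise
    :class:`UnsupportedDelayError`.
    """
    if h_b <= 0:
        raise InvalidParameterError("h_b must be positive")
    span = RING_SLOTS * h_b
    max_total = (MAX_EXTENSION_MULTIPLES + 1) * span
    if delay_total < h_b - 1e-9:
        raise InvalidParameterError(
            f"delay {delay_total} ms is below the time step {h_b} ms")
    if delay_total > max_total + 1e-9:
        raise UnsupportedDelayError(
            f"delay {delay_total} ms exceeds the supported maximum "
            f"{max_total} ms (one extension stage plus the ring buffer)")
    if delay_total <= span + 1e-9:
        return DelaySplit(delay_total, 0.0, delay_total)
    multiples = math.ceil(delay_total / span - 1e-9) - 1
    extended = multiples * span
    return DelaySplit(delay_total, extended, delay_total - extended)


def encode_synapse_word(target: int, delay_slots: int, synapse_type: int,
                        weight_bits: int) -> int:
    """Pack a synapse into a 32-bit word.

    Layout (most significant first): 16 weight bits, 2 reserved +
    2 synapse-type bits, 4 delay bits, 8 target-index bits.
    """
    if not 0 <= target <= 0xFF:
        raise InvalidParameterError("target index needs 8 bits (0..255)")
    if not 0 <= delay_slots <= 0xF:
        raise InvalidParameterError("delay needs 4 bits (0..15)")
    if not 0 <= synapse_type <= 0x3:
        raise InvalidParameterError("synapse type needs 2 bits (0..3)")
    if not 0 <= weight_bits <= 0xFFFF:
        raise InvalidParameterError("weight needs 16 bits (0..65535)")
    return (weight_bits << 16) | (synapse_type << 12) | (delay_slots << 8) | target


def decode_synapse_word(word: int) -> tuple[int, int, int, int]:
    """Inverse of :func:`encode_synapse_word`; returns
    ``(target, delay_slots, synapse_type, weight_bits)``."""
    if not 0 <= word <= 0xFFFFFFFF:
        raise InvalidParameterError("synapse word must fit in 32 bits")
    return (word & 0xFF, (word >> 8) & 0xF, (word >> 12) & 0x3,
            (word >> 16) & 0xFFFF)


@dataclass
class OverflowCounter:
    """Counts saturating ring-buffer additions; reported at end of run."""

    count: int = 0

    def add(self, k: int = 1) -> None:
        self.count += int(k)


class RingBufferState:
    """Per-neuron, per-synapse-type 16-slot accumulation buffers.

    ``quantized=True`` stores raw integers of an unsigned 16-bit weight
    format and saturates (counting overflows); otherwise plain float
    accumulators are used. Excitatory and inhibitory contributions live
    in separate unsigned buffers; signs are applied at delivery.
    """

    def __init__(self, n_neurons: int, quantized: bool = False,
                 overflow: Optional[OverflowCounter] = None):
        self.n_neurons = n_neurons
        self.quantized = quantized
        self.overflow = overflow if overflow is not None else OverflowCounter()
        dtype = np.int64 if quantized else np.float64
        self.exc = np.zeros((RING_SLOTS, n_neurons), dtype=dtype)
        self.inh = np.zeros((RING_SLOTS, n_neurons), dtype=dtype)
        # conservation ledger (raw units if quantized)
        self.routed = 0.0
        self.delivered = 0.0
        self.saturated_excess = 0.0

    _RAW_MAX = 0xFFFF

    def accumulate(self, slot: int, neuron: int, weight, inhibitory: bool = False):
        """Scalar saturating add of ``weight`` (raw int if quantized,
        nA magnitude otherwise) into one slot."""
        if not 0 <= slot < RING_SLOTS:
            raise InvalidParameterError("slot must lie in 0..15")
        buf = self.inh if inhibitory else self.exc
        if self.quantized:
            s = int(buf[slot, neuron]) + int(weight)
            clipped = min(s, self._RAW_MAX)
            if clipped != s:
                self.overflow.add()
                self.saturated_excess += s - clipped
            buf[slot, neuron] = clipped
            self.routed += int(weight)
        else:
            buf[slot, neuron] += weight
            self.routed += weight

    def accumulate_many(self, slot_idx: np.ndarray, neuron_idx: np.ndarray,
                        weights: np.ndarray, inhibitory: np.ndarray) -> None:
        """Vectorized accumulation of many contributions (saturating per
        addition order is approximated by saturating after the grouped
        add; excess and overflow counting remain exact per slot)."""
        for buf, mask in ((self.exc, ~inhibitory), (self.inh, inhibitory)):
            if not mask.any():
                continue
            sl, nr, w = slot_idx[mask], neuron_idx[mask], weights[mask]
            if self.quantized:
                np.add.at(buf, (sl, nr), w)
                over = buf[buf > self._RAW_MAX]
                if over.size:
                    # every slot pushed past the max counts as >= 1 overflow
                    self.overflow.add(over.size)
                    self.saturated_excess += float((over - self._RAW_MAX).sum())
                    np.clip(buf, 0, self._RAW_MAX, out=buf)
                self.routed += float(w.sum())
            else:
                np.add.at(buf, (sl, nr), w)
                self.routed += float(w.sum())

    def deliver(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        """Return and clear the due (excitatory, inhibitory) slot rows."""
        slot = step % RING_SLOTS
        exc = self.exc[slot].copy()
        inh = self.inh[slot].copy()
        self.exc[slot] = 0
        self.inh[slot] = 0
        self.delivered += float(exc.sum()) + float(inh.sum())
        return exc, inh


# ---------------------------------------------------------------------------
# Cost model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostModelSpec:
    """CPU-cycle budget of one core at the hardware design point: a 1 ms
    step splits as 10% neural update / 90% synapse processing for 1,000
    synapses per neuron on a 200 MHz clock."""

    neural_cycles_per_ms_at_spec: float = 20_000.0
    synaptic_cycles_per_ms_at_spec: float = 180_000.0
    design_synapses_per_neuron: float = 1_000.0
    clock_cycles_per_ms: float = 200_000.0
    spread_fraction: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.neural_cycles_per_ms_at_spec,
                  self.synaptic_cycles_per_ms_at_spec,
                  self.design_synapses_per_neuron,
                  self.clock_cycles_per_ms, self.spread_fraction):
            if v <= 0:
                raise InvalidParameterError("cost model values must be positive")


def cycles_per_ms(spec: CostModelSpec, h_b: float,
                  synapses_per_neuron: float) -> float:
    """CPU cycles needed per ms of biological time.

    The neural term scales inversely with the step size (more updates per
    ms); the synaptic term scales with the synapse count but not with the
    step size (the number of synaptic events per ms is step-independent).
    """
    if h_b <= 0 or synapses_per_neuron < 0:
        raise InvalidParameterError("h_b must be positive, synapse count >= 0")
    neural = spec.neural_cycles_per_ms_at_spec * (1.0 / h_b)
    synaptic = (spec.synaptic_cycles_per_ms_at_spec
                * synapses_per_neuron / spec.design_synapses_per_neuron)
    return neural + synaptic


def slowdown_factor(required_cycles_per_ms: float,
                    clock_cycles_per_ms: float) -> int:
    """Theoretical slowdown vs. real time: ``ceil(required/clock)``,
    at least 1. Practical overheads are reported, not computed."""
    if clock_cycles_per_ms <= 0:
        raise InvalidParameterError("clock must be positive")
    return max(1, math.ceil(required_cycles_per_ms / clock_cycles_per_ms))


def packet_spacing(n_packets: int, cycles_per_step: float,
                   spread_fraction: float = 1.0) -> int:
    """Clock cycles between packet sends when ``n_packets`` are spread
    over ``spread_fraction`` of a ``cycles_per_step``-cycle time step."""
    if n_packets < 1:
        raise InvalidParameterError("n_packets must be >= 1")
    return int(math.floor(cycles_per_step * spread_fraction / n_packets))


# ---------------------------------------------------------------------------
# Network propagation
# ---------------------------------------------------------------------------

@dataclass
class SpikeRecord:
    """All spikes of a run: parallel arrays of global neuron ids and
    grid-aligned spike times (ms), time-sorted."""

    neuron_ids: np.ndarray
    times: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    def for_neurons(self, lo: int, hi: int) -> "SpikeRecord":
        m = (self.neuron_ids >= lo) & (self.neuron_ids < hi)
        return SpikeRecord(self.neuron_ids[m], self.times[m])

    def events(self) -> list[SpikeEvent]:
        return [SpikeEvent(int(i), float(t))
                for i, t in zip(self.neuron_ids, self.times)]


def _mul15(a: np.ndarray, b) -> np.ndarray:
    """Vectorized s16.15 multiply: 64-bit intermediate, floor to 15
    fractional bits (arithmetic right shift)."""
    return (a * b) >> 15


_S16_15_MAX = 2 ** 31 - 1
_S16_15_MIN = -(2 ** 31)


def _sat15(a: np.ndarray) -> np.ndarray:
    return np.clip(a, _S16_15_MIN, _S16_15_MAX)


def _fx15(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) * 2 ** 15 + 0.5).astype(np.int64)


class NetworkSimulation:
    """Compiled, steppable network state for one backend.

    Construction flattens the instantiated network into CSR-style
    per-source synapse arrays, splits long delays through the extension
    stage, performs the ring-buffer weight scaling for the fixed-point
    backend, and seeds the drive substream. :meth:`step` advances one
    grid step in the documented substep order; :meth:`run_all` iterates
    and collects the spike record.
    """

    def __init__(self, network: NetworkInstance, config: EngineConfig):
        if abs(network.h - config.h_b) > 1e-12:
            raise ConfigurationError(
                "network was instantiated on a different grid than config.h_b")
        self.network = network
        self.config = config
        self.h = config.h_b
        self.n_steps = int(round(config.duration / self.h))
        self.step_index = 0
        N = network.total_neurons
        self.N = N

        self._compile_neurons()
        self._compile_synapses()
        self._compile_drive()

        self.fixed = config.backend == "exponential-fixed"
        self.overflow = OverflowCounter()
        self.buffers = RingBufferState(N, quantized=self.fixed,
                                       overflow=self.overflow)
        # extension stage: circular schedule of re-emitted contributions
        self._sched_len = MAX_EXTENSION_MULTIPLES * RING_SLOTS + 1
        self._sched: list[list] = [[] for _ in range(self._sched_len)]

        self._spike_ids: list[np.ndarray] = []
        self._spike_times: list[float] = []
        self._rec_ids = np.asarray(config.record_V_ids, dtype=np.int64)
        self._rec_V: list[np.ndarray] = []

        if self.fixed:
            self.weight_scaling_report = self.weight_scaling()
            self._quantize_weights()
            self._prepare_fixed()
            self._V_raw = _fx15(self.V)
            self._I_raw = np.zeros(N, dtype=np.int64)
        else:
            self.weight_scaling_report = None
            self.syn_w_raw = None

    # -- compilation ---------------------------------------------------
    def _compile_neurons(self) -> None:
        net, h = self.network, self.h
        N = net.total_neurons
        self.alpha = np.empty(N)
        self.beta = np.empty(N)
        self.P21 = np.empty(N)
        self.q = np.empty(N)
        self.g = np.empty(N)       # R_m * (1 - alpha)
        self.E_L = np.empty(N)
        self.theta = np.empty(N)
        self.V_r = np.empty(N)
        self.ref_steps = np.empty(N, dtype=np.int64)
        self.I_e = np.zeros(N)
        self.pop_of = np.empty(N, dtype=np.int64)
        for pi, pop in enumerate(net.spec.populations):
            sl = net.population_slice(pop.name)
            p = pop.params
            a = math.exp(-h / p.tau_m)
            b = math.exp(-h / p.tau_s)
            if p.tau_s == p.tau_m:
                p21 = p.R_m * (h / p.tau_m) * a
            else:
                p21 = p.R_m * p.tau_s * (b - a) / (p.tau_s - p.tau_m)
            self.alpha[sl] = a
            self.beta[sl] = b
            self.P21[sl] = p21
            self.q[sl] = p.tau_s * (1.0 - b) / h
            self.g[sl] = p.R_m * (1.0 - a)
            self.E_L[sl] = p.E_L
            self.theta[sl] = p.theta
            self.V_r[sl] = p.V_r
            self.ref_steps[sl] = int(round(p.tau_ref / h))
            self.pop_of[sl] = pi
            if pop.drive_mode == "dc":
                self.I_e[sl] = pop.I_DC
        self.V = net.V_init.copy()
        self.I = np.zeros(N)
        self.ref = np.zeros(N, dtype=np.int64)

    def _compile_synapses(self) -> None:
        net, h = self.network, self.h
        src = np.concatenate([p.sources for p in net.projections]) \
            if net.projections else np.empty(0, dtype=np.int64)
        tgt = np.concatenate([p.targets for p in net.projections]) \
            if net.projections else np.empty(0, dtype=np.int64)
        w = np.concatenate([p.weights for p in net.projections]) \
            if net.projections else np.empty(0)
        d = np.concatenate([p.delays for p in net.projections]) \
            if net.projections else np.empty(0)
        d_steps = np.round(d / h).astype(np.int64)
        max_steps = (MAX_EXTENSION_MULTIPLES + 1) * RING_SLOTS
        if len(d_steps) and (d_steps.max() > max_steps):
            bad = d[d_steps > max_steps].max()
            raise UnsupportedDelayError(
                f"delay {bad} ms exceeds the supported maximum "
                f"{max_steps * h} ms")
        # delay split in steps: extension multiples of 16 plus remainder 1..16
        ext = np.where(d_steps <= RING_SLOTS, 0,
                       (np.ceil(d_steps / RING_SLOTS).astype(np.int64) - 1)
                       * RING_SLOTS)
        rem = d_steps - ext
        order = np.argsort(src, kind="stable")
        self.syn_src = src[order]
        self.syn_tgt = tgt[order]
        self.syn_w = w[order]
        self.syn_ext = ext[order]
        self.syn_rem = rem[order]
        self.syn_inh = self.syn_w < 0
        counts = np.bincount(self.syn_src, minlength=self.N) \
            if len(src) else np.zeros(self.N, dtype=np.int64)
        self.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    def _compile_drive(self) -> None:
        net = self.network
        N = net.total_neurons
        self.drive_lam = np.zeros(N)
        self.drive_J = np.zeros(N)
        any_poisson = False
        for pop in net.spec.populations:
            if pop.drive_mode == "poisson":
                sl = net.population_slice(pop.name)
                self.drive_lam[sl] = pop.nu_ext * self.h / 1000.0
                self.drive_J[sl] = pop.J_ext
                any_poisson = True
        self.any_poisson = any_poisson
        self.drive_rng = derive_rng(self.config.master_seed, "drive", "all")

    # -- fixed-point weight scaling ------------------------------------
    def weight_scaling(self) -> dict:
        """Per-population ring-buffer scaling and bit allocation
        (fixed-point backend); recorded in the run manifest."""
        net, h = self.network, self.h
        report = {}
        self._frac_bits = np.zeros(self.N, dtype=np.int64)
        for pop in net.spec.populations:
            sl = net.population_slice(pop.name)
            lo, hi = sl.start, sl.stop
            m = (self.syn_tgt >= lo) & (self.syn_tgt < hi)
            wmag = np.abs(self.syn_w[m])
            n_syn = int(m.sum())
            n_neurons = hi - lo
            # expected arrivals per neuron per step: recurrent synapses at
            # the assumed network rate plus the known drive rate
            n_exp = (n_syn / n_neurons) * self.config.expected_rate * h / 1000.0
            if pop.drive_mode == "poisson":
                n_exp += pop.nu_ext * h / 1000.0
                wmag = np.concatenate([wmag, [abs(pop.J_ext)]])
            if n_exp <= 0 or wmag.size == 0:
                alloc = BitAllocation(integer_bits=0, frac_bits=16)
                scaling = None
            else:
                scaling = ring_buffer_max(RingBufferScalingInputs(
                    n=n_exp, w_mean=float(wmag.mean()),
                    w_var=float(wmag.var()), sigma=self.config.sigma))
                alloc = allocate_bits(scaling.M)
            self._frac_bits[sl] = alloc.frac_bits
            report[pop.name] = {
                "bit_allocation": alloc.to_dict(),
                "scaling": scaling.to_dict() if scaling else None,
                "expected_spikes_per_step": n_exp,
            }
        return report

    def _quantize_weights(self) -> None:
        f = self._frac_bits[self.syn_tgt]
        self.syn_w_raw = np.floor(np.abs(self.syn_w) * (2.0 ** f)).astype(np.int64)
        self.drive_J_raw = np.floor(self.drive_J * (2.0 ** self._frac_bits)
                                    ).astype(np.int64)

    # -- stepping ------------------------------------------------------
    def _route(self, ids: np.ndarray) -> None:
        """Route spikes of ``ids`` (and due extension re-emissions) into
        the ring buffers."""
        t = self.step_index
        segs = [np.arange(self.indptr[i], self.indptr[i + 1]) for i in ids
                if self.indptr[i + 1] > self.indptr[i]]
        if segs:
            idx = np.concatenate(segs)
            direct = self.syn_ext[idx] == 0
            di = idx[direct]
            if di.size:
                slots = (t + self.syn_rem[di]) % RING_SLOTS
                wvals = (self.syn_w_raw[di] if self.fixed
                         else np.abs(self.syn_w[di]))
                self.buffers.accumulate_many(slots, self.syn_tgt[di], wvals,
                                             self.syn_inh[di])
            ei = idx[~direct]
            if ei.size:
                for ext in np.unique(self.syn_ext[ei]):
                    sub = ei[self.syn_ext[ei] == ext]
                    due = (t + int(ext)) % self._sched_len
                    self._sched[due].append(sub)

    def _deliver_extension(self) -> None:
        t = self.step_index
        due = self._sched[t % self._sched_len]
        if due:
            idx = np.concatenate(due)
            self._sched[t % self._sched_len] = []
            slots = (t + self.syn_rem[idx]) % RING_SLOTS
            wvals = (self.syn_w_raw[idx] if self.fixed
                     else np.abs(self.syn_w[idx]))
            self.buffers.accumulate_many(slots, self.syn_tgt[idx], wvals,
                                         self.syn_inh[idx])

    def _neuron_step(self, w_in: np.ndarray) -> np.ndarray:
        """Advance every neuron one step; returns the boolean spike mask."""
        backend = self.config.backend
        refractory = self.ref > 0
        if backend == "exact-grid":
            V_new = (self.E_L + (self.V - self.E_L) * self.alpha
                     + self.I * self.P21 + self.g * self.I_e)
            self.I = self.beta * self.I + w_in
        else:  # exponential-grid
            self.I = self.beta * self.I + self.q * w_in
            V_new = (self.E_L + (self.V - self.E_L) * self.alpha
                     + self.g * (self.I + self.I_e))
        spiking = (~refractory) & (V_new >= self.theta)
        self.V = np.where(refractory | spiking, self.V_r, V_new)
        self.ref[refractory] -= 1
        self.ref[spiking] = self.ref_steps[spiking]
        return spiking

    def _neuron_step_fixed(self, w_in_raw: np.ndarray) -> np.ndarray:
        refractory = self.ref > 0
        # delivered ring value (weight format) -> s16.15
        shift = 15 - self._frac_bits
        w15 = np.where(shift >= 0, w_in_raw << np.maximum(shift, 0),
                       w_in_raw >> np.maximum(-shift, 0))
        self._I_raw = _sat15(_mul15(self._beta_raw, self._I_raw)
                             + _mul15(self._q_raw, w15))
        V_new = _sat15(self._EL_raw
                       + _mul15(self._V_raw - self._EL_raw, self._alpha_raw)
                       + _mul15(self._g_raw, _sat15(self._I_raw + self._Ie_raw)))
        spiking = (~refractory) & (V_new >= self._theta_raw)
        self._V_raw = np.where(spiking | refractory, self._Vr_raw, V_new)
        self.ref[refractory] -= 1
        self.ref[spiking] = self.ref_steps[spiking]
        self.V = self._V_raw * 2.0 ** -15
        return spiking

    def _prepare_fixed(self) -> None:
        self._alpha_raw = _fx15(self.alpha)
        self._beta_raw = _fx15(self.beta)
        self._q_raw = _fx15(self.q)
        self._g_raw = _fx15(self.g)
        self._EL_raw = _fx15(self.E_L)
        self._theta_raw = _fx15(self.theta)
        self._Vr_raw = _fx15(self.V_r)
        self._Ie_raw = _fx15(self.I_e)

    def step(self) -> np.ndarray:
        """Advance one grid step; returns the ids of neurons that spiked."""
        t = self.step_index
        exc, inh = self.buffers.deliver(t)
        if self.fixed:
            w_in = exc - inh  # raw, signed at delivery
            drive_raw = (self.drive_rng.poisson(self.drive_lam)
                         * self.drive_J_raw if self.any_poisson else 0)
            spiking = self._neuron_step_fixed(w_in + drive_raw)
        else:
            w_in = exc - inh
            if self.any_poisson:
                w_in = w_in + self.drive_rng.poisson(self.drive_lam) * self.drive_J
            spiking = self._neuron_step(w_in)
        ids = np.nonzero(spiking)[0]
        if ids.size:
            self._spike_ids.append(ids)
            self._spike_times.append((t + 1) * self.h)
            self._route(ids)
        self._deliver_extension()
        if self._rec_ids.size:
            self._rec_V.append(self.V[self._rec_ids].copy())
        self.step_index += 1
        return ids

    def run_all(self) -> SpikeRecord:
        while self.step_index < self.n_steps:
            self.step()
        if self._spike_ids:
            ids = np.concatenate(self._spike_ids)
            times = np.concatenate([
                np.full(len(a), tt) for a, tt in zip(self._spike_ids,
                                                     self._spike_times)])
        else:
            ids = np.empty(0, dtype=np.int64)
            times = np.empty(0)
        return SpikeRecord(neuron_ids=ids, times=times)

    def recorded_voltages(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values[steps, ids]) for the configured record ids."""
        times = (np.arange(len(self._rec_V)) + 1) * self.h
        values = (np.vstack(self._rec_V) if self._rec_V
                  else np.empty((0, len(self._rec_ids))))
        return times, values


def run(network: NetworkInstance, config: EngineConfig,
        cost_spec: CostModelSpec | None = None):
    """Simulate ``network`` under ``config``.

    Returns ``(record, sim, manifest)``: the spike record, the simulation
    object (for recorded voltages) and a manifest dict with seeds,
    overflow count, weight scaling and the cost-model report.
    """
    sim = NetworkSimulation(network, config)
    record = sim.run_all()
    if cost_spec is None:
        cost_spec = CostModelSpec()
    syn_per_neuron = (network.total_synapses / network.total_neurons
                      if network.total_neurons else 0.0)
    needed = cycles_per_ms(cost_spec, config.h_b, syn_per_neuron)
    manifest = {
        "backend": config.backend,
        "h_b_ms": config.h_b,
        "h_w_ms": config.h_w,
        "duration_ms": config.duration,
        "transient_discard_ms": config.transient_discard,
        "master_seed": config.master_seed,
        "n_neurons": network.total_neurons,
        "n_synapses": network.total_synapses,
        "n_spikes": len(record),
        "overflow_count": sim.overflow.count,
        "weight_scaling": sim.weight_scaling_report,
        "cost_model": {
            "cycles_per_ms": needed,
            "slowdown_factor_theoretical": slowdown_factor(
                needed, cost_spec.clock_cycles_per_ms),
            "slowdown_factor_practical": config.h_w / config.h_b,
        },
    }
    return record, sim, manifest
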