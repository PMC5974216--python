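"""Fixed- and reduced-precision numeric emulation.

Provides the s16.15 state arithmetic used by the hardware-emulation
backend, 16-bit weight quantization with a dynamic binary point, the
closed-form ring-buffer headroom bound used to place that binary point,
and IEEE-style rounding to reduced float precisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from spikebench.errors import InvalidParameterError

__all__ = [
    "FixedPointFormat",
    "RingBufferScalingInputs",
    "ScalingResult",
    "BitAllocation",
    "S16_15",
    "quantize_truncate",
    "float_round",
    "ring_buffer_max",
    "allocate_bits",
]


@dataclass(frozen=True)
class FixedPointFormat:
    """A binary fixed-point format with ``total_bits`` bits, ``frac_bits``
    of which are fractional.

    The canonical instances are the signed s16.15 state format
    ``(32, 15, signed)`` and the unsigned 16-bit weight formats
    ``(16, f, unsigned)``.
    """

    total_bits: int
    frac_bits: int
    signed: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.frac_bits <= self.total_bits <= 32):
            raise InvalidParameterError(
                "need 0 <= frac_bits <= total_bits <= 32")

    @property
    def resolution(self) -> float:
        """Value of one least-significant bit, ``2**-frac_bits``."""
        return 2.0 ** -self.frac_bits

    @property
    def max_value(self) -> float:
        """Largest representable value."""
        if self.signed:
            return (2 ** (self.total_bits - 1) - 1) * self.resolution
        return (2 ** self.total_bits - 1) * self.resolution

    @property
    def min_value(self) -> float:
        if self.signed:
            return -(2 ** (self.total_bits - 1)) * self.resolution
        return 0.0

    # --- raw integer representation -----------------------------------
    @property
    def _raw_max(self) -> int:
        return 2 ** (self.total_bits - 1) - 1 if self.signed else 2 ** self.total_bits - 1

    @property
    def _raw_min(self) -> int:
        return -(2 ** (self.total_bits - 1)) if self.signed else 0

    def from_float(self, x: float) -> int:
        """Nearest representable raw value (round half away from zero),
        saturating at the format bounds."""
        raw = int(math.floor(x * 2 ** self.frac_bits + 0.5))
        return self.sat(raw)

    def to_float(self, raw: int) -> float:
        return raw * self.resolution

    def sat(self, raw: int) -> int:
        """Clamp a raw value to the representable range."""
        if raw > self._raw_max:
            return self._raw_max
        if raw < self._raw_min:
            return self._raw_min
        return raw

    def add_sat(self, a: int, b: int) -> tuple[int, bool]:
        """Saturating addition; returns ``(sum, overflowed)``."""
        s = a + b
        c = self.sat(s)
        return c, c != s

    def mul(self, a: int, b: int) -> int:
        """Multiplication with a 64-bit intermediate truncated (floor)
        back to ``frac_bits`` fractional bits, saturated to the format."""
        return self.sat((a * b) >> self.frac_bits)


#: The signed s16.15 state format (32 bits, 15 fractional).
S16_15 = FixedPointFormat(total_bits=32, frac_bits=15, signed=True)


@dataclass(frozen=True)
class RingBufferScalingInputs:
    """Inputs of the ring-buffer headroom bound.

    ``n`` is the expected number of incoming spikes per step, ``w_mean``
    and ``w_var`` the mean (nA) and variance (nA²) of the incoming
    weights, and ``sigma`` the number of standard deviations of safety
    overhead above the mean.
    """

    n: float
    w_mean: float
    w_var: float
    sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidParameterError("n must be non-negative")
        if self.w_var < 0:
            raise InvalidParameterError("w_var must be non-negative")
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")


@dataclass(frozen=True)
class ScalingResult:
    """Output of :func:`ring_buffer_max`.

    ``M`` is the expected maximum summed weight (nA) in any delay
    ring-buffer slot; ``v_r`` and ``v_w`` are the rate- and
    weight-variance contributions (nA²) and ``U`` the integer truncation
    index of the series.
    """

    v_r: float
    U: int
    v_w: float
    M: float

    def to_dict(self) -> dict:
        return {"v_r": self.v_r, "U": self.U, "v_w": self.v_w, "M": self.M}


@dataclass(frozen=True)
class BitAllocation:
    """Split of the 16 weight bits into integer and fractional parts."""

    integer_bits: int
    frac_bits: int

    @property
    def weight_format(self) -> FixedPointFormat:
        return FixedPointFormat(total_bits=16, frac_bits=self.frac_bits,
                                signed=False)

    def to_dict(self) -> dict:
        return {"integer_bits": self.integer_bits, "frac_bits": self.frac_bits}


def quantize_truncate(x: float, frac_bits: int) -> float:
    """Truncating quantization ``floor(x * 2**f) / 2**f`` of a
    non-negative value to an unsigned format with ``frac_bits``
    fractional bits.

    Truncation (floor, equal to truncation toward zero for unsigned
    values) is the rule consistent with the hardware's weight encoding.
    """
    if x < 0:
        raise InvalidParameterError("unsigned weight format: x must be >= 0")
    if not 0 <= frac_bits <= 32:
        raise InvalidParameterError("frac_bits must be in [0, 32]")
    scaled = math.floor(x * 2 ** frac_bits)
    if scaled >= 2 ** 32:
        raise InvalidParameterError("integer part overflows the format")
    return scaled / 2 ** frac_bits


def float_round(x: float, precision: int = 32) -> float:
    """Round ``x`` to the nearest IEEE binary16/32/64 value
    (round-to-nearest-even), returned as a Python float."""
    if precision == 64:
        return float(np.float64(x))
    if precision == 32:
        return float(np.float32(x))
    if precision == 16:
        return float(np.float16(x))
    raise InvalidParameterError("precision must be one of 16, 32, 64")


def ring_buffer_max(inputs: RingBufferScalingInputs) -> ScalingResult:
    """Expected maximum summed weight in any delay ring-buffer slot.

    Under a Poisson assumption on the number of arriving spikes with
    ``n`` expected arrivals per step and i.i.d. weights of mean
    ``w_mean`` and variance ``w_var``::

        v_r = n * w_mean**2
        U   = round(n + 3*sqrt(n))
        v_w = exp(-n) * n * w_var * (-n**U + exp(n) * Γ(1+U, n)) / Γ(1+U)
        M   = n * w_mean + sigma * sqrt(v_r + v_w)

    with ``Γ(1+U, n)`` the non-regularized upper incomplete gamma
    function; as ``U -> ∞`` the bracket tends to ``n * w_var``, the
    weight-variance part of the compound-Poisson variance. The ``n**U``
    term is evaluated in log space (it is the Poisson pmf at ``U``) to
    avoid overflow.
    """
    n, w_mean, w_var, sigma = (inputs.n, inputs.w_mean, inputs.w_var,
                               inputs.sigma)
    if n <= 0:
        raise InvalidParameterError("n must be positive")
    v_r = n * w_mean ** 2
    U = int(round(n + 3.0 * math.sqrt(n)))
    # exp(-n) * n**U / Γ(1+U) == Poisson pmf at U, computed in log space
    log_pmf = U * math.log(n) - n - special.gammaln(1 + U)
    v_w = n * w_var * (special.gammaincc(1 + U, n) - math.exp(log_pmf))
    M = n * w_mean + sigma * math.sqrt(v_r + v_w)
    return ScalingResult(v_r=v_r, U=U, v_w=v_w, M=M)


def allocate_bits(M: float, total: int = 16) -> BitAllocation:
    """Smallest integer-bit count whose range covers ``M`` nA.

    ``integer_bits`` is the least ``i`` with ``2**i - 1 >= M``; the
    remaining ``total - i`` bits are fractional. ``M = 0`` yields the
    all-fractional single-neuron-test format.
    """
    if M < 0:
        raise InvalidParameterError("M must be non-negative")
    if M >= 2 ** total:
        raise InvalidParameterError(
            f"M = {M} nA cannot be represented in {total} bits")
    i = 0
    while 2 ** i - 1 < M:
        i += 1
    if i > total:
        raise InvalidParameterError(
            f"M = {M} nA cannot be represented in {total} bits")
    return BitAllocation(integer_bits=i, frac_bits=total - i)
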