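"""Bit-accurate model of a shift-and-truncate IEEE-754 single-precision FPU.

This mirrors the arithmetic datapath of the hardware design the numeric
pipeline was deployed on: 1 sign bit, 8 exponent bits (bias 127), 23
fraction bits, with the implicit leading 1 giving a 24-bit mantissa.
Alignment and normalisation are performed by plain shifts and the results
are *truncated*, never rounded.  The domain is restricted to normalised
finite values; the all-zero patterns (+-0) are special-cased, and denormals,
NaN and infinities are rejected.

The numeric pipeline itself runs on native double precision — this model
exists for fidelity tests and spot checks of the hardware arithmetic, not as
a computation backend.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

__all__ = [
    "Float32Parts",
    "unpack",
    "pack",
    "float_to_bits",
    "bits_to_float",
    "fp_add",
    "fp_sub",
    "fp_mul",
    "fp_compare",
    "GT",
    "EQ",
    "LT",
]

BIAS = 127
_MANT_BITS = 23
_IMPLICIT = 1 << _MANT_BITS

# 2-bit comparator codes.
GT, EQ, LT = 0b01, 0b00, 0b10

POS_ZERO = 0x00000000
NEG_ZERO = 0x80000000


class FPRangeError(ArithmeticError):
    """Exponent overflow/underflow after normalisation."""


class FPDomainError(ValueError):
    """Operand outside the supported domain (denormal, NaN or infinity)."""


@dataclass(frozen=True)
class Float32Parts:
    """Sign, biased exponent, fraction and full mantissa of one pattern."""

    s: int
    e: int
    f: int

    @property
    def m(self) -> int:
        """24-bit mantissa 1.f."""
        return _IMPLICIT | self.f

    @property
    def value(self) -> float:
        return (-1.0) ** self.s * (self.m / _IMPLICIT) * 2.0 ** (self.e - BIAS)


def _is_zero(bits: int) -> bool:
    return bits in (POS_ZERO, NEG_ZERO)


def unpack(bits: int) -> Float32Parts:
    """Split a normalised 32-bit pattern into sign/exponent/fraction."""
    if not (0 <= bits <= 0xFFFFFFFF):
        raise ValueError("bit pattern must fit in 32 bits")
    s = (bits >> 31) & 1
    e = (bits >> 23) & 0xFF
    f = bits & 0x7FFFFF
    if e == 0:
        raise FPDomainError("zero/denormal patterns are outside the normalised domain")
    if e == 0xFF:
        raise FPDomainError("NaN/Inf patterns are outside the normalised domain")
    return Float32Parts(s, e, f)


def pack(parts: Float32Parts) -> int:
    if not (1 <= parts.e <= 0xFE):
        raise FPRangeError(f"biased exponent {parts.e} outside [1, 254]")
    return (parts.s << 31) | (parts.e << 23) | (parts.f & 0x7FFFFF)


def float_to_bits(x: float) -> int:
    """The IEEE-754 single-precision pattern of x (round-to-nearest)."""
    return struct.unpack("<I", struct.pack("<f", float(x)))[0]


def bits_to_float(bits: int) -> float:
    return struct.unpack("<f", struct.pack("<I", bits & 0xFFFFFFFF))[0]


def _normalise(s: int, e: int, m: int) -> int:
    """Shift m into [2^23, 2^24), adjust e, truncate, and pack."""
    if m == 0:
        return POS_ZERO  # cancellation: canonical +0 (left-shift loop bounded)
    while m >= (_IMPLICIT << 1):
        m >>= 1  # carry-out: one right shift, exponent increment
        e += 1
    shifts = 0
    while m < _IMPLICIT:
        m <<= 1
        e -= 1
        shifts += 1
        if shifts > 24:  # cannot happen for m > 0; safety bound
            return POS_ZERO
    if not (1 <= e <= 0xFE):
        raise FPRangeError(f"exponent {e} out of range after normalisation")
    return pack(Float32Parts(s, e, m & 0x7FFFFF))


def fp_add(a: int, b: int) -> int:
    """Shift-align, add/subtract mantissas, normalise, truncate."""
    if _is_zero(a):
        return POS_ZERO if _is_zero(b) else b
    if _is_zero(b):
        return a
    pa, pb = unpack(a), unpack(b)
    ma, mb = pa.m, pb.m
    if pa.e >= pb.e:
        e_out = pa.e
        mb >>= pa.e - pb.e
    else:
        e_out = pb.e
        ma >>= pb.e - pa.e
    if pa.s == pb.s:
        return _normalise(pa.s, e_out, ma + mb)
    if ma > mb:
        return _normalise(pa.s, e_out, ma - mb)
    if mb > ma:
        return _normalise(pb.s, e_out, mb - ma)
    return POS_ZERO


def fp_sub(a: int, b: int) -> int:
    """a - b: the adder datapath with b's sign role inverted."""
    if _is_zero(b):
        return POS_ZERO if _is_zero(a) else a
    return fp_add(a, b ^ 0x80000000)


def fp_mul(a: int, b: int) -> int:
    """XOR signs, add exponents (minus bias), multiply 24-bit mantissas."""
    if _is_zero(a) or _is_zero(b):
        return POS_ZERO
    pa, pb = unpack(a), unpack(b)
    s_out = pa.s ^ pb.s
    e_out = pa.e + pb.e - BIAS
    prod = pa.m * pb.m  # 48 bits, value in [1, 4) after scaling
    if prod >= (1 << 47):
        m_out = prod >> (_MANT_BITS + 1)
        e_out += 1
    else:
        m_out = prod >> _MANT_BITS
    if not (1 <= e_out <= 0xFE):
        raise FPRangeError(f"exponent {e_out} out of range in multiply")
    return pack(Float32Parts(s_out, e_out, m_out & 0x7FFFFF))


def fp_compare(a: int, b: int, mode: str = "corrected") -> int:
    """Lexicographic sign/exponent/fraction comparison; returns GT/EQ/LT.

    ``mode="faithful"`` applies the raw field comparison even when both
    operands are negative, in which case the larger magnitude is (wrongly)
    declared larger; ``mode="corrected"`` reverses the exponent/fraction
    comparisons for two negative operands so the result matches the real
    numeric order.
    """
    if mode not in ("corrected", "faithful"):
        raise ValueError(f"unknown comparator mode {mode!r}")
    if _is_zero(a) and _is_zero(b):
        return EQ
    if _is_zero(a):
        return LT if unpack(b).s == 0 else GT
    if _is_zero(b):
        return GT if unpack(a).s == 0 else LT
    pa, pb = unpack(a), unpack(b)
    if pa.s > pb.s:
        return LT
    if pb.s > pa.s:
        return GT
    if pa.e != pb.e:
        mag = GT if pa.e > pb.e else LT
    elif pa.f != pb.f:
        mag = GT if pa.f > pb.f else LT
    else:
        return EQ
    if mode == "corrected" and pa.s == 1:
        return GT if mag == LT else LT
    return mag
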