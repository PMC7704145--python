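"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately written in the most literal way possible
(per-sample loops, nested sums, exact integer arithmetic) and shares no code
with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def literal_threshold_norm(x) -> dict:
    """Per-sample execution of the threshold procedure, exactly as listed.

    State registers m1 (precomputed whole-record mean), m2, R1, R2 start at
    zero; R3/R4 latch rising samples above m1; every sample below m1 emits
    the latched pair and accumulates pv/N into m2; th latches when the
    counter reaches N-1.  Returns recorded (first-emission) maxima, th, m1
    and m2 at the trigger.
    """
    x = list(map(float, x))
    n = len(x)
    inv_n = 1.0 / n
    m1 = 0.0
    for v in x:  # streamed accumulation, reciprocal-multiply form
        m1 += v * inv_n
    m2 = 0.0
    r1 = 0.0
    r2 = 0
    r3 = 0.0
    r4 = 0
    th = None
    m2_at_trigger = None
    fresh = False
    pl: list[int] = []
    pv: list[float] = []
    for k in range(n):
        cur = x[k]
        if cur > m1 and cur > r1:
            r3 = cur
            r4 = r2
            fresh = True
        elif cur < m1:
            m2 += r3 * inv_n
            if fresh:
                pl.append(r4)
                pv.append(r3)
                fresh = False
        r1 = cur
        r2 += 1
        if r2 == n - 1:
            th = (m1 + m2) / 2.0
            m2_at_trigger = m2
    if th is None:  # degenerate n == 1
        th = (m1 + m2) / 2.0
        m2_at_trigger = m2
    return {"pl": pl, "pv": pv, "th": th, "m1": m1, "m2": m2_at_trigger}


def nested_double_sum_baseline(x, n1: int, n2: int):
    """O(N*n) two-stage trailing mean with zero padding, straight from the sums."""
    x = list(map(float, x))
    n = len(x)

    def xval(i):
        return x[i] if 0 <= i < n else 0.0

    m1 = [sum(xval(k + i - n1 + 1) for i in range(n1)) / n1 for k in range(n)]

    def m1val(i):
        return m1[i] if 0 <= i < n else 0.0

    m2 = [sum(m1val(k + j - n2 + 1) for j in range(n2)) / n2 for k in range(n)]
    return np.array([xi - bi for xi, bi in zip(x, m2)]), np.array(m2)


def lms_step_bruteforce(w, xbuf, mu, x_new, d_new):
    """One adaptation step with explicit loops (no vector ops)."""
    m = len(w)
    new_buf = [float(x_new)] + [float(v) for v in xbuf[:-1]]
    y = 0.0
    for i in range(m):
        y += new_buf[i] * float(w[i])
    e = float(d_new) - y
    new_w = [float(w[i]) + 2.0 * float(mu) * e * new_buf[i] for i in range(m)]
    return new_w, new_buf, y, e


def trailing_mean_of_squared_diff(x, p: int):
    """Brute-force windowed mean of the squared first difference."""
    x = list(map(float, x))
    n = len(x)
    sdiff = [(x[k] - (x[k - 1] if k > 0 else 0.0)) ** 2 for k in range(n)]

    def sval(i):
        return sdiff[i] if i >= 0 else 0.0

    return np.array([sum(sval(k - j) for j in range(p)) / p for k in range(n)])


# -- exact float32 oracle ---------------------------------------------------

_BIAS = 127
_IMPLICIT = 1 << 23


def _decompose(bits: int):
    s = (bits >> 31) & 1
    e = (bits >> 23) & 0xFF
    m = _IMPLICIT | (bits & 0x7FFFFF)
    return s, e, m


def _truncate_to_float32(sign: int, mag_num: int, mag_exp: int) -> int:
    """Exact value (-1)^sign * mag_num * 2^mag_exp, truncated toward zero.

    Returns the bit pattern of the truncated normalised single, or raises
    OverflowError/ValueError outside the normalised range.
    """
    if mag_num == 0:
        return 0
    nbits = mag_num.bit_length()
    # want mantissa in [2^23, 2^24): shift so that exactly 24 bits remain
    shift = nbits - 24
    if shift >= 0:
        mant = mag_num >> shift  # truncation
    else:
        mant = mag_num << (-shift)
    e_unb = mag_exp + shift + 23
    e_biased = e_unb + _BIAS
    if not (1 <= e_biased <= 254):
        raise OverflowError(f"exponent {e_biased} out of normalised range")
    return (sign << 31) | (e_biased << 23) | (mant & 0x7FFFFF)


def exact_addsub_oracle(a_bits: int, b_bits: int, subtract: bool = False) -> int:
    """Exact rational sum/difference of two normalised singles, then truncate."""
    sa, ea, ma = _decompose(a_bits)
    sb, eb, mb = _decompose(b_bits)
    if subtract:
        sb ^= 1
    # value = (-1)^s * m * 2^(e - bias - 23); use common exponent grid
    e0 = min(ea, eb)
    va = (1 - 2 * sa) * (ma << (ea - e0))
    vb = (1 - 2 * sb) * (mb << (eb - e0))
    total = va + vb
    sign = 1 if total < 0 else 0
    return _truncate_to_float32(sign, abs(total), e0 - _BIAS - 23)


def exact_mul_oracle(a_bits: int, b_bits: int) -> int:
    """Exact product of two normalised singles, then truncate."""
    sa, ea, ma = _decompose(a_bits)
    sb, eb, mb = _decompose(b_bits)
    prod = ma * mb
    exp = (ea - _BIAS - 23) + (eb - _BIAS - 23)
    return _truncate_to_float32(sa ^ sb, prod, exp)
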