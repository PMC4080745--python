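"""Compiled merge kernels over sorted sparse frequency vectors.

Profiles store (sorted key array, frequency array) pairs; a pairwise
distance is one linear merge of the two key arrays.  Keys present in only
one profile contribute closed-form terms (0.5 * p for the JS divergence,
p**2 for the squared Euclidean norm), so logarithms are only evaluated on
the intersection of the supports.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2 = 0.6931471805599453  # ln 2


@njit(cache=True)
def js_sparse(k1, f1, k2, f2):  # pragma: no cover - exercised via wrapper
    """Jensen-Shannon divergence (bits) of two sparse probability vectors."""
    i = 0
    j = 0
    n1 = k1.size
    n2 = k2.size
    shared = 0.0
    p_shared = 0.0
    q_shared = 0.0
    while i < n1 and j < n2:
        a = k1[i]
        b = k2[j]
        if a < b:
            i += 1
        elif b < a:
            j += 1
        else:
            p = f1[i]
            q = f2[j]
            m = 0.5 * (p + q)
            if p > 0.0:
                shared += 0.5 * p * np.log(p / m)
            if q > 0.0:
                shared += 0.5 * q * np.log(q / m)
            p_shared += p
            q_shared += q
            i += 1
            j += 1
    # keys unique to one profile: KL term p*log2(p/(p/2)) = p bits, halved
    js = shared / _LOG2 + 0.5 * (1.0 - p_shared) + 0.5 * (1.0 - q_shared)
    if js < 0.0:
        js = 0.0
    return js


@njit(cache=True)
def js_sparse_precomp(k1, f1, fl1, k2, f2, fl2):  # pragma: no cover
    """JS divergence with precomputed ``f * ln(f)`` arrays.

    Only the midpoint term needs a logarithm per shared key:
    sum over shared x of p*log2(p/m) + q*log2(q/m)
      = [sum p ln p + sum q ln q - sum (p+q) ln((p+q)/2)] / ln 2.
    """
    i = 0
    j = 0
    n1 = k1.size
    n2 = k2.size
    s_plogp = 0.0
    s_mix = 0.0
    p_shared = 0.0
    q_shared = 0.0
    while i < n1 and j < n2:
        a = k1[i]
        b = k2[j]
        if a < b:
            i += 1
        elif b < a:
            j += 1
        else:
            p = f1[i]
            q = f2[j]
            s = p + q
            s_plogp += fl1[i] + fl2[j]
            s_mix += s * np.log(0.5 * s)
            p_shared += p
            q_shared += q
            i += 1
            j += 1
    js = (s_plogp - s_mix) / (2.0 * _LOG2) + 0.5 * (1.0 - p_shared) + 0.5 * (
        1.0 - q_shared
    )
    if js < 0.0:
        js = 0.0
    return js


@njit(cache=True)
def euclidean_sparse(k1, f1, k2, f2):  # pragma: no cover - exercised via wrapper
    """Euclidean distance of two sparse vectors (absent key = 0)."""
    i = 0
    j = 0
    n1 = k1.size
    n2 = k2.size
    total = 0.0
    while i < n1 and j < n2:
        a = k1[i]
        b = k2[j]
        if a < b:
            total += f1[i] * f1[i]
            i += 1
        elif b < a:
            total += f2[j] * f2[j]
            j += 1
        else:
            d = f1[i] - f2[j]
            total += d * d
            i += 1
            j += 1
    while i < n1:
        total += f1[i] * f1[i]
        i += 1
    while j < n2:
        total += f2[j] * f2[j]
        j += 1
    return np.sqrt(total)
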