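"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — O(n²) enumeration, direct definition
arithmetic — kept free of any code path they are used to check.
"""

import numpy as np


def brute_force_pair_counts(positions, counts, max_distance):
    """All-pairs dyad-distance counts by O(n²) enumeration."""
    out = np.zeros(max_distance + 1, dtype=np.int64)
    n = len(positions)
    for i in range(n):
        out[0] += counts[i] * (counts[i] - 1) // 2
        for j in range(i + 1, n):
            d = abs(int(positions[j]) - int(positions[i]))
            if 1 <= d <= max_distance:
                out[d] += counts[i] * counts[j]
    return out


def brute_force_has_match(q, subjects, f=None, reciprocal=False, min_bp=None):
    """Direct scan over every subject interval (chrom, start, end)."""
    qc, qs, qe = q
    for sc, ss, se in subjects:
        if sc != qc:
            continue
        ov = max(0, min(qe, se) - max(qs, ss))
        if f is not None:
            ok = ov >= f * (qe - qs)
            if reciprocal:
                ok = ok and ov >= f * (se - ss)
        else:
            ok = ov >= (1 if min_bp is None else min_bp)
        if ok:
            return True
    return False


def hypergeometric_two_sided_p(a, b, c, d):
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    Sums P(X = k) over all tables with the observed margins whose
    probability does not exceed the observed one (with the standard
    relative guard against floating-point knife edges).
    """
    from math import comb

    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)

    def pmf(k):
        if k < 0 or k > row1 or col1 - k > n - row1:
            return 0.0
        return comb(row1, k) * comb(n - row1, col1 - k) / denom

    p_obs = pmf(a)
    total = 0.0
    for k in range(0, min(row1, col1) + 1):
        p_k = pmf(k)
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


def brute_force_profile_mass(fragments, features, flank):
    """Sum over (fragment, feature) pairs of overlap with the flank window."""
    total = 0
    for fc, fs, fe in fragments:
        for rc, rs, re_ in features:
            if fc != rc:
                continue
            centre = rs + (re_ - rs) // 2
            lo, hi = centre - flank, centre + flank + 1
            total += max(0, min(fe, hi) - max(fs, lo))
    return total
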