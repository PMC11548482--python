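"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's vectorized/structured code paths:
plain Python loops over the rule definitions.
"""

from __future__ import annotations

import math


def spike_scan_bruteforce(channels, spike_neigh_diff):
    """All 1-based indices i in 1..197 where the three-condition spike rule
    fires: Ch[i+1] > Ch[i]*f and (Ch[i+1] > Ch[i+2]*f or Ch[i+2] > Ch[i+3]*f)."""
    f = (100.0 + spike_neigh_diff) / 100.0
    fired = []
    for i in range(1, 198):  # 1-based channel index
        ch_i = channels[i - 1]
        ch_i1 = channels[i]
        ch_i2 = channels[i + 1]
        ch_i3 = channels[i + 2]
        first = ch_i1 > ch_i * f
        second = ch_i1 > ch_i2 * f
        third = ch_i2 > ch_i3 * f
        if first and (second or third):
            fired.append(i)
    return fired


def ratio_match_bruteforce(doses, rows, tol):
    """Exhaustive row scan with explicit ratio arithmetic.

    ``doses`` is a sequence of 3-4 dose values (L4 may be absent); ``rows``
    are (l4_over_l3, l3_over_l1, l3_over_l2, l1_over_l4, beam) tuples.
    Returns the beam of the best-matching row (smallest max deviation) or
    None.  Semantics mirror the documented matching contract.
    """
    l1 = doses[0]
    l2 = doses[1]
    l3 = doses[2]
    l4 = doses[3] if len(doses) > 3 else None

    def ratio(num, den):
        if num is None or den is None:
            return None  # non-computable: element absent
        if den > 0:
            return num / den
        if num > 0:
            return math.inf
        return None  # 0/0

    measured = {
        0: ratio(l4, l3),
        1: ratio(l3, l1),
        2: ratio(l3, l2),
        3: ratio(l1, l4),
    }
    best = None
    for row in rows:
        worst = 0.0
        ok = True
        any_ratio = False
        for k in range(4):
            r = measured[k]
            if r is None:
                continue
            any_ratio = True
            v = row[k]
            if math.isinf(r):
                if not (v > 0 and 1.0 / v <= tol):
                    ok = False
                    break
                continue
            if abs(r - v) > tol:
                ok = False
                break
            worst = max(worst, abs(r - v))
        if ok and any_ratio and (best is None or worst < best[0]):
            best = (worst, row[4])
    return None if best is None else best[1]
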