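"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: quadrature by brute
force on fine grids, Shapley values by exhaustive coalition enumeration on
dumped tree structures, etc.
"""

from __future__ import annotations

from math import factorial

import numpy as np


def quad_delta_area(fa, fb, t_i, t_f, step=1e-4):
    """Brute-force trapezoid of |fa - fb| / (t_f - t_i)."""
    g = np.linspace(t_i, t_f, int(round((t_f - t_i) / step)) + 1)
    return np.trapezoid(np.abs(fa(g) - fb(g)), g) / (t_f - t_i)


def quad_chord_delay(chord_a, chord_b, y_lo, y_hi, step=1e-5):
    """Numeric quadrature of the level-averaged chord delay and sigma."""
    y = np.linspace(y_lo, y_hi, int(round((y_hi - y_lo) / step)) + 1)
    d = chord_b.t_of_y(y) - chord_a.t_of_y(y)
    mean = np.trapezoid(d, y) / (y_hi - y_lo)
    mean2 = np.trapezoid(d**2, y) / (y_hi - y_lo)
    return mean, np.sqrt(max(mean2 - mean**2, 0.0))


# ---------------------------------------------------------------------------
# path-dependent tree value function (cover-weighted conditional expectation)


def tree_expected_value(node, x, subset):
    """Lundberg's EXPVALUE: follow x for features in the subset, average
    children by training cover otherwise."""
    if "leaf_value" in node:
        return node["leaf_value"]
    j = node["split_feature"]
    if j in subset:
        v = x[j]
        assert node["decision_type"] == "<="
        go_left = bool(np.isnan(v) and node.get("default_left", False)) or (
            not np.isnan(v) and v <= node["threshold"]
        )
        child = node["left_child"] if go_left else node["right_child"]
        return tree_expected_value(child, x, subset)
    lc, rc = node["left_child"], node["right_child"]
    nl = lc.get("internal_count", lc.get("leaf_count"))
    nr = rc.get("internal_count", rc.get("leaf_count"))
    return (
        nl * tree_expected_value(lc, x, subset)
        + nr * tree_expected_value(rc, x, subset)
    ) / (nl + nr)


def brute_force_tree_shapley(booster, x):
    """Exact Shapley values of the path-dependent game by 2^M enumeration.

    Exponential; use only for toy models with <= 12 features.
    """
    x = np.asarray(x, dtype=float)
    m = x.size
    if m > 12:
        raise ValueError("toy oracle limited to 12 features")
    dump = booster.dump_model()
    fact = [factorial(k) for k in range(m + 1)]
    phi = np.zeros(m)
    base = 0.0
    for tree in dump["tree_info"]:
        root = tree["tree_structure"]
        v = np.empty(1 << m)
        for mask in range(1 << m):
            subset = {j for j in range(m) if mask >> j & 1}
            v[mask] = tree_expected_value(root, x, subset)
        base += v[0]
        for mask in range(1 << m):
            size = bin(mask).count("1")
            w = fact[size] * fact[m - size - 1] / fact[m]
            for j in range(m):
                if not mask >> j & 1:
                    phi[j] += w * (v[mask | (1 << j)] - v[mask])
    return phi, base
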