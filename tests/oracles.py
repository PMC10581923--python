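"""Independent numeric oracles used by the unit and acceptance tests.

These deliberately avoid the analytic formulas under test: stationary
points are located by brute-force evaluation of the curve on a dense
grid, candidate extrema are confirmed by a derivative sign change over a
bracket of several grid cells (which rejects floating-point wiggles in
monotone tails), and each confirmed extremum is polished by root-finding
on the central-difference slope.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

_BRACKET_CELLS = 25


def numeric_extrema(
    fn, lo: float, hi: float, n: int = 100_001, log: bool = False
) -> tuple[list[float], list[float]]:
    """All interior local maxima and minima of ``fn`` on [lo, hi].

    Returns ``(maxima, minima)`` as refined x locations.
    """
    xs = np.geomspace(lo, hi, n) if log else np.linspace(lo, hi, n)
    ys = fn(xs)
    inner = ys[1:-1]
    max_idx = np.flatnonzero((inner > ys[:-2]) & (inner > ys[2:])) + 1
    min_idx = np.flatnonzero((inner < ys[:-2]) & (inner < ys[2:])) + 1

    def confirm_and_refine(indices, want_max: bool) -> list[float]:
        found: list[float] = []
        for i in indices:
            j_lo = max(i - _BRACKET_CELLS, 0)
            j_hi = min(i + _BRACKET_CELLS, n - 1)
            # h ~ eps^(1/3): balances rounding noise vs truncation error
            h = 6e-6 * max(abs(float(xs[i])), 1.0)
            if log and xs[j_lo] - h <= 0:
                continue

            def slope(t: float) -> float:
                return float(fn(t + h) - fn(t - h))

            # ignore "extrema" where the curve has underflowed to the
            # numerically dead region (subnormal-scale tail noise)
            if max(abs(ys[j_lo]), abs(ys[i]), abs(ys[j_hi])) < 1e-150:
                continue
            s_lo, s_hi = slope(float(xs[j_lo])), float(slope(float(xs[j_hi])))
            ok = (s_lo > 0 > s_hi) if want_max else (s_lo < 0 < s_hi)
            if not ok:
                continue  # floating-point wiggle on a monotone stretch
            root = float(
                brentq(slope, float(xs[j_lo]), float(xs[j_hi]),
                       xtol=1e-14, rtol=1e-15)
            )
            if not any(
                abs(root - r) <= max(1e-9, 1e-6 * abs(root)) for r in found
            ):
                found.append(root)
        return found

    return confirm_and_refine(max_idx, True), confirm_and_refine(min_idx, False)


def numeric_stationary_point(
    fn, lo: float, hi: float, n: int = 100_001, log: bool = False
) -> float:
    """The single interior stationary point of a curve known to have one."""
    maxima, minima = numeric_extrema(fn, lo, hi, n, log)
    found = maxima + minima
    if len(found) != 1:
        raise AssertionError(
            f"expected exactly one interior extremum, found {found}"
        )
    return found[0]
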