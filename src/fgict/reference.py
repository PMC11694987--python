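"""Plain-Python scalar reference implementation of the FGI filter.

This module re-derives every stage of the filter directly from its defining
formulas, pixel by pixel, with no compiled code and no shared internals with
:mod:`fgict._engine`: membership functions are written out inline, windows
are gathered and sorted with Python lists, and the centre-of-gravity
defuzzification integrates the aggregated consequent polygon exactly from its
breakpoints rather than through per-triangle closed forms.  It exists as an
independent verification route (the engine must reproduce it to ~1e-12) and
as readable executable documentation; it is far too slow for real volumes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["defuzzify_weight_polygon", "filter_image_reference"]


def _eta_low(x: float, p4: float) -> float:
    c = 1.0 - p4
    return 1.0 - x / c if 0.0 <= x <= c else 0.0


def _eta_moderate(x: float, p4: float) -> float:
    c = 1.0 - p4
    if c < x <= 0.5:
        return (2.0 * x - 1.0) / (2.0 * p4 - 1.0) + 1.0
    if 0.5 < x < p4:
        return (1.0 - 2.0 * x) / (2.0 * p4 - 1.0) + 1.0
    return 0.0


def _eta_high(x: float, p4: float) -> float:
    return (x - 1.0) / (1.0 - p4) + 1.0 if p4 < x <= 1.0 else 0.0


def aggregate_consequents(alpha_l: float, alpha_m: float, alpha_h: float, p4: float):
    """The aggregated output region L(x) = max_c min(alpha_c, eta_c(x))."""

    def L(x: float) -> float:
        return max(
            min(alpha_l, _eta_low(x, p4)),
            min(alpha_m, _eta_moderate(x, p4)),
            min(alpha_h, _eta_high(x, p4)),
        )

    return L


def defuzzify_weight_polygon(alpha_l: float, alpha_m: float, alpha_h: float, p4: float) -> float:
    """Centre of gravity of the aggregated consequent region, computed by
    exact integration of the polygonal line between its breakpoints.

    For p4 > 0.5 the three consequent supports have disjoint interiors, so
    every kink of L(x) is a kink of one component: support endpoints, apexes
    and truncation crossings.  Between consecutive breakpoints L is linear
    and the trapezoid/first-moment formulas are exact.
    """
    c = 1.0 - p4
    xs = {0.0, c, 0.5, p4, 1.0}
    if alpha_l > 0.0:
        xs.add(c * (1.0 - alpha_l))
    if alpha_m > 0.0:
        xs.add(c + alpha_m * (0.5 - c))
        xs.add(p4 - alpha_m * (p4 - 0.5))
    if alpha_h > 0.0:
        xs.add(p4 + alpha_h * (1.0 - p4))
    grid = sorted(xs)
    L = aggregate_consequents(alpha_l, alpha_m, alpha_h, p4)
    area = 0.0
    moment = 0.0
    for x1, x2 in zip(grid[:-1], grid[1:]):
        y1, y2 = L(x1), L(x2)
        area += (x2 - x1) * (y1 + y2) / 2.0
        moment += (x2 - x1) * (x1 * (2.0 * y1 + y2) + x2 * (y1 + 2.0 * y2)) / 6.0
    if area <= 0.0:
        return 0.0
    return moment / area


def _sorted_window(img: np.ndarray, i: int, j: int, n: int):
    """Window pixels as (distance, value, row, col), ordered by ascending
    absolute difference to the centre with the centre first; ties keep raster
    order."""
    half = n // 2
    center = float(img[i, j])
    others = []
    idx = 0
    for a in range(max(0, i - half), min(img.shape[0], i + half + 1)):
        for b in range(max(0, j - half), min(img.shape[1], j + half + 1)):
            if a == i and b == j:
                idx += 1
                continue
            v = float(img[a, b])
            others.append((abs(v - center), idx, v, a, b))
            idx += 1
    others.sort(key=lambda e: (e[0], e[1]))
    return [(0.0, center, i, j)] + [(d, v, a, b) for d, _, v, a, b in others]


def _delta_map(img: np.ndarray, n: int, r: int, p1: float, p2: float) -> np.ndarray:
    delta = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = _sorted_window(img, i, j, n)
            dists = sorted(e[0] for e in win[1:])
            s_road = sum(dists[:r])
            if s_road <= p1:
                delta[i, j] = 0.0
            elif s_road >= p2:
                delta[i, j] = 1.0
            else:
                delta[i, j] = (s_road - p1) / (p2 - p1)
    return delta


def filter_image_reference(image: np.ndarray, params, iterations: int | None = None) -> np.ndarray:
    """Run the filter on a 2-D image with straight per-pixel Python loops.

    Honors the variant semantics: base/skip_q read the previous iterate only;
    chaotic variants update the image in place in raster-scan order (the
    impulsivity map of the iteration is still computed up front from the
    iterate as it stood at the start of the iteration).
    """
    img = np.array(image, dtype=float, copy=True)
    its = params.max_iterations if iterations is None else iterations
    skip = params.variant in ("skip_q", "chaotic_skip_q")
    in_place = params.variant in ("chaotic", "chaotic_skip_q")
    p3, p4 = params.p3, params.p4
    for _ in range(its):
        delta = _delta_map(img, params.n, params.r, params.p1, params.p2)
        out = img if in_place else np.empty_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                win = _sorted_window(img, i, j, params.n)
                di = delta[i, j]
                selected = win[: min(params.q, len(win))]
                num = 0.0
                den = 0.0
                for k, (L1, v, a, b) in enumerate(selected):
                    if skip and k == 0:
                        continue
                    # similarity memberships (high / moderate / low)
                    if L1 <= p3:
                        mu_h = 1.0
                    elif L1 < 4.0 * p3:
                        mu_h = -L1 / (3.0 * p3) + 4.0 / 3.0
                    else:
                        mu_h = 0.0
                    if p3 < L1 < 2.0 * p3:
                        mu_m = (L1 - p3) / p3
                    elif 2.0 * p3 <= L1 <= 3.0 * p3:
                        mu_m = 1.0
                    elif 3.0 * p3 < L1 < 4.0 * p3:
                        mu_m = (4.0 * p3 - L1) / p3
                    else:
                        mu_m = 0.0
                    mu_l = 1.0 - mu_h
                    dj = delta[a, b]
                    a_m = min(1.0 - dj, di, mu_m)
                    a_h = max(min(1.0 - dj, di, mu_l), min(1.0 - dj, 1.0 - di, mu_h))
                    a_l = max(
                        dj,
                        min(1.0 - dj, di, mu_h),
                        min(1.0 - dj, 1.0 - di, mu_m),
                        min(1.0 - dj, 1.0 - di, mu_l),
                    )
                    w = defuzzify_weight_polygon(a_l, a_m, a_h, p4)
                    num += w * (v - win[0][1])
                    den += w
                out[i, j] = win[0][1] + num / den if den > 0.0 else img[i, j]
        img = out
    return img
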