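"""Compiled slice kernels of the FGI filter.

The filter is a sliding-window method whose per-pixel work (stable partial
sort of up to n^2-1 absolute differences, three fuzzy rules, closed-form
centre-of-gravity defuzzification) does not map onto whole-array numpy
primitives, so the hot loops are numba-jitted scalar kernels instead.  Each
iteration is two passes over a slice, mirroring the restructured algorithm in
which every pixel's impulsivity degree is available before any weight needs
it:

* pass A (:func:`_impulsivity_pass`) writes the impulsivity degree of every
  pixel of the current image into a dense map;
* pass B (:func:`_filter_pass`) gathers each pixel's window, orders it by
  absolute difference to the centre (centre first, stable ties by raster
  index), evaluates the rules against the pass-A map and applies the
  weighted-average update.

Windows are recomputed on the fly each pass; nothing is precomputed per
volume.  base/skip_q write into a fresh buffer; chaotic variants alias
``dst`` to ``src`` and update in place in raster-scan order (a deterministic,
reproducible member of the unordered-update family).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["filter_volume_once", "filter_slice_iterations", "cog_weight", "impulsivity_map"]


@njit(cache=True)
def _cog(a_l, a_m, a_h, p4):
    """Centre of gravity of the union of the three truncated weight
    consequents.  Their supports ([0,1-p4], [1-p4,p4], [p4,1]) have disjoint
    interiors for p4 > 0.5, so area and moment are sums of closed forms of
    truncated triangles."""
    c = 1.0 - p4
    area = 0.0
    moment = 0.0
    # "low": right triangle (0,1)-(c,0), truncated at a_l
    if a_l > 0.0:
        x2 = c - a_l * c
        area += a_l * (x2 + 0.5 * (c - x2))
        moment += a_l * x2 * x2 / 2.0
        moment += c * a_l * a_l * c / 2.0 - a_l * a_l * a_l * c * c / 3.0
    # "moderate": symmetric triangle on [c, p4] with apex 0.5, truncated at a_m
    if a_m > 0.0:
        x1 = c + a_m * (0.5 - c)
        x2 = p4 - a_m * (p4 - 0.5)
        area += a_m * ((x2 - x1) + 0.5 * (x1 - c) + 0.5 * (p4 - x2))
        moment += a_m * (x2 * x2 - x1 * x1) / 2.0
        moment += a_m**3 * (0.5 - c) ** 2 / 3.0 + c * a_m * a_m * (0.5 - c) / 2.0
        moment += p4 * a_m * a_m * (p4 - 0.5) / 2.0 - a_m**3 * (p4 - 0.5) ** 2 / 3.0
    # "high": right triangle (p4,0)-(1,1), truncated at a_h
    if a_h > 0.0:
        x1 = p4 + a_h * (1.0 - p4)
        area += a_h * ((1.0 - x1) + 0.5 * (x1 - p4))
        moment += a_h * (1.0 - x1 * x1) / 2.0
        moment += a_h**3 * (1.0 - p4) ** 2 / 3.0 + p4 * a_h * a_h * (1.0 - p4) / 2.0
    if area <= 0.0:
        return 0.0
    return moment / area


@njit(cache=True)
def _impulsivity_pass(img, half, r, p1, p2, delta):
    rows, cols = img.shape
    n = 2 * half + 1
    d = np.empty(n * n - 1, dtype=img.dtype)
    for i in range(rows):
        r0 = i - half if i - half > 0 else 0
        r1 = i + half + 1 if i + half + 1 < rows else rows
        for j in range(cols):
            c0 = j - half if j - half > 0 else 0
            c1 = j + half + 1 if j + half + 1 < cols else cols
            c = img[i, j]
            cnt = 0
            for a in range(r0, r1):
                for b in range(c0, c1):
                    if a == i and b == j:
                        continue
                    diff = img[a, b] - c
                    if diff < 0.0:
                        diff = -diff
                    d[cnt] = diff
                    cnt += 1
            for s in range(1, cnt):  # insertion sort (<= n^2-1 elements)
                key = d[s]
                t = s - 1
                while t >= 0 and d[t] > key:
                    d[t + 1] = d[t]
                    t -= 1
                d[t + 1] = key
            m = r if r < cnt else cnt
            s_road = 0.0
            for s in range(m):
                s_road += d[s]
            if s_road <= p1:
                delta[i, j] = 0.0
            elif s_road >= p2:
                delta[i, j] = 1.0
            else:
                delta[i, j] = (s_road - p1) / (p2 - p1)


@njit(cache=True)
def _filter_pass(src, delta, dst, half, q, p3, p4, skip_center):
    rows, cols = src.shape
    n = 2 * half + 1
    vals = np.empty(n * n, dtype=src.dtype)
    dists = np.empty(n * n, dtype=src.dtype)
    djs = np.empty(n * n, dtype=delta.dtype)
    for i in range(rows):
        r0 = i - half if i - half > 0 else 0
        r1 = i + half + 1 if i + half + 1 < rows else rows
        for j in range(cols):
            c0 = j - half if j - half > 0 else 0
            c1 = j + half + 1 if j + half + 1 < cols else cols
            c = src[i, j]
            di = delta[i, j]
            vals[0] = c
            dists[0] = 0.0
            djs[0] = di
            cnt = 1
            for a in range(r0, r1):
                for b in range(c0, c1):
                    if a == i and b == j:
                        continue
                    v = src[a, b]
                    dist = v - c
                    if dist < 0.0:
                        dist = -dist
                    dj = delta[a, b]
                    pos = cnt  # stable insertion keeps raster order on ties
                    while pos > 1 and dists[pos - 1] > dist:
                        dists[pos] = dists[pos - 1]
                        vals[pos] = vals[pos - 1]
                        djs[pos] = djs[pos - 1]
                        pos -= 1
                    dists[pos] = dist
                    vals[pos] = v
                    djs[pos] = dj
                    cnt += 1
            m = q if q < cnt else cnt
            start = 1 if skip_center else 0
            num = 0.0
            den = 0.0
            ni = 1.0 - di
            for k in range(start, m):
                L1 = dists[k]
                # similarity memberships
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
                dj = djs[k]
                nj = 1.0 - dj
                # Mamdani rules: AND=min, OR=max, NOT=1-x
                a_m = min(nj, min(di, mu_m))
                a_h = max(min(nj, min(di, mu_l)), min(nj, min(ni, mu_h)))
                a_l = max(
                    max(dj, min(nj, min(di, mu_h))),
                    max(min(nj, min(ni, mu_m)), min(nj, min(ni, mu_l))),
                )
                w = _cog(a_l, a_m, a_h, p4)
                num += w * (vals[k] - c)  # difference form: exact on flat windows
                den += w
            if den > 0.0:
                dst[i, j] = c + num / den
            else:
                dst[i, j] = c


def cog_weight(a_l: float, a_m: float, a_h: float, p4: float) -> float:
    """Compiled closed-form COG (exposed for verification)."""
    return float(_cog(a_l, a_m, a_h, p4))


def impulsivity_map(image: np.ndarray, n: int, r: int, p1: float, p2: float) -> np.ndarray:
    """Impulsivity degree of every pixel of a 2-D image (pass A)."""
    img = np.ascontiguousarray(image, dtype=np.float64)
    delta = np.empty_like(img)
    _impulsivity_pass(img, n // 2, r, p1, p2, delta)
    return delta


def _iterate_slice(img, iterations, n, q, r, p1, p2, p3, p4, skip_center, in_place):
    half = n // 2
    delta = np.empty_like(img)
    buf = None if in_place else np.empty_like(img)
    for _ in range(iterations):
        _impulsivity_pass(img, half, r, p1, p2, delta)
        if in_place:
            _filter_pass(img, delta, img, half, q, p3, p4, skip_center)
        else:
            _filter_pass(img, delta, buf, half, q, p3, p4, skip_center)
            img, buf = buf, img
    return img


def filter_slice_iterations(img, iterations, n, q, r, p1, p2, p3, p4, skip_center, in_place):
    img = np.ascontiguousarray(img)  # dtype (float32/float64) chosen by caller
    return _iterate_slice(img, iterations, n, q, r, p1, p2, p3, p4, skip_center, in_place)


def filter_volume_once(current: np.ndarray, params) -> None:
    """Advance every slice of ``current`` (3-D array, modified in place) by
    one filter iteration with 2-D windows."""
    half = params.n // 2
    delta = np.empty(current.shape[1:], dtype=current.dtype)
    buf = None if params.in_place else np.empty(current.shape[1:], dtype=current.dtype)
    for k in range(current.shape[0]):
        sl = current[k]
        _impulsivity_pass(sl, half, params.r, params.p1, params.p2, delta)
        if params.in_place:
            _filter_pass(sl, delta, sl, half, params.q, params.p3, params.p4, params.skip_center)
        else:
            _filter_pass(sl, delta, buf, half, params.q, params.p3, params.p4, params.skip_center)
            current[k] = buf
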