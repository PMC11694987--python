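"""The fuzzy Gaussian-impulsive (FGI) filter.

The filter replaces each pixel by a weighted average of the q closest pixels
(by absolute intensity difference) in its n x n window,

    x_hat = sum_j w_j * x_j / sum_j w_j,

where each weight w_j in [0,1] comes from a three-rule Mamdani fuzzy system
combining two ingredients:

* an impulsivity degree delta(x) in [0,1], a ramp over the ROAD statistic
  (sum of the r smallest absolute differences to the window neighbours) —
  large ROAD marks a pixel as an impulse;
* a similarity degree between the centre and each neighbour, expressed as
  "high"/"moderate"/"low" memberships of the absolute difference L1.

The rules (AND = min, OR = max, NOT = 1-x) truncate three triangular weight
consequents ("low"/"moderate"/"high", shaped by p4) and the crisp weight is
the centre of gravity of their union.  Iterating the filter progressively
removes impulses and averages Gaussian noise while similar-valued structures
are preserved.

This module holds the parameter container and scalar (per-pixel) reference
semantics of every stage; :mod:`fgict._engine` provides the numba-compiled
slice kernels used by :func:`filter_volume`, and :mod:`fgict.reference` an
independent plain-Python implementation used for verification.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .volume import AttenuationVolume

__all__ = [
    "FilterParams",
    "NeighborSet",
    "RuleActivation",
    "neighborhood",
    "road",
    "impulsivity",
    "similarity",
    "rule_activations",
    "defuzzify_weight",
    "pixel_update",
    "filter_image",
    "filter_volume",
]

VARIANTS = ("base", "chaotic", "skip_q", "chaotic_skip_q")
STOP_MODES = ("fixed", "max_psnr", "max_ssim")


@dataclasses.dataclass
class FilterParams:
    """All tunables of the FGI filter.

    Parameters
    ----------
    n : odd int >= 3
        Window side length.
    q : int >= 1
        Number of closest pixels entering the weighted average (9 = the full
        3x3 window, centre included).
    r : int
        ROAD order: how many of the smallest neighbour differences are summed.
    p1, p2 : float
        Impulsivity ramp thresholds on the working intensity scale
        (delta = 0 below p1, 1 above p2).
    p3 : float
        Similarity scale; "high" similarity holds up to p3 and vanishes at
        4*p3.  Default 1.96/255, the value used for attenuation-coefficient
        volumes.
    p4 : float in (0.5, 1)
        Shape of the weight consequents: "high" rises on [p4, 1], "low" falls
        on [0, 1-p4], "moderate" is the triangle between them.
    variant : {"base", "chaotic", "skip_q", "chaotic_skip_q"}
        base/skip_q write each iteration into a fresh buffer; chaotic variants
        update in place in raster-scan order.  skip variants exclude the
        window centre from the weighted average.
    max_iterations : int
        Iteration count (exact for stop="fixed", upper bound otherwise).
    stop : {"fixed", "max_psnr", "max_ssim"}
        With a metric stop the iterate maximizing PSNR/SSIM against a
        reference volume is returned.
    """

    n: int = 3
    q: int = 9
    r: int = 4
    p1: float = 40.0 / 255.0
    p2: float = 220.0 / 255.0
    p3: float = 1.96 / 255.0
    p4: float = 0.9
    variant: str = "base"
    max_iterations: int = 15
    stop: str = "fixed"

    def __post_init__(self):
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError(f"n must be odd and >= 3, got {self.n}")
        if not 1 <= self.q <= self.n * self.n:
            raise ValueError(f"q must be in [1, n^2], got {self.q}")
        if not 1 <= self.r <= self.n * self.n - 1:
            raise ValueError(f"r must be in [1, n^2-1], got {self.r}")
        if not 0 <= self.p1 < self.p2:
            raise ValueError(f"need 0 <= p1 < p2, got p1={self.p1}, p2={self.p2}")
        if self.p3 <= 0:
            raise ValueError(f"p3 must be > 0, got {self.p3}")
        if not 0.5 < self.p4 < 1:
            raise ValueError(f"p4 must lie in (0.5, 1), got {self.p4}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.stop not in STOP_MODES:
            raise ValueError(f"stop must be one of {STOP_MODES}, got {self.stop!r}")

    @property
    def skip_center(self) -> bool:
        return self.variant in ("skip_q", "chaotic_skip_q")

    @property
    def in_place(self) -> bool:
        return self.variant in ("chaotic", "chaotic_skip_q")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterParams":
        return cls(**d)


@dataclasses.dataclass
class NeighborSet:
    """The ordered window of one pixel.

    ``neighbor_values``/``distances`` are ordered by ascending absolute
    difference to the centre, the centre itself first (distance 0); ties are
    broken by raster (spatial) index, stably.
    """

    center_value: float
    neighbor_values: list
    distances: list
    window_size: int


@dataclasses.dataclass
class RuleActivation:
    """Truncation levels of the three weight consequents for one neighbour."""

    alpha_M: float
    alpha_H: float
    alpha_L: float


def neighborhood(image: np.ndarray, row: int, col: int, n: int) -> NeighborSet:
    """Extract the (border-truncated) n x n window of ``image`` at (row, col),
    ordered by distance to the centre with the centre first."""
    half = n // 2
    r0, r1 = max(0, row - half), min(image.shape[0], row + half + 1)
    c0, c1 = max(0, col - half), min(image.shape[1], col + half + 1)
    center = float(image[row, col])
    entries = []  # (distance, raster index, value), centre excluded
    idx = 0
    for r in range(r0, r1):
        for c in range(c0, c1):
            if r == row and c == col:
                idx += 1
                continue
            v = float(image[r, c])
            entries.append((abs(v - center), idx, v))
            idx += 1
    entries.sort(key=lambda e: (e[0], e[1]))
    values = [center] + [e[2] for e in entries]
    dists = [0.0] + [e[0] for e in entries]
    return NeighborSet(center, values, dists, window_size=idx)


def road(neigh: NeighborSet, r: int) -> float:
    """Rank-ordered absolute differences: sum of the r smallest absolute
    differences between the centre and its window neighbours.  The centre's
    self-distance occupies rank 0 and contributes nothing; at truncated
    borders fewer than r neighbours may be available, in which case all are
    summed."""
    return float(sum(neigh.distances[1 : 1 + r]))


def impulsivity(road_value: float, p1: float, p2: float) -> float:
    """Fuzzy impulsivity degree: ramp from 0 (ROAD <= p1) to 1 (ROAD >= p2)."""
    if road_value <= p1:
        return 0.0
    if road_value >= p2:
        return 1.0
    return (road_value - p1) / (p2 - p1)


def similarity(L1: float, p3: float) -> tuple[float, float, float]:
    """Similarity memberships (mu_H, mu_M, mu_L) of an absolute difference L1.

    "High" is 1 up to p3 and ramps down to 0 at 4*p3; "low" is its fuzzy
    negation; "moderate" is a trapezoid with plateau on [2*p3, 3*p3].
    """
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
    return mu_h, mu_m, 1.0 - mu_h


def rule_activations(
    delta_i: float, delta_j: float, mu_H: float, mu_M: float, mu_L: float
) -> RuleActivation:
    """Evaluate the three fuzzy rules for one (centre, neighbour) pair.

    Rule 1 (moderate weight): neighbour not impulsive AND centre impulsive AND
    moderate similarity.  Rule 2 (high weight): neighbour not impulsive AND
    (centre impulsive with low similarity OR centre not impulsive with high
    similarity).  Rule 3 (low weight): neighbour impulsive, OR any remaining
    combination.  Connectives: AND = min, OR = max, NOT = 1 - x.
    """
    nj = 1.0 - delta_j
    ni = 1.0 - delta_i
    alpha_m = min(nj, delta_i, mu_M)
    alpha_h = max(min(nj, delta_i, mu_L), min(nj, ni, mu_H))
    alpha_l = max(delta_j, min(nj, delta_i, mu_H), min(nj, ni, mu_M), min(nj, ni, mu_L))
    return RuleActivation(alpha_m, alpha_h, alpha_l)


def _truncated_triangle(a: float, m: float, b: float, alpha: float) -> tuple[float, float]:
    """Area and first moment of min(alpha, tri(a, m, b)) on [a, b], where
    tri is the unit-height triangle with apex at m (a==m or m==b allowed,
    giving right triangles)."""
    if alpha <= 0.0 or b <= a:
        return 0.0, 0.0
    x1 = a + alpha * (m - a)
    x2 = b - alpha * (b - m)
    area = alpha * ((x2 - x1) + 0.5 * (x1 - a) + 0.5 * (b - x2))
    moment = alpha * (x2 * x2 - x1 * x1) / 2.0
    if m > a:
        moment += alpha**3 * (m - a) ** 2 / 3.0 + a * alpha**2 * (m - a) / 2.0
    if b > m:
        moment += b * alpha**2 * (b - m) / 2.0 - alpha**3 * (b - m) ** 2 / 3.0
    return area, moment


def defuzzify_weight(act: RuleActivation, p4: float) -> float:
    """Centre of gravity of the union of the truncated weight consequents.

    Because p4 > 0.5 the supports of the three consequents ("low" on
    [0, 1-p4], "moderate" on [1-p4, p4], "high" on [p4, 1]) have disjoint
    interiors, so the aggregate polygon integrates as the sum of three
    truncated triangles, each with a closed-form area and moment.  Returns 0
    when the aggregate has zero area.
    """
    c = 1.0 - p4
    a_l, m_l = _truncated_triangle(0.0, 0.0, c, act.alpha_L)
    a_m, m_m = _truncated_triangle(c, 0.5, p4, act.alpha_M)
    a_h, m_h = _truncated_triangle(p4, 1.0, 1.0, act.alpha_H)
    area = a_l + a_m + a_h
    if area <= 0.0:
        return 0.0
    return (m_l + m_m + m_h) / area


def pixel_update(neigh: NeighborSet, weights: Sequence[float], variant: str = "base") -> float:
    """Weighted average of the selected pixels (Mamdani output stage).

    ``weights`` aligns with ``neigh.neighbor_values`` (centre at rank 0).
    skip variants drop the centre from both sums.  A zero weight sum leaves
    the centre value unchanged.  Evaluated in the difference form
    ``c + sum(w*(v-c)) / sum(w)`` so that flat windows are exact fixed
    points in floating point.
    """
    start = 1 if variant in ("skip_q", "chaotic_skip_q") else 0
    c = neigh.center_value
    num = 0.0
    den = 0.0
    for w, v in zip(list(weights)[start:], neigh.neighbor_values[start:]):
        num += w * (v - c)
        den += w
    if den <= 0.0:
        return c
    return c + num / den


# ---------------------------------------------------------------------------
# engine drivers
# ---------------------------------------------------------------------------

def _working_dtype(precision: str):
    if precision == "double":
        return np.float64
    if precision == "single":
        return np.float32
    raise ValueError(f"precision must be 'single' or 'double', got {precision!r}")


def filter_image(
    image: np.ndarray,
    params: FilterParams,
    iterations: int | None = None,
    precision: str = "double",
) -> np.ndarray:
    """Filter a single 2-D image for a fixed number of iterations."""
    from ._engine import filter_slice_iterations

    img = np.array(image, dtype=_working_dtype(precision), copy=True)
    its = params.max_iterations if iterations is None else iterations
    return filter_slice_iterations(
        img,
        its,
        params.n,
        params.q,
        params.r,
        params.p1,
        params.p2,
        params.p3,
        params.p4,
        params.skip_center,
        params.in_place,
    )


def filter_volume(
    vol: AttenuationVolume,
    params: FilterParams,
    reference: AttenuationVolume | None = None,
    metrics_config=None,
    callback=None,
    precision: str = "double",
):
    """Filter every slice of a volume with the two-pass iteration engine.

    Each iteration computes, per slice, the impulsivity degree of every pixel
    from the current image (pass A) and only then the fuzzy weights and
    weighted-average updates (pass B), so no weight ever reads a stale or
    partially defined impulsivity.

    Parameters
    ----------
    vol : AttenuationVolume
    params : FilterParams
    reference : AttenuationVolume, optional
        Clean/full-dose volume.  Required for stop in {"max_psnr",
        "max_ssim"}; when present, per-iteration mean PSNR/SSIM are logged.
    metrics_config : MetricsConfig, optional
        How to score iterations against the reference.
    callback : callable, optional
        ``callback(entry_dict)`` invoked after each iteration (used by the
        CLI for JSON-lines logging).
    precision : {"double", "single"}
        Working floating-point precision of the iteration arithmetic.
        Single precision has no visible effect on image quality and exists
        for parity with accelerator backends; results are returned as
        float64 either way.

    Returns
    -------
    (AttenuationVolume, list of dict)
        The filtered volume (the metric-maximizing iterate for metric stops)
        and the per-iteration log.
    """
    from ._engine import filter_volume_once
    from .metrics import MetricsConfig, volume_quality

    if params.stop in ("max_psnr", "max_ssim") and reference is None:
        raise ValueError(f"stop={params.stop!r} requires a reference volume")
    cfg = metrics_config if metrics_config is not None else MetricsConfig()

    current = np.array(vol.voxels, dtype=_working_dtype(precision), copy=True)
    log: list[dict] = []
    best = None
    best_score = -np.inf
    best_iter = 0
    metric_key = "mean_psnr" if params.stop == "max_psnr" else "mean_ssim"

    for it in range(1, params.max_iterations + 1):
        filter_volume_once(current, params)
        entry: dict = {"iteration": it}
        if reference is not None:
            report = volume_quality(vol.with_voxels(current), reference, cfg)
            entry["mean_psnr"] = report.mean_psnr
            entry["mean_ssim"] = report.mean_ssim
        log.append(entry)
        if callback is not None:
            callback(entry)
        if params.stop in ("max_psnr", "max_ssim"):
            score = entry[metric_key]
            if score > best_score:
                best_score = score
                best = current.copy()
                best_iter = it

    if params.stop in ("max_psnr", "max_ssim"):
        out = best
        for e in log:
            e["selected"] = e["iteration"] == best_iter
    else:
        out = current
    return vol.with_voxels(np.asarray(out, dtype=np.float64), source="derived"), log
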