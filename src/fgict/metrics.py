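"""The quality-measurement stack: PSNR, SSIM, normalizations, volume
averaging with air-slice exclusion, and ROI standard deviation.

Two PSNR conventions are provided.  ``standard`` is the usual
10*log10(MAX^2 / MSE).  ``paper_eq11`` divides MAX^2 by the *root* of the
MSE — a non-standard form that appears in print in this literature; it is
kept available behind a flag but is not the default, because reported noisy-
phantom magnitudes are consistent with the standard form.

SSIM follows Wang et al.: local luminance/contrast/structure comparisons
under an 11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03, combined as
l^alpha * c^beta * s^gamma and averaged.  For unit exponents the computation
is delegated to scikit-image; non-unit exponents use an in-package path with
the same windowing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.metrics import structural_similarity

from .volume import AttenuationVolume

__all__ = [
    "MetricsConfig",
    "QualityReport",
    "normalize",
    "psnr",
    "ssim",
    "volume_quality",
    "roi_sd",
    "AIR_THRESHOLD",
]

#: a slice is "air-only" when every normalized reference voxel is below this
AIR_THRESHOLD = 1e-6


@dataclasses.dataclass
class MetricsConfig:
    psnr_variant: str = "standard"  # or "paper_eq11"
    normalization: str = "reference_max"  # or "zero_means", "none"
    ssim_exponents: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ssim_win_size: int = 11
    ssim_sigma: float = 1.5
    data_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if self.psnr_variant not in ("standard", "paper_eq11"):
            raise ValueError(f"unknown psnr_variant {self.psnr_variant!r}")
        if self.normalization not in ("reference_max", "zero_means", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.data_range <= 0:
            raise ValueError("data_range must be > 0")
        if any(e <= 0 for e in self.ssim_exponents):
            raise ValueError("ssim exponents must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ssim_exponents"] = list(self.ssim_exponents)
        return d


@dataclasses.dataclass
class QualityReport:
    per_slice_psnr: list
    per_slice_ssim: list
    mean_psnr: float
    mean_ssim: float
    excluded_slices: list
    config: MetricsConfig

    def to_dict(self) -> dict:
        return {
            "per_slice_psnr": [float(v) for v in self.per_slice_psnr],
            "per_slice_ssim": [float(v) for v in self.per_slice_ssim],
            "mean_psnr": float(self.mean_psnr),
            "mean_ssim": float(self.mean_ssim),
            "excluded_slices": [int(i) for i in self.excluded_slices],
            "config": self.config.to_dict(),
        }


def normalize(arr: np.ndarray, reference: np.ndarray | None, mode: str) -> np.ndarray:
    """Bring an array onto a comparable scale.

    reference_max: divide by the maximum of the reference (both the test and
    the reference volume are divided by the same constant, preserving
    ratios).  zero_means: standardize by the array's *own* mean and standard
    deviation.  none: identity.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if mode == "none":
        return arr
    if mode == "reference_max":
        if reference is None:
            raise ValueError("reference_max normalization needs a reference")
        m = float(np.max(reference))
        if m <= 0:
            raise ValueError("degenerate reference: max must be > 0")
        return arr / m
    if mode == "zero_means":
        sd = float(np.std(arr))
        if sd == 0:
            raise ValueError("degenerate input: zero variance")
        return (arr - float(np.mean(arr))) / sd
    raise ValueError(f"unknown normalization mode {mode!r}")


def psnr(x: np.ndarray, y: np.ndarray, config: MetricsConfig | None = None) -> float:
    """Peak signal-to-noise ratio in dB (+inf for identical inputs)."""
    cfg = config or MetricsConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0:
        return float("inf")
    denom = np.sqrt(mse) if cfg.psnr_variant == "paper_eq11" else mse
    return float(10.0 * np.log10(cfg.data_range**2 / denom))


def _ssim_general(x, y, cfg: MetricsConfig) -> float:
    # general-exponent path; same Gaussian windowing/cropping scheme as the
    # unit-exponent route so the two agree at (1,1,1)
    alpha, beta, gamma = cfg.ssim_exponents
    truncate = ((cfg.ssim_win_size - 1) // 2) / cfg.ssim_sigma
    f = lambda a: gaussian_filter(a, sigma=cfg.ssim_sigma, truncate=truncate)
    ux, uy = f(x), f(y)
    vx = f(x * x) - ux * ux
    vy = f(y * y) - uy * uy
    vxy = f(x * y) - ux * uy
    c1 = (cfg.k1 * cfg.data_range) ** 2
    c2 = (cfg.k2 * cfg.data_range) ** 2
    c3 = c2 / 2.0
    sx = np.sqrt(np.maximum(vx, 0.0))
    sy = np.sqrt(np.maximum(vy, 0.0))
    lum = (2 * ux * uy + c1) / (ux**2 + uy**2 + c1)
    con = (2 * sx * sy + c2) / (vx + vy + c2)
    stru = (vxy + c3) / (sx * sy + c3)
    smap = np.sign(lum) * np.abs(lum) ** alpha
    smap = smap * np.sign(con) * np.abs(con) ** beta
    smap = smap * np.sign(stru) * np.abs(stru) ** gamma
    pad = (cfg.ssim_win_size - 1) // 2
    return float(np.mean(smap[pad:-pad, pad:-pad]))


def ssim(x: np.ndarray, y: np.ndarray, config: MetricsConfig | None = None) -> float:
    """Mean structural similarity of two same-shape 2-D images."""
    cfg = config or MetricsConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if cfg.ssim_exponents != (1.0, 1.0, 1.0):
        return _ssim_general(x, y, cfg)
    return float(
        structural_similarity(
            x,
            y,
            win_size=cfg.ssim_win_size,
            gaussian_weights=True,
            sigma=cfg.ssim_sigma,
            use_sample_covariance=False,
            K1=cfg.k1,
            K2=cfg.k2,
            data_range=cfg.data_range,
        )
    )


def volume_quality(
    vol: AttenuationVolume | np.ndarray,
    reference: AttenuationVolume | np.ndarray,
    config: MetricsConfig | None = None,
) -> QualityReport:
    """Per-slice PSNR/SSIM of a volume against a reference, averaged over the
    slices that are not air-only in the reference.

    Both volumes are first normalized per the config (by default dividing by
    the maximum of the reference, after which the data range is 1).
    """
    cfg = config or MetricsConfig()
    v = vol.voxels if isinstance(vol, AttenuationVolume) else np.asarray(vol)
    ref = reference.voxels if isinstance(reference, AttenuationVolume) else np.asarray(reference)
    if v.shape != ref.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {ref.shape}")
    if cfg.normalization == "reference_max":
        v = normalize(v, ref, "reference_max")
        ref = normalize(ref, ref, "reference_max")
    elif cfg.normalization == "zero_means":
        v = normalize(v, None, "zero_means")
        ref = normalize(ref, None, "zero_means")

    per_psnr, per_ssim, excluded = [], [], []
    for k in range(ref.shape[0]):
        if np.all(np.abs(ref[k]) < AIR_THRESHOLD):
            excluded.append(k)
            continue
        per_psnr.append(psnr(v[k], ref[k], cfg))
        per_ssim.append(ssim(v[k], ref[k], cfg))
    if not per_psnr:
        raise ValueError("all slices are air-only; nothing to average")
    return QualityReport(
        per_slice_psnr=per_psnr,
        per_slice_ssim=per_ssim,
        mean_psnr=float(np.mean(per_psnr)),
        mean_ssim=float(np.mean(per_ssim)),
        excluded_slices=excluded,
        config=cfg,
    )


def roi_sd(
    vol: AttenuationVolume | np.ndarray,
    roi: tuple[int, int, int, int],
    slices: list[int] | None = None,
) -> list[float]:
    """Population standard deviation inside a rectangular ROI, per slice.

    ``roi`` is (row_start, row_stop, col_start, col_stop), half-open.
    """
    v = vol.voxels if isinstance(vol, AttenuationVolume) else np.asarray(vol)
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= v.shape[1] and 0 <= c0 < c1 <= v.shape[2]):
        raise ValueError(f"ROI {roi} out of bounds or empty for shape {v.shape}")
    idx = range(v.shape[0]) if slices is None else slices
    return [float(np.std(v[k, r0:r1, c0:c1])) for k in idx]
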