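"""Synthetic ground truth and corruption models.

Provides the 3-D Shepp-Logan head phantom (ten ellipsoids in the Kak-Slaney
geometry with the standard "modified" gray levels, which lie natively in
[0, 1]) and seeded noise injectors for the corruption types used in the
phantom experiments: clipped additive Gaussian noise, fixed-value
salt-and-pepper (impulsive) noise, their combination, and scaled Poisson
(photon-counting) noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume import AttenuationVolume, DEFAULT_MU_WATER

__all__ = ["NoiseSpec", "shepp_logan_3d", "add_noise", "SHEPP_LOGAN_ELLIPSOIDS"]

#: (intensity, a, b, c, x0, y0, z0, phi_deg) — semi-axes along (x, y, z),
#: centres in the [-1, 1]^3 cube, rotation phi about the z (slice) axis.
#: Kak-Slaney ellipsoid geometry with the "modified Shepp-Logan" gray levels.
SHEPP_LOGAN_ELLIPSOIDS: tuple[tuple[float, ...], ...] = (
    (1.00, 0.6900, 0.9200, 0.810, 0.00, 0.0000, 0.00, 0.0),
    (-0.80, 0.6624, 0.8740, 0.780, 0.00, -0.0184, 0.00, 0.0),
    (-0.20, 0.1100, 0.3100, 0.220, 0.22, 0.0000, 0.00, -18.0),
    (-0.20, 0.1600, 0.4100, 0.280, -0.22, 0.0000, 0.00, 18.0),
    (0.10, 0.2100, 0.2500, 0.410, 0.00, 0.3500, -0.15, 0.0),
    (0.10, 0.0460, 0.0460, 0.050, 0.00, 0.1000, 0.25, 0.0),
    (0.10, 0.0460, 0.0460, 0.050, 0.00, -0.1000, 0.25, 0.0),
    (0.10, 0.0460, 0.0230, 0.050, -0.08, -0.6050, 0.00, 0.0),
    (0.10, 0.0230, 0.0230, 0.020, 0.00, -0.6060, 0.00, 0.0),
    (0.10, 0.0230, 0.0460, 0.020, 0.06, -0.6050, 0.00, 0.0),
)


def shepp_logan_3d(n_rows: int = 256, n_cols: int = 256, n_slices: int = 64) -> AttenuationVolume:
    """Generate the 3-D Shepp-Logan phantom on an (n_slices, n_rows, n_cols)
    grid sampling [-1, 1]^3, intensities clipped to [0, 1].

    Ellipsoid intensities are additive, so e.g. the brain interior is
    1.0 - 0.8 = 0.2.  Slices beyond the outer ellipsoid's z extent
    (|z| > 0.81) contain only air (exact zeros).
    """
    if min(n_rows, n_cols, n_slices) < 16:
        raise ValueError("phantom dimensions must be >= 16")
    x = np.linspace(-1.0, 1.0, n_cols)
    y = np.linspace(-1.0, 1.0, n_rows)
    z = np.linspace(-1.0, 1.0, n_slices)
    xx, yy = np.meshgrid(x, y)  # (n_rows, n_cols)
    vol = np.zeros((n_slices, n_rows, n_cols), dtype=np.float64)
    for inten, a, b, c, x0, y0, z0, phi_deg in SHEPP_LOGAN_ELLIPSOIDS:
        phi = np.deg2rad(phi_deg)
        cphi, sphi = np.cos(phi), np.sin(phi)
        xr = cphi * (xx - x0) + sphi * (yy - y0)
        yr = -sphi * (xx - x0) + cphi * (yy - y0)
        planar = (xr / a) ** 2 + (yr / b) ** 2  # shared by all slices
        for k in range(n_slices):
            zz = (z[k] - z0) / c
            if abs(zz) > 1.0:
                continue
            inside = planar + zz * zz <= 1.0
            vol[k][inside] += inten
    np.clip(vol, 0.0, 1.0, out=vol)
    return AttenuationVolume(vol, mu_water=DEFAULT_MU_WATER, source="phantom")


NOISE_KINDS = ("gaussian", "impulsive", "gaussian_impulsive", "poisson")


@dataclasses.dataclass
class NoiseSpec:
    """Seeded description of one synthetic corruption.

    sigma2 applies to Gaussian kinds (variance on the [0,1] scale), density
    to impulsive kinds (fraction of pixels replaced by 0 or 1, equiprobably),
    peak to Poisson (photon count associated with intensity 1).  The same
    spec always produces the bit-identical corrupted volume.
    """

    kind: str
    sigma2: float | None = None
    density: float | None = None
    peak: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"kind must be one of {NOISE_KINDS}, got {self.kind!r}")
        needs_sigma = self.kind in ("gaussian", "gaussian_impulsive")
        needs_density = self.kind in ("impulsive", "gaussian_impulsive")
        needs_peak = self.kind == "poisson"
        if needs_sigma != (self.sigma2 is not None):
            raise ValueError(f"sigma2 must be set iff kind involves gaussian ({self.kind})")
        if needs_density != (self.density is not None):
            raise ValueError(f"density must be set iff kind involves impulsive ({self.kind})")
        if needs_peak != (self.peak is not None):
            raise ValueError(f"peak must be set iff kind is poisson ({self.kind})")
        if self.sigma2 is not None and self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.density is not None and not 0 <= self.density <= 1:
            raise ValueError("density must lie in [0, 1]")
        if self.peak is not None and self.peak <= 0:
            raise ValueError("peak must be > 0")

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(**d)


def _add_gaussian(voxels: np.ndarray, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    if sigma2 == 0:
        return voxels.copy()
    noisy = voxels + rng.normal(0.0, np.sqrt(sigma2), size=voxels.shape)
    return np.clip(noisy, 0.0, 1.0)


def _add_impulsive(voxels: np.ndarray, density: float, rng: np.random.Generator) -> np.ndarray:
    out = voxels.copy()
    n = out.size
    n_hit = int(round(density * n))
    if n_hit == 0:
        return out
    flat = rng.choice(n, size=n_hit, replace=False)
    values = rng.integers(0, 2, size=n_hit).astype(np.float64)  # salt or pepper
    out.reshape(-1)[flat] = values
    return out


def add_noise(vol: AttenuationVolume, spec: NoiseSpec) -> AttenuationVolume:
    """Corrupt a [0,1]-scaled volume according to ``spec`` (fully seeded).

    gaussian: add i.i.d. N(0, sigma2) then clip to [0,1].  impulsive: replace
    a ``density`` fraction of pixels with 0 or 1.  gaussian_impulsive:
    gaussian first, then impulsive.  poisson: draw Poisson(peak * v) / peak
    per voxel and clip to [0,1].
    """
    v = np.asarray(vol.voxels, dtype=np.float64)
    if v.min() < 0 or v.max() > 1:
        raise ValueError("add_noise expects a volume on the [0, 1] scale")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian":
        noisy = _add_gaussian(v, spec.sigma2, rng)
    elif spec.kind == "impulsive":
        noisy = _add_impulsive(v, spec.density, rng)
    elif spec.kind == "gaussian_impulsive":
        noisy = _add_impulsive(_add_gaussian(v, spec.sigma2, rng), spec.density, rng)
    else:  # poisson
        noisy = np.clip(rng.poisson(spec.peak * v) / spec.peak, 0.0, 1.0)
    return vol.with_voxels(noisy, source="derived")
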