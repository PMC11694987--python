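"""Calibrate the impulsivity thresholds p1, p2.

The impulsivity ramp thresholds are scan-scale dependent and are not fixed by
theory; this script selects them by grid search, maximizing the mean SSIM of
the filtered phantom under mixed Gaussian-impulsive noise (the corruption
type the thresholds exist to separate: the ROAD of a Gaussian-noise pixel
must stay below p1 while the ROAD of an impulse must exceed p2).

The search runs on a reduced phantom (128x128x32) to keep the grid cheap;
the selected values are printed and shipped as the FilterParams defaults.

Usage: python scripts/calibrate_p1p2.py [--seed N]
"""

import argparse
import itertools

from fgict import FilterParams, MetricsConfig, NoiseSpec, add_noise, shepp_logan_3d
from fgict.fgi import filter_volume
from fgict.metrics import volume_quality

P1_GRID = [10, 20, 40, 60, 80]  # /255
P2_GRID = [120, 160, 200, 220, 240]  # /255


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--size", type=int, nargs=3, default=(128, 128, 32))
    ap.add_argument("--iterations", type=int, default=15)
    args = ap.parse_args()

    clean = shepp_logan_3d(*args.size)
    noisy = add_noise(
        clean, NoiseSpec("gaussian_impulsive", sigma2=0.0005, density=0.10, seed=args.seed)
    )
    cfg = MetricsConfig()

    best = None
    for p1_255, p2_255 in itertools.product(P1_GRID, P2_GRID):
        if p1_255 >= p2_255:
            continue
        params = FilterParams(
            p1=p1_255 / 255.0, p2=p2_255 / 255.0, max_iterations=args.iterations
        )
        filtered, _ = filter_volume(noisy, params)
        report = volume_quality(filtered, clean, cfg)
        print(
            f"p1={p1_255:3d}/255 p2={p2_255:3d}/255  "
            f"PSNR {report.mean_psnr:7.3f}  SSIM {report.mean_ssim:.4f}",
            flush=True,
        )
        if best is None or report.mean_ssim > best[0]:
            best = (report.mean_ssim, p1_255, p2_255)

    print(f"\nselected: p1={best[1]}/255, p2={best[2]}/255 (SSIM {best[0]:.4f})")


if __name__ == "__main__":
    main()
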