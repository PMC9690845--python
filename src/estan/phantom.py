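"""Synthetic breast-ultrasound phantoms with ground-truth tumor masks.

Each phantom mimics the gross structure of a B-mode breast image: four
vertically stacked tissue bands (skin, premammary fat, mammary,
retromammary) with distinct mean echogenicity, a hypoechoic tumor seated
in the mammary band, an optional posterior shadow, and a smoothed
unit-mean gamma multiplicative field standing in for speckle. The tumor is
a rotated ellipse whose radius is perturbed by a low-order random harmonic
series, giving the irregular boundaries real lesions show; its realized
longest-axis length is calibrated to the requested value so generated
datasets land in the intended size groups.

This is a geometry-and-texture phantom, not a wave-propagation simulation:
it reproduces layered anatomy, contrast and multiplicative noise, but none
of the acoustic physics (refraction, reverberation, device-specific
post-processing).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import PhantomConfig
from .dataio import ImageSample, tumor_longest_axis

_HARMONIC_ORDERS = (2, 3, 4, 5)
_AXIS_TOL = 0.10          # realized longest axis within 10% of requested
_CALIBRATION_ROUNDS = 4


@dataclass
class PhantomSample:
    image: np.ndarray        # float64 in [0, 1]
    mask: np.ndarray         # uint8 in {0, 1}
    true_axis_px: float      # realized Feret diameter of the mask
    config: PhantomConfig

    def to_image_sample(self, sample_id: str) -> ImageSample:
        return ImageSample(id=sample_id, image=self.image, mask=self.mask,
                           axis_px=self.true_axis_px)


def _band_boundaries(cfg: PhantomConfig) -> np.ndarray:
    """Row indices of the four band boundaries, top to bottom (length 5)."""
    edges = np.round(np.cumsum((0.0,) + tuple(cfg.layer_fractions)) * cfg.height)
    edges = edges.astype(int)
    edges[-1] = cfg.height
    return edges


def mammary_band_rows(cfg: PhantomConfig) -> tuple[int, int]:
    """Half-open row range [top, bottom) of the mammary band (third layer)."""
    edges = _band_boundaries(cfg)
    return int(edges[2]), int(edges[3])


def _tumor_mask(cfg: PhantomConfig, center: tuple[float, float],
                semi_major: float, coeffs: np.ndarray,
                phases: np.ndarray) -> np.ndarray:
    """Rasterize the perturbed ellipse: rho(theta) <= 1 + delta(theta)."""
    a = semi_major
    b = cfg.tumor_aspect * a
    cr, cc = center
    rows = np.arange(cfg.height)[:, None] - cr
    cols = np.arange(cfg.width)[None, :] - cc
    ca, sa = math.cos(cfg.tumor_angle), math.sin(cfg.tumor_angle)
    u = cols * ca + rows * sa
    v = -cols * sa + rows * ca
    rho = np.hypot(u / a, v / b)
    if cfg.boundary_irregularity > 0:
        theta = np.arctan2(v / b, u / a)
        delta = np.zeros_like(theta)
        for k, c, p in zip(_HARMONIC_ORDERS, coeffs, phases):
            delta += c * np.cos(k * theta + p)
        limit = np.abs(delta).max()
        if limit > 0:
            delta *= cfg.boundary_irregularity / limit
        rho = rho / (1.0 + delta)
    return (rho <= 1.0).astype(np.uint8)


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom; bit-identical for a fixed (config, seed).

    Raises ValueError if the tumor cannot fit inside the image at the
    requested size/orientation, naming the offending dimensions.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    edges = _band_boundaries(cfg)

    # clean band template
    template = np.empty((cfg.height, cfg.width), dtype=np.float64)
    for i in range(4):
        template[edges[i]:edges[i + 1], :] = cfg.layer_means[i]

    # tumor geometry: bounding half-extents of the rotated, perturbed ellipse
    a0 = cfg.tumor_axis_px / 2.0
    b0 = cfg.tumor_aspect * a0
    ca, sa = math.cos(cfg.tumor_angle), math.sin(cfg.tumor_angle)
    grow = 1.0 + cfg.boundary_irregularity
    ext_c = math.hypot(a0 * ca, b0 * sa) * grow   # column half-extent
    ext_r = math.hypot(a0 * sa, b0 * ca) * grow   # row half-extent
    if 2 * ext_c >= cfg.width or 2 * ext_r >= cfg.height:
        raise ValueError(
            f"tumor (extent {2 * ext_r:.0f}x{2 * ext_c:.0f} px) does not fit in "
            f"a {cfg.height}x{cfg.width} image")

    mam_top, mam_bot = mammary_band_rows(cfg)
    if cfg.tumor_center is not None:
        cr, cc = map(float, cfg.tumor_center)
        if not (mam_top <= cr < mam_bot):
            raise ValueError(
                f"tumor center row {cr} outside mammary band [{mam_top}, {mam_bot})")
    else:
        # random center: tumor kept wholly inside the mammary band when it
        # fits, otherwise centred mid-band (the mask may then overrun the band)
        lo_r = max(mam_top + ext_r + 1, ext_r + 1)
        hi_r = min(mam_bot - ext_r - 1, cfg.height - ext_r - 1)
        if hi_r <= lo_r:
            lo_r = hi_r = (mam_top + mam_bot) / 2.0
        lo_c, hi_c = ext_c + 1, cfg.width - ext_c - 1
        cr = float(rng.uniform(lo_r, hi_r)) if hi_r > lo_r else float(lo_r)
        cc = float(rng.uniform(lo_c, hi_c))
    coeffs = rng.normal(size=len(_HARMONIC_ORDERS))
    phases = rng.uniform(0, 2 * math.pi, size=len(_HARMONIC_ORDERS))

    # rasterize and calibrate the realized Feret diameter to the request
    semi = a0
    mask = _tumor_mask(cfg, (cr, cc), semi, coeffs, phases)
    for _ in range(_CALIBRATION_ROUNDS):
        if not mask.any():
            raise ValueError(
                f"tumor of axis {cfg.tumor_axis_px} px rasterized to an empty "
                f"mask on a {cfg.height}x{cfg.width} grid")
        realized = tumor_longest_axis(mask)
        if realized > 0 and abs(realized - cfg.tumor_axis_px) <= 0.02 * cfg.tumor_axis_px:
            break
        if realized <= 0:
            semi *= 1.5
        else:
            semi *= cfg.tumor_axis_px / realized
        mask = _tumor_mask(cfg, (cr, cc), semi, coeffs, phases)
    realized = tumor_longest_axis(mask)

    clean = template.copy()
    clean[mask == 1] = np.maximum(clean[mask == 1] - cfg.tumor_contrast, 0.0)

    if cfg.shadow_strength > 0:
        tau = max(cfg.height / 10.0, 1.0)
        cols = np.where(mask.any(axis=0))[0]
        for c in cols:
            bottom = np.where(mask[:, c])[0].max()
            depth = np.arange(cfg.height - bottom - 1, dtype=np.float64) + 1.0
            atten = 1.0 - cfg.shadow_strength * (1.0 - np.exp(-depth / tau))
            clean[bottom + 1:, c] *= atten

    if cfg.speckle_enabled:
        field = rng.gamma(cfg.speckle_shape, 1.0 / cfg.speckle_shape,
                          size=(cfg.height, cfg.width))
        if cfg.speckle_smoothing_sigma > 0:
            field = gaussian_filter(field, cfg.speckle_smoothing_sigma)
        field /= field.mean()
        image = np.clip(clean * field, 0.0, 1.0)
    else:
        image = np.clip(clean, 0.0, 1.0)

    return PhantomSample(image=image, mask=mask, true_axis_px=realized, config=cfg)


def default_size_sampler(rng: np.random.Generator,
                         reference_px: float = 500.0) -> float:
    """Right-skewed longest-axis distribution: log-normal with mode 130 px
    at the 500-px reference resolution (sigma 0.45), clipped to [30, 320]
    px, so most tumors fall below 150 px with a long right tail. For other
    image sizes the whole distribution scales proportionally."""
    sigma = 0.45
    scale = reference_px / 500.0
    mu = math.log(130.0 * scale) + sigma ** 2
    return float(np.clip(rng.lognormal(mu, sigma), 30.0 * scale, 320.0 * scale))


def generate_dataset(n: int,
                     size_sampler: Callable[[np.random.Generator], float] | None = None,
                     base_config: PhantomConfig | None = None,
                     seed: int = 0) -> list[PhantomSample]:
    """Generate n phantoms with randomized geometry.

    Axis lengths come from ``size_sampler`` (default: right-skewed
    log-normal); aspect, orientation, boundary irregularity and contrast
    are drawn per sample from realistic ranges. Per-sample seeds are
    derived from the master seed, so the whole list is reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    base = (base_config or PhantomConfig()).validate()
    if size_sampler is None:
        ref = float(min(base.height, base.width))
        sampler = lambda rng: default_size_sampler(rng, reference_px=ref)
    else:
        sampler = size_sampler
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    samples = []
    for i in range(n):
        axis = float(sampler(rng))
        cfg = dataclasses.replace(
            base,
            tumor_axis_px=axis,
            tumor_aspect=float(rng.uniform(0.45, 0.85)),
            tumor_angle=float(rng.uniform(-math.pi / 6, math.pi / 6)),
            boundary_irregularity=float(rng.uniform(0.05, 0.25)),
            tumor_contrast=float(rng.uniform(0.25, 0.45)),
            tumor_center=None,
            seed=int(child_seeds[i]),
        )
        samples.append(generate_phantom(cfg))
    return samples


def write_dataset(samples: Sequence[PhantomSample], out_dir: str | Path) -> Path:
    """Write 8-bit PNG image/mask pairs plus a manifest CSV; returns the
    manifest path. Masks are stored as {0, 255}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        img_name, mask_name = f"img_{i:04d}.png", f"mask_{i:04d}.png"
        iio.imwrite(out / img_name, np.round(s.image * 255).astype(np.uint8))
        iio.imwrite(out / mask_name, (s.mask * 255).astype(np.uint8))
        rows.append({"image_path": img_name, "mask_path": mask_name,
                     "id": f"phantom_{i:04d}", "true_axis_px": s.true_axis_px})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
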