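"""Seeded generators for synthetic micrographs and tabular datasets.

The generators emulate the data the analysis pipeline consumes:

* 4x-magnification hematoxylin–eosin-like RGB micrographs containing four
  texturally distinct regions — background, type I collagen, extracellular
  matrix and cell nuclei — together with pixel-exact ground-truth label
  masks;
* a 0–44 day image series whose composition drifts the way a colonised
  scaffold does (extracellular matrix grows, collagen shrinks);
* mass-loss-versus-time records following a k-component logistic mixture;
* per-image feature tables following the log-linear mass-loss model.

Every generator is a pure function of its parameters and seed: the same
inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._utils import (
    CLASS_NAMES,
    DEFAULT_PIXEL_SCALE_UM,
    LABEL_BACKGROUND,
    LABEL_COLLAGEN,
    LABEL_ECM,
    LABEL_NUCLEI,
    N_CLASSES,
    ValidationError,
    check,
    rng_from_seed,
    spawn_seeds,
)
from .kinetics import mixture_predict

__all__ = [
    "ClassTexture",
    "SyntheticImageParams",
    "SyntheticSeriesParams",
    "MassLossSimSpec",
    "FeatureTableSimSpec",
    "Micrograph",
    "generate_micrograph",
    "generate_series",
    "simulate_mass_loss",
    "simulate_feature_table",
]


@dataclass(frozen=True)
class ClassTexture:
    """Appearance of one tissue class: base colour plus correlated noise.

    The noise is smoothed white noise at ``grain_px`` length-scale, so
    classes can differ in *texture* (entropy, gradient structure), not only
    in mean colour — the premise the texture features rely on.
    """

    mean_rgb: tuple[float, float, float]
    noise_sd: float = 12.0
    grain_px: float = 2.0

    def __post_init__(self):
        check(len(self.mean_rgb) == 3, "mean_rgb must have 3 components")
        check(self.noise_sd >= 0, "noise_sd must be >= 0")
        check(self.grain_px > 0, "grain_px must be > 0")


#: Hematoxylin–eosin-like default palette, indexed by label
#: (0 background, 1 collagen, 2 extracellular matrix, 3 nuclei).
DEFAULT_TEXTURES = (
    ClassTexture((243.0, 243.0, 245.0), noise_sd=4.0, grain_px=1.5),   # background
    ClassTexture((232.0, 158.0, 186.0), noise_sd=14.0, grain_px=3.0),  # collagen (eosin pink)
    ClassTexture((196.0, 130.0, 202.0), noise_sd=22.0, grain_px=1.2),  # ECM (purple-pink)
    ClassTexture((88.0, 52.0, 134.0), noise_sd=10.0, grain_px=1.0),    # nuclei (hematoxylin)
)


@dataclass(frozen=True)
class Micrograph:
    """An RGB image with its physical scale and experimental annotation."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    time_days: float | None = None
    group: str | None = None


@dataclass(frozen=True)
class SyntheticImageParams:
    """Parameters of one synthetic micrograph.

    ``class_fractions`` are target area fractions indexed by label
    (background, collagen, extracellular matrix, nuclei) and must sum to 1.
    ``nuclei_count`` caps the number of nuclear blobs drawn; drawing stops
    as soon as the nuclei area budget implied by ``class_fractions`` is met.
    """

    width_px: int = 128
    height_px: int = 128
    class_fractions: tuple[float, float, float, float] = (0.15, 0.45, 0.35, 0.05)
    textures: tuple[ClassTexture, ...] = DEFAULT_TEXTURES
    region_scale_px: float = 12.0
    nuclei_count: int = 10_000
    nuclei_radius_px: float = 4.0
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    seed: int = 0

    def __post_init__(self):
        check(self.width_px >= 64 and self.height_px >= 64,
              "image dimensions must be >= 64 px")
        f = np.asarray(self.class_fractions, dtype=float)
        check(f.shape == (N_CLASSES,), "class_fractions must have 4 entries")
        check(np.all(f >= 0), "class_fractions must be nonnegative")
        check(abs(f.sum() - 1.0) <= 1e-9, "class_fractions must sum to 1")
        check(len(self.textures) == N_CLASSES, "one texture per class required")
        check(self.nuclei_radius_px >= 1, "nuclei_radius_px must be >= 1")
        check(self.nuclei_count >= 0, "nuclei_count must be >= 0")


@dataclass(frozen=True)
class SyntheticSeriesParams:
    """A time series of synthetic micrographs over a degradation experiment.

    ``composition_trend`` maps each time point to a 4-vector of class
    fractions (label order).  Across the series the extracellular-matrix
    fraction must be nondecreasing and the collagen fraction nonincreasing,
    mirroring the observed colonisation trend.
    """

    times_days: tuple[float, ...]
    composition_trend: tuple[tuple[float, float, float, float], ...]
    image_params: SyntheticImageParams = field(default_factory=SyntheticImageParams)
    group: str = "CCO"
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.times_days, dtype=float)
        check(t.size >= 1, "at least one time point required")
        check(np.all(t >= 0) and np.all(t <= 44), "times must lie in [0, 44] days")
        check(np.all(np.diff(t) > 0), "times must be strictly increasing")
        check(len(self.composition_trend) == t.size,
              "one class-fraction vector per time point required")
        fracs = np.asarray(self.composition_trend, dtype=float)
        check(fracs.shape == (t.size, N_CLASSES), "fractions must be 4-vectors")
        check(np.all(fracs >= 0), "fractions must be nonnegative")
        check(np.allclose(fracs.sum(axis=1), 1.0, atol=1e-9),
              "fractions must sum to 1 at every time")
        if t.size > 1:
            check(np.all(np.diff(fracs[:, LABEL_ECM]) >= -1e-12),
                  "extracellular-matrix fraction must be nondecreasing in time")
            check(np.all(np.diff(fracs[:, LABEL_COLLAGEN]) <= 1e-12),
                  "collagen fraction must be nonincreasing in time")


@dataclass(frozen=True)
class MassLossSimSpec:
    """Mass-loss observations from a k-component logistic mixture.

    ``theta`` is the flat parameter vector (A_1, mu_1, scal_1, ..., A_k,
    mu_k, scal_k) in % mass loss and days.
    """

    theta: tuple[float, ...]
    times_days: tuple[float, ...]
    noise_sd: float = 0.0
    group: str = "CCO"
    seed: int = 0

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        check(th.size >= 3 and th.size % 3 == 0,
              "theta must have 3k entries for k >= 1 components")
        comps = th.reshape(-1, 3)
        check(np.all(comps[:, 0] > 0), "asymptotes A_i must be > 0")
        check(np.all(comps[:, 2] > 0), "scale parameters scal_i must be > 0")
        check(len(self.times_days) >= 1, "at least one time required")
        check(self.noise_sd >= 0, "noise_sd must be >= 0")


@dataclass(frozen=True)
class FeatureTableSimSpec:
    """Per-image feature tables on the multivariate log-linear model.

    Mass loss is generated as

        intercept + b_CCT*CCT + b_CO*CO + b_circ*ln(circularity)
        + b_mode*ln(mode) + b_area*ln(area) + noise

    with CCO the reference group (both dummies zero).  Predictors are drawn
    log-uniformly within their (strictly positive) ranges.
    """

    coefficients: dict[str, float]
    n_per_group: int = 20
    circularity_range: tuple[float, float] = (0.02, 0.9)
    mode_range: tuple[float, float] = (40.0, 240.0)
    area_range: tuple[float, float] = (50.0, 5000.0)
    noise_sd: float = 0.0
    seed: int = 0

    _REQUIRED = ("intercept", "CCT", "CO", "ln_circularity", "ln_mode", "ln_area")

    def __post_init__(self):
        missing = [k for k in self._REQUIRED if k not in self.coefficients]
        check(not missing, f"coefficients missing entries: {missing}")
        for name in ("circularity_range", "mode_range", "area_range"):
            lo, hi = getattr(self, name)
            check(0 < lo <= hi, f"{name} must be strictly positive and ordered")
        check(self.n_per_group >= 1, "n_per_group must be >= 1")
        check(self.noise_sd >= 0, "noise_sd must be >= 0")


def _correlated_noise(rng, shape, grain_px):
    """Smoothed white noise standardised to zero mean, unit variance."""
    raw = rng.standard_normal(shape)
    if grain_px > 0.3:
        raw = gaussian_filter(raw, sigma=grain_px, mode="reflect")
    sd = raw.std()
    if sd == 0:  # pathological tiny image; keep the raw field
        return raw
    return (raw - raw.mean()) / sd


def _place_nuclei(rng, mask, params: SyntheticImageParams) -> None:
    """Overlay quasi-elliptical nuclear blobs in place until the nuclei
    area budget is met (or ``nuclei_count`` blobs have been drawn).

    Nuclei sit on top of the tissue in stained sections, so they win every
    overlap.
    """
    h, w = mask.shape
    target = params.class_fractions[LABEL_NUCLEI] * h * w
    if target <= 0 or params.nuclei_count == 0:
        return
    yy, xx = np.mgrid[0:h, 0:w]
    covered = 0
    for _ in range(params.nuclei_count):
        if covered >= target:
            break
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = params.nuclei_radius_px
        a = r * rng.uniform(0.7, 1.3)
        b = r * rng.uniform(0.7, 1.3)
        phi = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(phi) + dx * np.sin(phi)
        v = -dy * np.sin(phi) + dx * np.cos(phi)
        blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        covered += int(np.count_nonzero(blob & (mask != LABEL_NUCLEI)))
        mask[blob] = LABEL_NUCLEI


def generate_micrograph(params: SyntheticImageParams) -> tuple[Micrograph, np.ndarray]:
    """Generate one synthetic micrograph with its ground-truth label mask.

    Region geometry comes from quantile-thresholding a smooth random field,
    so realised tissue-class areas track ``class_fractions`` closely (within
    a few tenths of a percentage point for the field-based classes; nuclei
    overshoot by at most one blob).  Returns ``(micrograph, mask)`` where
    ``mask`` is (H, W) uint8 with labels 0=background, 1=collagen, 2=ECM,
    3=nuclei.
    """
    rng = rng_from_seed(params.seed)
    h, w = params.height_px, params.width_px
    fracs = np.asarray(params.class_fractions, dtype=float)

    # --- geometry: smooth field -> quantile bands for the non-nuclei classes
    field_vals = _correlated_noise(rng, (h, w), params.region_scale_px)
    # tiny jitter breaks ties so quantile cuts land exactly
    field_vals = field_vals + rng.uniform(-1e-9, 1e-9, size=(h, w))
    base_labels = (LABEL_BACKGROUND, LABEL_COLLAGEN, LABEL_ECM)
    base_fracs = fracs[list(base_labels)]
    total_base = base_fracs.sum()
    if total_base <= 0:
        mask = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)
    else:
        shares = base_fracs / total_base
        cuts = np.quantile(field_vals, np.cumsum(shares)[:-1])
        bands = np.searchsorted(cuts, field_vals, side="right")
        mask = np.empty((h, w), dtype=np.uint8)
        for band, lab in enumerate(base_labels):
            mask[bands == band] = lab

    _place_nuclei(rng, mask, params)

    # --- appearance: per-class base colour + correlated colour noise
    img = np.zeros((h, w, 3), dtype=np.float64)
    for lab in range(N_CLASSES):
        tex = params.textures[lab]
        sel = mask == lab
        if not np.any(sel):
            continue
        patch = np.tile(np.asarray(tex.mean_rgb, float), (h, w, 1))
        if tex.noise_sd > 0:
            for c in range(3):
                patch[..., c] += tex.noise_sd * _correlated_noise(
                    rng, (h, w), tex.grain_px)
        img[sel] = patch[sel]
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    micro = Micrograph(pixels=pixels, pixel_scale_um=params.pixel_scale_um)
    return micro, mask


def generate_series(
    params: SyntheticSeriesParams,
) -> list[tuple[Micrograph, np.ndarray, float]]:
    """Generate a degradation image series: one (micrograph, mask, time)
    per time point, with composition following ``composition_trend``."""
    seeds = spawn_seeds(params.seed, len(params.times_days))
    out = []
    for t, fr, s in zip(params.times_days, params.composition_trend, seeds):
        p = SyntheticImageParams(
            width_px=params.image_params.width_px,
            height_px=params.image_params.height_px,
            class_fractions=tuple(fr),
            textures=params.image_params.textures,
            region_scale_px=params.image_params.region_scale_px,
            nuclei_count=params.image_params.nuclei_count,
            nuclei_radius_px=params.image_params.nuclei_radius_px,
            pixel_scale_um=params.image_params.pixel_scale_um,
            seed=s,
        )
        micro, mask = generate_micrograph(p)
        micro = Micrograph(pixels=micro.pixels,
                           pixel_scale_um=micro.pixel_scale_um,
                           time_days=float(t), group=params.group)
        out.append((micro, mask, float(t)))
    return out


def simulate_mass_loss(spec: MassLossSimSpec) -> pd.DataFrame:
    """Simulate mass-loss records: logistic-mixture mean plus Gaussian noise.

    With ``noise_sd == 0`` the records reproduce the mixture mean exactly.
    Returns a DataFrame with columns (time_days, group, mass_loss_pct).
    """
    rng = rng_from_seed(spec.seed)
    t = np.asarray(spec.times_days, dtype=float)
    theta = np.asarray(spec.theta, dtype=float)
    mean = mixture_predict(t, theta)
    noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else 0.0
    return pd.DataFrame({
        "time_days": t,
        "group": spec.group,
        "mass_loss_pct": mean + noise,
    })


def simulate_feature_table(spec: FeatureTableSimSpec) -> pd.DataFrame:
    """Simulate a per-image feature table on the multivariate log-linear
    model, with CCO as the reference group for the dummy coding.

    Returns columns (group, mean_circularity, gray_mode, mean_area_um2,
    mass_loss_pct).
    """
    rng = rng_from_seed(spec.seed)
    groups, circ, mode, area = [], [], [], []
    for g in ("CCO", "CCT", "CO"):
        groups += [g] * spec.n_per_group
        circ.append(np.exp(rng.uniform(*np.log(spec.circularity_range),
                                       size=spec.n_per_group)))
        mode.append(np.exp(rng.uniform(*np.log(spec.mode_range),
                                       size=spec.n_per_group)))
        area.append(np.exp(rng.uniform(*np.log(spec.area_range),
                                       size=spec.n_per_group)))
    circ = np.concatenate(circ)
    mode = np.concatenate(mode)
    area = np.concatenate(area)
    if np.any(circ <= 0) or np.any(mode <= 0) or np.any(area <= 0):
        raise ValidationError("predictor draws must be strictly positive")
    g = np.asarray(groups)
    c = spec.coefficients
    eta = (c["intercept"]
           + c["CCT"] * (g == "CCT")
           + c["CO"] * (g == "CO")
           + c["ln_circularity"] * np.log(circ)
           + c["ln_mode"] * np.log(mode)
           + c["ln_area"] * np.log(area))
    noise = rng.normal(0.0, spec.noise_sd, size=g.size) if spec.noise_sd > 0 else 0.0
    return pd.DataFrame({
        "group": g,
        "mean_circularity": circ,
        "gray_mode": mode,
        "mean_area_um2": area,
        "mass_loss_pct": eta + noise,
    })
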