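"""End-to-end orchestration: images -> segmentation -> features -> models.

``run_pipeline`` drives the full analysis from a single structured config
(a YAML/dict): generate or load a micrograph series, segment every image
with a texture-feature random forest, extract extracellular-matrix object
features, fit the degradation models (logistic mixture with bootstrap
intervals, P-spline GAM, log-linear models) and write a report bundle
whose manifest records the seed, config hash and library versions, so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import (
    DEFAULT_PIXEL_SCALE_UM,
    LABEL_ECM,
    ValidationError,
    check,
    spawn_seeds,
)
from .gam import fit_gam
from .kinetics import bootstrap_parameters, fit_mixture
from .linear import MassLossLinearModel, kfold_predictions, relative_importance_lmg
from .roi import extract_objects, summarize_image
from .segmentation import (
    RandomForestPixelSegmenter,
    confusion_and_metrics,
    misclassification_error,
    sample_training_pixels,
)
from .synthetic import (
    MassLossSimSpec,
    SyntheticImageParams,
    SyntheticSeriesParams,
    generate_series,
    simulate_mass_loss,
)
from .texture import TextureFeatureExtractor

log = logging.getLogger(__name__)

#: Two-component logistic mixture used by the demo series (asymptote %,
#: inflection day, scale days per component).
DEMO_THETA = (50.0, 2.0, 1.0, 23.0, 16.0, 1.5)


@dataclass
class PipelineConfig:
    """Structured configuration of one pipeline run.

    Every analysis parameter that is not fixed by the method surfaces
    here with its documented default.
    """

    out_dir: str = "scaffdeg_out"
    seed: int = 0
    # --- input: a synthetic series spec (or set input_dir to load images)
    input_dir: str | None = None
    times_days: tuple = (0.0, 7.0, 14.0, 28.0, 44.0)
    group: str = "CCO"
    image_size_px: int = 128
    collagen_fraction_range: tuple = (0.62, 0.20)
    ecm_fraction_range: tuple = (0.08, 0.50)
    nuclei_fraction: float = 0.05
    # --- texture features
    tensor_sigma: float = 2.0
    entropy_radius: int = 4
    entropy_bins: int = 256
    # --- forest
    n_trees: int = 200
    train_pixels_per_class: int = 400
    # --- roi features
    pixel_scale_um: float | None = None
    min_size_px: int = 10
    roi_label: int = LABEL_ECM
    # --- models
    mixture_components: int = 2
    mass_loss_theta: tuple = DEMO_THETA
    mass_loss_noise_sd: float = 1.0
    bootstrap_resamples: int = 200
    cv_folds: int = 3

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        known = {f for f in PipelineConfig.__dataclass_fields__}
        unknown = set(d) - known
        check(not unknown, f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in d.items()})


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps({k: getattr(cfg, k)
                       for k in sorted(cfg.__dataclass_fields__)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _series_from_config(cfg: PipelineConfig, pixel_scale: float):
    times = tuple(float(t) for t in cfg.times_days)
    n = len(times)
    coll = np.linspace(*cfg.collagen_fraction_range, n)
    ecm = np.linspace(*cfg.ecm_fraction_range, n)
    nuc = np.full(n, cfg.nuclei_fraction)
    bg = 1.0 - coll - ecm - nuc
    check(np.all(bg >= 0), "fractions exceed 1; shrink the ranges")
    trend = tuple((float(b), float(c), float(e), float(u))
                  for b, c, e, u in zip(bg, coll, ecm, nuc))
    params = SyntheticSeriesParams(
        times_days=times, composition_trend=trend,
        image_params=SyntheticImageParams(
            width_px=cfg.image_size_px, height_px=cfg.image_size_px,
            pixel_scale_um=pixel_scale),
        group=cfg.group, seed=cfg.seed)
    return generate_series(params)


def _load_series(input_dir: str, pixel_scale: float):
    import imageio.v3 as iio

    from .synthetic import Micrograph

    root = Path(input_dir)
    items = []
    for img_path in sorted(root.glob("image_*.png")) + sorted(root.glob("image_*.tif")):
        stem = img_path.stem.replace("image_", "")
        mask_path = next((p for p in (root / f"mask_{stem}{ext}"
                                      for ext in (".png", ".tif")) if p.exists()), None)
        check(mask_path is not None, f"no mask found for {img_path.name}")
        time = float(stem.split("_t")[-1]) if "_t" in stem else float(len(items))
        items.append((Micrograph(pixels=iio.imread(img_path),
                                 pixel_scale_um=pixel_scale,
                                 time_days=time),
                      iio.imread(mask_path), time))
    check(items, f"no image_*.png/tif files in {input_dir}")
    return items


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run the full analysis and write the report bundle to
    ``config.out_dir``.  Returns a manifest dict (also written as JSON).

    Per-image failures are isolated: the failing image is skipped and
    recorded in the manifest's ``warnings``.
    """
    import imageio.v3 as iio

    cfg = (config if isinstance(config, PipelineConfig)
           else PipelineConfig.from_dict(dict(config)))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    pixel_scale = cfg.pixel_scale_um
    if pixel_scale is None:
        pixel_scale = DEFAULT_PIXEL_SCALE_UM
        log.info("pixel scale not set; defaulting to 300/189 um/px")
        warnings.append("pixel_scale_um defaulted to 300/189 um/px")

    seeds = spawn_seeds(cfg.seed, 5)
    series = (_load_series(cfg.input_dir, pixel_scale) if cfg.input_dir
              else _series_from_config(cfg, pixel_scale))

    # --- features + pooled training sample --------------------------------
    extractor = TextureFeatureExtractor(
        sigma=cfg.tensor_sigma, entropy_radius=cfg.entropy_radius,
        n_bins=cfg.entropy_bins)
    stacks, train_sets = [], []
    sample_seeds = spawn_seeds(seeds[0], len(series))
    for (micro, mask, _), s in zip(series, sample_seeds):
        stack = extractor.transform(micro)
        stacks.append(stack)
        train_sets.append(sample_training_pixels(
            stack, mask, cfg.train_pixels_per_class, seed=s, strict=False))
    X = np.vstack([ts.X for ts in train_sets])
    y = np.concatenate([ts.y for ts in train_sets])
    model = RandomForestPixelSegmenter(
        n_trees=cfg.n_trees, random_state=seeds[1]).fit(
        X, y, feature_names=stacks[0].feature_names)

    # --- per-image segmentation + ROI features ----------------------------
    summaries, pooled_true, pooled_pred = [], [], []
    for i, ((micro, mask, t), stack) in enumerate(zip(series, stacks)):
        try:
            maps = model.predict_probability_maps(stack)
            pred = np.argmax(maps, axis=2).astype(np.uint8)
            iio.imwrite(out / f"probability_maps_{i:03d}.tif",
                        maps.astype(np.float32))
            iio.imwrite(out / f"label_mask_{i:03d}.tif", pred)
            objects = extract_objects(pred == cfg.roi_label,
                                      pixel_scale_um=pixel_scale,
                                      min_size_px=cfg.min_size_px)
            objects.to_csv(out / f"objects_{i:03d}.csv", index=False)
            summ = summarize_image(objects, micro, pred == cfg.roi_label,
                                   time_days=t, group=micro.group or cfg.group)
            summaries.append(summ.as_dict())
            pooled_true.append(mask.ravel())
            pooled_pred.append(pred.ravel())
        except Exception as exc:  # isolate the failing image
            warnings.append(f"image {i} failed: {exc}")
            log.warning("image %d failed: %s", i, exc)
    check(summaries, "every image failed")
    summary_df = pd.DataFrame(summaries)

    # --- segmentation validation ------------------------------------------
    counts, metrics = confusion_and_metrics(
        np.concatenate(pooled_true), np.concatenate(pooled_pred))
    metrics.per_class.to_csv(out / "segmentation_metrics.csv")
    (out / "segmentation_metrics.json").write_text(json.dumps({
        "accuracy": metrics.accuracy,
        "weighted": metrics.weighted.to_dict(),
        "confusion": counts.tolist(),
        "misclassification_error_roi": misclassification_error(
            np.concatenate(pooled_true), np.concatenate(pooled_pred),
            cfg.roi_label),
    }, indent=2))

    # --- mass-loss kinetics ------------------------------------------------
    mass = simulate_mass_loss(MassLossSimSpec(
        theta=cfg.mass_loss_theta,
        times_days=tuple(np.arange(0.0, 44.0 + 1e-9, 2.0)),
        noise_sd=cfg.mass_loss_noise_sd, group=cfg.group, seed=seeds[2]))
    mass.to_csv(out / "mass_loss.csv", index=False)
    mix = fit_mixture(mass, k=cfg.mixture_components, seed=seeds[3])
    ci = bootstrap_parameters(mix, B=cfg.bootstrap_resamples, seed=seeds[3])
    gam = fit_gam(mass["time_days"], mass["mass_loss_pct"])
    (out / "mixture_fit.json").write_text(json.dumps({
        "parameter_names": mix.parameter_names_,
        "estimates": mix.theta_.tolist(),
        "std_errors": mix.std_errors_.tolist(),
        "p_values": mix.p_values_.tolist(),
        "r_squared": mix.r_squared_,
        "bootstrap_lower": ci.lower.tolist(),
        "bootstrap_upper": ci.upper.tolist(),
        "bootstrap_level": ci.level,
        "bootstrap_resamples": ci.n_resamples,
        "bootstrap_failed": ci.n_failed,
        "gam_r_squared": gam.r_squared_,
        "gam_lambda": gam.lambda_,
        "seed": seeds[3],
    }, indent=2))

    # --- feature-based linear models ---------------------------------------
    feat = summary_df.dropna(subset=["mean_area_um2", "mean_circularity"])
    feat = feat.assign(mass_loss_pct=np.interp(
        feat["time_days"], mass["time_days"], mass["mass_loss_pct"]))
    feat.to_csv(out / "image_features.csv", index=False)
    linear_report: dict = {}
    if len(feat) >= 4:
        area_model = MassLossLinearModel(log_features=("mean_area_um2",)).fit(feat)
        linear_report["area_model"] = {
            "coefficients": area_model.params_.to_dict(),
            "r_squared": area_model.r_squared_,
        }
        n_groups = feat["group"].nunique()
        want_cols = 3 + (n_groups - 1)
        if len(feat) > want_cols + 2 and n_groups >= 2:
            multi = MassLossLinearModel(
                log_features=("mean_circularity", "gray_mode", "mean_area_um2"),
                group_col="group").fit(feat)
            cv = kfold_predictions(multi, feat, k=cfg.cv_folds, seed=seeds[4])
            cv.to_csv(out / "cv_predictions.csv", index=False)
            linear_report["multivariate_model"] = {
                "coefficients": multi.params_.to_dict(),
                "r_squared": multi.r_squared_,
                "lmg_shares": relative_importance_lmg(multi).to_dict(),
            }
        else:
            warnings.append("multivariate model skipped: needs >= 2 groups "
                            "and enough rows")
    else:
        warnings.append("linear models skipped: too few images with objects")
    (out / "linear_models.json").write_text(json.dumps(linear_report, indent=2))

    manifest = {
        "scaffdeg_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_images": len(series),
        "segmentation_accuracy": metrics.accuracy,
        "mixture_r_squared": mix.r_squared_,
        "warnings": warnings,
        "versions": _library_versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _library_versions() -> dict:
    import scipy
    import sklearn
    import skimage

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__}
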