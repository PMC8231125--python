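"""End-to-end quality-control analysis of grouped stain images.

The pipeline takes groups of deposits — either directories of
micrographs or synthetic groups generated on the fly — computes
per-region texture and morphometry features for every image, and
discriminates each test group against the control group with ROC/AUC
summaries, one row per region x feature x test group.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, roc, synthetic
from .texture import EmptyCooccurrenceError, GLCMConfig, GrayImage, compute_glcm, load_gray_image, texture_features

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "extract_features",
    "discrimination_table",
    "run_pipeline",
    "DISCRIMINATION_COLUMNS",
]

GLCM_FEATURES = ("energy", "inertia", "correlation", "idm", "entropy")

DEFAULT_FEATURES: dict[str, tuple[str, ...]] = {
    "complete": GLCM_FEATURES + ("mean_pixel_intensity",),
    "crown": GLCM_FEATURES + ("gamma_normalized",),
    "center": GLCM_FEATURES + ("aggregate_area",),
}

# A priori direction in which dilution moves each feature of the test
# group; fixed per feature and never flipped from the data.
DEFAULT_ORIENTATIONS: dict[str, str] = {
    "energy": "greater_is_positive",
    "inertia": "less_is_positive",
    "correlation": "greater_is_positive",
    "idm": "greater_is_positive",
    "entropy": "less_is_positive",
    "gamma_normalized": "less_is_positive",
    "aggregate_area": "greater_is_positive",
    "mean_pixel_intensity": "less_is_positive",
}

DISCRIMINATION_COLUMNS = [
    "region", "feature", "label", "auc", "std_error", "asymptotic_prob",
    "lcl95", "ucl95", "optimal_cutoff", "optimal_sensitivity",
    "optimal_specificity", "n_control", "n_test", "flags",
]


class PipelineError(RuntimeError):
    """Configuration or data problem that prevents the analysis."""


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    ``groups`` maps a condition label to either ``{"s": dilution,
    "n": group_size}`` (synthetic mode) or ``{"dir": path}`` /
    ``{"images": [paths]}`` (image mode). ``control`` names the
    unaltered group against which every other group is discriminated.
    """

    groups: dict
    control: str
    mode: str = "synthetic"
    regions: tuple[str, ...] = ("complete", "crown", "center")
    features: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_FEATURES.items()})
    orientations: dict = field(default_factory=lambda: dict(DEFAULT_ORIENTATIONS))
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    fractions: tuple[float, float, float] = (0.5, 0.6, 0.95)
    stain: dict = field(default_factory=dict)
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "images"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.control not in self.groups:
            raise PipelineError(f"control label {self.control!r} not among groups")
        unknown = set(self.regions) - {"complete", "crown", "center"}
        if unknown:
            raise PipelineError(f"unknown regions: {sorted(unknown)}")
        for region, feats in self.features.items():
            for f in feats:
                if f == "gamma_normalized" and region != "crown":
                    raise PipelineError("gamma_normalized is only defined on the crown")
                if f == "aggregate_area" and region != "center":
                    raise PipelineError("aggregate_area is only defined on the center")
        if isinstance(self.glcm, dict):
            self.glcm = GLCMConfig(**self.glcm)
        self.fractions = tuple(self.fractions)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PipelineError(f"malformed config file {path}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineError(f"malformed config: {exc}") from exc


def _load_groups(config: PipelineConfig) -> dict[str, list[GrayImage]]:
    """Materialize each group's images (generate or load from disk)."""
    out: dict[str, list[GrayImage]] = {}
    if config.mode == "synthetic":
        base = synthetic.StainParams(**config.stain)
        group_seed_rng = np.random.default_rng(config.seed)
        for label in sorted(config.groups):
            spec = config.groups[label]
            master = int(group_seed_rng.integers(0, 2**31 - 1))
            pairs = synthetic.make_group(base, float(spec["s"]), int(spec["n"]), master)
            out[label] = [img for img, _truth in pairs]
    else:
        for label in sorted(config.groups):
            spec = config.groups[label]
            if "images" in spec:
                paths = [Path(p) for p in spec["images"]]
            else:
                d = Path(spec["dir"])
                paths = sorted(p for p in d.iterdir()
                               if p.suffix.lower() in (".png", ".tif", ".tiff"))
            if not paths:
                raise PipelineError(f"group {label!r} has no images")
            out[label] = [load_gray_image(p) for p in paths]
    return out


def extract_features(
    images_by_group: dict[str, list[GrayImage]], config: PipelineConfig
) -> pd.DataFrame:
    """Per-image, per-region feature table.

    Each row is (image_id, group, region, feature, value, flag).
    Undefined values (e.g. correlation on a constant region) carry a
    flag and a NaN value, never a silent zero. A group in which more
    than half the images fail to segment aborts the run.
    """
    if config.control not in images_by_group:
        raise PipelineError(f"control group {config.control!r} missing")
    rows: list[dict] = []
    gammas: dict[str, list[tuple[str, float]]] = {}

    for label, images in images_by_group.items():
        failures = 0
        for i, image in enumerate(images):
            image_id = f"{label}_{i:02d}"
            try:
                geom = geometry.segment_stain(image)
            except geometry.SegmentationError as exc:
                logger.warning("%s: segmentation failed (%s)", image_id, exc)
                failures += 1
                for region in config.regions:
                    for feat in config.features.get(region, ()):
                        rows.append(_row(image_id, label, region, feat,
                                         float("nan"), "segmentation_failed"))
                continue
            regions = geometry.partition_regions(image, geom, config.fractions)
            masks = {"complete": regions.complete, "crown": regions.crown,
                     "center": regions.center}
            for region in config.regions:
                feats = config.features.get(region, ())
                glcm_wanted = [f for f in feats if f in GLCM_FEATURES]
                if glcm_wanted:
                    rows.extend(_glcm_rows(image, masks[region], config.glcm,
                                           glcm_wanted, image_id, label, region))
                if "mean_pixel_intensity" in feats:
                    mean_i = float(image.pixels[masks[region]].mean())
                    rows.append(_row(image_id, label, region,
                                     "mean_pixel_intensity", mean_i, ""))
                if "gamma_normalized" in feats:
                    cm = geometry.crown_thickness(image, geom,
                                                  f_center=config.fractions[0])
                    flag = "no_crown" if cm.no_crown else ""
                    gammas.setdefault(label, []).append((image_id, cm.gamma))
                    rows.append(_row(image_id, label, region, "gamma",
                                     cm.gamma, flag))
                if "aggregate_area" in feats:
                    agg = geometry.central_aggregate_area(image, regions)
                    rows.append(_row(image_id, label, region, "aggregate_area",
                                     agg.area, ""))
        if images and failures > 0.5 * len(images):
            raise PipelineError(
                f"group {label!r}: {failures}/{len(images)} images unsegmentable"
            )

    df = pd.DataFrame(rows)
    return _append_normalized_gamma(df, gammas, config)


def _glcm_rows(image, mask, glcm_config, wanted, image_id, label, region):
    try:
        glcm = compute_glcm(image.with_mask(mask), glcm_config)
    except (EmptyCooccurrenceError, ValueError) as exc:
        logger.warning("%s/%s: GLCM failed (%s)", image_id, region, exc)
        return [_row(image_id, label, region, f, float("nan"), "glcm_failed")
                for f in wanted]
    tf = texture_features(glcm, glcm_config)
    values = tf.as_dict()
    out = []
    for f in wanted:
        flag = ""
        if f == "correlation" and not tf.correlation_defined:
            flag = "undefined"
        out.append(_row(image_id, label, region, f, values[f], flag))
    return out


def _row(image_id, group, region, feature, value, flag):
    return {"image_id": image_id, "group": group, "region": region,
            "feature": feature, "value": value, "flag": flag}


def _append_normalized_gamma(df, gammas, config):
    """gamma / gamma0, with gamma0 the control group's mean thickness."""
    if not gammas:
        return df
    control = gammas.get(config.control, [])
    gamma0 = float(np.mean([g for _id, g in control])) if control else 0.0
    rows = []
    for label, pairs in gammas.items():
        for image_id, g in pairs:
            if gamma0 > 0:
                rows.append(_row(image_id, label, "crown", "gamma_normalized",
                                 geometry.normalize_crown(g, gamma0), ""))
            else:
                logger.warning("control gamma0 is zero; gamma_normalized undefined")
                rows.append(_row(image_id, label, "crown", "gamma_normalized",
                                 float("nan"), "gamma0_zero"))
    return pd.concat([df, pd.DataFrame(rows)], ignore_index=True)


def discrimination_table(features: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Control-vs-test ROC summary for every region x feature x group.

    Undefined feature values are dropped pairwise with a logged count;
    a comparison left with fewer than two usable values per group emits
    an NA row flagged ``insufficient_data``.
    """
    test_labels = [g for g in sorted(features["group"].unique())
                   if g != config.control]
    rows = []
    reportable = [f for f in features["feature"].unique() if f != "gamma"]
    for region in config.regions:
        sub_r = features[features["region"] == region]
        for feat in reportable:
            sub = sub_r[sub_r["feature"] == feat]
            if sub.empty:
                continue
            ctrl_vals = sub.loc[sub["group"] == config.control, "value"].dropna()
            orientation = config.orientations.get(feat, "greater_is_positive")
            for label in test_labels:
                test_vals = sub.loc[sub["group"] == label, "value"].dropna()
                n_drop = (sub["group"].isin([label, config.control]).sum()
                          - len(ctrl_vals) - len(test_vals))
                if n_drop:
                    logger.info("%s/%s vs %s: dropped %d undefined values",
                                region, feat, label, n_drop)
                if len(ctrl_vals) < 2 or len(test_vals) < 2:
                    rows.append(dict.fromkeys(DISCRIMINATION_COLUMNS, float("nan"))
                                | {"region": region, "feature": feat,
                                   "label": label, "n_control": len(ctrl_vals),
                                   "n_test": len(test_vals),
                                   "flags": "insufficient_data"})
                    continue
                summary = roc.summarize_groups(
                    roc.ScoreGroup(config.control, ctrl_vals.to_numpy()),
                    roc.ScoreGroup(label, test_vals.to_numpy()),
                    orientation,
                )
                rows.append({
                    "region": region, "feature": feat, "label": label,
                    "auc": summary.auc, "std_error": summary.std_error,
                    "asymptotic_prob": summary.asymptotic_p,
                    "lcl95": summary.lcl95, "ucl95": summary.ucl95,
                    "optimal_cutoff": summary.optimal_cutoff,
                    "optimal_sensitivity": summary.optimal_sensitivity,
                    "optimal_specificity": summary.optimal_specificity,
                    "n_control": len(ctrl_vals), "n_test": len(test_vals),
                    "flags": ";".join(summary.flags),
                })
    return pd.DataFrame(rows, columns=DISCRIMINATION_COLUMNS)


def run_pipeline(config, output_dir) -> dict[str, Path]:
    """Run the whole analysis and write its reports.

    ``config`` is a :class:`PipelineConfig` or a path to a YAML file.
    Writes ``features.csv``, ``discrimination.csv`` and ``run_log.json``
    (plus AUC trend plots when ``make_plots``) under ``output_dir`` and
    returns the paths.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    images = _load_groups(config)
    features = extract_features(images, config)
    report = discrimination_table(features, config)

    paths = {
        "features": out / "features.csv",
        "discrimination": out / "discrimination.csv",
        "log": out / "run_log.json",
    }
    features.to_csv(paths["features"], index=False, float_format="%.10g")
    report.to_csv(paths["discrimination"], index=False, float_format="%.10g")

    from . import __version__

    log = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "control": config.control,
        "groups": {k: {kk: str(vv) for kk, vv in v.items()}
                   for k, v in config.groups.items()},
        "n_images": {k: len(v) for k, v in images.items()},
        "glcm": dataclasses.asdict(config.glcm),
        "fractions": list(config.fractions),
        "n_feature_rows": int(len(features)),
        "n_report_rows": int(len(report)),
    }
    with open(paths["log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    if config.make_plots:
        paths["plots"] = _plot_auc_trends(report, out)
    return paths


def _plot_auc_trends(report: pd.DataFrame, out: Path) -> Path:
    """AUC versus test-group label, one line per region, per feature."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = report["feature"].unique()
    fig, axes = plt.subplots(1, len(feats), figsize=(3.2 * len(feats), 3),
                             squeeze=False)
    for ax, feat in zip(axes[0], feats):
        sub = report[report["feature"] == feat]
        for region, grp in sub.groupby("region"):
            ax.plot(grp["label"], grp["auc"], marker="o", label=region)
        ax.set_title(feat)
        ax.set_xlabel("group")
        ax.set_ylabel("AUC")
        ax.set_ylim(0, 1.05)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    path = out / "auc_trends.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
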