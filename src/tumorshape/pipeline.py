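"""End-to-end pipeline orchestration.

Stages communicate only through files in an artifact directory, so any
stage can be rerun from its cached inputs and a fixed master seed makes
every numeric artifact bit-reproducible.  Layout::

    out/
      config.json                  echo of the configuration
      manifests/<stage>.json       inputs, config hash, seed, version
      patches/                     labeled patch set for the classifier
      slides/<cohort>/<pid>.png    rendered slides
      truth/<cohort>/<pid>.txt     ground-truth label maps
      grids/<cohort>/<pid>.txt     tissue-cell flags of the patch grid
      probs/<cohort>/<pid>.<cls>.txt   per-class probability heatmaps
      labels/<cohort>/<pid>.txt    predicted label maps
      heatmaps/<cohort>/<pid>.png  colored label heatmaps
      regions/<cohort>.csv         per-region geometry tables
      features/<cohort>.csv        patient-level 22-feature matrices
      clinical/<cohort>.csv        survival + clinical covariates
      model/                       univariate screen, fitted model
      validation/                  risk groups, log-rank, KM, adjusted Cox
      report/                      KM plot and summary
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _matrixio as mio
from ._constants import CLASS_NAMES, N_CLASSES, WHITE
from .classifier import (
    ReferenceClassifier,
    assemble_probability_map,
    evaluate_accuracy,
    label_map_from_probs,
)
from .features import (
    FEATURE_NAMES,
    apply_reporting_scales,
    patient_aggregate,
    tissue_feature_vector,
)
from .regions import extract_tumor_regions, find_holes, segment_tissue_regions
from .survival import (
    cv_select_lambda,
    km_curve,
    logrank,
    multivariate_cox,
    risk_assign,
    univariate_screen,
)
from .synthetic import CohortSpec, render_patch_set, render_slide, simulate_cohort
from .tiling import scale_patches, split_assign, tile_grid, tissue_mask

log = logging.getLogger("tumorshape")

__all__ = ["PipelineConfig", "PipelineError", "STAGES", "run_stage", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed or its inputs are missing; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, exactly once.

    ``patch_size`` is the rendered pixels per heatmap cell (the real study
    uses 300; 32 keeps synthetic runs desk-sized).  Cohort sizes default to
    a small demonstration cohort; the study-scale analysis (150 training /
    389 validation patients) runs at label-map granularity through
    :func:`tumorshape.synthetic.simulate_cohort`.
    """

    out_dir: str = "tumorshape_run"
    master_seed: int = 0
    n_train: int = 30
    n_validation: int = 50
    tissues_per_image: int = 1
    patch_size: int = 32
    white_threshold: float = 200.0
    pixel_morph_radius: int = 1
    tissue_closing_radius: int = 1
    tissue_fraction: float = 0.0
    split_fractions: tuple = (0.72, 0.08, 0.20)
    patches_per_class: int = 150
    classifier_backend: str = "reference"
    connectivity: int = 8  # fixed; recorded for provenance
    alpha_mix: float = 0.5
    cv_folds: int = 10
    screen_alpha: float = 0.05
    cohort_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        if "cohort_overrides" in d:
            # JSON turns tuples into lists; restore them for equality
            d["cohort_overrides"] = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["cohort_overrides"].items()
            }
        return cls(**d)

    @property
    def path(self) -> Path:
        return Path(self.out_dir)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Independent per-stage stream split off the master seed."""
        ss = np.random.SeedSequence(
            self.master_seed,
            spawn_key=(sum(stage.encode()) % 1000, len(stage)),
        )
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def cohort_spec(self, cohort: str) -> CohortSpec:
        n = self.n_train if cohort == "train" else self.n_validation
        kwargs = dict(
            n_patients=n,
            tissues_per_image=self.tissues_per_image,
            seed=self.stage_seed(f"simulate-{cohort}"),
        )
        kwargs.update(self.cohort_overrides)
        return CohortSpec(**kwargs)


COHORTS = ("train", "validation")


def _manifest(cfg: PipelineConfig, stage: str, inputs, outputs):
    from importlib.metadata import version

    try:
        ver = version("tumorshape")
    except Exception:  # pragma: no cover - not installed
        ver = "unknown"
    mdir = cfg.path / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    mio.write_json(
        mdir / f"{stage}.json",
        {
            "stage": stage,
            "inputs": sorted(str(p) for p in inputs),
            "outputs": sorted(str(p) for p in outputs),
            "config_hash": cfg.config_hash(),
            "seed": cfg.stage_seed(stage),
            "version": ver,
        },
    )


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r}: missing required input {path} "
            "(run the earlier stages first)"
        )
    return path


def _pids(cfg: PipelineConfig, cohort: str):
    n = cfg.n_train if cohort == "train" else cfg.n_validation
    prefix = cohort[0].upper()  # T.../V...
    return [f"{prefix}{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig):
    """Generate cohorts: slides, ground-truth label maps, clinical tables,
    and a labeled patch set for classifier training."""
    out = cfg.path
    outputs = []
    for cohort in COHORTS:
        spec = cfg.cohort_spec(cohort)
        feats, clinical, label_maps, _specs = simulate_cohort(spec)
        pids = _pids(cfg, cohort)
        clinical = clinical.copy()
        clinical["patient_id"] = pids
        (out / "slides" / cohort).mkdir(parents=True, exist_ok=True)
        (out / "truth" / cohort).mkdir(parents=True, exist_ok=True)
        (out / "clinical").mkdir(parents=True, exist_ok=True)
        render_seed = cfg.stage_seed(f"render-{cohort}")
        for i, (pid, lm) in enumerate(zip(pids, label_maps)):
            img = render_slide(lm, cfg.patch_size, seed=render_seed + i)
            p_img = out / "slides" / cohort / f"{pid}.png"
            mio.write_image(p_img, img)
            p_truth = out / "truth" / cohort / f"{pid}.txt"
            mio.write_matrix(p_truth, lm, fmt="%d",
                             sidecar={"classes": list(CLASS_NAMES),
                                      "patient_id": pid})
            outputs += [p_img, p_truth]
        p_clin = out / "clinical" / f"{cohort}.csv"
        clinical.to_csv(p_clin, index=False)
        # ground-truth features, for diagnostics only
        feats.index = pids
        feats.to_csv(out / "truth" / f"{cohort}_features.csv")
        outputs.append(p_clin)
        log.info("simulate: %s cohort, %d patients", cohort, len(pids))

    patches, labels = render_patch_set(
        cfg.patches_per_class, cfg.patch_size, seed=cfg.stage_seed("patchset")
    )
    del patches, labels  # regenerable from the seed; persist the recipe only
    pdir = out / "patches"
    pdir.mkdir(parents=True, exist_ok=True)
    mio.write_json(pdir / "patchset.json",
                   {"n_per_class": cfg.patches_per_class,
                    "patch_size": cfg.patch_size,
                    "seed": cfg.stage_seed("patchset"),
                    "classes": list(CLASS_NAMES)})
    outputs.append(pdir / "patchset.json")
    mio.write_json(out / "config.json", cfg.to_dict())
    _manifest(cfg, "simulate", [], outputs)


def stage_tile(cfg: PipelineConfig):
    """Tissue masks and non-overlapping patch grids for every slide."""
    out = cfg.path
    inputs, outputs = [], []
    for cohort in COHORTS:
        for pid in _pids(cfg, cohort):
            p_img = _require(out / "slides" / cohort / f"{pid}.png", "tile")
            img = mio.read_image(p_img)
            tmask = tissue_mask(img, morph_radius=cfg.pixel_morph_radius)
            grid = tile_grid(img.shape, cfg.patch_size, tmask,
                             cfg.tissue_fraction)
            gdir = out / "grids" / cohort
            gdir.mkdir(parents=True, exist_ok=True)
            p_grid = gdir / f"{pid}.txt"
            mio.write_matrix(
                p_grid, grid.tissue.astype(int), fmt="%d",
                sidecar={"patch_size": cfg.patch_size,
                         "otsu_threshold": tmask.threshold,
                         "source": str(p_img)},
            )
            inputs.append(p_img)
            outputs.append(p_grid)
    _manifest(cfg, "tile", inputs, outputs)


def _fit_pipeline_classifier(cfg: PipelineConfig):
    if cfg.classifier_backend != "reference":
        raise PipelineError(
            f"stage 'classify': unknown classifier backend "
            f"{cfg.classifier_backend!r}"
        )
    patches, labels = render_patch_set(
        cfg.patches_per_class, cfg.patch_size, seed=cfg.stage_seed("patchset")
    )
    splits, _alloc = split_assign(labels, cfg.split_fractions,
                                  seed=cfg.stage_seed("split"))
    train = splits == "train"
    test = splits == "test"
    clf = ReferenceClassifier().fit(scale_patches(patches[train]),
                                    labels[train])
    overall, per_class, _ = evaluate_accuracy(
        clf.predict(scale_patches(patches[test])), labels[test]
    )
    return clf, {"test_accuracy": overall,
                 "per_class_accuracy": per_class,
                 "n_train": int(train.sum()), "n_test": int(test.sum())}


def stage_classify(cfg: PipelineConfig):
    """Train the patch classifier and predict every tissue cell of every
    slide, writing per-class probability heatmaps."""
    out = cfg.path
    clf, clf_info = _fit_pipeline_classifier(cfg)
    mio.write_json(out / "patches" / "classifier_eval.json", clf_info)
    inputs, outputs = [], []
    for cohort in COHORTS:
        for pid in _pids(cfg, cohort):
            p_img = _require(out / "slides" / cohort / f"{pid}.png",
                             "classify")
            p_grid = _require(out / "grids" / cohort / f"{pid}.txt",
                              "classify")
            img = mio.read_image(p_img)
            flags = mio.read_matrix(p_grid, dtype=int).astype(bool)
            grid = tile_grid(img.shape, cfg.patch_size)  # geometry only
            grid.tissue[:] = flags
            cells = np.argwhere(flags)
            if len(cells):
                batch = np.stack([
                    img[grid.window(i, j)] for i, j in cells
                ])
                preds = clf.predict_proba(scale_patches(batch))
            else:
                preds = np.zeros((0, N_CLASSES))
            prob = assemble_probability_map(grid, preds)
            pdir = out / "probs" / cohort
            pdir.mkdir(parents=True, exist_ok=True)
            for k, cls in enumerate(CLASS_NAMES):
                p_out = pdir / f"{pid}.{cls}.txt"
                mio.write_matrix(p_out, prob[..., k], fmt="%.8f",
                                 sidecar={"class": cls, "class_index": k,
                                          "class_order": list(CLASS_NAMES),
                                          "patch_size": cfg.patch_size,
                                          "source": str(p_img)})
                outputs.append(p_out)
            inputs += [p_img, p_grid]
    _manifest(cfg, "classify", inputs, outputs)


def _load_prob_map(cfg: PipelineConfig, cohort: str, pid: str, stage: str):
    out = cfg.path
    planes = []
    for cls in CLASS_NAMES:
        p = _require(out / "probs" / cohort / f"{pid}.{cls}.txt", stage)
        planes.append(mio.read_matrix(p))
    return np.stack(planes, axis=-1)


def stage_heatmap(cfg: PipelineConfig):
    """Argmax label maps and colored heatmap renderings."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    # palette roles: white/empty, tumor, non-malignant
    cmap = ListedColormap(["#2ca02c", "#1f77b4", "#ffdf00"])  # t, nm, white
    out = cfg.path
    inputs, outputs = [], []
    for cohort in COHORTS:
        for pid in _pids(cfg, cohort):
            prob = _load_prob_map(cfg, cohort, pid, "heatmap")
            labels = label_map_from_probs(prob)
            ldir = out / "labels" / cohort
            hdir = out / "heatmaps" / cohort
            ldir.mkdir(parents=True, exist_ok=True)
            hdir.mkdir(parents=True, exist_ok=True)
            p_lab = ldir / f"{pid}.txt"
            mio.write_matrix(p_lab, labels, fmt="%d",
                             sidecar={"classes": list(CLASS_NAMES)})
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(labels, cmap=cmap, vmin=0, vmax=2, interpolation="none")
            ax.set_title(f"{pid} predicted classes")
            ax.set_xticks([]), ax.set_yticks([])
            p_png = hdir / f"{pid}.png"
            fig.savefig(p_png, dpi=100)
            plt.close(fig)
            outputs += [p_lab, p_png]
    _manifest(cfg, "heatmap", inputs, outputs)


def stage_regions(cfg: PipelineConfig):
    """Segment tissue samples and tumor regions from predicted label maps."""
    out = cfg.path
    inputs, outputs = [], []
    for cohort in COHORTS:
        rows = []
        for pid in _pids(cfg, cohort):
            p_lab = _require(out / "labels" / cohort / f"{pid}.txt", "regions")
            labels = mio.read_matrix(p_lab, dtype=int)
            inputs.append(p_lab)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tissues = segment_tissue_regions(
                    labels, closing_radius=cfg.tissue_closing_radius)
            for tissue in tissues:
                for reg in extract_tumor_regions(tissue, labels):
                    holes = find_holes(reg.mask)
                    r0, c0, r1, c1 = reg.bbox
                    rows.append({
                        "patient_id": pid, "tissue_id": tissue.id,
                        "region_id": reg.id, "is_main": reg.is_main,
                        "area": reg.area, "n_holes": holes.n_holes,
                        "bbox_rmin": r0, "bbox_cmin": c0,
                        "bbox_rmax": r1, "bbox_cmax": c1,
                    })
        rdir = out / "regions"
        rdir.mkdir(parents=True, exist_ok=True)
        p_csv = rdir / f"{cohort}.csv"
        pd.DataFrame(
            rows,
            columns=["patient_id", "tissue_id", "region_id", "is_main",
                     "area", "n_holes", "bbox_rmin", "bbox_cmin",
                     "bbox_rmax", "bbox_cmax"],
        ).to_csv(p_csv, index=False)
        outputs.append(p_csv)
    _manifest(cfg, "regions", inputs, outputs)


def stage_features(cfg: PipelineConfig):
    """Per-tissue 22-feature vectors, averaged to the patient level."""
    out = cfg.path
    inputs, outputs = [], []
    for cohort in COHORTS:
        rows = []
        for pid in _pids(cfg, cohort):
            p_lab = _require(out / "labels" / cohort / f"{pid}.txt",
                             "features")
            labels = mio.read_matrix(p_lab, dtype=int)
            prob = _load_prob_map(cfg, cohort, pid, "features")
            inputs.append(p_lab)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vectors = []
                for tissue in segment_tissue_regions(
                        labels, closing_radius=cfg.tissue_closing_radius):
                    regs = extract_tumor_regions(tissue, labels)
                    vec = tissue_feature_vector(tissue, regs, prob)
                    if vec is not None:
                        vectors.append(vec)
                agg = patient_aggregate(vectors)
            if agg is None:
                log.warning("features: patient %s has no tumor regions; "
                            "excluded", pid)
                continue
            agg["patient_id"] = pid
            rows.append(agg)
        fdir = out / "features"
        fdir.mkdir(parents=True, exist_ok=True)
        p_csv = fdir / f"{cohort}.csv"
        df = pd.DataFrame(rows)
        if len(df):
            df = df[["patient_id", *FEATURE_NAMES]]
        df.to_csv(p_csv, index=False)
        outputs.append(p_csv)
    _manifest(cfg, "features", inputs, outputs)


def _load_features_clinical(cfg: PipelineConfig, cohort: str, stage: str):
    out = cfg.path
    p_feat = _require(out / "features" / f"{cohort}.csv", stage)
    p_clin = _require(out / "clinical" / f"{cohort}.csv", stage)
    feats = pd.read_csv(p_feat).set_index("patient_id")
    clin = pd.read_csv(p_clin).set_index("patient_id")
    common = feats.index.intersection(clin.index)
    return feats.loc[common], clin.loc[common], [p_feat, p_clin]


def stage_survival_train(cfg: PipelineConfig):
    """Univariate screen, then cross-validated elastic-net Cox on the
    selected features of the training cohort."""
    out = cfg.path
    feats, clin, inputs = _load_features_clinical(cfg, "train",
                                                  "survival-train")
    if len(feats) < 2 or clin["event"].sum() == 0:
        raise PipelineError(
            "stage 'survival-train': no usable tumor-bearing patients with "
            "events in the training cohort"
        )
    scaled = apply_reporting_scales(feats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, selected = univariate_screen(
            feats, clin["time_days"].to_numpy(), clin["event"].to_numpy(),
            alpha=cfg.screen_alpha)
    mdir = out / "model"
    mdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(mdir / "univariate.csv")
    if not selected:
        raise PipelineError(
            "stage 'survival-train': no feature passed the univariate "
            "screen; cannot build a model"
        )
    X = scaled[selected].to_numpy()
    model = cv_select_lambda(
        X, clin["time_days"].to_numpy(), clin["event"].to_numpy(),
        k=min(cfg.cv_folds, len(feats)), seed=cfg.stage_seed("cv"),
        alpha_mix=cfg.alpha_mix, names=selected)
    model.extras["selected_features"] = selected
    model.extras["screen_alpha"] = cfg.screen_alpha
    mio.write_json(mdir / "model.json", model.to_json_dict())
    _manifest(cfg, "survival-train", inputs,
              [mdir / "univariate.csv", mdir / "model.json"])


def _load_model(cfg: PipelineConfig, stage: str):
    from .survival import CoxnetModel

    p = _require(cfg.path / "model" / "model.json", stage)
    d = mio.read_json(p)
    return CoxnetModel(
        feature_names=d["feature_names"],
        beta=np.asarray(d["beta"]),
        lam=d["lambda"],
        alpha_mix=d["alpha_mix"],
        path_lambdas=np.asarray(d["path_lambdas"]),
        path_coefs=np.zeros((0, len(d["beta"]))),
        center=np.asarray(d["center"]),
        scale=np.asarray(d["scale"]),
        extras=d.get("extras", {}),
    ), p


def stage_survival_validate(cfg: PipelineConfig):
    """Risk-score the validation cohort, split at its median, and compare
    groups by log-rank, Kaplan-Meier, and an adjusted Cox model."""
    out = cfg.path
    model, p_model = _load_model(cfg, "survival-validate")
    feats, clin, inputs = _load_features_clinical(cfg, "validation",
                                                  "survival-validate")
    scaled = apply_reporting_scales(feats)
    X = scaled[model.feature_names].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assign = risk_assign(X, model)
    time = clin["time_days"].to_numpy()
    event = clin["event"].to_numpy()
    vdir = out / "validation"
    vdir.mkdir(parents=True, exist_ok=True)
    risk = pd.DataFrame({
        "patient_id": feats.index,
        "risk_score": assign.scores,
        "risk_group": assign.groups,
    })
    risk.to_csv(vdir / "risk_groups.csv", index=False)

    results = {"cutoff": assign.cutoff,
               "n_high": int(assign.high.sum()),
               "n_low": int((~assign.high).sum())}
    km_rows = []
    if 0 < assign.high.sum() < len(assign.high):
        chi2, df, p = logrank(assign.groups, time, event)
        results["logrank_chi2"] = chi2
        results["logrank_p"] = p
        for name, sel in (("high", assign.high), ("low", ~assign.high)):
            curve = km_curve(time[sel], event[sel])
            curve.insert(0, "group", name)
            km_rows.append(curve)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mv = multivariate_cox(assign.high, clin, time, event)
        mv.summary.to_csv(vdir / "multivariate.csv")
        results["multivariate_risk_hr"] = float(
            mv.summary.loc["risk_high_vs_low", "hr"])
    else:
        log.warning("survival-validate: degenerate risk split; "
                    "log-rank and adjusted model skipped")
    if km_rows:
        pd.concat(km_rows).to_csv(vdir / "km_curves.csv", index=False)
    mio.write_json(vdir / "validation.json", results)
    _manifest(cfg, "survival-validate", inputs + [p_model],
              [vdir / "validation.json", vdir / "risk_groups.csv"])


def stage_report(cfg: PipelineConfig):
    """Human-readable summary: KM plot, result tables, artifact index."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = cfg.path
    vdir = out / "validation"
    rdir = out / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    results = mio.read_json(_require(vdir / "validation.json", "report"))
    lines = ["# tumorshape run report", "",
             f"- config hash: {cfg.config_hash()}",
             f"- master seed: {cfg.master_seed}", ""]
    p_km_csv = vdir / "km_curves.csv"
    if p_km_csv.exists():
        km = pd.read_csv(p_km_csv)
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, sub in km.groupby("group"):
            ax.step(sub["time"], sub["survival"], where="post",
                    label=f"{name} risk (n={results[f'n_{name}']})")
        ax.set_xlabel("days"), ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02), ax.legend()
        if "logrank_p" in results:
            ax.set_title(f"log-rank p = {results['logrank_p']:.4g}")
        fig.tight_layout()
        fig.savefig(rdir / "km_plot.png", dpi=120)
        plt.close(fig)
        lines.append("![Kaplan-Meier plot](km_plot.png)")
        lines.append("")
    lines.append("## Validation results")
    for key, val in sorted(results.items()):
        lines.append(f"- {key}: {val}")
    lines += ["", "## Artifacts"]
    for sub in ("clinical", "features", "model", "validation", "heatmaps"):
        for p in sorted((out / sub).rglob("*")):
            if p.is_file():
                lines.append(f"- {p.relative_to(out)}")
    (rdir / "summary.md").write_text("\n".join(lines) + "\n")
    _manifest(cfg, "report", [vdir / "validation.json"],
              [rdir / "summary.md"])


STAGES = {
    "simulate": stage_simulate,
    "tile": stage_tile,
    "classify": stage_classify,
    "heatmap": stage_heatmap,
    "regions": stage_regions,
    "features": stage_features,
    "survival-train": stage_survival_train,
    "survival-validate": stage_survival_validate,
    "report": stage_report,
}


def run_stage(cfg: PipelineConfig, stage: str):
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}")
    log.info("running stage %s", stage)
    STAGES[stage](cfg)


def run_all(cfg: PipelineConfig):
    """Run every stage in order; idempotent for a fixed master seed."""
    cfg.path.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        run_stage(cfg, stage)
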