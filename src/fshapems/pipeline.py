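"""End-to-end orchestration: simulate → F-shapes → atlas/train → classify.

The three-part scheme:

(a) per eye, normalize orientation, restrict to the ROI, decimate onto the
    triangular mesh, and map GCIPL thickness onto the ILM geometry to form
    the F-shape;
(b) estimate the atlas (mean template + registered training F-shapes) on the
    training eyes, form residual features, reduce with PCA, and select an
    SVM by leave-one-out grid search;
(c) register each test eye to the frozen template, form its residual,
    project with the stored PCA, and classify.

The sectoral baseline runs the nine ETDRS sector means through the same
LOO-grid-search SVM on the identical split, for a head-to-head comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import etdrs, features, grids, meshing, registration, synthetic
from .grids import Label, ROIFrame, SubjectRecord, normalize_orientation, roi_point_count
from .meshing import FShape, TriMesh, build_tri_mesh, assemble_fshape
from .registration import RegistrationConfig, estimate_atlas, register_subject
from .synthetic import CohortConfig

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "build_fshapes",
    "mean_ilm_grid",
    "make_hypertemplate",
    "train_fshape_model",
    "classify_fshapes",
    "sectoral_baseline",
    "run_experiment",
]


@dataclass
class RunConfig:
    """Fully-defaulted, reproducible run configuration."""

    out_dir: str = "fshapems_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    roi: ROIFrame | None = None  # None → default frame scaled to the lattice
    subject_fraction: float = 0.04
    template_fraction: float = 0.045
    subject_side: float | None = None  # lattice units; None → sqrt(1/fraction)
    template_side: float | None = None
    registration: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(
            max_iter=12, inner_steps=1, update_template_geometry=False
        )
    )
    # per-eye registration budget at test time; None matches the per-eye
    # update budget the training eyes received inside the atlas loop, so
    # train and test residuals are on the same optimization scale
    classify_max_iter: int | None = None
    pca_k: int | None = None
    pca_flatten_gain: float = 0.01
    svm_grid: list[features.SVMConfig] = field(default_factory=features.default_svm_grid)
    n_train_healthy: int = 28
    n_train_ms: int = 26
    split_seed: int = 0

    def resolve_roi(self) -> ROIFrame:
        if self.roi is not None:
            return self.roi
        h, w = self.cohort.grid_shape
        if w >= 396 and h >= 361:
            return ROIFrame()
        return ROIFrame().scaled_to(w, h)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "cohort" in kw:
            c = dict(kw["cohort"])
            if "grid_shape" in c:
                c["grid_shape"] = tuple(c["grid_shape"])
            kw["cohort"] = CohortConfig(**c)
        if "registration" in kw:
            kw["registration"] = RegistrationConfig(**kw["registration"])
        if "roi" in kw and kw["roi"] is not None:
            kw["roi"] = ROIFrame(**{k: tuple(v) for k, v in kw["roi"].items()})
        if "svm_grid" in kw:
            kw["svm_grid"] = [features.SVMConfig(**g) for g in kw["svm_grid"]]
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = {k: clean(getattr(self, k)) for k in (f.name for f in dataclasses.fields(self))}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Part (a): F-shape generation


def build_fshapes(
    records: list[SubjectRecord],
    roi: ROIFrame,
    fraction: float,
    side: float | None = None,
) -> list[FShape]:
    """Orientation-normalize and assemble F-shapes on one shared connectivity."""
    if not records:
        return []
    recs = [normalize_orientation(r) for r in records]
    mesh_template = build_tri_mesh(roi, recs[0].ilm, fraction, side)
    return [assemble_fshape(r, mesh_template) for r in recs]


def mean_ilm_grid(records: list[SubjectRecord]) -> grids.ThicknessGrid:
    recs = [normalize_orientation(r) for r in records]
    vals = np.mean([r.ilm.values for r in recs], axis=0)
    g0 = recs[0].ilm
    return grids.ThicknessGrid(vals, g0.pixel_pitch, g0.eye_side, "ILM_mean")


def make_hypertemplate(
    records: list[SubjectRecord],
    roi: ROIFrame,
    fraction: float = 0.045,
    side: float | None = None,
) -> FShape:
    """Zero-signal hypertemplate on the denser template mesh.

    Geometry is the mesh of the pointwise mean ILM surface of the training
    eyes; the thickness signal starts at zero everywhere.
    """
    surface = mean_ilm_grid(records)
    mesh = build_tri_mesh(roi, surface, fraction, side)
    return FShape(mesh, np.zeros(mesh.n_vertices))


# ---------------------------------------------------------------------------
# Part (b): training


@dataclass
class TrainedModel:
    atlas: registration.AtlasResult
    residuals: features.ResidualSet
    pca: features.PCAModel | None
    svm_config: features.SVMConfig
    cv_score: float
    svm: object
    cv_report: list[dict]
    reg_config: RegistrationConfig

    @property
    def train_update_budget(self) -> int:
        """Per-eye parameter updates performed during atlas estimation."""
        sweeps = max(len(self.atlas.objective_trace) - 1, 1)
        return sweeps * self.reg_config.inner_steps

    def transform(self, residual_rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(residual_rows)
        if self.pca is None:
            return rows
        return features.pca_transform(self.pca, rows)


def train_fshape_model(
    train_shapes: list[FShape],
    train_labels: list[Label],
    hypertemplate: FShape,
    cfg: RunConfig,
) -> TrainedModel:
    atlas = estimate_atlas(train_shapes, hypertemplate, cfg.registration)
    resid = features.compute_residuals(atlas, train_labels)
    n, m = resid.matrix.shape
    use_pca = m > n or cfg.pca_k is not None
    pca = None
    feats = resid.matrix
    if use_pca:
        pca = features.fit_pca(resid.matrix, k=cfg.pca_k, flatten_gain=cfg.pca_flatten_gain)
        feats = features.pca_transform(pca, resid.matrix)
    best_cfg, cv_score, svm, report = features.loo_grid_search(feats, train_labels, cfg.svm_grid)
    log.info("best SVM config %s with LOO CV score %.3f", best_cfg, cv_score)
    return TrainedModel(atlas, resid, pca, best_cfg, cv_score, svm, report, cfg.registration)


# ---------------------------------------------------------------------------
# Part (c): classification


def residuals_for_new_eyes(
    model: TrainedModel, fshapes: list[FShape], max_iter: int | None = None
) -> np.ndarray:
    """Register new eyes to the frozen template and return residual rows."""
    template = model.atlas.template
    reg_cfg = dataclasses.replace(
        model.reg_config,
        max_iter=model.train_update_budget if max_iter is None else max_iter,
    )
    rows = []
    for fs in fshapes:
        _, registered, _ = register_subject(template, fs, reg_cfg)
        rows.append(template.signal - registered.signal)
    return np.array(rows)


def classify_fshapes(
    model: TrainedModel,
    fshapes: list[FShape],
    labels: list[Label] | None = None,
    max_iter: int | None = None,
):
    """Predict each eye; returns (predictions, metrics-or-None, residual rows)."""
    resid = residuals_for_new_eyes(model, fshapes, max_iter=max_iter)
    feats = model.transform(resid)
    pred_num = model.svm.predict(feats)
    preds = [Label.MS if p == 1 else Label.HEALTHY for p in pred_num]
    metrics = features.evaluate(model.svm, feats, labels) if labels is not None else None
    return preds, metrics, resid


# ---------------------------------------------------------------------------
# Sectoral baseline


def sectoral_features(records: list[SubjectRecord]) -> np.ndarray:
    rows = []
    for rec in records:
        rec = normalize_orientation(rec)
        grid = etdrs.build_etdrs_grid(rec.thickness.values.shape, rec.thickness.pixel_pitch)
        rows.append(etdrs.sector_means(rec.thickness, grid).to_numpy())
    return np.array(rows)


def sectoral_baseline(
    train_records: list[SubjectRecord],
    test_records: list[SubjectRecord],
    svm_grid: list[features.SVMConfig],
):
    """Nine ETDRS sector means → LOO grid-search SVM → test metrics."""
    Xtr = sectoral_features(train_records)
    Xte = sectoral_features(test_records)
    ytr = [r.label for r in train_records]
    yte = [r.label for r in test_records]
    best_cfg, cv_score, svm, report = features.loo_grid_search(Xtr, ytr, svm_grid)
    metrics = features.evaluate(svm, Xte, yte)
    return {
        "svm_config": best_cfg,
        "cv_score": cv_score,
        "metrics": metrics,
        "cv_report": report,
        "features_train": Xtr,
        "features_test": Xte,
    }


# ---------------------------------------------------------------------------
# Full experiment


def run_experiment(cfg: RunConfig) -> dict:
    """Simulate a cohort and run both pipelines end to end.

    Returns a dict with the F-shape test metrics, the sectoral baseline
    metrics, the residual-vs-raw significant-vertex fractions, and the
    objective trace.
    """
    records, _ = synthetic.generate_cohort(cfg.cohort)
    train_idx, test_idx = synthetic.make_split(
        records, cfg.n_train_healthy, cfg.n_train_ms, seed=cfg.split_seed
    )
    roi = cfg.resolve_roi()
    train_recs = [records[i] for i in train_idx]
    test_recs = [records[i] for i in test_idx]

    train_shapes = build_fshapes(train_recs, roi, cfg.subject_fraction, cfg.subject_side)
    test_shapes = build_fshapes(test_recs, roi, cfg.subject_fraction, cfg.subject_side)
    train_labels = [r.label for r in train_recs]
    test_labels = [r.label for r in test_recs]

    hyper = make_hypertemplate(train_recs, roi, cfg.template_fraction, cfg.template_side)
    model = train_fshape_model(train_shapes, train_labels, hyper, cfg)
    preds, metrics, test_resid = classify_fshapes(
        model, test_shapes, test_labels, max_iter=cfg.classify_max_iter
    )

    sect = sectoral_baseline(train_recs, test_recs, cfg.svm_grid)

    # residual-vs-raw discriminability on the training eyes
    resid = model.residuals.matrix
    is_ms = np.array([l == Label.MS for l in train_labels])
    frac_resid = features.pointwise_ttest_fraction(resid[~is_ms], resid[is_ms])
    raw = np.array([fs.signal for fs in train_shapes])
    frac_raw = features.pointwise_ttest_fraction(raw[~is_ms], raw[is_ms])

    return {
        "model": model,
        "test_metrics": metrics,
        "test_predictions": preds,
        "cv_score": model.cv_score,
        "svm_config": model.svm_config,
        "pca_k": model.pca.k if model.pca is not None else None,
        "sectoral": sect,
        "significant_fraction_residual": frac_resid,
        "significant_fraction_raw": frac_raw,
        "objective_trace": model.atlas.objective_trace,
        "n_train": len(train_idx),
        "n_test": len(test_idx),
    }


# ---------------------------------------------------------------------------
# Artifact persistence (used by the CLI)


def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = model.atlas
    meshing.export_ply(atlas.template, out / "template.ply")
    meshing.export_vtk(atlas.template, out / "template.vtk")
    np.savez(
        out / "atlas.npz",
        template_vertices=atlas.template.mesh.vertices,
        template_faces=atlas.template.mesh.faces,
        template_lattice=atlas.template.mesh.lattice_index,
        template_pitch=atlas.template.mesh.pixel_pitch,
        template_signal=atlas.template.signal,
        residuals=model.residuals.matrix,
        residual_labels=[l.value for l in model.residuals.labels],
        momenta=np.array([p.p for p in atlas.params]),
        zeta=np.array([p.zeta for p in atlas.params]),
    )
    with open(out / "trace.json", "w") as fh:
        json.dump({"objective_trace": atlas.objective_trace}, fh)
    with open(out / "cv_report.json", "w") as fh:
        json.dump(
            [
                {"config": dataclasses.asdict(r["config"]), "cv_score": r["cv_score"]}
                for r in model.cv_report
            ],
            fh,
            indent=1,
        )
    joblib.dump(
        {
            "svm": model.svm,
            "svm_config": model.svm_config,
            "cv_score": model.cv_score,
            "pca": model.pca,
            "reg_config": model.reg_config,
        },
        out / "classifier.joblib",
    )


def load_model(out_dir: str | Path) -> TrainedModel:
    out = Path(out_dir)
    clf_path = out / "classifier.joblib"
    if not clf_path.exists():
        raise FileNotFoundError(f"no trained model at {clf_path}; run `train` first")
    blob = joblib.load(clf_path)
    with np.load(out / "atlas.npz") as nz:
        mesh = TriMesh(
            nz["template_vertices"],
            nz["template_faces"],
            nz["template_lattice"],
            float(nz["template_pitch"]),
        )
        template = FShape(mesh, nz["template_signal"])
        resid = features.ResidualSet(
            nz["residuals"],
            [Label(l) for l in nz["residual_labels"]],
            mesh.lattice_index,
        )
        momenta = nz["momenta"]
        zeta = nz["zeta"]
    params = [registration.RegistrationParams(p, z) for p, z in zip(momenta, zeta)]
    with open(out / "trace.json") as fh:
        trace = json.load(fh)["objective_trace"]
    atlas = registration.AtlasResult(template, [], params, trace)
    return TrainedModel(
        atlas,
        resid,
        blob["pca"],
        blob["svm_config"],
        blob["cv_score"],
        blob["svm"],
        [],
        blob["reg_config"],
    )
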