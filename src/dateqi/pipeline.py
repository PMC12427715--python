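"""End-to-end analysis orchestration.

Wires the library stages into the reproducible workflow used by the
command line: simulate a storage study, preprocess spectra (every
stateful transform — MSC reference, normalization spec, input
standardization — is fitted on training rows only), build the composite
Qi, calibrate PLSR (with latent-variable selection) and the neural
regressor, and evaluate both on the held-out subsets with the full
figure-of-merit suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import MLPConfig, compare_models, mlp_fit, mlp_predict
from .chemometrics import (
    MetricsReport,
    aggregate_combined,
    compute_metrics,
    cross_validate_lv,
    make_group_folds,
    plsr_fit,
    plsr_predict,
    split_dataset,
)
from .degradation import compare_linear_quadratic
from .preprocessing import PreprocessingPipeline, SpectraMatrix
from .quality_index import DEFAULT_ATTRIBUTES, build_normalization_spec, qi_table
from .synthetic import (
    SpectralGeneratorParams,
    StudyDesign,
    TrajectoryParams,
    desk_design,
    generate_study,
    write_dataset,
)

__all__ = ["RunConfig", "run_simulate", "run_analysis", "run_degradation"]


@dataclass
class RunConfig:
    """Settings for a full simulate -> analyze -> degradation run."""

    seed: int = 0
    scale: str = "desk"  # "desk" or "full"
    split_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    qi_attributes: tuple[str, ...] = DEFAULT_ATTRIBUTES
    qi_directions: dict = field(default_factory=dict)
    window_lo_nm: float = 410.0
    window_hi_nm: float = 990.0
    sg_window_points: int = 13
    sg_poly_order: int = 2
    plsr_max_components: int = 10
    plsr_cv_folds: int = 10
    mlp_hidden: tuple[int, ...] = (32,)
    mlp_epochs: int = 500
    mlp_learning_rate: float = 2e-3
    mlp_batch_size: int = 64
    mlp_patience: int = 60
    mlp_cv_folds: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def __post_init__(self) -> None:
        self.split_fractions = tuple(self.split_fractions)
        self.qi_attributes = tuple(self.qi_attributes)
        self.mlp_hidden = tuple(self.mlp_hidden)
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")

    def design(self) -> StudyDesign:
        base = desk_design(self.seed) if self.scale == "desk" else StudyDesign(seed=self.seed)
        return base

    def provenance(self) -> dict:
        digest = hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return {"package_version": __version__, "seed": self.seed, "config_hash": digest}


def run_simulate(cfg: RunConfig, outdir) -> dict:
    """Generate the synthetic study and write the dataset files."""
    design = cfg.design()
    tparams, sparams = TrajectoryParams(), SpectralGeneratorParams()
    records, spectra = generate_study(design, tparams, sparams)
    paths = write_dataset(records, spectra, outdir, design, tparams, sparams)
    return {str(k): str(v) for k, v in paths.items()}


def _metrics_by_cultivar(
    cultivars_cal, y_cal, p_cal, cultivars_cv, y_cv, p_cv, cultivars_val, y_val, p_val
) -> dict[str, MetricsReport]:
    out: dict[str, MetricsReport] = {}
    for cul in sorted(set(cultivars_val)):
        mc = np.asarray(cultivars_cal) == cul
        mv = np.asarray(cultivars_cv) == cul
        mt = np.asarray(cultivars_val) == cul
        out[cul] = compute_metrics(
            y_cal[mc], p_cal[mc], y_cv[mv], p_cv[mv], y_val[mt], p_val[mt]
        )
    return out


def _report_block(per_cultivar: dict[str, MetricsReport], pooled: MetricsReport) -> dict:
    block = {
        "per_cultivar": {c: m.to_dict() for c, m in per_cultivar.items()},
        "pooled": pooled.to_dict(),
    }
    if len(per_cultivar) >= 2:
        block["combined"] = aggregate_combined(
            [m.to_dict() for m in per_cultivar.values()]
        )
    return block


def run_analysis(
    cfg: RunConfig, records: pd.DataFrame, spectra: SpectraMatrix
) -> dict:
    """Preprocess -> Qi -> split -> PLSR + MLP -> figure-of-merit report.

    Subset roles follow calibration practice: 70% calibration, 20%
    early-stopping/testing, 10% independent prediction (the RMSEP set).
    """
    # --- replicate-aware split at scan level
    plan = split_dataset(
        spectra.sample_ids,
        spectra.replicate_group_ids,
        fractions=cfg.split_fractions,
        seed=cfg.seed,
    )
    part = plan.partition_of()
    roles = np.array([part[s] for s in spectra.sample_ids])
    idx = {name: np.where(roles == name)[0] for name in ("train", "test", "validation")}

    # --- preprocessing fitted on the calibration rows only
    pipe = PreprocessingPipeline(
        lo_nm=cfg.window_lo_nm,
        hi_nm=cfg.window_hi_nm,
        sg_window_points=cfg.sg_window_points,
        sg_poly_order=cfg.sg_poly_order,
    )
    train_matrix = SpectraMatrix(
        sample_ids=[spectra.sample_ids[i] for i in idx["train"]],
        replicate_group_ids=[spectra.replicate_group_ids[i] for i in idx["train"]],
        wavelengths_nm=spectra.wavelengths_nm,
        values=spectra.values[idx["train"]],
        mode=spectra.mode,
    )
    pipe.fit_transform(train_matrix)
    processed = pipe.transform(spectra)
    X = processed.values

    # --- reference Qi from the quality table, spec frozen on training records
    rec = records.set_index(records["sample_id"].astype(str))
    train_record_ids = sorted({spectra.replicate_group_ids[i] for i in idx["train"]})
    spec = build_normalization_spec(
        rec.loc[train_record_ids], directions=cfg.qi_directions,
        attributes=cfg.qi_attributes,
    )
    qi_all = qi_table(rec, spec, cfg.qi_attributes)
    y = np.array([qi_all[g] for g in spectra.replicate_group_ids])
    cultivar = rec["cultivar"].reindex(spectra.replicate_group_ids).to_numpy()

    Xtr, ytr = X[idx["train"]], y[idx["train"]]
    Xte, yte = X[idx["test"]], y[idx["test"]]
    Xva, yva = X[idx["validation"]], y[idx["validation"]]
    groups_tr = [spectra.replicate_group_ids[i] for i in idx["train"]]
    cul_tr, cul_va = cultivar[idx["train"]], cultivar[idx["validation"]]

    # --- PLSR with grouped latent-variable selection
    lv = cross_validate_lv(
        Xtr, ytr, groups_tr,
        max_components=cfg.plsr_max_components,
        k_folds=cfg.plsr_cv_folds,
        seed=cfg.seed,
    )
    plsr = plsr_fit(Xtr, ytr, lv.selected_lv)
    plsr_cal = plsr_predict(plsr, Xtr)
    plsr_val = plsr_predict(plsr, Xva)
    plsr_per_cul = _metrics_by_cultivar(
        cul_tr, ytr, plsr_cal, cul_tr, ytr, lv.cv_predictions, cul_va, yva, plsr_val
    )
    plsr_pooled = compute_metrics(ytr, plsr_cal, ytr, lv.cv_predictions, yva, plsr_val)

    # --- neural regressor: early stopping on the 20% testing subset,
    #     grouped CV on the calibration subset for RMSECV
    mlp_cfg = MLPConfig(
        hidden_layer_sizes=cfg.mlp_hidden,
        max_epochs=cfg.mlp_epochs,
        learning_rate=cfg.mlp_learning_rate,
        batch_size=cfg.mlp_batch_size,
        early_stopping_patience=cfg.mlp_patience,
        seed=cfg.seed,
    )
    mlp = mlp_fit(Xtr, ytr, Xte, yte, mlp_cfg)
    mlp_cal = mlp_predict(mlp, Xtr)
    mlp_val = mlp_predict(mlp, Xva)

    # Fold fits early-stop on the 20% testing subset, which is replicate-
    # disjoint from every calibration fold, so no fold row leaks into its
    # own stopping criterion.
    folds = make_group_folds(groups_tr, cfg.mlp_cv_folds, seed=cfg.seed)
    mlp_cv = np.full(ytr.size, np.nan)
    for fold in folds:
        mask = np.ones(ytr.size, dtype=bool)
        mask[fold] = False
        fold_model = mlp_fit(Xtr[mask], ytr[mask], Xte, yte, mlp_cfg)
        mlp_cv[fold] = mlp_predict(fold_model, Xtr[fold])
    mlp_per_cul = _metrics_by_cultivar(
        cul_tr, ytr, mlp_cal, cul_tr, ytr, mlp_cv, cul_va, yva, mlp_val
    )
    mlp_pooled = compute_metrics(ytr, mlp_cal, ytr, mlp_cv, yva, mlp_val)

    report = {
        "provenance": cfg.provenance(),
        "n_samples": len(spectra.sample_ids),
        "split_sizes": {k: int(v.size) for k, v in idx.items()},
        "qi_attributes": list(cfg.qi_attributes),
        "plsr": {
            "selected_lv": lv.selected_lv,
            "rmsecv_per_lv": lv.rmsecv_per_lv.tolist(),
            **_report_block(plsr_per_cul, plsr_pooled),
        },
        "ann": {
            "best_epoch": mlp.best_epoch,
            **_report_block(mlp_per_cul, mlp_pooled),
        },
        "comparison": compare_models(plsr_pooled, mlp_pooled),
    }
    return report


def run_degradation(cfg: RunConfig, records: pd.DataFrame, qi_column: str = "qi") -> dict:
    """Aggregate Qi per (cultivar, month) and compare the nested
    linear/quadratic shelf-life models."""
    if qi_column not in records.columns:
        raise ValueError(f"quality table lacks a {qi_column!r} column")
    months = records["month"].unique()
    if months.size < 4:
        raise ValueError("need at least 4 storage time points")
    out: dict = {"provenance": cfg.provenance(), "per_cultivar": {}}
    for cul, sub in records.groupby("cultivar"):
        series = sub.groupby("month")[qi_column].mean()
        comp = compare_linear_quadratic(
            series.index.to_numpy(dtype=float), series.to_numpy()
        )
        out["per_cultivar"][cul] = json.loads(comp.to_json())
    return out
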