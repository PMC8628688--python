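"""Model/Results facade over the grading pipeline.

``GradeClassificationModel`` bundles a cohort's clinical records, per-section
spatial features and tumor-bed areas; ``fit()`` runs the full protocol —
collinearity pruning, patient-level stratified split, standardization,
minority oversampling (SMOTE for clinical features, borderline SMOTE for
spatial features), repeated SFFS with modal-subset voting, randomized
hyperparameter search, per-channel model training, TBR aggregation of section
probabilities, and the clinical/spatial fusion-weight scan — and returns a
``GradeClassificationResults`` carrying metric panels, the fusion curve, the
selected feature sets and a leakage audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ensemble, mlpipe
from .features import DensityConfig, extract_features_table

CLINICAL_FEATURES = ["age", "ER", "PR", "HER2"]
CLINICAL_CONTINUOUS = ["age", "ER", "PR"]


@dataclass(frozen=True)
class PipelineConfig:
    """Protocol sizes and knobs; defaults follow the full study protocol."""

    test_fraction: float = 0.30
    clinical_models: tuple[str, ...] = ("logistic",)
    spatial_models: tuple[str, ...] = ("random_forest",)
    sffs_iterations: int = 100
    sffs_folds: int = 10
    sffs_cap: int = 10
    sffs_tol: float = 1e-3
    rgs_iterations: int = 100
    rgs_folds: int = 10
    fusion_folds: int = 10
    fusion_step: float = 0.01
    r2_threshold: float = 0.7
    smote_k: int = 5
    threshold: float = 0.5
    run_rgs: bool = True
    seed: int = 0

    def scaled(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass
class ChannelFit:
    model_name: str
    selection: mlpipe.SelectionResult
    search: mlpipe.SearchResult | None
    features: tuple[str, ...]
    train_probs: pd.Series      # out-of-fold, patient-level
    test_probs: pd.Series       # patient-level
    model: object
    prune_report: pd.DataFrame | None = None

    def recovered(self, feature: str) -> bool:
        """True when the modal subset contains ``feature`` or the retained
        feature it was merged into during collinearity pruning."""
        rep = feature if self.prune_report is None else \
            mlpipe.pruned_representative(self.prune_report, feature)
        return rep in self.selection.modal_subset


class GradeClassificationModel:
    """Binary grade (G3 vs G1,2) classifier built from cohort tables.

    Parameters
    ----------
    clinical : DataFrame with patient_id, age, ER, PR, HER2, label
    spatial_features : DataFrame with patient_id, section_id + 52 feature columns
    sections : DataFrame with section_id, tumor_bed_area_px
    config : PipelineConfig
    """

    def __init__(self, clinical: pd.DataFrame, spatial_features: pd.DataFrame,
                 sections: pd.DataFrame, config: PipelineConfig | None = None):
        self.clinical = clinical.set_index("patient_id", drop=False)
        self.spatial_features = spatial_features
        self.sections = sections
        self.config = config or PipelineConfig()
        self.labels = self.clinical["label"].astype(int)
        self._audit: list[tuple[str, frozenset]] = []

    @classmethod
    def from_cohort(cls, cohort, density_config: DensityConfig | None = None,
                    config: PipelineConfig | None = None,
                    min_nuclei: int = 10) -> "GradeClassificationModel":
        feats, _ = extract_features_table(
            cohort.centroids, density_config, extent=cohort.spec.extent,
            min_nuclei=min_nuclei)
        return cls(cohort.clinical, feats, cohort.sections, config)

    # ------------------------------------------------------------- internals

    def _log(self, step: str, ids) -> None:
        self._audit.append((step, frozenset(ids)))

    def _oof_probs(self, model_name, params, X, y, groups, folds, seed,
                   oversample_variant) -> np.ndarray:
        fold_list = mlpipe._folds(y, groups, folds, seed)
        X = np.asarray(X, float)
        y = np.asarray(y).astype(int)
        oof = np.full(len(y), np.nan)
        for tr, va in fold_list:
            X_tr, y_tr = X[tr], y[tr]
            if oversample_variant:
                try:
                    X_tr, y_tr = mlpipe.oversample(
                        X_tr, y_tr, oversample_variant,
                        k=self.config.smote_k, seed=seed)
                except ValueError:
                    pass
            m = mlpipe.make_model(model_name, params, seed)
            m.fit(X_tr, y_tr)
            oof[va] = m.predict_proba(X[va])[:, 1]
        # folds partition the data; guard against a degenerate fold anyway
        oof[np.isnan(oof)] = 0.5
        return oof

    def _fit_channel(self, model_name: str, X: pd.DataFrame, y: pd.Series,
                     groups, variant: str, feature_set: str,
                     train_mask: np.ndarray,
                     patient_ids: pd.Series) -> ChannelFit:
        cfg = self.config
        X_train = X.loc[train_mask]
        y_train = y.loc[train_mask]
        g_train = patient_ids.loc[train_mask] if groups else None
        self._log(f"prune:{feature_set}", patient_ids.loc[train_mask])
        retained, prune_report = mlpipe.prune_collinear(
            X_train[[c for c in X_train.columns
                     if X_train[c].nunique() > 2]],
            y_train, cfg.r2_threshold)
        keep = [c for c in X.columns
                if c in retained or X_train[c].nunique() <= 2]
        std = mlpipe.StandardizationParams.fit(X_train[keep])
        Z_train = std.transform(X_train[keep])
        Z_test = std.transform(X.loc[~train_mask, keep])
        self._log(f"sffs:{feature_set}:{model_name}", patient_ids.loc[train_mask])
        sel = mlpipe.sffs_select(
            model_name, Z_train, y_train, groups=g_train,
            iterations=cfg.sffs_iterations, folds=cfg.sffs_folds,
            cap=cfg.sffs_cap, seed=cfg.seed, tol=cfg.sffs_tol,
            oversample_variant=variant)
        feats = list(sel.modal_subset) or list(keep)
        search = None
        params = None
        if cfg.run_rgs:
            self._log(f"rgs:{feature_set}:{model_name}",
                      patient_ids.loc[train_mask])
            search = mlpipe.random_search(
                model_name, Z_train[feats], y_train, groups=g_train,
                iterations=cfg.rgs_iterations, folds=cfg.rgs_folds,
                seed=cfg.seed, oversample_variant=variant)
            params = search.best_params
        X_bal, y_bal = mlpipe.oversample(
            Z_train[feats].to_numpy(), y_train.to_numpy(), variant,
            k=cfg.smote_k, seed=cfg.seed)
        model = mlpipe.train_model(model_name, X_bal, y_bal, params,
                                   feature_set=feature_set, seed=cfg.seed)
        oof = self._oof_probs(model_name, params, Z_train[feats], y_train,
                              g_train, cfg.sffs_folds, cfg.seed, variant)
        test_p = mlpipe.predict_proba1(model, Z_test[feats])
        train_probs = pd.Series(oof, index=X_train.index)
        test_probs = pd.Series(test_p, index=X.loc[~train_mask].index)
        return ChannelFit(model_name, sel, search, tuple(feats),
                          train_probs, test_probs, model, prune_report)

    # ------------------------------------------------------------------ fit

    def fit(self) -> "GradeClassificationResults":
        cfg = self.config
        train_ids, test_ids = mlpipe.split_cohort(
            self.labels, mlpipe.SplitSpec(cfg.test_fraction, seed=cfg.seed))
        train_set = set(train_ids)

        # clinical channel: one row per patient
        X_clin = self.clinical[CLINICAL_FEATURES].astype(float)
        mask_clin = self.clinical["patient_id"].isin(train_set).to_numpy()
        clinical_fits: dict[str, ChannelFit] = {}
        for name in cfg.clinical_models:
            clinical_fits[name] = self._fit_channel(
                name, X_clin, self.labels, groups=None, variant="smote",
                feature_set="clinical", train_mask=mask_clin,
                patient_ids=self.clinical["patient_id"])

        # spatial channel: one row per section, labeled with the patient grade
        feat_cols = [c for c in self.spatial_features.columns
                     if c not in ("patient_id", "section_id")]
        spat = self.spatial_features.set_index("section_id", drop=False)
        X_spat = spat[feat_cols].astype(float)
        y_spat = spat["patient_id"].map(self.labels).astype(int)
        mask_spat = spat["patient_id"].isin(train_set).to_numpy()
        spatial_fits: dict[str, ChannelFit] = {}
        for name in cfg.spatial_models:
            fit = self._fit_channel(
                name, X_spat, y_spat, groups=True, variant="borderline",
                feature_set="spatial", train_mask=mask_spat,
                patient_ids=spat["patient_id"])
            # section -> patient aggregation by tumor-bed ratio
            fit.train_probs = self._aggregate(fit.train_probs, spat)
            fit.test_probs = self._aggregate(fit.test_probs, spat)
            spatial_fits[name] = fit

        y_train = self.labels.loc[train_ids]
        clin_train = {n: f.train_probs.reindex(train_ids)
                      for n, f in clinical_fits.items()}
        spat_train = {n: f.train_probs.reindex(train_ids)
                      for n, f in spatial_fits.items()}
        self._log("fusion_scan", train_ids)
        best_pair, fusion, pair_table = ensemble.scan_all_pairs(
            clin_train, spat_train, y_train,
            folds=cfg.fusion_folds, step=cfg.fusion_step, seed=cfg.seed)

        # final, single touch of the test set
        self._log("evaluate", test_ids)
        y_test = self.labels.loc[test_ids]
        panels: dict[str, mlpipe.MetricPanel] = {}
        for n, f in clinical_fits.items():
            panels[f"clinical:{n}"] = mlpipe.evaluate(
                f.test_probs.reindex(test_ids), y_test, cfg.threshold)
        for n, f in spatial_fits.items():
            panels[f"spatial:{n}"] = mlpipe.evaluate(
                f.test_probs.reindex(test_ids), y_test, cfg.threshold)
        fused_test = ensemble.fuse(
            clinical_fits[best_pair[0]].test_probs.reindex(test_ids),
            spatial_fits[best_pair[1]].test_probs.reindex(test_ids),
            fusion.w_star)
        panels["ensemble"] = mlpipe.evaluate(fused_test, y_test, cfg.threshold)

        return GradeClassificationResults(
            model=self, train_ids=train_ids, test_ids=test_ids,
            clinical_fits=clinical_fits, spatial_fits=spatial_fits,
            best_pair=best_pair, fusion=fusion, pair_table=pair_table,
            panels=panels, audit=list(self._audit))

    @staticmethod
    def _aggregate(section_probs: pd.Series, spat: pd.DataFrame) -> pd.Series:
        df = pd.DataFrame({
            "section_id": section_probs.index,
            "patient_id": spat.loc[section_probs.index, "patient_id"],
            "probability": section_probs.to_numpy(),
        })
        return ensemble.aggregate_patients(df, None)


@dataclass
class GradeClassificationResults:
    """Fitted-pipeline results: estimates, diagnostics and summary table."""

    model: GradeClassificationModel
    train_ids: list
    test_ids: list
    clinical_fits: dict[str, ChannelFit]
    spatial_fits: dict[str, ChannelFit]
    best_pair: tuple[str, str]
    fusion: ensemble.FusionResult
    pair_table: pd.DataFrame
    panels: dict[str, mlpipe.MetricPanel]
    audit: list = field(default_factory=list)

    def panel_table(self) -> pd.DataFrame:
        return pd.DataFrame({k: v.as_series() for k, v in self.panels.items()}).T

    def selection_report(self) -> pd.DataFrame:
        rows = []
        for kind, fits in (("clinical", self.clinical_fits),
                           ("spatial", self.spatial_fits)):
            for name, f in fits.items():
                rows.append({
                    "channel": kind, "model": name,
                    "modal_subset": " + ".join(f.selection.modal_subset),
                    "frequency": f.selection.modal_frequency,
                    "cv_auc": f.selection.modal_auc,
                })
        return pd.DataFrame(rows)

    def leakage_audit_ok(self) -> bool:
        """True when test patients were touched only at final evaluation."""
        test = frozenset(self.test_ids)
        for step, ids in self.audit:
            if step != "evaluate" and ids & test:
                return False
        return True

    def summary(self) -> str:
        lines = ["Grade classification pipeline (G3 vs G1,2)",
                 "=" * 58,
                 f"patients: {len(self.train_ids)} train / "
                 f"{len(self.test_ids)} test",
                 f"selected ensemble: clinical={self.best_pair[0]} + "
                 f"spatial={self.best_pair[1]}",
                 f"fusion weight w* = {self.fusion.w_star:.2f} "
                 f"(clinical {self.fusion.clinical_weight_pct:.0f}% / "
                 f"spatial {100 - self.fusion.clinical_weight_pct:.0f}%)",
                 "",
                 "Modal feature sets",
                 "-" * 58]
        for _, row in self.selection_report().iterrows():
            lines.append(f"  {row.channel}:{row.model}  (f={row.frequency})")
            lines.append(f"    {row.modal_subset}")
        lines += ["", "Test-set metric panel", "-" * 58]
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:0.3f}".format):
            lines.append(self.panel_table()[
                ["AUC", "ACC", "Sn", "Sp", "PPV", "NPV", "LR+", "LR-",
                 "DOR", "f1"]].to_string())
        lines.append("")
        lines.append(f"leakage audit: "
                     f"{'clean' if self.leakage_audit_ok() else 'VIOLATION'}")
        return "\n".join(lines)
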