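"""Section-to-patient aggregation and clinical/spatial probability fusion.

Spatial-model predictions are made per CNB section; a patient-level spatial
probability is the tumor-bed-ratio (TBR) weighted average of their sections'
probabilities, where a section's TBR is its tumor-bed pixel area divided by
the summed tumor-bed areas on the slide. The patient-level clinical and
spatial probabilities are then fused linearly,

    p = (1 - w) * p_clinical + w * p_spatial,

with the mixing weight w scanned over {0, 0.01, ..., 1} and selected by mean
cross-validated AUC on the training patients; w = 0 is the clinical model
alone, w = 1 the spatial model alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


def compute_tbr(areas) -> np.ndarray:
    """Tumor-bed ratios of one patient's sections: area_s / sum(areas)."""
    a = np.asarray(areas, float)
    if a.size == 0:
        raise ValueError("need at least one section")
    if np.any(a < 0):
        raise ValueError("tumor-bed areas must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("total tumor-bed area is zero")
    return a / total


def aggregate_sections(probabilities, tbrs) -> float:
    """TBR-weighted average of one patient's section probabilities."""
    p = np.asarray(probabilities, float)
    t = np.asarray(tbrs, float)
    if p.shape != t.shape:
        raise ValueError("section probability and TBR lists differ in length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if abs(t.sum() - 1.0) > 1e-9 or np.any(t < 0):
        raise ValueError("TBRs must be non-negative and sum to 1")
    return float(np.dot(t, p))


def aggregate_patients(section_probs: pd.DataFrame,
                       sections: pd.DataFrame | None = None) -> pd.Series:
    """Patient-level spatial probabilities from per-section predictions.

    ``section_probs``: columns section_id, patient_id, probability.
    ``sections``: columns section_id, tumor_bed_area_px; if omitted, sections
    are weighted uniformly (logged fallback for missing TBR data).
    """
    df = section_probs.copy()
    if sections is not None:
        df = df.merge(sections[["section_id", "tumor_bed_area_px"]],
                      on="section_id", validate="one_to_one")
    else:
        df["tumor_bed_area_px"] = 1.0
    out = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        tbr = compute_tbr(grp["tumor_bed_area_px"].to_numpy())
        out[pid] = aggregate_sections(grp["probability"].to_numpy(), tbr)
    return pd.Series(out, name="probability")


def fuse(p_clin, p_spat, w: float):
    """Convex combination (1 - w) * clinical + w * spatial."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    pc = np.asarray(p_clin, float)
    ps = np.asarray(p_spat, float)
    if np.any((pc < 0) | (pc > 1)) or np.any((ps < 0) | (ps > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (1.0 - w) * pc + w * ps


@dataclass
class FusionResult:
    weights: np.ndarray          # the scanned grid (101 points by default)
    cv_auc: np.ndarray           # mean CV AUC per weight
    w_star: float                # argmax weight, ties -> smaller w
    clinical_weight_pct: float   # 100 * (1 - w_star)

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"w": self.weights, "cv_auc": self.cv_auc})

    def plot(self, ax=None):
        """AUC-vs-weight curve with the selected weight marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(self.weights, self.cv_auc, lw=1.5)
        ax.axvline(self.w_star, color="crimson", ls="--", lw=1,
                   label=f"w* = {self.w_star:.2f}")
        ax.set_xlabel("spatial weight w")
        ax.set_ylabel("mean CV AUC")
        ax.legend(frameon=False)
        return ax


def _fold_mean_auc(p: np.ndarray, y: np.ndarray, folds) -> float:
    aucs = [roc_auc_score(y[va], p[va]) for _, va in folds
            if len(np.unique(y[va])) == 2]
    return float(np.mean(aucs))


def scan_weights(
    p_clin: pd.Series,
    p_spat: pd.Series,
    labels: pd.Series,
    folds: int = 10,
    step: float = 0.01,
    seed: int = 0,
) -> FusionResult:
    """Scan the fusion weight grid by mean cross-validated AUC.

    All three inputs are indexed by patient id and must align. The same fold
    assignment is used at every weight, so the endpoints w=0 and w=1
    reproduce the single-channel CV AUCs exactly.
    """
    if not (p_clin.index.equals(p_spat.index) and p_clin.index.equals(labels.index)):
        p_spat = p_spat.reindex(p_clin.index)
        labels = labels.reindex(p_clin.index)
        if p_spat.isna().any() or labels.isna().any():
            raise ValueError("clinical/spatial predictions have misaligned patient ids")
    y = labels.to_numpy(dtype=int)
    pc = p_clin.to_numpy(dtype=float)
    ps = p_spat.to_numpy(dtype=float)
    n_steps = int(round(1.0 / step))
    weights = np.round(np.linspace(0.0, 1.0, n_steps + 1), 10)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_list = list(cv.split(np.zeros(len(y)), y))
    aucs = np.array([_fold_mean_auc(fuse(pc, ps, w), y, fold_list)
                     for w in weights])
    best = int(np.argmax(aucs))  # argmax returns the first (smallest w) on ties
    return FusionResult(weights, aucs, float(weights[best]),
                        100.0 * (1.0 - float(weights[best])))


def scan_all_pairs(
    clinical_preds: dict[str, pd.Series],
    spatial_preds: dict[str, pd.Series],
    labels: pd.Series,
    folds: int = 10,
    step: float = 0.01,
    seed: int = 0,
) -> tuple[tuple[str, str], FusionResult, pd.DataFrame]:
    """Evaluate every clinical x spatial model pairing; select the pair (and
    its weight) with the highest training-CV AUC — the test set stays
    untouched during selection."""
    rows = []
    best_key, best_result = None, None
    for cname, pc in sorted(clinical_preds.items()):
        for sname, ps in sorted(spatial_preds.items()):
            res = scan_weights(pc, ps, labels, folds=folds, step=step, seed=seed)
            rows.append({"clinical_model": cname, "spatial_model": sname,
                         "w_star": res.w_star,
                         "cv_auc": float(res.cv_auc.max())})
            if best_result is None or res.cv_auc.max() > best_result.cv_auc.max():
                best_key, best_result = (cname, sname), res
    return best_key, best_result, pd.DataFrame(rows)
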