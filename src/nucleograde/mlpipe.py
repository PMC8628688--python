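"""Machine-learning stage: collinearity pruning, patient-level splitting,
standardization, minority oversampling, repeated sequential forward feature
selection (SFFS) with modal-subset voting, randomized hyperparameter search,
model training, and an extended diagnostic metric panel.

Conventions baked in:

* All data-dependent steps (pruning, standardization parameters, oversampling,
  SFFS, randomized search) see training patients only; the test split is
  touched exactly once at final evaluation.
* SFFS is run for a number of independent iterations; each iteration reshuffles
  cross-validation folds, runs forward selection on mean CV AUC with a feature
  cap, and the most frequently occurring exact subset across iterations is the
  reported ("modal") feature set.
* The metric panel mirrors a standard diagnostic-test table: AUC, accuracy,
  sensitivity/specificity, prevalence, predictive values and their
  complements, likelihood ratios, diagnostic odds ratio and F1.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (ParameterSampler, StratifiedGroupKFold,
                                     StratifiedKFold)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

SUPPORTED_MODELS = ("knn", "logistic", "naive_bayes", "svm",
                    "random_forest", "xgboost")


# ------------------------------------------------------------------- pruning

def point_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of a continuous variable with a 0/1 label."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def prune_collinear(
    X: pd.DataFrame, y, r2_threshold: float = 0.7
) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of every highly correlated feature pair.

    Pairs with Pearson r^2 >= ``r2_threshold`` are visited in descending r^2;
    the member with the lower |point-biserial| correlation against the outcome
    label is dropped, until no violating pair remains among retained features.
    Constant features correlate with nothing; they are retained and flagged.
    """
    y = np.asarray(y).astype(float)
    cols = list(X.columns)
    V = X.to_numpy(dtype=float)
    stds = V.std(axis=0)
    constant = [c for c, s in zip(cols, stds) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(V, rowvar=False)
    r = np.nan_to_num(np.atleast_2d(r), nan=0.0)
    r2 = r**2
    pb = {c: abs(point_biserial(V[:, j], y)) for j, c in enumerate(cols)}
    pairs = [
        (r2[i, j], cols[i], cols[j])
        for i in range(len(cols)) for j in range(i + 1, len(cols))
        if r2[i, j] >= r2_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    report = []
    for r2_val, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        if pb[a] == pb[b]:  # tie -> drop the lexicographically later name
            loser = max(a, b)
        else:
            loser = a if pb[a] < pb[b] else b
        dropped.add(loser)
        report.append({"kept": a if loser == b else b, "dropped": loser,
                       "r2": float(r2_val)})
    retained = [c for c in cols if c not in dropped]
    rep = pd.DataFrame(report, columns=["kept", "dropped", "r2"])
    rep.attrs["constant_features"] = constant
    return retained, rep


def pruned_representative(report: pd.DataFrame, feature: str) -> str:
    """The retained feature standing in for ``feature`` after pruning.

    Follows dropped -> kept links transitively; a feature that was never
    dropped represents itself. Useful when a planted signal carrier is
    merged into a near-duplicate (r^2 above the pruning threshold)."""
    current = feature
    if report.empty:
        return current
    for _ in range(len(report) + 1):
        row = report[report["dropped"] == current]
        if row.empty:
            return current
        current = row["kept"].iloc[0]
    return current


# ------------------------------------------------------------------ splitting

@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.30
    stratify_by_label: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


def split_cohort(labels: pd.Series, spec: SplitSpec) -> tuple[list, list]:
    """Label-stratified patient-level split with per-class ceil test counts.

    ``labels``: Series of binary labels indexed by patient id. Test count per
    class = ceil(test_fraction * class size).
    """
    rng = np.random.default_rng(spec.seed)
    train, test = [], []
    classes = sorted(labels.unique()) if spec.stratify_by_label else [None]
    for c in classes:
        ids = np.asarray(labels.index if c is None else labels.index[labels == c])
        if len(ids) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 patients")
        n_test = math.ceil(spec.test_fraction * len(ids))
        perm = rng.permutation(len(ids))
        test += list(ids[perm[:n_test]])
        train += list(ids[perm[n_test:]])
    return sorted(train), sorted(test)


# -------------------------------------------------------------- standardizing

@dataclass
class StandardizationParams:
    """Training-set feature means/stddevs, re-applied verbatim to the test set."""

    mean: pd.Series
    std: pd.Series
    constant_features: list[str] = field(default_factory=list)

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "StandardizationParams":
        mean = X.mean()
        std = X.std(ddof=0)
        constant = list(std.index[std == 0])
        std = std.replace(0, 1.0)
        return cls(mean, std, constant)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mean) / self.std


# ---------------------------------------------------------------- oversampling

def _interpolate(rng, seeds: np.ndarray, nn_pool: np.ndarray,
                 nn_idx: np.ndarray, n_new: int) -> np.ndarray:
    picks = rng.integers(0, len(seeds), n_new)
    out = np.empty((n_new, seeds.shape[1]))
    for row, i in enumerate(picks):
        j = nn_idx[i, rng.integers(0, nn_idx.shape[1])]
        u = rng.random()
        out[row] = seeds[i] + u * (nn_pool[j] - seeds[i])
    return out


def oversample(
    X, y, variant: str = "smote", k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE / borderline-SMOTE up-sampling of the minority class.

    Plain SMOTE interpolates between a random minority point and one of its k
    minority-class neighbors. The borderline variant restricts the seed points
    to "danger" minority samples — at least half of their k nearest overall
    neighbors belong to the majority class, but not all (those are treated as
    noise) — and falls back to plain SMOTE with a warning when no danger
    points exist. Applied to training data only, by contract.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    counts = Counter(y)
    if len(counts) != 2:
        raise ValueError("oversample expects exactly two classes")
    (maj, n_maj), (mino, n_min) = counts.most_common()
    if n_maj == n_min:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    X_min = X[y == mino]
    k_eff = min(k, n_min - 1)
    if k_eff < 1:
        raise ValueError("minority class too small to oversample")
    if variant == "smote":
        seeds = X_min
    elif variant == "borderline":
        k_all = min(k, len(X) - 1)
        nn_all = NearestNeighbors(n_neighbors=k_all + 1).fit(X)
        _, idx = nn_all.kneighbors(X_min)
        n_majority_nb = np.array(
            [(y[row[1:]] == maj).sum() for row in idx])
        danger = (n_majority_nb * 2 >= k_all) & (n_majority_nb < k_all)
        if not danger.any():
            warnings.warn("no borderline (danger) minority points; "
                          "falling back to plain SMOTE", stacklevel=2)
            seeds = X_min
        else:
            seeds = X_min[danger]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    nn_min = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    _, nn_idx = nn_min.kneighbors(seeds)
    synth = _interpolate(rng, seeds, X_min, nn_idx[:, 1:], n_maj - n_min)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(len(synth), mino)])
    return X_out, y_out


# ------------------------------------------------------------------ models

DEFAULT_SEARCH_SPACES: dict[str, dict] = {
    "knn": {"n_neighbors": [3, 5, 7, 9, 11, 15], "weights": ["uniform", "distance"]},
    "logistic": {"C": [0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0]},
    "naive_bayes": {"var_smoothing": [1e-11, 1e-9, 1e-7, 1e-5]},
    "svm": {"C": [0.1, 0.3, 1.0, 3.0, 10.0], "gamma": ["scale", 0.01, 0.1, 1.0]},
    "random_forest": {"n_estimators": [50, 100, 200],
                      "max_depth": [None, 3, 5, 8],
                      "max_features": ["sqrt", 0.5]},
    "xgboost": {"n_estimators": [50, 100, 200], "max_depth": [2, 3, 4, 6],
                "learning_rate": [0.03, 0.1, 0.3], "subsample": [0.7, 1.0]},
}


def make_model(name: str, params: dict | None = None, seed: int = 0):
    """Instantiate a supported classifier producing class-1 probabilities."""
    params = dict(params or {})
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if name == "naive_bayes":
        return GaussianNB(**params)
    if name == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if name == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if name == "xgboost":
        from xgboost import XGBClassifier

        params.setdefault("n_estimators", 100)
        return XGBClassifier(random_state=seed, eval_metric="logloss",
                             verbosity=0, **params)
    raise ValueError(
        f"unknown model {name!r}; supported: {', '.join(SUPPORTED_MODELS)}")


def train_model(name: str, X, y, params: dict | None = None,
                feature_set: str = "spatial", seed: int = 0):
    """Fit one classifier; Naive Bayes is rejected for clinical feature sets
    (mixed continuous/ordinal inputs violate its Gaussian assumption)."""
    if name == "naive_bayes" and feature_set == "clinical":
        raise ValueError(
            "naive_bayes is excluded from clinical feature sets: HER2 status "
            "is ordinal and GaussianNB assumes continuous Gaussian features")
    model = make_model(name, params, seed)
    model.fit(np.asarray(X, float), np.asarray(y).astype(int))
    return model


def predict_proba1(model, X) -> np.ndarray:
    return model.predict_proba(np.asarray(X, float))[:, 1]


# --------------------------------------------------------------------- CV AUC

def _folds(y, groups, n_folds, seed):
    y = np.asarray(y).astype(int)
    if groups is not None:
        cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(y)), y, groups))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def cv_auc(model_name, params, X, y, folds, seed=0,
           oversample_variant: str | None = None, k_smote: int = 5) -> float:
    """Mean validation AUC over pre-computed folds; any oversampling is
    re-applied inside each training fold only."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    aucs = []
    for tr, va in folds:
        if len(np.unique(y[va])) < 2:
            continue
        X_tr, y_tr = X[tr], y[tr]
        if oversample_variant:
            try:
                X_tr, y_tr = oversample(X_tr, y_tr, oversample_variant,
                                        k=k_smote, seed=seed)
            except ValueError:
                pass
        model = make_model(model_name, params, seed)
        model.fit(X_tr, y_tr)
        aucs.append(roc_auc_score(y[va], model.predict_proba(X[va])[:, 1]))
    if not aucs:
        raise ValueError("no valid folds (a validation fold needs both classes)")
    return float(np.mean(aucs))


# ----------------------------------------------------------------------- SFFS

@dataclass
class SelectionResult:
    subsets: list[tuple[str, ...]]
    aucs: list[float]
    modal_subset: tuple[str, ...]
    modal_frequency: int
    modal_auc: float

    def frequency_table(self) -> pd.DataFrame:
        counts = Counter(self.subsets)
        rows = [{"subset": " + ".join(s), "size": len(s), "frequency": c}
                for s, c in counts.most_common()]
        return pd.DataFrame(rows)


def sffs_select(
    model_name: str,
    X: pd.DataFrame,
    y,
    groups=None,
    iterations: int = 100,
    folds: int = 10,
    cap: int = 10,
    seed: int = 0,
    tol: float = 1e-3,
    floating: bool = False,
    model_params: dict | None = None,
    oversample_variant: str | None = None,
) -> SelectionResult:
    """Repeated sequential forward feature selection with modal-subset voting.

    Each iteration draws fresh CV folds and grows a feature set greedily,
    adding the feature that maximizes mean CV AUC, until the cap is reached or
    the best addition improves the AUC by less than ``tol``. With
    ``floating=True`` a conditional-exclusion step may remove a previously
    added feature when that improves the criterion. The modal subset is the
    most frequent exact subset across iterations; ties break by higher mean
    CV AUC, then lexicographic name order.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    cols = list(X.columns)
    V = X.to_numpy(dtype=float)
    y = np.asarray(y).astype(int)
    subsets, aucs = [], []
    for it in range(iterations):
        it_seed = seed + 1000 * it
        fold_list = _folds(y, groups, folds, it_seed)

        def score(feature_idx: list[int]) -> float:
            return cv_auc(model_name, model_params, V[:, feature_idx], y,
                          fold_list, seed=it_seed,
                          oversample_variant=oversample_variant)

        selected: list[int] = []
        best_auc = -np.inf
        while len(selected) < cap:
            candidates = [j for j in range(len(cols)) if j not in selected]
            if not candidates:
                break
            scores = [(score(selected + [j]), j) for j in candidates]
            new_auc, j_best = max(scores, key=lambda t: (t[0], -t[1]))
            if new_auc <= best_auc + tol:
                break
            selected.append(j_best)
            best_auc = new_auc
            if floating and len(selected) > 2:
                improved = True
                while improved and len(selected) > 1:
                    improved = False
                    for j in list(selected):
                        trial = [s for s in selected if s != j]
                        a = score(trial)
                        if a > best_auc + tol:
                            selected, best_auc, improved = trial, a, True
                            break
        subsets.append(tuple(sorted(cols[j] for j in selected)))
        aucs.append(best_auc if np.isfinite(best_auc) else 0.5)
    counts = Counter(subsets)
    by_subset_auc = {
        s: float(np.mean([a for s2, a in zip(subsets, aucs) if s2 == s]))
        for s in counts
    }
    modal = sorted(counts, key=lambda s: (-counts[s], -by_subset_auc[s], s))[0]
    return SelectionResult(subsets, aucs, modal, counts[modal],
                           by_subset_auc[modal])


# ------------------------------------------------------------- random search

@dataclass
class SearchResult:
    best_params: dict
    best_auc: float
    trace: pd.DataFrame


def random_search(
    model_name: str,
    X,
    y,
    groups=None,
    space: dict | None = None,
    iterations: int = 100,
    folds: int = 10,
    seed: int = 0,
    oversample_variant: str | None = None,
) -> SearchResult:
    """Randomized hyperparameter search maximizing mean CV AUC.

    An empty search space returns the model defaults with a warning."""
    if space is None:
        space = DEFAULT_SEARCH_SPACES.get(model_name, {})
    if not space:
        warnings.warn(f"empty search space for {model_name}; using defaults",
                      stacklevel=2)
        fold_list = _folds(y, groups, folds, seed)
        auc = cv_auc(model_name, None, X, y, fold_list, seed=seed,
                     oversample_variant=oversample_variant)
        return SearchResult({}, auc, pd.DataFrame())
    sampler = ParameterSampler(space, n_iter=iterations, random_state=seed)
    rows = []
    best_params, best_auc = None, -np.inf
    for i, params in enumerate(sampler):
        fold_list = _folds(y, groups, folds, seed + i)
        auc = cv_auc(model_name, params, X, y, fold_list, seed=seed,
                     oversample_variant=oversample_variant)
        rows.append({**params, "cv_auc": auc})
        if auc > best_auc:
            best_params, best_auc = params, auc
    return SearchResult(best_params, float(best_auc), pd.DataFrame(rows))


# --------------------------------------------------------------- metric panel

@dataclass(frozen=True)
class MetricPanel:
    """Diagnostic-test metric panel at a fixed probability threshold.

    Percentages (ACC..FOR) are on the 0-100 scale; AUC, likelihood ratios,
    DOR and f1 are plain ratios.
    """

    auc: float
    acc: float
    sn: float
    sp: float
    prev: float
    fnr: float
    fpr: float
    ppv: float
    npv: float
    fdr: float
    f_or: float
    lr_pos: float
    lr_neg: float
    dor: float
    f1: float
    tp: int
    fn: int
    tn: int
    fp: int

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int,
                    auc: float = float("nan")) -> "MetricPanel":
        pos, neg = tp + fn, tn + fp
        if pos == 0 or neg == 0:
            raise ValueError("need at least one positive and one negative")
        sn = 100.0 * tp / pos
        sp = 100.0 * tn / neg
        ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
        npv = 100.0 * tn / (tn + fn) if tn + fn else float("nan")
        lr_pos = sn / (100.0 - sp) if sp < 100 else float("inf")
        lr_neg = (100.0 - sn) / sp if sp > 0 else float("inf")
        dor = lr_pos / lr_neg if lr_neg not in (0.0,) else float("inf")
        f1 = (2 * ppv * sn / (ppv + sn) / 100.0
              if np.isfinite(ppv) and ppv + sn > 0 else 0.0)
        return cls(
            auc=auc,
            acc=100.0 * (tp + tn) / (pos + neg),
            sn=sn, sp=sp,
            prev=100.0 * pos / (pos + neg),
            fnr=100.0 - sn, fpr=100.0 - sp,
            ppv=ppv, npv=npv,
            fdr=100.0 - ppv if np.isfinite(ppv) else float("nan"),
            f_or=100.0 - npv if np.isfinite(npv) else float("nan"),
            lr_pos=lr_pos, lr_neg=lr_neg, dor=dor, f1=f1,
            tp=tp, fn=fn, tn=tn, fp=fp,
        )

    def as_series(self) -> pd.Series:
        return pd.Series({
            "AUC": self.auc, "ACC": self.acc, "Sn": self.sn, "Sp": self.sp,
            "Prev": self.prev, "FNR": self.fnr, "FPR": self.fpr,
            "PPV": self.ppv, "NPV": self.npv, "FDR": self.fdr,
            "FOR": self.f_or, "LR+": self.lr_pos, "LR-": self.lr_neg,
            "DOR": self.dor, "f1": self.f1,
        })


def evaluate(probabilities, labels, threshold: float = 0.5) -> MetricPanel:
    """Confusion counts at a fixed threshold plus rank-based AUC."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    return MetricPanel.from_counts(tp, fn, tn, fp,
                                   auc=float(roc_auc_score(y, p)))
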