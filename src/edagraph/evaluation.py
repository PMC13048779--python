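"""Leakage-safe training and evaluation for arousal/valence regression.

The outer protocol is leave-one-subject-out (LOSO) cross-validation: every
window of one subject forms the test set, all other subjects form the
training set. Hyperparameters are tuned inside each outer fold with a
subject-grouped inner 5-fold grid search; feature standardization statistics
are estimated from the training rows only and applied to the held-out rows.
Nothing derived from the held-out subject ever touches the fitted model.

Also provided: the permutation-importance estimator I_f = (1/N) Σ (e_p − e_b)
over N label-preserving feature shuffles, tree-model impurity importances
(MDI), ablation-by-retraining with bootstrap confidence intervals, the
variance inflation factor, and the subject-level quadrant statistics
(per-subject per-quadrant medians → Mann-Whitney U across subjects →
Holm-Bonferroni step-down).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, HistGradientBoostingRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "TARGETS",
    "MODEL_SPECS",
    "DEFAULT_GRIDS",
    "FoldResult",
    "ImportanceReport",
    "AblationResult",
    "loso_folds",
    "make_model",
    "fit_fold",
    "run_loso",
    "metrics",
    "permutation_importance",
    "normalize_importances",
    "mdi_importance",
    "ablation_retrain",
    "vif",
    "holm_bonferroni",
    "quadrant_statistics",
    "assign_quadrant",
    "loso_rmse",
    "parameter_sweep",
]

TARGETS = ("arousal", "valence")

#: Label-scale bounds of the continuous annotation space.
LABEL_RANGE = (0.5, 9.5)
N_BALANCED_BINS = 9


def make_model(model_spec: str, params: Mapping | None = None, seed: int = 0):
    """Instantiate a regressor by tag.

    Linear family: ``ridge``, ``lasso``, ``elasticnet``. Gradient-boosted
    tree family: ``lgbm`` (LightGBM), ``histgb`` (histogram gradient
    boosting), ``gbr`` (classic gradient boosting).
    """
    params = dict(params or {})
    if model_spec == "ridge":
        return Ridge(**{"alpha": 1.0, **params})
    if model_spec == "lasso":
        return Lasso(**{"alpha": 0.01, "max_iter": 5000, **params})
    if model_spec == "elasticnet":
        return ElasticNet(**{"alpha": 0.01, "l1_ratio": 0.5, "max_iter": 5000, **params})
    if model_spec == "lgbm":
        import lightgbm as lgb

        return lgb.LGBMRegressor(
            **{"n_estimators": 100, "learning_rate": 0.05, "max_depth": -1,
               "num_leaves": 31, "random_state": seed, "verbose": -1, **params}
        )
    if model_spec == "histgb":
        return HistGradientBoostingRegressor(
            **{"max_iter": 100, "learning_rate": 0.05, "random_state": seed, **params}
        )
    if model_spec == "gbr":
        return GradientBoostingRegressor(
            **{"n_estimators": 100, "learning_rate": 0.05, "max_depth": 3,
               "random_state": seed, **params}
        )
    raise ValueError(f"unknown model_spec {model_spec!r}")


MODEL_SPECS = ("ridge", "lasso", "elasticnet", "lgbm", "histgb", "gbr")

#: Compact default grids spanning the search ranges used for tuning.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ridge": {"alpha": [1e-4, 1e-2, 1.0, 1e2]},
    "lasso": {"alpha": [1e-4, 1e-2, 1.0], "max_iter": [5000]},
    "elasticnet": {"alpha": [1e-3, 1e-1], "l1_ratio": [0.2, 0.8]},
    "lgbm": {"n_estimators": [50, 200], "learning_rate": [0.01, 0.1],
             "num_leaves": [20, 63]},
    "histgb": {"max_iter": [50, 200], "learning_rate": [0.01, 0.1],
               "max_depth": [3, 8]},
    "gbr": {"n_estimators": [50, 200], "learning_rate": [0.01, 0.1],
            "max_depth": [3, 6]},
}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics(y_true, y_pred) -> dict[str, float]:
    """RMSE, MAE, R², and balanced RMSE.

    Balanced RMSE is the mean of per-bin RMSEs over equal-width label bins
    spanning the annotation scale, which weights sparsely populated label
    regions equally with dense ones.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    edges = np.linspace(*LABEL_RANGE, N_BALANCED_BINS + 1)
    bin_rmses = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (y_true >= lo) & (y_true < hi if hi < LABEL_RANGE[1] else y_true <= hi)
        if mask.any():
            bin_rmses.append(float(np.sqrt(np.mean(err[mask] ** 2))))
    balanced = float(np.mean(bin_rmses)) if bin_rmses else rmse
    return {"rmse": rmse, "mae": mae, "r2": r2, "balanced_rmse": balanced}


# ---------------------------------------------------------------------------
# LOSO protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """Outcome of one LOSO fold: held-out subject, per-target metrics,
    chosen hyperparameters, and the fitted artifacts for inspection."""

    held_out_subject: str
    model_spec: str
    params: dict
    scores: dict[str, dict[str, float]]          # target -> metric -> value
    models: dict = field(default_factory=dict)   # target -> fitted estimator
    scaler: StandardScaler | None = None
    feature_names: tuple[str, ...] = ()
    predictions: dict[str, np.ndarray] = field(default_factory=dict)
    y_test: dict[str, np.ndarray] = field(default_factory=dict)
    X_test_scaled: np.ndarray | None = None


def loso_folds(subject_ids: Sequence[str]) -> list[tuple[list[str], str]]:
    """One (train_subjects, test_subject) fold per distinct subject."""
    uniq = list(dict.fromkeys(subject_ids))
    if len(uniq) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    return [([s for s in uniq if s != held], held) for held in uniq]


def _split_table(table: pd.DataFrame, feature_names: Sequence[str] | None):
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("subject_id", *TARGETS, "quadrant", "center_s")]
    X = table[list(feature_names)].to_numpy(dtype=float)
    y = {t: table[t].to_numpy(dtype=float) for t in TARGETS}
    groups = table["subject_id"].to_numpy()
    return np.nan_to_num(X, nan=0.0), y, groups, tuple(feature_names)


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def fit_fold(
    train: pd.DataFrame,
    test: pd.DataFrame,
    model_spec: str = "ridge",
    grid: Mapping[str, Sequence] | None = None,
    feature_names: Sequence[str] | None = None,
    inner_splits: int = 5,
    seed: int = 0,
    z_clip: float = 5.0,
) -> FoldResult:
    """Train on one LOSO training partition and score the held-out subject.

    Standardization and hyperparameter selection see training rows only; the
    best grid point minimizes mean inner-CV RMSE averaged over arousal and
    valence across subject-grouped inner folds. Zero-variance training
    features are dropped (with a log entry) before scaling.

    Standardized features are winsorized at ``|z| <= z_clip`` (training
    statistics, applied identically to train and test rows): several graph
    metrics are heavy-tailed — a near-constant window yields a tiny graph
    whose per-node flow scores sit far outside the cohort distribution — and
    unbounded z-scores would let a linear model extrapolate wildly on such
    windows. Set ``z_clip=None`` to disable.
    """
    X_tr, y_tr, groups_tr, names = _split_table(train, feature_names)
    X_te, y_te, _, _ = _split_table(test, names)

    # a relative floor guards against numerically-constant columns whose
    # float-noise std would otherwise explode the standardized test values
    stds = X_tr.std(axis=0)
    keep = stds > 1e-10 * (1.0 + np.abs(X_tr.mean(axis=0)))
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.info("dropping (near-)zero-variance training features: %s", dropped)
        X_tr, X_te = X_tr[:, keep], X_te[:, keep]
        names = tuple(n for n, k in zip(names, keep) if k)

    def _winsorize(Z: np.ndarray) -> np.ndarray:
        return np.clip(Z, -z_clip, z_clip) if z_clip is not None else Z

    scaler = StandardScaler().fit(X_tr)
    X_tr_s = _winsorize(scaler.transform(X_tr))
    X_te_s = _winsorize(scaler.transform(X_te))

    grid_pts = _grid_points(grid) if grid else [{}]
    if len(grid_pts) > 1:
        n_groups = len(np.unique(groups_tr))
        gkf = GroupKFold(n_splits=min(inner_splits, n_groups))
        best_params, best_score = {}, math.inf
        for params in grid_pts:
            fold_rmses = []
            for itr, ival in gkf.split(X_tr_s, groups=groups_tr):
                # refit the inner scaler on the inner-train rows only
                inner_scaler = StandardScaler().fit(X_tr[itr])
                Xi_tr = _winsorize(inner_scaler.transform(X_tr[itr]))
                Xi_val = _winsorize(inner_scaler.transform(X_tr[ival]))
                for target in TARGETS:
                    m = make_model(model_spec, params, seed=seed)
                    m.fit(Xi_tr, y_tr[target][itr])
                    pred = m.predict(Xi_val)
                    fold_rmses.append(metrics(y_tr[target][ival], pred)["rmse"])
            score = float(np.mean(fold_rmses))
            if score < best_score:
                best_score, best_params = score, params
    else:
        best_params = grid_pts[0]

    models, scores, preds, y_test = {}, {}, {}, {}
    for target in TARGETS:
        m = make_model(model_spec, best_params, seed=seed)
        m.fit(X_tr_s, y_tr[target])
        pred = m.predict(X_te_s)
        models[target] = m
        preds[target] = pred
        y_test[target] = y_te[target]
        scores[target] = metrics(y_te[target], pred)

    return FoldResult(
        held_out_subject=str(test["subject_id"].iloc[0]),
        model_spec=model_spec,
        params=dict(best_params),
        scores=scores,
        models=models,
        scaler=scaler,
        feature_names=names,
        predictions=preds,
        y_test=y_test,
        X_test_scaled=X_te_s,
    )


def run_loso(
    table: pd.DataFrame,
    model_spec: str = "ridge",
    grid: Mapping[str, Sequence] | None = None,
    feature_names: Sequence[str] | None = None,
    seed: int = 0,
) -> list[FoldResult]:
    """Full LOSO sweep over the feature table; one FoldResult per subject."""
    results = []
    for train_ids, test_id in loso_folds(table["subject_id"].tolist()):
        train = table[table["subject_id"].isin(train_ids)]
        test = table[table["subject_id"] == test_id]
        results.append(fit_fold(train, test, model_spec, grid, feature_names, seed=seed))
    return results


def loso_rmse(
    table: pd.DataFrame,
    model_spec: str = "ridge",
    params: Mapping | None = None,
    feature_names: Sequence[str] | None = None,
    shuffle_labels: bool = False,
    seed: int = 0,
) -> float:
    """Mean held-out RMSE (averaged over targets and folds) of an untuned
    model; with ``shuffle_labels`` the labels are permuted across windows
    first, giving the no-signal null."""
    work = table.copy()
    if shuffle_labels:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(work))
        for t in TARGETS:
            work[t] = work[t].to_numpy()[perm]
    grid = {k: [v] for k, v in (params or {}).items()} or None
    folds = run_loso(work, model_spec, grid, feature_names, seed=seed)
    return float(np.mean([f.scores[t]["rmse"] for f in folds for t in TARGETS]))


# ---------------------------------------------------------------------------
# Importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    """Per-feature importances: raw permutation importance, its [0, 1]
    normalization, and impurity importances where the model exposes them."""

    feature_names: tuple[str, ...]
    pi: np.ndarray
    pi_normalized: np.ndarray
    mdi: np.ndarray | None = None
    mdi_normalized: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        data = {"feature": self.feature_names, "pi": self.pi,
                "pi_normalized": self.pi_normalized}
        if self.mdi is not None:
            data["mdi"] = self.mdi
            data["mdi_normalized"] = self.mdi_normalized
        return pd.DataFrame(data)


def permutation_importance(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_repeats: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Raw permutation importance for every feature column.

    ``I_f = (1/N) Σ_i (e_i^(p) − e^(b))`` where ``e^(b)`` is the RMSE of the
    unchanged model on the held-out data and ``e_i^(p)`` the RMSE after
    shuffling only column f in repeat i.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    rng = np.random.default_rng(seed)
    e_base = metrics(y_test, model.predict(X_test))["rmse"]
    n_features = X_test.shape[1]
    importances = np.zeros(n_features)
    for f in range(n_features):
        deltas = np.empty(n_repeats)
        X_perm = X_test.copy()
        for i in range(n_repeats):
            X_perm[:, f] = rng.permutation(X_test[:, f])
            e_perm = metrics(y_test, model.predict(X_perm))["rmse"]
            deltas[i] = e_perm - e_base
        importances[f] = deltas.mean()
    return importances


def normalize_importances(values: np.ndarray) -> np.ndarray:
    """Map importances onto [0, 1]: clip negatives (noise), divide by the
    maximum; an all-zero vector stays all-zero."""
    v = np.clip(np.asarray(values, dtype=float), 0.0, None)
    peak = v.max()
    return v / peak if peak > 0 else v


def mdi_importance(model, n_features: int) -> np.ndarray | None:
    """Impurity importances for tree models; None where not applicable."""
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        return None
    imp = np.asarray(imp, dtype=float)
    return imp if imp.size == n_features else None


def fold_importance_report(
    folds: Sequence[FoldResult],
    target: str = "arousal",
    n_repeats: int = 100,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation importance computed within each LOSO fold on the held-out
    subject and averaged across folds, plus MDI where available."""
    names = folds[0].feature_names
    pis, mdis = [], []
    for i, fold in enumerate(folds):
        if fold.feature_names != names:
            raise ValueError("folds disagree on the feature roster")
        pis.append(
            permutation_importance(
                fold.models[target], fold.X_test_scaled, fold.y_test[target],
                n_repeats=n_repeats, seed=seed + i,
            )
        )
        m = mdi_importance(fold.models[target], len(names))
        if m is not None:
            mdis.append(m)
    pi = np.mean(pis, axis=0)
    mdi = np.mean(mdis, axis=0) if mdis else None
    return ImportanceReport(
        feature_names=names,
        pi=pi,
        pi_normalized=normalize_importances(pi),
        mdi=mdi,
        mdi_normalized=None if mdi is None else normalize_importances(mdi),
    )


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    feature: str
    mean_pct_delta_rmse: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_resamples: int
    fold_deltas: np.ndarray


def ablation_retrain(
    table: pd.DataFrame,
    feature: str,
    model_spec: str = "ridge",
    params: Mapping | None = None,
    feature_names: Sequence[str] | None = None,
    bootstrap: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> AblationResult:
    """Ablation by complete retraining: within every LOSO fold the model is
    refit from scratch without the target feature and the per-fold relative
    RMSE change ``100·(RMSE_without − RMSE_with)/RMSE_with`` is recorded;
    the CI is a percentile bootstrap over the fold-level values."""
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("subject_id", *TARGETS, "quadrant", "center_s")]
    if feature not in feature_names:
        raise ValueError(f"{feature!r} not in the feature roster")
    reduced = [f for f in feature_names if f != feature]
    grid = {k: [v] for k, v in (params or {}).items()} or None
    deltas = []
    for train_ids, test_id in loso_folds(table["subject_id"].tolist()):
        train = table[table["subject_id"].isin(train_ids)]
        test = table[table["subject_id"] == test_id]
        full = fit_fold(train, test, model_spec, grid, feature_names, seed=seed)
        without = fit_fold(train, test, model_spec, grid, reduced, seed=seed)
        rmse_with = np.mean([full.scores[t]["rmse"] for t in TARGETS])
        rmse_without = np.mean([without.scores[t]["rmse"] for t in TARGETS])
        deltas.append(100.0 * (rmse_without - rmse_with) / rmse_with)
    deltas = np.asarray(deltas)
    rng = np.random.default_rng(seed)
    boot = np.array([
        rng.choice(deltas, size=deltas.size, replace=True).mean()
        for _ in range(bootstrap)
    ])
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return AblationResult(
        feature=feature,
        mean_pct_delta_rmse=float(deltas.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_resamples=bootstrap,
        fold_deltas=deltas,
    )


# ---------------------------------------------------------------------------
# Collinearity
# ---------------------------------------------------------------------------

def vif(X: pd.DataFrame | np.ndarray, feature: str | int) -> float:
    """Variance inflation factor: 1/(1 − R²) of the feature regressed (with
    intercept) on all remaining features. Perfect collinearity yields +inf."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        idx = names.index(feature) if isinstance(feature, str) else int(feature)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        idx = int(feature)
    if arr.shape[1] < 2 or arr.shape[0] < 3:
        raise ValueError("VIF needs >= 2 features and >= 3 rows")
    y = arr[:, idx]
    others = np.delete(arr, idx, axis=1)
    reg = LinearRegression().fit(others, y)
    resid = y - reg.predict(others)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return math.inf
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 >= 1.0 - 1e-12:
        logger.info("perfect collinearity for feature %s: VIF = inf", feature)
        return math.inf
    return 1.0 / (1.0 - r2)


# ---------------------------------------------------------------------------
# Quadrant statistics
# ---------------------------------------------------------------------------

def assign_quadrant(arousal: float, valence: float, theta: float = 5.0,
                    neutral_halfwidth: float = 1.0) -> str:
    """Affective quadrant of a label pair: Neutral when both dimensions lie
    within the central band (checked first), else a θ-split quadrant."""
    if abs(arousal - theta) < neutral_halfwidth and abs(valence - theta) < neutral_halfwidth:
        return "Neutral"
    a = "H" if arousal >= theta else "L"
    v = "H" if valence >= theta else "L"
    return f"{a}A{v}V"


def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.005) -> np.ndarray:
    """Holm step-down rejection decisions controlling the family-wise error
    rate at ``alpha``. Sorted p-values p_(1) <= ... <= p_(m) are compared to
    alpha/(m − i + 1); the first failure stops all further rejections."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


_PAIR_FAMILIES = {
    "all_pairs": list(itertools.combinations(
        ("LALV", "LAHV", "HALV", "HAHV", "Neutral"), 2)),
    "versus_neutral": [(q, "Neutral") for q in ("LALV", "LAHV", "HALV", "HAHV")],
}


def quadrant_statistics(
    table: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    alpha: float = 0.005,
    family: str = "all_pairs",
    theta: float = 5.0,
) -> pd.DataFrame:
    """Subject-level quadrant comparison of every feature.

    For each subject and quadrant the median feature value is computed (one
    observation per subject per quadrant, removing window autocorrelation);
    each quadrant pair in the configured family is then compared across
    subjects with a two-sided Mann-Whitney U test, and Holm-Bonferroni is
    applied over the full feature × pair family at ``alpha``. Shapiro-Wilk
    normality p-values are reported per feature (screening, not gating).
    Pairs with a quadrant absent for all subjects are marked untestable.
    """
    if family not in _PAIR_FAMILIES:
        raise ValueError(f"family must be one of {sorted(_PAIR_FAMILIES)}")
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("subject_id", *TARGETS, "quadrant", "center_s")]
    work = table.copy()
    if "quadrant" not in work.columns:
        work["quadrant"] = [
            assign_quadrant(a, v, theta=theta)
            for a, v in zip(work["arousal"], work["valence"])
        ]
    medians = (
        work.groupby(["subject_id", "quadrant"], sort=True)[list(feature_names)]
        .median()
        .reset_index()
    )
    shapiro_p = {}
    for f in feature_names:
        vals = work[f].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if 3 <= vals.size <= 5000 and np.ptp(vals) > 0:
            shapiro_p[f] = float(stats.shapiro(vals).pvalue)
        else:
            shapiro_p[f] = math.nan

    rows = []
    for f in feature_names:
        for qa, qb in _PAIR_FAMILIES[family]:
            a = medians.loc[medians["quadrant"] == qa, f].dropna().to_numpy()
            b = medians.loc[medians["quadrant"] == qb, f].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                rows.append({"feature": f, "pair": f"{qa}-{qb}", "u": math.nan,
                             "p": math.nan, "testable": False,
                             "shapiro_p": shapiro_p[f]})
                continue
            if np.ptp(np.concatenate([a, b])) == 0:
                u, p = float(a.size * b.size / 2.0), 1.0
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
                u, p = float(res.statistic), float(res.pvalue)
            rows.append({"feature": f, "pair": f"{qa}-{qb}", "u": u, "p": p,
                         "testable": True, "shapiro_p": shapiro_p[f]})
    out = pd.DataFrame(rows)
    testable = out["testable"].to_numpy()
    reject = np.zeros(len(out), dtype=bool)
    if testable.any():
        reject[testable] = holm_bonferroni(out.loc[testable, "p"].to_numpy(), alpha=alpha)
    out["reject"] = reject
    return out


# ---------------------------------------------------------------------------
# Parameter sweep harness
# ---------------------------------------------------------------------------

def parameter_sweep(
    subjects,
    q_values: Sequence[float] = (0.05,),
    win_lens: Sequence[float] = (60.0,),
    overlaps: Sequence[float] = (0.5,),
    k_values: Sequence[int | None] = (None,),
    categories: Sequence[str | None] = (None,),
    model_spec: str = "ridge",
    params: Mapping | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid sweep over the graph-construction axes (quantization step Q,
    window length/overlap, neighbor count k, feature-category subset),
    reporting the mean LOSO RMSE per condition."""
    from .pipeline import graph_feature_table

    rows = []
    for Q, win, ov, k, cat in itertools.product(
            q_values, win_lens, overlaps, k_values, categories):
        table = graph_feature_table(subjects, Q=Q, win_len_s=win, overlap=ov, k=k)
        if cat is not None:
            from .graph_features import MANIFEST

            names = [s.name for s in MANIFEST if s.category == cat]
        else:
            names = None
        rmse = loso_rmse(table, model_spec, params, feature_names=names, seed=seed)
        rows.append({"Q": Q, "win_len_s": win, "overlap": ov,
                     "k": k if k is not None else "fs",
                     "category": cat or "all", "mean_rmse": rmse})
    return pd.DataFrame(rows)
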