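"""Proteomic stage classification and expression-profile biclustering.

Samples are grouped by sampling time (groups 1, 9 and 18 — first month,
nine months, eighteen months) regardless of tissue type and classified
with a linear support-vector machine (one-vs-one, C = 10).  Features are
ranked by a one-way ANOVA F statistic (with an optional ``s0`` fudge
added to the pooled within-group standard deviation); the error-vs-panel-
size curve over two cross-validation schemes (250 repeats of stratified
33 % hold-out and 250 repeats of stratified ten-fold CV) locates the
smallest protein panel classifying with under 10 % error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist, squareform
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .datamodel import OmicsMatrix, SampleSheet, ValidationError

SCHEMES = ("tenfold", "holdout33")


@dataclass
class StagingConfig:
    C: float = 10.0
    s0: float = 0.0
    n_repeats: int = 250
    schemes: tuple[str, ...] = SCHEMES
    feature_grid: tuple[int, ...] = (1, 2, 4, 8, 12, 16, 20, 24, 32, 48, 64)
    error_target: float = 0.10
    rank_globally: bool = False  # rank once on all data instead of per fold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("C must be positive")
        if self.s0 < 0:
            raise ValidationError("s0 must be non-negative")
        bad = set(self.schemes) - set(SCHEMES)
        if bad:
            raise ValidationError(f"unknown scheme(s): {sorted(bad)}")


def stage_groups(sheet: SampleSheet, layer: str = "protein",
                 include_controls: bool = False) -> pd.Series:
    """Sample -> stage-group labels (1/9/18) for one layer.

    By default only treated samples enter (the classifier separates HCC
    development stages, not treatment status).
    """
    rows = sheet.entries[sheet.entries["layer"] == layer]
    labels = {}
    for _, row in rows.iterrows():
        cond = sheet.conditions[row["condition_id"]]
        if cond.is_control and not include_controls:
            continue
        labels[row["sample_id"]] = cond.stage_group
    return pd.Series(labels, dtype=int)


def anova_rank(matrix: OmicsMatrix, groups: pd.Series,
               s0: float = 0.0) -> pd.DataFrame:
    """One-way ANOVA F per feature, in decreasing order.

    With ``s0 > 0`` the statistic is MS_between / (sqrt(MS_within) +
    s0)^2, damping features whose within-group spread is tiny; s0 = 0
    gives the plain F.  Ties are broken by feature id.
    """
    samples = [s for s in groups.index if s in matrix.values.columns]
    g = groups[samples]
    classes = sorted(g.unique())
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes")
    X = matrix.values[samples].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("matrix has missing values; impute first")
    n_total = X.shape[1]
    grand = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for c in classes:
        sel = (g == c).to_numpy()
        nc = int(sel.sum())
        if nc < 2:
            raise ValidationError(f"class {c} has fewer than 2 samples")
        mc = X[:, sel].mean(axis=1)
        ss_between += nc * (mc - grand) ** 2
        ss_within += ((X[:, sel] - mc[:, None]) ** 2).sum(axis=1)
    df_b = len(classes) - 1
    df_w = n_total - len(classes)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    denom = (np.sqrt(ms_w) + s0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(denom > 0, ms_b / denom, 0.0)
    tab = pd.DataFrame({"feature": matrix.feature_ids, "F": F})
    tab = tab.sort_values(["F", "feature"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    return tab


def _splits(scheme: str, y: np.ndarray, n_repeats: int, rng_seed: int):
    if scheme == "holdout33":
        sss = StratifiedShuffleSplit(n_splits=n_repeats, test_size=0.33,
                                     random_state=rng_seed)
        yield from sss.split(np.zeros(len(y)), y)
    elif scheme == "tenfold":
        # a class smaller than the fold count is tolerated (some folds
        # lack it in the test set); folds are capped by the largest class
        n_splits = min(10, int(np.bincount(
            pd.factorize(y)[0]).max()))
        rng = np.random.default_rng(rng_seed)
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="The least populated class")
            for _ in range(n_repeats):
                skf = StratifiedKFold(
                    n_splits=n_splits, shuffle=True,
                    random_state=int(rng.integers(2 ** 31)))
                yield from skf.split(np.zeros(len(y)), y)
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")


def cv_error(matrix: OmicsMatrix, groups: pd.Series,
             config: StagingConfig, m: int) -> dict[str, float]:
    """Mean cross-validated misclassification rate per scheme at panel
    size ``m``.

    Features are ranked on the training portion of each split (avoiding
    selection leakage) unless ``config.rank_globally`` ranks once on all data.
    Stratified splitting keeps every class present in every training set.
    """
    samples = [s for s in groups.index if s in matrix.values.columns]
    if m > matrix.shape[0]:
        raise ValidationError(f"m={m} exceeds feature count")
    y = groups[samples].to_numpy()
    X_full = matrix.values[samples].to_numpy(dtype=float).T  # samples × feat
    feat_index = {f: i for i, f in enumerate(matrix.feature_ids)}
    global_rank = None
    if config.rank_globally:
        ranked = anova_rank(matrix, groups, s0=config.s0)
        global_rank = [feat_index[f] for f in ranked["feature"][:m]]
    out = {}
    for s_i, scheme in enumerate(config.schemes):
        errs = []
        seed = (config.seed * 7919 + s_i * 104729 + m) % (2 ** 31)
        for train, test in _splits(scheme, y, config.n_repeats, seed):
            if global_rank is not None:
                cols = global_rank
            else:
                sub = OmicsMatrix(matrix.layer,
                                  matrix.values[[samples[i] for i in train]])
                ranked = anova_rank(sub, groups, s0=config.s0)
                cols = [feat_index[f] for f in ranked["feature"][:m]]
            clf = SVC(kernel="linear", C=config.C,
                      decision_function_shape="ovo")
            clf.fit(X_full[np.ix_(train, cols)], y[train])
            pred = clf.predict(X_full[np.ix_(test, cols)])
            errs.append(float(np.mean(pred != y[test])))
        out[scheme] = float(np.mean(errs))
    return out


@dataclass
class ErrorCurve:
    curve: pd.DataFrame  # columns: m, one column per scheme
    minimal_m: int | None
    panel: list[str] = field(default_factory=list)


def error_curve(matrix: OmicsMatrix, groups: pd.Series,
                config: StagingConfig) -> ErrorCurve:
    """Evaluate cv_error over the feature grid and select the smallest
    panel with mean error below the target under every scheme."""
    if not config.feature_grid:
        raise ValidationError("feature_grid is empty")
    grid = sorted(set(min(m, matrix.shape[0]) for m in config.feature_grid))
    rows = []
    for m in grid:
        res = cv_error(matrix, groups, config, m)
        rows.append({"m": m, **res})
    curve = pd.DataFrame(rows)
    ok = curve[[s for s in config.schemes]].lt(config.error_target).all(axis=1)
    minimal_m = int(curve.loc[ok, "m"].min()) if ok.any() else None
    panel: list[str] = []
    if minimal_m is not None:
        ranked = anova_rank(matrix, groups, s0=config.s0)
        panel = list(ranked["feature"][:minimal_m])
    return ErrorCurve(curve, minimal_m, panel)


def bicluster_profiles(logfc: pd.DataFrame
                       ) -> tuple[np.ndarray, np.ndarray,
                                  list[str], list[str]]:
    """Two-way hierarchical clustering of a log2FC matrix (features ×
    stages): Pearson-correlation distance for stage columns, Euclidean
    for feature rows, complete linkage both ways.

    Returns (row linkage, column linkage, row leaf order, column leaf
    order) backing a heat-map export.
    """
    if logfc.isna().to_numpy().any():
        raise ValidationError("logFC matrix has missing values")
    X = logfc.to_numpy(dtype=float)
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        stage = logfc.columns[int(np.argmax(col_sd == 0))]
        raise ValidationError(
            f"stage {stage!r} has constant logFC; Pearson undefined"
        )
    col_corr = np.corrcoef(X.T)
    col_dist = 1.0 - col_corr
    np.fill_diagonal(col_dist, 0.0)
    col_dist = np.clip((col_dist + col_dist.T) / 2.0, 0.0, 2.0)
    Zc = linkage(squareform(col_dist, checks=False), method="complete")
    Zr = linkage(pdist(X, metric="euclidean"), method="complete")
    row_order = [logfc.index[i] for i in leaves_list(Zr)]
    col_order = [logfc.columns[i] for i in leaves_list(Zc)]
    return Zr, Zc, row_order, col_order
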