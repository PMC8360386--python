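"""Weighted co-expression network analysis, written from first principles.

The network pipeline: biweight midcorrelation between gene expression
profiles, signed soft-threshold adjacency a_ij = ((1 + r_ij)/2)^beta with
beta chosen as the smallest power giving a scale-free topology fit above
a threshold, topological-overlap similarity (TOM), average-linkage
clustering of 1 - TOM with a height cut and a minimum module size, module
eigengenes (first principal component of each module), a module-stage
relevance statistic (median member |log2FC| with a Wilcoxon rank-sum
gate), and correlation of eigengene profiles with molecular features
(proteins, metabolites, miRNAs) measured on independent animals, aligned
at per-condition replicate means.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .datamodel import DiffTable, OmicsMatrix, ValidationError

#: module label palette, assigned in decreasing module-size order;
#: "grey" is reserved for unassigned features.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
    "steelblue", "paleturquoise", "violet", "darkolivegreen",
    "darkmagenta",
)

GREY = "grey"


# ---------------------------------------------------------------------------
# correlation


#: per-side cap on the fraction of samples the biweight may zero out.
#: Stage-specific expression spikes would otherwise be discarded as
#: outliers, destroying exactly the correlations of interest.
MAX_P_OUTLIERS = 0.1


def _bicor_transform(X: np.ndarray,
                     max_p_outliers: float = MAX_P_OUTLIERS
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-biweight transformed rows, unit-normalized.

    The biweight u = (x - med) / (9 mad) is rescaled per side so that at
    most ``max_p_outliers`` of the samples on either side of the median
    receive zero weight.  Returns (transformed rows, mask of rows that
    fell back to Pearson because their median absolute deviation was
    zero).
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = (X - med) / (9.0 * safe_mad)
    if max_p_outliers < 0.5:
        q_hi = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
        q_lo = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
        u = np.where((u > 0) & (q_hi > 1.0), u / np.maximum(q_hi, 1.0), u)
        u = np.where((u < 0) & (q_lo < -1.0), u / np.maximum(-q_lo, 1.0), u)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    xt = (X - med) * w
    # Pearson fallback: mean-centred raw values
    if fallback.any():
        centered = X - X.mean(axis=1, keepdims=True)
        xt[fallback] = centered[fallback]
    norms = np.linalg.norm(xt, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        raise ValidationError(
            "constant expression profile(s); cannot correlate "
            f"(rows {np.where(zero)[0][:5]})"
        )
    return xt / norms, fallback


def bicor(x, y) -> float:
    """Biweight midcorrelation of two profiles (Pearson fallback on zero
    MAD, with a warning)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    xt, fb = _bicor_transform(np.vstack([x, y]))
    if fb.any():
        warnings.warn("zero MAD; falling back to Pearson")
    return float(np.clip(xt[0] @ xt[1], -1.0, 1.0))


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """Feature × feature biweight midcorrelation matrix (rows = features)."""
    xt, fb = _bicor_transform(X)
    if fb.any():
        warnings.warn(f"{int(fb.sum())} feature(s) fell back to Pearson "
                      "(zero MAD)")
    C = xt @ xt.T
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


# ---------------------------------------------------------------------------
# network construction


def signed_adjacency(corr: np.ndarray, beta: float,
                     signed: bool = True) -> np.ndarray:
    """Soft-threshold adjacency: ((1 + r)/2)^beta (signed convention) or
    |r|^beta (unsigned); the diagonal is zeroed for connectivity sums."""
    if signed:
        adj = ((1.0 + corr) / 2.0) ** beta
    else:
        adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-width bins; log10
    frequency is regressed on log10 mean connectivity.  Returns
    (signed_fit, slope) where signed_fit = -sign(slope) * R^2, so a
    decreasing (scale-free-like) distribution scores positively.
    """
    k = adj.sum(axis=1)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValidationError("too few connected nodes for the fit")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2), float(slope)


def pick_soft_threshold(corr: np.ndarray,
                        candidates=range(1, 31),
                        fit_threshold: float = 0.85,
                        signed: bool = True) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit exceeds ``fit_threshold``.

    Returns (beta, diagnostics table); if no candidate passes, the
    best-fitting power is returned with a warning.
    """
    if corr.shape[0] < 10:
        raise ValidationError("need at least 10 features to pick a power")
    rows = []
    chosen = None
    for beta in candidates:
        adj = signed_adjacency(corr, beta, signed=signed)
        fit, slope = scale_free_fit(adj)
        rows.append({"beta": beta, "signed_fit": fit, "slope": slope,
                     "mean_k": adj.sum(axis=1).mean()})
        if chosen is None and fit > fit_threshold:
            chosen = beta
    diag = pd.DataFrame(rows)
    if chosen is None:
        chosen = int(diag.loc[diag["signed_fit"].idxmax(), "beta"])
        warnings.warn(
            f"no power reached fit > {fit_threshold}; using best "
            f"beta={chosen}"
        )
    return int(chosen), diag


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 -
    a_ij) with l_ij the shared-neighbour weight sum; diagonal = 1."""
    adj = np.asarray(adj, dtype=float)
    if adj.shape[0] != adj.shape[1] or not np.allclose(adj, adj.T,
                                                       atol=1e-12):
        raise ValidationError("adjacency must be square and symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if adj.min() < 0 or adj.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    k = adj.sum(axis=1)
    L = adj @ adj  # l_ij for zero-diagonal symmetric adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (L + adj) / denom
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return tom


# ---------------------------------------------------------------------------
# module detection


def detect_modules(tom: np.ndarray, feature_ids: list[str],
                   min_module_size: int = 20,
                   cut_fraction: float = 0.95
                   ) -> tuple[dict[str, str], np.ndarray]:
    """Cluster 1 - TOM by average linkage and cut into modules.

    The tree is cut at ``cut_fraction`` times the maximum merge height
    (0.95 by default: planted and empirical module joins complete well
    below it, while links between distinct modules merge just under the
    top of the tree);
    clusters below ``min_module_size`` are reassigned to grey.  Surviving
    modules are named by the standard colour sequence in decreasing size
    order.  Returns (feature -> module label, linkage matrix).
    """
    n = tom.shape[0]
    if len(feature_ids) != n:
        raise ValidationError("feature_ids length mismatch")
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    Z = linkage(squareform(dissim, checks=False), method="average")
    cut = cut_fraction * Z[:, 2].max() if Z[:, 2].max() > 0 else 0.0
    raw = fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    big.sort(key=lambda c: (-sizes[c], c))
    label_of_cluster = {c: MODULE_COLORS[i % len(MODULE_COLORS)]
                        for i, c in enumerate(big)}
    modules = {}
    for fid, c in zip(feature_ids, raw):
        modules[fid] = label_of_cluster.get(c, GREY)
    return modules, Z


@dataclass
class CoexpressionState:
    """Everything the network stage produced, for inspection and export."""

    feature_ids: list[str]
    corr: np.ndarray
    beta: int
    adjacency: np.ndarray = field(repr=False)
    tom: np.ndarray = field(repr=False)
    linkage: np.ndarray = field(repr=False)
    modules: dict[str, str] = field(default_factory=dict)

    def members(self, module: str) -> list[str]:
        return [f for f, m in self.modules.items() if m == module]

    @property
    def module_labels(self) -> list[str]:
        labels = [m for m in dict.fromkeys(self.modules.values())
                  if m != GREY]
        return sorted(labels, key=lambda m: -len(self.members(m)))


def build_network(matrix: OmicsMatrix, beta: int | None = 24,
                  min_module_size: int = 20,
                  fit_threshold: float = 0.85,
                  signed: bool = True) -> CoexpressionState:
    """Full network construction from an expression matrix.

    ``beta=None`` triggers automatic soft-threshold selection; the
    default of 24 is the signed-network power at which the chronological
    HCC transcriptome reached a scale-free fit above 0.85.
    """
    X = matrix.values.to_numpy(dtype=float)
    corr = bicor_matrix(X)
    if beta is None:
        beta, _ = pick_soft_threshold(corr, fit_threshold=fit_threshold,
                                      signed=signed)
    adj = signed_adjacency(corr, beta, signed=signed)
    tom = tom_similarity(adj)
    modules, Z = detect_modules(tom, matrix.feature_ids, min_module_size)
    return CoexpressionState(matrix.feature_ids, corr, int(beta), adj, tom,
                             Z, modules)


# ---------------------------------------------------------------------------
# eigengenes


def module_eigengene(matrix: OmicsMatrix, members: list[str]) -> pd.Series:
    """First principal component over samples of the standardized module
    submatrix, sign-aligned with mean module expression, unit norm."""
    sub = matrix.values.loc[list(members)].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValidationError("constant feature in module")
    Xs = (sub - sub.mean(axis=1, keepdims=True)) / sd
    if Xs.shape[0] == 1:
        v = Xs[0] / np.linalg.norm(Xs[0])
    else:
        _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
        v = Vt[0]
    mean_profile = Xs.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    return pd.Series(v, index=matrix.sample_ids)


def module_eigengenes(matrix: OmicsMatrix,
                      modules: dict[str, str]) -> pd.DataFrame:
    """Samples × modules eigengene matrix (grey excluded)."""
    cols = {}
    labels = [m for m in dict.fromkeys(modules.values()) if m != GREY]
    for label in labels:
        members = [f for f, m in modules.items() if m == label]
        cols[label] = module_eigengene(matrix, members)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# module relevance


@dataclass
class RelevanceRecord:
    module: str
    stage: str
    median_logfc: float
    wilcoxon_p: float
    relevant: bool
    direction: str  # up / down / none


def module_relevance(diff_tables: list[DiffTable],
                     modules: dict[str, str],
                     median_threshold: float = 0.9,
                     alpha: float = 0.05) -> list[RelevanceRecord]:
    """Flag (module, stage) pairs where the module's member log2 fold
    changes are both large (|median| > threshold) and distributionally
    distinct from the same module's values at all other stages (two-sided
    Wilcoxon rank-sum)."""
    lfc = {}
    for t in diff_tables:
        lfc[t.condition] = t.table.set_index("feature")["log2_fc"]
    lfc = pd.DataFrame(lfc)
    labels = [m for m in dict.fromkeys(modules.values()) if m != GREY]
    out = []
    for label in labels:
        members = [f for f, m in modules.items()
                   if m == label and f in lfc.index]
        if not members:
            warnings.warn(f"module {label!r} absent from diff tables; "
                          "skipped")
            continue
        sub = lfc.loc[members]
        for stage in lfc.columns:
            here = sub[stage].to_numpy()
            rest = sub.drop(columns=[stage]).to_numpy().ravel()
            med = float(np.median(here))
            if np.all(here == here[0]) and np.all(rest == here[0]):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(
                    here, rest, alternative="two-sided").pvalue)
            relevant = abs(med) > median_threshold and p < alpha
            direction = "none"
            if relevant:
                direction = "up" if med > 0 else "down"
            out.append(RelevanceRecord(label, stage, med, p, relevant,
                                       direction))
    return out


def relevance_table(records: list[RelevanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# module–feature integration


@dataclass
class FeatureCorrelation:
    module: str
    feature_id: str
    feature_class: str  # protein / metabolite / miRNA
    r: float
    p: float
    significant: bool
    cluster_label: str = ""


def correlate_features(me_profiles: pd.DataFrame,
                       feature_profiles: pd.DataFrame,
                       feature_class: str,
                       p_threshold: float = 0.001
                       ) -> list[FeatureCorrelation]:
    """Pearson correlation of eigengene and molecular-feature profiles.

    Both inputs are condition-level profiles: ``me_profiles`` is
    conditions × modules, ``feature_profiles`` is features × conditions.
    The layers come from independent animals, so per-condition replicate
    means are the only supportable alignment.  p is the two-sided t-test
    of r on n - 2 df; significance gate p <= p_threshold.
    """
    common = [c for c in me_profiles.index if c in feature_profiles.columns]
    n = len(common)
    if n < 4:
        raise ValidationError("need at least 4 aligned conditions")
    me = me_profiles.loc[common]
    fp = feature_profiles[common]
    out = []
    for module in me.columns:
        mvec = me[module].to_numpy(dtype=float)
        for fid in fp.index:
            fvec = fp.loc[fid].to_numpy(dtype=float)
            if np.std(fvec) == 0 or np.std(mvec) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(mvec, fvec)
            out.append(FeatureCorrelation(
                module, fid, feature_class, float(r), float(p),
                bool(p <= p_threshold)))
    return out


def significant_features(correlations: list[FeatureCorrelation],
                         r_threshold: float = 0.0) -> list[str]:
    """Feature ids significantly correlated with >= 1 module (optionally
    also requiring |r| above a reporting threshold)."""
    keep = []
    for c in correlations:
        if c.significant and abs(c.r) > r_threshold:
            keep.append(c.feature_id)
    return list(dict.fromkeys(keep))


def cluster_features(feature_profiles: pd.DataFrame,
                     k: int = 10) -> dict[str, str]:
    """Cluster molecular-feature profiles by Pearson correlation distance.

    Average-linkage tree on 1 - r, cut into ``k`` clusters (reduced with
    a warning when fewer features exist); labels A, B, ... assigned in
    dendrogram leaf order.
    """
    ids = list(feature_profiles.index)
    n = len(ids)
    if n == 0:
        return {}
    if n == 1:
        return {ids[0]: "A"}
    if k > n:
        warnings.warn(f"k={k} exceeds feature count {n}; reduced")
        k = n
    X = feature_profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    Xs = np.where(sd > 0, (X - X.mean(axis=1, keepdims=True)) / sd, 0.0)
    corr = np.corrcoef(Xs)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.clip(dist, 0.0, 2.0, out=dist)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    order = leaves_list(Z)
    letters = string.ascii_uppercase
    label_of_cluster: dict[int, str] = {}
    for pos in order:
        c = raw[pos]
        if c not in label_of_cluster:
            label_of_cluster[c] = letters[len(label_of_cluster)]
    return {ids[i]: label_of_cluster[raw[i]] for i in range(n)}


def feature_correlation_table(correlations: list[FeatureCorrelation]
                              ) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in correlations])
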