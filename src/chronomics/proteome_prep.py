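"""Proteomic pre-processing: completeness filter, normalization,
missingness classification and imputation.

Label-free proteomic intensities are left-censored: proteins near the
detection limit drop out preferentially (missing not at random, MNAR),
while occasional losses are unrelated to abundance (missing at random,
MAR).  The two mechanisms require different imputations: MNAR blocks are
drawn from a low-intensity Gaussian anchored at a low quantile of the
sample (MinProb), MAR entries are filled by k-nearest-neighbour
regression across proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import OmicsMatrix, SampleSheet, ValidationError

MISSINGNESS_LABELS = ("complete", "MAR", "MNAR")


@dataclass
class MissingnessMap:
    """Per (feature, condition) missingness label."""

    labels: pd.DataFrame  # index = features, columns = condition ids

    def of(self, feature: str, condition: str) -> str:
        return self.labels.at[feature, condition]

    def to_frame(self) -> pd.DataFrame:
        long = self.labels.stack().rename("label").reset_index()
        long.columns = ["feature", "condition", "label"]
        return long


def _condition_blocks(matrix: OmicsMatrix, sheet: SampleSheet
                      ) -> dict[str, list[str]]:
    conds: dict[str, list[str]] = {}
    for cid in dict.fromkeys(sheet.entries["condition_id"]):
        samp = [s for s in sheet.samples(cid, matrix.layer)
                if s in matrix.values.columns]
        if samp:
            conds[cid] = samp
    return conds


def filter_quantified(matrix: OmicsMatrix, sheet: SampleSheet,
                      min_complete_reps: int = 3) -> OmicsMatrix:
    """Keep proteins observed in all replicates of at least one condition.

    This is the standard completeness gate for label-free data: a protein
    never fully quantified in any condition carries no testable signal.
    """
    if matrix.layer != "protein":
        raise ValidationError("filter_quantified applies to the protein layer")
    blocks = _condition_blocks(matrix, sheet)
    max_reps = max(len(s) for s in blocks.values())
    if min_complete_reps > max_reps:
        raise ValidationError(
            f"min_complete_reps={min_complete_reps} exceeds the largest "
            f"replicate count ({max_reps})"
        )
    obs = matrix.values.notna()
    keep = pd.Series(False, index=matrix.values.index)
    for samp in blocks.values():
        if len(samp) >= min_complete_reps:
            keep |= obs[samp].sum(axis=1) >= min_complete_reps
    return OmicsMatrix("protein", matrix.values.loc[keep].copy())


def normalize_protein(matrix: OmicsMatrix) -> OmicsMatrix:
    """log2-transform intensities and centre each sample at its median.

    A simple, parameter-free stand-in for variance stabilization that
    removes per-sample loading differences; missing entries are preserved.
    """
    vals = matrix.values
    if (vals <= 0).any().any():
        raise ValidationError("intensities must be positive before log2")
    if vals.isna().all(axis=0).any():
        col = vals.columns[vals.isna().all(axis=0)][0]
        raise ValidationError(f"sample {col!r} has no observed values")
    logged = np.log2(vals)
    centered = logged - logged.median(axis=0, skipna=True)
    return OmicsMatrix(matrix.layer, centered)


def classify_missingness(matrix: OmicsMatrix, sheet: SampleSheet,
                         mnar_quantile: float = 0.25) -> MissingnessMap:
    """Label each (protein, condition) replicate block.

    complete: no missing replicate.  MNAR: the whole block is missing, or
    the observed block mean falls in the lowest ``mnar_quantile`` of all
    observed block means (intensity-dependent censoring).  MAR: everything
    else.
    """
    blocks = _condition_blocks(matrix, sheet)
    obs = matrix.values.notna()
    block_means = {}
    for cid, samp in blocks.items():
        block_means[cid] = matrix.values[samp].mean(axis=1, skipna=True)
    means = pd.DataFrame(block_means)
    cutoff = np.nanquantile(means.to_numpy(dtype=float), mnar_quantile)
    labels = pd.DataFrame("complete", index=matrix.values.index,
                          columns=list(blocks))
    for cid, samp in blocks.items():
        n_obs = obs[samp].sum(axis=1)
        incomplete = n_obs < len(samp)
        all_missing = n_obs == 0
        low = means[cid] <= cutoff
        labels.loc[incomplete, cid] = "MAR"
        labels.loc[incomplete & (all_missing | low), cid] = "MNAR"
    return MissingnessMap(labels)


def impute_mindet(matrix: OmicsMatrix) -> OmicsMatrix:
    """Deterministic left-censored imputation: per-sample observed minimum."""
    vals = matrix.values.copy()
    if vals.isna().all(axis=0).any():
        col = vals.columns[vals.isna().all(axis=0)][0]
        raise ValidationError(f"sample {col!r} has no observed values")
    mins = vals.min(axis=0, skipna=True)
    out = vals.fillna(mins)
    return OmicsMatrix(matrix.layer, out)


def impute_minprob(matrix: OmicsMatrix, q: float = 0.1,
                   tune_sigma: float = 1.0,
                   seed: int | np.random.Generator = 0,
                   mask: pd.DataFrame | None = None) -> OmicsMatrix:
    """Stochastic left-censored imputation (MinProb).

    Each missing entry is drawn from a Gaussian located at the ``q``
    quantile of its sample's observed values, with scale ``tune_sigma``
    times the median per-protein observed standard deviation.  With
    ``mask`` given, only entries marked True are imputed (MNAR entries in
    the split MNAR/MAR pipeline).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    vals = matrix.values.copy()
    feat_sd = vals.std(axis=1, skipna=True, ddof=1)
    scale = tune_sigma * float(np.nanmedian(feat_sd.to_numpy()))
    if not np.isfinite(scale) or scale <= 0:
        warnings.warn("degenerate spread; falling back to MinDet imputation")
        if mask is not None:
            det = impute_mindet(matrix).values
            out = vals.where(~(vals.isna() & mask), det)
            return OmicsMatrix(matrix.layer, out)
        return impute_mindet(matrix)
    for col in vals.columns:
        miss = vals[col].isna()
        if mask is not None:
            miss &= mask[col]
        n = int(miss.sum())
        if n == 0:
            continue
        observed = vals[col].dropna()
        if observed.empty:
            raise ValidationError(f"sample {col!r} has no observed values")
        loc = float(observed.quantile(q))
        vals.loc[miss, col] = rng.normal(loc, scale, size=n)
    return OmicsMatrix(matrix.layer, vals)


def impute_knn(matrix: OmicsMatrix, k: int = 11,
               mask: pd.DataFrame | None = None) -> OmicsMatrix:
    """k-nearest-neighbour imputation across proteins.

    For each missing (feature, sample), the k proteins closest in
    Euclidean distance over mutually observed samples — and themselves
    observed at that sample — contribute an inverse-distance-weighted
    mean.  Fewer than k candidates: all available are used; none: fall
    back to the feature's own mean with a warning.
    """
    vals = matrix.values
    X = vals.to_numpy(dtype=float)
    out = X.copy()
    missing = np.isnan(X)
    if mask is not None:
        missing &= mask.to_numpy(dtype=bool)
    if not missing.any():
        return OmicsMatrix(matrix.layer, vals.copy())
    obs = ~np.isnan(X)
    n_feat = X.shape[0]
    feat_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
    for i in range(n_feat):
        cols = np.where(missing[i])[0]
        if cols.size == 0:
            continue
        # squared distance to every other feature over shared observed samples
        shared = obs[i][None, :] & obs  # (n_feat, n_samples)
        diff = np.where(shared, X[i][None, :] - np.where(np.isnan(X), 0, X),
                        0.0)
        d2 = (diff ** 2).sum(axis=1)
        n_shared = shared.sum(axis=1)
        valid = (n_shared > 0)
        valid[i] = False
        dist = np.sqrt(np.where(valid, d2, np.inf))
        for j in cols:
            cand = valid & obs[:, j]
            if not cand.any():
                warnings.warn(
                    f"no neighbour for ({vals.index[i]!r}, "
                    f"{vals.columns[j]!r}); using feature mean"
                )
                out[i, j] = feat_means[i]
                continue
            order = np.argsort(dist[cand], kind="stable")
            idx = np.where(cand)[0][order][:k]
            d = dist[idx]
            if np.any(d == 0):
                out[i, j] = X[idx[d == 0], j].mean()
            else:
                w = 1.0 / d
                out[i, j] = float(np.average(X[idx, j], weights=w))
    return OmicsMatrix(matrix.layer,
                       pd.DataFrame(out, index=vals.index,
                                    columns=vals.columns))


def prepare_proteome(matrix: OmicsMatrix, sheet: SampleSheet,
                     min_complete_reps: int = 3, q: float = 0.1,
                     tune_sigma: float = 1.0, k: int = 11,
                     mnar_quantile: float = 0.25,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[OmicsMatrix, MissingnessMap]:
    """Full preparation: filter, normalize, classify, split imputation.

    MNAR blocks are imputed with MinProb, MAR entries with kNN, matching
    the mechanism of each missingness class.
    """
    filt = filter_quantified(matrix, sheet, min_complete_reps)
    norm = normalize_protein(filt)
    mmap = classify_missingness(norm, sheet, mnar_quantile)
    mnar_mask = pd.DataFrame(False, index=norm.values.index,
                             columns=norm.values.columns)
    mar_mask = mnar_mask.copy()
    for cid in mmap.labels.columns:
        samp = [s for s in sheet.samples(cid, "protein")
                if s in norm.values.columns]
        lab = mmap.labels[cid]
        mnar_mask.loc[lab == "MNAR", samp] = True
        mar_mask.loc[lab == "MAR", samp] = True
    step1 = impute_minprob(norm, q=q, tune_sigma=tune_sigma, seed=seed,
                           mask=mnar_mask)
    step2 = impute_knn(step1, k=k, mask=mar_mask)
    return step2, mmap
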