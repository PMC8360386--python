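"""Differential expression across the three omics layers.

Transcripts and proteins are tested with an empirical-Bayes moderated
two-sample t-statistic: per-feature sample variances are shrunk towards a
prior variance ``s0_sq`` with prior degrees of freedom ``d0``, both
estimated by moment matching on the log sample variances (the scaled-F /
inverse-chi-square hierarchical model).  Metabolite concentrations are
tested with an ordinary equal-variance Student t on the raw concentration
scale, reported with a signed natural-scale fold change and without
multiple-testing adjustment (eight targeted metabolites).

Calls: a transcript feature is "up" when BH-adjusted p < 0.05 and
log2 fold change >= 1 (two-fold), "down" symmetrically; the protein layer
uses adjusted p <= 0.05, as its source convention differs in boundary
handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import Condition, DiffTable, OmicsMatrix, SampleSheet, ValidationError


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes hyperparameters of the variance prior.

    ``d0`` may be ``math.inf`` when the observed variances are consistent
    with a single common variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError(f"d0 must be positive, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValidationError(f"s0_sq must be positive, got {self.s0_sq}")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return math.inf
    # trigamma(y) ~ 1/y for large y, ~ 1/y^2 for small y
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Moment-match the variance prior from per-feature sample variances.

    Under the hierarchical model, e_g = log(s2_g) - digamma(df/2) +
    log(df/2) has mean log(s0_sq) + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2) over trigamma(df/2); inverting the trigamma
    recovers d0.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValidationError("need >= 2 positive variances to moderate")
    e = np.log(s2) - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_bar = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = math.inf
        s0_sq = math.exp(e_bar)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(
            e_bar + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def _group_arrays(matrix: OmicsMatrix, sheet: SampleSheet,
                  condition: Condition) -> tuple[np.ndarray, np.ndarray]:
    if condition.is_control:
        raise ValidationError(
            f"condition {condition.id!r} is a control; nothing to contrast"
        )
    cols = set(matrix.values.columns)
    treated = [s for s in sheet.samples(condition.id, matrix.layer)
               if s in cols]
    control = [s for s in sheet.samples(condition.control_id, matrix.layer)
               if s in cols]
    if len(treated) < 2 or len(control) < 2:
        raise ValidationError(
            f"contrast {condition.id} vs {condition.control_id}: need >= 2 "
            f"replicates per side, got {len(treated)} vs {len(control)}"
        )
    x = matrix.values[treated].to_numpy(dtype=float)
    y = matrix.values[control].to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError(
            "matrix contains missing values; impute before testing"
        )
    return x, y


def moderated_t_contrast(matrix: OmicsMatrix, sheet: SampleSheet,
                         condition: Condition,
                         lfc_threshold: float = 1.0,
                         alpha: float = 0.05,
                         moderation: bool = True,
                         params: ModerationParams | None = None) -> DiffTable:
    """Moderated-t differential expression for one treated-vs-control pair.

    With ``moderation=False`` (or a degenerate prior) this reduces to the
    ordinary pooled two-sample t-test.  The protein layer uses the
    inclusive adjusted-p threshold (<= alpha); other layers use strict <.
    """
    x, y = _group_arrays(matrix, sheet, condition)
    n1, n2 = x.shape[1], y.shape[1]
    dg = n1 + n2 - 2
    lfc = x.mean(axis=1) - y.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / dg
    if moderation:
        if params is None:
            params = estimate_moderation(s2, dg)
        if math.isinf(params.d0):
            s2_post = np.full_like(s2, params.s0_sq)
            df_total = np.inf
        else:
            s2_post = (params.d0 * params.s0_sq + dg * s2) / (params.d0 + dg)
            df_total = params.d0 + dg
    else:
        s2_post = s2
        df_total = dg
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p_adj = bh_adjust(p)
    inclusive = matrix.layer == "protein"
    sig = (p_adj <= alpha) if inclusive else (p_adj < alpha)
    call = np.where(sig & (lfc >= lfc_threshold), "up",
                    np.where(sig & (lfc <= -lfc_threshold), "down", "ns"))
    table = pd.DataFrame({
        "feature": matrix.feature_ids,
        "log2_fc": lfc,
        "t_stat": t,
        "p_raw": p,
        "p_adj": p_adj,
        "call": call,
    })
    return DiffTable(table, condition=condition.id,
                     control=condition.control_id, layer=matrix.layer)


def metabolite_t(matrix: OmicsMatrix, sheet: SampleSheet,
                 condition: Condition, alpha: float = 0.05) -> DiffTable:
    """Equal-variance Student t on raw metabolite concentrations.

    Fold change is reported signed on the natural scale: m_t/m_c when the
    treated mean is the larger, else -m_c/m_t.  p-values are reported raw
    (no adjustment across the small targeted panel); log2_fc carries the
    signed log2 ratio for downstream plotting.
    """
    x, y = _group_arrays(matrix, sheet, condition)
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("metabolite concentrations must be non-negative")
    m_t = x.mean(axis=1)
    m_c = y.mean(axis=1)
    if np.any(m_c == 0):
        bad = matrix.feature_ids[int(np.argmax(m_c == 0))]
        raise ValidationError(f"zero control mean for metabolite {bad!r}")
    if np.any(m_t == 0):
        bad = matrix.feature_ids[int(np.argmax(m_t == 0))]
        raise ValidationError(f"zero treated mean for metabolite {bad!r}")
    t, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    ratio = m_t / m_c
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    sig = p < alpha
    call = np.where(sig & (fc > 1), "up",
                    np.where(sig & (fc < -1), "down", "ns"))
    table = pd.DataFrame({
        "feature": matrix.feature_ids,
        "fold_change": fc,
        "log2_fc": np.sign(fc) * np.abs(np.log2(np.abs(ratio))),
        "t_stat": t,
        "p_raw": p,
        "p_adj": p,
        "call": call,
    })
    return DiffTable(table, condition=condition.id,
                     control=condition.control_id, layer=matrix.layer)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def all_contrasts(matrix: OmicsMatrix, sheet: SampleSheet,
                  test: str = "moderated", **kwargs) -> list[DiffTable]:
    """Run every treated-vs-control contrast present in the sheet."""
    fn = {"moderated": moderated_t_contrast, "metabolite": metabolite_t}[test]
    out = []
    for cond, _ctrl in sheet.contrasts():
        if sheet.samples(cond.id, matrix.layer):
            out.append(fn(matrix, sheet, cond, **kwargs))
    return out
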