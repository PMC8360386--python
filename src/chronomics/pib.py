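"""Pathway-level integration of transcriptomic and proteomic enrichment.

Two complementary statistics are computed per (pathway, stage):

* An *enrichment status* from the lattice of directional ORA outcomes at
  the two biological levels.  Each level is summarized as none / up /
  down / both (significant in both directions), and the 16 combinations
  collapse onto 11 status categories; a pathway is *consistent* when both
  levels agree on a single direction and *discordant* when they point in
  opposite single directions (the signature of post-transcriptional
  regulation).

* A weighted Stouffer Z combination of the per-level enrichment
  p-values, with weights set to each layer's detected-feature universe
  size, which lets a strongly powered layer rescue pathways the weaker
  layer alone cannot call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import ValidationError
from .ora import OraRecord

LEVEL_STATES = ("none", "up", "down", "both")

#: the 11-category enrichment-status lattice: (rna_state, prot_state) -> code
STATUS_LATTICE: dict[tuple[str, str], str] = {
    ("none", "none"): "none",
    ("up", "none"): "rna_up",
    ("down", "none"): "rna_down",
    ("both", "none"): "rna_both",
    ("none", "up"): "prot_up",
    ("none", "down"): "prot_down",
    ("none", "both"): "prot_both",
    ("up", "up"): "consistent_up",
    ("down", "down"): "consistent_down",
    ("up", "down"): "discordant",
    ("down", "up"): "discordant",
    ("up", "both"): "mixed",
    ("down", "both"): "mixed",
    ("both", "up"): "mixed",
    ("both", "down"): "mixed",
    ("both", "both"): "mixed",
}

STATUS_CODES = tuple(dict.fromkeys(STATUS_LATTICE.values()))

P_CLAMP = 1e-15


@dataclass
class StatusRecord:
    pathway_id: str
    stage: str
    rna_state: str
    prot_state: str
    status_code: str
    consistent: bool
    discordant: bool


@dataclass
class CombinedRecord:
    pathway_id: str
    stage: str
    direction: str
    z_rna: float
    z_prot: float
    w_rna: float
    w_prot: float
    z_combined: float
    p_combined: float

    @property
    def significant(self) -> bool:
        return self.p_combined < 0.05


def _level_state(sig_directions: set[str]) -> str:
    if sig_directions == {"up", "down"}:
        return "both"
    if sig_directions == {"up"}:
        return "up"
    if sig_directions == {"down"}:
        return "down"
    return "none"


def _index_records(records: list[OraRecord]
                   ) -> dict[tuple[str, str, str], OraRecord]:
    idx: dict[tuple[str, str, str], OraRecord] = {}
    for r in records:
        key = (r.pathway_id, r.stage, r.direction)
        if key in idx and idx[key].p_raw != r.p_raw:
            raise ValidationError(
                f"conflicting duplicate ORA records for {key}"
            )
        idx[key] = r
    return idx


def assign_status(rna: list[OraRecord], prot: list[OraRecord],
                  alpha: float = 0.05) -> list[StatusRecord]:
    """Classify each (pathway, stage) into the 11-category status lattice.

    A direction is significant at a level when its BH-adjusted p < alpha.
    """
    rna_idx = _index_records(rna)
    prot_idx = _index_records(prot)
    keys = {(p, s) for p, s, _ in rna_idx} | {(p, s) for p, s, _ in prot_idx}
    out = []
    for pathway, stage in sorted(keys):
        rna_sig = {d for (p, s, d), r in rna_idx.items()
                   if p == pathway and s == stage and r.p_adj < alpha}
        prot_sig = {d for (p, s, d), r in prot_idx.items()
                    if p == pathway and s == stage and r.p_adj < alpha}
        rs, ps = _level_state(rna_sig), _level_state(prot_sig)
        code = STATUS_LATTICE[(rs, ps)]
        out.append(StatusRecord(
            pathway_id=pathway, stage=stage, rna_state=rs, prot_state=ps,
            status_code=code,
            consistent=code in ("consistent_up", "consistent_down"),
            discordant=code == "discordant",
        ))
    return out


def weighted_stouffer(p_values, weights) -> tuple[float, float]:
    """Weighted Stouffer combination of one-sided p-values.

    z_i = Phi^-1(1 - p_i); z_c = sum(w_i z_i) / sqrt(sum(w_i^2));
    p_c = 1 - Phi(z_c).  Scaling all weights by a constant leaves the
    statistic unchanged; equal weights recover the unweighted Stouffer
    test.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValidationError("p_values and weights must have equal length")
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    if np.any((p <= 0) | (p >= 1)):
        p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    z = stats.norm.isf(p)
    z_c = float(np.dot(w, z) / np.sqrt(np.dot(w, w)))
    return z_c, float(stats.norm.sf(z_c))


def combine_levels(rna: list[OraRecord], prot: list[OraRecord],
                   w_rna: float, w_prot: float,
                   use_adjusted: bool = False) -> list[CombinedRecord]:
    """Weighted-Z combination per (pathway, stage, direction).

    A level with no record for the key contributes p = 1, which maps to
    a *neutral* z of 0 (no evidence either way) rather than -inf: a
    pathway tested at only one level can then reach combined
    significance when that level is strongly weighted, without the
    untested level actively arguing against it.
    """
    rna_idx = _index_records(rna)
    prot_idx = _index_records(prot)
    keys = sorted(set(rna_idx) | set(prot_idx))
    out = []

    def _z(p: float) -> float:
        if p >= 1.0:
            return 0.0
        return float(stats.norm.isf(max(p, P_CLAMP)))

    for key in keys:
        pathway, stage, direction = key

        def _p(idx):
            r = idx.get(key)
            if r is None:
                return 1.0
            return r.p_adj if use_adjusted else r.p_raw

        p_r, p_p = _p(rna_idx), _p(prot_idx)
        z_r, z_p = _z(p_r), _z(p_p)
        z_c = (w_rna * z_r + w_prot * z_p) / np.sqrt(w_rna ** 2
                                                     + w_prot ** 2)
        p_c = float(stats.norm.sf(z_c))
        out.append(CombinedRecord(pathway, stage, direction, z_r, z_p,
                                  w_rna, w_prot, float(z_c), p_c))
    return out


def consistent_significant(records: list[CombinedRecord],
                           alpha: float = 0.05) -> list[CombinedRecord]:
    """Combined records significant in exactly one direction per
    (pathway, stage) — the directionally consistent calls."""
    by_key: dict[tuple[str, str], list[CombinedRecord]] = {}
    for r in records:
        by_key.setdefault((r.pathway_id, r.stage), []).append(r)
    out = []
    for recs in by_key.values():
        sig = [r for r in recs if r.p_combined < alpha]
        if len(sig) == 1:
            out.append(sig[0])
    return sorted(out, key=lambda r: (r.stage, r.pathway_id))
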