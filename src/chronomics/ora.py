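"""Directional hypergeometric pathway over-representation analysis (ORA).

The same upper-tail hypergeometric test serves differentially expressed
genes (split by direction), differentially expressed proteins, the gene
content of co-expression modules, and any other feature list versus a GMT
collection.  BH adjustment is applied within one (layer, stage,
direction) family of pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DiffTable, GeneSetCollection, ValidationError
from .diffexpr import bh_adjust

DIRECTIONS = ("up", "down", "undirected")


@dataclass
class OraRecord:
    """One pathway test: overlap k of a query of size n with a set of size
    K inside a universe of size N."""

    pathway_id: str
    layer: str
    stage: str
    direction: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float = np.nan
    q_value: float = np.nan

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"bad direction {self.direction!r}")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap between a random size-n draw (without
    replacement) from a universe of N features, K of which belong to the
    pathway.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"need 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"need 0 <= k <= min(K, n); got k={k}")
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _records_frame(records: list[OraRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def _test_sets(query: set[str], sets: GeneSetCollection,
               universe: set[str], layer: str, stage: str,
               direction: str) -> list[OraRecord]:
    query = query & universe
    n = len(query)
    N = len(universe)
    out = []
    for sid in sets:
        members = set(sets.members(sid)) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        out.append(OraRecord(sid, layer, stage, direction, k, K, n, N,
                             hypergeom_p(k, K, n, N)))
    return out


def _adjust_family(records: list[OraRecord]) -> None:
    if not records:
        return
    p = [r.p_raw for r in records]
    adj = bh_adjust(p)
    for r, a in zip(records, adj):
        r.p_adj = float(a)
        r.q_value = float(a)  # BH-style q-value (see module docs)


def directional_ora(diff: DiffTable, sets: GeneSetCollection,
                    direction: str,
                    universe_policy: str = "detected",
                    alpha: float = 0.05) -> list[OraRecord]:
    """ORA of the features called ``direction`` in one contrast.

    The universe defaults to the detected features of the layer (the
    rows of the tested matrix); ``universe_policy="annotated"`` restricts
    it further to features annotated in at least one set.
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    if universe_policy not in ("detected", "annotated"):
        raise ValidationError(f"unknown universe_policy {universe_policy!r}")
    universe = set(diff.table["feature"])
    if universe_policy == "annotated":
        annotated = set()
        for sid in sets:
            annotated.update(sets.members(sid))
        universe &= annotated
    query = set(diff.features_called(direction))
    if not query:
        return []
    records = _test_sets(query, sets, universe, diff.layer, diff.condition,
                         direction)
    _adjust_family(records)
    return records


def module_ora(module_genes: list[str], sets: GeneSetCollection,
               universe: set[str], module_label: str = "module",
               alpha: float = 0.05, qcut: float = 0.1) -> list[OraRecord]:
    """Undirected ORA of a co-expression module's genes.

    Significance requires both raw p < alpha and q < qcut, applied
    conjunctively.
    """
    if not module_genes:
        raise ValidationError("module gene list is empty")
    records = _test_sets(set(module_genes), sets, set(universe), "module",
                         module_label, "undirected")
    _adjust_family(records)
    return records


def significant(records: list[OraRecord], alpha: float = 0.05,
                qcut: float | None = None,
                use_raw: bool = False) -> list[OraRecord]:
    """Filter records by the adjusted-p threshold (and optionally q).

    ``use_raw=True`` thresholds the raw p instead (the module-ORA
    convention: p < alpha AND q < qcut).
    """
    out = []
    for r in records:
        p = r.p_raw if use_raw else r.p_adj
        if not (p < alpha):
            continue
        if qcut is not None and not (r.q_value < qcut):
            continue
        out.append(r)
    return out


def ora_table(records: list[OraRecord]) -> pd.DataFrame:
    """Long-format DataFrame of ORA records."""
    if not records:
        return pd.DataFrame(columns=["pathway_id", "layer", "stage",
                                     "direction", "k", "K", "n", "N",
                                     "p_raw", "p_adj", "q_value"])
    return _records_frame(records)
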