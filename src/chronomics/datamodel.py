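"""Core domain types for the chronological multi-omics study.

The study design follows the chemically induced rat hepatocellular-carcinoma
(HCC) time course: eleven treated stages (days 1-16, month-1 adjacent/nodule,
month-9 adjacent/nodule/tumor, month-18 adjacent/tumor), each contrasted
against the untreated age-matched control sacrificed at the same sampling
time (0, 9 or 18 months).  Three omics layers are measured on independent
animals: whole-transcriptome arrays (including miRNA genes), mitochondrial
protein iBAQ intensities, and mitochondrial metabolite concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("transcript", "protein", "metabolite")

#: tissue categories of the sampled material
TISSUES = ("whole", "adjacent", "nodule", "tumor", "control")


class ValidationError(ValueError):
    """Raised when an input file or object violates a domain invariant."""


@dataclass(frozen=True)
class Condition:
    """One experimental condition (stage × tissue) of the time course.

    ``control_id`` names the age-matched untreated control this condition is
    contrasted against; controls themselves carry ``control_id=None``.
    ``stage_group`` is the coarse sampling-time group (1, 9 or 18) used by
    the stage classifier.
    """

    id: str
    stage_group: int
    tissue: str
    control_id: str | None = None

    def __post_init__(self) -> None:
        if self.stage_group not in (1, 9, 18):
            raise ValidationError(
                f"condition {self.id!r}: stage_group must be 1, 9 or 18, "
                f"got {self.stage_group!r}"
            )
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"condition {self.id!r}: unknown tissue {self.tissue!r}"
            )

    @property
    def is_control(self) -> bool:
        return self.control_id is None


def default_study_conditions() -> dict[str, Condition]:
    """The canonical 14-condition chronological HCC design.

    Three untreated controls (C0, C9, C18) and eleven treated conditions,
    each mapped to the control of the same sampling time.
    """
    spec = [
        # id, stage_group, tissue, control
        ("C0", 1, "control", None),
        ("C9", 9, "control", None),
        ("C18", 18, "control", None),
        ("D1", 1, "whole", "C0"),
        ("D7", 1, "whole", "C0"),
        ("D11", 1, "whole", "C0"),
        ("D16", 1, "whole", "C0"),
        ("A1", 1, "adjacent", "C0"),
        ("N1", 1, "nodule", "C0"),
        ("A9", 9, "adjacent", "C9"),
        ("N9", 9, "nodule", "C9"),
        ("T9", 9, "tumor", "C9"),
        ("A18", 18, "adjacent", "C18"),
        ("T18", 18, "tumor", "C18"),
    ]
    return {cid: Condition(cid, g, t, c) for cid, g, t, c in spec}


#: conditions in chronological order (controls interleaved at sampling time)
CONDITION_ORDER = (
    "C0", "D1", "D7", "D11", "D16", "A1", "N1",
    "C9", "A9", "N9", "T9",
    "C18", "A18", "T18",
)


def validate_conditions(conditions: dict[str, Condition]) -> None:
    """Check control references resolve and stage groups match controls."""
    for cond in conditions.values():
        if cond.control_id is None:
            continue
        ctrl = conditions.get(cond.control_id)
        if ctrl is None:
            raise ValidationError(
                f"condition {cond.id!r} references unknown control "
                f"{cond.control_id!r}"
            )
        if not ctrl.is_control:
            raise ValidationError(
                f"condition {cond.id!r}: control {ctrl.id!r} is itself "
                "mapped to a control"
            )
        if ctrl.stage_group != cond.stage_group:
            raise ValidationError(
                f"condition {cond.id!r} (stage group {cond.stage_group}) "
                f"mapped to control {ctrl.id!r} of stage group "
                f"{ctrl.stage_group}"
            )


@dataclass
class SampleSheet:
    """Sample metadata: one row per measured sample.

    ``entries`` holds (sample_id, condition_id, replicate_index, layer)
    tuples; ``conditions`` the condition registry the entries resolve
    against.
    """

    entries: pd.DataFrame  # columns: sample_id, condition_id, replicate, layer
    conditions: dict[str, Condition] = field(default_factory=default_study_conditions)

    def __post_init__(self) -> None:
        required = ["sample_id", "condition_id", "replicate", "layer"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        self.entries = self.entries[required].reset_index(drop=True)
        dup = self.entries["sample_id"][self.entries["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate sample_id(s): {sorted(set(dup))}"
            )
        unknown = set(self.entries["condition_id"]) - set(self.conditions)
        if unknown:
            raise ValidationError(f"unknown condition_id(s): {sorted(unknown)}")
        bad_layer = set(self.entries["layer"]) - set(LAYERS)
        if bad_layer:
            raise ValidationError(f"unknown layer tag(s): {sorted(bad_layer)}")
        if (self.entries["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate_index must be >= 1")
        if len(self.entries) == 0:
            raise ValidationError("sample sheet has no entries")
        validate_conditions(self.conditions)

    def samples(self, condition_id: str, layer: str) -> list[str]:
        """Sample ids of one condition within one omics layer."""
        e = self.entries
        sel = (e["condition_id"] == condition_id) & (e["layer"] == layer)
        return list(e.loc[sel, "sample_id"])

    def condition_of(self, sample_id: str) -> Condition:
        e = self.entries
        row = e.loc[e["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return self.conditions[row["condition_id"].iloc[0]]

    def contrasts(self) -> list[tuple[Condition, Condition]]:
        """(treated, control) pairs, in chronological order where known."""
        used = set(self.entries["condition_id"])
        order = [c for c in CONDITION_ORDER if c in self.conditions]
        order += [c for c in self.conditions if c not in order]
        out = []
        for cid in order:
            cond = self.conditions[cid]
            if cond.is_control or cid not in used:
                continue
            out.append((cond, self.conditions[cond.control_id]))
        return out


@dataclass
class OmicsMatrix:
    """One omics layer: features × samples.

    Values are log2 intensities for transcripts and (normalized) proteins,
    and raw concentrations for metabolites.  Missing entries (NaN) are
    allowed only for the protein layer, where they encode non-detection.
    """

    layer: str
    values: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.values.index.duplicated().any():
            dups = list(self.values.index[self.values.index.duplicated()])
            raise ValidationError(f"duplicate feature ids: {sorted(set(dups))}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.layer != "protein" and self.values.isna().to_numpy().any():
            raise ValidationError(
                f"missing values not allowed in layer {self.layer!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.values.loc[list(features)])

    def condition_means(self, sheet: SampleSheet,
                        order: list[str] | None = None) -> pd.DataFrame:
        """Per-condition replicate means (features × conditions).

        This is the alignment used for cross-layer integration: the layers
        were measured on independent animals, so only condition-level
        profiles are comparable.
        """
        if order is None:
            present = set(
                sheet.entries.loc[sheet.entries["layer"] == self.layer,
                                  "condition_id"]
            )
            order = [c for c in CONDITION_ORDER if c in present]
            order += sorted(present - set(order))
        cols = {}
        for cid in order:
            samp = [s for s in sheet.samples(cid, self.layer)
                    if s in self.values.columns]
            if samp:
                cols[cid] = self.values[samp].mean(axis=1)
        return pd.DataFrame(cols)


@dataclass
class GeneSetCollection:
    """Named feature sets (pathways), e.g. from a GMT file."""

    sets: dict[str, tuple[str, list[str]]]  # id -> (name, members)

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def name(self, set_id: str) -> str:
        return self.sets[set_id][0]


DIFF_COLUMNS = ["feature", "log2_fc", "t_stat", "p_raw", "p_adj", "call"]


@dataclass
class DiffTable:
    """Per-feature differential-expression result for one contrast."""

    table: pd.DataFrame  # columns DIFF_COLUMNS
    condition: str
    control: str
    layer: str

    def __post_init__(self) -> None:
        missing = [c for c in DIFF_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"diff table missing columns: {missing}")
        calls = set(self.table["call"]) - {"up", "down", "ns"}
        if calls:
            raise ValidationError(f"invalid calls: {sorted(calls)}")

    def features_called(self, call: str) -> list[str]:
        return list(self.table.loc[self.table["call"] == call, "feature"])

    @property
    def n_significant(self) -> int:
        return int((self.table["call"] != "ns").sum())


def stack_diff_tables(tables: list[DiffTable]) -> pd.DataFrame:
    """Long-format concatenation of several contrasts."""
    frames = []
    for t in tables:
        f = t.table.copy()
        f.insert(0, "contrast", t.condition)
        f.insert(1, "control", t.control)
        f.insert(2, "layer", t.layer)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def logfc_matrix(tables: list[DiffTable],
                 features: list[str] | None = None) -> pd.DataFrame:
    """Features × contrasts matrix of log2 fold changes."""
    cols = {}
    for t in tables:
        cols[t.condition] = t.table.set_index("feature")["log2_fc"]
    mat = pd.DataFrame(cols)
    if features is not None:
        mat = mat.loc[list(features)]
    return mat
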