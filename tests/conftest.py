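import warnings

import numpy as np
import pandas as pd
import pytest

from chronomics import SyntheticSpec, generate_study
from chronomics import diffexpr, proteome_prep
from chronomics.datamodel import OmicsMatrix, SampleSheet


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, seed 1."""
    return generate_study(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def prepared_proteome(study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prepared, mmap = proteome_prep.prepare_proteome(
            study.protein, study.sheet, 3, seed=11)
    return prepared, mmap


@pytest.fixture(scope="session")
def transcript_diffs(study):
    return diffexpr.all_contrasts(study.transcript, study.sheet, "moderated")


@pytest.fixture
def toy_sheet():
    """Minimal two-condition sheet (D1 vs C0), 3 replicates per layer."""
    rows = []
    for layer, tag in (("transcript", "rna"), ("protein", "pro"),
                       ("metabolite", "met")):
        for cond in ("C0", "D1"):
            for r in (1, 2, 3):
                rows.append({"sample_id": f"{cond}_{tag}{r}",
                             "condition_id": cond, "replicate": r,
                             "layer": layer})
    return SampleSheet(pd.DataFrame(rows))


def make_matrix(values, layer="transcript", prefix="F", columns=None):
    arr = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i + 1}" for i in range(arr.shape[0])]
    cols = columns or [f"s{j + 1}" for j in range(arr.shape[1])]
    return OmicsMatrix(layer, pd.DataFrame(arr, index=idx, columns=cols))
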