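"""Synthetic chronological multi-omics study generator with ground truth.

Emulates the statistical structure the downstream analysis assumes, on
the 14-condition chronological HCC design: transcripts organised into
co-expression modules with stage-specific eigengene trajectories, miRNA
regulators anticorrelated with modules, planted differentially expressed
features feeding planted-enriched pathway sets at one or both omics
levels, mitochondrial protein intensities with intensity-dependent
(MNAR) plus random (MAR) missingness, targeted metabolites with planted
fold changes, and a small stage-discriminative protein panel.  Every
planted effect is recorded in a :class:`TruthManifest` so recovery can
be scored exactly.

Module eigengene trajectories are lattice random walks (steps in
{-step, 0, +step}) over the chronological condition ordering, rejected
and redrawn when nearly collinear with an existing module; the discrete
step keeps planted module-stage relevance unambiguous (noiseless median
member |log2FC| sits well clear of the 0.9 gate on either side).  One
module is forced high during the first-day response with a decaying
tail, and one is forced high in tumours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    CONDITION_ORDER,
    Condition,
    GeneSetCollection,
    OmicsMatrix,
    SampleSheet,
    ValidationError,
    default_study_conditions,
)

METABOLITE_NAMES = (
    "citric_acid", "malic_acid", "succinic_acid", "glutamate",
    "glutamine", "lactic_acid", "alpha_ketoglutaric_acid", "fumaric_acid",
)

#: planted metabolite fold changes (signed natural scale; negative =
#: decrease by that factor).  Values follow the reported chronological
#: profile: malic acid elevated through the treatment days, and a
#: first-day drop of glutamate, citrate and alpha-ketoglutarate with a
#: seventh-day glutamate rebound.
DEFAULT_METABOLITE_FC: dict[tuple[str, str], float] = {
    ("malic_acid", "D1"): 1.59,
    ("malic_acid", "D7"): 4.63,
    ("malic_acid", "D11"): 2.5,
    ("malic_acid", "D16"): 1.8,
    ("glutamate", "D1"): -3.95,
    ("glutamate", "D7"): 3.37,
    ("citric_acid", "D1"): -12.0,
    ("alpha_ketoglutaric_acid", "D1"): -17.8,
}

#: planted pathway enrichment: (pathway_id, condition, direction, layer).
#: Mirrors the qualitative integration verdicts: one consistent-up
#: pathway in late tumour, consistent-down metabolic pathways at day
#: one, one discordant pathway (RNA up, protein down) in late tumour,
#: and single-level enrichments.
DEFAULT_PLANTED_ENRICHED: tuple[tuple[str, str, str, str], ...] = (
    ("PW01", "T18", "up", "transcript"),
    ("PW01", "T18", "up", "protein"),
    ("PW02", "D1", "down", "transcript"),
    ("PW02", "D1", "down", "protein"),
    ("PW03", "T18", "up", "transcript"),
    ("PW03", "T18", "down", "protein"),
    ("PW04", "D1", "up", "transcript"),
    ("PW05", "D7", "down", "transcript"),
    ("PW06", "D1", "down", "protein"),
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults reproduce the design of the chronological HCC experiment:
    14 conditions, 4/3/3 replicates per layer, 2000 genes + 60 miRNA
    genes, 600 mitochondrial proteins, the 8 targeted metabolites, 9
    planted modules, and a 16-protein stage panel.
    """

    n_genes: int = 2000
    n_mirna: int = 60
    n_proteins: int = 600
    metabolite_names: tuple[str, ...] = METABOLITE_NAMES
    n_modules: int = 9
    module_sizes: tuple[int, ...] = (260, 240, 220, 200, 180, 160, 140,
                                     120, 100)
    replicates: dict = field(default_factory=lambda: {
        "transcript": 4, "protein": 3, "metabolite": 3})
    conditions: dict[str, Condition] = field(
        default_factory=default_study_conditions)
    # transcript signal
    trajectory_step: float = 0.7
    forced_amplitude: float = 2.1
    loading_mean: float = 1.0
    loading_sd: float = 0.2
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    # miRNA regulators
    regulators_per_module: int = 2
    regulator_amplitude: float = 1.5  # rho; profiles = -rho * eigengene
    # pathways / planted DE
    n_pathways: int = 80
    pathway_gene_size: tuple[int, int] = (25, 40)
    pathway_protein_size: tuple[int, int] = (12, 20)
    enriched_de_fraction: float = 0.6
    de_shift_gene: float = 2.0
    de_shift_protein: float = 2.0
    n_background_de: int = 150
    planted_enriched: tuple[tuple[str, str, str, str], ...] = \
        DEFAULT_PLANTED_ENRICHED
    n_module_pathways: int = 5
    # proteins
    protein_base_mean: float = 5.0
    protein_base_sd: float = 1.5
    protein_condition_sd: float = 0.3
    protein_noise_sd: float = 0.25
    mnar_threshold_quantile: float = 0.15
    mar_rate: float = 0.05
    panel_size: int = 16
    panel_shift: float = 2.5  # group-mean separation, units of noise sd
    panel_base_mean: float = 6.5
    panel_base_sd: float = 0.5
    # metabolites
    metabolite_fc: dict = field(
        default_factory=lambda: dict(DEFAULT_METABOLITE_FC))
    metabolite_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValidationError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError("module sizes exceed n_genes")
        if any(s < 20 for s in self.module_sizes):
            raise ValidationError("module sizes must be >= 20")
        if self.panel_size > self.n_proteins:
            raise ValidationError("panel_size exceeds n_proteins")
        for p in (self.mnar_threshold_quantile, self.mar_rate,
                  self.enriched_de_fraction):
            if not (0 <= p <= 1):
                raise ValidationError(f"probability {p} outside [0, 1]")

    @property
    def condition_order(self) -> list[str]:
        order = [c for c in CONDITION_ORDER if c in self.conditions]
        return order + sorted(set(self.conditions) - set(order))


def emulate_study_defaults() -> SyntheticSpec:
    """The spec whose design mirrors the chronological HCC study: 14
    conditions (incl. controls C0/C9/C18), 4/3/3 replicates, the 8
    targeted metabolites, and a 16-protein stage panel."""
    return SyntheticSpec()


@dataclass
class TruthManifest:
    """Ground truth of every planted effect, for recovery scoring."""

    module_of: dict[str, str | None]
    trajectories: pd.DataFrame          # modules × conditions
    loadings: pd.Series                 # gene -> loading
    regulator_of: dict[str, tuple[str, int]]  # miRNA -> (module, sign)
    regulator_r_true: pd.Series         # model correlation at condition level
    de_truth: pd.DataFrame              # layer, feature, condition, shift
    enriched_truth: tuple               # (pathway, condition, dir, layer)
    module_linked_pathways: dict[str, str]
    mnar_mask: pd.DataFrame             # proteins × samples, bool
    mar_mask: pd.DataFrame
    panel: list[str]
    panel_group_means: pd.DataFrame     # panel proteins × groups
    metabolite_fc_truth: pd.DataFrame   # metabolites × conditions
    noiseless_transcript: pd.DataFrame
    noiseless_protein_log2: pd.DataFrame
    metabolite_means: pd.DataFrame      # metabolites × conditions

    def planted_relevance(self, threshold: float = 0.9,
                          strict_alpha: float = 0.01) -> pd.DataFrame:
        """Noiseless module-stage relevance ground truth.

        Mirrors the operational rule on the noiseless fold changes:
        median member |log2FC| above ``threshold`` AND a Wilcoxon
        rank-sum of the stage's member values against the module's
        pooled other-stage values below ``strict_alpha``.  The stricter
        alpha keeps the planted set clear of the detection boundary, so
        noise cannot flip a truly relevant pair to undetectable.
        """
        from scipy import stats as _stats

        rows = []
        genes_by_mod: dict[str, list[str]] = {}
        for g, m in self.module_of.items():
            if m is not None:
                genes_by_mod.setdefault(m, []).append(g)
        de = self.de_truth
        de_tr = de[de["layer"] == "transcript"]
        shift_map = {(r.feature, r.condition): r.shift
                     for r in de_tr.itertuples()}
        treated = [c for c in self.trajectories.columns
                   if self._control_of.get(c) is not None]
        for mod, genes in genes_by_mod.items():
            traj = self.trajectories.loc[mod]
            lfc_by_cond = {}
            for cond in treated:
                delta = traj[cond] - traj[self._control_of[cond]]
                lfc_by_cond[cond] = np.array([
                    self.loadings[g] * delta + shift_map.get((g, cond), 0.0)
                    for g in genes])
            for cond in treated:
                here = lfc_by_cond[cond]
                rest = np.concatenate([lfc_by_cond[c] for c in treated
                                       if c != cond])
                med = float(np.median(here))
                if np.all(here == here[0]) and np.all(rest == here[0]):
                    p = 1.0
                else:
                    p = float(_stats.mannwhitneyu(
                        here, rest, alternative="two-sided").pvalue)
                rows.append({"module": mod, "condition": cond,
                             "median_logfc": med, "wilcoxon_p": p,
                             "relevant": abs(med) > threshold
                             and p < strict_alpha,
                             "direction": "up" if med > 0 else "down"})
        return pd.DataFrame(rows)

    _control_of: dict[str, str | None] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    sheet: SampleSheet
    transcript: OmicsMatrix
    protein: OmicsMatrix
    metabolite: OmicsMatrix
    gene_sets: GeneSetCollection
    truth: TruthManifest


def _lattice_walk(rng: np.random.Generator, n: int, step: float
                  ) -> np.ndarray:
    steps = rng.choice([-step, 0.0, step], size=n - 1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _make_trajectories(spec: SyntheticSpec, rng: np.random.Generator,
                       order: list[str]) -> pd.DataFrame:
    """Module eigengene trajectories over the condition ordering.

    Every module follows a lattice random walk; walks with too little
    spread (sd < 0.7) or near-collinear with an earlier module
    (|r| > 0.6) are redrawn so each module carries distinct, detectable
    signal.  The
    first two modules additionally receive forced stage programmes: an
    acute first-day response with a decaying tail, and a tumour rise.
    The forced offsets are multiples of the lattice step, keeping the
    planted module-stage relevance medians clear of the 0.9 gate.
    """
    n_cond = len(order)
    names = [f"M{i + 1}" for i in range(spec.n_modules)]
    traj = np.zeros((spec.n_modules, n_cond))
    idx = {c: i for i, c in enumerate(order)}
    amp = spec.forced_amplitude
    forced: list[dict[int, float]] = [dict() for _ in range(spec.n_modules)]
    if spec.n_modules >= 1:
        forced[0] = {idx[c]: v for c, v in
                     (("D1", amp), ("D7", amp / 2), ("D11", amp / 4))
                     if c in idx}
    if spec.n_modules >= 2:
        forced[1] = {idx[c]: v for c, v in
                     (("N9", amp / 2), ("T9", amp), ("A18", amp / 2),
                      ("T18", amp)) if c in idx}
    for _restart in range(50):
        placed = 0
        for m in range(spec.n_modules):
            for _attempt in range(3000):
                w = _lattice_walk(rng, n_cond, spec.trajectory_step)
                # the base walk itself must carry spread: a forced spike
                # on a flat background concentrates all signal in a few
                # samples, which any robust correlation downweights
                if w.std() < 0.7:
                    continue
                for j, v in forced[m].items():
                    w[j] += v
                # spread must not be carried by a couple of extreme
                # conditions: robust correlation trims those away
                dev = np.abs(w - np.median(w))
                trimmed = np.delete(w, np.argsort(dev)[-2:])
                if trimmed.std() < 0.6:
                    continue
                if all(abs(np.corrcoef(w, traj[p])[0, 1]) <= 0.6
                       for p in range(m)):
                    traj[m] = w
                    placed += 1
                    break
            else:
                break  # cornered by earlier placements: restart the set
        if placed == spec.n_modules:
            return pd.DataFrame(traj, index=names, columns=order)
    raise ValidationError("could not draw distinct trajectories")


def _sample_ids(order: list[str], layer: str, reps: int) -> list[str]:
    tag = {"transcript": "rna", "protein": "pro", "metabolite": "met"}[layer]
    return [f"{c}_{tag}{r + 1}" for c in order for r in range(reps)]


def generate_study(spec: SyntheticSpec | None = None) -> SyntheticStudy:
    """Generate the full synthetic study plus its truth manifest.

    Identical specs (including seed) yield bit-identical outputs.
    """
    if spec is None:
        spec = emulate_study_defaults()
    rng = np.random.default_rng(spec.seed)
    order = spec.condition_order
    control_of = {c: spec.conditions[c].control_id for c in order}

    gene_ids = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    mirna_ids = [f"miR{i + 1}" for i in range(spec.n_mirna)]
    protein_ids = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]

    # --- module structure -------------------------------------------------
    traj = _make_trajectories(spec, rng, order)
    module_names = list(traj.index)
    module_of: dict[str, str | None] = {g: None for g in gene_ids}
    pos = 0
    members: dict[str, list[str]] = {}
    for name, size in zip(module_names, spec.module_sizes):
        members[name] = gene_ids[pos:pos + size]
        for g in members[name]:
            module_of[g] = name
        pos += size
    loadings = pd.Series(
        rng.normal(spec.loading_mean, spec.loading_sd, size=spec.n_genes),
        index=gene_ids)

    # --- miRNA regulators -------------------------------------------------
    regulator_of: dict[str, tuple[str, int]] = {}
    r_true = {}
    n_reg = min(spec.regulators_per_module * spec.n_modules, spec.n_mirna)
    reps_t = spec.replicates["transcript"]
    for i in range(n_reg):
        mod = module_names[i % spec.n_modules]
        mid = mirna_ids[i]
        regulator_of[mid] = (mod, -1)
        e = traj.loc[mod].to_numpy()
        sig = spec.regulator_amplitude * e.std()
        noise = spec.noise_sd / np.sqrt(reps_t)
        r_true[mid] = -sig / np.sqrt(sig ** 2 + noise ** 2) \
            if sig > 0 else 0.0
    regulator_r_true = pd.Series(r_true)

    # protein baseline abundances are drawn up front: planted protein
    # effects are placed on reliably quantified (high-abundance) pathway
    # members, as only those are recoverable through left-censoring
    panel = list(rng.choice(protein_ids, size=spec.panel_size,
                            replace=False))
    base_p = pd.Series(rng.normal(spec.protein_base_mean,
                                  spec.protein_base_sd,
                                  size=spec.n_proteins), index=protein_ids)
    base_p[panel] = rng.normal(spec.panel_base_mean, spec.panel_base_sd,
                               size=spec.panel_size)

    # --- pathway sets and planted DE ---------------------------------------
    sets: dict[str, tuple[str, list[str]]] = {}
    lo_g, hi_g = spec.pathway_gene_size
    lo_p, hi_p = spec.pathway_protein_size
    for i in range(spec.n_pathways):
        pid = f"PW{i + 1:02d}"
        kg = int(rng.integers(lo_g, hi_g + 1))
        kp = int(rng.integers(lo_p, hi_p + 1))
        g_members = list(rng.choice(gene_ids, size=kg, replace=False))
        p_members = list(rng.choice(protein_ids, size=kp, replace=False))
        sets[pid] = (f"synthetic pathway {i + 1}", g_members + p_members)
    # module-linked pathways: ~60 % of members from one planted module
    module_linked: dict[str, str] = {}
    for i in range(min(spec.n_module_pathways, spec.n_modules)):
        mod = module_names[i]
        pid = f"PWM{i + 1}"
        n_mod = min(int(0.6 * 30), len(members[mod]))
        from_mod = list(rng.choice(members[mod], size=n_mod, replace=False))
        from_bg = list(rng.choice(gene_ids, size=30 - n_mod + 18,
                                  replace=False))
        sets[pid] = (f"pathway linked to {mod}",
                     list(dict.fromkeys(from_mod + from_bg)))
        module_linked[mod] = pid

    de_rows: list[dict] = []
    for pid, cond, direction, layer in spec.planted_enriched:
        if pid not in sets:
            raise ValidationError(f"planted pathway {pid!r} not generated")
        sign = 1.0 if direction == "up" else -1.0
        pool = [m for m in sets[pid][1]
                if (m in module_of) == (layer == "transcript")]
        n_de = max(1, int(round(spec.enriched_de_fraction * len(pool))))
        if layer == "protein":
            # most abundant members: recoverable through censoring;
            # panel proteins are reserved as clean stage markers
            pool = [p for p in pool if p not in set(panel)]
            pool = sorted(pool, key=lambda p: -base_p[p])
            chosen = np.array(pool[:min(n_de, len(pool))])
        else:
            chosen = rng.choice(pool, size=n_de, replace=False)
        shift = spec.de_shift_gene if layer == "transcript" \
            else spec.de_shift_protein
        for f in chosen:
            de_rows.append({"layer": layer, "feature": f,
                            "condition": cond, "shift": sign * shift})
    # background DE genes, spread over treated conditions
    treated = [c for c in order if control_of[c] is not None]
    bg_genes = rng.choice(gene_ids, size=spec.n_background_de, replace=False)
    for g in bg_genes:
        cond = treated[int(rng.integers(len(treated)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        de_rows.append({"layer": "transcript", "feature": g,
                        "condition": cond, "shift": sign * spec.de_shift_gene})
    de_truth = pd.DataFrame(de_rows,
                            columns=["layer", "feature", "condition",
                                     "shift"]).drop_duplicates(
        subset=["layer", "feature", "condition"], keep="first")

    # --- transcript matrix -------------------------------------------------
    t_samples = _sample_ids(order, "transcript", reps_t)
    cond_of_sample = {s: s.split("_")[0] for s in t_samples}
    n_tfeat = spec.n_genes + spec.n_mirna
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_tfeat)
    signal = np.zeros((n_tfeat, len(t_samples)))
    feat_index = {f: i for i, f in enumerate(gene_ids + mirna_ids)}
    for j, s in enumerate(t_samples):
        c = cond_of_sample[s]
        for mod in module_names:
            e = traj.at[mod, c]
            if e == 0:
                continue
            for g in members[mod]:
                signal[feat_index[g], j] += loadings[g] * e
        for mid, (mod, sign) in regulator_of.items():
            signal[feat_index[mid], j] += \
                sign * spec.regulator_amplitude * traj.at[mod, c]
    for row in de_truth.itertuples():
        if row.layer != "transcript":
            continue
        i = feat_index[row.feature]
        for j, s in enumerate(t_samples):
            if cond_of_sample[s] == row.condition:
                signal[i, j] += row.shift
    noiseless_t = baseline[:, None] + signal
    transcript_vals = noiseless_t + rng.normal(
        0.0, spec.noise_sd, size=noiseless_t.shape) \
        if spec.noise_sd > 0 else noiseless_t.copy()
    transcript = OmicsMatrix("transcript", pd.DataFrame(
        transcript_vals, index=gene_ids + mirna_ids, columns=t_samples))
    noiseless_transcript = pd.DataFrame(noiseless_t,
                                        index=gene_ids + mirna_ids,
                                        columns=t_samples)

    # --- protein matrix ----------------------------------------------------
    reps_p = spec.replicates["protein"]
    p_samples = _sample_ids(order, "protein", reps_p)
    cond_offsets = pd.DataFrame(
        rng.normal(0.0, spec.protein_condition_sd,
                   size=(spec.n_proteins, len(order))),
        index=protein_ids, columns=order)
    groups = sorted({c.stage_group for c in spec.conditions.values()})
    panel_means = pd.DataFrame(index=panel, columns=groups, dtype=float)
    sep = spec.panel_shift * spec.protein_noise_sd
    for pid in panel:
        pattern = rng.permutation([-1.0, 0.0, 1.0])[:len(groups)]
        panel_means.loc[pid] = pattern * sep
    # panel proteins follow their stage-group mean, not condition noise
    for pid in panel:
        for c in order:
            g = spec.conditions[c].stage_group
            cond_offsets.at[pid, c] = panel_means.at[pid, g]
    prot_shift = pd.DataFrame(0.0, index=protein_ids, columns=order)
    for row in de_truth.itertuples():
        if row.layer == "protein":
            prot_shift.at[row.feature, row.condition] += row.shift
    noiseless_log2 = pd.DataFrame(
        {s: base_p + cond_offsets[s.split("_")[0]]
         + prot_shift[s.split("_")[0]] for s in p_samples})
    noise_p = rng.normal(0.0, spec.protein_noise_sd,
                         size=noiseless_log2.shape) \
        if spec.protein_noise_sd > 0 else 0.0
    log2_obs = noiseless_log2 + noise_p
    # MNAR: left-censor below the per-sample quantile of noiseless signal
    mnar_mask = pd.DataFrame(False, index=protein_ids, columns=p_samples)
    q = spec.mnar_threshold_quantile
    if q > 0:
        for s in p_samples:
            thr = noiseless_log2[s].quantile(q)
            mnar_mask[s] = noiseless_log2[s] < thr
    # MAR: uniform dropout among entries that survived censoring
    mar_draw = rng.random(size=log2_obs.shape) < spec.mar_rate
    mar_mask = pd.DataFrame(mar_draw & ~mnar_mask.to_numpy(),
                            index=protein_ids, columns=p_samples)
    intensities = (2.0 ** log2_obs).where(~(mnar_mask | mar_mask))
    protein = OmicsMatrix("protein", intensities)

    # --- metabolite matrix -------------------------------------------------
    reps_m = spec.replicates["metabolite"]
    m_samples = _sample_ids(order, "metabolite", reps_m)
    met_names = list(spec.metabolite_names)
    control_mean = pd.Series(rng.uniform(50.0, 200.0, size=len(met_names)),
                             index=met_names)
    fc_truth = pd.DataFrame(1.0, index=met_names, columns=order)
    for (met, cond), fc in spec.metabolite_fc.items():
        if met in fc_truth.index and cond in fc_truth.columns:
            fc_truth.at[met, cond] = fc
    met_means = pd.DataFrame(index=met_names, columns=order, dtype=float)
    for c in order:
        fc = fc_truth[c]
        scaled = np.where(fc >= 1.0, control_mean * fc,
                          control_mean / np.abs(fc))
        met_means[c] = np.where(fc == 1.0, control_mean, scaled)
    met_vals = pd.DataFrame(index=met_names, columns=m_samples, dtype=float)
    for s in m_samples:
        mu = met_means[s.split("_")[0]]
        noise = rng.normal(0.0, 1.0, size=len(met_names)) \
            * spec.metabolite_cv * mu
        met_vals[s] = np.maximum(mu + noise, 1e-6)
    metabolite = OmicsMatrix("metabolite", met_vals)

    # --- sample sheet -------------------------------------------------------
    rows = []
    for layer, samples in (("transcript", t_samples), ("protein", p_samples),
                           ("metabolite", m_samples)):
        for s in samples:
            cond, tail = s.split("_")
            rows.append({"sample_id": s, "condition_id": cond,
                         "replicate": int(tail[3:]), "layer": layer})
    sheet = SampleSheet(pd.DataFrame(rows), dict(spec.conditions))

    truth = TruthManifest(
        module_of=module_of,
        trajectories=traj,
        loadings=loadings,
        regulator_of=regulator_of,
        regulator_r_true=regulator_r_true,
        de_truth=de_truth,
        enriched_truth=tuple(spec.planted_enriched),
        module_linked_pathways=module_linked,
        mnar_mask=mnar_mask,
        mar_mask=mar_mask,
        panel=panel,
        panel_group_means=panel_means,
        metabolite_fc_truth=fc_truth,
        noiseless_transcript=noiseless_transcript,
        noiseless_protein_log2=noiseless_log2,
        metabolite_means=met_means,
        _control_of=control_of,
    )
    return SyntheticStudy(sheet, transcript, protein, metabolite,
                          GeneSetCollection(sets), truth)


def noiseless_spec(spec: SyntheticSpec | None = None) -> SyntheticSpec:
    """Copy of a spec with all noise and missingness switched off."""
    spec = spec or emulate_study_defaults()
    return replace(spec, noise_sd=0.0, protein_noise_sd=0.0,
                   metabolite_cv=0.0, mnar_threshold_quantile=0.0,
                   mar_rate=0.0)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write all study files (TSV matrices, sample sheet, GMT sets)."""
    from pathlib import Path

    from .io import write_gmt, write_matrix, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_sheet(study.sheet, outdir / "samples.tsv")
    write_matrix(study.transcript, outdir / "transcript.tsv")
    write_matrix(study.protein, outdir / "protein.tsv")
    write_matrix(study.metabolite, outdir / "metabolite.tsv")
    write_gmt(study.gene_sets, outdir / "pathways.gmt")
    study.truth.de_truth.to_csv(outdir / "truth_de.tsv", sep="\t",
                                index=False)
    pd.Series(study.truth.module_of).rename("module").to_csv(
        outdir / "truth_modules.tsv", sep="\t")
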