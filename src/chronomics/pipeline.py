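"""End-to-end orchestration of the chronological multi-omics analysis.

Stages: proteomic preparation (two imputation tracks: deterministic
MinDet for differential testing, mechanism-split MinProb/kNN for network
integration) -> differential expression for all treated-vs-control
contrasts at the three layers -> directional pathway ORA at transcript
and protein level -> enrichment-status lattice and weighted Stouffer-Z
integration -> weighted co-expression modules, stage relevance and
module-feature correlation -> proteomic stage classification.  All
randomness flows from one root seed recorded in the run summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression as cx
from . import diffexpr, ora, pib, proteome_prep, staging
from .datamodel import (
    DiffTable,
    GeneSetCollection,
    OmicsMatrix,
    SampleSheet,
    ValidationError,
    logfc_matrix,
    stack_diff_tables,
)
from .io import load_gmt, load_matrix, load_sample_sheet
from .synthetic import SyntheticSpec, SyntheticStudy, generate_study


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run.

    Either ``synthetic`` is set (a generator spec) or the four input
    paths are; thresholds default to the study design's settings.
    """

    out_dir: str = "chronomics_out"
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    sample_sheet: str | None = None
    transcript_path: str | None = None
    protein_path: str | None = None
    metabolite_path: str | None = None
    gene_sets_path: str | None = None
    mirna_prefix: str = "miR"
    # differential expression
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    # proteome preparation
    min_complete_reps: int = 3
    minprob_q: float = 0.1
    tune_sigma: float = 1.0
    knn_k: int = 11
    mnar_quantile: float = 0.25
    # network
    beta: int | None = 24
    min_module_size: int = 20
    relevance_median: float = 0.9
    feature_p: float = 0.001
    feature_r_report: float = 0.40
    k_feature_clusters: int = 10
    module_ora_alpha: float = 0.05
    module_ora_qcut: float = 0.1
    # staging
    staging: staging.StagingConfig = field(
        default_factory=staging.StagingConfig)


@dataclass
class PipelineResult:
    """In-memory handles to everything the run produced."""

    config: RunConfig
    study: SyntheticStudy | None
    sheet: SampleSheet
    diff_transcript: list[DiffTable]
    diff_protein: list[DiffTable]
    diff_metabolite: list[DiffTable]
    ora_rna: list[ora.OraRecord]
    ora_prot: list[ora.OraRecord]
    status: list[pib.StatusRecord]
    combined: list[pib.CombinedRecord]
    network: cx.CoexpressionState
    eigengenes: pd.DataFrame
    relevance: list[cx.RelevanceRecord]
    feature_correlations: list[cx.FeatureCorrelation]
    feature_clusters: dict[str, str]
    module_ora: dict[str, list[ora.OraRecord]]
    error_curve: staging.ErrorCurve
    summary: dict


def _load_inputs(config: RunConfig
                 ) -> tuple[SampleSheet, OmicsMatrix, OmicsMatrix,
                            OmicsMatrix, GeneSetCollection,
                            SyntheticStudy | None]:
    if config.synthetic is not None:
        study = generate_study(config.synthetic)
        return (study.sheet, study.transcript, study.protein,
                study.metabolite, study.gene_sets, study)
    for name in ("sample_sheet", "transcript_path", "protein_path",
                 "metabolite_path", "gene_sets_path"):
        path = getattr(config, name)
        if path is None:
            raise ValidationError(f"config missing input path: {name}")
        if not Path(path).exists():
            raise ValidationError(f"input file not found: {path} ({name})")
    sheet = load_sample_sheet(config.sample_sheet)
    transcript = load_matrix(config.transcript_path, "transcript")
    protein = load_matrix(config.protein_path, "protein")
    metabolite = load_matrix(config.metabolite_path, "metabolite")
    sets = load_gmt(config.gene_sets_path)
    return sheet, transcript, protein, metabolite, sets, None


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis; optionally write all artifacts."""
    rng = np.random.default_rng(config.seed)
    seed_minprob = int(rng.integers(2 ** 31))
    seed_staging = int(rng.integers(2 ** 31))

    sheet, transcript, protein_raw, metabolite, sets, study = \
        _load_inputs(config)

    # --- proteome preparation -------------------------------------------
    filtered = proteome_prep.filter_quantified(
        protein_raw, sheet, config.min_complete_reps)
    normalized = proteome_prep.normalize_protein(filtered)
    protein_dep = proteome_prep.impute_mindet(normalized)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        protein_net, missmap = proteome_prep.prepare_proteome(
            protein_raw, sheet, config.min_complete_reps,
            q=config.minprob_q, tune_sigma=config.tune_sigma,
            k=config.knn_k, mnar_quantile=config.mnar_quantile,
            seed=seed_minprob)

    # --- differential expression -----------------------------------------
    diff_t = diffexpr.all_contrasts(
        transcript, sheet, "moderated",
        lfc_threshold=config.lfc_threshold, alpha=config.alpha)
    diff_p = diffexpr.all_contrasts(
        protein_dep, sheet, "moderated",
        lfc_threshold=config.lfc_threshold, alpha=config.alpha)
    diff_m = diffexpr.all_contrasts(metabolite, sheet, "metabolite",
                                    alpha=config.alpha)

    # --- pathway over-representation --------------------------------------
    ora_rna: list[ora.OraRecord] = []
    ora_prot: list[ora.OraRecord] = []
    for table, sink in ((diff_t, ora_rna), (diff_p, ora_prot)):
        for d in table:
            for direction in ("up", "down"):
                sink.extend(ora.directional_ora(d, sets, direction,
                                                alpha=config.alpha))

    # --- integration -------------------------------------------------------
    status = pib.assign_status(ora_rna, ora_prot, alpha=config.alpha)
    w_rna = float(transcript.shape[0])
    w_prot = float(protein_dep.shape[0])
    combined = pib.combine_levels(ora_rna, ora_prot, w_rna, w_prot)

    # --- co-expression network --------------------------------------------
    is_mirna = transcript.values.index.str.startswith(config.mirna_prefix)
    genes = transcript.subset_features(
        transcript.values.index[~is_mirna])
    mirna = transcript.subset_features(transcript.values.index[is_mirna])
    network = cx.build_network(genes, beta=config.beta,
                               min_module_size=config.min_module_size)
    eigengenes = cx.module_eigengenes(genes, network.modules)
    relevance = cx.module_relevance(diff_t, network.modules,
                                    median_threshold=config.relevance_median,
                                    alpha=config.alpha)

    me_by_cond = OmicsMatrix(
        "transcript", eigengenes.T).condition_means(sheet).T
    correlations: list[cx.FeatureCorrelation] = []
    profiles = {}
    if protein_net.shape[0]:
        prof = protein_net.condition_means(sheet)
        correlations += cx.correlate_features(me_by_cond, prof, "protein",
                                              p_threshold=config.feature_p)
        profiles.update(prof.T.to_dict("series"))
    met_prof = metabolite.condition_means(sheet)
    correlations += cx.correlate_features(me_by_cond, met_prof, "metabolite",
                                          p_threshold=config.feature_p)
    profiles.update(met_prof.T.to_dict("series"))
    if mirna.shape[0]:
        mir_prof = mirna.condition_means(sheet)
        correlations += cx.correlate_features(me_by_cond, mir_prof, "miRNA",
                                              p_threshold=config.feature_p)
        profiles.update(mir_prof.T.to_dict("series"))
    sig_ids = cx.significant_features(correlations)
    clusters: dict[str, str] = {}
    if sig_ids:
        common_conds = list(me_by_cond.index)
        prof_mat = pd.DataFrame(
            {f: profiles[f][common_conds] for f in sig_ids}).T
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clusters = cx.cluster_features(prof_mat,
                                           k=config.k_feature_clusters)
        for c in correlations:
            c.cluster_label = clusters.get(c.feature_id, "")

    module_universe = set(genes.feature_ids)
    module_ora_records: dict[str, list[ora.OraRecord]] = {}
    for label in network.module_labels:
        module_ora_records[label] = ora.module_ora(
            network.members(label), sets, module_universe, label,
            alpha=config.module_ora_alpha, qcut=config.module_ora_qcut)

    # --- staging ------------------------------------------------------------
    # classification uses the mechanism-aware imputation track: MinDet
    # floors random dropouts to the detection limit, which corrupts the
    # within-group variance of otherwise well-quantified markers
    groups = staging.stage_groups(sheet, "protein")
    stage_cfg = staging.StagingConfig(
        **{**vars(config.staging), "seed": seed_staging})
    curve = staging.error_curve(protein_net, groups, stage_cfg)

    # --- summary ------------------------------------------------------------
    deg = set()
    for d in diff_t:
        deg.update(d.features_called("up"))
        deg.update(d.features_called("down"))
    dep = set()
    for d in diff_p:
        dep.update(d.features_called("up"))
        dep.update(d.features_called("down"))
    sig_status = [s for s in status if s.status_code != "none"]
    summary = {
        "seed": config.seed,
        "n_transcript_features": transcript.shape[0],
        "n_proteins_quantified": int(protein_dep.shape[0]),
        "n_deg": len(deg),
        "n_dep": len(dep),
        "n_metabolite_hits": int(sum(d.n_significant for d in diff_m)),
        "n_pathway_enrichment_events": len(sig_status),
        "n_distinct_enriched_pathways": len(
            {s.pathway_id for s in sig_status}),
        "n_consistent": int(sum(s.consistent for s in sig_status)),
        "n_discordant": int(sum(s.discordant for s in sig_status)),
        "n_combined_significant": int(
            sum(r.significant for r in combined)),
        "n_modules": len(network.module_labels),
        "n_relevant_module_stages": int(
            sum(r.relevant for r in relevance)),
        "n_significant_feature_correlations": int(
            sum(c.significant for c in correlations)),
        "n_modules_with_enriched_pathways": int(sum(
            1 for recs in module_ora_records.values()
            if ora.significant(recs, config.module_ora_alpha,
                               config.module_ora_qcut, use_raw=True))),
        "staging_minimal_panel": curve.minimal_m,
        "staging_errors": {s: curve.curve[s].min()
                           for s in stage_cfg.schemes},
    }

    result = PipelineResult(
        config=config, study=study, sheet=sheet,
        diff_transcript=diff_t, diff_protein=diff_p, diff_metabolite=diff_m,
        ora_rna=ora_rna, ora_prot=ora_prot, status=status, combined=combined,
        network=network, eigengenes=eigengenes, relevance=relevance,
        feature_correlations=correlations, feature_clusters=clusters,
        module_ora=module_ora_records, error_curve=curve, summary=summary)
    if write:
        write_artifacts(result)
    return result


def write_artifacts(result: PipelineResult) -> None:
    """Write all long-format TSVs, the grid exports and summary.json."""
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        stack_diff_tables(result.diff_transcript).to_csv(
            out / "diff_transcript.tsv", sep="\t", index=False)
        stack_diff_tables(result.diff_protein).to_csv(
            out / "diff_protein.tsv", sep="\t", index=False)
        stack_diff_tables(result.diff_metabolite).to_csv(
            out / "diff_metabolite.tsv", sep="\t", index=False)
        ora.ora_table(result.ora_rna + result.ora_prot).to_csv(
            out / "ora.tsv", sep="\t", index=False)
        pd.DataFrame([vars(s) for s in result.status]).to_csv(
            out / "pib_status.tsv", sep="\t", index=False)
        pd.DataFrame([vars(c) for c in result.combined]).to_csv(
            out / "stouffer_combined.tsv", sep="\t", index=False)
        # status grid (pathway × stage)
        if result.status:
            grid = pd.DataFrame([vars(s) for s in result.status]).pivot(
                index="pathway_id", columns="stage", values="status_code")
            grid.to_csv(out / "pib_status_grid.tsv", sep="\t")
        pd.Series(result.network.modules).rename("module").to_csv(
            out / "modules.tsv", sep="\t")
        result.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        cx.relevance_table(result.relevance).to_csv(
            out / "module_relevance.tsv", sep="\t", index=False)
        fc = cx.feature_correlation_table(result.feature_correlations)
        fc.to_csv(out / "feature_correlations.tsv", sep="\t", index=False)
        if len(fc):
            sig = fc[fc["significant"]
                     & (fc["r"].abs()
                        > result.config.feature_r_report)]
            if len(sig):
                sig.pivot(index="feature_id", columns="module",
                          values="r").to_csv(
                    out / "feature_correlation_grid.tsv", sep="\t")
        mod_ora_rows = []
        for recs in result.module_ora.values():
            mod_ora_rows.extend(recs)
        ora.ora_table(mod_ora_rows).to_csv(out / "module_ora.tsv",
                                           sep="\t", index=False)
        result.error_curve.curve.to_csv(out / "staging_error_curve.tsv",
                                        sep="\t", index=False)
        if result.error_curve.panel:
            pd.Series(result.error_curve.panel, name="feature").to_csv(
                out / "staging_panel.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=2, default=_jsonable)
    except Exception:
        (out / "FAILED").touch()
        raise


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
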