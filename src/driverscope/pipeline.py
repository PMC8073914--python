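"""End-to-end orchestration: screen -> DE/intersect -> KD -> network (+ extras).

One global seed fans out to per-stage seeds derived by hashing the stage
name, so toggling a stage never shifts another stage's randomness.  Every
stage writes its table under the run directory and the manifest records
the funnel counts, which must satisfy the containment chain
|KD| <= |candidates ∩ DE| <= |candidates|.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort_io
from ._types import CohortBundle, ExpressionMatrix
from .candidate_screen import ScreenThresholds, candidate_set, screen_candidates
from .config import PipelineConfig
from .dysregulation_network import build_network
from .drug_response import drug_gene_associations, label_associations
from .prognostic_screen import (
    DeThresholds,
    SurvivalThresholds,
    builtin_de,
    intersect_candidates,
    read_external_de,
    survival_screen,
)
from .signature_grouping import (
    cluster_and_select_k,
    group_survival,
    patient_dissimilarity,
)
from .synthetic_cohort import (
    CohortParams,
    DrugPanelParams,
    derive_seed,
    generate_cohort,
    generate_drug_panel,
    generate_regulators,
)
from .variation_spectrum import build_profile

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    out_dir: Path
    counts: dict = field(default_factory=dict)
    candidate_table: pd.DataFrame | None = None
    kd_table: pd.DataFrame | None = None
    kd_genes: list = field(default_factory=list)
    network: object | None = None
    drug_table: pd.DataFrame | None = None
    grouping: object | None = None


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    io_cfg = cohort_io.IoConfig(
        barcode_length=paths.barcode_length, expression_scale=paths.expression_scale
    )
    bundle = cohort_io.read_cohort(
        paths.cna, paths.maf, paths.expression, paths.clinical, io_cfg
    )
    control = (
        cohort_io.read_expression(paths.control_expression, io_cfg)
        if paths.control_expression
        else None
    )
    interactions = (
        cohort_io.read_interactions(
            [(item["path"], item["class"]) for item in paths.interactions]
        )
        if paths.interactions
        else None
    )
    panel = (
        cohort_io.read_ic50(paths.ic50, paths.cell_line_expression, io_cfg)
        if paths.ic50 and paths.cell_line_expression
        else None
    )
    external_de = [read_external_de(p, DeThresholds(cfg.thresholds.de_fdr, cfg.thresholds.de_p)) for p in paths.external_de]
    return bundle, control, interactions, panel, external_de


def _simulate_inputs(cfg: PipelineConfig):
    overrides = {
        k: v for k, v in cfg.simulation.model_dump().items() if v is not None
    }
    if "freq_range" in overrides:
        overrides["freq_range"] = tuple(overrides["freq_range"])
    params = CohortParams(**overrides)
    bundle, truth, control = generate_cohort(params, seed=cfg.seed)
    mirna, tf, interactions, truth = generate_regulators(bundle, truth, seed=cfg.seed)
    bundle.expression["mirna"] = mirna
    bundle.expression["tf"] = tf
    panel = None
    if cfg.stages.drugs:
        panel, drug_truth = generate_drug_panel(
            list(truth.drivers["gene"]), DrugPanelParams(), seed=cfg.seed
        )
        truth.drug_assoc = drug_truth.drug_assoc
    return bundle, truth, control, interactions, panel


def run_pipeline(cfg: PipelineConfig, out_dir) -> PipelineResult:
    """Execute the configured stages and write all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    result = PipelineResult(out_dir=out)
    counts = result.counts

    truth = None
    if cfg.inputs is None:
        bundle, truth, control, interactions, panel = _simulate_inputs(cfg)
        external_de = []
        cohort_io.write_cohort_files(bundle, control, truth, out / "inputs")
    else:
        bundle, control, interactions, panel, external_de = _load_inputs(cfg)

    counts["samples"] = len(bundle.samples)
    counts["genes"] = int(bundle.cna.genes.size)

    # --- variation spectrum + candidate screen
    profile = build_profile(bundle.cna, bundle.mutations)
    cohort_io.write_table(profile.gene_summary(), out / "variation_summary.tsv", "gene")
    if not cfg.stages.screen:
        raise StageError("screen", "pipeline cannot proceed with the screen disabled")
    screen_th = ScreenThresholds(
        dominant_alpha=th.dominant_alpha,
        prevalence=th.prevalence,
        concordance_alpha=th.concordance_alpha,
        frequency=th.frequency,
    )
    candidate_table = screen_candidates(profile, bundle.mrna, screen_th)
    result.candidate_table = candidate_table
    candidates = candidate_set(candidate_table)
    counts["candidates"] = len(candidates)
    logger.info(
        "screen funnel: dominant %d, prevalence %d, concordance %d, frequency %d -> %d candidates",
        int(candidate_table["pass_dominant"].sum()),
        int(candidate_table["pass_prevalence"].sum()),
        int(candidate_table["pass_concordance"].sum()),
        int(candidate_table["pass_frequency"].sum()),
        len(candidates),
    )
    cohort_io.write_table(candidate_table, out / "candidates.tsv", "gene")

    # --- DE stage
    de_tables = list(external_de)
    if cfg.stages.de and control is not None:
        de_tables.append(
            builtin_de(bundle.mrna, control, DeThresholds(th.de_fdr, th.de_p))
        )
    if cfg.stages.kd and not de_tables:
        raise StageError("kd", "needs a DE table: enable the de stage or provide external_de")

    # --- KD survival screen
    if cfg.stages.kd:
        intersected = intersect_candidates(candidates, de_tables, combine=cfg.de_combine)
        counts["candidates_de"] = len(intersected)
        kd_table = survival_screen(
            intersected,
            profile.cna_binary,
            bundle.clinical,
            SurvivalThresholds(alpha=th.survival_alpha, min_group_size=th.min_group_size),
        )
        if not kd_table.empty:
            kd_table = kd_table.join(
                candidate_table[["dominant_type", "frequency"]], how="left"
            )
        result.kd_table = kd_table
        result.kd_genes = (
            list(kd_table.index[kd_table["kd_call"]]) if not kd_table.empty else []
        )
        counts["kd_genes"] = len(result.kd_genes)
        assert counts["kd_genes"] <= counts["candidates_de"] <= counts["candidates"]
        cohort_io.write_table(kd_table, out / "kd_genes.tsv", "gene")

    # --- dysregulation network
    if cfg.stages.network:
        if not cfg.stages.kd:
            raise StageError("network", "requires the kd stage")
        if interactions is None:
            raise StageError("network", "no interaction catalog provided")
        regs = [bundle.expression[k] for k in ("mirna", "tf") if k in bundle.expression]
        if not regs:
            raise StageError("network", "no regulator expression panels in cohort")
        reg_expr = ExpressionMatrix(
            pd.concat([r.values for r in regs]), scale="log2p1"
        )
        result.network = build_network(
            bundle.mrna, reg_expr, interactions, result.kd_genes, fdr=th.network_fdr
        )
        counts["network_edges"] = len(result.network.edges)
        cohort_io.write_network(result.network, out)

    # --- drug response
    if cfg.stages.drugs:
        if panel is None:
            raise StageError("drugs", "no IC50 panel provided")
        genes = result.kd_genes or candidates
        assoc = drug_gene_associations(panel, genes)
        result.drug_table = label_associations(assoc, alpha=th.drug_alpha)
        counts["drug_associations"] = int(
            (result.drug_table["label"] != "none").sum()
        )
        cohort_io.write_table(
            result.drug_table.set_index("drug"), out / "drug_associations.tsv"
        )

    # --- signature grouping
    if cfg.stages.signature:
        if not result.kd_genes or len(result.kd_genes) < 2:
            raise StageError("signature", "needs >= 2 KD genes")
        kd_expr = bundle.mrna.values.loc[result.kd_genes]
        diss = patient_dissimilarity(kd_expr)
        grouping = cluster_and_select_k(
            diss, kd_expr, k_max=min(th.k_max, len(bundle.samples)),
            linkage_method=cfg.linkage, k_override=cfg.k_override,
        )
        result.grouping = grouping
        counts["signature_k"] = grouping.k
        cohort_io.write_table(grouping.labels.to_frame(), out / "signature_groups.tsv", "sample")
        cohort_io.write_table(grouping.wss.to_frame(), out / "signature_wss.tsv", "k")
        surv = {
            ep: group_survival(grouping.labels, bundle.clinical, endpoint=ep)
            for ep in ("OS", "DFS")
        }
        import json

        (out / "signature_survival.json").write_text(json.dumps(surv, indent=2) + "\n")

    cohort_io.write_run_metadata(out, cfg.seed, cfg.config_hash(), counts)
    return result
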