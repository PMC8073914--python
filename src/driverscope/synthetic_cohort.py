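"""Synthetic multi-omics cohorts with known ground truth.

The generator plants driver genes with a dominant copy-number direction,
expression shifted concordantly in carriers, tumour-vs-normal
differential expression, and — for a subset — a multiplicative hazard on
survival.  Regulator panels (miRNA / TF) are constructed with configured
correlation to their true targets (negative for miRNAs), and drug panels
with configured Spearman association between IC50 and planted gene
expression.  Every output is fully determined by (params, seed).

Default sizes mirror a mid-sized tumour cohort: ~300 tumours with
clinical follow-up on ~90% of them, 2000 coding genes, 30 planted
drivers at 15-40% alteration frequency, half of them prognostic at
hazard ratio 2, and a 38-line drug panel.
"""
from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._types import (
    ClinicalTable,
    CnaMatrix,
    CohortBundle,
    DrugResponseMatrix,
    ExpressionMatrix,
    InteractionSet,
    MutationCatalog,
)

logger = logging.getLogger(__name__)

NON_SILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31, derived from a global seed."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class CohortParams:
    n_samples: int = 300
    n_genes: int = 2000
    n_drivers: int = 30
    freq_range: tuple[float, float] = (0.15, 0.4)
    expression_shift: float = 1.0  # SD units per CNA sign in carriers
    de_shift: float = 1.0  # tumour-vs-normal shift of driver genes, SD units
    n_controls: int = 30
    passenger_cna_rate: float = 0.05
    mutation_rate: float = 0.01
    silent_rate: float = 0.005
    frac_prognostic: float = 0.5
    hazard_ratio: float = 2.0
    baseline_hazard: float = np.log(2) / 24.0  # per month; 24-month median
    event_rate: float = 0.5
    clinical_fraction: float = 0.9
    frac_low_expressed: float = 0.05
    dropout_rate: float = 0.4
    expression_mean: float = 5.0

    def validate(self) -> None:
        lo, hi = self.freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"freq_range {self.freq_range} not within (0, 1)")
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("cohort must have >= 2 samples and >= 1 gene")
        if self.n_drivers > self.n_genes:
            raise ValueError("more drivers than genes")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0 < self.event_rate < 1:
            raise ValueError("event_rate must be in (0, 1)")
        if lo * self.n_samples < 5:
            warnings.warn(
                f"planted frequency {lo} x n={self.n_samples} < 5 carriers expected; "
                "screen will be underpowered",
                stacklevel=3,
            )


@dataclass
class RegulatorParams:
    n_mirnas: int = 60
    n_tfs: int = 30
    mirnas_per_gene: int = 2
    tfs_per_gene: int = 1
    mirna_strength: float = 0.5  # magnitude of planted (negative) correlation
    tf_strength: float = 0.4  # magnitude; sign drawn per edge
    n_decoys: int = 200

    def validate(self) -> None:
        for s in (self.mirna_strength, self.tf_strength):
            if not 0 <= s < 1:
                raise ValueError(f"requested |r| {s} must be < 1")


@dataclass
class DrugPanelParams:
    n_cell_lines: int = 38
    n_drugs: int = 24
    n_associations: int = 10
    rho_range: tuple[float, float] = (0.5, 0.8)

    def validate(self) -> None:
        if self.n_cell_lines < 5:
            raise ValueError("correlation over < 5 cell lines is meaningless")
        lo, hi = self.rho_range
        if not (0 <= lo <= hi < 1):
            raise ValueError(f"rho_range {self.rho_range} not within [0, 1)")


@dataclass
class GroundTruth:
    drivers: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene, direction (+1/-1), frequency, prognostic, hazard_ratio
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: regulator, reg_class, target, strength (signed planted r)
    drug_assoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: drug, gene, rho (planted Spearman)

    def __post_init__(self) -> None:
        if not self.drivers.empty:
            freqs = self.drivers["frequency"]
            if ((freqs <= 0) | (freqs >= 1)).any():
                raise ValueError("planted frequencies must lie in (0, 1)")
            if (self.drivers["hazard_ratio"] <= 0).any():
                raise ValueError("hazard ratios must be positive")
        if not self.edges.empty:
            mirna = self.edges["reg_class"] == "miRNA"
            if (self.edges.loc[mirna, "strength"] >= 0).any():
                raise ValueError("planted miRNA effects must be negative")


def _censor_horizon(lam: np.ndarray, target_event_rate: float) -> float:
    """Horizon c of Uniform(0, c) censoring hitting the target event rate.

    For exponential time T with rate lam and independent U ~ Uniform(0,c),
    P(T < U) = 1 - (1 - exp(-lam c)) / (lam c); solve the cohort average
    for c.
    """

    def mean_event_rate(c: float) -> float:
        lc = lam * c
        return float(np.mean(1.0 - (1.0 - np.exp(-lc)) / lc)) - target_event_rate

    return brentq(mean_event_rate, 1e-9, 1e9)


def generate_cohort(
    params: CohortParams | None = None, seed: int = 0
) -> tuple[CohortBundle, GroundTruth, ExpressionMatrix]:
    """Simulate one aligned multi-omics cohort.

    Returns the cohort bundle, its ground truth, and a matched normal
    (control) expression matrix for the differential-expression stage.
    """
    p = params or CohortParams()
    p.validate()
    rng = np.random.default_rng(derive_seed(seed, "cohort"))

    genes = [f"G{i:04d}" for i in range(p.n_genes)]
    samples = [f"S{i:03d}" for i in range(p.n_samples)]
    controls = [f"N{i:03d}" for i in range(p.n_controls)]

    driver_idx = rng.choice(p.n_genes, size=p.n_drivers, replace=False)
    driver_genes = [genes[i] for i in sorted(driver_idx)]
    directions = rng.choice([-1, 1], size=p.n_drivers)
    freqs = rng.uniform(*p.freq_range, size=p.n_drivers)
    n_prog = int(round(p.frac_prognostic * p.n_drivers))
    prognostic = np.zeros(p.n_drivers, dtype=bool)
    prognostic[rng.choice(p.n_drivers, size=n_prog, replace=False)] = True

    truth_drivers = pd.DataFrame(
        {
            "gene": driver_genes,
            "direction": directions,
            "frequency": freqs,
            "prognostic": prognostic,
            "hazard_ratio": np.where(prognostic, p.hazard_ratio, 1.0),
        }
    )

    # --- CNA codes: planted direction for drivers, symmetric noise elsewhere
    codes = np.zeros((p.n_genes, p.n_samples), dtype=np.int8)
    noise_mask = rng.random(codes.shape) < p.passenger_cna_rate
    noise_sign = rng.choice([-1, 1], size=codes.shape)
    noise_mag = np.where(rng.random(codes.shape) < 0.1, 2, 1)
    codes[noise_mask] = (noise_sign * noise_mag)[noise_mask]
    for j, (gi, direction, freq) in enumerate(zip(sorted(driver_idx), directions, freqs)):
        carriers = rng.random(p.n_samples) < freq
        mag = np.where(rng.random(p.n_samples) < 0.1, 2, 1)
        row = np.zeros(p.n_samples, dtype=np.int8)
        row[carriers] = (direction * mag)[carriers]
        codes[gi] = row
    cna = CnaMatrix(pd.DataFrame(codes, index=genes, columns=samples))

    # --- somatic mutations: background non-silent plus ignored silent records
    mut_mask = rng.random((p.n_genes, p.n_samples)) < p.mutation_rate
    gi_mut, si_mut = np.nonzero(mut_mask)
    classes = rng.choice(NON_SILENT_CLASSES, size=gi_mut.size)
    sil_mask = rng.random((p.n_genes, p.n_samples)) < p.silent_rate
    gi_sil, si_sil = np.nonzero(sil_mask)
    records = pd.DataFrame(
        {
            "gene": [genes[i] for i in np.concatenate([gi_mut, gi_sil])],
            "sample": [samples[i] for i in np.concatenate([si_mut, si_sil])],
            "variant_class": list(classes) + ["Silent"] * gi_sil.size,
        }
    )
    mutations = MutationCatalog(records)

    # --- expression: Gaussian on the log2 scale, unit variance
    base_means = rng.normal(p.expression_mean, 1.0, size=p.n_genes)
    low_mask = rng.random(p.n_genes) < p.frac_low_expressed
    low_mask[driver_idx] = False  # planted drivers are expressed genes
    expr = base_means[:, None] + rng.normal(0.0, 1.0, size=(p.n_genes, p.n_samples))
    # driver carriers shift concordantly with their CNA sign; passenger
    # expression is independent of the CNA noise (null by construction)
    drows = np.array(sorted(driver_idx), dtype=int)
    if drows.size:
        expr[drows] += p.expression_shift * np.sign(codes[drows])
    # tumours additionally shift driver genes relative to normal tissue
    de_dir = np.zeros(p.n_genes)
    de_dir[drows] = directions
    expr += p.de_shift * de_dir[:, None]
    expr = np.maximum(expr, 0.0)
    dropout = low_mask[:, None] & (rng.random((p.n_genes, p.n_samples)) < p.dropout_rate)
    expr[dropout] = 0.0

    ctrl = base_means[:, None] + rng.normal(0.0, 1.0, size=(p.n_genes, p.n_controls))
    ctrl = np.maximum(ctrl, 0.0)
    ctrl_dropout = low_mask[:, None] & (
        rng.random((p.n_genes, p.n_controls)) < p.dropout_rate
    )
    ctrl[ctrl_dropout] = 0.0

    mrna = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples), scale="log2p1")
    control = ExpressionMatrix(
        pd.DataFrame(ctrl, index=genes, columns=controls), scale="log2p1"
    )

    # --- survival: exponential, hazard multiplied per prognostic-driver CNA
    prog_rows = [gi for gi, is_p in zip(sorted(driver_idx), prognostic) if is_p]
    carrier_counts = (codes[prog_rows] != 0).sum(axis=0) if prog_rows else np.zeros(
        p.n_samples
    )
    lam = p.baseline_hazard * p.hazard_ratio**carrier_counts
    horizon = _censor_horizon(lam, p.event_rate)
    clinical_rows = {}
    n_clin = int(round(p.clinical_fraction * p.n_samples))
    clin_samples = sorted(rng.choice(p.n_samples, size=n_clin, replace=False))
    for ep in ("os", "dfs"):
        t_event = rng.exponential(1.0 / lam)
        t_censor = rng.uniform(0.0, horizon, size=p.n_samples)
        clinical_rows[f"{ep}_months"] = np.minimum(t_event, t_censor)
        clinical_rows[f"{ep}_event"] = (t_event <= t_censor).astype(int)
    clin = pd.DataFrame(clinical_rows, index=samples)
    clin["age"] = np.round(rng.normal(62.0, 10.0, size=p.n_samples), 1)
    clin["stage"] = rng.choice([1, 2, 3, 4], size=p.n_samples, p=[0.2, 0.3, 0.3, 0.2])
    clin["lymph_nodes"] = rng.poisson(3.0, size=p.n_samples)
    clin["histology"] = rng.choice(
        ["intestinal", "diffuse", "mixed"], size=p.n_samples, p=[0.55, 0.35, 0.10]
    )
    clinical = ClinicalTable(clin.iloc[clin_samples])

    bundle = CohortBundle(
        cna=cna,
        mutations=mutations,
        expression={"mrna": mrna},
        clinical=clinical,
        samples=samples,
    )
    truth = GroundTruth(drivers=truth_drivers)
    return bundle, truth, control


def generate_regulators(
    cohort: CohortBundle,
    truth: GroundTruth,
    params: RegulatorParams | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, InteractionSet, GroundTruth]:
    """Simulate miRNA / TF panels correlated with planted driver targets.

    Each driver gene receives ``mirnas_per_gene`` true miRNA edges
    (negative planted correlation) and ``tfs_per_gene`` true TF edges
    (sign drawn per edge).  Regulators are reused across genes, so hub
    regulators with several KD targets arise; for a regulator with k
    targets the attained per-target correlation shrinks roughly by
    1/sqrt(k).  The catalog is the true edges plus random decoy pairs
    with no constructed association.
    """
    p = params or RegulatorParams()
    p.validate()
    rng = np.random.default_rng(derive_seed(seed, "regulators"))
    targets = list(truth.drivers["gene"])
    missing = [g for g in targets if g not in cohort.mrna.features]
    if missing:
        raise ValueError(f"true edge targets absent from cohort: {missing[:5]}")
    mirnas = [f"miR-{i:03d}" for i in range(p.n_mirnas)]
    tfs = [f"TF{i:03d}" for i in range(p.n_tfs)]

    # one sign per TF so a reused (hub) TF acts consistently on all targets
    tf_signs = rng.choice([-1.0, 1.0], size=p.n_tfs)
    edge_rows = []
    for gene in targets:
        for m in rng.choice(p.n_mirnas, size=min(p.mirnas_per_gene, p.n_mirnas), replace=False):
            edge_rows.append((mirnas[m], "miRNA", gene, -p.mirna_strength))
        for t in rng.choice(p.n_tfs, size=min(p.tfs_per_gene, p.n_tfs), replace=False):
            edge_rows.append((tfs[t], "TF", gene, tf_signs[t] * p.tf_strength))
    edges = pd.DataFrame(edge_rows, columns=["regulator", "reg_class", "target", "strength"])
    edges = edges.drop_duplicates(["regulator", "target"]).reset_index(drop=True)

    expr = cohort.mrna.values
    z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1).replace(0, 1), axis=0)
    n = expr.shape[1]

    def panel(names: list[str], cls: str) -> pd.DataFrame:
        out = pd.DataFrame(
            rng.normal(0.0, 1.0, size=(len(names), n)), index=names, columns=expr.columns
        )
        for reg in names:
            sub = edges[(edges["regulator"] == reg) & (edges["reg_class"] == cls)]
            if sub.empty:
                continue
            strength = sub["strength"].iloc[0]
            combined = z.loc[sub["target"]].mean(axis=0)
            sd = combined.std()
            if sd == 0:
                continue
            combined = combined / sd
            rho = abs(strength)
            out.loc[reg] = np.sign(strength) * rho * combined + np.sqrt(
                1 - rho**2
            ) * rng.normal(0.0, 1.0, size=n)
        return out

    mirna_expr = ExpressionMatrix(panel(mirnas, "miRNA"), scale="log2p1")
    tf_expr = ExpressionMatrix(panel(tfs, "TF"), scale="log2p1")

    # decoy catalog entries: cataloged but unassociated pairs
    true_pairs = set(zip(edges["regulator"], edges["target"]))
    all_regs = [(m, "miRNA") for m in mirnas] + [(t, "TF") for t in tfs]
    decoys = []
    genes = list(cohort.mrna.features)
    while len(decoys) < p.n_decoys:
        reg, cls = all_regs[rng.integers(len(all_regs))]
        gene = genes[rng.integers(len(genes))]
        if (reg, gene) not in true_pairs:
            decoys.append((reg, cls, gene))
            true_pairs.add((reg, gene))
    catalog = pd.concat(
        [
            edges[["regulator", "reg_class", "target"]],
            pd.DataFrame(decoys, columns=["regulator", "reg_class", "target"]),
        ],
        ignore_index=True,
    )
    interactions = InteractionSet(catalog)
    truth_out = GroundTruth(
        drivers=truth.drivers, edges=edges, drug_assoc=truth.drug_assoc
    )
    return mirna_expr, tf_expr, interactions, truth_out


def generate_drug_panel(
    genes: list[str],
    params: DrugPanelParams | None = None,
    seed: int = 0,
) -> tuple[DrugResponseMatrix, GroundTruth]:
    """Simulate a cell-line panel with planted IC50-expression associations.

    The planted Spearman strength is realized through a Gaussian copula:
    the latent Pearson correlation 2 sin(pi rho_s / 6) yields the target
    Spearman rho_s in the bivariate-normal population.
    """
    p = params or DrugPanelParams()
    p.validate()
    rng = np.random.default_rng(derive_seed(seed, "drugs"))
    lines = [f"CL{i:02d}" for i in range(p.n_cell_lines)]
    drugs = [f"drug_{i:02d}" for i in range(p.n_drugs)]
    expr = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(genes), p.n_cell_lines)), index=genes, columns=lines
    )
    ic50_z = rng.normal(0.0, 1.0, size=(p.n_cell_lines, p.n_drugs))
    n_assoc = min(p.n_associations, p.n_drugs)
    assoc_drugs = rng.choice(p.n_drugs, size=n_assoc, replace=False)
    rows = []
    for d in assoc_drugs:
        g = int(rng.integers(len(genes)))
        rho_s = float(rng.uniform(*p.rho_range) * rng.choice([-1.0, 1.0]))
        rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        zg = expr.iloc[g].to_numpy()
        ic50_z[:, d] = rho_p * zg + np.sqrt(1 - rho_p**2) * rng.normal(
            0.0, 1.0, size=p.n_cell_lines
        )
        rows.append((drugs[d], genes[g], rho_s))
    ic50 = pd.DataFrame(np.exp(ic50_z), index=lines, columns=drugs)
    panel = DrugResponseMatrix(ic50=ic50, expression=expr)
    truth = GroundTruth(drug_assoc=pd.DataFrame(rows, columns=["drug", "gene", "rho"]))
    return panel, truth
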