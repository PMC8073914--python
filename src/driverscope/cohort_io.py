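"""Readers and writers for the tabular dialects the pipeline touches.

Reads a GISTIC ``all_thresholded.by_genes``-style CNA table, a MAF
mutation file, expression TSVs, a cBioPortal-dialect clinical table,
regulator-target interaction catalogs and an IC50 panel, and assembles
them into one sample-aligned :class:`~driverscope._types.CohortBundle`.
Sample identifiers are normalized by configurable barcode truncation
(MAF barcodes are longer than CNA/expression column headers in the
cBioPortal dialect).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import (
    ClinicalTable,
    CnaMatrix,
    CohortBundle,
    CohortError,
    DrugResponseMatrix,
    ExpressionMatrix,
    FormatError,
    InteractionSet,
    MutationCatalog,
)

logger = logging.getLogger(__name__)

#: GISTIC annotation columns that are not sample columns
_GISTIC_META_COLS = ("Locus ID", "Cytoband", "Entrez_Gene_Id")

_ROMAN_STAGE = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class IoConfig:
    barcode_length: int | None = None  # truncate sample IDs to this many chars
    expression_scale: str = "log2p1"  # scale of the expression files on disk

    def normalize(self, sample_id: str) -> str:
        sid = str(sample_id).strip()
        if self.barcode_length is not None:
            sid = sid[: self.barcode_length]
        return sid


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc


def _dedupe_genes(frame: pd.DataFrame, what: str) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the max-|mean| signal row."""
    if not frame.index.has_duplicates:
        return frame
    strength = frame.abs().mean(axis=1).to_numpy()
    first_pos = pd.Series(np.arange(len(frame)), index=frame.index).groupby(level=0).min()
    by_strength = frame.iloc[np.argsort(-strength, kind="stable")]
    deduped = by_strength[~by_strength.index.duplicated(keep="first")]
    logger.info(
        "dropped %d duplicate %s rows (kept max-|mean| row)", len(frame) - len(deduped), what
    )
    # restore first-appearance order so output is stable
    return deduped.loc[first_pos.sort_values().index]


def read_cna(path, config: IoConfig | None = None) -> CnaMatrix:
    config = config or IoConfig()
    raw = _read_tsv(path, index_col=0)
    raw = raw.drop(columns=[c for c in _GISTIC_META_COLS if c in raw.columns])
    raw.columns = [config.normalize(c) for c in raw.columns]
    try:
        raw = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric CNA value in {Path(path).name}: {exc}") from exc
    if not np.allclose(raw, np.round(raw)):
        raise FormatError(f"non-integer CNA code in {Path(path).name}")
    raw = _dedupe_genes(raw, "CNA gene")
    return CnaMatrix(raw.astype(int))


def read_maf(path, config: IoConfig | None = None) -> MutationCatalog:
    config = config or IoConfig()
    raw = _read_tsv(path)
    need = ["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise FormatError(f"MAF {Path(path).name} missing columns: {missing}")
    return MutationCatalog(
        pd.DataFrame(
            {
                "gene": raw["Hugo_Symbol"],
                "sample": raw["Tumor_Sample_Barcode"].map(config.normalize),
                "variant_class": raw["Variant_Classification"],
            }
        )
    )


def read_expression(path, config: IoConfig | None = None) -> ExpressionMatrix:
    config = config or IoConfig()
    raw = _read_tsv(path, index_col=0)
    raw.columns = [config.normalize(c) for c in raw.columns]
    try:
        raw = raw.astype(float)
    except ValueError as exc:
        raise FormatError(
            f"non-numeric expression value in {Path(path).name}: {exc}"
        ) from exc
    if raw.isna().to_numpy().any():
        raise FormatError(f"missing expression values in {Path(path).name}")
    raw = _dedupe_genes(raw, "expression feature")
    em = ExpressionMatrix(raw, scale=config.expression_scale)
    return em.to_log2p1()


def _parse_status(value) -> float:
    """cBioPortal status dialect: 0/1 or '0:LIVING' / '1:DECEASED' strings."""
    if pd.isna(value):
        return np.nan
    s = str(value).strip()
    if ":" in s:
        s = s.split(":", 1)[0]
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"unparseable survival status {value!r}") from exc


def _parse_stage(value) -> float:
    if pd.isna(value):
        return np.nan
    s = str(value).strip().upper().removeprefix("STAGE").strip()
    s = s.rstrip("ABC")  # substage letters collapse to the main stage
    if s in _ROMAN_STAGE:
        return float(_ROMAN_STAGE[s])
    try:
        stage = float(s)
    except ValueError as exc:
        raise FormatError(f"unparseable tumour stage {value!r}") from exc
    if stage not in (1, 2, 3, 4):
        raise FormatError(f"tumour stage {value!r} outside I-IV")
    return stage


def read_clinical(path, config: IoConfig | None = None) -> ClinicalTable:
    config = config or IoConfig()
    raw = _read_tsv(path)
    cols = {c.upper(): c for c in raw.columns}
    id_col = cols.get("SAMPLE_ID") or cols.get("PATIENT_ID")
    if id_col is None:
        raise FormatError(f"clinical table {Path(path).name} has no SAMPLE_ID/PATIENT_ID")
    index = raw[id_col].map(config.normalize)
    data = pd.DataFrame(index=pd.Index(index, name="sample"))
    for out_col, src in (
        ("os_months", "OS_MONTHS"),
        ("dfs_months", "DFS_MONTHS"),
    ):
        data[out_col] = (
            pd.to_numeric(raw[cols[src]], errors="coerce").to_numpy()
            if src in cols
            else np.nan
        )
    for out_col, src in (("os_event", "OS_STATUS"), ("dfs_event", "DFS_STATUS")):
        data[out_col] = (
            raw[cols[src]].map(_parse_status).to_numpy() if src in cols else np.nan
        )
    data["age"] = (
        pd.to_numeric(raw[cols["AGE"]], errors="coerce").to_numpy()
        if "AGE" in cols
        else np.nan
    )
    stage_col = cols.get("STAGE") or cols.get("TUMOR_STAGE") or cols.get("AJCC_PATHOLOGIC_TUMOR_STAGE")
    data["stage"] = raw[stage_col].map(_parse_stage).to_numpy() if stage_col else np.nan
    ln_col = cols.get("LYMPH_NODES") or cols.get("LYMPH_NODE_EXAMINED_COUNT")
    data["lymph_nodes"] = (
        pd.to_numeric(raw[ln_col], errors="coerce").to_numpy() if ln_col else np.nan
    )
    if "HISTOLOGY" in cols:
        data["histology"] = raw[cols["HISTOLOGY"]].to_numpy()
    return ClinicalTable(data[~data.index.duplicated()])


def read_interactions(paths_with_classes: list[tuple[str, str]]) -> InteractionSet:
    """Deduplicated union of interaction files, each tagged with its class.

    Each file is a two-column TSV (regulator, target); a regulator listed
    under two classes across files is a validation error.
    """
    frames = []
    for path, reg_class in paths_with_classes:
        raw = _read_tsv(path)
        if raw.shape[1] < 2:
            raise FormatError(f"interaction file {Path(path).name} needs 2 columns")
        frames.append(
            pd.DataFrame(
                {
                    "regulator": raw.iloc[:, 0],
                    "reg_class": reg_class,
                    "target": raw.iloc[:, 1],
                }
            )
        )
    return InteractionSet(pd.concat(frames, ignore_index=True))


def read_ic50(ic50_path, expression_path, config: IoConfig | None = None) -> DrugResponseMatrix:
    ic50 = _read_tsv(ic50_path, index_col=0).astype(float)
    expr = _read_tsv(expression_path, index_col=0).astype(float)
    return DrugResponseMatrix(ic50=ic50, expression=expr)


def read_cohort(
    cna_path,
    maf_path,
    expr_paths: dict[str, str],
    clinical_path,
    config: IoConfig | None = None,
) -> CohortBundle:
    """Assemble one cohort from its files.

    ``expr_paths`` maps panel name (``mrna`` required; ``mirna``/``tf``
    optional) to file path.  The cohort sample set is the intersection of
    CNA and mRNA samples; dropped samples and genes are logged.  Raises a
    cohort error when the intersection is empty.
    """
    config = config or IoConfig()
    cna = read_cna(cna_path, config)
    mutations = read_maf(maf_path, config)
    if "mrna" not in expr_paths:
        raise CohortError("expression paths must include an 'mrna' panel")
    expression = {name: read_expression(p, config) for name, p in expr_paths.items()}
    clinical = read_clinical(clinical_path, config)

    mrna = expression["mrna"]
    samples = [s for s in cna.samples if s in set(mrna.samples)]
    if not samples:
        raise CohortError("CNA and expression tables share no samples")
    n_drop_cna = cna.samples.size - len(samples)
    n_drop_expr = mrna.samples.size - len(samples)
    if n_drop_cna or n_drop_expr:
        logger.info(
            "sample intersection: kept %d, dropped %d CNA-only and %d expression-only",
            len(samples), n_drop_cna, n_drop_expr,
        )
    cna = CnaMatrix(cna.codes.loc[:, samples])
    expression["mrna"] = ExpressionMatrix(mrna.values.loc[:, samples], scale=mrna.scale)
    return CohortBundle(
        cna=cna,
        mutations=mutations,
        expression=expression,
        clinical=clinical,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# writers

def write_table(frame: pd.DataFrame, path, index_label: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index_label=index_label)
    return path


def write_network(network, out_dir, stem: str = "dysregulation_network") -> list[Path]:
    """Edge-list TSV plus GraphML for a dysregulation network."""
    import networkx as nx

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}.tsv"
    network.edges.to_csv(tsv, sep="\t", index=False)
    graphml = out_dir / f"{stem}.graphml"
    nx.write_graphml(network.to_graph(), graphml)
    return [tsv, graphml]


def write_run_metadata(out_dir, seed: int, config_hash: str, counts: dict) -> Path:
    import platform

    meta = {
        "seed": seed,
        "config_hash": config_hash,
        "counts": counts,
        "python": platform.python_version(),
    }
    path = Path(out_dir) / "run_metadata.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def write_cohort_files(bundle: CohortBundle, control, truth, out_dir) -> dict[str, Path]:
    """Write a (synthetic) cohort in the standard input dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["cna"] = write_table(bundle.cna.codes, out / "cna_thresholded.tsv", "Hugo_Symbol")
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": bundle.mutations.records["gene"],
            "Variant_Classification": bundle.mutations.records["variant_class"],
            "Tumor_Sample_Barcode": bundle.mutations.records["sample"],
        }
    )
    paths["maf"] = out / "mutations.maf"
    maf.to_csv(paths["maf"], sep="\t", index=False)
    for name, em in bundle.expression.items():
        paths[f"expr_{name}"] = write_table(
            em.values, out / f"expression_{name}.tsv", "feature"
        )
    if control is not None:
        paths["expr_control"] = write_table(
            control.values, out / "expression_control.tsv", "feature"
        )
    clin = bundle.clinical.data.copy()
    clin.insert(0, "SAMPLE_ID", clin.index)
    clin = clin.rename(
        columns={
            "os_months": "OS_MONTHS",
            "os_event": "OS_STATUS",
            "dfs_months": "DFS_MONTHS",
            "dfs_event": "DFS_STATUS",
            "age": "AGE",
            "stage": "STAGE",
            "lymph_nodes": "LYMPH_NODES",
            "histology": "HISTOLOGY",
        }
    )
    paths["clinical"] = out / "clinical.tsv"
    clin.to_csv(paths["clinical"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = out / "ground_truth.json"
        paths["truth"].write_text(
            json.dumps(
                {
                    "drivers": truth.drivers.to_dict(orient="records"),
                    "edges": truth.edges.to_dict(orient="records")
                    if not truth.edges.empty
                    else [],
                    "drug_assoc": truth.drug_assoc.to_dict(orient="records")
                    if not truth.drug_assoc.empty
                    else [],
                },
                indent=2,
            )
            + "\n"
        )
    return paths
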