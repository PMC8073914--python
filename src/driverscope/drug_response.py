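"""Drug-response association of KD genes across cell-line panels.

For each (drug, gene) pair the Spearman rank correlation between the
drug's IC50 and the gene's expression is computed over complete-case
cell lines.  A significant positive correlation marks a resistance
pattern (higher expression, higher survivable drug concentration), a
significant negative one a sensitivity pattern.  Because the statistic
is rank-based, raw vs log IC50 input is immaterial.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._types import DrugResponseMatrix
from .stat_kernels import correlation_test

logger = logging.getLogger(__name__)

RESISTANCE = "resistance"
SENSITIVITY = "sensitivity"
NO_LABEL = "none"


def drug_gene_associations(
    panel: DrugResponseMatrix, genes, min_cell_lines: int = 5
) -> pd.DataFrame:
    """Spearman rho and p per (drug, gene) over shared cell lines."""
    lines = panel.cell_lines
    genes = [g for g in genes if g in panel.expression.index]
    rows = []
    for drug in panel.ic50.columns:
        ic50 = panel.ic50.loc[lines, drug]
        for gene in genes:
            expr = panel.expression.loc[gene, lines]
            ok = ic50.notna() & expr.notna()
            n = int(ok.sum())
            if n < min_cell_lines:
                logger.info(
                    "pair (%s, %s) skipped: %d complete cases < %d",
                    drug, gene, n, min_cell_lines,
                )
                continue
            res = correlation_test(
                ic50[ok].to_numpy(), expr[ok].to_numpy(), method="spearman"
            )
            if res.degenerate:
                logger.info("pair (%s, %s) skipped: constant values", drug, gene)
                continue
            rows.append((drug, gene, res.estimate, res.p_value, n))
    return pd.DataFrame(rows, columns=["drug", "gene", "rho", "p_value", "n"])


def label_associations(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Partition associations into resistance / sensitivity / none."""
    out = table.copy()
    sig = out["p_value"] <= alpha
    out["label"] = NO_LABEL
    out.loc[sig & (out["rho"] > 0), "label"] = RESISTANCE
    out.loc[sig & (out["rho"] < 0), "label"] = SENSITIVITY
    return out


def cross_panel_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Sign agreement of significant associations shared by two panels.

    Per gene: among (drug, gene) pairs labeled (non-``none``) in both
    panels, the fraction whose rho signs agree.
    """
    labeled_a = table_a[table_a["label"] != NO_LABEL]
    labeled_b = table_b[table_b["label"] != NO_LABEL]
    merged = labeled_a.merge(labeled_b, on=["drug", "gene"], suffixes=("_a", "_b"))
    if merged.empty:
        logger.warning("no shared significant (drug, gene) pairs between panels")
        return pd.DataFrame(columns=["n_shared", "concordance"])
    merged["agree"] = np.sign(merged["rho_a"]) == np.sign(merged["rho_b"])
    return (
        merged.groupby("gene")
        .agg(n_shared=("agree", "size"), concordance=("agree", "mean"))
        .sort_values("n_shared", ascending=False)
    )
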