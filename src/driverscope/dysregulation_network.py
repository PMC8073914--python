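"""Sign-constrained transcriptional dysregulation network over KD genes.

Every cataloged (regulator, KD gene) pair with both features measured is
scored with a Pearson correlation over the complete-case sample
intersection.  Benjamini-Hochberg is applied once across the pooled
miRNA + TF candidate set.  Retained edges: TF pairs with padj <= fdr
(either sign, annotated from the sign of r); miRNA pairs with padj <= fdr
AND r < 0 — a miRNA can only appear as a repressor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._types import ExpressionMatrix, InteractionSet
from .stat_kernels import bh_adjust, correlation_test

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["regulator", "reg_class", "target", "r", "p_value", "padj", "sign", "n"]


@dataclass
class DysregulationNetwork:
    edges: pd.DataFrame  # EDGE_COLUMNS

    def regulator_degree(self) -> pd.Series:
        """KD-gene target count per regulator (hubs have >= 2)."""
        if self.edges.empty:
            return pd.Series(dtype=int, name="n_targets")
        return self.edges.groupby("regulator").size().rename("n_targets")

    def gene_regulator_counts(self) -> pd.DataFrame:
        """Per KD gene: number of regulators by class."""
        if self.edges.empty:
            return pd.DataFrame(columns=["miRNA", "TF"])
        counts = (
            self.edges.groupby(["target", "reg_class"]).size().unstack(fill_value=0)
        )
        for cls in ("miRNA", "TF"):
            if cls not in counts.columns:
                counts[cls] = 0
        return counts[["miRNA", "TF"]]

    def to_graph(self):
        import networkx as nx

        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_node(row.regulator, kind=row.reg_class)
            g.add_node(row.target, kind="KD_gene")
            g.add_edge(
                row.regulator,
                row.target,
                r=float(row.r),
                padj=float(row.padj),
                sign=row.sign,
            )
        return g


def score_edges(
    kd_expression: ExpressionMatrix,
    regulator_expression: ExpressionMatrix,
    interactions: InteractionSet,
    kd_genes,
    min_shared_samples: int = 10,
) -> pd.DataFrame:
    """Pearson r and p for every cataloged (regulator, KD gene) pair.

    Pairs outside the catalog are never scored; zero-variance features
    are skipped with a log line.  The sample set per pair is the
    complete-case intersection of the two expression panels.
    """
    kd_genes = [g for g in kd_genes if g in kd_expression.features.tolist()]
    cat = interactions.pairs
    cat = cat[cat["target"].isin(kd_genes)]
    shared = kd_expression.samples.intersection(regulator_expression.samples)
    if shared.size < min_shared_samples:
        raise ValueError(
            f"only {shared.size} shared samples between target and regulator panels "
            f"(need >= {min_shared_samples})"
        )
    target_vals = kd_expression.values.loc[:, shared]
    reg_vals = regulator_expression.values.loc[:, shared]
    rows = []
    for row in cat.itertuples(index=False):
        if row.regulator not in reg_vals.index:
            continue
        x = reg_vals.loc[row.regulator].to_numpy()
        y = target_vals.loc[row.target].to_numpy()
        res = correlation_test(x, y, method="pearson")
        if res.degenerate:
            logger.info(
                "pair (%s, %s) skipped: zero-variance feature", row.regulator, row.target
            )
            continue
        rows.append(
            (row.regulator, row.reg_class, row.target, res.estimate, res.p_value, res.n)
        )
    return pd.DataFrame(
        rows, columns=["regulator", "reg_class", "target", "r", "p_value", "n"]
    )


def filter_edges(candidate_edges: pd.DataFrame, fdr: float = 0.05) -> DysregulationNetwork:
    """BH across the pooled candidate set, then the sign constraints."""
    edges = candidate_edges.copy()
    if edges.empty:
        return DysregulationNetwork(pd.DataFrame(columns=EDGE_COLUMNS))
    # canonical order makes the retained set independent of input ordering
    edges = edges.sort_values(["regulator", "target"]).reset_index(drop=True)
    edges["padj"] = bh_adjust(edges["p_value"].to_numpy())
    significant = edges["padj"] <= fdr
    negative = edges["r"] < 0
    keep = significant & (negative | (edges["reg_class"] == "TF"))
    edges = edges[keep].copy()
    edges["sign"] = np.where(edges["r"] < 0, "repression", "activation")
    return DysregulationNetwork(edges[EDGE_COLUMNS].reset_index(drop=True))


def build_network(
    kd_expression: ExpressionMatrix,
    regulator_expression: ExpressionMatrix,
    interactions: InteractionSet,
    kd_genes,
    fdr: float = 0.05,
    min_shared_samples: int = 10,
) -> DysregulationNetwork:
    scored = score_edges(
        kd_expression, regulator_expression, interactions, kd_genes, min_shared_samples
    )
    return filter_edges(scored, fdr=fdr)


def hub_summary(network: DysregulationNetwork) -> pd.DataFrame:
    """Degree table: per regulator, class, target count and hub flag."""
    if network.edges.empty:
        return pd.DataFrame(columns=["reg_class", "n_targets", "hub"])
    deg = network.edges.groupby(["regulator", "reg_class"]).size().rename("n_targets")
    out = deg.reset_index().set_index("regulator")
    out["hub"] = out["n_targets"] >= 2
    return out.sort_values("n_targets", ascending=False)
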