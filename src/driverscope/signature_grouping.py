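"""Patient grouping by KD-gene expression signature.

Patients are compared by the Pearson correlation of their KD-gene
expression vectors; hierarchical clustering (average linkage by default)
on the 1 - r dissimilarity yields nested partitions for k = 1..k_max.
The elbow of the within-cluster sum-of-squares (WSS) curve — the k
maximizing the second difference — picks the group count, overridable by
the caller.  Group prognosis is assessed with the k-group log-rank test,
pairwise tests against a reference group, and a multivariate Cox model
adjusting for age, stage and lymph-node count.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._types import ClinicalTable
from .stat_kernels import CoxFit, fit_cox, logrank

__all__ = [
    "SignatureGrouping",
    "patient_dissimilarity",
    "cluster_and_select_k",
    "group_survival",
    "group_cox",
]


@dataclass
class SignatureGrouping:
    labels: pd.Series  # per-sample group label in 1..k
    k: int
    wss: pd.Series  # WSS per candidate k (index 1..k_max)
    linkage_method: str = "average"
    dissimilarity: str = "pearson"

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def patient_dissimilarity(kd_expression: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson r between samples' KD-gene expression vectors.

    ``kd_expression`` is genes x samples with >= 2 KD genes and >= 3
    samples; a zero-variance sample vector is an error (correlation with
    it is undefined).
    """
    if kd_expression.shape[0] < 2:
        raise ValueError("patient dissimilarity requires >= 2 KD genes")
    if kd_expression.shape[1] < 3:
        raise ValueError("patient dissimilarity requires >= 3 samples")
    values = kd_expression.to_numpy(dtype=float)
    sds = values.std(axis=0)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        raise ValueError(
            f"sample {kd_expression.columns[flat[0]]!r} has zero-variance KD vector"
        )
    corr = np.corrcoef(values, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # enforce exact symmetry
    return pd.DataFrame(d, index=kd_expression.columns, columns=kd_expression.columns)


def _wss(values: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squares about cluster means."""
    total = 0.0
    for lab in np.unique(labels):
        block = values[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def cluster_and_select_k(
    dissimilarity: pd.DataFrame,
    kd_expression: pd.DataFrame,
    k_max: int = 10,
    linkage_method: str = "average",
    k_override: int | None = None,
) -> SignatureGrouping:
    """Cut the hierarchical tree at k = 1..k_max and pick the elbow.

    WSS is computed in KD-expression space (samples as vectors of gene
    values) about cluster means; the chosen k maximizes the second
    difference of the WSS curve, i.e. the sharpest flattening.
    """
    n = dissimilarity.shape[0]
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds number of samples n={n}")
    condensed = squareform(dissimilarity.to_numpy(), checks=False)
    tree = linkage(condensed, method=linkage_method)
    values = kd_expression.to_numpy(dtype=float).T  # samples x genes
    wss = {}
    labels_per_k = {}
    for k in range(1, k_max + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        labels_per_k[k] = labels
        wss[k] = _wss(values, labels)
    wss_series = pd.Series(wss, name="wss")
    if k_override is not None:
        chosen = int(k_override)
        if not 1 <= chosen <= k_max:
            raise ValueError(f"k override {chosen} outside 1..{k_max}")
    else:
        chosen = _elbow(wss_series)
    return SignatureGrouping(
        labels=pd.Series(labels_per_k[chosen], index=dissimilarity.index, name="group"),
        k=chosen,
        wss=wss_series,
        linkage_method=linkage_method,
    )


def _elbow(wss: pd.Series) -> int:
    """k maximizing the second difference WSS(k-1) - 2 WSS(k) + WSS(k+1)."""
    ks = wss.index.to_numpy()
    if ks.size < 3:
        return int(ks[-1])
    second = wss.to_numpy()[:-2] - 2 * wss.to_numpy()[1:-1] + wss.to_numpy()[2:]
    return int(ks[1:-1][int(np.argmax(second))])


def group_survival(
    labels: pd.Series, clinical: ClinicalTable, endpoint: str = "OS", reference: int = 1
) -> dict:
    """Overall k-group log-rank plus pairwise tests vs a reference group."""
    surv = clinical.endpoint(endpoint)
    shared = surv.index.intersection(labels.index)
    dropped = labels.index.difference(shared)
    surv = surv.loc[shared]
    labs = labels.loc[shared]
    present = sorted(labs.unique())
    if len(present) < 2:
        raise ValueError("group survival requires >= 2 groups with survival data")
    overall = logrank(surv["time"].to_numpy(), surv["event"].to_numpy(), labs.to_numpy())
    pairwise = {}
    for grp in present:
        if grp == reference:
            continue
        mask = labs.isin([reference, grp])
        res = logrank(
            surv.loc[mask, "time"].to_numpy(),
            surv.loc[mask, "event"].to_numpy(),
            labs[mask].to_numpy(),
        )
        pairwise[int(grp)] = res.p_value
    return {
        "endpoint": endpoint.upper(),
        "overall_chi2": overall.statistic,
        "overall_p": overall.p_value,
        "pairwise_p_vs_reference": pairwise,
        "reference": int(reference),
        "n_dropped_no_survival": int(dropped.size),
    }


def group_cox(
    labels: pd.Series,
    clinical: ClinicalTable,
    covariates: tuple[str, ...] = ("age", "stage", "lymph_nodes"),
    reference_group: int = 1,
    endpoint: str = "OS",
) -> CoxFit:
    """Cox model: group dummies vs reference + clinical covariates.

    Age and lymph-node count enter as continuous terms; stage as dummy
    variables against stage I.  Complete cases only.
    """
    surv = clinical.endpoint(endpoint)
    shared = surv.index.intersection(labels.index)
    design = pd.DataFrame(index=shared)
    labs = labels.loc[shared]
    if reference_group not in set(labs):
        raise ValueError(f"reference group {reference_group} is empty")
    for grp in sorted(labs.unique()):
        if grp == reference_group:
            continue
        design[f"group_{grp}"] = (labs == grp).astype(float)
    clin = clinical.data.loc[shared]
    for cov in covariates:
        if cov == "stage":
            stage = clin["stage"]
            for level in sorted(stage.dropna().unique()):
                if level == stage.dropna().min():
                    continue  # lowest stage is the reference
                design[f"stage_{int(level)}"] = (stage == level).astype(float)
            design.loc[stage.isna(), [c for c in design.columns if c.startswith("stage_")]] = np.nan
        else:
            if cov not in clin.columns:
                raise ValueError(f"covariate {cov!r} missing from clinical table")
            design[cov] = clin[cov].astype(float)
    keep = design.notna().all(axis=1)
    design = design.loc[keep]
    surv = surv.loc[design.index]
    return fit_cox(design, surv["time"].to_numpy(), surv["event"].to_numpy())


def histology_crosstab(labels: pd.Series, clinical: ClinicalTable, column: str = "histology") -> pd.DataFrame:
    """Descriptive cross-tab of group labels vs a histology class column."""
    if column not in clinical.data.columns:
        raise ValueError(f"clinical table has no column {column!r}")
    shared = clinical.data.index.intersection(labels.index)
    return pd.crosstab(labels.loc[shared], clinical.data.loc[shared, column])
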