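"""Core in-memory containers shared by all pipeline stages.

All matrices are pandas DataFrames with feature rows and sample columns;
the thin dataclass wrappers enforce the domain invariants (GISTIC code
vocabulary, expression scale tags, unique interaction pairs) once at
construction so downstream stages can assume clean inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: GISTIC thresholded copy-number codes: homozygous deletion, loss,
#: neutral, gain, high-level amplification.
CNA_CODES = frozenset({-2, -1, 0, 1, 2})

#: MAF variant classes that do not alter the protein and are therefore
#: excluded from the binary variation spectrum.
SILENT_CLASSES = frozenset({"Silent", "Synonymous"})

EXPRESSION_SCALES = ("raw", "log2p1")


class FormatError(ValueError):
    """An input file violates its declared dialect."""


class CohortError(ValueError):
    """Cohort assembly failed (e.g. empty sample intersection)."""


@dataclass
class CnaMatrix:
    """Gene-level thresholded copy-number calls (genes x samples)."""

    codes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.codes.index.has_duplicates:
            dup = self.codes.index[self.codes.index.duplicated()][0]
            raise FormatError(f"duplicate gene symbol in CNA matrix: {dup!r}")
        values = self.codes.to_numpy()
        bad = ~np.isin(values, list(CNA_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"CNA code {values[i, j]!r} for gene {self.codes.index[i]!r}, "
                f"sample {self.codes.columns[j]!r} is outside {{-2,-1,0,1,2}}"
            )
        self.codes = self.codes.astype(np.int8)

    @property
    def genes(self) -> pd.Index:
        return self.codes.index

    @property
    def samples(self) -> pd.Index:
        return self.codes.columns


@dataclass
class MutationCatalog:
    """Somatic variant records: one row per (gene, sample, variant class)."""

    records: pd.DataFrame  # columns: gene, sample, variant_class

    REQUIRED = ("gene", "sample", "variant_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise FormatError(f"mutation catalog missing columns: {missing}")
        self.records = self.records.loc[:, list(self.REQUIRED)].reset_index(drop=True)

    def non_silent(self) -> pd.DataFrame:
        """Records after discarding silent (synonymous) substitutions."""
        keep = ~self.records["variant_class"].isin(SILENT_CLASSES)
        return self.records.loc[keep]


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance matrix with a declared scale tag.

    ``raw`` means non-negative abundances (RSEM-like); ``log2p1`` means
    log2(abundance + 1).  On either scale, a value > 0 is equivalent to a
    detectable (raw > 0) measurement.
    """

    values: pd.DataFrame
    scale: str = "log2p1"

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise FormatError(f"unknown expression scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature in expression matrix: {dup!r}")
        if self.values.isna().to_numpy().any():
            raise FormatError("expression matrix contains missing values")

    def to_log2p1(self) -> "ExpressionMatrix":
        if self.scale == "log2p1":
            return self
        if (self.values.to_numpy() < 0).any():
            raise FormatError("raw expression matrix contains negative values")
        return ExpressionMatrix(np.log2(self.values + 1.0), scale="log2p1")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and clinical covariates.

    Columns: os_months, os_event, dfs_months, dfs_event, age, stage
    (ordinal 1-4), lymph_nodes, optionally histology.  Missing covariates
    are NaN, never silently zero; samples lacking a survival endpoint are
    excluded from survival stages only.
    """

    data: pd.DataFrame

    SURVIVAL_COLS = ("os_months", "os_event", "dfs_months", "dfs_event")

    def __post_init__(self) -> None:
        for col in self.SURVIVAL_COLS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        for col in ("os_months", "dfs_months"):
            t = self.data[col]
            if (t.dropna() < 0).any():
                raise FormatError(f"negative survival time in {col}")
        for col in ("os_event", "dfs_event"):
            ev = self.data[col].dropna()
            if not ev.isin([0, 1]).all():
                raise FormatError(f"non-binary event indicator in {col}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def endpoint(self, which: str) -> pd.DataFrame:
        """Complete cases (time, event) for endpoint ``OS`` or ``DFS``."""
        which = which.lower()
        if which not in ("os", "dfs"):
            raise ValueError(f"unknown endpoint {which!r}")
        sub = self.data[[f"{which}_months", f"{which}_event"]].dropna()
        sub.columns = ["time", "event"]
        return sub.astype(float)


@dataclass
class InteractionSet:
    """Cataloged regulator -> target gene pairs with regulator class."""

    pairs: pd.DataFrame  # columns: regulator, reg_class, target

    def __post_init__(self) -> None:
        need = ["regulator", "reg_class", "target"]
        missing = [c for c in need if c not in self.pairs.columns]
        if missing:
            raise FormatError(f"interaction set missing columns: {missing}")
        bad = ~self.pairs["reg_class"].isin(["miRNA", "TF"])
        if bad.any():
            raise FormatError(
                f"unknown regulator class {self.pairs.loc[bad, 'reg_class'].iloc[0]!r}"
            )
        classes = self.pairs.groupby("regulator")["reg_class"].nunique()
        clash = classes[classes > 1]
        if not clash.empty:
            raise FormatError(
                f"regulator {clash.index[0]!r} listed under more than one class"
            )
        self.pairs = (
            self.pairs[need].drop_duplicates(["regulator", "target"]).reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DrugResponseMatrix:
    """Cell-line drug IC50 panel with matched cell-line expression."""

    ic50: pd.DataFrame  # cell lines x drugs
    expression: pd.DataFrame  # genes x cell lines

    def __post_init__(self) -> None:
        shared = self.ic50.index.intersection(self.expression.columns)
        if len(shared) == 0:
            raise CohortError("IC50 and expression tables share no cell lines")

    @property
    def cell_lines(self) -> pd.Index:
        return self.ic50.index.intersection(self.expression.columns)


@dataclass
class CohortBundle:
    """One cohort's aligned multi-omics views.

    ``samples`` is the ordered genomic sample set (CNA ∩ mRNA expression);
    every matrix is column-aligned to it.  The clinical table may cover a
    subset (survival stages drop samples without follow-up, mirroring the
    usual genomic-n > clinical-n situation in public cohorts).
    """

    cna: CnaMatrix
    mutations: MutationCatalog
    expression: dict[str, ExpressionMatrix]  # keys: mrna, and optionally mirna, tf
    clinical: ClinicalTable
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = list(self.cna.samples)
        for name, em in self.expression.items():
            if name == "mrna" and list(em.samples) != self.samples:
                raise CohortError("mRNA expression not aligned to cohort samples")

    @property
    def mrna(self) -> ExpressionMatrix:
        return self.expression["mrna"]
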