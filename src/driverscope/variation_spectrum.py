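"""Binary genomic-variation profile: CNA ∪ non-silent mutation.

A gene-sample pair counts as varied when its thresholded copy-number code
is non-neutral (gain, loss, high-level amplification or homozygous
deletion) or when the sample carries at least one non-silent somatic
mutation in the gene.  The union is the elementwise OR of the two binary
matrices; per-gene variation frequency is the row mean over the profiled
sample set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import SILENT_CLASSES, CnaMatrix, MutationCatalog

logger = logging.getLogger(__name__)


@dataclass
class BinaryVariationProfile:
    union: pd.DataFrame  # genes x samples, 0/1
    cna_binary: pd.DataFrame
    mutation_binary: pd.DataFrame
    signed_codes: pd.DataFrame  # retained GISTIC codes for direction/survival use
    frequency: pd.Series  # per-gene row mean of union

    def gene_summary(self) -> pd.DataFrame:
        """Per-gene event counts mirroring an oncoprint breakdown."""
        codes = self.signed_codes
        return pd.DataFrame(
            {
                "n_amp": (codes > 0).sum(axis=1),
                "n_del": (codes < 0).sum(axis=1),
                "n_highlevel": (codes.abs() == 2).sum(axis=1),
                "n_mut": self.mutation_binary.sum(axis=1).astype(int),
                "n_varied": self.union.sum(axis=1).astype(int),
                "frequency": self.frequency,
            }
        )


def binarize_cna(cna: CnaMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary CNA spectrum (1 = any non-neutral code) plus retained signs."""
    signed = cna.codes
    binary = (signed != 0).astype(np.int8)
    return binary, signed


def binarize_mutations(
    catalog: MutationCatalog, samples, genes
) -> pd.DataFrame:
    """0/1 matrix: 1 iff >= 1 non-silent record for (gene, sample).

    Records with a variant classification outside the MAF vocabulary are
    kept (treated as non-silent) with a warning — dropping them would
    silently shrink the variation spectrum.
    """
    genes = pd.Index(genes)
    samples = pd.Index(samples)
    out = pd.DataFrame(
        np.zeros((genes.size, samples.size), dtype=np.int8), index=genes, columns=samples
    )
    recs = catalog.records
    known = recs["variant_class"].isin(KNOWN_VARIANT_CLASSES)
    if (~known).any():
        unknown = sorted(recs.loc[~known, "variant_class"].unique())
        logger.warning(
            "unknown variant classifications treated as non-silent: %s", unknown
        )
    non_silent = catalog.non_silent()
    hit = non_silent[
        non_silent["gene"].isin(genes) & non_silent["sample"].isin(samples)
    ]
    if not hit.empty:
        gi = out.index.get_indexer(hit["gene"])
        si = out.columns.get_indexer(hit["sample"])
        out.values[gi, si] = 1
    return out


def combine_variation(
    cna_binary: pd.DataFrame,
    mutation_binary: pd.DataFrame,
    signed_codes: pd.DataFrame | None = None,
) -> BinaryVariationProfile:
    """Elementwise OR of the CNA and mutation spectra."""
    if not cna_binary.index.equals(mutation_binary.index) or not cna_binary.columns.equals(
        mutation_binary.columns
    ):
        raise ValueError("CNA and mutation matrices must share gene/sample axes")
    union = np.maximum(cna_binary, mutation_binary).astype(np.int8)
    if signed_codes is None:
        signed_codes = cna_binary
    return BinaryVariationProfile(
        union=union,
        cna_binary=cna_binary.astype(np.int8),
        mutation_binary=mutation_binary.astype(np.int8),
        signed_codes=signed_codes,
        frequency=union.mean(axis=1),
    )


def build_profile(cna: CnaMatrix, catalog: MutationCatalog) -> BinaryVariationProfile:
    """Full pipeline step: binarize both spectra and take their union."""
    cna_binary, signed = binarize_cna(cna)
    mut_binary = binarize_mutations(catalog, cna.samples, cna.genes)
    return combine_variation(cna_binary, mut_binary, signed)


#: MAF variant classification vocabulary (silent and non-silent classes)
KNOWN_VARIANT_CLASSES = SILENT_CLASSES | {
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Splice_Region",
    "Translation_Start_Site",
    "De_novo_Start_InFrame",
    "De_novo_Start_OutOfFrame",
}
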