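"""Four-criterion candidate key-gene screen.

A gene is a candidate when it

(i)   has a dominant CNA type — amplification or deletion — by an exact
      two-sided binomial test on the direction counts (p <= alpha);
(ii)  is expressed (raw abundance > 0) in more than 75% of tumour samples;
(iii) shows CNA-concordant expression: carriers differ from wild type by
      a two-sided rank-sum test (p <= alpha) in the direction the
      dominant CNA type predicts (amplification up, deletion down);
(iv)  has genomic-variation frequency (CNA ∪ mutation) exceeding 0.1.

All four filters are conjunctive; thresholds are configurable and applied
as stated (strict inequalities for prevalence and frequency, inclusive
for the p-value gates).  Direction counts weigh +-1 and +-2 codes
equally: the binomial test asks about the direction of events, not their
magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import ExpressionMatrix
from .stat_kernels import binomial_two_sided, rank_sum
from .variation_spectrum import BinaryVariationProfile

AMPLIFICATION = "amplification"
DELETION = "deletion"
NONE = "none"


@dataclass
class ScreenThresholds:
    dominant_alpha: float = 0.05
    prevalence: float = 0.75
    concordance_alpha: float = 0.05
    frequency: float = 0.1


def dominant_cna_type(signed_row: np.ndarray, alpha: float = 0.05) -> tuple[str, float]:
    """Majority CNA direction of a gene, gated by an exact binomial test.

    k = number of amplified samples among the n non-neutral ones; the
    direction is called dominant only when the two-sided binomial p at
    p0 = 0.5 is <= alpha.
    """
    signed_row = np.asarray(signed_row)
    n_amp = int((signed_row > 0).sum())
    n_del = int((signed_row < 0).sum())
    n = n_amp + n_del
    if n == 0:
        return NONE, 1.0
    p = binomial_two_sided(n_amp, n, 0.5).p_value
    if p > alpha:
        return NONE, p
    return (AMPLIFICATION if n_amp > n_del else DELETION), p


def prevalence_filter(
    expression_row: np.ndarray, threshold: float = 0.75
) -> tuple[float, bool]:
    """Fraction of samples with detectable expression; pass iff strictly above.

    Works on either scale: log2(x+1) > 0 iff raw x > 0.
    """
    row = np.asarray(expression_row, dtype=float)
    fraction = float((row > 0).mean())
    return fraction, fraction > threshold


def concordance_test(
    dominant: str,
    cna_binary_row: np.ndarray,
    expression_row: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, bool, bool]:
    """CNA-carrier vs wild-type expression comparison.

    Returns (p, direction_ok, passes).  direction_ok compares group
    medians in the direction the dominant type predicts.  Fails with a
    degenerate p when either group is empty.
    """
    if dominant == NONE:
        raise ValueError("concordance test requires a dominant CNA type")
    carrier = np.asarray(cna_binary_row) != 0
    expr = np.asarray(expression_row, dtype=float)
    if carrier.all() or not carrier.any():
        return 1.0, False, False
    res = rank_sum(expr[carrier], expr[~carrier], alternative="two_sided")
    med_c, med_w = np.median(expr[carrier]), np.median(expr[~carrier])
    direction_ok = med_c > med_w if dominant == AMPLIFICATION else med_c < med_w
    return res.p_value, bool(direction_ok), bool(res.p_value <= alpha and direction_ok)


def screen_candidates(
    profile: BinaryVariationProfile,
    expression: ExpressionMatrix,
    thresholds: ScreenThresholds | None = None,
) -> pd.DataFrame:
    """Apply criteria (i)-(iv) to every gene present in both views.

    Returns one row per gene with all per-criterion columns; the
    candidate set is ``table.index[table["candidate"]]``.
    """
    th = thresholds or ScreenThresholds()
    genes = profile.union.index.intersection(expression.features)
    expr = expression.values.loc[genes, profile.union.columns.intersection(expression.samples)]
    rows = []
    for gene in genes:
        signed = profile.signed_codes.loc[gene].to_numpy()
        dom, dom_p = dominant_cna_type(signed, th.dominant_alpha)
        pass_dom = dom != NONE

        erow = expr.loc[gene].to_numpy()
        prev_frac, pass_prev = prevalence_filter(erow, th.prevalence)

        if pass_dom:
            cna_row = profile.cna_binary.loc[gene, expr.columns].to_numpy()
            conc_p, direction_ok, pass_conc = concordance_test(
                dom, cna_row, erow, th.concordance_alpha
            )
        else:
            conc_p, direction_ok, pass_conc = np.nan, False, False

        freq = float(profile.frequency.loc[gene])
        pass_freq = freq > th.frequency

        rows.append(
            {
                "gene": gene,
                "dominant_type": dom,
                "dominant_p": dom_p,
                "pass_dominant": pass_dom,
                "prevalence": prev_frac,
                "pass_prevalence": pass_prev,
                "concordance_p": conc_p,
                "direction_ok": direction_ok,
                "pass_concordance": pass_conc,
                "frequency": freq,
                "pass_frequency": pass_freq,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    table["candidate"] = (
        table["pass_dominant"]
        & table["pass_prevalence"]
        & table["pass_concordance"]
        & table["pass_frequency"]
    )
    return table


def candidate_set(table: pd.DataFrame) -> list[str]:
    return list(table.index[table["candidate"]])
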