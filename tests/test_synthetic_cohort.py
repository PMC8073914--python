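"""Ground-truth recoverability and calibration of the cohort generator."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from driverscope.candidate_screen import concordance_test
from driverscope.stat_kernels import bh_adjust, correlation_test
from driverscope.synthetic_cohort import (
    CohortParams,
    DrugPanelParams,
    GroundTruth,
    RegulatorParams,
    generate_cohort,
    generate_drug_panel,
    generate_regulators,
)
from driverscope.variation_spectrum import build_profile


def test_seeded_determinism():
    params = CohortParams(n_samples=60, n_genes=80, n_drivers=5)
    b1, t1, c1 = generate_cohort(params, seed=3)
    b2, t2, c2 = generate_cohort(params, seed=3)
    pd.testing.assert_frame_equal(b1.cna.codes, b2.cna.codes)
    pd.testing.assert_frame_equal(b1.mrna.values, b2.mrna.values)
    pd.testing.assert_frame_equal(b1.clinical.data, b2.clinical.data)
    pd.testing.assert_frame_equal(t1.drivers, t2.drivers)
    b3, _, _ = generate_cohort(params, seed=4)
    assert not b1.cna.codes.equals(b3.cna.codes)


def test_carrier_fraction_within_binomial_bound():
    n = 300
    params = CohortParams(
        n_samples=n, n_genes=50, n_drivers=8, freq_range=(0.3, 0.3)
    )
    bundle, truth, _ = generate_cohort(params, seed=7)
    sd = np.sqrt(0.3 * 0.7 / n)
    for gene in truth.drivers["gene"]:
        frac = (bundle.cna.codes.loc[gene] != 0).mean()
        assert abs(frac - 0.3) <= 3 * sd, gene


def test_driver_codes_follow_planted_direction():
    bundle, truth, _ = generate_cohort(
        CohortParams(n_samples=200, n_genes=100, n_drivers=10), seed=5
    )
    for row in truth.drivers.itertuples(index=False):
        codes = bundle.cna.codes.loc[row.gene]
        nonzero = codes[codes != 0]
        assert (np.sign(nonzero) == row.direction).all()
        assert set(np.abs(nonzero)) <= {1, 2}


def test_passenger_concordance_pvalues_uniform():
    """With no planted shift, passenger concordance p-values are U(0,1)."""
    params = CohortParams(
        n_samples=265, n_genes=400, n_drivers=0, frac_low_expressed=0.0
    )
    bundle, _, _ = generate_cohort(params, seed=13)
    profile = build_profile(bundle.cna, bundle.mutations)
    pvals = []
    for gene in bundle.cna.genes:
        carrier = profile.cna_binary.loc[gene].to_numpy().astype(bool)
        if carrier.sum() < 3 or (~carrier).sum() < 3:
            continue
        expr = bundle.mrna.values.loc[gene].to_numpy()
        p, _, _ = concordance_test("amplification", carrier, expr)
        pvals.append(p)
    assert len(pvals) > 200
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_underpowered_frequency_warns():
    with pytest.warns(UserWarning, match="underpowered"):
        CohortParams(n_samples=20, n_genes=30, freq_range=(0.05, 0.2)).validate()
    with pytest.raises(ValueError):
        CohortParams(freq_range=(0.0, 0.5)).validate()


def test_event_rate_near_target():
    bundle, _, _ = generate_cohort(
        CohortParams(n_samples=400, n_genes=20, n_drivers=0, event_rate=0.5), seed=21
    )
    observed = bundle.clinical.data["os_event"].mean()
    assert abs(observed - 0.5) < 3 * np.sqrt(0.25 / 360)


def test_ground_truth_invariants():
    with pytest.raises(ValueError, match="negative"):
        GroundTruth(
            edges=pd.DataFrame(
                {"regulator": ["m1"], "reg_class": ["miRNA"], "target": ["G1"], "strength": [0.5]}
            )
        )
    with pytest.raises(ValueError, match="frequencies"):
        GroundTruth(
            drivers=pd.DataFrame(
                {"gene": ["G1"], "direction": [1], "frequency": [1.2], "prognostic": [True], "hazard_ratio": [2.0]}
            )
        )


class TestRegulators:
    def test_true_mirna_edges_recovered_significant(self, small_cohort):
        """Planted negative miRNA edges reach FDR significance at n=150."""
        bundle, truth, _ = small_cohort
        recovered = 0
        mirna, tf, interactions, truth2 = generate_regulators(
            bundle, truth, RegulatorParams(mirna_strength=0.5), seed=42
        )
        reg_expr = pd.concat([mirna.values, tf.values])
        results = []
        for row in interactions.pairs.itertuples(index=False):
            r = correlation_test(
                reg_expr.loc[row.regulator].to_numpy(),
                bundle.mrna.values.loc[row.target].to_numpy(),
            )
            results.append((row.regulator, row.target, r.estimate, r.p_value))
        res = pd.DataFrame(results, columns=["regulator", "target", "r", "p"])
        res["padj"] = bh_adjust(res["p"].to_numpy())
        merged = truth2.edges.merge(res, on=["regulator", "target"])
        mirna_edges = merged[merged["reg_class"] == "miRNA"]
        assert (mirna_edges["r"] < 0).mean() > 0.95
        assert (mirna_edges["padj"] <= 0.05).mean() >= 0.9

    def test_decoy_pairs_control_false_positives(self, small_cohort):
        bundle, truth, _ = small_cohort
        mirna, tf, interactions, truth2 = generate_regulators(
            bundle, truth, RegulatorParams(n_decoys=300), seed=17
        )
        reg_expr = pd.concat([mirna.values, tf.values])
        true_pairs = set(zip(truth2.edges["regulator"], truth2.edges["target"]))
        pvals = []
        for row in interactions.pairs.itertuples(index=False):
            if (row.regulator, row.target) in true_pairs:
                continue
            r = correlation_test(
                reg_expr.loc[row.regulator].to_numpy(),
                bundle.mrna.values.loc[row.target].to_numpy(),
            )
            pvals.append(r.p_value)
        padj = bh_adjust(pvals)
        # null decoys: BH retention stays at/below the nominal level + MC error
        assert (padj <= 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(pvals))

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError):
            RegulatorParams(mirna_strength=1.0).validate()


class TestDrugPanel:
    def test_planted_rho_recovered(self):
        """Planted |rho| 0.8 over 38 lines recovered within +-0.15 (>=90% of seeds)."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            panel, truth = generate_drug_panel(
                [f"G{i}" for i in range(10)],
                DrugPanelParams(n_associations=5, rho_range=(0.8, 0.8)),
                seed=seed,
            )
            ok = 0
            for row in truth.drug_assoc.itertuples(index=False):
                rho, _ = stats.spearmanr(
                    panel.ic50[row.drug], panel.expression.loc[row.gene, panel.ic50.index]
                )
                ok += abs(rho - row.rho) <= 0.15
            hits += ok == len(truth.drug_assoc)
        assert hits >= 8

    def test_null_drugs_rarely_significant(self):
        sig = []
        for seed in range(5):
            panel, truth = generate_drug_panel(
                [f"G{i}" for i in range(6)],
                DrugPanelParams(n_associations=0),
                seed=seed,
            )
            for drug in panel.ic50.columns:
                for gene in panel.expression.index:
                    rho, p = stats.spearmanr(
                        panel.ic50[drug], panel.expression.loc[gene, panel.ic50.index]
                    )
                    sig.append(p <= 0.05)
        rate = np.mean(sig)
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / len(sig))

    def test_determinism_and_validation(self):
        p1, _ = generate_drug_panel(["G1", "G2"], seed=9)
        p2, _ = generate_drug_panel(["G1", "G2"], seed=9)
        pd.testing.assert_frame_equal(p1.ic50, p2.ic50)
        with pytest.raises(ValueError):
            DrugPanelParams(n_cell_lines=4).validate()
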