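"""qPCR arithmetic: ddCt, allelic ratios, knockdown, Fisher, ChIP, reporter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from allelics import qpcr as qp
from allelics import simulate as sim

from conftest import fisher_enum_p


def ct_table(rows):
    defaults = dict(allele=None, template="cDNA", replicate=1)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestDdct:
    def test_one_cycle_difference_halves(self):
        tbl = ct_table([
            dict(sample="s", target="T", condition="treated", ct=25.0),
            dict(sample="s", target="R", condition="treated", ct=20.0),
            dict(sample="s", target="T", condition="calib", ct=24.0),
            dict(sample="s", target="R", condition="calib", ct=20.0),
        ])
        res = qp.ddct_expression(tbl, "T", "R", "calib").set_index("condition")
        assert res.loc["treated", "ddct"] == pytest.approx(1.0)
        assert res.loc["treated", "fold"] == pytest.approx(0.5)

    def test_calibrator_fold_exactly_one(self):
        tbl = ct_table([
            dict(sample="s", target="T", condition="calib", ct=24.3),
            dict(sample="s", target="R", condition="calib", ct=19.9),
        ])
        res = qp.ddct_expression(tbl, "T", "R", "calib")
        assert res["fold"].iloc[0] == 1.0

    def test_missing_reference_wells_named(self):
        tbl = ct_table([dict(sample="s", target="T", condition="calib", ct=24.0)])
        with pytest.raises(ValueError, match="reference"):
            qp.ddct_expression(tbl, "T", "R", "calib")

    def test_generator_round_trip_exact(self):
        spec = sim.QpcrSimSpec.for_expression(
            {("s", "calib"): 1.0, ("s", "kd"): 0.3}, ct_noise_sd=0.0)
        res = qp.ddct_expression(sim.simulate_qpcr(spec), "TERT", "GAPDH", "calib")
        assert res.set_index("condition").loc["kd", "fold"] == pytest.approx(0.3, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-5, 5))
    def test_shared_ct_offset_cancels(self, offset):
        rows = [
            dict(sample="s", target="T", condition="treated", ct=26.0),
            dict(sample="s", target="R", condition="treated", ct=21.0),
            dict(sample="s", target="T", condition="calib", ct=24.0),
            dict(sample="s", target="R", condition="calib", ct=20.5),
        ]
        base = qp.ddct_expression(ct_table(rows), "T", "R", "calib")
        shifted_rows = [dict(r, ct=r["ct"] + offset) for r in rows]
        shifted = qp.ddct_expression(ct_table(shifted_rows), "T", "R", "calib")
        assert np.allclose(base["fold"], shifted["fold"])


class TestAllelic:
    def test_one_cycle_gives_twofold(self):
        tbl = ct_table([
            dict(sample="s", target="A", allele="C", condition="x", ct=24.0),
            dict(sample="s", target="A", allele="G", condition="x", ct=25.0),
        ])
        res = qp.allelic_expression(tbl, "A")
        assert res["ratio_c_over_g"].iloc[0] == pytest.approx(2.0)

    def test_equal_ct_ratio_one(self):
        tbl = ct_table([
            dict(sample="s", target="A", allele="C", condition="x", ct=24.0),
            dict(sample="s", target="A", allele="G", condition="x", ct=24.0),
        ])
        assert qp.allelic_expression(tbl, "A")["ratio_c_over_g"].iloc[0] == 1.0

    def test_missing_allele_channel_errors(self):
        tbl = ct_table([dict(sample="s", target="A", allele="C", condition="x", ct=24.0)])
        with pytest.raises(ValueError, match="allele channel"):
            qp.allelic_expression(tbl, "A")

    def test_noisy_recovery_within_ten_percent(self):
        ratios = []
        for s in range(100):
            spec = sim.QpcrSimSpec.for_allelic({"cell": (2.0, 1.0)},
                                               ct_noise_sd=0.1, n_replicates=3, seed=s)
            tbl = sim.simulate_qpcr(spec)
            res = qp.allelic_expression(tbl, "TERT_rs2736098", "GAPDH")
            ratios.append(res.set_index("condition").loc["untreated", "ratio_c_over_g"])
        assert abs(np.mean(ratios) - 2.0) / 2.0 < 0.10


class TestCopyNumberAdjust:
    @pytest.mark.parametrize("expr,gdna,expected", [
        (2.0, 2.0, 1.0),
        (0.8, 0.5, 1.6),
        (1.7, 1.0, 1.7),
    ])
    def test_arithmetic(self, expr, gdna, expected):
        assert qp.copy_number_adjust(expr, gdna) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            qp.copy_number_adjust(0.0, 1.0)
        with pytest.raises(ValueError):
            qp.copy_number_adjust(1.0, -2.0)

    def test_generator_round_trip_with_copy_number(self):
        # planted expression ratio 2.0 on a 1.5x copy-number background:
        # cDNA assay sees 3.0, genomic assay sees 1.5, adjustment recovers 2.0
        spec = sim.QpcrSimSpec.for_allelic({"cell": (2.0, 1.5)}, ct_noise_sd=0.0)
        tbl = sim.simulate_qpcr(spec)
        expr = qp.allelic_expression(tbl, "TERT_rs2736098", template="cDNA")
        gdna = qp.allelic_expression(tbl, "TERT_rs2736098", template="gDNA")
        e = expr.set_index("condition").loc["untreated", "ratio_c_over_g"]
        g = gdna["ratio_c_over_g"].iloc[0]
        assert e == pytest.approx(3.0, abs=1e-12)
        assert qp.copy_number_adjust(e, g) == pytest.approx(2.0, abs=1e-12)


class TestKnockdown:
    def test_sixty_percent_knockdown(self):
        res = qp.allelic_knockdown([0.4, 0.4], [0.4, 0.4], [1.0, 1.0], [1.0, 1.0])
        assert res.mean_c == pytest.approx(60.0)

    def test_identical_alleles_p_one(self):
        res = qp.allelic_knockdown([0.5, 0.4, 0.6], [0.5, 0.4, 0.6],
                                   [1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0 and res.difference == 0.0

    def test_textbook_paired_difference(self):
        # knockdowns C = [60, 61, 59], G = [49, 50, 48]
        res = qp.allelic_knockdown(
            treated_c=[0.40, 0.39, 0.41], treated_g=[0.51, 0.50, 0.52],
            scrambled_c=[1.0, 1.0, 1.0], scrambled_g=[1.0, 1.0, 1.0])
        assert res.difference == pytest.approx(11.0, abs=1e-9)
        assert res.p_value < 0.01

    def test_zero_scrambled_rejected(self):
        with pytest.raises(ValueError, match="scrambled"):
            qp.allelic_knockdown([0.4, 0.4], [0.4, 0.4], [0.0, 1.0], [1.0, 1.0])


class TestFisher:
    def test_three_of_eight_vs_pooled_controls(self):
        # 3/8 target-gene hits against 0/24 pooled control-gene tests
        assert qp.sirna_specificity_test(3, 8, 0, 24) == pytest.approx(0.0113, abs=5e-4)

    def test_no_signal_p_one(self):
        assert qp.sirna_specificity_test(0, 8, 0, 24) == 1.0

    def test_extreme_table_matches_enumeration(self):
        assert qp.sirna_specificity_test(8, 8, 0, 24) == pytest.approx(
            fisher_enum_p(8, 0, 0, 24), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qp.sirna_specificity_test(-1, 8, 0, 24)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(1, 12), st.integers(1, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration_oracle(self, n1, n2, a, c):
        a, c = min(a, n1), min(c, n2)
        p = qp.sirna_specificity_test(a, n1, c, n2)
        assert p == pytest.approx(fisher_enum_p(a, n1 - a, c, n2 - c), rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 10), st.integers(1, 10), st.integers(0, 10), st.integers(0, 10))
    def test_group_swap_symmetry(self, n1, n2, a, c):
        a, c = min(a, n1), min(c, n2)
        assert qp.sirna_specificity_test(a, n1, c, n2) == pytest.approx(
            qp.sirna_specificity_test(c, n2, a, n1), rel=1e-9)


class TestChip:
    def _tables(self, ip_ct, ctrl_ct, input_ct=20.0, amp="amp6"):
        mk = lambda cts: pd.DataFrame(
            [dict(target=amp, replicate=i + 1, ct=c) for i, c in enumerate(cts)])
        return mk(ip_ct), mk(ctrl_ct), mk([input_ct, input_ct])

    def test_equal_ct_enrichment_one(self):
        ip, ctrl, inp = self._tables([25.0, 25.0], [25.0, 25.0])
        res = qp.chip_enrichment(ip, ctrl, inp)
        assert res["enrichment"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles(self):
        ip, ctrl, inp = self._tables([24.0, 24.0], [25.0, 25.0])
        res = qp.chip_enrichment(ip, ctrl, inp)
        assert res["enrichment"].iloc[0] == pytest.approx(2.0)

    def test_missing_input_errors(self):
        ip, ctrl, _ = self._tables([24.0, 24.0], [25.0, 25.0])
        empty = pd.DataFrame(columns=["target", "replicate", "ct"])
        with pytest.raises(ValueError, match="input"):
            qp.chip_enrichment(ip, ctrl, empty)

    def test_planted_enrichment_localised_to_one_amplicon(self):
        # nine amplicons, fourfold IP enrichment planted at amp6 only
        rng_seed = 0
        amps = [f"amp{i}" for i in range(1, 10)]
        levels = []
        for amp in amps:
            gain = 4.0 if amp == "amp6" else 1.0
            levels += [
                dict(sample="cl", target=amp, allele=None, condition="IP",
                     template="gDNA", amount=0.01 * gain),
                dict(sample="cl", target=amp, allele=None, condition="IgG",
                     template="gDNA", amount=0.01),
                dict(sample="cl", target=amp, allele=None, condition="input",
                     template="gDNA", amount=1.0),
            ]
        spec = sim.QpcrSimSpec(levels=pd.DataFrame(levels), n_replicates=3,
                               ct_noise_sd=0.1, seed=rng_seed)
        tbl = sim.simulate_qpcr(spec)
        pick = lambda cond: tbl[tbl["condition"] == cond]
        res = qp.chip_enrichment(pick("IP"), pick("IgG"), pick("input"),
                                 amplicons=amps).set_index("target")
        assert res.loc["amp6", "enrichment"] > 2.0
        assert (res.drop(index="amp6")["enrichment"] < 2.0).all()


class TestChipAllelic:
    def test_identical_vectors(self):
        fold, t, p = qp.chip_allelic_test([1.0, 1.1, 1.2], [1.0, 1.1, 1.2])
        assert fold == 1.0 and p == 1.0

    def test_textbook_paired(self):
        fold, t, p = qp.chip_allelic_test([1.2, 1.3, 1.4], [1.0, 1.1, 1.2])
        assert fold == pytest.approx(1.3 / 1.1, rel=1e-9)
        # constant per-pair differences drive the paired t to its limit
        assert p == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            qp.chip_allelic_test([1.0], [2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qp.chip_allelic_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestReporter:
    def _wells(self, c_activities, g_activities, empty=(1.0, 1.0, 1.0)):
        rows = [dict(construct="empty", orientation=None, allele=None,
                     firefly=f, renilla=1.0) for f in empty]
        for act, allele in ((c_activities, "C"), (g_activities, "G")):
            rows += [dict(construct=f"F{allele}", orientation="forward",
                          allele=allele, firefly=a, renilla=1.0) for a in act]
        return pd.DataFrame(rows)

    def test_empty_vector_activity_one(self):
        wells, _ = qp.reporter_activity(self._wells([1.5, 1.6], [1.2, 1.1]))
        empty = wells[wells["construct"] == "empty"]
        assert empty["activity"].mean() == pytest.approx(1.0)

    def test_uniform_fold_recovered(self):
        g = np.array([1.0, 1.1, 0.9])
        _, contrasts = qp.reporter_activity(self._wells(list(1.44 * g), list(g)))
        assert contrasts["fold_c_over_g"].iloc[0] == pytest.approx(1.44, rel=1e-9)

    def test_zero_renilla_rejected(self):
        tbl = self._wells([1.0, 1.0], [1.0, 1.0])
        tbl.loc[0, "renilla"] = 0.0
        with pytest.raises(ValueError, match="renilla"):
            qp.reporter_activity(tbl)

    def test_simulated_fold_recovery(self):
        rng = np.random.default_rng(2024)
        folds = []
        for _ in range(100):
            g = 1.2 * (1 + 0.1 * rng.standard_normal(9))
            c = 1.35 * 1.2 * (1 + 0.1 * rng.standard_normal(9))
            _, contrasts = qp.reporter_activity(self._wells(list(c), list(g)))
            folds.append(contrasts["fold_c_over_g"].iloc[0])
        assert abs(np.mean(folds) - 1.35) / 1.35 < 0.10
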