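"""Association-scan and LD machinery: oracles, invariances, QC rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from allelics import finemap as fm
from allelics import simulate as sim
from allelics.containers import (
    DegeneratePhenotypeError,
    GenotypeMatrix,
    MonomorphicError,
    make_variant_table,
)

from conftest import permutation_score_p


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

class TestVariantQc:
    def test_maf_and_info_thresholds(self):
        variants = make_variant_table(
            [f"v{i}" for i in range(5)],
            maf=[0.19, 0.005, 0.3, 0.02, 0.4],
            info=[0.92, 0.9, 0.48, 0.82, 0.96],
        )
        kept, log = fm.variant_qc_filter(variants)
        assert kept["id"].tolist() == ["v0", "v3", "v4"]
        reasons = dict(zip(log["id"], log["reason"]))
        assert "MAF" in reasons["v1"] and "INFO" in reasons["v2"]

    def test_empty_input(self):
        kept, log = fm.variant_qc_filter(make_variant_table([]))
        assert len(kept) == 0 and len(log) == 0

    def test_boundaries_inclusive(self):
        variants = make_variant_table(["v"], maf=[0.01], info=[0.5])
        kept, _ = fm.variant_qc_filter(variants)
        assert kept["id"].tolist() == ["v"]

    def test_absent_info_passes(self):
        variants = make_variant_table(["v"], maf=[0.3])
        kept, _ = fm.variant_qc_filter(variants)
        assert len(kept) == 1


# ---------------------------------------------------------------------------
# score test
# ---------------------------------------------------------------------------

class TestScoreTest:
    def test_hand_worked_example(self):
        # U = sum g (y - ybar) = 2, V = ybar(1-ybar) sum (g-gbar)^2 = 1
        res = fm.score_test([0, 1, 2, 0, 1, 2], [0, 0, 1, 0, 1, 1])
        assert res.score_stat == pytest.approx(4.0, abs=1e-10)
        assert res.p_value == pytest.approx(0.0455, abs=1e-4)

    def test_monomorphic_errors(self):
        with pytest.raises(MonomorphicError):
            fm.score_test([1, 1, 1, 1], [0, 1, 0, 1])

    def test_degenerate_phenotype_errors(self):
        with pytest.raises(DegeneratePhenotypeError):
            fm.score_test([0, 1, 2, 1], [1, 1, 1, 1])

    def test_matches_permutation_oracle(self):
        pool = sim.make_haplotype_pool(sim.HaplotypeSpec(["v"], [0.3]))
        G = sim.sample_genotypes(pool, 200, seed=11)
        data = sim.simulate_case_control(G, sim.CaseControlSpec({}, seed=12))
        g, y = G.genotypes[:, 0], data.phenotype
        p_score = fm.score_test(g, y, fit_beta=False).p_value
        p_perm = permutation_score_p(g, y, n_perm=20_000, seed=13)
        tol = 3 * np.sqrt(p_score * (1 - p_score) / 20_000)
        assert abs(p_score - p_perm) <= max(tol, 1e-3)

    def test_affine_covariate_recoding_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 300).astype(float)
        x = rng.standard_normal(300)
        y = (rng.random(300) < 1 / (1 + np.exp(-0.3 * x))).astype(float)
        a = fm.score_test(g, y, X=np.column_stack([np.ones(300), x]), fit_beta=False)
        b = fm.score_test(g, y, X=np.column_stack([np.ones(300), 2.5 * x - 7.0]),
                          fit_beta=False)
        assert a.score_stat == pytest.approx(b.score_stat, rel=1e-6)

    def test_label_swap_flips_beta_keeps_p(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 400).astype(float)
        y = (rng.random(400) < 0.4 + 0.05 * g).astype(float)
        a = fm.score_test(g, y)
        b = fm.score_test(g, 1 - y)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-8)
        assert a.beta == pytest.approx(-b.beta, rel=1e-4)

    def test_missing_genotypes_dropped_pairwise(self):
        g = np.array([0, 1, 2, np.nan, 1, 2, 0, 1])
        y = np.array([0, 0, 1, 1, 1, 1, 0, 0], dtype=float)
        res = fm.score_test(g, y)
        assert res.n == 7


# ---------------------------------------------------------------------------
# association scan / conditional analysis
# ---------------------------------------------------------------------------

def _two_snp_data(seed=0, n=600):
    spec = sim.HaplotypeSpec(["v1", "v2"], [0.3, 0.25], [("v1", "v2", 0.4)])
    pool = sim.make_haplotype_pool(spec)
    G = sim.sample_genotypes(pool, n, seed=seed)
    data = sim.simulate_case_control(G, sim.CaseControlSpec({"v1": 1.5}, seed=seed))
    return G, data.phenotype


class TestAssociationScan:
    def test_empty_conditioning_equals_per_variant_tests(self):
        G, y = _two_snp_data()
        scan = fm.association_scan(G, y)
        for _, row in scan.iterrows():
            single = fm.score_test(G.column(row["id"]), y, variant_id=row["id"])
            assert row["score_stat"] == pytest.approx(single.score_stat, rel=1e-10)
            assert row["p_value"] == pytest.approx(single.p_value, rel=1e-10)

    def test_conditioning_equals_manual_covariate(self):
        G, y = _two_snp_data()
        scan = fm.association_scan(G, y, condition_on=["v1"])
        X = np.column_stack([np.ones(G.n_samples), G.column("v1")])
        manual = fm.score_test(G.column("v2"), y, X=X)
        row = scan.set_index("id").loc["v2"]
        assert row["score_stat"] == manual.score_stat
        assert row["p_value"] == manual.p_value

    def test_conditioning_variant_reported_without_p(self):
        G, y = _two_snp_data()
        scan = fm.association_scan(G, y, condition_on=["v1"]).set_index("id")
        assert np.isnan(scan.loc["v1", "p_value"])
        assert scan.loc["v2", "conditioned_on"] == ("v1",)

    def test_unknown_conditioning_id_raises(self):
        G, y = _two_snp_data()
        with pytest.raises(KeyError, match="nope"):
            fm.association_scan(G, y, condition_on=["nope"])

    def test_signal_collapse_on_proxies(self):
        # one causal SNP with two tight proxies: conditioning on the causal
        # variant removes the proxies' signal
        ids = ["causal", "p1", "p2"]
        spec = sim.HaplotypeSpec(ids, [0.19, 0.2, 0.21],
                                 [("causal", "p1", 0.9), ("p1", "p2", 0.9)])
        pool = sim.make_haplotype_pool(spec)
        cc = sim.CaseControlSpec({"causal": 1.6}, mode="retrospective",
                                 n_cases=1500, n_controls=1500, seed=21)
        d = sim.simulate_case_control_study(pool, cc, cohort_multiplier=3)
        un = fm.association_scan(d.genotypes, d.phenotype, fit_beta=False).set_index("id")
        co = fm.association_scan(d.genotypes, d.phenotype, condition_on=["causal"],
                                 fit_beta=False).set_index("id")
        assert (un.loc[["p1", "p2"], "p_value"] < 1e-4).all()
        assert (co.loc[["p1", "p2"], "p_value"] > un.loc[["p1", "p2"], "p_value"]).all()


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

class TestLd:
    def test_perfect_ld_counts(self):
        pair = fm.ld_from_haplotype_counts(50, 0, 0, 50)
        assert pair.r2 == pytest.approx(1.0) and pair.d_prime == pytest.approx(1.0)

    def test_closed_form_counts(self):
        pair = fm.ld_from_haplotype_counts(40, 10, 10, 40)
        assert pair.r2 == pytest.approx(0.36, abs=1e-12)
        assert pair.d_prime == pytest.approx(0.6, abs=1e-12)

    def test_independent_loci(self):
        # product haplotype frequencies: 0.06, 0.14, 0.24, 0.56 (pA=0.2, pB=0.3)
        pair = fm.ld_from_haplotype_counts(6, 14, 24, 56)
        assert pair.r2 == pytest.approx(0.0, abs=1e-12)
        assert pair.d_prime == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_locus_undefined(self):
        with pytest.raises(MonomorphicError):
            fm.ld_from_haplotype_counts(50, 50, 0, 0)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 200), min_size=4, max_size=4))
    def test_r2_never_exceeds_dprime(self, counts):
        nAB, nAb, naB, nab = counts
        total = sum(counts)
        pA = (nAB + nAb), (naB + nab)
        pB = (nAB + naB), (nAb + nab)
        if total == 0 or 0 in pA or 0 in pB:
            return
        pair = fm.ld_from_haplotype_counts(nAB, nAb, naB, nab)
        assert pair.r2 <= pair.d_prime + 1e-9

    def test_symmetry(self):
        spec = sim.HaplotypeSpec(["a", "b"], [0.3, 0.4], [("a", "b", 0.5)])
        G = sim.sample_genotypes(sim.make_haplotype_pool(spec), 500, seed=3)
        assert fm.ld_pair(G, "a", "b").r2 == pytest.approx(fm.ld_pair(G, "b", "a").r2)

    def test_em_matches_phased_counting(self):
        # in strong (but imperfect) LD nearly every double heterozygote is
        # cis, so the EM estimate from unphased genotypes reproduces the
        # phase-known estimate; at weaker LD the phase information lost in
        # double heterozygotes makes a ~0.005 discrepancy irreducible
        spec = sim.HaplotypeSpec(["a", "b"], [0.3, 0.3], [("a", "b", 0.95)])
        pool = sim.make_haplotype_pool(spec)
        rng = np.random.default_rng(17)
        H = pool.sample_haplotypes(1000, rng)  # 500 diploid individuals
        phased = fm.ld_pair(H, 0, 1, phased=True)
        G = GenotypeMatrix(
            [f"s{i}" for i in range(500)],
            make_variant_table(["a", "b"]),
            (H[0::2] + H[1::2]).astype(float),
        )
        unphased = fm.ld_pair(G, "a", "b")
        assert unphased.r2 == pytest.approx(phased.r2, abs=1e-3)
        assert unphased.d_prime == pytest.approx(phased.d_prime, abs=1e-3)


@pytest.fixture(scope="module")
def region():
    # exactly 8 of 20 non-index variants sit above r2 = 0.6 to the index
    strong = [f"hi{i}" for i in range(8)]
    weak = [f"lo{i}" for i in range(12)]
    ids = ["idx"] + strong + weak
    targets = [("idx", v, 0.8) for v in strong] + [("idx", v, 0.2) for v in weak]
    spec = sim.HaplotypeSpec(ids, [0.25] * 21, targets)
    pool = sim.make_haplotype_pool(spec)
    return sim.sample_genotypes(pool, 2500, seed=99), strong


class TestCorrelatedSet:

    def test_recovers_planted_proxies(self, region):
        G, strong = region
        assert set(fm.correlated_set(G, "idx", 0.6)) == set(strong)

    def test_threshold_one_empty(self, region):
        G, _ = region
        assert fm.correlated_set(G, "idx", 1.0) == []

    def test_index_excluded_despite_perfect_self_ld(self, region):
        G, _ = region
        assert "idx" not in fm.correlated_set(G, "idx", 0.0)

    def test_absent_index_raises(self, region):
        G, _ = region
        with pytest.raises(KeyError):
            fm.correlated_set(G, "missing", 0.6)

    def test_sorted_by_position(self, region):
        G, _ = region
        hits = fm.correlated_set(G, "idx", 0.6)
        pos = [int(G.variants.set_index("id").loc[v, "pos"]) for v in hits]
        assert pos == sorted(pos)
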