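"""Summary-statistics PGS algebra: weights, subtraction, reconstruction,
group-wise comparison and case-case GWAS."""

import math

import numpy as np
import pandas as pd
import pytest

from pleiopc.decomposition import Decomposition
from pleiopc.pgs import (
    PGSError,
    PGSWeightSet,
    adjust_bonferroni,
    cc_gwas,
    counts_to_sumstats,
    group_pgs,
    inverse_variance_meta,
    meta_subtract,
    pc_pgs_weights,
    r2_from_t,
    reconstruct_counts,
)
from pleiopc.sumstats import SUMSTATS_COLUMNS


def sumstats_frame(snp_ids, beta, se, eaf, n_case, n_control, allele="A"):
    beta = np.broadcast_to(np.asarray(beta, float), (len(snp_ids),))
    se = np.broadcast_to(np.asarray(se, float), (len(snp_ids),))
    eaf = np.broadcast_to(np.asarray(eaf, float), (len(snp_ids),))
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, len(snp_ids) + 1) * 1000,
            "effect_allele": allele,
            "other_allele": "G",
            "beta": beta,
            "se": se,
            "p_value": 0.5,
            "eaf": eaf,
            "n_case": n_case,
            "n_control": n_control,
        }
    )
    return df[SUMSTATS_COLUMNS]


def meta_oracle(betas, ses):
    """Direct fixed-effect inverse-variance combination."""
    w = 1.0 / np.asarray(ses) ** 2
    return float((w * betas).sum() / w.sum()), float(w.sum() ** -0.5)


class TestWeights:
    def make_decomp(self):
        u = np.array([[0.6, 0.8], [-0.8, 0.6]])
        return Decomposition(["rs1", "rs2"], ["t1", "t2"], u,
                             np.array([2.0, 1.0]), np.eye(2))

    def panel(self):
        return pd.DataFrame(
            {"snp_id": ["rs1", "rs2"], "allele1": ["A", "T"],
             "allele2": ["G", "C"], "chrom": ["1", "1"], "pos": [1, 2]}
        )

    def test_signed_loadings_pass_through(self):
        w = pc_pgs_weights(self.make_decomp(), 0, self.panel())
        assert w.entries["rs1"] == ("A", pytest.approx(0.6))
        assert w.entries["rs2"] == ("T", pytest.approx(-0.8))

    def test_squared_variant_matches_contribution(self):
        d = self.make_decomp()
        w = pc_pgs_weights(d, 0, self.panel(), squared=True)
        vals = np.array([w.entries[s][1] for s in d.snp_ids])
        np.testing.assert_allclose(vals / vals.sum(), d.snp_vectors[:, 0] ** 2,
                                   atol=1e-12)

    def test_component_orientation_flips_weights(self):
        d = self.make_decomp()
        flipped = Decomposition(d.snp_ids, d.trait_ids, -d.snp_vectors,
                                d.singular_values, -d.pheno_vectors)
        wa = pc_pgs_weights(d, 0, self.panel())
        wb = pc_pgs_weights(flipped, 0, self.panel())
        for s in wa.entries:
            assert wb.entries[s][1] == pytest.approx(-wa.entries[s][1])


class TestMetaSubtract:
    def test_exact_leave_one_out_two_cohorts(self):
        a = sumstats_frame(["rs1"], 0.2, 0.1, 0.3, 1000, 1000)
        b = sumstats_frame(["rs1"], 0.0, 0.1, 0.3, 1000, 1000)
        meta = inverse_variance_meta([a, b])
        assert meta.loc[0, "beta"] == pytest.approx(0.1)
        assert meta.loc[0, "se"] == pytest.approx(0.1 / math.sqrt(2))
        out = meta_subtract(meta, b)
        assert out.loc[0, "beta"] == pytest.approx(0.2, abs=1e-12)
        assert out.loc[0, "se"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_cohort_dropped(self):
        a = sumstats_frame(["rs1"], 0.2, 0.1, 0.3, 1000, 1000)
        out = meta_subtract(a, a)
        assert out.empty

    @pytest.mark.parametrize("seed", range(5))
    def test_three_cohort_subtraction_equals_two_cohort_meta(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        snps = [f"rs{i}" for i in range(n)]
        cohorts = [
            sumstats_frame(snps, rng.normal(0, 0.2, n),
                           rng.uniform(0.05, 0.3, n), 0.3, 1000, 1000)
            for _ in range(3)
        ]
        meta3 = inverse_variance_meta(cohorts)
        left = meta_subtract(meta3, cohorts[2])
        meta2 = inverse_variance_meta(cohorts[:2])
        np.testing.assert_allclose(left["beta"], meta2["beta"], atol=1e-10)
        np.testing.assert_allclose(left["se"], meta2["se"], atol=1e-10)


class TestReconstructCounts:
    def record(self, beta, eaf, n_case=500, n_control=800):
        return sumstats_frame(["rs1"], beta, 0.1, eaf, n_case, n_control).iloc[0]

    def test_null_or_keeps_frequency(self):
        t = reconstruct_counts(self.record(0.0, 0.3))
        assert t.f_case == pytest.approx(0.3)
        assert t.f_control == pytest.approx(0.3)

    def test_odds_arithmetic(self):
        t = reconstruct_counts(self.record(math.log(2.25), 0.4))
        assert t.f_case == pytest.approx(0.6)

    def test_count_margins(self):
        t = reconstruct_counts(self.record(0.1, 0.3, 500, 800))
        assert t.a + t.b == pytest.approx(1000)
        assert t.c + t.d == pytest.approx(1600)

    @pytest.mark.parametrize("mode", ["control", "pooled"])
    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_from_known_frequencies(self, mode, seed):
        rng = np.random.default_rng(seed)
        f_case, f_ctrl = rng.uniform(0.05, 0.95, 2)
        n_case, n_control = 700, 1100
        or_ = (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))
        eaf = (
            f_ctrl if mode == "control"
            else (n_case * f_case + n_control * f_ctrl) / (n_case + n_control)
        )
        t = reconstruct_counts(self.record(math.log(or_), eaf, n_case, n_control),
                               freq_is=mode)
        assert t.f_case == pytest.approx(f_case, abs=1e-10)
        assert t.f_control == pytest.approx(f_ctrl, abs=1e-10)

    def test_counts_to_sumstats_inverts(self):
        rec = self.record(0.25, 0.35)
        t = reconstruct_counts(rec)
        back = counts_to_sumstats(t)
        assert back["beta"] == pytest.approx(0.25, abs=1e-12)
        assert back["eaf"] == pytest.approx(0.35, abs=1e-12)


class TestGroupPGS:
    def test_single_snp_closed_form(self):
        w = PGSWeightSet(0, {"rs1": ("A", 0.5)})
        f_case, f_ctrl = 0.6, 0.5
        or_ = (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))
        target = sumstats_frame(["rs1"], math.log(or_), 0.1, f_ctrl, 1000, 1000)
        res = group_pgs(w, target)
        assert res.mean_a == pytest.approx(0.6)
        assert res.mean_b == pytest.approx(0.5)
        assert res.sd_a == pytest.approx(math.sqrt(0.25 * 2 * 0.6 * 0.4))

    def test_equal_frequencies_null(self):
        snps = [f"rs{i}" for i in range(20)]
        w = PGSWeightSet(0, {s: ("A", 0.1 * (i + 1)) for i, s in enumerate(snps)})
        target = sumstats_frame(snps, 0.0, 0.1, 0.4, 1000, 1000)
        res = group_pgs(w, target)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_t_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(3)
        snps = [f"rs{i}" for i in range(30)]
        w = PGSWeightSet(0, {s: ("A", float(v)) for s, v
                             in zip(snps, rng.standard_normal(30))})
        beta = rng.normal(0, 0.2, 30)
        target = sumstats_frame(snps, beta, 0.1, rng.uniform(0.2, 0.8, 30),
                                1500, 1500)
        fwd = group_pgs(w, target)
        swapped = target.copy()
        # swapping groups = inverting the OR and declaring eaf as case freq
        tables = [reconstruct_counts(target.iloc[i].rename(s))
                  for i, s in enumerate(snps)]
        swapped["beta"] = -beta
        swapped["eaf"] = [t.f_case for t in tables]
        rev = group_pgs(w, swapped)
        assert rev.t == pytest.approx(-fwd.t, rel=1e-10)

    def test_matches_individual_level_simulation(self):
        from pleiopc.synthetic import generate_target_cohort

        rng = np.random.default_rng(5)
        snps = [f"rs{i:03d}" for i in range(100)]
        w = PGSWeightSet(0, {s: ("A", float(v)) for s, v
                             in zip(snps, rng.standard_normal(100))})
        target, extras = generate_target_cohort(w, n_case=4000, n_control=4000,
                                                effect_shift=0.02, seed=6)
        res = group_pgs(w, target)
        weights = np.array([w.entries[s][1] for s in snps])
        m = len(snps)
        for grp, mean_analytic, sd_analytic in [
            ("case", res.mean_a, res.sd_a),
            ("control", res.mean_b, res.sd_b),
        ]:
            g = extras[f"genotypes_{grp}"]
            scores = g @ weights / m
            mc_se = scores.std(ddof=1) / math.sqrt(len(scores))
            assert abs(mean_analytic - scores.mean()) < 3 * mc_se
            # SD agreement within a few percent (binomial vs realised draws)
            assert sd_analytic == pytest.approx(scores.std(ddof=1), rel=0.05)

    def test_allele_mismatch_fatal(self):
        w = PGSWeightSet(0, {"rs1": ("T", 0.5)})
        target = sumstats_frame(["rs1"], 0.1, 0.1, 0.4, 1000, 1000, allele="A")
        with pytest.raises(PGSError, match="mismatch"):
            group_pgs(w, target)

    def test_empty_intersection_fatal(self):
        w = PGSWeightSet(0, {"rs99": ("A", 0.5)})
        target = sumstats_frame(["rs1"], 0.1, 0.1, 0.4, 1000, 1000)
        with pytest.raises(PGSError):
            group_pgs(w, target)


class TestR2FromT:
    @pytest.mark.parametrize("t,df,expected", [
        (0.0, 100, 0.0),
        (3.0, 100, 9.0 / 109.0),
        (1e6, 10, pytest.approx(1.0, abs=1e-9)),
    ])
    def test_values(self, t, df, expected):
        assert r2_from_t(t, df) == pytest.approx(expected)

    def test_bad_df(self):
        with pytest.raises(PGSError):
            r2_from_t(1.0, 0.0)


class TestCcGwas:
    def paired_gwas(self, f_a, f_b, f_ctrl=0.4, n_case=1000, n_control=1500):
        def one(f_case):
            or_ = (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))
            return sumstats_frame(["rs1"], math.log(or_), 0.1, f_ctrl,
                                  n_case, n_control)
        return one(f_a), one(f_b)

    def test_equal_case_frequencies_null(self):
        a, b = self.paired_gwas(0.5, 0.5)
        out = cc_gwas(a, b)
        assert out.loc[0, "beta"] == pytest.approx(0.0, abs=1e-12)

    def test_odds_ratio_arithmetic(self):
        a, b = self.paired_gwas(0.6, 0.4)
        out = cc_gwas(a, b)
        assert math.exp(out.loc[0, "beta"]) == pytest.approx(2.25, abs=1e-10)

    def test_self_comparison_all_zero(self):
        rng = np.random.default_rng(1)
        snps = [f"rs{i}" for i in range(20)]
        g = sumstats_frame(snps, rng.normal(0, 0.3, 20), 0.1,
                           rng.uniform(0.2, 0.8, 20), 1000, 1000)
        out = cc_gwas(g, g)
        np.testing.assert_allclose(out["beta"], 0.0, atol=1e-12)

    def test_matches_direct_two_by_two_computation(self):
        rng = np.random.default_rng(2)
        f_a, f_b = rng.uniform(0.1, 0.9, 2)
        n_a, n_b = 1200, 900
        a, b = self.paired_gwas(f_a, f_b, n_case=n_a)
        b["n_case"] = n_b
        # adjust group B's OR for its own sample size (freqs unchanged)
        out = cc_gwas(a, b)
        aa, ba = 2 * n_a * f_a, 2 * n_a * (1 - f_a)
        ab, bb = 2 * n_b * f_b, 2 * n_b * (1 - f_b)
        beta_direct = math.log((aa / ba) / (ab / bb))
        se_direct = math.sqrt(1 / aa + 1 / ba + 1 / ab + 1 / bb)
        assert out.loc[0, "beta"] == pytest.approx(beta_direct, abs=1e-10)
        assert out.loc[0, "se"] == pytest.approx(se_direct, abs=1e-10)

    def test_output_feeds_group_pgs(self):
        rng = np.random.default_rng(3)
        snps = [f"rs{i}" for i in range(10)]
        a = sumstats_frame(snps, rng.normal(0.2, 0.1, 10), 0.1,
                           rng.uniform(0.3, 0.7, 10), 1000, 1500)
        b = sumstats_frame(snps, rng.normal(-0.2, 0.1, 10), 0.1,
                           rng.uniform(0.3, 0.7, 10), 800, 1500)
        cc = cc_gwas(a, b)
        w = PGSWeightSet(0, {s: ("A", float(v)) for s, v
                             in zip(snps, rng.standard_normal(10))})
        res = group_pgs(w, cc)
        assert np.isfinite(res.t)
        assert res.n_a == 1000 and res.n_b == 800


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.016, 3, True),   # below 0.05/3 ≈ 0.017
        (0.02, 3, False),
        (0.04, 1, True),
    ])
    def test_threshold(self, p, m, expected):
        assert adjust_bonferroni([p], m)[0] == expected

    def test_bad_m(self):
        with pytest.raises(PGSError):
            adjust_bonferroni([0.01], 0)
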