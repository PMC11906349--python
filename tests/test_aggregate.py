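"""Aggregate frameworks (BURDEN/SKAT/ACAT), reduction laws, conditioning
and the stepwise independence procedure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cispqtl import aggregate as agg
from cispqtl import annotate, simulate, single
from cispqtl.annotate import AggregateUnit


def _rare_geno(rng, n, m, p=0.01):
    G = rng.binomial(2, p, size=(n, m)).astype(float)
    while (G.sum(axis=0) == 0).any():  # ensure carriers everywhere
        empty = G.sum(axis=0) == 0
        G[:, empty] = rng.binomial(2, p, size=(n, int(empty.sum())))
    return G


def _adj(y, cov=None, cond=None):
    return agg.residualize_phenotype(y, cov, cond)


class TestAcat:
    def test_all_half_gives_half(self):
        assert agg.acat(np.array([0.5, 0.5, 0.5])) == pytest.approx(0.5)

    def test_single_p_identity(self):
        for p in (1e-8, 0.01, 0.4, 0.97):
            assert agg.acat(np.array([p])) == pytest.approx(p, abs=1e-12)

    def test_closed_form_oracle(self):
        p = np.array([1e-6, 0.5, 0.5])
        w = np.ones(3) / 3
        T = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
        expected = 0.5 - np.arctan(T) / np.pi
        assert agg.acat(p) == pytest.approx(expected, abs=1e-12)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(2, 12))
            p = rng.uniform(1e-10, 1 - 1e-10, size=k)
            w = rng.uniform(0.1, 2.0, size=k)
            wn = w / w.sum()
            T = float(np.sum(wn * np.tan((0.5 - p) * np.pi)))
            expected = 0.5 - np.arctan(T) / np.pi
            assert agg.acat(p, w) == pytest.approx(expected, abs=1e-12)

    def test_clipping_keeps_finite(self):
        out = agg.acat(np.array([0.0, 1.0, 0.5]))
        assert 0.0 < out < 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no valid"):
            agg.acat(np.array([]))

    def test_bad_weights_error(self):
        with pytest.raises(ValueError, match="weights"):
            agg.acat(np.array([0.5, 0.5]), np.array([0.0, 0.0]))


class TestAcatO:
    def test_fixed_point_equal_components(self):
        for p in (1e-9, 0.2, 0.8):
            r = agg.acat_o({"BURDEN": p, "SKAT": p, "ACAT_V": p})
            assert r.p == pytest.approx(p, abs=1e-12)

    def test_equals_equal_weight_acat(self):
        comp = {"BURDEN": 1e-8, "SKAT": 0.4, "ACAT_V": 0.6}
        r = agg.acat_o(comp)
        assert r.p == pytest.approx(
            agg.acat(np.array(list(comp.values()))), abs=1e-14)

    def test_missing_components_skipped(self):
        r = agg.acat_o({"BURDEN": 0.3, "SKAT": np.nan})
        assert r.p == pytest.approx(0.3, abs=1e-12)

    def test_all_missing_untestable(self):
        assert agg.acat_o({"BURDEN": np.nan}).untestable


class TestReductionLaws:
    """Aggregate tests on a single-variant unit equal single-variant tests."""

    def setup_method(self):
        rng = np.random.default_rng(42)
        self.n = 400
        self.G = _rare_geno(rng, self.n, 1, p=0.02)
        self.y = rng.standard_normal(self.n)
        self.adj = _adj(self.y)
        self.maf = self.G.sum(0) / (2 * self.n)

    def _single_t_p(self):
        Gr = self.G - self.adj.Q @ (self.adj.Q.T @ self.G)
        gtg = float(Gr[:, 0] @ Gr[:, 0])
        b = float(Gr[:, 0] @ self.adj.y) / gtg
        rss = float(self.adj.y @ self.adj.y) - b * b * gtg
        df = self.adj.df - 1
        t = abs(b) / np.sqrt(rss / df / gtg)
        return 2 * stats.t.sf(t, df)

    def test_burden_reduces_to_single_variant(self):
        r = agg.burden_test(self.G, self.maf, self.adj)
        assert r.p == pytest.approx(self._single_t_p(), abs=1e-10)

    def test_skat_reduces_to_single_variant(self):
        r = agg.skat_test(self.G, self.maf, self.adj)
        assert r.p == pytest.approx(self._single_t_p(), abs=1e-8)

    def test_acat_v_single_is_identity(self):
        pv = agg.per_variant_pvalues(self.G, self.adj)
        r = agg.acat_v(pv)
        assert r.p == pytest.approx(pv[0], abs=1e-12)
        assert pv[0] == pytest.approx(self._single_t_p(), abs=1e-12)

    def test_singleton_equals_burden_on_singleton_subunit(self):
        rng = np.random.default_rng(43)
        n = 300
        G = np.zeros((n, 3))
        G[0, 0] = 1
        G[1, 1] = 1
        G[2:5, 2] = 1  # MAC 3
        y = rng.standard_normal(n)
        adj = _adj(y)
        macs = G.sum(0)
        r = agg.singleton_test(G, macs, adj)
        assert r.n_variants == 2
        sub = agg.burden_test(G[:, :2], np.full(2, 0.5 / n), adj)
        assert r.p == pytest.approx(sub.p, abs=1e-12)

    def test_no_singletons_untestable(self):
        G = np.zeros((100, 1))
        G[:4, 0] = 1
        r = agg.singleton_test(G, G.sum(0), _adj(np.random.default_rng(0).standard_normal(100)))
        assert r.untestable


class TestSkat:
    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        n, m = 200, 10
        G = _rare_geno(rng, n, m, p=0.02)
        y = single.rank_inverse_normalize(rng.standard_normal(n))
        adj = _adj(y)
        mafs = G.sum(0) / (2 * n)
        cfg = agg.TestConfig()
        r = agg.skat_test(G, mafs, adj, cfg)
        n_perm = 5_000
        pp = agg.permutation_skat_p(G, cfg.weights(mafs), adj,
                                    n_perm=n_perm, seed=5)
        se = np.sqrt(pp * (1 - pp) / n_perm)
        assert abs(r.p - pp) < 3 * se + 1e-12

    def test_null_uniform(self):
        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            G = _rare_geno(rng, 300, 8, p=0.02)
            y = rng.standard_normal(300)
            pvals.append(agg.skat_test(G, G.sum(0) / 600, _adj(y)).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_all_zero_untestable(self):
        r = agg.skat_test(np.zeros((50, 3)), np.zeros(3),
                          _adj(np.random.default_rng(0).standard_normal(50)))
        assert r.untestable


class TestPowerRegimes:
    """Direction-consistent effects favour BURDEN; mixed signs favour SKAT."""

    def _compare(self, signs, n_seeds=50):
        burden_wins = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 100)
            n, m = 500, 8
            G = _rare_geno(rng, n, m, p=0.015)
            beta = 0.8 * signs(rng, m)
            y = G @ beta + rng.standard_normal(n)
            adj = _adj(y)
            mafs = G.sum(0) / (2 * n)
            b = agg.burden_test(G, mafs, adj)
            s = agg.skat_test(G, mafs, adj)
            if b.p < s.p:
                burden_wins += 1
        return burden_wins / n_seeds

    def test_same_sign_burden_wins(self):
        frac = self._compare(lambda rng, m: -np.ones(m))
        assert frac >= 0.8

    def test_mixed_sign_skat_wins(self):
        frac = self._compare(
            lambda rng, m: rng.choice([-1.0, 1.0], size=m))
        assert frac <= 0.2


class TestConditioning:
    def test_build_conditioning_set_maf_threshold(self, small_locus):
        v = small_locus.variants
        # fabricate a joint signal set with one common and one rare lead
        common_idx = int(np.flatnonzero(v["maf"].to_numpy() > 0.01)[0])
        # a singleton at n=500 has MAF exactly 0.001, not > 0.001
        rare_idx = int(np.flatnonzero(v["mac"].to_numpy() == 1)[0])
        sig = single.JointSignalSet(
            pd.DataFrame({"idx": [common_idx, rare_idx]}),
            np.array([common_idx, rare_idx]),
        )
        cond = agg.build_conditioning_set(sig, v, small_locus.gene.gene_id)
        assert common_idx in cond
        assert rare_idx not in cond  # below the 0.1% conditioning cut
        coding = v["consequence"].isin(annotate.CODING_CONSEQUENCES)
        cognate = v["annotated_gene"].fillna("") == small_locus.gene.gene_id
        for j in np.flatnonzero((coding & cognate).to_numpy()):
            assert j in cond  # coding variants enter regardless of P

    def test_empty_inputs_empty_set(self):
        v = pd.DataFrame({"maf": [0.2], "consequence": ["intron_variant"],
                          "annotated_gene": [None]})
        sig = single.JointSignalSet(pd.DataFrame({"idx": []}), np.empty(0, int))
        assert len(agg.build_conditioning_set(sig, v, "G1")) == 0

    def test_residuals_orthogonal(self, rng):
        n = 300
        y = rng.standard_normal(n)
        cov = pd.DataFrame({"c": rng.standard_normal(n)})
        C = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        adj = agg.residualize_phenotype(y, cov, C)
        for j in range(4):
            c = C[:, j] - C[:, j].mean()
            denom = np.linalg.norm(adj.y) * np.linalg.norm(c)
            assert abs(float(adj.y @ c)) / denom < 1e-10

    def test_empty_conditioning_is_covariate_residual(self, rng):
        n = 200
        y = rng.standard_normal(n)
        cov = pd.DataFrame({"c": rng.standard_normal(n)})
        a = agg.residualize_phenotype(y, cov, None)
        b = agg.residualize_phenotype(y, cov, np.empty((n, 0)))
        np.testing.assert_allclose(a.y, b.y, atol=1e-12)

    def test_too_many_conditioning_columns_errors(self, rng):
        with pytest.raises(ValueError, match="more conditioning columns"):
            agg.residualize_phenotype(
                rng.standard_normal(20), None,
                rng.standard_normal((20, 25)))

    def test_conditioning_on_causal_nulls_the_unit(self):
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 500
            G = _rare_geno(rng, n, 6, p=0.02)
            y = 1.0 * G[:, 0] + rng.standard_normal(n)
            adj = agg.residualize_phenotype(y, None, G[:, [0]])
            r = agg.skat_test(G[:, 1:], G[:, 1:].sum(0) / (2 * n), adj)
            if r.p < 0.05:
                rejections += 1
        # nominal alpha=0.05 within 3 binomial s.e.
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert rejections / n_seeds < 0.05 + 3 * se


class TestAllMask:
    def test_single_mask_identity(self):
        assert agg.all_mask_combine({"noncoding_all": 0.123}) == \
            pytest.approx(0.123)

    def test_mixing_coding_and_noncoding_errors(self):
        with pytest.raises(ValueError, match="cannot be combined"):
            agg.all_mask_combine({"coding_all": 0.1, "noncoding_all": 0.2})

    def test_two_mask_closed_form(self):
        p = {"noncoding_all": 1e-9, "gerp2": 0.5}
        expected = agg.acat(np.array([1e-9, 0.5]))
        assert agg.all_mask_combine(p) == pytest.approx(expected, abs=1e-15)


def _window_units(variants, window_start, window_len, n_samples):
    win = annotate.CisWindow("chr1", window_start, window_start + window_len,
                             "G1")
    return annotate.build_sliding_windows(win, variants)


def _synthetic_rare_locus(rng, n, m, window_len=20_000, start=0):
    """Hand-built rare-variant table + dosages for stepwise tests.

    Allele counts are placed exactly (MAC 1-5) so every variant stays below
    the 0.1% rare-mask MAF cut.
    """
    pos = np.sort(rng.choice(window_len, size=m, replace=False)) + start + 1
    G = np.zeros((n, m))
    hi = min(5, int(np.ceil(0.001 * 2 * n)) - 1)  # stay under MAF 0.1%
    for j in range(m):
        mac = int(rng.integers(1, max(hi, 1) + 1))
        chroms = rng.choice(2 * n, size=mac, replace=False)
        np.add.at(G[:, j], chroms // 2, 1)
    mac = G.sum(0).astype(int)
    variants = pd.DataFrame({
        "vid": [f"chr1:{p}:A:T" for p in pos],
        "chrom": "chr1", "pos": pos, "ref": "A", "alt": "T",
        "mac": mac, "maf": mac / (2 * n),
        "consequence": "intron_variant", "annotated_gene": "G1",
        "gerp": 0.0, "cadd": 1.0, "jarvis": 0.5, "spliceai": 0.0,
        "loftee_hc": False,
        "classification": annotate.PROXIMAL,
    })
    return variants, G


class TestStepwise:
    def test_two_disjoint_signals_two_iterations(self):
        rng = np.random.default_rng(1)
        n, m = 3_000, 60
        variants, G = _synthetic_rare_locus(rng, n, m)
        pos0 = variants["pos"].to_numpy() - 1
        in_a = (pos0 >= 0) & (pos0 < 2_000)
        in_b = (pos0 >= 10_000) & (pos0 < 12_000)
        beta = np.zeros(m)
        beta[in_a] = 1.6
        beta[in_b] = -1.6
        y = G @ beta + rng.standard_normal(n)
        units = _window_units(variants, 0, 20_000, n)
        out = agg.stepwise_aggregate_conditioning(
            G, variants, units, y, None, threshold=1e-6)
        assert len(out) >= 2
        starts = sorted(out["start"].iloc[:2].tolist())
        assert any(s < 2_000 for s in starts)
        assert any(9_000 <= s < 12_000 for s in starts)
        assert out["iteration"].iloc[0] == 0

    def test_overlapping_windows_record_one(self):
        rng = np.random.default_rng(2)
        n, m = 3_000, 40
        variants, G = _synthetic_rare_locus(rng, n, m, window_len=6_000)
        pos0 = variants["pos"].to_numpy() - 1
        core = (pos0 >= 1_000) & (pos0 < 2_000)  # shared by windows 0 and 1
        beta = np.zeros(m)
        beta[core] = 1.8
        y = G @ beta + rng.standard_normal(n)
        units = _window_units(variants, 0, 6_000, n)
        out = agg.stepwise_aggregate_conditioning(
            G, variants, units, y, None, threshold=1e-6)
        # the overlapping neighbour is conditioned away
        assert len(out) == 1

    def test_nothing_significant_empty(self):
        rng = np.random.default_rng(3)
        n, m = 500, 30
        variants, G = _synthetic_rare_locus(rng, n, m)
        y = rng.standard_normal(n)
        units = _window_units(variants, 0, 20_000, n)
        out = agg.stepwise_aggregate_conditioning(
            G, variants, units, y, None, threshold=1e-8)
        assert len(out) == 0


class TestFlagsAndSensitivity:
    def _setup(self):
        rng = np.random.default_rng(4)
        n, m = 2_000, 30
        variants, G = _synthetic_rare_locus(rng, n, m, window_len=4_000)
        pos0 = variants["pos"].to_numpy() - 1
        beta = np.where(pos0 < 2_000, 1.8, 0.0)  # whole first window causal
        y = G @ beta + rng.standard_normal(n)
        units = _window_units(variants, 0, 4_000, n)
        out = agg.stepwise_aggregate_conditioning(
            G, variants, units, y, None, threshold=1e-5)
        assert len(out) >= 1
        return variants, G, y, units, out

    def test_flags_match_hand_enumeration(self):
        variants, G, y, units, out = self._setup()
        unit_map = {(u.unit_id, u.mask): u for u in units}
        lead = np.array([0, 1])
        sig = np.array([0])
        flagged = agg.flag_single_lead_aggregates(out, units, lead, sig)
        for _, row in flagged.iterrows():
            members = set(
                unit_map[(row["unit_id"], row["mask"])].member_idx.tolist())
            expect = len(members & {0, 1})
            assert row["n_lead_members"] == expect
            assert row["contains_study_wide_single"] == (0 in members)

    def test_empty_extra_set_identical(self):
        variants, G, y, units, out = self._setup()
        res = agg.sensitivity_condition_all_pqtls(
            out, G, variants, units, y, None, np.empty(0, int),
            np.empty(0, int))
        np.testing.assert_allclose(res["p_after"].to_numpy(),
                                   res["p_before"].to_numpy(), rtol=1e-10)

    def test_conditioning_on_lead_absorbs_signal(self):
        rng = np.random.default_rng(5)
        n, m = 2_000, 20
        variants, G = _synthetic_rare_locus(rng, n, m, window_len=4_000)
        # one rare lead variant (largest MAC) drives the aggregate
        driver = int(np.argmax(G.sum(axis=0)))
        y = 3.0 * G[:, driver] + rng.standard_normal(n)
        units = _window_units(variants, 0, 4_000, n)
        out = agg.stepwise_aggregate_conditioning(
            G, variants, units, y, None, threshold=1e-5)
        assert len(out) >= 1
        res = agg.sensitivity_condition_all_pqtls(
            out, G, variants, units, y, None, np.empty(0, int),
            np.array([driver]))
        assert (res["p_after"] > 1e-5).all()
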