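"""The enrichment statistics, each checked against an independent oracle or
a hand-derived closed form."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirten import (
    DEAError,
    GeneSetPair,
    SimTruth,
    TargetCollection,
    adjust_bh,
    run_enrichment,
    simulate_collection,
    simulate_dea,
    compute_signal,
)
from mirten import TestConfig as Cfg
from mirten import enrich as en


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def hypergeom_upper_tail(N, K, n, a):
    """Brute-force P(X >= a), X ~ Hypergeom(N, K, n), by enumeration."""
    denom = math.comb(N, n)
    total = 0
    for x in range(a, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def bh_stepup(p):
    """Independent Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        k = m - rank_from_end  # 1-based rank of p[i]
        running = min(running, p[i] * m / k)
        adj[i] = running
    return adj


def gsea_es_bruteforce(s_ranked_desc, is_target):
    """Direct O(n) running-sum ES with weight exponent 1."""
    w = np.abs(s_ranked_desc)
    nr = w[is_target].sum()
    n_miss = (~is_target).sum()
    running = best = 0.0
    for i in range(len(w)):
        if is_target[i]:
            running += w[i] / nr
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def collection_from_sites(site_map, scores=None, site_types=None, utr=None):
    """Build a TargetCollection from {regulator: {feature: sites}}."""
    rows = []
    for reg, feats in site_map.items():
        for f, n in feats.items():
            rows.append(
                {
                    "regulator": reg,
                    "feature": f,
                    "sites": n,
                    "score": (scores or {}).get((reg, f), np.nan),
                    "site_type": (site_types or {}).get((reg, f)),
                }
            )
    meta = pd.DataFrame(columns=["utr_length"])
    if utr:
        meta = pd.DataFrame(
            {"utr_length": pd.Series(utr, dtype=float)}
        ).rename_axis("feature")
    return TargetCollection(pd.DataFrame(rows), feature_meta=meta)


def row(res, regulator):
    return res.set_index("regulator").loc[regulator]


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------


class TestOverlap:
    def test_known_instance(self):
        # N=20, K=5, n=10, a=5 -> 3003/184756
        universe = [f"G{i}" for i in range(20)]
        tc = collection_from_sites({"m": {f: 1 for f in universe[:5]}})
        # selected = first 10 genes, all 5 targets inside
        sets = GeneSetPair(frozenset(universe[:10]), frozenset(universe))
        res = en.test_overlap(sets, tc)
        assert row(res, "m")["pvalue"] == pytest.approx(3003 / 184756, rel=1e-12)

    def test_zero_hits_gives_p_one(self):
        universe = [f"G{i}" for i in range(10)]
        tc = collection_from_sites({"m": {f: 1 for f in universe[5:]}})
        sets = GeneSetPair(frozenset(universe[:5]), frozenset(universe))
        assert row(en.test_overlap(sets, tc), "m")["pvalue"] == 1.0

    def test_no_targets_in_universe_is_na(self):
        tc = collection_from_sites({"m": {"GX": 1}, "k": {"G0": 1}})
        universe = [f"G{i}" for i in range(4)]
        sets = GeneSetPair(frozenset(universe[:2]), frozenset(universe))
        res = en.test_overlap(sets, tc)
        assert np.isnan(row(res, "m")["pvalue"])
        assert not np.isnan(row(res, "k")["pvalue"])

    def test_matches_enumeration_oracle_randomly(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            N = rng.integers(5, 41)
            K = rng.integers(1, N + 1)
            n = rng.integers(1, N)
            universe = [f"G{i}" for i in range(N)]
            targets = rng.choice(universe, size=K, replace=False)
            selected = rng.choice(universe, size=n, replace=False)
            tc = collection_from_sites({"m": {f: 1 for f in targets}})
            sets = GeneSetPair(frozenset(selected), frozenset(universe))
            a = len(set(selected) & set(targets))
            expected = hypergeom_upper_tail(int(N), int(K), int(n), a)
            got = row(en.test_overlap(sets, tc), "m")["pvalue"]
            assert got == pytest.approx(expected, abs=1e-10)


class TestSiteOverlap:
    def test_hand_enumerated_instance(self):
        # m1: G1x2 G2x1; m2: G1x1 G2x1; selected {G1}: p = 7/10
        tc = collection_from_sites({"m1": {"G1": 2, "G2": 1}, "m2": {"G1": 1, "G2": 1}})
        sets = GeneSetPair(frozenset({"G1"}), frozenset({"G1", "G2"}))
        assert row(en.test_siteoverlap(sets, tc), "m1")["pvalue"] == pytest.approx(7 / 10, rel=1e-12)

    def test_selected_equals_universe_p_one(self):
        tc = collection_from_sites({"m1": {"G1": 2, "G2": 1}, "m2": {"G1": 1}})
        sets = GeneSetPair(frozenset({"G1", "G2"}), frozenset({"G1", "G2"}))
        assert row(en.test_siteoverlap(sets, tc), "m1")["pvalue"] == 1.0

    def test_absent_regulator_na(self):
        tc = collection_from_sites({"m1": {"G1": 1}, "m2": {"GX": 1}})
        sets = GeneSetPair(frozenset({"G1"}), frozenset({"G1", "G2"}))
        assert np.isnan(row(en.test_siteoverlap(sets, tc), "m2")["pvalue"])

    def test_reduces_to_gene_hypergeometric_with_one_site_per_gene(self):
        # when every universe gene carries exactly one site in total, the
        # site-level population coincides with the gene population and the
        # test equals the gene-level hypergeometric
        rng = np.random.default_rng(7)
        universe = [f"G{i}" for i in range(20)]
        targets = rng.choice(universe, size=6, replace=False)
        rest = [f for f in universe if f not in set(targets)]
        selected = rng.choice(universe, size=8, replace=False)
        tc = collection_from_sites(
            {"m": {f: 1 for f in targets}, "other": {f: 1 for f in rest}}
        )
        sets = GeneSetPair(frozenset(selected), frozenset(universe))
        p_site = row(en.test_siteoverlap(sets, tc), "m")["pvalue"]
        a = len(set(selected) & set(targets))
        expected = hypergeom_upper_tail(20, 6, 8, a)
        assert p_site == pytest.approx(expected, rel=1e-12)


class TestWOverlap:
    def test_half_length_all_hits(self):
        # S_m=4, selected holds half the UTR mass, a=4 -> 0.5^4
        utr = {"G1": 1000.0, "G2": 1000.0}
        tc = collection_from_sites({"m": {"G1": 4}}, utr=utr)
        sets = GeneSetPair(frozenset({"G1"}), frozenset({"G1", "G2"}))
        assert row(en.test_woverlap(sets, tc), "m")["pvalue"] == pytest.approx(0.0625, rel=1e-12)

    def test_zero_hits_p_one(self):
        utr = {"G1": 1000.0, "G2": 1000.0}
        tc = collection_from_sites({"m": {"G2": 3}}, utr=utr)
        sets = GeneSetPair(frozenset({"G1"}), frozenset({"G1", "G2"}))
        assert row(en.test_woverlap(sets, tc), "m")["pvalue"] == 1.0

    def test_equal_lengths_reduce_to_binomial(self):
        rng = np.random.default_rng(11)
        universe = [f"G{i}" for i in range(30)]
        utr = {f: 800.0 for f in universe}
        targets = {f: int(k) for f, k in zip(universe[:10], rng.integers(1, 4, 10))}
        tc = collection_from_sites({"m": targets}, utr=utr)
        selected = frozenset(universe[::2])  # 15 of 30
        sets = GeneSetPair(selected, frozenset(universe))
        S_m = sum(targets.values())
        a = sum(v for f, v in targets.items() if f in selected)
        expected = stats.binom.sf(a - 1, S_m, 15 / 30)
        got = row(en.test_woverlap(sets, tc), "m")["pvalue"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_utr_length_names_feature(self):
        from mirten import CollectionError

        tc = collection_from_sites({"m": {"G1": 1}}, utr={"G1": 500.0})
        sets = GeneSetPair(frozenset({"G1"}), frozenset({"G1", "G2"}))
        with pytest.raises(CollectionError, match="utr_length"):
            en.test_woverlap(sets, tc)


class TestRank:
    def sig(self, mapping):
        return pd.Series(mapping, name="signal").rename_axis("feature")

    def test_identical_distributions_p_one(self):
        vals = {"G1": -1.0, "G2": 0.5, "G3": -1.0, "G4": 0.5}
        tc = collection_from_sites({"m": {"G1": 1, "G2": 1}})
        res = en.test_rank(self.sig(vals), tc, "ks")
        assert row(res, "m")["statistic"] == 0.0
        assert row(res, "m")["pvalue"] == 1.0

    def test_mw_exact_small_sample(self):
        vals = {"G1": -3.0, "G2": -2.0, "G3": 1.0, "G4": 2.0}
        tc = collection_from_sites({"m": {"G1": 1, "G2": 1}})
        res = en.test_rank(self.sig(vals), tc, "mw")
        assert row(res, "m")["pvalue"] == pytest.approx(2 / 6, rel=1e-12)
        assert row(res, "m")["statistic"] == -1.0  # perfect separation, targets lower

    def test_single_target_na(self):
        vals = {"G1": -3.0, "G2": 1.0, "G3": 2.0}
        tc = collection_from_sites({"m": {"G1": 1}})
        assert np.isnan(row(en.test_rank(self.sig(vals), tc, "mw"), "m")["pvalue"])


class TestLinreg:
    def test_perfect_fit_hits_floor(self):
        x = {"G1": 1, "G2": 2, "G3": 3, "G4": 4, "G5": 5}
        tc = collection_from_sites({"m": x})
        sig = pd.Series({g: 2.0 * v for g, v in x.items()}).rename_axis("feature")
        r = row(en.test_linreg(sig, tc, "sites"), "m")
        assert r["pvalue"] <= 1e-290

    def test_no_targets_na(self):
        tc = collection_from_sites({"m": {"GX": 1}, "k": {"G1": 1}})
        sig = pd.Series({"G1": 0.1, "G2": -0.2, "G3": 0.3}).rename_axis("feature")
        assert np.isnan(row(en.test_linreg(sig, tc, "sites"), "m")["pvalue"])

    def test_null_calibration(self):
        # independent signal: fraction of p < .05 near nominal
        rng = np.random.default_rng(5)
        feats = [f"G{i}" for i in range(100)]
        tc = collection_from_sites(
            {
                f"m{j}": {f: 1 for f in rng.choice(feats, size=20, replace=False)}
                for j in range(20)
            }
        )
        ps = []
        for _ in range(50):
            sig = pd.Series(rng.normal(size=100), index=pd.Index(feats, name="feature"))
            ps.append(en.test_linreg(sig, tc, "sites")["pvalue"])
        frac = (pd.concat(ps) < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestEbayes:
    def _sim(self, seed=0):
        tc = simulate_collection(500, 20, seed=seed)
        dea = simulate_dea(tc, SimTruth(active={"mir-3": 1.0}, noise_sd=0.3, seed=seed))
        return tc, compute_signal(dea)

    def test_moderation_off_equals_linreg(self):
        tc, sig = self._sim()
        eb = en.test_ebayes(sig, tc, moderate=False)
        lr = en.test_linreg(sig, tc, "score")
        pd.testing.assert_frame_equal(eb, lr)

    def test_moderated_df_is_prior_plus_residual(self):
        tc, sig = self._sim()
        eb = en.test_ebayes(sig, tc)
        d0 = eb.attrs["prior_df"]
        n = 500
        assert eb.attrs["moderated_df"] == pytest.approx(d0 + (n - 2))

    def test_few_regulators_falls_back(self):
        tc = collection_from_sites(
            {"m1": {"G1": 1, "G2": 1}, "m2": {"G2": 1, "G3": 1}},
            scores={("m1", "G1"): -0.5, ("m1", "G2"): -0.2, ("m2", "G2"): -0.3, ("m2", "G3"): -0.4},
        )
        sig = pd.Series({"G1": -1.0, "G2": 0.2, "G3": 0.5, "G4": 0.1}).rename_axis("feature")
        eb = en.test_ebayes(sig, tc)
        lr = en.test_linreg(sig, tc, "score")
        pd.testing.assert_frame_equal(eb, lr)

    def test_true_regulator_top_across_seeds(self):
        hits = 0
        for seed in range(10):
            tc, sig = self._sim(seed)
            eb = en.test_ebayes(sig, tc).dropna(subset=["pvalue"])
            if eb.sort_values("pvalue").iloc[0]["regulator"] == "mir-3":
                hits += 1
        assert hits >= 9


class TestLmadd:
    def test_single_active_final_p_is_marginal(self):
        tc = simulate_collection(500, 12, seed=3)
        dea = simulate_dea(tc, SimTruth(active={"mir-5": 2.0}, noise_sd=0.2, seed=3))
        sig = compute_signal(dea)
        lm = en.test_lmadd(sig, tc, Cfg(alpha_add=1e-4))
        sel = lm[lm["selected"].fillna(False).astype(bool)]
        assert sel["regulator"].tolist() == ["mir-5"]
        marginal = row(en.test_linreg(sig, tc, "score"), "mir-5")["pvalue"]
        assert row(lm, "mir-5")["pvalue"] == pytest.approx(marginal, rel=1e-9)

    def test_identical_twin_never_added(self):
        rng = np.random.default_rng(9)
        feats = [f"G{i}" for i in range(60)]
        targets = {f: 1 for f in feats[:20]}
        scores = {("a", f): -0.5 for f in targets}
        scores.update({("b", f): -0.5 for f in targets})
        tc = collection_from_sites({"a": targets, "b": targets}, scores=scores)
        sig = pd.Series(
            np.where(np.arange(60) < 20, -1.0, 0.0) + rng.normal(0, 0.2, 60),
            index=pd.Index(feats, name="feature"),
        )
        lm = en.test_lmadd(sig, tc)
        assert lm["selected"].fillna(False).astype(bool).sum() <= 1

    def test_selected_subset_and_no_duplicated_columns(self):
        tc = simulate_collection(800, 20, twin_pairs=[("mir-1", "twin", 0.8)], seed=2)
        dea = simulate_dea(tc, SimTruth(active={"mir-1": 1.0}, noise_sd=0.3, seed=2))
        lm = en.test_lmadd(compute_signal(dea), tc)
        sel = set(lm.loc[lm["selected"].fillna(False).astype(bool), "regulator"])
        assert sel <= set(tc.regulators)


class TestAreamir:
    def test_single_target_close_to_quantile(self):
        from scipy.special import ndtri

        n = 2000
        rng = np.random.default_rng(1)
        feats = [f"G{i}" for i in range(n)]
        sig = pd.Series(rng.normal(size=n), index=pd.Index(feats, name="feature"))
        tc = collection_from_sites({"m": {"G5": 1}}, scores={("m", "G5"): -1.0})
        z = row(en.test_areamir(sig, tc), "m")["statistic"]
        rank = stats.rankdata(sig.to_numpy())[5]
        q = ndtri(rank / (n + 1))
        assert z == pytest.approx(q, rel=1e-2)

    def test_permutation_null_unit_variance(self):
        rng = np.random.default_rng(4)
        n = 300
        feats = [f"G{i}" for i in range(n)]
        targets = rng.choice(feats, size=40, replace=False)
        tc = collection_from_sites(
            {"m": {f: 1 for f in targets}},
            scores={("m", f): -float(v) for f, v in zip(targets, rng.uniform(0.1, 1, 40))},
        )
        base = rng.normal(size=n)
        zs = []
        for _ in range(400):
            rng.shuffle(base)
            sig = pd.Series(base.copy(), index=pd.Index(feats, name="feature"))
            zs.append(row(en.test_areamir(sig, tc), "m")["statistic"])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.15
        assert 0.85 <= zs.var() <= 1.15

    def test_bottom_ranks_minimize_z(self):
        # exhaustive over all placements of 3 targets among 10 features
        from itertools import combinations

        feats = [f"G{i}" for i in range(10)]
        sig = pd.Series(np.linspace(-2, 2, 10), index=pd.Index(feats, name="feature"))
        zvals = {}
        for combo in combinations(range(10), 3):
            tc = collection_from_sites(
                {"m": {feats[i]: 1 for i in combo}},
                scores={("m", feats[i]): -0.5 for i in combo},
            )
            zvals[combo] = row(en.test_areamir(sig, tc), "m")["statistic"]
        assert min(zvals, key=zvals.get) == (0, 1, 2)

    def test_all_zero_weights_na(self):
        feats = [f"G{i}" for i in range(12)]
        sig = pd.Series(np.linspace(-1, 1, 12), index=pd.Index(feats, name="feature"))
        tc = collection_from_sites({"m": {"G1": 1}})  # no score -> zero weight
        assert np.isnan(row(en.test_areamir(sig, tc), "m")["statistic"])


class TestRegmir:
    def test_zero_signal_all_p_one(self):
        tc = simulate_collection(300, 10, seed=1)
        feats = tc.feature_meta.index
        sig = pd.Series(0.0, index=feats)
        res = en.test_regmir(sig, tc, Cfg(seed=1))
        testable = res.dropna(subset=["pvalue"])
        assert (testable["pvalue"] == 1.0).all()
        assert not testable["selected"].astype(bool).any()

    def test_perfect_predictor_selected(self):
        rng = np.random.default_rng(2)
        feats = [f"G{i}" for i in range(200)]
        targets = {f: 1 for f in feats[:50]}
        scores = {("m", f): -float(v) for f, v in zip(targets, rng.uniform(0.2, 1, 50))}
        tc = collection_from_sites({"m": targets, "k": {feats[60]: 1}}, scores=scores)
        w = np.zeros(200)
        for i, f in enumerate(feats[:50]):
            w[i] = -scores[("m", f)]
        x = (w - w.mean()) / w.std()
        sig = pd.Series(x, index=pd.Index(feats, name="feature"))
        res = en.test_regmir(sig, tc, Cfg(seed=2))
        assert bool(row(res, "m")["selected"])
        assert row(res, "m")["pvalue"] <= 1e-200

    def test_recovers_single_active(self):
        hits = 0
        for seed in range(10):
            tc = simulate_collection(800, 20, seed=seed)
            dea = simulate_dea(tc, SimTruth(active={"mir-2": 1.0}, noise_sd=0.3, seed=seed))
            res = en.test_regmir(compute_signal(dea), tc, Cfg(seed=seed))
            if bool(row(res, "mir-2")["selected"]):
                hits += 1
        assert hits >= 9


class TestGsea:
    def _toy(self, seed=0, n=20, k=6):
        rng = np.random.default_rng(seed)
        feats = [f"G{i}" for i in range(n)]
        sig = pd.Series(rng.normal(size=n), index=pd.Index(feats, name="feature"))
        targets = rng.choice(feats, size=k, replace=False)
        tc = collection_from_sites({"m": {f: 1 for f in targets}})
        return sig, tc, targets

    def test_top_ranked_targets_give_es_one(self):
        feats = [f"G{i}" for i in range(20)]
        vals = np.linspace(2, -2, 20)  # descending, distinct
        sig = pd.Series(vals, index=pd.Index(feats, name="feature"))
        tc = collection_from_sites({"m": {f: 1 for f in feats[:6]}})
        res = en.test_gsea(sig, tc, Cfg(nperm=100, seed=0))
        assert row(res, "m")["statistic"] == pytest.approx(1.0)

    def test_set_spanning_universe_is_na(self):
        feats = [f"G{i}" for i in range(20)]
        sig = pd.Series(np.linspace(2, -2, 20), index=pd.Index(feats, name="feature"))
        tc = collection_from_sites({"m": {f: 1 for f in feats}})
        assert np.isnan(row(en.test_gsea(sig, tc, Cfg(nperm=100)), "m")["pvalue"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_es_matches_bruteforce_oracle(self, seed):
        sig, tc, targets = self._toy(seed)
        res = en.test_gsea(sig, tc, Cfg(nperm=100, seed=seed))
        order = np.argsort(-sig.to_numpy(), kind="stable")
        is_t = np.isin(np.array(sig.index)[order], targets)
        expected = gsea_es_bruteforce(sig.to_numpy()[order], is_t)
        assert row(res, "m")["statistic"] == pytest.approx(expected, rel=1e-12)
        assert -1.0 <= row(res, "m")["statistic"] <= 1.0

    def test_permutation_p_reproducible(self):
        sig, tc, _ = self._toy(3)
        a = en.test_gsea(sig, tc, Cfg(nperm=200, seed=5))
        b = en.test_gsea(sig, tc, Cfg(nperm=200, seed=5))
        pd.testing.assert_frame_equal(a, b)
        assert row(a, "m")["pvalue"] > 0


class TestAdjustBH:
    def test_hand_examples(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert adjust_bh([0.5]) == pytest.approx([0.5])
        out = adjust_bh([np.nan, 0.05])
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.05)

    def test_matches_stepup_oracle(self):
        from .test_enrich import bh_stepup

        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            assert adjust_bh(p) == pytest.approx(bh_stepup(p), abs=1e-12)


class TestRunEnrichment:
    def test_dispatch_matches_direct_call(self, tiny_collection):
        sets = GeneSetPair(frozenset({"G1"}), frozenset({"G1", "G2", "G3"}))
        via = run_enrichment(sets, tiny_collection, "overlap")
        direct = en.test_overlap(sets, tiny_collection)
        merged = via.set_index("regulator").loc[direct["regulator"]]
        assert merged["pvalue"].to_numpy() == pytest.approx(
            direct["pvalue"].to_numpy(), nan_ok=True
        )
        assert via["fdr"].notna().sum() == via["pvalue"].notna().sum()

    def test_continuous_test_rejects_set_input(self, tiny_collection):
        sets = GeneSetPair(frozenset({"G1"}), frozenset({"G1", "G2", "G3"}))
        with pytest.raises(DEAError, match="continuous signal"):
            run_enrichment(sets, tiny_collection, "gsea")

    def test_rank_test_uses_logfc(self, sim_collection, sim_active):
        dea, _ = sim_active
        via = run_enrichment(dea, sim_collection, "ks")
        lfc = pd.Series(
            dea["logFC"].to_numpy(), index=pd.Index(dea["feature"], name="feature")
        )
        direct = en.test_rank(lfc, sim_collection, "ks")
        a = via.set_index("regulator")["pvalue"]
        b = direct.set_index("regulator")["pvalue"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_unknown_test_name(self, tiny_collection):
        with pytest.raises(ValueError, match="unknown test"):
            run_enrichment(None, tiny_collection, "nope")

    def test_sorted_by_pvalue_na_last(self, sim_collection, sim_active):
        dea, _ = sim_active
        res = run_enrichment(dea, sim_collection, "modscore")
        p = res["pvalue"].to_numpy()
        non_na = p[~np.isnan(p)]
        assert (np.diff(non_na) >= 0).all()
        if np.isnan(p).any():
            assert np.isnan(p[-1])

    def test_pvalues_in_unit_interval(self, sim_collection, sim_active):
        dea, _ = sim_active
        for test in ("overlap", "modscore", "areamir", "mw"):
            res = run_enrichment(
                dea, sim_collection, test, Cfg(seed=0, sel_use="pvalue")
            )
            p = res["pvalue"].dropna()
            assert ((p > 0) & (p <= 1)).all()
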