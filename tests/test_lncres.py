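import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from irlnc import lncres, synth
from irlnc.de import bh_adjust
from irlnc.io import PipelineError


def es_oracle_extremes(rs_sorted, hit_mask, exponent=1.0):
    """Exhaustive running-sum oracle, written independently of the
    implementation: walk the list once, tracking both extremes."""
    rs_sorted = np.asarray(rs_sorted, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = len(rs_sorted)
    nh = int(hit_mask.sum())
    weights = np.abs(rs_sorted) ** exponent
    total = weights[hit_mask].sum()
    running = 0.0
    best_pos, best_neg = 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            running += (weights[i] / total) if total > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh) if n > nh else 0.0
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos, best_neg


def es_oracle(rs_sorted, hit_mask, exponent=1.0):
    best_pos, best_neg = es_oracle_extremes(rs_sorted, hit_mask, exponent)
    return best_pos if best_pos >= -best_neg else best_neg


def assert_es_matches_oracle(es, rs_sorted, hit_mask, exponent=1.0, abs_tol=1e-12):
    """ES equals the oracle extreme; on an exact +/- tie only the magnitude
    is pinned (the implementation documents a prefer-positive tie rule, but
    the oracle's sequential accumulation cannot resolve ties at 1e-12)."""
    best_pos, best_neg = es_oracle_extremes(rs_sorted, hit_mask, exponent)
    if best_pos + best_neg > 1e-9:
        assert es == pytest.approx(best_pos, abs=abs_tol)
    elif best_pos + best_neg < -1e-9:
        assert es == pytest.approx(best_neg, abs=abs_tol)
    else:
        assert abs(es) == pytest.approx(best_pos, abs=max(abs_tol, 1e-9))


def _ranked(rs_values, ids=None):
    ids = ids or [f"g{i}" for i in range(len(rs_values))]
    return lncres.ranked_list("lncX", pd.Series(rs_values, index=ids))


class TestCorrelate:
    def _frames(self, x, y):
        samples = [f"s{i}" for i in range(x.shape[1])]
        return (
            pd.DataFrame(x, index=[f"l{i}" for i in range(x.shape[0])], columns=samples),
            pd.DataFrame(y, index=[f"g{i}" for i in range(y.shape[0])], columns=samples),
        )

    def test_perfect_correlation_clamped(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        lf, mf = self._frames(x, x.copy())
        cc, p = lncres.correlate(lf, mf, p_min=1e-300)
        assert cc.iloc[0, 0] == pytest.approx(1.0)
        assert p.iloc[0, 0] == pytest.approx(1e-300)

    def test_zero_variance_gene(self):
        lf, mf = self._frames(
            np.array([[1.0, 2.0, 3.0, 4.0]]), np.array([[5.0, 5.0, 5.0, 5.0]])
        )
        cc, p = lncres.correlate(lf, mf)
        assert cc.iloc[0, 0] == 0.0
        assert p.iloc[0, 0] == 1.0
        assert lncres.rank_score(cc, p).iloc[0, 0] == 0.0

    def test_matches_closed_form_oracle(self, rng):
        x = rng.normal(size=(1, 5))
        y = rng.normal(size=(1, 5))
        lf, mf = self._frames(x, y)
        cc, p = lncres.correlate(lf, mf)
        r = np.corrcoef(x[0], y[0])[0, 1]
        t = r * np.sqrt(3 / (1 - r ** 2))
        p_direct = 2 * stats.t.sf(abs(t), 3)
        assert cc.iloc[0, 0] == pytest.approx(r, abs=1e-12)
        assert p.iloc[0, 0] == pytest.approx(p_direct, abs=1e-12)

    def test_too_few_samples(self):
        lf, mf = self._frames(np.ones((1, 3)), np.ones((1, 3)))
        with pytest.raises(PipelineError, match=">= 4"):
            lncres.correlate(lf, mf)


class TestRankScore:
    @pytest.mark.parametrize(
        "cc,p,expected",
        [(0.5, 1.0, 0.0), (-0.8, 0.01, -2.0), (0.0, 0.3, 0.0)],
    )
    def test_formula(self, cc, p, expected):
        assert lncres.rank_score(cc, p) == pytest.approx(expected)

    def test_floor_caps_rs(self):
        assert lncres.rank_score(1.0, 0.0, p_min=1e-300) == pytest.approx(300.0)


class TestRankedList:
    def test_descending_with_id_tie_break(self):
        rl = _ranked([1.0, 3.0, 1.0, 2.0], ids=["d", "a", "b", "c"])
        assert list(rl.genes) == ["a", "c", "b", "d"]
        assert (np.diff(rl.rs) <= 0).all()


class TestGseaEs:
    def test_front_loaded_set_positive(self):
        rl = _ranked([5.0, 4.0, 3.0, 1.0, 0.5, 0.2, -1.0, -2.0])
        es = lncres.gsea_es(rl, {"g0", "g1", "g2"})
        assert es > 0
        walk = lncres.running_sum(rl, {"g0", "g1", "g2"})
        assert es == pytest.approx(walk.max())
        assert np.argmax(walk) == 2  # maximal at the last hit

    def test_whole_list_set(self):
        rs = [3.0, 2.0, 1.0, -1.0, -2.0, 1.5, 0.5, -0.5, 0.2, -3.0]
        rl = _ranked(rs)
        full = set(rl.genes)
        es = lncres.gsea_es(rl, full)
        hit = np.ones(len(rs), dtype=bool)
        assert es == pytest.approx(es_oracle(rl.rs, hit))

    def test_hand_computed_example(self):
        # list rs = (3,2,1,-1,-2), set = {rank1, rank3}; hand running sum:
        # w = (3,1), total 4; steps: +3/4, -1/3, +1/4, -1/3, -1/3 -> max 0.75
        rl = _ranked([3.0, 2.0, 1.0, -1.0, -2.0])
        es = lncres.gsea_es(rl, {"g0", "g2"})
        assert es == pytest.approx(0.75)

    def test_empty_intersection_rejected(self):
        rl = _ranked([1.0, 2.0])
        with pytest.raises(PipelineError, match="empty intersection"):
            lncres.gsea_es(rl, {"nope"})

    @settings(max_examples=300, deadline=None)
    @given(st.data())
    def test_matches_oracle_on_short_lists(self, data):
        n = data.draw(st.integers(2, 10))
        rs = data.draw(
            st.lists(
                st.floats(-5, 5, allow_nan=False, allow_infinity=False),
                min_size=n, max_size=n,
            )
        )
        rs = sorted(rs, reverse=True)
        k = data.draw(st.integers(1, n))
        hits = data.draw(st.sets(st.integers(0, n - 1), min_size=k, max_size=k))
        rl = _ranked(rs)
        gene_set = {rl.genes[i] for i in hits}
        mask = np.isin(np.arange(n), list(hits))
        assert_es_matches_oracle(lncres.gsea_es(rl, gene_set), rl.rs, mask)


class TestGseaP:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        rl = _ranked(sorted(rng.normal(size=50), reverse=True))
        gene_set = set(rl.genes[:5])
        es = lncres.gsea_es(rl, gene_set)
        p1 = lncres.gsea_p(rl, gene_set, es, nperm=200, seed=9)
        p2 = lncres.gsea_p(rl, gene_set, es, nperm=200, seed=9)
        assert p1 == p2

    def test_strong_signal_attains_minimum(self):
        rng = np.random.default_rng(1)
        rs = np.concatenate([[50, 45, 40, 38, 35], rng.normal(0, 0.5, 95)])
        rl = _ranked(sorted(rs, reverse=True))
        gene_set = set(rl.genes[:5])
        es = lncres.gsea_es(rl, gene_set)
        nperm = 500
        p = lncres.gsea_p(rl, gene_set, es, nperm=nperm, seed=3)
        # minimum attainable p given the same-sign denominator
        w = np.abs(rl.rs)
        null = lncres.null_es(w, 5, nperm, np.random.default_rng(3))
        assert p == pytest.approx(1.0 / (1.0 + (null > 0).sum()))
        assert p < 0.02

    def test_null_calibration_uniform(self):
        # random sets on a shuffled list: KS test for uniformity of p
        rng = np.random.default_rng(5)
        ps = []
        for i in range(200):
            rs = sorted(rng.normal(size=80), reverse=True)
            rl = _ranked(rs)
            gene_set = set(rng.choice(rl.genes, size=8, replace=False))
            es = lncres.gsea_es(rl, gene_set)
            ps.append(lncres.gsea_p(rl, gene_set, es, nperm=199, seed=1000 + i))
        stat = stats.kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        rs = sorted(rng.normal(size=40), reverse=True)
        rl_a = _ranked(rs, ids=[f"a{i:02d}" for i in range(40)])
        rl_b = _ranked(rs, ids=[f"b{i:02d}" for i in range(40)])
        set_a = set(rl_a.genes[3:9])
        set_b = set(rl_b.genes[3:9])
        es_a = lncres.gsea_es(rl_a, set_a)
        es_b = lncres.gsea_es(rl_b, set_b)
        assert es_a == pytest.approx(es_b)
        assert lncres.gsea_p(rl_a, set_a, es_a, nperm=200, seed=7) == pytest.approx(
            lncres.gsea_p(rl_b, set_b, es_b, nperm=200, seed=7)
        )


class TestLncresTransform:
    @pytest.mark.parametrize(
        "es,p,expected",
        [
            (0.4, 0.0, 1.0),
            (-0.3, 0.5, 0.0),
            (0.4, 0.0025, 0.995),
            (0.0, 0.2, 0.0),
            (-0.4, 0.0, -1.0),
        ],
    )
    def test_values(self, es, p, expected):
        assert lncres.lncres_transform(es, p) == pytest.approx(expected)

    @given(
        st.floats(-1, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_bounds(self, es, p):
        val = lncres.lncres_transform(es, p)
        assert -1.0 <= val <= 1.0
        if es > 0:
            assert np.sign(val) == np.sign(1 - 2 * p) or val == 0

    def test_monotone_in_p(self):
        ps = np.linspace(0, 1, 11)
        pos = [lncres.lncres_transform(0.5, p) for p in ps]
        neg = [lncres.lncres_transform(-0.5, p) for p in ps]
        assert (np.diff(pos) < 0).all()
        assert (np.diff(neg) > 0).all()

    def test_rejects_bad_p(self):
        with pytest.raises(PipelineError):
            lncres.lncres_transform(0.5, 1.5)


def _score_params(**kw):
    defaults = dict(nperm=150, seed=0, min_set_size=3)
    defaults.update(kw)
    return lncres.LncresParams(**defaults)


class TestScoreAll:
    def test_vacuous_filter_flags_everything(self, small_data):
        bundle, sets, _ = small_data
        params = _score_params(lncres_cut=-1.0, fdr_cut=1.1)
        records = lncres.score_all(bundle, sets, params)
        assert records["significant"].all()
        assert len(records) == bundle.lnc.shape[0] * len(sets)

    def test_invariant_to_row_and_sample_order(self, small_data):
        bundle, sets, _ = small_data
        params = _score_params()
        base = lncres.score_all(bundle, sets, params).set_index(["lnc", "set"])

        rng = np.random.default_rng(0)
        mrna_shuffled = bundle.mrna.iloc[rng.permutation(bundle.mrna.shape[0])]
        samples = list(bundle.design.index[::-1])
        other = dataclasses.replace(
            bundle,
            mrna=mrna_shuffled[samples],
            lnc=bundle.lnc[samples],
            design=bundle.design.loc[samples],
        )
        redo = lncres.score_all(other, sets, params).set_index(["lnc", "set"])
        pd.testing.assert_series_equal(base["es"], redo["es"], atol=1e-10, rtol=0)

    def test_gene_label_null_mode(self, small_data):
        bundle, sets, _ = small_data
        params = _score_params(null_model="gene_label", null_pooling="per_lnc")
        records = lncres.score_all(bundle, sets, params)
        assert records["p"].between(0, 1).all()
        assert ((records["fdr"] >= records["p"] - 1e-12) | ~np.isfinite(records["fdr"])).all()

    def test_fdr_is_bh_of_p(self, small_data):
        bundle, sets, _ = small_data
        records = lncres.score_all(bundle, sets, _score_params())
        assert np.allclose(records["fdr"], bh_adjust(records["p"].to_numpy()))


class TestIntersectAndOverlap:
    def test_disjoint(self):
        out = lncres.intersect_with_de({"a", "b"}, {"c"})
        assert out["overlap"] == []
        assert out["n_overlap"] == 0

    def test_subset(self):
        out = lncres.intersect_with_de({"a", "b"}, {"a", "b", "c"})
        assert out["overlap"] == ["a", "b"]

    def test_identical_tables_jaccard_one(self, small_data):
        bundle, sets, _ = small_data
        records = lncres.score_all(bundle, sets, _score_params(lncres_cut=0.0, fdr_cut=1.1))
        out = lncres.overlap_validation(records, records)
        assert out["jaccard"] == 1.0
        assert out["lncres_rank_correlation"] == pytest.approx(1.0)

    def test_disjoint_significant_sets_jaccard_zero(self):
        cols = ["lnc", "set", "category", "size", "es", "p", "lncres", "fdr", "significant"]
        a = pd.DataFrame([["l1", "s1", "c", 5, 0.9, 0.001, 0.998, 0.01, True]], columns=cols)
        b = pd.DataFrame([["l2", "s1", "c", 5, 0.9, 0.001, 0.998, 0.01, True]], columns=cols)
        assert lncres.overlap_validation(a, b)["jaccard"] == 0.0


class TestReplication:
    def test_jaccard_across_replicate_bundles(self):
        cfg = synth.SynthConfig(
            n_normal=5, n_pulpitis=7, n_mrna=600, n_lnc=60,
            n_immune_sets=8, genes_per_set=15, n_planted_lnc=8,
            rho=0.8, de_frac=0.0, noise_sd=0.3, subtype_effect=0.0, seed=21,
        )
        bundle_a, sets, truth = synth.generate_bundle(cfg)
        bundle_b, _, _ = synth.generate_bundle(
            dataclasses.replace(cfg, seed=22), truth=truth
        )
        params = lncres.LncresParams(nperm=300, seed=5)
        rec_a = lncres.score_all(bundle_a, sets, params)
        rec_b = lncres.score_all(bundle_b, sets, params)
        out = lncres.overlap_validation(rec_a, rec_b)
        assert out["jaccard"] >= 0.7
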