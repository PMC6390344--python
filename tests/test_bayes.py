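"""Relationship matrix, repeatability model, record weights, and WGR."""

import numpy as np
import pandas as pd
import pytest

from recombscape.bayes import (
    WGRConfig,
    build_A_matrix,
    call_qtl,
    en_weights,
    fit_repeatability_model,
    fit_wgr,
    lead_snp_refit,
    repeatability_anova,
    single_snp_mixed_model,
    window_variance_partition,
)

from conftest import make_pedigree


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        ped = make_pedigree([(f"f{k}", "0", "0", "M") for k in range(4)])
        _, A = build_A_matrix(ped)
        np.testing.assert_allclose(A, np.eye(4))

    def test_textbook_relationships(self):
        ped = make_pedigree(
            [("s", "0", "0", "M"), ("d", "0", "0", "F"), ("d2", "0", "0", "F"),
             ("a", "s", "d", "M"), ("b", "s", "d", "F"), ("h", "s", "d2", "M")]
        )
        ids, A = build_A_matrix(ped)
        ix = {x: i for i, x in enumerate(ids)}
        assert A[ix["s"], ix["a"]] == pytest.approx(0.5)  # parent-offspring
        assert A[ix["a"], ix["b"]] == pytest.approx(0.5)  # full sibs
        assert A[ix["a"], ix["h"]] == pytest.approx(0.25)  # half sibs

    def test_full_sib_mating_inbreeding(self):
        ped = make_pedigree(
            [("s", "0", "0", "M"), ("d", "0", "0", "F"),
             ("a", "s", "d", "M"), ("b", "s", "d", "F"), ("x", "a", "b", "M")]
        )
        ids, A = build_A_matrix(ped)
        assert A[ids.index("x"), ids.index("x")] == pytest.approx(1.25)

    def test_unknown_subject_rejected(self):
        ped = make_pedigree([("s", "0", "0", "M")])
        with pytest.raises(KeyError):
            build_A_matrix(ped, subjects=["nope"])


class TestEnWeights:
    def test_single_record_weight_is_one(self):
        assert en_weights(0.3, 0.45, [1])[0] == pytest.approx(1.0)

    def test_t_equals_h2_gives_n(self):
        np.testing.assert_allclose(en_weights(0.2, 0.2, [1, 3, 8]), [1, 3, 8])

    def test_layer_parameter_evaluation(self):
        # h2 = 0.17, t = 0.24, n = 4 -> (1-0.17)/((1+3*0.24)/4 - 0.17) = 0.83/0.26
        assert en_weights(0.17, 0.24, [4])[0] == pytest.approx(0.83 / 0.26)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            en_weights(0.6, 0.1, [10])


def _repeat_records(rng, A, ids, s2a, s2p, s2e, sex):
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
    u = L @ rng.normal(0, np.sqrt(s2a), len(A))
    pe = rng.normal(0, np.sqrt(s2p), len(A))
    recs = []
    for i, p in enumerate(ids):
        for _ in range(int(rng.integers(2, 6))):
            recs.append((p, sex[p], u[i] + pe[i] + rng.normal(0, np.sqrt(s2e))))
    return pd.DataFrame(recs, columns=["parent", "sex", "y"])


class TestRepeatabilityModel:
    def _family_structure(self, n_groups=40, sibs=4):
        rows = []
        for f in range(n_groups):
            rows += [(f"S{f}", "0", "0", "M"), (f"D{f}", "0", "0", "F")]
        for f in range(n_groups):
            for k in range(sibs):
                rows.append((f"P{f}_{k}", f"S{f}", f"D{f}", "M" if k % 2 else "F"))
        ped = make_pedigree(rows)
        parents = [i for i in ped["individual"] if i.startswith("P")]
        ids, A = build_A_matrix(ped, parents)
        return ped, ids, A

    def test_null_variances_recovered(self):
        rng = np.random.default_rng(0)
        _, ids, A = self._family_structure(n_groups=60, sibs=5)
        sex = {p: ("M" if p.endswith(("1", "3")) else "F") for p in ids}
        records = _repeat_records(rng, A, ids, 0.0, 0.0, 1.0, sex)
        vc = fit_repeatability_model(records, A, ids, n_iter=1000, burn_in=300, seed=2)
        # positive-support priors keep posterior means slightly above zero
        assert vc.h2 < 0.08
        assert vc.repeatability < 0.13

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        _, ids, A = self._family_structure(n_groups=20)
        sex = {p: "M" for p in ids}
        records = _repeat_records(rng, A, ids, 0.2, 0.1, 0.7, sex)
        vc1 = fit_repeatability_model(records, A, ids, n_iter=400, burn_in=100, seed=3)
        doubled = records.assign(y=2 * records["y"])
        vc2 = fit_repeatability_model(doubled, A, ids, n_iter=400, burn_in=100, seed=3)
        assert vc2.sigma2_a == pytest.approx(4 * vc1.sigma2_a, rel=1e-10)
        assert vc2.h2 == pytest.approx(vc1.h2, rel=1e-10)
        assert vc2.repeatability == pytest.approx(vc1.repeatability, rel=1e-10)

    def test_single_records_unidentifiable(self):
        _, ids, A = self._family_structure(n_groups=5)
        records = pd.DataFrame(
            {"parent": ids[:10], "sex": "M", "y": np.arange(10.0)}
        )
        with pytest.raises(ValueError):
            fit_repeatability_model(records, A[:10, :10], ids[:10])

    def test_anova_cross_checks_gibbs_repeatability(self):
        rng = np.random.default_rng(4)
        _, ids, A = self._family_structure()
        sex = {p: "M" for p in ids}
        records = _repeat_records(rng, A, ids, 0.15, 0.15, 0.7, sex)
        vc = fit_repeatability_model(records, A, ids, n_iter=1200, burn_in=300, seed=5)
        t_mom = repeatability_anova(records)
        assert abs(vc.repeatability - t_mom) < 0.12


def _wgr_data(seed, n=120, m=60, h2=0.5):
    rng = np.random.default_rng(seed)
    M = rng.binomial(2, 0.5, size=(n, m)).astype(float)
    Mc = M - M.mean(axis=0)
    alpha = rng.normal(0, 1, m)
    g = Mc @ alpha
    g *= np.sqrt(h2) / g.std()
    y = g + rng.normal(0, np.sqrt(1 - h2), n)
    return y, M


class TestWGR:
    def test_seeded_runs_bit_reproducible(self):
        y, M = _wgr_data(0)
        cfg = WGRConfig(pi=0.9, chain=400, burn_in=100, seed=7,
                        genetic_variance=0.5, residual_variance=0.5)
        p1 = fit_wgr(y, M, cfg)
        p2 = fit_wgr(y, M, cfg)
        np.testing.assert_array_equal(p1.alpha_samples, p2.alpha_samples)
        np.testing.assert_array_equal(p1.sigma_e_samples, p2.sigma_e_samples)

    def test_pi_one_fits_nothing(self):
        y, M = _wgr_data(1)
        cfg = WGRConfig(pi=1.0, chain=300, burn_in=100, seed=1,
                        genetic_variance=0.5, residual_variance=0.5)
        post = fit_wgr(y, M, cfg)
        assert not post.include_samples.any()
        markers = pd.DataFrame(
            {"marker_id": post.marker_ids, "chromosome": "1",
             "position": np.arange(1, M.shape[1] + 1) * 100_000}
        )
        win = window_variance_partition(post, M, markers)
        assert (win["wppa"] == 0).all()
        assert (win["gv_pct"] == 0).all()

    def test_marker_h2_recovery(self):
        y, M = _wgr_data(2, n=400, m=200)
        cfg = WGRConfig(pi=0.0, chain=2500, burn_in=500, seed=2,
                        genetic_variance=0.5, residual_variance=0.5)
        post = fit_wgr(y, M, cfg)
        h2 = post.marker_h2_samples
        assert abs(h2.mean() - 0.5) < 2.5 * h2.std()

    def test_pure_noise_shrinks_marker_h2(self):
        rng = np.random.default_rng(3)
        M = rng.binomial(2, 0.5, size=(300, 300)).astype(float)
        y = rng.normal(0, 1, 300)
        cfg = WGRConfig(pi=0.99, chain=1500, burn_in=300, seed=3,
                        genetic_variance=0.05, residual_variance=1.0)
        post = fit_wgr(y, M, cfg)
        assert post.marker_h2_samples.mean() < 0.1

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            fit_wgr(np.zeros(10), np.zeros((10, 0)), WGRConfig())


class TestWindowPartition:
    def _markers(self, m, per_window=10):
        return pd.DataFrame(
            {"marker_id": [f"s{j}" for j in range(m)], "chromosome": "1",
             "position": (np.arange(m) // per_window) * 1_000_000
             + (np.arange(m) % per_window) * 50_000 + 1}
        )

    def test_single_causal_marker_takes_all_variance(self):
        rng = np.random.default_rng(4)
        M = rng.binomial(2, 0.5, size=(200, 40)).astype(float)
        y = (M[:, 7] - M[:, 7].mean()) * 2 + rng.normal(0, 0.3, 200)
        cfg = WGRConfig(pi=0.95, chain=1200, burn_in=300, seed=4,
                        genetic_variance=1.0, residual_variance=0.1)
        post = fit_wgr(y, M, cfg)
        win = window_variance_partition(post, M, self._markers(40))
        top = win.loc[win["gv_pct"].idxmax()]
        assert top["window"] == "1:0"
        assert top["gv_pct"] > 90
        assert post.sppi[7] == pytest.approx(post.sppi.max())

    def test_per_sample_shares_sum_to_one(self):
        y, M = _wgr_data(5, n=100, m=40)
        cfg = WGRConfig(pi=0.8, chain=500, burn_in=200, seed=5,
                        genetic_variance=0.5, residual_variance=0.5)
        post = fit_wgr(y, M, cfg)
        markers = self._markers(40)
        win = window_variance_partition(post, M, markers)
        assert win["gv_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        # direct per-sample recomputation
        Mc = M - M.mean(axis=0)
        alpha = post.alpha_samples.astype(float)
        var_w = []
        for wid, grp in markers.groupby(markers["position"] // 1_000_000, sort=True):
            cols = grp.index.to_numpy()
            var_w.append((Mc[:, cols] @ alpha[:, cols].T).var(axis=0))
        var_w = np.array(var_w)
        tot = var_w.sum(axis=0)
        shares = var_w[:, tot > 0] / tot[tot > 0]
        np.testing.assert_allclose(shares.sum(axis=0), 1.0, atol=1e-9)

    def test_wppa_bounds_sppi(self):
        y, M = _wgr_data(6, n=150, m=60)
        cfg = WGRConfig(pi=0.9, chain=800, burn_in=200, seed=6,
                        genetic_variance=0.5, residual_variance=0.5)
        post = fit_wgr(y, M, cfg)
        markers = self._markers(60)
        win = window_variance_partition(post, M, markers)
        sppi = post.sppi
        for _, row in win.iterrows():
            cols = markers.index[(markers["position"] // 1_000_000) * 1_000_000
                                 == row["start"]].to_numpy()
            assert row["wppa"] >= sppi[cols].max() - 1e-12


class TestCallQTL:
    def _results(self, gv, starts=None):
        n = len(gv)
        starts = starts if starts is not None else np.arange(n) * 1_000_000
        return pd.DataFrame(
            {"window": [f"1:{s // 1_000_000}" for s in starts], "chromosome": "1",
             "start": starts, "end": starts + 1_000_000, "n_markers": 5,
             "gv_pct": gv, "gv_pheno_pct": gv, "wppa": 0.5,
             "lead_snp": [f"s{i}" for i in range(n)], "lead_sppi": 0.3}
        )

    def test_single_seed_spans_three_mb(self):
        out = call_qtl(self._results([0.1, 0.1, 1.0, 0.1, 0.1]))
        assert len(out) == 1
        assert out.loc[0, "start"] == 1_000_000 and out.loc[0, "end"] == 4_000_000

    def test_nearby_seeds_merge(self):
        out = call_qtl(self._results([1.0, 0.1, 1.0, 0.1, 0.1]))
        assert len(out) == 1
        assert out.loc[0, "start"] == 0 and out.loc[0, "end"] == 4_000_000

    def test_no_seed_empty(self):
        assert len(call_qtl(self._results([0.1, 0.2, 0.3]))) == 0


class TestSingleSNP:
    def test_reduces_to_ols_under_identity_A(self):
        rng = np.random.default_rng(7)
        n = 80
        snp = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * snp + rng.normal(0, 1, n)
        res = single_snp_mixed_model(y, snp, np.eye(n), 0.3, 0.7)
        X = np.column_stack([np.ones(n), snp])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res["estimate"] == pytest.approx(beta[1], abs=1e-10)

    def test_strong_qtl_is_significant(self):
        rng = np.random.default_rng(8)
        n = 200
        snp = rng.binomial(2, 0.5, n).astype(float)
        y = snp * 1.0 + rng.normal(0, 1, n)
        res = single_snp_mixed_model(y, snp, np.eye(n), 0.2, 0.8)
        assert res["p_value"] < 1e-6


class TestLeadSnpRefit:
    def test_single_marker_panel_explains_everything(self):
        rng = np.random.default_rng(9)
        M = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        y = (M[:, 0] - M[:, 0].mean()) + rng.normal(0, 0.5, 100)
        markers = pd.DataFrame(
            {"marker_id": ["s0"], "chromosome": ["1"], "position": [500_000]}
        )
        cfg = WGRConfig(pi=0.0, chain=600, burn_in=200, seed=9,
                        genetic_variance=0.5, residual_variance=0.25)
        out = lead_snp_refit(
            y, M, markers, "s0",
            {"chromosome": "1", "start": 0, "end": 1_000_000}, cfg,
        )
        assert out["snp_gv_pct"] == pytest.approx(100.0)

    def test_unknown_lead_snp_rejected(self):
        markers = pd.DataFrame(
            {"marker_id": ["s0"], "chromosome": ["1"], "position": [500_000]}
        )
        with pytest.raises(KeyError):
            lead_snp_refit(np.zeros(5), np.zeros((5, 1)), markers, "nope",
                           {"chromosome": "1", "start": 0, "end": 1}, WGRConfig())
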