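import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from microstrata.datatypes import AsvTable
from microstrata.permanova import (
    SCHEME_BLOCKS,
    SCHEME_WITHIN,
    DesignError,
    DistanceMatrix,
    bray_curtis,
    compute_distance,
    euclidean,
    gower_center,
    jaccard_binary,
    permanova,
    run_variance_partition,
)
from microstrata.preprocessing import fourth_root_relabund
from .conftest import make_metadata, sample_row


def oneway_f_oracle(d: np.ndarray, labels: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from the direct pairwise-sum formula
    (independent of the projection-matrix route)."""
    n = len(labels)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    k = 0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        k += 1
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within <= 1e-300:
        return np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def euc(x):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    return euclidean(x, sample_ids=[f"s{i}" for i in range(x.shape[0])])


def simple_meta(labels, participants=None):
    rows = []
    for i, lab in enumerate(labels):
        rows.append(
            {
                "sample_id": f"s{i}",
                "group": lab,
                "participant_id": participants[i] if participants else f"p{i}",
            }
        )
    df = pd.DataFrame(rows)
    df = df.set_index(df["sample_id"])
    df.index.name = None
    return df


class TestDistances:
    def test_bray_curtis_worked_example(self):
        t = AsvTable(["a", "b"], ["x", "y"], [[0.5, 0.5], [0.25, 0.75]],
                     "transformed_relabund")
        d = bray_curtis(t)
        assert d.values[0, 1] == pytest.approx(0.25, abs=1e-15)

    def test_bray_curtis_extremes(self):
        t = AsvTable(["a", "b", "c"], ["x", "y"],
                     [[0.5, 0.5], [0.5, 0.5], [1.0, 0.0]], "transformed_relabund")
        d = bray_curtis(t)
        assert d.values[0, 1] == 0.0
        t2 = AsvTable(["a", "b"], ["x", "y"], [[1.0, 0.0], [0.0, 1.0]],
                      "transformed_relabund")
        assert bray_curtis(t2).values[0, 1] == 1.0

    def test_bray_curtis_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.dirichlet(np.ones(12), size=7)
        t = AsvTable([f"s{i}" for i in range(7)], [f"a{j}" for j in range(12)],
                     x, "transformed_relabund")
        from scipy.spatial.distance import pdist, squareform

        ref = squareform(pdist(x, "braycurtis"))
        np.testing.assert_allclose(bray_curtis(t).values, ref, atol=1e-12)

    def test_jaccard_binary(self):
        t = AsvTable(["a", "b"], ["x", "y", "z", "w"],
                     [[1, 1, 1, 0], [0, 1, 1, 1]])
        assert jaccard_binary(t).values[0, 1] == pytest.approx(0.5)

    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], [[0, 1], [0.5, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], [[0.1, 1], [1, 0]])


class TestGowerCenter:
    def test_zero_distances(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        np.testing.assert_allclose(gower_center(d), 0.0)

    def test_trace_identity_random(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(4, 10)
            x = rng.uniform(size=(n, 5))
            d = euc(x)
            g = gower_center(d)
            expected = (d.values[np.triu_indices(n, 1)] ** 2).sum() / n
            assert np.trace(g) == pytest.approx(expected, rel=1e-10)

    def test_row_sums_zero(self):
        rng = np.random.default_rng(2)
        d = euc(rng.uniform(size=(6, 4)))
        g = gower_center(d)
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-10)


class TestPermanovaCore:
    def perfect_separation(self):
        vals = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        d = DistanceMatrix([f"s{i}" for i in range(4)], vals)
        meta = simple_meta(["A", "A", "B", "B"])
        return d, meta

    def test_perfect_separation_r2_one(self):
        d, meta = self.perfect_separation()
        res = permanova(d, meta, ["group"], n_perm="exact", seed=0)
        assert res.term_map()["group"].r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_p_one_third(self):
        # 6 distinct labelings of 2+2, 2 reach maximal F -> p = 1/3
        d, meta = self.perfect_separation()
        res = permanova(d, meta, ["group"], n_perm="exact", seed=0)
        assert res.term_map()["group"].p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_exact_matches_bruteforce_count(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = 6
            x = rng.uniform(size=(n, 4))
            labels = np.array(["A", "A", "B", "B", "C", "C"])
            d = euc(x)
            res = permanova(d, simple_meta(labels), ["group"], n_perm="exact", seed=0)
            f_obs = oneway_f_oracle(d.values, labels)
            count = 0
            total = 0
            for perm in itertools.permutations(range(n)):
                f_p = oneway_f_oracle(d.values, labels[list(perm)])
                if f_p >= f_obs - 1e-12:
                    count += 1
                total += 1
            assert res.term_map()["group"].p_value == pytest.approx(
                count / total, abs=1e-12
            )
            assert res.term_map()["group"].pseudo_f == pytest.approx(f_obs, rel=1e-10)

    def test_continuous_covariate_matches_ls_oracle(self):
        rng = np.random.default_rng(4)
        n = 6
        x = rng.uniform(size=(n, 3))
        cov = rng.normal(size=n)
        d = euc(x)
        meta = simple_meta(["A"] * n)
        meta["score"] = cov
        res = permanova(d, meta, ["score"], n_perm=99, seed=0)
        g = gower_center(d)
        xmat = np.column_stack([np.ones(n), cov])
        h = xmat @ np.linalg.solve(xmat.T @ xmat, xmat.T)
        # intercept projection contributes nothing (G is double-centered)
        r2_oracle = np.vdot(h, g) / np.trace(g)
        assert res.term_map()["score"].df == 1
        assert res.term_map()["score"].r_squared == pytest.approx(r2_oracle, rel=1e-10)

    def test_one_factor_euclidean_equals_anova(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=12)
        labels = np.repeat(["A", "B", "C"], 4)
        d = euc(y[:, None])
        res = permanova(d, simple_meta(labels), ["group"], n_perm=9, seed=0)
        f_ref = sps.f_oneway(y[:4], y[4:8], y[8:]).statistic
        assert res.term_map()["group"].pseudo_f == pytest.approx(f_ref, abs=1e-10)

    def test_no_variation_in_term_errors(self):
        d = euc(np.random.default_rng(6).uniform(size=(4, 2)))
        meta = simple_meta(["A", "A", "A", "A"])
        with pytest.raises(DesignError, match="no variation"):
            permanova(d, meta, ["group"], n_perm=9)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(7)
        n = 10
        x = rng.uniform(size=(n, 4))
        labels = np.array(list("AABBCCAABB"))
        d = euc(x)
        meta = simple_meta(labels)
        res1 = permanova(d, meta, ["group"], n_perm=49, seed=1)
        perm = rng.permutation(n)
        d2 = DistanceMatrix(
            [d.sample_ids[i] for i in perm], d.values[np.ix_(perm, perm)]
        )
        res2 = permanova(d2, meta, ["group"], n_perm=49, seed=1)
        assert res1.term_map()["group"].r_squared == pytest.approx(
            res2.term_map()["group"].r_squared, rel=1e-10
        )

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        d = euc(rng.uniform(size=(9, 3)))
        meta = simple_meta(list("AAABBBCCC"))
        p1 = permanova(d, meta, ["group"], n_perm=199, seed=5).term_map()["group"].p_value
        p2 = permanova(d, meta, ["group"], n_perm=199, seed=5).term_map()["group"].p_value
        assert p1 == p2

    def test_exact_guard(self):
        rng = np.random.default_rng(9)
        d = euc(rng.uniform(size=(12, 3)))
        meta = simple_meta(list("AABBCCAABBCC"))
        with pytest.raises(ValueError, match="exact enumeration"):
            permanova(d, meta, ["group"], n_perm="exact")

    def test_partition_identities(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(8, 16))
            x = rng.uniform(size=(n, 5))
            d = euc(x)
            meta = simple_meta(rng.choice(["A", "B", "C"], n))
            meta["extra"] = rng.choice(["u", "v"], n)
            res = permanova(d, meta, ["group", "extra"], n_perm=9, seed=0)
            ss_sum = sum(t.ss for t in res.terms) + res.residual_ss
            assert ss_sum == pytest.approx(res.total_ss, abs=1e-9)
            r2_sum = sum(t.r_squared for t in res.terms) + res.residual_r_squared
            assert r2_sum == pytest.approx(1.0, abs=1e-9)


class TestStrata:
    def _blocked_instance(self, seed=0):
        rng = np.random.default_rng(seed)
        # 6 participants x 4 samples; status constant within participant
        rows = []
        x = []
        for i in range(6):
            status = "AD" if i < 3 else "HC"
            base = rng.normal(0, 2, 5)
            for t in range(4):
                rows.append(
                    {
                        "sample_id": f"p{i}t{t}",
                        "participant_id": f"p{i}",
                        "status": status,
                        "visit": str(t % 2),
                    }
                )
                x.append(base + rng.normal(0, 0.5, 5))
        meta = pd.DataFrame(rows)
        meta = meta.set_index(meta["sample_id"])
        meta.index.name = None
        d = euc(np.array(x))
        d = DistanceMatrix([r["sample_id"] for r in rows], d.values)
        return d, meta

    def test_block_constant_factor_uses_block_exchange(self):
        d, meta = self._blocked_instance()
        res = permanova(d, meta, ["status"], n_perm=49, strata="participant_id", seed=0)
        assert res.term_map()["status"].scheme == SCHEME_BLOCKS
        assert any("constant within strata" in w for w in res.warnings)

    def test_varying_factor_uses_within_block(self):
        d, meta = self._blocked_instance()
        res = permanova(d, meta, ["visit"], n_perm=49, strata="participant_id", seed=0)
        assert res.term_map()["visit"].scheme == SCHEME_WITHIN

    def test_within_block_permutations_preserve_blocks(self):
        from microstrata.permanova import _blocks_from_strata, _draw_perm

        d, meta = self._blocked_instance()
        blocks = _blocks_from_strata(meta, "participant_id")
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = _draw_perm(rng, SCHEME_WITHIN, d.n, blocks)
            assert sorted(perm) == list(range(d.n))
            for b in blocks:
                assert set(perm[b]) == set(b)

    def test_block_exchange_moves_whole_blocks(self):
        from microstrata.permanova import _blocks_from_strata, _draw_perm

        d, meta = self._blocked_instance()
        blocks = _blocks_from_strata(meta, "participant_id")
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = _draw_perm(rng, SCHEME_BLOCKS, d.n, blocks)
            assert sorted(perm) == list(range(d.n))
            for b in blocks:
                # the positions of one block receive exactly one other block
                assert any(set(perm[b]) == set(b2) for b2 in blocks)

    def test_exact_within_strata_counts(self):
        # 2 blocks of 2: 2! * 2! = 4 within-block arrangements
        rows = []
        for i in range(4):
            rows.append(
                {
                    "sample_id": f"s{i}",
                    "participant_id": "p0" if i < 2 else "p1",
                    "visit": str(i % 2),
                }
            )
        meta = pd.DataFrame(rows)
        meta = meta.set_index(meta["sample_id"])
        meta.index.name = None
        rng = np.random.default_rng(11)
        d = euc(rng.uniform(size=(4, 3)))
        res = permanova(d, meta, ["visit"], n_perm="exact",
                        strata="participant_id", seed=0)
        p = res.term_map()["visit"].p_value
        assert min(abs(p - v) for v in (0.25, 0.5, 0.75, 1.0)) < 1e-12


class TestAliasing:
    def test_status_after_participant_is_aliased(self):
        rng = np.random.default_rng(12)
        d, meta = TestStrata()._blocked_instance(seed=12)
        res = permanova(d, meta, ["participant_id", "status"], n_perm=9, seed=0)
        term = res.term_map()["status"]
        assert term.aliased and term.df == 0 and term.ss == 0.0

    def test_leading_status_order_keeps_status_testable(self):
        d, meta = TestStrata()._blocked_instance(seed=13)
        res = permanova(d, meta, ["status", "participant_id"], n_perm=9, seed=0)
        term = res.term_map()["status"]
        assert not term.aliased and term.df == 1


class TestVariancePartition:
    def test_suite_on_simulated_study(self, small_study):
        table, meta, tax, _ = small_study
        from microstrata.preprocessing import run_preprocessing

        res = run_preprocessing(table, meta, tax)
        meta_nc = meta.loc[~meta["is_negative_control"]]
        meta_nc = meta_nc.loc[meta_nc["sample_id"].isin(res.counts.sample_ids)]
        suite = run_variance_partition(res.normalized, meta_nc, n_perm=49, seed=0)
        pooled = suite["pooled_hc_nls"].term_map()
        # at this tiny size only the dominant participant effect is reliable;
        # the full depth > status ordering is checked at acceptance scale
        assert pooled["participant_id"].r_squared > 3 * pooled["depth"].r_squared
        assert pooled["participant_id"].r_squared > 3 * pooled["skin_status"].r_squared
        assert pooled["timepoint"].p_value > 0.05
        assert {"status_surface", "status_within"} <= set(suite)
        for name in ("status_surface", "status_within"):
            t = suite[name].term_map()["skin_status"]
            assert t.scheme == SCHEME_BLOCKS
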