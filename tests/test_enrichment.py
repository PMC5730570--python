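from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualrepress.enrichment import (
    EnrichmentInputError,
    RegulatoryNetwork,
    bonferroni_adjust,
    enrich_all,
    fisher_overrepresentation,
    regulator_rng,
    weighted_zscore,
)


def hypergeom_tail_bruteforce(n_universe, n_targets, n_degs, k_obs):
    """P(overlap >= k_obs) by direct enumeration of the hypergeometric pmf."""
    total = comb(n_universe, n_degs)
    return sum(
        comb(n_targets, k) * comb(n_universe - n_targets, n_degs - k)
        for k in range(k_obs, min(n_targets, n_degs) + 1)
    ) / total


def make_universe(n):
    return [f"g{i}" for i in range(n)]


class TestFisher:
    def test_zero_overlap_p_is_one(self):
        uni = set(make_universe(10))
        assert fisher_overrepresentation({"g0", "g1"}, {"g5", "g6"}, uni) == 1.0

    def test_hand_enumerated_example(self):
        # universe 20, targets 8, degs 5, overlap 4 -> 896/15504
        uni = make_universe(20)
        targets = set(uni[:8])
        degs = set(uni[:4]) | {uni[10]}
        p = fisher_overrepresentation(targets, degs, set(uni))
        assert p == pytest.approx(896 / 15504, rel=1e-12)

    def test_targets_equal_universe_forces_p_one(self):
        uni = set(make_universe(12))
        assert fisher_overrepresentation(uni, {"g0", "g3"}, uni) == pytest.approx(1.0)

    def test_empty_universe_raises(self):
        with pytest.raises(EnrichmentInputError):
            fisher_overrepresentation(set(), set(), set())

    def test_degs_outside_universe_raises(self):
        uni = set(make_universe(5))
        with pytest.raises(EnrichmentInputError, match="zz"):
            fisher_overrepresentation({"g0"}, {"zz"}, uni)

    @given(
        n_universe=st.integers(2, 25),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_enumeration(self, n_universe, data):
        n_targets = data.draw(st.integers(0, n_universe))
        n_degs = data.draw(st.integers(0, n_universe))
        k_max = min(n_targets, n_degs)
        k_min = max(0, n_targets + n_degs - n_universe)
        k = data.draw(st.integers(k_min, k_max))
        uni = make_universe(n_universe)
        targets = set(uni[:n_targets])
        # overlap k with targets, remaining degs from outside
        degs = set(uni[:k]) | set(uni[n_targets : n_targets + (n_degs - k)])
        p = fisher_overrepresentation(targets, degs, set(uni))
        expected = hypergeom_tail_bruteforce(n_universe, n_targets, n_degs, k)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_monotone_in_overlap(self):
        n_universe, n_targets, n_degs = 20, 8, 6
        ps = [
            hypergeom_tail_bruteforce(n_universe, n_targets, n_degs, k)
            for k in range(0, min(n_targets, n_degs) + 1)
        ]
        uni = make_universe(n_universe)
        for k, expected in enumerate(ps):
            degs = set(uni[:k]) | set(uni[n_targets : n_targets + n_degs - k])
            p = fisher_overrepresentation(set(uni[:n_targets]), degs, set(uni))
            assert p == pytest.approx(expected, rel=1e-10)
        assert all(ps[i + 1] <= ps[i] for i in range(len(ps) - 1))


class TestBonferroni:
    def test_single_test_unchanged(self):
        adj, sig = bonferroni_adjust([0.03])
        assert adj.tolist() == [0.03]
        assert sig.tolist() == [True]

    def test_two_tests(self):
        adj, sig = bonferroni_adjust([0.001, 0.5])
        assert adj.tolist() == [0.002, 1.0]

    def test_fifteen_regulators_borderline(self):
        adj, sig = bonferroni_adjust([0.004] + [1.0] * 14)
        assert adj[0] == pytest.approx(0.06)
        assert not sig[0]

    def test_invalid_p_rejected(self):
        with pytest.raises(EnrichmentInputError):
            bonferroni_adjust([1.5])


class TestWeightedZscore:
    SCORES = {"g1": 0.9, "g2": 0.5, "g3": 0.4, "g4": 0.2}

    def exhaustive_null(self, scores, k):
        sums = [sum(c) for c in combinations(scores, k)]
        return float(np.mean(sums)), float(np.std(sums))

    def test_worked_example_exhaustive_oracle(self):
        mu, sd = self.exhaustive_null(list(self.SCORES.values()), 2)
        assert mu == pytest.approx(1.0)
        assert sd == pytest.approx(0.29439202887759486)
        assert (1.4 - mu) / sd == pytest.approx(1.3587324409735149)

    def test_resampled_matches_exhaustive_within_mc_error(self):
        n = 100_000
        agg, mu, sd, z, degen = weighted_zscore(
            self.SCORES, {"g1", "g2"}, n_resamples=n, rng=np.random.default_rng(0)
        )
        assert agg == pytest.approx(1.4)
        mu_ex, sd_ex = self.exhaustive_null(list(self.SCORES.values()), 2)
        se_mu = sd_ex / np.sqrt(n)
        assert abs(mu - mu_ex) < 3 * se_mu
        z_ex = (1.4 - mu_ex) / sd_ex
        assert abs(z - z_ex) < 3 * (se_mu / sd_ex) * max(1.0, abs(z_ex))
        assert not degen

    def test_identical_scores_degenerate_z_zero(self):
        scores = {f"g{i}": 1.0 for i in range(6)}
        agg, mu, sd, z, degen = weighted_zscore(
            scores, {"g0", "g1"}, n_resamples=200, rng=np.random.default_rng(1)
        )
        assert z == 0.0
        assert degen

    def test_empty_overlap_raises(self):
        with pytest.raises(EnrichmentInputError, match="overlap"):
            weighted_zscore(self.SCORES, {"nope"}, n_resamples=10)

    def test_affine_invariance(self):
        rng_seed = 7
        scores = {f"g{i}": s for i, s in enumerate([0.11, 0.35, 0.52, 0.78, 0.93])}
        degs = {"g0", "g3"}
        _, _, _, z1, _ = weighted_zscore(
            scores, degs, n_resamples=5000, rng=np.random.default_rng(rng_seed)
        )
        shifted = {g: 0.5 * s + 0.2 for g, s in scores.items()}
        _, _, _, z2, _ = weighted_zscore(
            shifted, degs, n_resamples=5000, rng=np.random.default_rng(rng_seed)
        )
        assert z2 == pytest.approx(z1, rel=1e-9)

    @given(
        k=st.integers(1, 5),
        scores=st.lists(
            st.floats(0.01, 1.0, allow_nan=False), min_size=6, max_size=12, unique=True
        ),
    )
    @settings(max_examples=25, deadline=None)
    def test_resampling_converges_to_enumeration(self, k, scores):
        score_map = {f"g{i}": s for i, s in enumerate(scores)}
        degs = {f"g{i}" for i in range(k)}
        n = 20_000
        _, mu, sd, _, _ = weighted_zscore(
            score_map, degs, n_resamples=n, rng=np.random.default_rng(3)
        )
        mu_ex, sd_ex = self.exhaustive_null(scores, k)
        if sd_ex == 0:
            return
        assert abs(mu - mu_ex) < 4 * sd_ex / np.sqrt(n) + 1e-12


def toy_network():
    rows = []
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(30)]
    for reg in ["R1", "R2", "R3"]:
        targets = rng.choice(genes, size=10, replace=False)
        for g in targets:
            rows.append({"regulator": reg, "gene": g, "score": float(rng.uniform(0.1, 1.0))})
    return RegulatoryNetwork(edges=pd.DataFrame(rows)), set(genes)


class TestEnrichAll:
    def test_one_row_per_regulator(self):
        net, uni = toy_network()
        degs = set(list(uni)[:8])
        res = enrich_all(net, degs, uni, n_resamples=100, master_seed=1)
        assert len(res.table) == 3
        assert list(res.table.index) == ["R1", "R2", "R3"]

    def test_reproducible_to_the_bit(self):
        net, uni = toy_network()
        degs = set(sorted(uni)[:10])
        r1 = enrich_all(net, degs, uni, n_resamples=500, master_seed=42)
        r2 = enrich_all(net, degs, uni, n_resamples=500, master_seed=42)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_substreams_order_independent(self):
        # R1's null must not depend on which other regulators exist
        net, uni = toy_network()
        degs = set(sorted(uni)[:10])
        full = enrich_all(net, degs, uni, n_resamples=300, master_seed=9)
        only_r1 = RegulatoryNetwork(
            edges=net.edges[net.edges["regulator"] == "R1"].reset_index(drop=True)
        )
        solo = enrich_all(only_r1, degs, uni, n_resamples=300, master_seed=9)
        assert solo.table.loc["R1", "z"] == full.table.loc["R1", "z"]

    def test_bonferroni_uses_number_of_regulators(self):
        net, uni = toy_network()
        degs = set(sorted(uni)[:10])
        res = enrich_all(net, degs, uni, n_resamples=100, master_seed=1)
        t = res.table
        for reg in t.index:
            assert t.loc[reg, "p_adj"] == pytest.approx(
                min(1.0, 3 * t.loc[reg, "p_fisher"])
            )

    def test_empty_target_regulator_gets_missing_row(self):
        net, uni = toy_network()
        # regulator whose targets are all outside the universe
        extra = pd.DataFrame(
            [{"regulator": "R9", "gene": "zz", "score": 0.5}]
        )
        net2 = RegulatoryNetwork(edges=pd.concat([net.edges, extra], ignore_index=True))
        res = enrich_all(net2, set(sorted(uni)[:5]), uni, n_resamples=50, master_seed=0)
        row = res.table.loc["R9"]
        assert np.isnan(row["p_fisher"]) and np.isnan(row["z"])
        assert not row["significant"]

    def test_zero_overlap_reported_missing_not_zero(self):
        genes = [f"g{i}" for i in range(10)]
        edges = pd.DataFrame(
            [{"regulator": "R1", "gene": g, "score": 0.5} for g in genes[:4]]
        )
        net = RegulatoryNetwork(edges=edges)
        res = enrich_all(net, set(genes[8:]), set(genes), n_resamples=50, master_seed=0)
        row = res.table.loc["R1"]
        assert row["n_overlap"] == 0
        assert row["aggregate"] == 0.0
        assert np.isnan(row["z"])


class TestNetworkValidation:
    def test_score_out_of_range_rejected(self):
        with pytest.raises(EnrichmentInputError):
            RegulatoryNetwork(
                edges=pd.DataFrame(
                    [{"regulator": "R", "gene": "g", "score": 1.5}]
                )
            )

    def test_zero_score_rejected(self):
        with pytest.raises(EnrichmentInputError):
            RegulatoryNetwork(
                edges=pd.DataFrame([{"regulator": "R", "gene": "g", "score": 0.0}])
            )

    def test_duplicate_edge_rejected(self):
        edges = pd.DataFrame(
            [
                {"regulator": "R", "gene": "g", "score": 0.5},
                {"regulator": "R", "gene": "g", "score": 0.6},
            ]
        )
        with pytest.raises(EnrichmentInputError, match="duplicate"):
            RegulatoryNetwork(edges=edges)


def test_regulator_rng_is_stable():
    a = regulator_rng(5, "regA").random(3)
    b = regulator_rng(5, "regA").random(3)
    c = regulator_rng(5, "regB").random(3)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
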