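"""MARS: GCV arithmetic, forward/backward passes, interaction extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epistasis_dili.data import GenotypeMatrix, PhenotypeVector
from epistasis_dili.mars import (
    MARS,
    DegenerateModelError,
    backward_prune,
    extract_interactions,
    forward_pass,
    gcv_score,
)
from epistasis_dili.simulate import make_epistasis_dataset


def toy(columns, labels):
    gm = GenotypeMatrix.from_frame(pd.DataFrame(columns))
    return gm, PhenotypeVector(np.array(labels))


def null_dataset(seed, n=250, p=25):
    """Hardy-Weinberg genotypes with a phenotype independent of them."""
    rng = np.random.default_rng(seed)
    cols = {}
    for j in range(p):
        maf = rng.uniform(0.1, 0.4)
        cols[f"N{j}"] = rng.choice(
            ["AA", "AG", "GG"], size=n, p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        )
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n // 2, replace=False)] = 1
    return GenotypeMatrix.from_frame(pd.DataFrame(cols)), PhenotypeVector(y)


class TestGCV:
    def test_direct_substitution(self):
        # C = 1 + 3*3 = 10, GCV = 25 / (1 - 10/100)^2 = 30.864
        assert gcv_score(25, 100, 3, 3) == pytest.approx(30.864, abs=5e-4)

    def test_perfect_fit_is_zero(self):
        for k in (0, 1, 5):
            assert gcv_score(0.0, 100, k, 3) == 0.0

    def test_degenerate_denominator_raises(self):
        with pytest.raises(DegenerateModelError):
            gcv_score(1.0, 10, 3, 3)  # C = 10 = N

    @given(
        rss=st.floats(0.1, 100),
        n=st.integers(50, 500),
        k=st.integers(0, 10),
        p=st.floats(1, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_k_at_fixed_rss(self, rss, n, k, p):
        assert gcv_score(rss, n, k + 1, p) > gcv_score(rss, n, k, p)


class TestForwardPass:
    def test_exact_indicator_signal_recovered(self):
        rng = np.random.default_rng(3)
        col = rng.choice(["CC", "CT", "TT"], size=80)
        y = (col == "TT").astype(int)
        m, p = toy({"s": list(col), "z": list(rng.choice(["AA", "AG"], 80))}, list(y))
        model = forward_pass(m, p, max_degree=1)
        assert model.k == 1
        assert model.terms[0][1].snps == ("s",)
        assert model.rss == pytest.approx(0, abs=1e-18)

    def test_planted_pair_enters_as_degree_two_term(self, epistasis_data):
        m, p = epistasis_data
        model = forward_pass(m, p)
        snp_sets = {bf.snps for _, bf in model.terms if bf.degree == 2}
        assert ("SNP4", "SNP9") in snp_sets

    def test_null_data_stops_immediately_most_seeds(self):
        """Pure-noise data: the universal threshold halts the forward pass
        with no terms in >= 90% of seeds."""
        stopped = sum(
            forward_pass(*null_dataset(seed)).k == 0 for seed in range(100)
        )
        assert stopped >= 90

    def test_constant_response_rejected(self):
        m, _ = toy({"s": ["CC", "CT"]}, [0, 1])
        with pytest.raises(ValueError, match="constant"):
            forward_pass(m, PhenotypeVector(np.array([1, 1])))

    def test_additive_signal_yields_no_interactions(self):
        """A purely additive (single-SNP) effect should not induce
        degree-2 terms after pruning in >= 95% of replicates."""
        count = 0
        for seed in range(60):
            rng = np.random.default_rng([seed, 5])
            n = 250
            cols = {}
            for j in range(10):
                maf = rng.uniform(0.2, 0.4)
                cols[f"s{j}"] = rng.choice(
                    ["AA", "AG", "GG"],
                    size=n,
                    p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2],
                )
            risk = 0.15 + 0.55 * (np.array(cols["s0"]) != "AA")
            y = (rng.random(n) < risk).astype(int)
            m, p = toy(cols, list(y))
            res = MARS(m, p).fit()
            count += len(res.interactions) == 0
        assert count >= 0.95 * 60


class TestBackwardPrune:
    def _forced_model(self, epistasis_data, extra_noise_gain=0.0):
        m, p = epistasis_data
        return forward_pass(m, p, stop_gain=extra_noise_gain)

    def test_pruned_gcv_never_above_full_model(self, epistasis_data):
        m, p = epistasis_data
        full = forward_pass(m, p, stop_gain=1.0, max_terms=12)
        pruned = backward_prune(full)
        assert pruned.gcv <= full.gcv + 1e-12

    def test_useless_terms_removed_on_forced_overfit(self):
        """Force the forward pass to over-fit pure noise; the GCV penalty
        must prune the weak terms."""
        for seed in (2, 3, 4):
            m, p = null_dataset(seed, n=100, p=10)
            full = forward_pass(m, p, stop_gain=0.1, max_terms=10)
            assert full.k == 10
            pruned = backward_prune(full)
            assert pruned.k < full.k

    def test_planted_interaction_survives_forced_overfit(self, epistasis_data):
        m, p = epistasis_data
        full = forward_pass(m, p, stop_gain=0.5, max_terms=10)
        pruned = backward_prune(full)
        assert ("SNP4", "SNP9") in {bf.snps for _, bf in pruned.terms}

    def test_equals_exhaustive_best_subset_by_gcv(self):
        """On a small forced model, the deletion path finds the same model
        as exhaustive best-subset-by-GCV enumeration."""
        rng = np.random.default_rng(17)
        n = 120
        cols = {
            f"s{j}": rng.choice(["AA", "AG", "GG"], size=n, p=[0.4, 0.4, 0.2])
            for j in range(6)
        }
        signal = (np.array(cols["s0"]) == "GG").astype(float) - 0.6 * (
            np.array(cols["s1"]) == "AA"
        )
        y = (signal + 0.3 * rng.standard_normal(n) > 0).astype(int)
        m, p = toy({k: list(v) for k, v in cols.items()}, list(y))
        full = forward_pass(m, p, stop_gain=1.0, max_terms=6)
        assert 2 <= full.k <= 6
        pruned = backward_prune(full)

        X, yy = full._X, full._y
        best_gcv, best_set = np.inf, None
        for r in range(full.k + 1):
            for keep in itertools.combinations(range(full.k), r):
                design = np.column_stack([np.ones(n)] + [X[:, i] for i in keep])
                coef, *_ = np.linalg.lstsq(design, yy, rcond=None)
                rss = float(np.sum((yy - design @ coef) ** 2))
                g = gcv_score(rss, n, r, full.penalty_p)
                if g < best_gcv - 1e-12:
                    best_gcv, best_set = g, set(keep)
        kept_bfs = {bf.label() for _, bf in pruned.terms}
        best_bfs = {full.terms[i][1].label() for i in best_set}
        assert kept_bfs == best_bfs
        assert pruned.gcv == pytest.approx(best_gcv, rel=1e-9)


class TestExtractInteractions:
    def test_degree_filter(self, epistasis_data):
        m, p = epistasis_data
        res = MARS(m, p).fit()
        assert all(len(it.snps) >= 2 for it in res.interactions)

    def test_end_to_end_planted_pair(self, epistasis_data):
        m, p = epistasis_data
        res = MARS(m, p).fit()
        assert [it.snps for it in res.interactions] == [("SNP4", "SNP9")]
        # the high-risk combination is the rare-hom x rare-hom corner
        assert res.interactions[0].risk_combination == {
            "SNP4": "TT",
            "SNP9": "CC",
        }
        assert "interactions" in res.summary()

    def test_additive_only_model_gives_empty_list(self):
        rng = np.random.default_rng(9)
        col = rng.choice(["CC", "CT", "TT"], size=100)
        y = (col != "CC").astype(int)
        m, p = toy(
            {"s": list(col), "z": list(rng.choice(["AA", "AG"], 100))}, list(y)
        )
        res = MARS(m, p).fit()
        assert res.interactions == []
        assert {bf.snps for _, bf in res.model.terms} == {("s",)}


def test_whole_fit_deterministic(epistasis_data):
    m, p = epistasis_data
    a = MARS(m, p).fit()
    b = MARS(m, p).fit()
    assert [(c, bf.label()) for c, bf in a.model.terms] == [
        (c, bf.label()) for c, bf in b.model.terms
    ]
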