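"""MDR: cell labeling, cross-validated scoring, exhaustive search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epistasis_dili.data import GenotypeMatrix, PhenotypeVector
from epistasis_dili.mdr import (
    MDR,
    BudgetError,
    StratificationError,
    assign_folds,
    evaluate_model,
    label_cells,
    mdr_search,
)
from epistasis_dili.simulate import default_joint_counts, default_penetrance


def toy_dataset(columns: dict[str, list[str]], labels: list[int]):
    gm = GenotypeMatrix.from_frame(pd.DataFrame(columns))
    return gm, PhenotypeVector(np.array(labels))


def perfect_snp_dataset(n=40):
    """One SNP whose genotype equals the phenotype; one noise SNP."""
    rng = np.random.default_rng(7)
    y = np.tile([0, 1], n // 2)
    snp = np.where(y == 1, "TT", "CC")
    noise = rng.choice(["AA", "AG", "GG"], size=n)
    return toy_dataset({"good": list(snp), "noise": list(noise)}, list(y))


class TestLabelCells:
    def test_ratio_rule_and_tie_goes_high(self):
        m, p = toy_dataset(
            {"s": ["CC", "CC", "CC", "CC", "CT", "CT", "TT", "TT"]},
            [1, 1, 1, 0, 1, 0, 0, 0],
        )
        labels, unobserved = label_cells(m, p, ["s"], threshold=1.0)
        assert labels[("CC",)] == "high"  # 3 cases / 1 control
        assert labels[("CT",)] == "high"  # 1/1 tie -> >= rule
        assert labels[("TT",)] == "low"
        assert unobserved == frozenset()

    def test_zero_control_cell_is_high_and_empty_cell_low_flagged(self):
        m, p = toy_dataset(
            {"s": ["CC", "CC", "CT", "CT", "CT", "TT"]}, [1, 1, 0, 0, 1, 0]
        )
        labels, unobserved = label_cells(m, p, ["s"], threshold=1.0)
        assert labels[("CC",)] == "high"  # cases, no controls
        assert labels[("TT",)] == "low"
        assert unobserved == frozenset()
        # restrict to first four samples: TT becomes unobserved
        m2, p2 = toy_dataset({"s": ["CC", "CC", "CT", "CT"]}, [1, 1, 0, 0])
        labels2, unobserved2 = label_cells(m2, p2, ["s"], threshold=1.0)
        assert labels2.get(("TT",), "low") == "low"

    def test_default_threshold_is_case_control_ratio(self):
        # 2 cases / 6 controls: T = 1/3, so a 1-case/2-control cell is high
        m, p = toy_dataset(
            {"s": ["CC", "CC", "CC", "CT", "CT", "CT", "TT", "TT"]},
            [1, 0, 0, 1, 0, 0, 0, 0],
        )
        labels, _ = label_cells(m, p, ["s"])
        assert labels[("CC",)] == "high" and labels[("CT",)] == "high"
        assert labels[("TT",)] == "low"

    def test_high_risk_cells_match_generator_penetrance(self, epistasis_data):
        """On the planted fixture restricted to the causal pair, the
        high-risk cells are the penetrance cells above the mean case rate."""
        m, p = epistasis_data
        labels, _ = label_cells(m, p, ["SNP4", "SNP9"])
        pen = default_penetrance()
        strings4 = {0: "GG", 1: "GT", 2: "TT"}  # SNP4 alleles (G,T)
        strings9 = {0: "AA", 1: "AC", 2: "CC"}  # SNP9 alleles (A,C)
        for i in range(3):
            for j in range(3):
                if abs(pen[i, j] - 0.5) < 0.02:
                    continue  # near-threshold cells depend on rounding
                want = "high" if pen[i, j] > 0.5 else "low"
                assert labels[(strings4[i], strings9[j])] == want

    def test_no_samples_rejected(self):
        m = GenotypeMatrix.from_frame(pd.DataFrame({"s": []}, dtype=str))
        with pytest.raises(ValueError):
            label_cells(m, PhenotypeVector(np.array([], dtype=int)), ["s"])


class TestEvaluateModel:
    def test_perfect_predictor_has_zero_errors(self):
        m, p = perfect_snp_dataset()
        train, test = evaluate_model(m, p, ["good"], folds=5, seed=0)
        assert train == 0.0 and test == 0.0

    def test_shuffled_phenotype_test_error_near_half(self, epistasis_data):
        m, p = epistasis_data
        rng = np.random.default_rng(1234)
        errs = []
        for _ in range(60):
            y = rng.permutation(p.labels)
            _, te = evaluate_model(
                m, PhenotypeVector(y), ["SNP4", "SNP9"], folds=10, seed=3
            )
            errs.append(te)
        assert abs(np.mean(errs) - 0.5) < 0.03

    def test_planted_pair_beats_every_other_pair(self, epistasis_data):
        """Exhaustive comparison over all 300 pairs."""
        m, p = epistasis_data
        best_other = np.inf
        target = None
        for pair in itertools.combinations(m.snp_ids, 2):
            _, te = evaluate_model(m, p, list(pair), folds=10, seed=5)
            if set(pair) == {"SNP4", "SNP9"}:
                target = te
            else:
                best_other = min(best_other, te)
        assert target < best_other

    def test_single_class_fold_raises(self):
        m, p = toy_dataset({"s": ["CC"] * 6}, [0, 0, 0, 0, 0, 1])
        with pytest.raises(StratificationError):
            assign_folds(p, 2, seed=0)


def naive_mdr_oracle(matrix, phenotype, max_order, folds, seed):
    """Independent re-implementation of the search used as an oracle:
    plain Python loops, explicit dictionaries of cell counts."""
    fold = assign_folds(phenotype, folds, seed)
    y = phenotype.labels
    geno = matrix.genotypes

    def subset_errors(snps):
        keys = geno[list(snps)].apply(tuple, axis=1)
        tr_errs, te_errs = [], []
        for f in range(folds):
            tr = fold != f
            counts = {}
            for k, yy in zip(keys[tr], y[tr]):
                ca, co = counts.get(k, (0, 0))
                counts[k] = (ca + yy, co + (1 - yy))
            thr = y[tr].sum() / (len(y[tr]) - y[tr].sum())
            high = {
                k
                for k, (ca, co) in counts.items()
                if (co == 0 and ca > 0) or (co > 0 and ca / co >= thr)
            }
            tr_errs.append(
                np.mean([(k in high) != bool(yy) for k, yy in zip(keys[tr], y[tr])])
            )
            te_errs.append(
                np.mean(
                    [(k in high) != bool(yy) for k, yy in zip(keys[~tr], y[~tr])]
                )
            )
        return float(np.mean(tr_errs)), float(np.mean(te_errs))

    winners = []
    for order in range(1, max_order + 1):
        scored = [
            (subset_errors(c), tuple(sorted(c)))
            for c in itertools.combinations(matrix.snp_ids, order)
        ]
        tr_best = min(s[0][0] for s in scored)
        best = min(
            (name, errs) for errs, name in scored if errs[0] == tr_best
        )
        winners.append((best[0], best[1]))
    final = min(winners, key=lambda w: (w[1][1], len(w[0]), w[0]))
    return winners, final


class TestMDRSearch:
    def test_recovers_planted_pair(self, epistasis_data):
        m, p = epistasis_data
        res = MDR(m, p, max_order=2, seed=1).fit()
        assert set(res.final.snp_subset) == {"SNP4", "SNP9"}
        assert len(res.per_order) == 2
        assert "MDR search summary" in res.summary()

    def test_perfect_single_snp_wins_over_pairs(self):
        m, p = perfect_snp_dataset()
        _, final = mdr_search(m, p, max_order=2, folds=5, seed=0)
        assert final.snp_subset == ("good",)
        assert final.test_error == 0.0

    def test_final_test_error_minimal_among_orders(self, epistasis_data):
        m, p = epistasis_data
        per_order, final = mdr_search(m, p, max_order=2, seed=2)
        assert final.test_error == min(mm.test_error for mm in per_order)

    def test_matches_naive_oracle_on_toy_data(self):
        """5-SNP toy dataset: search equals a naive brute-force re-scorer."""
        rng = np.random.default_rng(20)
        n = 60
        cols = {
            f"s{i}": list(rng.choice(["AA", "AG", "GG"], size=n)) for i in range(5)
        }
        y = rng.integers(0, 2, size=n)
        # make s1 x s3 weakly informative
        both = (np.array(cols["s1"]) == "AA") & (np.array(cols["s3"]) == "GG")
        y[both] = 1
        m, p = toy_dataset(cols, list(y))
        per_order, final = mdr_search(m, p, max_order=2, folds=5, seed=4)
        oracle_winners, oracle_final = naive_mdr_oracle(
            m, p, max_order=2, folds=5, seed=4
        )
        for mine, (name, errs) in zip(per_order, oracle_winners):
            assert tuple(sorted(mine.snp_subset)) == name
            assert mine.train_error == pytest.approx(errs[0], abs=1e-12)
            assert mine.test_error == pytest.approx(errs[1], abs=1e-12)
        assert tuple(sorted(final.snp_subset)) == oracle_final[0]

    def test_deterministic_given_seed(self, epistasis_data):
        m, p = epistasis_data
        a = mdr_search(m, p, max_order=2, seed=11)[1]
        b = mdr_search(m, p, max_order=2, seed=11)[1]
        assert a == b

    def test_order_one_labels_equal_marginal_grouping_rule(self, epistasis_data):
        """Order-1 MDR labeling is the marginal genotype-grouping rule:
        a category is high-risk iff its contingency-table case/control
        ratio (from the association layer) clears the overall ratio."""
        from epistasis_dili.association import build_table

        m, p = epistasis_data
        ratio = p.n_cases / p.n_controls
        for snp in ("SNP1", "SNP4", "SNP15"):
            labels, _ = label_cells(m, p, [snp])
            for cat in m.categories(snp):
                t = build_table(m, p, {snp: cat})
                want = "high" if (t.a == 0 and t.b > 0) or (
                    t.a > 0 and t.b / t.a >= ratio
                ) else "low"
                assert labels[(cat,)] == want

    def test_budget_error_instructs_prefiltering(self, cohort_data):
        m, p = cohort_data
        with pytest.raises(BudgetError, match="pre-filter"):
            mdr_search(m, p, max_order=3)
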