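"""Random-Forest importance ranking followed by a logistic interaction scan.

A forest of classification trees on additive-coded genotypes (bootstrap
samples, random feature subsets, majority voting) ranks the SNPs by mean
impurity (Gini) decrease.  A logistic regression with the interaction
parameterisation

    log(p / (1 - p)) = b0 + b1*A + b2*B + b3*A*B

is then fitted by maximum likelihood for every pair among the top-ranked
SNPs; the pair with the smallest Wald p-value for b3 is reported when it
passes the significance level (no multiplicity correction is applied
across pairs).  Pairs whose likelihood fails to converge — typically
(quasi-)separated configurations — are skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

from .data import GenotypeMatrix, PhenotypeVector

__all__ = [
    "ImportanceRanking",
    "LogisticInteractionFit",
    "rf_rank",
    "lr_interaction_scan",
    "RandomForestLogistic",
    "RFLRResults",
]


@dataclass(frozen=True)
class ImportanceRanking:
    """SNPs ordered by decreasing importance (ties broken by SNP id)."""

    ranking: tuple[tuple[str, float], ...]
    n_trees: int
    seed: int

    def top(self, k: int) -> list[str]:
        return [snp for snp, _ in self.ranking[:k]]


@dataclass(frozen=True)
class LogisticInteractionFit:
    snp_pair: tuple[str, str]
    coefficients: tuple[float, float, float, float]  # b0, b1, b2, b3
    interaction_p: float

    def __post_init__(self):
        if not 0 <= self.interaction_p <= 1:
            raise ValueError("interaction p-value outside [0, 1]")


def rf_rank(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceRanking:
    """Gini-importance ranking from a random forest on additive codes."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = phenotype.labels
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has a single class")
    codes = matrix.additive()
    if (codes < 0).any():
        raise ValueError("RF ranking requires complete data")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2**31), n_jobs=1
    )
    forest.fit(codes, y)
    scores = forest.feature_importances_
    order = sorted(
        range(matrix.n_snps), key=lambda j: (-scores[j], matrix.snp_ids[j])
    )
    return ImportanceRanking(
        ranking=tuple((matrix.snp_ids[j], float(scores[j])) for j in order),
        n_trees=n_trees,
        seed=seed,
    )


def _fit_pair(
    codes: np.ndarray, y: np.ndarray, i: int, j: int
) -> tuple[np.ndarray, np.ndarray] | None:
    a = codes[:, i].astype(float)
    b = codes[:, j].astype(float)
    X = np.column_stack([np.ones(len(y)), a, b, a * b])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return None
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged or not np.all(np.isfinite(res.bse)) or np.any(
        np.abs(res.params) > 50
    ):
        return None
    return res.params, res.pvalues


def lr_interaction_scan(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    top_snps: list[str],
    alpha: float = 0.05,
) -> LogisticInteractionFit | None:
    """Fit the interaction logistic model for every pair among ``top_snps``
    and return the pair with the smallest interaction (b3) Wald p-value if
    it is below ``alpha``, else None."""
    if len(top_snps) < 2:
        raise ValueError("need at least two SNPs to scan")
    codes = matrix.additive(list(top_snps))
    if (codes < 0).any():
        raise ValueError("interaction scan requires complete data")
    y = phenotype.labels
    best: LogisticInteractionFit | None = None
    for i, j in combinations(range(len(top_snps)), 2):
        fit = _fit_pair(codes, y, i, j)
        if fit is None:
            warnings.warn(
                f"logistic fit for ({top_snps[i]}, {top_snps[j]}) did not "
                "converge (possible separation); pair skipped"
            )
            continue
        params, pvals = fit
        p3 = float(pvals[3])
        if not np.isfinite(p3):
            continue
        if best is None or p3 < best.interaction_p:
            best = LogisticInteractionFit(
                snp_pair=(top_snps[i], top_snps[j]),
                coefficients=tuple(float(v) for v in params),
                interaction_p=p3,
            )
    if best is not None and best.interaction_p < alpha:
        return best
    return None


class RFLRResults:
    def __init__(
        self,
        ranking: ImportanceRanking,
        top_snps: list[str],
        best_fit: LogisticInteractionFit | None,
        alpha: float,
    ):
        self.ranking = ranking
        self.top_snps = top_snps
        self.best_fit = best_fit
        self.alpha = alpha

    def summary(self) -> str:
        lines = [
            "Random Forest + logistic regression summary",
            f"forest: {self.ranking.n_trees} trees; top {len(self.top_snps)} "
            f"SNPs carried to the interaction scan: {', '.join(self.top_snps)}",
        ]
        if self.best_fit is None:
            lines.append(
                f"no pair reached the interaction significance level "
                f"alpha={self.alpha:g}"
            )
        else:
            b0, b1, b2, b3 = self.best_fit.coefficients
            lines.append(
                f"best pair {self.best_fit.snp_pair[0]} x "
                f"{self.best_fit.snp_pair[1]}: b3 = {b3:+.3f} "
                f"(Wald p = {self.best_fit.interaction_p:.3g})"
            )
            lines.append(
                f"log-odds = {b0:+.3f} {b1:+.3f}*A {b2:+.3f}*B {b3:+.3f}*A*B"
            )
        return "\n".join(lines)


class RandomForestLogistic:
    """Model-object interface: RF ranking then pairwise logistic scan."""

    def __init__(
        self,
        matrix: GenotypeMatrix,
        phenotype: PhenotypeVector,
        n_trees: int = 500,
        top_k: int = 5,
        alpha: float = 0.05,
        seed: int = 0,
    ):
        self.matrix = matrix
        self.phenotype = phenotype
        self.n_trees = n_trees
        self.top_k = top_k
        self.alpha = alpha
        self.seed = seed

    def fit(self) -> RFLRResults:
        ranking = rf_rank(self.matrix, self.phenotype, self.n_trees, self.seed)
        top = ranking.top(self.top_k)
        best = lr_interaction_scan(self.matrix, self.phenotype, top, self.alpha)
        return RFLRResults(ranking, top, best, self.alpha)
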