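"""Multifactor Dimensionality Reduction (MDR).

MDR collapses an n-locus genotype model to one dimension: every observed
multilocus genotype cell is labeled *high-risk* when its case/control
ratio reaches a threshold T (default: the case/control ratio of the
training data, which reduces to 1 on balanced designs), otherwise
*low-risk*; the resulting binary classifier is scored by stratified
cross-validation.  For each order n, the subset of n SNPs minimizing the
average training classification error is kept, and among these per-order
winners the model minimizing the average prediction (testing) error is
the final one.  Cross-validation consistency — in how many folds the
winning subset is also that fold's best — is reported and used to break
ties.

The exhaustive search is vectorised over SNP subsets; it refuses to run
past a configurable evaluation budget (subsets x folds), in which case a
marginal pre-filter should be applied first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .data import GenotypeMatrix, PhenotypeVector

__all__ = [
    "MDR",
    "MDRModel",
    "MDRResults",
    "label_cells",
    "evaluate_model",
    "mdr_search",
    "assign_folds",
    "BudgetError",
    "StratificationError",
]

DEFAULT_BUDGET = 5_000_000


class BudgetError(RuntimeError):
    """The exhaustive search would exceed the evaluation budget."""


class StratificationError(ValueError):
    """Folds cannot contain both phenotype classes."""


@dataclass(frozen=True)
class MDRModel:
    snp_subset: tuple[str, ...]
    cell_labels: dict[tuple[str, ...], str]
    unobserved: frozenset[tuple[str, ...]]
    train_error: float
    test_error: float
    cv_consistency: int
    folds: int


def assign_folds(phenotype: PhenotypeVector, folds: int, seed: int) -> np.ndarray:
    """Stratified fold ids: class proportions preserved per fold."""
    y = phenotype.labels
    for cls in (0, 1):
        if (y == cls).sum() < folds:
            raise StratificationError(
                f"class {cls} has fewer than {folds} members; every training "
                "fold must contain both classes"
            )
    rng = np.random.default_rng([seed, 55])
    fold = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % folds
    return fold


def _complete_codes(matrix: GenotypeMatrix, snps: list[str]) -> np.ndarray:
    codes = matrix.additive(snps)
    if (codes < 0).any():
        raise ValueError(
            "MDR requires complete data; drop incomplete samples first"
        )
    return codes


def label_cells(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    snp_subset: list[str],
    threshold: float | None = None,
) -> tuple[dict[tuple[str, ...], str], frozenset]:
    """High/low-risk label per multilocus genotype cell.

    A cell is high-risk iff cases/controls >= T (cells with cases but no
    controls are high-risk); cells with no observations are low-risk and
    returned in the ``unobserved`` set.  T defaults to the overall
    case/control ratio of the data.
    """
    if matrix.n_samples == 0:
        raise ValueError("no samples")
    y = phenotype.labels
    if threshold is None:
        n_ctrl = (y == 0).sum()
        threshold = (y == 1).sum() / n_ctrl if n_ctrl else np.inf
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    codes = _complete_codes(matrix, list(snp_subset))
    cats = []
    for snp in snp_subset:
        major, minor = matrix.allele_map[snp]
        from .data import canonical_genotype

        if minor is None:
            cats.append([major * 2])
        else:
            cats.append([major * 2, canonical_genotype(major + minor), minor * 2])
    labels: dict[tuple[str, ...], str] = {}
    unobserved = set()
    for combo_codes in itertools.product(*[range(len(c)) for c in cats]):
        mask = np.all(codes == np.array(combo_codes), axis=1)
        key = tuple(cats[k][c] for k, c in enumerate(combo_codes))
        ca, co = int(y[mask].sum()), int(mask.sum() - y[mask].sum())
        if ca == 0 and co == 0:
            labels[key] = "low"
            unobserved.add(key)
        elif co == 0:
            labels[key] = "high"
        else:
            labels[key] = "high" if ca / co >= threshold else "low"
    return labels, frozenset(unobserved)


def _score_subsets(
    codes: np.ndarray,
    y: np.ndarray,
    subsets: np.ndarray,
    fold: np.ndarray,
    folds: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold train/test misclassification for many subsets at once.

    Returns (train_err, test_err), each of shape (n_subsets, folds).
    """
    n_sub, order = subsets.shape
    ncell = 3**order
    weights = 3 ** np.arange(order)
    cells = codes[:, subsets.reshape(-1)].reshape(len(y), n_sub, order) @ weights
    cells = cells + ncell * np.arange(n_sub)[None, :]
    tr_err = np.zeros((n_sub, folds))
    te_err = np.zeros((n_sub, folds))
    for f in range(folds):
        tr = fold != f
        ca = np.bincount(cells[tr & (y == 1)].ravel(), minlength=ncell * n_sub)
        co = np.bincount(cells[tr & (y == 0)].ravel(), minlength=ncell * n_sub)
        thr = (y[tr] == 1).sum() / (y[tr] == 0).sum()
        high = ((co == 0) & (ca > 0)) | ((co > 0) & (ca >= thr * co))
        pred_tr = high[cells[tr]]
        tr_err[:, f] = np.mean(pred_tr != (y[tr] == 1)[:, None], axis=0)
        pred_te = high[cells[~tr]]
        te_err[:, f] = np.mean(pred_te != (y[~tr] == 1)[:, None], axis=0)
    return tr_err, te_err


def evaluate_model(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    snp_subset: list[str],
    folds: int = 10,
    seed: int = 0,
    fold_ids: np.ndarray | None = None,
) -> tuple[float, float]:
    """Average train/test misclassification of one SNP subset under
    stratified cross-validation (labels learned per training fold)."""
    fold = assign_folds(phenotype, folds, seed) if fold_ids is None else fold_ids
    codes = _complete_codes(matrix, list(snp_subset))
    subs = np.arange(len(snp_subset))[None, :]
    tr, te = _score_subsets(codes, phenotype.labels, subs, fold, folds)
    return float(tr.mean()), float(te.mean())


def mdr_search(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    max_order: int = 2,
    folds: int = 10,
    seed: int = 0,
    budget: int = DEFAULT_BUDGET,
    candidate_snps: list[str] | None = None,
    chunk: int = 8192,
) -> tuple[list[MDRModel], MDRModel]:
    """Exhaustive MDR search.

    Returns the per-order winners (each the subset of its size minimizing
    average training error) and the final model (the per-order winner with
    the smallest average prediction error; ties broken by higher CV
    consistency, then smaller order, then SNP ids).
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    snps = list(candidate_snps) if candidate_snps is not None else list(matrix.snp_ids)
    p = len(snps)
    evaluations = sum(comb(p, n) for n in range(1, min(max_order, p) + 1)) * folds
    if evaluations > budget:
        raise BudgetError(
            f"{evaluations:,} subset-fold evaluations exceed the budget of "
            f"{budget:,}; pre-filter the SNPs (e.g. top-m by marginal Fisher p) "
            "or lower max_order"
        )
    fold = assign_folds(phenotype, folds, seed)
    codes = _complete_codes(matrix, snps)
    y = phenotype.labels

    per_order: list[MDRModel] = []
    for order in range(1, min(max_order, p) + 1):
        combos = np.array(list(itertools.combinations(range(p), order)))
        tr_parts, te_parts = [], []
        for start in range(0, len(combos), chunk):
            tr, te = _score_subsets(
                codes, y, combos[start : start + chunk], fold, folds
            )
            tr_parts.append(tr)
            te_parts.append(te)
        tr_err = np.vstack(tr_parts)
        te_err = np.vstack(te_parts)
        mean_tr = tr_err.mean(axis=1)
        names = [tuple(sorted(snps[i] for i in c)) for c in combos]
        best = min(range(len(combos)), key=lambda i: (mean_tr[i], names[i]))
        fold_best = tr_err.min(axis=0)
        consistency = int(np.sum(np.isclose(tr_err[best], fold_best)))
        labels, unobserved = label_cells(
            matrix.subset_snps([snps[i] for i in combos[best]]),
            phenotype,
            [snps[i] for i in combos[best]],
        )
        per_order.append(
            MDRModel(
                snp_subset=tuple(snps[i] for i in combos[best]),
                cell_labels=labels,
                unobserved=unobserved,
                train_error=float(mean_tr[best]),
                test_error=float(te_err[best].mean()),
                cv_consistency=consistency,
                folds=folds,
            )
        )
    final = min(
        per_order,
        key=lambda m: (
            m.test_error,
            -m.cv_consistency,
            len(m.snp_subset),
            tuple(sorted(m.snp_subset)),
        ),
    )
    return per_order, final


class MDRResults:
    """Fitted MDR search: per-order winners and the selected final model."""

    def __init__(self, per_order: list[MDRModel], final: MDRModel):
        self.per_order = per_order
        self.final = final

    def summary(self) -> str:
        lines = [
            "MDR search summary",
            f"{'order':>5s} {'snps':<40s} {'train_err':>9s} {'test_err':>9s} {'cv':>3s}",
        ]
        for m in self.per_order:
            mark = " *" if m is self.final else ""
            lines.append(
                f"{len(m.snp_subset):>5d} {'+'.join(m.snp_subset):<40s} "
                f"{m.train_error:9.4f} {m.test_error:9.4f} "
                f"{m.cv_consistency:>2d}/{m.folds}{mark}"
            )
        lines.append("* final model (minimum average prediction error)")
        return "\n".join(lines)


class MDR:
    """Model-object interface to the exhaustive MDR search."""

    def __init__(
        self,
        matrix: GenotypeMatrix,
        phenotype: PhenotypeVector,
        max_order: int = 2,
        folds: int = 10,
        seed: int = 0,
        budget: int = DEFAULT_BUDGET,
        candidate_snps: list[str] | None = None,
    ):
        self.matrix = matrix
        self.phenotype = phenotype
        self.max_order = max_order
        self.folds = folds
        self.seed = seed
        self.budget = budget
        self.candidate_snps = candidate_snps

    def fit(self) -> MDRResults:
        per_order, final = mdr_search(
            self.matrix,
            self.phenotype,
            max_order=self.max_order,
            folds=self.folds,
            seed=self.seed,
            budget=self.budget,
            candidate_snps=self.candidate_snps,
        )
        return MDRResults(per_order, final)
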