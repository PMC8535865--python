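"""End-to-end interaction-discovery workflow.

The pipeline mirrors the published analysis design: run the three
detectors (MARS, MDR, RF-LR), convert each detector's finding into an
interaction candidate (SNP set + high-risk genotype combination + 2x2
association), keep only candidates whose combined-genotype odds ratio
strictly exceeds the marginal odds ratio of *every* constituent SNP,
pool the SNPs of the surviving interactions, fit a CART decision tree on
genotype-category indicators, and evaluate it by stratified k-fold
cross-validation with chronic (case) as the positive class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from . import association as assoc
from .data import GenotypeMatrix, PhenotypeVector
from .mars import MARS
from .mdr import MDR, BudgetError
from .rf_lr import RandomForestLogistic

__all__ = [
    "InteractionCandidate",
    "CVMetrics",
    "DecisionTreeModel",
    "PipelineConfig",
    "ChronicityPipeline",
    "PipelineResults",
    "run_detectors",
    "select_improved",
    "pool_snps",
    "fit_tree",
    "stratified_cv",
    "marginal_prefilter",
]


@dataclass(frozen=True)
class InteractionCandidate:
    detector: str  # "MARS" | "MDR" | "RF-LR"
    snp_set: tuple[str, ...]
    risk_combination: dict[str, str]
    association: assoc.AssociationResult

    def __post_init__(self):
        if set(self.risk_combination) != set(self.snp_set):
            raise ValueError(
                "risk combination must assign exactly one genotype per SNP"
            )


@dataclass(frozen=True)
class CVMetrics:
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2


@dataclass
class DecisionTreeModel:
    """CART on genotype-category indicator splits.

    Each internal node tests one SNP against a genotype-category subset;
    the ``match`` branch collects samples whose genotype lies in the
    subset.  Leaves carry the predicted class and per-class counts.
    """

    features: list[str]
    estimator: DecisionTreeClassifier
    structure: dict
    indicator_columns: list[tuple[str, str]]  # (snp, category) per column

    def predict(self, matrix: GenotypeMatrix) -> np.ndarray:
        X = _indicator_matrix(matrix, self.indicator_columns)
        return self.estimator.predict(X)


def _indicator_matrix(
    matrix: GenotypeMatrix, columns: list[tuple[str, str]]
) -> np.ndarray:
    out = np.zeros((matrix.n_samples, len(columns)))
    for j, (snp, cat) in enumerate(columns):
        out[:, j] = (matrix.genotypes[snp] == cat).to_numpy(dtype=float)
    return out


def _export_structure(
    est: DecisionTreeClassifier,
    columns: list[tuple[str, str]],
    all_cats: dict[str, list[str]],
) -> dict:
    tree = est.tree_

    def node(i: int) -> dict:
        v = np.asarray(tree.value[i][0], dtype=float)
        # sklearn stores normalized class fractions per node; recover counts
        if abs(v.sum() - 1.0) < 1e-9:
            v = v * tree.weighted_n_node_samples[i]
        by_class = dict(zip(est.classes_, v))
        n_ctrl, n_case = float(by_class.get(0, 0.0)), float(by_class.get(1, 0.0))
        if tree.children_left[i] == -1:
            cls = int(np.argmax(v))
            label = "chronic" if (est.classes_[cls] == 1) else "acute"
            return {
                "leaf": True,
                "class": label,
                "n_acute": round(n_ctrl),
                "n_chronic": round(n_case),
            }
        snp, cat = columns[tree.feature[i]]
        return {
            "leaf": False,
            "snp": snp,
            "genotypes": [cat],
            "other_genotypes": [c for c in all_cats[snp] if c != cat],
            # sklearn sends indicator <= 0.5 left; the right child matches
            "match": node(tree.children_right[i]),
            "other": node(tree.children_left[i]),
        }

    return node(0)


def fit_tree(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    features: list[str],
    min_leaf: int = 3,
    ccp_alpha: float = 0.01,
    seed: int = 0,
) -> DecisionTreeModel:
    """CART with Gini impurity on genotype-category indicator splits."""
    if not features:
        raise ValueError("feature list is empty")
    columns = [
        (snp, cat) for snp in features for cat in matrix.categories(snp)
    ]
    X = _indicator_matrix(matrix, columns)
    est = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_leaf,
        ccp_alpha=ccp_alpha,
        random_state=int(seed) % (2**31),
    )
    est.fit(X, phenotype.labels)
    all_cats = {snp: matrix.categories(snp) for snp in features}
    return DecisionTreeModel(
        features=list(features),
        estimator=est,
        structure=_export_structure(est, columns, all_cats),
        indicator_columns=columns,
    )


def stratified_cv(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    features: list[str],
    folds: int = 5,
    seed: int = 0,
    min_leaf: int = 3,
    ccp_alpha: float = 0.01,
) -> CVMetrics:
    """Stratified k-fold CV of the CART model; a tree is refit per fold and
    the confusion counts are pooled before computing the metrics
    (chronic = positive class)."""
    y = phenotype.labels
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        raise ValueError("a class is too small to stratify into the folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    tp = tn = fp = fn = 0
    idx = np.arange(len(y))
    for f, (tr, te) in enumerate(skf.split(idx, y)):
        sub_tr = _subset_samples(matrix, tr)
        sub_te = _subset_samples(matrix, te)
        tree = fit_tree(
            sub_tr,
            PhenotypeVector(y[tr]),
            features,
            min_leaf=min_leaf,
            ccp_alpha=ccp_alpha,
            seed=seed + f,
        )
        pred = tree.predict(sub_te)
        truth = y[te]
        tp += int(((pred == 1) & (truth == 1)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
    total = tp + tn + fp + fn
    return CVMetrics(
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        accuracy=(tp + tn) / total,
    )


def _subset_samples(matrix: GenotypeMatrix, rows: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        sample_ids=[matrix.sample_ids[i] for i in rows],
        snp_ids=list(matrix.snp_ids),
        genotypes=matrix.genotypes.iloc[rows],
        allele_map=dict(matrix.allele_map),
        missing_code=matrix.missing_code,
    )


def marginal_prefilter(
    matrix: GenotypeMatrix, phenotype: PhenotypeVector, top_m: int
) -> list[str]:
    """Top-m SNPs by their best single-genotype Fisher exact p-value."""
    scores = []
    for snp in matrix.snp_ids:
        best = 1.0
        for cat in matrix.categories(snp):
            table = assoc.build_table(matrix, phenotype, {snp: cat})
            best = min(best, assoc.fisher_exact_two_sided(table))
        scores.append((best, snp))
    scores.sort(key=lambda t: (t[0], t[1]))
    return [snp for _, snp in scores[:top_m]]


@dataclass
class PipelineConfig:
    detectors: tuple[str, ...] = ("MARS", "MDR", "RF-LR")
    # MARS
    mars_max_terms: int = 30
    mars_max_degree: int = 2
    mars_penalty: float | None = None
    mars_stop_margin: float = 6.0
    mars_stop_gain: float | None = None
    mars_min_support: int = 10
    # MDR
    mdr_max_order: int = 3
    mdr_folds: int = 10
    mdr_prefilter_top: int | None = None
    # RF-LR
    rf_trees: int = 500
    rf_top_k: int = 5
    lr_alpha: float = 0.05
    # decision tree + CV
    tree_min_leaf: int = 3
    tree_ccp_alpha: float = 0.01
    cv_folds: int = 5
    seed: int = 0


def _mdr_risk_cell(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    model,
) -> dict[str, str]:
    """Highest-OR high-risk multilocus cell of the final MDR model."""
    best_cell, best_or = None, -np.inf
    for cell, label in sorted(model.cell_labels.items()):
        if label != "high" or cell in model.unobserved:
            continue
        grouping = dict(zip(model.snp_subset, cell))
        table = assoc.build_table(matrix, phenotype, grouping)
        if table.b + table.a == 0:
            continue
        value = assoc.odds_ratio(table)
        if value > best_or:
            best_or, best_cell = value, cell
    if best_cell is None:
        raise RuntimeError("MDR final model has no observed high-risk cell")
    return dict(zip(model.snp_subset, best_cell))


def _rflr_risk_cell(
    matrix: GenotypeMatrix, fit
) -> dict[str, str]:
    """Genotype cell maximizing the fitted log-odds of the pair model."""
    (s1, s2) = fit.snp_pair
    b0, b1, b2, b3 = fit.coefficients
    best, best_val = None, -np.inf
    for c1 in matrix.categories(s1):
        for c2 in matrix.categories(s2):
            a = matrix.genotype_code(s1, c1)
            b = matrix.genotype_code(s2, c2)
            val = b0 + b1 * a + b2 * b + b3 * a * b
            if val > best_val + 1e-12:
                best_val, best = val, {s1: c1, s2: c2}
    return best


def run_detectors(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    config: PipelineConfig | None = None,
) -> list[InteractionCandidate]:
    """Run the enabled detectors; each contributes at most one candidate.

    A failing detector is skipped with a warning and the pipeline
    continues with the remaining ones.
    """
    config = config or PipelineConfig()
    candidates: list[InteractionCandidate] = []

    if "MARS" in config.detectors:
        try:
            res = MARS(
                matrix,
                phenotype,
                max_terms=config.mars_max_terms,
                max_degree=config.mars_max_degree,
                penalty=config.mars_penalty,
                stop_margin=config.mars_stop_margin,
                stop_gain=config.mars_stop_gain,
                min_support=config.mars_min_support,
            ).fit()
            if res.interactions:
                top = res.interactions[0]
                table = assoc.build_table(matrix, phenotype, top.risk_combination)
                candidates.append(
                    InteractionCandidate(
                        detector="MARS",
                        snp_set=top.snps,
                        risk_combination=top.risk_combination,
                        association=assoc.associate(table),
                    )
                )
        except Exception as exc:  # noqa: BLE001 - detector isolation
            warnings.warn(f"MARS detector failed: {exc}")

    if "MDR" in config.detectors:
        try:
            candidate_snps = None
            if config.mdr_prefilter_top is not None:
                candidate_snps = marginal_prefilter(
                    matrix, phenotype, config.mdr_prefilter_top
                )
            res = MDR(
                matrix,
                phenotype,
                max_order=config.mdr_max_order,
                folds=config.mdr_folds,
                seed=config.seed + 1,
                candidate_snps=candidate_snps,
            ).fit()
            final = res.final
            if len(final.snp_subset) >= 2:
                combo = _mdr_risk_cell(matrix, phenotype, final)
                table = assoc.build_table(matrix, phenotype, combo)
                candidates.append(
                    InteractionCandidate(
                        detector="MDR",
                        snp_set=tuple(final.snp_subset),
                        risk_combination=combo,
                        association=assoc.associate(table),
                    )
                )
        except BudgetError as exc:
            warnings.warn(
                f"MDR detector skipped: {exc}"
            )
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"MDR detector failed: {exc}")

    if "RF-LR" in config.detectors:
        try:
            res = RandomForestLogistic(
                matrix,
                phenotype,
                n_trees=config.rf_trees,
                top_k=config.rf_top_k,
                alpha=config.lr_alpha,
                seed=config.seed + 2,
            ).fit()
            if res.best_fit is not None:
                combo = _rflr_risk_cell(matrix, res.best_fit)
                table = assoc.build_table(matrix, phenotype, combo)
                candidates.append(
                    InteractionCandidate(
                        detector="RF-LR",
                        snp_set=tuple(sorted(res.best_fit.snp_pair)),
                        risk_combination=combo,
                        association=assoc.associate(table),
                    )
                )
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"RF-LR detector failed: {exc}")

    return candidates


def marginal_best_or(
    matrix: GenotypeMatrix, phenotype: PhenotypeVector, snp: str
) -> tuple[float, str]:
    """Largest single-genotype odds ratio of one SNP (the per-SNP exposed
    grouping a contingency table would report)."""
    best_or, best_cat = -np.inf, None
    for cat in matrix.categories(snp):
        table = assoc.build_table(matrix, phenotype, {snp: cat})
        value = assoc.odds_ratio(table)
        if value > best_or:
            best_or, best_cat = value, cat
    return best_or, best_cat


def select_improved(
    candidates: list[InteractionCandidate],
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
) -> tuple[list[InteractionCandidate], list[tuple[InteractionCandidate, str]]]:
    """Keep candidates whose combined-genotype OR strictly exceeds every
    constituent SNP's best marginal OR.  Returns (kept, dropped+reason)."""
    kept, dropped = [], []
    for cand in candidates:
        cand_or = cand.association.odds_ratio
        verdict = None
        for snp in cand.snp_set:
            marg, cat = marginal_best_or(matrix, phenotype, snp)
            if cand_or <= marg:
                verdict = (
                    f"combined OR {cand_or:.2f} does not exceed marginal OR "
                    f"{marg:.2f} of {snp}={cat}"
                )
                break
        if verdict is None:
            kept.append(cand)
        else:
            dropped.append((cand, verdict))
    return kept, dropped


def pool_snps(selected: list[InteractionCandidate]) -> list[str]:
    """Union of the selected SNP sets: candidate order, then lexicographic
    within a set, de-duplicated."""
    out: list[str] = []
    for cand in selected:
        for snp in sorted(cand.snp_set):
            if snp not in out:
                out.append(snp)
    return out


class PipelineResults:
    def __init__(
        self,
        candidates,
        kept,
        dropped,
        pooled_snps,
        tree: DecisionTreeModel | None,
        cv_metrics: CVMetrics | None,
    ):
        self.candidates = candidates
        self.kept = kept
        self.dropped = dropped
        self.pooled_snps = pooled_snps
        self.tree = tree
        self.cv_metrics = cv_metrics

    def summary(self) -> str:
        from ._util import fmt_pct

        lines = ["SNP-SNP interaction pipeline summary", "", "detector candidates:"]
        if not self.candidates:
            lines.append("  (none)")
        for cand in self.candidates:
            res = cand.association
            combo = " and ".join(
                f"{s}={cand.risk_combination[s]}" for s in cand.snp_set
            )
            lines.append(
                f"  {cand.detector:5s} {' + '.join(cand.snp_set)} [{combo}] "
                f"OR={res.odds_ratio:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f}, "
                f"Fisher p={res.p_value:.3g})"
            )
        lines.append("")
        lines.append(
            "kept after the interaction-beats-marginals filter: "
            + (", ".join("+".join(c.snp_set) for c in self.kept) or "(none)")
        )
        for cand, reason in self.dropped:
            lines.append(f"  dropped {cand.detector} candidate: {reason}")
        lines.append(f"pooled predictor SNPs: {', '.join(self.pooled_snps) or '(none)'}")
        if self.cv_metrics is not None:
            m = self.cv_metrics
            lines.append(
                "decision-tree stratified CV: "
                f"sensitivity {fmt_pct(m.sensitivity)}, "
                f"specificity {fmt_pct(m.specificity)}, "
                f"accuracy {fmt_pct(m.accuracy)}, "
                f"balanced accuracy {fmt_pct(m.balanced_accuracy)}"
            )
        return "\n".join(lines)


class ChronicityPipeline:
    """Detector ensemble -> OR filter -> SNP pool -> CART -> stratified CV."""

    def __init__(
        self,
        matrix: GenotypeMatrix,
        phenotype: PhenotypeVector,
        config: PipelineConfig | None = None,
    ):
        self.matrix = matrix
        self.phenotype = phenotype
        self.config = config or PipelineConfig()

    def fit(self) -> PipelineResults:
        cfg = self.config
        candidates = run_detectors(self.matrix, self.phenotype, cfg)
        kept, dropped = select_improved(candidates, self.matrix, self.phenotype)
        pooled = pool_snps(kept)
        tree = cv = None
        if pooled:
            tree = fit_tree(
                self.matrix,
                self.phenotype,
                pooled,
                min_leaf=cfg.tree_min_leaf,
                ccp_alpha=cfg.tree_ccp_alpha,
                seed=cfg.seed + 3,
            )
            cv = stratified_cv(
                self.matrix,
                self.phenotype,
                pooled,
                folds=cfg.cv_folds,
                seed=cfg.seed + 4,
                min_leaf=cfg.tree_min_leaf,
                ccp_alpha=cfg.tree_ccp_alpha,
            )
        return PipelineResults(candidates, kept, dropped, pooled, tree, cv)
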