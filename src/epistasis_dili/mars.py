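"""Multivariate adaptive regression splines, specialised for genotypes.

The model is a least-squares expansion f(x) = c0 + sum_i Ci * Bi(x) whose
basis functions Bi are products of *atoms*, at most one atom per SNP:

* indicator atoms — 1 when a SNP's genotype lies in a category set
  (each observed category, plus the pooled non-wild-type "carrier" set);
* optional hinge atoms — max(0, x - t) / max(0, t - x) on the additive
  0/1/2 coding, with knots restricted to the observed codes.

The forward pass greedily adds the candidate basis function with the
largest residual-sum-of-squares reduction.  Candidates are single atoms,
direct products of two atoms from different SNPs, and (above degree 2)
products of an in-model basis function with a new atom.  Admitting
two-atom products directly is essential for genotype interaction
screening: a pure epistatic signal has *no* marginal component, so the
classical parent-in-model rule could never reach it.  The pass stops when
the best reduction falls below a universal screening threshold
sigma^2 * (2 ln C + margin) for C candidates — i.e. the gain demanded of
a term scales with the multiplicity of the search space — or when
``max_terms`` is reached.

The backward pass deletes one basis function at a time, refitting at
every step, and returns the model along the deletion path with the
lowest generalized cross-validation score

    GCV = RSS / (1 - C/N)^2,      C = 1 + p*k,

where k is the number of basis functions, p the penalty per function and
N the number of observations.  (This GCV form carries no 1/N prefactor;
the factor is constant for a given dataset and does not affect model
selection.)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, PhenotypeVector

__all__ = [
    "IndicatorAtom",
    "HingeAtom",
    "BasisFunction",
    "MARSModel",
    "Interaction",
    "MARS",
    "MARSResults",
    "gcv_score",
    "forward_pass",
    "backward_prune",
    "extract_interactions",
    "DegenerateModelError",
]


class DegenerateModelError(ValueError):
    """GCV denominator is non-positive (effective parameters C >= N)."""


def gcv_score(rss: float, n_obs: int, k: int, penalty: float) -> float:
    """Generalized cross-validation score RSS / (1 - C/N)^2 with C = 1 + p*k."""
    if rss < 0:
        raise ValueError("negative residual sum of squares")
    c = 1 + penalty * k
    if c >= n_obs:
        raise DegenerateModelError(
            f"effective parameter count C={c} reaches N={n_obs}"
        )
    return rss / (1 - c / n_obs) ** 2


@dataclass(frozen=True)
class IndicatorAtom:
    snp: str
    categories: frozenset[str]

    def evaluate(self, matrix: GenotypeMatrix) -> np.ndarray:
        col = matrix.genotypes[self.snp].to_numpy()
        return np.isin(col, sorted(self.categories)).astype(float)

    def evaluate_genotype(self, genotype: str) -> float:
        return float(genotype in self.categories)

    def label(self) -> str:
        return f"{self.snp}∈{{{','.join(sorted(self.categories))}}}"


@dataclass(frozen=True)
class HingeAtom:
    snp: str
    knot: float
    direction: int  # +1: max(0, x - t); -1: max(0, t - x)

    def evaluate(self, matrix: GenotypeMatrix) -> np.ndarray:
        x = matrix.additive([self.snp])[:, 0].astype(float)
        return np.maximum(0.0, self.direction * (x - self.knot))

    def evaluate_genotype(self, genotype: str, matrix: GenotypeMatrix) -> float:
        x = matrix.genotype_code(self.snp, genotype)
        return max(0.0, self.direction * (x - self.knot))

    def label(self) -> str:
        if self.direction > 0:
            return f"max(0,{self.snp}-{self.knot:g})"
        return f"max(0,{self.knot:g}-{self.snp})"


@dataclass(frozen=True)
class BasisFunction:
    """Product of atoms over distinct SNPs; degree = number of SNPs."""

    factors: tuple

    def __post_init__(self):
        snps = [a.snp for a in self.factors]
        if len(set(snps)) != len(snps):
            raise ValueError("a SNP may appear at most once per basis function")

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def snps(self) -> tuple[str, ...]:
        return tuple(sorted(a.snp for a in self.factors))

    def evaluate(self, matrix: GenotypeMatrix) -> np.ndarray:
        out = np.ones(matrix.n_samples)
        for atom in self.factors:
            out = out * atom.evaluate(matrix)
        return out

    def evaluate_combo(self, combo: dict[str, str], matrix: GenotypeMatrix) -> float:
        out = 1.0
        for atom in self.factors:
            if isinstance(atom, IndicatorAtom):
                out *= atom.evaluate_genotype(combo[atom.snp])
            else:
                out *= atom.evaluate_genotype(combo[atom.snp], matrix)
        return out

    def label(self) -> str:
        return " * ".join(a.label() for a in self.factors)


@dataclass
class MARSModel:
    intercept: float
    terms: list  # (coefficient, BasisFunction)
    penalty_p: float
    gcv: float
    rss: float
    N: int
    _matrix: GenotypeMatrix = field(repr=False)
    _y: np.ndarray = field(repr=False)
    _X: np.ndarray = field(repr=False)  # basis columns, no intercept

    @property
    def k(self) -> int:
        return len(self.terms)

    def predict(self, matrix: GenotypeMatrix | None = None) -> np.ndarray:
        if matrix is None or matrix is self._matrix:
            if self.k == 0:
                return np.full(self.N, self.intercept)
            coefs = np.array([c for c, _ in self.terms])
            return self.intercept + self._X @ coefs
        out = np.full(matrix.n_samples, self.intercept)
        for coef, bf in self.terms:
            out += coef * bf.evaluate(matrix)
        return out


def build_atoms(
    matrix: GenotypeMatrix, include_hinges: bool = False
) -> list:
    """Candidate atoms: per-category indicators, the carrier (non-wild-type)
    pool for three-category SNPs, and optional hinge atoms on the additive
    coding.  Atoms whose columns duplicate an earlier atom of the same SNP
    are dropped."""
    atoms = []
    for snp in matrix.snp_ids:
        cats = matrix.categories(snp)
        seen = set()
        per_snp = [IndicatorAtom(snp, frozenset({c})) for c in cats]
        if len(cats) > 2:
            major = matrix.allele_map[snp][0] * 2
            carrier = frozenset(c for c in cats if c != major)
            per_snp.append(IndicatorAtom(snp, carrier))
        if include_hinges:
            per_snp += [
                HingeAtom(snp, 0.0, +1),
                HingeAtom(snp, 1.0, +1),
                HingeAtom(snp, 1.0, -1),
                HingeAtom(snp, 2.0, -1),
            ]
        for atom in per_snp:
            key = atom.evaluate(matrix).tobytes()
            if key not in seen:
                seen.add(key)
                atoms.append(atom)
    return atoms


def _forward_threshold(
    rss: float, n: int, ncols: int, n_candidates: int, margin: float
) -> float:
    sigma2 = rss / max(n - ncols, 1)
    return sigma2 * (2 * np.log(max(n_candidates, 2)) + margin)


def forward_pass(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    max_terms: int = 30,
    max_degree: int = 2,
    penalty: float | None = None,
    stop_margin: float = 6.0,
    stop_gain: float | None = None,
    include_hinges: bool = False,
    min_support: int = 10,
) -> MARSModel:
    """Greedy forward construction of the basis expansion (unpruned).

    ``stop_gain`` fixes an absolute RSS-gain floor; when ``None`` the
    universal threshold sigma^2 (2 ln C + stop_margin) is used.
    ``min_support`` rejects candidate basis functions that are nonzero on
    fewer observations (a term supported by a handful of samples is an
    artefact, the analogue of MARS minspan / CART minimum leaf size).
    """
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    y = phenotype.labels.astype(float)
    n = len(y)
    if n != matrix.n_samples:
        raise ValueError("phenotype not aligned with genotype matrix")
    if np.all(y == y[0]):
        raise ValueError("constant response: nothing to fit")
    if penalty is None:
        penalty = 3.0 if max_degree >= 2 else 2.0

    atoms = build_atoms(matrix, include_hinges)
    A = np.column_stack([a.evaluate(matrix) for a in atoms])
    snp_idx = np.array([matrix.snp_ids.index(a.snp) for a in atoms])
    m = len(atoms)
    same_snp = snp_idx[:, None] == snp_idx[None, :]
    pair_sq = (A * A).T @ (A * A)  # |u.v|^2 for all atom pairs
    nonzero = (A > 0).astype(float)
    support1 = nonzero.sum(axis=0)
    support2 = nonzero.T @ nonzero  # samples where both atoms are active

    terms: list[BasisFunction] = []
    cols: list[np.ndarray] = []
    design = np.ones((n, 1))
    q_mat = design / np.sqrt(n)
    resid = y - y.mean()
    rss = float(resid @ resid)
    gain_floor = 1e-8 * rss  # numerical floor against near-perfect fits

    while len(terms) < max_terms:
        qta = q_mat.T @ A  # k x m
        # --- degree-1 candidates
        num1 = A.T @ resid
        den1 = (A * A).sum(axis=0) - (qta**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            red1 = np.where(den1 > 1e-9, num1**2 / den1, 0.0)
        red1[support1 < min_support] = 0.0
        n_cand = m
        best_gain = float(np.max(red1)) if m else 0.0
        best_choice = ("atom", int(np.argmax(red1))) if m else None

        # --- degree-2 candidates: direct products of two atoms
        if max_degree >= 2:
            num2 = (A * resid[:, None]).T @ A
            den2 = pair_sq.copy()
            for qcol in q_mat.T:
                g = (A * qcol[:, None]).T @ A
                den2 -= g * g
            with np.errstate(divide="ignore", invalid="ignore"):
                red2 = np.where(den2 > 1e-9, num2**2 / den2, 0.0)
            red2[same_snp] = 0.0
            red2[support2 < min_support] = 0.0
            iu = np.triu_indices(m, k=1)
            n_cand += len(iu[0])
            i2 = int(np.argmax(red2[iu]))
            if red2[iu][i2] > best_gain:
                best_gain = float(red2[iu][i2])
                best_choice = ("pair", int(iu[0][i2]), int(iu[1][i2]))

        # --- higher-degree candidates: in-model parent x new atom
        if max_degree >= 3:
            for t_idx, bf in enumerate(terms):
                if not (2 <= bf.degree < max_degree):
                    continue
                parent_col = cols[t_idx]
                V = parent_col[:, None] * A
                numv = V.T @ resid
                denv = (V * V).sum(axis=0) - ((q_mat.T @ V) ** 2).sum(axis=0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    redv = np.where(denv > 1e-9, numv**2 / denv, 0.0)
                used = np.isin([a.snp for a in atoms], bf.snps)
                redv[used] = 0.0
                redv[(V > 0).sum(axis=0) < min_support] = 0.0
                n_cand += int((~used).sum())
                j = int(np.argmax(redv))
                if redv[j] > best_gain:
                    best_gain = float(redv[j])
                    best_choice = ("extend", t_idx, j)

        if stop_gain is not None:
            threshold = stop_gain
        else:
            threshold = _forward_threshold(
                rss, n, design.shape[1], n_cand, stop_margin
            )
        if best_choice is None or best_gain <= max(threshold, gain_floor):
            break

        if best_choice[0] == "atom":
            bf = BasisFunction((atoms[best_choice[1]],))
        elif best_choice[0] == "pair":
            bf = BasisFunction((atoms[best_choice[1]], atoms[best_choice[2]]))
        else:
            parent = terms[best_choice[1]]
            bf = BasisFunction(parent.factors + (atoms[best_choice[2]],))
        col = bf.evaluate(matrix)
        terms.append(bf)
        cols.append(col)
        design = np.column_stack([design, col])
        q_mat, _ = np.linalg.qr(design)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        rss = float(resid @ resid)

    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted_rss = float(np.sum((y - design @ coef) ** 2))
    X = design[:, 1:]
    return MARSModel(
        intercept=float(coef[0]),
        terms=[(float(c), bf) for c, bf in zip(coef[1:], terms)],
        penalty_p=penalty,
        gcv=gcv_score(fitted_rss, n, len(terms), penalty),
        rss=fitted_rss,
        N=n,
        _matrix=matrix,
        _y=y,
        _X=X,
    )


def _refit(X: np.ndarray, y: np.ndarray, keep: list[int]) -> tuple[np.ndarray, float]:
    design = np.column_stack([np.ones(len(y))] + [X[:, i] for i in keep])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    return coef, rss


def backward_prune(model: MARSModel) -> MARSModel:
    """One-at-a-time backward deletion; returns the model along the
    deletion path (full model included) with the lowest GCV, refit."""
    X, y = model._X, model._y
    n = model.N
    current = list(range(model.k))
    best_keep = list(current)
    _, rss = _refit(X, y, current)
    best_gcv = gcv_score(rss, n, len(current), model.penalty_p)
    while current:
        options = []
        for drop in current:
            keep = [i for i in current if i != drop]
            _, rss_k = _refit(X, y, keep)
            options.append((gcv_score(rss_k, n, len(keep), model.penalty_p), keep))
        gcv_k, keep = min(options, key=lambda t: (t[0], len(t[1])))
        current = keep
        if gcv_k <= best_gcv:
            best_gcv, best_keep = gcv_k, list(keep)
    coef, rss = _refit(X, y, best_keep)
    return MARSModel(
        intercept=float(coef[0]),
        terms=[
            (float(c), model.terms[i][1]) for c, i in zip(coef[1:], best_keep)
        ],
        penalty_p=model.penalty_p,
        gcv=best_gcv,
        rss=rss,
        N=n,
        _matrix=model._matrix,
        _y=y,
        _X=X[:, best_keep] if best_keep else X[:, :0],
    )


@dataclass(frozen=True)
class Interaction:
    snps: tuple[str, ...]
    risk_combination: dict[str, str]
    contribution: float  # RSS increase if the set's terms are dropped

    def label(self) -> str:
        combo = " and ".join(f"{s}={self.risk_combination[s]}" for s in self.snps)
        return f"{' + '.join(self.snps)} [{combo}]"


def extract_interactions(model: MARSModel) -> list[Interaction]:
    """Distinct SNP sets of degree >= 2 terms, ordered by their RSS
    contribution (increase in RSS when all of the set's terms are removed).

    The risk combination is the genotype assignment over the set's SNPs
    that maximizes the terms' total contribution to the predicted risk;
    for indicator products with positive coefficients this is simply the
    indicated categories.
    """
    matrix = model._matrix
    groups: dict[tuple[str, ...], list[int]] = {}
    for idx, (_, bf) in enumerate(model.terms):
        if bf.degree >= 2:
            groups.setdefault(bf.snps, []).append(idx)
    out = []
    all_idx = list(range(model.k))
    _, rss_full = _refit(model._X, model._y, all_idx)
    for snps, idxs in groups.items():
        keep = [i for i in all_idx if i not in idxs]
        _, rss_wo = _refit(model._X, model._y, keep)
        contribution = rss_wo - rss_full
        cat_lists = [matrix.categories(s) for s in snps]
        best_combo, best_val = None, -np.inf
        for combo_vals in itertools.product(*cat_lists):
            combo = dict(zip(snps, combo_vals))
            val = sum(
                coef * bf.evaluate_combo(combo, matrix)
                for i in idxs
                for coef, bf in [model.terms[i]]
            )
            if val > best_val + 1e-12:
                best_val, best_combo = val, combo
        out.append(Interaction(snps, best_combo, float(contribution)))
    out.sort(key=lambda it: (-it.contribution, it.snps))
    return out


class MARSResults:
    """Fitted MARS model: pruned expansion plus extracted interactions."""

    def __init__(self, model: MARSModel, unpruned: MARSModel):
        self.model = model
        self.unpruned = unpruned
        self.interactions = extract_interactions(model)

    def summary(self) -> str:
        lines = [
            "MARS model summary",
            f"N = {self.model.N}, basis functions = {self.model.k} "
            f"(forward pass: {self.unpruned.k}), penalty p = {self.model.penalty_p:g}",
            f"RSS = {self.model.rss:.4f}, GCV = {self.model.gcv:.4f}",
            f"intercept = {self.model.intercept:+.4f}",
        ]
        for coef, bf in self.model.terms:
            lines.append(f"  {coef:+.4f} * {bf.label()}")
        if self.interactions:
            lines.append("interactions (by RSS contribution):")
            for it in self.interactions:
                lines.append(f"  {it.label()}  (ΔRSS={it.contribution:.3f})")
        else:
            lines.append("no degree->=2 interactions retained")
        return "\n".join(lines)


class MARS:
    """Model-object interface: forward pass then GCV backward pruning."""

    def __init__(
        self,
        matrix: GenotypeMatrix,
        phenotype: PhenotypeVector,
        max_terms: int = 30,
        max_degree: int = 2,
        penalty: float | None = None,
        stop_margin: float = 6.0,
        stop_gain: float | None = None,
        include_hinges: bool = False,
        min_support: int = 10,
    ):
        self.matrix = matrix
        self.phenotype = phenotype
        self.params = dict(
            max_terms=max_terms,
            max_degree=max_degree,
            penalty=penalty,
            stop_margin=stop_margin,
            stop_gain=stop_gain,
            include_hinges=include_hinges,
            min_support=min_support,
        )

    def fit(self) -> MARSResults:
        unpruned = forward_pass(self.matrix, self.phenotype, **self.params)
        return MARSResults(backward_prune(unpruned), unpruned)
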