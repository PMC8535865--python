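"""Odds ratios, confidence intervals and exact tests on 2x2 tables.

Tables are built from single-SNP or multilocus genotype groupings of a
case-control dataset: a sample is *exposed* when it carries the specified
genotype at every SNP of the grouping.  The module provides

* the sample (cross-product) odds ratio, with the Haldane-Anscombe +0.5
  correction when a cell is empty,
* the two-sided Fisher exact test (point-probability rule, via scipy),
* three interval constructions: Wald on ln(OR), exact-conditional
  (inversion of the noncentral hypergeometric, via scipy) and
  profile-likelihood from the saturated 2x2 logistic model, and
* the Wald z-test on ln(OR) — the p-value a logistic-regression summary
  reports for a binary exposure.

The profile-likelihood interval and the Wald z-test are what reproduce
the intervals and p-values printed for the reference DILI cohort; the
Fisher exact test and the conditional-exact interval are reported
alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .data import GenotypeMatrix, PhenotypeVector

CI_METHODS = ("wald", "exact-conditional", "profile")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts.

    a: exposed controls, b: exposed cases, c: unexposed controls,
    d: unexposed cases.
    """

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = ""

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table has no observations")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        """Outcome-major layout: rows = case/control, cols = exposed/unexposed."""
        return np.array([[self.b, self.d], [self.a, self.c]])

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_method: str
    p_value: float  # two-sided Fisher exact
    wald_p: float  # Wald z-test on ln(OR), as a logistic summary reports
    conditional_mle: float
    haldane_corrected: bool
    table: ContingencyTable2x2

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def build_table(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    grouping: dict[str, str | set[str]],
) -> ContingencyTable2x2:
    """2x2 table for an all-of multilocus genotype grouping.

    ``grouping`` maps each SNP to the genotype category (or set of
    categories) defining exposure at that SNP; a sample is exposed iff it
    matches at every SNP.  An empty grouping exposes every sample.
    """
    exposed = np.ones(matrix.n_samples, dtype=bool)
    label_parts = []
    for snp, cats in grouping.items():
        if snp not in matrix.allele_map:
            raise ValueError(f"unknown SNP {snp!r}")
        cats = {cats} if isinstance(cats, str) else set(cats)
        known = set(matrix.categories(snp)) | {matrix.missing_code}
        unknown = cats - known
        if unknown:
            raise ValueError(
                f"genotype categories {sorted(unknown)} never observed at {snp!r}"
            )
        col = matrix.genotypes[snp].to_numpy()
        exposed &= np.isin(col, sorted(cats))
        label_parts.append(f"{snp}={'|'.join(sorted(cats))}")
    y = phenotype.labels.astype(bool)
    return ContingencyTable2x2(
        a=int((exposed & ~y).sum()),
        b=int((exposed & y).sum()),
        c=int((~exposed & ~y).sum()),
        d=int((~exposed & y).sum()),
        exposure_label=" and ".join(label_parts),
    )


def _cells(table: ContingencyTable2x2, corrected: bool) -> tuple[float, ...]:
    if corrected:
        return table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5
    return float(table.a), float(table.b), float(table.c), float(table.d)


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Sample cross-product ratio (b*c)/(a*d).

    With any empty cell the Haldane-Anscombe +0.5 correction is applied
    to all four cells (use :func:`associate` to see the correction flag).
    """
    a, b, c, d = _cells(table, table.has_zero_cell())
    return (b * c) / (a * d)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (point-probability / minimum-likelihood rule):
    the total probability of margin-preserving tables no more probable than
    the observed one under the hypergeometric null."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def wald_p_value(table: ContingencyTable2x2) -> float:
    """Two-sided Wald z-test on ln(OR) (what ``summary(glm(...))`` prints
    for a binary exposure); Haldane-corrected when a cell is empty."""
    a, b, c, d = _cells(table, table.has_zero_cell())
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log((b * c) / (a * d)) / se
    return float(2 * stats.norm.sf(abs(z)))


def _profile_ci(table: ContingencyTable2x2, level: float) -> tuple[float, float]:
    """Profile-likelihood CI for ln(OR) in the saturated 2x2 logistic model."""
    a, b, c, d = _cells(table, table.has_zero_cell())

    def loglik(b0: float, b1: float) -> float:
        eta1, eta0 = b0 + b1, b0
        # log-likelihood of (cases, controls) in exposed / unexposed groups
        return (
            b * eta1
            - (a + b) * np.logaddexp(0.0, eta1)
            + d * eta0
            - (c + d) * np.logaddexp(0.0, eta0)
        )

    bhat1 = np.log((b * c) / (a * d))
    bhat0 = np.log(d / c)
    llmax = loglik(bhat0, bhat1)
    crit = stats.chi2.ppf(level, 1) / 2

    def profile(b1: float) -> float:
        res = optimize.minimize_scalar(
            lambda b0: -loglik(b0, b1),
            bounds=(bhat0 - 25, bhat0 + 25),
            method="bounded",
            options={"xatol": 1e-11},
        )
        return -res.fun

    def shifted(b1: float) -> float:
        return profile(b1) - (llmax - crit)

    span = 1.0
    while shifted(bhat1 - span) > 0:
        span += 1.0
    lo = optimize.brentq(shifted, bhat1 - span, bhat1, xtol=1e-10)
    span = 1.0
    while shifted(bhat1 + span) > 0:
        span += 1.0
    hi = optimize.brentq(shifted, bhat1, bhat1 + span, xtol=1e-10)
    return float(np.exp(lo)), float(np.exp(hi))


def or_confidence_interval(
    table: ContingencyTable2x2,
    method: str = "exact-conditional",
    level: float = 0.95,
) -> tuple[float, float]:
    """Confidence interval for the odds ratio.

    ``wald``: exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)), Haldane-
    corrected (and flagged via :func:`associate`) when a cell is empty.
    ``exact-conditional``: inversion of the noncentral hypergeometric
    tails (the interval R's ``fisher.test`` reports).
    ``profile``: profile likelihood from the 2x2 logistic model (the
    interval R's ``confint.glm`` reports).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method == "wald":
        a, b, c, d = _cells(table, table.has_zero_cell())
        log_or = np.log((b * c) / (a * d))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(0.5 + level / 2)
        return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))
    if method == "exact-conditional":
        res = _scipy_odds_ratio(table.as_array(), kind="conditional")
        ci = res.confidence_interval(confidence_level=level)
        return float(ci.low), float(ci.high)
    if method == "profile":
        return _profile_ci(table, level)
    raise ValueError(f"unknown ci method {method!r}; choose from {CI_METHODS}")


def associate(
    table: ContingencyTable2x2,
    ci_method: str = "exact-conditional",
    level: float = 0.95,
) -> AssociationResult:
    """Full association summary of one 2x2 table."""
    ci_low, ci_high = or_confidence_interval(table, ci_method, level)
    cond = _scipy_odds_ratio(table.as_array(), kind="conditional")
    return AssociationResult(
        odds_ratio=odds_ratio(table),
        ci_low=ci_low,
        ci_high=ci_high,
        ci_method=ci_method,
        p_value=fisher_exact_two_sided(table),
        wald_p=wald_p_value(table),
        conditional_mle=float(cond.statistic),
        haldane_corrected=table.has_zero_cell(),
        table=table,
    )
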