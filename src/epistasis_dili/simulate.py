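"""Synthetic case-control genotype datasets.

Two generators back the whole test surface of this package:

``make_epistasis_dataset``
    A balanced 250 x 25 simulation carrying one planted two-locus
    interaction (SNP4 x SNP9) with *no marginal effect*: each causal
    locus's penetrance, averaged over the partner locus, equals the
    overall case rate exactly.  The minority (rare-homozygote) genotype
    counts of the two causal SNPs are fixed at 52/250 and 57/250.  The
    default penetrance combines a strong high-risk rare-hom x rare-hom
    corner with a balanced crossing pattern over the common genotypes,
    calibrated so that MDR, MARS and RF-LR all recover the planted pair
    at this sample size while every single-locus association stays null.

``make_cohort_dataset``
    A 271-patient DILI-chronicity-like cohort (33 chronic / 238 acute,
    872 bile-acid-pathway SNPs) whose 2x2 contingency tables for five
    anchored SNPs, and the joint-genotype cells of three anchored SNP
    combinations, reproduce the published counts exactly.  All other
    SNPs are phenotype-independent Hardy-Weinberg noise.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeVector, canonical_genotype

__all__ = [
    "EpistasisSimConfig",
    "CohortSimConfig",
    "make_epistasis_dataset",
    "make_cohort_dataset",
    "permute_observations",
    "default_joint_counts",
    "default_penetrance",
    "COHORT_ANCHOR_SINGLES",
    "COHORT_ANCHOR_COMBOS",
    "COHORT_OTHER_GENOTYPES",
]


class SimulationError(ValueError):
    """Configuration cannot be realised exactly."""


# ---------------------------------------------------------------------------
# Planted-epistasis simulation
# ---------------------------------------------------------------------------

def default_joint_counts() -> np.ndarray:
    """Joint genotype counts of the two causal loci (rows: SNP4 dose 0/1/2,
    cols: SNP9 dose 0/1/2).  Margins give rare-homozygote counts 52 and 57
    of 250, i.e. implied minor-allele frequencies of about 0.46 and 0.48."""
    return np.array([[25, 37, 12], [34, 71, 19], [9, 17, 26]])


def default_penetrance(p_common: float = 0.85) -> np.ndarray:
    """Marginal-effect-free two-locus penetrance used by the simulation.

    The rare-hom x rare-hom corner cell is almost fully penetrant (25/26),
    the rest of each rare-hom margin is almost never a case, and the
    common 2x2 block carries a crossing (interaction-only) pattern whose
    strength is set by ``p_common``.  The remaining entries are solved so
    that every row and column of ``counts * penetrance`` sums to half the
    corresponding genotype count — the no-marginal-effect constraint —
    to machine precision.
    """
    nj = default_joint_counts()
    p = np.zeros((3, 3))
    p[2, 2] = 25 / 26
    p[2, 0] = p[2, 1] = 1 / 26
    p[0, 2] = p[1, 2] = 3.5 / 31
    p[0, 0] = p_common
    p[0, 1] = (nj[0].sum() / 2 - nj[0, 2] * p[0, 2] - nj[0, 0] * p[0, 0]) / nj[0, 1]
    p[1, 0] = (nj[:, 0].sum() / 2 - nj[2, 0] * p[2, 0] - nj[0, 0] * p[0, 0]) / nj[1, 0]
    p[1, 1] = (nj[1].sum() / 2 - nj[1, 2] * p[1, 2] - nj[1, 0] * p[1, 0]) / nj[1, 1]
    return p


# allele letter pairs cycled over SNP columns: (major, minor)
_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


def _genotype_strings(major: str, minor: str) -> list[str]:
    """Genotype category per additive code 0/1/2."""
    return [major * 2, canonical_genotype(major + minor), minor * 2]


@dataclass
class EpistasisSimConfig:
    """Configuration of the planted two-locus interaction simulation."""

    n_samples: int = 250
    n_cases: int = 125
    n_snps: int = 25
    causal_pair: tuple[int, int] = (3, 8)  # 0-based -> SNP4, SNP9
    penetrance: np.ndarray = field(default_factory=default_penetrance)
    joint_counts: np.ndarray = field(default_factory=default_joint_counts)
    target_minority_counts: tuple[int, int] = (52, 57)
    noise_maf_range: tuple[float, float] = (0.1, 0.4)
    seed: int = 0

    def validate(self) -> None:
        nj = np.asarray(self.joint_counts)
        p = np.asarray(self.penetrance)
        if nj.shape != (3, 3) or p.shape != (3, 3):
            raise SimulationError("joint_counts and penetrance must be 3x3")
        if self.n_cases > self.n_samples:
            raise SimulationError("n_cases exceeds n_samples")
        if nj.sum() != self.n_samples:
            raise SimulationError("joint_counts must sum to n_samples")
        if (p < 0).any() or (p > 1).any():
            raise SimulationError("penetrance entries must lie in [0, 1]")
        if nj[2].sum() != self.target_minority_counts[0]:
            raise SimulationError(
                "first causal SNP minority (rare-hom) count != target "
                f"({nj[2].sum()} vs {self.target_minority_counts[0]})"
            )
        if nj[:, 2].sum() != self.target_minority_counts[1]:
            raise SimulationError(
                "second causal SNP minority (rare-hom) count != target "
                f"({nj[:, 2].sum()} vs {self.target_minority_counts[1]})"
            )
        rate = self.n_cases / self.n_samples
        expected = nj * p
        if not np.allclose(expected.sum(axis=1), nj.sum(axis=1) * rate, atol=1e-9):
            raise SimulationError(
                "penetrance has a marginal effect at the first causal SNP"
            )
        if not np.allclose(expected.sum(axis=0), nj.sum(axis=0) * rate, atol=1e-9):
            raise SimulationError(
                "penetrance has a marginal effect at the second causal SNP"
            )
        i, j = self.causal_pair
        if not (0 <= i < self.n_snps and 0 <= j < self.n_snps and i != j):
            raise SimulationError("invalid causal pair indices")


def _largest_remainder(expected: np.ndarray, total: int, rng) -> np.ndarray:
    """Round non-negative expectations to integers summing to ``total``.

    Largest-remainder rounding; exact .5 ties are broken by an
    infinitesimal seeded jitter so replicates average to the expectation.
    """
    base = np.floor(expected).astype(int)
    short = total - base.sum()
    if short < 0 or short > len(expected):
        raise SimulationError("case expectations incompatible with exact total")
    order = np.argsort(-(expected - base + rng.random(expected.size) * 1e-9))
    out = base.copy()
    out[order[:short]] += 1
    return out


def make_epistasis_dataset(
    config: EpistasisSimConfig | None = None, seed: int | None = None
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Generate the balanced planted-interaction dataset.

    Genotypes of the causal pair are laid out cell-exactly from
    ``joint_counts``; case labels are assigned within each two-locus cell
    by integer (largest-remainder) realisation of ``counts * penetrance``;
    noise SNPs are drawn in Hardy-Weinberg proportions independently of
    the phenotype; finally the sample order is shuffled.
    """
    config = config or EpistasisSimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng([config.seed, 977])
    nj = np.asarray(config.joint_counts)
    pen = np.asarray(config.penetrance)
    n = config.n_samples

    expected = (nj * pen).ravel()
    if (np.floor(expected + 1e-12) > nj.ravel()).any():
        raise SimulationError("expected cases exceed a cell's size")
    cases = _largest_remainder(expected, config.n_cases, rng).reshape(3, 3)
    if (cases > nj).any():
        raise SimulationError(
            "penetrance table incompatible with exact case total: "
            f"cell cases {cases.tolist()} exceed counts {nj.tolist()}"
        )

    g_a = np.repeat([0, 1, 2], nj.sum(axis=1))
    g_b = np.concatenate([np.repeat([0, 1, 2], nj[i]) for i in range(3)])
    y = np.zeros(n, dtype=int)
    pos = 0
    for i in range(3):
        for j in range(3):
            m = nj[i, j]
            pick = rng.choice(m, size=cases[i, j], replace=False)
            y[pos + pick] = 1
            pos += m

    codes = np.zeros((n, config.n_snps), dtype=np.int8)
    ia, ib = config.causal_pair
    codes[:, ia] = g_a
    codes[:, ib] = g_b
    lo, hi = config.noise_maf_range
    for k in range(config.n_snps):
        if k in (ia, ib):
            continue
        maf = rng.uniform(lo, hi)
        codes[:, k] = rng.choice(
            [0, 1, 2], size=n, p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        )

    perm = rng.permutation(n)
    codes, y = codes[perm], y[perm]

    snp_ids = [f"SNP{k + 1}" for k in range(config.n_snps)]
    frame = {}
    for k, snp in enumerate(snp_ids):
        major, minor = _ALLELE_CYCLE[k % len(_ALLELE_CYCLE)]
        strings = _genotype_strings(major, minor)
        frame[snp] = [strings[c] for c in codes[:, k]]
    geno = pd.DataFrame(frame, index=[f"S{i + 1:04d}" for i in range(n)])
    matrix = GenotypeMatrix.from_frame(geno, validate=False)
    return matrix, PhenotypeVector(y)


def permute_observations(
    matrix: GenotypeMatrix,
    k: int,
    protected_snps: set[str] | set[int] = frozenset(),
    seed: int = 0,
) -> GenotypeMatrix:
    """Perturb ``k`` observations at every non-protected SNP.

    For each non-protected column, the genotypes of the ``k`` selected
    rows are replaced by independent draws from that column's empirical
    genotype distribution (a draw may coincide with the original value).
    Protected columns, non-selected rows and the phenotype are untouched.
    """
    if k < 0 or k > matrix.n_samples:
        raise ValueError(f"k must be in [0, {matrix.n_samples}], got {k}")
    protected = {
        matrix.snp_ids[s] if isinstance(s, (int, np.integer)) else s
        for s in protected_snps
    }
    unknown = protected - set(matrix.snp_ids)
    if unknown:
        raise ValueError(f"protected SNPs not in data: {sorted(unknown)}")
    rng = np.random.default_rng([seed, 31])
    geno = matrix.genotypes.copy()
    if k > 0:
        rows = rng.choice(matrix.n_samples, size=k, replace=False)
        for snp in matrix.snp_ids:
            if snp in protected:
                continue
            col = matrix.genotypes[snp].to_numpy()
            geno.iloc[rows, geno.columns.get_loc(snp)] = rng.choice(col, size=k)
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        snp_ids=list(matrix.snp_ids),
        genotypes=geno,
        allele_map=dict(matrix.allele_map),
        missing_code=matrix.missing_code,
    )


# ---------------------------------------------------------------------------
# DILI-chronicity-like cohort with exact contingency anchors
# ---------------------------------------------------------------------------

# Published per-SNP contingency counts the cohort reproduces exactly:
# snp -> (exposed genotype, exposed acute, exposed chronic)
COHORT_ANCHOR_SINGLES: dict[str, tuple[str, int, int]] = {
    "rs6487213": ("CC", 76, 20),
    "rs5417": ("AA", 74, 19),
    "rs7658048": ("AG", 113, 18),
    "rs12453290": ("AA", 105, 19),
    "rs3785157": ("CC", 106, 18),
}

# Multilocus combination anchors: ({snp: genotype}, acute, chronic) for the
# all-of exposed cell.  The three rows correspond to the interactions the
# MARS, MDR and RF-LR detectors reported on the real cohort.
COHORT_ANCHOR_COMBOS: list[tuple[dict[str, str], int, int]] = [
    ({"rs6487213": "CC", "rs3785157": "CC"}, 32, 14),
    ({"rs5417": "AA", "rs7658048": "AG", "rs12453290": "AA"}, 12, 6),
    ({"rs5417": "AA", "rs3785157": "CC"}, 36, 10),
]

# Non-exposed genotype categories per anchored SNP.
COHORT_OTHER_GENOTYPES: dict[str, tuple[str, str]] = {
    "rs6487213": ("CT", "TT"),
    "rs5417": ("AC", "CC"),
    "rs7658048": ("AA", "GG"),
    "rs12453290": ("AG", "GG"),
    "rs3785157": ("CT", "TT"),
}


@dataclass
class CohortSimConfig:
    """Configuration of the contingency-anchored cohort simulation."""

    n_samples: int = 271
    n_cases: int = 33
    n_snps: int = 872
    anchor_singles: dict[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(COHORT_ANCHOR_SINGLES)
    )
    anchor_combos: list[tuple[dict[str, str], int, int]] = field(
        default_factory=lambda: [(dict(g), a, c) for g, a, c in COHORT_ANCHOR_COMBOS]
    )
    other_genotypes: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(COHORT_OTHER_GENOTYPES)
    )
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def validate(self) -> None:
        n_ctrl = self.n_samples - self.n_cases
        for snp, (gt, a, c) in self.anchor_singles.items():
            if a > n_ctrl or c > self.n_cases:
                raise SimulationError(
                    f"anchor for {snp} exceeds class totals ({a}/{c})"
                )
        for geno_map, a, c in self.anchor_combos:
            for snp in geno_map:
                if snp not in self.anchor_singles:
                    raise SimulationError(
                        f"combination anchor uses unanchored SNP {snp!r}"
                    )
                if geno_map[snp] != self.anchor_singles[snp][0]:
                    raise SimulationError(
                        f"combination genotype for {snp!r} differs from its "
                        "single-SNP anchor genotype"
                    )
                sa, sc = self.anchor_singles[snp][1:]
                if a > sa or c > sc:
                    raise SimulationError(
                        "combination cell counts exceed constituent "
                        f"{snp!r} exposed counts ({a}/{c} vs {sa}/{sc})"
                    )
        if self.n_snps < len(self.anchor_singles):
            raise SimulationError("n_snps smaller than the number of anchors")


def _allocate_exposures(
    n: int,
    singles: dict[str, int],
    combos: list[tuple[frozenset, int]],
    rng,
    attempts: int = 200,
) -> dict[str, np.ndarray]:
    """Assign per-sample exposure indicators matching exact single and
    combination counts.

    Greedy constructive search: combination cores first (largest first,
    reusing already-exposed samples when a SNP's capacity forces overlap),
    then one-at-a-time round-robin filling of the single-SNP remainders,
    never letting a sample's exposure pattern complete a combination it
    was not counted for.  Retries with reshuffled candidate orders; the
    result is verified exactly before being returned.
    """
    snps = list(singles)
    combo_list = sorted(combos, key=lambda t: -len(t[0]))

    def attempt(local_rng):
        exposed = {s: np.zeros(n, dtype=bool) for s in snps}

        def pattern(x):
            return frozenset(s for s in snps if exposed[s][x])

        def completes_unintended(x, new_pat, current=None):
            for cs, _ in combo_list:
                if cs == current:
                    continue  # the combination being allocated
                if cs <= pattern(x):
                    continue  # already counted before this change
                if cs <= new_pat:
                    return True
            return False

        for cs, m in combo_list:
            already = sum(1 for x in range(n) if cs <= pattern(x))
            need = m - already
            if need < 0:
                return None
            cand = list(range(n))
            local_rng.shuffle(cand)
            # prefer samples overlapping the combination's SNPs: reuse
            # capacity on tight margins before consuming fresh samples
            cand.sort(key=lambda x: -len(pattern(x) & cs))
            placed = 0
            for x in cand:
                if placed == need:
                    break
                pat = pattern(x)
                if cs <= pat:
                    continue
                new = cs - pat
                if any(exposed[s].sum() >= singles[s] for s in new):
                    continue
                if completes_unintended(x, pat | cs, current=cs):
                    continue
                for s in new:
                    exposed[s][x] = True
                placed += 1
            if placed < need:
                return None

        # round-robin single fills, most-constrained SNP first each turn
        while True:
            remaining = {s: singles[s] - int(exposed[s].sum()) for s in snps}
            if any(r < 0 for r in remaining.values()):
                return None
            todo = [s for s in snps if remaining[s] > 0]
            if not todo:
                break
            s = max(todo, key=lambda t: remaining[t])
            cand = [x for x in range(n) if not exposed[s][x]]
            local_rng.shuffle(cand)
            # prefer lightly-loaded samples to preserve future safety
            cand.sort(key=lambda x: len(pattern(x)))
            placed = False
            for x in cand:
                if completes_unintended(x, pattern(x) | {s}):
                    continue
                exposed[s][x] = True
                placed = True
                break
            if not placed:
                return None
        return exposed

    for _ in range(attempts):
        result = attempt(rng)
        if result is None:
            continue
        ok = all(int(result[s].sum()) == singles[s] for s in snps)
        for cs, m in combo_list:
            got = int(np.logical_and.reduce([result[s] for s in cs]).sum())
            ok = ok and got == m
        if ok:
            return result
    raise SimulationError(
        "could not realise the anchor constraints exactly; the anchor set "
        f"appears infeasible for a class of {n} samples: {singles}, "
        f"{[(sorted(c), m) for c, m in combo_list]}"
    )


def make_cohort_dataset(
    config: CohortSimConfig | None = None, seed: int | None = None
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Generate the contingency-anchored DILI-like cohort.

    Every anchored single-SNP 2x2 table (exposed genotype vs. others by
    chronic vs. acute) and every anchored combination cell in the output
    equals its anchor exactly, for every seed; the remaining SNPs are
    Hardy-Weinberg noise independent of the phenotype.
    """
    config = config or CohortSimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng([config.seed, 1463])
    n_case, n_ctrl = config.n_cases, config.n_samples - config.n_cases
    snps = list(config.anchor_singles)

    combos = [
        (frozenset(g), a, c) for g, a, c in config.anchor_combos
    ]
    exp_ctrl = _allocate_exposures(
        n_ctrl,
        {s: config.anchor_singles[s][1] for s in snps},
        [(cs, a) for cs, a, _ in combos],
        rng,
    )
    exp_case = _allocate_exposures(
        n_case,
        {s: config.anchor_singles[s][2] for s in snps},
        [(cs, c) for cs, _, c in combos],
        rng,
    )

    n = config.n_samples
    y = np.concatenate([np.zeros(n_ctrl, dtype=int), np.ones(n_case, dtype=int)])
    columns: dict[str, np.ndarray] = {}
    for s in snps:
        exposed_gt = config.anchor_singles[s][0]
        others = config.other_genotypes[s]
        flags = np.concatenate([exp_ctrl[s], exp_case[s]])
        col = np.where(
            flags, exposed_gt, rng.choice(others, size=n, p=[0.65, 0.35])
        )
        columns[s] = col

    lo, hi = config.noise_maf_range
    n_noise = config.n_snps - len(snps)
    for k in range(n_noise):
        name = f"SNP{k + 1:04d}"
        major, minor = _ALLELE_CYCLE[k % len(_ALLELE_CYCLE)]
        strings = _genotype_strings(major, minor)
        maf = rng.uniform(lo, hi)
        code = rng.choice(
            [0, 1, 2], size=n, p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        )
        columns[name] = np.array(strings)[code]

    perm = rng.permutation(n)
    geno = pd.DataFrame(columns, index=[f"P{i + 1:04d}" for i in range(n)])
    geno = geno.iloc[perm].set_axis([f"P{i + 1:04d}" for i in range(n)], axis=0)
    matrix = GenotypeMatrix.from_frame(geno, validate=False)
    return matrix, PhenotypeVector(y[perm])
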