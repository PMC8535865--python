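"""Recovery-rate evaluation of the detectors on the planted simulation.

The robustness protocol perturbs the genotypes of k of the 250
observations at the 23 non-causal SNPs (the causal pair is protected) and
measures, over repeated perturbations, how often each detector still
reports exactly the planted interaction.
"""

from __future__ import annotations

from .data import GenotypeMatrix, PhenotypeVector
from .mars import MARS
from .mdr import mdr_search
from .rf_lr import RandomForestLogistic
from .simulate import EpistasisSimConfig, make_epistasis_dataset, permute_observations

__all__ = ["mars_recovers", "mdr_recovers", "rflr_recovers", "permutation_recovery"]


def mars_recovers(
    matrix: GenotypeMatrix, phenotype: PhenotypeVector, pair: tuple[str, str]
) -> bool:
    """True iff the pruned MARS model's extracted interaction set is
    exactly the planted pair (no extra, no missing interactions)."""
    res = MARS(matrix, phenotype).fit()
    return [it.snps for it in res.interactions] == [tuple(sorted(pair))]


def mdr_recovers(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    pair: tuple[str, str],
    folds: int = 10,
    seed: int = 0,
) -> bool:
    """True iff the exhaustive order-<=2 MDR search selects the pair."""
    _, final = mdr_search(
        matrix, phenotype, max_order=2, folds=folds, seed=seed
    )
    return set(final.snp_subset) == set(pair)


def rflr_recovers(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    pair: tuple[str, str],
    seed: int = 0,
) -> bool:
    """True iff RF ranks both SNPs into the top set and the logistic scan
    reports their interaction as the significant minimum-p pair."""
    res = RandomForestLogistic(matrix, phenotype, seed=seed).fit()
    return res.best_fit is not None and set(res.best_fit.snp_pair) == set(pair)


_DETECTORS = {
    "MARS": lambda m, p, pair, i: mars_recovers(m, p, pair),
    "MDR": lambda m, p, pair, i: mdr_recovers(m, p, pair, seed=i),
    "RF-LR": lambda m, p, pair, i: rflr_recovers(m, p, pair, seed=i),
}


def permutation_recovery(
    fixture_seed: int = 1,
    k: int = 10,
    n_replicates: int = 100,
    detectors: tuple[str, ...] = ("MARS", "MDR", "RF-LR"),
    config: EpistasisSimConfig | None = None,
) -> dict[str, int]:
    """Recovery counts over ``n_replicates`` perturbation replicates.

    The fixture is generated once from ``fixture_seed``; replicate i
    perturbs k observations with permutation seed 1000*fixture_seed + i,
    protecting the causal pair.
    """
    config = config or EpistasisSimConfig(seed=fixture_seed)
    matrix, phen = make_epistasis_dataset(config)
    ia, ib = config.causal_pair
    pair = (matrix.snp_ids[ia], matrix.snp_ids[ib])
    counts = {d: 0 for d in detectors}
    for i in range(1, n_replicates + 1):
        perturbed = (
            permute_observations(
                matrix, k, set(pair), seed=1000 * fixture_seed + i
            )
            if k > 0
            else matrix
        )
        for d in detectors:
            counts[d] += bool(_DETECTORS[d](perturbed, phen, pair, i))
    return counts
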