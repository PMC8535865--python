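"""Case-control genotype data model and file I/O.

A dataset is a samples x SNPs table of two-letter genotype categories
(e.g. ``"CC"``, ``"CT"``, ``"TT"``) together with a binary phenotype
aligned to the sample order (1 = case, e.g. chronic DILI; 0 = control,
e.g. acute DILI).  Heterozygotes are canonicalized to alphabetical order
("TC" -> "CT") so that a category never splits into two spellings.

Supported on-disk formats are delimited text (CSV/TSV with a header row)
and the PLINK ``.raw`` additive-coded export.  A ``.raw`` file carries
only the counted (minor) allele letter per SNP, so genotype *letters*
cannot be reconstructed from it; cross-format equivalence is therefore
defined on sample/SNP identifiers, additive codes and phenotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
DEFAULT_MISSING = "NN"


class GenotypeParseError(ValueError):
    """A token in the input file is not a valid genotype."""


class GenotypeDataError(ValueError):
    """The data violate a structural constraint (e.g. >2 alleles at a SNP)."""


def canonical_genotype(token: str) -> str:
    """Return the genotype with alleles in alphabetical order ('TC' -> 'CT')."""
    return token if token[0] <= token[1] else token[1] + token[0]


@dataclass(frozen=True)
class PhenotypeVector:
    """Binary outcome per sample (1 = case/chronic, 0 = control/acute)."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels, dtype=np.int64)
        if arr.ndim != 1:
            raise GenotypeDataError("phenotype must be one-dimensional")
        if not np.isin(arr, (0, 1)).all():
            raise GenotypeDataError("phenotype values must be strictly binary (0/1)")
        object.__setattr__(self, "labels", arr)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, PhenotypeVector) and np.array_equal(
            self.labels, other.labels
        )

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass
class GenotypeMatrix:
    """Samples x SNPs table of genotype categories with per-SNP allele order.

    Parameters
    ----------
    sample_ids, snp_ids
        Unique identifiers; order is meaningful and aligned with ``genotypes``.
    genotypes
        DataFrame of canonical two-letter genotype strings (or the missing
        code), indexed by ``sample_ids`` with ``snp_ids`` as columns.
    allele_map
        Per SNP the ordered pair ``(major, minor)``; ``minor`` is ``None``
        for a monomorphic SNP.  Used to derive additive 0/1/2 coding.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    genotypes: pd.DataFrame
    allele_map: dict[str, tuple[str, str | None]]
    missing_code: str = DEFAULT_MISSING

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeDataError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise GenotypeDataError("duplicate SNP ids")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        missing_code: str = DEFAULT_MISSING,
        validate: bool = True,
    ) -> "GenotypeMatrix":
        """Build from a genotype-string DataFrame, inferring the allele map.

        The major allele is the more frequent one; ties are broken
        alphabetically.  Tokens are canonicalized in place.
        """
        frame = frame.copy()
        frame.index = pd.Index([str(s) for s in frame.index], name=None)
        frame.columns = [str(c) for c in frame.columns]
        allele_map: dict[str, tuple[str, str | None]] = {}
        for col in frame.columns:
            values = frame[col].astype(str)
            if validate:
                for row_id, tok in values.items():
                    if tok == missing_code:
                        continue
                    if len(tok) != 2 or not set(tok) <= VALID_ALLELES:
                        raise GenotypeParseError(
                            f"malformed genotype {tok!r} at sample {row_id!r}, "
                            f"SNP {col!r}"
                        )
            values = values.map(
                lambda t: t if t == missing_code else canonical_genotype(t)
            )
            frame[col] = values
            counts: dict[str, int] = {}
            for tok in values:
                if tok == missing_code:
                    continue
                for ch in tok:
                    counts[ch] = counts.get(ch, 0) + 1
            alleles = sorted(counts)  # alphabetical, for deterministic ties
            if len(alleles) > 2:
                raise GenotypeDataError(
                    f"SNP {col!r} has more than two alleles: {alleles}"
                )
            if len(alleles) == 0:
                allele_map[col] = ("N", None)
            elif len(alleles) == 1:
                allele_map[col] = (alleles[0], None)
            else:
                a, b = alleles
                # most frequent allele is major; alphabetical on exact tie
                major, minor = (a, b) if counts[a] >= counts[b] else (b, a)
                allele_map[col] = (major, minor)
        return cls(
            sample_ids=[str(s) for s in frame.index],
            snp_ids=[str(c) for c in frame.columns],
            genotypes=frame,
            allele_map=allele_map,
            missing_code=missing_code,
        )

    # -- basic properties --------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and self.genotypes.equals(other.genotypes)
            and self.allele_map == other.allele_map
            and self.missing_code == other.missing_code
        )

    def categories(self, snp: str) -> list[str]:
        """Observed non-missing genotype categories at ``snp``, sorted."""
        vals = set(self.genotypes[snp]) - {self.missing_code}
        return sorted(vals)

    def genotype_code(self, snp: str, genotype: str) -> int:
        """Additive (minor-allele count) code of one genotype at ``snp``."""
        major, minor = self.allele_map[snp]
        if minor is None:
            return 0
        return sum(ch == minor for ch in genotype)

    def additive(self, snps: list[str] | None = None) -> np.ndarray:
        """Additive 0/1/2 coding (minor-allele counts); missing -> -1."""
        snps = list(self.snp_ids) if snps is None else list(snps)
        out = np.empty((self.n_samples, len(snps)), dtype=np.int8)
        for j, snp in enumerate(snps):
            major, minor = self.allele_map[snp]
            col = self.genotypes[snp].to_numpy()
            codes = np.full(self.n_samples, -1, dtype=np.int8)
            if minor is None:
                codes[col != self.missing_code] = 0
            else:
                codes[col == major + major] = 0
                het = canonical_genotype(major + minor)
                codes[col == het] = 1
                codes[col == minor + minor] = 2
            out[:, j] = codes
        return out

    def subset_snps(self, snps: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=list(snps),
            genotypes=self.genotypes[list(snps)].copy(),
            allele_map={s: self.allele_map[s] for s in snps},
            missing_code=self.missing_code,
        )

    def has_missing(self) -> bool:
        return bool((self.genotypes == self.missing_code).any().any())


def drop_incomplete(
    matrix: GenotypeMatrix, phenotype: PhenotypeVector
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Remove samples with any missing genotype (analysis modules need
    complete data; how the original cohort handled missingness is unknown)."""
    keep = ~(matrix.genotypes == matrix.missing_code).any(axis=1).to_numpy()
    gm = GenotypeMatrix(
        sample_ids=[s for s, k in zip(matrix.sample_ids, keep) if k],
        snp_ids=list(matrix.snp_ids),
        genotypes=matrix.genotypes.loc[keep].copy(),
        allele_map=dict(matrix.allele_map),
        missing_code=matrix.missing_code,
    )
    return gm, PhenotypeVector(phenotype.labels[keep])


# -- delimited text --------------------------------------------------------

def read_delimited(
    path,
    phenotype_column: str = "phenotype",
    missing_code: str = DEFAULT_MISSING,
    sample_column: str = "sample_id",
    sep: str | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read a CSV/TSV genotype table with a phenotype column.

    The delimiter is inferred from the file extension unless given
    (.tsv/.tab -> tab, otherwise comma).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if phenotype_column not in df.columns:
        raise GenotypeDataError(f"phenotype column {phenotype_column!r} not found")
    if sample_column in df.columns:
        df = df.set_index(sample_column)
    else:
        df.index = [f"S{i + 1:04d}" for i in range(len(df))]
    try:
        labels = df[phenotype_column].astype(int).to_numpy()
    except ValueError as exc:
        raise GenotypeDataError(f"non-numeric phenotype value: {exc}") from exc
    frame = df.drop(columns=[phenotype_column])
    matrix = GenotypeMatrix.from_frame(frame, missing_code=missing_code)
    phen = PhenotypeVector(labels)
    if len(phen) != matrix.n_samples:
        raise GenotypeDataError("phenotype length does not match sample count")
    return matrix, phen


def write_delimited(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    path,
    phenotype_column: str = "phenotype",
    sample_column: str = "sample_id",
    sep: str | None = None,
) -> None:
    """Write a dataset so that :func:`read_delimited` round-trips it."""
    if len(phenotype) != matrix.n_samples:
        raise GenotypeDataError("phenotype not aligned with genotype matrix")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out = matrix.genotypes.copy()
    out.insert(0, phenotype_column, phenotype.labels)
    out.index.name = sample_column
    out.to_csv(path, sep=sep)


# -- PLINK .raw ------------------------------------------------------------

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read a PLINK ``.raw`` additive export.

    Columns are ``FID IID PAT MAT SEX PHENOTYPE`` followed by one
    ``SNP_allele`` column per SNP holding the counted-allele dosage
    (0/1/2 or NA).  PLINK phenotype coding 1/2 is mapped to 0/1.
    Genotype letters are reconstructed with the counted allele as minor
    and a placeholder major allele (the file does not carry it).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [c for c in _RAW_META if c not in df.columns]
    if missing:
        raise GenotypeDataError(f".raw file lacks mandatory columns: {missing}")
    phen_raw = df["PHENOTYPE"]
    if not set(phen_raw) <= {"1", "2"}:
        raise GenotypeDataError(
            "PHENOTYPE must use PLINK 1/2 coding (control/case)"
        )
    labels = (phen_raw == "2").astype(int).to_numpy()
    sample_ids = df["IID"].tolist()
    geno_cols = [c for c in df.columns if c not in _RAW_META]
    frame = {}
    allele_map = {}
    for col in geno_cols:
        snp, _, counted = col.rpartition("_")
        if not snp or counted not in VALID_ALLELES:
            raise GenotypeDataError(
                f"SNP column {col!r} is not of the form NAME_allele"
            )
        minor = counted
        major = next(a for a in "ACGT" if a != minor)
        allele_map[snp] = (major, minor)
        tokens = []
        for i, v in enumerate(df[col]):
            if v == "NA":
                tokens.append(DEFAULT_MISSING)
            elif v in ("0", "1", "2"):
                d = int(v)
                gt = major * (2 - d) + minor * d
                tokens.append(canonical_genotype(gt))
            else:
                raise GenotypeDataError(
                    f"invalid dosage {v!r} at sample {sample_ids[i]!r}, SNP {snp!r}"
                )
        frame[snp] = tokens
    geno = pd.DataFrame(frame, index=sample_ids)
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=list(geno.columns),
        genotypes=geno,
        allele_map=allele_map,
    )
    return matrix, PhenotypeVector(labels)


def write_plink_raw(matrix: GenotypeMatrix, phenotype: PhenotypeVector, path) -> None:
    """Write a PLINK ``.raw`` additive export (counted allele = minor)."""
    codes = matrix.additive()
    with open(path, "w") as fh:
        headers = []
        for snp in matrix.snp_ids:
            _, minor = matrix.allele_map[snp]
            headers.append(f"{snp}_{minor if minor is not None else 'A'}")
        fh.write(" ".join(_RAW_META + headers) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            dose = [
                "NA" if codes[i, j] < 0 else str(int(codes[i, j]))
                for j in range(matrix.n_snps)
            ]
            phen = "2" if phenotype.labels[i] == 1 else "1"
            fh.write(" ".join([sid, sid, "0", "0", "0", phen] + dose) + "\n")


def datasets_equivalent(
    a: tuple[GenotypeMatrix, PhenotypeVector],
    b: tuple[GenotypeMatrix, PhenotypeVector],
) -> bool:
    """Format-independent equality: ids, additive codes and phenotype."""
    (ma, pa), (mb, pb) = a, b
    return (
        ma.sample_ids == mb.sample_ids
        and ma.snp_ids == mb.snp_ids
        and np.array_equal(ma.additive(), mb.additive())
        and pa == pb
    )
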