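"""SNP matrices and their on-disk representations.

The central container is :class:`SnpMatrix`: an ``n × p`` integer matrix of
unphased genotypes (allele dosages in {0, 1, 2}) or phased haplotypes
(alleles in {0, 1}), one row per individual (or per haplotype for phased
data) and one column per marker.  A sentinel of ``-1`` marks a missing call
on input; :meth:`SnpMatrix.fill_missing` removes it before any modeling.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


class Coding(str, enum.Enum):
    """Value domain of a SNP matrix."""

    genotype_012 = "genotype_012"
    haplotype_01 = "haplotype_01"

    @property
    def cardinality(self) -> int:
        return 3 if self is Coding.genotype_012 else 2


@dataclass(frozen=True)
class MarkerMetadata:
    """Name, chromosome and 1-based base-pair position of one marker."""

    name: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass
class SnpMatrix:
    """Individuals × markers categorical SNP data.

    Parameters
    ----------
    values : ndarray of int, shape (n, p)
        Genotype dosages or haplotype alleles; ``-1`` marks missing input.
    coding : Coding
        Declares the admissible value domain.
    marker_names : list of str
        Unique column labels, length ``p``.
    positions : list of int, optional
        Non-decreasing 1-based base-pair coordinates.
    chromosome : str, optional
    """

    values: np.ndarray
    coding: Coding
    marker_names: list[str] = field(default_factory=list)
    positions: list[int] | None = None
    chromosome: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("SNP matrix must be a non-empty 2-D array")
        self.coding = Coding(self.coding)
        if not self.marker_names:
            self.marker_names = [f"SNP{j + 1}" for j in range(self.p)]
        if len(self.marker_names) != self.p:
            raise ValueError(
                f"{len(self.marker_names)} marker names for {self.p} columns"
            )
        if len(set(self.marker_names)) != self.p:
            raise ValueError("marker names must be unique")
        if self.positions is not None:
            if len(self.positions) != self.p:
                raise ValueError("positions length must equal number of markers")
            if any(b < a for a, b in zip(self.positions, self.positions[1:])):
                raise ValueError("positions must be non-decreasing")
        self._check_domain()

    def _check_domain(self) -> None:
        hi = self.coding.cardinality - 1
        bad = (self.values > hi) | ((self.values < 0) & (self.values != MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"value {self.values[i, j]} at row {i}, column "
                f"'{self.marker_names[j]}' outside {{0..{hi}}} for {self.coding.value}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.values == MISSING).any())

    def fill_missing(self) -> "SnpMatrix":
        """Return a copy with missing cells imputed to the per-marker mode.

        The mode is taken over observed calls of the same marker; ties break
        toward the smaller code.  The number of imputed cells is logged.
        """
        if not self.has_missing:
            return self
        vals = self.values.copy()
        n_filled = 0
        for j in range(self.p):
            col = vals[:, j]
            miss = col == MISSING
            if not miss.any():
                continue
            observed = col[~miss]
            if observed.size == 0:
                mode = 0
            else:
                mode = int(np.bincount(observed).argmax())
            col[miss] = mode
            n_filled += int(miss.sum())
        logger.info("imputed %d missing genotype calls to per-marker modes", n_filled)
        return replace(self, values=vals)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.marker_names)


def read_matrix(path, coding: Coding | str) -> SnpMatrix:
    """Read a TSV SNP matrix (header = marker names, one row per individual)."""
    coding = Coding(coding)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty SNP matrix")
    try:
        values = df.to_numpy(dtype=np.int64)
    except ValueError:
        # locate the offending cell for the error message
        for j, name in enumerate(df.columns):
            for i, cell in enumerate(df.iloc[:, j]):
                try:
                    int(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-integer cell '{cell}' at row {i}, column '{name}'"
                    ) from None
        raise
    return SnpMatrix(values, coding, marker_names=list(df.columns))


def write_matrix(matrix: SnpMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index=False)


def read_vcf(path, phased: bool = False) -> SnpMatrix:
    """Extract a SnpMatrix from the GT fields of a VCF.

    Biallelic sites only; other sites are skipped with a logged count.  With
    ``phased=False`` each individual contributes one row of allele dosages in
    {0, 1, 2}; with ``phased=True`` each individual contributes two haplotype
    rows in {0, 1} and any unphased call raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    columns: list[np.ndarray] = []
    names: list[str] = []
    positions: list[int] = []
    chrom: str | None = None
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        gts = variant.genotypes  # [a0, a1, phased_flag] per sample
        if phased:
            col = np.empty(2 * len(gts), dtype=np.int64)
            for i, (a0, a1, is_phased) in enumerate(gts):
                if not is_phased and a0 >= 0 and a1 >= 0:
                    raise ValueError(
                        f"unphased genotype at {variant.CHROM}:{variant.POS} "
                        "with phased=True"
                    )
                col[2 * i] = a0 if a0 >= 0 else MISSING
                col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        else:
            col = np.empty(len(gts), dtype=np.int64)
            for i, (a0, a1, _) in enumerate(gts):
                col[i] = a0 + a1 if (a0 >= 0 and a1 >= 0) else MISSING
        columns.append(col)
        names.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        positions.append(variant.POS)
        chrom = chrom or variant.CHROM
    if n_skipped:
        logger.info("skipped %d non-biallelic sites", n_skipped)
    if not columns:
        raise ValueError(f"{path}: no biallelic sites with GT data")
    values = np.column_stack(columns)
    coding = Coding.haplotype_01 if phased else Coding.genotype_012
    return SnpMatrix(values, coding, marker_names=names, positions=positions,
                     chromosome=chrom)
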