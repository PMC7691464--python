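"""Lightweight in-memory containers shared across the pipeline.

The pipeline is keyed throughout by ``tree_id``.  Tabular data (stand maps,
traits, ecological variables, fitness) travel as plain :class:`pandas.DataFrame`
objects; the two containers defined here wrap the objects that need extra
bookkeeping: an allele-dosage matrix with its allele frequencies, and a
symmetric additive-relationship matrix with its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "RelatednessMatrix"]


@dataclass
class GenotypeMatrix:
    """SNP genotypes coded as dosage of the alternate allele (0/1/2).

    Parameters
    ----------
    dosages : pandas.DataFrame
        Rows are individuals (index = tree_id), columns are loci.  Entries in
        {0, 1, 2}; missing genotypes as NaN.
    allele_freqs : pandas.Series, optional
        Alternate-allele frequency per locus.  When absent, observed sample
        frequencies are computed on demand.
    """

    dosages: pd.DataFrame
    allele_freqs: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        bad = vals[~np.isnan(vals)]
        if bad.size and (bad.min() < 0 or bad.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")
        if self.allele_freqs is not None:
            self.allele_freqs = self.allele_freqs.reindex(self.dosages.columns)

    # -- basic geometry -------------------------------------------------
    @property
    def ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def observed_freqs(self) -> pd.Series:
        """Alternate-allele frequency per locus from the observed sample."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def freqs(self) -> pd.Series:
        return self.allele_freqs if self.allele_freqs is not None else self.observed_freqs()

    def subset(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[ids], self.allele_freqs)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.dosages.rename_axis("tree_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="tree_id"))

    def to_vcf(self, path, chrom: str = "1") -> None:
        """Write a minimal sites-by-sample VCF (GT field only).

        Loci are laid out on a single synthetic chromosome at consecutive
        positions; REF/ALT are placeholder A/G since only dosage matters here.
        """
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        samples = [str(s) for s in self.ids]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            arr = self.dosages.to_numpy()
            for j, locus in enumerate(self.dosages.columns):
                gts = ["./." if np.isnan(v) else gt_codes[int(v)] for v in arr[:, j]]
                fh.write(f"{chrom}\t{j + 1}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")


@dataclass
class RelatednessMatrix:
    """Symmetric additive-relationship matrix keyed by tree_id.

    ``provenance`` records how the matrix was built (``genomic``, ``pedigree``
    or ``hybrid``); ``bending_applied`` is set by eigenvalue conditioning.
    """

    values: np.ndarray
    ids: pd.Index
    provenance: str = "genomic"
    bending_applied: bool = False
    offdiag_variance: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = pd.Index(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relatedness matrix must be symmetric")
        # exact symmetry downstream
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def reindex(self, ids) -> "RelatednessMatrix":
        """Row/column subset (and reordering) by tree_id."""
        pos = self.ids.get_indexer(ids)
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"ids absent from relatedness matrix: {missing[:5]}")
        return RelatednessMatrix(self.values[np.ix_(pos, pos)], pd.Index(ids),
                                 self.provenance, self.bending_applied,
                                 self.offdiag_variance, dict(self.meta))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("tree_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, provenance: str = "genomic") -> "RelatednessMatrix":
        df = pd.read_csv(path, sep="\t", index_col="tree_id")
        df.columns = df.index
        return cls(df.to_numpy(), df.index, provenance)
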