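"""The diploid genotype matrix: the universal substrate of the pipeline.

Genotypes are stored as allele indices (0 = reference) in an int8 array of
shape ``(n_sites, n_samples, 2)`` with ``-1`` marking a missing call.
Positions are 0-based internally; serialisation to VCF converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ValidationError

MISSING = -1
MAX_ALLELE = 3  # A site may carry at most 4 distinct alleles (quadriallelic).


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid allele indices plus site/sample annotation.

    Attributes
    ----------
    contig : array of str, per-site contig name
    pos : int64 array, 0-based position within the contig
    alleles : list of tuples of allele strings, ``alleles[i][0]`` is REF
    gt : int8 array (n_sites, n_samples, 2), -1 = missing
    samples : list of sample identifiers, column order of ``gt``
    """

    contig: np.ndarray
    pos: np.ndarray
    alleles: list
    gt: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.ndim != 3 or self.gt.shape[2] != 2:
            raise ValidationError("gt must have shape (n_sites, n_samples, 2)")
        if len(self.contig) != self.n_sites or len(self.pos) != self.n_sites:
            raise ValidationError("contig/pos length must match gt")
        if self.samples and len(self.samples) != self.n_samples:
            raise ValidationError("sample list length must match gt")
        if self.gt.size and self.gt.max() > MAX_ALLELE:
            raise DataError(f"allele index exceeds {MAX_ALLELE}")

    # -- basic shape ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def contig_names(self) -> list:
        seen: dict = {}
        for c in self.contig:
            seen.setdefault(c, None)
        return list(seen)

    # -- subsetting -----------------------------------------------------
    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            contig=self.contig[idx],
            pos=self.pos[idx],
            alleles=[self.alleles[i] for i in np.atleast_1d(idx)],
            gt=self.gt[idx],
            samples=self.samples,
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            contig=self.contig,
            pos=self.pos,
            alleles=self.alleles,
            gt=self.gt[:, idx],
            samples=[self.samples[i] for i in idx] if self.samples else [],
        )

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - defensive
            raise ValidationError(f"unknown sample id {e}") from e

    # -- summaries ------------------------------------------------------
    def allele_counts(self, sample_idx=None) -> np.ndarray:
        """Per-site counts of each allele (0..MAX_ALLELE) over non-missing calls.

        Returns an int64 array of shape ``(n_sites, MAX_ALLELE + 1)``.
        """
        g = self.gt if sample_idx is None else self.gt[:, np.asarray(sample_idx)]
        flat = g.reshape(g.shape[0], -1)
        n_alleles = MAX_ALLELE + 1
        out = np.zeros((flat.shape[0], n_alleles), dtype=np.int64)
        site_idx = np.repeat(np.arange(flat.shape[0]), flat.shape[1])
        called = flat.ravel() >= 0
        np.add.at(out, (site_idx[called], flat.ravel()[called].astype(np.int64)), 1)
        return out

    def n_called_chromosomes(self, sample_idx=None) -> np.ndarray:
        return self.allele_counts(sample_idx).sum(axis=1)

    def dosage(self, site_idx=None, impute: bool = True) -> np.ndarray:
        """Alternate-allele dosage matrix, shape (n_samples, n_sites), float32.

        Dosage counts non-reference alleles per call (0/1/2). Missing calls are
        imputed to the per-site mean dosage when ``impute`` is True, otherwise
        returned as NaN.
        """
        g = self.gt if site_idx is None else self.gt[np.asarray(site_idx)]
        alt = (g > 0).sum(axis=2).astype(np.float32)
        miss = (g < 0).any(axis=2)
        alt[miss] = np.nan
        X = alt.T  # samples x sites
        if impute:
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(X, axis=0)
            col_mean = np.nan_to_num(col_mean)
            nan_mask = np.isnan(X)
            if nan_mask.any():
                X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
        return X

    def __eq__(self, other) -> bool:  # used in round-trip tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            list(self.contig) == list(other.contig)
            and np.array_equal(self.pos, other.pos)
            and [tuple(a) for a in self.alleles] == [tuple(a) for a in other.alleles]
            and np.array_equal(self.gt, other.gt)
            and self.samples == other.samples
        )
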