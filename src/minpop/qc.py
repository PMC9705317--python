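"""Sample- and site-level quality control and the site-class census.

Sample QC follows the coverage rule used for the cohort: a sample fails if
its median genome-wide coverage is below 10x or if less than 80% of the
reference is covered at >=1x (boundary values pass). The census counts
invariant / biallelic / triallelic / quadriallelic sites from the distinct
alleles observed among non-missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .genotypes import GenotypeMatrix, MAX_ALLELE


@dataclass
class SiteClassCensus:
    n_invariant: int
    n_biallelic: int
    n_triallelic: int
    n_quadriallelic: int
    n_unclassified: int = 0       # sites with every call missing
    accessible_sites: int | None = None

    @property
    def n_segregating(self) -> int:
        return self.n_biallelic + self.n_triallelic + self.n_quadriallelic

    @property
    def n_classified(self) -> int:
        return self.n_invariant + self.n_segregating

    @property
    def multiallelic_fraction(self) -> float:
        """Share of segregating sites with more than two alleles."""
        seg = self.n_segregating
        return (self.n_triallelic + self.n_quadriallelic) / seg if seg else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [
                    "invariant", "biallelic", "triallelic", "quadriallelic",
                    "segregating", "unclassified", "accessible",
                ],
                "count": [
                    self.n_invariant, self.n_biallelic, self.n_triallelic,
                    self.n_quadriallelic, self.n_segregating, self.n_unclassified,
                    -1 if self.accessible_sites is None else self.accessible_sites,
                ],
            }
        )


def sample_qc(
    summaries: pd.DataFrame,
    min_median: float = 10.0,
    min_breadth: float = 0.8,
    required_samples=None,
) -> pd.DataFrame:
    """Pass/fail per sample from coverage summaries.

    ``summaries`` needs columns sample_id, median_coverage, breadth_1x.
    A sample fails iff median_coverage < min_median OR breadth_1x <
    min_breadth; values exactly at the threshold pass.
    """
    need = {"sample_id", "median_coverage", "breadth_1x"}
    if not need.issubset(summaries.columns):
        raise ValidationError(f"coverage summaries need columns {sorted(need)}")
    if required_samples is not None:
        missing = set(required_samples) - set(summaries["sample_id"])
        if missing:
            raise ValidationError(
                f"no coverage summary for samples: {sorted(missing)[:5]}..."
                if len(missing) > 5
                else f"no coverage summary for samples: {sorted(missing)}"
            )
    out = summaries[["sample_id", "median_coverage", "breadth_1x"]].copy()
    out["qc_pass"] = (out["median_coverage"] >= min_median) & (
        out["breadth_1x"] >= min_breadth
    )
    return out


def classify_sites(gm: GenotypeMatrix, accessible_sites: int | None = None) -> SiteClassCensus:
    """Census of site classes from distinct alleles among non-missing calls."""
    if gm.gt.size and gm.gt.max() > MAX_ALLELE:  # pragma: no cover - guarded upstream
        raise DataError(f"allele index exceeds {MAX_ALLELE}")
    counts = gm.allele_counts()
    called = counts.sum(axis=1)
    distinct = (counts > 0).sum(axis=1)
    unclassified = int((called == 0).sum())
    cls = distinct[called > 0]
    return SiteClassCensus(
        n_invariant=int((cls == 1).sum()),
        n_biallelic=int((cls == 2).sum()),
        n_triallelic=int((cls == 3).sum()),
        n_quadriallelic=int((cls == 4).sum()),
        n_unclassified=unclassified,
        accessible_sites=accessible_sites,
    )


def apply_site_mask(gm: GenotypeMatrix, mask: dict):
    """Keep only sites inside the accessibility mask.

    ``mask`` maps contig name to a boolean array over positions whose length
    must equal the contig length. Returns ``(filtered_gm, accessible_count)``
    where the count is the total number of masked-in positions (the
    denominator for per-base statistics).
    """
    keep = np.zeros(gm.n_sites, dtype=bool)
    for c in gm.contig_names():
        if c not in mask:
            raise ValidationError(f"mask missing contig {c!r}")
    accessible = 0
    for c, arr in mask.items():
        arr = np.asarray(arr, dtype=bool)
        sel = gm.contig == c
        if sel.any() and gm.pos[sel].max() >= len(arr):
            raise ValidationError(f"mask for {c!r} shorter than site positions")
        accessible += int(arr.sum())
        keep[sel] = arr[gm.pos[sel]]
    return gm.take_sites(np.flatnonzero(keep)), accessible
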