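"""Per-population allele frequencies at configured insecticide-resistance
genes (Ace1, Rdl, KDR, GSTe2 or any user-supplied regions), reported when a
variant exceeds a frequency threshold in at least one population.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


def population_allele_frequencies(
    gm: GenotypeMatrix, populations: dict, regions: pd.DataFrame
) -> pd.DataFrame:
    """Alternate-allele frequencies per population for variants inside gene
    regions.

    ``populations`` maps population name -> list of sample ids (the assigned
    samples from the structure stage). ``regions`` has columns contig, start,
    end (0-based half-open), name. Multiallelic variants are decomposed into
    one record per alternate allele. Frequencies are computed over
    non-missing chromosomes; a population with no called chromosomes at a
    site gets NaN.
    """
    pop_idx = {k: gm.sample_indices(v) for k, v in populations.items()}
    rows = []
    for region in regions.itertuples(index=False):
        sel = np.flatnonzero(
            (gm.contig == region.contig)
            & (gm.pos >= int(region.start))
            & (gm.pos < int(region.end))
        )
        if sel.size == 0:
            log.info("region %s has no variants", region.name)
            continue
        sub = gm.take_sites(sel)
        counts = {k: sub.allele_counts(idx) for k, idx in pop_idx.items()}
        totals = {k: c.sum(axis=1) for k, c in counts.items()}
        for i in range(sub.n_sites):
            alleles = sub.alleles[i]
            for alt_i in range(1, len(alleles)):
                row = {
                    "gene": region.name,
                    "contig": sub.contig[i],
                    "pos": int(sub.pos[i]) + 1,  # 1-based for reporting
                    "ref": alleles[0],
                    "alt": alleles[alt_i],
                }
                for k in populations:
                    n = int(totals[k][i])
                    row[f"freq_{k}"] = (
                        counts[k][i, alt_i] / n if n > 0 else np.nan
                    )
                    row[f"n_chrom_{k}"] = n
                rows.append(row)
    cols = ["gene", "contig", "pos", "ref", "alt"]
    cols += [f"freq_{k}" for k in populations] + [f"n_chrom_{k}" for k in populations]
    return pd.DataFrame(rows, columns=cols)


def filter_ir_variants(records: pd.DataFrame, min_freq: float = 0.02) -> pd.DataFrame:
    """Keep records whose frequency strictly exceeds ``min_freq`` in at least
    one population (NaN frequencies are ignored); sort by gene then position."""
    if len(records) == 0:
        return records
    freq_cols = [c for c in records.columns if c.startswith("freq_")]
    best = records[freq_cols].max(axis=1, skipna=True)
    out = records[best > min_freq].copy()
    return out.sort_values(["gene", "pos"]).reset_index(drop=True)


def ir_report(
    gm: GenotypeMatrix, populations: dict, regions: pd.DataFrame, min_freq: float = 0.02
) -> pd.DataFrame:
    return filter_ir_variants(
        population_allele_frequencies(gm, populations, regions), min_freq=min_freq
    )
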