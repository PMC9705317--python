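"""Degeneracy-aware diversity statistics.

Nucleotide diversity (pi), Watterson's theta and Tajima's D are computed
from per-site allele counts over four-fold degenerate coding sites, with
populations downsampled to a common size and sample-bootstrap percentile
confidence intervals.

pi and theta_W are per-base quantities: sums over polymorphic sites divided
by the number of accessible (masked-in) degenerate positions, so invariant
accessible positions contribute zero to the numerator but count in the
denominator. Tajima's D uses the standard constants of the normalised
difference between the pairwise and segregating-site estimators of theta,
and is undefined (NaN) when no site segregates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .errors import ValidationError
from .genotypes import GenotypeMatrix
from .rng import substream

log = logging.getLogger(__name__)

_BASES = "ACGT"


def _fourfold_prefixes() -> frozenset:
    fwd = standard_dna_table.forward_table
    pref = set()
    for a in _BASES:
        for b in _BASES:
            aas = {fwd.get(a + b + c) for c in _BASES}
            if None not in aas and len(aas) == 1:
                pref.add(a + b)
    return frozenset(pref)


FOURFOLD_PREFIXES = _fourfold_prefixes()


# ------------------------------------------------------------- degeneracy
def _prefix_table() -> np.ndarray:
    """4x4 boolean table: is the 2-base codon prefix four-fold degenerate?"""
    tab = np.zeros((4, 4), dtype=bool)
    for pref in FOURFOLD_PREFIXES:
        tab[_BASES.index(pref[0]), _BASES.index(pref[1])] = True
    return tab


_PREFIX_4FOLD = _prefix_table()
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


def fourfold_degenerate_mask(contigs: dict, cds: pd.DataFrame) -> dict:
    """Per-contig boolean mask of four-fold degenerate third codon positions.

    ``cds`` needs columns contig, start, end (0-based half-open), strand,
    phase. For minus-strand features the codon is read on the reverse
    complement and the flag is placed on the corresponding forward-strand
    coordinate (the third codon position maps to the *smallest* genomic
    coordinate of its codon). Positions covered by more than one CDS are
    flagged only if every covering frame calls them four-fold degenerate;
    incomplete terminal codons are ignored.
    """
    codes = {c: _CODE[np.frombuffer(s.encode(), dtype=np.uint8)] for c, s in contigs.items()}
    cover = {c: np.zeros(len(s), dtype=np.int32) for c, s in contigs.items()}
    four = {c: np.zeros(len(s), dtype=np.int32) for c, s in contigs.items()}
    for row in cds.itertuples(index=False):
        if row.contig not in contigs:
            log.warning(
                "CDS %s on unknown contig %s; skipped",
                getattr(row, "cds_id", "?"), row.contig,
            )
            continue
        seq = codes[row.contig]
        start, end = int(row.start), int(row.end)
        if start < 0 or end > len(seq):
            log.warning("CDS running off contig %s; skipped", row.contig)
            continue
        phase = int(getattr(row, "phase", 0) or 0)
        if row.strand == "+":
            cstart = start + phase
            n_codons = (end - cstart) // 3
            if n_codons < 1:
                continue
            g = cstart + 3 * np.arange(n_codons)  # codon starts (1st position)
            b1, b2 = seq[g], seq[g + 1]
            ok = (b1 < 4) & (b2 < 4)
            is4 = np.zeros(n_codons, dtype=bool)
            is4[ok] = _PREFIX_4FOLD[b1[ok], b2[ok]]
            third = g + 2
        else:
            cend = end - phase
            n_codons = (cend - start) // 3
            if n_codons < 1:
                continue
            # codon k (5'->3' on the minus strand) occupies forward
            # coordinates [cend-3k-3, cend-3k); its 1st/2nd bases are the
            # complements of forward positions cend-3k-1 and cend-3k-2.
            g3 = cend - 3 * np.arange(n_codons) - 3
            b1 = 3 - seq[g3 + 2]  # complement of a 0..3 code is 3-code
            b2 = 3 - seq[g3 + 1]
            ok = (seq[g3 + 2] < 4) & (seq[g3 + 1] < 4)
            is4 = np.zeros(n_codons, dtype=bool)
            is4[ok] = _PREFIX_4FOLD[b1[ok], b2[ok]]
            third = g3
        full = np.concatenate([third - 2, third - 1, third]) if row.strand == "+" else \
            np.concatenate([third, third + 1, third + 2])
        np.add.at(cover[row.contig], full, 1)
        np.add.at(four[row.contig], third[is4], 1)
    return {c: (cover[c] > 0) & (four[c] == cover[c]) for c in contigs}


# ------------------------------------------------------------- statistics
def site_pairwise_diversity(counts: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference from allele counts.

    For counts c_a with n = sum(c_a): sum_{a<b} c_a c_b / C(n, 2). Sites with
    fewer than two called chromosomes contribute NaN.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diffs = (n**2 - (counts**2).sum(axis=1)) / 2.0
        pairs = n * (n - 1) / 2.0
        out = np.where(n >= 2, diffs / np.where(pairs > 0, pairs, 1.0), np.nan)
    return out


def nucleotide_diversity(counts: np.ndarray, accessible: int) -> float:
    """pi per base: summed mean pairwise differences / accessible positions."""
    if accessible <= 0:
        raise ValidationError("accessible site count must be positive for pi")
    per_site = site_pairwise_diversity(counts)
    return float(np.nansum(per_site) / accessible)


def harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float((1.0 / i**power).sum())


def watterson_theta(n_segregating: int, n_chromosomes: int, accessible: int) -> float:
    """theta_W per base = S / a_n / L with a_n the (n-1)th harmonic number."""
    if n_chromosomes < 2:
        raise ValidationError("Watterson's theta needs n >= 2 chromosomes")
    if accessible <= 0:
        raise ValidationError("accessible site count must be positive for theta_W")
    return n_segregating / harmonic(n_chromosomes) / accessible


def tajimas_d(counts: np.ndarray, n_chromosomes: int | None = None) -> float:
    """Tajima's D from per-site allele counts at uniform sample size.

    Returns NaN when no site segregates (never 0: an empty scan is
    "undefined", not "neutral").
    """
    counts = np.asarray(counts, dtype=np.int64)
    totals = counts.sum(axis=1)
    if n_chromosomes is None:
        if len(totals) == 0:
            return float("nan")
        n_chromosomes = int(totals[0])
    if counts.size and not (totals == n_chromosomes).all():
        raise ValidationError("Tajima's D requires a uniform chromosome count per site")
    n = int(n_chromosomes)
    if n < 2:
        raise ValidationError("Tajima's D needs n >= 2 chromosomes")
    seg = (counts > 0).sum(axis=1) > 1
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi_total = float(np.nansum(site_pairwise_diversity(counts[seg])))
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


# ------------------------------------------------------------- sampling
def downsample_population(populations: dict, target: int | None = None, seed: int = 0) -> dict:
    """Uniform, seeded draw without replacement so every population has the
    same size (default: the smallest population's size)."""
    sizes = {k: len(v) for k, v in populations.items()}
    if target is None:
        target = min(sizes.values())
    for k, s in sizes.items():
        if target > s:
            raise ValidationError(f"cannot downsample {k} (n={s}) to {target}")
    out = {}
    for k in populations:
        members = list(populations[k])
        rng = substream(seed, "downsample", k)
        if len(members) == target:
            out[k] = list(members)
        else:
            idx = np.sort(rng.choice(len(members), size=target, replace=False))
            out[k] = [members[i] for i in idx]
    return out


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    n_boot: int
    n_undefined: int = 0

    @property
    def unreliable(self) -> bool:
        return self.n_undefined > 0.2 * self.n_boot


def bootstrap_ci(
    stat_fn,
    samples,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    stream: str = "bootstrap",
    recenter: bool = True,
) -> BootstrapCI:
    """Percentile bootstrap over individuals.

    ``stat_fn`` maps a list of sample identifiers to a float; replicates
    resample individuals with replacement at the original size. Replicates
    where the statistic is undefined (NaN) are dropped; the CI is flagged
    unreliable when more than 20% fail.

    With ``recenter`` (the default) the replicate distribution is shifted so
    its mean sits at the full-sample point estimate before taking
    percentiles. Resampling individuals with replacement duplicates
    genotypes, which systematically depresses diversity statistics (fewer
    distinct lineages per replicate); recentring removes that resampling
    bias while keeping the bootstrap spread.
    """
    samples = list(samples)
    rng = substream(seed, stream)
    values = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(samples), size=len(samples))
        values.append(stat_fn([samples[i] for i in idx]))
    values = np.asarray(values, dtype=float)
    bad = int(np.isnan(values).sum())
    good = values[~np.isnan(values)]
    if good.size == 0:
        return BootstrapCI(float("nan"), float("nan"), n_boot, bad)
    if recenter:
        point = float(stat_fn(samples))
        if np.isfinite(point):
            good = good - good.mean() + point
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(good, [100 * alpha, 100 * (1 - alpha)])
    ci = BootstrapCI(float(lo), float(hi), n_boot, bad)
    if ci.unreliable:
        log.warning("bootstrap CI unreliable: %d/%d replicates undefined", bad, n_boot)
    return ci


# ------------------------------------------------------------- report
def diversity_report(
    gm: GenotypeMatrix,
    populations: dict,
    mask: dict,
    min_contig_bp: int = 2_000_000,
    x_contigs=(),
    n_boot: int = 100,
    level: float = 0.95,
    downsample_to: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """pi, theta_W and Tajima's D with bootstrap CIs per population.

    Statistics are pooled over the four-fold degenerate accessible sites of
    autosomal contigs longer than ``min_contig_bp``; populations are first
    downsampled to a common size (default: smallest population).
    """
    keep_contigs = {
        c for c, arr in mask.items()
        if len(arr) > min_contig_bp and c not in set(x_contigs)
    }
    if not keep_contigs:
        raise ValidationError(f"no contig longer than {min_contig_bp} bp")
    sub_mask = {c: mask[c] for c in keep_contigs}
    in_contig = np.isin(gm.contig, list(keep_contigs))
    keep = np.zeros(gm.n_sites, dtype=bool)
    for c in keep_contigs:
        sel = (gm.contig == c) & in_contig
        keep[sel] = np.asarray(sub_mask[c], dtype=bool)[gm.pos[sel]]
    sub = gm.take_sites(np.flatnonzero(keep))
    accessible = int(sum(np.asarray(a, dtype=bool).sum() for a in sub_mask.values()))

    down = downsample_population(populations, target=downsample_to, seed=seed)
    n_target = len(next(iter(down.values())))
    rows = []
    for popname, members in down.items():
        def stat(ids, which):
            idx = sub.sample_indices(ids)
            counts = sub.allele_counts(idx)
            if which == "pi":
                return nucleotide_diversity(counts, accessible)
            if which == "theta_w":
                S = int(((counts > 0).sum(axis=1) > 1).sum())
                return watterson_theta(S, 2 * len(ids), accessible)
            full = counts.sum(axis=1) == 2 * len(ids)  # uniform n: fully called
            return tajimas_d(counts[full], 2 * len(ids))

        for which in ("pi", "theta_w", "tajimas_d"):
            point = stat(members, which)
            ci = bootstrap_ci(
                lambda ids, w=which: stat(ids, w),
                members,
                n_boot=n_boot,
                level=level,
                seed=seed,
                stream=f"bootstrap:{popname}:{which}",
            )
            rows.append(
                {
                    "population": popname,
                    "statistic": which,
                    "estimate": point,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                    "unreliable": ci.unreliable,
                    "n_samples": n_target,
                    "accessible_sites": accessible,
                }
            )
    return pd.DataFrame(rows)
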