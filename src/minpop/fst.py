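"""Windowed Hudson Fst, genome averages, selection-signal detection and
peak-to-gene annotation.

Hudson's estimator (Bhatia et al. parameterisation) is computed per
biallelic site as a (numerator, denominator) pair and combined within
windows as a ratio of sums, which avoids the small-window bias of averaging
per-site ratios. Contig and genome averages are means over window values.
A selection signal is a run of at least ``min_run`` consecutive 1000-SNP
windows above ``threshold_mult`` times the genome-wide mean window Fst,
ranked by peak value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


# ------------------------------------------------------------ per-site
def hudson_fst_components(ac1: np.ndarray, ac2: np.ndarray):
    """Per-site Hudson numerator/denominator from biallelic allele counts.

    ``ac1``/``ac2`` are (n_sites, 2) ref/alt counts. With p_k the alt
    frequency and n_k the called chromosome count:

        num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    Returns ``(num, den, usable)`` where ``usable`` marks sites with n >= 2
    in both populations and polymorphic in their union (den > 0 or a fixed
    difference); other sites carry NaN.
    """
    ac1 = np.asarray(ac1, dtype=np.float64)
    ac2 = np.asarray(ac2, dtype=np.float64)
    n1, n2 = ac1.sum(axis=1), ac2.sum(axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, ac1[:, 1] / np.maximum(n1, 1), np.nan)
        p2 = np.where(n2 > 0, ac2[:, 1] / np.maximum(n2, 1), np.nan)
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    usable = ok & (den > 0)
    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)
    return num, den, usable


def pair_allele_counts(gm: GenotypeMatrix, idx1, idx2, biallelic_only: bool = True):
    """Ref/alt counts for two sample groups at biallelic sites.

    Returns ``(site_indices, ac1, ac2)``. Only sites biallelic over the full
    matrix enter (multiallelic sites are excluded from the two-allele
    estimator).
    """
    counts_all = gm.allele_counts()
    distinct = (counts_all > 0).sum(axis=1)
    only01 = counts_all[:, 2:].sum(axis=1) == 0  # alleles restricted to {ref, alt1}
    sites = np.flatnonzero((distinct <= 2) & only01) if biallelic_only else np.arange(gm.n_sites)
    sub = gm.take_sites(sites)
    ac1 = sub.allele_counts(idx1)[:, :2]
    ac2 = sub.allele_counts(idx2)[:, :2]
    return sites, ac1, ac2


# ------------------------------------------------------------ windows
def windowed_fst(
    contig: np.ndarray,
    pos: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
    mode: str = "snp",
    window_snps: int = 1000,
    window_bp: int = 20_000,
    contig_lengths: dict | None = None,
) -> pd.DataFrame:
    """Ratio-of-sums Fst per window.

    ``mode='snp'``: consecutive non-overlapping blocks of exactly
    ``window_snps`` usable SNPs per contig (final partial block dropped).
    ``mode='position'``: half-open tiles of ``window_bp`` over
    [0, contig_length); windows without usable sites are omitted.
    """
    contig = np.asarray(contig, dtype=object)
    pos = np.asarray(pos)
    usable = np.isfinite(num) & np.isfinite(den)
    rows = []
    seen: dict = {}
    for c in contig:
        seen.setdefault(c, None)
    for c in seen:
        sel = (contig == c) & usable
        p = pos[sel]
        nm = num[sel]
        dn = den[sel]
        order = np.argsort(p, kind="stable")
        p, nm, dn = p[order], nm[order], dn[order]
        if mode == "snp":
            n_win = len(p) // window_snps
            for w in range(n_win):
                s = slice(w * window_snps, (w + 1) * window_snps)
                d = dn[s].sum()
                rows.append(
                    {
                        "contig": c,
                        "start": int(p[s][0]),
                        "end": int(p[s][-1]) + 1,
                        "n_snps": window_snps,
                        "fst": float(nm[s].sum() / d) if d > 0 else np.nan,
                    }
                )
        elif mode == "position":
            if contig_lengths is None or c not in contig_lengths:
                raise ValidationError("positional windows need contig_lengths")
            L = int(contig_lengths[c])
            edges = np.arange(0, L + window_bp, window_bp)
            which = np.searchsorted(edges, p, side="right") - 1
            for w in np.unique(which):
                s = which == w
                d = dn[s].sum()
                if s.sum() == 0 or d <= 0:
                    continue
                rows.append(
                    {
                        "contig": c,
                        "start": int(edges[w]),
                        "end": int(min(edges[w] + window_bp, L)),
                        "n_snps": int(s.sum()),
                        "fst": float(nm[s].sum() / d),
                    }
                )
        else:  # pragma: no cover
            raise ValidationError(f"unknown window mode {mode!r}")
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "n_snps", "fst"])
    if len(df):
        df["midpoint"] = (df["start"] + df["end"]) // 2
    else:
        df["midpoint"] = pd.Series(dtype=np.int64)
    return df.dropna(subset=["fst"]).reset_index(drop=True)


def pair_windowed_fst(
    gm: GenotypeMatrix,
    idx1,
    idx2,
    mode: str = "snp",
    window_snps: int = 1000,
    window_bp: int = 20_000,
    contig_lengths: dict | None = None,
    contigs=None,
) -> pd.DataFrame:
    """Convenience: allele counts -> Hudson components -> windowed series."""
    sites, ac1, ac2 = pair_allele_counts(gm, idx1, idx2)
    num, den, _ = hudson_fst_components(ac1, ac2)
    contig = gm.contig[sites]
    pos = gm.pos[sites]
    if contigs is not None:
        keep = np.isin(contig, list(contigs))
        contig, pos, num, den = contig[keep], pos[keep], num[keep], den[keep]
    return windowed_fst(
        contig, pos, num, den,
        mode=mode, window_snps=window_snps, window_bp=window_bp,
        contig_lengths=contig_lengths,
    )


def average_fst_matrix(
    gm: GenotypeMatrix,
    populations: dict,
    contig: str,
    window_bp: int = 20_000,
    contig_lengths: dict | None = None,
) -> pd.DataFrame:
    """Mean 20-kb-window Fst for every population pair over one contig."""
    if len(populations) < 2:
        raise ValidationError("need at least two populations")
    if contig not in set(gm.contig_names()):
        raise ValidationError(f"contig {contig!r} absent from genotypes")
    names = list(populations)
    mat = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            win = pair_windowed_fst(
                gm,
                gm.sample_indices(populations[names[i]]),
                gm.sample_indices(populations[names[j]]),
                mode="position",
                window_bp=window_bp,
                contig_lengths=contig_lengths,
                contigs=[contig],
            )
            mat[i, j] = mat[j, i] = float(win["fst"].mean())
    return pd.DataFrame(mat, index=names, columns=names)


# ------------------------------------------------------------ signals
@dataclass
class SelectionSignal:
    pair: tuple
    contig: str
    run_start: int          # bp of first window start in the run
    run_end: int            # bp of last window end in the run
    n_windows_above: int
    peak_midpoint: int      # bp
    peak_fst: float
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def peak_mbp(self) -> float:
        return round(self.peak_midpoint / 1e6, 2)


def detect_signals(
    windows: pd.DataFrame,
    pair=("pop1", "pop2"),
    min_run: int = 5,
    threshold_mult: float = 2.0,
    gap_tolerance: int = 0,
) -> list:
    """Runs of >= ``min_run`` consecutive windows above ``threshold_mult`` x
    the genome-wide mean window Fst, ranked by peak Fst (ties broken by
    contig id then position)."""
    if windows is None or len(windows) == 0:
        raise ValidationError("empty windowed series")
    threshold = threshold_mult * float(windows["fst"].mean())
    signals = []
    for c, sub in windows.groupby("contig", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        above = (sub["fst"] > threshold).to_numpy()
        i = 0
        while i < len(sub):
            if not above[i]:
                i += 1
                continue
            j = i
            gap = 0
            end = i
            while j + 1 < len(sub):
                if above[j + 1]:
                    j += 1
                    end = j
                    gap = 0
                elif gap < gap_tolerance:
                    j += 1
                    gap += 1
                else:
                    break
            run = sub.iloc[i : end + 1]
            n_above = int((run["fst"] > threshold).sum())
            if n_above >= min_run:
                peak = run.loc[run["fst"].idxmax()]
                signals.append(
                    SelectionSignal(
                        pair=tuple(pair),
                        contig=str(c),
                        run_start=int(run["start"].iloc[0]),
                        run_end=int(run["end"].iloc[-1]),
                        n_windows_above=n_above,
                        peak_midpoint=int(peak["midpoint"]),
                        peak_fst=float(peak["fst"]),
                    )
                )
            i = end + 1
    signals.sort(key=lambda s: (-s.peak_fst, s.contig, s.peak_midpoint))
    return signals


def annotate_signals(signals, genes: pd.DataFrame, radius: int = 100_000) -> list:
    """Attach genes within ``radius`` bp of each signal peak (inclusive).

    ``genes`` has columns gene_id, contig, start, end (0-based half-open),
    product. Distance is 0 for genes overlapping the peak, otherwise the
    signed distance from the peak to the nearest feature edge (negative for
    genes upstream of the peak).
    """
    for sig in signals:
        sub = genes[genes["contig"] == sig.contig]
        if len(sub) == 0:
            log.warning("no annotation for contig %s", sig.contig)
            sig.genes = pd.DataFrame(columns=["gene_id", "product", "distance_bp"])
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        peak = sig.peak_midpoint
        inside = (start <= peak) & (peak < end)
        dist = np.where(
            inside, 0, np.where(end <= peak, peak - (end - 1), start - peak)
        )
        keep = np.abs(dist) <= radius
        out = sub.loc[keep, ["gene_id", "product"]].copy()
        signed = dist[keep].astype(np.int64)
        out["distance_bp"] = np.where(end[keep] <= peak, -np.abs(signed), np.abs(signed))
        out.loc[inside[keep], "distance_bp"] = 0
        sig.genes = out.sort_values("distance_bp", key=np.abs).reset_index(drop=True)
    return signals


def signals_to_frame(signals) -> pd.DataFrame:
    rows = []
    for rank, s in enumerate(signals, start=1):
        rows.append(
            {
                "rank": rank,
                "comparison": "_vs_".join(s.pair),
                "contig": s.contig,
                "peak_mbp": s.peak_mbp,
                "peak_fst": round(s.peak_fst, 4),
                "n_windows_above": s.n_windows_above,
                "run_start": s.run_start,
                "run_end": s.run_end,
                "genes": ";".join(s.genes["gene_id"]) if len(s.genes) else "",
                "products": ";".join(s.genes["product"]) if len(s.genes) else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "comparison", "contig", "peak_mbp", "peak_fst",
            "n_windows_above", "run_start", "run_end", "genes", "products",
        ],
    )
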