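"""Population structure: PCA, iterative outlier exclusion, mislabel flagging,
population assignment, and SNP thinning for external structure tools.

The outlier rule is median +/- ``threshold_mads`` x MAD along any of the top
principal components, iterated to a fixed point, with two guards that keep
the rule aimed at *isolated* individuals rather than small populations:

* a component whose flagged set exceeds ``max_flag_fraction`` of samples is
  treated as population structure and skipped (a genuine cluster of tens of
  samples sits far beyond any MAD threshold along its own axis);
* a flagged sample must be separated from the nearest unflagged score on
  that component by at least ``isolation_gap_mads`` MADs, so marginal tail
  fluctuations of the main body are not excluded.

Mislabel flagging assigns each recorded label a "home" cluster (the cluster
holding the majority of samples carrying that label); samples sitting in a
different cluster than their label's home are excluded as anomalous. This
reproduces the manual judgement "labeled as collected in one province but
clustering with another population" as a testable rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .genotypes import GenotypeMatrix
from .rng import substream

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    coords: np.ndarray                 # (n_samples, k)
    explained_variance_ratio: np.ndarray
    site_indices: np.ndarray
    samples: list = field(default_factory=list)


@dataclass
class PopulationAssignment:
    table: pd.DataFrame  # sample_id, status, cluster, population, dist_to_centroid

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "assigned"]

    @property
    def n_assigned(self) -> int:
        return int((self.table["status"] == "assigned").sum())

    @property
    def n_anomalous(self) -> int:
        return int((self.table["status"] == "excluded_anomalous").sum())


# ------------------------------------------------------------------ sites
def select_pca_sites(
    gm: GenotypeMatrix,
    n_target: int = 100_000,
    seed: int = 0,
    exclude_contigs=(),
) -> np.ndarray:
    """Biallelic segregating non-singleton sites on autosomal contigs,
    down-sampled uniformly to ``n_target`` when the supply exceeds it."""
    counts = gm.allele_counts()
    distinct = (counts > 0).sum(axis=1)
    biallelic = distinct == 2
    # minor allele observed on >= 2 chromosomes
    sorted_counts = np.sort(counts, axis=1)
    minor = sorted_counts[:, -2]
    autosomal = ~np.isin(gm.contig, list(exclude_contigs))
    cand = np.flatnonzero(biallelic & (minor >= 2) & autosomal)
    if cand.size == 0:
        raise ValidationError("no biallelic non-singleton sites available for PCA")
    if cand.size <= n_target:
        if cand.size < n_target:
            log.warning(
                "only %d PCA candidate sites available (target %d); using all",
                cand.size, n_target,
            )
        return cand
    rng = substream(seed, "pca_sites")
    return np.sort(rng.choice(cand, size=n_target, replace=False))


# ------------------------------------------------------------------ PCA
def pca(
    gm: GenotypeMatrix,
    site_indices=None,
    n_components: int = 10,
    sample_idx=None,
    dosage: np.ndarray | None = None,
) -> PcaResult:
    """Centered eigendecomposition of the alternate-allele dosage matrix.

    Missing dosages are imputed to the per-site mean before centering.
    Components are ordered by decreasing variance; each component's sign is
    fixed so its largest-magnitude coordinate is positive (sign is otherwise
    arbitrary).
    """
    if dosage is None:
        idx = None if site_indices is None else np.asarray(site_indices)
        dosage = gm.dosage(idx, impute=False)
    X = dosage if sample_idx is None else dosage[np.asarray(sample_idx)]
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 sites")
    X = X.astype(np.float32, copy=True)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.nan_to_num(np.nanmean(X, axis=0))
        X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
    X -= X.mean(axis=0, keepdims=True)
    G = (X @ X.T).astype(np.float64)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = max(evals.sum(), np.finfo(float).tiny)
    k = min(n_components, n)
    if k < n_components:
        log.info("only %d components available (requested %d)", k, n_components)
    evals_k = np.clip(evals[:k], 0, None)
    coords = evecs[:, :k] * np.sqrt(evals_k)
    flip = np.sign(coords[np.argmax(np.abs(coords), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    coords *= flip
    samples = gm.samples if sample_idx is None else [gm.samples[i] for i in sample_idx]
    return PcaResult(
        coords=coords,
        explained_variance_ratio=evals_k / total,
        site_indices=np.asarray(site_indices) if site_indices is not None else np.arange(m),
        samples=samples,
    )


# ------------------------------------------------------------------ outliers
def iterative_outlier_removal(
    gm: GenotypeMatrix,
    site_indices=None,
    threshold_mads: float = 6.0,
    top_pcs: int = 10,
    max_iter: int = 20,
    max_flag_fraction: float = 0.05,
    isolation_gap_mads: float = 3.0,
) -> pd.DataFrame:
    """Iteratively exclude samples that are isolated outliers along any of the
    top principal components. Returns a table (sample_id, iteration)."""
    dosage = gm.dosage(
        None if site_indices is None else np.asarray(site_indices), impute=False
    )
    keep = np.arange(gm.n_samples)
    removed: list = []
    for it in range(1, max_iter + 1):
        res = pca(gm, site_indices, n_components=top_pcs, sample_idx=keep, dosage=dosage)
        flagged = _flag_outliers(
            res.coords, threshold_mads, max_flag_fraction, isolation_gap_mads
        )
        if flagged.size == 0:
            break
        if flagged.size >= keep.size:
            raise ValidationError(
                "outlier rule flagged every sample; threshold is degenerate"
            )
        for j in flagged:
            removed.append((gm.samples[keep[j]], it))
            log.info("iteration %d: excluded %s as PCA outlier", it, gm.samples[keep[j]])
        keep = np.delete(keep, flagged)
    return pd.DataFrame(removed, columns=["sample_id", "iteration"])


def _flag_outliers(coords, threshold_mads, max_flag_fraction, isolation_gap_mads):
    n = coords.shape[0]
    flagged = np.zeros(n, dtype=bool)
    for c in range(coords.shape[1]):
        s = coords[:, c]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        if mad <= 0:
            continue
        cand = np.abs(s - med) > threshold_mads * mad
        k = int(cand.sum())
        if k == 0 or k > max(1, int(np.floor(max_flag_fraction * n))):
            # a large flagged set along one axis is population structure
            continue
        body = s[~cand]
        for j in np.flatnonzero(cand):
            if np.min(np.abs(body - s[j])) > isolation_gap_mads * mad:
                flagged[j] = True
    return np.flatnonzero(flagged)


# ------------------------------------------------------------------ assignment
def assign_and_flag(
    pca_result: PcaResult,
    recorded_labels: pd.Series,
    n_pcs: int = 2,
    cutoff: float = 0.15,
    expected_clusters: int | None = None,
) -> PopulationAssignment:
    """Single-linkage clustering on the top PCs plus mislabel flagging.

    ``recorded_labels`` maps sample_id -> recorded population label (from the
    metadata sheet). The linkage tree is cut at ``cutoff`` times the largest
    pairwise distance (a proxy for the inter-centroid scale). Each cluster is
    named by its majority recorded label; samples whose cluster is not their
    label's home cluster are excluded as anomalous.
    """
    coords = pca_result.coords[:, :n_pcs]
    samples = pca_result.samples
    labels = recorded_labels.reindex(samples)
    if labels.isna().any():
        raise ValidationError("recorded label missing for some samples")
    if len(samples) < 2:
        raise ValidationError("need at least two samples to cluster")
    d = pdist(coords)
    Z = linkage(d, method="single")
    clusters = fcluster(Z, t=cutoff * d.max(), criterion="distance")
    n_clusters = len(set(clusters))
    if expected_clusters and n_clusters < expected_clusters:
        log.warning(
            "found %d cluster(s), expected %d; consider more PCs or a smaller cutoff",
            n_clusters, expected_clusters,
        )

    df = pd.DataFrame(
        {"sample_id": samples, "cluster": clusters, "recorded": labels.to_numpy()}
    )
    home = (
        df.groupby(["recorded", "cluster"]).size().rename("n").reset_index()
        .sort_values(["n", "cluster"], ascending=[False, True])
        .drop_duplicates("recorded")
        .set_index("recorded")["cluster"]
    )
    majority = (
        df.groupby(["cluster", "recorded"]).size().rename("n").reset_index()
        .sort_values(["n", "recorded"], ascending=[False, True])
        .drop_duplicates("cluster")
        .set_index("cluster")["recorded"]
    )
    anomalous = df["cluster"].to_numpy() != df["recorded"].map(home).to_numpy()
    df["status"] = np.where(anomalous, "excluded_anomalous", "assigned")
    df["population"] = df["cluster"].map(majority)

    dist = np.full(len(df), np.nan)
    for c in np.unique(clusters):
        members = np.flatnonzero((clusters == c) & ~anomalous)
        if members.size:
            centroid = coords[members].mean(axis=0)
            in_c = np.flatnonzero(clusters == c)
            dist[in_c] = np.linalg.norm(coords[in_c] - centroid, axis=1)
    df["dist_to_centroid"] = dist
    for row in df[df["status"] == "excluded_anomalous"].itertuples(index=False):
        log.info(
            "excluded %s as anomalous: recorded %s but clustered with %s",
            row.sample_id, row.recorded, row.population,
        )
    return PopulationAssignment(
        table=df[["sample_id", "status", "cluster", "population", "dist_to_centroid"]]
    )


# ------------------------------------------------------------------ thinning
def thin_snps_for_structure(
    gm: GenotypeMatrix, maf_min: float = 0.01, n_per_contig: int = 50_000
) -> dict:
    """Biallelic SNPs with minor-allele frequency strictly above ``maf_min``,
    thinned by even rank spacing to exactly ``n_per_contig`` per contig."""
    counts = gm.allele_counts()
    called = counts.sum(axis=1)
    distinct = (counts > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(
            called > 0, np.sort(counts, axis=1)[:, -2] / np.maximum(called, 1), 0.0
        )
    passing = (distinct == 2) & (maf > maf_min)
    out: dict = {}
    for c in gm.contig_names():
        idx = np.flatnonzero(passing & (gm.contig == c))
        if idx.size > n_per_contig:
            sel = np.floor(np.linspace(0, idx.size - 1, n_per_contig)).astype(int)
            idx = idx[sel]
        elif idx.size < n_per_contig:
            log.warning(
                "contig %s: only %d SNPs pass MAF filter (target %d)",
                c, idx.size, n_per_contig,
            )
        out[c] = idx
    return out
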