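"""Structured-cohort simulator.

Generates a reference genome with implanted protein-coding gene models, a
multi-population diploid genotype matrix under a hierarchical
Balding-Nichols model, and the truth tables needed to score every
downstream pipeline stage.

The divergence model
--------------------
Per site an ancestral allele frequency ``p`` is drawn uniform on
[0.05, 0.95]. Population frequencies arise by Beta drift along a rooted
hierarchy fitted to the configured pairwise-F matrix: UPGMA (average
linkage) on the F matrix gives an ultrametric tree whose node heights are
pairwise F values; each edge contributes Balding-Nichols drift equal to its
height span, i.e. child frequency ~ Beta with mean q and variance
q(1-q)*F_edge around its parent's frequency q. Hudson's Fst estimator then
recovers the configured pairwise F in expectation (exactly to second order
in F), which is what makes the generator a quantitative oracle for the
divergence scan.

Sweeps replace the target population's terminal-edge F by ``f_sweep``
inside the configured interval; outlier individuals are each drawn from
their own private population with large drift (so they are isolated points
in PCA space, not a fifth cluster); mislabeled samples are genuine draws
from one population recorded under another population's collection site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .config import CohortConfig
from .errors import ConfigurationError
from .genotypes import GenotypeMatrix
from . import io
from .rng import substream

log = logging.getLogger(__name__)

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = (b"TAA", b"TAG", b"TGA")
_SENSE_CODONS = [
    bytes(c)
    for c in (
        bytes([a, b, d])
        for a in b"ACGT"
        for b in b"ACGT"
        for d in b"ACGT"
    )
    if bytes(c) not in _STOPS
]
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP[_a] = _b

_IR_PRODUCTS = {
    "Ace1": "acetylcholinesterase",
    "Rdl": "GABA-gated chloride channel subunit",
    "KDR": "voltage-gated sodium channel",
    "GSTe2": "glutathione S-transferase epsilon 2",
}
_PROVINCES = {"TD": "West", "PV": "North", "RK1": "Northeast", "RK2": "Northeast"}


@dataclass
class Reference:
    """Synthetic reference: contig sequences plus single-CDS gene models."""

    contigs: dict
    genes: pd.DataFrame
    ir_regions: pd.DataFrame

    def lengths(self) -> dict:
        return {c: len(s) for c, s in self.contigs.items()}


@dataclass
class CohortTruth:
    """Ground truth for scoring pipeline stages."""

    samples: pd.DataFrame       # per-sample origin, labels, flags, coverage
    sweeps: pd.DataFrame        # planted sweep intervals
    site_n_alleles: np.ndarray  # distinct alleles per site before missingness
    pop_names: list = field(default_factory=list)

    def metadata(self) -> pd.DataFrame:
        """The sample-metadata sheet a field study would ship (no truth columns)."""
        cols = [
            "sample_id", "collection_site", "province", "year",
            "median_coverage", "breadth_1x", "recorded_population",
        ]
        return self.samples[cols].copy()


def revcomp(seq: bytes) -> bytes:
    return _COMP[np.frombuffer(seq, dtype=np.uint8)][::-1].tobytes()


# ===================================================================
# Reference + gene models
# ===================================================================
def build_reference(config: CohortConfig) -> Reference:
    """Random contigs with implanted, non-overlapping, frame-valid CDS genes.

    Each gene is a single-exon CDS: ATG, a run of sense codons, and a stop
    codon; minus-strand genes are implanted as the reverse complement so the
    annotated strand reads as a valid ORF.
    """
    config.validate()
    contigs: dict = {}
    gene_rows = []
    for ci, cname in enumerate(config.contig_names()):
        rng = substream(config.seed, "reference", ci)
        L = config.contig_length_bp
        seq = _NUC[rng.integers(0, 4, L)]
        if config.gene_fraction > 0:
            mean_bp = max(9, 3 * (config.mean_gene_bp // 3))
            n_genes = int(round(config.gene_fraction * L / mean_bp))
            if n_genes > 0:
                lengths = 3 * rng.integers(
                    max(3, mean_bp // 6), max(4, mean_bp // 2), size=n_genes
                )  # codons in [mean/6, mean/2) -> bp in [mean/2, 3mean/2)
                free = L - int(lengths.sum())
                if free < 0:
                    raise ConfigurationError(
                        f"contig {cname} too short for requested gene density"
                    )
                gaps = np.floor(rng.dirichlet(np.ones(n_genes + 1)) * free).astype(int)
                start = 0
                for gi in range(n_genes):
                    start += int(gaps[gi])
                    end = start + int(lengths[gi])
                    strand = "+" if rng.random() < 0.5 else "-"
                    n_codons = int(lengths[gi]) // 3
                    body = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
                    cds = (
                        b"ATG"
                        + b"".join(_SENSE_CODONS[j] for j in body)
                        + _STOPS[rng.integers(0, 3)]
                    )
                    ins = cds if strand == "+" else revcomp(cds)
                    seq[start:end] = np.frombuffer(ins, dtype=np.uint8)
                    gene_rows.append(
                        {
                            "gene_id": f"{cname}_g{gi + 1:04d}",
                            "contig": cname,
                            "start": start,
                            "end": end,
                            "strand": strand,
                            "product": "hypothetical protein",
                        }
                    )
                    start = end
        contigs[cname] = seq.tobytes().decode()
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "contig", "start", "end", "strand", "product"],
    )
    ir_regions = _name_ir_genes(genes, config)
    return Reference(contigs=contigs, genes=genes, ir_regions=ir_regions)


def _name_ir_genes(genes: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Mark one mid-contig gene per contig (up to four) as a canonical
    insecticide-resistance locus so the IR report stage has configured targets."""
    rows = []
    for name, cname in zip(_IR_PRODUCTS, config.contig_names()):
        sub = genes.index[genes["contig"] == cname]
        if len(sub) == 0:
            continue
        gi = sub[len(sub) // 2]
        genes.loc[gi, "product"] = _IR_PRODUCTS[name]
        rows.append(
            {
                "contig": cname,
                "start": int(genes.loc[gi, "start"]),
                "end": int(genes.loc[gi, "end"]),
                "name": name,
            }
        )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])


# ===================================================================
# Divergence hierarchy
# ===================================================================
def _hierarchy(fst: np.ndarray):
    """UPGMA hierarchy over the pairwise-F matrix.

    Returns (children, heights) where node ids 0..n-1 are leaves (height 0)
    and internal node n+k merges ``children[k]`` at height Z[k, 2].
    """
    n = fst.shape[0]
    if n == 1:
        return [], np.zeros(1)
    Z = linkage(squareform(fst, checks=False), method="average")
    heights = np.zeros(2 * n - 1)
    children = []
    for k in range(n - 1):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        h = max(Z[k, 2], heights[a], heights[b])  # enforce monotone heights
        heights[n + k] = h
        children.append((a, b))
    return children, heights


def _beta_drift(rng: np.random.Generator, q: np.ndarray, f) -> np.ndarray:
    """Balding-Nichols draw: Beta with mean q, variance q(1-q)*f (per site)."""
    f = np.broadcast_to(np.asarray(f, dtype=float), q.shape)
    out = q.copy()
    drift = f > 0
    if drift.any():
        qq = np.clip(q[drift], 1e-9, 1 - 1e-9)
        ff = f[drift]
        scale = (1.0 - ff) / ff
        out[drift] = rng.beta(qq * scale, (1.0 - qq) * scale)
    return out


# ===================================================================
# Genotype simulation
# ===================================================================
def simulate_genotypes(config: CohortConfig, reference: Reference):
    """Draw the cohort's diploid genotypes and the associated truth tables.

    Returns ``(GenotypeMatrix, CohortTruth)``. Sample columns are shuffled
    (seeded) unless ``config.shuffle_samples`` is False.
    """
    config.validate()
    if config.sweep_specs and config.fst().max() == 0 and any(
        sw.f_sweep <= 0 for sw in config.sweep_specs
    ):  # pragma: no cover - caught by validate
        raise ConfigurationError("sweeps require positive f_sweep")

    n_pops = config.n_populations
    children, heights = _hierarchy(config.fst())
    root = 2 * n_pops - 2 if n_pops > 1 else 0

    sample_table = _sample_table(config)
    col_of_pop = {
        name: np.flatnonzero(
            (sample_table["true_population"] == name).to_numpy()
        )
        for name in config.pop_names
    }
    outlier_cols = np.flatnonzero(sample_table["is_outlier"].to_numpy())

    all_contig, all_pos, all_gt = [], [], []
    site_classes = []
    for ci, cname in enumerate(config.contig_names()):
        rng = substream(config.seed, "genotypes", ci)
        L = len(reference.contigs[cname])
        m = config.n_sites_per_contig
        pos = np.sort(rng.choice(L, size=m, replace=False))
        if config.ancestral_sfs == "neutral":
            # density ~ 1/p on [0.001, 0.999]: log-uniform draw
            lo, hi = 1e-3, 1 - 1e-3
            p_anc = lo * np.exp(rng.random(m) * np.log(hi / lo))
        else:
            p_anc = rng.uniform(0.05, 0.95, size=m)

        # frequencies down the hierarchy
        node_freq = {root: p_anc}
        for k in range(len(children) - 1, -1, -1):
            a, b = children[k]
            parent = n_pops + k
            for child in (a, b):
                edge_f = max(0.0, heights[parent] - heights[child])
                if child < n_pops:
                    f_site = np.full(m, edge_f)
                    for sw in config.sweep_specs:
                        if (
                            sw.contig == cname
                            and sw.target_population == config.pop_names[child]
                        ):
                            in_sw = (pos >= sw.start_bp) & (pos < sw.end_bp)
                            f_site[in_sw] = sw.f_sweep
                    node_freq[child] = _beta_drift(rng, node_freq[parent], f_site)
                else:
                    node_freq[child] = _beta_drift(rng, node_freq[parent], edge_f)
        if n_pops == 1:
            node_freq[0] = p_anc
        for pi, name in enumerate(config.pop_names):
            extra = config.pop_extra_f.get(name, 0.0)
            if extra > 0:
                node_freq[pi] = _beta_drift(rng, node_freq[pi], extra)

        gt = np.zeros((m, config.n_samples, 2), dtype=np.int8)
        for pi, name in enumerate(config.pop_names):
            cols = col_of_pop[name]
            pk = node_freq[pi][:, None, None]
            gt[:, cols, :] = (rng.random((m, len(cols), 2)) < pk).astype(np.int8)
        for j, col in enumerate(outlier_cols):
            p_out = _beta_drift(rng, p_anc, config.outlier_f)
            gt[:, col, :] = (rng.random((m, 2)) < p_out[:, None]).astype(np.int8)

        _split_multiallelic(rng, gt, config)
        site_classes.append(_n_distinct_alleles(gt))

        if config.missing_rate > 0:
            miss = rng.random((m, config.n_samples)) < config.missing_rate
            gt[miss] = -1

        all_contig.append(np.full(m, cname, dtype=object))
        all_pos.append(pos)
        all_gt.append(gt)

    contig = np.concatenate(all_contig)
    pos = np.concatenate(all_pos)
    gt = np.concatenate(all_gt)
    site_n_alleles = np.concatenate(site_classes)

    if config.shuffle_samples:
        perm = substream(config.seed, "shuffle").permutation(config.n_samples)
        gt = gt[:, perm]
        sample_table = sample_table.iloc[perm].reset_index(drop=True)

    alleles = _assign_alleles(config, reference, contig, pos, gt)
    gm = GenotypeMatrix(
        contig=contig,
        pos=pos,
        alleles=alleles,
        gt=gt,
        samples=sample_table["sample_id"].tolist(),
    )
    sweeps = pd.DataFrame(
        [
            {
                "contig": sw.contig,
                "start": sw.start_bp,
                "end": sw.end_bp,
                "target_population": sw.target_population,
                "f_sweep": sw.f_sweep,
            }
            for sw in config.sweep_specs
        ],
        columns=["contig", "start", "end", "target_population", "f_sweep"],
    )
    truth = CohortTruth(
        samples=sample_table,
        sweeps=sweeps,
        site_n_alleles=site_n_alleles,
        pop_names=list(config.pop_names),
    )
    return gm, truth


def _sample_table(config: CohortConfig) -> pd.DataFrame:
    rng = substream(config.seed, "metadata")
    rows = []
    k = 0

    def site_of(pop):
        return f"{pop}_village"

    def province_of(pop):
        return _PROVINCES.get(pop, f"{pop}_province")

    for name, size in zip(config.pop_names, config.pop_sizes):
        for _ in range(size):
            k += 1
            rows.append((f"AM{k:04d}", name, name, site_of(name), False, False))
    for _ in range(config.n_mislabeled):
        k += 1
        rec = config.mislabel_recorded_pop
        rows.append(
            (f"AM{k:04d}", config.mislabel_true_pop, rec, site_of(rec), False, True)
        )
    for j in range(config.n_outliers):
        k += 1
        rec = config.pop_names[j % config.n_populations]
        rows.append((f"AM{k:04d}", "outlier", rec, site_of(rec), True, False))
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "true_population", "recorded_population",
            "collection_site", "is_outlier", "is_mislabeled",
        ],
    )
    df["province"] = df["recorded_population"].map(province_of)
    df["year"] = rng.choice([2010, 2011, 2014, 2015], size=len(df))
    # coverage summaries for a cohort that passed sequencing QC (median ~35x)
    df["median_coverage"] = np.round(np.clip(rng.normal(35, 6, len(df)), 12, None), 1)
    df["breadth_1x"] = np.round(rng.uniform(0.90, 0.995, len(df)), 4)
    return df


def _split_multiallelic(rng, gt: np.ndarray, config: CohortConfig) -> None:
    """Relabel alternate-allele copies at a configured fraction of segregating
    sites so they become tri-/quadriallelic; total allele count is conserved."""
    if config.multiallelic_fraction <= 0:
        return
    alt_counts = (gt == 1).sum(axis=(1, 2))
    called = gt.shape[1] * 2
    segregating = np.flatnonzero((alt_counts > 0) & (alt_counts < called))
    n_multi = int(round(config.multiallelic_fraction * len(segregating)))
    eligible = segregating[alt_counts[segregating] >= 2]
    n_multi = min(n_multi, len(eligible))
    if n_multi == 0:
        return
    chosen = rng.choice(eligible, size=n_multi, replace=False)
    n_quad = int(round(config.quadriallelic_share * n_multi))
    quad_ok = chosen[alt_counts[chosen] >= 3]
    quad = set(quad_ok[:n_quad].tolist())
    for s in chosen:
        flat = gt[s].reshape(-1)
        idx = np.flatnonzero(flat == 1)
        top = 3 if s in quad else 2
        labels = rng.integers(1, top + 1, size=len(idx)).astype(np.int8)
        labels[:top] = np.arange(1, top + 1)  # guarantee all classes present
        flat[idx] = labels


def _n_distinct_alleles(gt: np.ndarray) -> np.ndarray:
    counts = np.zeros((gt.shape[0], 4), dtype=np.int64)
    flat = gt.reshape(gt.shape[0], -1)
    site_idx = np.repeat(np.arange(flat.shape[0]), flat.shape[1])
    called = flat.ravel() >= 0
    np.add.at(counts, (site_idx[called], flat.ravel()[called].astype(np.int64)), 1)
    return (counts > 0).sum(axis=1)


def _assign_alleles(config, reference, contig, pos, gt) -> list:
    """REF = reference base at the site; ALTs drawn from the other nucleotides."""
    others = {
        "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG",
    }
    max_allele = gt.max(axis=(1, 2))
    alleles = []
    rng = substream(config.seed, "alleles")
    perms = rng.permuted(np.tile(np.arange(3), (len(pos), 1)), axis=1)
    for i in range(len(pos)):
        ref = reference.contigs[contig[i]][pos[i]]
        alt_pool = others.get(ref, "ACG")
        n_alt = max(1, int(max_allele[i]))
        alleles.append((ref, *[alt_pool[j] for j in perms[i, :n_alt]]))
    return alleles


# ===================================================================
# Serialisation
# ===================================================================
def write_cohort(gm: GenotypeMatrix, truth: CohortTruth, reference: Reference, outdir):
    """Write FASTA + GFF3 + VCF + metadata/truth TSVs + IR-region BED."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fasta",
        "gff3": outdir / "genes.gff3",
        "vcf": outdir / "cohort.vcf",
        "metadata": outdir / "metadata.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "truth_sweeps": outdir / "truth_sweeps.tsv",
        "ir_regions": outdir / "ir_regions.bed",
    }
    io.write_fasta(reference.contigs, paths["fasta"])
    io.write_gff3(reference.genes, paths["gff3"])
    io.write_vcf(gm, paths["vcf"], contig_lengths=reference.lengths())
    io.write_tsv(truth.metadata(), paths["metadata"])
    io.write_tsv(truth.samples, paths["truth_samples"])
    io.write_tsv(truth.sweeps, paths["truth_sweeps"])
    io.write_bed(truth_ir_regions(reference), paths["ir_regions"])
    return paths


def truth_ir_regions(reference: Reference) -> pd.DataFrame:
    return reference.ir_regions


def simulate_cohort(config: CohortConfig):
    """Convenience: build the reference and draw the cohort in one call."""
    reference = build_reference(config)
    gm, truth = simulate_genotypes(config, reference)
    return reference, gm, truth
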