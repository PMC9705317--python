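import numpy as np
import pytest

import minpop


def make_gm(gt, contig="c1", pos=None, alleles=None, samples=None):
    """Build a small GenotypeMatrix from a nested list of diploid calls.

    ``gt`` is (n_sites, n_samples, 2) allele indices with -1 for missing.
    """
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape[0], gt.shape[1]
    if pos is None:
        pos = np.arange(n_sites)
    if isinstance(contig, str):
        contig = np.full(n_sites, contig, dtype=object)
    if alleles is None:
        alleles = [("A", "C", "G", "T")[: max(2, int(gt[i].max()) + 1)] for i in range(n_sites)]
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return minpop.GenotypeMatrix(
        contig=np.asarray(contig, dtype=object),
        pos=np.asarray(pos),
        alleles=list(alleles),
        gt=gt,
        samples=list(samples),
    )


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Small two-population cohort with multiallelic sites and missing calls."""
    cfg = minpop.CohortConfig(
        n_contigs=2,
        contig_length_bp=200_000,
        n_sites_per_contig=3000,
        pop_names=["A", "B"],
        pop_sizes=[10, 12],
        fst_matrix=0.05,
        multiallelic_fraction=0.134,
        n_outliers=2,
        n_mislabeled=2,
        mislabel_true_pop="B",
        mislabel_recorded_pop="A",
        missing_rate=0.02,
        seed=1,
    )
    reference, gm, truth = minpop.simulate_cohort(cfg)
    return cfg, reference, gm, truth


@pytest.fixture(scope="session")
def four_pop_cohort():
    """Scaled-down structured cohort: 4 populations (one pair weakly diverged),
    3 planted isolated outliers and 3 mislabeled samples."""
    F = np.full((4, 4), 0.1)
    F[0, 1] = F[1, 0] = 0.01
    np.fill_diagonal(F, 0.0)
    cfg = minpop.CohortConfig(
        n_contigs=2,
        contig_length_bp=300_000,
        n_sites_per_contig=6000,
        pop_names=["A", "B", "C", "D"],
        pop_sizes=[12, 30, 14, 10],
        fst_matrix=F,
        multiallelic_fraction=0.1,
        n_outliers=3,
        n_mislabeled=3,
        mislabel_true_pop="D",
        mislabel_recorded_pop="B",
        seed=21,
    )
    reference, gm, truth = minpop.simulate_cohort(cfg)
    return cfg, reference, gm, truth


def populations_of(truth):
    """population name -> sample ids, from the truth table (non-outliers)."""
    t = truth.samples
    return {
        p: t.loc[t["true_population"] == p, "sample_id"].tolist()
        for p in truth.pop_names
    }
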