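"""Degeneracy annotation and the diversity statistics, checked against
independently coded brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import minpop
from minpop.diversity import (
    bootstrap_ci,
    downsample_population,
    fourfold_degenerate_mask,
    nucleotide_diversity,
    site_pairwise_diversity,
    tajimas_d,
    watterson_theta,
)
from minpop.errors import ValidationError

from conftest import populations_of


# =================================================================
# Independent oracles (pair enumeration, scalar arithmetic)
# =================================================================
def pi_oracle(counts):
    """Mean pairwise difference per site by explicit pair enumeration."""
    total = 0.0
    for c in counts:
        chroms = []
        for allele, k in enumerate(c):
            chroms.extend([allele] * int(k))
        n = len(chroms)
        if n < 2:
            continue
        diff = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if chroms[i] != chroms[j]
        )
        total += diff / (n * (n - 1) / 2)
    return total


def tajima_oracle(counts, n):
    """Tajima (1989) D recomputed from scratch with scalar arithmetic."""
    S = sum(1 for c in counts if sum(1 for x in c if x > 0) > 1)
    if S == 0:
        return float("nan")
    Pi = pi_oracle([c for c in counts if sum(1 for x in c if x > 0) > 1])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (Pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# =================================================================
# four-fold degeneracy
# =================================================================
def cds_row(contig, start, end, strand, phase=0):
    return pd.DataFrame(
        [{"contig": contig, "start": start, "end": end, "strand": strand, "phase": phase}]
    )


def test_fourfold_plus_strand_ala_and_trp():
    # GCT (Ala: GCx all Ala -> 3rd position 4-fold), TGG (Trp: unique codon)
    mask = fourfold_degenerate_mask({"c": "GCTTGG"}, cds_row("c", 0, 6, "+"))["c"]
    assert mask.tolist() == [False, False, True, False, False, False]


def test_fourfold_minus_strand_lands_on_forward_coordinates():
    # minus-strand CDS whose coding sequence is AGC GGC:
    # forward contig = revcomp("AGCGGC") = "GCCGCT".
    # AGC (Ser, 2-fold) occupies forward [3,6) with 3rd codon position at 3;
    # GGC (Gly, 4-fold) occupies [0,3) with 3rd codon position at 0.
    mask = fourfold_degenerate_mask({"c": "GCCGCT"}, cds_row("c", 0, 6, "-"))["c"]
    assert mask.tolist() == [True, False, False, False, False, False]


def test_fourfold_overlapping_frames_must_agree():
    # same interval annotated in two frames: position 2 is 4-fold in the
    # phase-0 frame (GCT=Ala) but a 1st/2nd codon position in the shifted
    # frame, so it must not be flagged.
    cds = pd.concat(
        [cds_row("c", 0, 6, "+", phase=0), cds_row("c", 1, 7, "+", phase=0)]
    )
    mask = fourfold_degenerate_mask({"c": "GCTGCTGC"}, cds)["c"]
    assert not mask[2]


def test_fourfold_mask_respects_cds_bounds(two_pop_cohort):
    _, ref, _, _ = two_pop_cohort
    mask = fourfold_degenerate_mask(ref.contigs, ref.genes.assign(phase=0))
    for contig, sub in ref.genes.groupby("contig"):
        m = mask[contig]
        assert m.sum() <= len(m) / 3
        inside = np.zeros(len(m), dtype=bool)
        for row in sub.itertuples(index=False):
            inside[row.start : row.end] = True
        assert not m[~inside].any(), "flags only inside annotated CDS"


def test_incomplete_terminal_codon_ignored():
    mask = fourfold_degenerate_mask({"c": "GCTGC"}, cds_row("c", 0, 5, "+"))["c"]
    assert mask.tolist() == [False, False, True, False, False]


# =================================================================
# pi
# =================================================================
@pytest.mark.parametrize(
    "counts,expected",
    [
        ([[4, 0]], 0.0),            # monomorphic
        ([[1, 1]], 1.0),            # single discordant pair
        ([[2, 2]], 4 / 6),          # 4 differing of 6 pairs
    ],
)
def test_pi_single_site_values(counts, expected):
    assert nucleotide_diversity(np.array(counts), accessible=1) == pytest.approx(expected)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_pi_kernel_equals_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n_sites = rng.integers(1, 40)
    n = rng.integers(2, 20)
    counts = rng.multinomial(n, [0.55, 0.25, 0.15, 0.05], size=n_sites)
    ours = np.nansum(site_pairwise_diversity(counts))
    assert ours == pytest.approx(pi_oracle(counts), abs=1e-10)


def test_pi_requires_accessible_sites():
    with pytest.raises(ValidationError):
        nucleotide_diversity(np.array([[1, 1]]), accessible=0)


# =================================================================
# Watterson's theta
# =================================================================
def test_watterson_values_and_scaling():
    assert watterson_theta(0, 10, 100) == 0.0
    assert watterson_theta(11, 4, 100) == pytest.approx(0.06)  # a_4 = 11/6
    assert watterson_theta(11, 4, 200) == pytest.approx(0.03)


def test_watterson_needs_two_chromosomes():
    with pytest.raises(ValidationError):
        watterson_theta(5, 1, 100)


# =================================================================
# Tajima's D
# =================================================================
def test_tajimas_d_matches_oracle_on_spec_case():
    counts = np.array([[1, 9]] * 3 + [[5, 5]])
    assert tajimas_d(counts, 10) == pytest.approx(tajima_oracle(counts.tolist(), 10), abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_tajimas_d_matches_oracle_on_random_spectra(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    n_sites = int(rng.integers(2, 60))
    freqs = rng.integers(0, n + 1, size=n_sites)
    counts = np.stack([n - freqs, freqs], axis=1)
    if ((counts > 0).sum(axis=1) > 1).sum() == 0:
        counts[0] = [n - 1, 1]
    assert tajimas_d(counts, n) == pytest.approx(
        tajima_oracle(counts.tolist(), n), abs=1e-10
    )


def test_excess_singletons_give_negative_d():
    n = 40
    counts = np.array([[n - 1, 1]] * 50)
    assert tajimas_d(counts, n) < 0


def test_neutral_sfs_gives_mean_d_near_zero():
    """E[D] ~ 0 when site frequencies follow the neutral 1/i spectrum."""
    n, S, reps = 20, 2000, 50
    weights = 1.0 / np.arange(1, n)
    weights /= weights.sum()
    rng = np.random.default_rng(2024)
    ds = []
    for _ in range(reps):
        i = rng.choice(np.arange(1, n), size=S, p=weights)
        counts = np.stack([n - i, i], axis=1)
        ds.append(tajimas_d(counts, n))
    assert abs(np.mean(ds)) < 0.15


def test_d_undefined_without_segregating_sites():
    assert math.isnan(tajimas_d(np.array([[4, 0], [4, 0]]), 4))


def test_d_requires_uniform_sample_size():
    with pytest.raises(ValidationError):
        tajimas_d(np.array([[2, 2], [1, 2]]))


# =================================================================
# downsampling and bootstrap
# =================================================================
def test_downsampling_to_smallest_population():
    pops = {
        "TD": [f"td{i}" for i in range(41)],
        "PV": [f"pv{i}" for i in range(156)],
        "RK1": [f"r1{i}" for i in range(58)],
        "RK2": [f"r2{i}" for i in range(28)],
    }
    down = downsample_population(pops, seed=1)
    assert {k: len(v) for k, v in down.items()} == {k: 28 for k in pops}
    for k in pops:
        assert set(down[k]) <= set(pops[k])
    assert down == downsample_population(pops, seed=1)
    assert down["RK2"] == pops["RK2"]  # target equals size -> identity


def test_downsampling_target_too_large_raises():
    with pytest.raises(ValidationError):
        downsample_population({"A": ["a", "b"]}, target=3)


def test_bootstrap_constant_statistic_zero_width():
    ci = bootstrap_ci(lambda ids: 1.5, list("abcdef"), n_boot=30, seed=0)
    assert ci.lower == ci.upper == 1.5


def test_bootstrap_is_seeded():
    stat = lambda ids: float(len(set(ids)))
    a = bootstrap_ci(stat, list("abcdefgh"), n_boot=50, seed=5)
    b = bootstrap_ci(stat, list("abcdefgh"), n_boot=50, seed=5)
    assert (a.lower, a.upper) == (b.lower, b.upper)


def test_bootstrap_flags_unreliable():
    calls = iter(range(10**6))
    stat = lambda ids: float("nan") if next(calls) % 2 else 1.0
    ci = bootstrap_ci(stat, list("abcd"), n_boot=40, seed=1)
    assert ci.unreliable


# =================================================================
# the full report
# =================================================================
@pytest.fixture(scope="module")
def diversity_cohort():
    cfg = minpop.CohortConfig(
        n_contigs=1, contig_length_bp=2_100_000, n_sites_per_contig=40_000,
        pop_names=["A", "B"], pop_sizes=[28, 30], fst_matrix=0.01,
        multiallelic_fraction=0.05, pop_extra_f={"B": 0.3},
        ancestral_sfs="neutral", n_outliers=0, n_mislabeled=0, seed=4,
    )
    ref, gm, truth = minpop.simulate_cohort(cfg)
    mask = fourfold_degenerate_mask(ref.contigs, ref.genes.assign(phase=0))
    rep = minpop.diversity_report(
        gm, populations_of(truth), mask, min_contig_bp=2_000_000, n_boot=50, seed=2
    )
    return rep


def test_report_cis_bracket_point_estimates(diversity_cohort):
    rep = diversity_cohort
    assert ((rep["ci_lower"] <= rep["estimate"]) & (rep["estimate"] <= rep["ci_upper"])).all()
    piv = rep.pivot(index="population", columns="statistic", values="estimate")
    assert (piv["pi"] >= 0).all() and (piv["theta_w"] >= 0).all()


def test_higher_drift_population_has_lower_diversity(diversity_cohort):
    piv = diversity_cohort.pivot(index="population", columns="statistic", values="estimate")
    assert piv.loc["B", "pi"] < piv.loc["A", "pi"]
    assert piv.loc["B", "theta_w"] < piv.loc["A", "theta_w"]


def test_pi_and_theta_agree_without_drift():
    cfg = minpop.CohortConfig(
        n_contigs=1, contig_length_bp=2_100_000, n_sites_per_contig=50_000,
        pop_names=["A"], pop_sizes=[28], fst_matrix=0.0, multiallelic_fraction=0.0,
        ancestral_sfs="neutral", n_outliers=0, n_mislabeled=0, seed=12,
    )
    _, gm, _ = minpop.simulate_cohort(cfg)
    counts = gm.allele_counts()
    accessible = cfg.contig_length_bp
    pi = nucleotide_diversity(counts, accessible)
    S = int(((counts > 0).sum(axis=1) > 1).sum())
    theta = watterson_theta(S, 56, accessible)
    assert pi == pytest.approx(theta, rel=0.05)
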