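"""Hudson Fst components, windowing, genome averages, signal detection and
peak-to-gene annotation."""

import numpy as np
import pandas as pd
import pytest

import minpop
from minpop.errors import ValidationError
from minpop.fst import (
    annotate_signals,
    average_fst_matrix,
    detect_signals,
    hudson_fst_components,
    pair_windowed_fst,
    windowed_fst,
)

from conftest import make_gm, populations_of


# ------------------------------------------------------------ per-site
def test_fixed_difference_gives_unit_fst():
    num, den, usable = hudson_fst_components(np.array([[0, 10]]), np.array([[8, 0]]))
    assert usable[0]
    assert num[0] == pytest.approx(1.0) and den[0] == pytest.approx(1.0)


def test_within_population_sampling_correction_is_negative():
    # identical frequencies: numerator is minus the sampling terms
    num, den, _ = hudson_fst_components(np.array([[5, 5]]), np.array([[5, 5]]))
    assert num[0] == pytest.approx(-2 * 0.25 / 9)
    assert den[0] == pytest.approx(0.5)


def test_hand_computed_components():
    num, den, _ = hudson_fst_components(np.array([[2, 8]]), np.array([[8, 2]]))
    assert num[0] == pytest.approx(0.324444, abs=1e-6)
    assert den[0] == pytest.approx(0.68)
    assert num[0] / den[0] == pytest.approx(0.477124, abs=1e-6)


def test_monomorphic_in_both_site_excluded():
    num, den, usable = hudson_fst_components(np.array([[10, 0]]), np.array([[6, 0]]))
    assert not usable[0] and np.isnan(num[0])


def test_insufficient_chromosomes_skipped():
    num, den, usable = hudson_fst_components(np.array([[1, 0]]), np.array([[5, 5]]))
    assert not usable[0]


def test_label_swap_symmetry():
    rng = np.random.default_rng(0)
    ac1 = rng.integers(0, 10, (50, 2)) + 1
    ac2 = rng.integers(0, 10, (50, 2)) + 1
    n1, d1, _ = hudson_fst_components(ac1, ac2)
    n2, d2, _ = hudson_fst_components(ac2, ac1)
    assert np.allclose(n1, n2, equal_nan=True) and np.allclose(d1, d2, equal_nan=True)


# ------------------------------------------------------------ windows
def _fixed_difference_gm(n_sites=250):
    gt = np.zeros((n_sites, 8, 2), dtype=np.int8)
    gt[:, 4:] = 1  # second half of samples fixed for the alternate allele
    return make_gm(gt, pos=np.arange(0, n_sites * 100, 100))


def test_all_fixed_difference_windows_are_one():
    gm = _fixed_difference_gm()
    win = pair_windowed_fst(
        gm, np.arange(4), np.arange(4, 8), mode="snp", window_snps=50
    )
    assert len(win) == 5
    assert np.allclose(win["fst"], 1.0)


def test_window_fst_bounded_by_one_and_symmetric(two_pop_cohort):
    _, _, gm, truth = two_pop_cohort
    pops = populations_of(truth)
    i1 = gm.sample_indices(pops["A"])
    i2 = gm.sample_indices(pops["B"])
    w12 = pair_windowed_fst(gm, i1, i2, mode="snp", window_snps=200)
    w21 = pair_windowed_fst(gm, i2, i1, mode="snp", window_snps=200)
    assert (w12["fst"] <= 1 + 1e-12).all()
    assert np.allclose(w12["fst"], w21["fst"])


def test_snp_windows_have_exact_size_and_drop_partial():
    gm = _fixed_difference_gm(n_sites=230)
    win = pair_windowed_fst(gm, np.arange(4), np.arange(4, 8), mode="snp", window_snps=100)
    assert len(win) == 2
    assert (win["n_snps"] == 100).all()


def test_positional_windows_tile_half_open():
    num = np.full(4, 0.5)
    den = np.ones(4)
    pos = np.array([0, 19_999, 20_000, 45_000])
    win = windowed_fst(
        np.array(["c"] * 4, dtype=object), pos, num, den,
        mode="position", window_bp=20_000, contig_lengths={"c": 60_000},
    )
    assert win["start"].tolist() == [0, 20_000, 40_000]
    assert win["n_snps"].tolist() == [2, 1, 1]


def test_identical_populations_average_near_zero():
    rng = np.random.default_rng(42)
    n_sites = 4000
    p = rng.uniform(0.1, 0.9, n_sites)
    gt = (rng.random((n_sites, 40, 2)) < p[:, None, None]).astype(np.int8)
    gm = make_gm(gt, pos=np.arange(n_sites) * 10)
    win = pair_windowed_fst(gm, np.arange(20), np.arange(20, 40), mode="snp", window_snps=500)
    m = win["fst"].mean()
    se = win["fst"].std() / np.sqrt(len(win))
    assert abs(m) < 3 * se


# ------------------------------------------------------------ averages
def test_average_fst_matrix_properties(two_pop_cohort):
    _, ref, gm, truth = two_pop_cohort
    pops = populations_of(truth)
    mat = average_fst_matrix(gm, pops, "ctg01", contig_lengths=ref.lengths())
    assert np.allclose(mat.values, mat.values.T, atol=1e-12)
    assert np.allclose(np.diag(mat.values), 0.0)
    assert mat.loc["A", "B"] > 0.02  # configured F=0.05


def test_random_split_of_one_population_has_near_zero_fst(two_pop_cohort):
    _, ref, gm, truth = two_pop_cohort
    b = populations_of(truth)["B"]
    rng = np.random.default_rng(7)
    perm = rng.permutation(len(b))
    half = {"B1": [b[i] for i in perm[:7]], "B2": [b[i] for i in perm[7:]]}
    mat = average_fst_matrix(gm, half, "ctg01", contig_lengths=ref.lengths())
    assert abs(mat.loc["B1", "B2"]) < 0.01


def test_average_fst_matrix_missing_contig_raises(two_pop_cohort):
    _, ref, gm, truth = two_pop_cohort
    with pytest.raises(ValidationError):
        average_fst_matrix(gm, populations_of(truth), "nope", contig_lengths=ref.lengths())


# ------------------------------------------------------------ signals
def _windows(values, contig="c", start=0):
    starts = start + 10_000 * np.arange(len(values))
    return pd.DataFrame(
        {
            "contig": contig,
            "start": starts,
            "end": starts + 10_000,
            "n_snps": 1000,
            "fst": values,
            "midpoint": starts + 5_000,
        }
    )


def test_flat_series_has_no_signals():
    assert detect_signals(_windows([0.02] * 50)) == []


def test_run_of_four_windows_is_too_short():
    vals = [0.01] * 50 + [0.9] * 4 + [0.01] * 50
    assert detect_signals(_windows(vals), min_run=5) == []


def test_run_of_eight_windows_is_one_signal_with_peak():
    vals = [0.01] * 50 + [0.5, 0.6, 0.9, 0.7, 0.6, 0.55, 0.5, 0.5] + [0.01] * 50
    sigs = detect_signals(_windows(vals))
    assert len(sigs) == 1
    s = sigs[0]
    assert s.n_windows_above == 8
    assert s.peak_fst == pytest.approx(0.9)
    assert s.peak_midpoint == 10_000 * 52 + 5_000
    assert s.run_start == 10_000 * 50 and s.run_end == 10_000 * 58


def test_signals_ranked_by_peak_descending():
    vals = [0.01] * 30 + [0.5] * 6 + [0.01] * 30 + [0.8] * 6 + [0.01] * 30
    sigs = detect_signals(_windows(vals))
    assert [round(s.peak_fst, 2) for s in sigs] == [0.8, 0.5]


def test_empty_series_raises():
    with pytest.raises(ValidationError):
        detect_signals(pd.DataFrame())


def test_signal_detection_invariant_to_contig_order():
    a = _windows([0.01] * 40 + [0.9] * 6 + [0.01] * 40, contig="c1")
    b = _windows([0.01] * 86, contig="c2")
    s1 = detect_signals(pd.concat([a, b], ignore_index=True))
    s2 = detect_signals(pd.concat([b, a], ignore_index=True))
    assert [(s.contig, s.peak_midpoint) for s in s1] == [
        (s.contig, s.peak_midpoint) for s in s2
    ]


# ------------------------------------------------------------ annotation
def _genes():
    return pd.DataFrame(
        [
            {"gene_id": "g_at_peak", "contig": "c", "start": 5_990_000, "end": 6_010_000,
             "strand": "+", "product": "p1"},
            {"gene_id": "g_near", "contig": "c", "start": 5_920_000, "end": 5_950_000,
             "strand": "+", "product": "p2"},
            {"gene_id": "g_far", "contig": "c", "start": 6_150_000, "end": 6_200_000,
             "strand": "+", "product": "p3"},
            {"gene_id": "g_edge", "contig": "c", "start": 6_090_000, "end": 6_100_001,
             "strand": "+", "product": "p4"},
        ]
    )


def _signal(peak):
    from minpop.fst import SelectionSignal

    return SelectionSignal(
        pair=("A", "B"), contig="c", run_start=peak - 50_000, run_end=peak + 50_000,
        n_windows_above=6, peak_midpoint=peak, peak_fst=0.8,
    )


def test_annotation_distances_and_radius():
    sigs = annotate_signals([_signal(6_000_000)], _genes(), radius=100_000)
    g = sigs[0].genes.set_index("gene_id")
    assert g.loc["g_at_peak", "distance_bp"] == 0
    assert g.loc["g_near", "distance_bp"] == -(6_000_000 - 5_949_999)
    assert "g_far" not in g.index                      # 150 kb away
    assert "g_edge" in g.index                         # starts exactly 90 kb away


def test_gene_ending_exactly_at_radius_included():
    genes = pd.DataFrame(
        [{"gene_id": "g", "contig": "c", "start": 5_800_000, "end": 5_900_001,
          "strand": "+", "product": "p"}]
    )
    sigs = annotate_signals([_signal(6_000_000)], genes, radius=100_000)
    assert list(sigs[0].genes["gene_id"]) == ["g"]


def test_unknown_contig_gives_empty_gene_list():
    genes = _genes().assign(contig="other")
    sigs = annotate_signals([_signal(6_000_000)], genes)
    assert len(sigs[0].genes) == 0
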