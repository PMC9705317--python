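"""Generate a small structured cohort and inspect its site-class census.

The generator plants two populations with Balding-Nichols differentiation
F = 0.05, ~13.4% multiallelic segregating sites, two isolated outlier
individuals and two samples recorded under the wrong collection site, then
writes reference FASTA, GFF3 gene models, a GT-only VCF, metadata and truth
tables.
"""

import minpop

cfg = minpop.CohortConfig(
    n_contigs=2, contig_length_bp=200_000, n_sites_per_contig=3000,
    pop_names=["A", "B"], pop_sizes=[10, 12], fst_matrix=0.05,
    n_outliers=2, n_mislabeled=2, mislabel_true_pop="B",
    mislabel_recorded_pop="A", seed=1,
)
reference, gm, truth = minpop.simulate_cohort(cfg)
paths = minpop.write_cohort(gm, truth, reference, "scratch/example_cohort")

census = minpop.classify_sites(gm)
print(f"cohort: {gm.n_samples} samples x {gm.n_sites} sites")
print(f"invariant      {census.n_invariant:6d}")
print(f"biallelic      {census.n_biallelic:6d}")
print(f"triallelic     {census.n_triallelic:6d}")
print(f"quadriallelic  {census.n_quadriallelic:6d}")
print(f"multiallelic share of segregating sites: {census.multiallelic_fraction:.3f}")
print("files written:", ", ".join(p.name for p in paths.values()))
# The multiallelic share should sit within ~2% of the configured 0.134,
# mirroring the 13.4% multiallelic fraction seen in deep mosquito cohorts.
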