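"""Configuration objects for the cohort generator and the pipeline.

All statistical defaults are the study conditions the pipeline targets:
a 302-mosquito cohort split 41/156/58/28 across four populations (TD, PV,
RK1, RK2), TD-PV differentiation of 0.003 and ~0.03 for every pair involving
an RK population, 9 mislabeled samples recorded under the wrong collection
site, 10 genetically isolated outlier individuals, and ~13.4% multiallelic
segregating sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np

from .errors import ConfigurationError

PAPER_POP_NAMES = ["TD", "PV", "RK1", "RK2"]
PAPER_POP_SIZES = [41, 156, 58, 28]
PAPER_FST_LOW = 0.003   # TD vs PV
PAPER_FST_HIGH = 0.03   # every pair involving RK1 or RK2
PAPER_MULTIALLELIC_FRACTION = 0.134
# 286,459 quadriallelic of 5,093,814 multiallelic segregating sites
PAPER_QUADRIALLELIC_SHARE = 0.056


@dataclass
class SweepSpec:
    """A planted local-differentiation sweep.

    Within ``[start_bp, end_bp)`` of ``contig`` the target population's drift
    parameter is replaced by ``f_sweep`` (which must exceed every background
    pairwise F).
    """

    contig: str
    start_bp: int
    end_bp: int
    target_population: str
    f_sweep: float


@dataclass
class CohortConfig:
    n_contigs: int = 4
    contig_length_bp: int = 2_500_000
    n_sites_per_contig: int = 32_000
    pop_names: list = field(default_factory=lambda: list(PAPER_POP_NAMES))
    pop_sizes: list = field(default_factory=lambda: list(PAPER_POP_SIZES))
    fst_matrix: object = None  # scalar or (n_pops, n_pops) array-like
    multiallelic_fraction: float = PAPER_MULTIALLELIC_FRACTION
    quadriallelic_share: float = PAPER_QUADRIALLELIC_SHARE
    sweep_specs: list = field(default_factory=list)
    n_outliers: int = 10
    outlier_f: float = 0.5
    n_mislabeled: int = 9
    mislabel_true_pop: str = "RK2"
    mislabel_recorded_pop: str = "PV"
    missing_rate: float = 0.0
    # extra per-population Beta drift applied after the hierarchy draw;
    # models populations with reduced diversity (and elevated divergence)
    pop_extra_f: dict = field(default_factory=dict)
    # ancestral-frequency spectrum: "uniform" on [0.05, 0.95] (dense
    # intermediate-frequency polymorphism) or "neutral" (density ~ 1/p on
    # [0.001, 0.999], the infinite-sites equilibrium shape)
    ancestral_sfs: str = "uniform"
    gene_fraction: float = 0.3
    mean_gene_bp: int = 900
    x_contigs: list = field(default_factory=list)
    shuffle_samples: bool = True
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def n_populations(self) -> int:
        return len(self.pop_sizes)

    @property
    def n_samples(self) -> int:
        return sum(self.pop_sizes) + self.n_mislabeled + self.n_outliers

    def contig_names(self) -> list:
        return [f"ctg{i + 1:02d}" for i in range(self.n_contigs)]

    def fst(self) -> np.ndarray:
        n = self.n_populations
        m = self.fst_matrix
        if m is None:
            m = _default_fst(self.pop_names)
        m = np.asarray(m, dtype=float)
        if m.ndim == 0:
            m = np.full((n, n), float(m))
            np.fill_diagonal(m, 0.0)
        return m

    def validate(self) -> None:
        if self.n_contigs < 1 or self.contig_length_bp < 1:
            raise ConfigurationError("need at least one contig of positive length")
        if len(self.pop_names) != len(self.pop_sizes):
            raise ConfigurationError("pop_names and pop_sizes must align")
        if any(s < 1 for s in self.pop_sizes):
            raise ConfigurationError("population sizes must be positive")
        if self.n_sites_per_contig > self.contig_length_bp:
            raise ConfigurationError("more sites requested than contig positions")
        for p in ("multiallelic_fraction", "quadriallelic_share", "missing_rate",
                  "gene_fraction"):
            v = getattr(self, p)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{p} must lie in [0, 1)")
        m = self.fst()
        n = self.n_populations
        if m.shape != (n, n):
            raise ConfigurationError("fst_matrix must be n_pops x n_pops")
        if not np.allclose(m, m.T) or (np.diag(m) != 0).any():
            raise ConfigurationError("fst_matrix must be symmetric with zero diagonal")
        if ((m < 0) | (m >= 1)).any():
            raise ConfigurationError("pairwise F must lie in [0, 1)")
        max_f = float(m.max()) if n > 1 else 0.0
        names = set(self.contig_names())
        for sw in self.sweep_specs:
            if sw.contig not in names:
                raise ConfigurationError(f"sweep contig {sw.contig!r} not in cohort")
            if sw.target_population not in self.pop_names:
                raise ConfigurationError(
                    f"sweep target {sw.target_population!r} not a population"
                )
            if not (0 <= sw.start_bp < sw.end_bp <= self.contig_length_bp):
                raise ConfigurationError("sweep interval out of contig bounds")
            if sw.f_sweep <= max_f:
                raise ConfigurationError("f_sweep must exceed every background pairwise F")
        if self.n_mislabeled:
            if self.mislabel_true_pop not in self.pop_names:
                raise ConfigurationError("mislabel_true_pop not a population")
            if self.mislabel_recorded_pop not in self.pop_names:
                raise ConfigurationError("mislabel_recorded_pop not a population")
            if self.mislabel_true_pop == self.mislabel_recorded_pop:
                raise ConfigurationError("mislabeled samples need a different recorded label")
        if self.n_outliers and not (0 < self.outlier_f < 1):
            raise ConfigurationError("outlier_f must lie in (0, 1) when outliers are planted")
        if self.gene_fraction > 0 and self.mean_gene_bp > self.contig_length_bp:
            raise ConfigurationError("contig too short for requested gene density")
        if self.ancestral_sfs not in ("uniform", "neutral"):
            raise ConfigurationError("ancestral_sfs must be 'uniform' or 'neutral'")
        for k, v in self.pop_extra_f.items():
            if k not in self.pop_names:
                raise ConfigurationError(f"pop_extra_f key {k!r} not a population")
            if not (0.0 <= v < 1.0):
                raise ConfigurationError("pop_extra_f values must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.fst_matrix is not None:
            d["fst_matrix"] = np.asarray(self.fst_matrix, dtype=float).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort config keys: {sorted(unknown)}")
        sweeps = d.get("sweep_specs") or []
        d["sweep_specs"] = [
            sw if isinstance(sw, SweepSpec) else SweepSpec(**sw) for sw in sweeps
        ]
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _default_fst(pop_names: list) -> np.ndarray:
    """Study-scale pairwise differentiation: 0.003 between the first two
    populations (TD/PV analogues), 0.03 for every other pair."""
    n = len(pop_names)
    m = np.full((n, n), PAPER_FST_HIGH)
    if n >= 2:
        m[0, 1] = m[1, 0] = PAPER_FST_LOW
    np.fill_diagonal(m, 0.0)
    return m


def paper_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The study-configuration cohort: 302 samples, four populations
    (41/156/58/28), 9 mislabeled, 10 outliers, 13.4% multiallelic sites."""
    cfg = CohortConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg
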