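"""Orchestration: one configuration drives simulate -> qc -> structure ->
diversity -> fst-scan -> ir-report, with a manifest recording parameters,
seed and output checksums for every stage."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import fst as fst_mod
from . import io, ir, qc, structure
from .config import CohortConfig
from .diversity import diversity_report, fourfold_degenerate_mask
from .errors import ConfigurationError, ValidationError
from .genotypes import GenotypeMatrix
from .simulate import Reference, build_reference, simulate_genotypes, write_cohort

log = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "structure", "diversity", "fst_scan", "ir_report"]


def _from_dict(cls, d):
    d = dict(d or {})
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class ContigRules:
    min_scan_bp: int = 2_000_000
    x_contigs: list = field(default_factory=list)
    fst_table_contig: str | None = None  # default: largest contig


@dataclass
class QcParams:
    min_median_coverage: float = 10.0
    min_breadth_1x: float = 0.8


@dataclass
class StructureParams:
    n_pca_sites: int = 100_000
    n_components: int = 10
    threshold_mads: float = 6.0
    top_pcs: int = 10
    max_iter: int = 20
    max_flag_fraction: float = 0.05
    isolation_gap_mads: float = 3.0
    n_cluster_pcs: int = 2
    cluster_cutoff: float = 0.15
    expected_clusters: int | None = None
    thin_maf: float = 0.01
    thin_per_contig: int = 50_000


@dataclass
class DiversityParams:
    n_boot: int = 100
    level: float = 0.95
    downsample_to: int | None = None


@dataclass
class FstScanParams:
    window_snps: int = 1000
    window_bp: int = 20_000
    min_run: int = 5
    threshold_mult: float = 2.0
    gap_tolerance: int = 0
    gene_radius_bp: int = 100_000


@dataclass
class IrParams:
    min_freq: float = 0.02
    regions: str | None = None  # path to BED/YAML; default: simulated regions


@dataclass
class RunConfig:
    seed: int = 0
    simulate: CohortConfig | None = None
    inputs: dict | None = None
    stages: list = field(default_factory=lambda: list(STAGES))
    contigs: ContigRules = field(default_factory=ContigRules)
    qc: QcParams = field(default_factory=QcParams)
    structure: StructureParams = field(default_factory=StructureParams)
    diversity: DiversityParams = field(default_factory=DiversityParams)
    fst_scan: FstScanParams = field(default_factory=FstScanParams)
    ir: IrParams = field(default_factory=IrParams)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown run config keys: {sorted(unknown)}")
        sim = d.pop("simulate", None)
        cfg = cls(
            seed=int(d.pop("seed", 0)),
            simulate=None,
            inputs=d.pop("inputs", None),
            stages=list(d.pop("stages", STAGES)),
            contigs=_from_dict(ContigRules, d.pop("contigs", None)),
            qc=_from_dict(QcParams, d.pop("qc", None)),
            structure=_from_dict(StructureParams, d.pop("structure", None)),
            diversity=_from_dict(DiversityParams, d.pop("diversity", None)),
            fst_scan=_from_dict(FstScanParams, d.pop("fst_scan", None)),
            ir=_from_dict(IrParams, d.pop("ir", None)),
        )
        if sim is not None:
            if isinstance(sim, CohortConfig):
                cfg.simulate = sim
            else:
                sim = dict(sim)
                sim.setdefault("seed", cfg.seed)
                cfg.simulate = CohortConfig.from_dict(sim)
        unknown_stages = set(cfg.stages) - set(STAGES)
        if unknown_stages:
            raise ConfigurationError(f"unknown stages: {sorted(unknown_stages)}")
        if cfg.simulate is None and cfg.inputs is None:
            raise ConfigurationError("config needs either a 'simulate' block or 'inputs'")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ===================================================================
def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "config": _config_snapshot(config),
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, outdir)
        except Exception:
            log.error("stage %r failed; downstream stages not run", stage)
            _write_manifest(manifest, outdir)
            raise
        manifest["stages"][stage] = {
            "params": _stage_params(config, stage),
            "outputs": {str(p.name): io.sha256_of(p) for p in outputs},
            "seconds": round(time.time() - t0, 2),
        }
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest, outdir):
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _config_snapshot(config: RunConfig) -> dict:
    d = asdict(config)
    if config.simulate is not None:
        d["simulate"] = config.simulate.to_dict()
    return d


def _stage_params(config: RunConfig, stage: str) -> dict:
    obj = {
        "simulate": config.simulate,
        "qc": config.qc,
        "structure": config.structure,
        "diversity": config.diversity,
        "fst_scan": config.fst_scan,
        "ir_report": config.ir,
    }[stage]
    if obj is None:
        return {}
    return obj.to_dict() if isinstance(obj, CohortConfig) else asdict(obj)


# ------------------------------------------------------------------ stages
def _stage_simulate(config: RunConfig, state: dict, outdir: Path):
    if config.simulate is not None:
        reference = build_reference(config.simulate)
        gm, truth = simulate_genotypes(config.simulate, reference)
        paths = write_cohort(gm, truth, reference, outdir / "cohort")
        state.update(
            reference=reference, gm=gm, metadata=truth.metadata(),
            ir_regions=reference.ir_regions, truth=truth,
        )
        return list(paths.values())
    inputs = config.inputs or {}
    contigs = io.read_fasta(inputs["fasta"])
    gff = io.read_gff3(inputs["gff3"])
    genes = io.gene_table(gff)
    state.update(
        reference=Reference(contigs=contigs, genes=genes, ir_regions=pd.DataFrame()),
        cds=io.cds_table(gff),
        gm=io.read_vcf(inputs["vcf"]),
        metadata=io.read_tsv(inputs["metadata"]),
    )
    if inputs.get("ir_regions"):
        state["ir_regions"] = io.read_ir_regions(inputs["ir_regions"])
    return []


def _stage_qc(config: RunConfig, state: dict, outdir: Path):
    gm: GenotypeMatrix = state["gm"]
    meta = state["metadata"]
    report = qc.sample_qc(
        meta,
        min_median=config.qc.min_median_coverage,
        min_breadth=config.qc.min_breadth_1x,
        required_samples=gm.samples,
    )
    passing = set(report.loc[report["qc_pass"], "sample_id"])
    failed = [s for s in gm.samples if s not in passing]
    for s in failed:
        log.info("excluded %s: failed coverage QC", s)
    if failed:
        keep = [i for i, s in enumerate(gm.samples) if s in passing]
        gm = gm.take_samples(np.array(keep))
        state["gm"] = gm
    census = qc.classify_sites(gm)
    p1 = outdir / "qc_samples.tsv"
    p2 = outdir / "site_census.tsv"
    io.write_tsv(report, p1)
    io.write_tsv(census.to_frame(), p2)
    state["census"] = census
    return [p1, p2]


def _stage_structure(config: RunConfig, state: dict, outdir: Path):
    gm: GenotypeMatrix = state["gm"]
    meta = state["metadata"]
    sp = config.structure
    sites = structure.select_pca_sites(
        gm, n_target=sp.n_pca_sites, seed=config.seed,
        exclude_contigs=config.contigs.x_contigs,
    )
    excluded = structure.iterative_outlier_removal(
        gm, sites,
        threshold_mads=sp.threshold_mads, top_pcs=sp.top_pcs,
        max_iter=sp.max_iter, max_flag_fraction=sp.max_flag_fraction,
        isolation_gap_mads=sp.isolation_gap_mads,
    )
    keep = np.array(
        [i for i, s in enumerate(gm.samples) if s not in set(excluded["sample_id"])]
    )
    res = structure.pca(gm, sites, n_components=sp.n_components, sample_idx=keep)
    labels = meta.set_index("sample_id")["recorded_population"]
    assignment = structure.assign_and_flag(
        res, labels,
        n_pcs=sp.n_cluster_pcs, cutoff=sp.cluster_cutoff,
        expected_clusters=sp.expected_clusters,
    )
    coords = pd.DataFrame(
        res.coords, columns=[f"PC{i + 1}" for i in range(res.coords.shape[1])]
    )
    coords.insert(0, "sample_id", res.samples)
    table = assignment.table.copy()
    out_rows = excluded.assign(
        status="excluded_outlier", cluster=-1, population="", dist_to_centroid=np.nan
    )[["sample_id", "status", "cluster", "population", "dist_to_centroid"]]
    full = pd.concat([table, out_rows], ignore_index=True)

    thin = structure.thin_snps_for_structure(
        gm, maf_min=sp.thin_maf, n_per_contig=sp.thin_per_contig
    )
    paths = []
    for c, idx in thin.items():
        p = outdir / f"thinned_{c}.txt"
        pd.DataFrame({"contig": gm.contig[idx], "pos": gm.pos[idx] + 1}).to_csv(
            p, sep="\t", index=False, header=False
        )
        paths.append(p)
    p_coords = outdir / "pc_coords.tsv"
    p_assign = outdir / "assignments.tsv"
    p_excl = outdir / "excluded_samples.tsv"
    io.write_tsv(coords, p_coords)
    io.write_tsv(full, p_assign)
    io.write_tsv(excluded, p_excl)
    state["assignment"] = assignment
    state["populations"] = {
        p: sub["sample_id"].tolist()
        for p, sub in assignment.assigned.groupby("population")
    }
    return [p_coords, p_assign, p_excl] + paths


def _get_mask(state: dict):
    if "mask4d" not in state:
        ref: Reference = state["reference"]
        cds = state.get("cds")
        if cds is None:
            cds = ref.genes.assign(phase=0, cds_id=ref.genes["gene_id"])
        state["mask4d"] = fourfold_degenerate_mask(ref.contigs, cds)
    return state["mask4d"]


def _stage_diversity(config: RunConfig, state: dict, outdir: Path):
    gm: GenotypeMatrix = state["gm"]
    pops = state.get("populations")
    if not pops:
        raise ValidationError("diversity stage needs population assignments")
    mask = _get_mask(state)
    report = diversity_report(
        gm, pops, mask,
        min_contig_bp=config.contigs.min_scan_bp,
        x_contigs=config.contigs.x_contigs,
        n_boot=config.diversity.n_boot,
        level=config.diversity.level,
        downsample_to=config.diversity.downsample_to,
        seed=config.seed,
    )
    p1 = outdir / "diversity.tsv"
    p2 = outdir / "fourfold_mask.bed"
    io.write_tsv(report, p1)
    io.write_bed(io.mask_to_bed(mask), p2, cols=("contig", "start", "end"))
    return [p1, p2]


def _stage_fst_scan(config: RunConfig, state: dict, outdir: Path):
    gm: GenotypeMatrix = state["gm"]
    ref: Reference = state["reference"]
    pops = state.get("populations")
    if not pops or len(pops) < 2:
        raise ValidationError("fst scan needs >= 2 assigned populations")
    fp = config.fst_scan
    lengths = ref.lengths()
    scan_contigs = [
        c for c in gm.contig_names()
        if lengths.get(c, 0) > config.contigs.min_scan_bp
        and c not in set(config.contigs.x_contigs)
    ]
    names = sorted(pops)
    all_windows, all_signals = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair = (names[i], names[j])
            win = fst_mod.pair_windowed_fst(
                gm,
                gm.sample_indices(pops[pair[0]]),
                gm.sample_indices(pops[pair[1]]),
                mode="snp", window_snps=fp.window_snps, contigs=scan_contigs,
            )
            win.insert(0, "comparison", "_vs_".join(pair))
            all_windows.append(win)
            sigs = fst_mod.detect_signals(
                win, pair=pair, min_run=fp.min_run,
                threshold_mult=fp.threshold_mult, gap_tolerance=fp.gap_tolerance,
            ) if len(win) else []
            fst_mod.annotate_signals(sigs, ref.genes, radius=fp.gene_radius_bp)
            all_signals.extend(sigs)
    windows = pd.concat(all_windows, ignore_index=True)
    table_contig = config.contigs.fst_table_contig or max(lengths, key=lengths.get)
    matrix = fst_mod.average_fst_matrix(
        gm, pops, table_contig, window_bp=fp.window_bp, contig_lengths=lengths
    )
    p1 = outdir / "fst_windows.tsv"
    p2 = outdir / "fst_signals.tsv"
    p3 = outdir / "fst_signals.bed"
    p4 = outdir / "fst_matrix.tsv"
    io.write_tsv(windows, p1)
    io.write_tsv(fst_mod.signals_to_frame(all_signals), p2)
    bed = pd.DataFrame(
        [
            {
                "contig": s.contig, "start": s.run_start, "end": s.run_end,
                "name": "_vs_".join(s.pair),
            }
            for s in all_signals
        ],
        columns=["contig", "start", "end", "name"],
    )
    io.write_bed(bed, p3)
    matrix.to_csv(p4, sep="\t")
    state["signals"] = all_signals
    return [p1, p2, p3, p4]


def _stage_ir_report(config: RunConfig, state: dict, outdir: Path):
    gm: GenotypeMatrix = state["gm"]
    pops = state.get("populations")
    if not pops:
        raise ValidationError("IR report needs population assignments")
    if config.ir.regions:
        regions = io.read_ir_regions(config.ir.regions)
    else:
        regions = state.get("ir_regions")
        if regions is None or len(regions) == 0:
            raise ValidationError("no IR gene regions configured")
    report = ir.ir_report(gm, pops, regions, min_freq=config.ir.min_freq)
    p = outdir / "ir_report.tsv"
    io.write_tsv(report, p)
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "structure": _stage_structure,
    "diversity": _stage_diversity,
    "fst_scan": _stage_fst_scan,
    "ir_report": _stage_ir_report,
}
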