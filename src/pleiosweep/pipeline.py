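"""End-to-end orchestration: one config in, a directory of tables out.

A run goes summary-statistics ingestion (or simulation) -> MHC/region
exclusion -> conditional+conjunctional FDR in both directions -> locus
definition -> LD-score regression -> sweep-score analyses, writing every
stage's tables plus a machine-readable manifest (parameters, seeds, row
counts, and a sha256 per output file).  Stages whose inputs are absent
(e.g. no score track) are marked skipped rather than failing the run.

With a three-trait panel the two pairings (trait1|trait2, trait1|trait3)
are analyzed separately and their locus sets compared, reproducing the
two-secondary-trait analysis topology (overlap, distinct-locus union,
shared lead SNPs).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import condfdr as cf
from . import ldsc, loci as loci_mod, nss as nss_mod
from .regions import GenomicRegion, MHC_REGION, parse_region, read_bed, write_bed
from .simulate import LdBlocks, SimConfig, simulate_gene_annotation, \
    simulate_nss_track, simulate_panel, simulate_region_set
from .sumstats import DEFAULT_COLUMN_MAP, HarmonizedPanel, exclude_region, \
    harmonize_panel, read_sumstats

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration of a full run."""

    # either simulated input ...
    sim: SimConfig | None = None
    simulate_track: bool = True
    sweep_delta: float = -2.0
    sweep_fraction: float = 0.1          # fraction of genome under planted sweeps
    mask_fraction: float = 0.6           # track positions missing (real-data regime)
    n_genes: int = 500
    # ... or real input files
    sumstats_paths: list[str] = field(default_factory=list)
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    nss_track_path: str | None = None
    gene_annotation_path: str | None = None

    threshold: float = 0.05
    candidate_threshold: float = 0.10
    exclude_regions: list[str] = field(
        default_factory=lambda: ["chr6:25119106-33854733"])
    r2_independent: float = 0.6
    lead_r2: float = 0.1
    merge_kb: float = 250.0
    n_prune: int = 0                     # random-pruning iterations (0 = off)
    window_bp: int = 100_000
    step_bp: int = 50_000
    tail_quantile: float = 0.05
    min_window_snps: int = 5
    seed: int = 0
    outdir: str = "pleiosweep_run"

    def validate(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.sim is None and not self.sumstats_paths:
            raise ValueError("config needs either a SimConfig or input paths")
        if self.sim is not None:
            self.sim.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim") is not None:
            d["sim"] = SimConfig(**d["sim"])
        return cls(**d)

    def parsed_exclude_regions(self) -> list[GenomicRegion]:
        out = []
        for item in self.exclude_regions:
            if str(item).endswith(".bed"):
                out.extend(read_bed(item))
            else:
                out.append(parse_region(str(item), "excluded"))
        return out


@dataclass
class RunReport:
    """All result tables of one run plus provenance."""

    config: PipelineConfig
    tables: dict = field(default_factory=dict)       # name -> DataFrame
    bed_outputs: dict = field(default_factory=dict)  # name -> list[GenomicRegion]
    loci: dict = field(default_factory=dict)         # pair -> list[Locus]
    stages: dict = field(default_factory=dict)       # stage -> "done" | "skipped"
    summary: dict = field(default_factory=dict)      # headline counts


def _load_panel(cfg: PipelineConfig):
    if cfg.sim is not None:
        panel, truth, blocks = simulate_panel(cfg.sim)
        return panel, truth, blocks
    stats = [read_sumstats(p, cfg.column_map) for p in cfg.sumstats_paths]
    return harmonize_panel(stats), None, None


def _bh_candidates(p: np.ndarray, threshold: float) -> np.ndarray:
    """Unconditional empirical-FDR (BH-style) mask: p / ecdf(p) < threshold."""
    order = np.argsort(p)
    m = len(p)
    ecdf = np.empty(m)
    ecdf[order] = (np.arange(1, m + 1)) / m
    return p / ecdf < threshold


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage the configuration allows; see module docstring."""
    cfg.validate()
    report = RunReport(config=cfg)
    panel, truth, blocks = _load_panel(cfg)
    report.stages["input"] = "done"

    panel = exclude_region(panel, cfg.parsed_exclude_regions())
    if blocks is not None:
        blocks = LdBlocks(labels=panel.ld_block, r=blocks.r)
    report.stages["exclude_regions"] = "done"
    report.tables["panel"] = panel.to_frame()

    pairs = [(0, 1)] + ([(0, 2)] if panel.n_traits > 2 else [])
    loci_by_pair: dict[str, list[loci_mod.Locus]] = {}
    shared_members_by_pair: dict[str, pd.DataFrame] = {}
    for i, j in pairs:
        name = f"{panel.traits[i]}_{panel.traits[j]}"
        res = cf.analyze_pair(panel, i, j, threshold=cfg.threshold,
                              blocks=blocks, n_prune=cfg.n_prune,
                              seed=cfg.seed)
        report.tables[f"condfdr_{name}"] = res.to_frame(panel.p[:, i],
                                                        panel.p[:, j])
        report.tables[f"grid_{name}_12"] = pd.DataFrame(res.grid_12.values)
        report.tables[f"grid_{name}_21"] = pd.DataFrame(res.grid_21.values)
        qq = pd.concat([
            cf.stratified_qq(panel.p[:, i], panel.p[:, j]).assign(
                direction=f"{panel.traits[i]}|{panel.traits[j]}"),
            cf.stratified_qq(panel.p[:, j], panel.p[:, i]).assign(
                direction=f"{panel.traits[j]}|{panel.traits[i]}"),
        ], ignore_index=True)
        report.tables[f"stratified_qq_{name}"] = qq

        df = panel.snps.copy()
        df["conjfdr"] = res.conjfdr
        df["p1"] = panel.p[:, i]
        if blocks is not None:
            ind = loci_mod.select_independent_snps(
                df, blocks, cfg.threshold, cfg.r2_independent)
            locs = loci_mod.define_loci(
                df, ind, blocks, cfg.candidate_threshold, cfg.r2_independent,
                cfg.lead_r2, cfg.merge_kb)
            loci_by_pair[name] = locs
            report.loci[name] = locs
            report.tables[f"independent_snps_{name}"] = ind
            report.tables[f"loci_{name}"] = loci_mod.loci_to_frame(locs)
            report.bed_outputs[f"loci_{name}"] = [L.region for L in locs]
            members = sorted({s for L in locs for s in L.members})
            shared_members_by_pair[name] = panel.snps[
                panel.snps["snp"].isin(members)]
            report.summary[f"n_loci_{name}"] = len(locs)
            report.summary[f"n_independent_snps_{name}"] = len(ind)
        report.stages[f"condfdr_{name}"] = "done"

    if len(pairs) > 1 and len(loci_by_pair) == 2:
        names = list(loci_by_pair)
        comp = loci_mod.cross_overlap(loci_by_pair[names[0]],
                                      loci_by_pair[names[1]])
        report.tables["locus_comparison"] = pd.DataFrame([{
            "set_a": names[0], "set_b": names[1], "n_a": comp.n_a,
            "n_b": comp.n_b, "n_overlap": comp.n_overlap,
            "n_distinct": comp.n_distinct,
            "shared_leads": ",".join(comp.shared_leads),
        }])
        report.summary["n_distinct_loci"] = comp.n_distinct
        report.stages["locus_comparison"] = "done"

    if blocks is not None:
        lscores = ldsc.ld_scores_from_blocks(blocks)
        rows = []
        for i, j in pairs:
            r = ldsc.fit_rg(panel.z[:, i], panel.z[:, j],
                            float(panel.n[0, i]), float(panel.n[0, j]),
                            lscores, m=len(panel))
            rows.append({"pair": f"{panel.traits[i]}_{panel.traits[j]}",
                         **r.to_row()})
        report.tables["ldsc"] = pd.DataFrame(rows)
        report.stages["ldsc"] = "done"
    else:
        report.stages["ldsc"] = "skipped"

    track = None
    genes = None
    if cfg.sim is not None and cfg.simulate_track:
        rng = np.random.default_rng(cfg.seed + 1)
        chrom_lengths = cfg.sim.chrom_lengths
        sweep_regions = [
            (r, cfg.sweep_delta) for r in simulate_region_set(
                chrom_lengths,
                n_regions=max(1, int(cfg.sweep_fraction * 20)),
                mean_length=int(cfg.sweep_fraction * sum(
                    chrom_lengths.values()) / max(1, int(cfg.sweep_fraction * 20))),
                seed=cfg.seed + 2, label="sweep")
        ]
        track_df, covered = simulate_nss_track(
            panel.snps["chrom"].to_numpy(object), panel.snps["pos"].to_numpy(),
            sweep_regions, seed=cfg.seed + 3, mask_fraction=cfg.mask_fraction)
        track = nss_mod.NssTrack(df=track_df)
        genes = simulate_gene_annotation(chrom_lengths, cfg.n_genes,
                                         seed=cfg.seed + 4)
        if truth is not None:
            truth.sweep_regions = [r for r, _ in sweep_regions]
    elif cfg.nss_track_path:
        track = nss_mod.NssTrack.read_tsv(cfg.nss_track_path)
        if cfg.gene_annotation_path:
            genes = pd.read_csv(cfg.gene_annotation_path, sep="\t")

    if track is None:
        report.stages["nss"] = "skipped"
        log.info("no sweep-score track supplied: evolutionary stage skipped")
    else:
        background = nss_mod.join_scores(panel.snps, track, "background")
        sets = [background]
        for i in range(panel.n_traits):
            mask = _bh_candidates(panel.p[:, i], cfg.threshold)
            sets.append(nss_mod.join_scores(panel.snps[mask], track,
                                            panel.traits[i]))
        for name, members in shared_members_by_pair.items():
            sets.append(nss_mod.join_scores(members, track, f"shared_{name}"))
        usable = [s for s in sets if s.n_scored >= 2]
        if len(usable) >= 2:
            summary, tests = nss_mod.compare_sets(usable)
            report.tables["nss_set_summary"] = summary
            report.tables["nss_pairwise_tests"] = tests
        for s in sets[1:]:
            if s.n_scored == 0:
                continue
            curve, p = nss_mod.enrichment_qq(s.scores, background.scores)
            curve["set"] = s.label
            curve["p_one_sided"] = p if p is not None else np.nan
            report.tables[f"nss_qq_{s.label}"] = curve
        extreme, windows = nss_mod.extreme_windows(
            track, cfg.window_bp, cfg.step_bp, cfg.tail_quantile,
            cfg.min_window_snps)
        report.tables["nss_windows"] = windows
        report.bed_outputs["nss_extreme_regions"] = extreme
        region_sets = {"extreme_nss": extreme}
        if truth is not None and truth.sweep_regions:
            region_sets["planted_sweeps"] = truth.sweep_regions
        for name, locs in loci_by_pair.items():
            overlap_df, counts = nss_mod.region_overlap(locs, region_sets)
            report.tables[f"locus_region_overlap_{name}"] = overlap_df
            for k, v in counts.items():
                report.summary[f"n_loci_{name}_in_{k}"] = v
        if genes is not None and loci_by_pair:
            first = next(iter(loci_by_pair))
            gmap = loci_mod.map_genes_positional(loci_by_pair[first], genes)
            # expand the gene map to member SNPs for per-gene averaging
            rows = []
            for L_id, L in enumerate(loci_by_pair[first]):
                for g in gmap.loc[gmap["locus_id"] == L_id, "gene"]:
                    for s in L.members:
                        rows.append({"gene": g, "snp": s})
            if rows:
                gene_snps = pd.DataFrame(rows)
                scored_all = nss_mod.join_scores(panel.snps, track, "panel")
                report.tables["gene_nss_scores"] = nss_mod.gene_mean_scores(
                    gene_snps, scored_all)
        report.stages["nss"] = "done"

    if truth is not None:
        report.tables["truth_flags"] = truth.flags
        report.bed_outputs["truth_shared_regions"] = truth.shared_regions

    for k, v in report.summary.items():
        log.info("summary: %s = %s", k, v)
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(report: RunReport, outdir: str | Path) -> dict:
    """Write every table/BED with stable names; return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in sorted(report.tables.items()):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        files.append(path)
    for name, regions in sorted(report.bed_outputs.items()):
        path = out / f"{name}.bed"
        write_bed(regions, path)
        files.append(path)
    cfg_path = out / "config.yaml"
    report.config.to_yaml(cfg_path)
    files.append(cfg_path)
    manifest = {
        "parameters": yaml.safe_load(cfg_path.read_text()),
        "stages": report.stages,
        "summary": report.summary,
        "row_counts": {name: int(len(df)) for name, df in report.tables.items()},
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
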