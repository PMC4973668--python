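"""Config-driven orchestration of the full analysis surface.

One :class:`RunConfig` (YAML-serialisable) drives either a synthetic
simulation or a real VCF through the filter cascade and every analysis:
LD decay profile, sliding-window and non-overlapping-window FST/DXY scans
per comparison, genome-wide pairwise FST matrix, f4 table, NNI clustering
report and Mantel isolation-by-distance report, plus a machine-readable
run manifest.  All outputs are tab-separated UTF-8 with a header; BED-like
window files are 0-based half-open.

Randomness: one global seed fans out to per-stage child seeds by stable
hashing of the stage name, so adding a stage never perturbs the draws of
earlier stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import f4_test
from .divergence import (
    genome_fst_matrix,
    nonoverlapping_windows,
    sliding_windows,
    window_divergence,
    write_windows_tsv,
)
from .geo_ibd import GeoSite, geo_distance_matrix, mantel_test
from .linkage import ld_decay
from .outliers import nni_report_all
from .synthetic_data import (
    GenomeLayout,
    PopulationModel,
    load_layout,
    simulate_dataset,
    write_vcf,
)
from .variant_io import (
    GenotypeMatrix,
    apply_quality_masks,
    filter_sites,
    read_vcf,
    snapp_prepare,
    write_pop_map,
    write_snapp_summary,
)

logger = logging.getLogger("popgenscan.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the global seed (below 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.  YAML round-trips losslessly."""

    mode: str = "synthetic"  # "synthetic" | "vcf"
    seed: int = 0
    outdir: str = "popgenscan_out"

    # synthetic-mode parameters
    n_sites: int = 25_000
    n_per_pop: int = 12
    missing_rate: float = 0.1
    ld_block_bp: int = 200_000
    topology: Any = (("popA", "popB"), ("popC", "popD"))
    drift_F: dict = field(
        default_factory=lambda: {"popA": 0.05, "popB": 0.05, "popC": 0.05, "popD": 0.05}
    )
    internal_F: float = 0.05
    admix_edges: list = field(default_factory=list)
    n_lg: int = 22
    lg_bp: int = 40_000_000

    # vcf-mode parameters
    vcf: str | None = None
    pop_map: str | None = None
    layout: str | None = None

    # filter cascade
    snp_qual: float = 20.0
    geno_qual: float = 20.0
    map_qual: float = 20.0
    min_depth: int = 5
    high_depth_percentile: float = 99.5
    biallelic_only: bool = True
    max_missing_frac: float = 0.25
    min_maf: float = 0.1

    # windows (min_sites counts usable SNPs per window; SNP-only panels need
    # far smaller values than all-sites alignments)
    sliding_size: int = 1_000_000
    sliding_step: int = 100_000
    sliding_min_sites: int = 10
    tile_size: int = 100_000
    tile_min_sites: int = 1

    # comparisons & tests
    comparisons: list = field(default_factory=lambda: [["popA", "popB"], ["popC", "popD"]])
    max_per_pop: int | None = 8
    f4_rows: list = field(
        default_factory=lambda: [["popA", "popB", "popC", "popD"]]
    )
    block_bp: int = 500_000
    nni_quantiles: list = field(default_factory=lambda: [0.01, 0.05])
    nni_n_perm: int = 10_000
    ld_population: str | None = None
    ld_max_pairs_per_bin: int = 20_000
    ld_max_background_pairs: int = 100_000
    mantel_n_perm: int = 9_999
    snapp_min_bp: int = 500_000
    # population geographic coordinates: {pop: [lat, lon]}
    pop_coords: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "vcf"):
            raise ValueError(f"mode must be 'synthetic' or 'vcf', got {self.mode!r}")
        if self.mode == "vcf" and (self.vcf is None or self.pop_map is None):
            raise ValueError("vcf mode needs 'vcf' and 'pop_map' paths")
        for counts in ("n_sites", "n_per_pop", "sliding_size", "sliding_step",
                       "tile_size", "block_bp", "nni_n_perm", "mantel_n_perm"):
            if getattr(self, counts) <= 0:
                raise ValueError(f"{counts} must be positive")

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        # YAML has no tuple type; normalise topology lists to tuples
        cfg.topology = _as_topology(cfg.topology)
        cfg.validate()
        return cfg


def _as_topology(node):
    if isinstance(node, str):
        return node
    return tuple(_as_topology(c) for c in node)


def select_balanced_samples(
    gm: GenotypeMatrix,
    pop: str,
    n: int,
    quality_rank: Mapping[str, float] | None = None,
) -> list[str]:
    """Deterministic top-*n* samples of a population by quality rank.

    Higher rank wins; ties break on lexicographic sample id.  Without a
    user-supplied rank, genotype call rate serves as the rank.
    """
    rows = gm.pop_rows(pop)
    ids = [gm.samples["id"].iat[i] for i in rows]
    if len(ids) < n:
        raise ValueError(f"population {pop!r} has only {len(ids)} samples; {n} requested")
    if quality_rank is None:
        call = (gm.dosages[rows] != -1).mean(axis=1)
        quality_rank = dict(zip(ids, call))
    chosen = sorted(ids, key=lambda s: (-float(quality_rank.get(s, 0.0)), s))[:n]
    return chosen


def _balanced_subset(gm: GenotypeMatrix, pops: Sequence[str], cap: int | None) -> GenotypeMatrix:
    ids: list[str] = []
    for pop in pops:
        rows = gm.pop_rows(pop)
        if cap is not None and rows.size > cap:
            ids.extend(select_balanced_samples(gm, pop, cap))
        else:
            ids.extend(gm.samples["id"].iat[i] for i in rows)
    return gm.subset_samples(ids)


def run(config: RunConfig, log_level: int = logging.INFO) -> dict[str, Path]:
    """Execute the full pipeline; returns a mapping of output name -> path."""
    logging.basicConfig(level=log_level, format="%(levelname)s %(name)s: %(message)s")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict[str, Any] = {
        "package": "popgenscan",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name: str):
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}
        logger.info("stage %s (child seed %d)", name, manifest["stages"][name]["seed"])
        return manifest["stages"][name]

    try:
        info = stage("data")
        if config.mode == "synthetic":
            model = PopulationModel(
                topology=config.topology,
                drift_F=dict(config.drift_F),
                admix_edges=tuple(tuple(e) for e in config.admix_edges),
                internal_F=config.internal_F,
            )
            layout = GenomeLayout.uniform(n_lg=config.n_lg, lg_bp=config.lg_bp)
            gm, layout = simulate_dataset(
                model=model,
                layout=layout,
                n_sites=config.n_sites,
                n_per_pop=config.n_per_pop,
                missing_rate=config.missing_rate,
                ld_block_bp=config.ld_block_bp,
                seed=info["seed"],
            )
            outputs["vcf"] = write_vcf(gm, outdir / "synthetic.vcf")
            outputs["pop_map"] = write_pop_map(gm, outdir / "pop_map.tsv")
        else:
            gm = read_vcf(config.vcf, pop_map=config.pop_map)
            if config.layout:
                layout = load_layout(config.layout)
            else:  # infer linkage-group extents from observed sites
                ext = gm.sites.groupby("lg", sort=True)["pos"].max()
                layout = GenomeLayout(tuple(ext.index), tuple(int(v) for v in ext))
        info["n_samples"] = gm.n_samples
        info["n_sites"] = gm.n_sites
    except Exception as exc:
        raise PipelineStageError("data", exc) from exc

    try:
        info = stage("filter")
        n0 = gm.n_sites
        if gm.depth is not None and gm.geno_qual is not None:
            gm = apply_quality_masks(
                gm,
                snp_qual=config.snp_qual,
                geno_qual=config.geno_qual,
                map_qual=config.map_qual,
                min_depth=config.min_depth,
                high_depth_percentile=config.high_depth_percentile,
            )
        gm = filter_sites(
            gm,
            biallelic_only=config.biallelic_only,
            max_missing_frac=config.max_missing_frac,
            min_maf=config.min_maf,
        )
        info["sites_in"] = n0
        info["sites_out"] = gm.n_sites
        summary = pd.DataFrame(
            {
                "population": gm.populations(),
                "n_samples": [len(gm.pop_rows(p)) for p in gm.populations()],
            }
        )
        summary["n_sites"] = gm.n_sites
        outputs["filter_summary"] = outdir / "filter_summary.tsv"
        summary.to_csv(outputs["filter_summary"], sep="\t", index=False)

        panel = snapp_prepare(gm, min_bp=config.snapp_min_bp)
        outputs["snapp_panel"] = write_snapp_summary(panel, gm, outdir / "snapp_panel.tsv")
    except Exception as exc:
        raise PipelineStageError("filter", exc) from exc

    try:
        info = stage("ld")
        pop = config.ld_population or gm.populations()[0]
        profile = ld_decay(
            gm,
            pop,
            max_pairs_per_bin=config.ld_max_pairs_per_bin,
            max_background_pairs=config.ld_max_background_pairs,
            seed=info["seed"],
        )
        outputs["ld_profile"] = outdir / "ld_profile.tsv"
        profile.to_frame().to_csv(outputs["ld_profile"], sep="\t", index=False)
        info["population"] = pop
    except Exception as exc:
        raise PipelineStageError("ld", exc) from exc

    try:
        stage("scan")
        slide = sliding_windows(
            layout,
            size=config.sliding_size,
            step=config.sliding_step,
            min_sites=config.sliding_min_sites,
        )
        tiles = nonoverlapping_windows(
            layout, size=config.tile_size, min_sites=config.tile_min_sites
        )
        tile_stats: dict[str, pd.DataFrame] = {}
        for popA, popB in config.comparisons:
            sub = _balanced_subset(gm, [popA, popB], config.max_per_pop)
            label = f"{popA}_vs_{popB}"
            s = window_divergence(sub, popA, popB, slide)
            t = window_divergence(sub, popA, popB, tiles)
            outputs[f"scan_sliding_{label}"] = outdir / f"scan_sliding_{label}.tsv"
            outputs[f"scan_tiles_{label}"] = outdir / f"scan_tiles_{label}.tsv"
            write_windows_tsv(s, outputs[f"scan_sliding_{label}"])
            write_windows_tsv(t, outputs[f"scan_tiles_{label}"])
            tile_stats[label] = t
    except Exception as exc:
        raise PipelineStageError("scan", exc) from exc

    try:
        stage("fst_matrix")
        fst_mat = genome_fst_matrix(
            gm, layout, size=config.tile_size, min_sites=config.tile_min_sites
        )
        outputs["fst_matrix"] = outdir / "fst_matrix.tsv"
        fst_mat.to_csv(outputs["fst_matrix"], sep="\t")
    except Exception as exc:
        raise PipelineStageError("fst_matrix", exc) from exc

    try:
        stage("f4")
        rows = []
        for A, B, C, D in config.f4_rows:
            sub = _balanced_subset(gm, [A, B, C, D], config.max_per_pop)
            r = f4_test(sub, A, B, C, D, block_bp=config.block_bp)
            rows.append(dataclasses.asdict(r))
        f4_table = pd.DataFrame(
            rows, columns=["A", "B", "C", "D", "f4", "sem", "z", "p", "n_blocks", "n_sites"]
        )
        outputs["f4_table"] = outdir / "f4_table.tsv"
        f4_table.to_csv(outputs["f4_table"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineStageError("f4", exc) from exc

    try:
        info = stage("nni")
        report = nni_report_all(
            tile_stats,
            quantiles=tuple(config.nni_quantiles),
            n_perm=config.nni_n_perm,
            seed=info["seed"],
        )
        outputs["nni_report"] = outdir / "nni_report.tsv"
        report.to_csv(outputs["nni_report"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineStageError("nni", exc) from exc

    try:
        info = stage("ibd")
        coords = {p: v for p, v in config.pop_coords.items() if p in gm.populations()}
        if len(coords) >= 3:
            pops = sorted(coords)
            sites = [GeoSite(code=p, lat=coords[p][0], lon=coords[p][1]) for p in pops]
            geo = geo_distance_matrix(sites)
            gen = genome_fst_matrix(
                gm, layout, pops=pops, size=config.tile_size, min_sites=config.tile_min_sites
            )
            res = mantel_test(gen, geo, n_perm=config.mantel_n_perm, seed=info["seed"])
            ibd = pd.DataFrame(
                [{"r": res.r, "p": res.p, "n_perm": res.n_perm, "seed": res.seed,
                  "n_pops": len(pops)}]
            )
        else:
            logger.info("ibd: fewer than 3 populations with coordinates; writing empty report")
            ibd = pd.DataFrame(columns=["r", "p", "n_perm", "seed", "n_pops"])
        outputs["ibd_report"] = outdir / "ibd_report.tsv"
        ibd.to_csv(outputs["ibd_report"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineStageError("ibd", exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["outputs"] = {k: str(v) for k, v in outputs.items()}
    outputs["manifest"] = outdir / "manifest.json"
    with open(outputs["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outputs
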