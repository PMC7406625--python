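"""End-to-end runs: simulate/read -> QC -> bin map -> traits -> scan -> regions.

Every stage persists its output under the run directory so any stage can be
re-run from its persisted inputs, and a provenance JSON captures the full
configuration, seed and package version; identical config + seed reproduce
the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binmap import BinGenotypes, BinMap, WindowBinCaller, write_summary_json
from .germination import traits_from_counts
from .io import (QCReport, SNPMatrix, read_counts_csv, read_genotypes,
                 write_counts_csv, write_genotypes_csv, write_genotypes_vcf)
from .qc import qc_pipeline
from .qtl import (QTLRecord, ScanConfig, SDRegion, RidgeQTLScanner, assign_pve,
                  cluster_sd_regions, declare_qtls)
from .sim import (BaseCurve, GeneticMap, PopulationSpec, QTLEffect, TruthSet,
                  default_study_effects, simulate_germination, simulate_population)

log = logging.getLogger("dormqtl")

TRAITS = ("G3d", "G7d", "T50", "AUC")

# embedded fixture seeds: fixtures regenerate deterministically from these
TINY_SEED = 101
DEFAULT_SEED = 107


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """A simulated population with phenotypes and ground truth."""

    gmap: GeneticMap
    spec: PopulationSpec
    effects: list[QTLEffect]
    snp: SNPMatrix
    truth: TruthSet
    counts: pd.DataFrame
    latents: pd.DataFrame


def make_fixture(scale: str = "tiny", seed: int | None = None) -> FixtureBundle:
    """Programmatic test populations.

    ``tiny``   — 2 chromosomes x 30 markers, 40 BILs, one planted t50 QTL;
    ``default``— 5 chromosomes x 120 markers, 400 BILs, four planted QTLs
    (three on t50, one on Gmax) echoing the study's 400-line panel.
    """
    if scale == "tiny":
        seed = TINY_SEED if seed is None else seed
        gmap = GeneticMap.regular(n_chrom=2, markers_per_chrom=30)
        spec = PopulationSpec("BIL", n_lines=40, seed=seed)
        effects = [QTLEffect("t50", "chr1", gmap.lengths_bp["chr1"] // 2, additive=5.0)]
    elif scale == "default":
        seed = DEFAULT_SEED if seed is None else seed
        gmap = GeneticMap.regular(n_chrom=5, markers_per_chrom=120)
        spec = PopulationSpec("BIL", n_lines=400, seed=seed)
        effects = default_study_effects(gmap)
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    snp, truth = simulate_population(spec, gmap)
    counts, latents = simulate_germination(truth, effects, seed=seed)
    return FixtureBundle(gmap, spec, effects, snp, truth, counts, latents)


def make_fixtures(scale: str = "tiny", out_dir: str | Path | None = None,
                  seed: int | None = None) -> FixtureBundle:
    """Build a fixture and optionally persist it under ``out_dir``."""
    fx = make_fixture(scale, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes_csv(fx.snp, out / "genotypes.csv")
        write_genotypes_vcf(fx.snp, out / "genotypes.vcf",
                            chrom_lengths=fx.gmap.lengths_bp)
        write_counts_csv(fx.counts, out / "counts.csv")
        fx.truth.to_bed(out / "truth.bed")
        fx.truth.effects_to_json(out / "effects.json")
    return fx


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One run: either a simulation spec or input paths, plus stage settings."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None   # {design, n_lines, n_chrom, markers_per_chrom, ...}
    inputs: dict | None = None     # {genotypes, format, counts, donor_sample, recurrent_sample}
    design: str = "BIL"
    qc: dict = field(default_factory=dict)        # {threshold, recode_het}
    binmap: dict = field(default_factory=dict)    # BinCallConfig kwargs
    scan: dict = field(default_factory=dict)      # ScanConfig kwargs
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be set")
        if self.inputs is not None:
            for key in ("genotypes", "counts"):
                if key not in self.inputs:
                    raise ValueError(f"inputs requires {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise FileNotFoundError(self.inputs[key])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class RunResult:
    out_dir: Path
    snp: SNPMatrix
    qc_report: QCReport
    bin_map: BinMap
    bin_genotypes: BinGenotypes
    traits: pd.DataFrame
    qtls: list[QTLRecord]
    regions: list[SDRegion]
    truth: TruthSet | None = None
    scan_pvalues: dict[str, np.ndarray] = field(default_factory=dict)


def _simulate_stage(cfg: PipelineConfig, out: Path
                    ) -> tuple[SNPMatrix, pd.DataFrame, TruthSet, GeneticMap]:
    simc = dict(cfg.simulate or {})
    design = simc.pop("design", cfg.design)
    gmap = GeneticMap.regular(
        n_chrom=simc.pop("n_chrom", 5),
        markers_per_chrom=simc.pop("markers_per_chrom", 120),
        spacing_bp=simc.pop("spacing_bp", 270_000),
        kb_per_cm=simc.pop("kb_per_cm", 270.0),
    )
    effects_cfg = simc.pop("effects", "default")
    base = BaseCurve(**simc.pop("base_curve", {}))
    germ_kwargs = {k: simc.pop(k) for k in
                   ("n_seeds", "replicates", "gmax_env_sd", "t50_env_sd") if k in simc}
    spec = PopulationSpec(design=design, seed=cfg.seed,
                          n_lines=simc.pop("n_lines", 400), **simc)
    snp, truth = simulate_population(spec, gmap)
    if effects_cfg == "default":
        effects = default_study_effects(gmap)
    else:
        effects = [QTLEffect(**e) for e in (effects_cfg or [])]
    counts, _ = simulate_germination(truth, effects, base_curve=base,
                                     seed=cfg.seed, **germ_kwargs)
    write_genotypes_csv(snp, out / "genotypes.csv")
    write_counts_csv(counts, out / "counts.csv")
    truth.to_bed(out / "truth.bed")
    truth.effects_to_json(out / "effects.json")
    return snp, counts, truth, gmap


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """Execute all stages in order, persisting artifacts under cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: TruthSet | None = None
    gmap: GeneticMap | None = None

    stage = "input"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            snp, counts, truth, gmap = _simulate_stage(cfg, out)
        else:
            ins = cfg.inputs or {}
            snp = read_genotypes(ins["genotypes"], ins.get("format", "csv"),
                                 ins.get("donor_sample", "NIP"),
                                 ins.get("recurrent_sample", "9311"))
            counts = read_counts_csv(ins["counts"])

        stage = "qc"
        snp_qc, qc_report = qc_pipeline(snp, design=cfg.design,
                                        **{k: v for k, v in cfg.qc.items()})
        qc_report.to_json(out / "qc_report.json")

        stage = "binmap"
        caller = WindowBinCaller(**cfg.binmap)
        chrom_lengths = gmap.lengths_bp if gmap is not None else None
        caller.fit(snp_qc, chrom_lengths=chrom_lengths)
        caller.bin_map_.to_bed(out / "binmap.bed")
        caller.bin_genotypes_.to_csv(out / "bin_genotypes.csv")
        write_summary_json(caller.bin_map_, out / "binmap_summary.json")

        stage = "germination"
        traits = traits_from_counts(counts)
        traits = traits[traits["line_id"].isin(snp_qc.line_ids)]
        traits.to_csv(out / "traits.csv", index=False)

        stage = "scan"
        scan_cfg = ScanConfig(seed=cfg.seed, **cfg.scan)
        bg = caller.bin_genotypes_
        X, kept, dropped = bg.to_numeric()
        trait_by_line = traits.set_index("line_id")
        order = [lid for lid in bg.line_ids if lid in trait_by_line.index]
        if len(order) < len(bg.line_ids):
            log.warning("scan: %d lines lack trait values", len(bg.line_ids) - len(order))
        rows = [bg.line_ids.index(lid) for lid in order]
        records: list[QTLRecord] = []
        scan_pvalues: dict[str, np.ndarray] = {}
        lambdas: dict[str, float] = {}
        for trait in cfg.traits:
            y = trait_by_line.loc[order, trait].to_numpy(dtype=float)
            scanner = RidgeQTLScanner(
                alpha=scan_cfg.alpha, n_permutations=scan_cfg.n_permutations,
                penalty=scan_cfg.penalty, p_method=scan_cfg.p_method,
                random_state=scan_cfg.seed,
            ).fit(X[rows], y)
            pfull = np.full(caller.bin_map_.n_bins, np.nan)
            sfull = np.zeros(caller.bin_map_.n_bins, dtype=int)
            cfull = np.zeros(caller.bin_map_.n_bins)
            pfull[kept] = scanner.pvalues_
            sfull[kept] = scanner.signs_
            cfull[kept] = scanner.marginal_stat_
            scan_pvalues[trait] = pfull
            lambdas[trait] = scanner.lambda_
            recs = declare_qtls(pfull, sfull, caller.bin_map_, trait,
                                scan_cfg.alpha, stats=cfull)
            if recs:
                peak_cols = [r.peak_bin_index for r in recs]
                col_of = {int(k): i for i, k in enumerate(kept)}
                Xpeaks = X[np.ix_(rows, [col_of[c] for c in peak_cols])]
                assign_pve(recs, Xpeaks, y, scan_cfg.max_exact_lmg_predictors,
                           seed=scan_cfg.seed)
            records.extend(recs)

        stage = "regions"
        regions = cluster_sd_regions(records, n_traits_total=len(cfg.traits))
        _write_qtl_tsv(records, out / "qtls.tsv")
        _write_region_outputs(regions, out)

        stage = "provenance"
        prov = {
            "version": __version__,
            "seed": cfg.seed,
            "config": _config_dict(cfg),
            "n_lines_post_qc": snp_qc.n_lines,
            "n_bins": caller.bin_map_.n_bins,
            "dropped_zero_variance_bins": dropped,
            "ridge_lambda": lambdas,
            "binmap_metadata": caller.metadata(),
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return RunResult(out, snp_qc, qc_report, caller.bin_map_, bg, traits,
                     records, regions, truth, scan_pvalues)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["traits"] = list(d["traits"])
    return d


def _write_qtl_tsv(records: list[QTLRecord], path) -> None:
    cols = ["trait", "name", "chrom", "peak_bin_id", "peak_start", "peak_end",
            "pvalue", "sign", "pve", "span_start", "span_end", "n_span_bins"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    df.to_csv(path, sep="\t", index=False)


def _write_region_outputs(regions: list[SDRegion], out: Path) -> None:
    rows = [{"name": r.name, "chrom": r.chrom, "start": r.start, "end": r.end,
             "n_traits": r.n_traits, "all_traits": r.all_traits,
             "members": ",".join(m.name for m in r.members)} for r in regions]
    pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "n_traits",
                                "all_traits", "members"]).to_csv(
        out / "sd_regions.tsv", sep="\t", index=False)
    with open(out / "sd_regions.bed", "w") as fh:
        fh.write("# dormqtl seed-dormancy regions; 0-based half-open\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.n_traits}\n")
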