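"""End-to-end orchestration of the dual-screen integration analysis.

``run_pipeline`` drives the stages in order — plate normalization and
phenotype correlation, differential expression per knockdown, the
dual-evidence network, gene-set overlap enrichment, clustering and
trajectory summaries, and peak/coverage integration — writing every
intermediate as a tab-delimited text file plus a machine-readable JSON
manifest.  All randomness flows from the single config seed, so a rerun
with the same config produces byte-identical outputs.
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

from . import __version__
from . import enrichment as enr
from . import genomics as gx
from . import highcontent as hc
from . import network as nw
from . import synthetic as syn
from . import transcriptome as tx

__all__ = ["PipelineConfig", "ConfigError", "PipelineError", "run_pipeline"]

log = logging.getLogger("dualscreen")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; round-trips losslessly through YAML.

    Analysis parameters default to the screening conventions: dual network
    threshold R > 0.4, DE cutoff padj < 0.05, summit windows +/- 5 kb.
    With ``simulate`` true all inputs are generated into ``outdir/inputs``
    from the seed; otherwise the ``*_path`` entries must point at existing
    files.
    """

    outdir: str = "dualscreen_out"
    seed: int = 0
    simulate: bool = True
    # input paths (required when simulate is false)
    screen_path: str | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    timecourse_path: str | None = None
    genes_path: str | None = None
    peaks_path: str | None = None
    coverage_path: str | None = None
    # analysis parameters
    threshold: float = 0.4
    alpha: float = 0.05
    min_replicates: int = 2
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    flank: int = 5000
    n_bins: int = 100
    n_boot: int = 1000
    cluster_k: int = 3
    control_label: str = "nt"
    hit_feature: str = "feat00"
    # simulation sizes (the synthetic study conditions)
    sim_n_knockdowns: int = 30
    sim_n_features: int = 27
    sim_n_replicates: int = 4
    sim_n_plates: int = 2
    sim_module_size: int = 3
    sim_effect_size: float = 2.0
    sim_noise_sd: float = 1.0
    sim_n_genes: int = 2000
    sim_reps_per_group: int = 3
    sim_dispersion: float = 0.05
    sim_n_timepoints: int = 4
    sim_annotation_size: int = 300
    sim_n_target_genes: int = 60
    sim_frac_targeted: float = 0.8

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.flank <= 0 or self.n_bins < 1 or self.n_bins % 2:
            raise ConfigError("flank must be > 0 and n_bins a positive even number")
        if self.cluster_k < 2:
            raise ConfigError("cluster_k must be >= 2")
        if not self.simulate:
            required = (
                "screen_path counts_path samples_path timecourse_path "
                "genes_path peaks_path coverage_path"
            ).split()
            for name in required:
                value = getattr(self, name)
                if value is None:
                    raise ConfigError(f"{name} is required when simulate is false")
                if not Path(value).exists():
                    raise ConfigError(f"{name}: no such file: {value}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def _simulate_inputs(cfg: PipelineConfig, indir: Path) -> dict[str, object]:
    """Generate all pipeline inputs from the config seed and write them."""
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(s) for k, s in zip(
        ("screen", "expression", "timecourse", "tracks"),
        rng.integers(0, 2**31 - 1, size=4),
    )}
    knockdowns = [f"kd{i:03d}" for i in range(cfg.sim_n_knockdowns)]
    module = frozenset(knockdowns[: cfg.sim_module_size])
    screen_truth = syn.ScreenTruth(
        modules=(module,),
        effect_size=cfg.sim_effect_size,
        noise_sd=cfg.sim_noise_sd,
    )
    screen, _ = syn.generate_screen(
        cfg.sim_n_knockdowns,
        cfg.sim_n_features,
        cfg.sim_n_replicates,
        cfg.sim_n_plates,
        screen_truth,
        seed=seeds["screen"],
    )
    hc.write_screen_table(screen, indir / "screen.tsv")

    counts, expr_truth = syn.generate_knockdown_expression(
        knockdowns,
        modules=[module],
        n_genes=cfg.sim_n_genes,
        reps_per_group=cfg.sim_reps_per_group,
        dispersion=cfg.sim_dispersion,
        seed=seeds["expression"],
        control=cfg.control_label,
    )
    _write_tsv(counts.rename_axis("gene"), indir / "counts.tsv")
    meta = pd.DataFrame(
        {
            "sample": counts.columns,
            "condition": [s.rsplit("_r", 1)[0] for s in counts.columns],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in counts.columns],
        }
    )
    _write_tsv(meta, indir / "samples.tsv", index=False)

    timepoints = [f"day{d}" for d in range(cfg.sim_n_timepoints)]
    n_tc = 400
    decay = tuple(f"g{i:05d}" for i in range(0, 50))
    tc = syn.generate_time_course(
        n_tc, timepoints, {decay: (1.0, 0.25)}, seed=seeds["timecourse"]
    )
    _write_tsv(tc.rename_axis("gene"), indir / "timecourse.tsv")

    # annotation shares the expression gene namespace; targets are drawn
    # from the first knockdown's planted up-regulated genes
    first_kd_up = sorted(
        g for g, v in expr_truth.de_genes[knockdowns[0]].items() if v > 0
    )
    targets = first_kd_up[: cfg.sim_n_target_genes]
    filler = (
        g for i in range(cfg.sim_n_genes)
        if (g := f"g{i:05d}") not in set(targets)
    )
    ann_names = sorted(set(targets) | {
        g for g, _ in zip(filler, range(cfg.sim_annotation_size - len(targets)))
    })
    genes, peaks, track = syn.generate_genomic_tracks(
        cfg.sim_annotation_size,
        {"chr1": 4_000_000, "chr2": 3_000_000, "chr3": 2_000_000},
        targets,
        cfg.sim_frac_targeted,
        flank=1000,
        seed=seeds["tracks"],
        n_background_peaks=20,
        gene_names=ann_names,
    )
    gx.write_bed(genes, indir / "genes.bed")
    gx.write_peaks(peaks, indir / "peaks.bed")
    track.to_bedgraph(indir / "coverage.bedgraph")
    (indir / "coverage.total_reads.txt").write_text(
        f"{int(track.total_reads)}\n", encoding="utf-8"
    )
    return {"module": sorted(module), "targets": targets}


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage; returns a result bundle of in-memory objects and paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    results: dict[str, object] = {"outdir": str(outdir)}
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "simulate"
        if config.simulate:
            indir = outdir / "inputs"
            indir.mkdir(exist_ok=True)
            sim_info = _simulate_inputs(config, indir)
            results["simulated"] = sim_info
            paths = {
                "screen": indir / "screen.tsv",
                "counts": indir / "counts.tsv",
                "samples": indir / "samples.tsv",
                "timecourse": indir / "timecourse.tsv",
                "genes": indir / "genes.bed",
                "peaks": indir / "peaks.bed",
                "coverage": indir / "coverage.bedgraph",
            }
            total_reads = float(
                (indir / "coverage.total_reads.txt").read_text().strip()
            )
        else:
            paths = {
                "screen": Path(config.screen_path),
                "counts": Path(config.counts_path),
                "samples": Path(config.samples_path),
                "timecourse": Path(config.timecourse_path),
                "genes": Path(config.genes_path),
                "peaks": Path(config.peaks_path),
                "coverage": Path(config.coverage_path),
            }
            total_reads = None

        # ---- screen normalization and phenotype correlation ---------------
        stage = "screen"
        log.info("normalizing screen features and correlating profiles")
        screen = hc.read_screen_table(paths["screen"])
        zscored = hc.zscore_by_plate(screen)
        hc.write_screen_table(zscored, outdir / "screen_zscored.tsv")
        profiles = hc.aggregate_replicates(zscored, config.min_replicates)
        _write_tsv(profiles.values.rename_axis("knockdown"), outdir / "profiles.tsv")
        hits = hc.rank_hits(profiles, config.hit_feature)
        pd.DataFrame(hits, columns=["knockdown", "score"]).to_csv(
            outdir / "hits.tsv", sep="\t", index=False, lineterminator="\n"
        )
        corr_hc = hc.phenotype_correlation(profiles)
        _write_tsv(corr_hc.to_frame().rename_axis("knockdown"),
                   outdir / "corr_highcontent.tsv")
        results["corr_highcontent"] = corr_hc

        # ---- differential expression per knockdown ------------------------
        stage = "de"
        log.info("differential expression per knockdown")
        counts = tx.read_counts(paths["counts"])
        meta = pd.read_csv(paths["samples"], sep="\t")
        control_samples = list(
            meta.loc[meta["condition"] == config.control_label, "sample"]
        )
        if len(control_samples) < 2:
            raise ConfigError(
                f"control condition {config.control_label!r} has fewer than 2 samples"
            )
        de_tables: dict[str, pd.DataFrame] = {}
        summary_rows = []
        de_dir = outdir / "de"
        de_dir.mkdir(exist_ok=True)
        conditions = [
            c for c in meta["condition"].unique() if c != config.control_label
        ]
        for cond in conditions:
            cond_samples = list(meta.loc[meta["condition"] == cond, "sample"])
            res = tx.simple_de(counts, control_samples, cond_samples)
            de_tables[cond] = res.table
            tx.write_de_table(res.table, de_dir / f"de_{cond}.tsv")
            s = tx.de_summary(res.table, config.alpha)
            summary_rows.append(
                (cond, s.n_deregulated,
                 "" if s.fraction_up is None else f"{s.fraction_up:.4f}",
                 "" if s.mean_abs_log2fc is None else f"{s.mean_abs_log2fc:.4f}")
            )
        pd.DataFrame(
            summary_rows,
            columns=["condition", "n_deregulated", "fraction_up", "mean_abs_log2fc"],
        ).to_csv(outdir / "de_summary.tsv", sep="\t", index=False, lineterminator="\n")
        results["de_tables"] = de_tables

        # ---- transcriptome correlation and dual-evidence network ----------
        stage = "network"
        log.info("building the dual-evidence network")
        union_genes = sorted(
            set().union(
                *(
                    set(t.loc[t["padj"] < config.alpha, "gene"])
                    for t in de_tables.values()
                )
            )
        )
        if len(union_genes) < 3:
            raise PipelineError("network", "fewer than 3 DE genes across knockdowns")
        lfc = tx.log2fc_matrix(dict(de_tables), union_genes)
        _write_tsv(lfc.rename_axis("gene"), outdir / "log2fc_matrix.tsv")
        corr_rna = tx.transcriptome_correlation(lfc)
        _write_tsv(corr_rna.to_frame().rename_axis("knockdown"),
                   outdir / "corr_transcriptome.tsv")
        net = nw.dual_evidence_network(corr_hc, corr_rna, config.threshold)
        nw.export_network(net, outdir / "network.graphml", "graphml")
        nw.export_network(net, outdir / "network.tsv", "tsv")
        nw.export_network(net, outdir / "network.sif", "sif")
        results["network"] = net
        results["corr_transcriptome"] = corr_rna

        # ---- peak/gene overlap enrichment ---------------------------------
        stage = "enrichment"
        log.info("overlap enrichment of peak-associated genes vs DE sets")
        gene_ann = gx.read_bed(paths["genes"])
        peaks = gx.read_peaks(paths["peaks"])
        peak_map = gx.map_peaks_to_genes(
            peaks, gene_ann, mode="interval",
            upstream=config.promoter_upstream, downstream=config.promoter_downstream,
        )
        peak_gene_set = enr.GeneSet.from_symbols("peak_genes", peak_map.keys())
        enrich_results = []
        for cond in conditions:
            up, down, universe = tx.de_gene_sets(de_tables[cond], config.alpha, cond)
            peak_in_universe = enr.GeneSet(
                "peak_genes", peak_gene_set.members & universe.members
            )
            for s in (up, down):
                if len(s) == 0:
                    continue
                enrich_results.append(
                    enr.overlap_enrichment(s, peak_in_universe, universe)
                )
        enr.write_enrichment_table(enrich_results, outdir / "enrichment.tsv")
        results["enrichment"] = enrich_results

        # ---- clustering and trajectory summaries --------------------------
        stage = "clusters"
        log.info("clustering the log2FC matrix and summarizing trajectories")
        k = min(config.cluster_k, lfc.shape[0])
        labels = tx.hierarchical_clusters(lfc, k=max(k, 2))
        pd.DataFrame({"gene": lfc.index, "cluster": labels}).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False, lineterminator="\n"
        )
        rowz = tx.row_zscore(lfc)
        _write_tsv(rowz.rename_axis("gene"), outdir / "log2fc_rowzscore.tsv")
        tc = tx.read_counts(paths["timecourse"])
        decay_genes = [g for g in tc.index[:50]]
        flat_genes = [g for g in tc.index[50:]]
        rows = []
        for name, genes_ in (("planted_decay", decay_genes), ("background", flat_genes)):
            traj = tx.trajectory_summary(
                tc.loc[genes_], n_boot=config.n_boot, seed=config.seed
            )
            for tp, m, lo, hi in zip(
                traj.timepoints, traj.median, traj.ci_low, traj.ci_high
            ):
                rows.append((name, tp, f"{m:.6f}", f"{lo:.6f}", f"{hi:.6f}"))
        pd.DataFrame(
            rows, columns=["gene_set", "timepoint", "median", "ci_low", "ci_high"]
        ).to_csv(outdir / "trajectory.tsv", sep="\t", index=False, lineterminator="\n")

        # ---- summit-centered signal matrices ------------------------------
        stage = "genomics"
        log.info("summit-centered signal quantification")
        track = gx.CoverageTrack.from_bedgraph(paths["coverage"], total_reads=total_reads)
        mat, row_order = gx.summit_matrix(
            track, peaks, flank=config.flank, n_bins=config.n_bins, norm="rpkm"
        )
        mat_df = pd.DataFrame(
            mat,
            index=[peaks.peaks[i].name for i in row_order],
            columns=[f"bin{j:03d}" for j in range(config.n_bins)],
        )
        _write_tsv(mat_df.rename_axis("peak"), outdir / "summit_matrix.tsv")
        windows = gx.promoter_windows(
            [g for g in gene_ann if g.name in peak_map],
            config.promoter_upstream, config.promoter_downstream,
        )
        rpm = gx.region_signal(track, windows, norm="rpm")
        pd.DataFrame(
            {"gene": [w.name for w in windows], "rpm": rpm}
        ).to_csv(outdir / "region_signal.tsv", sep="\t", index=False,
                 lineterminator="\n")

        # ---- manifest -----------------------------------------------------
        stage = "manifest"
        manifest = {
            "package": "dualscreen",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "inputs": {k: _sha256(p) for k, p in sorted(paths.items())},
            "outputs": {
                p.name: _sha256(p)
                for p in sorted(outdir.glob("*.tsv"))
                + sorted(outdir.glob("*.graphml"))
                + sorted(outdir.glob("*.sif"))
                + sorted((outdir / "de").glob("*.tsv"))
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        results["manifest"] = manifest
    except PipelineError:
        failed_marker.write_text(f"{stage}\n", encoding="utf-8")
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        failed_marker.write_text(f"{stage}\n", encoding="utf-8")
        if isinstance(exc, ConfigError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return results
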