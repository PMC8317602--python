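"""End-to-end orchestration: simulate -> filter -> scan -> xpclr -> detect.

Every stage is a pure function of its inputs and the config, so rerunning
with the same seed reproduces identical statistic files; each output TSV
carries a '#'-prefixed metadata header (version, seed, parameters) and the
manifest records a SHA-256 checksum per file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DegenerateError, PoolsweepError
from .simulate import SimulationConfig, SweepSpec, TruthTable, simulate_dataset, write_outputs
from .sweep_detect import intersect_top_windows, overlap_genes, summarize, write_candidates
from .variant_io import FilterConfig, apply_filters, compute_tstv, read_gff3, read_vcf_counts
from .window_stats import (
    WindowingConfig, top_quantile, window_fst, window_hp, z_transform,
)
from .xpclr import XpclrConfig, normalize_scores, window_xpclr

logger = logging.getLogger(__name__)


def normalized_or_zero(raw) -> np.ndarray:
    """Z-normalized scores, or zeros when the distribution is degenerate.

    Fully neutral data can leave every raw composite score at exactly 0
    (the alternative never beats the null anywhere); ranking then falls
    back to the raw scores and the normalized column is all-zero.
    """
    try:
        return normalize_scores(raw)
    except DegenerateError:
        import warnings

        warnings.warn("raw scores have zero variance; normalized scores set to 0")
        return np.zeros_like(np.asarray(raw, dtype=float))


@dataclass
class PipelineConfig:
    """Everything one run needs; ``seed`` drives every random draw."""

    outdir: str
    seed: int
    simulation: SimulationConfig | None = None
    sweeps: tuple = ()
    filters: FilterConfig = field(default_factory=FilterConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    xpclr: XpclrConfig | None = None
    q: float = 0.01
    target_pool: int = 1
    fst_mode: str = "ratio-of-sums"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ConfigError("q must lie in (0, 1)")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.xpclr is None:
            self.xpclr = XpclrConfig(window=self.windowing,
                                     object_pool=self.target_pool)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        sweeps = tuple(SweepSpec(**s) for s in raw.pop("sweeps", []))
        filters = FilterConfig(**raw.pop("filters", {}))
        windowing = WindowingConfig(**raw.pop("windowing", {}))
        xp = raw.pop("xpclr", None)
        cfg = cls(filters=filters, windowing=windowing, sweeps=sweeps, **raw)
        if sim is not None:
            if "pools" in sim:
                from .variant_io import PoolSpec
                sim["pools"] = tuple(PoolSpec(n) for n in sim["pools"])
            if "chrom_lengths" in sim:
                sim["chrom_lengths"] = tuple(sim["chrom_lengths"])
            cfg.simulation = SimulationConfig(seed=cfg.seed, **sim)
        if xp is not None:
            cfg.xpclr = XpclrConfig(window=windowing,
                                    object_pool=cfg.target_pool, **xp)
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, config: PipelineConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# poolsweep {__version__} stage={stage} seed={config.seed} "
                 f"window={config.windowing.size} min_snps={config.windowing.min_snps} "
                 f"q={config.q} target_pool={config.target_pool} "
                 f"fst_mode={config.fst_mode}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class Manifest:
    """Files a run produced, with checksums; failed stages leave earlier
    outputs listed and ``failed_stage`` set."""

    files: dict = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.failed_stage is None

    def add(self, name: str, path) -> None:
        self.files[name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"ok": self.ok, "failed_stage": self.failed_stage,
                       "error": self.error, "files": self.files}, fh, indent=2)


def compute_window_table(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """F_ST, Hp and -ZHp per retained window, joined on the window grid."""
    pools = config.simulation.pools
    fst = window_fst(records, pools, config.windowing, mode=config.fst_mode)
    hp = window_hp(records, target_pool=config.target_pool, config=config.windowing)
    table = fst.merge(hp[["chrom", "start", "hp"]], on=["chrom", "start"], how="inner")
    zhp, params = z_transform(table["hp"].to_numpy())
    table["zhp"] = zhp
    logger.info("window table: %d retained windows (mu_Hp=%.4f sigma_Hp=%.4f)",
                len(table), params.mu, params.sigma)
    return table


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Run all stages in dependency order; returns the output manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()
    stage = "simulate"
    try:
        records, annotation, truth = simulate_dataset(config.simulation, config.sweeps)
        paths = write_outputs(records, annotation, truth, outdir,
                              config=config.simulation)
        for name, p in paths.items():
            manifest.add(name, p)

        stage = "filter"
        records = read_vcf_counts(paths["vcf"])
        filtered, report = apply_filters(records, config.filters)
        ts, tv, tstv = compute_tstv(filtered)
        logger.info("Ts/Tv after filtering: %d/%d = %s", ts, tv, f"{tstv:.3f}")
        fpath = outdir / "filtered.tsv"
        _write_tsv(filtered, fpath, config, "filter")
        report.write(outdir / "filter_report.tsv")
        manifest.add("filtered", fpath)
        manifest.add("filter_report", outdir / "filter_report.tsv")

        stage = "scan"
        table = compute_window_table(filtered, config)
        wpath = outdir / "windows.tsv"
        _write_tsv(table, wpath, config, "scan")
        manifest.add("windows", wpath)

        stage = "xpclr"
        xp = window_xpclr(filtered, config.xpclr)
        xp["xpclr"] = normalized_or_zero(xp["xpclr_raw"].to_numpy())
        xpath = outdir / "xpclr.tsv"
        _write_tsv(xp, xpath, config, "xpclr")
        manifest.add("xpclr", xpath)

        stage = "detect"
        genes = read_gff3(paths["gff3"])
        merged = table.merge(
            xp[["chrom", "start", "xpclr_raw", "xpclr"]],
            on=["chrom", "start"], how="inner")
        _, top_fst = top_quantile(merged, "fst", config.q)
        _, top_zhp = top_quantile(merged, "zhp", config.q)
        # raw scores rank identically to normalized ones (monotone
        # transform) and stay usable when normalization degenerates
        _, top_xp = top_quantile(merged, "xpclr_raw", config.q)
        candidates = intersect_top_windows(top_fst, top_zhp, top_xp)
        regions = overlap_genes(candidates, genes, stats=merged)
        report = summarize(regions)
        cpath = outdir / "candidates.tsv"
        write_candidates(regions, cpath)
        (outdir / "genes.txt").write_text(
            "\n".join(report.distinct_genes) + ("\n" if report.distinct_genes else ""))
        manifest.add("candidates", cpath)
        manifest.add("genes", outdir / "genes.txt")

        stage = "evaluate"
        recovery = evaluate_recovery(candidates, truth)
        rpath = outdir / "recovery.tsv"
        _write_tsv(pd.DataFrame([dataclasses.asdict(recovery)]), rpath, config, "evaluate")
        manifest.add("recovery", rpath)
    except PoolsweepError as exc:
        manifest.failed_stage = stage
        manifest.error = str(exc)
        logger.error("pipeline failed at stage %s: %s", stage, exc)
    manifest.write(outdir / "manifest.json")
    return manifest


@dataclass
class RecoveryResult:
    """Window-level and sweep-level recovery of planted truth."""

    sensitivity: float
    fdp: float
    n_candidates: int
    n_truth_windows: int
    sweeps_recovered: int
    n_sweeps: int

    @property
    def sweep_recovery(self) -> float:
        return self.sweeps_recovered / self.n_sweeps if self.n_sweeps else float("nan")


def evaluate_recovery(candidates, truth: TruthTable) -> RecoveryResult:
    """Compare candidate windows with the planted-sweep truth.

    Sensitivity counts recovered truth windows; the false-discovery
    proportion counts candidates outside every footprint; a sweep is
    recovered when any candidate lies in its footprint.  An empty truth
    table leaves sensitivity undefined (NaN) with a warning.
    """
    cand = {(c[0], int(c[1]), int(c[2])) for c in candidates}
    truth_set = {(c, int(s), int(e)) for (c, s, e) in truth.windows}
    per_sweep = truth.per_sweep()
    if not truth_set:
        import warnings
        warnings.warn("empty truth table: sensitivity undefined")
        sens = float("nan")
    else:
        sens = len(cand & truth_set) / len(truth_set)
    fdp = (len(cand - truth_set) / len(cand)) if cand else 0.0
    recovered = sum(
        1 for wins in per_sweep.values()
        if cand & {(c, int(s), int(e)) for (c, s, e) in wins})
    return RecoveryResult(
        sensitivity=sens, fdp=fdp, n_candidates=len(cand),
        n_truth_windows=len(truth_set), sweeps_recovered=recovered,
        n_sweeps=len(per_sweep))


def plot_scan(table: pd.DataFrame, column: str, path, threshold: float | None = None) -> None:
    """Basic per-chromosome genome-scan figure of one window statistic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(table.groupby("chrom", sort=True)):
        x = grp["start"].to_numpy() + offset
        ax.scatter(x, grp[column], s=3, color=["#1f77b4", "#ff7f0e"][i % 2])
        ticks.append(offset + grp["start"].max() / 2)
        labels.append(str(chrom))
        offset += grp["start"].max() + table["end"].iloc[0]
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_ylabel(column)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
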