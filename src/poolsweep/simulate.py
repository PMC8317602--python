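"""Synthetic two-population pool-seq data with known, plantable sweeps.

The generator emulates the study design the scan targets: two dog breeds
split from a common ancestor (pools of 35 and 59 diploids sequenced to
~30x), with tunable background differentiation and optional localized
selective sweeps.  It is deliberately minimal:

* Neutral divergence follows the Balding-Nichols model — each population's
  allele frequency is a Beta draw around the ancestral frequency with
  variance ``F * p * (1 - p)``, independently per site, so genome-wide
  Weir-Cockerham F_ST has analytic expectation ``F``.
* A sweep moves linked allele frequencies deterministically toward
  fixation under the star-like hitchhiking approximation: at recombination
  distance ``d`` from the focal site, the escape probability is
  ``c = 1 - (2 N s) ** (-r d / s)`` and the linked-allele frequency becomes
  ``p' = (1 - c) + c * p0`` (complete hitchhiking at ``d = 0``, untouched
  as ``d -> inf``).
* Pooled sequencing draws the pool's allele frequency binomially from the
  population frequency (2n chromosomes), a zero-truncated Poisson depth,
  and binomial read counts with a symmetric base-error flip.

Sites are independent given the sweep transform; read-level artifacts,
linkage beyond the deterministic transform, and complex demography are out
of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .variant_io import PoolSpec, VARIANT_COLUMNS, write_sync, write_vcf

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
#: transition partner of each base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

DEFAULT_WINDOW_SIZE = 25_000


@dataclass
class SimulationConfig:
    """Study-scale defaults: a 20 Mb genome (4 x 5 Mb), ~60k SNPs, pools of
    35 and 59 diploids at 30x mean depth.

    ``fst`` is the Balding-Nichols background differentiation F;
    ``ts_fraction`` is the probability a simulated substitution is a
    transition (0.649 gives Ts/Tv ~ 1.85, typical of dog variant sets).
    """

    seed: int
    chrom_lengths: tuple = (5_000_000, 5_000_000, 5_000_000, 5_000_000)
    snp_density: float = 0.003
    fst: float = 0.05
    ancestral_range: tuple = (0.05, 0.95)
    pools: tuple = (PoolSpec(35, "pool1"), PoolSpec(59, "pool2"))
    mean_depth: float = 30.0
    base_error: float = 0.002
    indel_density: float = 1e-4
    ts_fraction: float = 0.649
    qual_range: tuple = (20.0, 90.0)
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("empty genome")
        if any(L < self.window_size for L in self.chrom_lengths):
            raise ConfigError("every chromosome must span at least one window")
        if not 0 < self.fst < 1:
            raise ConfigError("background F must lie in (0, 1)")
        if self.mean_depth <= 0:
            raise ConfigError("mean depth must be positive")
        if not 0 <= self.base_error < 0.01:
            raise ConfigError("base error must lie in [0, 0.01)")
        lo, hi = self.ancestral_range
        if not 0 < lo < hi < 1:
            raise ConfigError("ancestral frequency bounds must satisfy 0 < lo < hi < 1")
        if len(self.pools) != 2:
            raise ConfigError("exactly two pools are supported")

    @property
    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


@dataclass(frozen=True)
class SweepSpec:
    """A planted hard sweep in one population."""

    chrom: str
    position: int
    s: float = 0.05
    rec_rate: float = 1e-8
    n_e: int = 10_000
    population: int = 1  # 1 or 2

    def __post_init__(self) -> None:
        if self.s <= 0 or self.rec_rate <= 0 or self.n_e <= 0:
            raise ConfigError("s, recombination rate and N must be positive")
        if self.population not in (1, 2):
            raise ConfigError("target population must be 1 or 2")

    @property
    def half_width(self) -> float:
        """Footprint half-width: distance at which the escape probability
        reaches 1/2, ``s ln 2 / (r ln 2Ns)``."""
        return self.s * math.log(2.0) / (self.rec_rate * math.log(2 * self.n_e * self.s))


@dataclass
class TruthTable:
    """Windows occupied by planted sweeps, aligned to the analysis grid."""

    windows: list = field(default_factory=list)  # (chrom, start, end)
    sweep_ids: list = field(default_factory=list)  # parallel to windows
    half_width: float = 0.0
    window_size: int = DEFAULT_WINDOW_SIZE

    def per_sweep(self) -> dict:
        out: dict = {}
        for w, i in zip(self.windows, self.sweep_ids):
            out.setdefault(i, []).append(w)
        return out

    def write(self, path) -> None:
        df = pd.DataFrame(
            [(c, s, e, i) for (c, s, e), i in zip(self.windows, self.sweep_ids)],
            columns=["chrom", "start", "end", "sweep"],
        )
        with open(path, "w") as fh:
            fh.write(f"#half_width={self.half_width}\twindow_size={self.window_size}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path):
        with open(path) as fh:
            header = fh.readline().lstrip("#").strip().split("\t")
            meta = dict(kv.split("=") for kv in header)
            df = pd.read_csv(fh, sep="\t")
        return cls(
            windows=[(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()],
            sweep_ids=[int(r.sweep) for r in df.itertuples()],
            half_width=float(meta["half_width"]),
            window_size=int(meta["window_size"]),
        )


def truth_table(config: SimulationConfig, sweeps) -> TruthTable:
    """Grid-aligned windows within each sweep's footprint half-width."""
    size = config.window_size
    windows, ids = [], []
    lengths = dict(zip(config.chrom_names, config.chrom_lengths))
    for i, sw in enumerate(sweeps):
        hw = sw.half_width
        lo = max(0, int((sw.position - hw) // size) * size)
        hi = min(lengths[sw.chrom], sw.position + hw)
        start = lo
        while start < hi:
            windows.append((sw.chrom, start, start + size))
            ids.append(i)
            start += size
    return TruthTable(windows, ids, half_width=sweeps[0].half_width if sweeps else 0.0,
                      window_size=size)


# ---------------------------------------------------------------------------
# frequency simulation
# ---------------------------------------------------------------------------

def simulate_frequencies(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-site ancestral and population allele frequencies.

    Returns a frame with columns chrom, pos, anc, p1, p2; ``p1``/``p2``
    are Balding-Nichols draws (Beta with mean ``anc`` and parameter F)
    independently per population and site.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    F = config.fst
    lo, hi = config.ancestral_range
    frames = []
    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        n_sites = int(round(length * config.snp_density))
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        anc = rng.uniform(lo, hi, size=n_sites)
        shape = (1.0 - F) / F
        p1 = rng.beta(anc * shape, (1.0 - anc) * shape)
        p2 = rng.beta(anc * shape, (1.0 - anc) * shape)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "anc": anc, "p1": p1, "p2": p2}
        ))
    out = pd.concat(frames, ignore_index=True)
    logger.info("simulated %d sites on %d chromosomes (F=%g)",
                len(out), len(config.chrom_lengths), F)
    return out


def escape_probability(d, s: float, rec_rate: float, n_e: int):
    """Probability a lineage at distance ``d`` recombines off the sweeping
    background: ``c = 1 - (2 N s) ** (-r d / s)`` (star-like approximation)."""
    d = np.asarray(d, dtype=float)
    return 1.0 - np.power(2.0 * n_e * s, -(rec_rate * d) / s)


def apply_sweep(freqs: pd.DataFrame, sweep: SweepSpec) -> pd.DataFrame:
    """Push the target population's alt-allele frequencies toward fixation
    around the focal site: ``p' = (1 - c) + c * p0``, clipped to [0, 1].

    Returns a modified copy; the alt allele is the one linked to the
    beneficial background.
    """
    if sweep.chrom not in set(freqs["chrom"]):
        raise ConfigError(f"sweep chromosome {sweep.chrom} not in the simulated genome")
    out = freqs.copy()
    col = f"p{sweep.population}"
    sel = (out["chrom"] == sweep.chrom).to_numpy()
    d = np.abs(out.loc[sel, "pos"].to_numpy() - sweep.position)
    c = escape_probability(d, sweep.s, sweep.rec_rate, sweep.n_e)
    p0 = out.loc[sel, col].to_numpy()
    out.loc[sel, col] = np.clip((1.0 - c) + c * p0, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------

def _truncated_poisson(rng, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1 (the pipeline never emits
    zero-depth records)."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def sample_pool_counts(freqs: pd.DataFrame, pools, mean_depth: float,
                       base_error: float, seed: int,
                       qual_range=(20.0, 90.0),
                       ts_fraction: float = 0.649) -> pd.DataFrame:
    """Turn population frequencies into a pooled read-count variant table.

    Per pool and site: the pool allele frequency is a Binomial(2n, p)/2n
    draw, depth is zero-truncated Poisson, and alt reads are binomial in
    depth with the frequency error-adjusted by ``f(1-e) + (1-f)e``.
    Ref/alt bases are drawn with transition probability ``ts_fraction``;
    site qualities are uniform over ``qual_range``.
    """
    if mean_depth <= 0:
        raise ConfigError("mean depth must be positive")
    if len(pools) != 2:
        raise ConfigError("exactly two pools are supported")
    rng = np.random.default_rng(seed)
    n = len(freqs)

    ref = rng.choice(_BASES, size=n)
    is_ts = rng.random(n) < ts_fraction
    tv_pick = rng.integers(0, 2, size=n)
    alt = np.array([
        _TRANSITION[r] if t else _TRANSVERSIONS[r][k]
        for r, t, k in zip(ref, is_ts, tv_pick)
    ])

    counts = []
    for i, pool in enumerate(pools, start=1):
        p = freqs[f"p{i}"].to_numpy()
        n_hap = pool.n_haploid
        pool_freq = rng.binomial(n_hap, p) / n_hap
        depth = _truncated_poisson(rng, mean_depth, n)
        f_obs = pool_freq * (1.0 - base_error) + (1.0 - pool_freq) * base_error
        alt_reads = rng.binomial(depth, f_obs)
        counts.extend([depth - alt_reads, alt_reads])

    qual = rng.uniform(*qual_range, size=n)
    out = pd.DataFrame({
        "chrom": freqs["chrom"].to_numpy(),
        "pos": freqs["pos"].to_numpy(),
        "ref": ref,
        "alt": alt,
        "is_indel": False,
        "qual": qual,
        "ref1": counts[0], "alt1": counts[1],
        "ref2": counts[2], "alt2": counts[3],
    })
    return out[VARIANT_COLUMNS]


def plant_indels(config: SimulationConfig, records: pd.DataFrame,
                 seed: int | None = None):
    """Interleave indel records at Poisson-random positions.

    Returns ``(records_with_indels, indel_positions)`` where the
    positions frame has columns chrom, pos.  With zero density the table
    is returned unchanged.
    """
    if config.indel_density == 0:
        return records.copy(), pd.DataFrame(columns=["chrom", "pos"])
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        n_indels = rng.poisson(config.indel_density * length)
        pos = np.sort(rng.choice(length, size=min(n_indels, length), replace=False)) + 1
        for p in pos:
            ref = rng.choice(_BASES)
            ins = rng.random() < 0.5
            alt = ref + rng.choice(_BASES) if ins else ref
            ref_allele = ref if ins else ref + rng.choice(_BASES)
            depth1 = max(1, rng.poisson(config.mean_depth))
            depth2 = max(1, rng.poisson(config.mean_depth))
            a1 = rng.binomial(depth1, 0.2)
            a2 = rng.binomial(depth2, 0.2)
            rows.append((chrom, int(p), ref_allele, alt, True,
                         float(rng.uniform(*config.qual_range)),
                         depth1 - a1, a1, depth2 - a2, a2))
    indels = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    merged = (
        pd.concat([records, indels], ignore_index=True)
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    positions = indels[["chrom", "pos"]].reset_index(drop=True)
    logger.info("planted %d indels", len(indels))
    return merged, positions


# ---------------------------------------------------------------------------
# annotation + output bundle
# ---------------------------------------------------------------------------

def make_toy_annotation(config: SimulationConfig, sweeps=(),
                        genes_per_chrom: int = 8) -> pd.DataFrame:
    """A small gene annotation: one gene straddling each sweep focus plus
    evenly spaced background genes, 30 kb long, on alternating strands."""
    rows = []
    gene_len = 30_000
    k = 0
    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        for j in range(genes_per_chrom):
            start = int((j + 0.5) * length / genes_per_chrom)
            rows.append((f"GENE{k:04d}", f"GENE{k:04d}", chrom,
                         start, min(start + gene_len, length), "+-"[j % 2]))
            k += 1
    for i, sw in enumerate(sweeps):
        rows.append((f"SWEEPGENE{i}", f"SWEEPGENE{i}", sw.chrom,
                     max(1, sw.position - gene_len // 2),
                     sw.position + gene_len // 2, "+"))
    df = pd.DataFrame(rows, columns=["id", "symbol", "chrom", "start", "end", "strand"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            attrs = f"ID={g.id};Name={g.symbol}"
            fh.write(f"{g.chrom}\tpoolsweep\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def write_outputs(records: pd.DataFrame, annotation: pd.DataFrame,
                  truth: TruthTable, outdir, config: SimulationConfig | None = None,
                  prefix: str = "sim") -> dict:
    """Write the sync, VCF, GFF3 and truth-table files; returns their paths."""
    from pathlib import Path

    if records.empty:
        raise ConfigError("refusing to write an empty variant table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sync": outdir / f"{prefix}.sync",
        "vcf": outdir / f"{prefix}.vcf",
        "gff3": outdir / f"{prefix}.gff3",
        "truth": outdir / f"{prefix}.truth.tsv",
    }
    contigs = (dict(zip(config.chrom_names, config.chrom_lengths))
               if config is not None else None)
    names = (tuple(p.name or f"pool{i+1}" for i, p in enumerate(config.pools))
             if config is not None else ("pool1", "pool2"))
    write_sync(records, paths["sync"])
    write_vcf(records, paths["vcf"], contig_lengths=contigs, sample_names=names)
    write_gff3(annotation, paths["gff3"])
    truth.write(paths["truth"])
    return paths


def simulate_dataset(config: SimulationConfig, sweeps=()):
    """Convenience end-to-end generator.

    Returns ``(records, annotation, truth)``: the variant table with
    indels interleaved, a toy gene annotation, and the truth windows.
    """
    freqs = simulate_frequencies(config)
    for sw in sweeps:
        freqs = apply_sweep(freqs, sw)
    records = sample_pool_counts(
        freqs, config.pools, config.mean_depth, config.base_error,
        seed=config.seed + 2, qual_range=config.qual_range,
        ts_fraction=config.ts_fraction,
    )
    records, _ = plant_indels(config, records)
    annotation = make_toy_annotation(config, sweeps)
    truth = truth_table(config, list(sweeps))
    return records, annotation, truth
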