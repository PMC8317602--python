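"""Windowed differentiation and pooled-heterozygosity statistics.

SNPs are partitioned into non-overlapping 25-kb windows (a 1-based
position ``p`` belongs to the window starting at ``floor((p-1)/size) *
size``; windows occupy ``[start, end)`` so consecutive windows share a
printed boundary).  Windows with fewer than ``min_snps`` SNPs are
discarded before any statistic is computed.

Per-site differentiation is the two-population Weir-Cockerham estimator.
With haploid sample sizes ``n1, n2`` and sample allele frequencies
``p1, p2``::

    MSP = n1 n2 / (n1 + n2) * (p1 - p2)**2
    MSG = (n1 p1 (1 - p1) + n2 p2 (1 - p2)) / (n1 + n2 - 2)
    nc  = 2 n1 n2 / (n1 + n2)
    F   = (MSP - MSG) / (MSP + (nc - 1) MSG)
      = 1 - nc MSG / (MSP + (nc - 1) MSG)

Window F_ST aggregates sites either as a ratio of sums (default) or as a
mean of per-site ratios; negative values are legitimate estimates and are
never clamped.

Pooled heterozygosity of one pool over a window is
``Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))**2`` where
``nMAJ``/``nMIN`` are the pool's read counts of each SNP's within-pool
major/minor allele; ``-ZHp = (mu - Hp) / sigma`` standardizes across
retained windows (population standard deviation) so that large positive
values mark heterozygosity deficits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateError

logger = logging.getLogger(__name__)


@dataclass
class WindowingConfig:
    size: int = 25_000
    min_snps: int = 10

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ConfigError("window size must be positive")
        if self.min_snps < 1:
            raise ConfigError("min_snps must be >= 1")


class WindowKey(NamedTuple):
    chrom: str
    start: int
    end: int


def window_starts(positions, size: int) -> np.ndarray:
    """Window start (0-based, multiple of ``size``) of each 1-based position."""
    pos = np.asarray(positions, dtype=np.int64)
    return (pos - 1) // size * size


def assign_windows(records: pd.DataFrame, config: WindowingConfig | None = None) -> dict:
    """Partition records into windows; returns ``{WindowKey: sub-frame}``.

    Every record lands in exactly one window; no minimum-SNP filter is
    applied here.
    """
    if config is None:
        config = WindowingConfig()
    if records.empty:
        return {}
    starts = window_starts(records["pos"].to_numpy(), config.size)
    out = {}
    for (chrom, start), grp in records.groupby(
            [records["chrom"].to_numpy(), starts], sort=True):
        out[WindowKey(chrom, int(start), int(start) + config.size)] = grp
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def site_fst_components(p1, p2, n1, n2):
    """Per-site Weir-Cockerham mean squares; returns ``(MSP, MSG, nc)``.

    ``n1``/``n2`` are haploid sample sizes (scalars or arrays); requires
    ``n1 + n2 > 2``.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 + n2 <= 2):
        raise DegenerateError("need n1 + n2 > 2 haploid samples")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n = n1 + n2
    msp = n1 * n2 / n * (p1 - p2) ** 2
    msg = (n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)) / (n - 2.0)
    nc = 2.0 * n1 * n2 / n
    return msp, msg, nc


def site_fst(p1, p2, n1, n2):
    """Single-site estimate ``(MSP - MSG) / (MSP + (nc - 1) MSG)``; NaN when
    the denominator vanishes (site monomorphic in both pools)."""
    msp, msg, nc = site_fst_components(p1, p2, n1, n2)
    denom = msp + (nc - 1.0) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (msp - msg) / denom, np.nan)


def _sample_sizes(records: pd.DataFrame, pools, sample_size: str):
    n1h, n2h = pools[0].n_haploid, pools[1].n_haploid
    d1 = (records["ref1"] + records["alt1"]).to_numpy(float)
    d2 = (records["ref2"] + records["alt2"]).to_numpy(float)
    if sample_size == "haploid":
        n1 = np.full(len(records), float(n1h))
        n2 = np.full(len(records), float(n2h))
    elif sample_size == "depth-capped":
        n1 = np.minimum(n1h, d1)
        n2 = np.minimum(n2h, d2)
    else:
        raise ConfigError("sample_size must be 'haploid' or 'depth-capped'")
    return n1, n2, d1, d2


def window_fst(records: pd.DataFrame, pools, config: WindowingConfig | None = None,
               mode: str = "ratio-of-sums", sample_size: str = "haploid") -> pd.DataFrame:
    """Per-window Weir-Cockerham F_ST between the two pools.

    Sample allele frequencies are alt-read fractions per pool.  Windows
    with fewer than ``config.min_snps`` SNPs are dropped.  ``mode``
    selects ratio-of-sums (default) or mean-of-ratios aggregation.
    """
    if config is None:
        config = WindowingConfig()
    if mode not in ("ratio-of-sums", "mean-of-ratios"):
        raise ConfigError("mode must be 'ratio-of-sums' or 'mean-of-ratios'")
    n1, n2, d1, d2 = _sample_sizes(records, pools, sample_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(d1 > 0, records["alt1"].to_numpy(float) / d1, np.nan)
        p2 = np.where(d2 > 0, records["alt2"].to_numpy(float) / d2, np.nan)
    msp, msg, nc = site_fst_components(p1, p2, n1, n2)
    denom = msp + (nc - 1.0) * msg
    starts = window_starts(records["pos"].to_numpy(), config.size)
    df = pd.DataFrame({
        "chrom": records["chrom"].to_numpy(), "start": starts,
        "num": msp - msg, "den": denom,
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ratio"] = np.where(denom > 0, (msp - msg) / denom, np.nan)
    grouped = df.groupby(["chrom", "start"], sort=True)
    agg = grouped.agg(n_snps=("num", "size"), num=("num", "sum"),
                      den=("den", "sum"), mean_ratio=("ratio", "mean"))
    agg = agg[agg["n_snps"] >= config.min_snps].reset_index()
    if mode == "ratio-of-sums":
        fst = agg["num"] / agg["den"]
    else:
        fst = agg["mean_ratio"]
    return pd.DataFrame({
        "chrom": agg["chrom"], "start": agg["start"].astype(int),
        "end": (agg["start"] + config.size).astype(int),
        "n_snps": agg["n_snps"].astype(int), "fst": fst,
    })


# ---------------------------------------------------------------------------
# pooled heterozygosity
# ---------------------------------------------------------------------------

def window_hp(records: pd.DataFrame, target_pool: int = 1,
              config: WindowingConfig | None = None) -> pd.DataFrame:
    """Per-window pooled heterozygosity of one pool.

    Major/minor is decided per SNP within the target pool; counts are
    summed over the window before the Hp formula is applied.  Windows
    whose summed counts are zero are skipped with a warning.
    """
    if config is None:
        config = WindowingConfig()
    if target_pool not in (1, 2):
        raise ConfigError("target_pool must be 1 or 2")
    ref = records[f"ref{target_pool}"].to_numpy(float)
    alt = records[f"alt{target_pool}"].to_numpy(float)
    nmaj = np.maximum(ref, alt)
    nmin = np.minimum(ref, alt)
    starts = window_starts(records["pos"].to_numpy(), config.size)
    df = pd.DataFrame({
        "chrom": records["chrom"].to_numpy(), "start": starts,
        "nmaj": nmaj, "nmin": nmin,
    })
    agg = (df.groupby(["chrom", "start"], sort=True)
             .agg(n_snps=("nmaj", "size"), nmaj=("nmaj", "sum"), nmin=("nmin", "sum"))
             .reset_index())
    agg = agg[agg["n_snps"] >= config.min_snps]
    total = agg["nmaj"] + agg["nmin"]
    zero = total == 0
    if zero.any():
        import warnings
        warnings.warn(f"{int(zero.sum())} window(s) skipped: zero summed read counts")
        agg = agg[~zero]
        total = total[~zero]
    hp = 2.0 * agg["nmaj"] * agg["nmin"] / total ** 2
    return pd.DataFrame({
        "chrom": agg["chrom"], "start": agg["start"].astype(int),
        "end": (agg["start"] + config.size).astype(int),
        "n_snps": agg["n_snps"].astype(int), "hp": hp.to_numpy(),
    })


@dataclass(frozen=True)
class ZTransformParams:
    """Mean and (population) standard deviation of window Hp, kept so the
    transform can be re-applied to new values."""

    mu: float
    sigma: float

    def apply(self, hp):
        """-ZHp of the given Hp value(s): ``(mu - hp) / sigma``."""
        return (self.mu - np.asarray(hp, dtype=float)) / self.sigma

    @classmethod
    def solve(cls, hp_a: float, zhp_a: float, hp_b: float, zhp_b: float):
        """Recover (mu, sigma) from two (Hp, -ZHp) pairs."""
        sigma = (hp_b - hp_a) / (zhp_a - zhp_b)
        mu = hp_a + zhp_a * sigma
        return cls(mu=mu, sigma=sigma)


def z_transform(hp_values):
    """Standardize window Hp into -ZHp; returns ``(zhp, ZTransformParams)``.

    Uses the mean and population (divide-by-N) standard deviation over
    all supplied windows; raises on a degenerate (constant) distribution.
    """
    hp = np.asarray(hp_values, dtype=float)
    if hp.size < 2:
        raise DegenerateError("need at least two windows to standardize")
    mu = float(hp.mean())
    sigma = float(hp.std(ddof=0))
    # constant input can leave a ~1e-17 std from summation round-off
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise DegenerateError("window Hp has zero variance")
    params = ZTransformParams(mu=mu, sigma=sigma)
    return params.apply(hp), params


# ---------------------------------------------------------------------------
# outlier selection
# ---------------------------------------------------------------------------

def top_quantile(windows: pd.DataFrame, column: str, q: float = 0.01,
                 direction: str = "high"):
    """Select the ``ceil(q * N)`` most extreme windows of a statistic.

    Returns ``(threshold, [WindowKey, ...])``; the threshold is the least
    extreme selected value.  Ties beyond the cutoff break deterministically
    by (chromosome, start).
    """
    if not 0 < q < 1:
        raise ConfigError("q must lie in (0, 1)")
    if windows.empty:
        raise ConfigError("no windows to select from")
    n = len(windows)
    k = math.ceil(q * n)
    sign = -1.0 if direction == "high" else 1.0
    if direction not in ("high", "low"):
        raise ConfigError("direction must be 'high' or 'low'")
    order = windows.assign(_v=sign * windows[column].to_numpy()).sort_values(
        ["_v", "chrom", "start"], kind="mergesort")
    sel = order.head(k)
    threshold = float(sel[column].iloc[-1])
    keys = [WindowKey(r.chrom, int(r.start), int(r.end))
            for r in sel.itertuples(index=False)]
    keys.sort()
    logger.info("top %g%% of %s: %d/%d windows, threshold %.4g",
                100 * q, column, k, n, threshold)
    return threshold, keys
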