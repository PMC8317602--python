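"""Cross-population composite likelihood ratio (XP-CLR) scan for pool-seq.

The test contrasts, per 25-kb window, a neutral-drift model of the object
population's allele frequencies against a selective-sweep model:

* **Null (s = 0).** Given the reference-population frequency ``p1``, the
  object frequency ``p`` drifts as a Gaussian with variance
  ``omega * p1 * (1 - p1)``, censored to [0, 1] with the overflow mass as
  point masses at the boundaries.  ``omega`` is the drift variance scale,
  estimated from genome-wide data by a moment estimator.
* **Sweep (s > 0).** A lineage at recombination distance ``d`` from the
  focal point escapes the sweep with probability
  ``c = 1 - (2 N s) ** (-r d / s)``; the post-sweep frequency is the
  neutral frequency pushed through the deterministic hitchhiking map
  ``q = (1 - c) + c p`` (beneficial background linked to the alt allele)
  or ``q = c p`` (linked to the ref allele), mixed with equal weight since
  the favored allele's identity is unknown.
* **Emission.** Observed pool read counts enter through a binomial in the
  sequencing depth at the modeled frequency; the marginal site likelihood
  integrates the emission over the frequency density by Gauss-Legendre
  quadrature plus the boundary atoms.

The window score is ``2 * max_s (sum_sites ll(s) - ll(0))`` over an s-grid
that includes the null, so scores are non-negative by construction; scores
are then Z-normalized across retained windows.  Distances are measured
from the window center with a constant recombination rate unless a map is
supplied per site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .errors import ConfigError, DegenerateError
from .window_stats import WindowingConfig, window_starts

logger = logging.getLogger(__name__)

_TINY = 1e-300


def _default_grid() -> tuple:
    return (0.0, *np.geomspace(1e-4, 0.1, 10))


@dataclass
class XpclrConfig:
    """Scan parameters.

    ``s_grid`` must contain the null (0); ``omega`` of ``None`` triggers
    the moment estimate; ``resolution`` is the quadrature size (>= 64).
    """

    s_grid: tuple = field(default_factory=_default_grid)
    n_e: int = 10_000
    rec_rate: float = 1e-8
    omega: float | None = None
    window: WindowingConfig = field(default_factory=WindowingConfig)
    resolution: int = 256
    object_pool: int = 1

    def __post_init__(self) -> None:
        if 0.0 not in self.s_grid:
            raise ConfigError("the s-grid must contain the null s = 0")
        if self.resolution < 64:
            raise ConfigError("quadrature resolution must be >= 64")
        if self.omega is not None and self.omega <= 0:
            raise ConfigError("omega must be positive")
        if self.object_pool not in (1, 2):
            raise ConfigError("object_pool must be 1 or 2")


#: lower bound applied to a degenerate (zero) drift-variance estimate
OMEGA_FLOOR = 1e-4


def estimate_omega(ref_freqs, obj_freqs, resolution: int = 256,
                   min_sites: int = 1000) -> float:
    """Moment estimate of the drift variance scale.

    ``omega = mean((p2 - p1)**2 / (p1 (1 - p1)))`` over putatively neutral
    sites, with the reference frequency clamped away from 0/1 by the
    quadrature resolution.  A degenerate (zero) estimate is floored at
    :data:`OMEGA_FLOOR` with a warning.
    """
    p1 = np.asarray(ref_freqs, dtype=float)
    p2 = np.asarray(obj_freqs, dtype=float)
    if p1.size < min_sites:
        raise DegenerateError(
            f"need >= {min_sites} sites to estimate omega, got {p1.size}")
    eps = 1.0 / resolution
    p1c = np.clip(p1, eps, 1.0 - eps)
    omega = float(np.mean((p2 - p1c) ** 2 / (p1c * (1.0 - p1c))))
    if omega < OMEGA_FLOOR:
        import warnings
        warnings.warn("degenerate drift variance (object == reference); floored")
        omega = OMEGA_FLOOR
    return omega


@lru_cache(maxsize=8)
def _gauss_legendre_01(resolution: int):
    """Gauss-Legendre nodes/weights mapped to (0, 1), cached."""
    t, w = np.polynomial.legendre.leggauss(resolution)
    return 0.5 * (t + 1.0), 0.5 * w

#: half-width of the per-site integration window, in drift standard
#: deviations; the Gaussian mass beyond it is below 1e-15
_PEAK_SD = 8.0


def _frequency_masses(p1, sigma, resolution: int):
    """Censored-Gaussian masses of the null density on a per-site grid.

    Interior nodes are Gauss-Legendre points mapped onto the +/- 8 sd
    window around each site's drift peak (intersected with [0, 1]) so
    narrow peaks are fully resolved; the censored overflow sits in atoms
    at 0 and 1.  Returns ``(points, masses)``, both ``(n_sites,
    resolution + 2)``, the first and last column being the atoms.
    """
    t, w = _gauss_legendre_01(resolution)
    lo = np.maximum(0.0, p1 - _PEAK_SD * sigma)[:, None]
    hi = np.minimum(1.0, p1 + _PEAK_SD * sigma)[:, None]
    x = lo + (hi - lo) * t[None, :]
    interior = ((hi - lo) * w[None, :] / sigma[:, None]
                * np.exp(-0.5 * ((x - p1[:, None]) / sigma[:, None]) ** 2)
                / math.sqrt(2.0 * math.pi))
    z0 = (0.0 - p1[:, None]) / sigma[:, None]
    z1 = (1.0 - p1[:, None]) / sigma[:, None]
    points = np.concatenate([np.zeros_like(z0), x, np.ones_like(z1)], axis=1)
    masses = np.concatenate([ndtr(z0), interior, 1.0 - ndtr(z1)], axis=1)
    return points, masses


def escape_probability(d, s, rec_rate: float, n_e: int):
    """Hitchhiking escape probability, clipped to [0, 1]; identically 1
    under the null (s = 0, no sweep)."""
    d = np.asarray(d, dtype=float)
    if s == 0.0:
        return np.ones_like(d)
    return np.clip(1.0 - np.power(2.0 * n_e * s, -(rec_rate * d) / s), 0.0, 1.0)


def _loglik_matrix(p1, k, n, d, omega: float, config: XpclrConfig) -> np.ndarray:
    """Per-site log composite likelihood at every grid s.

    Arrays are per site; returns shape ``(n_sites, len(s_grid))``.
    Vectorized over (sites x quadrature x grid), chunked to bound memory.
    """
    p1 = np.asarray(p1, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    d = np.asarray(d, dtype=float)
    eps = 1.0 / config.resolution
    p1c = np.clip(p1, eps, 1.0 - eps)
    sigma = np.sqrt(omega * p1c * (1.0 - p1c))
    logc = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)

    out = np.empty((p1.size, len(config.s_grid)))
    chunk = max(1, int(4_000_000 / (config.resolution + 2)))
    for lo in range(0, p1.size, chunk):
        hi = min(lo + chunk, p1.size)
        points, masses = _frequency_masses(p1c[lo:hi], sigma[lo:hi], config.resolution)
        kk = k[lo:hi, None]
        nk = (n[lo:hi] - k[lo:hi])[:, None]
        lc = logc[lo:hi, None]
        for si, s in enumerate(config.s_grid):
            c = escape_probability(d[lo:hi], s, config.rec_rate, config.n_e)[:, None]
            # ref-linked branch: q = c * x; alt-linked: q = (1 - c) + c * x
            q0 = np.clip(c * points, 1e-12, 1.0 - 1e-12)
            em = np.exp(lc + kk * np.log(q0) + nk * np.log1p(-q0))
            if s == 0.0:
                like = np.einsum("ij,ij->i", masses, em)
            else:
                q1 = np.clip((1.0 - c) + c * points, 1e-12, 1.0 - 1e-12)
                em1 = np.exp(lc + kk * np.log(q1) + nk * np.log1p(-q1))
                like = 0.5 * np.einsum("ij,ij->i", masses, em + em1)
            out[lo:hi, si] = np.log(np.maximum(like, _TINY))
    return out


def site_loglik(p1, k, n, d, s, omega, config: XpclrConfig | None = None) -> float:
    """Log composite likelihood of one site's object-pool counts.

    ``p1`` reference frequency, ``k`` alt reads of ``n`` total in the
    object pool, ``d`` bp distance to the scored focal point.
    """
    if config is None:
        config = XpclrConfig()
    if d < 0:
        raise ConfigError("distance must be non-negative")
    cfg = XpclrConfig(
        s_grid=(0.0, s) if s != 0.0 else (0.0,),
        n_e=config.n_e, rec_rate=config.rec_rate, omega=omega,
        window=config.window, resolution=config.resolution,
        object_pool=config.object_pool,
    )
    mat = _loglik_matrix([p1], [k], [n], [d], omega, cfg)
    val = float(mat[0, -1])
    if not np.isfinite(val):
        raise FloatingPointError(
            f"non-finite likelihood at p1={p1}, k={k}, n={n}, d={d}, s={s}")
    return val


def window_xpclr(records: pd.DataFrame, config: XpclrConfig | None = None) -> pd.DataFrame:
    """Score every retained window; returns chrom/start/end/n_snps/
    xpclr_raw/s_hat.

    The reference population is the pool that is not ``object_pool``;
    sites with zero reference depth are dropped.  Distances run from each
    window's center.
    """
    if config is None:
        config = XpclrConfig()
    obj, ref = (1, 2) if config.object_pool == 1 else (2, 1)
    d_ref = (records[f"ref{ref}"] + records[f"alt{ref}"]).to_numpy(float)
    d_obj = (records[f"ref{obj}"] + records[f"alt{obj}"]).to_numpy(float)
    usable = (d_ref > 0) & (d_obj > 0)
    rec = records.loc[usable]
    d_ref, d_obj = d_ref[usable], d_obj[usable]
    p1 = rec[f"alt{ref}"].to_numpy(float) / d_ref
    k = rec[f"alt{obj}"].to_numpy(float)

    omega = config.omega
    if omega is None:
        p2 = k / d_obj
        omega = estimate_omega(p1, p2, resolution=config.resolution)
        logger.info("estimated drift variance omega = %.4g", omega)

    size = config.window.size
    starts = window_starts(rec["pos"].to_numpy(), size)
    center = starts + size / 2.0
    d = np.abs(rec["pos"].to_numpy(float) - center)

    ll = _loglik_matrix(p1, k, d_obj, d, omega, config)
    s_grid = np.asarray(config.s_grid)
    null_idx = int(np.where(s_grid == 0.0)[0][0])

    frame = pd.DataFrame({"chrom": rec["chrom"].to_numpy(), "start": starts})
    grouped = frame.groupby(["chrom", "start"], sort=True)
    rows = []
    for (chrom, start), idx in grouped.indices.items():
        if len(idx) < config.window.min_snps:
            continue
        sums = ll[idx].sum(axis=0)
        scores = 2.0 * (sums - sums[null_idx])
        best = int(np.argmax(scores))
        rows.append((chrom, int(start), int(start) + size, len(idx),
                     float(max(scores[best], 0.0)), float(s_grid[best])))
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "xpclr_raw", "s_hat"])
    logger.info("scored %d windows (omega=%.4g, grid=%d s-values)",
                len(out), omega, len(s_grid))
    return out


def normalize_scores(values, groups=None):
    """Z-normalize raw scores over retained windows.

    ``groups`` switches to per-group (e.g. per-chromosome) normalization.
    Raises on zero variance.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateError("need at least two windows to normalize")
    tol = 1e-12 * max(1.0, float(np.abs(v).max(initial=0.0)))
    if groups is None:
        sd = v.std(ddof=0)
        if sd <= tol:
            raise DegenerateError("scores have zero variance")
        return (v - v.mean()) / sd
    out = np.empty_like(v)
    ser = pd.Series(v)
    for _, idx in ser.groupby(np.asarray(groups)).groups.items():
        sub = v[idx]
        sd = sub.std(ddof=0)
        if sd <= tol:
            raise DegenerateError("scores have zero variance within a group")
        out[idx] = (sub - sub.mean()) / sd
    return out
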