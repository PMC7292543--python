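"""Bulked-segregant Δ(SNP-index) scanning with simulated null envelopes.

The SNP index of a bulk at a site is the fraction of its reads carrying the
long-neck parent's (P) allele; Δ(SNP-index) is the long-bulk index minus the
short-bulk index.  At a site where the long bulk carries only P reads and the
short bulk only M reads, Δ = +1; with bulk labels exchanged, Δ = −1; equal
allele composition in both bulks gives Δ = 0.  A historically used variant
that scores the short bulk by its M-allele fraction is available as
``convention="literal"`` (it drives Δ toward 0 at a true QTL and is provided
only for textual fidelity with some published methods sections).

Significance is assessed against a Monte-Carlo null: bulks of ``bulk_size``
F2 individuals drawn from 1:2:1 genotype frequencies at an unlinked locus,
binomial read sampling at the observed depths, and empirical two-sided
quantiles at the requested confidence.  Smoothing is loess (tricube local
linear regression, via statsmodels) or a sliding-window mean, evaluated on a
regular grid; regions are maximal runs of grid points whose fitted value
escapes the envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .variants import BulkCounts

__all__ = [
    "SnpIndexRecord",
    "ThresholdCurve",
    "QtlRegion",
    "snp_index",
    "snp_index_table",
    "smooth_profile",
    "null_threshold",
    "call_regions",
    "intersect_intervals",
]


@dataclass
class SnpIndexRecord:
    """Per-site SNP indices; NaN where the bulk has zero depth."""

    index_ln: float
    index_sn: float
    delta: float
    depth_ln: int
    depth_sn: int


def snp_index(counts: BulkCounts, convention: str = "p_fraction") -> SnpIndexRecord:
    """SNP indices and Δ for one site from oriented bulk counts."""
    dl, ds = counts.depth_ln, counts.depth_sn
    idx_ln = counts.p_ln / dl if dl else np.nan
    if convention == "p_fraction":
        idx_sn = counts.p_sn / ds if ds else np.nan
    elif convention == "literal":
        idx_sn = counts.m_sn / ds if ds else np.nan
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return SnpIndexRecord(idx_ln, idx_sn, idx_ln - idx_sn, dl, ds)


def snp_index_table(
    counts: pd.DataFrame, convention: str = "p_fraction"
) -> pd.DataFrame:
    """Vectorised :func:`snp_index` over a counts table.

    Requires columns p_ln, m_ln, p_sn, m_sn (plus any site metadata, which is
    carried through).  Adds depth_ln/depth_sn/index_ln/index_sn/delta.
    """
    for col in ("p_ln", "m_ln", "p_sn", "m_sn"):
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
        if (counts[col] < 0).any():
            raise ValueError(f"negative read counts in {col!r}")
    df = counts.copy()
    dl = df["p_ln"] + df["m_ln"]
    ds = df["p_sn"] + df["m_sn"]
    with np.errstate(invalid="ignore", divide="ignore"):
        idx_ln = np.where(dl > 0, df["p_ln"] / dl, np.nan)
        sn_num = df["p_sn"] if convention == "p_fraction" else df["m_sn"]
        if convention not in ("p_fraction", "literal"):
            raise ValueError(f"unknown convention {convention!r}")
        idx_sn = np.where(ds > 0, sn_num / ds, np.nan)
    df["depth_ln"] = dl
    df["depth_sn"] = ds
    df["index_ln"] = idx_ln
    df["index_sn"] = idx_sn
    df["delta"] = idx_ln - idx_sn
    return df


def _window_means(
    pos: np.ndarray, delta: np.ndarray, grid: np.ndarray, half: float
) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(delta)])
    lo = np.searchsorted(pos, grid - half, side="left")
    hi = np.searchsorted(pos, grid + half, side="right")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)


def smooth_profile(
    table: pd.DataFrame,
    method: str = "loess",
    span: float = 0.1,
    window_bp: float = 1_000_000,
    grid_step_bp: float = 10_000,
    min_sites: int = 10,
    clamp: bool = True,
) -> pd.DataFrame:
    """Smooth per-site delta along each chromosome onto a regular grid.

    ``loess`` fits a tricube-weighted local linear regression of delta on
    position with span = fraction of sites per window; ``window`` takes the
    mean delta in a sliding window of ``window_bp``.  Chromosomes with fewer
    than ``min_sites`` informative sites are skipped with a warning.  Fitted
    values are clamped to [−1, 1].
    """
    if method not in ("loess", "window"):
        raise ValueError(f"unknown smoothing method {method!r}")
    out = []
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.dropna(subset=["delta"]).sort_values("pos")
        if len(sub) < min_sites:
            warnings.warn(
                f"{chrom}: only {len(sub)} informative sites, skipped", stacklevel=2
            )
            continue
        pos = sub["pos"].to_numpy(dtype=float)
        delta = sub["delta"].to_numpy(dtype=float)
        grid = np.arange(pos[0], pos[-1] + 0.5 * grid_step_bp, grid_step_bp)
        if method == "loess":
            fit = lowess(delta, pos, frac=span, return_sorted=True)
            fitted = np.interp(grid, fit[:, 0], fit[:, 1])
        else:
            fitted = _window_means(pos, delta, grid, window_bp / 2.0)
        if clamp:
            fitted = np.clip(fitted, -1.0, 1.0)
        chunk = pd.DataFrame({"chrom": chrom, "pos": grid, "fitted": fitted})
        out.append(chunk.dropna(subset=["fitted"]))
    if not out:
        return pd.DataFrame(columns=["chrom", "pos", "fitted"])
    result = pd.concat(out, ignore_index=True)
    result.attrs["method"] = method
    result.attrs["params"] = {"span": span, "window_bp": window_bp,
                              "grid_step_bp": grid_step_bp}
    return result


@dataclass
class ThresholdCurve:
    """Null confidence envelope on Δ(SNP-index), keyed by binned depth pair.

    Bounds per (depth_ln, depth_sn) bin are empirical (1±confidence)/2
    quantiles of the simulated null; an isotonic pass over total depth
    enforces that the envelope never widens as depth grows.
    """

    confidence: float = 0.99
    bulk_size: int = 50
    n_sims: int = 10_000
    seed: int = 0
    depth_bin: int = 5
    table: dict = field(default_factory=dict)

    def _simulate_pair(self, dl: int, ds: int) -> tuple[float, float]:
        rng = np.random.default_rng(
            [int(self.seed) & 0x7FFFFFFF, 101, int(dl), int(ds)]
        )
        n2 = 2 * self.bulk_size
        f_ln = rng.binomial(n2, 0.5, self.n_sims) / n2
        f_sn = rng.binomial(n2, 0.5, self.n_sims) / n2
        delta = rng.binomial(dl, f_ln) / dl - rng.binomial(ds, f_sn) / ds
        alpha = (1.0 - self.confidence) / 2.0
        lo, hi = np.quantile(delta, [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def _bin(self, d: float) -> int:
        return int(max(self.depth_bin, round(d / self.depth_bin) * self.depth_bin))

    def bounds_for(
        self, depth_ln: Sequence[float], depth_sn: Sequence[float]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper envelope per site, simulating missing depth bins lazily
        and re-applying the monotonicity pass over the cached bins."""
        dl = np.asarray(depth_ln, dtype=float)
        ds = np.asarray(depth_sn, dtype=float)
        pairs = [(self._bin(a), self._bin(b)) for a, b in zip(dl, ds)]
        for pair in dict.fromkeys(pairs):
            if pair not in self.table:
                self.table[pair] = self._simulate_pair(*pair)
        self._enforce_monotone()
        lo = np.array([self.table[p][0] for p in pairs])
        hi = np.array([self.table[p][1] for p in pairs])
        return lo, hi

    def _enforce_monotone(self) -> None:
        keys = sorted(self.table, key=lambda p: (p[0] + p[1], p))
        lo_run, hi_run = -np.inf, np.inf
        for k in keys:
            lo, hi = self.table[k]
            lo_run = max(lo_run, lo)
            hi_run = min(hi_run, hi)
            self.table[k] = (lo_run, hi_run)


def null_threshold(
    depths: pd.DataFrame | np.ndarray,
    bulk_size: int = 50,
    confidence: float = 0.99,
    n_sims: int = 10_000,
    seed: int = 0,
    depth_bin: int = 5,
) -> ThresholdCurve:
    """Simulate the null Δ(SNP-index) envelope for the observed depth profile.

    ``depths`` is a table/array with per-site (depth_ln, depth_sn).  Each bulk
    is a fresh draw of ``bulk_size`` F2 genotypes from 1:2:1 at an unlinked
    locus, followed by binomial read sampling at the site's depths.
    """
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    if n_sims < 1000:
        warnings.warn("n_sims < 1000: envelope quantiles may be unstable",
                      stacklevel=2)
    if isinstance(depths, pd.DataFrame):
        dl = depths["depth_ln"].to_numpy()
        ds = depths["depth_sn"].to_numpy()
    else:
        arr = np.asarray(depths)
        dl, ds = arr[:, 0], arr[:, 1]
    curve = ThresholdCurve(confidence=confidence, bulk_size=bulk_size,
                           n_sims=n_sims, seed=seed, depth_bin=depth_bin)
    curve.bounds_for(dl, ds)
    return curve


@dataclass
class QtlRegion:
    """A called region: maximal run of grid points escaping the envelope."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_delta: float
    peak_pos: int
    sign: int
    mean_index_ln: float = np.nan
    mean_index_sn: float = np.nan
    n_sites: int = 0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def call_regions(
    profile: pd.DataFrame,
    threshold,
    sites: pd.DataFrame | None = None,
    min_span_bp: float = 0.0,
    merge_gap_bp: float = 0.0,
) -> list[QtlRegion]:
    """Call candidate QTL regions from a smoothed profile.

    ``threshold`` is a scalar t (bounds ±t), a (lower, upper) pair of arrays
    aligned to the profile grid, or a :class:`ThresholdCurve` (requires
    ``sites`` with per-site depths; grid depths taken from the nearest site).
    Runs separated by ≤ ``merge_gap_bp`` are merged; runs spanning less than
    ``min_span_bp`` are dropped.  ``sites`` also supplies per-site indices for
    region summary statistics.
    """
    regions: list[QtlRegion] = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy(dtype=float)
        fitted = sub["fitted"].to_numpy(dtype=float)
        site_sub = None
        if sites is not None:
            site_sub = sites[sites["chrom"] == chrom].sort_values("pos")
        if isinstance(threshold, ThresholdCurve):
            if site_sub is None or site_sub.empty:
                raise ValueError("ThresholdCurve thresholds require per-site depths")
            spos = site_sub["pos"].to_numpy(dtype=float)
            nearest = np.clip(np.searchsorted(spos, pos), 0, len(spos) - 1)
            left = np.clip(nearest - 1, 0, len(spos) - 1)
            use_left = np.abs(spos[left] - pos) < np.abs(spos[nearest] - pos)
            pick = np.where(use_left, left, nearest)
            lower, upper = threshold.bounds_for(
                site_sub["depth_ln"].to_numpy()[pick],
                site_sub["depth_sn"].to_numpy()[pick],
            )
        elif np.isscalar(threshold):
            upper = np.full(pos.size, float(threshold))
            lower = -upper
        else:
            lower, upper = (np.asarray(a, dtype=float) for a in threshold)
            if lower.size != pos.size or upper.size != pos.size:
                raise ValueError("threshold arrays must match the profile grid")
        for sign, mask in ((1, fitted > upper), (-1, fitted < lower)):
            runs = _runs(mask)
            merged: list[list[int]] = []
            for a, b in runs:
                if merged and pos[a] - pos[merged[-1][1]] <= merge_gap_bp:
                    merged[-1][1] = b
                else:
                    merged.append([a, b])
            for a, b in merged:
                if min_span_bp > 0 and pos[b] - pos[a] < min_span_bp:
                    continue
                seg = fitted[a:b + 1]
                rel = int(np.argmax(sign * seg))
                region = QtlRegion(
                    chrom=str(chrom), start_bp=int(pos[a]), end_bp=int(pos[b]),
                    peak_delta=float(seg[rel]), peak_pos=int(pos[a + rel]),
                    sign=sign,
                )
                if site_sub is not None and not site_sub.empty:
                    inside = site_sub[(site_sub["pos"] >= region.start_bp)
                                      & (site_sub["pos"] <= region.end_bp)]
                    if {"index_ln", "index_sn"} <= set(inside.columns):
                        region.mean_index_ln = float(inside["index_ln"].mean())
                        region.mean_index_sn = float(inside["index_sn"].mean())
                    region.n_sites = int(len(inside))
                regions.append(region)
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def intersect_intervals(
    a: tuple[float, float],
    b: tuple[float, float],
    round_start: int | None = None,
    round_end: int | None = None,
) -> tuple[tuple[float, float] | None, float]:
    """Consensus interval of two closed intervals on the same chromosome.

    Returns ``(interval, width)``; empty overlap gives ``(None, 0.0)``.
    Optional decimal rounding is applied to either endpoint before the width
    is computed (matching how printed interval endpoints are usually quoted).
    """
    start = max(a[0], b[0])
    end = min(a[1], b[1])
    if start > end:
        return None, 0.0
    if round_start is not None:
        start = round(start, round_start)
    if round_end is not None:
        end = round(end, round_end)
    return (start, end), end - start
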