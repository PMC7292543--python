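"""Genetic-map construction and Haley–Knott interval mapping for an F2.

Markers are ordered by physical coordinate; adjacent recombination fractions
are estimated by EM maximum likelihood over the 9 two-locus F2 genotype
classes (the double-heterozygote phase ambiguity is resolved in the E-step)
and converted to map distance with the Kosambi function

    d = 25 · ln((1 + 2r) / (1 − 2r))  cM.

The QTL scan is Haley–Knott regression: at each grid position the three QTL
genotype probabilities are computed conditionally on the nearest informative
flanking markers (Kosambi-consistent recombination fractions, no interference
between the flanking intervals; missing flanks fall back to one-sided
conditioning or the 1:2:1 prior), and the phenotype is regressed on the
expected additive and dominance predictors plus optional marker cofactors.

    LOD = (n/2) · log10(RSS0 / RSS1),    R² = 1 − 10^(−2·LOD/n).

A 2.0-LOD support interval is the maximal contiguous grid run around the peak
with LOD ≥ peak − 2; physical bounds come from interpolating marker positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import genotypes_to_dosage

__all__ = [
    "kosambi",
    "kosambi_inverse",
    "estimate_rf",
    "build_map",
    "scan_f2",
    "support_interval",
    "permutation_threshold",
    "ScanResult",
]

F2_PRIOR = np.array([0.25, 0.5, 0.25])  # dosage 0, 1, 2


def kosambi(r):
    """Recombination fraction -> Kosambi map distance (cM)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d):
    """Kosambi map distance (cM) -> recombination fraction."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# expected recombinant-gamete count per two-locus genotype class (dosages
# i, j); the double heterozygote (1,1) is phase-ambiguous and handled in EM
_REC_COUNT = np.array([
    [0, 1, 2],
    [1, -1, 1],
    [2, 1, 0],
], dtype=float)


def _class_probs(r: float) -> np.ndarray:
    """P(dosage_A = i, dosage_B = j) for an F2 under recombination r."""
    gametes = [((1, 1), (1 - r) / 2), ((0, 0), (1 - r) / 2),
               ((1, 0), r / 2), ((0, 1), r / 2)]
    T = np.zeros((3, 3))
    for (a1, b1), p1 in gametes:
        for (a2, b2), p2 in gametes:
            T[a1 + a2, b1 + b2] += p1 * p2
    return T


def _dosage_pair(g1, g2) -> tuple[np.ndarray, np.ndarray]:
    def to_dosage(g):
        arr = np.asarray(g)
        if arr.dtype.kind in "USO":
            d = genotypes_to_dosage(pd.DataFrame(arr.astype("<U2").reshape(-1, 1)))[:, 0]
        else:
            d = arr.astype(np.int8)
        return d

    d1, d2 = to_dosage(g1), to_dosage(g2)
    keep = (d1 >= 0) & (d2 >= 0)
    return d1[keep], d2[keep]


def estimate_rf(g1, g2, tol: float = 1e-6, max_iter: int = 200):
    """ML recombination fraction between two codominant F2 markers via EM.

    Accepts genotype codes (PP/PM/MM/NN) or dosage arrays.  Returns
    ``(r_hat, loglik)``.
    """
    d1, d2 = _dosage_pair(g1, g2)
    if d1.size < 2:
        raise ValueError("need at least 2 jointly informative individuals")
    counts = np.zeros((3, 3))
    np.add.at(counts, (d1, d2), 1.0)
    n = counts.sum()
    r = 0.25
    for _ in range(max_iter):
        rec = _REC_COUNT.copy()
        denom = (1 - r) ** 2 + r ** 2
        rec[1, 1] = 2 * r ** 2 / denom if denom > 0 else 0.0
        r_new = float((counts * rec).sum() / (2.0 * n))
        r_new = min(max(r_new, 0.0), 0.499999)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    with np.errstate(divide="ignore"):
        logp = np.log(_class_probs(r))
    loglik = float(np.where(counts > 0, counts * logp, 0.0).sum())
    return r, loglik


def build_map(genotypes: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Marker map with estimated adjacent r and cumulative Kosambi cM.

    Marker order is fixed by physical position within each chromosome.
    """
    sub = markers[markers["marker"].isin(genotypes.columns)].copy()
    out = []
    for chrom, chunk in sub.groupby("chrom", sort=False):
        chunk = chunk.sort_values("pos_bp").reset_index(drop=True)
        names = chunk["marker"].tolist()
        r_next = []
        for a, b in zip(names[:-1], names[1:]):
            r, _ = estimate_rf(genotypes[a], genotypes[b])
            r_next.append(min(r, 0.4999))
        cm = np.concatenate([[0.0], np.cumsum(kosambi(np.array(r_next)))]) \
            if r_next else np.array([0.0])
        chunk["r_to_next"] = r_next + [np.nan]
        chunk["cm"] = cm
        out.append(chunk)
    return pd.concat(out, ignore_index=True)[
        ["marker", "chrom", "pos_bp", "r_to_next", "cm"]
    ]


def _transition(r: float) -> np.ndarray:
    """F2 genotype transition matrix between two loci (rows: left dosage)."""
    return np.array([
        [(1 - r) ** 2, 2 * r * (1 - r), r ** 2],
        [r * (1 - r), (1 - r) ** 2 + r ** 2, r * (1 - r)],
        [r ** 2, 2 * r * (1 - r), (1 - r) ** 2],
    ])


def _nearest_informative(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per (individual, marker): index of nearest informative marker at or
    left / at or right of each column; −1 where none exists."""
    n, m = dosage.shape
    cols = np.arange(m)
    informative = dosage >= 0
    left = np.where(informative, cols, -1)
    left = np.maximum.accumulate(left, axis=1)
    right = np.where(informative, cols, m)
    right = np.minimum.accumulate(right[:, ::-1], axis=1)[:, ::-1]
    right[right == m] = -1
    return left, right


def _genoprob_at(
    dosage: np.ndarray,
    cm: np.ndarray,
    grid_cm: float,
    left_all: np.ndarray,
    right_all: np.ndarray,
) -> np.ndarray:
    """QTL genotype probabilities (n, 3) at one grid position."""
    n, m = dosage.shape
    jl = int(np.searchsorted(cm, grid_cm, side="right")) - 1
    jr = int(np.searchsorted(cm, grid_cm, side="left"))
    jl = min(max(jl, 0), m - 1)
    jr = min(max(jr, 0), m - 1)
    li = left_all[:, jl] if grid_cm >= cm[0] else np.full(n, -1)
    ri = right_all[:, jr] if grid_cm <= cm[-1] else np.full(n, -1)
    # a flanking marker only counts if it is on the correct side
    li = np.where((li >= 0) & (cm[np.maximum(li, 0)] <= grid_cm + 1e-9), li, -1)
    ri = np.where((ri >= 0) & (cm[np.maximum(ri, 0)] >= grid_cm - 1e-9), ri, -1)
    probs = np.empty((n, 3))
    key = li.astype(np.int64) * (m + 1) + ri
    for k in np.unique(key):
        sel = key == k
        l_idx = int(li[sel][0])
        r_idx = int(ri[sel][0])
        if l_idx < 0 and r_idx < 0:
            probs[sel] = F2_PRIOR
            continue
        if l_idx >= 0 and r_idx >= 0 and l_idx != r_idx:
            r1 = kosambi_inverse(grid_cm - cm[l_idx])
            r2 = kosambi_inverse(cm[r_idx] - grid_cm)
            T1, T2 = _transition(r1), _transition(r2)
            gl = dosage[sel, l_idx]
            gr = dosage[sel, r_idx]
            num = T1[gl] * T2[:, gr].T
            denom = num.sum(axis=1, keepdims=True)
            probs[sel] = num / denom
        elif l_idx >= 0 and (r_idx < 0 or l_idx == r_idx):
            r1 = kosambi_inverse(abs(grid_cm - cm[l_idx]))
            probs[sel] = _transition(r1)[dosage[sel, l_idx]]
        else:
            r2 = kosambi_inverse(abs(cm[r_idx] - grid_cm))
            probs[sel] = _transition(r2)[dosage[sel, r_idx]]
    return probs


@dataclass
class ScanResult:
    """Interval-mapping LOD profile and peak summary."""

    table: pd.DataFrame  # chrom, pos_cm, pos_bp, lod
    n: int
    peak_chrom: str
    peak_cm: float
    peak_bp: float
    peak_lod: float
    r_squared: float
    capped: bool = False


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(np.sum((y - X @ beta) ** 2))


def _cofactor_columns(
    dosage: np.ndarray, names: list[str], cofactors, positions_cm: np.ndarray
):
    cols, col_cm = [], []
    for c in cofactors:
        j = names.index(c)
        d = dosage[:, j].astype(float)
        add = np.where(d >= 0, d - 1.0, 0.0)
        dom = np.where(d >= 0, (d == 1).astype(float), 0.5)
        cols.extend([add, dom])
        col_cm.extend([positions_cm[j], positions_cm[j]])
    return cols, np.array(col_cm)


def scan_f2(
    mapping: pd.DataFrame,
    genotypes: pd.DataFrame,
    phenotypes: pd.Series,
    step_cm: float = 1.0,
    cofactors: tuple = (),
    cofactor_window_cm: float = 10.0,
    lod_cap: float = 50.0,
) -> ScanResult:
    """Haley–Knott interval-mapping scan over the map grid.

    ``phenotypes`` are per-genotyped-individual values (F2:3 family means are
    used as the phenotype of the F2 parent).  Cofactor markers within
    ``cofactor_window_cm`` of the scan position are dropped from the model at
    that position.
    """
    pheno = phenotypes.reindex(genotypes.index).astype(float)
    keep = pheno.notna().to_numpy()
    if keep.sum() < 5:
        raise ValueError("need at least 5 phenotyped individuals")
    y_all = pheno.to_numpy()[keep]
    rows = []
    capped = False
    for chrom, cmap in mapping.groupby("chrom", sort=False):
        cmap = cmap.sort_values("pos_bp").reset_index(drop=True)
        names = cmap["marker"].tolist()
        dosage = genotypes_to_dosage(genotypes[names])[keep]
        cm = cmap["cm"].to_numpy(dtype=float)
        pos_bp = cmap["pos_bp"].to_numpy(dtype=float)
        left_all, right_all = _nearest_informative(dosage)
        grid = np.arange(cm[0], cm[-1] + step_cm / 2.0, step_cm)
        cof_cols, cof_cm = _cofactor_columns(dosage, names, cofactors, cm)
        ones = np.ones(dosage.shape[0])
        tss = float(np.sum((y_all - y_all.mean()) ** 2))
        for g in grid:
            use = [c for c, cc in zip(cof_cols, cof_cm)
                   if abs(cc - g) > cofactor_window_cm] if cof_cols else []
            X0 = np.column_stack([ones] + use)
            probs = _genoprob_at(dosage, cm, float(g), left_all, right_all)
            add = probs[:, 2] - probs[:, 0]
            dom = probs[:, 1]
            X1 = np.column_stack([ones, add, dom] + use)
            rss0 = _rss(y_all, X0)
            rss1 = _rss(y_all, X1)
            n = y_all.size
            if rss1 <= max(1e-12 * max(tss, 1.0), 1e-300):
                lod = lod_cap
                capped = True
            else:
                lod = (n / 2.0) * np.log10(rss0 / rss1)
                lod = min(max(lod, 0.0), lod_cap)
            rows.append((chrom, float(g),
                         float(np.interp(g, cm, pos_bp)), float(lod)))
    table = pd.DataFrame(rows, columns=["chrom", "pos_cm", "pos_bp", "lod"])
    peak_i = int(table["lod"].idxmax())  # idxmax -> first (leftmost) maximum
    n = y_all.size
    peak_lod = float(table.loc[peak_i, "lod"])
    return ScanResult(
        table=table,
        n=n,
        peak_chrom=str(table.loc[peak_i, "chrom"]),
        peak_cm=float(table.loc[peak_i, "pos_cm"]),
        peak_bp=float(table.loc[peak_i, "pos_bp"]),
        peak_lod=peak_lod,
        r_squared=float(1.0 - 10.0 ** (-2.0 * peak_lod / n)),
        capped=capped,
    )


def support_interval(scan: ScanResult, drop: float = 2.0):
    """LOD-drop support interval around the peak, in cM and bp.

    Returns ``(cm_lo, cm_hi, bp_lo, bp_hi)``.  A flat profile yields the
    whole chromosome with a warning.
    """
    sub = scan.table[scan.table["chrom"] == scan.peak_chrom].reset_index(drop=True)
    lod = sub["lod"].to_numpy()
    if lod.max() - lod.min() < 1e-9:
        warnings.warn("flat LOD profile: support interval is the whole chromosome",
                      stacklevel=2)
        return (float(sub["pos_cm"].iloc[0]), float(sub["pos_cm"].iloc[-1]),
                float(sub["pos_bp"].iloc[0]), float(sub["pos_bp"].iloc[-1]))
    peak_i = int(np.argmax(lod))
    cut = lod[peak_i] - drop
    lo = peak_i
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = peak_i
    while hi < lod.size - 1 and lod[hi + 1] >= cut:
        hi += 1
    return (float(sub["pos_cm"].iloc[lo]), float(sub["pos_cm"].iloc[hi]),
            float(sub["pos_bp"].iloc[lo]), float(sub["pos_bp"].iloc[hi]))


def permutation_threshold(
    mapping: pd.DataFrame,
    genotypes: pd.DataFrame,
    phenotypes: pd.Series,
    n_perm: int = 200,
    quantile: float = 0.95,
    step_cm: float = 1.0,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD significance threshold by phenotype permutation.

    Returns ``(threshold, max_lod_distribution)``.  Uses per-position QR
    bases so each permutation costs two matrix-vector products per position.
    """
    pheno = phenotypes.reindex(genotypes.index).astype(float)
    keep = pheno.notna().to_numpy()
    y = pheno.to_numpy()[keep]
    n = y.size
    bases = []
    for chrom, cmap in mapping.groupby("chrom", sort=False):
        cmap = cmap.sort_values("pos_bp").reset_index(drop=True)
        names = cmap["marker"].tolist()
        dosage = genotypes_to_dosage(genotypes[names])[keep]
        cm = cmap["cm"].to_numpy(dtype=float)
        left_all, right_all = _nearest_informative(dosage)
        grid = np.arange(cm[0], cm[-1] + step_cm / 2.0, step_cm)
        ones = np.ones(n)
        for g in grid:
            probs = _genoprob_at(dosage, cm, float(g), left_all, right_all)
            X1 = np.column_stack([ones, probs[:, 2] - probs[:, 0], probs[:, 1]])
            q1, _ = np.linalg.qr(X1)
            bases.append(q1)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        rss0 = float(yc @ yc)
        best = 0.0
        for q1 in bases:
            proj = q1.T @ yp
            rss1 = float(yp @ yp - proj @ proj)
            if rss1 > 1e-300:
                best = max(best, (n / 2.0) * np.log10(rss0 / rss1))
        maxima[p] = best
    return float(np.quantile(maxima, quantile)), maxima
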