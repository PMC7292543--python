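"""Recombinant-haplotype fine mapping of a single causal locus.

Recombinants between two flanking markers localise crossovers; each
recombinant's F2:3 progeny test reveals the F2 parent's genotype at the
causal locus (all-long family -> PP, all-short -> MM, segregating -> PM).
A recombinant's ordered marker haplotype then constrains where the causal
locus can sit: it must lie where the haplotype carries (or, inside a
crossover gap, could carry) the implied genotype.  The candidate interval is
the intersection of all per-recombinant constraints, reported by its
bounding markers — a gap between adjacent markers is treated as compatible
with either flanking genotype, so interval bounds are the markers flanking
the allowed span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecombinantRecord",
    "CandidateInterval",
    "ConflictError",
    "find_recombinants",
    "classify_family",
    "default_family_cuts",
    "delimit_interval",
    "cosegregation_check",
]

CLASS_TO_GENOTYPE = {"long": "PP", "short": "MM", "segregating": "PM"}


@dataclass
class RecombinantRecord:
    """One recombinant: ordered marker haplotype plus its progeny-test class."""

    individual: str
    markers: Sequence[str]
    positions: Sequence[int]
    genotypes: Sequence[str]
    family_class: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.markers):
            raise ValueError("genotype vector length must equal marker count")
        if len(self.positions) != len(self.markers):
            raise ValueError("positions length must equal marker count")


class ConflictError(ValueError):
    """Raised when the recombinant constraints have an empty intersection."""

    def __init__(self, message: str, conflicting: list[str]):
        super().__init__(message)
        self.conflicting = conflicting


@dataclass
class CandidateInterval:
    """Delimited candidate region, expressed by its bounding markers."""

    left_marker: str
    right_marker: str
    left_bp: int
    right_bp: int
    supporting: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)

    @property
    def width_bp(self) -> int:
        return self.right_bp - self.left_bp


def find_recombinants(
    genotypes: pd.DataFrame, marker_a: str, marker_b: str
) -> tuple[list[str], int]:
    """Individuals whose genotypes differ between two flanking markers.

    Returns ``(ids, n_skipped)``; individuals missing either genotype are
    skipped and counted.
    """
    ga = genotypes[marker_a].to_numpy()
    gb = genotypes[marker_b].to_numpy()
    valid = (ga != "NN") & (gb != "NN")
    rec = valid & (ga != gb)
    ids = list(genotypes.index.to_numpy()[rec])
    return ids, int((~valid).sum())


def default_family_cuts(mu_pp: float = 7.5, mu_mm: float = 2.2):
    """Progeny-test cuts halfway between the midparent and each parent mean."""
    mid = (mu_pp + mu_mm) / 2.0
    return mid + (mu_pp - mid) / 2.0, mid - (mid - mu_mm) / 2.0


def classify_family(
    phenotypes: Sequence[float],
    long_cut: float,
    short_cut: float,
    min_n: int = 15,
    min_tail: int = 2,
) -> str:
    """Classify an F2:3 progeny test as long / short / segregating / unknown.

    ``segregating`` requires at least ``min_tail`` plants in each tail; a
    uniform family beyond one cut is scored homozygous; families smaller than
    ``min_n`` (or fitting no rule) are ``unknown``.
    """
    values = np.asarray(list(phenotypes), dtype=float)
    values = values[~np.isnan(values)]
    if values.size < min_n:
        return "unknown"
    n_long = int(np.sum(values > long_cut))
    n_short = int(np.sum(values < short_cut))
    if n_long >= min_tail and n_short >= min_tail:
        return "segregating"
    if n_long == values.size:
        return "long"
    if n_short == values.size:
        return "short"
    return "unknown"


def _compatible_segments(rec: RecombinantRecord) -> np.ndarray:
    """Boolean over the 2m−1 elementary segments (marker, gap, marker, ...).

    A marker segment is compatible when the haplotype carries the implied
    genotype there; a gap is compatible when either flanking marker is.
    """
    target = CLASS_TO_GENOTYPE[rec.family_class]
    ok = [g == target for g in rec.genotypes]
    m = len(ok)
    segs = np.zeros(2 * m - 1, dtype=bool)
    segs[0::2] = ok
    for i in range(m - 1):
        segs[2 * i + 1] = ok[i] or ok[i + 1]
    return segs


def delimit_interval(recombinants: Sequence[RecombinantRecord]) -> CandidateInterval:
    """Intersect all recombinant constraints into the candidate interval.

    Recombinants whose own constraint is empty (class contradicts the whole
    haplotype) are reported in ``conflicts`` and excluded; if the remaining
    constraints still intersect to nothing, a :class:`ConflictError` carries
    a minimal conflicting subset.
    """
    if not recombinants:
        raise ValueError("need at least one recombinant")
    ref = recombinants[0]
    markers = list(ref.markers)
    positions = list(ref.positions)
    for rec in recombinants:
        if rec.family_class == "unknown":
            raise ValueError(f"{rec.individual}: family class is unknown")
        if list(rec.markers) != markers:
            raise ValueError("all recombinants must share the same marker order")

    per_rec = {r.individual: _compatible_segments(r) for r in recombinants}
    conflicts = [i for i, seg in per_rec.items() if not seg.any()]
    consistent = [r for r in recombinants if r.individual not in conflicts]
    if not consistent:
        raise ConflictError("every recombinant contradicts its haplotype", conflicts)
    allowed = np.logical_and.reduce([per_rec[r.individual] for r in consistent])
    if not allowed.any():
        minimal = [
            r.individual
            for r in consistent
            if np.logical_and.reduce(
                [per_rec[o.individual] for o in consistent if o is not r]
            ).any()
        ] or [r.individual for r in consistent]
        raise ConflictError("recombinant constraints are mutually exclusive", minimal)

    m = len(markers)
    first = int(np.flatnonzero(allowed)[0])
    last = int(np.flatnonzero(allowed)[-1])
    # even index = marker i, odd index = gap between markers (i-1)//2, (i+1)//2
    left_i = (first - 1) // 2 if first % 2 == 1 else max(first // 2 - 1, 0)
    right_i = (last + 1) // 2 if last % 2 == 1 else min(last // 2 + 1, m - 1)
    return CandidateInterval(
        left_marker=markers[left_i],
        right_marker=markers[right_i],
        left_bp=int(positions[left_i]),
        right_bp=int(positions[right_i]),
        supporting=[r.individual for r in consistent],
        conflicts=conflicts,
    )


def cosegregation_check(marker_genotypes, implied_genotypes) -> float:
    """Fraction of individuals whose marker genotype equals the causal
    genotype implied by their phenotype class; 1.0 means co-segregation."""
    a = pd.Series(marker_genotypes)
    b = pd.Series(implied_genotypes)
    if isinstance(marker_genotypes, pd.Series) and isinstance(
        implied_genotypes, pd.Series
    ):
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]
    elif len(a) != len(b):
        raise ValueError("inputs must cover the same individuals")
    keep = (a != "NN") & (b != "NN")
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no jointly informative individuals")
    return float((a.to_numpy() == b.to_numpy()).mean())
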