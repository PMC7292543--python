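"""Forward simulation of a biparental F2 mapping experiment.

Every input the analysis stages consume is generated here with known ground
truth: an F2 cross between a long-necked parent (P, Jin5-508 analogue) and a
short-necked parent (M, YN analogue), fruit-neck-length phenotypes driven by a
single major QTL, extreme-phenotype DNA bulks with pooled read counts, F2:3
progeny families, a natural-accession panel genotyped at promoter variants,
and qPCR cycle-threshold tables.

Crossovers follow the Haldane model (Poisson count, no interference); the
crossover rate per interval is set by a uniform cM/Mb scaling of physical
marker positions.  Genotypes are coded ``PP``/``PM``/``MM`` (``NN`` missing)
with P the long-neck parent's allele.  All operations are pure functions of
their configuration and seed: each draws from its own substream derived from
the master seed, so a stage can be regenerated without replaying earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CrossConfig",
    "TraitModel",
    "BulkConfig",
    "BulkSelection",
    "PanelConfig",
    "simulate_f2",
    "simulate_phenotypes",
    "make_bulks",
    "simulate_readcounts",
    "simulate_f23",
    "simulate_panel",
    "simulate_qpcr",
    "genotypes_to_dosage",
    "dosage_to_codes",
]

GENOTYPE_CODES = ("MM", "PM", "PP")
MISSING_CODE = "NN"

# fixed substream ids so stages are independently reproducible
_STREAMS = {
    "f2": 11,
    "phenotype": 12,
    "bulks": 13,
    "readcounts": 14,
    "f23": 15,
    "panel": 16,
    "qpcr": 17,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stage], int(seed) & 0x7FFFFFFF])


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class CrossConfig:
    """Layout of the simulated genome and F2 population.

    Marker positions are 1-based and strictly increasing within a chromosome;
    by default they are evenly spaced along each chromosome.  ``cm_per_mb``
    converts physical to genetic distance (a cucumber-like density of
    ~5 cM/Mb gives ≈100 cM on a 20-Mb chromosome).
    """

    n_chromosomes: int = 1
    chrom_length_bp: int = 20_000_000
    n_markers: int = 2000
    cm_per_mb: float = 5.0
    n_f2: int = 1231
    seed: int = 0
    positions: Mapping[str, Sequence[int]] | None = None

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ConfigError("n_markers must be >= 2")
        if self.chrom_length_bp <= 0:
            raise ConfigError("chrom_length_bp must be positive")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.n_f2 < 1:
            raise ConfigError("n_f2 must be >= 1")
        if self.cm_per_mb < 0:
            raise ConfigError("cm_per_mb must be >= 0")
        if self.positions is not None:
            for chrom, pos in self.positions.items():
                arr = np.asarray(pos)
                if arr.ndim != 1 or arr.size < 2:
                    raise ConfigError(f"{chrom}: need >= 2 marker positions")
                if np.any(arr < 1):
                    raise ConfigError(f"{chrom}: positions must be 1-based")
                if np.any(np.diff(arr) <= 0):
                    raise ConfigError(
                        f"{chrom}: marker positions must be strictly increasing"
                    )

    @property
    def chromosomes(self) -> list[str]:
        if self.positions is not None:
            return list(self.positions)
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_positions(self, chrom: str) -> np.ndarray:
        if self.positions is not None:
            return np.asarray(self.positions[chrom], dtype=np.int64)
        pos = np.linspace(1, self.chrom_length_bp, self.n_markers)
        pos = np.unique(np.round(pos).astype(np.int64))
        if pos.size != self.n_markers:
            raise ConfigError("chromosome too short for the requested marker count")
        return pos

    def marker_table(self) -> pd.DataFrame:
        """Marker metadata: name, chrom, pos_bp, cm (map position)."""
        rows = []
        for chrom in self.chromosomes:
            pos = self.chrom_positions(chrom)
            cm = (pos - pos[0]) / 1e6 * self.cm_per_mb
            for p, c in zip(pos, cm):
                rows.append((f"{chrom}_{p}", chrom, int(p), float(c)))
        return pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "cm"])


@dataclass
class TraitModel:
    """Single-QTL three-class phenotype model (cm).

    Class means default to the parental and F1 means of the cross this package
    emulates (long parent 7.5 cm, short parent 2.2 cm, F1 4.6 cm), giving an
    additive effect a = 2.65 and dominance d = −0.25.  ``sigma_e`` defaults to
    2.87 cm so that the QTL explains ≈30% of single-plant phenotypic variance.
    """

    qtl_chrom: str = "chr1"
    qtl_pos_bp: int = 12_000_000
    mu_pp: float = 7.5
    mu_mm: float = 2.2
    mu_pm: float = 4.6
    sigma_e: float = 2.87

    def __post_init__(self) -> None:
        if self.sigma_e < 0:
            raise ConfigError("sigma_e must be >= 0")
        if self.qtl_pos_bp < 1:
            raise ConfigError("qtl_pos_bp must be >= 1 (1-based)")

    @property
    def additive_effect(self) -> float:
        return (self.mu_pp - self.mu_mm) / 2.0

    @property
    def dominance(self) -> float:
        return self.mu_pm - (self.mu_pp + self.mu_mm) / 2.0

    @property
    def class_means(self) -> np.ndarray:
        """Means indexed by P-allele dosage 0, 1, 2."""
        return np.array([self.mu_mm, self.mu_pm, self.mu_pp])


@dataclass
class BulkConfig:
    """Extreme-bulk construction and pooled sequencing model."""

    n_per_bulk: int = 50
    long_threshold_cm: float = 7.5
    short_threshold_cm: float = 2.5
    depth_long: float = 61.0
    depth_short: float = 52.0
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ConfigError("error_rate must be in [0, 0.5)")
        if self.short_threshold_cm >= self.long_threshold_cm:
            raise ConfigError("short_threshold_cm must be below long_threshold_cm")
        if self.n_per_bulk < 1:
            raise ConfigError("n_per_bulk must be >= 1")
        if self.depth_long <= 0 or self.depth_short <= 0:
            raise ConfigError("mean depths must be positive")


@dataclass
class BulkSelection:
    """Selected bulk memberships plus the rule that produced each side."""

    long_ids: list[str]
    short_ids: list[str]
    rule_long: str
    rule_short: str


@dataclass
class PanelConfig:
    """Natural-accession panel with group founder haplotypes.

    Defaults emulate a 158-accession panel split into four genotype groups
    (62 East Asian, 71 Eurasian, 21 Indian cultivated, 4 wild/semi-wild) typed
    at 32 promoter variants (25 SNP-like, 7 InDel-like), with group-linked
    neck-length means.
    """

    group_sizes: Sequence[int] = (62, 71, 21, 4)
    n_variants: int = 32
    within_group_mut_rate: float = 0.02
    fnl_group_means: Sequence[float] = (6.5, 2.5, 4.5, 4.5)
    fnl_sd: float = 1.5
    geographies: Sequence[str] = ("East Asia", "Eurasia", "India", "India")
    founders: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.group_sizes) < 2:
            raise ConfigError("need at least 2 groups")
        if not (0 <= self.within_group_mut_rate < 0.5):
            raise ConfigError("within_group_mut_rate must be in [0, 0.5)")
        if len(self.fnl_group_means) != len(self.group_sizes):
            raise ConfigError("fnl_group_means must match group_sizes")
        if len(self.geographies) != len(self.group_sizes):
            raise ConfigError("geographies must match group_sizes")
        if self.n_variants < 1:
            raise ConfigError("n_variants must be >= 1")
        if self.founders is not None:
            f = np.asarray(self.founders)
            if f.shape != (len(self.group_sizes), self.n_variants):
                raise ConfigError("founders must be (n_groups, n_variants)")

    @property
    def panel_size(self) -> int:
        return int(sum(self.group_sizes))


def genotypes_to_dosage(genotypes: pd.DataFrame) -> np.ndarray:
    """Genotype codes -> P-allele dosage int8 array (2/1/0, -1 missing)."""
    arr = genotypes.to_numpy()
    out = np.full(arr.shape, -1, dtype=np.int8)
    out[arr == "PP"] = 2
    out[arr == "PM"] = 1
    out[arr == "MM"] = 0
    return out


def dosage_to_codes(dosage: np.ndarray) -> np.ndarray:
    out = np.full(dosage.shape, MISSING_CODE, dtype="<U2")
    for d, code in enumerate(GENOTYPE_CODES):
        out[dosage == d] = code
    return out


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


def _simulate_gametes(rng: np.random.Generator, n: int, r: np.ndarray) -> np.ndarray:
    """n gametes over len(r)+1 markers; allele 1 = P.  Haldane crossovers."""
    start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
    if r.size:
        switch = (rng.random((n, r.size)) < r).astype(np.int8)
        track = np.concatenate([start, switch], axis=1)
    else:
        track = start
    return np.cumsum(track, axis=1, dtype=np.int32).astype(np.int8) % 2


def simulate_f2(cross: CrossConfig) -> pd.DataFrame:
    """Simulate an F2 genotype table (individual x marker, codes PP/PM/MM).

    Each individual is the union of two independently simulated gametes; the
    crossover process is Poisson with no interference on the cM map implied by
    ``cm_per_mb``.  Deterministic for a fixed config + seed.
    """
    rng = _rng(cross.seed, "f2")
    n = cross.n_f2
    blocks = []
    names: list[str] = []
    for chrom in cross.chromosomes:
        pos = cross.chrom_positions(chrom)
        cm = np.diff(pos) / 1e6 * cross.cm_per_mb
        r = _haldane_r(cm)
        dosage = _simulate_gametes(rng, n, r) + _simulate_gametes(rng, n, r)
        blocks.append(dosage)
        names.extend(f"{chrom}_{p}" for p in pos)
    dosage = np.concatenate(blocks, axis=1)
    ids = [f"F2_{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(dosage_to_codes(dosage), index=ids, columns=names)


def _qtl_marker(markers: pd.DataFrame, chrom: str, pos_bp: int) -> str:
    """Name of the marker nearest the QTL position on its chromosome."""
    sub = markers[markers["chrom"] == chrom]
    if sub.empty:
        raise ConfigError(f"QTL chromosome {chrom!r} not in the simulated genome")
    i = (sub["pos_bp"] - pos_bp).abs().idxmin()
    return str(sub.loc[i, "marker"])


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    trait: TraitModel,
    markers: pd.DataFrame,
    seed: int = 0,
    chrom_length_bp: int | None = None,
) -> pd.Series:
    """Fruit-neck-length phenotypes (cm): class mean + Normal(0, sigma_e).

    The QTL genotype is taken at the marker nearest ``trait.qtl_pos_bp``.
    """
    if chrom_length_bp is not None and trait.qtl_pos_bp > chrom_length_bp:
        raise ConfigError("QTL position lies outside the simulated genome")
    qtl = _qtl_marker(markers, trait.qtl_chrom, trait.qtl_pos_bp)
    dosage = genotypes_to_dosage(genotypes[[qtl]])[:, 0]
    if np.any(dosage < 0):
        raise ConfigError("missing genotypes at the QTL marker")
    rng = _rng(seed, "phenotype")
    values = trait.class_means[dosage] + rng.normal(0.0, trait.sigma_e, len(dosage))
    return pd.Series(values, index=genotypes.index, name="fnl_cm")


def make_bulks(
    phenotypes: pd.Series, cfg: BulkConfig | None = None, seed: int = 0
) -> BulkSelection:
    """Select the long- and short-neck extreme bulks.

    Threshold rule: if at least ``n_per_bulk`` individuals lie beyond a
    threshold, the most extreme ``n_per_bulk`` of them are taken.  Otherwise
    the side falls back to plain rank-based extremes; ties are broken by a
    seeded shuffle so degenerate inputs remain reproducible.
    """
    cfg = cfg or BulkConfig()
    n = len(phenotypes)
    k = cfg.n_per_bulk
    if k > n // 2:
        raise ConfigError("n_per_bulk exceeds half the population")
    values = phenotypes.to_numpy(dtype=float)
    rng = _rng(seed, "bulks")
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, values))  # ascending phenotype

    n_long = int(np.sum(values > cfg.long_threshold_cm))
    n_short = int(np.sum(values < cfg.short_threshold_cm))
    rule_long = "threshold" if n_long >= k else "rank"
    rule_short = "threshold" if n_short >= k else "rank"
    long_idx = order[-k:]
    short_idx = order[:k]
    ids = phenotypes.index.to_numpy()
    return BulkSelection(
        long_ids=list(ids[long_idx]),
        short_ids=list(ids[short_idx]),
        rule_long=rule_long,
        rule_short=rule_short,
    )


def simulate_readcounts(
    genotypes: pd.DataFrame,
    markers: pd.DataFrame,
    bulks: BulkSelection,
    cfg: BulkConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled allele read counts per site for the two bulks.

    Per site and bulk the true P-allele frequency is the mean dosage / 2 over
    bulk members; read depth is Poisson around the configured mean and P reads
    are binomial with an allele-flip error ``error_rate``.
    """
    cfg = cfg or BulkConfig()
    if not bulks.long_ids or not bulks.short_ids:
        raise ConfigError("bulk sets must be non-empty")
    rng = _rng(seed, "readcounts")
    dosage = genotypes_to_dosage(genotypes).astype(float)
    dosage[dosage < 0] = np.nan
    idx = {a: i for i, a in enumerate(genotypes.index)}
    out = {"chrom": [], "pos": []}
    sub = markers.set_index("marker").loc[list(genotypes.columns)]
    out["chrom"] = sub["chrom"].to_numpy()
    out["pos"] = sub["pos_bp"].to_numpy()
    eps = cfg.error_rate
    for tag, members, mean_depth in (
        ("ln", bulks.long_ids, cfg.depth_long),
        ("sn", bulks.short_ids, cfg.depth_short),
    ):
        rows = [idx[a] for a in members]
        f = np.nanmean(dosage[rows], axis=0) / 2.0
        depth = rng.poisson(mean_depth, size=f.size)
        p_reads = rng.binomial(depth, f * (1 - eps) + (1 - f) * eps)
        out[f"p_{tag}"] = p_reads
        out[f"m_{tag}"] = depth - p_reads
    return pd.DataFrame(out)


def simulate_f23(
    genotypes: pd.DataFrame,
    trait: TraitModel,
    markers: pd.DataFrame,
    n_families: int = 102,
    plants_per_family: int = 10,
    sigma_family: float = 2.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Self each F2 parent into an F2:3 family and phenotype its plants.

    Offspring QTL genotypes follow selfing segregation (PP→PP, MM→MM,
    PM→1:2:1).  Each plant gets class mean + Normal(0, sigma_e); each family
    additionally shares a Normal(0, sigma_family) environmental effect,
    emulating plot-to-plot field variation that family-mean averaging cannot
    remove.  Returns ``(family_means, plants)`` — the means table is what the
    QTL scan consumes as the phenotype of the F2 parent.
    """
    if n_families > len(genotypes):
        raise ConfigError("n_families exceeds the F2 population size")
    if plants_per_family < 1:
        raise ConfigError("plants_per_family must be >= 1")
    qtl = _qtl_marker(markers, trait.qtl_chrom, trait.qtl_pos_bp)
    parent_dosage = genotypes_to_dosage(genotypes[[qtl]])[:, 0][:n_families]
    rng = _rng(seed, "f23")
    means = trait.class_means
    fam_effect = rng.normal(0.0, sigma_family, n_families)
    rows = []
    mean_rows = []
    ids = genotypes.index[:n_families]
    for fi, (fam, pdos) in enumerate(zip(ids, parent_dosage)):
        if pdos == 1:
            off = rng.choice([0, 1, 2], size=plants_per_family, p=[0.25, 0.5, 0.25])
        else:
            off = np.full(plants_per_family, pdos)
        vals = (
            means[off]
            + rng.normal(0.0, trait.sigma_e, plants_per_family)
            + fam_effect[fi]
        )
        for pi, v in enumerate(vals):
            rows.append((fam, pi + 1, float(v)))
        mean_rows.append((fam, float(np.mean(vals)), plants_per_family))
    plants = pd.DataFrame(rows, columns=["family", "plant", "fnl_cm"])
    family_means = pd.DataFrame(
        mean_rows, columns=["family", "mean_fnl_cm", "n_plants"]
    ).set_index("family")
    return family_means, plants


def simulate_panel(
    cfg: PanelConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accession panel: binary promoter-variant calls + phenotype/geography.

    Each group descends from a distinct founder haplotype; individual calls
    flip from the founder with ``within_group_mut_rate``; neck length is
    Normal(group mean, fnl_sd).  Returns ``(calls, info)``.
    """
    cfg = cfg or PanelConfig()
    rng = _rng(seed, "panel")
    g = len(cfg.group_sizes)
    if cfg.founders is not None:
        founders = np.asarray(cfg.founders, dtype=np.int8)
    else:
        founders = rng.integers(0, 2, size=(g, cfg.n_variants), dtype=np.int8)
        for _ in range(100):
            dup = False
            for i in range(g):
                for j in range(i + 1, g):
                    if np.array_equal(founders[i], founders[j]):
                        founders[j] = rng.integers(0, 2, cfg.n_variants, dtype=np.int8)
                        dup = True
            if not dup:
                break
    calls = []
    info_rows = []
    acc = 0
    for gi, size in enumerate(cfg.group_sizes):
        flips = rng.random((size, cfg.n_variants)) < cfg.within_group_mut_rate
        calls.append(np.where(flips, 1 - founders[gi], founders[gi]))
        fnl = rng.normal(cfg.fnl_group_means[gi], cfg.fnl_sd, size)
        for k in range(size):
            acc += 1
            info_rows.append(
                (f"acc{acc:03d}", f"group{gi + 1}", cfg.geographies[gi], float(fnl[k]))
            )
    ids = [r[0] for r in info_rows]
    variant_ids = [f"pv{j + 1:02d}" for j in range(cfg.n_variants)]
    calls_df = pd.DataFrame(np.concatenate(calls), index=ids, columns=variant_ids)
    info = pd.DataFrame(
        info_rows, columns=["accession", "group", "geography", "fnl_cm"]
    ).set_index("accession")
    return calls_df, info


def simulate_qpcr(
    samples: Sequence[str],
    fold_changes: Mapping[str, float] | float,
    ct_noise_sd: float = 0.1,
    reps: int = 3,
    seed: int = 0,
    reference_ct: float = 20.0,
    target_base_ct: float = 25.0,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> pd.DataFrame:
    """Simulate a qPCR plate in long format (sample, gene, replicate, ct).

    The reference gene has a constant expected Ct; the target's expected Ct is
    ``target_base_ct − log2(fold change)`` so a 2^−ΔΔCt analysis against a
    fold-1 calibrator recovers the configured fold changes.  ``reps``
    technical replicates per well (3 by convention).
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if ct_noise_sd < 0:
        raise ConfigError("ct_noise_sd must be >= 0")
    if not isinstance(fold_changes, Mapping):
        fold_changes = {s: float(fold_changes) for s in samples}
    rng = _rng(seed, "qpcr")
    rows = []
    for s in samples:
        fold = float(fold_changes[s])
        if fold <= 0:
            raise ConfigError(f"fold change for {s!r} must be > 0")
        target_ct = target_base_ct - np.log2(fold)
        for gene, base in ((target_gene, target_ct), (reference_gene, reference_ct)):
            for rep in range(1, reps + 1):
                rows.append((s, gene, rep, base + rng.normal(0.0, ct_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
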