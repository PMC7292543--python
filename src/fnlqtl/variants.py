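"""Variant tables with per-bulk allele depths: I/O, orientation, filtering.

Sites carry read counts of the long-neck parent's allele (P) and the
short-neck parent's allele (M) in the two extreme bulks.  Three filter
profiles mirror the three stages of a bulked-segregant study:

* ``qtlseq``     — per-bulk depth strictly > 5 and base quality strictly > 20;
* ``marker``     — depth ≥ 30, quality ≥ 30, within-sample major-allele
  fraction ≥ 0.90, mapping PASS, optional chromosome restriction;
* ``population`` — depth ≥ 15, quality ≥ 30, major-allele fraction ≥ 0.90.

"Variant frequency" is interpreted as the within-sample major-allele read
fraction (a homozygosity proxy); thresholds and strictness are configurable.
Serialisation is a TSV with a fixed header, or a minimal VCF 4.2 subset
(CHROM/POS/REF/ALT/QUAL plus per-sample AD) read back through pysam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

logger = logging.getLogger("fnlqtl.variants")

__all__ = [
    "BulkCounts",
    "VariantSite",
    "FilterProfile",
    "read_variants",
    "write_variants",
    "orient_to_parents",
    "orient_all",
    "apply_filter",
    "sites_to_table",
    "table_to_sites",
]

TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "p_allele",
    "p_ln",
    "m_ln",
    "p_sn",
    "m_sn",
    "base_quality",
]


@dataclass(frozen=True)
class BulkCounts:
    """Parent-assigned read counts: P/M allele in the long (Ln) and short
    (Sn) bulks."""

    p_ln: int
    m_ln: int
    p_sn: int
    m_sn: int

    def __post_init__(self) -> None:
        if min(self.p_ln, self.m_ln, self.p_sn, self.m_sn) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth_ln(self) -> int:
        return self.p_ln + self.m_ln

    @property
    def depth_sn(self) -> int:
        return self.p_sn + self.m_sn


@dataclass
class VariantSite:
    """One biallelic site.  ``p_allele`` is 'ref' or 'alt': which allele the
    long-neck parent carries (set by :func:`orient_to_parents`)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    counts: BulkCounts
    p_allele: str = "ref"
    base_quality: float = 60.0
    mapping_pass: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.p_allele not in ("ref", "alt"):
            raise ValueError("p_allele must be 'ref' or 'alt'")
        if self.base_quality < 0:
            raise ValueError("base_quality must be >= 0")

    @property
    def p_allele_base(self) -> str:
        return self.ref_allele if self.p_allele == "ref" else self.alt_allele


@dataclass
class FilterProfile:
    """One named set of site-retention criteria.

    ``depth_strict``/``quality_strict`` choose > versus ≥.  Depth is checked
    per bulk (both must pass) unless ``pooled_depth``.
    """

    name: str
    min_depth: int = 0
    depth_strict: bool = False
    min_quality: float = 0.0
    quality_strict: bool = False
    min_variant_frequency: float = 0.0
    require_pass: bool = False
    chrom_restrict: str | None = None
    pooled_depth: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_quality < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0.0 <= self.min_variant_frequency <= 1.0):
            raise ValueError("min_variant_frequency must be in [0, 1]")

    @classmethod
    def qtlseq(cls) -> "FilterProfile":
        return cls("qtlseq", min_depth=5, depth_strict=True, min_quality=20,
                   quality_strict=True)

    @classmethod
    def marker(cls, chrom: str | None = None) -> "FilterProfile":
        return cls("marker", min_depth=30, min_quality=30,
                   min_variant_frequency=0.90, require_pass=True,
                   chrom_restrict=chrom)

    @classmethod
    def population(cls) -> "FilterProfile":
        return cls("population", min_depth=15, min_quality=30,
                   min_variant_frequency=0.90, require_pass=True)

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "FilterProfile":
        try:
            factory = {"qtlseq": cls.qtlseq, "marker": cls.marker,
                       "population": cls.population}[name]
        except KeyError:
            raise ValueError(f"unknown filter profile {name!r}") from None
        return factory(**kwargs)


def sites_to_table(sites: Iterable[VariantSite]) -> pd.DataFrame:
    rows = [
        (s.chrom, s.pos, s.ref_allele, s.alt_allele, s.p_allele_base,
         s.counts.p_ln, s.counts.m_ln, s.counts.p_sn, s.counts.m_sn,
         s.base_quality)
        for s in sites
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def table_to_sites(df: pd.DataFrame) -> list[VariantSite]:
    sites = []
    for i, row in enumerate(df.itertuples(index=False)):
        if str(row.p_allele) == str(row.ref):
            p_allele = "ref"
        elif str(row.p_allele) == str(row.alt):
            p_allele = "alt"
        else:
            raise ValueError(f"row {i}: p_allele matches neither ref nor alt")
        sites.append(
            VariantSite(
                chrom=str(row.chrom), pos=int(row.pos), ref_allele=str(row.ref),
                alt_allele=str(row.alt), p_allele=p_allele,
                base_quality=float(row.base_quality),
                counts=BulkCounts(int(row.p_ln), int(row.m_ln),
                                  int(row.p_sn), int(row.m_sn)),
            )
        )
    return sites


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "vcf" if str(path).endswith(".vcf") else "tsv"


def read_variants(
    path: str | Path,
    fmt: str | None = None,
    ln_sample: str = "Ln",
    sn_sample: str = "Sn",
) -> list[VariantSite]:
    """Read variant sites from TSV or the minimal VCF subset.

    VCF records must carry per-sample AD (ref, alt read counts) for the two
    bulk samples.  Multiallelic sites are skipped with a logged count; the
    returned sites are unoriented (``p_allele='ref'``) for VCF input.
    """
    fmt = _detect_format(path, fmt)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = set(TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return table_to_sites(df)
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")
    sites: list[VariantSite] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for sample in (ln_sample, sn_sample):
            if sample not in vf.header.samples:
                raise ValueError(f"{path}: sample {sample!r} not in VCF header")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            try:
                ad_ln = rec.samples[ln_sample]["AD"]
                ad_sn = rec.samples[sn_sample]["AD"]
            except KeyError:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: missing AD depth field"
                ) from None
            sites.append(
                VariantSite(
                    chrom=rec.chrom, pos=rec.pos, ref_allele=rec.ref,
                    alt_allele=rec.alts[0], p_allele="ref",
                    base_quality=float(rec.qual) if rec.qual is not None else 0.0,
                    mapping_pass=("PASS" in rec.filter or len(rec.filter) == 0),
                    counts=BulkCounts(int(ad_ln[0]), int(ad_ln[1]),
                                      int(ad_sn[0]), int(ad_sn[1])),
                )
            )
    if skipped:
        logger.info("%s: skipped %d non-biallelic site(s)", path, skipped)
    return sites


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ln}\t{sn}
"""


def write_variants(
    sites: Sequence[VariantSite],
    path: str | Path,
    fmt: str | None = None,
    ln_sample: str = "Ln",
    sn_sample: str = "Sn",
) -> None:
    """Write sites as TSV or as the minimal VCF subset (AD in ref,alt order)."""
    fmt = _detect_format(path, fmt)
    if fmt == "tsv":
        sites_to_table(sites).to_csv(path, sep="\t", index=False)
        return
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(ln=ln_sample, sn=sn_sample))
        for s in sites:
            c = s.counts
            if s.p_allele == "ref":
                ad_ln, ad_sn = (c.p_ln, c.m_ln), (c.p_sn, c.m_sn)
            else:
                ad_ln, ad_sn = (c.m_ln, c.p_ln), (c.m_sn, c.p_sn)
            filt = "PASS" if s.mapping_pass else "FAIL"
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{s.base_quality:g}\t{filt}\t.\tAD\t"
                f"{ad_ln[0]},{ad_ln[1]}\t{ad_sn[0]},{ad_sn[1]}\n"
            )


def _normalise_parent(site: VariantSite, genotype: str) -> str | None:
    """Map a parent genotype to 'ref'/'alt' if homozygous, else None."""
    g = str(genotype)
    if g == "ref" or g == site.ref_allele or g == site.ref_allele * 2:
        return "ref"
    if g == "alt" or g == site.alt_allele or g == site.alt_allele * 2:
        return "alt"
    return None


def orient_to_parents(
    site: VariantSite, parent_ln_genotype: str, parent_sn_genotype: str
) -> tuple[VariantSite | None, str | None]:
    """Assign the P allele (long-neck parent's) and relabel counts.

    Parents must be homozygous for different alleles; genotypes are accepted
    as 'ref'/'alt' tokens or literal allele strings.  Returns ``(site, None)``
    on success or ``(None, reason)`` for non-informative sites.
    """
    ln = _normalise_parent(site, parent_ln_genotype)
    sn = _normalise_parent(site, parent_sn_genotype)
    if ln is None or sn is None:
        return None, "parent_heterozygous_or_unknown"
    if ln == sn:
        return None, "parents_identical"
    if ln == site.p_allele:
        return replace(site), None
    c = site.counts
    return (
        replace(site, p_allele=ln,
                counts=BulkCounts(c.m_ln, c.p_ln, c.m_sn, c.p_sn)),
        None,
    )


def orient_all(
    sites: Iterable[VariantSite],
    parent_ln_genotypes: Sequence[str],
    parent_sn_genotypes: Sequence[str],
) -> tuple[list[VariantSite], dict[str, int]]:
    """Orient a batch of sites; excluded sites tallied by reason."""
    oriented = []
    tally: dict[str, int] = {}
    for site, pl, ps in zip(sites, parent_ln_genotypes, parent_sn_genotypes):
        out, reason = orient_to_parents(site, pl, ps)
        if out is None:
            tally[reason] = tally.get(reason, 0) + 1
        else:
            oriented.append(out)
    return oriented, tally


def _passes_depth(site: VariantSite, p: FilterProfile) -> bool:
    c = site.counts
    depths = [c.depth_ln + c.depth_sn] if p.pooled_depth else [c.depth_ln, c.depth_sn]
    if p.depth_strict:
        return all(d > p.min_depth for d in depths)
    return all(d >= p.min_depth for d in depths)


def _passes_vf(site: VariantSite, p: FilterProfile) -> bool:
    c = site.counts
    for hi, lo in ((c.p_ln, c.m_ln), (c.p_sn, c.m_sn)):
        depth = hi + lo
        if depth == 0:
            return False
        if max(hi, lo) / depth < p.min_variant_frequency:
            return False
    return True


def apply_filter(
    sites: Iterable[VariantSite], profile: FilterProfile
) -> tuple[list[VariantSite], dict[str, int]]:
    """Retain sites passing every enabled criterion; tally rejections by the
    first failed criterion (mapping, chromosome, depth, quality, frequency)."""
    retained: list[VariantSite] = []
    tally: dict[str, int] = {}

    def reject(reason: str) -> None:
        tally[reason] = tally.get(reason, 0) + 1

    for site in sites:
        if profile.require_pass and not site.mapping_pass:
            reject("mapping_fail")
        elif profile.chrom_restrict is not None and site.chrom != profile.chrom_restrict:
            reject("chromosome")
        elif not _passes_depth(site, profile):
            reject("depth")
        elif (site.base_quality <= profile.min_quality
              if profile.quality_strict
              else site.base_quality < profile.min_quality):
            reject("quality")
        elif profile.min_variant_frequency > 0 and not _passes_vf(site, profile):
            reject("variant_frequency")
        else:
            retained.append(site)
    return retained, tally
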