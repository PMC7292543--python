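"""Stage orchestration: simulate -> qtlseq -> scan -> finemap -> express -> phylo.

Each stage reads its inputs from the run directory (written by an earlier
stage), writes versioned outputs into ``<run_dir>/<stage>/`` and records the
files' checksums in ``<run_dir>/manifest.json`` together with the seed and a
hash of the resolved configuration, so a rerun with the same config + seed
produces identical checksums for every deterministic stage.

Configuration is a nested key-value mapping (YAML on disk); unknown keys are
rejected with field-level messages and every block is optional with the
defaults below.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import finemap as fm
from . import linkage, phylo, qtlseq
from . import simulate as sim
from . import variants as vio
from .simulate import (
    BulkConfig,
    BulkSelection,
    ConfigError,
    CrossConfig,
    PanelConfig,
    TraitModel,
)
from .expression import relative_expression

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_stage", "run_all", "STAGES"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "cross": {
            "n_chromosomes": 1,
            "chrom_length_bp": 20_000_000,
            "n_markers": 2000,
            "cm_per_mb": 5.0,
            "n_f2": 1231,
        },
        "trait": {
            "qtl_chrom": "chr1",
            "qtl_pos_bp": 12_000_000,
            "mu_pp": 7.5,
            "mu_mm": 2.2,
            "mu_pm": 4.6,
            "sigma_e": 2.87,
        },
        "bulks": {
            "n_per_bulk": 50,
            "long_threshold_cm": 7.5,
            "short_threshold_cm": 2.5,
            "depth_long": 61.0,
            "depth_short": 52.0,
            "error_rate": 0.005,
        },
        "f23": {"n_families": 102, "plants_per_family": 10, "sigma_family": 2.7},
        "finemap_screen": {
            "n_f2": 4000,
            "halfwidth_bp": 250_000,
            "n_markers": 6,
            "plants_per_family": 15,
            "sigma_within": 0.97,
        },
        "panel": {
            "group_sizes": [62, 71, 21, 4],
            "n_variants": 32,
            "within_group_mut_rate": 0.02,
            "fnl_group_means": [6.5, 2.5, 4.5, 4.5],
            "fnl_sd": 1.5,
        },
        "qpcr": {
            "samples": ["parent_short", "parent_long"],
            "fold_changes": {"parent_short": 1.0, "parent_long": 4.0},
            "ct_noise_sd": 0.1,
            "reps": 3,
        },
    },
    "qtlseq": {
        "smooth": {"method": "loess", "span": 0.1, "grid_step_bp": 10_000},
        "threshold": {"confidence": 0.99, "n_sims": 10_000},
        "regions": {"min_span_bp": 0, "merge_gap_bp": 100_000},
    },
    "scan": {"step_cm": 1.0, "drop": 2.0},
    "finemap": {"min_n": 15},
    "express": {"calibrator": "parent_short"},
    "phylo": {"n_boot": 1000, "k_groups": 4},
}

STAGES = ["simulate", "qtlseq", "scan", "finemap", "express", "phylo"]


def _check_keys(cfg: dict, ref: dict, path: str = "") -> None:
    for key, value in cfg.items():
        here = f"{path}{key}"
        if key not in ref:
            raise ConfigError(f"unknown configuration key: {here}")
        # dict leaves whose defaults hold data (fold_changes) are free-form
        if isinstance(ref[key], dict) and isinstance(value, dict) \
                and key not in ("fold_changes",):
            _check_keys(value, ref[key], here + ".")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict) \
                and key != "fold_changes":
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(config: dict | None) -> dict:
    """Merge a partial configuration over the defaults, rejecting unknown
    keys and re-validating every stage block through its dataclass."""
    config = config or {}
    _check_keys(config, DEFAULT_CONFIG)
    cfg = _merge(DEFAULT_CONFIG, config)
    try:
        CrossConfig(**cfg["simulate"]["cross"], seed=cfg["seed"])
        TraitModel(**cfg["simulate"]["trait"])
        BulkConfig(**cfg["simulate"]["bulks"])
        PanelConfig(**cfg["simulate"]["panel"])
    except (ConfigError, TypeError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _update_manifest(run_dir: Path, cfg: dict, stage: str, elapsed: float) -> None:
    manifest_path = run_dir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else
        {"config_hash": _config_hash(cfg), "seed": cfg["seed"], "stages": {}}
    )
    stage_dir = run_dir / stage
    files = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file()
    }
    manifest["stages"][stage] = {"files": files, "elapsed_s": round(elapsed, 3)}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name!r}: run the {stage!r} stage first"
        )
    return path


def _stage_simulate(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    s = cfg["simulate"]
    cross = CrossConfig(**s["cross"], seed=seed)
    trait = TraitModel(**s["trait"])
    bulk_cfg = BulkConfig(**s["bulks"])
    markers = cross.marker_table()
    genotypes = sim.simulate_f2(cross)
    phenotypes = sim.simulate_phenotypes(
        genotypes, trait, markers, seed=seed, chrom_length_bp=cross.chrom_length_bp
    )
    bulks = sim.make_bulks(phenotypes, bulk_cfg, seed=seed)
    counts = sim.simulate_readcounts(genotypes, markers, bulks, bulk_cfg, seed=seed)
    fam_means, fam_plants = sim.simulate_f23(
        genotypes, trait, markers, seed=seed, **s["f23"]
    )

    markers.to_csv(out / "markers.tsv", sep="\t", index=False)
    genotypes.to_csv(out / "f2_genotypes.tsv", sep="\t")
    phenotypes.to_frame().to_csv(out / "f2_phenotypes.tsv", sep="\t")
    counts.to_csv(out / "bulk_counts.tsv", sep="\t", index=False)
    sites = [
        vio.VariantSite(
            chrom=row.chrom, pos=int(row.pos), ref_allele="A", alt_allele="T",
            p_allele="ref",
            counts=vio.BulkCounts(row.p_ln, row.m_ln, row.p_sn, row.m_sn),
        )
        for row in counts.itertuples(index=False)
    ]
    vio.write_variants(sites, out / "bulk_counts.vcf")
    fam_means.to_csv(out / "f23_family_means.tsv", sep="\t")
    fam_plants.to_csv(out / "f23_plants.tsv", sep="\t", index=False)

    # fine-mapping screen: dense markers around the QTL plus the hidden
    # causal position itself (dropped from the visible marker set)
    fs = s["finemap_screen"]
    lo = max(1, trait.qtl_pos_bp - fs["halfwidth_bp"])
    hi = min(cross.chrom_length_bp, trait.qtl_pos_bp + fs["halfwidth_bp"])
    visible = np.linspace(lo, hi, fs["n_markers"]).round().astype(int)
    positions = np.unique(np.concatenate([visible, [trait.qtl_pos_bp]]))
    screen_cross = CrossConfig(
        positions={trait.qtl_chrom: positions},
        n_markers=len(positions),
        chrom_length_bp=cross.chrom_length_bp,
        cm_per_mb=cross.cm_per_mb,
        n_f2=fs["n_f2"],
        seed=seed + 7,
    )
    screen_markers = screen_cross.marker_table()
    screen_geno = sim.simulate_f2(screen_cross)
    causal_name = f"{trait.qtl_chrom}_{trait.qtl_pos_bp}"
    # progeny-test plants share a plot: only the within-family component of
    # the residual applies (see docs/methods.md on variance decomposition)
    screen_trait = replace(trait, sigma_e=fs["sigma_within"])
    fam_means2, fam_plants2 = sim.simulate_f23(
        screen_geno, screen_trait, screen_markers,
        n_families=len(screen_geno),
        plants_per_family=fs["plants_per_family"],
        sigma_family=0.0,
        seed=seed + 7,
    )
    visible_names = [c for c in screen_geno.columns if c != causal_name]
    screen_geno[visible_names].to_csv(out / "screen_genotypes.tsv", sep="\t")
    screen_markers[screen_markers["marker"] != causal_name].to_csv(
        out / "screen_markers.tsv", sep="\t", index=False
    )
    screen_geno[[causal_name]].rename(
        columns={causal_name: "causal_genotype"}
    ).to_csv(out / "screen_causal.tsv", sep="\t")
    fam_plants2.to_csv(out / "screen_f23_plants.tsv", sep="\t", index=False)

    panel_calls, panel_info = sim.simulate_panel(PanelConfig(**s["panel"]), seed=seed)
    panel_calls.to_csv(out / "panel_calls.tsv", sep="\t")
    panel_info.to_csv(out / "panel_info.tsv", sep="\t")

    qp = s["qpcr"]
    sim.simulate_qpcr(
        qp["samples"], qp["fold_changes"], ct_noise_sd=qp["ct_noise_sd"],
        reps=qp["reps"], seed=seed,
    ).to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)

    truth = {
        "qtl_chrom": trait.qtl_chrom,
        "qtl_pos_bp": trait.qtl_pos_bp,
        "additive_effect": trait.additive_effect,
        "dominance": trait.dominance,
        "bulk_rule": [bulks.rule_long, bulks.rule_short],
        "long_bulk": bulks.long_ids,
        "short_bulk": bulks.short_ids,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _stage_qtlseq(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "qtlseq"
    out.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(
        _require(run_dir / "simulate" / "bulk_counts.tsv", "simulate"), sep="\t"
    )
    q = cfg["qtlseq"]
    table = qtlseq.snp_index_table(counts)
    table.to_csv(out / "snp_index.tsv", sep="\t", index=False)
    profile = qtlseq.smooth_profile(
        table, method=q["smooth"]["method"], span=q["smooth"]["span"],
        grid_step_bp=q["smooth"]["grid_step_bp"],
    )
    profile.to_csv(out / "smoothed.tsv", sep="\t", index=False)
    curve = qtlseq.null_threshold(
        table[["depth_ln", "depth_sn"]].dropna(),
        bulk_size=cfg["simulate"]["bulks"]["n_per_bulk"],
        confidence=q["threshold"]["confidence"],
        n_sims=q["threshold"]["n_sims"],
        seed=cfg["seed"],
    )
    regions = qtlseq.call_regions(
        profile, curve, sites=table,
        min_span_bp=q["regions"]["min_span_bp"],
        merge_gap_bp=q["regions"]["merge_gap_bp"],
    )
    # BED is 0-based half-open; internal coordinates are 1-based closed
    with open(out / "regions.bed", "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                     f"delta_peak={r.peak_delta:.3f}\n")
    (out / "regions.json").write_text(json.dumps(
        [r.__dict__ for r in regions], indent=2, default=float
    ))


def _stage_scan(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "scan"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = run_dir / "simulate"
    genotypes = pd.read_csv(
        _require(sim_dir / "f2_genotypes.tsv", "simulate"), sep="\t", index_col=0
    )
    markers = pd.read_csv(sim_dir / "markers.tsv", sep="\t")
    fam_means = pd.read_csv(sim_dir / "f23_family_means.tsv", sep="\t", index_col=0)
    # thin the map for the scan: the full QTL-seq marker set is denser than a
    # genetic map needs
    n_map = min(40, len(markers))
    keep = markers.iloc[np.linspace(0, len(markers) - 1, n_map).round().astype(int)]
    mapping = linkage.build_map(genotypes[keep["marker"].tolist()], keep)
    mapping.to_csv(out / "map.tsv", sep="\t", index=False)
    scan = linkage.scan_f2(
        mapping, genotypes.loc[fam_means.index], fam_means["mean_fnl_cm"],
        step_cm=cfg["scan"]["step_cm"],
    )
    scan.table.to_csv(out / "scan.tsv", sep="\t", index=False)
    cm_lo, cm_hi, bp_lo, bp_hi = linkage.support_interval(
        scan, drop=cfg["scan"]["drop"]
    )
    summary = {
        "peak_cm": scan.peak_cm, "peak_bp": scan.peak_bp,
        "peak_lod": scan.peak_lod, "r_squared": scan.r_squared,
        "support_cm": [cm_lo, cm_hi], "support_bp": [bp_lo, bp_hi],
        "n_families": scan.n,
    }
    regions_path = run_dir / "qtlseq" / "regions.json"
    if regions_path.exists():
        regions = json.loads(regions_path.read_text())
        if regions:
            top = max(regions, key=lambda r: abs(r["peak_delta"]))
            consensus, width = qtlseq.intersect_intervals(
                (top["start_bp"], top["end_bp"]), (bp_lo, bp_hi)
            )
            summary["consensus_bp"] = list(consensus) if consensus else None
            summary["consensus_width_bp"] = width
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def _stage_finemap(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "finemap"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = run_dir / "simulate"
    genotypes = pd.read_csv(
        _require(sim_dir / "screen_genotypes.tsv", "simulate"), sep="\t", index_col=0
    )
    markers = pd.read_csv(sim_dir / "screen_markers.tsv", sep="\t")
    plants = pd.read_csv(sim_dir / "screen_f23_plants.tsv", sep="\t")
    trait = TraitModel(**cfg["simulate"]["trait"])
    long_cut, short_cut = fm.default_family_cuts(trait.mu_pp, trait.mu_mm)
    names = markers["marker"].tolist()
    rec_ids, _ = fm.find_recombinants(genotypes, names[0], names[-1])
    by_family = plants.groupby("family")["fnl_cm"]
    records = []
    for rid in rec_ids:
        values = by_family.get_group(rid) if rid in by_family.groups else []
        klass = fm.classify_family(
            values, long_cut, short_cut, min_n=cfg["finemap"]["min_n"]
        )
        if klass == "unknown":
            continue
        records.append(
            fm.RecombinantRecord(
                individual=rid, markers=names,
                positions=markers["pos_bp"].tolist(),
                genotypes=genotypes.loc[rid, names].tolist(),
                family_class=klass,
            )
        )
    interval = fm.delimit_interval(records)
    rows = [
        (r.individual, r.family_class, *r.genotypes) for r in records
    ]
    pd.DataFrame(rows, columns=["individual", "family_class", *names]).to_csv(
        out / "recombinant_constraints.tsv", sep="\t", index=False
    )
    (out / "interval.json").write_text(json.dumps({
        "left_marker": interval.left_marker, "right_marker": interval.right_marker,
        "left_bp": interval.left_bp, "right_bp": interval.right_bp,
        "width_bp": interval.width_bp,
        "n_recombinants": len(records),
        "conflicts": interval.conflicts,
    }, indent=2))


def _stage_express(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "express"
    out.mkdir(parents=True, exist_ok=True)
    ct = pd.read_csv(_require(run_dir / "simulate" / "qpcr_ct.tsv", "simulate"),
                     sep="\t")
    result = relative_expression(ct, calibrator=cfg["express"]["calibrator"])
    result.to_csv(out / "expression.tsv", sep="\t")


def _stage_phylo(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "phylo"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = run_dir / "simulate"
    calls = pd.read_csv(_require(sim_dir / "panel_calls.tsv", "simulate"),
                        sep="\t", index_col=0)
    info = pd.read_csv(sim_dir / "panel_info.tsv", sep="\t", index_col=0)
    dist = phylo.genotype_distance(calls)
    dist.to_csv(out / "distances.tsv", sep="\t")
    tree = phylo.bootstrap_support(calls, n_boot=cfg["phylo"]["n_boot"],
                                   seed=cfg["seed"])
    (out / "tree.nwk").write_text(phylo.to_newick(tree) + "\n")
    groups = phylo.cut_tree(tree, k=cfg["phylo"]["k_groups"])
    classes, threshold = phylo.classify_fnl(info["fnl_cm"])
    table = phylo.group_enrichment(groups.loc[info.index], classes,
                                   info["geography"])
    groups.rename("tree_group").to_frame().to_csv(out / "groups.tsv", sep="\t")
    table.to_csv(out / "contingency.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps(
        {"fnl_threshold_cm": threshold, "n_accessions": len(calls)}, indent=2
    ))


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "qtlseq": _stage_qtlseq,
    "scan": _stage_scan,
    "finemap": _stage_finemap,
    "express": _stage_express,
    "phylo": _stage_phylo,
}


def run_stage(stage: str, config: dict | None, run_dir: str | Path) -> None:
    """Run one named stage into ``run_dir`` and update the manifest."""
    if stage not in _STAGE_FNS:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    cfg = validate_config(config)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    _STAGE_FNS[stage](cfg, run_dir)
    _update_manifest(run_dir, cfg, stage, time.perf_counter() - t0)


def run_all(config: dict | None, run_dir: str | Path) -> dict:
    """Chain every stage on synthetic data; returns the final manifest."""
    for stage in STAGES:
        run_stage(stage, config, run_dir)
    return json.loads((Path(run_dir) / "manifest.json").read_text())
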