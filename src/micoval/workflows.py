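"""End-to-end workflows: single-study analysis, cross-project validation,
stratified (advanced) validation, and simulation. The CLI is a thin layer
over these functions; every output is a plain TSV/JSON file and every
random choice flows from the config-level seed."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consistency import (
    WCS_CONVENTION,
    consistency_table,
    fb_ratio_cross_project,
    heatmap_matrix,
    pathway_consistency,
    records_frame,
    sankey_edges,
    select_consistent,
    stratified_consistency,
)
from .differential import compare_features, write_comparison
from .diversity import alpha_diversity, anosim, beta_distance, fb_ratio, nmds, pcoa
from .io import (
    ComparisonDesign,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
    collapse_to_rank,
    enumerate_comparisons,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)
from .network import build_coabundance, compare_properties, node_properties
from .preprocess import (
    filter_low_prevalence,
    impute_zeros,
    median_of_ratios_normalize,
    rarefy,
    tss_normalize,
)
from .simulate import PlantedEffect, SimulationSpec, simulate_multiproject, taxonomy_for

logger = logging.getLogger(__name__)

DEFAULTS = {
    "alpha": 0.05,
    "use_fdr": False,
    "method": "kw",
    "lda_threshold": 2.0,
    "seed": 0,
    "rank": None,
    "preprocess": {"filter_missing": 0.80, "impute": True, "normalize": "tss", "depth": "min"},
    "consistency": {"min_projects": 3, "min_abs_cs": 0.6, "denominator": "significant"},
    "network": {"top_n": 30, "min_abs_rho": 0.3, "enabled": True},
}


def _merged(config: dict) -> dict:
    out = {**DEFAULTS, **(config or {})}
    for key in ("preprocess", "consistency", "network"):
        out[key] = {**DEFAULTS[key], **(config.get(key) or {})}
    return out


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: dict, stages: list[str]) -> None:
    manifest = {
        "micoval_version": __version__,
        "config_sha256": _config_hash(config),
        "seed": config.get("seed", 0),
        "wcs_convention": WCS_CONVENTION,
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _preprocess(table: FeatureTable, cfg: dict, seed: int) -> tuple[FeatureTable, FeatureTable]:
    """(normalized table, filtered-but-unimputed table for presence/absence)."""
    pp = cfg["preprocess"]
    filtered = filter_low_prevalence(table, pp["filter_missing"])
    working = impute_zeros(filtered) if pp["impute"] else filtered
    norm = pp["normalize"]
    if norm == "tss":
        working = tss_normalize(working)
    elif norm == "mor":
        working = median_of_ratios_normalize(working)
    elif norm == "rarefy":
        working = rarefy(filtered, depth=pp.get("depth", "min"), seed=seed)
        working = tss_normalize(impute_zeros(working) if pp["impute"] else working)
    else:
        raise ValidationError(f"unknown normalization {norm!r}")
    return working, filtered


def _load_dataset(entry: dict) -> tuple[FeatureTable, SampleMetadata, TaxonomyMap | None]:
    if "table" not in entry or "metadata" not in entry:
        raise ValidationError("dataset entry needs 'table' and 'metadata' paths")
    units = entry.get("units", "counts")
    if entry.get("lineage_ids"):
        table, tax = read_feature_table(entry["table"], units=units, extract_taxonomy=True)
    else:
        table = read_feature_table(entry["table"], units=units)
        tax = read_taxonomy(entry["taxonomy"]) if entry.get("taxonomy") else None
    meta = read_metadata(entry["metadata"])
    table, meta = meta.align_table(table)
    return table, meta, tax


def _spec_from_config(sim: dict, seed: int) -> SimulationSpec:
    effects = []
    n_projects = int(sim.get("n_projects", 6))
    for eff in sim.get("planted_effects", []):
        if "signs" in eff:
            signs = tuple(int(s) for s in eff["signs"])
        else:
            signs = tuple([int(eff.get("sign", 1))] * n_projects)
        effects.append(PlantedEffect(eff["taxon"], signs, float(eff["log2fc"])))
    fields = {
        k: sim[k]
        for k in (
            "n_taxa",
            "samples_per_group",
            "depth_mean",
            "depth_dispersion",
            "concentration",
            "base_concentration",
            "phenotypes",
            "interventions",
            "case_group",
            "control_group",
        )
        if k in sim
    }
    return SimulationSpec(
        n_projects=n_projects,
        planted_effects=effects,
        seed=int(sim.get("seed", seed)),
        **fields,
    )


# ---------------------------------------------------------------------------
# analyze


def run_analyze(config: dict, outdir: str | Path) -> Path:
    """Single-study pipeline: preprocess, feature, diversity, functional,
    network analysis. Writes module exports plus a run manifest."""
    cfg = _merged(config)
    section = cfg.get("analyze") or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages: list[str] = []

    table, meta, tax = _load_dataset(section)
    if cfg["rank"] and tax is not None:
        table = collapse_to_rank(table, tax, cfg["rank"])
    norm, filtered = _preprocess(table, cfg, seed)
    write_feature_table(norm, outdir / "preprocessed_table.tsv")
    stages.append("preprocess")

    case = section.get("case_group")
    control = section.get("control_group")
    designs = enumerate_comparisons(meta, case, control) if case and control else []
    for design in designs:
        result = compare_features(
            norm,
            design,
            meta,
            method=cfg["method"],
            alpha=cfg["alpha"],
            use_fdr=cfg["use_fdr"],
            lda_threshold=cfg["lda_threshold"],
            seed=seed,
        )
        write_comparison(result, outdir / f"differential_{design.project}.tsv")
    group_of = meta.frame.loc[norm.sample_ids, "group"]
    composition = norm.data.T.groupby(group_of).mean().T
    composition.to_csv(outdir / "composition_by_group.tsv", sep="\t")
    stages.append("feature")

    alpha_div = alpha_diversity(norm)
    alpha_div.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    if tax is not None:
        phylum = collapse_to_rank(table, tax, "phylum")
        phylum_norm, _ = _preprocess(phylum, cfg, seed)
        try:
            fb = fb_ratio(phylum_norm)
            fb.to_frame().to_csv(outdir / "fb_ratio.tsv", sep="\t")
        except ValidationError as exc:
            logger.warning("F/B ratio skipped: %s", exc)
    groups = meta.groups_for(norm.sample_ids)
    for metric, source in (("bray_curtis", norm), ("jaccard", filtered)):
        dm = beta_distance(source, metric=metric)
        dm.frame.to_csv(outdir / f"distance_{metric}.tsv", sep="\t")
        if metric == "bray_curtis":
            ord_pcoa = pcoa(dm, k=2)
            with open(outdir / "pcoa_coordinates.tsv", "w") as fh:
                shares = ", ".join(f"{v:.6f}" for v in ord_pcoa.proportion_explained)
                fh.write(f"# proportion_explained: {shares}\n")
                ord_pcoa.coordinates.to_csv(fh, sep="\t")
            ord_nmds = nmds(dm, k=2, seed=seed)
            with open(outdir / "nmds_coordinates.tsv", "w") as fh:
                fh.write(f"# stress: {ord_nmds.stress:.6f}\n")
                ord_nmds.coordinates.to_csv(fh, sep="\t")
            res = anosim(dm, groups, permutations=999, seed=seed)
            (outdir / "anosim.json").write_text(
                json.dumps(
                    {"R": res.r, "p": res.p, "permutations": res.permutations, "seed": res.seed},
                    indent=2,
                )
            )
    stages.append("diversity")

    if section.get("functional_table"):
        ftable = read_feature_table(section["functional_table"], units=section.get("functional_units", "counts"))
        ftable, fmeta = meta.align_table(ftable)
        fnorm, _ = _preprocess(ftable, cfg, seed)
        for design in designs:
            result = compare_features(
                fnorm, design, fmeta, method="lefse",
                alpha=cfg["alpha"], lda_threshold=cfg["lda_threshold"], seed=seed,
            )
            write_comparison(result, outdir / f"functional_{design.project}.tsv")
        stages.append("functional")

    netcfg = cfg["network"]
    if netcfg.get("enabled", True) and section.get("network", True):
        nets = {}
        for group in sorted(groups.unique()):
            samples = groups.index[groups == group].tolist()
            if len(samples) < 5:
                logger.warning("group %r too small for a network; skipped", group)
                continue
            net = build_coabundance(
                norm, samples, group_label=group,
                top_n=netcfg["top_n"], min_abs_rho=netcfg["min_abs_rho"], alpha=cfg["alpha"],
            )
            nets[group] = net
            net.edge_frame.to_csv(outdir / f"network_edges_{group}.tsv", sep="\t", index=False)
            node_properties(net).to_csv(outdir / f"network_nodes_{group}.tsv", sep="\t")
        if case in nets and control in nets:
            comparison = compare_properties(nets[case], nets[control])
            (outdir / "network_property_tests.json").write_text(json.dumps(comparison, indent=2))
        stages.append("network")

    _write_manifest(outdir, cfg, stages)
    return outdir


# ---------------------------------------------------------------------------
# crossval


def _project_datasets(cfg: dict, section: dict, seed: int):
    """Load or simulate the per-project datasets for multi-study workflows."""
    if section.get("simulate"):
        spec = _spec_from_config(section["simulate"], seed)
        datasets, _ = simulate_multiproject(spec)
        tax = taxonomy_for(spec)
        return [(t, m, tax) for t, m in datasets]
    projects = section.get("projects") or []
    return [_load_dataset(entry) for entry in projects]


def _comparison_results(cfg: dict, section: dict, datasets, seed: int):
    """Preprocess each project and run its case-vs-control comparison."""
    case = section.get("case_group", "case")
    control = section.get("control_group", "control")
    results, designs = [], []
    meta_by_comp, phylum_tables = {}, {}
    functional_results = []
    for table, meta, tax in datasets:
        if cfg["rank"] and tax is not None:
            analysis_table = collapse_to_rank(table, tax, cfg["rank"])
        else:
            analysis_table = table
        norm, _ = _preprocess(analysis_table, cfg, seed)
        for design in enumerate_comparisons(meta, case, control):
            res = compare_features(
                norm, design, meta,
                method=cfg["method"], alpha=cfg["alpha"], use_fdr=cfg["use_fdr"],
                lda_threshold=cfg["lda_threshold"], seed=seed,
            )
            results.append(res)
            designs.append(design)
            meta_by_comp[design.comparison_id] = meta
            if tax is not None:
                phylum = collapse_to_rank(table, tax, "phylum")
                phylum_tables[design.comparison_id], _ = _preprocess(phylum, cfg, seed)
            if section.get("functional_tables"):
                fpath = section["functional_tables"].get(design.project)
                if fpath:
                    ftab = read_feature_table(fpath, units="counts")
                    ftab, fmeta = meta.align_table(ftab)
                    fnorm, _ = _preprocess(ftab, cfg, seed)
                    functional_results.append(
                        compare_features(
                            fnorm, design, fmeta, method="lefse",
                            alpha=cfg["alpha"], lda_threshold=cfg["lda_threshold"], seed=seed,
                        )
                    )
    return results, designs, meta_by_comp, phylum_tables, functional_results


def _mark_local(labels, local_project: str | None):
    if not local_project:
        return list(labels)
    return [
        f"{lab} #" if lab.startswith(f"{local_project}:") else lab for lab in labels
    ]


def run_crossval(config: dict, outdir: str | Path) -> Path:
    """Multi-project validation: per-comparison differential results,
    CS/WCS consistency table, the >=3-projects & |CS|>0.6 selection,
    cross-project F/B fold changes, pathway LDA matrix and network-degree
    matrix."""
    cfg = _merged(config)
    section = cfg.get("crossval") or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages: list[str] = []

    datasets = _project_datasets(cfg, section, seed)
    if len(datasets) < 2:
        raise ValidationError("cross-project validation needs >=2 projects")
    results, designs, meta_by_comp, phylum_tables, functional_results = _comparison_results(
        cfg, section, datasets, seed
    )
    if len(results) < 2:
        raise ValidationError("cross-project validation needs >=2 comparisons")
    local = section.get("local_project")
    for res in results:
        write_comparison(res, outdir / f"differential_{res.design.project}.tsv")
    stages.append("differential")

    ccfg = cfg["consistency"]
    records = consistency_table(results, denominator=ccfg["denominator"])
    records_frame(records).to_csv(outdir / "consistency_table.tsv", sep="\t")
    selected = select_consistent(records, ccfg["min_projects"], ccfg["min_abs_cs"])
    records_frame(selected).to_csv(outdir / "consistent_features.tsv", sep="\t")
    hm = heatmap_matrix(results, [r.feature for r in selected])
    hm.columns = _mark_local(hm.columns, local)
    hm.to_csv(outdir / "consistency_heatmap.tsv", sep="\t")
    stages.append("consistency")

    if phylum_tables:
        fb = fb_ratio_cross_project(phylum_tables, designs, meta_by_comp)
        fb.index = _mark_local(fb.index, local)
        fb.to_csv(outdir / "fb_ratio_cross_project.tsv", sep="\t")
        stages.append("fb_ratio")

    if functional_results:
        pw = pathway_consistency(functional_results, cfg["lda_threshold"], cfg["alpha"])
        pw.columns = _mark_local(pw.columns, local)
        pw.to_csv(outdir / "pathway_lda_matrix.tsv", sep="\t")
        stages.append("functional")

    netcfg = cfg["network"]
    if netcfg.get("enabled", True):
        degree_cols = {}
        for (table, meta, tax), design in zip(datasets, designs):
            if cfg["rank"] and tax is not None:
                analysis_table = collapse_to_rank(table, tax, cfg["rank"])
            else:
                analysis_table = table
            norm, _ = _preprocess(analysis_table, cfg, seed)
            for group in (design.case_group, design.control_group):
                samples = meta.samples_in_group(design.project, group)
                if len(samples) < 5:
                    continue
                net = build_coabundance(
                    norm, samples, group_label=group,
                    top_n=netcfg["top_n"], min_abs_rho=netcfg["min_abs_rho"], alpha=cfg["alpha"],
                )
                degree_cols[f"{design.comparison_id}|{group}"] = node_properties(net)["degree"]
        if degree_cols:
            deg = pd.DataFrame(degree_cols)
            deg.columns = _mark_local(deg.columns, local)
            deg.to_csv(outdir / "network_degree_matrix.tsv", sep="\t")
            stages.append("network")

    taxmaps = [tax for _, _, tax in datasets if tax is not None]
    if taxmaps and selected:
        merged = TaxonomyMap()
        for tax in taxmaps:
            merged.lineages.update(tax.lineages)
        rank = cfg["rank"] or "genus"
        sankey_edges(selected, merged, to_rank=rank).to_csv(
            outdir / "sankey_edges.tsv", sep="\t", index=False
        )

    _write_manifest(outdir, cfg, stages)
    return outdir


# ---------------------------------------------------------------------------
# advanced (stratified) validation


def run_advanced(config: dict, outdir: str | Path) -> Path:
    """Cross-phenotype / cross-intervention validation: CS matrices per
    stratum with a concordance flag."""
    cfg = _merged(config)
    section = cfg.get("advanced") or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stratify_by = section.get("stratify_by", "phenotype")
    if stratify_by not in ("phenotype", "intervention"):
        raise ValidationError("stratify_by must be 'phenotype' or 'intervention'")

    datasets = _project_datasets(cfg, section, seed)
    results, designs, *_ = _comparison_results(cfg, section, datasets, seed)
    by_stratum: dict[str, list] = {}
    for res, design in zip(results, designs):
        label = getattr(design, stratify_by)
        if not label:
            raise ValidationError(
                f"design {design.comparison_id} lacks a {stratify_by} label"
            )
        by_stratum.setdefault(label, []).append(res)
    if len(by_stratum) < 2:
        raise ValidationError(f"need >=2 {stratify_by} strata, got {len(by_stratum)}")
    ccfg = cfg["consistency"]
    frame = stratified_consistency(
        by_stratum, ccfg["min_projects"], ccfg["min_abs_cs"], ccfg["denominator"]
    )
    frame.to_csv(outdir / f"stratified_consistency_{stratify_by}.tsv", sep="\t")
    _write_manifest(outdir, cfg, [f"stratified_{stratify_by}"])
    return outdir


# ---------------------------------------------------------------------------
# simulate


def run_simulate(config: dict, outdir: str | Path) -> Path:
    """Write per-project synthetic tables, metadata, taxonomy, the planted
    truth table and the resolved spec."""
    cfg = _merged(config)
    section = cfg.get("simulate") or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = _spec_from_config(section, int(cfg["seed"]))
    datasets, truth = simulate_multiproject(spec)
    tax = taxonomy_for(spec)
    for j, (table, meta) in enumerate(datasets):
        write_feature_table(table, outdir / f"project_P{j + 1}_table.tsv")
        write_metadata(meta, outdir / f"project_P{j + 1}_metadata.tsv")
    write_taxonomy(tax, outdir / "taxonomy.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    resolved = {
        "n_projects": spec.n_projects,
        "n_taxa": spec.n_taxa,
        "samples_per_group": spec.samples_per_group,
        "depth_mean": spec.depth_mean,
        "depth_dispersion": spec.depth_dispersion,
        "concentration": spec.concentration,
        "base_concentration": spec.base_concentration,
        "seed": spec.seed,
        "planted_effects": [
            {"taxon": e.taxon, "signs": list(e.signs), "log2fc": e.log2fc}
            for e in spec.planted_effects
        ],
    }
    (outdir / "spec_resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    _write_manifest(outdir, cfg, ["simulate"])
    return outdir
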