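"""Config-driven orchestration of the full analysis.

Fixed stage order: load or simulate inputs -> RPM normalization ->
low-coverage sample exclusion -> low-abundance taxon filtering ->
content/diversity comparisons -> species restriction, Bray-Curtis, PCoA
and group ellipses -> differential abundance against the control and the
infection group (genus and species level) -> correlation of significant
taxa with immune markers -> host assays when fixtures are present.
Every run writes its stage outputs as TSV plus a machine-readable
manifest (config echo, version, seed, exclusions, filtered taxa) that
suffices to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from . import assays as assays_mod
from .da import LogAbundanceTable, differential_abundance, fold_change_matrix, log_transform
from .diversity import (
    bray_curtis_matrix,
    compare_content,
    group_content_summary,
    group_ellipses,
    pcoa,
    restrict_species_for_pcoa,
    shannon_by_sample,
)
from .immune import correlate_with_markers, correlation_matrix, select_significant_taxa
from .tables import (
    collapse_to_genus,
    exclude_samples,
    filter_low_abundance,
    normalize_rpm,
    read_count_table,
    read_sample_metadata,
    write_sample_metadata,
)
from .synth import EffectSpec, StudyDesign, generate_assay_fixtures, generate_study

log = logging.getLogger("periobiome")


@dataclass
class PipelineConfig:
    """All knobs of one run; defaults are the standard analysis values."""

    counts: str | None = None
    metadata: str | None = None
    markers: str | None = None
    synthetic: dict | None = None
    low_abundance_rpm: float = 1.0
    pcoa_rpm_cap: float = 500.0
    pseudocount: float = 0.1
    fdr_tiers: tuple = (0.1, 0.2, 0.3)
    ellipse_level: float = 0.95
    control_group: str = "Control"
    infection_group: str = "Infection"
    exclude_samples: tuple = ()
    min_total_reads: float | None = None
    run_assays: bool = True
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("low_abundance_rpm", "pcoa_rpm_cap", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        tiers = tuple(self.fdr_tiers)
        if len(tiers) != 3 or not (0 < tiers[0] < tiers[1] < tiers[2]):
            raise ConfigError(f"fdr_tiers must be 3 strictly increasing values, got {tiers}")
        self.fdr_tiers = tiers
        if not 0 < self.ellipse_level < 1:
            raise ConfigError("ellipse_level must be in (0, 1)")
        if self.counts is None and self.synthetic is None:
            raise ConfigError("give either input paths ('counts') or a 'synthetic' block")
        self.exclude_samples = tuple(self.exclude_samples)


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys or invalid values raise ConfigError."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    if "counts" not in raw and "synthetic" not in raw:
        raw["synthetic"] = {}
    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    log.info("config loaded: %s", cfg)
    return cfg


def write_config(cfg: PipelineConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["fdr_tiers"] = list(cfg.fdr_tiers)
    d["exclude_samples"] = list(cfg.exclude_samples)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    return wrap


def run_pipeline(config: PipelineConfig, effects: EffectSpec | None = None) -> dict:
    """Execute the full analysis and write all stage outputs.

    Returns a result bundle (dict) with the in-memory tables keyed by
    stage name; the same content is written under ``config.out_dir``.
    A stage failure aborts the run with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "seed": config.seed,
        "stages": [],
    }
    results: dict = {}

    # --- inputs -----------------------------------------------------------
    if config.synthetic is not None:
        syn = dict(config.synthetic or {})
        design = StudyDesign(**{**syn.get("design", {}), "seed": config.seed})
        low_cov = tuple(syn.get("low_coverage_samples", ()))
        table, meta, markers, truth = _stage("simulate")(
            generate_study, design, effects, config.seed, low_cov
        )
        fixtures = generate_assay_fixtures(design, config.seed) if config.run_assays else None
        table.to_tsv(out / "counts.tsv")
        write_sample_metadata(meta, out / "metadata.tsv")
        markers.rename_axis("sample_id").to_csv(out / "markers.tsv", sep="\t")
        truth.to_json(out / "truth.json")
        if fixtures is not None:
            fixtures.write(out / "assays")
        results["truth"] = truth
    else:
        table = _stage("read")(read_count_table, config.counts, config.metadata)
        markers = None
        if config.markers:
            markers = pd.read_csv(config.markers, sep="\t", index_col="sample_id")
        fixtures = None
    manifest["stages"].append("inputs")
    results["counts"] = table

    for ref in (config.control_group, config.infection_group):
        if ref not in set(table.samples["group"]):
            raise ConfigError(f"reference group '{ref}' not present in metadata")

    # --- normalize / exclude / filter ------------------------------------
    abundance = _stage("normalize")(normalize_rpm, table)
    excluded_ran = True
    if config.exclude_samples:
        abundance = _stage("exclude")(exclude_samples, abundance, list(config.exclude_samples))
    elif config.min_total_reads is not None:
        abundance = _stage("exclude")(
            exclude_samples, abundance, None, config.min_total_reads
        )
    else:
        excluded_ran = False
    abundance = _stage("filter")(filter_low_abundance, abundance, config.low_abundance_rpm)
    manifest["excluded_samples"] = [
        s for rec in abundance.provenance if rec["step"] == "exclude_samples"
        for s in rec["excluded"]
    ]
    manifest["filtered_taxa"] = [
        t for rec in abundance.provenance if rec["step"] == "filter_low_abundance"
        for t in rec["removed_taxa"]
    ]
    abundance.to_tsv(out / "abundance_species.tsv")
    manifest["stages"] += ["normalize"] + (["exclude"] if excluded_ran else []) + ["filter"]
    results["abundance"] = abundance

    genus_counts = collapse_to_genus(table)
    genus_ab = normalize_rpm(genus_counts)
    keep = [s for s in abundance.sample_ids]
    genus_ab = exclude_samples(
        genus_ab, [s for s in genus_ab.sample_ids if s not in keep]
    ) if len(keep) < len(genus_ab.sample_ids) else genus_ab
    genus_ab = filter_low_abundance(genus_ab, config.low_abundance_rpm)
    genus_ab.to_tsv(out / "abundance_genus.tsv")
    results["abundance_genus"] = genus_ab

    # --- content & diversity ----------------------------------------------
    content = pd.concat(
        [group_content_summary(abundance, k) for k in ("bacteria", "virus")],
        ignore_index=True,
    )
    content.to_csv(out / "content.tsv", sep="\t", index=False)
    diversity = pd.concat(
        [shannon_by_sample(abundance, k) for k in ("bacteria", "virus")], ignore_index=True
    )
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
    groups = abundance.samples["group"]
    test_rows = []
    for kingdom in ("bacteria", "virus"):
        totals = abundance.subset_kingdom(kingdom).data.sum(axis=0)
        div = diversity[diversity["kingdom"] == kingdom].set_index("sample_id")["H"]
        for ref in (config.control_group, config.infection_group):
            for g in pd.unique(groups):
                if g == ref:
                    continue
                for quantity, series in (("content", totals), ("shannon", div)):
                    r = compare_content(
                        series[groups.index[groups == g]].dropna(),
                        series[groups.index[groups == ref]].dropna(),
                    )
                    test_rows.append(
                        {
                            "kingdom": kingdom, "quantity": quantity,
                            "comparison": f"{g} vs {ref}",
                            "t": r.t, "df": r.df, "p": r.p, "degenerate": r.degenerate,
                        }
                    )
    pd.DataFrame(test_rows).to_csv(out / "group_tests.tsv", sep="\t", index=False)
    manifest["stages"] += ["content", "diversity"]
    results["content"] = content
    results["diversity"] = diversity

    # --- ordination --------------------------------------------------------
    restricted, removed = _stage("restrict")(
        restrict_species_for_pcoa, abundance, config.pcoa_rpm_cap
    )
    manifest["pcoa_removed_species"] = removed
    bc = _stage("braycurtis")(bray_curtis_matrix, restricted)
    bc.to_csv(out / "braycurtis.tsv", sep="\t")
    ord_res = _stage("pcoa")(pcoa, bc)
    coords = ord_res.coordinates.copy()
    coords.insert(0, "group", groups.reindex(coords.index))
    coords.rename_axis("sample_id").to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {
            "eigenvalue": ord_res.eigenvalues,
            "proportion_explained": np.concatenate(
                [ord_res.proportion_explained,
                 np.full(len(ord_res.eigenvalues) - len(ord_res.proportion_explained), np.nan)]
            ),
        }
    ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
    ellipses = group_ellipses(
        ord_res.coordinates, groups, axes=("PC1", "PC2"), level=config.ellipse_level
    )
    (out / "ellipses.json").write_text(
        json.dumps({g: dataclasses.asdict(e) for g, e in ellipses.items()}, indent=2)
    )
    manifest["stages"] += ["restrict", "braycurtis", "pcoa", "ellipses"]
    results["pcoa"] = ord_res
    results["ellipses"] = ellipses

    # --- differential abundance -------------------------------------------
    log_species = log_transform(abundance, config.pseudocount)
    log_genus = log_transform(genus_ab, config.pseudocount)
    combined = LogAbundanceTable(
        data=pd.concat([log_species.data, log_genus.data]),
        taxa=pd.concat([log_species.taxa, log_genus.taxa]),
        samples=log_species.samples,
        pseudocount=config.pseudocount,
    )
    da_parts = []
    for ref in (config.control_group, config.infection_group):
        da_parts.append(
            _stage("differential_abundance")(
                differential_abundance, combined, ref, None,
                ("genus", "species"), config.fdr_tiers,
            )
        )
    da_results = pd.concat(da_parts, ignore_index=True)
    da_results.to_csv(out / "da_results.tsv", sep="\t", index=False)
    for level in ("genus", "species"):
        fold_change_matrix(da_results, level).to_csv(
            out / f"da_fold_matrix_{level}.tsv", sep="\t"
        )
    manifest["stages"].append("differential_abundance")
    results["da"] = da_results

    # --- immune correlation -------------------------------------------------
    if markers is not None:
        significant = select_significant_taxa(da_results)
        if significant:
            corr = _stage("correlate")(
                correlate_with_markers, combined, markers, significant,
                config.pseudocount, config.fdr_tiers,
            )
            corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
            correlation_matrix(corr).to_csv(out / "correlation_matrix.tsv", sep="\t")
            results["correlations"] = corr
        else:
            log.warning("no significant taxa; correlation stage skipped")
            results["correlations"] = None
        manifest["stages"].append("correlate")

    # --- host assays ----------------------------------------------------------
    if fixtures is not None:
        results["assays"] = _run_assays(fixtures, config, out)
        manifest["stages"].append("assays")

    from importlib.metadata import version

    try:
        manifest["version"] = version("periobiome")
    except Exception:
        manifest["version"] = "unknown"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results


def _run_assays(fixtures, config: PipelineConfig, out: Path) -> dict:
    res: dict = {}
    site_cols = [c for c in fixtures.bone_loss.columns if c.startswith("site_")]
    bl = fixtures.bone_loss.copy()
    bl["mean_mm"] = [assays_mod.bone_loss_mean(r) for r in bl[site_cols].to_numpy()]
    bl_rows = []
    ctrl = bl.loc[bl["group"] == config.control_group, "mean_mm"]
    inf = bl.loc[bl["group"] == config.infection_group, "mean_mm"]
    for g, sub in bl.groupby("group"):
        row = {"group": g, "n": len(sub), "mean_mm": sub["mean_mm"].mean(),
               "sd_mm": sub["mean_mm"].std(ddof=1)}
        for ref_name, ref_vals in (("control", ctrl), ("infection", inf)):
            if g not in (config.control_group, config.infection_group) or (
                (g == config.control_group) != (ref_name == "control")
            ):
                if not sub["mean_mm"].equals(ref_vals):
                    row[f"p_vs_{ref_name}"] = assays_mod.two_group_t(
                        sub["mean_mm"], ref_vals
                    ).p
        bl_rows.append(row)
    bone = pd.DataFrame(bl_rows)
    bone.to_csv(out / "boneloss_summary.tsv", sep="\t", index=False)
    res["bone_loss"] = bone

    dt = fixtures.defects.set_index("group")
    ref_row = dt.loc[config.infection_group]
    def_rows = []
    for g, row in dt.iterrows():
        rec = {"group": g, "defects": int(row["defects"]), "total": int(row["total_surfaces"]),
               "percent": 100.0 * row["defects"] / row["total_surfaces"]}
        if g != config.infection_group:
            try:
                chi = assays_mod.defect_chi_square(
                    int(row["defects"]), int(row["total_surfaces"]),
                    int(ref_row["defects"]), int(ref_row["total_surfaces"]),
                )
                rec.update({"chi2_vs_infection": chi.chi2, "p_vs_infection": chi.p})
            except ValueError:
                rec.update({"chi2_vs_infection": np.nan, "p_vs_infection": np.nan})
        def_rows.append(rec)
    defects = pd.DataFrame(def_rows)
    defects.to_csv(out / "defect_tests.tsv", sep="\t", index=False)
    res["defects"] = defects

    from .synth import PATHOGENS

    q = fixtures.qpcr.copy()
    for p in PATHOGENS:
        q[f"{p}_pct"] = [
            assays_mod.pathogen_percentage(a, b) for a, b in zip(q[p], q["total_16s"])
        ]
    q.to_csv(out / "qpcr_percent.tsv", sep="\t", index=False)
    res["qpcr"] = q

    dd_parts = []
    for gene, sub in fixtures.ct.groupby("gene"):
        dd = assays_mod.ddct_fold_change(sub, config.control_group)
        dd_parts.append(dd)
    ddct = pd.concat(dd_parts, ignore_index=True)
    ddct.to_csv(out / "ddct.tsv", sep="\t", index=False)
    res["ddct"] = ddct

    igg = fixtures.igg
    ig_rows = []
    ctrl_od = igg.loc[igg["group"] == config.control_group, "od"]
    for g, sub in igg.groupby("group"):
        rec = {"group": g, "n": len(sub), "mean_od": sub["od"].mean()}
        if g != config.control_group:
            rec["p_vs_control"] = assays_mod.two_group_t(sub["od"], ctrl_od).p
        ig_rows.append(rec)
    igg_out = pd.DataFrame(ig_rows)
    igg_out.to_csv(out / "igg_tests.tsv", sep="\t", index=False)
    res["igg"] = igg_out
    return res
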