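"""End-to-end controls-first analysis pipeline.

Runs the ordered stages on a feature table + metadata (+ taxonomy):
optional lineage-based taxon exclusion, contaminant classification by both
the major-contaminant rule and the blank-prevalence rule (always both, so
their agreement is reported even when only one drives removal), removal,
alpha/beta diversity with negative controls retained in every output, the
control-proximity screen, the planned hypothesis tests, genus aggregation
with differential abundance per contrast, and a JSON manifest recording
every parameter, seed and per-stage record count.

Negative controls are never dropped from any output table; given the same
config and seed, every output file is byte-identical on rerun.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from . import tables as tio
from .decontam import (
    classify_major_contaminants,
    classify_prevalence_rule,
    compare_classifications,
    remove_contaminants,
)
from .diversity import (
    alpha_diversity_table,
    bray_curtis,
    control_proximity,
    pcoa,
)
from .inference import (
    holm_adjust,
    nb_wald_diff_abundance,
    permanova,
    two_way_anova,
    wilcoxon_rank_sum,
)
from .tables import FeatureTable, SampleMetadata, ValidationError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "default_inference_plan"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_inference_plan() -> list:
    """The factor analyses mirrored by the default pipeline run.

    Alpha comparisons between replicates on mock-treated specimens,
    distance-based tests on replicate and on treatment (with the
    treatment x timepoint interaction), a two-way ANOVA of the Shannon
    index on treatment and timepoint, and genus-level contrasts:
    blanks vs specimens, and control vs each antibiotic arm at 24 h.
    """
    return [
        {"test": "wilcoxon_alpha", "name": "shannon_by_replicate",
         "metric": "shannon", "field": "replicate",
         "subset": {"treatment": "control"}},
        {"test": "wilcoxon_alpha", "name": "chao1_by_replicate",
         "metric": "chao1", "field": "replicate",
         "subset": {"treatment": "control"}},
        {"test": "permanova", "name": "bray_by_replicate",
         "factors": ["replicate"], "subset": {"treatment": "control"}},
        {"test": "permanova", "name": "bray_by_treatment_time",
         "factors": ["treatment", "timepoint_h"], "interaction": True},
        {"test": "anova", "name": "shannon_treatment_x_time",
         "metric": "shannon", "factors": ["treatment", "timepoint_h"]},
        {"test": "diffabund", "name": "genus_role",
         "contrast": ["role", "negative_control", "specimen"]},
        {"test": "diffabund", "name": "genus_amox_24h",
         "contrast": ["treatment", "control", "amox"],
         "subset": {"timepoint_h": 24}},
        {"test": "diffabund", "name": "genus_amoxclav_24h",
         "contrast": ["treatment", "control", "amox_clav"],
         "subset": {"timepoint_h": 24}},
    ]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    table_path: str = None
    metadata_path: str = None
    taxonomy_path: str = None
    out_dir: str = "contamscope_out"
    exclude_lineages: tuple = ("Mitochondria", "Chloroplast")
    removal_method: str = "major"  # major | prevalence | none
    mode: str = "relative"
    prevalence_threshold: float = 0.8
    prevalence_rule_threshold: float = 0.5
    proximity_k: int = 6
    n_permutations: int = 999
    genus_rank: str = "genus"
    inference_plan: tuple = None
    seed: int = None

    def plan(self) -> list:
        return list(self.inference_plan) if self.inference_plan is not None \
            else default_inference_plan()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "inference_plan" in raw and raw["inference_plan"] is not None:
            raw["inference_plan"] = tuple(raw["inference_plan"])
        if "exclude_lineages" in raw:
            raw["exclude_lineages"] = tuple(raw["exclude_lineages"])
        return cls(**raw)

    def validate(self):
        if self.removal_method not in ("major", "prevalence", "none"):
            raise ValidationError(f"unknown removal_method {self.removal_method!r}")
        needs_seed = any(e["test"] == "permanova" for e in self.plan())
        if needs_seed and self.seed is None:
            raise ValidationError("a seed is mandatory when permutation tests "
                                  "are planned")


def _write_tsv(df: pd.DataFrame, path, index_name: str):
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig, table: FeatureTable = None,
                 metadata: SampleMetadata = None,
                 taxonomy: tio.TaxonomyTable = None) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {"config": _config_record(config), "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # abort with the stage name
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _dump_manifest(manifest, config.out_dir, partial=True)
                raise PipelineError(name, exc) from exc
        return wrap

    # ---- load -------------------------------------------------------------
    def _load():
        t = table if table is not None else tio.read_feature_table(config.table_path)
        m = metadata if metadata is not None else tio.read_metadata(config.metadata_path)
        x = taxonomy
        if x is None and config.taxonomy_path:
            x = tio.read_taxonomy(config.taxonomy_path)
        m.check_paired(t)
        return t, m, x

    t, md, tax = stage("load")(_load)
    n_controls = len([s for s in t.sample_ids
                      if md.data.loc[s, "role"] == "negative_control"])
    manifest["stages"]["load"] = {
        "n_taxa": len(t.taxon_ids), "n_samples": len(t.sample_ids),
        "n_controls": n_controls,
    }

    # ---- 1. lineage filter ------------------------------------------------
    if config.exclude_lineages and tax is not None:
        def _filter():
            return tio.filter_taxa_by_lineage(t, tax, list(config.exclude_lineages))
        t, removed_lineage = stage("lineage_filter")(_filter)
        manifest["stages"]["lineage_filter"] = {
            "exclude_terms": list(config.exclude_lineages),
            "n_removed": len(removed_lineage),
            "n_taxa_after": len(t.taxon_ids),
        }

    # ---- 2. classify by both methods --------------------------------------
    def _classify():
        major = classify_major_contaminants(
            t, md, mode=config.mode,
            prevalence_threshold=config.prevalence_threshold)
        prev = classify_prevalence_rule(
            t, md, threshold=config.prevalence_rule_threshold)
        comp = compare_classifications(major, prev)
        return major, prev, comp

    major, prev, comp = stage("classify")(_classify)
    flag_major = "flag_major_relative" if config.mode == "relative" else "flag_major_raw"
    major.to_tsv(os.path.join(config.out_dir, "contaminant_report.tsv"))
    prev.to_tsv(os.path.join(config.out_dir, "contaminant_report_prevalence.tsv"))
    manifest["stages"]["classify"] = {
        "major": major.summary(), "prevalence_rule": prev.summary(),
        "n_intersection": comp["n_intersection"],
        "n_flagged_major": comp["n_flagged_a"],
        "n_flagged_prevalence": comp["n_flagged_b"],
    }

    # ---- 3. removal --------------------------------------------------------
    def _remove():
        if config.removal_method == "none":
            return t, []
        report = major if config.removal_method == "major" else prev
        which = flag_major if config.removal_method == "major" else "flag_prevalence_rule"
        return remove_contaminants(t, report, which)

    polished, removal_log = stage("remove")(_remove)
    tio.write_feature_table(polished, os.path.join(config.out_dir, "polished_table.tsv"))
    manifest["stages"]["remove"] = {
        "method": config.removal_method,
        "n_removed": len(removal_log),
        "removed_taxa": [r["taxon_id"] for r in removal_log],
        "n_taxa_after": len(polished.taxon_ids),
        "n_controls": n_controls,
    }

    # ---- 4. diversity ------------------------------------------------------
    def _diversity():
        alpha = alpha_diversity_table(polished, md)
        dm = bray_curtis(polished)
        ord_res = pcoa(dm)
        return alpha, dm, ord_res

    alpha, dm, ord_res = stage("diversity")(_diversity)
    _write_tsv(alpha, os.path.join(config.out_dir, "alpha.tsv"), "sample_id")
    _write_tsv(dm.to_dataframe(), os.path.join(config.out_dir, "bray_curtis.tsv"),
               "sample_id")
    _write_tsv(ord_res.coordinates_frame(),
               os.path.join(config.out_dir, "pcoa_coordinates.tsv"), "sample_id")
    eig = pd.DataFrame({"eigenvalue": ord_res.eigenvalues})
    eig.index = [f"axis{i + 1}" for i in range(len(eig))]
    _write_tsv(eig, os.path.join(config.out_dir, "pcoa_eigenvalues.tsv"), "axis")
    manifest["stages"]["diversity"] = {
        "n_samples": len(alpha), "n_controls": int((alpha["role"] == "negative_control").sum()),
        "n_negative_eigenvalues": ord_res.n_negative_eigenvalues,
    }

    # ---- 5. control proximity ----------------------------------------------
    def _proximity():
        return control_proximity(polished, md, k=config.proximity_k)

    prox = stage("proximity")(_proximity)
    _write_tsv(prox.per_specimen, os.path.join(config.out_dir, "proximity.tsv"),
               "sample_id")
    manifest["stages"]["proximity"] = prox.summary

    # ---- 6/7. inference plan -----------------------------------------------
    tests_dir = os.path.join(config.out_dir, "tests")
    diff_dir = os.path.join(config.out_dir, "diffabund")
    os.makedirs(tests_dir, exist_ok=True)
    os.makedirs(diff_dir, exist_ok=True)
    genus_table = None
    if tax is not None:
        genus_table = tio.aggregate_by_rank(polished, tax, config.genus_rank)
        tio.write_feature_table(
            genus_table, os.path.join(config.out_dir, "genus_table.tsv"))
    inference_records = {}
    for entry in config.plan():
        name = entry.get("name", entry["test"])

        def _run_entry(entry=entry, name=name):
            return _run_inference_entry(
                entry, polished, genus_table, md, alpha, config)

        result = stage(f"inference:{name}")(_run_entry)
        inference_records[name] = result["summary"]
        if result.get("frame") is not None:
            where = diff_dir if entry["test"] == "diffabund" else tests_dir
            _write_tsv(result["frame"], os.path.join(where, f"{name}.tsv"),
                       result.get("index_name", "term"))
    manifest["stages"]["inference"] = inference_records
    if genus_table is not None:
        manifest["stages"]["genus_aggregation"] = {
            "rank": config.genus_rank, "n_genera": len(genus_table.taxon_ids),
        }

    _dump_manifest(manifest, config.out_dir)
    return manifest


def _subset_for(entry, table, metadata, keep_controls=False):
    subset = entry.get("subset")
    if not subset:
        return table
    return tio.subset_samples(table, metadata, subset, keep_controls=keep_controls)


def _run_inference_entry(entry, polished, genus_table, md, alpha, config):
    kind = entry["test"]
    if kind == "wilcoxon_alpha":
        sub = _subset_for(entry, polished, md)
        sub_md = md.data.loc[sub.sample_ids]
        specs = sub_md.index[sub_md["role"] == "specimen"]
        values = alpha.loc[specs, entry["metric"]]
        groups = sub_md.loc[specs, entry["field"]]
        levels = sorted(pd.unique(groups))
        pairs, pvals = [], []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                x = values[groups == levels[i]].to_numpy()
                y = values[groups == levels[j]].to_numpy()
                pairs.append(f"{levels[i]}_vs_{levels[j]}")
                pvals.append(wilcoxon_rank_sum(x, y))
        padj = holm_adjust(pvals)
        frame = pd.DataFrame({"p": pvals, "p_holm": padj}, index=pairs)
        return {"summary": {"metric": entry["metric"], "field": entry["field"],
                            "p_holm": dict(zip(pairs, np.round(padj, 6)))},
                "frame": frame, "index_name": "comparison"}
    if kind == "permanova":
        sub = _subset_for(entry, polished, md)
        sub_md = md.data.loc[sub.sample_ids]
        specs = [s for s in sub.sample_ids if sub_md.loc[s, "role"] == "specimen"]
        dm = bray_curtis(sub.select_samples(specs))
        factors = {f: sub_md.loc[specs, f] for f in entry["factors"]}
        res = permanova(dm, factors,
                        include_interaction=entry.get("interaction", False),
                        n_permutations=config.n_permutations, seed=config.seed)
        return {"summary": {
                    "terms": {t: {"pseudo_F": round(float(r["pseudo_F"]), 6),
                                  "p_perm": float(r["p_perm"])}
                              for t, r in res.table.iterrows()},
                    "n_permutations": res.n_permutations},
                "frame": res.table, "index_name": "term"}
    if kind == "anova":
        sub = _subset_for(entry, polished, md)
        sub_md = md.data.loc[sub.sample_ids]
        specs = sub_md.index[sub_md["role"] == "specimen"]
        fa, fb = entry["factors"]
        tab = two_way_anova(alpha.loc[specs, entry["metric"]],
                            sub_md.loc[specs, fa], sub_md.loc[specs, fb],
                            names=(fa, fb))
        return {"summary": {t: {"F": None if np.isnan(r["F"]) else round(float(r["F"]), 6),
                                "p": None if np.isnan(r["p"]) else float(r["p"])}
                            for t, r in tab.iterrows()},
                "frame": tab, "index_name": "term"}
    if kind == "diffabund":
        if genus_table is None:
            raise ValidationError("diffabund planned but no taxonomy provided")
        field_name, level_a, level_b = entry["contrast"]
        sub = _subset_for(entry, genus_table, md,
                          keep_controls=(field_name == "role"))
        res = nb_wald_diff_abundance(sub, md, (field_name, level_a, level_b))
        sig = res.significant()
        return {"summary": {"contrast": list(entry["contrast"]),
                            "n_genera": len(res.table),
                            "n_significant": len(sig),
                            "significant": sig},
                "frame": res.table, "index_name": "genus"}
    raise ValidationError(f"unknown inference test {kind!r}")


def _config_record(config: PipelineConfig) -> dict:
    rec = {}
    for k, v in config.__dict__.items():
        if isinstance(v, tuple):
            v = list(v)
        rec[k] = v
    return rec


def _dump_manifest(manifest: dict, out_dir: str, partial: bool = False):
    manifest = dict(manifest)
    manifest["partial"] = partial
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
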