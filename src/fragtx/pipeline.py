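"""End-to-end pipeline: synthesize (or load), analyze, export, report.

Every intermediate artifact is written in a re-loadable text format and
hashed into a run manifest, so a rerun with the same configuration and
seed is byte-identical and fully auditable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from . import io as fio
from .clustering import cut_and_select, hcluster_profiles, impute_profiles, select_candidates
from .core import (
    ENRICHMENT_ALPHA,
    FC_CAP,
    FC_THRESHOLD,
    FPKM_FLOOR,
    MARGIN_NT,
    PEARSON_THRESHOLD,
    ConfigError,
)
from .enrichment import enrich, propagate_annotations
from .foldchange import fold_change_matrix, fold_change_table
from .fragments import collapse, detect_fragment_pairs, pair_precision_recall
from .pathway import reconstruct_step
from .pictogram import categorize_matrix, render_pictograms
from .simulate import REVERSE_FILE_NAMES, SynthConfig, generate_dataset, write_dataset
from .stages import (
    STAGE_NAMES,
    cluster_samples,
    js_sample_distance,
    stage_gene_sets,
    stage_response,
    venn_partition,
)


@dataclass
class PipelineConfig:
    """Thresholds of the analysis; defaults are the study's stated values."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    fc_threshold: float = FC_THRESHOLD
    fpkm_floor: float = FPKM_FLOOR
    pearson_threshold: float = PEARSON_THRESHOLD
    margin_nt: int = MARGIN_NT
    alpha: float = ENRICHMENT_ALPHA
    cap: float = FC_CAP
    k_range: tuple[int, ...] = (3, 4, 5, 6, 7)
    forced_k: int | None = None

    def validate(self) -> None:
        if not (0 < self.pearson_threshold <= 1):
            raise ConfigError("pearson_threshold must lie in (0, 1]")
        if self.fc_threshold <= 0 or self.fpkm_floor <= 0 or self.cap <= 0:
            raise ConfigError("thresholds must be positive")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.margin_nt < 0:
            raise ConfigError("margin_nt must be non-negative")
        if any(k < 2 for k in self.k_range):
            raise ConfigError("k_range entries must be >= 2")
        self.synth.validate()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline on a synthetic study; returns the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: synthesize and round-trip through the on-disk formats
    dataset = generate_dataset(config.synth)
    write_dataset(dataset, out / "dataset")
    matrix = fio.read_expression(out / "dataset" / "expression.tsv")
    models = fio.read_gene_models(out / "dataset" / "models.gff3")
    annotations = fio.read_annotations(out / "dataset" / "annotations.tsv")
    records = fio.combine_records(models, annotations)
    dag = fio.read_obo(out / "dataset" / "ontology.obo")
    forward_table = fio.read_hit_table(out / "dataset" / "hits_forward.tsv")
    reverse_tables = {
        org: fio.read_hit_table(out / "dataset" / name)
        for org, name in REVERSE_FILE_NAMES.items()
    }
    from .pathway import read_steps

    steps = read_steps(out / "dataset" / "steps.tsv")
    truth = dataset.truth

    # stage 2: fold changes
    fc = fold_change_matrix(matrix, floor=config.fpkm_floor)
    fold_change_table(fc, cap=config.cap).to_csv(out / "fold_changes.tsv", sep="\t", index=False)

    # stage 3: fragment detection and collapse
    merge = detect_fragment_pairs(
        matrix, records, r_threshold=config.pearson_threshold, margin=config.margin_nt
    )
    merge.to_json(out / "merge_map.json")
    collapsed = collapse(matrix, merge)
    fio.write_expression(collapsed, out / "expression_collapsed.tsv")

    # stage 4: stage responses, gene sets, Venn partitions
    response = stage_response(
        collapsed, floor=config.fpkm_floor, threshold=config.fc_threshold
    )
    response.to_csv(out / "stage_response.tsv", sep="\t", index_label="locus_id")
    sets = stage_gene_sets(response)
    venn = {}
    for direction in ("up", "down"):
        regions = venn_partition(*[sets[f"{direction}_{s}"] for s in STAGE_NAMES])
        venn[direction] = {key: sorted(v) for key, v in regions.items()}
    fio.write_json(venn, out / "venn.json")

    # stage 5: sample clustering by Jensen-Shannon distance
    js = js_sample_distance(matrix)
    js.to_csv(out / "js_distance.tsv", sep="\t", index_label="sample")
    linkage_tree = cluster_samples(js)
    fio.write_json(
        {"samples": list(js.columns), "linkage": np.round(linkage_tree, 12).tolist()},
        out / "sample_dendrogram.json",
    )

    # stage 6: gene-family clustering
    family = sorted(select_candidates(records) & set(collapsed.index))
    fc_collapsed = fold_change_matrix(collapsed, floor=config.fpkm_floor)
    profiles = impute_profiles(
        fc_collapsed.log2fc.loc[family], fc_collapsed.na_mask.loc[family]
    )
    tree = hcluster_profiles(profiles)
    cluster_result = cut_and_select(
        tree, profiles, k_range=list(config.k_range), k=config.forced_k
    )
    fio.write_json(
        {
            "members": cluster_result.member_ids,
            "assignment": cluster_result.assignment,
            "silhouettes": {str(k): v for k, v in cluster_result.silhouettes.items()},
            "chosen_k": cluster_result.chosen_k,
        },
        out / "family_clusters.json",
    )

    # stage 7: GO enrichment of the six stage sets
    direct = {locus: records[locus].go_ids for locus in collapsed.index if locus in records}
    propagated = propagate_annotations(direct, dag)
    bp_universe = {g for g, ts in propagated.items() if ts & dag.bp_terms()}
    enrichment_results = {}
    for name, gene_set in sets.items():
        result = enrich(gene_set & bp_universe, propagated, dag, alpha=config.alpha)
        result.to_csv(out / f"enrichment_{name.replace('+', 'p')}.tsv", sep="\t", index=False)
        enrichment_results[name] = result

    # stage 8: pathway-step candidate validation
    recon = {}
    for step in steps:
        result = reconstruct_step(
            step,
            forward_table,
            reverse_tables,
            records,
            matrix,
            r_threshold=config.pearson_threshold,
            margin=config.margin_nt,
        )
        recon[step.step_id] = {
            "retained": result.retained,
            "provenance": result.provenance,
        }
    fio.write_json(recon, out / "pathway_candidates.json")

    # stage 9: pictogram export for the clustered gene family
    categories = categorize_matrix(matrix)
    fragment_flags = {locus: locus in merge.paired_ids for locus in family}
    family_order = sorted(family, key=lambda l: (cluster_result.assignment[l], l))
    fc_family = fold_change_matrix(matrix.loc[family_order], floor=config.fpkm_floor)
    render_pictograms(
        fc_family,
        categories,
        records,
        fragment_flags,
        out / "pictogram.svg",
        out / "pictogram.tsv",
        cap=config.cap,
    )

    # stage 10: truth-recovery report
    recovery = _recovery_report(
        truth, merge, response, cluster_result, enrichment_results, recon, config
    )
    fio.write_json(recovery, out / "recovery.json")

    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "fragtx_version": __version__,
        "seed": config.synth.seed,
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "fpkm_floor": config.fpkm_floor,
            "pearson_threshold": config.pearson_threshold,
            "margin_nt": config.margin_nt,
            "alpha": config.alpha,
            "cap": config.cap,
            "k_range": list(config.k_range),
        },
        "files": {name: _sha256(out / name) for name in files},
    }
    fio.write_json(manifest, out / "manifest.json")
    return manifest


def _recovery_report(
    truth, merge, response, cluster_result, enrichment_results, recon, config
) -> dict:
    precision, recall = pair_precision_recall(
        merge, {tuple(sorted(p)) for p in truth.pairs}
    )
    retained_ok = sum(
        1
        for pair in merge.pairs
        if tuple(sorted(pair)) in {tuple(sorted(p)) for p in truth.pairs}
        and merge.retained[pair] == truth.retained_member[tuple(sorted(pair))]
    )
    # stage classification accuracy over loci with planted direction
    total = correct = 0
    for locus, directions in truth.stage_direction.items():
        if locus not in response.index:
            continue
        for stage, expected in directions.items():
            total += 1
            if response.loc[locus, f"class_{stage}"] == expected:
                correct += 1
    stage_accuracy = correct / total if total else float("nan")

    truth_clusters = truth.cluster_id
    shared = [l for l in cluster_result.member_ids if l in truth_clusters]
    if shared:
        ari = float(
            adjusted_rand_score(
                [truth_clusters[l] for l in shared],
                [cluster_result.assignment[l] for l in shared],
            )
        )
    else:
        ari = float("nan")
    enriched_found = {}
    for set_name, term in truth.enriched_terms.items():
        result = enrichment_results.get(set_name)
        found = False
        if result is not None and not result.empty:
            rows = result[result["term"] == term]
            found = bool(len(rows)) and bool(rows.iloc[0]["significant"])
        enriched_found[set_name] = found
    steps_ok = {
        step_id: sorted(recon[step_id]["retained"]) == sorted(expected)
        for step_id, expected in truth.step_truth.items()
        if step_id in recon
    }
    return {
        "fragment_precision": precision,
        "fragment_recall": recall,
        "retained_member_correct": retained_ok,
        "n_detected_pairs": len(merge.pairs),
        "n_true_pairs": len(truth.pairs),
        "stage_classification_accuracy": stage_accuracy,
        "chosen_k": cluster_result.chosen_k,
        "cluster_ari": ari,
        "enriched_term_recovered": enriched_found,
        "pathway_steps_correct": steps_ok,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def config_from_dict(payload: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain (JSON) dict of overrides."""
    synth_payload = payload.pop("synth", {})
    synth = SynthConfig(**{**{}, **synth_payload})
    if "cluster_sizes" in synth_payload:
        synth.cluster_sizes = tuple(synth_payload["cluster_sizes"])
    cfg = PipelineConfig(synth=synth)
    for key, value in payload.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown configuration key {key!r}")
        setattr(cfg, key, tuple(value) if key == "k_range" else value)
    return cfg


def config_to_dict(config: PipelineConfig) -> dict:
    payload = asdict(config)
    payload["k_range"] = list(config.k_range)
    payload["synth"]["cluster_sizes"] = list(config.synth.cluster_sizes)
    return payload
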