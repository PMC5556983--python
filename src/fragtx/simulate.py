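"""Synthetic study generator with planted, recoverable structure.

Generates a complete miniature study — FPKM matrix over the twelve
canonical time points, gene models on scaffolds, annotation table,
GO DAG, homology hit tables and step definitions — together with the
planted truth used to validate every downstream stage: fragment pairs
(one latent profile split over two margin gene models with
complementary truncated domain hits), stage-responsive genes (effect
only at their stage's time points), housekeeping genes (flat, with an
optional transient resupply excursion), profile clusters within a
lipase-like gene family, and one GO term planted at elevated frequency
in each up-regulated stage set.

The noise model is additive Gaussian on log2 abundance (multiplicative
on FPKM); baselines are lognormal so the abundance range spans several
orders of magnitude, as in real deep mRNA-seq data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .core import (
    MARGIN_NT,
    STAGES,
    TIME_POINTS,
    ConfigError,
    DomainHit,
    LocusRecord,
)
from .enrichment import GoDag
from .pathway import MODEL_ORGANISMS, Step

STAGE_NAMES = tuple(STAGES)

#: stage-sign patterns (e-N, l-N, r+N) assigned cyclically to fragment pairs
PAIR_PATTERNS: tuple[tuple[int, int, int], ...] = (
    (1, 1, 0),
    (0, 1, -1),
    (1, 0, 0),
    (0, 1, 0),
    (-1, -1, 1),
    (0, 0, 1),
)

#: stage-sign patterns of the planted profile clusters (first k are used)
CLUSTER_PATTERNS: tuple[tuple[int, int, int], ...] = (
    (1, 1, -1),
    (-1, -1, 1),
    (0, 1, 0),
    (0, -1, 0),
    (1, 0, 1),
    (-1, 0, 0),
    (0, 0, 1),
)

BP_ROOT = "GO:9000000"
ENRICHED_LEAVES = {
    "up_e-N": "GO:9000010",
    "up_l-N": "GO:9000011",
    "up_r+N": "GO:9000012",
}


@dataclass
class SynthConfig:
    """Study conditions of the synthetic dataset.

    Baseline abundance is lognormal: log2 FPKM ~ N(baseline_logmean,
    baseline_logsd), spanning more than four orders of magnitude at the
    defaults. ``effect_log2fc`` is the planted stage effect;
    ``noise_sd`` the additive Gaussian noise on log2 abundance.
    """

    n_loci: int = 500
    n_scaffolds: int = 40
    scaffold_length: int = 1_000_000
    frac_fragment_pairs: float = 0.08
    responsive_up: dict[str, int] = field(
        default_factory=lambda: {"e-N": 25, "l-N": 25, "r+N": 25}
    )
    responsive_down: dict[str, int] = field(
        default_factory=lambda: {"e-N": 25, "l-N": 25, "r+N": 25}
    )
    n_housekeeping: int = 40
    n_profile_clusters: int = 4
    cluster_sizes: tuple[int, ...] = (12, 15, 18, 10)
    noise_sd: float = 0.1
    baseline_logmean: float = 3.5
    baseline_logsd: float = 3.3
    effect_log2fc: float = 2.0
    frac_reciprocal_fail: float = 0.25
    seed: int = 1

    @property
    def n_pairs(self) -> int:
        return round(self.frac_fragment_pairs * self.n_loci / 2)

    def validate(self) -> None:
        if not (0.0 <= self.frac_fragment_pairs <= 0.3):
            raise ConfigError("frac_fragment_pairs must lie in [0, 0.3]")
        if not (2 <= self.n_profile_clusters <= 7):
            raise ConfigError("n_profile_clusters must lie in [2, 7]")
        if len(self.cluster_sizes) != self.n_profile_clusters:
            raise ConfigError("cluster_sizes inconsistent with n_profile_clusters")
        if any(s < 2 for s in self.cluster_sizes):
            raise ConfigError("every cluster needs at least 2 members")
        if self.effect_log2fc <= 1.0:
            raise ConfigError("effect_log2fc must exceed 1 to be recoverable")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        planted = (
            2 * self.n_pairs
            + sum(self.responsive_up.values())
            + sum(self.responsive_down.values())
            + self.n_housekeeping
            + sum(self.cluster_sizes)
        )
        if planted > self.n_loci:
            raise ConfigError(
                f"planted-class counts ({planted}) exceed n_loci ({self.n_loci})"
            )
        if 2 * self.n_pairs + 4 > 2 * self.n_scaffolds:
            raise ConfigError("not enough scaffold margins for the fragment pairs")
        if set(self.responsive_up) != set(STAGE_NAMES) or set(
            self.responsive_down
        ) != set(STAGE_NAMES):
            raise ConfigError("responsive counts must cover exactly the three stages")


@dataclass
class SyntheticTruth:
    """Planted labels used as the downstream acceptance oracle."""

    pairs: list[tuple[str, str]]
    retained_member: dict[tuple[str, str], str]
    stage_direction: dict[str, dict[str, str]]
    cluster_id: dict[str, int]
    enriched_terms: dict[str, str]
    housekeeping: list[str]
    step_truth: dict[str, list[str]]

    def to_payload(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "retained_member": {"|".join(p): m for p, m in self.retained_member.items()},
            "stage_direction": self.stage_direction,
            "cluster_id": self.cluster_id,
            "enriched_terms": self.enriched_terms,
            "housekeeping": self.housekeeping,
            "step_truth": self.step_truth,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "SyntheticTruth":
        return cls(
            pairs=[tuple(p) for p in payload["pairs"]],
            retained_member={
                tuple(k.split("|")): v for k, v in payload["retained_member"].items()
            },
            stage_direction=payload["stage_direction"],
            cluster_id={k: int(v) for k, v in payload["cluster_id"].items()},
            enriched_terms=payload["enriched_terms"],
            housekeeping=payload["housekeeping"],
            step_truth=payload["step_truth"],
        )


@dataclass
class SyntheticDataset:
    config: SynthConfig
    matrix: pd.DataFrame
    records: dict[str, LocusRecord]
    dag: GoDag
    forward_table: pd.DataFrame
    reverse_tables: dict[str, pd.DataFrame]
    steps: list[Step]
    truth: SyntheticTruth


def _locus_id(i: int) -> str:
    return f"locus_{i:04d}"


def _build_dag() -> GoDag:
    """A small synthetic is_a DAG: one BP root, 7 mid terms, 40 leaves
    (two of them diamonds), plus a separate molecular_function branch."""
    terms: dict[str, tuple[str, str]] = {
        BP_ROOT: ("biological_process", "biological_process"),
        "GO:9100000": ("molecular_function", "molecular_function"),
        "GO:9100001": ("catalytic activity", "molecular_function"),
    }
    parents: dict[str, set[str]] = {
        BP_ROOT: set(),
        "GO:9100000": set(),
        "GO:9100001": {"GO:9100000"},
    }
    mids = [f"GO:900000{i}" for i in range(1, 8)]
    mid_names = (
        "nitrogen compound metabolic process",
        "lipid metabolic process",
        "carbohydrate metabolic process",
        "photosynthesis",
        "translation",
        "transport",
        "cell cycle",
    )
    for mid, name in zip(mids, mid_names):
        terms[mid] = (name, "biological_process")
        parents[mid] = {BP_ROOT}
    for i in range(40):
        leaf = f"GO:90000{10 + i}"
        terms[leaf] = (f"specific process {i}", "biological_process")
        parents[leaf] = {mids[i % len(mids)]}
        if i in (20, 21):  # diamond: two parents
            parents[leaf].add(mids[(i + 1) % len(mids)])
    return GoDag(terms=terms, parents=parents)


def _stage_effect_row(pattern: tuple[int, int, int], effect: float) -> dict[str, float]:
    row = {tp: 0.0 for tp in TIME_POINTS}
    for sign, stage in zip(pattern, STAGE_NAMES):
        for tp in STAGES[stage]:
            row[tp] = sign * effect
    return row


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate the full synthetic study; fully determined by config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    ids = [_locus_id(i) for i in range(n)]

    # ---- assign planted classes in fixed order
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        chunk = ids[cursor : cursor + k]
        cursor += k
        return chunk

    pair_members = take(2 * config.n_pairs)
    pairs = [
        (pair_members[2 * i], pair_members[2 * i + 1]) for i in range(config.n_pairs)
    ]
    responsive: dict[tuple[str, str], list[str]] = {}
    for stage in STAGE_NAMES:
        responsive[(stage, "up")] = take(config.responsive_up[stage])
    for stage in STAGE_NAMES:
        responsive[(stage, "down")] = take(config.responsive_down[stage])
    housekeeping = take(config.n_housekeeping)
    cluster_members: dict[int, list[str]] = {}
    for c, size in enumerate(config.cluster_sizes, start=1):
        cluster_members[c] = take(size)
    background = ids[cursor:]

    # ---- latent log2 profiles
    baseline = rng.normal(config.baseline_logmean, config.baseline_logsd, size=n)
    planted_floor = config.effect_log2fc + 1.0
    latent = pd.DataFrame(0.0, index=ids, columns=list(TIME_POINTS))
    stage_direction: dict[str, dict[str, str]] = {}

    def plant(locus: str, pattern: tuple[int, int, int]) -> None:
        row = _stage_effect_row(pattern, config.effect_log2fc)
        for tp, eff in row.items():
            latent.loc[locus, tp] += eff
        stage_direction[locus] = {
            stage: {1: "up", -1: "down", 0: "none"}[sign]
            for sign, stage in zip(pattern, STAGE_NAMES)
        }

    idx_of = {locus: i for i, locus in enumerate(ids)}
    for locus in (
        pair_members
        + [l for v in responsive.values() for l in v]
        + housekeeping
        + [l for v in cluster_members.values() for l in v]
    ):
        i = idx_of[locus]
        baseline[i] = max(baseline[i], planted_floor)

    for p, (a, b) in enumerate(pairs):
        pattern = PAIR_PATTERNS[p % len(PAIR_PATTERNS)]
        baseline[idx_of[b]] = baseline[idx_of[a]]  # members share one latent profile
        plant(a, pattern)
        plant(b, pattern)
    for stage in STAGE_NAMES:
        for locus in responsive[(stage, "up")]:
            plant(locus, tuple(1 if s == stage else 0 for s in STAGE_NAMES))
        for locus in responsive[(stage, "down")]:
            plant(locus, tuple(-1 if s == stage else 0 for s in STAGE_NAMES))
    for k, locus in enumerate(housekeeping):
        stage_direction[locus] = {s: "none" for s in STAGE_NAMES}
        if k % 2 == 0:  # transient resupply excursion at R_2 only
            latent.loc[locus, "R_2"] += 1.5
    for c, members in cluster_members.items():
        pattern = CLUSTER_PATTERNS[(c - 1) % len(CLUSTER_PATTERNS)]
        for locus in members:
            plant(locus, pattern)

    latent = latent.add(pd.Series(baseline, index=ids), axis=0)
    noise = rng.normal(0.0, config.noise_sd, size=latent.shape) if config.noise_sd > 0 else 0.0
    matrix = np.power(2.0, latent + noise)
    matrix = pd.DataFrame(matrix, index=ids, columns=list(TIME_POINTS))
    matrix.index.name = "locus_id"

    # ---- geometry: pairs at scaffold margins, everything else interior
    L = config.scaffold_length
    records: dict[str, LocusRecord] = {}
    margin_slots = [(s, side) for s in range(config.n_scaffolds) for side in ("R", "L")]
    slot_i = 0

    def place_margin(locus: str) -> tuple[str, int, int]:
        nonlocal slot_i
        s, side = margin_slots[slot_i]
        slot_i += 1
        off = int(rng.integers(0, MARGIN_NT + 1))
        length = int(rng.integers(800, 1500))
        if side == "L":
            start = 1 + off
            end = start + length
        else:
            end = L - off
            start = end - length
        return f"scaffold_{s:04d}", start, end

    interior_cursor: dict[int, int] = {}

    def place_interior(locus: str) -> tuple[str, int, int]:
        s = idx_of[locus] % config.n_scaffolds
        pos = interior_cursor.get(s, 2000)
        interior_cursor[s] = pos + 3000
        length = int(rng.integers(800, 2500))
        return f"scaffold_{s:04d}", pos, pos + length

    localizations = np.array(["C", "M", "S", "O"])

    def base_record(locus: str, margin: bool, **kw) -> LocusRecord:
        scaffold, start, end = place_margin(locus) if margin else place_interior(locus)
        defaults = dict(
            locus_id=locus,
            scaffold_id=scaffold,
            start=start,
            end=end,
            scaffold_length=L,
            strand="+" if rng.random() < 0.5 else "-",
            has_start_codon=True,
            defline="hypothetical protein",
            go_ids=frozenset(),
            domain_hits=(),
            localization=str(rng.choice(localizations)),
        )
        defaults.update(kw)
        return LocusRecord(**defaults)

    for p, (a, b) in enumerate(pairs):
        dom = f"pd{p:04d}"
        records[a] = base_record(
            a,
            margin=True,
            defline=f"enzyme candidate {p}, fragment",
            domain_hits=(DomainHit(dom, "C"),),  # N-terminal half present
            has_start_codon=True,
        )
        records[b] = base_record(
            b,
            margin=True,
            defline=f"enzyme candidate {p}, fragment",
            domain_hits=(DomainHit(dom, "N"),),
            has_start_codon=False,
            localization="NA",
        )
    for stage in STAGE_NAMES:
        for direction in ("up", "down"):
            for j, locus in enumerate(responsive[(stage, direction)]):
                records[locus] = base_record(
                    locus,
                    margin=False,
                    defline=f"{stage} {direction}-responsive protein {j}",
                )
    for j, locus in enumerate(housekeeping):
        records[locus] = base_record(
            locus, margin=False, defline=f"40S ribosomal protein S{j}"
        )
    for c, members in cluster_members.items():
        for j, locus in enumerate(members):
            records[locus] = base_record(
                locus,
                margin=False,
                defline=f"putative lipase, class {c} family protein {j}",
            )
    # margin decoys among the background: same-side truncations or no domains
    decoys = background[:4]
    for j, locus in enumerate(decoys):
        hits = (DomainHit("dx0001", "C"),) if j < 2 else ()
        records[locus] = base_record(
            locus, margin=True, defline="hypothetical protein, scaffold margin", domain_hits=hits
        )
    for locus in background[4:]:
        records[locus] = base_record(locus, margin=False)

    # ---- GO annotations
    dag = _build_dag()
    leaves = [f"GO:90000{10 + i}" for i in range(40)]
    go_direct: dict[str, set[str]] = {locus: set() for locus in ids}
    planted_terms = set(ENRICHED_LEAVES.values())
    free_leaves = [t for t in leaves if t not in planted_terms]
    for locus in ids:
        k = int(rng.integers(1, 3))
        go_direct[locus].update(rng.choice(free_leaves, size=k, replace=False))
        for term in planted_terms:  # background frequency
            if rng.random() < 0.05:
                go_direct[locus].add(term)
    for stage in STAGE_NAMES:
        term = ENRICHED_LEAVES[f"up_{stage}"]
        for locus in responsive[(stage, "up")]:
            if rng.random() < 0.8:
                go_direct[locus].add(term)
    for locus, rec in records.items():
        rec.go_ids = frozenset(go_direct[locus])

    # ---- pathway steps and hit tables
    step_defs: list[tuple[str, list[str], str]] = []  # (step, valid candidates, domain)
    pair0 = pairs[0] if pairs else None
    if pair0 is not None:
        step_defs.append(("PRK", [pair0[0], pair0[1]], "pd0000"))
    fat_cands = background[4:6]
    step_defs.append(("FAT", list(fat_cands), "cdFAT"))
    acx_cands = background[6:7]
    step_defs.append(("ACX", list(acx_cands), "cdACX"))
    domain_fail = background[7:8]
    decoy_pool = list(background[8:])

    for step_id, cands, dom in step_defs:
        for locus in cands:
            if dom.startswith("cd"):
                records[locus].domain_hits = records[locus].domain_hits + (
                    DomainHit(dom, "none"),
                )

    steps: list[Step] = []
    fwd_rows: list[dict] = []
    rev_rows: dict[str, list[dict]] = {org: [] for org in MODEL_ORGANISMS}
    step_truth: dict[str, list[str]] = {}
    decoy_i = 0
    frac = config.frac_reciprocal_fail
    for step_id, cands, dom in step_defs:
        templates = {
            MODEL_ORGANISMS[0]: frozenset({f"AT_{step_id}1"}),
            MODEL_ORGANISMS[1]: frozenset({f"CRE_{step_id}1"}),
        }
        steps.append(
            Step(step_id=step_id, templates=templates, required_domains=frozenset({dom}))
        )
        n_fail = round(frac * len(cands) / (1.0 - frac)) if frac < 1.0 else len(cands)
        failing = decoy_pool[decoy_i : decoy_i + n_fail]
        decoy_i += n_fail
        all_cands = list(cands) + failing
        if step_id == "FAT" and domain_fail:
            all_cands += domain_fail  # passes reciprocity, lacks the domain
        for rank, locus in enumerate(all_cands):
            fwd_rows.append(
                {
                    "qseqid": step_id,
                    "sseqid": locus,
                    "evalue": 1e-50 * (rank + 1),
                    "bitscore": 500.0 - rank,
                }
            )
        for locus in all_cands:
            fails = locus in failing
            for org in MODEL_ORGANISMS:
                best = f"{'AT' if org == MODEL_ORGANISMS[0] else 'CRE'}_{step_id}1"
                if fails:
                    best = f"{'AT' if org == MODEL_ORGANISMS[0] else 'CRE'}_OTHER"
                rev_rows[org].append(
                    {"qseqid": locus, "sseqid": best, "evalue": 1e-40, "bitscore": 400.0}
                )
                rev_rows[org].append(
                    {"qseqid": locus, "sseqid": "UNRELATED", "evalue": 1e-5, "bitscore": 50.0}
                )
        if step_id == "PRK" and pair0 is not None:
            step_truth[step_id] = [pair0[0]]  # pair collapses to its 5' member
        else:
            step_truth[step_id] = sorted(cands)

    forward_table = pd.DataFrame(fwd_rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])
    reverse_tables = {
        org: pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])
        for org, rows in rev_rows.items()
    }

    truth = SyntheticTruth(
        pairs=pairs,
        retained_member={tuple(sorted(p)): p[0] for p in pairs},
        stage_direction=stage_direction,
        cluster_id={
            locus: c for c, members in cluster_members.items() for locus in members
        },
        enriched_terms=dict(ENRICHED_LEAVES),
        housekeeping=list(housekeeping),
        step_truth=step_truth,
    )
    return SyntheticDataset(
        config=config,
        matrix=matrix,
        records=records,
        dag=dag,
        forward_table=forward_table,
        reverse_tables=reverse_tables,
        steps=steps,
        truth=truth,
    )


REVERSE_FILE_NAMES = {
    "A.thaliana": "hits_reverse_athaliana.tsv",
    "C.reinhardtii": "hits_reverse_creinhardtii.tsv",
}


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write every component of the dataset; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_expression(dataset.matrix, out / "expression.tsv")
    fio.write_gene_models(dataset.records, out / "models.gff3")
    fio.write_annotations(dataset.records, out / "annotations.tsv")
    fio.write_obo(dataset.dag, out / "ontology.obo")
    fio.write_hit_table(dataset.forward_table, out / "hits_forward.tsv")
    for org, table in dataset.reverse_tables.items():
        fio.write_hit_table(table, out / REVERSE_FILE_NAMES[org])
    from .pathway import write_steps

    write_steps(dataset.steps, out / "steps.tsv")
    fio.write_json(dataset.truth.to_payload(), out / "truth.json")
    files = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": dataset.config.seed,
        "config": _config_payload(dataset.config),
        "files": {name: _sha256(out / name) for name in files},
    }
    fio.write_json(manifest, out / "manifest.json")
    return manifest


def _config_payload(config: SynthConfig) -> dict:
    payload = asdict(config)
    payload["cluster_sizes"] = list(config.cluster_sizes)
    return payload


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path, encoding="utf-8") as fh:
        return SyntheticTruth.from_payload(json.load(fh))
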