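"""Candidate validation for metabolic-pathway reconstruction.

For each enzymatic step, forward homology hits yield a candidate locus
list. A candidate survives only if (1) its best reverse hit in each of
the two model organisms maps back to the step's template enzymes
(reciprocal validation), and (2) its predicted domain hits include a
domain required by the step (truncated hits count). Finally, fragment
pairs inside the surviving list are collapsed to their 5' member,
giving the minimal candidate list per step with full per-filter
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import MARGIN_NT, PEARSON_THRESHOLD, FragtxError, LocusRecord
from .fragments import MergeMap, detect_fragment_pairs

MODEL_ORGANISMS = ("A.thaliana", "C.reinhardtii")


@dataclass(frozen=True)
class Step:
    """One enzymatic step: template enzymes per organism + required domains."""

    step_id: str
    templates: dict[str, frozenset[str]] = field(default_factory=dict)
    required_domains: frozenset[str] = frozenset()


@dataclass
class StepCandidateList:
    """Validated candidates of one step with per-filter provenance.

    ``provenance`` maps every input candidate to exactly one of
    ``retained``, ``failed-reciprocal``, ``failed-domain`` or
    ``collapsed-into-pair``.
    """

    step_id: str
    retained: list[str]
    provenance: dict[str, str]
    merge_map: MergeMap


def read_steps(path: str | Path) -> list[Step]:
    """Read step definitions from a TSV (step_id, organism, template_ids,
    required_domains; ids semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    steps: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        entry = steps.setdefault(
            row.step_id, {"templates": {}, "domains": set()}
        )
        entry["templates"][row.organism] = frozenset(
            t for t in row.template_ids.split(";") if t and t != "."
        )
        entry["domains"].update(
            d for d in row.required_domains.split(";") if d and d != "."
        )
    return [
        Step(step_id=sid, templates=e["templates"], required_domains=frozenset(e["domains"]))
        for sid, e in sorted(steps.items())
    ]


def write_steps(steps: list[Step], path: str | Path) -> None:
    rows = []
    for step in steps:
        for organism, templates in sorted(step.templates.items()):
            rows.append(
                {
                    "step_id": step.step_id,
                    "organism": organism,
                    "template_ids": ";".join(sorted(templates)) or ".",
                    "required_domains": ";".join(sorted(step.required_domains)) or ".",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def best_hit(table: pd.DataFrame, query: str) -> str | None:
    """Rank-1 subject for a query: lowest e-value, then highest bit-score,
    then lexicographically smallest subject id."""
    rows = table[table["qseqid"] == query]
    if rows.empty:
        return None
    rows = rows.sort_values(
        ["evalue", "bitscore", "sseqid"], ascending=[True, False, True], kind="stable"
    )
    return str(rows.iloc[0]["sseqid"])


def forward_candidates(step: Step, forward_table: pd.DataFrame) -> list[str]:
    """Candidate loci of a step: subjects of forward hits queried by the step."""
    rows = forward_table[forward_table["qseqid"] == step.step_id]
    return sorted(set(rows["sseqid"].astype(str)))


def validate_reciprocal(
    candidate: str,
    step: Step,
    reverse_tables: dict[str, pd.DataFrame],
    require_all: bool = True,
) -> tuple[bool, str]:
    """Reciprocal-hit validation against the model organisms.

    With ``require_all`` (default) the best reverse hit must map to the
    step's templates in every organism; otherwise one organism suffices.
    Returns (flag, reason).
    """
    verdicts = []
    for organism, templates in step.templates.items():
        table = reverse_tables.get(organism)
        if table is None:
            raise FragtxError(f"missing reverse table for {organism}")
        top = best_hit(table, candidate)
        if top is None:
            verdicts.append((False, f"no reverse hit in {organism}"))
        elif top in templates:
            verdicts.append((True, ""))
        else:
            verdicts.append((False, f"best reverse hit in {organism} is {top}"))
    if require_all:
        ok = all(v for v, _ in verdicts)
    else:
        ok = any(v for v, _ in verdicts)
    reason = "; ".join(r for v, r in verdicts if not v)
    return ok, reason if not ok else ""


def validate_domain(record: LocusRecord, step: Step) -> bool:
    """True iff the candidate carries a required domain (truncated counts)."""
    return bool(record.domain_ids & step.required_domains)


def reconstruct_step(
    step: Step,
    forward_table: pd.DataFrame,
    reverse_tables: dict[str, pd.DataFrame],
    records: dict[str, LocusRecord],
    matrix: pd.DataFrame,
    r_threshold: float = PEARSON_THRESHOLD,
    margin: int = MARGIN_NT,
    require_all: bool = True,
) -> StepCandidateList:
    """Run the full filter chain for one enzymatic step."""
    candidates = forward_candidates(step, forward_table)
    provenance: dict[str, str] = {}
    surviving: list[str] = []
    for cand in candidates:
        ok, _reason = validate_reciprocal(cand, step, reverse_tables, require_all)
        if not ok:
            provenance[cand] = "failed-reciprocal"
            continue
        if cand not in records or not validate_domain(records[cand], step):
            provenance[cand] = "failed-domain"
            continue
        surviving.append(cand)
    merge_map = detect_fragment_pairs(
        matrix.loc[[c for c in surviving if c in matrix.index]],
        records,
        r_threshold=r_threshold,
        margin=margin,
        candidates=set(surviving),
    )
    dropped = merge_map.dropped
    retained = [c for c in surviving if c not in dropped]
    for cand in surviving:
        provenance[cand] = "collapsed-into-pair" if cand in dropped else "retained"
    return StepCandidateList(
        step_id=step.step_id,
        retained=retained,
        provenance=provenance,
        merge_map=merge_map,
    )
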