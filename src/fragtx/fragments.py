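"""Detection and collapse of gene-fragment pairs.

Draft-genome assemblies split genes across scaffold margins, so one
true gene can appear as two gene models ("fragments") whose transcript
profiles are near-identical. A pair is called when three criteria hold:
(1) Pearson correlation of the log2(FPKM + 1) profiles over all twelve
time points exceeds 0.9, (2) both gene models lie within 500 nt of a
scaffold margin, and (3) the two models carry complementary C- and
N-terminally truncated hits to a shared domain. Of a detected pair only
the 5'-most fragment — the one carrying the start codon — is retained,
because it encodes the putative targeting peptide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core import (
    MARGIN_NT,
    PEARSON_THRESHOLD,
    FragtxError,
    LocusRecord,
)


class ConstantProfileError(FragtxError):
    """Correlation is undefined for a constant profile."""


@dataclass
class MergeMap:
    """Detected fragment pairs and the retained member of each.

    ``retained`` maps the (sorted) pair tuple to the retained locus id;
    ``dropped`` holds the other member of every pair.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)
    retained: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def dropped(self) -> set[str]:
        out = set()
        for pair in self.pairs:
            keep = self.retained[pair]
            out.update(m for m in pair if m != keep)
        return out

    @property
    def paired_ids(self) -> set[str]:
        return {m for pair in self.pairs for m in pair}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": [
                {"members": list(pair), "retained": self.retained[pair]}
                for pair in self.pairs
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MergeMap":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        mm = cls()
        for entry in payload["pairs"]:
            pair = tuple(sorted(entry["members"]))
            mm.pairs.append(pair)
            mm.retained[pair] = entry["retained"]
        return mm


def profile_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two abundance profiles after log2(FPKM + 1).

    Raises
    ------
    ConstantProfileError
        if either transformed profile is constant.
    """
    x = np.log2(np.asarray(x, dtype=float) + 1.0)
    y = np.log2(np.asarray(y, dtype=float) + 1.0)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ConstantProfileError("correlation undefined for a constant profile")
    return float(pearsonr(x, y).statistic)


def is_margin_gene(rec: LocusRecord, margin: int = MARGIN_NT) -> bool:
    """True iff the gene model lies within ``margin`` nt of a scaffold end."""
    return rec.margin_distance <= margin


def domains_compatible(a: LocusRecord, b: LocusRecord) -> bool:
    """True iff the two models share a domain with complementary truncation.

    Complementary means one hit is C-terminally truncated and the other
    N-terminally truncated — the split halves of one full-length domain.
    """
    hits_a = {(h.domain_id, h.truncation) for h in a.domain_hits}
    hits_b = {(h.domain_id, h.truncation) for h in b.domain_hits}
    for dom, trunc in hits_a:
        other = {"C": "N", "N": "C"}.get(trunc)
        if other and (dom, other) in hits_b:
            return True
    return False


def _retention_choice(pair: tuple[str, str], records: dict[str, LocusRecord]) -> str:
    """Pick the 5'-most member: start codon, then N-terminally intact domain,
    then lexicographically smaller id."""
    a, b = pair
    ra, rb = records[a], records[b]
    if ra.has_start_codon != rb.has_start_codon:
        return a if ra.has_start_codon else b
    shared = ra.domain_ids & rb.domain_ids
    # a C-truncated hit keeps the N-terminal part of the domain
    a_nterm = any(h.domain_id in shared and h.truncation == "C" for h in ra.domain_hits)
    b_nterm = any(h.domain_id in shared and h.truncation == "C" for h in rb.domain_hits)
    if a_nterm != b_nterm:
        return a if a_nterm else b
    return min(a, b)


def detect_fragment_pairs(
    matrix: pd.DataFrame,
    records: dict[str, LocusRecord],
    r_threshold: float = PEARSON_THRESHOLD,
    margin: int = MARGIN_NT,
    candidates: set[str] | None = None,
) -> MergeMap:
    """Three-step fragment-pair detection with greedy 1-to-1 matching.

    Candidate pairs are margin genes sharing at least one domain id
    (optionally restricted to ``candidates``, e.g. one enzymatic step's
    candidate list); pairs must have correlation > ``r_threshold`` and
    complementary truncations. Matching is greedy by descending
    correlation, ties broken lexicographically, so no locus joins two
    pairs and the result is independent of input row order.
    """
    loci = [l for l in matrix.index if candidates is None or l in candidates]
    missing = [l for l in loci if l not in records]
    if missing:
        raise FragtxError(f"loci without records: {missing[:5]}")
    margin_loci = sorted(
        l for l in loci if records[l].domain_hits and is_margin_gene(records[l], margin)
    )
    # group by shared domain to keep the candidate universe small
    scored: list[tuple[float, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for a, b in combinations(margin_loci, 2):
        ra, rb = records[a], records[b]
        if not (ra.domain_ids & rb.domain_ids):
            continue
        if not domains_compatible(ra, rb):
            continue
        pair = (a, b)
        if pair in seen:
            continue
        seen.add(pair)
        try:
            r = profile_correlation(
                matrix.loc[a].to_numpy(), matrix.loc[b].to_numpy()
            )
        except ConstantProfileError:
            continue
        if r > r_threshold:
            scored.append((r, a, b))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    merge = MergeMap()
    used: set[str] = set()
    for _, a, b in scored:
        if a in used or b in used:
            continue
        used.update((a, b))
        pair = (a, b)
        merge.pairs.append(pair)
        merge.retained[pair] = _retention_choice(pair, records)
    return merge


def collapse(matrix: pd.DataFrame, merge_map: MergeMap) -> pd.DataFrame:
    """Drop the non-retained member of every pair from the matrix."""
    dropped = merge_map.dropped
    missing = merge_map.paired_ids - set(matrix.index)
    if missing:
        raise FragtxError(f"merge map references loci absent from matrix: {sorted(missing)[:5]}")
    return matrix.drop(index=sorted(dropped))


def pair_precision_recall(
    detected: MergeMap, true_pairs: set[tuple[str, str]]
) -> tuple[float, float]:
    """Precision and recall of detected pairs against planted truth."""
    found = {tuple(sorted(p)) for p in detected.pairs}
    truth = {tuple(sorted(p)) for p in true_pairs}
    tp = len(found & truth)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall
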