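"""True-path propagation and hypergeometric over-representation."""

from itertools import combinations

import pytest

from fragtx.core import FragtxError
from fragtx.enrichment import (
    GoDag,
    enrich,
    propagate_annotations,
    term_test,
)


def chain_dag():
    terms = {
        "GO:1": ("root", "biological_process"),
        "GO:2": ("mid", "biological_process"),
        "GO:3": ("leaf", "biological_process"),
    }
    parents = {"GO:1": set(), "GO:2": {"GO:1"}, "GO:3": {"GO:2"}}
    return GoDag(terms=terms, parents=parents)


def diamond_dag():
    terms = {t: (t, "biological_process") for t in ("root", "p1", "p2", "leaf")}
    parents = {
        "root": set(),
        "p1": {"root"},
        "p2": {"root"},
        "leaf": {"p1", "p2"},
    }
    return GoDag(terms=terms, parents=parents)


def test_propagation_chain_and_fixpoint():
    dag = chain_dag()
    out = propagate_annotations({"g": {"GO:3"}, "h": {"GO:1"}}, dag)
    assert out["g"] == {"GO:1", "GO:2", "GO:3"}
    assert out["h"] == {"GO:1"}  # root is a fixpoint


def test_propagation_diamond_set_semantics_and_idempotence():
    dag = diamond_dag()
    once = propagate_annotations({"g": {"leaf"}}, dag)
    assert once["g"] == {"root", "p1", "p2", "leaf"}
    twice = propagate_annotations({k: set(v) for k, v in once.items()}, dag)
    assert twice == once


def test_propagation_unknown_term_is_error():
    with pytest.raises(FragtxError):
        propagate_annotations({"g": {"GO:404"}}, chain_dag())


def test_cyclic_dag_rejected():
    terms = {t: (t, "biological_process") for t in ("a", "b")}
    with pytest.raises(ValueError):
        GoDag(terms=terms, parents={"a": {"b"}, "b": {"a"}})


def enumeration_p(set_size, universe_size, term_in_set, term_in_universe):
    """Exhaustive subset enumeration of the hypergeometric upper tail."""
    universe = range(universe_size)
    annotated = set(range(term_in_universe))
    hits = total = 0
    for subset in combinations(universe, set_size):
        total += 1
        if len(annotated.intersection(subset)) >= term_in_set:
            hits += 1
    return hits / total


def test_term_test_matches_enumeration_example():
    # universe 10, term covers 4, set of 3 all annotated: C(4,3)/C(10,3)
    assert term_test(3, 10, 3, 4) == pytest.approx(4 / 120, abs=1e-12)
    assert term_test(3, 10, 3, 4) == pytest.approx(enumeration_p(3, 10, 3, 4), abs=1e-12)


def test_term_test_trivial_tails():
    # a term annotating the whole universe is never enriched
    assert term_test(5, 20, 5, 20) == pytest.approx(1.0)
    # zero observed hits: P(X >= 0) = 1
    assert term_test(3, 10, 0, 4) == pytest.approx(1.0)
    assert term_test(3, 10, 0, 4) == pytest.approx(enumeration_p(3, 10, 0, 4))


def test_term_test_inconsistent_counts():
    with pytest.raises(FragtxError):
        term_test(5, 4, 1, 2)
    with pytest.raises(FragtxError):
        term_test(3, 10, 4, 4)  # more hits than draws


def test_term_test_exhaustive_small_universes():
    for universe in range(2, 9):
        for m in range(universe + 1):
            for n_set in range(1, universe + 1):
                for k in range(0, min(n_set, m) + 1):
                    assert term_test(n_set, universe, k, m) == pytest.approx(
                        enumeration_p(n_set, universe, k, m), abs=1e-12
                    ), (n_set, universe, k, m)


def _flat_dag(n_terms=5):
    terms = {"root": ("root", "biological_process")}
    parents = {"root": set()}
    for i in range(n_terms):
        terms[f"T{i}"] = (f"T{i}", "biological_process")
        parents[f"T{i}"] = {"root"}
    return GoDag(terms=terms, parents=parents)


def test_enrich_flags_planted_term(rng):
    dag = _flat_dag()
    genes = [f"g{i}" for i in range(1000)]
    direct = {}
    gene_set = set(genes[:50])
    for g in genes:
        terms = {t for t in ("T1", "T2", "T3") if rng.random() < 0.1}
        if g in gene_set and rng.random() < 0.8:
            terms.add("T0")
        elif rng.random() < 0.1:
            terms.add("T0")
        terms.add("T4")  # keeps every gene in the universe
        direct[g] = terms
    propagated = propagate_annotations(direct, dag)
    result = enrich(gene_set, propagated, dag)
    row = result[result["term"] == "T0"].iloc[0]
    assert row["significant"]
    assert row["p_value"] < 1e-4
    # root annotates everything, so it can never be enriched
    assert result[result["term"] == "root"].iloc[0]["p_value"] == pytest.approx(1.0)


def test_enrich_set_equals_universe_gives_p_one():
    dag = _flat_dag()
    direct = {f"g{i}": {"T0"} for i in range(10)}
    propagated = propagate_annotations(direct, dag)
    result = enrich(set(direct), propagated, dag)
    assert (result["p_value"] == 1.0).all()


def test_enrich_reports_only_terms_annotated_in_set(rng):
    dag = _flat_dag()
    direct = {f"g{i}": {"T0"} if i < 5 else {"T1"} for i in range(20)}
    propagated = propagate_annotations(direct, dag)
    result = enrich({"g0", "g1"}, propagated, dag)
    assert "T1" not in set(result["term"])


def test_enrich_requires_subset_of_universe():
    dag = _flat_dag()
    propagated = propagate_annotations({"g0": {"T0"}}, dag)
    with pytest.raises(FragtxError):
        enrich({"stranger"}, propagated, dag)


def test_planted_terms_recovered_in_synthetic_study(zero_noise_dataset):
    from fragtx.stages import stage_gene_sets, stage_response

    ds = zero_noise_dataset
    direct = {l: r.go_ids for l, r in ds.records.items()}
    propagated = propagate_annotations(direct, ds.dag)
    universe = {g for g, ts in propagated.items() if ts & ds.dag.bp_terms()}
    sets = stage_gene_sets(stage_response(ds.matrix))
    for set_name, term in ds.truth.enriched_terms.items():
        result = enrich(sets[set_name] & universe, propagated, ds.dag)
        row = result[result["term"] == term]
        assert len(row) == 1 and bool(row.iloc[0]["significant"]), set_name
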