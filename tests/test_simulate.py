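"""The synthetic-study generator: determinism, planted structure, round trips."""

import numpy as np
import pytest

from fragtx import io as fio
from fragtx.core import MARGIN_NT, STAGES, TIME_POINTS, ConfigError
from fragtx.foldchange import fold_change_matrix, is_housekeeping_stable
from fragtx.fragments import is_margin_gene, profile_correlation
from fragtx.simulate import (
    SynthConfig,
    SyntheticTruth,
    generate_dataset,
    read_truth,
    write_dataset,
)


def small_config(**kw):
    defaults = dict(
        n_loci=80,
        n_scaffolds=12,
        frac_fragment_pairs=0.1,
        responsive_up={"e-N": 4, "l-N": 4, "r+N": 4},
        responsive_down={"e-N": 4, "l-N": 4, "r+N": 4},
        n_housekeeping=6,
        n_profile_clusters=3,
        cluster_sizes=(4, 5, 6),
        noise_sd=0.0,
        seed=7,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


def test_dataset_is_deterministic(tmp_path):
    d1 = generate_dataset(small_config())
    d2 = generate_dataset(small_config())
    assert d1.matrix.equals(d2.matrix)
    write_dataset(d1, tmp_path / "x")
    write_dataset(d2, tmp_path / "y")
    for name in sorted(p.name for p in (tmp_path / "x").iterdir()):
        assert (tmp_path / "x" / name).read_bytes() == (tmp_path / "y" / name).read_bytes(), name


def test_planted_effect_is_exact_at_zero_noise():
    ds = generate_dataset(small_config())
    # one planted l-N up locus: stage points at baseline * 2^effect, others at baseline
    locus = next(
        l
        for l, d in ds.truth.stage_direction.items()
        if d == {"e-N": "none", "l-N": "up", "r+N": "none"}
    )
    row = ds.matrix.loc[locus]
    base = row["N_0"]
    for tp in STAGES["l-N"]:
        assert row[tp] == pytest.approx(base * 4.0)  # effect_log2fc = 2
    for tp in STAGES["e-N"] + STAGES["r+N"]:
        assert row[tp] == pytest.approx(base)


def test_pair_members_correlate_perfectly_at_zero_noise():
    ds = generate_dataset(small_config())
    assert ds.truth.pairs, "config plants pairs"
    for a, b in ds.truth.pairs:
        r = profile_correlation(ds.matrix.loc[a].to_numpy(), ds.matrix.loc[b].to_numpy())
        assert r == pytest.approx(1.0)


def test_fragment_placement_and_margin_rule():
    ds = generate_dataset(small_config())
    for a, b in ds.truth.pairs:
        for member in (a, b):
            rec = ds.records[member]
            assert rec.margin_distance <= MARGIN_NT
            assert is_margin_gene(rec)
        # complementary truncations on one shared domain
        ra, rb = ds.records[a], ds.records[b]
        assert ra.domain_ids == rb.domain_ids
        truncs = {ra.domain_hits[0].truncation, rb.domain_hits[0].truncation}
        assert truncs == {"C", "N"}


def test_retained_member_carries_start_codon():
    ds = generate_dataset(small_config())
    for pair, keep in ds.truth.retained_member.items():
        other = next(m for m in pair if m != keep)
        assert ds.records[keep].has_start_codon
        assert not ds.records[other].has_start_codon


def test_truth_pair_count_matches_config():
    cfg = small_config()
    ds = generate_dataset(cfg)
    assert len(ds.truth.pairs) == round(cfg.frac_fragment_pairs * cfg.n_loci / 2)


def test_every_pair_member_in_exactly_one_pair():
    ds = generate_dataset(small_config())
    members = [m for p in ds.truth.pairs for m in p]
    assert len(members) == len(set(members))


def test_housekeeping_satisfies_stability_criterion():
    ds = generate_dataset(small_config())
    fc = fold_change_matrix(ds.matrix)
    for locus in ds.truth.housekeeping:
        assert is_housekeeping_stable(fc.log2fc.loc[locus], fc.na_mask.loc[locus])


def test_matrix_has_canonical_columns_and_positive_values():
    ds = generate_dataset(small_config())
    assert list(ds.matrix.columns) == list(TIME_POINTS)
    assert (ds.matrix.to_numpy() > 0).all()


def test_infeasible_configs_rejected():
    with pytest.raises(ConfigError):
        small_config(n_loci=10).validate()  # planted counts exceed loci
    with pytest.raises(ConfigError):
        small_config(frac_fragment_pairs=0.5).validate()
    with pytest.raises(ConfigError):
        small_config(cluster_sizes=(4, 5)).validate()
    with pytest.raises(ConfigError):
        small_config(effect_log2fc=0.8).validate()
    with pytest.raises(ConfigError):
        small_config(n_profile_clusters=8, cluster_sizes=(2,) * 8).validate()


def test_write_read_round_trip(tmp_path):
    ds = generate_dataset(small_config())
    manifest = write_dataset(ds, tmp_path)
    assert manifest["seed"] == 7
    assert set(manifest["files"]) >= {"expression.tsv", "models.gff3", "truth.json"}
    matrix = fio.read_expression(tmp_path / "expression.tsv")
    assert matrix.equals(ds.matrix)
    models = fio.read_gene_models(tmp_path / "models.gff3")
    assert set(models) == set(ds.records)
    for locus, rec in models.items():
        assert rec.start == ds.records[locus].start
        assert 1 <= rec.start <= rec.end <= rec.scaffold_length
    truth = read_truth(tmp_path / "truth.json")
    assert isinstance(truth, SyntheticTruth)
    assert truth.pairs == [tuple(p) for p in ds.truth.pairs]
    assert truth.stage_direction == ds.truth.stage_direction


def test_go_term_planting_elevates_frequency():
    ds = generate_dataset(small_config(n_loci=200, responsive_up={"e-N": 20, "l-N": 20, "r+N": 20}))
    term = ds.truth.enriched_terms["up_l-N"]
    up_loci = [
        l for l, d in ds.truth.stage_direction.items()
        if d.get("l-N") == "up" and l not in ds.truth.cluster_id
        and all(l not in p for p in ds.truth.pairs)
    ]
    freq_in = np.mean([term in ds.records[l].go_ids for l in up_loci])
    freq_bg = np.mean([term in r.go_ids for r in ds.records.values()])
    assert freq_in > 4 * freq_bg
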