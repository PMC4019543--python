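"""Synthetic-data generator: determinism, planted structure, screening."""

import numpy as np
import pytest

from orthoarray import fixtures, io, probematch
from orthoarray.fixtures import FixtureSpec, largest_remainder_counts


SMALL = dict(n_genes=20, n_probesets=20, core_length=400, flank_length=60,
             n_planted_de=4, n_gene_sets=6, gene_set_size=6, enriched_de_overlap=3)


def test_identical_spec_gives_byte_identical_artifacts(tmp_path):
    spec = FixtureSpec(seed=33, **SMALL)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    fixtures.write_fixture(fixtures.generate(spec), d1)
    fixtures.write_fixture(fixtures.generate(spec), d2)
    for p1 in sorted(d1.rglob("*")):
        p2 = d2 / p1.relative_to(d1)
        if p1.is_file():
            assert p1.read_bytes() == p2.read_bytes(), p1.name


def test_gene_map_covers_every_transcript(small_bundle):
    assert set(small_bundle.gene_map) == {
        t.transcript_id for t in small_bundle.transcripts
    }


def test_gc_content_near_half_at_one_megabase():
    spec = FixtureSpec(seed=4, n_genes=700, core_length=1400, flank_length=100,
                       n_probesets=700, n_planted_de=10)
    rng = np.random.default_rng(spec.seed)
    recs, _ = fixtures.make_transcriptome(spec, rng)
    seq = "".join(r.sequence for r in recs)
    assert len(seq) >= 1_000_000
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.5) <= 0.02


def test_largest_remainder_tier_counts_exact(small_bundle):
    spec = small_bundle.spec
    total = spec.n_probesets * spec.probes_per_set
    expected = largest_remainder_counts(spec.tier_mix, total)
    got = small_bundle.probe_truth["tier"].value_counts().to_dict()
    assert got == {k: v for k, v in expected.items() if v}


def test_planted_exact_probe_found_as_exact(small_bundle):
    truth = small_bundle.probe_truth
    pm = {r.probe_id: r for r in small_bundle.probe_rows if r.role == "PM"}
    row = truth[truth["tier"] == "EXACT"].iloc[0]
    cfg = probematch.MatchConfig()
    idx = probematch.build_index(small_bundle.transcripts, cfg)
    hits = probematch.find_hits(pm[row["probe_id"]], idx, cfg)
    assert any(h.tier == "EXACT" and h.gene_id == row["source_gene"] for h in hits)


def test_no_hit_probes_yield_zero_hits_even_with_rescue(small_bundle):
    truth = small_bundle.probe_truth
    pm = {r.probe_id: r for r in small_bundle.probe_rows if r.role == "PM"}
    cfg = probematch.MatchConfig(rescue_enabled=True)
    idx = probematch.build_index(small_bundle.transcripts, cfg)
    for pid in truth.loc[truth["tier"] == "NO_HIT", "probe_id"]:
        assert probematch.find_hits(pm[pid], idx, cfg) == []


def test_multi_gene_probes_hit_two_genes(small_bundle):
    truth = small_bundle.probe_truth
    pm = {r.probe_id: r for r in small_bundle.probe_rows if r.role == "PM"}
    cfg = probematch.MatchConfig()
    idx = probematch.build_index(small_bundle.transcripts, cfg)
    for _, row in truth[truth["tier"] == "MULTI_GENE"].iterrows():
        genes = {h.gene_id for h in probematch.find_hits(pm[row["probe_id"]], idx, cfg)}
        assert {row["source_gene"], row["secondary_gene"]} <= genes


def test_de_truth_lists_exactly_n_planted(default_bundle):
    assert len(default_bundle.de_truth) == default_bundle.spec.n_planted_de
    assert (default_bundle.de_truth["effect_log2"].abs()
            == default_bundle.spec.de_effect_log2).all()


def _noiseless_run(n_de):
    from orthoarray import rma
    from conftest import build_library_from

    small = dict(SMALL)
    small["n_planted_de"] = n_de
    spec = FixtureSpec(seed=12, noise_sd=0.0, probe_affinity_sd=0.0,
                       optical_background_sd=0.0, **small)
    b = fixtures.generate(spec)
    hits = probematch.find_all_hits(b.probe_rows, b.transcripts)
    lib, _ = build_library_from(b, hits)
    expr = rma.rma_pipeline(b.intensities, lib, rma.RmaConfig(background=False))
    treated = list(b.samples.loc[b.samples.dose == "high", "sample_id"])
    control = list(b.samples.loc[b.samples.dose == "vehicle", "sample_id"])
    est = expr[treated].mean(1) - expr[control].mean(1)
    planted = b.de_truth.set_index("probeset_id")["effect_log2"]
    truth = np.array([planted.get(p, 0.0) for p in expr.index])
    return est.to_numpy(), truth


def test_noiseless_limit_without_effects_is_exact():
    """Zero noise, zero affinity spread, no differential genes: every
    array is identical, quantile normalization is a fixed point, and all
    fold changes come out exactly 1 (log2 difference exactly 0)."""
    est, truth = _noiseless_run(0)
    assert (truth == 0).all()
    np.testing.assert_array_equal(est, 0.0)


def test_noiseless_limit_recovers_planted_effects():
    """With planted effects but no noise the additive model holds exactly,
    so summarization (remap -> log2 -> median polish) reproduces every
    planted effect to the precision of the unit intensity floor.
    Quantile normalization is excluded: on noiseless data a shift that
    crosses no other gene's values is removed entirely by rank mapping,
    which is a property of the normalization, not an error."""
    from orthoarray import rma
    from orthoarray.celremap import remap
    from conftest import build_library_from

    small = dict(SMALL)
    small["n_planted_de"] = 4
    spec = FixtureSpec(seed=12, noise_sd=0.0, probe_affinity_sd=0.0,
                       optical_background_sd=0.0, baseline_log2_mean=12.0,
                       **small)
    b = fixtures.generate(spec)
    hits = probematch.find_all_hits(b.probe_rows, b.transcripts)
    lib, _ = build_library_from(b, hits)
    treated = b.samples["dose"] == "high"
    control = b.samples["dose"] == "vehicle"
    planted = b.de_truth.set_index("probeset_id")["effect_log2"]
    for ps in remap(b.intensities, lib):
        _, _, col, _ = rma.median_polish(np.log2(ps.pm.to_numpy()))
        est = col[treated.to_numpy()].mean() - col[control.to_numpy()].mean()
        assert est == pytest.approx(planted.get(ps.probeset_id, 0.0), abs=1e-3)


def test_gmt_round_trips_through_io(tmp_path, small_bundle):
    p = tmp_path / "sets.gmt"
    io.write_gmt(small_bundle.gene_sets, p)
    assert io.read_gmt(p) == small_bundle.gene_sets


def test_planted_enriched_set_overlap_matches_spec(small_bundle):
    spec = small_bundle.spec
    de = set(small_bundle.de_truth["gene_id"])
    overlap = len(small_bundle.gene_sets[small_bundle.enriched_set_name] & de)
    assert overlap == min(spec.enriched_de_overlap, len(de))


def test_non_planted_sets_background_overlap(default_bundle):
    """Random sets' DE overlaps stay near the hypergeometric expectation."""
    spec = default_bundle.spec
    de = set(default_bundle.de_truth["gene_id"])
    overlaps = [
        len(members & de)
        for name, members in default_bundle.gene_sets.items()
        if name != default_bundle.enriched_set_name
    ]
    expected = spec.gene_set_size * len(de) / spec.n_genes  # = 2 at defaults
    assert np.mean(overlaps) == pytest.approx(expected, abs=1.0)
    assert max(overlaps) < spec.enriched_de_overlap


def test_expression_matrix_fixture_shapes_and_plant():
    expr, labels, informative = fixtures.make_expression_matrix(
        n_transcripts=100, n_per_class=5, n_informative=7, seed=3
    )
    assert expr.shape == (100, 10)
    assert len(informative) == 7
    diffs = expr.loc[informative, labels == 1].mean(1) - \
        expr.loc[informative, labels == 0].mean(1)
    # planted 2-SD shifts dominate the sampling noise of 5v5 group means
    assert diffs.abs().mean() > 1.0
    others = expr.drop(index=informative)
    null = others[labels[labels == 1].index].mean(1) - \
        others[labels[labels == 0].index].mean(1)
    assert abs(null.mean()) < 0.2


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="sum"):
        FixtureSpec(seed=1, tier_mix={"EXACT": 0.5})
    with pytest.raises(ValueError, match="exceed"):
        FixtureSpec(seed=1, n_genes=5, n_probesets=6)
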