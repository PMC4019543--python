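"""Seed-and-extend matcher: tier classification, completeness, properties."""

import numpy as np
import pytest

from orthoarray import fixtures, probematch
from orthoarray.io import ProbeTableRow, TranscriptRecord
from orthoarray.probematch import MatchConfig, build_index, classify_window, find_hits

from oracles import brute_force_hits


def _pm(seq, pid="p1", psid="ps1"):
    return ProbeTableRow(psid, pid, 0, 0, 13, seq, "PM")


def _mutate(seq, pos, rng=None):
    repl = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return seq[:pos] + repl[seq[pos]] + seq[pos + 1 :]


@pytest.fixture(scope="module")
def transcriptome(request):
    rng = np.random.default_rng(99)
    recs = []
    for i in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        recs.append(TranscriptRecord(f"t{i:02d}", f"g{i % 12:02d}", seq))
    return recs


class TestClassifyWindow:
    CFG = MatchConfig()

    def test_exact(self):
        w = "ACGTACGTACGTACGTACGTACGTA"
        assert classify_window(w, w, self.CFG) == ("EXACT", 0, 25, 0, 0)

    def test_end_mismatch_left_two(self):
        w = "ACGTACGTACGTACGTACGTACGTA"
        probe = _mutate(_mutate(w, 0), 1)
        tier, start, length, left, right = classify_window(probe, w, self.CFG)
        assert (tier, start, length, left, right) == ("END_MM", 2, 23, 2, 0)

    def test_end_mismatch_both_ends(self):
        w = "ACGTACGTACGTACGTACGTACGTA"
        probe = _mutate(_mutate(w, 0), 24)
        tier, _, length, left, right = classify_window(probe, w, self.CFG)
        assert (tier, length, left, right) == ("END_MM", 23, 1, 1)

    def test_tandem_internal_flank_mismatches(self):
        w = "ACGTACGTACGTACGTACGTACGTA"
        probe = _mutate(_mutate(w, 1), 23)
        tier, start, length, _, _ = classify_window(probe, w, self.CFG)
        assert (tier, start, length) == ("TANDEM", 2, 21)

    def test_three_terminal_mismatches_need_rescue(self):
        w = "ACGTACGTACGTACGTACGTACGTA"
        probe = _mutate(_mutate(_mutate(w, 0), 1), 2)
        # core 22 < min_tandem is false (22 >= 20) -> TANDEM, not END_MM
        tier, _, length, _, _ = classify_window(probe, w, self.CFG)
        assert (tier, length) == ("TANDEM", 22)
        # with seven terminal mismatches only the rescue tier can fire
        probe7 = w
        for pos in (0, 1, 2, 3, 22, 23, 24):
            probe7 = _mutate(probe7, pos)
        assert classify_window(probe7, w, self.CFG) is None
        rescued = classify_window(probe7, w, MatchConfig(rescue_enabled=True))
        assert rescued == ("RESCUE", 4, 18, 4, 3)

    def test_n_in_transcript_never_matches(self):
        w = "ACGTACGTACGTACGTACGTACGTA"
        window = "N" + w[1:]
        tier, _, _, left, _ = classify_window(w, window, self.CFG)
        assert (tier, left) == ("END_MM", 1)


class TestSeedIndex:
    def test_homopolymer_counting(self):
        recs = [TranscriptRecord("t1", "g1", "A" * 30)]
        idx = build_index(recs, MatchConfig())
        assert len(idx.positions["A" * 20]) == 11

    def test_short_transcript_skipped(self, caplog):
        recs = [TranscriptRecord("t1", "g1", "ACGTACGT")]
        idx = build_index(recs, MatchConfig())
        assert idx.positions == {}

    def test_small_seed_refused(self):
        recs = [TranscriptRecord("t1", "g1", "A" * 30)]
        with pytest.raises(ValueError, match="seed"):
            build_index(recs, MatchConfig(min_tandem=7))

    def test_index_matches_brute_force_enumeration(self, transcriptome):
        cfg = MatchConfig()
        idx = build_index(transcriptome, cfg)
        expected: dict[str, list] = {}
        for t_i, rec in enumerate(transcriptome):
            for pos in range(len(rec.sequence) - cfg.seed_k + 1):
                expected.setdefault(rec.sequence[pos : pos + cfg.seed_k], []).append(
                    (t_i, pos)
                )
        assert idx.positions == expected


class TestFindHits:
    def test_exact_substring_hit(self, transcriptome):
        cfg = MatchConfig()
        idx = build_index(transcriptome, cfg)
        probe = _pm(transcriptome[3].sequence[100:125])
        hits = find_hits(probe, idx, cfg)
        own = [h for h in hits if h.transcript_id == "t03"]
        assert len(own) == 1 and own[0].tier == "EXACT" and own[0].offset == 100

    def test_reverse_complement_hit_recorded_on_minus_strand(self, transcriptome):
        cfg = MatchConfig()
        idx = build_index(transcriptome, cfg)
        probe = _pm(probematch.reverse_complement(transcriptome[5].sequence[40:65]))
        hits = [h for h in find_hits(probe, idx, cfg) if h.transcript_id == "t05"]
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].offset == 40
        # restricting to as-given orientation removes it
        cfg_fwd = MatchConfig(search_reverse_complement=False)
        idx_fwd = build_index(transcriptome, cfg_fwd)
        assert not [
            h for h in find_hits(probe, idx_fwd, cfg_fwd) if h.transcript_id == "t05"
        ]

    def test_no_hits_returns_empty(self, transcriptome):
        cfg = MatchConfig()
        idx = build_index(transcriptome, cfg)
        # NO_HIT-screened probe from the fixtures generator logic
        rng = np.random.default_rng(5)
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=25))
            probe = _pm(seq)
            if not find_hits(probe, idx, cfg):
                break
        assert find_hits(probe, idx, cfg) == []

    def test_deterministic_total_order(self, transcriptome):
        cfg = MatchConfig()
        idx = build_index(transcriptome, cfg)
        probe = _pm(transcriptome[0].sequence[10:35])
        h1 = find_hits(probe, idx, cfg)
        h2 = find_hits(probe, idx, cfg)
        assert h1 == h2 == sorted(h1, key=lambda h: h.sort_key)


def _random_probes(rng, transcripts, n):
    """Planted + mutated + random probes stressing every tier boundary."""
    probes = []
    for i in range(n):
        kind = i % 4
        rec = transcripts[rng.integers(len(transcripts))]
        pos = int(rng.integers(0, len(rec.sequence) - 25))
        window = rec.sequence[pos : pos + 25]
        while "N" in window:  # probes are ACGT-only by design
            pos = int(rng.integers(0, len(rec.sequence) - 25))
            window = rec.sequence[pos : pos + 25]
        if kind == 0:
            seq = window
        elif kind == 1:  # a few scattered mutations
            seq = window
            for p in rng.choice(25, size=rng.integers(1, 6), replace=False):
                seq = _mutate(seq, int(p))
        elif kind == 2:  # reverse-complement planted
            seq = probematch.reverse_complement(window)
        else:
            seq = "".join(rng.choice(list("ACGT"), size=25))
        probes.append(_pm(seq, pid=f"p{i:03d}", psid=f"ps{i // 8:03d}"))
    return probes


@pytest.mark.parametrize(
    "config",
    [
        MatchConfig(),
        MatchConfig(rescue_enabled=True),
        MatchConfig(min_tandem=22, max_end_mismatch=1),
        MatchConfig(search_reverse_complement=False),
    ],
    ids=["default", "rescue", "tight", "forward-only"],
)
def test_find_hits_equals_brute_force(config):
    rng = np.random.default_rng(321)
    transcripts = [
        TranscriptRecord(f"t{i:02d}", f"g{i:02d}",
                         "".join(rng.choice(list("ACGTN"), size=300, p=[0.24] * 4 + [0.04])))
        for i in range(12)
    ]
    probes = _random_probes(rng, transcripts, 48)
    got = {
        (h.probe_id, h.transcript_id, h.offset, h.strand, h.tier)
        for hits in probematch.find_all_hits(probes, transcripts, config).values()
        for h in hits
    }
    assert got == brute_force_hits(probes, transcripts, config)


def test_tightening_config_is_monotone():
    rng = np.random.default_rng(17)
    transcripts = [
        TranscriptRecord(f"t{i}", f"g{i}", "".join(rng.choice(list("ACGT"), size=400)))
        for i in range(10)
    ]
    probes = _random_probes(rng, transcripts, 40)

    def hitset(cfg):
        return {
            (h.probe_id, h.transcript_id, h.offset, h.strand)
            for hits in probematch.find_all_hits(probes, transcripts, cfg).values()
            for h in hits
        }

    loose = hitset(MatchConfig(min_tandem=20, max_end_mismatch=2))
    tighter = hitset(MatchConfig(min_tandem=23, max_end_mismatch=2))
    tightest = hitset(MatchConfig(min_tandem=23, max_end_mismatch=0))
    assert tightest <= tighter <= loose


def test_hits_to_genes_collapses_transcripts_of_one_gene():
    hit = lambda t, g: probematch.ProbeHit("p1", t, g, 0, "+", 0, 25, 0, 0, "EXACT")
    assert probematch.hits_to_genes([hit("t1", "G1"), hit("t2", "G1")]) == {"G1"}
    assert probematch.hits_to_genes([]) == set()
    with pytest.raises(KeyError, match="t9"):
        probematch.hits_to_genes([hit("t9", "G1")], {"t1": "G1"})


def test_hits_to_genes_matches_grouping_oracle(rng):
    gene_of = {f"t{i}": f"G{i % 7}" for i in range(40)}
    hits = [
        probematch.ProbeHit("p1", f"t{rng.integers(40)}", "", 0, "+", 0, 25, 0, 0, "EXACT")
        for _ in range(60)
    ]
    expected = {gene_of[h.transcript_id] for h in hits}
    assert probematch.hits_to_genes(hits, gene_of) == expected
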