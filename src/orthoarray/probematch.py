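"""Seed-and-extend matching of 25-mer PM probes against a cDNA database.

A hit is an ungapped alignment of the full probe to a 25-nt window of a
transcript (offset ∈ [0, len(transcript) − 25]), classified into tiers:

EXACT    all 25 bases match.
END_MM   every mismatch sits at a probe terminus and there are at most
         ``max_end_mismatch`` (default 2) of them — the "one or two
         mismatch bases at the end" class.
TANDEM   the longest contiguous run of matching bases is at least
         ``min_tandem`` (default 20) nucleotides.
RESCUE   every mismatch is terminal and there are at most
         ``rescue_max_end_mismatch`` (default 9); opt-in, modelling the
         manual salvage of probe sets that fail the stricter tiers.

Tier precedence is EXACT > END_MM > TANDEM > RESCUE; each (transcript,
offset, strand) yields at most one hit at its best tier.  ``N`` bases in
transcripts never match any probe base.  The seed index guarantees that
any qualifying hit shares a contiguous exact k-mer with the transcript
(k = min_tandem, or 25 − rescue_max_end_mismatch when rescue is on) and
is therefore discoverable — the completeness contract that replaces an
external word-seeded aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import ProbeTableRow, TranscriptRecord

__all__ = [
    "MatchConfig",
    "ProbeHit",
    "SeedIndex",
    "TIER_RANK",
    "build_index",
    "find_hits",
    "hits_to_genes",
    "classify_window",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

TIER_RANK = {"EXACT": 4, "END_MM": 3, "TANDEM": 2, "RESCUE": 1}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchConfig:
    """Tier thresholds and search options for probe matching."""

    min_tandem: int = 20
    max_end_mismatch: int = 2
    rescue_enabled: bool = False
    rescue_max_end_mismatch: int = 9
    search_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_tandem <= 25):
            raise ValueError("min_tandem must be in [1, 25]")
        if not (0 <= self.max_end_mismatch <= 2):
            raise ValueError("max_end_mismatch must be in [0, 2]")
        if not (0 <= self.rescue_max_end_mismatch < 10):
            raise ValueError("rescue_max_end_mismatch must be in [0, 10)")

    @property
    def seed_k(self) -> int:
        """Seed length preserving completeness for the enabled tiers."""
        k = self.min_tandem
        if self.rescue_enabled:
            k = min(k, 25 - self.rescue_max_end_mismatch)
        return k

    def to_dict(self) -> dict:
        return {
            "min_tandem": self.min_tandem,
            "max_end_mismatch": self.max_end_mismatch,
            "rescue_enabled": self.rescue_enabled,
            "rescue_max_end_mismatch": self.rescue_max_end_mismatch,
            "search_reverse_complement": self.search_reverse_complement,
        }


@dataclass(frozen=True)
class ProbeHit:
    """One classified probe→transcript alignment.

    ``offset`` is the 0-based start of the 25-nt window on the transcript
    (forward coordinates regardless of strand); ``core_start`` is relative
    to the window and refers to the probe in its aligned orientation
    (reverse-complemented for strand '−').  ``n_end_mismatch_left/right``
    count mismatches before/after the core run.
    """

    probe_id: str
    transcript_id: str
    gene_id: str
    offset: int
    strand: str
    core_start: int
    core_len: int
    n_end_mismatch_left: int
    n_end_mismatch_right: int
    tier: str

    @property
    def sort_key(self):
        return (self.probe_id, self.transcript_id, self.offset, self.strand)


@dataclass
class SeedIndex:
    """Exact k-mer index over the forward strands of the transcripts."""

    k: int
    positions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    transcripts: list[TranscriptRecord] = field(default_factory=list)


def build_index(transcripts: Sequence[TranscriptRecord], config: MatchConfig) -> SeedIndex:
    """Index every k-mer occurrence of every transcript (forward strand).

    Reverse-complement search is handled at query time by also seeding
    with the reverse-complemented probe, so a forward index suffices.
    Transcripts shorter than 25 nt can never host a full window and are
    skipped with a warning (as are those shorter than k).
    """
    if not transcripts:
        raise ValueError("transcript database is empty")
    k = config.seed_k
    if k < 8:
        raise ValueError(f"seed length {k} < 8 would blow up the seed table")
    index = SeedIndex(k=k, transcripts=list(transcripts))
    for t_idx, rec in enumerate(transcripts):
        seq = rec.sequence
        if len(seq) < max(k, 25):
            logger.warning(
                "transcript %s length %d shorter than %d; skipped from index",
                rec.transcript_id, len(seq), max(k, 25),
            )
            continue
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            index.positions.setdefault(kmer, []).append((t_idx, pos))
    return index


def classify_window(probe_seq: str, window: str, config: MatchConfig):
    """Classify one probe/window alignment; return None when below all tiers.

    Returns (tier, core_start, core_len, left_mm, right_mm).
    """
    mism = [
        i
        for i in range(25)
        if window[i] == "N" or probe_seq[i] != window[i]
    ]
    if not mism:
        return ("EXACT", 0, 25, 0, 0)

    # Longest contiguous exact run (leftmost on ties).
    best_start, best_len = 0, 0
    prev = -1
    for m in mism + [25]:
        run_len = m - prev - 1
        if run_len > best_len:
            best_start, best_len = prev + 1, run_len
        prev = m

    # Leading/trailing mismatch counts; all-terminal iff they cover mism.
    left = 0
    while left < len(mism) and mism[left] == left:
        left += 1
    right = 0
    while right < len(mism) - left and mism[-1 - right] == 24 - right:
        right += 1
    terminal = (left + right == len(mism)) and (left + right < 25)

    if terminal and 1 <= len(mism) <= config.max_end_mismatch:
        return ("END_MM", left, 25 - left - right, left, right)
    if best_len >= config.min_tandem:
        n_left = sum(1 for m in mism if m < best_start)
        n_right = len(mism) - n_left
        return ("TANDEM", best_start, best_len, n_left, n_right)
    if (
        config.rescue_enabled
        and terminal
        and len(mism) <= config.rescue_max_end_mismatch
    ):
        return ("RESCUE", left, 25 - left - right, left, right)
    return None


def find_hits(
    probe: ProbeTableRow,
    index: SeedIndex,
    config: MatchConfig,
) -> list[ProbeHit]:
    """All qualifying hits of one PM probe, sorted deterministically.

    Every candidate (transcript, offset, strand) discovered through any
    seed is classified once at its best tier.
    """
    if probe.role != "PM":
        raise ValueError(f"find_hits expects a PM probe, got {probe.role}")
    queries = [(probe.sequence, "+")]
    if config.search_reverse_complement:
        queries.append((reverse_complement(probe.sequence), "-"))
    k = index.k
    hits: list[ProbeHit] = []
    for qseq, strand in queries:
        candidates: set[tuple[int, int]] = set()
        for p in range(25 - k + 1):
            kmer = qseq[p : p + k]
            for t_idx, t_pos in index.positions.get(kmer, ()):
                offset = t_pos - p
                if offset < 0:
                    continue
                rec = index.transcripts[t_idx]
                if offset + 25 <= len(rec.sequence):
                    candidates.add((t_idx, offset))
        for t_idx, offset in candidates:
            rec = index.transcripts[t_idx]
            result = classify_window(qseq, rec.sequence[offset : offset + 25], config)
            if result is None:
                continue
            tier, core_start, core_len, left, right = result
            hits.append(
                ProbeHit(
                    probe_id=probe.probe_id,
                    transcript_id=rec.transcript_id,
                    gene_id=rec.gene_id,
                    offset=offset,
                    strand=strand,
                    core_start=core_start,
                    core_len=core_len,
                    n_end_mismatch_left=left,
                    n_end_mismatch_right=right,
                    tier=tier,
                )
            )
    hits.sort(key=lambda h: h.sort_key)
    return hits


def find_all_hits(
    probes: Iterable[ProbeTableRow],
    transcripts: Sequence[TranscriptRecord],
    config: MatchConfig | None = None,
) -> dict[str, list[ProbeHit]]:
    """Match every PM probe; returns probe_id → hit list (may be empty)."""
    config = config or MatchConfig()
    index = build_index(transcripts, config)
    out: dict[str, list[ProbeHit]] = {}
    for probe in probes:
        if probe.role != "PM":
            continue
        out[probe.probe_id] = find_hits(probe, index, config)
    return out


def hits_to_genes(
    hits: Iterable[ProbeHit],
    transcript_gene_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Distinct gene ids hit by one probe.

    Multiple transcripts of one gene count once.  When an explicit map is
    given it must cover every hit transcript.
    """
    genes: set[str] = set()
    for hit in hits:
        if transcript_gene_map is not None:
            if hit.transcript_id not in transcript_gene_map:
                raise KeyError(
                    f"transcript {hit.transcript_id!r} missing from gene map"
                )
            genes.add(transcript_gene_map[hit.transcript_id])
        else:
            genes.add(hit.gene_id)
    return genes
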