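"""Probe-set specificity filtering and cross-species library construction.

Per probe set the selection pipeline is:

1. drop probes whose hits span two or more genes (multi-hit elimination);
2. assign the probe set to the gene with the plurality of remaining
   probes (ties: higher summed tier rank, then smallest gene id);
3. drop probes whose hits point to a gene other than the assigned one
   (the "intermingling" probes);
4. pick the representative transcript of the assigned gene as the one
   hit by the most retained probes (ties: smallest transcript id);
5. reject the probe set when fewer than three probe pairs remain.

The surviving probe sets are then collapsed to one per gene, and the
result is emitted as a versioned JSON "library file" — the virtual array
mapping grid coordinates to cross-species probe sets.  Rejections are
data, never exceptions, so the attrition is fully auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import FormatError, ProbeTableRow
from .probematch import TIER_RANK, MatchConfig, ProbeHit

__all__ = [
    "RetainedProbe",
    "OrthologProbeSet",
    "Rejection",
    "LibraryFile",
    "REJECTION_REASONS",
    "select_probes",
    "collapse_redundancy",
    "build_library",
    "library_summary",
    "write_library",
    "read_library",
    "write_cdf_text",
    "write_rejections_tsv",
    "database_checksum",
]

logger = logging.getLogger(__name__)

LIBRARY_SCHEMA_VERSION = 1

REJECTION_REASONS = ("NO_HITS", "MULTI_GENE", "MIN_PROBES", "REDUNDANT")

MIN_PROBE_PAIRS = 3


@dataclass(frozen=True)
class RetainedProbe:
    probe_id: str
    x: int
    y: int
    tier: str


@dataclass(frozen=True)
class OrthologProbeSet:
    probeset_id: str
    target_gene_id: str
    target_transcript_id: str
    retained_probes: tuple[RetainedProbe, ...]

    @property
    def n_probe_pairs(self) -> int:
        return len(self.retained_probes)

    @property
    def tier_rank_sum(self) -> int:
        return sum(TIER_RANK[p.tier] for p in self.retained_probes)


@dataclass(frozen=True)
class Rejection:
    probeset_id: str
    reason: str
    detail: str = ""

    def __post_init__(self):
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass
class LibraryFile:
    """The virtual array: probe-set → probe-coordinate definitions."""

    name: str
    source_array: str
    target_species: str
    parameters: MatchConfig
    database_checksum: str
    probesets: list[OrthologProbeSet]
    created: str = ""

    def __post_init__(self):
        ids = [ps.probeset_id for ps in self.probesets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate probeset_id in library")
        genes = [ps.target_gene_id for ps in self.probesets]
        if len(set(genes)) != len(genes):
            raise ValueError("library is not one-to-one: duplicate target gene")
        coords = [(p.x, p.y) for ps in self.probesets for p in ps.retained_probes]
        if len(set(coords)) != len(coords):
            raise ValueError("a grid coordinate appears in more than one probe set")
        for ps in self.probesets:
            if ps.n_probe_pairs < MIN_PROBE_PAIRS:
                raise ValueError(
                    f"probe set {ps.probeset_id} has {ps.n_probe_pairs} probe pairs "
                    f"(minimum {MIN_PROBE_PAIRS})"
                )


def database_checksum(transcripts) -> str:
    """Content hash of the cDNA database (id, gene, sequence triples)."""
    h = hashlib.sha256()
    for rec in transcripts:
        h.update(f"{rec.transcript_id}\t{rec.gene_id}\t{rec.sequence}\n".encode())
    return h.hexdigest()


def _probe_gene_sets(
    hits_by_probe: Mapping[str, Sequence[ProbeHit]], best_tier_only: bool
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for pid, hits in hits_by_probe.items():
        if not hits:
            out[pid] = set()
            continue
        if best_tier_only:
            best = max(TIER_RANK[h.tier] for h in hits)
            out[pid] = {h.gene_id for h in hits if TIER_RANK[h.tier] == best}
        else:
            out[pid] = {h.gene_id for h in hits}
    return out


def select_probes(
    probeset_rows: Sequence[ProbeTableRow],
    hits_by_probe: Mapping[str, Sequence[ProbeHit]],
    config: MatchConfig | None = None,
) -> OrthologProbeSet | Rejection:
    """Apply the five-step specificity rule to one probe set.

    ``probeset_rows`` are the PM rows of a single probe set;
    ``hits_by_probe`` maps each PM probe_id to its classified hits.
    """
    config = config or MatchConfig()
    pm_rows = [r for r in probeset_rows if r.role == "PM"]
    if not pm_rows:
        raise ValueError("probe set has no PM rows")
    psid = pm_rows[0].probeset_id
    if any(r.probeset_id != psid for r in pm_rows):
        raise ValueError("rows from multiple probe sets passed to select_probes")

    hits = {r.probe_id: list(hits_by_probe.get(r.probe_id, [])) for r in pm_rows}
    if all(not h for h in hits.values()):
        return Rejection(psid, "NO_HITS", "no probe has any qualifying hit")

    # Step 1: multi-hit elimination at the gene level.
    gene_sets = _probe_gene_sets(hits, best_tier_only=False)
    single = [r for r in pm_rows if len(gene_sets[r.probe_id]) == 1]
    if not single and config.rescue_enabled:
        # Rescue-mode retention: when every probe is multi-gene, judge
        # specificity on each probe's best-tier hits only.
        gene_sets = _probe_gene_sets(hits, best_tier_only=True)
        single = [r for r in pm_rows if len(gene_sets[r.probe_id]) == 1]
    if not single:
        return Rejection(psid, "MULTI_GENE", "every hit probe matches >=2 genes")

    # Step 2: plurality gene assignment.
    votes: dict[str, int] = {}
    rank_sum: dict[str, int] = {}
    for r in single:
        (gene,) = gene_sets[r.probe_id]
        votes[gene] = votes.get(gene, 0) + 1
        best = max(
            TIER_RANK[h.tier] for h in hits[r.probe_id] if h.gene_id == gene
        )
        rank_sum[gene] = rank_sum.get(gene, 0) + best
    assigned = min(votes, key=lambda g: (-votes[g], -rank_sum[g], g))

    # Step 3: drop intermingling probes.
    retained_rows = [r for r in single if gene_sets[r.probe_id] == {assigned}]
    if len(retained_rows) < MIN_PROBE_PAIRS:
        return Rejection(
            psid,
            "MIN_PROBES",
            f"{len(retained_rows)} probe pairs remain after filtering "
            f"(minimum {MIN_PROBE_PAIRS})",
        )

    # Step 4: representative transcript = most retained probes (tie: smallest id).
    t_votes: dict[str, int] = {}
    for r in retained_rows:
        for tid in {h.transcript_id for h in hits[r.probe_id] if h.gene_id == assigned}:
            t_votes[tid] = t_votes.get(tid, 0) + 1
    representative = min(t_votes, key=lambda t: (-t_votes[t], t))

    retained = tuple(
        RetainedProbe(
            probe_id=r.probe_id,
            x=r.x,
            y=r.y,
            tier=max(
                (h for h in hits[r.probe_id] if h.gene_id == assigned),
                key=lambda h: TIER_RANK[h.tier],
            ).tier,
        )
        for r in retained_rows
    )
    return OrthologProbeSet(psid, assigned, representative, retained)


def collapse_redundancy(
    probesets: Iterable[OrthologProbeSet],
) -> tuple[list[OrthologProbeSet], list[Rejection]]:
    """Keep one probe set per gene: most probes, then tier rank, then id."""
    by_gene: dict[str, list[OrthologProbeSet]] = {}
    for ps in probesets:
        by_gene.setdefault(ps.target_gene_id, []).append(ps)
    kept: list[OrthologProbeSet] = []
    rejections: list[Rejection] = []
    for gene in by_gene:
        group = sorted(
            by_gene[gene],
            key=lambda ps: (-ps.n_probe_pairs, -ps.tier_rank_sum, ps.probeset_id),
        )
        kept.append(group[0])
        for loser in group[1:]:
            rejections.append(
                Rejection(
                    loser.probeset_id,
                    "REDUNDANT",
                    f"gene {gene} better covered by {group[0].probeset_id}",
                )
            )
    kept.sort(key=lambda ps: ps.probeset_id)
    return kept, rejections


def build_library(
    probesets: Sequence[OrthologProbeSet],
    name: str,
    source_array: str,
    target_species: str,
    config: MatchConfig,
    checksum: str,
    created: str | None = None,
) -> LibraryFile:
    """Assemble the library file with provenance; deterministic ordering.

    ``created`` defaults to a content-derived tag rather than wall-clock
    time so identical inputs always produce byte-identical libraries.
    """
    if not probesets:
        logger.warning("building an empty library (%s)", name)
    if created is None:
        h = hashlib.sha256(
            (checksum + json.dumps(config.to_dict(), sort_keys=True)).encode()
        ).hexdigest()[:12]
        created = f"content:{h}"
    ordered = sorted(probesets, key=lambda ps: ps.probeset_id)
    return LibraryFile(
        name=name,
        source_array=source_array,
        target_species=target_species,
        parameters=config,
        database_checksum=checksum,
        probesets=list(ordered),
        created=created,
    )


def library_summary(
    library: LibraryFile, rejections: Sequence[Rejection] = ()
) -> dict:
    """Attrition and composition report for a built library."""
    per_reason = {reason: 0 for reason in REJECTION_REASONS}
    for rej in rejections:
        per_reason[rej.reason] += 1
    per_tier: dict[str, int] = {t: 0 for t in TIER_RANK}
    sizes: dict[int, int] = {}
    for ps in library.probesets:
        sizes[ps.n_probe_pairs] = sizes.get(ps.n_probe_pairs, 0) + 1
        for p in ps.retained_probes:
            per_tier[p.tier] += 1
    return {
        "probesets_kept": len(library.probesets),
        "probesets_rejected": dict(per_reason),
        "probes_per_tier": per_tier,
        "probes_retained": sum(ps.n_probe_pairs for ps in library.probesets),
        "probes_per_set_distribution": dict(sorted(sizes.items())),
    }


# ---------------------------------------------------------------------------
# Library serialization


def write_library(library: LibraryFile, path: str | os.PathLike) -> None:
    doc = {
        "schema_version": LIBRARY_SCHEMA_VERSION,
        "name": library.name,
        "source_array": library.source_array,
        "target_species": library.target_species,
        "parameters": library.parameters.to_dict(),
        "database_checksum": library.database_checksum,
        "created": library.created,
        "probesets": [
            {
                "probeset_id": ps.probeset_id,
                "target_gene_id": ps.target_gene_id,
                "target_transcript_id": ps.target_transcript_id,
                "probes": [
                    {"probe_id": p.probe_id, "x": p.x, "y": p.y, "tier": p.tier}
                    for p in ps.retained_probes
                ],
            }
            for ps in library.probesets
        ],
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_library(path: str | os.PathLike) -> LibraryFile:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != LIBRARY_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported library schema version {doc.get('schema_version')!r}"
        )
    probesets = [
        OrthologProbeSet(
            probeset_id=ps["probeset_id"],
            target_gene_id=ps["target_gene_id"],
            target_transcript_id=ps["target_transcript_id"],
            retained_probes=tuple(
                RetainedProbe(p["probe_id"], p["x"], p["y"], p["tier"])
                for p in ps["probes"]
            ),
        )
        for ps in doc["probesets"]
    ]
    return LibraryFile(
        name=doc["name"],
        source_array=doc["source_array"],
        target_species=doc["target_species"],
        parameters=MatchConfig(**doc["parameters"]),
        database_checksum=doc["database_checksum"],
        probesets=probesets,
        created=doc["created"],
    )


def write_cdf_text(library: LibraryFile, path: str | os.PathLike) -> None:
    """ASCII CDF-like export: one [Unit…] block of (x, y) rows per set."""
    with open(path, "w", newline="\n") as fh:
        fh.write("[CDF]\nVersion=orthoarray-text-1\n\n")
        fh.write(f"[Chip]\nName={library.name}\nNumberOfUnits={len(library.probesets)}\n\n")
        for i, ps in enumerate(library.probesets, 1):
            fh.write(f"[Unit{i}]\n")
            fh.write(f"Name={ps.probeset_id}\n")
            fh.write(f"Gene={ps.target_gene_id}\n")
            fh.write(f"NumberOfProbes={ps.n_probe_pairs}\n")
            for p in ps.retained_probes:
                fh.write(f"Cell={p.x}\t{p.y}\t{p.probe_id}\t{p.tier}\n")
            fh.write("\n")


def write_rejections_tsv(rejections: Sequence[Rejection], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("probeset_id\treason\tdetail\n")
        for rej in sorted(rejections, key=lambda r: r.probeset_id):
            fh.write(f"{rej.probeset_id}\t{rej.reason}\t{rej.detail}\n")
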