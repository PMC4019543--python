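"""Deterministic synthetic data with planted ground truth.

Generates every input the pipeline consumes — transcript FASTA with a
gene map, an Affymetrix-style probe table, ASCII CEL intensity files, a
sample sheet and GMT gene sets — as a pure function of a
:class:`FixtureSpec`.  Every probe carries a planted orthology tier,
every differential gene a planted effect, and one gene set a planted
enrichment, so recovery can be scored against known truth.

The default sample design mirrors a two-species hepatocyte treatment
study: 3 biological replicates × 2 time points × 3 dose groups
(vehicle / low / high) = 18 arrays, class 0 for vehicle and 1 for
treated.  Planted differential effects are dose-responsive (half effect
at low dose, full at high).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    IntensityMatrix,
    ProbeTableRow,
    TranscriptRecord,
    write_cel_text,
    write_fasta,
    write_gmt,
    write_probe_tab,
)

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "make_transcriptome",
    "make_probes",
    "make_intensities",
    "make_genesets",
    "make_expression_matrix",
    "generate",
    "write_fixture",
]

TIERS = ("EXACT", "END_MM", "TANDEM", "RESCUE", "MULTI_GENE", "NO_HIT")
GOOD_TIERS = ("EXACT", "END_MM", "TANDEM")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _default_tier_mix() -> dict[str, float]:
    return {
        "EXACT": 0.56,
        "END_MM": 0.12,
        "TANDEM": 0.11,
        "RESCUE": 0.05,
        "MULTI_GENE": 0.08,
        "NO_HIT": 0.08,
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int
    n_genes: int = 200
    min_transcripts_per_gene: int = 1
    max_transcripts_per_gene: int = 3
    n_probesets: int = 200
    probes_per_set: int = 11
    tier_mix: dict = field(default_factory=_default_tier_mix)
    core_length: int = 600
    flank_length: int = 150
    n_replicates: int = 3
    n_time_points: int = 2
    n_planted_de: int = 20
    de_effect_log2: float = 1.5
    expressed_fraction: float = 1.0
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.0
    probe_affinity_sd: float = 1.0
    noise_sd: float = 0.25
    optical_background_mean: float = 1.0
    optical_background_sd: float = 0.1
    n_gene_sets: int = 30
    gene_set_size: int = 20
    enriched_de_overlap: int = 10

    def __post_init__(self):
        total = sum(self.tier_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tier_mix proportions sum to {total}, not 1")
        if set(self.tier_mix) - set(TIERS):
            raise ValueError(f"unknown tiers {set(self.tier_mix) - set(TIERS)}")
        if self.n_probesets > self.n_genes:
            raise ValueError("n_probesets may not exceed n_genes (one gene per set)")
        if self.n_planted_de > self.n_probesets:
            raise ValueError("more planted DE genes than probe sets")

    @property
    def n_samples(self) -> int:
        return self.n_replicates * self.n_time_points * 3  # 3 dose groups


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    transcripts: list[TranscriptRecord]
    gene_map: dict[str, str]
    probe_rows: list[ProbeTableRow]
    probe_truth: pd.DataFrame
    samples: pd.DataFrame
    intensities: IntensityMatrix
    de_truth: pd.DataFrame
    gene_sets: dict[str, set[str]]
    enriched_set_name: str


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: list[str], pos: int) -> None:
    choices = [b for b in "ACGT" if b != seq[pos]]
    seq[pos] = choices[rng.integers(len(choices))]


def largest_remainder_counts(proportions: dict[str, float], total: int) -> dict[str, int]:
    """Integer apportionment of ``total`` over categories, largest remainder."""
    keys = list(proportions)
    exact = {k: proportions[k] * total for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    leftover = total - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(exact[k] - counts[k]), keys.index(k)))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# Transcriptome


def make_transcriptome(spec: FixtureSpec, rng: np.random.Generator | None = None):
    """Random transcripts, 1–3 per gene sharing a common core sequence.

    Returns (records, gene_map).  The first transcript of each gene is
    the bare core; additional transcripts add random 5' or 3' flanks,
    emulating splice/UTR variants of one gene.
    """
    rng = rng or np.random.default_rng(spec.seed)
    records: list[TranscriptRecord] = []
    gene_map: dict[str, str] = {}
    t_counter = 0
    for g in range(spec.n_genes):
        gene_id = f"G{g:04d}"
        core = _random_seq(rng, spec.core_length)
        n_tx = int(
            rng.integers(spec.min_transcripts_per_gene, spec.max_transcripts_per_gene + 1)
        )
        for v in range(n_tx):
            tid = f"T{t_counter:05d}"
            t_counter += 1
            if v == 0:
                seq = core
            elif v % 2 == 1:
                seq = _random_seq(rng, spec.flank_length) + core
            else:
                seq = core + _random_seq(rng, spec.flank_length)
            records.append(TranscriptRecord(tid, gene_id, seq))
            gene_map[tid] = gene_id
    return records, gene_map


# ---------------------------------------------------------------------------
# Probes


def _plant_tier(rng, window: str, tier: str) -> str:
    """Derive the PM sequence from its source window per planted tier."""
    seq = list(window)
    if tier in ("EXACT", "MULTI_GENE"):
        return window
    if tier == "END_MM":
        left, right = [(1, 0), (0, 1), (1, 1), (2, 0), (0, 2)][rng.integers(5)]
        for i in range(left):
            _mutate(rng, seq, i)
        for i in range(right):
            _mutate(rng, seq, 24 - i)
    elif tier == "TANDEM":
        # Internal-flank mismatches at 1 and 23: longest run 21, not terminal.
        _mutate(rng, seq, 1)
        _mutate(rng, seq, 23)
    elif tier == "RESCUE":
        # 4 + 3 terminal mismatches: core 18 (< 20), total 7 (< 10).
        for i in range(4):
            _mutate(rng, seq, i)
        for i in range(3):
            _mutate(rng, seq, 24 - i)
    else:
        raise ValueError(tier)
    return "".join(seq)


def make_probes(
    spec: FixtureSpec,
    transcripts: list[TranscriptRecord],
    rng: np.random.Generator | None = None,
):
    """Plant PM/MM probe pairs with known tiers.

    Returns (probe_rows, truth, updated_transcripts).  Tier counts follow
    ``tier_mix`` exactly (largest-remainder rounding) and are dealt
    round-robin across probe sets so every set receives a balanced mix.
    MULTI_GENE probes are additionally copied into a transcript of a
    second gene (appended, so no other planted site is disturbed);
    NO_HIT probes are rejection-sampled to share no 16-mer with the
    final transcriptome on either strand.  The MM partner complements
    base 13 of its PM.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    total = spec.n_probesets * spec.probes_per_set
    counts = largest_remainder_counts(spec.tier_mix, total)
    labels = [t for t in TIERS for _ in range(counts.get(t, 0))]
    # Deal labels across probe sets so each set gets a balanced tier mix.
    per_set: list[list[str]] = [[] for _ in range(spec.n_probesets)]
    for i, lab in enumerate(labels):
        per_set[i % spec.n_probesets].append(lab)
    for slots in per_set:
        rng.shuffle(slots)

    by_gene_first_tx: dict[str, int] = {}
    for idx, rec in enumerate(transcripts):
        by_gene_first_tx.setdefault(rec.gene_id, idx)
    genes = sorted(by_gene_first_tx)
    seqs = [list(rec.sequence) for rec in transcripts]

    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rows: list[ProbeTableRow] = []
    truth_rows = []
    pending_no_hit = []  # (probeset_id, probe_index, source_gene)

    slot = spec.core_length // spec.probes_per_set
    for s in range(spec.n_probesets):
        gene_id = genes[s]
        psid = f"ps{s:04d}_at"
        t_idx = by_gene_first_tx[gene_id]
        for p, tier in enumerate(per_set[s]):
            probe_id = f"{psid}:p{p:02d}"
            pos = p * slot + int(rng.integers(0, max(1, slot - 25)))
            window = "".join(seqs[t_idx][pos : pos + 25])
            if tier == "NO_HIT":
                pending_no_hit.append((psid, probe_id, gene_id, pos))
                continue
            pm = _plant_tier(rng, window, tier)
            secondary = ""
            if tier == "MULTI_GENE":
                other = genes[(s + 1 + int(rng.integers(spec.n_genes - 1))) % spec.n_genes]
                if other == gene_id:
                    other = genes[(s + 1) % spec.n_genes]
                seqs[by_gene_first_tx[other]].extend(pm)
                secondary = other
            truth_rows.append((probe_id, psid, tier, gene_id, secondary, pos))
            rows.append((psid, probe_id, pos, pm))

    # Rebuild transcript records after MULTI_GENE appends, then screen
    # NO_HIT probes against a 16-mer index of the final sequences.
    final = [
        TranscriptRecord(rec.transcript_id, rec.gene_id, "".join(seqs[i]))
        for i, rec in enumerate(transcripts)
    ]
    k = 16
    kmers: set[str] = set()
    for rec in final:
        s_ = rec.sequence
        for i in range(len(s_) - k + 1):
            kmers.add(s_[i : i + k])
    comp = str.maketrans("ACGTN", "TGCAN")

    def clean(seq25: str) -> bool:
        rc = seq25.translate(comp)[::-1]
        for q in (seq25, rc):
            for i in range(25 - k + 1):
                if q[i : i + k] in kmers:
                    return False
        return True

    for psid, probe_id, gene_id, pos in pending_no_hit:
        while True:
            pm = _random_seq(rng, 25)
            if clean(pm):
                break
        truth_rows.append((probe_id, psid, "NO_HIT", gene_id, "", pos))
        rows.append((psid, probe_id, pos, pm))

    # Grid assignment: PM cell immediately left of its MM partner.
    n_cells = 2 * len(rows)
    cols = int(np.ceil(np.sqrt(n_cells)))
    if cols % 2:
        cols += 1  # keep PM/MM pairs on one row
    probe_rows: list[ProbeTableRow] = []
    for i, (psid, probe_id, pos, pm) in enumerate(sorted(rows, key=lambda r: r[1])):
        mm = pm[:12] + complement[pm[12]] + pm[13:]
        cell = 2 * i
        x, y = cell % cols, cell // cols
        probe_rows.append(ProbeTableRow(psid, probe_id, x, y, pos + 13, pm, "PM"))
        probe_rows.append(ProbeTableRow(psid, probe_id, x + 1, y, pos + 13, mm, "MM"))

    truth = pd.DataFrame(
        truth_rows,
        columns=["probe_id", "probeset_id", "tier", "source_gene", "secondary_gene", "position"],
    ).sort_values("probe_id", kind="stable").reset_index(drop=True)
    truth["good"] = truth["tier"].isin(GOOD_TIERS)
    return probe_rows, truth, final


# ---------------------------------------------------------------------------
# Intensities


def _sample_sheet(spec: FixtureSpec) -> pd.DataFrame:
    rows = []
    i = 0
    for dose in ("vehicle", "low", "high"):
        for time_h in (24, 72)[: spec.n_time_points]:
            for rep in range(1, spec.n_replicates + 1):
                i += 1
                rows.append(
                    (f"s{i:02d}_{dose}_{time_h}h_r{rep}", dose, time_h, rep,
                     0 if dose == "vehicle" else 1)
                )
    return pd.DataFrame(rows, columns=["sample_id", "dose", "time_h", "replicate", "label"])


def make_intensities(
    spec: FixtureSpec,
    probe_rows: list[ProbeTableRow],
    rng: np.random.Generator | None = None,
):
    """Simulate CEL-scale intensities with planted differential genes.

    log2 signal of a PM probe = gene baseline + probe affinity + planted
    dose-responsive class effect + Gaussian noise, exponentiated to the
    linear scale.  By default the model is purely multiplicative: the
    additive "optical" floor is negligible (mean 1) and every gene is
    expressed, so in the noiseless limit RMA recovers planted fold
    changes exactly.  Raising ``optical_background_mean`` and lowering
    ``expressed_fraction`` yields a realistic variant with a
    background-dominated probe population (unexpressed genes sit at the
    floor), the regime convolution background correction is built for.
    MM probes carry the same construction at 1/4 signal.  Returns
    (samples, intensities, de_truth).
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    samples = _sample_sheet(spec)
    probesets = sorted({r.probeset_id for r in probe_rows})
    n_sets = len(probesets)
    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n_sets)
    set_index = {ps: i for i, ps in enumerate(probesets)}
    expressed = rng.random(n_sets) < spec.expressed_fraction
    if expressed.sum() < spec.n_planted_de:
        raise ValueError("fewer expressed genes than planted differential genes")

    de_sets = sorted(
        rng.choice(np.where(expressed)[0], size=spec.n_planted_de, replace=False)
    )
    effects = np.zeros(n_sets)
    for rank, s in enumerate(de_sets):
        effects[s] = spec.de_effect_log2 * (1 if rank % 2 == 0 else -1)

    dose_scale = samples["dose"].map({"vehicle": 0.0, "low": 0.5, "high": 1.0}).to_numpy()

    cols = max(r.x for r in probe_rows) + 1
    rows_n = max(r.y for r in probe_rows) + 1
    n_samples = len(samples)
    values = np.empty((n_samples, rows_n, cols))
    # Background floor everywhere (also fills unused cells).
    bg = rng.normal(
        spec.optical_background_mean, spec.optical_background_sd,
        size=(n_samples, rows_n, cols),
    )
    values[:] = np.clip(bg, 1.0, None)

    for r in probe_rows:
        s_idx = set_index[r.probeset_id]
        affinity = rng.normal(0.0, spec.probe_affinity_sd)
        noise = rng.normal(0.0, spec.noise_sd, n_samples)
        if not expressed[s_idx]:
            continue
        log2_signal = baseline[s_idx] + affinity + effects[s_idx] * dose_scale + noise
        if r.role == "MM":
            log2_signal = log2_signal - 2.0
        values[:, r.y, r.x] += np.power(2.0, log2_signal)

    intensities = IntensityMatrix(list(samples["sample_id"]), values)
    de_truth = pd.DataFrame(
        {
            "probeset_id": [probesets[s] for s in de_sets],
            "gene_id": [f"G{s:04d}" for s in de_sets],
            "effect_log2": [effects[s] for s in de_sets],
        }
    )
    return samples, intensities, de_truth


# ---------------------------------------------------------------------------
# Gene sets


def make_genesets(
    spec: FixtureSpec,
    gene_ids: list[str],
    de_genes: list[str],
    rng: np.random.Generator | None = None,
):
    """Random GMT sets plus one set enriched for the planted DE genes.

    The planted set contains ``enriched_de_overlap`` DE genes (several
    times the background expectation); all other sets are uniform draws.
    Returns (sets, enriched_set_name).
    """
    rng = rng or np.random.default_rng(spec.seed + 3)
    universe = list(gene_ids)
    sets: dict[str, set[str]] = {}
    for i in range(spec.n_gene_sets):
        name = f"SET{i:03d}"
        members = rng.choice(len(universe), size=spec.gene_set_size, replace=False)
        sets[name] = {universe[j] for j in members}
    enriched = "SET_PLANTED"
    n_de = min(spec.enriched_de_overlap, len(de_genes), spec.gene_set_size)
    chosen_de = list(rng.choice(sorted(de_genes), size=n_de, replace=False))
    # fill from non-differential genes only, so the planted overlap is exact
    others = [g for g in universe if g not in set(de_genes)]
    fill = list(
        np.array(others)[rng.choice(len(others), size=spec.gene_set_size - n_de, replace=False)]
    )
    sets[enriched] = set(chosen_de) | set(fill)
    return sets, enriched


# ---------------------------------------------------------------------------
# Direct expression matrices (for supervised-ranking studies)


def make_expression_matrix(
    n_transcripts: int = 2000,
    n_per_class: int = 9,
    n_informative: int = 20,
    shift_sd: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Expression matrix with informative transcripts shifted by class.

    Returns (expr probe sets × samples, labels Series, informative ids).
    Informative transcripts are shifted by ``shift_sd`` noise standard
    deviations in class-1 samples.
    """
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_class
    ids = [f"t{i:05d}" for i in range(n_transcripts)]
    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    labels = pd.Series(
        [0] * n_per_class + [1] * n_per_class, index=sample_ids, name="label"
    )
    data = rng.normal(0.0, noise_sd, size=(n_transcripts, n_samples))
    informative = sorted(rng.choice(n_transcripts, size=n_informative, replace=False))
    for rank, t in enumerate(informative):
        sign = 1 if rank % 2 == 0 else -1
        data[t, labels.to_numpy() == 1] += sign * shift_sd * noise_sd
    expr = pd.DataFrame(data, index=ids, columns=sample_ids)
    return expr, labels, [ids[t] for t in informative]


# ---------------------------------------------------------------------------
# Bundle


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate the complete fixture; pure function of the spec."""
    rng = np.random.default_rng(spec.seed)
    transcripts, gene_map = make_transcriptome(spec, rng)
    probe_rows, probe_truth, transcripts = make_probes(spec, transcripts, rng)
    gene_map = {t.transcript_id: t.gene_id for t in transcripts}
    samples, intensities, de_truth = make_intensities(spec, probe_rows, rng)
    gene_ids = sorted({t.gene_id for t in transcripts})
    gene_sets, enriched = make_genesets(
        spec, gene_ids, list(de_truth["gene_id"]), rng
    )
    return FixtureBundle(
        spec=spec,
        transcripts=transcripts,
        gene_map=gene_map,
        probe_rows=probe_rows,
        probe_truth=probe_truth,
        samples=samples,
        intensities=intensities,
        de_truth=de_truth,
        gene_sets=gene_sets,
        enriched_set_name=enriched,
    )


def write_fixture(bundle: FixtureBundle, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every artifact to ``outdir``; returns name → path."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    cel_dir = os.path.join(outdir, "cel")
    os.makedirs(cel_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "transcripts.fasta"),
        "gene_map": os.path.join(outdir, "gene_map.tsv"),
        "probe_tab": os.path.join(outdir, "probes.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "gmt": os.path.join(outdir, "gene_sets.gmt"),
        "truth_probes": os.path.join(outdir, "truth_probes.tsv"),
        "truth_de": os.path.join(outdir, "truth_de.tsv"),
    }
    write_fasta(bundle.transcripts, paths["fasta"])
    with open(paths["gene_map"], "w", newline="\n") as fh:
        for tid, gene in bundle.gene_map.items():
            fh.write(f"{tid}\t{gene}\n")
    write_probe_tab(bundle.probe_rows, paths["probe_tab"])
    bundle.samples.to_csv(paths["samples"], sep="\t", index=False)
    write_gmt(bundle.gene_sets, paths["gmt"])
    bundle.probe_truth.to_csv(paths["truth_probes"], sep="\t", index=False)
    bundle.de_truth.to_csv(paths["truth_de"], sep="\t", index=False)
    cel_paths = []
    for i, sid in enumerate(bundle.intensities.sample_ids):
        p = os.path.join(cel_dir, f"{sid}.CEL")
        write_cel_text(bundle.intensities.values[i], p)
        cel_paths.append(p)
    paths["cels"] = cel_paths
    return paths
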