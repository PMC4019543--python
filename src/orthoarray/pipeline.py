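"""End-to-end run orchestration with a reproducibility manifest.

The pipeline chains match → library build → remap → RMA → ANN ranking →
marker interactions → fold changes → enrichment over file-level
artifacts.  Every stage writes its output to the run directory and the
manifest records content hashes of all inputs and outputs plus the full
parameter set, so a finished run can be re-executed and verified
byte-for-byte.  Stage seeds are derived from the master seed by stage
name, so adding or skipping a stage never shifts another stage's
randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import pandas as pd

from . import annrank, enrich, libbuild, probematch, rma
from .io import (
    IntensityMatrix,
    read_fasta,
    read_gene_map,
    read_gmt,
    read_probe_tab,
    write_expression_tsv,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one full run."""

    fasta: str
    probe_tab: str
    cel_files: list[str]
    labels: str  # sample sheet TSV with sample_id and label columns
    gmt: str
    out_dir: str
    gene_map: str | None = None
    seed: int = 0
    fc_threshold: float = 2.0
    library_name: str = "cross-species-library"
    source_array: str = "synthetic-array"
    target_species: str = "target"
    skip_ann: bool = False
    match: probematch.MatchConfig = field(default_factory=probematch.MatchConfig)
    rma: rma.RmaConfig = field(default_factory=rma.RmaConfig)
    ann: annrank.AnnConfig = field(default_factory=annrank.AnnConfig)

    def to_dict(self) -> dict:
        d = {
            "fasta": self.fasta,
            "probe_tab": self.probe_tab,
            "cel_files": list(self.cel_files),
            "labels": self.labels,
            "gmt": self.gmt,
            "gene_map": self.gene_map,
            "seed": self.seed,
            "fc_threshold": self.fc_threshold,
            "library_name": self.library_name,
            "source_array": self.source_array,
            "target_species": self.target_species,
            "skip_ann": self.skip_ann,
            "match": self.match.to_dict(),
            "rma": {
                "background": self.rma.background,
                "mp_max_iter": self.rma.mp_max_iter,
                "mp_tol": self.rma.mp_tol,
            },
            "ann": {
                "hidden_units": self.ann.hidden_units,
                "learning_rate": self.ann.learning_rate,
                "momentum": self.ann.momentum,
                "patience": self.ann.patience,
                "max_cycles": self.ann.max_cycles,
                "n_resamples": self.ann.n_resamples,
                "top_k": self.ann.top_k,
                "early_stop_mode": self.ann.early_stop_mode,
            },
        }
        return d


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (master ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Artifacts land in ``config.out_dir``: hits.tsv, library.json,
    rejections.tsv, expression.tsv, fold_changes.tsv, enrichment.tsv and
    (unless ``skip_ann``) ranked.tsv, interactions.tsv, edges.tsv, plus
    manifest.json.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    inputs = {
        "fasta": config.fasta,
        "probe_tab": config.probe_tab,
        "labels": config.labels,
        "gmt": config.gmt,
    }
    if config.gene_map:
        inputs["gene_map"] = config.gene_map
    input_hashes = {k: _sha256(v) for k, v in inputs.items()}
    input_hashes["cel_files"] = {os.path.basename(p): _sha256(p) for p in config.cel_files}

    gene_map = read_gene_map(config.gene_map) if config.gene_map else None
    transcripts = read_fasta(config.fasta, gene_map)
    probe_rows = read_probe_tab(config.probe_tab)
    samples = pd.read_csv(config.labels, sep="\t")
    intensities = IntensityMatrix.from_cels(config.cel_files)
    gene_sets = read_gmt(config.gmt)

    # --- match
    logger.info("stage match: %d PM probes vs %d transcripts",
                sum(r.role == "PM" for r in probe_rows), len(transcripts))
    hits_by_probe = probematch.find_all_hits(probe_rows, transcripts, config.match)
    hits_path = os.path.join(out, "hits.tsv")
    with open(hits_path, "w", newline="\n") as fh:
        fh.write(
            "probe_id\ttranscript_id\tgene_id\toffset\tstrand\tcore_start\t"
            "core_len\tn_end_mismatch_left\tn_end_mismatch_right\ttier\n"
        )
        for pid in sorted(hits_by_probe):
            for h in hits_by_probe[pid]:
                fh.write(
                    f"{h.probe_id}\t{h.transcript_id}\t{h.gene_id}\t{h.offset}\t"
                    f"{h.strand}\t{h.core_start}\t{h.core_len}\t"
                    f"{h.n_end_mismatch_left}\t{h.n_end_mismatch_right}\t{h.tier}\n"
                )

    # --- library build
    by_set: dict[str, list] = {}
    for r in probe_rows:
        if r.role == "PM":
            by_set.setdefault(r.probeset_id, []).append(r)
    selected, rejections = [], []
    for psid in sorted(by_set):
        result = libbuild.select_probes(by_set[psid], hits_by_probe, config.match)
        if isinstance(result, libbuild.Rejection):
            rejections.append(result)
        else:
            selected.append(result)
    kept, redundant = libbuild.collapse_redundancy(selected)
    rejections.extend(redundant)
    library = libbuild.build_library(
        kept,
        name=config.library_name,
        source_array=config.source_array,
        target_species=config.target_species,
        config=config.match,
        checksum=libbuild.database_checksum(transcripts),
    )
    lib_path = os.path.join(out, "library.json")
    libbuild.write_library(library, lib_path)
    rej_path = os.path.join(out, "rejections.tsv")
    libbuild.write_rejections_tsv(rejections, rej_path)
    summary = libbuild.library_summary(library, rejections)
    logger.info("library: %d probe sets kept, rejected per reason %s",
                summary["probesets_kept"], summary["probesets_rejected"])

    # --- remap + RMA
    expr = rma.rma_pipeline(intensities, library, config.rma)
    expr_path = os.path.join(out, "expression.tsv")
    write_expression_tsv(expr, expr_path)

    labels = samples.set_index("sample_id")["label"].reindex(expr.columns)

    artifacts = {
        "hits": hits_path,
        "library": lib_path,
        "rejections": rej_path,
        "expression": expr_path,
    }

    # --- ANN ranking + interactions
    if not config.skip_ann:
        ann_cfg = annrank.AnnConfig(
            hidden_units=config.ann.hidden_units,
            learning_rate=config.ann.learning_rate,
            momentum=config.ann.momentum,
            patience=config.ann.patience,
            max_cycles=config.ann.max_cycles,
            n_resamples=config.ann.n_resamples,
            top_k=min(config.ann.top_k, expr.shape[0]),
            early_stop_mode=config.ann.early_stop_mode,
            seed=stage_seed(config.seed, "rank"),
        )
        ranking = annrank.rank_transcripts(expr, labels, ann_cfg)
        rank_path = os.path.join(out, "ranked.tsv")
        ranking.to_csv(rank_path, sep="\t", index=False)
        top = list(ranking["probeset_id"].head(ann_cfg.top_k))
        est = annrank.MarkerInteraction(
            hidden_units=config.ann.hidden_units,
            random_state=stage_seed(config.seed, "interact"),
        )
        est.fit(expr.loc[top].T)
        influence = est.influence_
        inter_path = os.path.join(out, "interactions.tsv")
        influence.to_csv(inter_path, sep="\t")
        edges = est.top_edges(10)
        edges_path = os.path.join(out, "edges.tsv")
        edges.to_csv(edges_path, sep="\t", index=False)
        artifacts.update(ranked=rank_path, interactions=inter_path, edges=edges_path)

    # --- fold changes + enrichment (high dose vs vehicle when dose
    #     metadata is present, else class 1 vs class 0)
    if "dose" in samples.columns:
        treated = list(samples.loc[samples["dose"] == "high", "sample_id"])
        control = list(samples.loc[samples["dose"] == "vehicle", "sample_id"])
    else:
        treated = list(samples.loc[samples["label"] == 1, "sample_id"])
        control = list(samples.loc[samples["label"] == 0, "sample_id"])
    fc = enrich.fold_change(expr, treated, control)
    gene_of = {ps.probeset_id: ps.target_gene_id for ps in library.probesets}
    fc_genes = pd.Series(fc.to_numpy(), index=[gene_of[p] for p in fc.index],
                         name="fold_change")
    fc_path = os.path.join(out, "fold_changes.tsv")
    fc_frame = pd.DataFrame(
        {"probeset_id": fc.index, "gene_id": fc_genes.index, "fold_change": fc.to_numpy()}
    )
    fc_frame.to_csv(fc_path, sep="\t", index=False)

    foreground = enrich.select_differential(fc_genes, config.fc_threshold)
    background = sorted(fc_genes.index)
    results = enrich.enrich(gene_sets, foreground, background)
    enr_path = os.path.join(out, "enrichment.tsv")
    results.to_csv(enr_path, sep="\t", index=False)
    artifacts.update(fold_changes=fc_path, enrichment=enr_path)

    manifest = {
        "config": config.to_dict(),
        "inputs": input_hashes,
        "outputs": {k: _sha256(v) for k, v in artifacts.items()},
        "library_summary": summary,
        "n_differential": len(foreground),
    }
    with open(os.path.join(out, "manifest.json"), "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
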