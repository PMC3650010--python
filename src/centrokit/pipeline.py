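"""End-to-end orchestration: import -> tracks -> stats -> segmentation ->
coverage -> network -> report.

``RunConfig`` collects every input path and every decision threshold of
the analysis; the defaults are the published decision rules, so an empty
override reproduces them.  Stages whose optional inputs are missing are
skipped with a log entry; a missing required input (the FASTA) fails
before any stage runs.  Given the same config and seed, the JSON report
is byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import coverage as ck_coverage
from . import io as ck_io
from . import network as ck_network
from . import predictors as ck_predictors
from . import segmentation as ck_segmentation
from . import stats as ck_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str = ""
    set_label: str = "study"
    tracks_dir: Optional[str] = None
    smart_table: Optional[str] = None
    zscore_table: Optional[str] = None
    hit_table: Optional[str] = None
    edge_list: Optional[str] = None
    out_dir: str = "centro_out"
    # thresholds; defaults are the published decision rules
    disorder_threshold: float = 0.5
    coil_threshold: float = 0.5
    stretch_min_run: int = 20          # strict: runs must exceed this
    dual_coverage_threshold: float = 0.20  # strict: fraction must exceed this
    smart_min_len: int = 30            # inclusive
    residual_min_len: int = 40         # strict
    z_threshold: float = 3.0           # strict
    max_disorder_coil: float = 0.30    # strict (below)
    identity_discard: float = 0.40     # strict (above)
    hmm_min_probability: float = 0.95
    hmm_min_span: int = 30
    hmm_min_identity: float = 0.20
    high_identity_min: float = 0.70
    min_new_residues: int = 30
    disorder_coil_mode: str = "union"
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_tracks(config: RunConfig, proteins) -> dict:
    """Per-protein track bundles, imported from ``tracks_dir`` or produced
    by the builtin predictors when no directory is given."""
    track_set: dict = {}
    if config.tracks_dir:
        tdir = Path(config.tracks_dir)
        for rec in proteins:
            bundle = {}
            for kind in ("disorder", "coil", "ss", "modeled"):
                path = tdir / f"{rec.id}.{kind}.tsv"
                if path.exists():
                    bundle[kind] = ck_io.import_track(
                        path, "generic_tsv", rec, kind=kind,
                        disorder_threshold=config.disorder_threshold,
                        coil_threshold=config.coil_threshold)
            if "disorder" not in bundle or "coil" not in bundle:
                raise ValueError(f"tracks_dir is missing disorder/coil tracks "
                                 f"for {rec.id!r}")
            track_set[rec.id] = bundle
    else:
        logger.info("no tracks_dir given: using builtin stand-in predictors")
        for rec in proteins:
            track_set[rec.id] = {
                "disorder": ck_predictors.disorder_index_track(rec),
                "coil": ck_predictors.coil_score_track(rec),
            }
    return track_set


def run_pipeline(config: RunConfig) -> dict:
    """Run all applicable stages and write the report bundle.

    Returns the report dictionary (also written as ``report.json`` in
    ``out_dir`` alongside per-protein TSV tables).
    """
    if not config.fasta:
        raise ValueError("config.fasta is required")
    fasta = Path(config.fasta)
    if not fasta.exists():
        raise FileNotFoundError(f"FASTA not found: {fasta}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": asdict(config), "version": __version__,
                    "stages": {}}

    records = ck_io.read_sequences(fasta, set_label=config.set_label)
    proteins = ck_io.select_longest_isoform(records)
    by_id = {p.id: p for p in proteins}
    report["stages"]["import"] = {"n_sequences": len(records),
                                  "n_longest_isoforms": len(proteins)}

    track_set = _load_tracks(config, proteins)

    # ---- joint statistics -------------------------------------------------
    joint = ck_stats.joint_residue_counts(track_set)
    fractions = ck_stats.per_protein_fractions(
        track_set, dual_coverage_threshold=config.dual_coverage_threshold)
    stats_out = {"joint": joint.as_dict(),
                 "n_dual_above_threshold": fractions["n_dual_above_threshold"],
                 "histograms": fractions["histograms"]}
    if all("ss" in b for b in track_set.values()):
        stats_out["ss"] = ck_stats.ss_class_fractions(track_set)
    report["stages"]["stats"] = stats_out
    _write_fraction_table(fractions["fractions"], out / "protein_fractions.tsv")

    # ---- domain segmentation ---------------------------------------------
    smart_by_protein: dict = defaultdict(list)
    if config.smart_table:
        for iv in ck_io.import_domain_table(config.smart_table, proteins):
            smart_by_protein[iv.protein_id].append(iv)
    alignments = (ck_io.import_zscore_table(config.zscore_table)
                  if config.zscore_table else {})
    if config.smart_table or config.zscore_table:
        all_calls = []
        for rec in proteins:
            bundle = track_set[rec.id]
            partition = ck_segmentation.partition_sequence(
                len(rec), rec.id, smart_by_protein.get(rec.id, []),
                bundle.get("coil"), bundle.get("disorder"),
                min_run=config.stretch_min_run)
            calls = ck_segmentation.call_globular(
                partition, alignments, bundle.get("disorder"),
                bundle.get("coil"), smart_min_len=config.smart_min_len,
                residual_min_len=config.residual_min_len,
                z_threshold=config.z_threshold,
                max_disorder_coil=config.max_disorder_coil,
                disorder_coil_mode=config.disorder_coil_mode)
            all_calls.extend(calls)
        n_glob = sum(1 for c in all_calls if c.verdict.startswith("globular"))
        report["stages"]["segmentation"] = {
            "n_intervals": len(all_calls), "n_globular": n_glob}
        _write_calls(all_calls, out / "domain_calls.tsv")
    else:
        logger.info("segmentation skipped: no SMART or Z-score table")
        report["stages"]["segmentation"] = {"skipped": True}

    # ---- template coverage ------------------------------------------------
    if config.hit_table:
        try:
            hits = ck_io.import_hit_table(config.hit_table)
        except Exception as exc:
            raise ValueError(
                f"coverage stage: cannot parse hit table "
                f"{config.hit_table!r}: {exc}") from exc
        params = ck_coverage.HitFilterParams(
            hmm_min_probability=config.hmm_min_probability,
            hmm_min_span=config.hmm_min_span,
            hmm_min_identity=config.hmm_min_identity,
            high_identity_min=config.high_identity_min,
            min_new_residues=config.min_new_residues)
        by_query: dict = defaultdict(list)
        for h in ck_coverage.filter_hits(hits, params):
            by_query[h.query_id].append(h)
        accepted = {q: ck_coverage.greedy_select(hs, config.min_new_residues)
                    for q, hs in by_query.items()}
        lengths = {p.id: len(p) for p in proteins}
        summary = ck_coverage.coverage_summary(accepted, lengths, track_set)
        report["stages"]["coverage"] = {
            "set_modeled_fraction": summary.set_modeled_fraction,
            "n_fragments": summary.n_fragments,
            "n_fragments_below_30": summary.n_fragments_below_30,
            "n_fragments_above_90": summary.n_fragments_above_90,
            "identity_histogram": summary.identity_histogram,
            "crosstab": summary.crosstab,
        }
        for pid, acc in accepted.items():
            track_set[pid]["modeled"] = ck_coverage.modeled_track(
                pid, lengths[pid], acc)
    else:
        logger.info("coverage skipped: no hit table")
        report["stages"]["coverage"] = {"skipped": True}

    # ---- interaction network ----------------------------------------------
    if config.edge_list:
        edges = ck_io.import_edge_list(config.edge_list)
        metrics = ck_network.graph_metrics(edges, total_proteins=len(proteins))
        disorder_fractions = {
            pid: sum(b["disorder"].values) / len(b["disorder"])
            for pid, b in track_set.items()}
        ranking = ck_network.centrality_report(metrics, disorder_fractions)
        report["stages"]["network"] = {
            "n_nodes": metrics.n_nodes, "n_edges": metrics.n_edges,
            "average_degree": metrics.average_degree,
            "average_degree_over_total": metrics.average_degree_over_total,
            "average_clustering": metrics.average_clustering,
            "top_betweenness": ranking[:10],
        }
        _write_ranking(ranking, out / "network_ranking.tsv")
    else:
        logger.info("network skipped: no edge list")
        report["stages"]["network"] = {"skipped": True}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_fraction_table(fractions, path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-protein coverage fractions\n")
        fh.write("protein_id\tf_disorder_and_coil\tf_disorder_not_coil\t"
                 "f_modeled\tf_ss_rest\n")
        for f in fractions:
            fm = "" if f.f_modeled is None else f"{f.f_modeled:.4f}"
            fs = ("" if f.f_ss_not_disorder_not_coil_not_modeled is None
                  else f"{f.f_ss_not_disorder_not_coil_not_modeled:.4f}")
            fh.write(f"{f.protein_id}\t{f.f_disorder_and_coil:.4f}\t"
                     f"{f.f_disorder_not_coil:.4f}\t{fm}\t{fs}\n")


def _write_calls(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("# domain calls, coordinates=1-based inclusive\n")
        fh.write("protein_id\tstart\tend\ttype\tverdict\treason\tevidence\n")
        for c in calls:
            iv = c.interval
            ev = ";".join(f"{k}={v}" for k, v in sorted(iv.evidence.items()))
            fh.write(f"{iv.protein_id}\t{iv.start}\t{iv.end}\t{iv.type}\t"
                     f"{c.verdict}\t{c.rejection_reason}\t{ev}\n")


def _write_ranking(ranking, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tprotein_id\tbetweenness\tdegree\tclustering\t"
                 "disorder_fraction\n")
        for row in ranking:
            df = ("" if row["disorder_fraction"] is None
                  else f"{row['disorder_fraction']:.4f}")
            fh.write(f"{row['rank']}\t{row['protein_id']}\t"
                     f"{row['betweenness']:.4f}\t{row['degree']}\t"
                     f"{row['clustering']:.4f}\t{df}\n")
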