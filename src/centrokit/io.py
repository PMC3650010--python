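"""Readers and writers for all external formats.

Handles FASTA sequence sets, per-residue predictor outputs in several
tab-separated dialects, SMART-style domain tables, template-hit tables and
interaction edge lists, plus the longest-isoform convention used to pick
one representative sequence per gene.

All coordinates are 1-based inclusive; every file this module writes states
that in a ``#`` header line.  Lines starting with ``#`` are ignored on
input.  Importing never silently truncates: clipping and dropping are
counted and logged through :mod:`logging`.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .records import (
    ALPHABET,
    AnnotationTrack,
    EdgeList,
    Interval,
    ProteinRecord,
    TemplateHit,
)

logger = logging.getLogger(__name__)

TRACK_DIALECTS = ("disopred", "psipred_ss2", "coils", "dssp", "generic_tsv")

#: conventional collapse of the 8 DSSP states onto 3 classes
DSSP_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E",
                 "T": "C", "S": "C", "-": "C", " ": "C", "C": "C", "P": "C"}


# ---------------------------------------------------------------------------
# sequences

def read_sequences(path, set_label: str = "study",
                   gene_id_field: Optional[int] = None) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The first whitespace-delimited header token is the record id.  The gene
    id defaults to the id itself; ``gene_id_field`` selects instead the
    n-th (0-based) ``|``- or whitespace-delimited header field.

    Raises ``ValueError`` on an empty file, a duplicate id, or any
    character outside the 20 standard amino acids plus ``X`` (reported
    with its 1-based position).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate sequence id {pid!r}")
        seen.add(pid)
        seq = str(entry.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"{path}: sequence {pid!r} has invalid residue {ch!r} "
                    f"at position {pos}"
                )
        gene_id = pid
        if gene_id_field is not None:
            fields = entry.description.replace("|", " ").split()
            if gene_id_field < len(fields):
                gene_id = fields[gene_id_field]
        records.append(ProteinRecord(id=pid, sequence=seq, gene_id=gene_id,
                                     set_label=set_label))
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def write_sequences(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} gene={rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def select_longest_isoform(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep the longest isoform of each gene.

    Ties are broken by lexicographically smallest id, so the selection is
    deterministic.  Returned records carry ``isoform_rank`` 1; the function
    is idempotent.
    """
    by_gene: dict[str, list[ProteinRecord]] = defaultdict(list)
    for rec in records:
        by_gene[rec.gene_id].append(rec)
    chosen = []
    for gene in sorted(by_gene):
        ranked = sorted(by_gene[gene], key=lambda r: (-len(r.sequence), r.id))
        best = ranked[0]
        chosen.append(ProteinRecord(id=best.id, sequence=best.sequence,
                                    gene_id=best.gene_id, isoform_rank=1,
                                    set_label=best.set_label))
    return chosen


# ---------------------------------------------------------------------------
# per-residue tracks

def _read_rows(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
    return rows


def import_track(path, dialect: str, protein: ProteinRecord, *,
                 kind: Optional[str] = None,
                 disorder_threshold: float = 0.5,
                 coil_threshold: float = 0.5,
                 source: str = "imported") -> AnnotationTrack:
    """Parse a per-residue predictor output file into a track.

    Dialects
    --------
    ``disopred``
        rows ``index residue marker confidence``; a residue is disordered
        when the marker is ``*``, or when the confidence column exceeds
        ``disorder_threshold`` if no ``*`` markers appear in the file.
    ``psipred_ss2``
        rows ``index residue state pC pH pE``; the state column is taken
        as-is (no recomputation from probabilities).
    ``coils``
        rows ``index residue score probability``; coil iff probability
        ``>= coil_threshold``.
    ``dssp``
        rows ``index residue state`` with 8-class DSSP states, collapsed
        H,G,I->H; E,B->E; else C.
    ``generic_tsv``
        rows ``index residue state`` with state in {0,1} or {H,E,C}; the
        round-trip format written by :func:`write_track`.

    Every row must align with the protein: a row-count or residue-letter
    mismatch is an error naming both counts / the offending position.
    """
    if dialect not in TRACK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {TRACK_DIALECTS}")
    rows = _read_rows(path)
    if len(rows) != len(protein):
        raise ValueError(
            f"{path}: {len(rows)} rows but protein {protein.id!r} has "
            f"{len(protein)} residues"
        )
    residue_col = 1
    for i, row in enumerate(rows):
        if row[residue_col] != protein.sequence[i]:
            raise ValueError(
                f"{path}: residue mismatch at position {i + 1}: file has "
                f"{row[residue_col]!r}, sequence has {protein.sequence[i]!r}"
            )

    scores: Optional[list] = None
    if dialect == "disopred":
        markers = [row[2] for row in rows]
        scores = [float(row[3]) for row in rows]
        if any(m == "*" for m in markers):
            values = [m == "*" for m in markers]
        else:
            values = [s > disorder_threshold for s in scores]
        out_kind = "disorder"
    elif dialect == "psipred_ss2":
        values = [row[2] for row in rows]
        out_kind = "ss"
    elif dialect == "coils":
        scores = [float(row[2]) for row in rows]
        probs = [float(row[3]) for row in rows]
        values = [p >= coil_threshold for p in probs]
        out_kind = "coil"
    elif dialect == "dssp":
        values = []
        for i, row in enumerate(rows):
            state = row[2]
            if state not in DSSP_COLLAPSE:
                raise ValueError(f"{path}: unknown DSSP state {state!r} at row {i + 1}")
            values.append(DSSP_COLLAPSE[state])
        out_kind = "ss"
    else:  # generic_tsv
        states = [row[2] for row in rows]
        if all(s in ("0", "1") for s in states):
            values = [s == "1" for s in states]
            out_kind = kind or "disorder"
        else:
            values = states
            out_kind = "ss"
        if len(rows[0]) > 3:
            scores = [float(row[3]) for row in rows]
    if kind is not None:
        out_kind = kind
    return AnnotationTrack(protein_id=protein.id, kind=out_kind, values=values,
                           source=source, scores=scores)


def write_track(track: AnnotationTrack, protein: ProteinRecord, path) -> None:
    """Write a track in the generic_tsv dialect (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write(f"# generic_tsv track kind={track.kind} protein={track.protein_id} "
                 "coordinates=1-based inclusive\n")
        for i, v in enumerate(track.values):
            state = v if track.kind == "ss" else ("1" if v else "0")
            line = f"{i + 1}\t{protein.sequence[i]}\t{state}"
            if track.scores is not None:
                line += f"\t{track.scores[i]:.6g}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# domain tables, hit tables, edge lists

def import_domain_table(path, proteins: Sequence[ProteinRecord]) -> list[Interval]:
    """Read a SMART-style domain table (TSV) into smart_domain intervals.

    Expected columns: protein_id, domain_name, start, end, significant.
    Intervals ending beyond the sequence are clipped to its length with a
    logged warning; start > end or an unknown protein id is an error.
    """
    by_id = {p.id: p for p in proteins}
    df = pd.read_csv(path, sep="\t", comment="#")
    intervals: list[Interval] = []
    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        if pid not in by_id:
            raise ValueError(f"{path}: unknown protein_id {pid!r}")
        start, end = int(row.start), int(row.end)
        if start > end:
            raise ValueError(
                f"{path}: domain {row.domain_name!r} on {pid!r} has start "
                f"{start} > end {end}"
            )
        length = len(by_id[pid])
        if end > length:
            logger.warning("%s: clipping domain %s on %s from [%d,%d] to [%d,%d]",
                           path, row.domain_name, pid, start, end, start, length)
            end = length
        intervals.append(Interval(protein_id=pid, start=start, end=end,
                                  type="smart_domain",
                                  evidence={"domain_name": str(row.domain_name),
                                            "significant": bool(row.significant)}))
    return intervals


def import_hit_table(path) -> list[TemplateHit]:
    """Read a template-hit table (TSV).

    Columns: query_id, template_id, q_start, q_end, identity, probability,
    channel; an optional identical_residues column overrides the derived
    round(identity x span) count.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    hits = []
    for row in df.itertuples(index=False):
        explicit = getattr(row, "identical_residues", None)
        hits.append(TemplateHit(
            query_id=str(row.query_id), template_id=str(row.template_id),
            q_start=int(row.q_start), q_end=int(row.q_end),
            identity=float(row.identity), probability=float(row.probability),
            channel=str(row.channel),
            identical_residues=None if explicit is None or pd.isna(explicit)
            else int(explicit)))
    return hits


def write_hit_table(hits: Iterable[TemplateHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("# template hits, coordinates=1-based inclusive\n")
        fh.write("query_id\ttemplate_id\tq_start\tq_end\tidentity\t"
                 "probability\tchannel\tidentical_residues\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.template_id}\t{h.q_start}\t{h.q_end}\t"
                     f"{h.identity:.4f}\t{h.probability:.4f}\t{h.channel}\t"
                     f"{h.identical_residues}\n")


def import_zscore_table(path) -> dict[tuple[str, int, int], dict]:
    """Read structural-alignment records keyed by (protein_id, start, end).

    Columns: protein_id, start, end, z_score, match_length.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        out[(str(row.protein_id), int(row.start), int(row.end))] = {
            "z_score": float(row.z_score),
            "match_length": int(row.match_length),
        }
    return out


def import_edge_list(path) -> EdgeList:
    """Read a two-column TSV of interacting protein pairs.

    The graph is undirected: duplicates (in either order) collapse to one
    edge and self-loops are dropped; both counts are logged.  A row with
    fewer than two columns is an error naming the line.
    """
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            pairs.append((fields[0], fields[1]))
    el = EdgeList.from_pairs(pairs)
    if el.n_self_loops_dropped or el.n_duplicates_dropped:
        logger.info("%s: dropped %d self-loops and %d duplicate edges", path,
                    el.n_self_loops_dropped, el.n_duplicates_dropped)
    return el


def write_edge_list(edges: EdgeList, path) -> None:
    with open(path, "w") as fh:
        fh.write("# undirected edge list\n")
        for a, b in sorted(edges.edges):
            fh.write(f"{a}\t{b}\n")
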