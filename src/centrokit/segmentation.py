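"""Putative-globular-domain selection.

Each protein sequence is parsed into a priority partition of
non-overlapping intervals:

1. SMART domains (highest priority; overlapping SMART intervals are merged
   into their union),
2. coiled-coil stretches — maximal runs of more than 20 predicted coil
   residues,
3. disordered stretches — maximal runs of more than 20 predicted
   disordered residues,
4. residual regions — everything left over.

When a lower-priority stretch is truncated by a higher-priority interval,
the "more than 20 residues" test is re-applied to each surviving piece; a
piece that no longer qualifies reverts to residual.  The partition covers
every residue exactly once.

Globular calls on the partition:

* condition 1 — a SMART interval with significant evidence spanning at
  least 30 residues (inclusive);
* condition 2 — a residual region strictly longer than 40 residues whose
  structural alignment has Z-score > 3 and whose disordered-or-coil
  residue fraction is strictly below 30%.

Calls with more than 40% sequence identity to a known structure are
discarded as of little interest (strict >0.40; calls without an identity
record are retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .records import AnnotationTrack, Interval
from .stats import extract_stretches

logger = logging.getLogger(__name__)

REJECTION_REASONS = ("too_short", "low_Z", "too_disordered", "high_identity",
                     "missing_evidence", "not_applicable", "none")


@dataclass
class DomainCall:
    interval: Interval
    verdict: str  # globular_condition1 | globular_condition2 | rejected
    rejection_reason: str = "none"
    pdb_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.verdict.startswith("globular") and self.rejection_reason != "none":
            raise ValueError("a globular verdict cannot carry a rejection reason")
        if self.rejection_reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.rejection_reason!r}")


def _merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of possibly overlapping SMART intervals (nested repeats)."""
    if not intervals:
        return []
    merged = []
    for iv in sorted(intervals, key=lambda x: (x.start, x.end)):
        if merged and iv.start <= merged[-1].end + 0:
            last = merged[-1]
            if iv.start <= last.end:
                logger.warning("merging overlapping SMART intervals [%d,%d] and "
                               "[%d,%d] on %s", last.start, last.end, iv.start,
                               iv.end, iv.protein_id)
                names = last.evidence.get("domain_name", "")
                new_name = iv.evidence.get("domain_name", "")
                evidence = dict(last.evidence)
                if new_name and new_name not in names:
                    evidence["domain_name"] = f"{names}+{new_name}" if names else new_name
                evidence["significant"] = (last.evidence.get("significant", False)
                                           or iv.evidence.get("significant", False))
                merged[-1] = Interval(protein_id=last.protein_id, start=last.start,
                                      end=max(last.end, iv.end),
                                      type="smart_domain", evidence=evidence)
                continue
        merged.append(iv)
    return merged


def partition_sequence(protein_length: int, protein_id: str,
                       smart: Sequence[Interval],
                       coil_track: Optional[AnnotationTrack],
                       disorder_track: Optional[AnnotationTrack],
                       min_run: int = 20) -> list[Interval]:
    """Priority partition of [1, L] into SMART/coil/disorder/residual.

    ``min_run`` is the strict run-length threshold for stretches (a run
    must exceed it, both before and after truncation by higher-priority
    intervals).
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    # 0 = unassigned, then priority labels
    label = [None] * protein_length

    for iv in _merge_intervals(list(smart)):
        if iv.end > protein_length:
            raise ValueError(f"SMART interval [{iv.start},{iv.end}] exceeds "
                             f"protein length {protein_length}")
        for i in range(iv.start - 1, iv.end):
            label[i] = ("smart_domain", iv)

    for kind, track in (("coil_stretch", coil_track),
                        ("disorder_stretch", disorder_track)):
        if track is None:
            continue
        if len(track) != protein_length:
            raise ValueError(f"{kind} track length {len(track)} != protein "
                             f"length {protein_length}")
        for stretch in extract_stretches(track, min_run=min_run):
            # truncate around already-assigned residues, then re-test the
            # strict run-length rule on each surviving piece
            free = [i for i in range(stretch.start - 1, stretch.end)
                    if label[i] is None]
            for lo, hi in _contiguous_runs(free):
                if hi - lo + 1 > min_run:
                    piece = Interval(protein_id=protein_id, start=lo + 1,
                                     end=hi + 1, type=kind)
                    for i in range(lo, hi + 1):
                        label[i] = (kind, piece)

    # stitch labels into ordered intervals; unassigned residues -> residual
    partition: list[Interval] = []
    i = 0
    while i < protein_length:
        if label[i] is None:
            j = i
            while j < protein_length and label[j] is None:
                j += 1
            partition.append(Interval(protein_id=protein_id, start=i + 1,
                                      end=j, type="residual"))
            i = j
        else:
            kind, iv = label[i]
            j = i
            while j < protein_length and label[j] is not None and label[j][1] is iv:
                j += 1
            partition.append(Interval(protein_id=protein_id, start=i + 1, end=j,
                                      type=kind, evidence=dict(iv.evidence)))
            i = j
    return partition


def _contiguous_runs(indices: Sequence[int]):
    runs = []
    for idx in indices:
        if runs and idx == runs[-1][1] + 1:
            runs[-1][1] = idx
        else:
            runs.append([idx, idx])
    return [(lo, hi) for lo, hi in runs]


def interval_disorder_coil_fraction(interval: Interval,
                                    disorder_track: Optional[AnnotationTrack],
                                    coil_track: Optional[AnnotationTrack],
                                    mode: str = "union") -> float:
    """Fraction of an interval's residues that are disordered and/or coil.

    ``union`` counts a residue once if it is disordered OR coil (default);
    ``sum`` adds the two fractions with double counting of dual residues.
    """
    if mode not in ("union", "sum"):
        raise ValueError("mode must be 'union' or 'sum'")
    n = interval.length
    count = 0
    for i in range(interval.start - 1, interval.end):
        d = bool(disorder_track.values[i]) if disorder_track is not None else False
        c = bool(coil_track.values[i]) if coil_track is not None else False
        if mode == "union":
            count += 1 if (d or c) else 0
        else:
            count += int(d) + int(c)
    return count / n


def call_globular(partition: Sequence[Interval],
                  alignments: Mapping[tuple, Mapping],
                  disorder_track: Optional[AnnotationTrack] = None,
                  coil_track: Optional[AnnotationTrack] = None,
                  smart_min_len: int = 30,
                  residual_min_len: int = 40,
                  z_threshold: float = 3.0,
                  max_disorder_coil: float = 0.30,
                  disorder_coil_mode: str = "union") -> list[DomainCall]:
    """Apply the two globular-domain conditions to a partition.

    ``alignments`` maps (protein_id, start, end) of residual regions to
    records with ``z_score`` and ``match_length``.  A residual region long
    enough to be eligible but lacking an alignment record is rejected with
    reason ``missing_evidence`` (logged), never an exception.
    """
    calls = []
    for iv in partition:
        if iv.type == "smart_domain":
            significant = bool(iv.evidence.get("significant", False))
            if significant and iv.length >= smart_min_len:
                calls.append(DomainCall(interval=iv, verdict="globular_condition1"))
            else:
                reason = "too_short" if significant else "missing_evidence"
                calls.append(DomainCall(interval=iv, verdict="rejected",
                                        rejection_reason=reason))
        elif iv.type == "residual":
            if iv.length <= residual_min_len:
                calls.append(DomainCall(interval=iv, verdict="rejected",
                                        rejection_reason="too_short"))
                continue
            rec = alignments.get((iv.protein_id, iv.start, iv.end))
            if rec is None:
                logger.info("no alignment record for eligible residual region "
                            "[%d,%d] on %s", iv.start, iv.end, iv.protein_id)
                calls.append(DomainCall(interval=iv, verdict="rejected",
                                        rejection_reason="missing_evidence"))
                continue
            if rec["z_score"] <= z_threshold:
                calls.append(DomainCall(interval=iv, verdict="rejected",
                                        rejection_reason="low_Z"))
                continue
            frac = interval_disorder_coil_fraction(iv, disorder_track, coil_track,
                                                   mode=disorder_coil_mode)
            if frac < max_disorder_coil:
                ev = dict(iv.evidence)
                ev.update({"z_score": rec["z_score"],
                           "match_length": rec.get("match_length")})
                called = Interval(protein_id=iv.protein_id, start=iv.start,
                                  end=iv.end, type=iv.type, evidence=ev)
                calls.append(DomainCall(interval=called,
                                        verdict="globular_condition2"))
            else:
                calls.append(DomainCall(interval=iv, verdict="rejected",
                                        rejection_reason="too_disordered"))
        else:  # coil/disorder stretches are never globular candidates
            calls.append(DomainCall(interval=iv, verdict="rejected",
                                    rejection_reason="not_applicable"))
    return calls


def identity_filter(calls: Sequence[DomainCall],
                    identities: Mapping[tuple, float],
                    max_identity: float = 0.40) -> list[DomainCall]:
    """Discard globular calls with known-structure identity strictly above
    ``max_identity``; calls without an identity record are retained.

    ``identities`` maps (protein_id, start, end) to an identity fraction
    in [0, 1]; a value outside that range is an error.
    """
    out = []
    for call in calls:
        key = (call.interval.protein_id, call.interval.start, call.interval.end)
        ident = identities.get(key)
        if ident is None:
            out.append(call)
            continue
        if not (0.0 <= ident <= 1.0):
            raise ValueError(f"identity {ident} for {key} outside [0,1]")
        if call.verdict.startswith("globular") and ident > max_identity:
            out.append(DomainCall(interval=call.interval, verdict="rejected",
                                  rejection_reason="high_identity",
                                  pdb_identity=ident))
        else:
            out.append(DomainCall(interval=call.interval, verdict=call.verdict,
                                  rejection_reason=call.rejection_reason,
                                  pdb_identity=ident))
    return out
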