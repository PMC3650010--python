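"""Homology-template filtering, greedy selection and coverage accounting.

Candidate template hits arrive through two channels: ``hmm`` hits from a
profile-HMM search (kept when the match probability exceeds 95%, the
aligned span exceeds 30 residues and the sequence identity exceeds 20%)
and ``high_identity`` hits from a plain sequence search (kept above 70%
identity).  All these thresholds are strict and configurable.

For each query the templates yielding the maximum number of identical
residues are selected greedily: hits are ranked by identical-residue count
(ties: longer span, then lexicographic template id), the best is accepted,
and each subsequent hit is accepted only if it contributes at least 30
query residues not already covered.  Modeled coverage is the union of
accepted spans.

Accepted fragments with >= 95% identity are flagged ``retrieve`` — close
enough to an experimental structure that one would download it rather than
model it.  No model building happens here; coverage accounting is the
point: per-protein and set-level modeled fractions, the identity histogram
of selected fragments, and the residue cross-tabulation of modeled status
against disordered-or-coiled-coil prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import AnnotationTrack, TemplateHit

#: fragments at or above this identity are retrieved from the PDB, not modeled
RETRIEVE_IDENTITY = 0.95
#: longest chain gap that may be built without template support
MAX_UNTEMPLATED_GAP = 6


@dataclass
class HitFilterParams:
    hmm_min_probability: float = 0.95
    hmm_min_span: int = 30          # strict: span must exceed this
    hmm_min_identity: float = 0.20  # strict
    high_identity_min: float = 0.70  # strict
    min_new_residues: int = 30      # inclusive: >= this many new residues


def filter_hits(hits: Iterable[TemplateHit],
                params: Optional[HitFilterParams] = None) -> list[TemplateHit]:
    """Apply the per-channel significance filters (all inequalities strict)."""
    params = params or HitFilterParams()
    kept = []
    for h in hits:
        if h.channel == "hmm":
            if (h.probability > params.hmm_min_probability
                    and h.span > params.hmm_min_span
                    and h.identity > params.hmm_min_identity):
                kept.append(h)
        else:  # high_identity
            if h.identity > params.high_identity_min:
                kept.append(h)
    return kept


def _sort_key(h: TemplateHit):
    return (-h.identical_residues, -h.span, h.template_id)


def greedy_select(hits: Sequence[TemplateHit],
                  min_new_residues: int = 30) -> list[TemplateHit]:
    """Greedy maximum-identical-residues template selection for one query.

    Hits are processed in a total order (identical residues descending,
    then span descending, then template id), so the output is invariant to
    the input order.  The first hit is accepted; each later hit is accepted
    iff it covers at least ``min_new_residues`` query residues not covered
    by any previously accepted hit.
    """
    if not hits:
        return []
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"greedy_select expects hits of a single query, "
                         f"got {sorted(queries)}")
    accepted: list[TemplateHit] = []
    covered: set[int] = set()
    for h in sorted(hits, key=_sort_key):
        new = set(range(h.q_start, h.q_end + 1)) - covered
        if not accepted or len(new) >= min_new_residues:
            accepted.append(h)
            covered |= new
    return accepted


def modeled_track(protein_id: str, length: int,
                  accepted: Sequence[TemplateHit]) -> AnnotationTrack:
    """Boolean per-residue track of the union of accepted template spans."""
    values = [False] * length
    for h in accepted:
        if h.q_end > length:
            raise ValueError(f"hit {h.template_id!r} ends at {h.q_end} beyond "
                             f"protein length {length}")
        for i in range(h.q_start - 1, h.q_end):
            values[i] = True
    return AnnotationTrack(protein_id=protein_id, kind="modeled", values=values,
                           source="imported")


@dataclass
class CoverageSummary:
    per_protein: dict            # protein_id -> {modeled_fraction, n_models, ...}
    set_modeled_fraction: float
    n_residues: int
    n_fragments: int
    identity_histogram: dict     # bin label -> count
    n_fragments_below_30: int
    n_fragments_above_90: int
    crosstab: dict = field(default_factory=dict)
    fragment_flags: list = field(default_factory=list)


def coverage_summary(accepted_by_protein: Mapping[str, Sequence[TemplateHit]],
                     lengths: Mapping[str, int],
                     track_set: Optional[Mapping[str, Mapping[str, AnnotationTrack]]]
                     = None,
                     identity_bin_width: float = 0.10) -> CoverageSummary:
    """Coverage accounting over a protein set.

    Reports per-protein modeled fraction and model count; the set-level
    modeled residue fraction; the identity histogram of accepted fragments
    (default 10% bins) with the counts below 30% and above 90% identity;
    and, when disorder/coil tracks are supplied, the 2x2 residue cross-tab
    of modeled status against disordered-or-coil with all four conditional
    fractions (degenerate conditionals reported as None, not 0).
    """
    per_protein = {}
    total = modeled_total = 0
    frag_identities = []
    flags = []
    ct = {"modeled_dc": 0, "modeled_ord": 0, "unmodeled_dc": 0, "unmodeled_ord": 0}
    have_tracks = track_set is not None

    for pid, length in lengths.items():
        accepted = list(accepted_by_protein.get(pid, ()))
        track = modeled_track(pid, length, accepted)
        n_mod = sum(track.values)
        per_protein[pid] = {
            "length": length,
            "n_models": len(accepted),
            "modeled_residues": n_mod,
            "modeled_fraction": n_mod / length,
        }
        total += length
        modeled_total += n_mod
        for h in accepted:
            frag_identities.append(h.identity)
            flags.append({"query_id": pid, "template_id": h.template_id,
                          "identity": h.identity,
                          "action": ("retrieve" if h.identity >= RETRIEVE_IDENTITY
                                     else "model"),
                          "max_untemplated_gap": MAX_UNTEMPLATED_GAP})
        if have_tracks:
            bundle = track_set.get(pid)
            if bundle is None:
                continue
            dis = bundle.get("disorder")
            coil = bundle.get("coil")
            for i in range(length):
                d = bool(dis.values[i]) if dis is not None else False
                c = bool(coil.values[i]) if coil is not None else False
                dc = d or c
                m = track.values[i]
                key = ("modeled" if m else "unmodeled") + ("_dc" if dc else "_ord")
                ct[key] += 1

    if total == 0:
        raise ValueError("empty protein set")

    edges = np.arange(0.0, 1.0 + identity_bin_width / 2, identity_bin_width)
    hist_counts, _ = (np.histogram(frag_identities, bins=edges)
                      if frag_identities else (np.zeros(len(edges) - 1, dtype=int), edges))
    identity_histogram = {
        f"[{edges[i]:.0%},{edges[i+1]:.0%})": int(hist_counts[i])
        for i in range(len(edges) - 1)
    }

    crosstab: dict = {}
    if have_tracks:
        n_dc = ct["modeled_dc"] + ct["unmodeled_dc"]
        n_ord = ct["modeled_ord"] + ct["unmodeled_ord"]
        n_unmod = ct["unmodeled_dc"] + ct["unmodeled_ord"]
        n_mod = ct["modeled_dc"] + ct["modeled_ord"]
        crosstab = {
            "counts": dict(ct),
            "f_disorder_or_coil": n_dc / total,
            "f_ordered": n_ord / total,
            "p_modeled_given_ordered": ct["modeled_ord"] / n_ord if n_ord else None,
            "p_modeled_given_disorder_or_coil": (ct["modeled_dc"] / n_dc
                                                 if n_dc else None),
            "p_disorder_or_coil_given_unmodeled": (ct["unmodeled_dc"] / n_unmod
                                                   if n_unmod else None),
            "p_disorder_or_coil_given_modeled": (ct["modeled_dc"] / n_mod
                                                 if n_mod else None),
        }

    return CoverageSummary(
        per_protein=per_protein,
        set_modeled_fraction=modeled_total / total,
        n_residues=total,
        n_fragments=len(frag_identities),
        identity_histogram=identity_histogram,
        n_fragments_below_30=sum(1 for x in frag_identities if x < 0.30),
        n_fragments_above_90=sum(1 for x in frag_identities if x > 0.90),
        crosstab=crosstab,
        fragment_flags=flags,
    )
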