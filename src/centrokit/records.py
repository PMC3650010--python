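"""Core domain types shared across the toolkit.

Conventions used everywhere in this package:

* residue coordinates are 1-based and inclusive, matching the numbering of
  per-residue predictor output files;
* sequences use the 20 standard amino-acid letters plus ``X`` for unknown
  residues;
* per-residue annotation tracks are stored as plain lists/arrays aligned
  1:1 with the protein sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

#: valid three-class secondary-structure states
SS_CLASSES = ("H", "E", "C")

TRACK_KINDS = ("disorder", "coil", "ss", "modeled")
SET_LABELS = ("study", "control")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its gene and set membership.

    ``isoform_rank`` orders isoforms of a gene by decreasing length;
    rank 1 is the longest isoform (ties broken by lexicographically
    smallest id), the per-gene representative used throughout.
    """

    id: str
    sequence: str
    gene_id: str = ""
    isoform_rank: int = 1
    set_label: str = "study"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"protein {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        if self.set_label not in SET_LABELS:
            raise ValueError(f"set_label must be one of {SET_LABELS}")
        if not self.gene_id:
            object.__setattr__(self, "gene_id", self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationTrack:
    """A per-residue annotation vector aligned 1:1 with a protein sequence.

    ``values`` holds booleans for disorder/coil/modeled tracks and one of
    ``H``/``E``/``C`` for secondary-structure tracks.  ``source`` records
    provenance: ``imported`` for tracks read from external predictor files,
    ``builtin`` for tracks produced by the shipped stand-in predictors.
    The two are never mixed silently in set-level statistics.
    """

    protein_id: str
    kind: str
    values: list
    source: str = "imported"
    scores: Optional[list] = None

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"track kind must be one of {TRACK_KINDS}")
        self.values = list(self.values)
        if self.kind == "ss":
            bad = [v for v in self.values if v not in SS_CLASSES]
            if bad:
                raise ValueError(
                    f"ss track for {self.protein_id!r}: invalid state {bad[0]!r}; "
                    f"collapse to {SS_CLASSES} on import"
                )
        else:
            self.values = [bool(v) for v in self.values]
        if self.source not in ("imported", "builtin"):
            raise ValueError("source must be 'imported' or 'builtin'")
        if self.scores is not None and len(self.scores) != len(self.values):
            raise ValueError("scores and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)


#: interval type labels, in decreasing partition priority
INTERVAL_TYPES = ("smart_domain", "coil_stretch", "disorder_stretch", "residual")


@dataclass
class Interval:
    """A 1-based inclusive [start, end] span on a protein.

    ``evidence`` carries whatever the interval type needs: a SMART domain
    name and significance flag, an alignment Z-score and match length, or
    nothing for plain stretches and residual regions.
    """

    protein_id: str
    start: int
    end: int
    type: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in INTERVAL_TYPES:
            raise ValueError(f"interval type must be one of {INTERVAL_TYPES}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}] on {self.protein_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class EdgeList:
    """An undirected simple graph as a set of unordered id pairs."""

    edges: set
    node_ids: set
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @classmethod
    def from_pairs(cls, pairs) -> "EdgeList":
        """Build from (a, b) pairs, deduplicating and dropping self-loops."""
        edges: set = set()
        nodes: set = set()
        loops = dups = 0
        for a, b in pairs:
            nodes.add(a)
            nodes.add(b)
            if a == b:
                loops += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key in edges:
                dups += 1
            else:
                edges.add(key)
        return cls(edges=edges, node_ids=nodes,
                   n_self_loops_dropped=loops, n_duplicates_dropped=dups)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


@dataclass
class TemplateHit:
    """A candidate homology template match on a query protein.

    ``identical_residues`` — the ranking criterion for template selection —
    defaults to round-half-up(identity x aligned length) when the hit table
    carries no explicit count; an explicit count takes precedence.
    """

    query_id: str
    q_start: int
    q_end: int
    template_id: str
    identity: float
    probability: float = 1.0
    channel: str = "hmm"
    identical_residues: Optional[int] = None

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.template_id!r} on {self.query_id!r}: q_start > q_end"
            )
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0,1]")
        if self.channel not in ("hmm", "high_identity"):
            raise ValueError("channel must be 'hmm' or 'high_identity'")
        if self.identical_residues is None:
            self.identical_residues = _round_half_up(self.identity * self.span)

    @property
    def span(self) -> int:
        return self.q_end - self.q_start + 1
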