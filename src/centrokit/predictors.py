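"""Built-in stand-in predictors for coiled-coil and disorder tracks.

These are deliberately simple, fully deterministic scorers so that the
whole pipeline can be exercised without external prediction software.
They are NOT reimplementations of the published coiled-coil or disorder
predictors whose output files the I/O module imports; tracks they produce
carry ``source="builtin"`` and set-level statistics report that provenance
rather than mixing builtin and imported tracks silently.

* :func:`coil_score_track` scores the heptad (abcdefg) periodicity of
  coiled-coils with a sliding window over all seven register offsets,
  using a small shipped residue-propensity table that favours L/M/I/V at
  the hydrophobic core positions a/d and E/K/Q/R at the flanking e/g
  positions.
* :func:`disorder_index_track` computes a charge-hydropathy fold index
  (the classical linear discriminant a*<H> - |<q>| - b on the rescaled
  Kyte-Doolittle hydropathy and the mean net charge); residues with a
  negative index are called disordered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from .records import AnnotationTrack, ProteinRecord

logger = logging.getLogger(__name__)

# heptad positions grouped by structural role: a/d hydrophobic core,
# e/g charged flank, b/c/f solvent-exposed outer face
HEPTAD_GROUPS = ("core", "flank", "outer")
_POSITION_GROUP = ("core", "outer", "outer", "core", "flank", "outer", "flank")

_CORE = {"L": 3.0, "M": 2.5, "I": 2.5, "V": 2.2, "A": 1.5, "F": 1.5,
         "G": 0.2, "P": 0.1, "X": 1.0}
_FLANK = {"E": 2.5, "K": 2.5, "Q": 2.0, "R": 2.0, "D": 1.5, "N": 1.2,
          "G": 0.3, "P": 0.1, "X": 1.0}
_OUTER = {"G": 0.6, "P": 0.3, "X": 1.0}


def _full_table(base: dict, default: float) -> dict:
    table = {aa: default for aa in "ACDEFGHIKLMNPQRSTVWYX"}
    table.update(base)
    return table


DEFAULT_PROPENSITIES = {
    "core": _full_table(_CORE, 0.5),
    "flank": _full_table(_FLANK, 0.7),
    "outer": _full_table(_OUTER, 1.0),
}

# Kyte-Doolittle hydropathy; X gets the scale midpoint after rescaling
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}
RESIDUE_CHARGE = {aa: 0 for aa in "ACFGHILMNPQSTVWYX"}
RESIDUE_CHARGE.update({"D": -1, "E": -1, "K": 1, "R": 1})


@dataclass
class HeptadParams:
    """Parameters of the heptad coiled-coil scorer.

    ``window`` is the sliding-window width in residues (default 21, three
    heptads); ``position_weights`` multiply the propensity at each of the
    seven heptad positions a-g; ``residue_propensities`` maps each heptad
    position group to a residue->propensity table (strictly positive);
    ``score_threshold`` converts the real-valued score into boolean calls.
    """

    window: int = 21
    position_weights: tuple = (1.0,) * 7
    residue_propensities: dict = field(
        default_factory=lambda: {g: dict(DEFAULT_PROPENSITIES[g])
                                 for g in HEPTAD_GROUPS})
    score_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 7:
            raise ValueError("window must be >= 7 residues")
        if len(self.position_weights) != 7:
            raise ValueError("position_weights must have 7 entries")
        for group, table in self.residue_propensities.items():
            if any(v <= 0 for v in table.values()):
                raise ValueError(f"propensities in group {group!r} must be > 0")


@dataclass
class ChargeHydropathyParams:
    """Parameters of the charge-hydropathy disorder index.

    ``coefficients`` are the (a, b) of index = a*<H> - |<q>| - b with the
    hydropathy rescaled to [0, 1]; the defaults are the classical fold-index
    discriminant.  ``window`` of ``None`` means whole-sequence mode.
    """

    hydropathy_scale: dict = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    charge: dict = field(default_factory=lambda: dict(RESIDUE_CHARGE))
    coefficients: tuple = (2.785, 1.151)
    window: Optional[int] = None


def coil_score_track(protein: ProteinRecord,
                     params: Optional[HeptadParams] = None) -> AnnotationTrack:
    """Score heptad periodicity and call coiled-coil residues.

    For every window placement and each of the 7 register offsets the score
    is the geometric mean of the position-weighted residue propensities;
    each residue receives the maximum score over all window/register
    combinations covering it, and is called coil when that score reaches
    ``score_threshold``.  A sequence shorter than the window yields an
    all-false track with a logged warning.
    """
    params = params or HeptadParams()
    seq = protein.sequence
    n, w = len(seq), params.window
    if n < w:
        logger.warning("protein %s (%d aa) shorter than coil window %d; "
                       "all-false coil track", protein.id, n, w)
        return AnnotationTrack(protein_id=protein.id, kind="coil",
                               values=[False] * n, source="builtin",
                               scores=[0.0] * n)

    # log-propensity lookup per (register offset mod 7, residue)
    log_prop = [{} for _ in range(7)]
    for pos in range(7):
        group = _POSITION_GROUP[pos]
        weight = params.position_weights[pos]
        for aa, p in params.residue_propensities[group].items():
            log_prop[pos][aa] = math.log(weight * p)

    best = [float("-inf")] * n
    for start in range(0, n - w + 1):
        for register in range(7):
            total = 0.0
            for i in range(start, start + w):
                total += log_prop[(i - start + register) % 7][seq[i]]
            score = math.exp(total / w)
            for i in range(start, start + w):
                if score > best[i]:
                    best[i] = score
    values = [s >= params.score_threshold for s in best]
    return AnnotationTrack(protein_id=protein.id, kind="coil", values=values,
                           source="builtin", scores=best)


def disorder_index_track(protein: ProteinRecord,
                         params: Optional[ChargeHydropathyParams] = None
                         ) -> AnnotationTrack:
    """Charge-hydropathy disorder index; disordered iff index < 0.

    In whole-sequence mode every residue receives the same index (the mean
    is permutation-invariant); in windowed mode the index is computed over
    a centred window truncated at the sequence ends.
    """
    params = params or ChargeHydropathyParams()
    a, b = params.coefficients
    seq = protein.sequence
    n = len(seq)
    # hydropathy rescaled to [0,1]; X sits at the midpoint
    hmin, hmax = -4.5, 4.5
    h = [(params.hydropathy_scale[aa] - hmin) / (hmax - hmin) for aa in seq]
    q = [float(params.charge[aa]) for aa in seq]

    if params.window is None:
        mean_h = sum(h) / n
        mean_q = sum(q) / n
        idx = a * mean_h - abs(mean_q) - b
        scores = [idx] * n
    else:
        half = params.window // 2
        scores = []
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            mean_h = sum(h[lo:hi]) / (hi - lo)
            mean_q = sum(q[lo:hi]) / (hi - lo)
            scores.append(a * mean_h - abs(mean_q) - b)
    values = [s < 0 for s in scores]
    return AnnotationTrack(protein_id=protein.id, kind="disorder",
                           values=values, source="builtin", scores=scores)
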