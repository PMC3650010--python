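"""Joint-annotation statistics over per-residue tracks.

The central quantity is the log-ratio propensity

    Prop(A&B) = ln P(A&B) - ln P(A) - ln P(B)

which measures over-representation of a joint annotation (here: coiled-coil
and disordered at the same time) relative to independence of the two
marginals.  P(coil) is always the full coil marginal, i.e. dual
(coil-and-disorder) plus coil-only residues.

Set-level fractions are residue-weighted (pooled counts over all residues
of the set), because proteins differ hugely in length and the quantities of
interest are fractions "of the residues".  Per-protein fraction
distributions are available separately for histogramming.  Uncertainties
come from a protein-level bootstrap: residues within one protein are
strongly correlated, so resampling proteins (not residues) with
replacement is the honest resampling unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import AnnotationTrack, Interval

# a "track bundle" maps kind -> AnnotationTrack for one protein;
# a "track set" maps protein_id -> bundle


@dataclass
class JointStats:
    """Residue counts over joint annotation categories for a protein set."""

    n_residues: int
    n_proteins: int
    counts: dict
    p_disorder: float
    p_coil: float
    p_coil_and_disorder: float
    p_coil_not_disorder: float
    propensity: Optional[float]
    sources: tuple = ()

    def as_dict(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "n_proteins": self.n_proteins,
            "p_disorder": self.p_disorder,
            "p_coil": self.p_coil,
            "p_coil_and_disorder": self.p_coil_and_disorder,
            "p_coil_not_disorder": self.p_coil_not_disorder,
            "propensity_coil_and_disorder": self.propensity,
            "track_sources": list(self.sources),
        }


@dataclass
class ProteinFractions:
    """Per-protein coverage fractions behind the headline histograms."""

    protein_id: str
    f_disorder_and_coil: float
    f_disorder_not_coil: float
    f_modeled: Optional[float] = None
    f_ss_not_disorder_not_coil_not_modeled: Optional[float] = None


@dataclass
class SetComparison:
    """A study-vs-control metric with bootstrap standard errors."""

    metric: str
    study_value: float
    control_value: float
    study_se: float
    control_se: float
    unreliable: bool = False

    @property
    def difference(self) -> float:
        return self.study_value - self.control_value

    @property
    def combined_se(self) -> float:
        return math.hypot(self.study_se, self.control_se)


def propensity(p_joint: float, p_coil: float, p_disorder: float) -> float:
    """Log-ratio propensity ln(p_joint) - ln(p_coil) - ln(p_disorder).

    Natural-log units.  All arguments must lie in (0, 1]; a zero or
    negative argument makes the statistic undefined and raises rather than
    silently returning -inf.
    """
    for name, p in (("p_joint", p_joint), ("p_coil", p_coil),
                    ("p_disorder", p_disorder)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name}={p}: propensity requires values in (0, 1]")
    return math.log(p_joint) - math.log(p_coil) - math.log(p_disorder)


def _require(bundle: Mapping, pid: str, kind: str) -> AnnotationTrack:
    track = bundle.get(kind)
    if track is None:
        raise ValueError(f"protein {pid!r} is missing required {kind!r} track")
    return track


def joint_residue_counts(track_set: Mapping[str, Mapping[str, AnnotationTrack]]
                         ) -> JointStats:
    """Pool joint disorder x coil (and, when present, disorder x ss-class)
    residue counts over a protein set.

    Fractions are counts divided by the total residue count of the set.
    The propensity is None when any of its three inputs is zero (undefined,
    reported as absent).
    """
    counts = {"d_and_c": 0, "d_not_c": 0, "c_not_d": 0, "neither": 0}
    ss_counts: dict = {}
    total = 0
    sources = set()
    for pid, bundle in track_set.items():
        dis = _require(bundle, pid, "disorder")
        coil = _require(bundle, pid, "coil")
        if len(dis) != len(coil):
            raise ValueError(f"protein {pid!r}: track length mismatch")
        ss = bundle.get("ss")
        sources.add(dis.source)
        sources.add(coil.source)
        for i in range(len(dis)):
            d, c = dis.values[i], coil.values[i]
            if d and c:
                counts["d_and_c"] += 1
            elif d:
                counts["d_not_c"] += 1
            elif c:
                counts["c_not_d"] += 1
            else:
                counts["neither"] += 1
            if ss is not None:
                key = ("d" if d else "o", ss.values[i])
                ss_counts[key] = ss_counts.get(key, 0) + 1
        total += len(dis)
    if total == 0:
        raise ValueError("empty protein set")
    p_dual = counts["d_and_c"] / total
    p_d = (counts["d_and_c"] + counts["d_not_c"]) / total
    p_c = (counts["d_and_c"] + counts["c_not_d"]) / total
    prop = None
    if p_dual > 0 and p_c > 0 and p_d > 0:
        prop = propensity(p_dual, p_c, p_d)
    all_counts = dict(counts)
    if ss_counts:
        all_counts["disorder_x_ss"] = ss_counts
    return JointStats(n_residues=total, n_proteins=len(track_set),
                      counts=all_counts, p_disorder=p_d, p_coil=p_c,
                      p_coil_and_disorder=p_dual,
                      p_coil_not_disorder=counts["c_not_d"] / total,
                      propensity=prop, sources=tuple(sorted(sources)))


def extract_stretches(track: AnnotationTrack, min_run: int = 20,
                      type_label: Optional[str] = None) -> list[Interval]:
    """Maximal runs of true values STRICTLY longer than ``min_run``.

    With the default ``min_run=20`` this implements "consecutive stretches
    of more than 20 residues": a run of exactly 20 does not qualify.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if type_label is None:
        type_label = {"coil": "coil_stretch", "disorder": "disorder_stretch"}.get(
            track.kind, "residual")
    out = []
    start = None
    values = list(track.values) + [False]
    for i, v in enumerate(values):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > min_run:
                out.append(Interval(protein_id=track.protein_id,
                                    start=start + 1, end=i, type=type_label))
            start = None
    return out


def per_protein_fractions(track_set: Mapping[str, Mapping[str, AnnotationTrack]],
                          dual_coverage_threshold: float = 0.20,
                          bin_width: float = 0.05) -> dict:
    """Fractions of each protein's length in the four headline categories.

    Returns the per-protein table, histograms (default 5% bins over [0,1]),
    and the count of proteins whose disorder-and-coil fraction STRICTLY
    exceeds ``dual_coverage_threshold`` (a fraction of exactly the
    threshold is not counted).
    """
    fractions: list[ProteinFractions] = []
    for pid, bundle in track_set.items():
        dis = _require(bundle, pid, "disorder")
        coil = _require(bundle, pid, "coil")
        n = len(dis)
        ss = bundle.get("ss")
        modeled = bundle.get("modeled")
        dual = d_not_c = 0
        m_count = 0
        ss_rest = 0
        for i in range(n):
            d, c = dis.values[i], coil.values[i]
            m = bool(modeled.values[i]) if modeled is not None else False
            if d and c:
                dual += 1
            elif d:
                d_not_c += 1
            if m:
                m_count += 1
            if (ss is not None and ss.values[i] in ("H", "E")
                    and not d and not c and not m):
                ss_rest += 1
        fractions.append(ProteinFractions(
            protein_id=pid,
            f_disorder_and_coil=dual / n,
            f_disorder_not_coil=d_not_c / n,
            f_modeled=m_count / n if modeled is not None else None,
            f_ss_not_disorder_not_coil_not_modeled=(
                ss_rest / n if ss is not None and modeled is not None else None),
        ))

    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    hists = {}
    for name, attr in (("disorder_and_coil", "f_disorder_and_coil"),
                       ("disorder_not_coil", "f_disorder_not_coil"),
                       ("modeled", "f_modeled"),
                       ("ss_not_d_not_c_not_modeled",
                        "f_ss_not_disorder_not_coil_not_modeled")):
        vals = [getattr(f, attr) for f in fractions if getattr(f, attr) is not None]
        if vals:
            counts, _ = np.histogram(vals, bins=edges)
            hists[name] = counts.tolist()
    n_above = sum(1 for f in fractions
                  if f.f_disorder_and_coil > dual_coverage_threshold)
    return {"fractions": fractions, "histogram_bin_edges": edges.tolist(),
            "histograms": hists, "n_dual_above_threshold": n_above,
            "dual_coverage_threshold": dual_coverage_threshold}


def ss_class_fractions(track_set: Mapping[str, Mapping[str, AnnotationTrack]]
                       ) -> dict:
    """Residue-weighted secondary-structure class fractions over a set.

    Reports overall P(H), P(E), P(C), the joint fractions P(disorder & H)
    and P(disorder & C), and the same classes conditional on being
    disordered.  With no disordered residues the conditionals are undefined
    and reported as None, never as 0.
    """
    total = 0
    ss_tot = {"H": 0, "E": 0, "C": 0}
    dis_tot = 0
    dis_ss = {"H": 0, "E": 0, "C": 0}
    for pid, bundle in track_set.items():
        ss = bundle.get("ss")
        if ss is None:
            raise ValueError(f"protein {pid!r} is missing required 'ss' track")
        dis = _require(bundle, pid, "disorder")
        for i in range(len(ss)):
            total += 1
            ss_tot[ss.values[i]] += 1
            if dis.values[i]:
                dis_tot += 1
                dis_ss[ss.values[i]] += 1
    if total == 0:
        raise ValueError("empty protein set")
    out = {
        "p_H": ss_tot["H"] / total,
        "p_E": ss_tot["E"] / total,
        "p_C": ss_tot["C"] / total,
        "p_disorder_and_H": dis_ss["H"] / total,
        "p_disorder_and_C": dis_ss["C"] / total,
        "n_residues": total,
    }
    if dis_tot > 0:
        out["p_H_given_disorder"] = dis_ss["H"] / dis_tot
        out["p_C_given_disorder"] = dis_ss["C"] / dis_tot
    else:
        out["p_H_given_disorder"] = None
        out["p_C_given_disorder"] = None
    return out


# metrics the bootstrap comparison knows how to pool per protein:
# (dual, disorder-only, coil-only, residue count) suffice for all of them
def _protein_counts(bundle: Mapping[str, AnnotationTrack], pid: str):
    dis = _require(bundle, pid, "disorder")
    coil = _require(bundle, pid, "coil")
    dual = sum(1 for d, c in zip(dis.values, coil.values) if d and c)
    d_only = sum(1 for d, c in zip(dis.values, coil.values) if d and not c)
    c_only = sum(1 for d, c in zip(dis.values, coil.values) if c and not d)
    return np.array([dual, d_only, c_only, len(dis)], dtype=float)


def _pooled_metrics(counts: np.ndarray) -> dict:
    dual, d_only, c_only, n = counts.sum(axis=0)
    return {
        "p_disorder": (dual + d_only) / n,
        "p_coil": (dual + c_only) / n,
        "p_coil_and_disorder": dual / n,
    }


def compare_sets(study: Mapping[str, Mapping[str, AnnotationTrack]],
                 control: Mapping[str, Mapping[str, AnnotationTrack]],
                 n_boot: int = 1000, seed: int = 0) -> list[SetComparison]:
    """Study-vs-control residue fractions with protein-level bootstrap SEs.

    Proteins are resampled with replacement within each set (``n_boot``
    replicates, seeded and bit-reproducible); the SE is the standard
    deviation of the pooled metric over replicates.  A single-protein set
    still gets an SE but the comparison is flagged unreliable.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not study or not control:
        raise ValueError("both sets must be non-empty")
    rng = np.random.default_rng(seed)

    def prepare(track_set):
        pids = sorted(track_set)
        counts = np.stack([_protein_counts(track_set[p], p) for p in pids])
        point = _pooled_metrics(counts)
        reps: dict = {k: [] for k in point}
        n = len(pids)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            rep = _pooled_metrics(counts[idx])
            for k, v in rep.items():
                reps[k].append(v)
        ses = {k: float(np.std(v, ddof=1)) for k, v in reps.items()}
        return point, ses, n

    s_point, s_se, s_n = prepare(study)
    c_point, c_se, c_n = prepare(control)
    unreliable = s_n < 2 or c_n < 2
    return [SetComparison(metric=k, study_value=s_point[k],
                          control_value=c_point[k], study_se=s_se[k],
                          control_se=c_se[k], unreliable=unreliable)
            for k in s_point]
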