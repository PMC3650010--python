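"""Synthetic protein cohorts with controlled statistical structure.

The generator emulates the statistical anatomy of a centrosome-like
proteome so that every pipeline stage has a no-download test bed with
exact ground truth:

* protein lengths are log-normal with a heavy right tail (defaults target
  a mean of ~796 residues for the study-like set; a control-like set uses
  ~599);
* each protein is assembled segment by segment from a five-type grammar —
  globular, disordered loop, disordered helical, coil-and-disordered,
  coil-and-ordered — with segment-type probabilities derived from target
  joint residue fractions (defaults: P(disorder)=0.57,
  P(coil&disorder)=0.124, P(coil&not-disorder)=0.007,
  P(disorder&helical)=0.30, matching the study-set residue fractions the
  pipeline is meant to recover);
* sequences are composed per segment type (heptad repeats for coil
  segments, disorder-promoting composition for disordered segments, mixed
  composition for globular ones), but the emitted annotation tracks come
  from the generating segment labels — the ground truth — not from any
  predictor, so statistics tests are independent of predictor quality;
* template hits are placed preferentially on ordered regions with a
  bimodal identity mixture (low ~0.25 / high ~0.92 peaks, mixture weights
  99:174), calibrated so ideal selection models ~27.6% of residues;
* interaction graphs have exact node and edge counts under a uniform or
  preferential-attachment degree model.

All randomness flows from the single ``seed`` of the spec through
``numpy.random.SeedSequence`` child streams (one per subsystem), so equal
seeds give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import math

import networkx as nx
import numpy as np

from .records import AnnotationTrack, EdgeList, ProteinRecord, TemplateHit

SEGMENT_TYPES = ("globular", "disordered_loop", "disordered_helical",
                 "coil_disordered", "coil_ordered")

# residue composition per segment type (weights, normalized at use)
_DISORDER_COMP = {"P": 8, "E": 10, "S": 9, "Q": 6, "K": 8, "G": 8, "A": 7,
                  "D": 6, "T": 5, "R": 5, "N": 4, "L": 3, "V": 2, "I": 1,
                  "M": 1, "H": 2, "F": 1, "Y": 1, "C": 1, "W": 1}
_GLOBULAR_COMP = {"A": 8, "L": 9, "V": 7, "I": 6, "F": 4, "M": 2, "W": 1,
                  "Y": 3, "C": 2, "G": 7, "P": 4, "S": 6, "T": 5, "N": 4,
                  "Q": 4, "D": 5, "E": 6, "K": 6, "R": 5, "H": 2}
_HEPTAD_CORE = {"L": 10, "M": 3, "I": 4, "V": 4, "A": 2}
_HEPTAD_FLANK = {"E": 8, "K": 7, "Q": 4, "R": 4, "D": 2, "N": 1}
_HEPTAD_OUTER = {"A": 5, "S": 4, "Q": 4, "E": 4, "K": 4, "N": 3, "T": 3,
                 "R": 3, "D": 3, "L": 2}


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic cohort.

    ``target_joint`` drives the segment grammar: segment-type residue
    fractions are derived from the requested joint fractions (coil
    segments are helical, so P(disorder&H) splits into the coil-disordered
    fraction plus a disordered-helical remainder).  Inconsistent targets
    (e.g. P(coil&disorder) > P(disorder)) are rejected before sampling.
    """

    n_proteins: int = 500
    length_mean: float = 796.0
    length_log_sigma: float = 0.8
    min_length: int = 60
    target_joint: dict = field(default_factory=lambda: {
        "p_disorder": 0.57,
        "p_coil_and_disorder": 0.124,
        "p_coil_not_disorder": 0.007,
        "p_disorder_and_H": 0.30,
    })
    mean_segment_length: dict = field(default_factory=lambda: {
        "globular": 150.0, "disordered_loop": 60.0, "disordered_helical": 40.0,
        "coil_disordered": 60.0, "coil_ordered": 30.0,
    })
    # secondary structure inside globular segments (H, E, C); chosen so the
    # pooled helix/strand fractions land near 52%/7% with the default grammar
    globular_ss_probs: tuple = (0.504, 0.165, 0.331)
    # per-protein dispersion of dual (coil-and-disordered) content: each
    # protein's dual-residue fraction is drawn from a Gamma law with the
    # pooled target as mean, concentrating coiled-coil content in a subset
    # of proteins as in real proteomes.  Shape 2.6 puts ~15% of proteins
    # above 20% dual coverage at the default mean of 0.124 while
    # preserving the pooled fraction.  None reverts to iid segment typing.
    dual_dispersion_shape: Optional[float] = 2.6
    dual_fraction_cap: float = 0.6
    # Dirichlet concentration of the remaining per-protein composition
    # around the grammar fractions; smaller = more protein-to-protein
    # heterogeneity in disorder/globular content
    composition_concentration: float = 8.0
    # template model
    hit_rate_ordered: float = 0.64
    hit_rate_disordered: float = 0.09
    ordered_cover_range: tuple = (0.85, 1.0)
    disordered_cover_range: tuple = (0.5, 0.8)
    min_ordered_run: int = 40
    min_disordered_run: int = 60
    identity_low: tuple = (0.25, 0.03)     # mean, sd of the low peak
    identity_high: tuple = (0.92, 0.025)
    identity_weights: tuple = (99, 174)    # low : high mixture weights
    decoy_rate: float = 0.15
    # network model
    n_nodes: int = 167
    n_edges: int = 354
    network_model: str = "uniform"         # uniform | preferential
    seed: int = 0

    def segment_fractions(self) -> dict:
        t = self.target_joint
        p_d = t["p_disorder"]
        p_cd = t["p_coil_and_disorder"]
        p_co = t["p_coil_not_disorder"]
        p_dh = t.get("p_disorder_and_H", p_cd)
        fr = {
            "coil_disordered": p_cd,
            "coil_ordered": p_co,
            "disordered_helical": p_dh - p_cd,
            "disordered_loop": p_d - p_dh,
            "globular": 1.0 - p_d - p_co,
        }
        for name, f in fr.items():
            if f < 0 or f > 1:
                raise ValueError(
                    f"inconsistent target_joint: derived fraction "
                    f"{name}={f:.4f} outside [0,1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("segment fractions do not sum to 1")
        return fr


def _draw(rng, table: dict, size: int) -> list[str]:
    letters = list(table)
    w = np.array([table[x] for x in letters], dtype=float)
    w /= w.sum()
    return list(rng.choice(letters, size=size, p=w))


def _coil_sequence(rng, length: int) -> str:
    core = _draw(rng, _HEPTAD_CORE, length)
    flank = _draw(rng, _HEPTAD_FLANK, length)
    outer = _draw(rng, _HEPTAD_OUTER, length)
    groups = ("core", "outer", "outer", "core", "flank", "outer", "flank")
    out = []
    for i in range(length):
        g = groups[i % 7]
        out.append({"core": core, "flank": flank, "outer": outer}[g][i])
    return "".join(out)


def _segment_sequence(rng, seg_type: str, length: int) -> str:
    if seg_type.startswith("coil"):
        return _coil_sequence(rng, length)
    table = _DISORDER_COMP if seg_type.startswith("disordered") else _GLOBULAR_COMP
    return "".join(_draw(rng, table, length))


def sample_protein_set(spec: SyntheticSpec, set_label: str = "study"):
    """Generate a cohort of proteins with ground-truth annotation tracks.

    Returns ``(records, track_set, ledger)`` where ``track_set`` maps
    protein id to its disorder/coil/ss tracks (emitted from the generating
    segment labels) and ``ledger`` holds the exact realized joint residue
    fractions alongside the requested targets.
    """
    fractions = spec.segment_fractions()
    rng = _subrng(spec.seed, 0)

    def blocks(total: int, mean_len: float) -> list[int]:
        """Split a residue budget into contiguous blocks of ~mean_len."""
        if total <= 0:
            return []
        k = max(1, int(round(total / mean_len)))
        if k == 1:
            return [total]
        cuts = sorted(int(c) + 1 for c in rng.choice(total - 1, size=k - 1,
                                                     replace=False))
        return [b - a for a, b in zip([0] + cuts, cuts + [total])]

    mu = math.log(spec.length_mean) - spec.length_log_sigma ** 2 / 2
    gH, gE, gC = spec.globular_ss_probs

    records, track_set = [], {}
    seg_counter = 0
    for k in range(spec.n_proteins):
        pid = f"SYN{k:04d}"
        length = max(spec.min_length,
                     int(round(rng.lognormal(mean=mu,
                                             sigma=spec.length_log_sigma))))

        # per-protein dual (coil-and-disordered) residue budget, drawn from
        # a gamma law around the pooled target so a realistic minority of
        # proteins is strongly coiled-coil; the budget is then laid down as
        # coil-stretch-sized blocks, the rest follows the iid grammar
        base_dual = fractions["coil_disordered"]
        if spec.dual_dispersion_shape and base_dual > 0:
            v = min(rng.gamma(spec.dual_dispersion_shape,
                              base_dual / spec.dual_dispersion_shape),
                    spec.dual_fraction_cap)
        else:
            v = base_dual
        n_dual = int(round(v * length))

        # remaining residues: per-protein composition drawn from a
        # Dirichlet around the grammar fractions (unbiased, heterogeneous),
        # laid down as blocks of the type's characteristic length and
        # shuffled into random order together with the dual blocks
        remaining = length - n_dual
        rest_types = [t for t in SEGMENT_TYPES
                      if t != "coil_disordered" and fractions[t] > 0]
        segments: list = []  # (type, length) pairs
        if remaining > 0 and rest_types:
            base = np.array([fractions[t] for t in rest_types])
            base /= base.sum()
            if len(rest_types) > 1 and spec.composition_concentration:
                comp = rng.dirichlet(spec.composition_concentration * base)
            else:
                comp = base
            budgets = np.floor(comp * remaining).astype(int)
            shortfall = remaining - int(budgets.sum())
            for _ in range(shortfall):  # distribute rounding remainder
                budgets[int(rng.choice(len(rest_types), p=base))] += 1
            for t, budget in zip(rest_types, budgets):
                for size in blocks(int(budget), spec.mean_segment_length[t]):
                    segments.append((t, size))
        elif remaining > 0:
            segments.append(("disordered_loop", remaining))
        for size in blocks(n_dual, spec.mean_segment_length["coil_disordered"]):
            segments.append(("coil_disordered", size))
        order = rng.permutation(len(segments))
        segments = [segments[int(i)] for i in order]

        seq_parts, dis, coil, ss = [], [], [], []
        for seg_type, seg_len in segments:
            seg_counter += 1
            seq_parts.append(_segment_sequence(rng, seg_type, seg_len))
            d = seg_type in ("disordered_loop", "disordered_helical",
                             "coil_disordered")
            c = seg_type.startswith("coil")
            dis.extend([d] * seg_len)
            coil.extend([c] * seg_len)
            if seg_type == "globular":
                ss.extend(rng.choice(["H", "E", "C"], size=seg_len,
                                     p=[gH, gE, gC]))
            elif seg_type == "disordered_loop":
                ss.extend(["C"] * seg_len)
            else:  # helical: disordered_helical and both coil types
                ss.extend(["H"] * seg_len)
        sequence = "".join(seq_parts)
        records.append(ProteinRecord(id=pid, sequence=sequence,
                                     set_label=set_label))
        track_set[pid] = {
            "disorder": AnnotationTrack(pid, "disorder", dis, source="builtin"),
            "coil": AnnotationTrack(pid, "coil", coil, source="builtin"),
            "ss": AnnotationTrack(pid, "ss", list(ss), source="builtin"),
        }

    ledger = _realized_fractions(track_set)
    ledger["targets"] = dict(spec.target_joint)
    ledger["n_proteins"] = spec.n_proteins
    ledger["n_segments"] = seg_counter
    ledger["mean_length"] = (sum(len(r) for r in records) / len(records))
    return records, track_set, ledger


def _realized_fractions(track_set) -> dict:
    total = dual = d_tot = c_only = d_and_H = 0
    for pid, bundle in track_set.items():
        dis, coil, ss = (bundle["disorder"].values, bundle["coil"].values,
                         bundle["ss"].values)
        for i in range(len(dis)):
            total += 1
            if dis[i]:
                d_tot += 1
                if coil[i]:
                    dual += 1
                if ss[i] == "H":
                    d_and_H += 1
            elif coil[i]:
                c_only += 1
    return {
        "realized": {
            "p_disorder": d_tot / total,
            "p_coil_and_disorder": dual / total,
            "p_coil_not_disorder": c_only / total,
            "p_disorder_and_H": d_and_H / total,
            "n_residues": total,
        }
    }


def _subrng(seed: int, stream: int) -> np.random.Generator:
    """Child generator ``stream`` of the top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def _bool_runs(values, min_len: int):
    runs, start = [], None
    vals = list(values) + [False]
    for i, v in enumerate(vals):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                runs.append((start + 1, i))  # 1-based inclusive
            start = None
    return runs


def sample_template_hits(spec: SyntheticSpec, records, track_set):
    """Generate a template-hit table with known ideal coverage.

    One primary hit at most per ordered (neither disordered nor coil) run
    and per long disordered-or-coil run, so the primary hits of a protein
    are span-disjoint and the modeled fraction implied by ideal selection
    is exactly the union of their spans (recorded in the returned ledger).
    Nested decoy hits with lower identity exercise the overlap rule
    downstream without changing the ideal coverage.
    """
    rng = _subrng(spec.seed, 1)
    low_w, high_w = spec.identity_weights
    p_high = high_w / (low_w + high_w)

    def draw_identity(force_low=False):
        if not force_low and rng.random() < p_high:
            m, s = spec.identity_high
        else:
            m, s = spec.identity_low
        lo = 0.21 if (force_low or (m, s) == spec.identity_low) else 0.71
        return float(np.clip(rng.normal(m, s), lo, 0.999))

    hits, t_counter = [], 0
    ideal_modeled = total = 0
    for rec in records:
        pid = rec.id
        total += len(rec)
        bundle = track_set[pid]
        dc = [d or c for d, c in zip(bundle["disorder"].values,
                                     bundle["coil"].values)]
        ordered_runs = _bool_runs([not x for x in dc], spec.min_ordered_run)
        dis_runs = _bool_runs(dc, spec.min_disordered_run)

        def place(run, cover_range, force_low):
            nonlocal t_counter, ideal_modeled
            lo, hi = run
            run_len = hi - lo + 1
            cover = rng.uniform(*cover_range)
            span = int(round(cover * run_len))
            if span < 32:
                return
            start = lo + int(rng.integers(0, run_len - span + 1))
            identity = draw_identity(force_low)
            t_counter += 1
            hit = TemplateHit(
                query_id=pid, q_start=start, q_end=start + span - 1,
                template_id=f"T{t_counter:05d}",
                identity=identity,
                probability=float(rng.uniform(0.96, 0.9999)),
                channel="high_identity" if identity > 0.70 else "hmm")
            hits.append(hit)
            ideal_modeled += span
            if rng.random() < spec.decoy_rate and span >= 80:
                t_counter += 1
                d_span = int(span * rng.uniform(0.3, 0.5))
                d_start = hit.q_start + int(rng.integers(5, span - d_span - 4))
                hits.append(TemplateHit(
                    query_id=pid, q_start=d_start, q_end=d_start + d_span - 1,
                    template_id=f"T{t_counter:05d}",
                    identity=max(0.21, identity * 0.8),
                    probability=float(rng.uniform(0.96, 0.9999)),
                    channel="hmm"))

        for run in ordered_runs:
            if rng.random() < spec.hit_rate_ordered:
                place(run, spec.ordered_cover_range, force_low=False)
        for run in dis_runs:
            if rng.random() < spec.hit_rate_disordered:
                place(run, spec.disordered_cover_range, force_low=True)

    ledger = {"ideal_modeled_fraction": ideal_modeled / total,
              "n_hits": len(hits), "n_residues": total}
    return hits, ledger


def sample_network(spec: SyntheticSpec,
                   node_ids: Optional[list] = None) -> EdgeList:
    """Random interaction graph with exact node and edge counts."""
    n, m = spec.n_nodes, spec.n_edges
    if m > n * (n - 1) // 2:
        raise ValueError(f"cannot place {m} edges on {n} nodes")
    rng = _subrng(spec.seed, 2)
    if spec.network_model == "uniform":
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(0, 2 ** 31)))
    elif spec.network_model == "preferential":
        ba_m = max(1, round(m / n))
        g = nx.barabasi_albert_graph(n, ba_m,
                                     seed=int(rng.integers(0, 2 ** 31)))
        # trim or top up to the exact edge count
        edges = list(g.edges())
        while g.number_of_edges() > m:
            e = edges.pop(int(rng.integers(0, len(edges))))
            g.remove_edge(*e)
        while g.number_of_edges() < m:
            u, v = rng.integers(0, n, size=2)
            if u != v and not g.has_edge(int(u), int(v)):
                g.add_edge(int(u), int(v))
    else:
        raise ValueError("network_model must be 'uniform' or 'preferential'")
    if node_ids is None:
        node_ids = [f"SYN{i:04d}" for i in range(n)]
    if len(node_ids) < n:
        raise ValueError("need at least n_nodes node ids")
    mapping = {i: node_ids[i] for i in range(n)}
    pairs = [(mapping[a], mapping[b]) for a, b in g.edges()]
    el = EdgeList.from_pairs(pairs)
    el.node_ids.update(node_ids[:n])
    return el


def write_bundle(out_dir, spec: SyntheticSpec, set_label: str = "study") -> dict:
    """Generate a full cohort and write it as plain-text files.

    Writes FASTA sequences, one generic_tsv track file per protein and
    kind, the template-hit table, the edge list, and a ground_truth.json
    with the realized fractions.  Returns the ground-truth dictionary.
    """
    from . import io as ckio

    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    records, track_set, ledger = sample_protein_set(spec, set_label=set_label)
    ckio.write_sequences(records, out / "proteins.fasta")
    by_id = {r.id: r for r in records}
    for pid, bundle in track_set.items():
        for kind, track in bundle.items():
            ckio.write_track(track, by_id[pid], out / "tracks" / f"{pid}.{kind}.tsv")
    hits, hit_ledger = sample_template_hits(spec, records, track_set)
    ckio.write_hit_table(hits, out / "hits.tsv")
    net_spec_nodes = [r.id for r in records[:spec.n_nodes]]
    edges = sample_network(spec, node_ids=net_spec_nodes)
    ckio.write_edge_list(edges, out / "edges.tsv")
    ground_truth = {"spec": asdict(spec), **ledger, "templates": hit_ledger,
                    "network": {"n_nodes": edges.n_nodes, "n_edges": edges.n_edges}}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
    return ground_truth
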