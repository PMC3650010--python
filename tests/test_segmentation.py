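"""Priority partition and globular-domain calls, against brute force."""

import itertools
import random

import pytest

from centrokit import (
    AnnotationTrack,
    Interval,
    call_globular,
    identity_filter,
    partition_sequence,
)
from centrokit.segmentation import DomainCall, interval_disorder_coil_fraction


def smart(pid, start, end, name="DOM", significant=True):
    return Interval(pid, start, end, "smart_domain",
                    {"domain_name": name, "significant": significant})


def track(pid, kind, values):
    return AnnotationTrack(pid, kind, values)


def run_track(length, runs):
    values = [False] * length
    for lo, hi in runs:  # 1-based inclusive
        for i in range(lo - 1, hi):
            values[i] = True
    return values


# ---------------------------------------------------------------------------
# independent oracle: per-residue priority painting + strict re-testing

def oracle_partition(length, smart_ivs, coil_values, disorder_values,
                     min_run=20):
    """Re-derive the partition with a different mechanism: paint residues
    in priority order, splitting surviving stretch pieces by groupby."""
    paint = ["residual"] * length
    owner = [None] * length
    merged = []
    for iv in sorted(smart_ivs, key=lambda x: (x.start, x.end)):
        if merged and iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    for idx, (lo, hi) in enumerate(merged):
        for i in range(lo - 1, hi):
            paint[i] = "smart_domain"
            owner[i] = ("s", idx)

    for label, values in (("coil_stretch", coil_values),
                          ("disorder_stretch", disorder_values)):
        if values is None:
            continue
        # maximal true runs strictly longer than min_run
        runs = []
        for k, grp in itertools.groupby(range(length), key=lambda i: values[i]):
            idxs = list(grp)
            if k and len(idxs) > min_run:
                runs.append(idxs)
        for ridx, idxs in enumerate(runs):
            free = [i for i in idxs if paint[i] == "residual"]
            for k2, grp in itertools.groupby(enumerate(free),
                                             key=lambda t: t[1] - t[0]):
                piece = [i for _, i in grp]
                if len(piece) > min_run:
                    for i in piece:
                        paint[i] = label
                        owner[i] = (label, ridx, piece[0])

    out = []
    for key, grp in itertools.groupby(range(length),
                                      key=lambda i: (paint[i], owner[i])):
        idxs = list(grp)
        out.append((idxs[0] + 1, idxs[-1] + 1, key[0]))
    return out


def oracle_call(start, end, kind, evidence, z_rec, dc_fraction,
                smart_min=30, residual_min=40, z_thr=3.0, dc_max=0.30):
    """Direct re-statement of the published conditions for one interval."""
    length = end - start + 1
    if kind == "smart_domain":
        return ("globular_condition1"
                if evidence.get("significant") and length >= smart_min
                else "rejected")
    if kind == "residual":
        if length > residual_min and z_rec is not None \
                and z_rec > z_thr and dc_fraction < dc_max:
            return "globular_condition2"
        return "rejected"
    return "rejected"


def random_layout(rng, length):
    smart_ivs = []
    for _ in range(rng.randint(0, 3)):
        lo = rng.randint(1, length - 5)
        hi = min(length, lo + rng.randint(5, 120))
        smart_ivs.append(smart("P", lo, hi))
    def rand_values():
        values = [False] * length
        pos = 0
        while pos < length:
            run = rng.randint(1, 80)
            if rng.random() < 0.45:
                for i in range(pos, min(length, pos + run)):
                    values[i] = True
            pos += run
        return values
    return smart_ivs, rand_values(), rand_values()


class TestPartition:
    def test_hand_traced_layout(self):
        length = 500
        coil = track("P", "coil", run_track(length, [(130, 200)]))
        dis = track("P", "disorder", run_track(length, [(70, 120)]))
        part = partition_sequence(length, "P", [smart("P", 10, 60)], coil, dis)
        got = [(iv.start, iv.end, iv.type) for iv in part]
        assert got == [(1, 9, "residual"), (10, 60, "smart_domain"),
                       (61, 69, "residual"), (70, 120, "disorder_stretch"),
                       (121, 129, "residual"), (130, 200, "coil_stretch"),
                       (201, 500, "residual")]

    def test_truncated_stretch_reverts_to_residual(self):
        # coil run [50,80] truncated by SMART [10,60] -> [61,80] has 20
        # residues, not more than 20, so it becomes residual
        length = 100
        coil = track("P", "coil", run_track(length, [(50, 80)]))
        part = partition_sequence(length, "P", [smart("P", 10, 60)], coil, None)
        got = [(iv.start, iv.end, iv.type) for iv in part]
        assert got == [(1, 9, "residual"), (10, 60, "smart_domain"),
                       (61, 100, "residual")]

    def test_no_annotations_single_residual(self):
        part = partition_sequence(80, "P", [], None, None)
        assert [(iv.start, iv.end, iv.type) for iv in part] == \
            [(1, 80, "residual")]

    def test_overlapping_smart_merged(self, caplog):
        with caplog.at_level("WARNING"):
            part = partition_sequence(100, "P",
                                      [smart("P", 10, 40), smart("P", 30, 70)],
                                      None, None)
        types = [(iv.start, iv.end, iv.type) for iv in part]
        assert (10, 70, "smart_domain") in types
        assert "merging" in caplog.text

    def test_covers_every_residue_exactly_once_random(self):
        rng = random.Random(42)
        for _ in range(200):
            length = rng.randint(30, 400)
            smart_ivs, coil_v, dis_v = random_layout(rng, length)
            part = partition_sequence(length, "P", smart_ivs,
                                      track("P", "coil", coil_v),
                                      track("P", "disorder", dis_v))
            covered = []
            for iv in part:
                covered.extend(range(iv.start, iv.end + 1))
            assert covered == list(range(1, length + 1))

    def test_agrees_with_oracle_on_random_layouts(self):
        rng = random.Random(7)
        for _ in range(300):
            length = rng.randint(30, 400)
            smart_ivs, coil_v, dis_v = random_layout(rng, length)
            part = partition_sequence(length, "P", smart_ivs,
                                      track("P", "coil", coil_v),
                                      track("P", "disorder", dis_v))
            got = [(iv.start, iv.end, iv.type) for iv in part]
            assert got == oracle_partition(length, smart_ivs, coil_v, dis_v)

    def test_raising_min_run_shrinks_stretch_coverage(self):
        """Per track, raising the run-length threshold can only shrink the
        residues covered by qualifying stretches.  (The full priority
        partition is NOT monotone: un-claiming a short coil run can let a
        long disorder run survive unfragmented.)"""
        from centrokit import extract_stretches

        rng = random.Random(3)
        for _ in range(50):
            length = rng.randint(50, 300)
            _, coil_v, dis_v = random_layout(rng, length)
            for values in (coil_v, dis_v):
                t = track("P", "coil", values)
                prev = None
                for min_run in (5, 10, 20, 30):
                    cov = sum(iv.length
                              for iv in extract_stretches(t, min_run=min_run))
                    if prev is not None:
                        assert cov <= prev
                    prev = cov


class TestCallGlobular:
    def test_significant_smart_of_51_residues(self):
        part = [smart("P", 10, 60)]
        (call,) = call_globular(part, {})
        assert call.verdict == "globular_condition1"

    def test_smart_of_29_residues_too_short(self):
        part = [smart("P", 10, 38)]
        (call,) = call_globular(part, {})
        assert call.verdict == "rejected"
        assert call.rejection_reason == "too_short"

    def test_smart_of_exactly_30_residues_inclusive(self):
        part = [smart("P", 11, 40)]
        (call,) = call_globular(part, {})
        assert call.verdict == "globular_condition1"

    def _residual_case(self, dc_count, z=3.5, length=291):
        iv = Interval("P", 1, length, "residual")
        dis = track("P", "disorder",
                    [True] * dc_count + [False] * (length - dc_count))
        coil = track("P", "coil", [False] * length)
        aligns = {("P", 1, length): {"z_score": z, "match_length": length}}
        (call,) = call_globular([iv], aligns, dis, coil)
        return call

    def test_condition2_low_disorder(self):
        call = self._residual_case(dc_count=29)  # 29/291 ~ 0.10
        assert call.verdict == "globular_condition2"

    def test_exactly_30_percent_disorder_rejected(self):
        call = self._residual_case(dc_count=87, length=290)  # exactly 0.30
        assert call.verdict == "rejected"
        assert call.rejection_reason == "too_disordered"

    def test_z_at_threshold_rejected(self):
        call = self._residual_case(dc_count=0, z=3.0)
        assert call.verdict == "rejected"
        assert call.rejection_reason == "low_Z"

    def test_residual_of_exactly_40_too_short(self):
        iv = Interval("P", 1, 40, "residual")
        (call,) = call_globular([iv], {("P", 1, 40): {"z_score": 9.0,
                                                      "match_length": 40}})
        assert call.rejection_reason == "too_short"

    def test_residual_of_41_is_eligible(self):
        iv = Interval("P", 1, 41, "residual")
        dis = track("P", "disorder", [False] * 41)
        (call,) = call_globular([iv], {("P", 1, 41): {"z_score": 9.0,
                                                      "match_length": 41}},
                                dis, None)
        assert call.verdict == "globular_condition2"

    def test_missing_alignment_recorded_not_raised(self):
        iv = Interval("P", 1, 100, "residual")
        (call,) = call_globular([iv], {})
        assert call.verdict == "rejected"
        assert call.rejection_reason == "missing_evidence"

    def test_union_vs_sum_counting_modes(self):
        iv = Interval("P", 1, 100, "residual")
        dis = track("P", "disorder", [True] * 20 + [False] * 80)
        coil = track("P", "coil", [True] * 20 + [False] * 80)
        assert interval_disorder_coil_fraction(iv, dis, coil, "union") == 0.20
        assert interval_disorder_coil_fraction(iv, dis, coil, "sum") == 0.40

    def test_agrees_with_oracle_on_random_partitions(self):
        """Verdicts match a direct re-statement of the published
        conditions on 1000 random annotation layouts."""
        rng = random.Random(13)
        n_layouts = 0
        while n_layouts < 1000:
            length = rng.randint(30, 350)
            smart_ivs, coil_v, dis_v = random_layout(rng, length)
            coil_t, dis_t = track("P", "coil", coil_v), track("P", "disorder", dis_v)
            part = partition_sequence(length, "P", smart_ivs, coil_t, dis_t)
            aligns = {}
            for iv in part:
                if iv.type == "residual" and rng.random() < 0.8:
                    aligns[("P", iv.start, iv.end)] = {
                        "z_score": rng.uniform(0, 8),
                        "match_length": iv.length}
            calls = call_globular(part, aligns, dis_t, coil_t)
            for call in calls:
                iv = call.interval
                rec = aligns.get(("P", iv.start, iv.end))
                dc = interval_disorder_coil_fraction(iv, dis_t, coil_t)
                expected = oracle_call(iv.start, iv.end, iv.type, iv.evidence,
                                       rec["z_score"] if rec else None, dc)
                assert call.verdict == expected, (iv, call)
            n_layouts += 1


class TestIdentityFilter:
    def _call(self, start=1, end=60):
        return DomainCall(interval=smart("P", start, end),
                          verdict="globular_condition1")

    def test_identity_above_40_discarded(self):
        (out,) = identity_filter([self._call()], {("P", 1, 60): 0.45})
        assert out.verdict == "rejected"
        assert out.rejection_reason == "high_identity"

    def test_identity_exactly_40_retained(self):
        (out,) = identity_filter([self._call()], {("P", 1, 60): 0.40})
        assert out.verdict == "globular_condition1"
        assert out.pdb_identity == 0.40

    def test_no_identity_record_retained(self):
        (out,) = identity_filter([self._call()], {})
        assert out.verdict == "globular_condition1"

    def test_identity_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            identity_filter([self._call()], {("P", 1, 60): 1.2})
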