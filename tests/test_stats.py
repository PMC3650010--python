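"""Joint-annotation statistics: counts, propensity, stretches, comparisons."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from centrokit import (
    AnnotationTrack,
    compare_sets,
    extract_stretches,
    joint_residue_counts,
    per_protein_fractions,
    propensity,
    ss_class_fractions,
)


def bundle(pid, disorder, coil, ss=None, modeled=None):
    b = {"disorder": AnnotationTrack(pid, "disorder", disorder),
         "coil": AnnotationTrack(pid, "coil", coil)}
    if ss is not None:
        b["ss"] = AnnotationTrack(pid, "ss", ss)
    if modeled is not None:
        b["modeled"] = AnnotationTrack(pid, "modeled", modeled)
    return b


class TestJointCounts:
    def test_hand_count(self):
        ts = {"P1": bundle("P1", [True] * 10, [True] * 5 + [False] * 5),
              "P2": bundle("P2", [True] * 10, [False] * 10)}
        js = joint_residue_counts(ts)
        assert js.p_disorder == 1.0
        assert js.p_coil_and_disorder == 0.25
        assert js.p_coil_not_disorder == 0.0

    def test_all_false(self):
        ts = {"P1": bundle("P1", [False] * 8, [False] * 8)}
        js = joint_residue_counts(ts)
        assert js.p_disorder == js.p_coil == js.p_coil_and_disorder == 0.0
        assert js.propensity is None  # undefined, not -inf

    def test_missing_track_names_protein(self):
        ts = {"P1": {"disorder": AnnotationTrack("P1", "disorder", [True])}}
        with pytest.raises(ValueError, match="P1"):
            joint_residue_counts(ts)

    def test_additive_over_disjoint_sets(self, small_cohort):
        _, _, track_set, _ = small_cohort
        pids = sorted(track_set)
        half = len(pids) // 2
        a = joint_residue_counts({p: track_set[p] for p in pids[:half]})
        b = joint_residue_counts({p: track_set[p] for p in pids[half:]})
        both = joint_residue_counts(track_set)
        for key in ("d_and_c", "d_not_c", "c_not_d", "neither"):
            assert a.counts[key] + b.counts[key] == both.counts[key]

    def test_provenance_reported(self):
        ts = {"P1": bundle("P1", [True] * 4, [False] * 4)}
        assert joint_residue_counts(ts).sources == ("imported",)


class TestPropensity:
    def test_study_worked_value(self):
        # dual 12.4%, coil-only 0.7%, disorder 57% -> 0.51 in natural log
        assert propensity(0.124, 0.124 + 0.007, 0.57) == pytest.approx(0.51,
                                                                       abs=0.005)

    def test_control_worked_value(self):
        assert propensity(0.033, 0.033 + 0.007, 0.39) == pytest.approx(0.75,
                                                                       abs=0.005)

    def test_natural_log_not_log10(self):
        v = propensity(0.124, 0.131, 0.57)
        assert v == pytest.approx(math.log(0.124 / (0.131 * 0.57)))
        assert abs(v / math.log(10) - 0.51) > 0.2  # log10 would give ~0.22

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_independence_gives_zero(self, p, q):
        assert propensity(p * q, p, q) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [(0.0, 0.5, 0.5), (0.5, -0.1, 0.5),
                                     (0.5, 0.5, 0.0)])
    def test_zero_or_negative_rejected(self, bad):
        with pytest.raises(ValueError):
            propensity(*bad)


class TestStretches:
    def make(self, values):
        return AnnotationTrack("P", "coil", values)

    def test_run_of_exactly_20_excluded(self):
        track = self.make([False] * 4 + [True] * 20 + [False] * 4)
        assert extract_stretches(track, min_run=20) == []

    def test_run_of_21_included(self):
        track = self.make([False] * 4 + [True] * 21 + [False] * 4)
        (iv,) = extract_stretches(track, min_run=20)
        assert (iv.start, iv.end) == (5, 25)

    def test_alternating_never_qualifies(self):
        track = self.make([True, False] * 20)
        assert extract_stretches(track, min_run=1) == []

    @given(st.lists(st.booleans(), min_size=1, max_size=120),
           st.integers(1, 25))
    def test_stretches_are_maximal_true_runs(self, values, min_run):
        """Every stretch holds only True, is flanked by False/edges, and
        every qualifying run is reported."""
        track = self.make(values)
        stretches = extract_stretches(track, min_run=min_run)
        covered = set()
        for iv in stretches:
            assert iv.length > min_run
            assert all(values[i] for i in range(iv.start - 1, iv.end))
            assert iv.start == 1 or not values[iv.start - 2]
            assert iv.end == len(values) or not values[iv.end]
            covered |= set(range(iv.start - 1, iv.end))
        # no qualifying run was missed: scan independently
        i = 0
        while i < len(values):
            if values[i]:
                j = i
                while j < len(values) and values[j]:
                    j += 1
                if j - i > min_run:
                    assert set(range(i, j)) <= covered
                i = j
            else:
                i += 1


class TestPerProteinFractions:
    def test_dual_fraction_counted_above_threshold(self):
        ts = {"P1": bundle("P1", [True] * 30 + [False] * 70,
                           [True] * 30 + [False] * 70)}
        out = per_protein_fractions(ts)
        assert out["fractions"][0].f_disorder_and_coil == pytest.approx(0.30)
        assert out["n_dual_above_threshold"] == 1

    def test_exactly_20_percent_not_counted(self):
        ts = {"P1": bundle("P1", [True] * 20 + [False] * 80,
                           [True] * 20 + [False] * 80)}
        assert per_protein_fractions(ts)["n_dual_above_threshold"] == 0

    def test_threshold_recovery_on_synthetic_set(self, study_cohort):
        """The >20% dual-coverage protein count matches a direct per-protein
        recount of the ground-truth tracks."""
        _, track_set, _ = study_cohort
        out = per_protein_fractions(track_set)
        expected = 0
        for pid, b in track_set.items():
            dual = sum(1 for d, c in zip(b["disorder"].values, b["coil"].values)
                       if d and c)
            if dual / len(b["disorder"]) > 0.20:
                expected += 1
        assert out["n_dual_above_threshold"] == expected
        assert expected > 0


class TestSSFractions:
    def test_all_disordered_helical(self):
        ts = {"P1": bundle("P1", [True] * 10, [False] * 10, ss=["H"] * 10)}
        out = ss_class_fractions(ts)
        assert out["p_disorder_and_H"] == 1.0
        assert out["p_H_given_disorder"] == 1.0

    def test_no_disorder_conditionals_absent(self):
        ts = {"P1": bundle("P1", [False] * 10, [False] * 10, ss=["H"] * 10)}
        out = ss_class_fractions(ts)
        assert out["p_H_given_disorder"] is None
        assert out["p_C_given_disorder"] is None

    def test_missing_ss_is_error(self):
        ts = {"P1": bundle("P1", [True] * 4, [False] * 4)}
        with pytest.raises(ValueError, match="ss"):
            ss_class_fractions(ts)


class TestCompareSets:
    def test_identical_sets_zero_difference(self, small_cohort):
        _, _, track_set, _ = small_cohort
        comps = compare_sets(track_set, track_set, n_boot=50, seed=3)
        for c in comps:
            assert c.difference == pytest.approx(0.0, abs=1e-12)
            assert c.study_se > 0

    def test_bootstrap_reproducible(self, small_cohort):
        _, _, track_set, _ = small_cohort
        a = compare_sets(track_set, track_set, n_boot=50, seed=9)
        b = compare_sets(track_set, track_set, n_boot=50, seed=9)
        assert [(c.study_se, c.control_se) for c in a] == \
               [(c.study_se, c.control_se) for c in b]

    def test_single_protein_flagged_unreliable(self):
        one = {"P1": bundle("P1", [True] * 50, [False] * 50)}
        comps = compare_sets(one, one, n_boot=20, seed=0)
        assert all(c.unreliable for c in comps)

    def test_n_boot_too_small(self, small_cohort):
        _, _, track_set, _ = small_cohort
        with pytest.raises(ValueError):
            compare_sets(track_set, track_set, n_boot=1, seed=0)

    def test_known_difference_recovered(self):
        """Two cohorts generated at P(d)=0.57 vs 0.39 differ by ~0.18
        within 3 combined bootstrap SEs, with SE magnitude around 1%."""
        from centrokit import SyntheticSpec, sample_protein_set

        study_spec = SyntheticSpec(n_proteins=300, length_mean=600.0, seed=11)
        control_spec = SyntheticSpec(
            n_proteins=300, length_mean=600.0, seed=12,
            target_joint={"p_disorder": 0.39, "p_coil_and_disorder": 0.033,
                          "p_coil_not_disorder": 0.007,
                          "p_disorder_and_H": 0.097})
        _, study_ts, _ = sample_protein_set(study_spec)
        _, control_ts, _ = sample_protein_set(control_spec, set_label="control")
        comps = {c.metric: c for c in compare_sets(study_ts, control_ts,
                                                   n_boot=200, seed=5)}
        c = comps["p_disorder"]
        assert abs(c.difference - (0.57 - 0.39)) <= 3 * c.combined_se
        assert 0.001 < c.study_se < 0.03
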