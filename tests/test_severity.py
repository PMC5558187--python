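"""Mild/severe classification, boundary semantics and threshold stabilisation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystivar.patient_scoring import PatientGenotype
from cystivar.severity import (
    BoundaryRule,
    DEFAULT_METHOD_SPECS,
    Direction,
    Method,
    MethodSpec,
    classify_mutation_severity,
    select_stable_threshold,
    severity_for_consequence,
    threshold_scan,
)
from cystivar.variant_core import Consequence, Gene, parse_hgvs_p


class TestBoundarySemantics:
    @pytest.mark.parametrize(
        "method,score,expected",
        [
            (Method.SIFT, 0.03, 1), (Method.SIFT, 0.01, 2),
            (Method.SIFT, 0.025, 2),          # inclusive boundary
            (Method.POLYPHEN2, 0.80, 2), (Method.POLYPHEN2, 0.79, 1),
            (Method.MUTATION_ASSESSOR, 2.7, 2), (Method.MUTATION_ASSESSOR, 2.69, 1),
            (Method.FATHMM, -9.0, 2), (Method.FATHMM, -8.5, 1),  # strict boundary
            (Method.CONDEL, 0.672, 1), (Method.CONDEL, 0.673, 2),
            (Method.CADD, 27.5, 2), (Method.CADD, 27.4, 1),
        ],
    )
    def test_printed_inequalities(self, method, score, expected):
        call = classify_mutation_severity(score, DEFAULT_METHOD_SPECS[method])
        assert call.severity == expected

    def test_tolerated_scores_still_map_to_mild(self):
        # SIFT 0.5 is predicted tolerated but the mild band is unbounded
        assert classify_mutation_severity(0.5, DEFAULT_METHOD_SPECS[Method.SIFT]).severity == 1

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValueError):
            classify_mutation_severity(float("nan"), DEFAULT_METHOD_SPECS[Method.SIFT])

    def test_dense_grid_matches_literal_rederivation(self):
        """Classifier output equals the printed inequality pair, per method."""
        literal = {
            Method.SIFT: lambda s: 2 if s <= 0.025 else 1,
            Method.POLYPHEN2: lambda s: 2 if s >= 0.80 else 1,
            Method.MUTATION_ASSESSOR: lambda s: 2 if s >= 2.7 else 1,
            Method.FATHMM: lambda s: 2 if s < -8.5 else 1,
            Method.CONDEL: lambda s: 2 if s > 0.672 else 1,
            Method.CADD: lambda s: 2 if s >= 27.5 else 1,
        }
        grids = {
            Method.SIFT: [i / 1000 for i in range(0, 101)],
            Method.POLYPHEN2: [i / 1000 for i in range(0, 1001)],
            Method.MUTATION_ASSESSOR: [i / 100 for i in range(-100, 601)],
            Method.FATHMM: [i / 100 for i in range(-1600, 201)],
            Method.CONDEL: [i / 1000 for i in range(0, 1001)],
            Method.CADD: [i / 10 for i in range(0, 501)],
        }
        for method, rule in literal.items():
            spec = DEFAULT_METHOD_SPECS[method]
            for score in grids[method]:
                assert classify_mutation_severity(score, spec).severity == rule(score), (
                    method, score
                )

    @given(st.floats(-20, 40, allow_nan=False),
           st.sampled_from(list(Method)),
           st.floats(0.01, 5.0))
    @settings(max_examples=300, derandomize=True)
    def test_raising_stringency_never_raises_severity(self, score, method, delta):
        from dataclasses import replace

        spec = DEFAULT_METHOD_SPECS[method]
        sign = 1.0 if spec.direction is Direction.HIGHER_IS_WORSE else -1.0
        stricter = replace(spec, severe_threshold=spec.severe_threshold + sign * delta)
        assert (
            classify_mutation_severity(score, stricter).severity
            <= classify_mutation_severity(score, spec).severity
        )


class TestNonMissenseRule:
    @pytest.mark.parametrize(
        "consequence",
        [Consequence.FRAMESHIFT, Consequence.DELETION,
         Consequence.SPLICE_SITE, Consequence.NONSENSE],
    )
    def test_always_severe(self, consequence):
        call = severity_for_consequence(consequence)
        assert call.severity == 2
        assert call.method is None and call.score is None

    def test_missense_dispatch_rejected(self):
        with pytest.raises(ValueError):
            severity_for_consequence(Consequence.MISSENSE)


def _two_patient_cohort():
    mut_a = parse_hgvs_p("p.Ala182Thr")
    mut_b = parse_hgvs_p("p.Gly105Arg")
    return (
        [
            PatientGenotype("P1", Gene.SLC7A9, (mut_a,), ()),
            PatientGenotype("P2", Gene.SLC7A9, (mut_b,), ()),
        ],
        {"p.Ala182Thr": 0.3, "p.Gly105Arg": 0.9},
    )


class TestThresholdScan:
    GRID = [0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95]

    def test_scan_length_matches_grid(self):
        cohort, scores = _two_patient_cohort()
        scan = threshold_scan(cohort, scores,
                              DEFAULT_METHOD_SPECS[Method.POLYPHEN2], self.GRID)
        assert len(scan) == len(self.GRID)

    def test_groupings_change_only_when_a_score_is_crossed(self):
        cohort, scores = _two_patient_cohort()
        scan = threshold_scan(cohort, scores,
                              DEFAULT_METHOD_SPECS[Method.POLYPHEN2], self.GRID)
        # 0.9 stays severe while threshold <= 0.90; drops to mild at 0.95
        for threshold, assignment in scan[:-1]:
            assert assignment == {"P1": 1, "P2": 2}
        assert scan[-1][1] == {"P1": 1, "P2": 1}

    def test_stable_threshold_is_most_stringent_of_longest_run(self):
        cohort, scores = _two_patient_cohort()
        scan = threshold_scan(cohort, scores,
                              DEFAULT_METHOD_SPECS[Method.POLYPHEN2], self.GRID)
        assert select_stable_threshold(scan) == 0.90

    def test_scores_outside_grid_span_give_identical_groupings(self):
        cohort, _ = _two_patient_cohort()
        scores = {"p.Ala182Thr": 0.2, "p.Gly105Arg": 0.3}
        scan = threshold_scan(cohort, scores,
                              DEFAULT_METHOD_SPECS[Method.POLYPHEN2], self.GRID)
        assignments = {tuple(sorted(a.items())) for _, a in scan}
        assert len(assignments) == 1
        # all-stable scan selects the most stringent grid point
        assert select_stable_threshold(scan) == self.GRID[-1]

    def test_missing_scores_error_lists_mutations(self):
        cohort, scores = _two_patient_cohort()
        del scores["p.Gly105Arg"]
        with pytest.raises(ValueError, match="p.Gly105Arg"):
            threshold_scan(cohort, scores,
                           DEFAULT_METHOD_SPECS[Method.POLYPHEN2], self.GRID)

    def test_empty_grid_rejected(self):
        cohort, scores = _two_patient_cohort()
        with pytest.raises(ValueError):
            threshold_scan(cohort, scores,
                           DEFAULT_METHOD_SPECS[Method.POLYPHEN2], [])

    def test_selection_invariant_to_appended_stable_points(self):
        cohort, scores = _two_patient_cohort()
        spec = DEFAULT_METHOD_SPECS[Method.POLYPHEN2]
        scan = threshold_scan(cohort, scores, spec, self.GRID[:-1])
        # appending grid points that do not change any grouping within the
        # chosen run extends that run; the selected threshold moves with it
        chosen = select_stable_threshold(scan)
        assert chosen == 0.90
        extended = threshold_scan(cohort, scores, spec, self.GRID[:-1] + [0.90])
        assert select_stable_threshold(extended) == 0.90

    def test_min_run_not_reached_advises_finer_grid(self):
        cohort, scores = _two_patient_cohort()
        spec = DEFAULT_METHOD_SPECS[Method.POLYPHEN2]
        scan = threshold_scan(cohort, scores, spec, [0.85, 0.95])
        with pytest.raises(ValueError, match="grid"):
            select_stable_threshold(scan, min_run=3)


class TestMethodSpecInvariants:
    def test_directions_follow_score_scales(self):
        lower = {Method.SIFT, Method.FATHMM}
        for method, spec in DEFAULT_METHOD_SPECS.items():
            expected = (Direction.LOWER_IS_WORSE if method in lower
                        else Direction.HIGHER_IS_WORSE)
            assert spec.direction is expected

    def test_severe_threshold_must_be_stringent(self):
        with pytest.raises(ValueError):
            MethodSpec(Method.POLYPHEN2, Direction.HIGHER_IS_WORSE,
                       0.5, 0.4, BoundaryRule.SEVERE_AT_THRESHOLD)

    def test_yaml_config_round_trip(self, tmp_path):
        from importlib import resources

        from cystivar.severity import load_method_specs

        shipped = resources.files("cystivar") / "data" / "method_thresholds.yaml"
        specs = load_method_specs(str(shipped))
        assert specs == DEFAULT_METHOD_SPECS
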