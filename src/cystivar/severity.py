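"""Per-mutation mild/severe classification from predictor scores.

Six variant-effect predictors are supported (SIFT, PolyPhen2,
MutationAssessor, FATHMM, Condel, CADD).  Each method has a published
deleterious-vs-neutral threshold and, for this pipeline, a more stringent
"severe" threshold separating mildly deleterious (severity 1) from severe
(severity 2) mutations.  The severe thresholds are selected by scanning
increasingly stringent candidate cut-offs and choosing the most stringent
point of the longest range over which the patient grouping is stable.

Boundary semantics are method-specific and encoded literally:

==================  ==========  ====================  ==================
method              direction   deleterious           severe (score 2)
==================  ==========  ====================  ==================
SIFT                lower bad   score < 0.05          score <= 0.025
PolyPhen2           higher bad  score >= 0.5          score >= 0.80
MutationAssessor    higher bad  score > 1.9           score >= 2.7
FATHMM              lower bad   score <= -1.5         score < -8.5
Condel              higher bad  score > 0.522         score > 0.672
CADD                higher bad  score >= 15           score >= 27.5
==================  ==========  ====================  ==================

Frameshift, deletion, splice-site and nonsense mutations bypass the
predictors entirely and are always assigned severity 2.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .variant_core import Consequence, ProteinMutation

__all__ = [
    "Method",
    "Direction",
    "BoundaryRule",
    "MethodSpec",
    "SeverityCall",
    "CallReason",
    "DEFAULT_METHOD_SPECS",
    "load_method_specs",
    "classify_mutation_severity",
    "severity_for_consequence",
    "threshold_scan",
    "select_stable_threshold",
    "default_grid",
]

logger = logging.getLogger(__name__)


class Method(str, enum.Enum):
    SIFT = "sift"
    POLYPHEN2 = "polyphen2"
    MUTATION_ASSESSOR = "mutation_assessor"
    FATHMM = "fathmm"
    CONDEL = "condel"
    CADD = "cadd"


class Direction(str, enum.Enum):
    LOWER_IS_WORSE = "lower_is_worse"
    HIGHER_IS_WORSE = "higher_is_worse"


class BoundaryRule(str, enum.Enum):
    #: a score exactly at the severe threshold is severe (e.g. SIFT <= 0.025)
    SEVERE_AT_THRESHOLD = "severe_at_threshold"
    #: severity 2 requires strictly passing the threshold (e.g. FATHMM < -8.5)
    SEVERE_BEYOND_THRESHOLD = "severe_beyond_threshold"


class CallReason(str, enum.Enum):
    THRESHOLD = "threshold"
    NON_MISSENSE_RULE = "non_missense_rule"


@dataclass(frozen=True)
class MethodSpec:
    method: Method
    direction: Direction
    standard_deleterious_threshold: float
    severe_threshold: float
    boundary_rule: BoundaryRule

    def __post_init__(self) -> None:
        # the severe threshold must be at least as stringent as the standard
        # deleterious threshold, on the method's own scale
        if self.direction is Direction.HIGHER_IS_WORSE:
            ok = self.severe_threshold >= self.standard_deleterious_threshold
        else:
            ok = self.severe_threshold <= self.standard_deleterious_threshold
        if not ok:
            raise ValueError(
                f"{self.method.value}: severe threshold "
                f"{self.severe_threshold} is less stringent than the standard "
                f"deleterious threshold {self.standard_deleterious_threshold}"
            )

    def is_severe(self, score: float) -> bool:
        """Whether `score` falls on the severe side of the severe threshold."""
        at = self.boundary_rule is BoundaryRule.SEVERE_AT_THRESHOLD
        if self.direction is Direction.HIGHER_IS_WORSE:
            return score >= self.severe_threshold if at else score > self.severe_threshold
        return score <= self.severe_threshold if at else score < self.severe_threshold

    def is_deleterious(self, score: float) -> bool:
        """Whether `score` passes the method's own deleterious cut-off."""
        # the standard thresholds' printed strictness also differs by method;
        # exact boundary behaviour there does not affect severity calls
        if self.direction is Direction.HIGHER_IS_WORSE:
            return score >= self.standard_deleterious_threshold
        return score <= self.standard_deleterious_threshold


@dataclass(frozen=True)
class SeverityCall:
    mutation: Optional[ProteinMutation]
    method: Optional[MethodSpec]
    score: Optional[float]
    severity: int
    reason: CallReason

    def __post_init__(self) -> None:
        if self.severity not in (1, 2):
            raise ValueError(f"severity must be 1 or 2, got {self.severity}")
        if self.reason is CallReason.NON_MISSENSE_RULE:
            if self.severity != 2 or self.method is not None or self.score is not None:
                raise ValueError(
                    "non-missense calls are severity 2 with no method/score"
                )


DEFAULT_METHOD_SPECS: Dict[Method, MethodSpec] = {
    Method.SIFT: MethodSpec(
        Method.SIFT, Direction.LOWER_IS_WORSE, 0.05, 0.025,
        BoundaryRule.SEVERE_AT_THRESHOLD),
    Method.POLYPHEN2: MethodSpec(
        Method.POLYPHEN2, Direction.HIGHER_IS_WORSE, 0.5, 0.80,
        BoundaryRule.SEVERE_AT_THRESHOLD),
    Method.MUTATION_ASSESSOR: MethodSpec(
        Method.MUTATION_ASSESSOR, Direction.HIGHER_IS_WORSE, 1.9, 2.7,
        BoundaryRule.SEVERE_AT_THRESHOLD),
    Method.FATHMM: MethodSpec(
        Method.FATHMM, Direction.LOWER_IS_WORSE, -1.5, -8.5,
        BoundaryRule.SEVERE_BEYOND_THRESHOLD),
    Method.CONDEL: MethodSpec(
        Method.CONDEL, Direction.HIGHER_IS_WORSE, 0.522, 0.672,
        BoundaryRule.SEVERE_BEYOND_THRESHOLD),
    Method.CADD: MethodSpec(
        Method.CADD, Direction.HIGHER_IS_WORSE, 15.0, 27.5,
        BoundaryRule.SEVERE_AT_THRESHOLD),
}

#: default stabilisation-scan grid step per method (probability-scaled
#: methods use 0.05; MutationAssessor/FATHMM 0.5; CADD 2.5)
DEFAULT_GRID_STEP: Dict[Method, float] = {
    Method.SIFT: 0.05,
    Method.POLYPHEN2: 0.05,
    Method.CONDEL: 0.05,
    Method.MUTATION_ASSESSOR: 0.5,
    Method.FATHMM: 0.5,
    Method.CADD: 2.5,
}


def load_method_specs(path) -> Dict[Method, MethodSpec]:
    """Load method specs from a YAML file (same schema as the shipped default)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    specs: Dict[Method, MethodSpec] = {}
    for name, entry in raw["methods"].items():
        method = Method(name)
        specs[method] = MethodSpec(
            method=method,
            direction=Direction(entry["direction"]),
            standard_deleterious_threshold=float(entry["standard_deleterious_threshold"]),
            severe_threshold=float(entry["severe_threshold"]),
            boundary_rule=BoundaryRule(entry["boundary_rule"]),
        )
    return specs


def classify_mutation_severity(
    score: float,
    spec: MethodSpec,
    mutation: Optional[ProteinMutation] = None,
) -> SeverityCall:
    """Classify a missense mutation's predictor score as mild (1) or severe (2).

    Scores on the tolerated side of the method's own deleterious threshold
    still map to severity 1 (the mild band is unbounded on the tolerated
    side); a warning is logged because such mutations are predicted neutral.
    """
    import math

    if not isinstance(score, (int, float)) or not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    severity = 2 if spec.is_severe(score) else 1
    if severity == 1 and not spec.is_deleterious(score):
        logger.warning(
            "%s score %s is on the tolerated side of the deleterious "
            "threshold; scored as mild (1) but predicted neutral",
            spec.method.value, score,
        )
    return SeverityCall(mutation, spec, float(score), severity, CallReason.THRESHOLD)


def severity_for_consequence(consequence: Consequence) -> SeverityCall:
    """Severity call for a non-missense mutation: always severe (2)."""
    if consequence is Consequence.MISSENSE:
        raise ValueError(
            "missense mutations must be scored through classify_mutation_severity"
        )
    return SeverityCall(None, None, None, 2, CallReason.NON_MISSENSE_RULE)


def default_grid(spec: MethodSpec, n: int = 10) -> List[float]:
    """Candidate severe thresholds from the standard deleterious threshold
    towards higher stringency, ordered least to most stringent."""
    step = DEFAULT_GRID_STEP[spec.method]
    sign = 1.0 if spec.direction is Direction.HIGHER_IS_WORSE else -1.0
    start = spec.standard_deleterious_threshold
    return [round(start + sign * step * i, 10) for i in range(n)]


def threshold_scan(
    cohort: Sequence,  # Sequence[PatientGenotype]
    scores: Mapping[str, Optional[float]],
    spec: MethodSpec,
    grid: Sequence[float],
) -> List[Tuple[float, Dict[str, int]]]:
    """Re-score the cohort at every candidate severe threshold.

    `scores` maps each mutation's HGVS p. string to its predictor score
    (None for non-missense mutations, which always score 2).  Returns one
    (threshold, {patient_id: patient severity score}) pair per grid point,
    in grid order.
    """
    from .patient_scoring import score_cohort

    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    missing = sorted(
        {
            str(m)
            for patient in cohort
            for m in patient.all_mutations()
            if m.consequence is Consequence.MISSENSE
            and scores.get(str(m)) is None
        }
    )
    if missing:
        raise ValueError(
            f"no {spec.method.value} score for mutation(s): {', '.join(missing)}"
        )

    out: List[Tuple[float, Dict[str, int]]] = []
    for threshold in grid:
        spec_t = replace(spec, severe_threshold=float(threshold))
        calls = {}
        for patient in cohort:
            for m in patient.all_mutations():
                key = str(m)
                if key in calls:
                    continue
                if m.consequence is Consequence.MISSENSE:
                    calls[key] = classify_mutation_severity(scores[key], spec_t, m)
                else:
                    calls[key] = severity_for_consequence(m.consequence)
        patient_scores = score_cohort(cohort, calls)
        out.append((float(threshold), {ps.patient_id: ps.score for ps in patient_scores}))
    return out


def select_stable_threshold(
    scan: Sequence[Tuple[float, Dict[str, int]]], min_run: int = 3
) -> float:
    """Most stringent threshold of the longest stable run of a threshold scan.

    A run is a maximal block of consecutive grid points with identical
    patient-to-score assignments.  Ties between equally long runs go to the
    more stringent (later) run.  Raises if no run spans `min_run` points,
    which usually means the grid is too coarse.
    """
    if len(scan) == 0:
        raise ValueError("threshold scan is empty")
    runs: List[Tuple[int, int]] = []  # (start, end) inclusive indices
    start = 0
    for i in range(1, len(scan)):
        if scan[i][1] != scan[i - 1][1]:
            runs.append((start, i - 1))
            start = i
    runs.append((start, len(scan) - 1))

    best = max(runs, key=lambda r: (r[1] - r[0], r[1]))
    if best[1] - best[0] + 1 < min_run:
        raise ValueError(
            f"no stable run of >= {min_run} grid points; refine the grid "
            f"(longest run spans {best[1] - best[0] + 1})"
        )
    return scan[best[1]][0]
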