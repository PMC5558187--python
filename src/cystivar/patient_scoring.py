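"""Aggregate per-mutation severity calls into per-patient severity scores.

SLC7A9 mutations act in an autosomal dominant pattern with incomplete
penetrance, so a patient's score is the *sum* of the severity scores of the
mutations across their alleles (range 1-4).  SLC3A1 cystinuria is autosomal
recessive — both alleles must be mutated — and the allele carrying the worse
mutation is assumed not to be expressed, so the patient's score is the
*minimum* of the two allele scores (range 1-2).

The scheme deliberately treats a patient with two mild mutations the same
as one with a single severe mutation (dominant sum 2 in both cases); this
simplification is part of the scoring model, not an implementation detail.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

from .severity import SeverityCall
from .variant_core import Gene, ProteinMutation

__all__ = [
    "ScoringModel",
    "PatientGenotype",
    "PatientScore",
    "score_patient_dominant",
    "score_patient_recessive",
    "score_cohort",
]

logger = logging.getLogger(__name__)


class ScoringModel(str, enum.Enum):
    DOMINANT_SUM = "dominant_sum"
    RECESSIVE_MIN = "recessive_min"


@dataclass(frozen=True)
class PatientGenotype:
    """A patient's per-allele mutation lists for one gene."""

    patient_id: str
    gene: Gene
    allele1: Tuple[ProteinMutation, ...] = field(default_factory=tuple)
    allele2: Tuple[ProteinMutation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele1", tuple(self.allele1))
        object.__setattr__(self, "allele2", tuple(self.allele2))
        if self.gene is Gene.SLC3A1:
            for name, allele in (("allele1", self.allele1), ("allele2", self.allele2)):
                if len(allele) > 1:
                    raise ValueError(
                        f"patient {self.patient_id}: SLC3A1 {name} carries "
                        f"{len(allele)} mutations; at most one per allele"
                    )

    def all_mutations(self) -> Tuple[ProteinMutation, ...]:
        return self.allele1 + self.allele2

    @property
    def n_mutated_alleles(self) -> int:
        return (len(self.allele1) > 0) + (len(self.allele2) > 0)


@dataclass(frozen=True)
class PatientScore:
    patient_id: str
    gene: Gene
    score: int
    model: ScoringModel

    def __post_init__(self) -> None:
        valid = {ScoringModel.DOMINANT_SUM: range(1, 5),
                 ScoringModel.RECESSIVE_MIN: range(1, 3)}[self.model]
        if self.score not in valid:
            raise ValueError(
                f"{self.model.value} score must be in "
                f"{valid.start}..{valid.stop - 1}, got {self.score}"
            )


def _check_severities(values: Sequence[int]) -> None:
    bad = [v for v in values if v not in (1, 2)]
    if bad:
        raise ValueError(f"severity scores must be 1 or 2, got {bad}")


def score_patient_dominant(
    allele_scores: Sequence[int], patient_id: str = "", gene: Gene = Gene.SLC7A9
) -> PatientScore:
    """Dominant-model patient score: sum of the per-allele severities (1-4)."""
    if len(allele_scores) == 0:
        raise ValueError(f"patient {patient_id!r}: no mutated allele to score")
    if len(allele_scores) > 2:
        raise ValueError(
            f"patient {patient_id!r}: at most two alleles, got {len(allele_scores)}"
        )
    _check_severities(allele_scores)
    return PatientScore(patient_id, gene, int(sum(allele_scores)),
                        ScoringModel.DOMINANT_SUM)


def score_patient_recessive(
    allele1_score: int, allele2_score: int,
    patient_id: str = "", gene: Gene = Gene.SLC3A1,
) -> PatientScore:
    """Recessive-model patient score: min of the two allele severities (1-2)."""
    _check_severities([allele1_score, allele2_score])
    return PatientScore(patient_id, gene,
                        min(allele1_score, allele2_score),
                        ScoringModel.RECESSIVE_MIN)


def _allele_severity(
    patient: PatientGenotype,
    allele: Sequence[ProteinMutation],
    calls: Mapping[str, SeverityCall],
) -> int:
    severities = []
    for mutation in allele:
        key = str(mutation)
        if key not in calls:
            raise KeyError(
                f"patient {patient.patient_id}: no severity call for {key}"
            )
        severities.append(calls[key].severity)
    if len(severities) > 1:
        # not observed in practice for these genes: score the allele by its
        # worst mutation so the patient-level range is preserved
        logger.warning(
            "patient %s: %d mutations on one allele; using the worst",
            patient.patient_id, len(severities),
        )
    return max(severities)


def score_cohort(
    cohort: Sequence[PatientGenotype],
    calls: Mapping[str, SeverityCall],
) -> List[PatientScore]:
    """Score every patient, dispatching on the gene's inheritance model.

    `calls` maps HGVS p. strings to severity calls.  Patients with no
    identified mutation are excluded with a logged notice; a recessive
    (SLC3A1) patient with only one mutated allele is an error because the
    genotype is inconsistent with recessive disease.  A patient id appearing
    with both genes is an error (such patients are excluded upstream).
    """
    genes_by_patient: Dict[str, set] = {}
    for patient in cohort:
        genes_by_patient.setdefault(patient.patient_id, set()).add(patient.gene)
    both = sorted(pid for pid, gs in genes_by_patient.items() if len(gs) > 1)
    if both:
        raise ValueError(
            f"patient(s) with mutations in both genes must be excluded "
            f"before scoring: {', '.join(both)}"
        )

    out: List[PatientScore] = []
    for patient in cohort:
        if patient.n_mutated_alleles == 0:
            logger.info(
                "patient %s: no identified mutation; excluded from scoring",
                patient.patient_id,
            )
            continue
        if patient.gene is Gene.SLC7A9:
            allele_scores = [
                _allele_severity(patient, allele, calls)
                for allele in (patient.allele1, patient.allele2)
                if len(allele) > 0
            ]
            out.append(score_patient_dominant(
                allele_scores, patient.patient_id, patient.gene))
        else:
            if patient.n_mutated_alleles < 2:
                raise ValueError(
                    f"patient {patient.patient_id}: SLC3A1 genotype has only "
                    f"one mutated allele, inconsistent with recessive disease"
                )
            out.append(score_patient_recessive(
                _allele_severity(patient, patient.allele1, calls),
                _allele_severity(patient, patient.allele2, calls),
                patient.patient_id, patient.gene))
    return out
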