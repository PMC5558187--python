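"""Group patients by severity score and compare phenotype distributions.

Patients are partitioned by their aggregate severity score; every unordered
pair of sufficiently large groups is compared on every phenotype with the
two-sided Wilcoxon rank-sum test, and all p-values from one analysis run
form a single Bonferroni family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .patient_scoring import PatientScore
from .stats import RankTestResult, bonferroni, wilcoxon_rank_sum

__all__ = [
    "PHENOTYPE_COLUMNS",
    "GroupComparison",
    "group_patients",
    "compare_groups",
    "summarize_groups",
    "comparisons_to_frame",
]

logger = logging.getLogger(__name__)

#: phenotype columns of the patient table: urinary dibasic amino acid
#: levels (as supplied), age at presentation (years), and counts of stone
#: episodes / interventions over a three-year window
PHENOTYPE_COLUMNS = (
    "urine_cystine",
    "urine_ornithine",
    "urine_arginine",
    "urine_lysine",
    "age_at_presentation",
    "stone_episodes_3yr",
    "interventions_3yr",
)


@dataclass(frozen=True)
class GroupComparison:
    phenotype: str
    group_a: int
    group_b: int
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    median_a: float
    median_b: float
    test: RankTestResult
    adjusted_p: float


def group_patients(
    scores: Sequence[PatientScore], min_n: int = 2
) -> Dict[int, Set[str]]:
    """Partition patients by severity score.

    Groups smaller than `min_n` are kept in the mapping (the partition is
    complete) but flagged with a log notice; compare_groups excludes them
    from testing.
    """
    groups: Dict[int, Set[str]] = {}
    for ps in scores:
        groups.setdefault(ps.score, set()).add(ps.patient_id)
    for score, members in sorted(groups.items()):
        if len(members) < min_n:
            logger.info(
                "severity group %d has %d patient(s) (< %d); "
                "excluded from testing", score, len(members), min_n,
            )
    return groups


def _phenotype_values(
    phenotypes: pd.DataFrame, patients: Set[str], column: str
) -> np.ndarray:
    sub = phenotypes.loc[phenotypes.index.intersection(sorted(patients)), column]
    return sub.dropna().to_numpy(dtype=float)


def compare_groups(
    groups: Dict[int, Set[str]],
    phenotypes: pd.DataFrame,
    min_n: int = 2,
    family_size: Optional[int] = None,
    phenotype_columns: Sequence[str] = PHENOTYPE_COLUMNS,
    mode: str = "auto",
) -> List[GroupComparison]:
    """Rank-sum comparison of every group pair on every phenotype.

    `phenotypes` is indexed by patient_id.  Null phenotype values are
    dropped pairwise; a (pair, phenotype) combination with fewer than
    `min_n` non-null values on either side is skipped.  Bonferroni is
    applied across all comparisons performed in this call (overridable
    with an explicit `family_size`).
    """
    eligible = sorted(s for s, members in groups.items() if len(members) >= min_n)
    if len(eligible) < 2:
        logger.warning("fewer than two eligible groups; nothing to compare")
        return []

    partial: List[GroupComparison] = []
    raw_p: List[float] = []
    for (a, b), column in itertools.product(
        itertools.combinations(eligible, 2), phenotype_columns
    ):
        xa = _phenotype_values(phenotypes, groups[a], column)
        xb = _phenotype_values(phenotypes, groups[b], column)
        if len(xa) < min_n or len(xb) < min_n:
            logger.info(
                "skipping %s for groups %d vs %d: too few non-null values",
                column, a, b,
            )
            continue
        test = wilcoxon_rank_sum(xa, xb, mode=mode)
        partial.append(GroupComparison(
            phenotype=column, group_a=a, group_b=b,
            n_a=len(xa), n_b=len(xb),
            mean_a=float(xa.mean()), mean_b=float(xb.mean()),
            sd_a=float(xa.std(ddof=1)) if len(xa) > 1 else float("nan"),
            sd_b=float(xb.std(ddof=1)) if len(xb) > 1 else float("nan"),
            median_a=float(np.median(xa)), median_b=float(np.median(xb)),
            test=test, adjusted_p=float("nan"),
        ))
        raw_p.append(test.p_two_sided)

    if not partial:
        return []
    corrected = bonferroni(raw_p, family_size)
    return [
        GroupComparison(**{**comp.__dict__, "adjusted_p": adj})
        for comp, adj in zip(partial, corrected.adjusted_p)
    ]


def summarize_groups(
    groups: Dict[int, Set[str]],
    phenotypes: pd.DataFrame,
    phenotype_columns: Sequence[str] = PHENOTYPE_COLUMNS,
) -> pd.DataFrame:
    """Per-(group, phenotype) n / mean / SD / median summary table.

    Rows are ordered by severity score then phenotype; single-value groups
    report a null SD.
    """
    rows = []
    for score in sorted(groups):
        for column in phenotype_columns:
            values = _phenotype_values(phenotypes, groups[score], column)
            rows.append({
                "severity_group": score,
                "phenotype": column,
                "n": len(values),
                "mean": float(values.mean()) if len(values) else float("nan"),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
                "median": float(np.median(values)) if len(values) else float("nan"),
            })
    return pd.DataFrame(
        rows, columns=["severity_group", "phenotype", "n", "mean", "sd", "median"]
    )


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison results for report output."""
    rows = []
    for c in comparisons:
        rows.append({
            "phenotype": c.phenotype,
            "group_a": c.group_a, "group_b": c.group_b,
            "n_a": c.n_a, "n_b": c.n_b,
            "mean_a": c.mean_a, "mean_b": c.mean_b,
            "sd_a": c.sd_a, "sd_b": c.sd_b,
            "median_a": c.median_a, "median_b": c.median_b,
            "rank_sum": c.test.statistic,
            "p_raw": c.test.p_two_sided,
            "p_adjusted": c.adjusted_p,
            "test_mode": c.test.mode.value,
        })
    return pd.DataFrame(rows, columns=[
        "phenotype", "group_a", "group_b", "n_a", "n_b",
        "mean_a", "mean_b", "sd_a", "sd_b", "median_a", "median_b",
        "rank_sum", "p_raw", "p_adjusted", "test_mode",
    ])
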