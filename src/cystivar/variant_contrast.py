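"""Contrast disease-associated and population-only variant sets.

Disease-associated mutations are expected to be rarer, more conserved and
more destabilising than variants seen only in a population panel.  This
module compares the two sets on allele frequency, ConSurf conservation
grade and predicted stability change (ddG), builds frequency spectra, finds
sequence clusters of mutated positions, and tests for a frequency/
conservation correlation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .stats import (
    RankTestResult,
    SpearmanResult,
    bonferroni,
    spearman_correlation,
    wilcoxon_rank_sum,
)
from .variant_core import Variant

__all__ = [
    "ContrastAttribute",
    "ContrastReport",
    "PositionRun",
    "contrast_sets",
    "contrast_all",
    "frequency_spectrum",
    "DEFAULT_FREQUENCY_THRESHOLDS",
    "sequence_clustering_runs",
    "af_conservation_correlation",
]


class ContrastAttribute(str, enum.Enum):
    ALLELE_FREQUENCY = "allele_frequency"
    CONSURF = "consurf"
    DDG = "ddg"


@dataclass(frozen=True)
class ContrastReport:
    attribute: ContrastAttribute
    n_disease: int
    n_population: int
    median_disease: float
    median_population: float
    bin_edges: Tuple[float, ...]
    bin_labels: Tuple[str, ...]
    hist_disease: Tuple[int, ...]
    hist_population: Tuple[int, ...]
    test: RankTestResult
    adjusted_p: Optional[float] = None


@dataclass(frozen=True)
class PositionRun:
    start: int
    end: int
    n_positions: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _attribute_values(variants: Sequence[Variant], attribute: ContrastAttribute):
    values = [getattr(v, attribute.value) for v in variants]
    return np.asarray([v for v in values if v is not None], dtype=float)


def _histogram(values: np.ndarray, attribute: ContrastAttribute):
    """Attribute-appropriate binning.

    ConSurf: one bin per integer grade 1..9.  Allele frequency: a literal
    zero bin (absent from the panel) plus decade-spaced bins.  ddG: fixed
    0.5 kcal/mol bins spanning the data.
    """
    if attribute is ContrastAttribute.CONSURF:
        edges = np.arange(0.5, 10.0, 1.0)
        counts, _ = np.histogram(values, bins=edges)
        labels = tuple(str(g) for g in range(1, 10))
        return tuple(edges), labels, tuple(int(c) for c in counts)
    if attribute is ContrastAttribute.ALLELE_FREQUENCY:
        decades = [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0]
        zero = int((values == 0).sum())
        nonzero = values[values > 0]
        counts, _ = np.histogram(np.clip(nonzero, decades[0], None), bins=decades)
        labels = ("0",) + tuple(
            f"[{lo:g},{hi:g})" for lo, hi in zip(decades[:-1], decades[1:])
        )
        return tuple([0.0] + decades), labels, (zero,) + tuple(int(c) for c in counts)
    lo = math.floor(values.min() / 0.5) * 0.5
    hi = math.ceil(values.max() / 0.5) * 0.5
    if hi <= lo:
        hi = lo + 0.5
    edges = np.arange(lo, hi + 0.25, 0.5)
    counts, _ = np.histogram(values, bins=edges)
    labels = tuple(
        f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])
    )
    return tuple(edges), labels, tuple(int(c) for c in counts)


def contrast_sets(
    disease: Sequence[Variant],
    population: Sequence[Variant],
    attribute: ContrastAttribute,
    mode: str = "auto",
) -> ContrastReport:
    """Compare the two variant sets on one attribute.

    Null annotations are dropped per set; the rank-sum test is two-sided
    with the disease set as sample 1.
    """
    attribute = ContrastAttribute(attribute)
    dv = _attribute_values(disease, attribute)
    pv = _attribute_values(population, attribute)
    for name, vals in (("disease", dv), ("population", pv)):
        if len(vals) == 0:
            raise ValueError(
                f"attribute {attribute.value} absent from every member of "
                f"the {name} set"
            )
    test = wilcoxon_rank_sum(dv, pv, mode=mode)
    edges_d, labels, hist_d = _histogram(dv, attribute)
    if attribute is ContrastAttribute.DDG:
        # share one edge vector across both sets so panels align
        both = np.concatenate([dv, pv])
        edges_all, labels, _ = _histogram(both, attribute)
        hist_d = tuple(int(c) for c in np.histogram(dv, bins=edges_all)[0])
        hist_p = tuple(int(c) for c in np.histogram(pv, bins=edges_all)[0])
        edges_d = edges_all
    else:
        _, _, hist_p = _histogram(pv, attribute)
    return ContrastReport(
        attribute=attribute,
        n_disease=len(dv), n_population=len(pv),
        median_disease=float(np.median(dv)),
        median_population=float(np.median(pv)),
        bin_edges=tuple(float(e) for e in edges_d),
        bin_labels=labels,
        hist_disease=hist_d, hist_population=hist_p,
        test=test,
    )


def contrast_all(
    disease: Sequence[Variant],
    population: Sequence[Variant],
    attributes: Sequence[ContrastAttribute] = tuple(ContrastAttribute),
    mode: str = "auto",
) -> List[ContrastReport]:
    """Contrast on several attributes with one Bonferroni family."""
    reports = [contrast_sets(disease, population, a, mode=mode) for a in attributes]
    corrected = bonferroni([r.test.p_two_sided for r in reports])
    return [
        ContrastReport(**{**r.__dict__, "adjusted_p": adj})
        for r, adj in zip(reports, corrected.adjusted_p)
    ]


DEFAULT_FREQUENCY_THRESHOLDS = (1e-4, 1e-2)


def frequency_spectrum(
    variants: Sequence[Variant],
    thresholds: Sequence[float] = DEFAULT_FREQUENCY_THRESHOLDS,
) -> Dict[str, int]:
    """Allele-frequency spectrum with a literal zero bin.

    Variants absent from the population panel (frequency exactly 0) form
    their own bin; positive frequencies fall into half-open bins between
    consecutive thresholds, with an overflow bin at or above the last
    threshold.  Variants without a frequency annotation are dropped.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])) or any(
        t <= 0 for t in thresholds
    ):
        raise ValueError("thresholds must be strictly increasing and positive")
    freqs = [v.allele_frequency for v in variants if v.allele_frequency is not None]
    out: Dict[str, int] = {"0": 0}
    bounds = (0.0,) + thresholds
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out[f"({lo:g},{hi:g})" if lo == 0.0 else f"[{lo:g},{hi:g})"] = 0
    out[f">={thresholds[-1]:g}"] = 0
    labels = list(out)
    for f in freqs:
        if f == 0.0:
            out["0"] += 1
            continue
        placed = False
        for i, hi in enumerate(thresholds):
            if f < hi:
                out[labels[1 + i]] += 1
                placed = True
                break
        if not placed:
            out[labels[-1]] += 1
    return out


def sequence_clustering_runs(
    mutated_positions, max_gap: int = 1
) -> List[PositionRun]:
    """Maximal runs of mutated positions with inter-position gaps <= max_gap.

    With max_gap 1 a run is a block of strictly consecutive residues;
    larger gaps merge near-adjacent positions into one stretch.
    """
    positions = sorted(set(int(p) for p in mutated_positions))
    if any(p < 1 for p in positions):
        raise ValueError("positions must be >= 1")
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    runs: List[PositionRun] = []
    if not positions:
        return runs
    start = prev = positions[0]
    count = 1
    for p in positions[1:]:
        if p - prev <= max_gap:
            prev = p
            count += 1
        else:
            runs.append(PositionRun(start, prev, count))
            start = prev = p
            count = 1
    runs.append(PositionRun(start, prev, count))
    return runs


def af_conservation_correlation(variants: Sequence[Variant]) -> SpearmanResult:
    """Spearman correlation between allele frequency and ConSurf grade.

    Pairs missing either annotation are dropped; ConSurf's integer scale
    makes ties routine, handled by mid-ranks.
    """
    pairs = [
        (v.allele_frequency, float(v.consurf))
        for v in variants
        if v.allele_frequency is not None and v.consurf is not None
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"need >= 3 variants with both annotations, got {len(pairs)}"
        )
    x, y = zip(*pairs)
    return spearman_correlation(x, y)
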