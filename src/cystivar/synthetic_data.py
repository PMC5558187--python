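"""Seeded simulator for variant tables and patient cohorts.

The generator emulates the statistical structure the analysis assumes:

* disease-associated variants are rare (mostly absent or <0.01% in the
  population panel), highly conserved (~80% at ConSurf grades 6-9) and
  destabilising (ddG centred near -1.1 kcal/mol), while population-only
  variants are more common, less conserved (~40% at grades 6-9) and less
  destabilising (centred near -0.65 kcal/mol);
* each disease variant carries a latent true severity (mild=1 / severe=2)
  and its six predictor scores are drawn from severity-conditional
  distributions on each method's native scale and direction;
* the cohort mirrors the clinical structure: 41 recessive SLC3A1 patients
  with exactly one mutation per allele, 32 dominant SLC7A9 patients with
  one or two mutated alleles; phenotypes shift with the patient's latent
  aggregate severity (higher urinary dibasic amino acids, earlier
  presentation, more stone episodes and interventions).

All draws come from per-component numpy Generators spawned from the master
seed, so e.g. enlarging the cohort does not perturb the variant draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .severity import DEFAULT_METHOD_SPECS, Method
from .variant_core import Gene, ONE_TO_THREE, PREDICTOR_METHODS

__all__ = [
    "PredictorEmission",
    "VariantSetModel",
    "PhenotypeModel",
    "SimulationConfig",
    "simulate_variants",
    "simulate_predictor_scores",
    "simulate_cohort",
    "simulate",
]

#: modelled protein lengths (rBAT and b(0+)AT), used only to place mutations
PROTEIN_LENGTH = {Gene.SLC3A1: 685, Gene.SLC7A9: 487}


@dataclass(frozen=True)
class PredictorEmission:
    """Severity-conditional normal score model for one predictor."""

    mild_mean: float
    mild_sd: float
    severe_mean: float
    severe_sd: float
    lo: Optional[float] = None
    hi: Optional[float] = None

    def draw(self, severe: bool, rng: np.random.Generator) -> float:
        mean, sd = (
            (self.severe_mean, self.severe_sd) if severe
            else (self.mild_mean, self.mild_sd)
        )
        value = float(rng.normal(mean, sd))
        if self.lo is not None:
            value = max(self.lo, value)
        if self.hi is not None:
            value = min(self.hi, value)
        return value


# Mild means sit in each method's deleterious-but-mild band (predictors
# call most disease mutations deleterious; the mild/severe split is within
# the deleterious range) and severe means clearly beyond the severe
# threshold; SDs give roughly 2-6% per-method misclassification of the
# latent severity, consistent with predictors that agree with each other
# for most but not all mutations.
DEFAULT_PREDICTOR_EMISSIONS: Dict[Method, PredictorEmission] = {
    Method.SIFT: PredictorEmission(0.04, 0.008, 0.008, 0.008, lo=0.0, hi=1.0),
    Method.POLYPHEN2: PredictorEmission(0.65, 0.08, 0.92, 0.07, lo=0.0, hi=1.0),
    Method.MUTATION_ASSESSOR: PredictorEmission(2.3, 0.25, 3.4, 0.4, lo=-6.0, hi=6.0),
    Method.FATHMM: PredictorEmission(-5.0, 1.8, -11.5, 1.8),
    Method.CONDEL: PredictorEmission(0.60, 0.04, 0.80, 0.06, lo=0.0, hi=1.0),
    Method.CADD: PredictorEmission(21.0, 3.0, 33.0, 3.0, lo=0.0),
}


@dataclass(frozen=True)
class VariantSetModel:
    """Annotation model for one variant set (disease or population-only)."""

    consurf_weights: Tuple[float, ...]
    zero_inflation: float       # probability of allele frequency exactly 0
    log10_freq_range: Tuple[float, float]
    ddg_mean: float             # kcal/mol, negative = destabilising
    ddg_sd: float

    def __post_init__(self) -> None:
        w = np.asarray(self.consurf_weights, dtype=float)
        if w.shape != (9,) or (w < 0).any() or not math.isclose(w.sum(), 1.0):
            raise ValueError("consurf_weights must be 9 probabilities summing to 1")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.ddg_sd <= 0:
            raise ValueError("ddg_sd must be positive")


#: ~80% of disease-variant positions at ConSurf 6-9; frequency 0 for half,
#: otherwise below 0.01%; ddG centred at -1.1 kcal/mol
DISEASE_SET_MODEL = VariantSetModel(
    consurf_weights=(0.02, 0.02, 0.04, 0.05, 0.07, 0.15, 0.15, 0.20, 0.30),
    zero_inflation=0.5,
    log10_freq_range=(-6.0, -4.0),
    ddg_mean=-1.1, ddg_sd=0.8,
)

#: ~40% at grades 6-9 with a large spike at grade 1; broader, higher
#: frequencies; milder ddG centred at -0.65 kcal/mol
POPULATION_SET_MODEL = VariantSetModel(
    consurf_weights=(0.30, 0.08, 0.08, 0.07, 0.07, 0.10, 0.10, 0.10, 0.10),
    zero_inflation=0.0,
    log10_freq_range=(-6.0, -2.0),
    ddg_mean=-0.65, ddg_sd=0.8,
)


@dataclass(frozen=True)
class PhenotypeModel:
    """Severity-conditional phenotype model.

    Urinary levels are log-normal with a multiplicative shift per unit of
    severity above the minimum score; age at presentation is normal with a
    negative shift per unit; stone episodes and interventions are Poisson
    with a multiplicative rate factor per unit.
    """

    urine_baseline_median: Mapping[str, float] = field(
        default_factory=lambda: {
            "urine_cystine": 400.0,
            "urine_ornithine": 150.0,
            "urine_arginine": 100.0,
            "urine_lysine": 700.0,
        }
    )
    urine_sigma_log: float = 0.5
    urine_effect_per_unit: Mapping[str, float] = field(
        default_factory=lambda: {
            "urine_cystine": 1.10,
            "urine_ornithine": 1.20,
            "urine_arginine": 1.40,
            "urine_lysine": 1.20,
        }
    )
    age_mean: float = 28.0          # years, at minimum severity
    age_sd: float = 8.0
    age_shift_per_unit: float = 2.5  # years earlier per severity unit
    episode_rate: float = 2.0        # 3-year stone episodes at minimum severity
    intervention_rate: float = 1.0
    rate_factor_per_unit: float = 1.2


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_disease_variants: Mapping[Gene, int] = field(
        default_factory=lambda: {Gene.SLC3A1: 94, Gene.SLC7A9: 58}
    )
    n_population_variants: Mapping[Gene, int] = field(
        default_factory=lambda: {Gene.SLC3A1: 318, Gene.SLC7A9: 144}
    )
    disease_model: VariantSetModel = DISEASE_SET_MODEL
    population_model: VariantSetModel = POPULATION_SET_MODEL
    predictor_emissions: Mapping[Method, PredictorEmission] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTOR_EMISSIONS)
    )
    severe_prevalence: float = 0.5   # latent severity mix among disease variants
    cohort_sizes: Mapping[Gene, int] = field(
        default_factory=lambda: {Gene.SLC3A1: 41, Gene.SLC7A9: 32}
    )
    p_single_allele_dominant: float = 0.4
    #: optional exact per-score patient counts for the dominant gene; when
    #: set, overrides cohort_sizes[SLC7A9] and the allele-count probabilities
    dominant_group_sizes: Optional[Mapping[int, int]] = None
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.severe_prevalence <= 1.0:
            raise ValueError("severe_prevalence must lie in [0, 1]")
        if not 0.0 <= self.p_single_allele_dominant <= 1.0:
            raise ValueError("p_single_allele_dominant must lie in [0, 1]")
        for mapping, what in (
            (self.n_disease_variants, "n_disease_variants"),
            (self.n_population_variants, "n_population_variants"),
            (self.cohort_sizes, "cohort_sizes"),
        ):
            if any(v < 0 for v in mapping.values()):
                raise ValueError(f"{what} must be non-negative")
        if self.dominant_group_sizes is not None:
            bad = set(self.dominant_group_sizes) - {1, 2, 3, 4}
            if bad:
                raise ValueError(
                    f"dominant_group_sizes keys must be scores 1-4, got {sorted(bad)}"
                )

    def noiseless(self) -> "SimulationConfig":
        """Copy with degenerate predictor emissions (score SDs of zero)."""
        emissions = {
            m: replace(e, mild_sd=0.0, severe_sd=0.0)
            for m, e in self.predictor_emissions.items()
        }
        return replace(self, predictor_emissions=emissions)

    def _streams(self) -> Tuple[np.random.Generator, ...]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


_AA = list(ONE_TO_THREE)  # one-letter codes of the 20 standard amino acids


def _random_hgvs(rng: np.random.Generator, gene: Gene, used: set) -> str:
    """A fresh missense HGVS p. string at a random position of the protein."""
    while True:
        pos = int(rng.integers(1, PROTEIN_LENGTH[gene] + 1))
        wt, mut = rng.choice(_AA, size=2, replace=False)
        hgvs = f"p.{ONE_TO_THREE[wt]}{pos}{ONE_TO_THREE[mut]}"
        if hgvs not in used:
            used.add(hgvs)
            return hgvs


def simulate_predictor_scores(
    true_severity: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Dict[str, float]:
    """Draw all six predictor scores conditional on the latent severity."""
    if true_severity not in (1, 2):
        raise ValueError(f"true_severity must be 1 or 2, got {true_severity}")
    return {
        method.value: config.predictor_emissions[method].draw(
            true_severity == 2, rng
        )
        for method in Method
    }


def _draw_annotations(
    model: VariantSetModel, rng: np.random.Generator
) -> Tuple[float, int, float]:
    if rng.random() < model.zero_inflation:
        freq = 0.0
    else:
        lo, hi = model.log10_freq_range
        freq = float(10.0 ** rng.uniform(lo, hi))
    consurf = int(rng.choice(np.arange(1, 10), p=model.consurf_weights))
    ddg = float(rng.normal(model.ddg_mean, model.ddg_sd))
    return freq, consurf, ddg


def simulate_variants(config: SimulationConfig) -> pd.DataFrame:
    """Variant table for both genes and both sets.

    Columns follow the on-disk schema (gene, hgvs_p, consequence,
    allele_frequency, consurf, ddg, the six predictor scores,
    disease_associated) plus a `true_severity` column that is populated for
    disease variants only and is not part of the table schema.
    """
    rng_variants, rng_scores, _ = config._streams()
    rows: List[dict] = []
    for gene in (Gene.SLC3A1, Gene.SLC7A9):
        used: set = set()
        for disease, model, n in (
            (True, config.disease_model, config.n_disease_variants[gene]),
            (False, config.population_model, config.n_population_variants[gene]),
        ):
            for _ in range(n):
                hgvs = _random_hgvs(rng_variants, gene, used)
                freq, consurf, ddg = _draw_annotations(model, rng_variants)
                if disease:
                    severity = 2 if rng_variants.random() < config.severe_prevalence else 1
                    scores = simulate_predictor_scores(severity, config, rng_scores)
                else:
                    # population variants are treated as functionally mild
                    severity = None
                    scores = simulate_predictor_scores(1, config, rng_scores)
                rows.append({
                    "gene": gene.value,
                    "hgvs_p": hgvs,
                    "consequence": "missense",
                    "allele_frequency": freq,
                    "consurf": consurf,
                    "ddg": round(ddg, 4),
                    **{m: round(scores[m], 6) for m in PREDICTOR_METHODS},
                    "disease_associated": disease,
                    "true_severity": severity,
                })
    df = pd.DataFrame(rows)
    df["true_severity"] = df["true_severity"].astype("Int64")
    return df


def _dominant_allele_plan(
    score: int, rng: np.random.Generator
) -> List[int]:
    """Per-allele severities realising a target dominant patient score."""
    if score == 1:
        return [1]
    if score == 2:
        return [2] if rng.random() < 0.5 else [1, 1]
    if score == 3:
        return [1, 2] if rng.random() < 0.5 else [2, 1]
    return [2, 2]


def simulate_cohort(
    config: SimulationConfig, variants: pd.DataFrame
) -> pd.DataFrame:
    """Patient table with genotypes, phenotypes and the latent true score.

    Recessive (SLC3A1) patients receive exactly one disease mutation per
    allele; dominant (SLC7A9) patients receive one or two mutated alleles.
    Each patient's latent score applies the aggregation rules to the
    variants' latent severities, and phenotypes are drawn conditional on it.
    """
    _, _, rng = config._streams()
    disease = variants[variants["disease_associated"].astype(bool)]
    pool: Dict[Gene, Dict[int, List[str]]] = {}
    for gene in (Gene.SLC3A1, Gene.SLC7A9):
        sub = disease[disease["gene"] == gene.value]
        pool[gene] = {
            s: sub.loc[sub["true_severity"] == s, "hgvs_p"].tolist()
            for s in (1, 2)
        }

    def _pick(gene: Gene, severity: int) -> str:
        options = pool[gene][severity]
        if not options:
            raise ValueError(
                f"variant table has no {gene.value} disease variant with "
                f"latent severity {severity}; enlarge the variant simulation"
            )
        return str(rng.choice(options))

    rows: List[dict] = []
    counter = 0

    def _add_patient(gene: Gene, alleles: List[List[str]], true_score: int) -> None:
        nonlocal counter
        counter += 1
        units = true_score - 1
        model = config.phenotype_model
        row = {
            "patient_id": f"P{counter:04d}",
            "gene": gene.value,
            "allele1_mutations": ";".join(alleles[0]),
            "allele2_mutations": ";".join(alleles[1]) if len(alleles) > 1 else "",
            "true_score": true_score,
        }
        for col, base in model.urine_baseline_median.items():
            effect = model.urine_effect_per_unit[col]
            row[col] = round(float(
                math.exp(
                    math.log(base)
                    + units * math.log(effect)
                    + rng.normal(0.0, model.urine_sigma_log)
                )
            ), 2)
        row["age_at_presentation"] = round(max(0.5, float(
            rng.normal(model.age_mean - units * model.age_shift_per_unit,
                       model.age_sd)
        )), 1)
        factor = model.rate_factor_per_unit ** units
        row["stone_episodes_3yr"] = int(rng.poisson(model.episode_rate * factor))
        row["interventions_3yr"] = int(rng.poisson(model.intervention_rate * factor))
        rows.append(row)

    # recessive cohort: both alleles mutated, score = min of latent severities
    for _ in range(config.cohort_sizes.get(Gene.SLC3A1, 0)):
        severities = [
            2 if rng.random() < config.severe_prevalence else 1 for _ in range(2)
        ]
        alleles = [[_pick(Gene.SLC3A1, s)] for s in severities]
        _add_patient(Gene.SLC3A1, alleles, min(severities))

    # dominant cohort: 1-2 mutated alleles, score = sum of latent severities
    if config.dominant_group_sizes is not None:
        targets = [
            score
            for score in sorted(config.dominant_group_sizes)
            for _ in range(config.dominant_group_sizes[score])
        ]
        for score in targets:
            plan = _dominant_allele_plan(score, rng)
            alleles = [[_pick(Gene.SLC7A9, s)] for s in plan]
            _add_patient(Gene.SLC7A9, alleles, score)
    else:
        for _ in range(config.cohort_sizes.get(Gene.SLC7A9, 0)):
            n_alleles = 1 if rng.random() < config.p_single_allele_dominant else 2
            severities = [
                2 if rng.random() < config.severe_prevalence else 1
                for _ in range(n_alleles)
            ]
            alleles = [[_pick(Gene.SLC7A9, s)] for s in severities]
            _add_patient(Gene.SLC7A9, alleles, sum(severities))

    columns = [
        "patient_id", "gene", "allele1_mutations", "allele2_mutations",
        "urine_cystine", "urine_ornithine", "urine_arginine", "urine_lysine",
        "age_at_presentation", "stone_episodes_3yr", "interventions_3yr",
        "true_score",
    ]
    return pd.DataFrame(rows, columns=columns)


def simulate(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: (variant table, patient table) for one config."""
    variants = simulate_variants(config)
    patients = simulate_cohort(config, variants)
    return variants, patients
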