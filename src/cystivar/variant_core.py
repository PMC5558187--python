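"""Domain types for protein-level variants in SLC3A1 / SLC7A9.

Cystinuria-associated mutations are catalogued at the protein level in HGVS
p. notation (e.g. ``p.Arg365Leu``).  This module provides the residue and
mutation types, the physicochemical amino-acid classification used for
substitution cross-tabulations, and small bookkeeping computations
(distinct mutated positions, expected affected individuals in a cohort).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AAClass",
    "Consequence",
    "Gene",
    "Residue",
    "ProteinMutation",
    "Variant",
    "ClassCrossTab",
    "HgvsParseError",
    "parse_hgvs_p",
    "format_hgvs_p",
    "classify_residue",
    "build_crosstab",
    "class_conservation_count",
    "distinct_positions",
    "expected_affected",
    "PREDICTOR_METHODS",
]


class Gene(str, enum.Enum):
    SLC3A1 = "SLC3A1"
    SLC7A9 = "SLC7A9"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    DELETION = "deletion"
    SPLICE_SITE = "splice_site"
    NONSENSE = "nonsense"


class AAClass(str, enum.Enum):
    HYDROPHOBIC = "hydrophobic"
    POLAR = "polar"
    POSITIVE = "positive"
    NEGATIVE = "negative"


#: Canonical three-letter <-> one-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Physicochemical classes. Aromatic Tyr/Trp and small Gly/Cys are grouped as
# hydrophobic; His is grouped with the positively charged residues.  Both
# choices are conventional for membrane-transporter work and overridable via
# the `scheme` argument of classify_residue / build_crosstab.
DEFAULT_CLASS_SCHEME: Mapping[str, AAClass] = {
    **{aa: AAClass.HYDROPHOBIC for aa in "GAVLIPFMWCY"},
    **{aa: AAClass.POLAR for aa in "STNQ"},
    **{aa: AAClass.POSITIVE for aa in "KRH"},
    **{aa: AAClass.NEGATIVE for aa in "DE"},
}

#: Predictor methods whose scores a variant row may carry.
PREDICTOR_METHODS = (
    "sift", "polyphen2", "mutation_assessor", "fathmm", "condel", "cadd",
)


class HgvsParseError(ValueError):
    """Raised when an HGVS p. string cannot be interpreted."""


@dataclass(frozen=True)
class Residue:
    """One of the 20 standard amino acids."""

    three_letter_code: str

    def __post_init__(self) -> None:
        if self.three_letter_code not in THREE_TO_ONE:
            raise ValueError(
                f"not a standard amino acid: {self.three_letter_code!r}"
            )

    @property
    def one_letter_code(self) -> str:
        return THREE_TO_ONE[self.three_letter_code]

    @property
    def aa_class(self) -> AAClass:
        return DEFAULT_CLASS_SCHEME[self.one_letter_code]

    @classmethod
    def from_one_letter(cls, code: str) -> "Residue":
        if code not in ONE_TO_THREE:
            raise ValueError(f"not a standard amino acid: {code!r}")
        return cls(ONE_TO_THREE[code])

    def __str__(self) -> str:
        return self.three_letter_code


@dataclass(frozen=True)
class ProteinMutation:
    """A protein-level mutation at a 1-based residue position.

    Missense mutations carry a mutant residue; frameshift, deletion,
    splice-site and nonsense changes do not.
    """

    wild_type: Residue
    position: int
    mutant: Optional[Residue] = None
    consequence: Consequence = Consequence.MISSENSE

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.consequence is Consequence.MISSENSE:
            if self.mutant is None:
                raise ValueError("missense mutation requires a mutant residue")
            if self.mutant == self.wild_type:
                raise ValueError(
                    f"wild type equals mutant ({self.wild_type}) at position "
                    f"{self.position}: synonymous changes are not mutations"
                )
        elif self.mutant is not None:
            raise ValueError(
                f"{self.consequence.value} mutation must not carry a mutant residue"
            )

    def __str__(self) -> str:
        return format_hgvs_p(self)


@dataclass(frozen=True)
class Variant:
    """A mutation together with its population and predictor annotations.

    ``allele_frequency`` is the ExAC-style population fraction (0 meaning
    absent from the panel), ``consurf`` the 1-9 conservation grade (9 = most
    conserved), ``ddg`` the predicted folding stability change in kcal/mol
    (negative = destabilising).  Any annotation may be missing (None).
    """

    gene: Gene
    mutation: ProteinMutation
    allele_frequency: Optional[float] = None
    consurf: Optional[int] = None
    ddg: Optional[float] = None
    predictor_scores: Mapping[str, float] = field(default_factory=dict)
    disease_associated: bool = False

    def __post_init__(self) -> None:
        if self.allele_frequency is not None and not (
            0.0 <= self.allele_frequency <= 1.0
        ):
            raise ValueError(
                f"allele_frequency must lie in [0, 1], got {self.allele_frequency}"
            )
        if self.consurf is not None and self.consurf not in range(1, 10):
            raise ValueError(f"consurf must be an integer in 1..9, got {self.consurf}")
        unknown = set(self.predictor_scores) - set(PREDICTOR_METHODS)
        if unknown:
            raise ValueError(f"unknown predictor method(s): {sorted(unknown)}")

    @property
    def hgvs_p(self) -> str:
        return format_hgvs_p(self.mutation)


_MISSENSE_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
_TOKEN_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)(fs|del|Ter|\*)$")
_BARE_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)$")

_TOKEN_CONSEQUENCE = {
    "fs": Consequence.FRAMESHIFT,
    "del": Consequence.DELETION,
    "Ter": Consequence.NONSENSE,
    "*": Consequence.NONSENSE,
}
_CONSEQUENCE_TOKEN = {
    Consequence.FRAMESHIFT: "fs",
    Consequence.DELETION: "del",
    Consequence.NONSENSE: "Ter",
}


def parse_hgvs_p(
    text: str, consequence: Optional[Consequence] = None
) -> ProteinMutation:
    """Parse an HGVS protein-level mutation string.

    Recognised forms: ``p.Arg365Leu`` (missense), ``p.Thr216fs`` (frameshift),
    ``p.Gly259del`` (deletion), ``p.Arg365Ter`` / ``p.Arg365*`` (nonsense).
    A bare ``p.Gly259`` is accepted only when a non-missense `consequence`
    is supplied by the caller (used for splice-site rows of the variant
    table, which have no standard protein-level token).
    """
    if not isinstance(text, str) or not text.startswith("p."):
        raise HgvsParseError(f"HGVS p. string must start with 'p.': {text!r}")

    def _residue(code: str, role: str) -> Residue:
        try:
            return Residue(code)
        except ValueError:
            raise HgvsParseError(
                f"unknown {role} residue code {code!r} in {text!r}"
            ) from None

    m = _TOKEN_RE.match(text)
    if m:
        wt = _residue(m.group(1), "wild-type")
        token_cons = _TOKEN_CONSEQUENCE[m.group(3)]
        if consequence is not None and consequence is not token_cons:
            raise HgvsParseError(
                f"{text!r} encodes {token_cons.value} but consequence "
                f"{consequence.value!r} was declared"
            )
        return ProteinMutation(wt, int(m.group(2)), None, token_cons)

    m = _MISSENSE_RE.match(text)
    if m:
        wt = _residue(m.group(1), "wild-type")
        mut = _residue(m.group(3), "mutant")
        if wt == mut:
            raise HgvsParseError(
                f"wild type equals mutant ({m.group(1)}) in {text!r}"
            )
        if consequence not in (None, Consequence.MISSENSE):
            raise HgvsParseError(
                f"{text!r} is a missense notation but consequence "
                f"{consequence.value!r} was declared"
            )
        return ProteinMutation(wt, int(m.group(2)), mut, Consequence.MISSENSE)

    m = _BARE_RE.match(text)
    if m:
        if consequence is None or consequence is Consequence.MISSENSE:
            raise HgvsParseError(
                f"missing mutant residue or consequence token in {text!r}"
            )
        wt = _residue(m.group(1), "wild-type")
        return ProteinMutation(wt, int(m.group(2)), None, consequence)

    raise HgvsParseError(f"unrecognised HGVS p. notation: {text!r}")


def format_hgvs_p(mutation: ProteinMutation) -> str:
    """Format a ProteinMutation back to HGVS p. notation (inverse of parse)."""
    stem = f"p.{mutation.wild_type}{mutation.position}"
    if mutation.consequence is Consequence.MISSENSE:
        return f"{stem}{mutation.mutant}"
    if mutation.consequence is Consequence.SPLICE_SITE:
        return stem
    return f"{stem}{_CONSEQUENCE_TOKEN[mutation.consequence]}"


def classify_residue(
    residue: Residue, scheme: Mapping[str, AAClass] = DEFAULT_CLASS_SCHEME
) -> AAClass:
    """Return the physicochemical class of a standard amino acid."""
    try:
        return scheme[residue.one_letter_code]
    except KeyError:
        raise ValueError(
            f"residue {residue} not covered by the classification scheme"
        ) from None


_CLASS_ORDER = (
    AAClass.HYDROPHOBIC, AAClass.POLAR, AAClass.POSITIVE, AAClass.NEGATIVE,
)


@dataclass(frozen=True)
class ClassCrossTab:
    """4x4 substitution counts indexed (wild-type class, mutant class).

    Rows/columns follow the order hydrophobic, polar, positive, negative.
    """

    counts: tuple  # 4-tuple of 4-tuples of ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (4, 4):
            raise ValueError(f"counts must be 4x4, got shape {arr.shape}")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @classmethod
    def from_array(cls, arr) -> "ClassCrossTab":
        a = np.asarray(arr, dtype=int)
        return cls(tuple(tuple(int(v) for v in row) for row in a))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def row_totals(self) -> tuple:
        return tuple(int(v) for v in self.array.sum(axis=1))

    @property
    def col_totals(self) -> tuple:
        return tuple(int(v) for v in self.array.sum(axis=0))

    @property
    def grand_total(self) -> int:
        return int(self.array.sum())

    def cell(self, wild: AAClass, mutant: AAClass) -> int:
        return int(self.array[_CLASS_ORDER.index(wild), _CLASS_ORDER.index(mutant)])


def build_crosstab(
    mutations: Iterable[ProteinMutation],
    scheme: Mapping[str, AAClass] = DEFAULT_CLASS_SCHEME,
) -> ClassCrossTab:
    """Cross-tabulate missense mutations by (wild-type class, mutant class)."""
    arr = np.zeros((4, 4), dtype=int)
    for mut in mutations:
        if mut.consequence is not Consequence.MISSENSE:
            raise ValueError(
                f"cross-tabulation requires missense mutations, got "
                f"{mut.consequence.value} at {format_hgvs_p(mut)}"
            )
        i = _CLASS_ORDER.index(classify_residue(mut.wild_type, scheme))
        j = _CLASS_ORDER.index(classify_residue(mut.mutant, scheme))
        arr[i, j] += 1
    return ClassCrossTab.from_array(arr)


def class_conservation_count(tab: ClassCrossTab) -> int:
    """Number of mutations that stay within their physicochemical class."""
    return int(np.trace(tab.array))


def distinct_positions(
    n_variants: int, multiplicities: Mapping[int, int]
) -> int:
    """Distinct mutated positions given per-position variant multiplicities.

    `multiplicities` maps k (variants observed at one position) to the number
    of positions carrying exactly k variants; positions not listed carry one.
    E.g. 94 variants with ten 2-variant positions and one 4-variant position
    occupy 94 - (10*1 + 1*3) = 81 distinct positions.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    shared = 0
    excess = 0
    for k, count in multiplicities.items():
        if k < 2 or count < 0:
            raise ValueError(
                f"multiplicity entries need k >= 2 and count >= 0, got {k}: {count}"
            )
        shared += k * count
        excess += (k - 1) * count
    if shared > n_variants:
        raise ValueError(
            f"multiplicities account for {shared} variants but only "
            f"{n_variants} exist"
        )
    return n_variants - excess


def expected_affected(cohort_size: int, prevalence: float) -> int:
    """Expected number of affected individuals, rounded to nearest integer."""
    if cohort_size < 0:
        raise ValueError("cohort_size must be non-negative")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    return int(round(cohort_size * prevalence))
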