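"""Readers and writers for the variant and patient tables.

Both tables are UTF-8 TSV with Unix newlines; missing values are encoded
as empty strings ('.' is not accepted).  Writers are atomic: content goes
to a temporary file in the target directory which is then renamed into
place, so partial outputs never appear under the final name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .cohort_analysis import PHENOTYPE_COLUMNS
from .patient_scoring import PatientGenotype
from .variant_core import (
    Consequence,
    Gene,
    HgvsParseError,
    PREDICTOR_METHODS,
    Variant,
    parse_hgvs_p,
)

__all__ = [
    "VARIANT_COLUMNS",
    "PATIENT_COLUMNS",
    "TableFormatError",
    "read_variant_table",
    "write_variant_table",
    "read_patient_table",
    "write_patient_table",
    "genotypes_from_frame",
    "phenotypes_from_frame",
    "variants_to_frame",
    "atomic_write_text",
    "write_tsv",
    "RunManifest",
]

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = (
    "gene", "hgvs_p", "consequence", "allele_frequency", "consurf", "ddg",
    *PREDICTOR_METHODS, "disease_associated",
)
PATIENT_COLUMNS = (
    "patient_id", "gene", "allele1_mutations", "allele2_mutations",
    *PHENOTYPE_COLUMNS,
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class TableFormatError(ValueError):
    """Raised when an input table violates its declared schema."""


def atomic_write_text(path, content: str) -> None:
    """Write text to `path` via a temporary file + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path) -> None:
    """Atomic TSV write with empty strings for nulls."""
    atomic_write_text(path, df.to_csv(sep="\t", index=False, na_rep=""))


def _parse_optional_float(raw: str, column: str, row: int, lo=None, hi=None):
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        raise TableFormatError(
            f"row {row}: {column} value {raw!r} is not a number"
        ) from None
    if lo is not None and not (lo <= value <= (hi if hi is not None else value)):
        raise TableFormatError(
            f"row {row}: {column} value {value} outside [{lo}, {hi}]"
        )
    return value


def read_variant_table(path) -> List[Variant]:
    """Read a variant TSV into Variant records.

    The header must match the declared schema exactly (order-insensitive,
    no unknown columns); empty strings encode nulls.  Row numbers in error
    messages are 1-based data rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(VARIANT_COLUMNS)
    if unknown:
        raise TableFormatError(f"unknown column(s): {sorted(unknown)}")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"missing column(s): {sorted(missing)}")

    variants: List[Variant] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            consequence = Consequence(rec["consequence"])
        except ValueError:
            raise TableFormatError(
                f"row {i}: unknown consequence {rec['consequence']!r}"
            ) from None
        try:
            mutation = parse_hgvs_p(
                rec["hgvs_p"],
                None if consequence is Consequence.MISSENSE else consequence,
            )
        except HgvsParseError as exc:
            raise TableFormatError(f"row {i}: {exc}") from None
        try:
            gene = Gene(rec["gene"])
        except ValueError:
            raise TableFormatError(f"row {i}: unknown gene {rec['gene']!r}") from None

        freq = _parse_optional_float(rec["allele_frequency"], "allele_frequency",
                                     i, lo=0.0, hi=1.0)
        consurf_raw = rec["consurf"]
        if consurf_raw == "":
            consurf = None
        else:
            try:
                consurf = int(float(consurf_raw))
                if consurf != float(consurf_raw):
                    raise ValueError
            except ValueError:
                raise TableFormatError(
                    f"row {i}: consurf value {consurf_raw!r} is not an integer"
                ) from None
            if consurf not in range(1, 10):
                raise TableFormatError(
                    f"row {i}: consurf value {consurf} outside 1..9"
                )
        ddg = _parse_optional_float(rec["ddg"], "ddg", i)
        scores = {}
        for method in PREDICTOR_METHODS:
            value = _parse_optional_float(rec[method], method, i)
            if value is not None:
                scores[method] = value
        flag = rec["disease_associated"].strip().lower()
        if flag not in _TRUE | _FALSE:
            raise TableFormatError(
                f"row {i}: disease_associated must be boolean, got "
                f"{rec['disease_associated']!r}"
            )
        variants.append(Variant(
            gene=gene, mutation=mutation, allele_frequency=freq,
            consurf=consurf, ddg=ddg, predictor_scores=scores,
            disease_associated=flag in _TRUE,
        ))
    return variants


def variants_to_frame(variants: Sequence[Variant]) -> pd.DataFrame:
    """Variant records as a schema-conformant DataFrame."""
    rows = []
    for v in variants:
        rows.append({
            "gene": v.gene.value,
            "hgvs_p": v.hgvs_p,
            "consequence": v.mutation.consequence.value,
            "allele_frequency": v.allele_frequency,
            "consurf": v.consurf,
            "ddg": v.ddg,
            **{m: v.predictor_scores.get(m) for m in PREDICTOR_METHODS},
            "disease_associated": v.disease_associated,
        })
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df["consurf"] = df["consurf"].astype("Int64")
    return df


def write_variant_table(frame_or_variants, path) -> None:
    """Write a variant table, keeping only schema columns."""
    if isinstance(frame_or_variants, pd.DataFrame):
        df = frame_or_variants.loc[:, list(VARIANT_COLUMNS)]
    else:
        df = variants_to_frame(frame_or_variants)
    write_tsv(df, path)


def _split_allele(raw: str, patient_id: str, gene) -> Tuple:
    mutations = []
    for token in raw.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            mutations.append(parse_hgvs_p(token))
        except HgvsParseError as exc:
            raise TableFormatError(f"patient {patient_id}: {exc}") from None
    return tuple(mutations)


def read_patient_table(
    path, strict_recessive: bool = False
) -> Tuple[List[PatientGenotype], pd.DataFrame]:
    """Read a patient TSV into genotypes plus a phenotype frame.

    Returns (genotypes, phenotypes) where phenotypes is indexed by
    patient_id.  A patient id appearing under both genes is excluded with a
    warning, matching the exclusion applied to the clinical cohort; a
    recessive (SLC3A1) patient with fewer than two mutated alleles is
    excluded with a warning, or rejected when `strict_recessive` is set.
    Patients with no identified mutation are kept (the scorer skips them).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(PATIENT_COLUMNS)
    if unknown:
        raise TableFormatError(f"unknown column(s): {sorted(unknown)}")
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"missing column(s): {sorted(missing)}")

    genes_by_patient: Dict[str, set] = {}
    for rec in df.to_dict("records"):
        genes_by_patient.setdefault(rec["patient_id"], set()).add(rec["gene"])
    both_genes = {p for p, gs in genes_by_patient.items() if len(gs) > 1}
    for pid in sorted(both_genes):
        logger.warning(
            "patient %s has mutations in both SLC3A1 and SLC7A9; excluded "
            "(mixed-gene genotypes are outside the scoring model)", pid,
        )

    genotypes: List[PatientGenotype] = []
    pheno_rows = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        pid = rec["patient_id"]
        if not pid:
            raise TableFormatError(f"row {i}: empty patient_id")
        if pid in both_genes:
            continue
        try:
            gene = Gene(rec["gene"])
        except ValueError:
            raise TableFormatError(
                f"patient {pid}: unknown gene {rec['gene']!r}"
            ) from None
        allele1 = _split_allele(rec["allele1_mutations"], pid, gene)
        allele2 = _split_allele(rec["allele2_mutations"], pid, gene)
        genotype = PatientGenotype(pid, gene, allele1, allele2)
        if (
            gene is Gene.SLC3A1
            and genotype.n_mutated_alleles == 1
        ):
            message = (
                f"patient {pid}: SLC3A1 genotype has one mutated allele, "
                f"inconsistent with recessive disease"
            )
            if strict_recessive:
                raise TableFormatError(message)
            logger.warning("%s; excluded", message)
            continue
        genotypes.append(genotype)
        pheno_rows.append({
            "patient_id": pid,
            **{
                col: _parse_optional_float(rec[col], col, i, lo=0.0)
                for col in PHENOTYPE_COLUMNS
            },
        })
    phenotypes = pd.DataFrame(
        pheno_rows, columns=["patient_id", *PHENOTYPE_COLUMNS]
    ).set_index("patient_id")
    return genotypes, phenotypes


def genotypes_from_frame(df: pd.DataFrame) -> List[PatientGenotype]:
    """Build PatientGenotype records from an in-memory patient frame."""
    out = []
    for rec in df.to_dict("records"):
        pid = rec["patient_id"]
        out.append(PatientGenotype(
            pid, Gene(rec["gene"]),
            _split_allele(str(rec["allele1_mutations"]), pid, rec["gene"]),
            _split_allele(str(rec["allele2_mutations"]), pid, rec["gene"]),
        ))
    return out


def phenotypes_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Phenotype columns of an in-memory patient frame, indexed by patient."""
    return df.set_index("patient_id")[list(PHENOTYPE_COLUMNS)].astype(float)


def write_patient_table(df: pd.DataFrame, path) -> None:
    """Write a patient table, keeping only schema columns."""
    write_tsv(df.loc[:, list(PATIENT_COLUMNS)], path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    tool_version: str
    inputs: Dict[str, str] = field(default_factory=dict)   # path -> sha256
    config: Dict = field(default_factory=dict)
    seed: Optional[int] = None
    started: str = ""
    finished: str = ""
    warnings: List[str] = field(default_factory=list)

    @classmethod
    def start(cls, version: str, input_paths: Sequence, config: Dict,
              seed: Optional[int] = None) -> "RunManifest":
        return cls(
            tool_version=version,
            inputs={str(p): _sha256(p) for p in input_paths},
            config=config,
            seed=seed,
            started=datetime.now(timezone.utc).isoformat(),
        )

    def finish(self, out_dir) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        path = Path(out_dir) / "manifest.json"
        atomic_write_text(path, json.dumps(self.__dict__, indent=2, default=str))
        return path
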