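"""Annotation tables: canonical model, platform export dialects, filters, I/O.

The canonical unit is one putative lipid identification — formula, lipid
class, retention time (minutes), MS level and name — as exported from
lipidomics processing software. Readers are provided for a canonical
5-column CSV plus best-effort dialects for MS DIAL alignment exports
(TSV) and Lipostar exports (CSV); because export layouts drift between
software versions every dialect's column mapping can be overridden.

Rows whose formula, class or retention time cannot be parsed are dropped
and counted rather than failing the whole file: real exports routinely
carry unknowns ("??", blank formulas) and header junk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .formula import AtomComposition, FormulaError, parse_formula

if TYPE_CHECKING:  # pragma: no cover
    from .rt_qc import QCReport

__all__ = [
    "MS1",
    "MS2",
    "LipidAnnotation",
    "AnnotationTable",
    "SchemaError",
    "read_annotation_table",
    "write_annotation_table",
    "filter_void_volume",
    "canonical_class",
    "write_qc_report",
]

logger = logging.getLogger("lipidqc")

MS1 = "MS1"
MS2 = "MS2"

#: default run length in minutes (0-15 min gradient incl. re-equilibration)
DEFAULT_RUNTIME_MIN = 15.0


class SchemaError(ValueError):
    """Required columns could not be resolved in an annotation export."""


def canonical_class(label: str) -> str:
    """Canonicalize a lipid class token: trim and collapse whitespace."""
    return re.sub(r"\s+", " ", str(label).strip())


@dataclass(frozen=True)
class LipidAnnotation:
    """One putative lipid identification from a processing platform."""

    id: str
    name: str
    lipid_class: str
    formula: str
    composition: AtomComposition
    rt_min: float
    ms_level: str  # MS1 | MS2
    score: float | None = None
    platform: str = ""

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError(f"negative retention time: {self.rt_min}")
        if self.ms_level not in (MS1, MS2):
            raise ValueError(f"ms_level must be MS1 or MS2, got {self.ms_level!r}")


@dataclass
class AnnotationTable:
    """An ordered collection of annotations from one platform export."""

    annotations: list[LipidAnnotation]
    runtime_min: float = DEFAULT_RUNTIME_MIN
    platform: str = ""
    source: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.runtime_min <= 0:
            raise ValueError("runtime_min must be positive")
        ids = [a.id for a in self.annotations]
        if len(set(ids)) != len(ids):
            raise ValueError("annotation ids must be unique within a table")

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def replace(self, annotations: list[LipidAnnotation]) -> "AnnotationTable":
        return dataclasses.replace(self, annotations=annotations)

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular view (one row per annotation)."""
        return pd.DataFrame(
            {
                "id": [a.id for a in self.annotations],
                "name": [a.name for a in self.annotations],
                "lipid_class": [a.lipid_class for a in self.annotations],
                "formula": [a.formula for a in self.annotations],
                "rt_min": [a.rt_min for a in self.annotations],
                "ms_level": [a.ms_level for a in self.annotations],
                "score": [a.score for a in self.annotations],
            }
        )


# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------

# role -> candidate column names, first match wins (case-insensitive).
_DIALECTS: dict[str, dict] = {
    "canonical": {
        "sep": ",",
        "columns": {
            "formula": ["formula"],
            "lipid_class": ["lipid_class", "class"],
            "rt_min": ["rt_min", "rt"],
            "ms_level": ["ms_level"],
            "name": ["name"],
            "score": ["score"],
        },
    },
    "msdial": {
        "sep": "\t",
        "columns": {
            "formula": ["Formula"],
            "lipid_class": ["Ontology"],
            "rt_min": ["Average Rt(min)", "RT (min)"],
            "name": ["Metabolite name"],
            "ms_level": ["MS/MS assigned", "MS/MS matched"],
            "score": ["Total score"],
        },
    },
    "lipostar": {
        "sep": ",",
        "columns": {
            "formula": ["Formula", "Molecular Formula"],
            "lipid_class": ["Class", "Lipid Class"],
            "rt_min": ["RT", "Retention Time", "RT (min)"],
            "name": ["Name", "Identification", "Lipid"],
            "ms_level": ["MS/MS", "Fragmentation", "MS2"],
            "score": ["Score", "Identification Score"],
        },
    },
}

_TRUTHY = {"true", "yes", "1", "y", "t", "ms2"}


def _resolve_columns(
    header: list[str], dialect: str, column_map: dict[str, str] | None
) -> dict[str, str]:
    spec = _DIALECTS[dialect]["columns"]
    lower = {c.lower(): c for c in header}
    resolved: dict[str, str] = {}
    for role, candidates in spec.items():
        if column_map and role in column_map:
            candidates = [column_map[role]]
        for cand in candidates:
            if cand.lower() in lower:
                resolved[role] = lower[cand.lower()]
                break
    missing = [r for r in ("formula", "lipid_class", "rt_min") if r not in resolved]
    if missing:
        raise SchemaError(
            f"could not resolve required columns {missing} for dialect "
            f"{dialect!r}; sought {[spec[r] for r in missing]}, header has {header}"
        )
    return resolved


def _infer_ms_level(value, dialect: str) -> str:
    """MS level from the dialect's evidence column.

    Canonical tables state MS1/MS2 explicitly; MS DIAL and Lipostar
    exports carry a fragmentation-evidence column whose truthiness (or
    mere non-emptiness) marks an MS2-backed identification.
    """
    if pd.isna(value) or str(value).strip() == "":
        return MS1
    text = str(value).strip().lower()
    if dialect == "canonical":
        if text in ("ms1", "1"):
            return MS1
        if text in ("ms2", "2"):
            return MS2
        raise ValueError(f"unrecognised ms_level value {value!r}")
    if text in _TRUTHY:
        return MS2
    if text in ("false", "no", "0", "n", "f", "ms1"):
        return MS1
    return MS2  # non-empty fragment evidence


def read_annotation_table(
    path: str | Path,
    dialect: str = "canonical",
    column_map: dict[str, str] | None = None,
    runtime_min: float = DEFAULT_RUNTIME_MIN,
    platform: str | None = None,
    class_synonyms: dict[str, str] | None = None,
    merge_deuterium: bool = False,
) -> AnnotationTable:
    """Read a platform annotation export into the canonical model.

    Rows with a missing or unparseable formula, class or retention time
    are dropped and counted in ``table.n_skipped`` (and logged). Raises
    ``SchemaError`` if required columns cannot be resolved and
    ``ValueError`` if no row survives.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    df = pd.read_csv(path, sep=_DIALECTS[dialect]["sep"], dtype=str)
    cols = _resolve_columns(list(df.columns), dialect, column_map)

    annotations: list[LipidAnnotation] = []
    skipped = 0
    plat = platform if platform is not None else dialect
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        try:
            formula = str(rec[cols["formula"]]).strip()
            composition = parse_formula(formula, merge_deuterium=merge_deuterium)
            rt = float(rec[cols["rt_min"]])
            if not rt >= 0:
                raise ValueError("negative rt")
            klass = canonical_class(rec[cols["lipid_class"]])
            if not klass or klass.lower() == "nan":
                raise ValueError("missing class")
        except (FormulaError, ValueError, TypeError, KeyError) as exc:
            skipped += 1
            logger.debug("skipping row %d of %s: %s", i, path, exc)
            continue
        if class_synonyms:
            klass = class_synonyms.get(klass, klass)
        ms_level = (
            _infer_ms_level(rec.get(cols["ms_level"]), dialect)
            if "ms_level" in cols
            else MS1
        )
        score = None
        if "score" in cols and not pd.isna(rec.get(cols["score"])):
            try:
                score = float(rec[cols["score"]])
            except (TypeError, ValueError):
                score = None
        name = str(rec.get(cols.get("name", ""), "")).strip() if "name" in cols else ""
        annotations.append(
            LipidAnnotation(
                id=f"{plat}-{i}",
                name="" if name.lower() == "nan" else name,
                lipid_class=klass,
                formula=formula,
                composition=composition,
                rt_min=rt,
                ms_level=ms_level,
                score=score,
                platform=plat,
            )
        )
    if skipped:
        logger.info("%s: skipped %d unparseable rows", path, skipped)
    if not annotations:
        raise ValueError(f"no usable annotation rows in {path}")
    return AnnotationTable(
        annotations=annotations,
        runtime_min=runtime_min,
        platform=plat,
        source=str(path),
        n_skipped=skipped,
    )


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    """Write a table as canonical CSV (re-readable with dialect='canonical')."""
    df = table.to_frame().drop(columns=["id"])
    df = df[["formula", "lipid_class", "rt_min", "ms_level", "name", "score"]]
    df.to_csv(path, index=False, float_format="%.6f")


def filter_void_volume(table: AnnotationTable, min_rt: float = 1.0) -> AnnotationTable:
    """Drop annotations eluting with the solvent front (rt below ``min_rt``).

    Unretained lipids carry no usable retention information, so anything
    with rt_min strictly below the cutoff (default 1 min) is excluded;
    the boundary value itself is kept. Idempotent; order preserving.
    """
    if min_rt < 0:
        raise ValueError("min_rt must be >= 0")
    kept = [a for a in table.annotations if a.rt_min >= min_rt]
    removed = len(table.annotations) - len(kept)
    if removed:
        logger.info(
            "%s: removed %d annotations below %.2f min (void volume)",
            table.source or table.platform,
            removed,
            min_rt,
        )
    return table.replace(kept)


# ---------------------------------------------------------------------------
# QC report output
# ---------------------------------------------------------------------------

def write_qc_report(report: "QCReport", path: str | Path) -> None:
    """Write a QC report as CSV plus a JSON summary sidecar.

    The CSV has one row per annotation (identity, observed and predicted
    retention time, residual, outlier flag); numeric fields are written
    at 6 decimal places so a read-back round trip is bit-exact. The
    sidecar ``<path>.summary.json`` carries the consistency percentages
    and the config echo.
    """
    path = Path(path)
    df = report.per_annotation.copy()
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = path.with_suffix(path.suffix + ".summary.json")
    with open(sidecar, "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
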