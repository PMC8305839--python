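"""Core data containers and the TSV dialect shared by every pipeline stage.

A study is carried through preprocessing as a :class:`StudyMatrix`: a wide
sample x metabolite table of non-negative intensities (``NaN`` marks a
missing measurement) plus per-sample metadata (role, analytical batch,
study phase) and a processing-stage tag.  Metabolite annotations (ontology
class, lipid subclass, pathway memberships) travel separately in an
:class:`AnnotationTable`, and the known-concentration calibrant replicates
in a :class:`CalibrantPanel`.

All tables round-trip through tab-separated text with a header row, UTF-8,
'.' decimal separator and an empty cell for a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: processing stages in the only order transitions are allowed
STAGES = ("raw", "pool_normalized", "calibrated", "log10", "imputed", "autoscaled")

ROLES = ("patient", "reference", "calibrant")

#: ontology class used for the complex-lipid / fatty-acid compartment
LIPID_CLASS = "complex lipids and fatty acids"

META_COLUMNS = ("role", "batch", "phase")


class StudyFormatError(ValueError):
    """Raised when a study table violates the container contract."""


def _stage_index(stage: str) -> int:
    try:
        return STAGES.index(stage)
    except ValueError:
        raise StudyFormatError(f"unknown stage {stage!r}; expected one of {STAGES}")


@dataclass
class StudyMatrix:
    """Sample x metabolite intensity table plus per-sample metadata.

    Parameters
    ----------
    values
        Wide DataFrame, one row per sample, one column per metabolite.
        ``NaN`` encodes a missing measurement.  At stages before the log
        transform all non-missing entries must be strictly positive.
    sample_meta
        DataFrame indexed like ``values`` with columns ``role`` (one of
        ``patient``/``reference``/``calibrant``), ``batch`` and ``phase``.
    stage
        Current processing stage; transitions must follow :data:`STAGES`.
    flags
        Per-metabolite QC flags, e.g. ``semi_quantitative`` for metabolites
        that could not be calibrated.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    stage: str = "raw"
    flags: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _stage_index(self.stage)
        if not self.values.index.equals(self.sample_meta.index):
            raise StudyFormatError("values and sample_meta must share the same sample index")
        missing_cols = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing_cols:
            raise StudyFormatError(f"sample_meta lacks columns {missing_cols}")
        bad_roles = set(self.sample_meta["role"]) - set(ROLES)
        if bad_roles:
            raise StudyFormatError(f"unknown sample roles {sorted(bad_roles)}")
        if _stage_index(self.stage) <= _stage_index("calibrated"):
            v = self.values.to_numpy(dtype=float)
            if np.any(v[~np.isnan(v)] <= 0):
                raise StudyFormatError(
                    f"non-positive intensity at stage {self.stage!r}; "
                    "pre-log stages require strictly positive values"
                )

    # -- convenience views -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator, True where the value is missing."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def rows_with_role(self, role: str) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["role"] == role]

    @property
    def patient_ids(self) -> pd.Index:
        return self.rows_with_role("patient")

    def patient_values(self) -> pd.DataFrame:
        return self.values.loc[self.patient_ids]

    # -- stage machinery ---------------------------------------------------

    def advanced(
        self,
        values: pd.DataFrame,
        stage: str,
        extra_flags: Mapping[str, tuple[str, ...]] | None = None,
        sample_meta: pd.DataFrame | None = None,
    ) -> "StudyMatrix":
        """Return a new matrix at a later stage, enforcing stage order."""
        if _stage_index(stage) <= _stage_index(self.stage):
            raise StudyFormatError(
                f"stage may only advance ({self.stage!r} -> {stage!r} is not forward)"
            )
        meta = self.sample_meta if sample_meta is None else sample_meta
        flags = dict(self.flags)
        if extra_flags:
            for met, fl in extra_flags.items():
                flags[met] = tuple(flags.get(met, ())) + tuple(fl)
        flags = {m: f for m, f in flags.items() if m in values.columns}
        return StudyMatrix(values=values, sample_meta=meta.loc[values.index], stage=stage, flags=flags)


@dataclass
class AnnotationTable:
    """Metabolite annotations: ontology class, lipid subclass, pathways.

    ``table`` is indexed by metabolite id with columns ``class``,
    ``subclass`` (empty string for non-lipids) and ``pathways`` (a tuple of
    pathway names, at least one per metabolite).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("class", "subclass", "pathways"):
            if col not in self.table.columns:
                raise StudyFormatError(f"annotation table lacks column {col!r}")
        self.table = self.table.copy()
        self.table["pathways"] = self.table["pathways"].map(tuple)
        if any(len(p) == 0 for p in self.table["pathways"]):
            raise StudyFormatError("every metabolite needs at least one pathway membership")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.table.index)

    def lipid_ids(self) -> list[str]:
        return list(self.table.index[self.table["class"] == LIPID_CLASS])

    def subclass_of(self) -> pd.Series:
        return self.table["subclass"]

    def pathway_members(self, restrict_to: list[str] | None = None) -> dict[str, list[str]]:
        """Map pathway name -> member metabolite ids (optionally restricted)."""
        keep = set(self.table.index if restrict_to is None else restrict_to)
        members: dict[str, list[str]] = {}
        for met, paths in self.table["pathways"].items():
            if met not in keep:
                continue
            for p in paths:
                members.setdefault(p, []).append(met)
        return members


@dataclass
class CalibrantPanel:
    """Calibrant replicate measurements with known concentrations.

    ``replicate_values`` holds one row per calibrant replicate (same unit
    and stage as the study the panel was extracted from); ``concentrations``
    maps metabolite id to its known concentration (NaN where unknown).
    """

    replicate_values: pd.DataFrame
    concentrations: pd.Series

    def __post_init__(self) -> None:
        if len(self.replicate_values) < 2:
            raise StudyFormatError("calibrant panel needs at least 2 replicates")
        conc = self.concentrations.dropna()
        if (conc <= 0).any():
            raise StudyFormatError("calibrant concentrations must be positive where defined")


# ---------------------------------------------------------------------------
# TSV input/output


def _check_rectangular(path: str | Path) -> None:
    """Reject ragged TSV files with a line-precise error message."""
    with open(path, "r", encoding="utf-8") as fh:
        width = None
        for i, line in enumerate(fh, start=1):
            n = line.rstrip("\n").count("\t")
            if width is None:
                width = n
            elif n != width:
                raise StudyFormatError(
                    f"{path}: ragged row at line {i} ({n + 1} fields, expected {width + 1})"
                )


def write_study_tsv(study: StudyMatrix, path: str | Path) -> None:
    out = study.sample_meta[list(META_COLUMNS)].join(study.values)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_study_tsv(path: str | Path, stage: str = "raw") -> StudyMatrix:
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta = df[list(META_COLUMNS)].copy()
    values = df.drop(columns=list(META_COLUMNS)).astype(float)
    return StudyMatrix(values=values, sample_meta=meta, stage=stage)


def write_annotation_tsv(annotation: AnnotationTable, path: str | Path) -> None:
    out = annotation.table.copy()
    out["pathways"] = out["pathways"].map(";".join)
    out.index.name = "metabolite_id"
    out.to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> AnnotationTable:
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col="metabolite_id", keep_default_na=False)
    df["pathways"] = df["pathways"].map(lambda s: tuple(p for p in s.split(";") if p))
    return AnnotationTable(table=df)


def write_series_tsv(series: pd.Series, path: str | Path, index_name: str, value_name: str) -> None:
    s = series.copy()
    s.index.name = index_name
    s.name = value_name
    s.to_frame().to_csv(path, sep="\t", na_rep="")


def read_series_tsv(path: str | Path, index_name: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=index_name)
    return df[df.columns[0]]
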