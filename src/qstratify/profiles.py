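"""Domain types and tabular I/O for QST sensory profiles.

Quantitative sensory testing (QST) after the DFNS protocol measures 13
thermal and mechanical detection/pain parameters.  Eleven of them are
z-transformed against age-, sex- and body-region-matched normative data, so
that a healthy population has mean 0 and SD 1.  Two parameters cannot be
normalized because they are (nearly) absent in healthy subjects and are
instead coded discretely: paradoxical heat sensation (PHS, 0 = absent,
+2 = present) and dynamic mechanical allodynia (DMA, 0 = none, +2 = mean
pain rating below 1/100, +3 = mean rating between 1 and 100).

This module defines the parameter battery, per-subject profiles with
missing-value support, the phenotype centroid table (per-parameter mean and
SD for the sensory-loss, thermal-hyperalgesia and mechanical-hyperalgesia
clusters, plus the implicit healthy reference at mean 0 / SD 1), the two
discrete codings, abnormality flagging at |z| > 1.96, and CSV round-trip
I/O.  Computing z-values from raw measurements is out of scope: profiles
enter on the z-scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Abnormality bound on the z-scale: values outside the 95% reference
#: interval, i.e. z < -1.96 or z > 1.96 (strict).
ABNORMAL_Z = 1.96

PHS_CODES: tuple[float, ...] = (0.0, 2.0)
DMA_CODES: tuple[float, ...] = (0.0, 2.0, 3.0)


class QSTParameter(Enum):
    """The 13 QST parameters, in the fixed DFNS battery order.

    The member order below is the canonical parameter order used throughout
    the package (tables, CSV columns, simulation).  PHS and DMA are the two
    coded-discrete parameters; all others carry continuous z-values.
    """

    CDT = "CDT"  #: cold detection threshold
    WDT = "WDT"  #: warm detection threshold
    TSL = "TSL"  #: thermal sensory limen
    PHS = "PHS"  #: paradoxical heat sensations (coded 0/2)
    CPT = "CPT"  #: cold pain threshold
    HPT = "HPT"  #: heat pain threshold
    MPT = "MPT"  #: mechanical pain threshold
    MPS = "MPS"  #: mechanical pain sensitivity
    DMA = "DMA"  #: dynamic mechanical allodynia (coded 0/2/3)
    PPT = "PPT"  #: pressure pain threshold
    WUR = "WUR"  #: wind-up ratio
    MDT = "MDT"  #: mechanical detection threshold
    VDT = "VDT"  #: vibration detection threshold

    @property
    def is_coded(self) -> bool:
        """True for the two discrete-coded parameters (PHS, DMA)."""
        return self in (QSTParameter.PHS, QSTParameter.DMA)

    @property
    def code_set(self) -> tuple[float, ...] | None:
        if self is QSTParameter.PHS:
            return PHS_CODES
        if self is QSTParameter.DMA:
            return DMA_CODES
        return None


#: Canonical parameter order.
PARAMETERS: tuple[QSTParameter, ...] = tuple(QSTParameter)


class Phenotype(str, Enum):
    """Sensory phenotype labels, in the fixed tie-break order."""

    SL = "SL"  #: sensory loss
    TH = "TH"  #: thermal hyperalgesia
    MH = "MH"  #: mechanical hyperalgesia
    HEALTHY = "HEALTHY"  #: healthy-like reference profile


#: The three patient phenotypes with published centroids.
PATIENT_PHENOTYPES: tuple[Phenotype, ...] = (
    Phenotype.SL,
    Phenotype.TH,
    Phenotype.MH,
)


def code_phs(present: bool | int | float) -> float:
    """Code paradoxical heat sensations as a binary 0/+2 variable.

    Accepts a boolean (present/absent) or a non-negative count of
    paradoxical sensations; any presence maps to +2.  Idempotent on
    already-coded values (0 -> 0, 2 -> 2).
    """
    if isinstance(present, bool):
        return 2.0 if present else 0.0
    count = float(present)
    if math.isnan(count) or count < 0:
        raise ValueError(f"PHS count must be non-negative, got {present!r}")
    return 2.0 if count >= 1 else 0.0


def code_dma(mean_rating: float) -> float:
    """Code dynamic mechanical allodynia as a 0/+2/+3 variable.

    ``mean_rating`` is the mean pain rating of light tactile stimuli on a
    0-100 numerical rating scale: 0 -> 0 (no allodynia), ratings strictly
    below 1 -> +2, ratings from 1 to 100 inclusive -> +3.
    """
    r = float(mean_rating)
    if math.isnan(r) or not (0.0 <= r <= 100.0):
        raise ValueError(f"DMA mean rating must lie in [0, 100], got {mean_rating!r}")
    if r == 0.0:
        return 0.0
    return 2.0 if r < 1.0 else 3.0


def flag_abnormal(z: float | None) -> bool | None:
    """Flag a z-value as abnormal (outside the 95% reference interval).

    Returns True iff |z| > 1.96 (strict; the boundary itself is normal),
    None for a missing value.
    """
    if z is None:
        return None
    z = float(z)
    if math.isnan(z):
        return None
    if math.isinf(z):
        raise ValueError("z-value must be finite")
    return abs(z) > ABNORMAL_Z


@dataclass(frozen=True)
class QSTProfile:
    """One subject's QST profile on the z-scale.

    ``values`` maps parameters to z-values (or PHS/DMA codes); parameters
    absent from the mapping are missing.  NaNs passed in are normalized to
    missing.  At least one parameter must be non-missing.

    ``validate=False`` skips the PHS/DMA code-set check; it exists for
    deliberately non-conformant stress profiles produced by the synthetic
    generator's continuous-Gaussian mode.
    """

    subject_id: str
    values: Mapping[QSTParameter, float]
    etiology: str | None = None
    is_patient: bool | None = None
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        clean: dict[QSTParameter, float] = {}
        for param, value in self.values.items():
            param = QSTParameter(param)
            if value is None:
                continue
            value = float(value)
            if math.isnan(value):
                continue
            if not math.isfinite(value):
                raise ValueError(
                    f"subject {self.subject_id!r}: non-finite value for {param.value}"
                )
            if self.validate and param.is_coded and value not in param.code_set:
                raise ValueError(
                    f"subject {self.subject_id!r}: {param.value} value {value!r} "
                    f"not in code set {param.code_set}"
                )
            clean[param] = value
        if not clean:
            raise ValueError(f"subject {self.subject_id!r}: all 13 parameters missing")
        object.__setattr__(self, "values", clean)

    def z(self, param: QSTParameter) -> float | None:
        """z-value for ``param``, or None when missing."""
        return self.values.get(QSTParameter(param))

    @property
    def missing(self) -> frozenset[QSTParameter]:
        return frozenset(p for p in PARAMETERS if p not in self.values)

    @property
    def n_missing(self) -> int:
        return len(PARAMETERS) - len(self.values)

    def abnormal_flags(self) -> dict[QSTParameter, bool | None]:
        """Per-parameter abnormality flags (None where missing)."""
        return {p: flag_abnormal(self.values.get(p)) for p in PARAMETERS}

    def with_values(self, values: Mapping[QSTParameter, float]) -> "QSTProfile":
        """Copy of this profile with a replaced value mapping."""
        return QSTProfile(
            subject_id=self.subject_id,
            values=values,
            etiology=self.etiology,
            is_patient=self.is_patient,
            validate=self.validate,
        )


@dataclass(frozen=True)
class CentroidTable:
    """Per-phenotype mean (mu) and SD (sigma) of each QST parameter.

    Covers the three patient phenotypes (SL, TH, MH); the healthy reference
    is implicit and fixed at mu = 0, sigma = 1 for every parameter, which is
    the definition of the z-scale.  All 3 x 13 entries must be present and
    every sigma strictly positive.
    """

    _mu: Mapping[Phenotype, Mapping[QSTParameter, float]]
    _sigma: Mapping[Phenotype, Mapping[QSTParameter, float]]

    def __post_init__(self) -> None:
        for pheno in PATIENT_PHENOTYPES:
            for table, name in ((self._mu, "mu"), (self._sigma, "sigma")):
                if pheno not in table:
                    raise ValueError(f"centroid table: phenotype {pheno.value} missing")
                for param in PARAMETERS:
                    if param not in table[pheno]:
                        raise ValueError(
                            f"centroid table: {name}({pheno.value}, {param.value}) missing"
                        )
                    v = float(table[pheno][param])
                    if not math.isfinite(v):
                        raise ValueError(
                            f"centroid table: {name}({pheno.value}, {param.value}) not finite"
                        )
            for param in PARAMETERS:
                if self._sigma[pheno][param] <= 0:
                    raise ValueError(
                        f"centroid table: sigma({pheno.value}, {param.value}) must be > 0"
                    )

    def mu(self, phenotype: Phenotype, param: QSTParameter) -> float:
        phenotype = Phenotype(phenotype)
        if phenotype is Phenotype.HEALTHY:
            return 0.0
        return float(self._mu[phenotype][QSTParameter(param)])

    def sigma(self, phenotype: Phenotype, param: QSTParameter) -> float:
        phenotype = Phenotype(phenotype)
        if phenotype is Phenotype.HEALTHY:
            return 1.0
        return float(self._sigma[phenotype][QSTParameter(param)])

    def arrays(
        self, phenotype: Phenotype, params: Sequence[QSTParameter]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) vectors over ``params`` for one phenotype."""
        mu = np.array([self.mu(phenotype, p) for p in params])
        sigma = np.array([self.sigma(phenotype, p) for p in params])
        return mu, sigma

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CentroidTable":
        """Build from a long-format frame (phenotype, parameter, mu, sigma)."""
        required = {"phenotype", "parameter", "mu", "sigma"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"centroid frame lacks columns: {sorted(missing)}")
        mu: dict[Phenotype, dict[QSTParameter, float]] = {}
        sigma: dict[Phenotype, dict[QSTParameter, float]] = {}
        for row in df.itertuples(index=False):
            pheno = Phenotype(str(row.phenotype).upper())
            param = QSTParameter(str(row.parameter).upper())
            mu.setdefault(pheno, {})[param] = float(row.mu)
            sigma.setdefault(pheno, {})[param] = float(row.sigma)
        return cls(mu, sigma)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CentroidTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def load_default(cls) -> "CentroidTable":
        """Load the packaged default centroid table.

        The packaged table is a synthetic stand-in constructed from the
        published qualitative description of the three phenotypes (sensory
        loss; preserved detection with thermal hyperalgesia; thermal loss
        with pinprick hyperalgesia/allodynia); it is not the defining
        cohort's table.  Supply your own table via :meth:`from_csv` for any
        substantive use.
        """
        ref = resources.files(__package__) / "data" / "centroids_synthetic.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phenotype": pheno.value,
                "parameter": param.value,
                "mu": self.mu(pheno, param),
                "sigma": self.sigma(pheno, param),
            }
            for pheno in PATIENT_PHENOTYPES
            for param in PARAMETERS
        ]
        return pd.DataFrame(rows)


_META_COLUMNS = {
    "subject_id": "subject_id",
    "id": "subject_id",
    "subject": "subject_id",
    "etiology": "etiology",
    "aetiology": "etiology",
    "is_patient": "is_patient",
    "true_phenotype": None,  # ignored on read; written by the simulator
}


def _resolve_columns(
    columns: Iterable[str], column_map: Mapping[str, str] | None
) -> tuple[dict[str, QSTParameter], dict[str, str]]:
    """Map CSV header names to parameters / metadata fields.

    Matching is case-insensitive; ``column_map`` (CSV name -> parameter code
    or metadata field) takes precedence.  Unresolvable columns raise.
    """
    column_map = {k.lower(): v for k, v in (column_map or {}).items()}
    by_code = {p.value.lower(): p for p in PARAMETERS}
    params: dict[str, QSTParameter] = {}
    meta: dict[str, str] = {}
    unresolved: list[str] = []
    for col in columns:
        key = col.strip().lower()
        key = column_map.get(key, key).strip().lower() if key in column_map else key
        if key in by_code:
            params[col] = by_code[key]
        elif key in _META_COLUMNS:
            if _META_COLUMNS[key] is not None:
                meta[col] = _META_COLUMNS[key]
        else:
            unresolved.append(col)
    if unresolved:
        raise ValueError(
            f"unrecognized columns {unresolved}; map them to QST parameter codes "
            f"via column_map or rename them"
        )
    if "subject_id" not in meta.values():
        raise ValueError("no subject-id column found (expected 'subject_id')")
    return params, meta


def read_profiles(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[QSTProfile]:
    """Read subject profiles from a CSV file (one row per subject).

    Empty cells are missing values.  PHS/DMA cells outside their code sets
    raise with the offending row and column named.  A parse report (missing
    cells per parameter) is logged at INFO level.
    """
    df = pd.read_csv(path)
    param_cols, meta_cols = _resolve_columns(df.columns, column_map)
    profiles: list[QSTProfile] = []
    for idx, row in df.iterrows():
        values: dict[QSTParameter, float] = {}
        for col, param in param_cols.items():
            cell = row[col]
            if pd.isna(cell):
                continue
            value = float(cell)
            if param.is_coded and value not in param.code_set:
                raise ValueError(
                    f"row {idx}, column {col!r}: value {cell!r} not in "
                    f"{param.value} code set {param.code_set}"
                )
            values[param] = value
        meta = {field: row[col] for col, field in meta_cols.items()}
        etiology = meta.get("etiology")
        is_patient = meta.get("is_patient")
        profiles.append(
            QSTProfile(
                subject_id=str(meta["subject_id"]),
                values=values,
                etiology=None if pd.isna(etiology) else str(etiology),
                is_patient=None if pd.isna(is_patient) else bool(is_patient),
            )
        )
    n_missing = {
        p.value: sum(1 for prof in profiles if prof.z(p) is None) for p in PARAMETERS
    }
    log.info(
        "read %d profiles from %s; missing cells per parameter: %s",
        len(profiles),
        path,
        n_missing,
    )
    return profiles


def profiles_frame(profiles: Sequence[QSTProfile]) -> pd.DataFrame:
    """Tabulate profiles: metadata columns then the 13 parameter columns."""
    rows = []
    for prof in profiles:
        row: dict[str, object] = {"subject_id": prof.subject_id}
        if prof.etiology is not None:
            row["etiology"] = prof.etiology
        if prof.is_patient is not None:
            row["is_patient"] = prof.is_patient
        for p in PARAMETERS:
            row[p.value] = prof.z(p)
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(profiles: Sequence[QSTProfile], path: str | Path) -> None:
    """Write profiles to CSV; missing values become empty cells."""
    profiles_frame(profiles).to_csv(path, index=False)
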