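"""Reading, validating and typing the patient-by-variable CDE table.

The analysis operates on a cohort of TBI patients measured on NINDS common
data elements (CDEs): coded head-CT findings, a PTSD diagnosis with its
symptom checklist score, neuropsychological scores, the Glasgow Outcome
Scale-Extended (GOS-E) at 3 and 6 months, and 3-level SNP genotype columns.
Seventeen of these variables form the multivariate input of the topological
mapping stage; the rest color the map or feed the confirmatory models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column or metadata entry is absent."""


class CohortValidationError(ValueError):
    """Cell values violate the variable specification."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number."""


VALID_KINDS = ("binary", "ordinal", "continuous", "categorical-genotype")
VALID_ROLES = ("tda-input", "color-only", "outcome", "genotype", "id")

#: Conventional missing markers in delimited exports.
MISSING_STRINGS = frozenset({"", "na", "n/a", "nan", "none", "null", "."})


@dataclass(frozen=True)
class VariableSpec:
    """Type, admissible values, and analytic role of one cohort variable.

    ``valid_range`` is a ``(min, max)`` pair for binary/ordinal/continuous
    variables and a tuple of allowed codes for genotype variables (exactly
    three: homozygote-1, heterozygote, homozygote-2, coded 1/2/3).
    """

    name: str
    kind: str
    valid_range: tuple
    role: str
    allow_missing: bool = True

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name}")
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown variable role {self.role!r} for {self.name}")
        if len(self.valid_range) == 0:
            raise ValueError(f"empty valid_range for {self.name}")
        if self.kind == "categorical-genotype" and len(self.valid_range) != 3:
            raise ValueError(
                f"genotype variable {self.name} must list exactly 3 codes "
                f"(got {len(self.valid_range)})"
            )

    def in_range(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values (non-missing) inside the admissible set."""
        if self.kind == "categorical-genotype":
            return np.isin(values, np.asarray(self.valid_range, dtype=float))
        if self.kind == "binary":
            return np.isin(values, (0.0, 1.0))
        lo, hi = self.valid_range
        return (values >= lo) & (values <= hi)


# The 17 variables of the topological stage, in their conventional order:
# 10 binary CT findings, 2 ordinal CT severity scores, PTSD diagnosis and
# checklist score, processing speed, and two verbal-learning z-scores.
TDA_VARIABLES: tuple[str, ...] = (
    "ct_brain_pathology",
    "skull_fracture",
    "skull_base_fracture",
    "facial_fracture",
    "epidural_hematoma",
    "subdural_hematoma",
    "subarachnoid_hemorrhage",
    "contusion",
    "midline_shift",
    "cisternal_compression",
    "marshall_ct",
    "rotterdam_ct",
    "ptsd_dx_6m",
    "pcl_6m",
    "wais_psi_6m",
    "cvlt_sdc_6m",
    "cvlt_ldc_6m",
)

OUTCOME_VARIABLES: tuple[str, ...] = ("gose_3m", "gose_6m")

SNP_VARIABLES: tuple[str, ...] = (
    "PARP1_rs3219119",
    "ANKK1_rs1800497",
    "ANKK1_rs4938016",
    "ANKK1_rs11604671",
    "COMT_rs4680",
    "DRD2_rs6277",
)

# Variables collected at the 6-month follow-up; the only ones permitted to
# be missing in the curated study table.
SIX_MONTH_VARIABLES: tuple[str, ...] = (
    "ptsd_dx_6m",
    "pcl_6m",
    "wais_psi_6m",
    "cvlt_sdc_6m",
    "cvlt_ldc_6m",
    "gose_6m",
)


def default_specs() -> list[VariableSpec]:
    """Variable specifications for the standard analysis set."""
    binary_ct = TDA_VARIABLES[:10]
    specs = [
        VariableSpec(name, "binary", (0, 1), "tda-input", allow_missing=False)
        for name in binary_ct
    ]
    specs += [
        VariableSpec("marshall_ct", "ordinal", (1, 6), "tda-input", allow_missing=False),
        VariableSpec("rotterdam_ct", "ordinal", (1, 6), "tda-input", allow_missing=False),
        VariableSpec("ptsd_dx_6m", "binary", (0, 1), "tda-input"),
        VariableSpec("pcl_6m", "continuous", (17, 85), "tda-input"),
        VariableSpec("wais_psi_6m", "continuous", (50, 150), "tda-input"),
        VariableSpec("cvlt_sdc_6m", "continuous", (-4.0, 2.5), "tda-input"),
        VariableSpec("cvlt_ldc_6m", "continuous", (-3.5, 2.5), "tda-input"),
        VariableSpec("gose_3m", "ordinal", (1, 8), "outcome"),
        VariableSpec("gose_6m", "ordinal", (1, 8), "outcome"),
    ]
    specs += [
        VariableSpec(name, "categorical-genotype", (1, 2, 3), "genotype")
        for name in SNP_VARIABLES
    ]
    return specs


@dataclass
class CohortTable:
    """Validated patient-by-variable table.

    ``data`` holds one float column per variable, indexed by unique patient
    id, with ``NaN`` as the single internal missing state. ``truth`` is only
    populated by the synthetic generator and carries the generating labels.
    """

    data: pd.DataFrame
    specs: list[VariableSpec]
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -----------------------------------------------------
    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def columns_with_role(self, role: str) -> list[str]:
        return [s.name for s in self.specs if s.role == role and s.name in self.data]

    @property
    def tda_columns(self) -> list[str]:
        return self.columns_with_role("tda-input")

    def tda_matrix(self) -> pd.DataFrame:
        """The analysis-input columns, in declaration order.

        When the cohort carries the standard variable dictionary, all 17
        canonical analysis variables must be present.
        """
        declared = [s.name for s in self.specs if s.role == "tda-input"]
        missing = [c for c in declared if c not in self.data.columns]
        if missing:
            raise SchemaError(f"TDA input columns absent from cohort: {missing}")
        if not declared:
            raise SchemaError("no tda-input variables declared")
        return self.data[declared]

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicate patient ids: {dupes}")
        spec_names = {s.name for s in self.specs}
        unknown = [c for c in self.data.columns if c not in spec_names]
        if unknown:
            raise SchemaError(f"columns without a metadata entry: {unknown}")
        for s in self.specs:
            if s.name not in self.data.columns:
                continue
            col = self.data[s.name].to_numpy(dtype=float)
            miss = np.isnan(col)
            if miss.any() and not s.allow_missing:
                raise CohortValidationError(
                    f"column {s.name!r} does not permit missing values "
                    f"({int(miss.sum())} found)"
                )
            ok = s.in_range(col[~miss])
            if not ok.all():
                bad = np.asarray(col[~miss])[~ok][:5]
                raise CohortValidationError(
                    f"out-of-range values in {s.name!r}: {bad.tolist()}"
                )

    # -- IO --------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = out.index.name or "patient_id"
        out.to_csv(path, encoding="utf-8")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=object)
    return pd.read_csv(path, dtype=object, keep_default_na=False)


def _coerce_numeric(
    raw: pd.Series, name: str, sentinels: Sequence[float]
) -> np.ndarray:
    """Map a raw object column to floats with NaN missing; report bad cells."""
    values = np.full(len(raw), np.nan)
    for i, cell in enumerate(raw):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            continue
        text = str(cell).strip()
        if text.lower() in MISSING_STRINGS:
            continue
        try:
            x = float(text)
        except ValueError as exc:
            raise ParseError(
                f"non-numeric value {cell!r} in column {name!r}, row {i}"
            ) from exc
        if x in sentinels:
            continue
        values[i] = x
    return values


def read_metadata(path: str | Path) -> list[VariableSpec]:
    """Metadata dictionary: columns name, kind, min, max, codes, role
    (optional allow_missing)."""
    raw = _read_table(path)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    required = {"name", "kind", "role"}
    if not required <= set(raw.columns):
        raise SchemaError(f"metadata must contain columns {sorted(required)}")
    specs = []
    for _, row in raw.iterrows():
        kind = str(row["kind"]).strip()
        if kind == "categorical-genotype":
            codes = str(row.get("codes", "1|2|3")).split("|")
            valid: tuple = tuple(float(c) for c in codes)
        else:
            valid = (float(row["min"]), float(row["max"]))
        allow = row.get("allow_missing", "")
        allow_missing = str(allow).strip().lower() not in {"0", "false", "no"}
        specs.append(
            VariableSpec(
                name=str(row["name"]).strip(),
                kind=kind,
                valid_range=valid,
                role=str(row["role"]).strip(),
                allow_missing=allow_missing,
            )
        )
    return specs


def load_cohort(
    table_path: str | Path,
    metadata_path: str | Path | None = None,
    name_map: Mapping[str, str] | None = None,
    missing_sentinels: Sequence[float] = (),
) -> CohortTable:
    """Load and validate a cohort table (CSV or XLSX).

    The first column is the patient identifier. ``name_map`` renames raw
    column headers to the canonical variable names so that deposited tables
    with site-specific headers can be loaded without editing the file.
    Blank cells, NA-like strings, and any value in ``missing_sentinels`` are
    normalized to the single internal missing state.
    """
    raw = _read_table(table_path)
    if raw.shape[1] < 2:
        raise SchemaError("cohort table needs an id column plus data columns")
    if name_map:
        raw = raw.rename(columns=dict(name_map))
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str).str.strip()
    specs = read_metadata(metadata_path) if metadata_path else default_specs()
    spec_names = [s.name for s in specs]

    data = {}
    for col in raw.columns[1:]:
        if col not in spec_names:
            raise SchemaError(f"column {col!r} has no metadata entry")
        data[col] = _coerce_numeric(raw[col], str(col), missing_sentinels)
    frame = pd.DataFrame(data, index=pd.Index(ids, name="patient_id"))
    return CohortTable(frame, [s for s in specs if s.name in frame.columns])


def summarize_variables(cohort: CohortTable) -> pd.DataFrame:
    """Descriptive table: N (non-missing), missing, min, max, mean, SD.

    Mean and SD are computed over non-missing values only (sample SD); an
    empty column reports N=0 with undefined moments left as NaN.
    """
    rows = []
    for name in cohort.data.columns:
        col = cohort.data[name].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        rows.append(
            {
                "variable": name,
                "N": len(obs),
                "missing": len(col) - len(obs),
                "min": obs.min() if len(obs) else np.nan,
                "max": obs.max() if len(obs) else np.nan,
                "mean": obs.mean() if len(obs) else np.nan,
                "SD": obs.std(ddof=1) if len(obs) > 1 else (0.0 if len(obs) else np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def write_metadata(specs: Iterable[VariableSpec], path: str | Path) -> None:
    rows = []
    for s in specs:
        if s.kind == "categorical-genotype":
            rows.append(
                {"name": s.name, "kind": s.kind, "min": "", "max": "",
                 "codes": "|".join(str(c) for c in s.valid_range),
                 "role": s.role, "allow_missing": s.allow_missing}
            )
        else:
            rows.append(
                {"name": s.name, "kind": s.kind, "min": s.valid_range[0],
                 "max": s.valid_range[1], "codes": "", "role": s.role,
                 "allow_missing": s.allow_missing}
            )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
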