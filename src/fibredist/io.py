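"""Reading, parsing, validating and subsetting electrospinning meta-datasets.

A meta-dataset has one row per measured fibre diameter.  Columns follow the
canonical literature-table layout: a study identifier (DOI or synthetic ID),
polymer, up to three solvents with percentage ratios, the six modelling
predictors (concentration, needle gauge, rotation speed, voltage, flow rate,
tip-to-collector distance), optional ambient fields, and the outcome fibre
diameter in nanometres.

Values arrive as free text from heterogeneous literature tables, so every
numeric cell passes through :func:`parse_numeric`, which strips units,
reconciles comma/dot decimal conventions and never raises.  Rows with any
missing modelling field, or a non-finite / non-positive diameter, are dropped
(no imputation).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six numeric process parameters used as model predictors.
PREDICTORS = [
    "concentration",
    "needle_gauge",
    "rotation_speed",
    "voltage",
    "flow_rate",
    "distance",
]

#: The outcome column (fibre diameter, nm).
OUTCOME = "diameter"

#: Fields that must be present and finite for a record to be retained.
MODELLING_FIELDS = PREDICTORS + [OUTCOME]

#: Full canonical column order for a meta-dataset.
CANONICAL_COLUMNS = [
    "study_id",
    "polymer",
    "solvent1",
    "solvent2",
    "solvent3",
    "solvent1_ratio",
    "solvent2_ratio",
    "solvent3_ratio",
    "concentration",
    "needle_gauge",
    "collector_type",
    "rotation_speed",
    "voltage",
    "flow_rate",
    "distance",
    "temperature",
    "humidity",
    "diameter",
]

NUMERIC_COLUMNS = [
    "solvent1_ratio",
    "solvent2_ratio",
    "solvent3_ratio",
    "concentration",
    "needle_gauge",
    "rotation_speed",
    "voltage",
    "flow_rate",
    "distance",
    "temperature",
    "humidity",
    "diameter",
]

# Common literature spellings mapped to canonical names (after normalisation
# to lowercase with whitespace/punctuation removed).
_ALIASES = {
    "doi": "study_id",
    "studyid": "study_id",
    "study": "study_id",
    "needlediameter": "needle_gauge",
    "needlediameterg": "needle_gauge",
    "needlegauge": "needle_gauge",
    "needle": "needle_gauge",
    "typeofcollector": "collector_type",
    "collector": "collector_type",
    "collectortype": "collector_type",
    "rotationspeed": "rotation_speed",
    "rotationspeedrpm": "rotation_speed",
    "rpm": "rotation_speed",
    "voltagekv": "voltage",
    "flowrate": "flow_rate",
    "flowratemlh": "flow_rate",
    "tiptocollectordistance": "distance",
    "tiptocollectordistancecm": "distance",
    "distancecm": "distance",
    "concentrationpct": "concentration",
    "temperaturec": "temperature",
    "humiditypct": "humidity",
    "fibrediameter": "diameter",
    "fibrediameternm": "diameter",
    "fiberdiameter": "diameter",
    "diameternm": "diameter",
}


def _normalise_colname(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


@dataclass
class Provenance:
    """Row bookkeeping for a loaded dataset."""

    source: str
    raw: int
    parsed: int
    retained: int


@dataclass
class MetaDataset:
    """An ordered collection of cleaned electrospinning records.

    ``df`` holds one row per retained observation with the canonical columns;
    ``provenance`` records the source path and raw/parsed/retained counts.
    """

    df: pd.DataFrame
    provenance: Provenance = field(
        default_factory=lambda: Provenance(source="<memory>", raw=0, parsed=0, retained=0)
    )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def polymers(self) -> list[str]:
        """Distinct polymer labels, in order of first appearance."""
        return list(dict.fromkeys(self.df["polymer"].astype(str)))

    @property
    def studies(self) -> list[str]:
        """Sorted distinct study identifiers."""
        return sorted(set(self.df["study_id"].astype(str)))

    def write_csv(self, path) -> None:
        """Write the cleaned dataset as CSV with '#'-prefixed provenance lines."""
        with open(path, "w", newline="") as fh:
            fh.write(f"# source: {self.provenance.source}\n")
            fh.write(
                f"# rows: raw={self.provenance.raw} parsed={self.provenance.parsed} "
                f"retained={self.provenance.retained}\n"
            )
            self.df.to_csv(fh, index=False)


_NUM_KEEP = re.compile(r"[^0-9.,+\-]")


def parse_numeric(raw) -> float:
    """Recover a single numeric value from free literature text.

    Unit suffixes and symbols are stripped ("12%" -> 12.0, "20 G" -> 20.0).
    A comma is read as the decimal separator only when no dot is present and
    at most one comma occurs ("1,5" -> 1.5); a comma alongside a dot is a
    thousands separator and removed ("1,204.5" -> 1204.5).  Anything that
    does not reduce to one numeric token yields NaN; the function never
    raises and never returns +/-infinity.
    """
    if raw is None:
        return math.nan
    if isinstance(raw, (int, float, np.integer, np.floating)):
        value = float(raw)
        return value if math.isfinite(value) else math.nan
    text = str(raw).strip()
    if not text:
        return math.nan
    text = text.replace("−", "-")  # unicode minus
    cleaned = _NUM_KEEP.sub("", text)
    if not any(ch.isdigit() for ch in cleaned):
        return math.nan
    if "." in cleaned:
        cleaned = cleaned.replace(",", "")
    elif cleaned.count(",") == 1:
        cleaned = cleaned.replace(",", ".")
    else:
        cleaned = cleaned.replace(",", "")
    try:
        value = float(cleaned)
    except ValueError:
        return math.nan
    return value if math.isfinite(value) else math.nan


class SchemaError(ValueError):
    """A required column is absent from the input table."""


def _map_columns(columns, schema: dict | None) -> dict:
    """Resolve raw column names to canonical names.

    Matching is case- and whitespace-insensitive, with a user-supplied
    ``schema`` mapping (raw name -> canonical name) taking precedence.
    """
    override = { _normalise_colname(k): v for k, v in (schema or {}).items() }
    mapping = {}
    for col in columns:
        key = _normalise_colname(col)
        if key in override:
            mapping[col] = override[key]
        elif key in _ALIASES:
            mapping[col] = _ALIASES[key]
        else:
            for canon in CANONICAL_COLUMNS:
                if key == _normalise_colname(canon):
                    mapping[col] = canon
                    break
    return mapping


def clean_dataframe(df: pd.DataFrame, source: str = "<memory>") -> MetaDataset:
    """Parse numeric columns and apply the row-retention policy to ``df``.

    ``df`` must already use canonical column names.  Numeric columns are
    parsed cell-wise with :func:`parse_numeric`; rows missing any modelling
    field, with a non-finite or non-positive diameter, or with an empty
    study_id are dropped.  No imputation is performed.
    """
    raw_n = len(df)
    out = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[CANONICAL_COLUMNS]
    for col in NUMERIC_COLUMNS:
        out[col] = out[col].map(parse_numeric).astype(float)
    out["study_id"] = out["study_id"].astype(str).str.strip()
    out["polymer"] = out["polymer"].astype(str).str.strip()
    parsed_n = len(out)
    keep = out["study_id"].ne("") & out["study_id"].str.lower().ne("nan")
    for fieldname in PREDICTORS:
        keep &= np.isfinite(out[fieldname].to_numpy())
    diam = out[OUTCOME].to_numpy()
    keep &= np.isfinite(diam) & (diam > 0)
    out = out.loc[keep].reset_index(drop=True)
    return MetaDataset(
        df=out,
        provenance=Provenance(source=source, raw=raw_n, parsed=parsed_n, retained=len(out)),
    )


def load_dataset(path, schema: dict | None = None) -> MetaDataset:
    """Load a CSV or XLSX meta-dataset, parse it, and drop invalid rows.

    All cells are first read as text to avoid implicit coercion, then parsed
    with :func:`parse_numeric`.  ``schema`` optionally maps raw column names
    to canonical ones; otherwise names are matched case/space-insensitively
    against the canonical layout and common aliases.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SchemaError
        If a required column cannot be resolved, naming the column.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        raw = pd.read_excel(path, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    mapping = _map_columns(raw.columns, schema)
    raw = raw.rename(columns=mapping)
    required = ["study_id", "polymer"] + MODELLING_FIELDS
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"required column '{col}' not found in {path}")
    return clean_dataframe(raw, source=path)


def subset_polymer(ds: MetaDataset, polymer: str) -> MetaDataset:
    """Return the records whose polymer label matches ``polymer``.

    Matching is case-insensitive and whitespace-trimmed.  An unknown polymer
    raises a KeyError listing the available labels.
    """
    target = str(polymer).strip().lower()
    labels = ds.df["polymer"].astype(str).str.strip().str.lower()
    mask = labels == target
    if not mask.any():
        available = sorted(set(ds.df["polymer"].astype(str).str.strip()))
        raise KeyError(f"polymer {polymer!r} not in dataset; available: {available}")
    sub = ds.df.loc[mask].reset_index(drop=True)
    prov = Provenance(
        source=f"{ds.provenance.source}[polymer={polymer}]",
        raw=len(ds.df),
        parsed=len(ds.df),
        retained=len(sub),
    )
    return MetaDataset(df=sub, provenance=prov)
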