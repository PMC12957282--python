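"""Out-of-range detection and historical solvent recommendation.

The range check flags any queried process parameter outside the observed
[min, max] for the chosen polymer; prediction is never blocked by a flag —
out-of-range simply means the setting is outside conditions commonly
reported for stable Taylor-cone formation.

The solvent advisor scores historical records of the polymer subset by a
convex combination of (i) proximity to the user's six process settings,
each axis scaled by its observed standard deviation, and (ii) closeness of
the record's measured diameter to the current prediction.  The most
frequent solvent triplet among the top-scoring candidates is recommended,
with median ratio percentages where available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OUTCOME, PREDICTORS, MetaDataset

log = logging.getLogger(__name__)

DEFAULT_W = 0.5
DEFAULT_TOP_N = 10


@dataclass
class QuerySettings:
    """A user query: polymer, collector, and the six process parameters."""

    polymer: str
    concentration: float
    needle_gauge: float
    rotation_speed: float
    voltage: float
    flow_rate: float
    distance: float
    collector_type: str = ""

    def validate(self) -> None:
        for name in PREDICTORS:
            value = getattr(self, name)
            if value is None or not np.isfinite(float(value)):
                raise ValueError(f"query parameter {name!r} must be a finite number")
        if not str(self.polymer).strip():
            raise ValueError("query must name a polymer")

    def as_series(self) -> pd.Series:
        return pd.Series({name: float(getattr(self, name)) for name in PREDICTORS})

    def as_frame(self) -> pd.DataFrame:
        return self.as_series().to_frame().T


@dataclass
class RangeCheck:
    """Per-parameter in/out flags with the polymer's observed extremes."""

    table: pd.DataFrame  # columns: parameter, value, min, max, in_range

    @property
    def all_in_range(self) -> bool:
        return bool(self.table["in_range"].all())

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table.loc[~self.table["in_range"]]


def range_check(q: QuerySettings, ds: MetaDataset) -> RangeCheck:
    """Inclusive-bounds check of each query parameter for the polymer subset."""
    if len(ds) == 0:
        raise ValueError("empty polymer subset")
    q.validate()
    rows = []
    for name in PREDICTORS:
        observed = ds.df[name].to_numpy(dtype=float)
        lo, hi = float(observed.min()), float(observed.max())
        value = float(getattr(q, name))
        rows.append(
            {"parameter": name, "value": value, "min": lo, "max": hi,
             "in_range": bool(lo <= value <= hi)}
        )
    return RangeCheck(table=pd.DataFrame(rows))


@dataclass
class Recommendation:
    """A scored solvent triplet with median ratios and supporting candidates."""

    triplet: tuple  # (solvent1, solvent2, solvent3); empty slots are None
    median_ratios: dict  # solvent slot -> median percentage among supporters
    support: int  # top candidates sharing the triplet
    candidate_table: pd.DataFrame
    w: float = DEFAULT_W
    message: str = ""


def _min_max(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def recommend_solvents(
    q: QuerySettings,
    y_hat: float,
    ds: MetaDataset,
    w: float = DEFAULT_W,
    N: int = DEFAULT_TOP_N,
) -> Recommendation:
    """Recommend a historical solvent system for the queried settings.

    score(r) = w * d_param(r) + (1 - w) * d_diam(r), lower is better, where
    d_param is the sd-scaled Euclidean distance to the query in the
    six-parameter space and d_diam the sd-scaled distance of the record's
    diameter to the prediction; both are min-max normalised over the
    candidate subset.  Ties are broken by d_param then by row order.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    q.validate()
    df = ds.df
    labels = df["solvent1"].astype(str).str.strip().str.lower()
    has_solvent = ~labels.isin(["", "nan", "none"])
    cand = df.loc[has_solvent]
    if cand.empty:
        return Recommendation(
            triplet=(None, None, None), median_ratios={}, support=0,
            candidate_table=pd.DataFrame(), w=w,
            message="no recommendation available: subset has no solvent data",
        )
    if q.collector_type:
        match = cand["collector_type"].astype(str).str.strip().str.lower() == \
            str(q.collector_type).strip().lower()
        if match.sum() >= 5:
            cand = cand.loc[match]
        else:
            log.warning(
                "fewer than 5 records match collector %r; ignoring collector filter",
                q.collector_type,
            )
    X = cand[PREDICTORS].to_numpy(dtype=float)
    qvec = q.as_series().to_numpy(dtype=float)
    sds = np.std(X, axis=0, ddof=1) if len(cand) > 1 else np.zeros(len(PREDICTORS))
    keep_axes = sds > 0
    if keep_axes.any():
        d_param = np.sqrt(
            (((X[:, keep_axes] - qvec[keep_axes]) / sds[keep_axes]) ** 2).sum(axis=1)
        )
    else:
        d_param = np.zeros(len(cand))
    diam = cand[OUTCOME].to_numpy(dtype=float)
    diam_sd = float(np.std(diam, ddof=1)) if len(cand) > 1 else 0.0
    d_diam = np.abs(diam - float(y_hat)) / diam_sd if diam_sd > 0 else np.zeros(len(cand))
    dp_norm = _min_max(d_param)
    dd_norm = _min_max(d_diam)
    score = w * dp_norm + (1.0 - w) * dd_norm
    table = cand.copy()
    table["d_param"] = d_param
    table["d_diam"] = d_diam
    table["score"] = score
    table["_row"] = np.arange(len(table))
    top = table.sort_values(["score", "d_param", "_row"], kind="stable").head(N)

    def _slot(value) -> str | None:
        text = str(value).strip()
        return text if text and text.lower() not in ("nan", "none") else None

    triplets = [
        (_slot(r.solvent1), _slot(r.solvent2), _slot(r.solvent3))
        for r in top.itertuples()
    ]
    counts: dict[tuple, int] = {}
    for t in triplets:
        counts[t] = counts.get(t, 0) + 1
    modal = max(counts, key=lambda t: (counts[t], -triplets.index(t)))
    supporters = top.loc[[t == modal for t in triplets]]
    ratios = {}
    for i, slot in enumerate(("solvent1_ratio", "solvent2_ratio", "solvent3_ratio")):
        if modal[i] is not None:
            vals = supporters[slot].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                ratios[modal[i]] = float(np.median(vals))
    return Recommendation(
        triplet=modal,
        median_ratios=ratios,
        support=int(len(supporters)),
        candidate_table=top.drop(columns="_row").reset_index(drop=True),
        w=w,
        message="",
    )
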