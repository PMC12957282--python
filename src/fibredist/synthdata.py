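"""Seeded generator of synthetic electrospinning meta-datasets.

The generator emulates the structural features of literature-derived
meta-databases: study-clustered near-replicate conditions (each study explores a handful
of distinct experimental conditions and measures many near-replicate
diameters around each), a nonlinear,
concentration-dominant diameter response, study-level random effects,
heteroscedastic noise, optionally bimodal diameter spectra (as seen in
healthy ligament collagen), per-study solvent systems, and optional
missingness.  Every dataset ships with its ground truth so calibration and
parameter-recovery claims are testable.

Default response (diameter in nm):

    f = a * max(0, conc - knee)^pow + b / gauge + c * voltage
        + d * conc * flow - e * sqrt(rpm) + intercept

The hinge-power concentration term emulates the entanglement transition:
below the knee concentration the jet forms beads/thin fibres of roughly
constant diameter, above it diameter grows steeply with chain
entanglement.  Coefficients are chosen so solution concentration explains
the largest variance share, mirroring the known parameter hierarchy in
electrospinning.  Studies draw their experimental conditions from a shared
pool of popular operating points (as literature compilations do), so local
learners can exploit near-duplicate conditions across studies.  A purely
linear response is available for exact-recovery pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MODELLING_FIELDS, PREDICTORS, MetaDataset, clean_dataframe

DEFAULT_RANGES = {
    "concentration": (5.0, 20.0),      # % w/v
    "needle_gauge": (18.0, 27.0),      # G
    "rotation_speed": (0.0, 3000.0),   # rpm (drum collectors)
    "voltage": (10.0, 30.0),           # kV
    "flow_rate": (0.2, 3.0),           # mL/h
    "distance": (5.0, 25.0),           # cm
}

DEFAULT_NONLINEAR_COEFFS = {
    "conc_coef": 2.5,
    "conc_knee": 11.0,
    "conc_pow": 2.5,
    "gauge_inv": 1200.0,
    "voltage": 1.2,
    "conc_flow": 0.8,
    "rpm_sqrt": 0.5,
    "intercept": 120.0,
}

DEFAULT_LINEAR_COEFFS = {
    "concentration": 20.0,
    "needle_gauge": -5.0,
    "rotation_speed": -0.01,
    "voltage": 2.0,
    "flow_rate": 10.0,
    "distance": -1.5,
    "intercept": 150.0,
}

DEFAULT_SOLVENT_POOL = [
    (("water", None, None), (100.0, None, None)),
    (("water", "ethanol", None), (70.0, 30.0, None)),
    (("dmf", None, None), (100.0, None, None)),
    (("dmf", "acetone", None), (60.0, 40.0, None)),
    (("chloroform", "methanol", None), (75.0, 25.0, None)),
    (("acetic acid", "water", None), (80.0, 20.0, None)),
]


@dataclass
class BimodalSpec:
    """Two-component diameter mixture replacing the deterministic response."""

    means: tuple[float, float] = (150.0, 400.0)
    weights: tuple[float, float] = (0.5, 0.5)
    sd: float = 20.0


@dataclass
class GeneratorConfig:
    """Stated world for the synthetic meta-dataset generator."""

    n_studies: int = 30
    rows_per_study: tuple[int, int] = (30, 70)
    conditions_per_study: tuple[int, int] = (3, 8)
    condition_pool_size: int = 40
    study_offset: float = 0.02  # study-specific shift, fraction of each range
    polymers: tuple[str, ...] = ("PVA",)
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    response: str = "nonlinear"  # or "linear"
    coeffs: dict | None = None
    study_effect_sd: float = 15.0  # nm
    noise_sd: float = 20.0  # nm
    noise: str = "normal"  # or "lognormal" for right-skew
    heteroscedastic: bool = False  # noise sd proportional to the true mean
    bimodal: BimodalSpec | None = None
    solvent_pool: list = field(default_factory=lambda: list(DEFAULT_SOLVENT_POOL))
    static_collector_prob: float = 0.3
    within_study_jitter: float = 0.01  # replicate jitter, fraction of each range
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("invalid config field n_studies: must be >= 1")
        lo, hi = self.rows_per_study
        if not (1 <= lo <= hi):
            raise ValueError("invalid config field rows_per_study: need 1 <= lo <= hi")
        clo, chi = self.conditions_per_study
        if not (1 <= clo <= chi):
            raise ValueError("invalid config field conditions_per_study: need 1 <= lo <= hi")
        if self.condition_pool_size < chi:
            raise ValueError(
                "invalid config field condition_pool_size: must cover conditions_per_study"
            )
        for name in PREDICTORS:
            if name not in self.ranges:
                raise ValueError(f"invalid config field ranges: missing {name!r}")
            a, b = self.ranges[name]
            if not a < b:
                raise ValueError(f"invalid config field ranges[{name!r}]: degenerate range")
        if self.response not in ("nonlinear", "linear"):
            raise ValueError("invalid config field response: must be 'nonlinear' or 'linear'")
        if self.study_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("invalid config field study_effect_sd/noise_sd: must be >= 0")
        if self.bimodal is not None:
            if abs(sum(self.bimodal.weights) - 1.0) > 1e-9:
                raise ValueError("invalid config field bimodal.weights: must sum to 1")
            if self.bimodal.sd < 0:
                raise ValueError("invalid config field bimodal.sd: must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("invalid config field missing_rate: must be in [0, 1)")

    def response_function(self):
        """The deterministic mean response f(params) -> nm."""
        if self.response == "linear":
            c = dict(DEFAULT_LINEAR_COEFFS, **(self.coeffs or {}))

            def f(params: dict) -> float:
                return float(
                    sum(c[name] * float(params[name]) for name in PREDICTORS)
                    + c["intercept"]
                )
        else:
            c = dict(DEFAULT_NONLINEAR_COEFFS, **(self.coeffs or {}))

            def f(params: dict) -> float:
                conc = float(params["concentration"])
                return float(
                    c["conc_coef"] * max(0.0, conc - c["conc_knee"]) ** c["conc_pow"]
                    + c["gauge_inv"] / float(params["needle_gauge"])
                    + c["voltage"] * float(params["voltage"])
                    + c["conc_flow"] * conc * float(params["flow_rate"])
                    - c["rpm_sqrt"] * np.sqrt(max(0.0, float(params["rotation_speed"])))
                    + c["intercept"]
                )
        return f


@dataclass
class GroundTruth:
    """Everything the generator knows: response, effects and noise draws."""

    config: GeneratorConfig
    study_effects: dict  # study_id -> effect (nm)
    mu: np.ndarray  # deterministic mean per raw row
    noise: np.ndarray  # noise draw per raw row
    retained_index: np.ndarray  # raw-row indices surviving cleaning

    def f(self, params: dict) -> float:
        return self.config.response_function()(params)


def _noise_sd_for(config: GeneratorConfig, mu: np.ndarray) -> np.ndarray:
    if config.heteroscedastic:
        scale = np.maximum(mu, 1.0) / max(1.0, float(np.mean(np.abs(mu))))
        return config.noise_sd * scale
    return np.full_like(mu, config.noise_sd, dtype=float)


def generate(config: GeneratorConfig) -> tuple[MetaDataset, GroundTruth]:
    """Generate a synthetic meta-dataset and its ground truth.

    Reproducible: the same config (including seed) yields bit-identical
    output.  The returned MetaDataset has already passed the standard
    cleaning policy; with no missingness injected, no rows are dropped.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    f = config.response_function()
    records = []
    study_effects: dict[str, float] = {}
    mu_all, noise_all = [], []
    # literature compilations revisit popular operating points: studies pick
    # their conditions from a dataset-level pool, with small study offsets
    pool = [
        {name: rng.uniform(*config.ranges[name]) for name in PREDICTORS}
        for _ in range(config.condition_pool_size)
    ]
    for s in range(config.n_studies):
        study_id = f"10.9999/synth.{s:04d}"
        polymer = str(rng.choice(list(config.polymers)))
        is_static = rng.random() < config.static_collector_prob
        collector = "static plate" if is_static else "rotating drum"
        effect = rng.normal(0.0, config.study_effect_sd) if config.study_effect_sd else 0.0
        study_effects[study_id] = float(effect)
        triplet, ratios = config.solvent_pool[int(rng.integers(len(config.solvent_pool)))]
        n_rows = int(rng.integers(config.rows_per_study[0], config.rows_per_study[1] + 1))
        n_cond = int(rng.integers(config.conditions_per_study[0],
                                  config.conditions_per_study[1] + 1))
        # a study explores a handful of pool conditions, each shifted by a
        # small study-specific offset, with near-replicate rows around each
        chosen = rng.choice(len(pool), size=n_cond, replace=False)
        centroids = []
        for idx in chosen:
            centroid = {}
            for name in PREDICTORS:
                lo, hi = config.ranges[name]
                offset = rng.uniform(-1.0, 1.0) * config.study_offset * (hi - lo)
                centroid[name] = float(np.clip(pool[idx][name] + offset, lo, hi))
            centroids.append(centroid)
        for row_idx in range(n_rows):
            centroid = centroids[row_idx % n_cond]
            params = {}
            for name in PREDICTORS:
                lo, hi = config.ranges[name]
                jitter = rng.uniform(-1.0, 1.0) * config.within_study_jitter * (hi - lo)
                params[name] = float(np.clip(centroid[name] + jitter, lo, hi))
            if is_static:
                params["rotation_speed"] = 0.0
            if config.bimodal is not None:
                comp = int(rng.random() >= config.bimodal.weights[0])
                mu = float(config.bimodal.means[comp])
            else:
                mu = f(params)
            sd = _noise_sd_for(config, np.asarray([mu]))[0]
            if config.bimodal is not None:
                sd = config.bimodal.sd
            if config.noise == "lognormal" and sd > 0:
                # right-skewed noise with mean ~0 and sd ~sd
                sigma2 = np.log1p((sd / max(mu, 1.0)) ** 2)
                eps = mu * (rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)) - 1.0)
            elif sd > 0:
                eps = rng.normal(0.0, sd)
            else:
                eps = 0.0
            diameter = max(mu + effect + eps, 1.0)
            mu_all.append(mu)
            noise_all.append(eps)
            records.append(
                {
                    "study_id": study_id,
                    "polymer": polymer,
                    "solvent1": triplet[0],
                    "solvent2": triplet[1],
                    "solvent3": triplet[2],
                    "solvent1_ratio": ratios[0],
                    "solvent2_ratio": ratios[1],
                    "solvent3_ratio": ratios[2],
                    "collector_type": collector,
                    "temperature": 25.0,
                    "humidity": 45.0,
                    "diameter": diameter,
                    **params,
                }
            )
    df = pd.DataFrame.from_records(records)
    if config.missing_rate > 0:
        mask = rng.random((len(df), len(MODELLING_FIELDS))) < config.missing_rate
        for j, fieldname in enumerate(MODELLING_FIELDS):
            df.loc[mask[:, j], fieldname] = np.nan
    df["_raw_row"] = np.arange(len(df))
    ds = clean_dataframe(df.drop(columns="_raw_row"), source=f"synthetic(seed={config.seed})")
    # recompute retained raw-row indices with the same keep rule
    keep = np.ones(len(df), dtype=bool)
    for fieldname in PREDICTORS:
        keep &= np.isfinite(pd.to_numeric(df[fieldname]).to_numpy())
    diam = pd.to_numeric(df["diameter"]).to_numpy()
    keep &= np.isfinite(diam) & (diam > 0)
    gt = GroundTruth(
        config=config,
        study_effects=study_effects,
        mu=np.asarray(mu_all),
        noise=np.asarray(noise_all),
        retained_index=np.flatnonzero(keep),
    )
    return ds, gt


@dataclass
class TruthSummary:
    """True conditional diameter distribution at a query point."""

    mean: float  # deterministic response f(q), nm
    noise_sd: float  # within-study noise sd at q, nm
    study_effect_sd: float  # between-study sd, nm

    @property
    def total_sd(self) -> float:
        return float(np.hypot(self.noise_sd, self.study_effect_sd))


def truth_conditional(gt: GroundTruth, q) -> TruthSummary:
    """True mean and noise scale at query ``q`` (dict or QuerySettings)."""
    params = {name: float(getattr(q, name, None) if hasattr(q, name) else q[name])
              for name in PREDICTORS}
    for name, value in params.items():
        lo, hi = gt.config.ranges[name]
        if not lo <= value <= hi:
            raise ValueError(f"query {name}={value} outside generator range [{lo}, {hi}]")
    mu = gt.f(params)
    sd = float(_noise_sd_for(gt.config, np.asarray([mu]))[0])
    return TruthSummary(mean=mu, noise_sd=sd, study_effect_sd=gt.config.study_effect_sd)


def sample_at(gt: GroundTruth, q, n: int, seed: int = 0) -> np.ndarray:
    """Fresh draws from the generator's conditional distribution at ``q``.

    Each draw takes a new study effect and a new noise term, i.e. it
    answers "what would a brand-new study measure at these settings".
    """
    truth = truth_conditional(gt, q)
    rng = np.random.default_rng(seed)
    effects = rng.normal(0.0, truth.study_effect_sd, size=n) if truth.study_effect_sd else 0.0
    eps = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd else 0.0
    return truth.mean + effects + eps
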