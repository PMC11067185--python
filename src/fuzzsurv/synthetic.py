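"""Synthetic clinicopathologic cohorts.

The study cohort itself is private, so this module generates stand-in data
with the same tabular structure: 15 categorical predictors whose marginal
level frequencies default to the published 581-patient cohort table, and a
planted, tunable dependence of survival time on the prognostic variables
(TNM stage, locoregional recurrence, distant metastasis, extranodal
extension, margin status).

Dependence model. Each record gets a latent risk score r — the sum of
per-level log-odds contributions of the prognostic variables, centered so
the cohort mean is zero — and a constant monthly death hazard
h = logistic(a + b * signal_strength * r). Survival months are the first
failure of a geometric clock, truncated at 120 months, so high-risk patients
concentrate in the early classes and low-risk patients in the terminal
class, reproducing the bimodal class profile of the real table. At
``signal_strength = 0`` the hazard is constant and survival class is
independent of every predictor.

Internal consistency: a record has positive lymph-node metastasis exactly
when its pN stage is not N0 (the published counts agree: 298 N0 = 298
negative). TNM stage is tied to the drawn T and pN stages through an
AJCC-7-style lookup whose output is mapped onto the published TNM marginal
by ordinal quantile coupling, keeping stage monotone in (T, pN) severity
while leaving the TNM level frequencies exact in expectation. (A hard
deterministic lookup cannot reproduce the published table: it prints 9
stage-IVb patients but only 3 T4b + 5 N3.)

``exact_fixture`` instead reproduces the published table count-for-count:
each variable's level column is an exact multiset, independently shuffled;
the joint distribution across variables is NOT claimed to match the real
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import Dataset, bin_survival_times
from .schema import (
    N_CLASSES,
    SURVIVAL_CLASS,
    SURVIVAL_MONTHS,
    CohortSchema,
    default_schema,
    table1_counts,
)

MONTHS_CAP = 120
#: inclusive month intervals per survival class (terminal class capped at 120)
CLASS_INTERVALS = ((0, 12), (13, 24), (25, 36), (37, 48), (49, 60), (61, MONTHS_CAP))

DEFAULT_RISK_MODEL: dict[str, dict[str, float]] = {
    "tnm_stage": {"I": -1.0, "II": -0.5, "III": 0.0, "IVa": 1.0, "IVb": 1.5},
    "locoregional_recurrence": {"local": 1.0, "none": 0.0},
    "distant_metastasis": {"lung": 1.5, "bone": 1.5, "none": 0.0},
    "extranodal_extension": {"positive": 0.8, "negative": 0.0},
    "margin": {"positive": 0.8, "close": 0.3, "clear": 0.0},
}

#: baseline monthly death hazard (log-odds): logistic(-4.41) ~ 0.012, i.e. a
#: median survival near five years for an average-risk patient
DEFAULT_BASE_LOG_HAZARD = -4.41
DEFAULT_RISK_SLOPE = 1.0

_TNM_ORDER = ("I", "II", "III", "IVa", "IVb")


def _table1_marginals() -> dict[str, dict[str, float]]:
    t1 = table1_counts()
    n = t1["n"]
    return {
        var: {lev: c / n for lev, c in levels.items()}
        for var, levels in t1["counts"].items()
        if var != SURVIVAL_CLASS
    }


@dataclass
class SyntheticCohortConfig:
    """Generator settings; defaults emulate the published cohort table."""

    n: int = 581
    marginals: dict[str, dict[str, float]] = field(default_factory=_table1_marginals)
    risk_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {v: dict(d) for v, d in DEFAULT_RISK_MODEL.items()}
    )
    base_log_hazard: float = DEFAULT_BASE_LOG_HAZARD
    risk_slope: float = DEFAULT_RISK_SLOPE
    signal_strength: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        for var, probs in self.marginals.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"marginals for {var!r} sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability in marginals for {var!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        kwargs = {k: d[k] for k in (
            "n", "marginals", "risk_model", "base_log_hazard", "risk_slope",
            "signal_strength", "missing_rate", "seed") if k in d}
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "marginals": self.marginals, "risk_model": self.risk_model,
            "base_log_hazard": self.base_log_hazard, "risk_slope": self.risk_slope,
            "signal_strength": self.signal_strength,
            "missing_rate": self.missing_rate, "seed": self.seed,
        }


def _ajcc7_stage_index(t: np.ndarray, n: np.ndarray) -> np.ndarray:
    """AJCC-7-style oral cavity stage group (0..4 = I..IVb) from T and pN."""
    stage = np.zeros(len(t), dtype=int)
    stage[(t == "T2") & (n == "N0")] = 1
    stage[(t == "T3") & (n == "N0")] = 2
    stage[(n == "N1") & np.isin(t, ("T1", "T2", "T3"))] = 2
    stage[np.isin(n, ("N2a", "N2b", "N2c"))] = 3
    stage[t == "T4a"] = 3
    stage[(t == "T4b") | (n == "N3")] = 4
    return stage


def _lookup_stage_pmf(marginals: dict[str, dict[str, float]]) -> np.ndarray:
    """Distribution of the lookup stage under independent T and pN draws."""
    pmf = np.zeros(len(_TNM_ORDER))
    for t, pt in marginals["t_stage"].items():
        for n, pn in marginals["pn_stage"].items():
            s = _ajcc7_stage_index(np.array([t]), np.array([n]))[0]
            pmf[s] += pt * pn
    return pmf


def _draw_categorical(rng: np.random.Generator, levels: list[str],
                      probs: list[float], n: int) -> np.ndarray:
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=np.asarray(probs))


def _expected_risk(config: SyntheticCohortConfig) -> float:
    r = 0.0
    for var, contrib in config.risk_model.items():
        probs = config.marginals[var]
        r += sum(probs.get(lev, 0.0) * c for lev, c in contrib.items())
    return r


def generate_cohort(config: SyntheticCohortConfig,
                    schema: CohortSchema | None = None) -> Dataset:
    """Draw a cohort of ``config.n`` records; identical for a fixed seed."""
    schema = schema or default_schema()
    rng = np.random.default_rng(config.seed)
    n = config.n
    cols: dict[str, np.ndarray] = {}

    for var in schema.variables:
        if var.name in ("ln_metastasis", "tnm_stage"):
            continue  # derived below
        probs = config.marginals[var.name]
        levels = list(var.levels)
        cols[var.name] = _draw_categorical(
            rng, levels, [probs[lev] for lev in levels], n
        )

    # consistency: positive lymph-node metastasis <=> pN stage above N0
    cols["ln_metastasis"] = np.where(
        cols["pn_stage"] == "N0", "negative", "positive"
    ).astype(object)

    # TNM stage: AJCC lookup from (T, pN), quantile-coupled onto the target
    # marginal so level frequencies stay exact in expectation
    lookup_pmf = _lookup_stage_pmf(config.marginals)
    lookup_cdf = np.concatenate([[0.0], np.cumsum(lookup_pmf)])
    stage = _ajcc7_stage_index(cols["t_stage"], cols["pn_stage"])
    u = lookup_cdf[stage] + rng.random(n) * lookup_pmf[stage]
    target_probs = np.array([config.marginals["tnm_stage"][s] for s in _TNM_ORDER])
    target_cdf = np.cumsum(target_probs)
    tnm_idx = np.minimum(np.searchsorted(target_cdf, u, side="right"),
                         len(_TNM_ORDER) - 1)
    cols["tnm_stage"] = np.asarray(_TNM_ORDER, dtype=object)[tnm_idx]

    # latent risk -> constant monthly hazard -> geometric survival months
    risk = np.zeros(n)
    for var, contrib in config.risk_model.items():
        lut = np.zeros(len(schema.levels(var)))
        for j, lev in enumerate(schema.levels(var)):
            lut[j] = contrib.get(lev, 0.0)
        level_index = np.array(
            [schema.levels(var).index(v) for v in cols[var]], dtype=int
        )
        risk += lut[level_index]
    risk -= _expected_risk(config)
    eta = config.base_log_hazard + config.risk_slope * config.signal_strength * risk
    hazard = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-9, 1.0 - 1e-9)
    months = np.minimum(rng.geometric(hazard), MONTHS_CAP)

    df = pd.DataFrame({v.name: pd.Series(cols[v.name], dtype=object)
                       for v in schema.variables})
    if config.missing_rate > 0:
        mask = rng.random((n, len(schema.variables))) < config.missing_rate
        for j, var in enumerate(schema.variables):
            col = df[var.name].to_numpy(dtype=object)
            col[mask[:, j]] = pd.NA
            df[var.name] = col
    df[SURVIVAL_MONTHS] = pd.array(months, dtype="Int64")
    df[SURVIVAL_CLASS] = pd.array(bin_survival_times(months), dtype="Int64")
    return Dataset(df=df, schema=schema, provenance="synthetic")


# ---------------------------------------------------------------------------
# exact fixture

def exact_fixture(counts: dict | None = None, seed: int = 0,
                  schema: CohortSchema | None = None) -> Dataset:
    """A cohort whose per-variable level counts equal the published table
    exactly (581 records by default).

    Columns are exact multisets shuffled independently, except that negative
    lymph-node metastasis is assigned to exactly the N0 records. Survival
    months are uniform within each record's class interval. Joint structure
    across variables is synthetic and not claimed.
    """
    schema = schema or default_schema()
    t1 = counts or table1_counts()
    n = int(t1["n"])
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}

    for var in schema.variables:
        if var.name == "ln_metastasis":
            continue
        level_counts = t1["counts"][var.name]
        total = sum(level_counts.values())
        if total != n:
            raise ValueError(f"{var.name!r} counts sum to {total}, expected {n}")
        col = np.repeat(
            np.asarray(list(level_counts.keys()), dtype=object),
            list(level_counts.values()),
        )
        rng.shuffle(col)
        cols[var.name] = col
    cols["ln_metastasis"] = np.where(
        cols["pn_stage"] == "N0", "negative", "positive"
    ).astype(object)

    cls_counts = t1["counts"][SURVIVAL_CLASS]
    if sum(cls_counts.values()) != n:
        raise ValueError("survival_class counts do not sum to n")
    classes = np.repeat(
        np.asarray([int(k) for k in cls_counts.keys()]),
        list(cls_counts.values()),
    )
    rng.shuffle(classes)
    lo = np.asarray([CLASS_INTERVALS[k][0] for k in classes])
    hi = np.asarray([CLASS_INTERVALS[k][1] for k in classes])
    months = rng.integers(lo, hi + 1)

    df = pd.DataFrame({v.name: pd.Series(cols[v.name], dtype=object)
                       for v in schema.variables})
    df[SURVIVAL_MONTHS] = pd.array(months, dtype="Int64")
    df[SURVIVAL_CLASS] = pd.array(classes, dtype="Int64")
    return Dataset(df=df, schema=schema, provenance="exact_fixture")
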