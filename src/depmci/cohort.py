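"""Synthetic longitudinal aging-cohort generator.

Emulates a CHARLS-style multi-wave panel of adults aged 60+ in which a latent
depressive-severity process drives both the 10-item CES-D responses and an
accelerated decline of a latent cognition process.  The planted temporal
effect — next-wave cognitive decline increases with the current positive
change in depressive severity — gives every downstream stage (scoring,
labeling, screening, windowing, modelling) a test signal without any data
download.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per participant per wave (see :data:`SCHEMA_COLUMNS`); :func:`write_cohort`
and :func:`read_cohort` round-trip it through a plain CSV dialect (UTF-8,
one header row, empty string = missing).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SchemaError",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "aux_columns",
    "SCHEMA_COLUMNS",
    "CESD_COLUMNS",
    "COG_COLUMNS",
    "COG_RANGES",
    "SEX_LEVELS",
    "EDUCATION_LEVELS",
    "RESIDENCE_LEVELS",
    "MARITAL_LEVELS",
]

CESD_COLUMNS = [f"cesd_{i}" for i in range(1, 11)]
COG_COLUMNS = ["imm_recall", "del_recall", "orientation", "calculation", "pentagon"]
COG_RANGES = {
    "imm_recall": (0, 10),
    "del_recall": (0, 10),
    "orientation": (0, 5),
    "calculation": (0, 5),
    "pentagon": (0, 1),
}

SEX_LEVELS = ["male", "female"]
EDUCATION_LEVELS = [
    "primary_or_below",
    "middle_school",
    "high_or_technical",
    "college_or_above",
]
RESIDENCE_LEVELS = ["rural", "urban"]
MARITAL_LEVELS = ["married", "unmarried", "divorced", "widowed"]

_KEY_COLUMNS = ["participant_id", "wave"]
_DEMO_COLUMNS = ["age", "sex", "education", "residence", "marital"]
#: Fixed column order of the cohort table (aux columns appended at the end).
SCHEMA_COLUMNS = _KEY_COLUMNS + _DEMO_COLUMNS + CESD_COLUMNS + COG_COLUMNS

_CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS,
    "education": EDUCATION_LEVELS,
    "residence": RESIDENCE_LEVELS,
    "marital": MARITAL_LEVELS,
}


class SchemaError(ValueError):
    """A cohort table violates the wave-record schema."""


@dataclass
class CohortConfig:
    """Configuration of the synthetic panel.

    ``effect_size`` is the planted temporal effect: extra latent-cognition
    decline (in cognition points) per unit of positive depressive-severity
    change between consecutive waves.  ``effect_size=0`` plants no signal.
    Demographic marginals default to the composition of a large rural-majority
    Chinese aging cohort.
    """

    n_participants: int = 2000
    n_waves: int = 4
    seed: int = 0
    depressed_fraction: float = 0.5
    effect_size: float = 6.0
    missing_rate: float = 0.10
    n_aux_features: int = 5
    dropout_per_wave: float = 0.0
    wave_gap_years: int = 2
    sex_probs: tuple = (0.52, 0.48)
    education_probs: tuple = (0.83, 0.11, 0.04, 0.02)
    residence_probs: tuple = (0.65, 0.35)
    marital_probs: tuple = (0.81, 0.01, 0.015, 0.165)
    # latent-process parameters
    severity_rho: float = 0.7
    severity_noise_sd: float = 0.5
    severity_group_sep: float = 1.2
    severity_baseline_sd: float = 0.6
    cognition_baseline_mean: float = 25.0
    cognition_baseline_sd: float = 1.0
    cognition_age_slope: float = -0.12
    base_decline: float = 0.4
    cognition_noise_sd: float = 0.5

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_waves < 2:
            raise ValueError("n_waves must be at least 2")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if not 0.0 < self.depressed_fraction < 1.0:
            raise ValueError("depressed_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_aux_features < 0:
            raise ValueError("n_aux_features must be non-negative")
        if not 0.0 <= self.dropout_per_wave < 1.0:
            raise ValueError("dropout_per_wave must lie in [0, 1)")
        for name in ("sex_probs", "education_probs", "residence_probs", "marital_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError(f"{name} must be non-negative and sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


def aux_columns(n_aux: int) -> list[str]:
    return [f"aux_{i}" for i in range(1, n_aux + 1)]


# CES-D item emission: 30 graded thresholds spread over the severity axis.
# The calibration offset centres the instrument so that P(total >= 10) = 0.5
# exactly at severity 0, making observed depression status agree with the
# latent group assignment apart from symmetric near-cutoff noise.
_THRESH_LO, _THRESH_HI = -2.0, 4.0
_ITEM_NOISE_SCALE = 0.15
_CUTOFF_OFFSET = 0.138


def _cesd_thresholds() -> np.ndarray:
    """(10, 3) matrix of item thresholds; each item gets one low/mid/high cut."""
    grid = np.linspace(_THRESH_LO, _THRESH_HI, 30) + _CUTOFF_OFFSET
    # interleave so all ten items have comparable difficulty spreads
    return grid.reshape(3, 10).T


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a seeded panel; identical config+seed gives an identical table.

    Latent model per participant i with group mean mu_i (+/- group separation):

        severity_t - mu_i = rho * (severity_{t-1} - mu_i) + noise
        cognition_t = cognition_{t-1} - base_decline
                      - effect_size * max(0, severity_t - severity_{t-1}) + noise

    CES-D items are graded-threshold emissions of severity with logistic item
    noise; cognitive subtasks are linear reads of cognition, rounded and
    clipped to their ranges.  Auxiliary features are MCAR-missing at
    ``missing_rate``; scale items are always complete.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, waves = config.n_participants, config.n_waves

    depressed = rng.random(n) < config.depressed_fraction
    mu = np.where(depressed, config.severity_group_sep, -config.severity_group_sep)

    sev = np.empty((n, waves))
    sev[:, 0] = mu + rng.normal(0.0, config.severity_baseline_sd, n)
    for t in range(1, waves):
        sev[:, t] = (
            mu
            + config.severity_rho * (sev[:, t - 1] - mu)
            + rng.normal(0.0, config.severity_noise_sd, n)
        )

    age1 = 60 + np.round(rng.gamma(1.5, 4.0, n)).astype(int)
    age1 = np.clip(age1, 60, 95)

    cog = np.empty((n, waves))
    cog[:, 0] = (
        config.cognition_baseline_mean
        + config.cognition_age_slope * (age1 - 60)
        + rng.normal(0.0, config.cognition_baseline_sd, n)
    )
    for t in range(1, waves):
        worsening = np.maximum(0.0, sev[:, t] - sev[:, t - 1])
        cog[:, t] = (
            cog[:, t - 1]
            - config.base_decline
            - config.effect_size * worsening
            + rng.normal(0.0, config.cognition_noise_sd, n)
        )

    sex = rng.choice(SEX_LEVELS, size=n, p=config.sex_probs)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=config.education_probs)
    residence = rng.choice(RESIDENCE_LEVELS, size=n, p=config.residence_probs)
    marital = rng.choice(MARITAL_LEVELS, size=n, p=config.marital_probs)

    thresholds = _cesd_thresholds()  # (10, 3)
    width = len(str(n))
    rows: list[dict] = []
    # per-wave retention mask for the optional attrition mechanism
    retained = np.ones(n, dtype=bool)
    for t in range(waves):
        if t > 0 and config.dropout_per_wave > 0:
            retained &= rng.random(n) >= config.dropout_per_wave
        # graded-threshold CES-D emission with logistic item noise
        noise = rng.logistic(0.0, _ITEM_NOISE_SCALE, size=(n, 10, 3))
        items = (sev[:, t, None, None] + noise > thresholds[None, :, :]).sum(axis=2)
        frac = cog[:, t] / 31.0
        sub = {
            "imm_recall": np.clip(np.round(10 * frac + rng.normal(0, 0.35, n)), 0, 10),
            "del_recall": np.clip(np.round(10 * frac + rng.normal(0, 0.35, n)), 0, 10),
            "orientation": np.clip(np.round(5 * frac + rng.normal(0, 0.25, n)), 0, 5),
            "calculation": np.clip(np.round(5 * frac + rng.normal(0, 0.25, n)), 0, 5),
            "pentagon": np.clip(np.round(frac + rng.normal(0, 0.15, n)), 0, 1),
        }
        aux = rng.normal(0.0, 1.0, size=(n, config.n_aux_features))
        miss = rng.random(size=aux.shape) < config.missing_rate
        aux[miss] = np.nan
        for i in range(n):
            if not retained[i]:
                continue
            row = {
                "participant_id": f"P{i:0{width}d}",
                "wave": t + 1,
                "age": int(age1[i] + t * config.wave_gap_years),
                "sex": sex[i],
                "education": education[i],
                "residence": residence[i],
                "marital": marital[i],
            }
            row.update({c: int(items[i, j]) for j, c in enumerate(CESD_COLUMNS)})
            row.update({c: int(sub[c][i]) for c in COG_COLUMNS})
            row.update({c: aux[i, j] for j, c in enumerate(aux_columns(config.n_aux_features))})
            rows.append(row)

    cols = SCHEMA_COLUMNS + aux_columns(config.n_aux_features)
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["participant_id", "wave"], kind="stable").reset_index(drop=True)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming the offending row/column if invalid."""
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"malformed header: missing columns {missing_cols}")
    dup = df.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(f"duplicate (participant, wave) key at row {row}")
    ranges = {c: (0, 3) for c in CESD_COLUMNS}
    ranges.update(COG_RANGES)
    for col, (lo, hi) in ranges.items():
        vals = df[col].to_numpy()
        bad = (vals < lo) | (vals > hi) | (vals != np.floor(vals))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"value {vals[row]!r} out of range [{lo},{hi}] at row {row}, column {col!r}"
            )
    for col, levels in _CATEGORICAL_LEVELS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"unknown level at row {row}, column {col!r}")


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write CSV (UTF-8, one header row, empty string = missing)."""
    validate_cohort(df)
    df.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; inverse of :func:`write_cohort`."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "sex": str, "education": str,
               "residence": str, "marital": str},
        keep_default_na=False,
        na_values=[""],
        encoding="utf-8",
    )
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"malformed header: missing columns {missing_cols}")
    if len(df) == 0:
        # empty table with a valid header is a valid (empty) cohort
        for c in df.columns:
            if c in ("wave", "age") or c in CESD_COLUMNS or c in COG_COLUMNS:
                df[c] = df[c].astype(np.int64)
            elif c.startswith("aux_"):
                df[c] = df[c].astype(float)
        return df
    for c in ["wave", "age"] + CESD_COLUMNS + COG_COLUMNS:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SchemaError(f"non-numeric value at row {row}, column {c!r}")
        df[c] = vals
    validate_cohort(df)
    for c in ["wave", "age"] + CESD_COLUMNS + COG_COLUMNS:
        df[c] = df[c].astype(np.int64)
    for c in df.columns:
        if c.startswith("aux_"):
            df[c] = df[c].astype(float)
    return df
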