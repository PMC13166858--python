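"""Feature screening, imputation, window construction and splitting.

Four screening rules, applied to declared per-feature metadata: drop features
that are (1) outcome-derived, (2) inconsistently measured across waves,
(3) missing in more than 20% of cells pooled over waves, or (4) composite
indicators overlapping other retained variables.  Remaining missingness is
completed by a multiple-imputation mean strategy: several chained-equation
imputations are drawn and each missing cell receives their mean, keeping the
completion conservative.  Scored, labeled cohorts are then cut into sliding
(wave t -> wave t+1) windows — exposure features at both waves, next-wave MCI
as the binary label — restricted to participants depressed and MCI-free at
wave t.  Splitting is by participant (no person contributes windows to two
splits) and stratified on the participant's outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .cohort import CESD_COLUMNS, COG_COLUMNS, aux_columns

__all__ = [
    "FeatureMeta",
    "WindowSample",
    "MISSING_RATE_THRESHOLD",
    "default_declarations",
    "compute_feature_meta",
    "screen_features",
    "impute_mi_mean",
    "encode_features",
    "build_windows",
    "split_dataset",
    "Standardizer",
]

MISSING_RATE_THRESHOLD = 0.20


@dataclass(frozen=True)
class FeatureMeta:
    name: str
    missing_rate: float
    outcome_derived: bool = False
    inconsistent_across_waves: bool = False
    composite_overlapping: bool = False


@dataclass
class WindowSample:
    """One (wave t -> wave t+1) training unit."""

    participant_id: str
    window_index: int  # t, 1-based wave of the exposure
    features: np.ndarray  # (2, n_features): rows are waves t and t+1
    label: int  # MCI at wave t+1


def default_declarations(n_aux: int = 5) -> dict[str, dict]:
    """Screening flags for the standard synthetic-cohort schema.

    Cognitive subtasks and their totals define the outcome and are excluded
    as outcome-derived; the two scale totals overlap their item/subtask
    scores and are excluded as composites.
    """
    decl: dict[str, dict] = {}
    for c in ["age", "sex", "education", "residence", "marital"]:
        decl[c] = {}
    for c in CESD_COLUMNS:
        decl[c] = {}
    for c in COG_COLUMNS + ["cog_total", "mci"]:
        decl[c] = {"outcome_derived": True}
    decl["cesd_total"] = {"composite_overlapping": True}
    for c in aux_columns(n_aux):
        decl[c] = {}
    return decl


def compute_feature_meta(cohort: pd.DataFrame,
                         declarations: dict[str, dict]) -> list[FeatureMeta]:
    """Per-feature missing rate (cells pooled across all waves) plus flags."""
    metas = []
    for name, flags in declarations.items():
        if name not in cohort.columns:
            raise KeyError(f"declared feature {name!r} absent from cohort table")
        col = cohort[name]
        rate = float(col.isna().mean()) if len(col) else 0.0
        metas.append(
            FeatureMeta(
                name=name,
                missing_rate=rate,
                outcome_derived=bool(flags.get("outcome_derived", False)),
                inconsistent_across_waves=bool(flags.get("inconsistent_across_waves", False)),
                composite_overlapping=bool(flags.get("composite_overlapping", False)),
            )
        )
    return metas


def screen_features(meta: list[FeatureMeta]) -> list[str]:
    """Retain features passing all four rules, preserving input order.

    The missingness rule is strictly 'more than 20%': a rate of exactly 0.20
    is retained.
    """
    return [
        m.name
        for m in meta
        if not m.outcome_derived
        and not m.inconsistent_across_waves
        and m.missing_rate <= MISSING_RATE_THRESHOLD
        and not m.composite_overlapping
    ]


def impute_mi_mean(table: pd.DataFrame, m: int = 5, iters: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """Complete a numeric table by the mean over ``m`` chained-equation draws.

    Each draw runs iterative regression imputation with posterior sampling
    (a distinct stream derived from ``seed``); a missing cell's completion is
    the across-draw mean.  Observed cells are returned bit-exactly unchanged.
    """
    if not all(np.issubdtype(dt, np.number) for dt in table.dtypes):
        raise TypeError("impute_mi_mean requires an all-numeric table")
    all_missing = [c for c in table.columns if table[c].isna().all()]
    if all_missing:
        raise ValueError(f"columns entirely missing, cannot initialize: {all_missing}")
    if not table.isna().to_numpy().any():
        return table.copy()

    X = table.to_numpy(dtype=float)
    if X.shape[1] == 1:
        # no covariates to regress on: the chained model collapses to the mean
        col = X[:, 0]
        fill = np.nanmean(col)
        out = table.copy()
        out.iloc[np.isnan(col), 0] = fill
        return out

    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31 - 1)
    draws = []
    for s in seeds:
        imp = IterativeImputer(
            max_iter=iters,
            sample_posterior=True,
            random_state=int(s),
            keep_empty_features=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws.append(imp.fit_transform(X))
    completed = np.mean(draws, axis=0)
    mask = np.isnan(X)
    out_arr = X.copy()
    out_arr[mask] = completed[mask]
    out = pd.DataFrame(out_arr, index=table.index, columns=table.columns)
    # restore observed cells bit-exactly (and original dtypes where intact)
    for c in table.columns:
        obs = ~table[c].isna()
        out.loc[obs, c] = table.loc[obs, c].astype(float)
    return out


from .cohort import SEX_LEVELS, EDUCATION_LEVELS, RESIDENCE_LEVELS, MARITAL_LEVELS

_CATEGORICAL = {
    "sex": SEX_LEVELS,
    "education": EDUCATION_LEVELS,
    "residence": RESIDENCE_LEVELS,
    "marital": MARITAL_LEVELS,
}


def encode_features(cohort: pd.DataFrame, retained: list[str]):
    """One-hot encode categorical retained features; pass numerics through.

    Categorical columns use the canonical level sets (first level as the
    reference) so the encoded column set is identical across cohorts.
    Returns ``(numeric_df, feature_names)`` where ``numeric_df`` has one row
    per cohort row and ``feature_names`` fixes the model's feature order
    (the heatmap manifest).
    """
    pieces, names = [], []
    for name in retained:
        if name in _CATEGORICAL:
            col = cohort[name].astype(str)
            for lv in _CATEGORICAL[name][1:]:  # first level is the reference
                names.append(f"{name}={lv}")
                pieces.append((col == lv).astype(float).to_numpy())
        else:
            names.append(name)
            pieces.append(cohort[name].to_numpy(dtype=float))
    mat = np.column_stack(pieces) if pieces else np.empty((len(cohort), 0))
    return pd.DataFrame(mat, index=cohort.index, columns=names), names


def build_windows(cohort: pd.DataFrame, features: pd.DataFrame) -> list[WindowSample]:
    """Sliding (t -> t+1) samples from a scored, labeled cohort.

    Eligibility at wave t: the participant is depressed and not MCI at t, and
    has an observed cognition assessment (hence an MCI label) at wave t+1.
    ``features`` must be row-aligned with ``cohort`` (output of
    :func:`encode_features`, after imputation).
    """
    for col in ("depressed", "mci", "cog_total", "wave", "participant_id"):
        if col not in cohort.columns:
            raise KeyError(f"cohort not scored/labeled: missing {col!r}")
    samples: list[WindowSample] = []
    max_waves = 0
    for pid, grp in cohort.groupby("participant_id", sort=True):
        grp = grp.sort_values("wave")
        waves = {int(w): i for w, i in zip(grp["wave"], grp.index)}
        max_waves = max(max_waves, len(waves))
        for t in sorted(waves):
            if t + 1 not in waves:
                continue
            i_t, i_t1 = waves[t], waves[t + 1]
            if cohort.loc[i_t, "depressed"] != 1 or cohort.loc[i_t, "mci"] != 0:
                continue
            if pd.isna(cohort.loc[i_t1, "cog_total"]):
                continue
            seq = np.stack([
                features.loc[i_t].to_numpy(dtype=float),
                features.loc[i_t1].to_numpy(dtype=float),
            ])
            samples.append(
                WindowSample(
                    participant_id=str(pid),
                    window_index=t,
                    features=seq,
                    label=int(cohort.loc[i_t1, "mci"]),
                )
            )
    if not samples and max_waves < 2:
        warnings.warn("no participant has two consecutive waves; no windows built",
                      stacklevel=2)
    return samples


def split_dataset(samples: list[WindowSample], fractions=(0.7, 0.15, 0.15),
                  seed: int = 0):
    """Participant-disjoint, outcome-stratified train/validation/test split.

    Participants (not windows) are allocated to splits with largest-remainder
    rounding inside each stratum (any-positive-window vs none), so realized
    participant counts stay within one of the targets.
    """
    fractions = tuple(float(f) for f in fractions)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    by_pid: dict[str, list[WindowSample]] = {}
    for s in samples:
        by_pid.setdefault(s.participant_id, []).append(s)
    pos_pids = sorted(p for p, ws in by_pid.items() if any(w.label for w in ws))
    neg_pids = sorted(p for p, ws in by_pid.items() if not any(w.label for w in ws))

    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for pids in (pos_pids, neg_pids):
        pids = list(pids)
        rng.shuffle(pids)
        n = len(pids)
        exact = np.array(fractions) * n
        counts = np.floor(exact).astype(int)
        # largest remainder
        for k in np.argsort(-(exact - counts))[: n - counts.sum()]:
            counts[k] += 1
        start = 0
        for split_idx, c in enumerate(counts):
            for p in pids[start:start + c]:
                assignment[p] = split_idx
            start += c

    splits = ([], [], [])
    for p, ws in by_pid.items():
        splits[assignment[p]].extend(ws)
    for name, part in zip(("train", "validation", "test"), splits):
        labels = {w.label for w in part}
        if labels != {0, 1}:
            raise ValueError(
                f"{name} split lacks a class (labels present: {sorted(labels)}); "
                "use more participants or different fractions"
            )
    return splits


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on the training split (all waves pooled)."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sd: np.ndarray = field(default_factory=lambda: np.ones(0))

    @classmethod
    def fit(cls, samples: list[WindowSample]) -> "Standardizer":
        mat = np.concatenate([s.features for s in samples], axis=0)
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(mean=mat.mean(axis=0), sd=sd)

    def transform(self, samples: list[WindowSample]) -> list[WindowSample]:
        return [
            WindowSample(s.participant_id, s.window_index,
                         (s.features - self.mean) / self.sd, s.label)
            for s in samples
        ]
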