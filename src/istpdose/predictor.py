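"""Effective-half-life prediction from pretherapy features.

An organ's effective half-life is regressed on pretherapy data — patient
characteristics (age, weight), clinical labs (PSA, LDH, creatinine,
hemoglobin), per-organ PET SUV_mean including the urinary bladder, a
categorical organ-condition class, and the cycle index — with RBF-kernel
support vector regression.  One independent model is trained per organ.

Features are standardized to zero mean and unit variance with the scaler
fitted on training folds only; median imputation and a zero-variance column
guard sit in the same leakage-safe pipeline.  Hyperparameters (C, epsilon,
and the RBF gamma) are selected by inner cross-validation minimizing the
mean absolute percentage error, with ties broken toward stronger
regularization (smaller C, then larger epsilon).  Model validation is
k-fold (default k=10) with the per-fold mean percentage error and its
mean +/- SD across folds as the headline metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import VarianceThreshold
from sklearn.impute import SimpleImputer
from sklearn.model_selection import GroupKFold, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cohort import ORGAN_CONDITION_CLASSES
from .kinetics import ORGANS, PET_ORGANS

log = logging.getLogger(__name__)

KEY_COLUMNS = ["patient_id", "cycle"]
NUMERIC_FEATURES = [
    "age_y",
    "weight_kg",
    "psa_ng_ml",
    "ldh",
    "creatinine",
    "hemoglobin",
    *[f"suv_mean_{o}" for o in PET_ORGANS],
    "cycle",
]
OPTIONAL_FEATURES = ["injected_pet_activity_MBq"]
CATEGORICAL_FEATURE = "organ_condition_class"

#: Floor on predicted T_eff, hours; SVR output is clamped here.
MIN_TEFF_HOURS = 1.0


@dataclass(frozen=True)
class SvrConfig:
    """RBF-kernel SVR hyperparameters.

    ``gamma`` may be a float or the scale heuristic
    1 / (n_features * Var(X)) used by scikit-learn.
    """

    C: float = 10.0
    epsilon: float = 0.5
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def default_grid() -> list[SvrConfig]:
    """Small C/epsilon/gamma grid; epsilon in hours (target units)."""
    return [
        SvrConfig(C=c, epsilon=e, gamma=g)
        for c in (1.0, 10.0, 100.0)
        for e in (0.1, 0.5, 2.0)
        for g in ("scale", 0.01, 0.1)
    ]


def build_design(rows: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix (fixed column order) from a feature table.

    Categorical organ-condition is one-hot encoded against the explicit
    category list; unknown categories are rejected.  Missing optional values
    stay NaN for the pipeline's median imputer.
    """
    df = rows.copy()
    missing = [c for c in NUMERIC_FEATURES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks mandatory columns {missing}")
    for col in NUMERIC_FEATURES:
        if df[col].isna().all():
            raise ValueError(f"mandatory feature column {col!r} is entirely missing")
    unknown = set(df[CATEGORICAL_FEATURE].dropna()) - set(ORGAN_CONDITION_CLASSES)
    if unknown:
        raise ValueError(
            f"unknown organ-condition categories {sorted(unknown)}; "
            f"expected {ORGAN_CONDITION_CLASSES}"
        )
    cols = {c: pd.to_numeric(df[c]) for c in NUMERIC_FEATURES}
    for c in OPTIONAL_FEATURES:
        cols[c] = pd.to_numeric(df[c]) if c in df.columns else np.nan
    for cat in ORGAN_CONDITION_CLASSES:
        cols[f"condition_{cat}"] = (df[CATEGORICAL_FEATURE] == cat).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    n_imputed = int(X.isna().sum().sum())
    if n_imputed:
        log.info("design matrix: %d missing values left for median imputation", n_imputed)
    return X


def build_feature_matrix(
    rows: pd.DataFrame, organ: str, targets: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Align the design matrix with per-(patient, cycle) T_eff targets.

    ``targets`` needs columns (patient_id, cycle, organ, teff_hours).
    Returns (X, y, keys); raises on duplicated (patient, cycle) rows or
    rows lacking a matching target.
    """
    if organ not in ORGANS:
        raise ValueError(f"unknown organ {organ!r}")
    if rows.duplicated(subset=KEY_COLUMNS).any():
        dup = rows.loc[rows.duplicated(subset=KEY_COLUMNS), KEY_COLUMNS]
        raise ValueError(f"duplicated (patient, cycle) feature rows: {dup.values.tolist()}")
    tgt = targets.loc[targets["organ"] == organ, KEY_COLUMNS + ["teff_hours"]]
    merged = rows.merge(tgt, on=KEY_COLUMNS, how="inner", validate="one_to_one")
    if len(merged) < len(rows):
        log.info(
            "build_feature_matrix(%s): %d feature rows without a target dropped",
            organ,
            len(rows) - len(merged),
        )
    X = build_design(merged)
    y = merged["teff_hours"].astype(float)
    y.name = "teff_hours"
    return X, y, merged[KEY_COLUMNS].copy()


class TeffModel:
    """Leakage-safe imputation/scaling/SVR pipeline with a positive floor."""

    def __init__(self, cfg: SvrConfig, min_teff_hours: float = MIN_TEFF_HOURS):
        self.cfg = cfg
        self.min_teff_hours = min_teff_hours
        self.pipeline = Pipeline(
            [
                ("impute", SimpleImputer(strategy="median")),
                ("zero_var", VarianceThreshold(threshold=0.0)),
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=cfg.C, epsilon=cfg.epsilon, gamma=cfg.gamma)),
            ]
        )
        self.feature_names_: list[str] | None = None
        self.dropped_columns_: list[str] = []

    def fit(self, X: pd.DataFrame, y: pd.Series | np.ndarray) -> "TeffModel":
        if len(X) < 2:
            raise ValueError("SVR training needs at least 2 rows")
        if np.any(np.asarray(y) <= 0):
            raise ValueError("targets (T_eff) must be positive")
        self.pipeline.fit(X, np.asarray(y, dtype=float))
        self.feature_names_ = list(X.columns)
        support = self.pipeline.named_steps["zero_var"].get_support()
        self.dropped_columns_ = [c for c, keep in zip(X.columns, support) if not keep]
        if self.dropped_columns_:
            log.info("zero-variance columns dropped: %s", self.dropped_columns_)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        pred = self.pipeline.predict(X)
        return np.maximum(pred, self.min_teff_hours)


def train_svr(
    X: pd.DataFrame, y: pd.Series | np.ndarray, cfg: SvrConfig = SvrConfig()
) -> TeffModel:
    """Fit the standardized RBF-SVR pipeline; deterministic given inputs."""
    return TeffModel(cfg).fit(X, y)


def mape(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute percentage error, in percent."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.any(y_true <= 0):
        raise ValueError("MAPE needs positive reference values")
    return float(np.mean(np.abs(y_pred / y_true - 1.0)) * 100.0)


def optimize_hyperparameters(
    X: pd.DataFrame,
    y: pd.Series,
    grid: Sequence[SvrConfig] | None = None,
    inner_k: int = 3,
    seed: int = 0,
) -> SvrConfig:
    """Select the grid point minimizing inner-CV mean absolute percentage error.

    Ties break toward smaller C then larger epsilon (stronger
    regularization), then by gamma for full determinism.
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if len(grid) == 1:
        return grid[0]
    splitter = KFold(n_splits=min(inner_k, len(X)), shuffle=True, random_state=seed)
    scores: list[tuple[float, float, float, str, SvrConfig]] = []
    y_arr = np.asarray(y, dtype=float)
    for cfg in grid:
        errs = []
        for tr, va in splitter.split(X):
            model = train_svr(X.iloc[tr], y_arr[tr], cfg)
            errs.append(mape(y_arr[va], model.predict(X.iloc[va])))
        gamma_key = f"{cfg.gamma}" if isinstance(cfg.gamma, str) else f"{cfg.gamma:.6g}"
        scores.append((float(np.mean(errs)), cfg.C, -cfg.epsilon, gamma_key, cfg))
    scores.sort(key=lambda s: s[:4])
    return scores[0][4]


@dataclass
class CvReport:
    """k-fold validation outcome for one organ's predictor."""

    organ: str
    k: int
    fold_me_percent: list[float]
    me_mean_percent: float
    me_sd_percent: float
    signed_bias_percent: float
    predictions: pd.DataFrame  # patient_id, cycle, teff_true, teff_pred, fold
    grouping: str
    seed: int


def kfold_validate(
    rows: pd.DataFrame,
    targets: pd.DataFrame,
    organ: str,
    k: int = 10,
    grouping: str = "plain",
    seed: int = 0,
    grid: Sequence[SvrConfig] | None = None,
    fixed_config: SvrConfig | None = None,
    inner_k: int = 3,
    predictor_factory: Callable[[pd.DataFrame, pd.Series], object] | None = None,
) -> CvReport:
    """k-fold cross-validation of the organ T_eff predictor.

    Hyperparameter search and scaling happen strictly inside training folds.
    ``grouping='by_patient'`` keeps all of a patient's cycles in one fold
    (no cross-cycle leakage); the default plain row-level split matches the
    conventional description.  ``fixed_config`` skips the inner search;
    ``predictor_factory`` swaps in an arbitrary regressor (used for oracle
    checks).
    """
    X, y, keys = build_feature_matrix(rows, organ, targets)
    if len(X) < k:
        raise ValueError(f"{len(X)} rows < k={k}; use a smaller k")
    if grouping == "plain":
        splits = list(
            KFold(n_splits=k, shuffle=True, random_state=seed).split(X)
        )
    elif grouping == "by_patient":
        groups = keys["patient_id"].to_numpy()
        splits = list(GroupKFold(n_splits=k).split(X, groups=groups))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    y_arr = np.asarray(y, dtype=float)
    fold_me: list[float] = []
    pred_all = np.full(len(X), np.nan)
    fold_of = np.full(len(X), -1, dtype=int)
    for fold, (tr, va) in enumerate(splits):
        if predictor_factory is not None:
            model = predictor_factory(X.iloc[tr], y.iloc[tr])
        else:
            cfg = fixed_config or optimize_hyperparameters(
                X.iloc[tr], y.iloc[tr], grid=grid, inner_k=inner_k, seed=seed
            )
            model = train_svr(X.iloc[tr], y_arr[tr], cfg)
        pred = np.asarray(model.predict(X.iloc[va]), dtype=float)
        pred_all[va] = pred
        fold_of[va] = fold
        fold_me.append(mape(y_arr[va], pred))

    predictions = keys.copy()
    predictions["teff_true"] = y_arr
    predictions["teff_pred"] = pred_all
    predictions["fold"] = fold_of
    signed = float(np.mean(pred_all / y_arr - 1.0) * 100.0)
    return CvReport(
        organ=organ,
        k=k,
        fold_me_percent=fold_me,
        me_mean_percent=float(np.mean(fold_me)),
        me_sd_percent=float(np.std(fold_me, ddof=1)) if k > 1 else 0.0,
        signed_bias_percent=signed,
        predictions=predictions,
        grouping=grouping,
        seed=seed,
    )


def predict_teff(
    models: dict[str, TeffModel],
    rows: pd.DataFrame,
    mode: str = "per_cycle",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-(patient, cycle, organ) T_eff predictions.

    ``per_cycle`` uses each cycle's own pretherapy features;
    ``first_cycle_only`` substitutes the patient's cycle-1 features for every
    cycle (a single pretherapy PET for the whole treatment).  Patients
    without a cycle-1 feature row are excluded from the latter mode and
    returned in the exclusion list.
    """
    if mode not in ("per_cycle", "first_cycle_only"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = rows.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
    excluded: list[str] = []
    if mode == "first_cycle_only":
        has_c1 = set(rows.loc[rows["cycle"] == 1, "patient_id"])
        excluded = sorted(set(rows["patient_id"]) - has_c1)
        if excluded:
            log.info(
                "first_cycle_only: excluding %d patient(s) without cycle-1 "
                "features: %s",
                len(excluded),
                excluded,
            )
        rows = rows[rows["patient_id"].isin(has_c1)]
        c1 = rows[rows["cycle"] == 1].set_index("patient_id")
        substituted = c1.loc[rows["patient_id"]].reset_index()
        substituted["cycle"] = rows["cycle"].to_numpy()  # keep cycle index feature
        rows = substituted
    X = build_design(rows)
    out = []
    for organ, model in models.items():
        pred = model.predict(X)
        frame = rows[KEY_COLUMNS].copy()
        frame["organ"] = organ
        frame["teff_pred_hours"] = pred
        out.append(frame)
    result = pd.concat(out, ignore_index=True)
    return result, excluded
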