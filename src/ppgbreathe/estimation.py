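"""Gradient-boosted breathing-rate regression with quality-conditional fusion,
plus the two spectral baseline estimators.

Three XGBoost regressors are trained on nested feature subsets: the full
model (all 53 features), a Rule-1 model (P-P-derived features only) and a
Rule-2 model (respiration-band PPG spectral features only).  At prediction
time the quality verdicts route each window to the matching model; a window
failing both rules is abstained from.  Predictions are clipped to the 4–40
bpm plausible guided-breathing range.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from xgboost import Booster, XGBRegressor

from .features import (
    ALL_FEATURES,
    FEATURE_GROUPS,
    Spectrum,
    welch_psd,
)

BPM_MIN, BPM_MAX = 4.0, 40.0

MODEL_FEATURES = {
    "full": list(ALL_FEATURES),
    "rule1_only": FEATURE_GROUPS["PRV"]
    + FEATURE_GROUPS["RR_PSD"]
    + FEATURE_GROUPS["PEAK_VALLEY"],
    "rule2_only": list(FEATURE_GROUPS["PPG_PSD"]),
}

DEFAULT_HYPERPARAMS = {
    "n_estimators": 300,
    "learning_rate": 0.05,
    "max_depth": 4,
    "subsample": 0.8,
}


@dataclass
class BreathModel:
    """Three fitted regressors keyed by the quality route, with their manifests."""

    regressors: dict
    feature_names: dict
    hyperparams: dict
    seed: int


@dataclass
class BreathEstimate:
    """Predicted breathing rate for one window, or an abstention."""

    bpm: float | None
    model_used: str  # full | rule1_only | rule2_only | none
    subject_id: str = ""
    start_s: float = float("nan")


def _make_regressor(hyperparams: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        objective="reg:squarederror",
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        **hyperparams,
    )


def fit(
    feature_table: pd.DataFrame,
    labels,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> BreathModel:
    """Fit the three route models on named feature columns.

    Requires at least 50 labeled windows.  All windows are used for every
    route model (each sees only its feature subset); missing values (NaN) are
    handled natively by the trees.  Constant labels degenerate gracefully to
    a constant predictor.
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    y = np.asarray(labels, dtype=float)
    if len(feature_table) < 50:
        raise ValueError("need at least 50 labeled windows to fit")
    regressors, names = {}, {}
    for route, cols in MODEL_FEATURES.items():
        X = feature_table[cols].to_numpy(dtype=float)
        reg = _make_regressor(hp, seed)
        reg.fit(X, y)
        regressors[route] = reg
        names[route] = list(cols)
    return BreathModel(regressors, names, hp, seed)


def route_for(rule1_keep: bool, rule2_keep: bool) -> str:
    """The quality-fusion truth table: both rules → full model; one rule →
    that rule's subset model; neither → abstain."""
    if rule1_keep and rule2_keep:
        return "full"
    if rule1_keep:
        return "rule1_only"
    if rule2_keep:
        return "rule2_only"
    return "none"


def predict(
    model: BreathModel, features: pd.Series | dict, rule1_keep: bool, rule2_keep: bool
) -> BreathEstimate:
    """Predict one window's breathing rate via quality-conditional routing."""
    route = route_for(rule1_keep, rule2_keep)
    if route == "none":
        return BreathEstimate(bpm=None, model_used="none")
    feats = pd.Series(features)
    X = feats[model.feature_names[route]].to_numpy(dtype=float)[None, :]
    bpm = float(np.clip(model.regressors[route].predict(X)[0], BPM_MIN, BPM_MAX))
    return BreathEstimate(bpm=bpm, model_used=route)


def predict_table(model: BreathModel, table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized routing prediction over a feature table.

    ``table`` must carry ``rule1_keep``/``rule2_keep`` columns plus the named
    feature columns; returns a copy with ``pred_bpm`` (NaN on abstention) and
    ``model_used`` columns.
    """
    out = table.copy()
    out["pred_bpm"] = np.nan
    out["model_used"] = "none"
    routes = [
        route_for(r1, r2)
        for r1, r2 in zip(table["rule1_keep"].to_numpy(), table["rule2_keep"].to_numpy())
    ]
    out["model_used"] = routes
    for route in ("full", "rule1_only", "rule2_only"):
        mask = np.asarray([r == route for r in routes])
        if not mask.any():
            continue
        X = table.loc[mask, model.feature_names[route]].to_numpy(dtype=float)
        out.loc[mask, "pred_bpm"] = np.clip(
            model.regressors[route].predict(X), BPM_MIN, BPM_MAX
        )
    return out


# --- spectral baselines ----------------------------------------------------

RESP_BAND = (0.1, 0.5)  # Hz, spontaneous breathing rates


def _dominant_in_band(spec: Spectrum, band: tuple[float, float]) -> float:
    sel = (spec.frequencies >= band[0]) & (spec.frequencies <= band[1])
    if not np.any(sel):
        return np.nan
    p = spec.power[sel]
    if np.max(p) <= 0 or np.max(p) < 1e-12 * max(np.sum(spec.power), 1e-30):
        return np.nan
    return float(spec.frequencies[sel][np.argmax(p)])


def baseline_ppg_dominant(
    ppg_resp, fs: float, band: tuple[float, float] = RESP_BAND, welch_params: dict | None = None
) -> float:
    """Breathing rate as 60 × the dominant frequency of the respiration-band PPG."""
    spec = welch_psd(ppg_resp, fs, **(welch_params or {}))
    f = _dominant_in_band(spec, band)
    return 60.0 * f if np.isfinite(f) else np.nan


def baseline_rr_dominant(
    interp_values, fs: float = 25.0, band: tuple[float, float] = RESP_BAND,
    welch_params: dict | None = None,
) -> float:
    """Breathing rate as 60 × the dominant frequency of the oversampled P-P series.

    A constant series has no spectral peak in the band and yields NaN.
    """
    x = np.asarray(interp_values, dtype=float)
    if len(x) < 8 or np.ptp(x) == 0:
        return np.nan
    spec = welch_psd(x - np.mean(x), fs, **(welch_params or {}))
    f = _dominant_in_band(spec, band)
    return 60.0 * f if np.isfinite(f) else np.nan


# --- serialization ---------------------------------------------------------


def save_model(model: BreathModel, path) -> None:
    """Serialize the three regressors plus a feature manifest and config hash."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for route, reg in model.regressors.items():
        # serialize the underlying booster: the sklearn-wrapper save path is
        # brittle across xgboost/scikit-learn version pairings
        reg.get_booster().save_model(str(path / f"{route}.ubj"))
    manifest = {
        "feature_names": model.feature_names,
        "hyperparams": model.hyperparams,
        "seed": model.seed,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path, expected_features: dict | None = None) -> BreathModel:
    """Load a serialized model; refuse when the manifest mismatches ``expected_features``."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if expected_features is not None and manifest["feature_names"] != expected_features:
        raise ValueError("feature manifest mismatch between model and incoming features")
    regressors = {}
    for route in manifest["feature_names"]:
        reg = _make_regressor(manifest["hyperparams"], manifest["seed"])
        booster = Booster()
        booster.load_model(str(path / f"{route}.ubj"))
        reg._Booster = booster
        regressors[route] = reg
    return BreathModel(
        regressors, manifest["feature_names"], manifest["hyperparams"], manifest["seed"]
    )
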