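"""Leave-one-subject-out evaluation, error metrics, and rejection statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import DEFAULT_HYPERPARAMS, fit, predict_table


def mae(y_pred, y_true) -> float:
    """Mean absolute error, in breaths per minute."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    return float(np.mean(np.abs(y_pred - y_true)))


def pcc(y_pred, y_true) -> float:
    """Pearson's correlation coefficient; NaN (not zero) when a vector is constant."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    dp = y_pred - np.mean(y_pred)
    dt = y_true - np.mean(y_true)
    denom = np.sqrt(np.sum(dt**2) * np.sum(dp**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(dt * dp) / denom)


@dataclass
class EvalResult:
    """Per-subject and pooled LOSO metrics plus abstention/rejection accounting."""

    per_subject: pd.DataFrame
    pooled_mae: float
    pooled_pcc: float
    n_windows: int
    n_abstained: int
    rejection: dict
    predictions: pd.DataFrame


def rejection_stats(table: pd.DataFrame) -> dict:
    """Fractions of windows rejected by Rule 1, Rule 2, and both combined.

    'Both' counts windows failing the two rules simultaneously (those are the
    abstentions), not the union.
    """
    r1 = ~table["rule1_keep"].to_numpy(dtype=bool)
    r2 = ~table["rule2_keep"].to_numpy(dtype=bool)
    return {
        "rule1": float(np.mean(r1)),
        "rule2": float(np.mean(r2)),
        "both": float(np.mean(r1 & r2)),
    }


def loso(
    table: pd.DataFrame,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> EvalResult:
    """Leave-one-subject-out cross-validation of the fused model.

    One fold per subject; the fold's subject never appears in its training
    table.  Abstained windows (both rules failed) are excluded from MAE/PCC
    and reported separately.  Pooled metrics are computed over the
    concatenation of all test-fold predictions.
    """
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    hp = hyperparams or DEFAULT_HYPERPARAMS
    fold_frames = []
    rows = []
    for subj in subjects:
        test = table[table["subject_id"] == subj]
        train = table[table["subject_id"] != subj]
        model = fit(train, train["label_bpm"], hyperparams=hp, seed=seed)
        pred = predict_table(model, test)
        fold_frames.append(pred)
        kept = pred[pred["pred_bpm"].notna()]
        rows.append(
            {
                "subject_id": subj,
                "mae": mae(kept["pred_bpm"], kept["label_bpm"]) if len(kept) else np.nan,
                "pcc": pcc(kept["pred_bpm"], kept["label_bpm"]) if len(kept) > 1 else np.nan,
                "n_windows": int(len(pred)),
                "n_abstained": int(pred["pred_bpm"].isna().sum()),
            }
        )
    predictions = pd.concat(fold_frames, ignore_index=True)
    kept = predictions[predictions["pred_bpm"].notna()]
    return EvalResult(
        per_subject=pd.DataFrame(rows),
        pooled_mae=mae(kept["pred_bpm"], kept["label_bpm"]),
        pooled_pcc=pcc(kept["pred_bpm"], kept["label_bpm"]),
        n_windows=int(len(predictions)),
        n_abstained=int(predictions["pred_bpm"].isna().sum()),
        rejection=rejection_stats(table),
        predictions=predictions,
    )


def baseline_metrics(table: pd.DataFrame, column: str) -> dict:
    """Pooled MAE/PCC of a per-window baseline column against the labels."""
    sel = table[table[column].notna()]
    return {
        "mae": mae(sel[column], sel["label_bpm"]) if len(sel) else np.nan,
        "pcc": pcc(sel[column], sel["label_bpm"]) if len(sel) > 1 else np.nan,
        "n": int(len(sel)),
    }


def sweep_window_sizes(
    recordings,
    sizes=(15.0, 20.0, 25.0, 30.0),
    seed: int = 0,
    slide_s: float = 2.0,
    threshold: float | None = None,
    hyperparams: dict | None = None,
) -> pd.DataFrame:
    """Re-run featurization + LOSO at several window sizes.

    Emits one row per (window size, method) with MAE and PCC, mirroring the
    shape of a window-size ablation table; methods are the fused model and
    the two spectral baselines.
    """
    from .pipeline import calibrate_cohort_threshold, featurize_cohort

    thr = threshold if threshold is not None else calibrate_cohort_threshold(recordings)
    rows = []
    for w in sizes:
        table = featurize_cohort(recordings, threshold=thr, window_s=w, slide_s=slide_s)
        res = loso(table, seed=seed, hyperparams=hyperparams)
        rows.append(
            {"window_s": w, "method": "fused_model", "mae": res.pooled_mae, "pcc": res.pooled_pcc}
        )
        for col, name in (("bl_rr_bpm", "rr_dominant"), ("bl_ppg_bpm", "ppg_dominant")):
            m = baseline_metrics(table, col)
            rows.append({"window_s": w, "method": name, "mae": m["mae"], "pcc": m["pcc"]})
    return pd.DataFrame(rows)
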