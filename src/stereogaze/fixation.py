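"""Fixation-window extraction and accuracy/precision metrics.

A fixation window keeps the samples between 0.6 s after stimulus onset
(discarding the orienting saccade) and 0.5 s before stimulus offset
(discarding anticipatory behaviour); with 2-s trials at 50 Hz that is a
0.9-s window of 45 samples.  Windows whose horizontal or vertical gaze SD
exceeds 2 degrees are flagged as outliers (blinks, large eye movements)
and excluded from aggregation.

Metrics per window, on gaze angles in degrees:

* MAE  — mean absolute error to the stimulus, per axis and vectorially;
* SD   — population standard deviation (divisor n) about the window mean;
* BCEA — bivariate contour ellipse area ``2 k pi SDx SDy sqrt(1 - rho^2)``
  with k = 1.14 (68.3% coverage for a bivariate normal);
* S2S  — sample-to-sample RMS displacement ``sqrt(1/(n-1) sum theta_i^2)``
  with ``theta_i`` the (vectorial or per-axis) step between consecutive
  samples.

Stimuli are stratified by horizontal eccentricity into central
(|x| <= 14 deg, inclusive) and peripheral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIM_START_S = 0.6
TRIM_END_S = 0.5
OUTLIER_SD_DEG = 2.0
CENTRAL_BOUNDARY_DEG = 14.0
BCEA_K = 1.14
MIN_VALID_SAMPLES = 10


@dataclass
class FixationWindow:
    gx: np.ndarray  # deg
    gy: np.ndarray  # deg
    timestamps: np.ndarray  # s
    target: tuple[float, float]  # (x, y) deg
    eye: str = ""
    condition: str = ""
    subject: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gx = np.asarray(self.gx, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)

    @property
    def n(self) -> int:
        return int(np.sum(self.valid_mask))

    @property
    def valid_mask(self) -> np.ndarray:
        return ~(np.isnan(self.gx) | np.isnan(self.gy))

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.valid_mask
        return self.gx[m], self.gy[m]

    @property
    def stratum(self) -> str:
        return "central" if abs(self.target[0]) <= CENTRAL_BOUNDARY_DEG else "peripheral"


def extract_window(
    trial: pd.DataFrame,
    onset_s: float,
    duration_s: float = 2.0,
    target_deg: tuple[float, float] = (0.0, 0.0),
    **labels,
) -> FixationWindow:
    """Trim a trial's gaze series to the fixation window
    ``[onset + 0.6 s, onset + duration - 0.5 s)`` (half-open).

    ``trial`` needs columns ``timestamp_s``, ``gx_deg``, ``gy_deg``.
    """
    if duration_s <= TRIM_START_S + TRIM_END_S:
        keep = trial.iloc[0:0]
    else:
        t = trial["timestamp_s"]
        keep = trial[(t >= onset_s + TRIM_START_S) & (t < onset_s + duration_s - TRIM_END_S)]
    return FixationWindow(
        gx=keep["gx_deg"].to_numpy(float),
        gy=keep["gy_deg"].to_numpy(float),
        timestamps=keep["timestamp_s"].to_numpy(float),
        target=tuple(target_deg),
        **labels,
    )


def flag_outlier(window: FixationWindow) -> bool:
    """True when SD_x > 2 deg or SD_y > 2 deg (large movements / blinks)."""
    if window.n < 2:
        return True
    sx, sy = sd_precision(window)
    return bool(sx > OUTLIER_SD_DEG or sy > OUTLIER_SD_DEG)


def mae_gaze(window: FixationWindow) -> tuple[float, float, float]:
    """(mae_x, mae_y, mae_r) in degrees: componentwise mean absolute error
    to the stimulus, and the mean Euclidean (vectorial) error."""
    gx, gy = window.valid()
    if len(gx) == 0:
        return (np.nan,) * 3
    ex = gx - window.target[0]
    ey = gy - window.target[1]
    return (
        float(np.mean(np.abs(ex))),
        float(np.mean(np.abs(ey))),
        float(np.mean(np.hypot(ex, ey))),
    )


def sd_precision(window: FixationWindow) -> tuple[float, float]:
    """Population SD (divisor n) of the gaze about the window mean, per axis."""
    gx, gy = window.valid()
    if len(gx) < 2:
        return (np.nan, np.nan)
    return float(np.std(gx)), float(np.std(gy))


def bcea(window: FixationWindow, k: float = BCEA_K) -> float:
    """Bivariate contour ellipse area (deg^2), ``2 k pi SDx SDy sqrt(1-rho^2)``."""
    gx, gy = window.valid()
    if len(gx) < 3:
        return np.nan
    sx, sy = np.std(gx), np.std(gy)
    if sx == 0 or sy == 0:
        return 0.0
    rho = float(np.corrcoef(gx, gy)[0, 1])
    return float(2 * k * np.pi * sx * sy * np.sqrt(max(0.0, 1 - rho**2)))


def s2s_precision(window: FixationWindow) -> tuple[float, float, float]:
    """(s2s_x, s2s_y, s2s_r) in degrees: RMS (divisor n-1) of consecutive
    single-axis and vectorial sample-to-sample displacements."""
    gx, gy = window.valid()
    n = len(gx)
    if n < 2:
        return (np.nan,) * 3
    dx = np.diff(gx)
    dy = np.diff(gy)
    theta = np.hypot(dx, dy)
    denom = n - 1
    return (
        float(np.sqrt(np.sum(dx**2) / denom)),
        float(np.sqrt(np.sum(dy**2) / denom)),
        float(np.sqrt(np.sum(theta**2) / denom)),
    )


def window_metrics(window: FixationWindow, k: float = BCEA_K) -> dict:
    """All per-window metrics as one record."""
    mx, my, mr = mae_gaze(window)
    sx, sy = sd_precision(window)
    s2x, s2y, s2r = s2s_precision(window)
    return {
        "subject": window.subject,
        "eye": window.eye,
        "condition": window.condition,
        "target_x_deg": window.target[0],
        "target_y_deg": window.target[1],
        "stratum": window.stratum,
        "n_samples": window.n,
        "outlier": flag_outlier(window),
        "invalid": window.n < MIN_VALID_SAMPLES,
        "mae_x": mx,
        "mae_y": my,
        "mae_r": mr,
        "sd_x": sx,
        "sd_y": sy,
        "bcea": bcea(window, k),
        "s2s_x": s2x,
        "s2s_y": s2y,
        "s2s_r": s2r,
    }


_METRIC_COLS = ["mae_x", "mae_y", "mae_r", "sd_x", "sd_y", "bcea", "s2s_x", "s2s_y", "s2s_r"]


def stratify_and_aggregate(
    windows: list[FixationWindow],
    boundary_deg: float = CENTRAL_BOUNDARY_DEG,
    k: float = BCEA_K,
) -> pd.DataFrame:
    """Per-subject/condition metric means for the all/central/peripheral
    strata, plus pooled means +/- SD across subjects.

    Outlier and invalid windows are removed first; per-subject values
    average over both eyes and all selected stimulus positions; the pooled
    rows (subject = '__pooled__') carry mean and SD across subjects.
    """
    recs = pd.DataFrame([window_metrics(w, k) for w in windows])
    if len(recs) == 0:
        return pd.DataFrame()
    recs["stratum"] = np.where(
        recs["target_x_deg"].abs() <= boundary_deg, "central", "peripheral"
    )
    good = recs[~recs["outlier"] & ~recs["invalid"]]
    if len(good) == 0:
        import warnings

        warnings.warn("all fixation windows were outliers or invalid")
        return pd.DataFrame()
    out = []
    for stratum in ("all", "central", "peripheral"):
        sel = good if stratum == "all" else good[good["stratum"] == stratum]
        if len(sel) == 0:
            continue
        per_subj = (
            sel.groupby(["subject", "condition"])[_METRIC_COLS].mean().reset_index()
        )
        per_subj.insert(0, "stratum", stratum)
        out.append(per_subj)
        pooled = per_subj.groupby("condition")[_METRIC_COLS].agg(["mean", "std"])
        for cond, row in pooled.iterrows():
            rec = {"stratum": stratum, "subject": "__pooled__", "condition": cond}
            for m in _METRIC_COLS:
                rec[m] = row[(m, "mean")]
                rec[f"{m}_sd"] = row[(m, "std")]
            out.append(pd.DataFrame([rec]))
    return pd.concat(out, ignore_index=True)
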