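"""Thrombin-generation curve characteristics.

Calibrated automated thrombography yields thrombin concentration (nM) versus
time (min) per plasma sample.  This module reduces such a curve to the three
standard characteristics used alongside the flow parameters:

* C1 — "shorter time to first thrombin": assay cap minus the lag time, so a
  faster onset gives a larger value (mirrors the ``11 - t`` convention of the
  time-to-fibrin parameter);
* C2 — endogenous thrombin potential (ETP), the area under the curve in
  nM*min (trapezoidal rule);
* C3 — thrombin peak height in nM.

Raw-fluorescence calibration (substrate depletion, inner-filter effects) is
out of scope: curves enter already expressed as thrombin concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThrombinCurve",
    "CurveCharacteristics",
    "LagPolicy",
    "characterize",
    "tm_suppression",
    "curves_from_frame",
]

#: Default assay duration (min) used as the cap in C1 = cap - lag.
DEFAULT_ASSAY_CAP_MIN = 60.0


@dataclass(frozen=True)
class ThrombinCurve:
    """Thrombin concentration (nM) on a strictly increasing time grid (min)."""

    time_min: np.ndarray
    thrombin_nm: np.ndarray
    trigger: str = "TF 1 pM"  # TF 1 pM | ellagic acid | TM 0.325 nM | ...
    analytic_etp: float | None = None  # known for synthetic noiseless curves

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        y = np.asarray(self.thrombin_nm, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and thrombin arrays must be 1-D and aligned")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("thrombin concentrations must be non-negative")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "thrombin_nm", y)

    def scaled(self, factor: float) -> "ThrombinCurve":
        return ThrombinCurve(
            self.time_min,
            self.thrombin_nm * factor,
            trigger=self.trigger,
            analytic_etp=None if self.analytic_etp is None else self.analytic_etp * factor,
        )


@dataclass(frozen=True)
class LagPolicy:
    """Lag detection: first time the curve exceeds a threshold, sustained.

    threshold = max(abs_floor_nm, rel_floor * peak); the excursion must hold
    for ``sustain_points`` consecutive grid points to reject single-point
    noise spikes.
    """

    abs_floor_nm: float = 2.0
    rel_floor: float = 0.05
    sustain_points: int = 2


@dataclass(frozen=True)
class CurveCharacteristics:
    lag_min: float | None  # None when the curve never exceeds threshold
    c1_shorter_time_min: float  # cap - lag (0 when lag undefined)
    c2_etp_nm_min: float
    c3_peak_nm: float


def characterize(
    curve: ThrombinCurve,
    lag_policy: LagPolicy = LagPolicy(),
    assay_cap_min: float = DEFAULT_ASSAY_CAP_MIN,
) -> CurveCharacteristics:
    """Compute (C1, C2, C3) for one thrombin curve.

    The peak is the curve maximum; the ETP integrates the full trace with the
    trapezoidal rule (exactly linear in the curve); the lag is the first grid
    time where the concentration exceeds the policy threshold for the required
    number of consecutive points.  An all-zero curve has no lag and reports
    C1 = ETP = peak = 0 rather than raising.
    """
    t, y = curve.time_min, curve.thrombin_nm
    if t.size < 5:
        raise ValueError("need at least 5 grid points to characterize a curve")
    peak = float(y.max())
    etp = float(np.trapezoid(y, t))
    if peak <= 0:
        return CurveCharacteristics(None, 0.0, 0.0, 0.0)
    thr = max(lag_policy.abs_floor_nm, lag_policy.rel_floor * peak)
    above = y > thr
    lag: float | None = None
    k = max(1, lag_policy.sustain_points)
    for i in range(above.size):
        window = above[i : i + k] if i + k <= above.size else above[i:]
        if window.size and window.all():
            lag = float(t[i])
            break
    if lag is None:
        return CurveCharacteristics(None, 0.0, etp, peak)
    if lag > float(t[int(np.argmax(y))]):
        # lag can never exceed the time of peak by construction of the threshold
        lag = float(t[int(np.argmax(y))])
    c1 = max(0.0, assay_cap_min - lag)
    return CurveCharacteristics(lag, c1, etp, peak)


def tm_suppression(
    curve_ref: ThrombinCurve,
    curve_tm: ThrombinCurve,
    lag_policy: LagPolicy = LagPolicy(),
) -> dict[str, float | None]:
    """Ratio (TM-triggered / reference) for ETP and peak.

    Values below 1 indicate thrombomodulin-mediated suppression of thrombin
    generation.  A zero reference makes the ratio undefined (``None``).
    """
    if curve_ref.time_min.shape != curve_tm.time_min.shape or not np.allclose(
        curve_ref.time_min, curve_tm.time_min
    ):
        raise ValueError("curves must share the same time grid")
    ref = characterize(curve_ref, lag_policy)
    tm = characterize(curve_tm, lag_policy)
    return {
        "etp_ratio": None if ref.c2_etp_nm_min == 0 else tm.c2_etp_nm_min / ref.c2_etp_nm_min,
        "peak_ratio": None if ref.c3_peak_nm == 0 else tm.c3_peak_nm / ref.c3_peak_nm,
    }


def curves_from_frame(frame: pd.DataFrame) -> list[ThrombinCurve]:
    """Build curves from a tidy table (curve_id, time_min, thrombin_nM[, trigger])."""
    curves = []
    for _, grp in frame.groupby("curve_id", sort=True):
        grp = grp.sort_values("time_min")
        trigger = str(grp["trigger"].iloc[0]) if "trigger" in grp else "TF 1 pM"
        curves.append(
            ThrombinCurve(
                grp["time_min"].to_numpy(float),
                grp["thrombin_nM"].to_numpy(float),
                trigger=trigger,
            )
        )
    return curves
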