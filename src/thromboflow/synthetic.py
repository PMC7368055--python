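"""Synthetic flow-run generator with known ground truth.

The raw flow-chamber recordings behind the multiparameter assay are not
publicly deposited, so this module generates stand-ins with exact ground
truth at three levels:

1. :func:`generate_run_images` — multicolour time-lapse frames (platelet,
   phosphatidylserine, fibrin fluorescence plus a bright-field proxy) with
   per-frame binary ground-truth masks, for exercising the segmentation and
   scoring pipeline;
2. :func:`generate_parameter_cohort` — P1-P9 parameter records for whole
   cohorts (controls plus patient effect templates), bypassing image
   synthesis, for the heatmap / phenotyping / prediction layers;
3. :func:`generate_thrombin_curve` — smooth unimodal thrombin-generation
   pulses with an analytic ETP for oracle tests.

The generative model is deliberately simple: each channel's surface coverage
follows a logistic (saturating, monotone) curve in time, with fibrin gated by
an onset time T_fib.  Per-surface plateaus implement the reactivity ladder
M1 < M2,M3 < M4,M5 < M6 <= M7; tissue factor shortens T_fib with a
saturating dose-response; thrombomodulin/APC co-coatings delay it; patient
templates scale plateaus and shift onsets.  All plateau numbers are
plausible defaults for testing, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .registry import (
    CAPTURE_TIMES,
    OBSERVATION_LIMIT_MIN,
    P9_DEFAULT_MIN,
    Condition,
    MicrospotDesign,
    ParameterRecord,
    load_registry,
)
from .thrombin import ThrombinCurve

__all__ = [
    "LogisticCurve",
    "KineticProfile",
    "EffectTemplate",
    "CohortNoise",
    "NoiseSpec",
    "FlowRunImages",
    "SceneGroundTruth",
    "SURFACE_KINETICS",
    "PATIENT_TEMPLATES",
    "CONTROL_TEMPLATE",
    "tf_shortened_onset",
    "profile_for",
    "expected_p9",
    "generate_run_images",
    "generate_parameter_cohort",
    "cohort_to_frame",
    "generate_thrombin_curve",
]


# --------------------------------------------------------------------------
# kinetic model


@dataclass(frozen=True)
class LogisticCurve:
    """Saturating coverage curve, pinned to zero at t = 0.

    coverage(t) = c_max * (s(t) - s(0)) / (1 - s(0)) with the logistic
    s(t) = 1 / (1 + exp(-(t - t50) / tau)); non-decreasing, 0 at t = 0 and
    approaching the plateau ``c_max`` (%SAC).
    """

    c_max: float  # plateau coverage, %SAC
    t50: float  # half-time, min
    tau: float  # steepness, min

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_max <= 100.0):
            raise ValueError("plateau coverage must be in [0, 100] %SAC")
        if self.t50 <= 0 or self.tau <= 0:
            raise ValueError("t50 and tau must be positive")

    def coverage(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        s = 1.0 / (1.0 + np.exp(-(t - self.t50) / self.tau))
        s0 = 1.0 / (1.0 + np.exp(self.t50 / self.tau))
        out = self.c_max * (s - s0) / (1.0 - s0)
        return float(out) if out.ndim == 0 else out

    def scaled(self, factor: float) -> "LogisticCurve":
        return replace(self, c_max=float(np.clip(self.c_max * factor, 0.0, 100.0)))


@dataclass(frozen=True)
class KineticProfile:
    """Per-channel kinetics of one flow run.

    Fibrin coverage is zero before the onset ``t_fib`` (min; ``inf`` when no
    fibrin forms) and follows its logistic curve in ``t - t_fib`` afterwards.
    """

    platelet: LogisticCurve
    ps: LogisticCurve
    thrombus: LogisticCurve
    fibrin: LogisticCurve
    t_fib: float = math.inf

    def __post_init__(self) -> None:
        if not (self.t_fib > 0):
            raise ValueError("t_fib must be positive (use inf for no fibrin)")

    def coverage(self, channel: str, t: float) -> float:
        if channel == "fibrin":
            if not np.isfinite(self.t_fib) or t < self.t_fib:
                return 0.0
            return float(self.fibrin.coverage(t - self.t_fib))
        return float(getattr(self, channel).coverage(t))


@dataclass(frozen=True)
class EffectTemplate:
    """Named multiplicative/additive modifiers applied to a base profile.

    ``tm_delay_scale`` scales the fibrin delay produced by thrombomodulin /
    APC co-coatings: 1 = full anticoagulant response, 0 = resistant (the
    FV-Leiden situation, where APC cannot inactivate mutant FVa).
    """

    name: str = "control"
    platelet_scale: float = 1.0
    ps_scale: float = 1.0
    thrombus_scale: float = 1.0
    fibrin_scale: float = 1.0
    t_fib_shift: float = 0.0  # min, positive = delayed fibrin
    tm_delay_scale: float = 1.0


CONTROL_TEMPLATE = EffectTemplate()

#: Patient effect templates. Directions follow the clinical phenotypes:
#: contact-pathway and FV deficiencies impair thrombus/fibrin build-up,
#: FV-Leiden is prothrombotic and resistant to the TM/APC pathway.
PATIENT_TEMPLATES: dict[str, EffectTemplate] = {
    "FXII-def": EffectTemplate(
        name="FXII-def", thrombus_scale=0.65, fibrin_scale=0.55, t_fib_shift=1.0
    ),
    "FXI-def": EffectTemplate(
        name="FXI-def", thrombus_scale=0.75, fibrin_scale=0.65, t_fib_shift=1.0
    ),
    "FV-def": EffectTemplate(
        name="FV-def",
        platelet_scale=0.85,
        thrombus_scale=0.6,
        fibrin_scale=0.15,
        t_fib_shift=4.0,
    ),
    "FV-Leiden": EffectTemplate(
        name="FV-Leiden",
        ps_scale=1.3,
        fibrin_scale=1.45,
        t_fib_shift=-1.5,
        tm_delay_scale=0.0,
    ),
}

#: Per-surface base kinetics (no TF, control blood, 1000 1/s).  The plateau
#: ladder encodes the reactivity ordering M1 < M2,M3 < M4,M5 < M6 <= M7;
#: the numbers are plausible defaults, not measurements.
SURFACE_KINETICS: dict[str, dict[str, float]] = {
    "M1": {"platelet": 3.0, "ps_frac": 0.10, "t_fib": math.inf, "fibrin": 0.0},
    "M2": {"platelet": 20.0, "ps_frac": 0.20, "t_fib": 9.5, "fibrin": 14.0},
    "M3": {"platelet": 22.0, "ps_frac": 0.20, "t_fib": 9.5, "fibrin": 15.0},
    "M4": {"platelet": 33.0, "ps_frac": 0.25, "t_fib": 9.0, "fibrin": 20.0},
    "M5": {"platelet": 36.0, "ps_frac": 0.30, "t_fib": 8.5, "fibrin": 22.0},
    "M6": {"platelet": 52.0, "ps_frac": 0.35, "t_fib": 8.5, "fibrin": 30.0},
    "M7": {"platelet": 55.0, "ps_frac": 0.35, "t_fib": 6.5, "fibrin": 35.0},
    # M8/M9 are the M6 coating plus TM/APC co-coating; TF arrives in medium.
    "M8": {"platelet": 52.0, "ps_frac": 0.35, "t_fib": 8.5, "fibrin": 30.0},
    "M9": {"platelet": 52.0, "ps_frac": 0.35, "t_fib": 8.5, "fibrin": 30.0},
}

_PLATELET_T50 = 1.8
_PLATELET_TAU = 0.9
_THROMBUS_T50 = 2.4
_THROMBUS_TAU = 1.0
_PS_T50 = 3.0
_PS_TAU = 1.1
_FIBRIN_T50 = 1.5  # after onset
_FIBRIN_TAU = 0.7

#: TF dose-response on the fibrin onset time (saturating, strictly
#: decreasing in dose): t_fib(d) = t_min + (base - t_min) * K / (K + d).
#: The response saturates at low dose (10 pM in-medium TF already yields
#: fibrin by ~6.5 min on reactive collagen surfaces) and even maximal TF
#: leaves the onset in the second 4-min interval of the capture window.
TF_HALF_DOSE_PM = 10.0
TF_MIN_ONSET_MIN = 4.5
#: Finite onset assumed once TF is present, even for surfaces without
#: intrinsic fibrin formation (TF triggers fibrin on every surface).
TF_BASE_ONSET_MIN = 10.5
#: Extra fibrin delay produced by a TM or APC co-coating, min.
TM_DELAY_MIN = 3.0


def tf_shortened_onset(base_onset: float, dose_pm: float) -> float:
    """Fibrin onset time after TF dose-response shortening (min)."""
    if dose_pm <= 0:
        return base_onset
    base = base_onset if np.isfinite(base_onset) else TF_BASE_ONSET_MIN
    base = min(base, TF_BASE_ONSET_MIN)
    return TF_MIN_ONSET_MIN + (base - TF_MIN_ONSET_MIN) * TF_HALF_DOSE_PM / (
        TF_HALF_DOSE_PM + dose_pm
    )


def profile_for(
    design: MicrospotDesign | str,
    condition: Condition,
    template: EffectTemplate = CONTROL_TEMPLATE,
) -> KineticProfile:
    """Deterministic expected kinetic profile for a surface x condition run.

    Applies, in order: the surface base kinetics, shear-rate attenuation,
    the TF dose-response (co-coated or in-medium TF), the iFVIIa and CTI
    interventions, the TM/APC co-coating delay, and the subject template.
    """
    if isinstance(design, str):
        design = load_registry().surfaces[design]
    base = SURFACE_KINETICS[design.id]

    platelet = base["platelet"]
    ps = base["platelet"] * base["ps_frac"]
    thrombus = min(100.0, base["platelet"] * 1.2)
    fibrin = base["fibrin"]
    t_fib = base["t_fib"]

    if condition.shear_rate == 150:
        platelet *= 0.8
        ps *= 0.8
        thrombus *= 0.8

    dose = condition.tf_dose_pm if condition.tf else 0.0
    if design.tf_in_medium and dose == 0.0:
        dose = 10.0
    if condition.ifviia:
        # inactivated FVIIa out-competes FVIIa on TF; extrinsic trigger ~gone
        dose *= 0.05
        thrombus *= 0.9
        fibrin *= 0.8
    if dose > 0:
        frac = dose / (dose + TF_HALF_DOSE_PM)
        fibrin = min(100.0, (fibrin if fibrin > 0 else 12.0) * (1.0 + 0.8 * frac))
        thrombus = min(100.0, thrombus * (1.0 + 0.15 * frac))
        ps = min(100.0, ps * (1.0 + 0.2 * frac))
    t_fib = tf_shortened_onset(t_fib, dose)
    if condition.cti:
        # blocking FXIIa delays fibrin; the effect is larger with TF present
        t_fib += 2.0 if dose > 0 else 1.0
        fibrin *= 0.7 if dose > 0 else 0.85
    if design.co_coating in ("TM", "APC"):
        t_fib += TM_DELAY_MIN * template.tm_delay_scale
        ps *= 1.0 - 0.4 * template.tm_delay_scale
    if condition.soluble == "sAPC":
        t_fib += TM_DELAY_MIN * template.tm_delay_scale
    elif condition.soluble == "C4BP":
        # C4BP lowers protein S activity -> less APC cofactor -> faster fibrin
        t_fib = max(1.0, t_fib - 1.0)

    platelet = float(np.clip(platelet * template.platelet_scale, 0.0, 100.0))
    ps = float(np.clip(ps * template.ps_scale, 0.0, 100.0))
    thrombus = float(np.clip(thrombus * template.thrombus_scale, 0.0, 100.0))
    fibrin = float(np.clip(fibrin * template.fibrin_scale, 0.0, 100.0))
    if np.isfinite(t_fib):
        t_fib = max(1.0, t_fib + template.t_fib_shift)
    if fibrin == 0.0:
        t_fib = math.inf

    return KineticProfile(
        platelet=LogisticCurve(platelet, _PLATELET_T50, _PLATELET_TAU),
        ps=LogisticCurve(ps, _PS_T50, _PS_TAU),
        thrombus=LogisticCurve(thrombus, _THROMBUS_T50, _THROMBUS_TAU),
        fibrin=LogisticCurve(fibrin, _FIBRIN_T50, _FIBRIN_TAU),
        t_fib=t_fib,
    )


def expected_p9(t_fib: float) -> float:
    """P9 implied by a fibrin onset time on the 2-min capture grid.

    The first grid time >= t_fib (up to the 10-min observation limit) counts
    as the observed time-to-fibrin; unseen fibrin defaults to 11 min, i.e.
    P9 = 0.
    """
    grid = np.arange(0.0, OBSERVATION_LIMIT_MIN + 1e-9, 2.0)
    if not np.isfinite(t_fib) or t_fib > OBSERVATION_LIMIT_MIN:
        return 0.0
    t_obs = float(grid[grid >= min(max(t_fib, 0.0), OBSERVATION_LIMIT_MIN)][0])
    return P9_DEFAULT_MIN - t_obs


# --------------------------------------------------------------------------
# parameter cohorts (bypassing image synthesis)


@dataclass(frozen=True)
class CohortNoise:
    """Between-subject and residual variability of the cohort generator.

    Plateau noise is lognormal (multiplicative); onset noise is additive in
    minutes.  The subject effect is shared across all of a subject's runs,
    producing the donor-dependent thrombus signature seen across related
    surfaces.
    """

    subject_sd: float = 0.12  # lognormal sigma on plateaus, per subject
    residual_sd: float = 0.08  # lognormal sigma per run x time point
    t_fib_subject_sd: float = 0.4  # min
    t_fib_residual_sd: float = 0.3  # min


# rubric tiers used to emit ordinal scores from coverage (monotone maps)
_P4_TIERS = (0.5, 3.0, 8.0, 18.0, 35.0)
_P5_TIERS = (8.0, 25.0, 45.0)
_P6_TIERS = (8.0, 20.0, 40.0)
_P8_TIERS = (1.0, 8.0, 20.0)


def _tier(value: float, cuts: tuple[float, ...]) -> int:
    return int(sum(value >= c for c in cuts))


def _record_from_profile(
    subject: str,
    design: MicrospotDesign,
    condition: Condition,
    profile: KineticProfile,
    rng: np.random.Generator,
    noise: CohortNoise,
    subject_factor: float,
    subject_tfib_shift: float,
    seed: int,
) -> ParameterRecord:
    t_fib = profile.t_fib
    if np.isfinite(t_fib):
        t_fib = max(
            1.0,
            t_fib + subject_tfib_shift + rng.normal(0.0, noise.t_fib_residual_sd),
        )
    values: dict[tuple[str, int], float] = {}
    for t in CAPTURE_TIMES:
        noisy = {}
        for channel in ("platelet", "ps", "thrombus"):
            cov = profile.coverage(channel, t) * subject_factor
            cov *= rng.lognormal(0.0, noise.residual_sd) if noise.residual_sd else 1.0
            noisy[channel] = float(np.clip(cov, 0.0, 100.0))
        fib = 0.0
        if np.isfinite(t_fib) and t >= t_fib:
            fib = float(profile.fibrin.coverage(t - t_fib)) * subject_factor
            fib *= rng.lognormal(0.0, noise.residual_sd) if noise.residual_sd else 1.0
            fib = float(np.clip(fib, 0.0, 100.0))
        values[("P1", t)] = noisy["platelet"]
        values[("P2", t)] = noisy["ps"]
        values[("P3", t)] = noisy["thrombus"]
        values[("P4", t)] = float(_tier(noisy["thrombus"], _P4_TIERS))
        values[("P5", t)] = float(_tier(noisy["platelet"], _P5_TIERS))
        values[("P6", t)] = float(_tier(noisy["thrombus"] * min(1.0, t / 4.0), _P6_TIERS))
        values[("P7", t)] = fib
        values[("P8", t)] = float(_tier(fib, _P8_TIERS))
    return ParameterRecord(
        subject=subject,
        surface=design.id,
        condition=condition,
        values=values,
        p9=expected_p9(t_fib),
        provenance="synthetic",
        seed=seed,
    )


def generate_parameter_cohort(
    n_controls: int,
    patients: dict[str, EffectTemplate] | list[EffectTemplate] | None,
    surfaces: list[str],
    conditions: list[Condition],
    seed: int,
    noise: CohortNoise = CohortNoise(),
    n_replicates: int = 2,
) -> list[ParameterRecord]:
    """Generate P1-P9 records for a cohort of controls plus patients.

    Every subject gets ``n_replicates`` records per surface x condition
    (flow runs are performed in duplicate per blood sample as standard).
    Control subjects are named ``Ctrl01``..; patient subjects carry their
    template name.  All randomness flows from ``seed``.
    """
    if n_controls < 2:
        raise ValueError("need at least 2 control subjects")
    if not surfaces:
        raise ValueError("surface list must not be empty")
    if not conditions:
        raise ValueError("condition list must not be empty")
    registry = load_registry()
    if patients is None:
        patients = {}
    if isinstance(patients, list):
        patients = {t.name or f"Pat{i + 1}": t for i, t in enumerate(patients)}

    rng = np.random.default_rng(seed)
    subjects: list[tuple[str, EffectTemplate]] = [
        (f"Ctrl{i + 1:02d}", CONTROL_TEMPLATE) for i in range(n_controls)
    ] + list(patients.items())

    records: list[ParameterRecord] = []
    for subject, template in subjects:
        subject_factor = (
            rng.lognormal(0.0, noise.subject_sd) if noise.subject_sd else 1.0
        )
        subject_tfib = (
            rng.normal(0.0, noise.t_fib_subject_sd) if noise.t_fib_subject_sd else 0.0
        )
        for surface in surfaces:
            design = registry.surfaces[surface]
            for condition in conditions:
                profile = profile_for(design, condition, template)
                for _ in range(max(1, n_replicates)):
                    records.append(
                        _record_from_profile(
                            subject,
                            design,
                            condition,
                            profile,
                            rng,
                            noise,
                            subject_factor,
                            subject_tfib,
                            seed,
                        )
                    )
    return records


def cohort_to_frame(records: list[ParameterRecord]) -> pd.DataFrame:
    """Tidy long table (subject, surface, condition fields, parameter, time, value).

    P9 is emitted once per record with time = NA.
    """
    rows = []
    for rec in records:
        meta = {
            "subject": rec.subject,
            "surface": rec.surface,
            "shear_rate": rec.condition.shear_rate,
            "tf": rec.condition.tf,
            "tf_dose_pm": rec.condition.tf_dose_pm,
            "ifviia": rec.condition.ifviia,
            "cti": rec.condition.cti,
            "soluble": rec.condition.soluble,
            "provenance": rec.provenance,
        }
        for (pid, t), value in sorted(rec.values.items()):
            rows.append({**meta, "parameter": pid, "time": t, "value": value})
        if rec.p9 is not None:
            rows.append({**meta, "parameter": "P9", "time": np.nan, "value": rec.p9})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# image synthesis


@dataclass(frozen=True)
class NoiseSpec:
    """Imaging noise model: flat background, tilted illumination plane,
    additive Gaussian read noise and optional Poisson shot noise."""

    background: float = 20.0
    object_intensity: float = 150.0
    illumination_amp: float = 8.0
    gaussian_sd: float = 5.0
    shot_noise: bool = True
    shot_scale: float = 0.5  # photons per gray level in the Poisson stage


@dataclass
class SceneGroundTruth:
    """Exact per-frame truth for a synthetic run."""

    masks: dict[str, dict[int, np.ndarray]]  # channel -> time -> bool HxW
    sac: dict[str, dict[int, float]]  # true %SAC (mask fraction x 100)
    object_areas: dict[int, list[int]]  # platelet-channel object areas per time
    t_fib: float


@dataclass
class FlowRunImages:
    """8-bit frame stack for one run: channel -> time -> HxW uint8."""

    frames: dict[str, dict[int, np.ndarray]]
    times: tuple[int, ...]
    channels: tuple[str, ...]
    pixel_size_um: float
    seed: int


_MIN_FRAME_PX = 48
_FLUOR_CHANNELS = ("platelet", "ps", "fibrin")


def _paint_disc(mask: np.ndarray, cy: int, cx: int, r: int) -> None:
    h, w = mask.shape
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _grow_discs(
    mask: np.ndarray,
    discs: list[tuple[int, int, int]],
    target_fraction: float,
    rng: np.random.Generator,
    r_lo: int = 4,
    r_hi: int = 12,
    cluster_prob: float = 0.6,
) -> None:
    """Accrete discs until the mask reaches the target coverage fraction."""
    h, w = mask.shape
    if target_fraction <= 0:
        return
    for _ in range(20_000):
        if mask.mean() >= target_fraction:
            break
        r = int(rng.integers(r_lo, r_hi + 1))
        if discs and rng.random() < cluster_prob:
            cy0, cx0, r0 = discs[int(rng.integers(len(discs)))]
            ang = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(0.4, 1.1) * (r0 + r)
            cy = int(np.clip(cy0 + d * np.sin(ang), 0, h - 1))
            cx = int(np.clip(cx0 + d * np.cos(ang), 0, w - 1))
        else:
            cy = int(rng.integers(h))
            cx = int(rng.integers(w))
        _paint_disc(mask, cy, cx, r)
        discs.append((cy, cx, r))


def _grow_fibres(
    mask: np.ndarray,
    anchors: np.ndarray,
    target_fraction: float,
    rng: np.random.Generator,
    step: float = 3.0,
    turn_sd: float = 0.12,
) -> None:
    """Accrete fibre-like random-walk polylines (width ~3 px) into the mask.

    Fibres start at anchor pixels (platelet-thrombus foreground when
    available) and protrude outward, mimicking fibrin fibres growing from
    thrombi.
    """
    h, w = mask.shape
    centre = np.zeros_like(mask)
    for _ in range(2_000):
        if mask.mean() >= target_fraction:
            break
        if anchors.size:
            iy = int(rng.integers(anchors.shape[0]))
            y, x = float(anchors[iy, 0]), float(anchors[iy, 1])
        else:
            y, x = float(rng.integers(h)), float(rng.integers(w))
        ang = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.integers(15, 40))
        for _ in range(n_steps):
            ang += rng.normal(0.0, turn_sd)
            y += step * np.sin(ang)
            x += step * np.cos(ang)
            if not (0 <= y < h and 0 <= x < w):
                break
            rr, cc = int(y), int(x)
            # 3x3 stamps along the walk give a fibre ~3 px wide
            centre[max(0, rr - 1) : rr + 2, max(0, cc - 1) : cc + 2] = True
        mask |= centre
        centre[:] = False


def generate_run_images(
    design: MicrospotDesign | str,
    condition: Condition,
    profile: KineticProfile,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    times: tuple[int, ...] = CAPTURE_TIMES,
    pixel_size_um: float = 0.108,
) -> tuple[FlowRunImages, SceneGroundTruth]:
    """Render one multicolour flow run with exact ground truth.

    The platelet channel shows disc-shaped platelets accreting into
    aggregates along the coverage curve; the phosphatidylserine channel is a
    subset of the platelet foreground; fibrin fibres appear only from the
    onset time onward; the bright-field proxy is the inverted composite.
    Deterministic for a fixed seed.
    """
    if isinstance(design, str):
        design = load_registry().surfaces[design]
    if min(shape) < _MIN_FRAME_PX:
        raise ValueError(f"frame size must be at least {_MIN_FRAME_PX} px")
    rng = np.random.default_rng(seed)
    h, w = shape

    # fixed per-run illumination plane (low-frequency background structure)
    gy, gx = np.mgrid[0:h, 0:w]
    direction = rng.uniform(0, 2 * np.pi)
    plane = (gy / h) * np.sin(direction) + (gx / w) * np.cos(direction)
    plane = noise.illumination_amp * (plane - plane.mean())

    platelet_mask = np.zeros(shape, dtype=bool)
    ps_mask = np.zeros(shape, dtype=bool)
    fibrin_mask = np.zeros(shape, dtype=bool)
    discs: list[tuple[int, int, int]] = []
    ps_disc_count = 0

    masks: dict[str, dict[int, np.ndarray]] = {c: {} for c in (*_FLUOR_CHANNELS, "brightfield")}
    sac: dict[str, dict[int, float]] = {c: {} for c in (*_FLUOR_CHANNELS, "brightfield")}
    frames: dict[str, dict[int, np.ndarray]] = {c: {} for c in (*_FLUOR_CHANNELS, "brightfield")}
    object_areas: dict[int, list[int]] = {}

    for t in times:
        _grow_discs(platelet_mask, discs, profile.coverage("platelet", t) / 100.0, rng)
        # PS-positive platelets: earliest-adherent discs first (monotone subset)
        ps_target = profile.coverage("ps", t) / 100.0
        while ps_mask.mean() < ps_target and ps_disc_count < len(discs):
            cy, cx, r = discs[ps_disc_count]
            _paint_disc(ps_mask, cy, cx, r)
            ps_disc_count += 1
        ps_mask &= platelet_mask
        fib_target = profile.coverage("fibrin", t) / 100.0
        if fib_target > 0:
            anchors = np.argwhere(platelet_mask)
            _grow_fibres(fibrin_mask, anchors, fib_target, rng)

        labeled, n_obj = ndimage.label(platelet_mask, structure=np.ones((3, 3)))
        object_areas[t] = (
            np.bincount(labeled.ravel())[1:].tolist() if n_obj else []
        )

        bf_mask = platelet_mask | fibrin_mask
        for channel, mask in (
            ("platelet", platelet_mask),
            ("ps", ps_mask),
            ("fibrin", fibrin_mask),
            ("brightfield", bf_mask),
        ):
            masks[channel][t] = mask.copy()
            sac[channel][t] = float(mask.mean() * 100.0)

        for channel in _FLUOR_CHANNELS:
            img = noise.background + plane + noise.object_intensity * masks[channel][t]
            img = ndimage.gaussian_filter(img, 0.8)  # optical blur
            if noise.shot_noise and noise.shot_scale > 0:
                img = rng.poisson(np.clip(img, 0, None) * noise.shot_scale) / noise.shot_scale
            if noise.gaussian_sd:
                img = img + rng.normal(0.0, noise.gaussian_sd, size=shape)
            frames[channel][t] = np.clip(img, 0, 255).astype(np.uint8)
        composite = (
            0.7 * masks["platelet"][t] + 0.5 * masks["fibrin"][t]
        )
        bf = 235.0 - plane - noise.object_intensity * np.clip(composite, 0, 1)
        bf = ndimage.gaussian_filter(bf, 0.8)
        if noise.gaussian_sd:
            bf = bf + rng.normal(0.0, noise.gaussian_sd, size=shape)
        frames["brightfield"][t] = np.clip(bf, 0, 255).astype(np.uint8)

    run = FlowRunImages(
        frames=frames,
        times=tuple(times),
        channels=(*_FLUOR_CHANNELS, "brightfield"),
        pixel_size_um=pixel_size_um,
        seed=seed,
    )
    truth = SceneGroundTruth(
        masks=masks, sac=sac, object_areas=object_areas, t_fib=profile.t_fib
    )
    return run, truth


# --------------------------------------------------------------------------
# thrombin curves


def generate_thrombin_curve(
    lag: float,
    peak: float,
    width: float,
    grid: float = 0.25,
    seed: int | None = None,
    kind: str = "gamma",
    shape: float = 3.0,
    duration: float = 60.0,
    noise_sd: float = 0.0,
    trigger: str = "TF 1 pM",
) -> ThrombinCurve:
    """Smooth unimodal thrombin pulse with a known analytic ETP.

    ``kind="gamma"``: after the lag, T(t) = peak * (x/width)^a *
    exp(a (1 - x/width)) with x = t - lag, peaking at x = width with height
    ``peak``; its full-area ETP is peak * width * e^a * Gamma(a+1) / a^(a+1).
    ``kind="triangle"``: linear rise over ``width`` then linear fall over
    ``width`` (ETP = peak * width exactly).
    """
    if peak < 0:
        raise ValueError("peak must be non-negative")
    if width <= 0:
        raise ValueError("width must be positive")
    if grid <= 0:
        raise ValueError("grid step must be positive")
    t = np.arange(0.0, duration + grid / 2, grid)
    x = np.clip(t - lag, 0.0, None)
    if peak == 0:
        y = np.zeros_like(t)
        analytic = 0.0
    elif kind == "gamma":
        a = float(shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = peak * np.where(x > 0, (x / width) ** a * np.exp(a * (1 - x / width)), 0.0)
        analytic = float(peak * width * math.exp(a) * math.gamma(a + 1) / a ** (a + 1))
    elif kind == "triangle":
        y = peak * np.clip(np.minimum(x / width, 2.0 - x / width), 0.0, None)
        analytic = float(peak * width)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, size=y.shape), 0.0, None)
    return ThrombinCurve(t, y, trigger=trigger, analytic_etp=analytic)
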