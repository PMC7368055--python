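"""From per-time quantification to the 9-parameter kinetic record.

P1-P3 and P7 are %SAC readouts taken directly from the segmentation; P4-P6
and P8 were originally human visual scores against reference images and are
implemented here as automated surrogates: explicit, monotone rubrics on mask
statistics (documented in the record provenance).  P9 is the time-to-fibrin
statistic, reported as ``11 - t`` min with a default of 11 min (P9 = 0) when
no persistent fibres appear within the 10-min observation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

from .imaging import BinaryMask, QuantResult
from .registry import (
    CAPTURE_TIMES,
    OBSERVATION_LIMIT_MIN,
    P9_DEFAULT_MIN,
    Condition,
    ParameterRecord,
    load_registry,
)

__all__ = [
    "ScoreRubric",
    "FibreCriteria",
    "score_morphology",
    "score_aggregation",
    "score_contraction",
    "score_fibrin",
    "fibre_stats",
    "detect_time_to_fibrin",
    "assemble_record",
    "record_from_run",
]


@dataclass(frozen=True)
class ScoreRubric:
    """Thresholds mapping mask statistics to the ordinal scores.

    Area cutoffs are in px^2 at the default optical scale and are rescaled
    by (0.108 / pixel_size_um)^2 when a different pixel size is supplied.
    All tier sequences are strictly increasing, keeping every score monotone
    in its driving statistic.
    """

    sac_epsilon: float = 0.2  # below this %SAC the field counts as blank
    single_platelet_area_px: float = 80.0  # objects below this are singles
    aggregate_tiers_px: tuple[float, ...] = (80.0, 500.0, 2000.0)
    extensive_singles_sac: float = 10.0  # %SAC of singles for morphology 2
    aggregation_fraction_tiers: tuple[float, ...] = (0.1, 0.35, 0.6)
    contraction_shrink_tiers: tuple[float, ...] = (0.05, 0.15, 0.30)
    fibrin_tiers: tuple[float, ...] = (1.0, 3.0, 10.0)  # fibre count / coverage

    def __post_init__(self) -> None:
        for tiers in (
            self.aggregate_tiers_px,
            self.aggregation_fraction_tiers,
            self.contraction_shrink_tiers,
            self.fibrin_tiers,
        ):
            if any(b <= a for a, b in zip(tiers, tiers[1:])):
                raise ValueError("rubric tiers must be strictly increasing")

    def area_scale(self, pixel_size_um: float) -> float:
        return (0.108 / pixel_size_um) ** 2 if pixel_size_um > 0 else 1.0


@dataclass(frozen=True)
class FibreCriteria:
    """What counts as a fibrin fibre: long, thin, and persistent."""

    min_skeleton_px: int = 20
    min_elongation: float = 4.0  # major / minor axis ratio
    require_persistence: bool = True  # fibres must re-appear at the next frame


def score_morphology(
    stats: QuantResult, rubric: ScoreRubric = ScoreRubric(), pixel_size_um: float = 0.108
) -> int:
    """Thrombus morphology score P4 (0-5).

    0 blank field; 1 a few single platelets; 2 extensive coverage of
    singles; 3-5 by largest-aggregate area tier (small aggregates, medium
    aggregates/thrombi, large aggregates/thrombi).  Monotone non-decreasing
    in both coverage and maximum object size.
    """
    scale = rubric.area_scale(pixel_size_um)
    if stats.sac < rubric.sac_epsilon or stats.n_objects == 0:
        return 0
    max_area = stats.max_object_area_px * scale
    t1, t2, t3 = rubric.aggregate_tiers_px
    if max_area >= t3:
        return 5
    if max_area >= t2:
        return 4
    if max_area >= t1:
        return 3
    # only single platelets present
    return 2 if stats.sac >= rubric.extensive_singles_sac else 1


def _aggregate_fraction(
    stats: QuantResult, rubric: ScoreRubric, pixel_size_um: float
) -> float:
    scale = rubric.area_scale(pixel_size_um)
    total = sum(stats.object_areas_px)
    if total == 0:
        return 0.0
    in_aggregates = sum(
        a for a in stats.object_areas_px if a * scale >= rubric.single_platelet_area_px
    )
    return in_aggregates / total


def score_aggregation(
    stats_series: list[QuantResult],
    rubric: ScoreRubric = ScoreRubric(),
    pixel_size_um: float = 0.108,
) -> int:
    """Thrombus aggregation score P5 (0-3): tiered on the fraction of
    foreground residing in objects above the single-platelet cutoff at the
    final time point."""
    if len(stats_series) < 2:
        raise ValueError("need at least 2 time points")
    frac = _aggregate_fraction(stats_series[-1], rubric, pixel_size_um)
    return sum(frac >= c for c in rubric.aggregation_fraction_tiers)


def score_contraction(
    stats_series: list[QuantResult],
    rubric: ScoreRubric = ScoreRubric(),
    pixel_size_um: float = 0.108,
) -> int:
    """Thrombus contraction score P6 (0-3).

    Contraction densifies a thrombus: its footprint shrinks from the peak
    while the mean foreground intensity does not fall.  Tiered on the
    relative footprint decrease; a static or still-growing scene scores 0.
    """
    if len(stats_series) < 2:
        raise ValueError("need at least 2 time points")
    sacs = [s.sac for s in stats_series]
    peak_i = int(np.argmax(sacs))
    last = stats_series[-1]
    if sacs[peak_i] <= 0 or peak_i == len(sacs) - 1:
        return 0
    shrink = (sacs[peak_i] - last.sac) / sacs[peak_i]
    peak_int = stats_series[peak_i].mean_foreground_intensity
    last_int = last.mean_foreground_intensity
    if peak_int is not None and last_int is not None and last_int < peak_int * 0.98:
        return 0  # fading signal, not densification
    return sum(shrink >= c for c in rubric.contraction_shrink_tiers)


@dataclass(frozen=True)
class FibreStats:
    n_fibres: int
    total_skeleton_px: float
    coverage_sac: float


def fibre_stats(
    mask: BinaryMask | np.ndarray, criteria: FibreCriteria = FibreCriteria()
) -> FibreStats:
    """Count fibre-like objects (elongated and long enough) in a fibrin mask."""
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    labeled = label(m, connectivity=2)
    n = 0
    total_skel = 0.0
    for region in regionprops(labeled):
        minor = region.axis_minor_length
        elongation = region.axis_major_length / minor if minor > 0 else np.inf
        skel = skeletonize(region.image)
        skel_len = int(skel.sum())
        if skel_len >= criteria.min_skeleton_px and elongation >= criteria.min_elongation:
            n += 1
            total_skel += skel_len
    return FibreStats(n, total_skel, float(m.mean() * 100.0))


def score_fibrin(
    stats: FibreStats, rubric: ScoreRubric = ScoreRubric()
) -> int:
    """Fibrin score P8 (0-3): 0 with no fibres, otherwise tiered on fibrin
    coverage (a dense fibre mat reaches the top tier)."""
    if stats.n_fibres == 0 and stats.coverage_sac < rubric.fibrin_tiers[0]:
        return 0
    driving = max(stats.coverage_sac, float(stats.n_fibres > 0) * rubric.fibrin_tiers[0])
    return max(
        int(stats.n_fibres > 0),
        sum(driving >= c for c in rubric.fibrin_tiers),
    )


def detect_time_to_fibrin(
    fibrin_masks: list[BinaryMask],
    criteria: FibreCriteria = FibreCriteria(),
    limit_min: float = OBSERVATION_LIMIT_MIN,
) -> tuple[float, float]:
    """Earliest time with persistent fibre-like objects; returns (t_fib, P9).

    Fibres must satisfy the criteria at a frame and the fibrin signal must
    persist at the next frame (noise rejection): either fibre-like objects
    are still resolvable there, or the fibrin coverage has not receded
    (fibres that merged into a dense mat no longer count as individual
    elongated objects but certainly persist).  Appearance at the final frame
    is accepted as-is since persistence cannot be checked there.  Without
    fibres by ``limit_min``, t_fib defaults to 11 min and P9 = 0; otherwise
    P9 = 11 - t_fib.
    """
    if len(fibrin_masks) < 2:
        raise ValueError("need at least 2 frames to verify fibre persistence")
    masks = sorted(fibrin_masks, key=lambda m: m.time_min)
    present = [
        fibre_stats(m, criteria).n_fibres > 0 and m.time_min <= limit_min
        for m in masks
    ]
    for i, ok in enumerate(present):
        if not ok:
            continue
        is_last = i == len(present) - 1
        persists = (
            is_last
            or present[i + 1]
            or masks[i + 1].mask.mean() >= masks[i].mask.mean()
        )
        if not criteria.require_persistence or persists:
            t_fib = float(masks[i].time_min)
            return t_fib, P9_DEFAULT_MIN - t_fib
    return P9_DEFAULT_MIN, 0.0


def assemble_record(
    subject: str,
    surface: str,
    condition: Condition,
    quant: dict[str, dict[int, QuantResult]],
    scores: dict[tuple[str, int], int],
    p9: float,
    provenance: str = "measured",
    seed: int | None = None,
) -> ParameterRecord:
    """Assemble and validate the complete 41-value parameter record.

    ``quant`` maps channel -> time -> QuantResult for the %SAC parameters;
    ``scores`` maps (parameter id, time) -> ordinal score for P4-P6 and P8.
    Missing cells leave the record incomplete (flagged via ``.complete``);
    out-of-range values raise.
    """
    channel_to_param = {"platelet": "P1", "ps": "P2", "brightfield": "P3", "fibrin": "P7"}
    values: dict[tuple[str, int], float] = {}
    for channel, pid in channel_to_param.items():
        for t in CAPTURE_TIMES:
            q = quant.get(channel, {}).get(t)
            if q is not None:
                values[(pid, t)] = float(q.sac)
    for (pid, t), score in scores.items():
        values[(pid, t)] = float(score)
    record = ParameterRecord(
        subject=subject,
        surface=surface,
        condition=condition,
        values=values,
        p9=float(p9),
        provenance=provenance,
        seed=seed,
    )
    record.validate(load_registry())
    return record


def record_from_run(
    run,
    masks_by_channel: dict[str, list[BinaryMask]],
    quant: dict[str, dict[int, QuantResult]],
    subject: str,
    surface: str,
    condition: Condition,
    rubric: ScoreRubric = ScoreRubric(),
    criteria: FibreCriteria = FibreCriteria(),
) -> ParameterRecord:
    """Derive the full P1-P9 record from a segmented, quantified run."""
    bf_series = [quant["brightfield"][t] for t in run.times if t in quant["brightfield"]]
    fibrin_masks = masks_by_channel["fibrin"]
    scores: dict[tuple[str, int], int] = {}
    for i, t in enumerate(run.times):
        series_to_t = bf_series[: i + 1]
        if t == 0:
            # t = 0 is the blank reference field by construction
            scores[("P4", t)] = 0
            scores[("P5", t)] = 0
            scores[("P6", t)] = 0
            scores[("P8", t)] = 0
            continue
        scores[("P4", t)] = score_morphology(
            quant["brightfield"][t], rubric, run.pixel_size_um
        )
        scores[("P5", t)] = score_aggregation(series_to_t, rubric, run.pixel_size_um)
        scores[("P6", t)] = score_contraction(series_to_t, rubric, run.pixel_size_um)
        fmask = next(m for m in fibrin_masks if m.time_min == t)
        scores[("P8", t)] = score_fibrin(fibre_stats(fmask, criteria), rubric)
    _, p9 = detect_time_to_fibrin(fibrin_masks, criteria)
    return assemble_record(
        subject, surface, condition, quant, scores, p9, provenance="measured",
        seed=run.seed,
    )
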