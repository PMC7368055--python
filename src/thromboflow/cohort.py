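"""Patient-versus-control phenotyping.

Individual patient runs are compared against a reference range built from a
control cohort: per (surface, condition, parameter, time) cell, the control
mean and sample SD on the 0-10 scaled values.  A patient's deviation is
"relevant" only when it falls outside mean +/- SD; relevant changes are
integrated (summed) over time points and surfaces per parameter group
(platelet P1-P2, thrombus P3-P6, fibrin P7-P9), separately for TF-present
and TF-absent runs.  The thrombomodulin effect per subject is the mean
relevance-filtered (no-TM minus TM) difference over the fibrin parameters.
Group comparisons use the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heatmap import scale_rows

__all__ = [
    "ReferenceRange",
    "RelevantChangeMap",
    "PARAMETER_GROUPS",
    "scaled_cell_table",
    "build_reference",
    "patient_changes",
    "integrate_changes",
    "tm_effect",
    "group_compare",
]

#: Disjoint parameter groups covering P1-P9.
PARAMETER_GROUPS: dict[str, tuple[str, ...]] = {
    "platelet": ("P1", "P2"),
    "thrombus": ("P3", "P4", "P5", "P6"),
    "fibrin": ("P7", "P8", "P9"),
}

_CELL_KEYS = ["surface", "tf", "parameter", "time"]


def scaled_cell_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Scale a tidy record table to 0-10 per parameter across all cells.

    Input columns: subject, surface, tf, parameter, time, value (P9 rows
    carry time = NaN).  Each parameter is scaled across every surface x
    condition x time x subject cell of the comparison set, so control and
    patient values share one scale.  Returns the tidy table with a
    ``scaled`` column.
    """
    out = frame.copy()
    out["time"] = out["time"].fillna(-1.0)
    wide = out.pivot_table(
        index="parameter",
        columns=["surface", "tf", "time", "subject"],
        values="value",
        aggfunc="mean",
    )
    scaled = scale_rows(wide).data.stack(list(range(4)), future_stack=True)
    scaled.name = "scaled"
    merged = out.merge(
        scaled.reset_index(),
        on=["parameter", "surface", "tf", "time", "subject"],
        how="left",
    )
    return merged


@dataclass
class ReferenceRange:
    """Control mean and sample SD (n-1) per cell, on the 0-10 scale."""

    table: pd.DataFrame  # index: (surface, tf, parameter, time); cols mean, sd, n

    def align(self, cells: pd.Index) -> pd.DataFrame:
        return self.table.reindex(cells)


def build_reference(scaled_controls: pd.DataFrame) -> ReferenceRange:
    """Build the reference range from scaled control records.

    Input: tidy table with columns subject, surface, tf, parameter, time,
    scaled (from :func:`scaled_cell_table`, controls only).  Every cell must
    carry at least 2 controls.
    """
    grouped = scaled_controls.groupby(_CELL_KEYS)["scaled"]
    table = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    if (table["n"] < 2).any():
        bad = table.index[table["n"] < 2][:3].tolist()
        raise ValueError(f"cells with fewer than 2 controls, e.g. {bad}")
    return ReferenceRange(table)


@dataclass
class RelevantChangeMap:
    """Signed scaled deviations of one patient, zeroed inside mean +/- SD."""

    subject: str
    table: pd.DataFrame  # index cells; cols delta, retained, mean, sd

    def check_invariant(self) -> bool:
        kept = self.table[self.table["retained"] != 0.0]
        return bool((kept["retained"].abs() > kept["sd"] - 1e-12).all())


def patient_changes(
    scaled_patient: pd.DataFrame, ref: ReferenceRange
) -> RelevantChangeMap:
    """Relevance-filtered deviation map for one patient.

    delta = patient scaled value - control mean; retained iff |delta| > SD.
    Positive retained values are relevant increases (red by the heatmap
    convention), negative relevant decreases (green).  Cells missing from
    the reference are excluded.
    """
    subjects = scaled_patient["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("patient_changes expects a single patient's records")
    cells = scaled_patient.groupby(_CELL_KEYS)["scaled"].mean()
    aligned = ref.align(cells.index)
    keep = aligned["mean"].notna()
    cells, aligned = cells[keep.to_numpy()], aligned[keep.to_numpy()]
    delta = cells - aligned["mean"]
    retained = delta.where(delta.abs() > aligned["sd"], 0.0)
    table = pd.DataFrame(
        {"delta": delta, "retained": retained, "mean": aligned["mean"], "sd": aligned["sd"]}
    )
    return RelevantChangeMap(str(subjects[0]), table)


def integrate_changes(
    change_map: RelevantChangeMap,
    groups: dict[str, tuple[str, ...]] = PARAMETER_GROUPS,
    surfaces: list[str] | None = None,
    how: str = "sum",
) -> pd.DataFrame:
    """Cumulative relevant changes per parameter group and TF stratum.

    Sums (default; optionally means) the retained signed deviations over all
    time points and the selected surfaces, for each parameter group,
    reporting TF-present and TF-absent strata separately.  Additive over
    disjoint surface subsets by construction.
    """
    covered = sorted(p for ps in groups.values() for p in ps)
    if len(covered) != len(set(covered)):
        raise ValueError("parameter groups must be disjoint")
    t = change_map.table.reset_index()
    if surfaces is not None:
        t = t[t["surface"].isin(surfaces)]
    rows = []
    for tf_present, strat in t.groupby("tf"):
        for group, params in groups.items():
            vals = strat.loc[strat["parameter"].isin(params), "retained"]
            agg = float(vals.sum()) if how == "sum" else float(vals.mean()) if len(vals) else 0.0
            rows.append(
                {
                    "subject": change_map.subject,
                    "group": group,
                    "tf": bool(tf_present),
                    "value": agg,
                    "n_cells": int((vals != 0).sum()),
                }
            )
    return pd.DataFrame(rows)


def tm_effect(
    scaled_records: pd.DataFrame,
    ref_sd: pd.DataFrame | None = None,
    fibrin_params: tuple[str, ...] = PARAMETER_GROUPS["fibrin"],
    no_tm_surface: str = "M6",
    tm_surface: str = "M8",
) -> pd.DataFrame:
    """Mean thrombomodulin effect on fibrin parameters, per subject.

    Pairs each subject's runs on the TM-co-coated collagen-I surface against
    the matching plain collagen-I surface and averages the (no-TM - TM)
    scaled difference over the fibrin parameters and time points; a relevance
    band per (parameter, time) may be supplied to zero sub-SD differences.
    Positive values mean TM suppressed fibrin formation.  Subjects missing
    either surface raise.
    """
    recs = scaled_records[scaled_records["parameter"].isin(fibrin_params)]
    rows = []
    for subject, grp in recs.groupby("subject"):
        a = grp[grp["surface"] == no_tm_surface]
        b = grp[grp["surface"] == tm_surface]
        if a.empty or b.empty:
            raise ValueError(f"subject {subject!r} lacks paired TM runs")
        keys = ["parameter", "time"]
        pa = a.groupby(keys)["scaled"].mean()
        pb = b.groupby(keys)["scaled"].mean()
        common = pa.index.intersection(pb.index)
        diff = pa.loc[common] - pb.loc[common]
        if ref_sd is not None:
            sd = ref_sd.reindex(common)["sd"].fillna(0.0)
            diff = diff.where(diff.abs() > sd, 0.0)
        rows.append({"subject": subject, "tm_effect": float(diff.mean())})
    return pd.DataFrame(rows)


def tm_reference_band(
    scaled_records: pd.DataFrame,
    control_subjects: list[str],
    fibrin_params: tuple[str, ...] = PARAMETER_GROUPS["fibrin"],
    no_tm_surface: str = "M6",
    tm_surface: str = "M8",
) -> pd.DataFrame:
    """Per-cell SD of the control (no-TM - TM) scaled difference.

    Used as the relevance band for :func:`tm_effect`: patient differences
    within the control replication noise are not counted as a TM response.
    """
    recs = scaled_records[
        scaled_records["parameter"].isin(fibrin_params)
        & scaled_records["subject"].isin(control_subjects)
    ]
    keys = ["parameter", "time"]
    diffs = []
    for subject, grp in recs.groupby("subject"):
        pa = grp[grp["surface"] == no_tm_surface].groupby(keys)["scaled"].mean()
        pb = grp[grp["surface"] == tm_surface].groupby(keys)["scaled"].mean()
        common = pa.index.intersection(pb.index)
        diffs.append((pa.loc[common] - pb.loc[common]).rename(subject))
    table = pd.concat(diffs, axis=1)
    return pd.DataFrame({"sd": table.std(axis=1, ddof=1)})


def group_compare(values_a, values_b) -> float:
    """Two-sided Mann-Whitney U p-value for two independent groups.

    Exact rank enumeration for small untied samples, normal approximation
    with tie correction otherwise; fully tied data return p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    small = a.size <= 8 and b.size <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
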