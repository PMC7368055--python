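"""Modelling layer: kNN imputation, platelet-contribution regression,
8-class condition prediction with a classifier roster, and FDR-corrected
classifier comparisons.

Each flow run contributes 41 features (P1-P8 at five times plus P9); the
condition class is the (TF, iFVIIa, CTI) triple encoded 0..7.  Per surface,
every classifier in a roster of distinct model families is evaluated by
leave-one-out cross-validation (each fold retrained from scratch); surface
pairs are compared by paired two-sided t-tests across the roster with
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "PredictionReport",
    "default_roster",
    "feature_table_from_records",
    "impute_missing",
    "platelet_contribution",
    "classify_conditions",
    "compare_classifiers",
]


@dataclass
class FeatureTable:
    """Run-by-feature matrix with class labels and metadata.

    ``features`` holds the numeric P1-P9-over-time columns (NaN = missing);
    ``meta`` carries subject / surface / condition class per row.
    """

    features: pd.DataFrame
    meta: pd.DataFrame  # columns: subject, surface, condition_class

    def __post_init__(self) -> None:
        if len(self.features) != len(self.meta):
            raise ValueError("features and meta must align row-wise")
        classes = self.meta["condition_class"]
        if not classes.between(0, 7).all():
            raise ValueError("condition classes must be in 0..7")


def feature_table_from_records(records) -> FeatureTable:
    """Flatten parameter records into one 41-feature row per flow run."""
    from .registry import CAPTURE_TIMES, condition_class

    rows, meta = [], []
    for rec in records:
        row = {
            f"{pid}_t{t}": rec.values.get((pid, t), np.nan)
            for pid in rec.TIMED_PARAMETERS
            for t in CAPTURE_TIMES
        }
        row["P9"] = np.nan if rec.p9 is None else rec.p9
        rows.append(row)
        meta.append(
            {
                "subject": rec.subject,
                "surface": rec.surface,
                "condition_class": condition_class(rec.condition),
            }
        )
    return FeatureTable(pd.DataFrame(rows), pd.DataFrame(meta))


# --------------------------------------------------------------------------
# kNN imputation


def impute_missing(table: FeatureTable, k: int = 3) -> FeatureTable:
    """Impute missing cells from the k nearest rows (Euclidean distance on
    co-observed features, mean-square-normalized by feature count).

    A missing cell becomes the mean of that feature over the k nearest rows
    that observe it; distance ties break deterministically toward the lowest
    row index.  A feature missing in every row raises.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = table.features.to_numpy(dtype=float).copy()
    missing = np.isnan(x)
    if not missing.any():
        return table
    if missing.all(axis=0).any():
        bad = table.features.columns[missing.all(axis=0)].tolist()
        raise ValueError(f"features missing in every row: {bad}")
    if missing.all(axis=1).any():
        raise ValueError("a row with no observed features cannot be imputed")

    n = x.shape[0]
    filled = x.copy()
    for i in range(n):
        cols = np.where(missing[i])[0]
        if cols.size == 0:
            continue
        dists = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            shared = ~missing[i] & ~missing[j]
            if not shared.any():
                continue
            d = x[i, shared] - x[j, shared]
            dists[j] = float(np.sqrt(np.mean(d * d)))
        order = np.argsort(dists, kind="stable")  # stable sort = lowest-index ties
        for c in cols:
            donors = [j for j in order if np.isfinite(dists[j]) and not missing[j, c]]
            if not donors:
                col_mean = float(np.nanmean(x[:, c]))
                filled[i, c] = col_mean
                continue
            filled[i, c] = float(np.mean(x[donors[:k], c]))
    features = pd.DataFrame(
        filled, columns=table.features.columns, index=table.features.index
    )
    return FeatureTable(features, table.meta.copy())


# --------------------------------------------------------------------------
# platelet contribution regression


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    """R^2 of an OLS fit of y on x (with intercept)."""
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def platelet_contribution(
    frame: pd.DataFrame,
    targets: tuple[str, ...] = ("P3", "P4", "P5", "P6", "P7", "P8", "P9"),
    min_runs: int = 5,
    unstable_r2: float = 0.05,
) -> pd.DataFrame:
    """Contribution of the platelet parameters P1 and P2 to each outcome.

    For each target parameter (and time where applicable), a linear model on
    {P1, P2} at the same time point is compared with the single-predictor
    models; the contribution of Pi is R^2(Pi alone) / R^2(full) x 100,
    floored at 0 and capped at 100.  Cells with a zero-variance target are
    reported missing; near-zero full-model R^2 flags the ratio unstable.

    *frame* is a run-per-row table with columns P1_t{t}.. (as produced by
    :func:`feature_table_from_records`, features joined with meta).
    """
    rows = []
    times = sorted(
        {int(c.split("_t")[1]) for c in frame.columns if c.startswith("P1_t")}
    )
    if len(frame) < min_runs:
        raise ValueError(f"need at least {min_runs} runs")
    for target in targets:
        cols = (
            [f"{target}_t{t}" for t in times if f"{target}_t{t}" in frame]
            if target != "P9"
            else (["P9"] if "P9" in frame else [])
        )
        for col in cols:
            t = int(col.split("_t")[1]) if "_t" in col else None
            p1 = frame[f"P1_t{t}" if t is not None else f"P1_t{times[-1]}"].to_numpy(float)
            p2 = frame[f"P2_t{t}" if t is not None else f"P2_t{times[-1]}"].to_numpy(float)
            y = frame[col].to_numpy(float)
            if np.std(y) == 0:
                rows.append(
                    {"target": target, "time": t, "p1_pct": np.nan, "p2_pct": np.nan,
                     "r2_full": np.nan, "unstable": True}
                )
                continue
            r2_full = _r2(y, np.column_stack([p1, p2]))
            r2_p1 = _r2(y, p1[:, None]) if np.std(p1) > 0 else 0.0
            r2_p2 = _r2(y, p2[:, None]) if np.std(p2) > 0 else 0.0
            unstable = not np.isfinite(r2_full) or r2_full < unstable_r2
            if r2_full and r2_full > 0:
                c1 = float(np.clip(r2_p1 / r2_full * 100.0, 0.0, 100.0))
                c2 = float(np.clip(r2_p2 / r2_full * 100.0, 0.0, 100.0))
            else:
                c1 = c2 = np.nan
            rows.append(
                {"target": target, "time": t, "p1_pct": c1, "p2_pct": c2,
                 "r2_full": r2_full, "unstable": unstable}
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# condition classification


def default_roster(seed: int = 0) -> dict[str, Callable[[], object]]:
    """Roster of classifier families for condition prediction.

    Distance/margin-based members are wrapped with training-fold-only
    standardization; tree ensembles get per-classifier fixed seeds derived
    from ``seed`` so reruns are exact.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    return {
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seeds[0]),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seeds[1]
        ),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seeds[2]),
        "naive_bayes": lambda: GaussianNB(),
        "logistic": lambda: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=500, random_state=seeds[3])
        ),
        "ridge": lambda: make_pipeline(StandardScaler(), RidgeClassifier()),
        "svm_rbf": lambda: make_pipeline(StandardScaler(), SVC(random_state=seeds[4])),
        "svm_linear": lambda: make_pipeline(
            StandardScaler(), SVC(kernel="linear", random_state=seeds[5])
        ),
        "knn": lambda: make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=3)
        ),
    }


@dataclass
class PredictionReport:
    """LOOCV accuracies per surface x classifier, plus comparison p-values."""

    accuracies: pd.DataFrame  # index surface, columns classifier, values in [0,1]
    skipped_runs: dict[str, int] = field(default_factory=dict)
    comparisons: pd.DataFrame | None = None

    def mean_accuracy(self) -> pd.Series:
        return self.accuracies.mean(axis=1)


def _loocv_accuracy(
    x: np.ndarray, y: np.ndarray, make_clf: Callable[[], object]
) -> tuple[float, int]:
    """Leave-one-out accuracy; folds whose class appears once are counted
    as unpredictable (wrong), returned as the skipped count."""
    n = len(y)
    counts = pd.Series(y).value_counts()
    correct = 0
    skipped = 0
    for i in range(n):
        if counts[y[i]] < 2:
            skipped += 1
            continue  # counted as unpredictable below
        train = np.ones(n, dtype=bool)
        train[i] = False
        clf = make_clf()
        clf.fit(x[train], y[train])
        if clf.predict(x[i : i + 1])[0] == y[i]:
            correct += 1
    return correct / n, skipped


def classify_conditions(
    table: FeatureTable,
    roster: dict[str, Callable[[], object]] | None = None,
    seed: int = 0,
) -> PredictionReport:
    """Per-surface LOOCV accuracy of condition-class prediction.

    Every fold retrains the classifier from scratch; runs whose class has a
    single representative are flagged and counted as unpredictable.  Requires
    a roster of at least 2 classifier families.
    """
    roster = roster or default_roster(seed)
    if len(roster) < 2:
        raise ValueError("roster must contain at least 2 classifier families")
    if table.features.isna().any().any():
        raise ValueError("impute missing values before classification")
    acc_rows = {}
    skipped_all: dict[str, int] = {}
    for surface, idx in table.meta.groupby("surface").groups.items():
        x = table.features.loc[idx].to_numpy(float)
        y = table.meta.loc[idx, "condition_class"].to_numpy()
        counts = pd.Series(y).value_counts()
        if (counts >= 2).sum() < 2:
            raise ValueError(f"surface {surface!r} needs >= 2 runs in >= 2 classes")
        accs = {}
        skipped = 0
        for name, make_clf in roster.items():
            accs[name], skipped = _loocv_accuracy(x, y, make_clf)
        acc_rows[surface] = accs
        if skipped:
            skipped_all[str(surface)] = skipped
    return PredictionReport(pd.DataFrame(acc_rows).T.sort_index(), skipped_all)


def compare_classifiers(report: PredictionReport, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise surface comparisons of roster accuracies with FDR control.

    Paired two-sided t-test across the classifier roster for every surface
    pair; Benjamini-Hochberg adjustment across all pairs.  Identical
    accuracy vectors have an undefined t and report p = 1 (flagged).
    """
    surfaces = list(report.accuracies.index)
    if report.accuracies.shape[1] < 2:
        raise ValueError("need accuracies from at least 2 classifiers")
    rows = []
    for i, a in enumerate(surfaces):
        for b in surfaces[i + 1 :]:
            va = report.accuracies.loc[a].to_numpy(float)
            vb = report.accuracies.loc[b].to_numpy(float)
            degenerate = bool(np.allclose(va, vb)) or np.std(va - vb) == 0
            if degenerate:
                p = 1.0
                t = np.nan
            else:
                t, p = stats.ttest_rel(va, vb)
            rows.append(
                {"surface_a": a, "surface_b": b, "t": t, "p_raw": float(p),
                 "degenerate": degenerate}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = multipletests(out["p_raw"], alpha=alpha, method="fdr_bh")[1]
    report.comparisons = out
    return out
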