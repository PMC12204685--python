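"""Probing trained models: what do they actually use?

* Permutation importance over ISI bins: for the units of one class, shuffle
  a single histogram bin across units and measure the increase in the
  model's error on that class (error = 1 - class sensitivity by default).
  Informative bins raise the error when destroyed; uninformative ones do
  not.
* Permutation importance over stimulus conditions: the same idea for the
  concatenated-PSTH model, shuffling a condition's whole 30-bin block as a
  unit.
* Duration sensitivity: truncate each test unit's spike train to
  progressively shorter windows, re-featurize, and track per-class
  sensitivity — how much data does the decoder need?
* ISI-window statistics: per-unit mean/variance of raw ISIs inside a time
  window plus the OLS slope of the normalized ISI histogram there, compared
  between one class and all others with Bonferroni-corrected t-tests and
  absolute Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import Dataset, compute_isis
from .features import FeatureConfig, FeatureMatrix, isi_bin_edges, isi_distribution

__all__ = [
    "ImportanceProfile",
    "WindowStats",
    "permutation_importance_bins",
    "permutation_importance_conditions",
    "importance_profile",
    "duration_sensitivity",
    "isi_window_stats",
    "compare_window_stats",
]


def _class_error(model, X, y, class_label, metric: str = "sensitivity") -> float:
    """Model error restricted to units of one class."""
    pred = model.predict(X)
    if metric == "sensitivity":
        return 1.0 - float(np.mean(pred == class_label))
    if metric == "accuracy":
        return 1.0 - float(np.mean(pred == np.asarray(y)))
    raise ValueError(f"unknown error metric {metric!r}")


def _permute_columns(X, cols, rng) -> np.ndarray:
    """Shuffle the given column block jointly across rows."""
    Xp = X.copy()
    perm = rng.permutation(X.shape[0])
    Xp[:, cols] = X[np.ix_(perm, cols)]
    return Xp


def _importance(model, X, y, class_label, cols, n_reps, rng,
                error_metric) -> tuple[float, float]:
    """Shuffle ``cols`` across *all* test units; score the class subset.

    Mixing values from every class is what destroys class-specific
    information in the feature — a within-class shuffle would preserve the
    class marginal and report no importance even for a perfectly
    informative bin.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    mask = y == class_label
    if not mask.any():
        raise ValueError(f"class {class_label!r} absent from the test set")
    baseline = _class_error(model, X[mask], y[mask], class_label, error_metric)
    deltas = np.empty(n_reps)
    for r in range(n_reps):
        Xp = _permute_columns(X, cols, rng)
        deltas[r] = _class_error(model, Xp[mask], y[mask], class_label,
                                 error_metric) - baseline
    return float(deltas.mean()), float(deltas.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0


def permutation_importance_bins(
    model, X_test, y_test, class_label, bin_index: int,
    n_reps: int = 100, seed: int = 0, error_metric: str = "sensitivity",
) -> float:
    """Importance of one ISI-distribution bin for one class.

    Mean over repetitions of (permuted error - baseline error) on the test
    units of ``class_label``; each repetition shuffles the bin's values
    across those units.
    """
    X = np.asarray(X_test, float)
    if not 0 <= bin_index < X.shape[1]:
        raise IndexError(f"bin_index {bin_index} out of range [0, {X.shape[1]})")
    rng = np.random.default_rng(seed)
    mean, _ = _importance(model, X, y_test, class_label, [bin_index],
                          n_reps, rng, error_metric)
    return mean


def permutation_importance_conditions(
    model, X_test, y_test, class_label, condition, feature_matrix: FeatureMatrix,
    n_reps: int = 100, seed: int = 0, error_metric: str = "sensitivity",
) -> float:
    """Importance of one grating condition block in a concatenated-PSTH model."""
    conds = feature_matrix.meta.get("conditions")
    bpc = feature_matrix.meta.get("bins_per_condition")
    if conds is None or bpc is None:
        raise ValueError("feature matrix lacks concatenated-PSTH condition metadata")
    condition = (float(condition[0]), float(condition[1]))
    if condition not in conds:
        raise ValueError(f"unknown condition {condition!r}")
    k = conds.index(condition)
    cols = list(range(k * bpc, (k + 1) * bpc))
    rng = np.random.default_rng(seed)
    mean, _ = _importance(model, X_test, y_test, class_label, cols,
                          n_reps, rng, error_metric)
    return mean


@dataclass(frozen=True)
class ImportanceProfile:
    """Per (feature-or-condition, class) importance mean and SEM."""

    axis: str  # 'isi_bin' or 'stimulus_condition'
    table: pd.DataFrame  # columns: class_label, feature, importance, sem

    def for_class(self, class_label) -> pd.DataFrame:
        return self.table[self.table["class_label"] == class_label]


def importance_profile(
    model, X_test, y_test, feature_matrix: FeatureMatrix,
    axis: str = "isi_bin", class_labels=None, n_reps: int = 100,
    seed: int = 0, error_metric: str = "sensitivity",
) -> ImportanceProfile:
    """Full importance profile over all bins (or conditions) and classes.

    Shuffles use independent sub-streams per (feature, repetition) spawned
    from the master seed, so profiles are reproducible and features
    independent.
    """
    X = np.asarray(X_test, float)
    y = np.asarray(y_test)
    if class_labels is None:
        class_labels = sorted(set(y))
    if axis == "isi_bin":
        col_groups = [(i, [i]) for i in range(X.shape[1])]
    elif axis == "stimulus_condition":
        conds = feature_matrix.meta["conditions"]
        bpc = feature_matrix.meta["bins_per_condition"]
        col_groups = [
            (c, list(range(k * bpc, (k + 1) * bpc))) for k, c in enumerate(conds)
        ]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    master = np.random.default_rng(seed)
    rows = []
    for cls in class_labels:
        for name, cols in col_groups:
            rng = np.random.default_rng(master.integers(2**31 - 1))
            mean, sem = _importance(model, X, y, cls, cols, n_reps, rng, error_metric)
            rows.append({"class_label": cls, "feature": name,
                         "importance": mean, "sem": sem})
    return ImportanceProfile(axis, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# duration sensitivity
# ---------------------------------------------------------------------------

def duration_sensitivity(
    model, ds: Dataset, unit_ids, y_true, durations,
    cfg: FeatureConfig | None = None,
    stimulus: str = "drifting_gratings",
    t0: float | None = None,
) -> pd.DataFrame:
    """Per-class sensitivity when tested on truncated spike trains.

    For each duration ``d``, test units keep only spikes in ``[t0, t0+d)``
    (``t0`` defaults to the start of the stimulus block), ISI-distribution
    features are recomputed and per-class sensitivity (true positive rate)
    is reported.  Durations longer than the block use all of it and are
    flagged in the output.
    """
    cfg = cfg or FeatureConfig()
    durations = list(durations)
    if any(d <= 0 for d in durations):
        raise ValueError("durations must be positive")
    start, stop = ds.stimuli.span(stimulus)
    if t0 is None:
        t0 = start
    y_true = pd.Series(np.asarray(y_true), index=list(unit_ids))
    classes = sorted(y_true.unique())
    units = {u.unit_id: u for u in ds.units}
    rows = []
    for d in durations:
        hi = min(t0 + d, stop)
        truncated = d > stop - t0
        feats, kept = [], []
        for uid in unit_ids:
            isis = compute_isis(units[uid].spike_times_s, (t0, hi))
            feats.append(isi_distribution(isis, cfg))
            kept.append(uid)
        pred = model.predict(np.vstack(feats))
        pred = pd.Series(pred, index=kept)
        for cls in classes:
            in_cls = y_true[y_true == cls].index
            sens = float(np.mean(pred.loc[in_cls] == cls))
            rows.append({"duration_s": d, "class_label": cls,
                         "sensitivity": sens, "truncated_to_available": truncated})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ISI-window statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowStats:
    """Per-unit mean/variance of raw ISIs and histogram slope in a window."""

    window: tuple[float, float]
    table: pd.DataFrame  # index unit_id; columns mean_s, variance_s2, slope


def isi_window_stats(
    ds: Dataset, window: tuple[float, float],
    cfg: FeatureConfig | None = None,
    stimulus: str = "drifting_gratings",
) -> WindowStats:
    """Mean, variance and histogram slope of each unit's ISIs in ``window``.

    Mean and variance are of the raw ISIs falling in the (half-open) window.
    Slope is the OLS slope of the unit's min-max-normalized ISI histogram
    against bin centers, over the bins inside the window.  Units with no
    in-window ISIs are excluded.
    """
    cfg = cfg or FeatureConfig()
    lo, hi = window
    if not (cfg.isi_min_s <= lo < hi <= cfg.isi_max_s):
        raise ValueError("window must lie within the histogram support")
    edges = isi_bin_edges(cfg)
    centers = (edges[:-1] + edges[1:]) / 2
    inwin_bins = (centers >= lo) & (centers < hi)
    span = ds.stimuli.span(stimulus)
    rows = {}
    for u in ds.units:
        isis = compute_isis(u.spike_times_s, span)
        sel = isis[(isis >= lo) & (isis < hi)]
        if sel.size == 0:
            continue
        hist = isi_distribution(isis, cfg)
        slope = float(
            stats.linregress(centers[inwin_bins], hist[inwin_bins]).slope
        ) if inwin_bins.sum() >= 2 else np.nan
        rows[u.unit_id] = {
            "mean_s": float(sel.mean()),
            "variance_s2": float(sel.var(ddof=1)) if sel.size > 1 else 0.0,
            "slope": slope,
        }
    return WindowStats(window, pd.DataFrame.from_dict(rows, orient="index"))


def compare_window_stats(
    ws: WindowStats, labels: pd.Series, class_label,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Class-vs-rest t-tests with Bonferroni correction and |Cohen's d|.

    One two-sample t-test per statistic (mean, variance, slope); corrected
    significance threshold is ``alpha / m`` for the m comparisons.  Cohen's
    d uses the pooled SD and is reported as NaN when degenerate.
    """
    df = ws.table.join(labels.rename("class_label"), how="inner")
    a = df[df["class_label"] == class_label]
    b = df[df["class_label"] != class_label]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 units on each side of the contrast")
    stats_cols = ["mean_s", "variance_s2", "slope"]
    m = len(stats_cols)
    rows = []
    for col in stats_cols:
        x, y = a[col].dropna(), b[col].dropna()
        t, p = stats.ttest_ind(x, y, equal_var=True)
        pooled = np.sqrt(
            ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
            / (len(x) + len(y) - 2)
        )
        d = abs(x.mean() - y.mean()) / pooled if pooled > 0 else np.nan
        rows.append({
            "statistic": col,
            "t": float(t),
            "p": float(p),
            "p_bonferroni": min(1.0, float(p) * m),
            "significant": float(p) < alpha / m,
            "abs_cohens_d": float(d) if np.isfinite(d) else np.nan,
        })
    return pd.DataFrame(rows)
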