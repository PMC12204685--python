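"""Electrode-consensus smoothing and hierarchical localization.

Classifier probabilities are per unit, but anatomy is spatially contiguous
along a probe: if a unit's neighbours on nearby electrodes are confidently
hippocampal, an isolated "thalamus" call is probably a stochastic error.
Smoothing exploits this by (1) averaging class probabilities over the units
of each occupied electrode and (2) replacing each electrode's vector with a
Gaussian-weighted convex combination of the occupied electrodes of the same
probe (weights are normal pdfs of electrode-index distance with standard
deviation ``sigma``, renormalized over occupied electrodes).  Units inherit
their electrode's smoothed vector; winner-take-all labels are re-derived.

Probes are never smoothed into each other, and unoccupied electrodes take
no part in either weighting or targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .metrics import balanced_accuracy
from .models import ProbabilityTable

__all__ = [
    "SmoothingConfig",
    "SmoothedPrediction",
    "electrode_probabilities",
    "gaussian_smooth",
    "smooth_unit_probabilities",
    "tune_smoothing_sigma",
    "ProbeGaussianSmoother",
    "hierarchical_classify",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Gaussian kernel width, in electrode-index units."""

    sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class SmoothedPrediction:
    """Smoothed per-electrode and inherited per-unit probability vectors."""

    class_labels: tuple[str, ...]
    electrode_probs: pd.DataFrame  # index (probe_id, electrode_index)
    unit_probs: ProbabilityTable

    @property
    def unit_labels(self) -> np.ndarray:
        return self.unit_probs.predicted_labels


def _unit_sites(units) -> pd.DataFrame:
    rows = [
        {"unit_id": u.unit_id, "probe_id": u.probe_id,
         "electrode_index": u.electrode_index}
        for u in units
    ]
    return pd.DataFrame(rows).set_index("unit_id")


def electrode_probabilities(pt: ProbabilityTable, units) -> pd.DataFrame:
    """Mean probability vector of each occupied (probe, electrode) site.

    Electrodes with no units simply do not appear.
    """
    sites = _unit_sites(units).loc[list(pt.unit_ids)]
    df = pt.to_frame()
    df["probe_id"] = sites["probe_id"].values
    df["electrode_index"] = sites["electrode_index"].values
    out = df.groupby(["probe_id", "electrode_index"]).mean()
    return out[list(pt.class_labels)]


def gaussian_smooth(electrode_probs: pd.DataFrame,
                    cfg: SmoothingConfig) -> pd.DataFrame:
    """Gaussian-kernel smoothing of per-electrode vectors within each probe.

    For target electrode e, occupied electrode e' gets weight
    ``pdf(e' ; mean=e, sd=sigma)``; the smoothed vector is the weight-
    normalized sum.  Exactly preserves the probability simplex.
    """
    pieces = []
    for probe, block in electrode_probs.groupby(level="probe_id", sort=False):
        e = block.index.get_level_values("electrode_index").to_numpy(float)
        P = block.to_numpy(float)
        W = norm.pdf(e[None, :], loc=e[:, None], scale=cfg.sigma)
        W /= W.sum(axis=1, keepdims=True)
        pieces.append(pd.DataFrame(W @ P, index=block.index, columns=block.columns))
    return pd.concat(pieces)


def smooth_unit_probabilities(pt: ProbabilityTable, units,
                              cfg: SmoothingConfig) -> SmoothedPrediction:
    """Average per electrode, smooth along each probe, re-assign to units."""
    ep = electrode_probabilities(pt, units)
    smoothed = gaussian_smooth(ep, cfg)
    sites = _unit_sites(units).loc[list(pt.unit_ids)]
    idx = pd.MultiIndex.from_arrays(
        [sites["probe_id"], sites["electrode_index"]],
        names=["probe_id", "electrode_index"],
    )
    unit_vals = smoothed.loc[idx].to_numpy(float)
    unit_pt = ProbabilityTable(
        pt.unit_ids, pt.class_labels,
        unit_vals / unit_vals.sum(axis=1, keepdims=True),
    )
    return SmoothedPrediction(pt.class_labels, smoothed, unit_pt)


def tune_smoothing_sigma(
    pt: ProbabilityTable,
    units,
    val_labels: pd.Series,
    sigma_range: tuple[float, float] = (0.5, 50.0),
    budget: int = 20,
    seed: int = 0,
) -> tuple[SmoothingConfig, pd.DataFrame]:
    """Pick the kernel width maximizing validation balanced accuracy.

    ``pt`` holds probabilities for every unit taking part in the consensus;
    ``val_labels`` (unit_id -> class) names the held-out units the candidate
    widths are scored on.  Candidates are log-spaced over ``sigma_range``
    with seeded jitter; the search log is returned alongside the winner.
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log(sigma_range[0]), np.log(sigma_range[1])
    base = np.linspace(lo, hi, budget)
    jitter = rng.uniform(-0.5, 0.5, size=budget) * (hi - lo) / max(budget - 1, 1)
    sigmas = np.exp(np.clip(base + jitter, lo, hi))
    val_ids = [u for u in pt.unit_ids if u in val_labels.index]
    y_val = val_labels.loc[val_ids]
    trials = []
    best_sigma, best_score = None, -np.inf
    for s in sigmas:
        sp = smooth_unit_probabilities(pt, units, SmoothingConfig(float(s)))
        pred = sp.unit_probs.subset(val_ids).predicted_labels
        score = balanced_accuracy(y_val, pred)
        trials.append({"sigma": float(s), "objective": score})
        if score > best_score:
            best_sigma, best_score = float(s), score
    return SmoothingConfig(best_sigma), pd.DataFrame(trials)


class ProbeGaussianSmoother:
    """Estimator-style wrapper: ``fit`` tunes sigma, ``transform`` smooths."""

    def __init__(self, sigma: float | None = None,
                 sigma_range: tuple[float, float] = (0.5, 50.0),
                 budget: int = 20, seed: int = 0):
        self.sigma = sigma
        self.sigma_range = sigma_range
        self.budget = budget
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"sigma": self.sigma, "sigma_range": self.sigma_range,
                "budget": self.budget, "seed": self.seed}

    def set_params(self, **params) -> "ProbeGaussianSmoother":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, pt: ProbabilityTable, units, val_labels=None) -> "ProbeGaussianSmoother":
        if self.sigma is not None:
            self.config_ = SmoothingConfig(self.sigma)
        else:
            if val_labels is None:
                raise ValueError("tuning sigma requires validation labels")
            self.config_, self.trials_ = tune_smoothing_sigma(
                pt, units, val_labels, self.sigma_range, self.budget, self.seed
            )
        return self

    def transform(self, pt: ProbabilityTable, units) -> SmoothedPrediction:
        return smooth_unit_probabilities(pt, units, self.config_)


def hierarchical_classify(
    region_probs: ProbabilityTable | SmoothedPrediction,
    structure_probs: dict[str, ProbabilityTable | SmoothedPrediction],
    terminal_regions: tuple[str, ...] = ("midbrain",),
) -> pd.Series:
    """Two-stage labels: region winner routes each unit to a structure model.

    ``structure_probs`` maps region -> (smoothed) structure probabilities for
    at least the units routed to that region.  Regions without structure
    subdivision (midbrain) are terminal: the region name itself is the final
    label.  On the canonical atlas this yields the 19-label output
    (18 structures + midbrain).
    """
    if isinstance(region_probs, SmoothedPrediction):
        region_probs = region_probs.unit_probs
    region_winner = pd.Series(region_probs.predicted_labels,
                              index=list(region_probs.unit_ids))
    out = {}
    for region in region_probs.class_labels:
        routed = region_winner[region_winner == region].index
        if len(routed) == 0:
            continue
        if region in terminal_regions:
            for u in routed:
                out[u] = region
            continue
        sp = structure_probs.get(region)
        if sp is None:
            raise ValueError(f"no structure model for region {region!r}")
        if isinstance(sp, SmoothedPrediction):
            sp = sp.unit_probs
        winner = pd.Series(sp.predicted_labels, index=list(sp.unit_ids))
        missing = [u for u in routed if u not in winner.index]
        if missing:
            raise ValueError(
                f"structure probabilities for region {region!r} missing "
                f"{len(missing)} routed units"
            )
        for u in routed:
            out[u] = winner[u]
    return pd.Series(out, name="hierarchical_label").loc[list(region_probs.unit_ids)]
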