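"""Spike-train representations.

Three featurizations of a unit's spike train are supported:

``metrics14``
    Fourteen classical spike-timing metrics: CV2, LV, LVR, mean firing rate,
    SD / CV / min / median / max of the interspike intervals, and the five
    periodogram band-power ratios (delta 0.1-4 Hz, theta 4-8, alpha 8-12,
    beta 12-40, gamma 40-100).
``isi_dist``
    The binned ISI distribution over [0, 3) s (default 300 bins of 10 ms),
    min-max normalized per unit.
``avg_psth`` / ``cat_psth``
    The trial-averaged peristimulus time histogram over the 3 s
    drifting-grating trial (1 s gray + 2 s stimulus), either averaged over
    all trials (100 bins) or computed per condition (30 bins each) and
    concatenated over the 40 orientation x frequency conditions (1200
    features).  Min-max normalization is per unit, and for the concatenated
    variant per condition block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft

from .datasets import (
    ORIENTATIONS_DEG,
    TEMPORAL_FREQUENCIES_HZ,
    Dataset,
    StimulusEpochTable,
    UnitRecord,
    compute_isis,
)

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "REPRESENTATIONS",
    "METRIC_NAMES",
    "local_variation_stats",
    "psd_band_features",
    "metrics14",
    "isi_distribution",
    "average_psth",
    "concatenated_psth",
    "featurize",
    "SpikeFeaturizer",
]

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("metrics14", "isi_dist", "avg_psth", "cat_psth")

#: Refractoriness constant of the revised local variation, seconds.
LVR_REFRACTORINESS_S = 0.005

METRIC_NAMES = (
    "cv2",
    "lv",
    "lvr",
    "firing_rate_hz",
    "isi_sd_s",
    "isi_cv",
    "isi_min_s",
    "isi_median_s",
    "isi_max_s",
    "psd_delta",
    "psd_theta",
    "psd_alpha",
    "psd_beta",
    "psd_gamma",
)


class UnfeaturizableUnit(ValueError):
    """Unit has too few in-window spikes for the requested representation."""


@dataclass(frozen=True)
class FeatureConfig:
    isi_bins: int = 300
    isi_min_s: float = 0.0
    isi_max_s: float = 3.0
    psth_pre_s: float = 1.0
    psth_post_s: float = 2.0
    avg_psth_bins: int = 100
    cat_psth_bins_per_condition: int = 30
    psd_bin_ms: float = 1.0
    psd_bands_hz: tuple = ((0.1, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 40.0), (40.0, 100.0))
    min_spikes: int = 3

    def __post_init__(self) -> None:
        if min(self.isi_bins, self.avg_psth_bins, self.cat_psth_bins_per_condition) < 1:
            raise ValueError("bin counts must be >= 1")
        if self.isi_max_s <= self.isi_min_s:
            raise ValueError("isi_max_s must exceed isi_min_s")
        los = [b[0] for b in self.psd_bands_hz]
        his = [b[1] for b in self.psd_bands_hz]
        if any(h <= l for l, h in zip(los, his)) or max(his) > 100.0 + 1e-12:
            raise ValueError("psd bands must be well-formed and <= 100 Hz")

    @property
    def trial_duration_s(self) -> float:
        return self.psth_pre_s + self.psth_post_s


@dataclass(frozen=True)
class FeatureMatrix:
    """Units x features under one named representation."""

    representation: str
    unit_ids: tuple[str, ...]
    values: np.ndarray
    feature_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.unit_ids), len(self.feature_names)):
            raise ValueError("values shape does not match unit_ids x feature_names")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.unit_ids),
                            columns=list(self.feature_names))


def _minmax(v: np.ndarray) -> np.ndarray:
    """Per-vector min-max scaling; a constant vector maps to all-zeros."""
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# timing metrics
# ---------------------------------------------------------------------------

def local_variation_stats(isis) -> tuple[float, float, float]:
    """CV2, LV and LVR of an ISI sequence (needs >= 2 intervals).

    All three compare consecutive interval pairs and are 0 for perfectly
    regular trains and about 1 for Poisson-like trains; LVR corrects for the
    refractory period (R = 5 ms).
    """
    x = np.asarray(isis, dtype=float)
    if x.size < 2:
        raise UnfeaturizableUnit("need >= 2 ISIs for CV2/LV/LVR")
    a, b = x[:-1], x[1:]
    s = a + b
    cv2 = float(np.mean(2.0 * np.abs(b - a) / s))
    n = x.size
    lv = float(3.0 / (n - 1) * np.sum(((a - b) / s) ** 2))
    r = LVR_REFRACTORINESS_S
    lvr = float(
        3.0 / (n - 1) * np.sum((1.0 - 4.0 * a * b / s**2) * (1.0 + 4.0 * r / s))
    )
    return cv2, lv, lvr


def psd_band_features(spike_times_s, window: tuple[float, float],
                      cfg: FeatureConfig | None = None) -> np.ndarray:
    """Relative band power of the binned spike-count periodogram.

    Spikes in ``window`` are binned at ``psd_bin_ms`` into a count signal and
    a one-sided periodogram is taken (no detrending or tapering).  Each
    band's power is the mean periodogram value inside the band; features are
    these means normalized by their sum over the sub-100 Hz bands, so they
    are non-negative and sum to 1.  Using the per-band mean (rather than the
    integral) keeps narrow oscillatory bands comparable to wide ones: a
    periodic train peaks in the band holding its fundamental.
    """
    cfg = cfg or FeatureConfig()
    start, stop = window
    if stop - start < 10.0:
        logger.warning("psd window %.1f s < 10 s: low-frequency bands unresolvable",
                       stop - start)
    st = np.asarray(spike_times_s, dtype=float)
    st = st[(st >= start) & (st < stop)]
    if st.size < 2:
        raise UnfeaturizableUnit("need >= 2 in-window spikes for PSD features")
    dt = cfg.psd_bin_ms / 1000.0
    n_bins = int(np.ceil((stop - start) / dt))
    counts, _ = np.histogram(st, bins=n_bins, range=(start, start + n_bins * dt))
    # boxcar periodogram computed directly; the one-sided scaling constant
    # cancels in the band ratios
    spec = rfft(counts.astype(float))
    psd = (spec.real**2 + spec.imag**2) / (n_bins / dt)
    freqs = np.fft.rfftfreq(n_bins, d=dt)
    means = np.zeros(len(cfg.psd_bands_hz))
    for i, (lo, hi) in enumerate(cfg.psd_bands_hz):
        band = (freqs >= lo) & (freqs < hi) & (freqs > 0)
        if band.any():
            means[i] = psd[band].mean()
    total = means.sum()
    return means / total if total > 0 else means


def metrics14(unit: UnitRecord, window: tuple[float, float],
              cfg: FeatureConfig | None = None) -> np.ndarray:
    """The 14 spiking metrics of one unit over ``window``.

    ISI-based statistics use the interspike intervals of the in-window
    spikes; firing rate is in-window spike count over window duration.
    """
    cfg = cfg or FeatureConfig()
    start, stop = window
    st = unit.spike_times_s
    inwin = st[(st >= start) & (st < stop)]
    if inwin.size < cfg.min_spikes:
        raise UnfeaturizableUnit(
            f"unit {unit.unit_id}: {inwin.size} spikes in window (< {cfg.min_spikes})"
        )
    isis = np.diff(inwin)
    cv2, lv, lvr = local_variation_stats(isis)
    rate = inwin.size / (stop - start)
    sd = float(np.std(isis, ddof=1)) if isis.size > 1 else 0.0
    mean_isi = float(np.mean(isis))
    cv = sd / mean_isi if mean_isi > 0 else 0.0
    psd = psd_band_features(st, window, cfg)
    return np.array(
        [cv2, lv, lvr, rate, sd, cv,
         float(isis.min()), float(np.median(isis)), float(isis.max()), *psd]
    )


# ---------------------------------------------------------------------------
# distribution / PSTH representations
# ---------------------------------------------------------------------------

def isi_distribution(isis, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Min-max-normalized ISI histogram on [isi_min_s, isi_max_s).

    ISIs at or beyond the upper edge are discarded.  A constant histogram
    (including all-empty) maps to all-zeros.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(isis, dtype=float)
    x = x[(x >= cfg.isi_min_s) & (x < cfg.isi_max_s)]
    counts, _ = np.histogram(x, bins=cfg.isi_bins, range=(cfg.isi_min_s, cfg.isi_max_s))
    return _minmax(counts.astype(float))


def isi_bin_edges(cfg: FeatureConfig | None = None) -> np.ndarray:
    cfg = cfg or FeatureConfig()
    return np.linspace(cfg.isi_min_s, cfg.isi_max_s, cfg.isi_bins + 1)


def _counts_for_starts(st: np.ndarray, starts: np.ndarray, n_bins: int,
                       duration: float) -> np.ndarray:
    """Per-trial binned spike counts aligned to trial starts; trials x bins.

    Spike times are sorted, so trial membership comes from binary search and
    binning from index arithmetic; fully vectorized over spikes.
    """
    lo = np.searchsorted(st, starts, side="left")
    hi = np.searchsorted(st, starts + duration, side="left")
    lengths = hi - lo
    total = int(lengths.sum())
    if total == 0:
        return np.zeros((len(starts), n_bins))
    # flat spike indices: concatenation of arange(lo[i], hi[i])
    heads = np.cumsum(lengths) - lengths
    pos = np.arange(total) - np.repeat(heads, lengths)
    idx = np.repeat(lo, lengths) + pos
    rel = st[idx] - np.repeat(starts, lengths)
    width = duration / n_bins
    b = np.minimum((rel / width).astype(int), n_bins - 1)
    trial = np.repeat(np.arange(len(starts)), lengths)
    flat = np.bincount(trial * n_bins + b, minlength=len(starts) * n_bins)
    return flat.reshape(len(starts), n_bins).astype(float)


def _trial_counts(unit, trials: pd.DataFrame, n_bins: int, duration: float) -> np.ndarray:
    return _counts_for_starts(unit.spike_times_s,
                              trials["start_s"].to_numpy(float), n_bins, duration)


def average_psth(unit: UnitRecord, gratings: StimulusEpochTable,
                 cfg: FeatureConfig | None = None) -> np.ndarray:
    """Trial-averaged PSTH over all grating trials, min-max normalized.

    Trials span 3 s (1 s gray pre-period + 2 s stimulus); counts in
    ``avg_psth_bins`` uniform bins are averaged across every trial
    irrespective of condition.
    """
    cfg = cfg or FeatureConfig()
    trials = gratings.of_class("drifting_gratings").df
    if trials.empty:
        raise ValueError("no drifting-grating trials")
    counts = _trial_counts(unit, trials, cfg.avg_psth_bins, cfg.trial_duration_s)
    return _minmax(counts.mean(axis=0))


def grating_condition_order(cfg: FeatureConfig | None = None) -> list[tuple[float, float]]:
    """Fixed condition ordering: orientation-major ascending, frequency ascending."""
    return [(float(o), float(f)) for o in sorted(ORIENTATIONS_DEG)
            for f in sorted(TEMPORAL_FREQUENCIES_HZ)]


def _condition_starts(gratings: StimulusEpochTable, cfg: FeatureConfig) -> list[np.ndarray]:
    """Trial start times per condition, in canonical condition order."""
    trials = gratings.of_class("drifting_gratings").df
    out = []
    for o, f in grating_condition_order(cfg):
        sel = trials[(trials["orientation_deg"] == o) & (trials["temporal_frequency_hz"] == f)]
        if sel.empty:
            raise ValueError(f"missing grating condition (ori={o:g}, tf={f:g})")
        out.append(sel["start_s"].to_numpy(float))
    return out


def _cat_psth_from_starts(unit: UnitRecord, cond_starts: list[np.ndarray],
                          cfg: FeatureConfig) -> np.ndarray:
    blocks = []
    for starts in cond_starts:
        counts = _counts_for_starts(unit.spike_times_s, starts,
                                    cfg.cat_psth_bins_per_condition,
                                    cfg.trial_duration_s)
        blocks.append(_minmax(counts.mean(axis=0)))
    return np.concatenate(blocks)


def concatenated_psth(unit: UnitRecord, gratings: StimulusEpochTable,
                      cfg: FeatureConfig | None = None) -> np.ndarray:
    """Per-condition PSTHs (30 bins over the 3 s trial) concatenated.

    Each condition's PSTH is averaged over its trials and min-max normalized
    independently before concatenation; with the canonical 8 x 5 protocol
    this yields 1200 features.  A missing condition is an error.
    """
    cfg = cfg or FeatureConfig()
    return _cat_psth_from_starts(unit, _condition_starts(gratings, cfg), cfg)


# ---------------------------------------------------------------------------
# dataset-level driver
# ---------------------------------------------------------------------------

def featurize(
    ds: Dataset,
    representation: str,
    stimulus: str = "drifting_gratings",
    cfg: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Feature matrix of every featurizable unit under one representation.

    ``stimulus`` selects the epoch context whose spikes are used (PSTH
    representations require ``drifting_gratings``).  Units with fewer than
    ``cfg.min_spikes`` spikes in the context window are dropped with a log
    entry.
    """
    cfg = cfg or FeatureConfig()
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    if representation in ("avg_psth", "cat_psth") and stimulus != "drifting_gratings":
        raise ValueError(f"{representation} is defined for drifting gratings only")
    window = ds.stimuli.span(stimulus)
    gratings = ds.stimuli.of_class("drifting_gratings") if representation in (
        "avg_psth", "cat_psth") else None
    cond_starts = _condition_starts(gratings, cfg) if representation == "cat_psth" else None

    rows, kept = [], []
    for u in ds.units:
        st = u.spike_times_s
        n_in = int(np.count_nonzero((st >= window[0]) & (st < window[1])))
        if n_in < cfg.min_spikes:
            logger.info("unit %s dropped from featurization: %d in-window spikes",
                        u.unit_id, n_in)
            continue
        if representation == "metrics14":
            rows.append(metrics14(u, window, cfg))
        elif representation == "isi_dist":
            rows.append(isi_distribution(compute_isis(st, window), cfg))
        elif representation == "avg_psth":
            rows.append(average_psth(u, gratings, cfg))
        else:
            rows.append(_cat_psth_from_starts(u, cond_starts, cfg))
        kept.append(u.unit_id)

    if representation == "metrics14":
        names = METRIC_NAMES
        meta = {}
    elif representation == "isi_dist":
        edges = isi_bin_edges(cfg)
        names = tuple(f"isi[{edges[i]:.3f},{edges[i + 1]:.3f})" for i in range(cfg.isi_bins))
        meta = {"bin_edges_s": edges}
    elif representation == "avg_psth":
        names = tuple(f"psth_bin{i}" for i in range(cfg.avg_psth_bins))
        meta = {"trial_duration_s": cfg.trial_duration_s}
    else:
        conds = grating_condition_order(cfg)
        names = tuple(
            f"ori{int(o)}_tf{f:g}_bin{b}"
            for (o, f) in conds
            for b in range(cfg.cat_psth_bins_per_condition)
        )
        meta = {"conditions": conds, "bins_per_condition": cfg.cat_psth_bins_per_condition}
    return FeatureMatrix(
        representation=representation,
        unit_ids=tuple(kept),
        values=np.vstack(rows) if rows else np.empty((0, len(names))),
        feature_names=names,
        meta={**meta, "stimulus": stimulus},
    )


class SpikeFeaturizer:
    """Transformer-style wrapper around :func:`featurize`.

    ``fit`` is stateless (kept for pipeline compatibility); ``transform``
    maps a :class:`Dataset` to a :class:`FeatureMatrix`.
    """

    def __init__(self, representation: str = "isi_dist",
                 stimulus: str = "drifting_gratings",
                 cfg: FeatureConfig | None = None):
        self.representation = representation
        self.stimulus = stimulus
        self.cfg = cfg

    def get_params(self, deep: bool = True) -> dict:
        return {"representation": self.representation, "stimulus": self.stimulus,
                "cfg": self.cfg}

    def set_params(self, **params) -> "SpikeFeaturizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, ds: Dataset, y=None) -> "SpikeFeaturizer":
        self.n_features_out_ = len(featurize(ds.subset(ds.unit_ids[:1]) if len(ds) else ds,
                                             self.representation, self.stimulus,
                                             self.cfg).feature_names)
        return self

    def transform(self, ds: Dataset) -> FeatureMatrix:
        return featurize(ds, self.representation, self.stimulus, self.cfg)

    def fit_transform(self, ds: Dataset, y=None) -> FeatureMatrix:
        return self.fit(ds).transform(ds)
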