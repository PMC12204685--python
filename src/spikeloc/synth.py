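"""Synthetic multi-animal Neuropixels-style datasets.

The generator produces labelled spike-train datasets with the statistical
structure the decoding pipeline assumes:

* structure-specific interspike-interval statistics — each structure has its
  own mean rate and gamma-renewal regularity (shape ``kappa``; ``kappa=1`` is
  Poisson-like, larger is more regular);
* stimulus-locked tuning across the 8 orientations x 5 temporal frequencies
  of the drifting-gratings protocol (von Mises in orientation, log-Gaussian
  in temporal frequency, both normalized to mean 1 over conditions);
* per-animal idiosyncrasy — multiplicative log-normal factors on rate and
  regularity shared by all of one animal's units, plus a per-animal rotation
  of orientation preference.  This is what lets transductive models exploit
  within-animal regularities that inductive models cannot;
* spatially contiguous anatomical labels along each probe, so that
  electrode-consensus smoothing has structure to exploit, with an optional
  iid label-noise knob for smoothing experiments.

Spike trains are inhomogeneous gamma-renewal processes generated by time
rescaling: ISIs are gamma(kappa, mean 1/kappa) in rescaled time, mapped back
through the inverse integrated rate.  The rate is piecewise constant over
stimulus epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import (
    ORIENTATIONS_DEG,
    TEMPORAL_FREQUENCIES_HZ,
    Dataset,
    LabelHierarchy,
    StimulusEpochTable,
    UnitRecord,
)

__all__ = [
    "StructureParams",
    "SyntheticConfig",
    "default_structure_params",
    "make_gratings_protocol",
    "make_session_stimuli",
    "simulate_spike_train",
    "simulate_dataset",
]


@dataclass(frozen=True)
class StructureParams:
    """Generative parameters for one anatomical structure."""

    structure: str
    region: str
    base_rate_hz: float
    gamma_shape: float
    orientation_pref_deg: float = 0.0
    orientation_kappa: float = 0.0
    tf_pref_hz: float = 4.0
    tf_bandwidth_oct: float = 2.0
    modulation_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.base_rate_hz <= 0:
            raise ValueError("base_rate_hz must be > 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be >= 0")
        if self.tf_bandwidth_oct <= 0:
            raise ValueError("tf_bandwidth_oct must be > 0")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")


def default_structure_params() -> tuple[StructureParams, ...]:
    """Default atlas: 12 structures over 4 regions.

    Rates and regularities are chosen to be physiologically plausible and
    separable between regions (hippocampal units slow and bursty, thalamic
    units faster and more regular, cortical units intermediate and strongly
    orientation tuned, midbrain fast).  They are not fit to any recording.

    Between-region differences are large (rate roughly doubling region to
    region, regularity from bursty to clock-like) while within-region
    differences are deliberately subtle, mirroring the observation that
    structures of one region share a timing phenotype: the region task is
    easier than the structure tasks, and the secondary visual areas differ
    mostly in their stimulus preferences rather than their ISI statistics.
    """
    p = StructureParams
    return (
        p("CA1", "hippocampus", 2.3, 0.52, 0, 0.3, 2, 2.5, 0.15),
        p("CA3", "hippocampus", 1.8, 0.60, 45, 0.3, 2, 2.5, 0.12),
        p("DG", "hippocampus", 1.5, 0.68, 90, 0.2, 2, 2.5, 0.10),
        p("SUB", "hippocampus", 2.7, 0.58, 135, 0.3, 2, 2.5, 0.15),
        p("LGd", "thalamus", 8.0, 2.5, 0, 0.5, 8, 1.5, 0.45),
        p("LP", "thalamus", 6.6, 2.0, 90, 0.5, 4, 1.8, 0.35),
        p("PO", "thalamus", 7.3, 2.9, 180, 0.4, 4, 1.8, 0.30),
        p("VISp", "visual_cortex", 4.0, 1.00, 0, 1.5, 4, 1.2, 0.65),
        p("VISal", "visual_cortex", 3.6, 0.95, 45, 1.2, 8, 1.2, 0.55),
        p("VISam", "visual_cortex", 3.8, 1.05, 90, 1.2, 2, 1.2, 0.55),
        p("VISl", "visual_cortex", 3.7, 0.92, 135, 1.2, 4, 1.2, 0.55),
        p("MB", "midbrain", 12.0, 1.4, 0, 0.2, 8, 2.0, 0.20),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-conditions knob block for :func:`simulate_dataset`.

    Defaults mirror the recording protocol the pipeline targets: 8 animals,
    2 probes each, >= 150 units per structure (so the class filter passes at
    its default), a 30 min drifting-gratings block of 8 x 5 x 15 three-second
    trials, a 20 min movie block and a 20 min spontaneous block.
    ``animal_sd_log`` is the log-normal SD of the per-animal rate and
    regularity factors; ``animal_pref_rot_sd_deg`` rotates each animal's
    orientation preferences; ``animal_latency_sd_s`` jitters each animal's
    stimulus-response latency around ``base_latency_s``.  These shared
    idiosyncrasies give transductive models (which see training units from
    the test animals) their edge over inductive ones: pure rate scaling is
    removed by per-unit min-max normalization, so the latency and
    preference signatures carry the animal identity visible in PSTH
    features.  ``label_noise_rate`` relabels that fraction of
    units with a uniformly random wrong structure (recorded labels only; the
    spike trains keep their true parameters) to exercise smoothing.
    """

    n_animals: int = 8
    structures: tuple[StructureParams, ...] = field(default_factory=default_structure_params)
    units_per_structure: int = 150
    animal_sd_log: float = 0.2
    animal_pref_rot_sd_deg: float = 20.0
    animal_latency_sd_s: float = 0.08
    base_latency_s: float = 0.05
    electrodes_per_structure_span: int = 20
    label_noise_rate: float = 0.0
    gratings_repeats: int = 15
    movie_duration_s: float = 1200.0
    spontaneous_duration_s: float = 1200.0
    movie_rate_factor: float = 1.15
    spontaneous_rate_factor: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.units_per_structure < 1:
            raise ValueError("units_per_structure must be >= 1")
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise ValueError("label_noise_rate must lie in [0, 1)")

    def hierarchy(self) -> LabelHierarchy:
        regions: dict[str, list[str]] = {}
        for sp in self.structures:
            regions.setdefault(sp.region, [])
            if sp.region != "midbrain":
                regions[sp.region].append(sp.structure)
        return LabelHierarchy(
            region_structures={r: tuple(ss) for r, ss in regions.items()},
            superstructures={
                s: ("VISp" if s == "VISp" else "VISs")
                for r, ss in regions.items()
                if r == "visual_cortex"
                for s in ss
            },
        )


# ---------------------------------------------------------------------------
# stimulus protocol
# ---------------------------------------------------------------------------

def make_gratings_protocol(
    n_repeats: int = 15,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
) -> StimulusEpochTable:
    """The drifting-gratings block: 8 orientations x 5 frequencies x repeats.

    Each trial spans 3 s (1 s of gray screen then 2 s of gratings); trials
    are contiguous from ``t0`` in pseudo-random order.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = rng or np.random.default_rng(0)
    conditions = [
        (o, f) for o in ORIENTATIONS_DEG for f in TEMPORAL_FREQUENCIES_HZ
    ] * n_repeats
    order = rng.permutation(len(conditions))
    rows = []
    for trial, idx in enumerate(order):
        o, f = conditions[idx]
        start = t0 + 3.0 * trial
        rows.append(
            {
                "trial_id": trial,
                "stimulus_class": "drifting_gratings",
                "orientation_deg": float(o),
                "temporal_frequency_hz": float(f),
                "start_s": start,
                "stop_s": start + 3.0,
            }
        )
    return StimulusEpochTable(pd.DataFrame(rows))


def make_session_stimuli(cfg: SyntheticConfig, rng: np.random.Generator) -> StimulusEpochTable:
    """Gratings block, then movie repeats, then one spontaneous epoch."""
    gr = make_gratings_protocol(cfg.gratings_repeats, rng).df
    t = float(gr["stop_s"].max())
    rows = []
    trial = int(gr["trial_id"].max()) + 1
    if cfg.movie_duration_s > 0:
        n_rep = max(1, int(round(cfg.movie_duration_s / 120.0)))
        for _ in range(n_rep):
            rows.append(
                {
                    "trial_id": trial,
                    "stimulus_class": "natural_movie",
                    "orientation_deg": np.nan,
                    "temporal_frequency_hz": np.nan,
                    "start_s": t,
                    "stop_s": t + cfg.movie_duration_s / n_rep,
                }
            )
            t += cfg.movie_duration_s / n_rep
            trial += 1
    if cfg.spontaneous_duration_s > 0:
        rows.append(
            {
                "trial_id": trial,
                "stimulus_class": "spontaneous",
                "orientation_deg": np.nan,
                "temporal_frequency_hz": np.nan,
                "start_s": t,
                "stop_s": t + cfg.spontaneous_duration_s,
            }
        )
    return StimulusEpochTable(pd.concat([gr, pd.DataFrame(rows)], ignore_index=True))


# ---------------------------------------------------------------------------
# tuning and spike generation
# ---------------------------------------------------------------------------

def _tuning_tables(params: StructureParams, pref_rot_deg: float = 0.0):
    """Condition gain per orientation and frequency, each normalized to mean 1."""
    ori = np.deg2rad(np.asarray(ORIENTATIONS_DEG, float))
    pref = np.deg2rad(params.orientation_pref_deg + pref_rot_deg)
    vm = np.exp(params.orientation_kappa * np.cos(ori - pref))
    vm = vm / vm.mean()
    tf = np.asarray(TEMPORAL_FREQUENCIES_HZ, float)
    lg = np.exp(-(np.log2(tf / params.tf_pref_hz) ** 2) / (2 * params.tf_bandwidth_oct**2))
    lg = lg / lg.mean()
    return (
        dict(zip(ORIENTATIONS_DEG, vm)),
        dict(zip(TEMPORAL_FREQUENCIES_HZ, lg)),
    )


def condition_gain(params: StructureParams, orientation_deg, temporal_frequency_hz,
                   pref_rot_deg: float = 0.0) -> float:
    """Multiplicative tuning gain for one grating condition (mean ~1)."""
    vm, lg = _tuning_tables(params, pref_rot_deg)
    return float(vm[int(orientation_deg)] * lg[int(temporal_frequency_hz)])


def _rate_profile(
    params: StructureParams,
    animal_factor: float,
    epochs: StimulusEpochTable,
    pref_rot_deg: float,
    movie_rate_factor: float,
    spontaneous_rate_factor: float,
    latency_s: float = 0.0,
):
    """Piecewise-constant rate: knot times and the rate on each segment."""
    vm, lg = _tuning_tables(params, pref_rot_deg)
    base = params.base_rate_hz * animal_factor
    m = params.modulation_depth
    times = [0.0]
    rates = []

    def push(t0, t1, r):
        if r <= 0:
            raise ValueError("instantaneous rate <= 0")
        if t0 > times[-1]:
            times.append(t0)
            rates.append(base)  # inter-epoch gap at baseline
        times.append(t1)
        rates.append(r)

    df = epochs.df.sort_values("start_s")
    for row in df.itertuples(index=False):
        if row.stimulus_class == "drifting_gratings":
            gain = vm[int(row.orientation_deg)] * lg[int(row.temporal_frequency_hz)]
            r_stim = base * (1.0 + m * (gain - 1.0))
            # 1 s gray pre-period at baseline, then the 2 s stimulus whose
            # rate change follows the animal's response latency
            onset = min(row.start_s + 1.0 + latency_s, row.stop_s)
            push(row.start_s, onset, base)
            if onset < row.stop_s:
                push(onset, row.stop_s, r_stim)
        elif row.stimulus_class == "natural_movie":
            push(row.start_s, row.stop_s, base * movie_rate_factor)
        else:
            push(row.start_s, row.stop_s, base * spontaneous_rate_factor)
    return np.asarray(times), np.asarray(rates)


def simulate_spike_train(
    params: StructureParams,
    animal_factor: float,
    epochs: StimulusEpochTable,
    rng: np.random.Generator,
    pref_rot_deg: float = 0.0,
    movie_rate_factor: float = 1.0,
    spontaneous_rate_factor: float = 1.0,
    latency_s: float = 0.0,
) -> np.ndarray:
    """One unit's spike times over the session, by time rescaling.

    In rescaled (operational) time the train is a gamma renewal process with
    shape ``params.gamma_shape`` and unit mean interval; spikes are mapped
    back through the inverse of the integrated rate, which is piecewise
    linear for a piecewise-constant rate.
    """
    times, rates = _rate_profile(
        params, animal_factor, epochs, pref_rot_deg,
        movie_rate_factor, spontaneous_rate_factor, latency_s,
    )
    return _sample_renewal(times, rates, params.gamma_shape, rng)


def _sample_renewal(times, rates, kappa, rng: np.random.Generator) -> np.ndarray:
    seg = np.diff(times)
    cum = np.concatenate([[0.0], np.cumsum(seg * rates)])
    total_mass = cum[-1]
    # draw gamma ISIs in rescaled time until the mass is exhausted
    expected = int(total_mass) + 1
    isis = []
    mass = 0.0
    while mass < total_mass:
        block = rng.gamma(kappa, 1.0 / kappa, size=max(64, expected))
        isis.append(block)
        mass += block.sum()
        expected = max(16, int((total_mass - mass)) + 1)
    rescaled = np.cumsum(np.concatenate(isis))
    rescaled = rescaled[rescaled < total_mass]
    # strictly increasing inverse map: cum is non-decreasing, rates > 0
    spikes = np.interp(rescaled, cum, times)
    spikes = spikes[np.diff(np.concatenate([[-1.0], spikes])) > 0]
    return spikes


# ---------------------------------------------------------------------------
# whole-dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SyntheticConfig) -> Dataset:
    """Generate a labelled multi-animal dataset under ``cfg``.

    Per animal, two probes traverse contiguous spans of structures along the
    electrode index; each unit sits on an electrode within its structure's
    span.  Quality metrics are drawn from comfortably passing ranges so the
    generated data survive the default unit filter.  Deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    stimuli = make_session_stimuli(cfg, rng)
    hierarchy = cfg.hierarchy()
    structures = list(cfg.structures)
    by_name = {sp.structure: sp for sp in structures}

    # split the atlas across the two probes of every animal
    half = (len(structures) + 1) // 2
    probe_layouts = [structures[:half], structures[half:]]

    animal_rate = np.exp(rng.normal(0.0, cfg.animal_sd_log, size=cfg.n_animals))
    animal_shape = np.exp(rng.normal(0.0, cfg.animal_sd_log, size=cfg.n_animals))
    animal_rot = rng.normal(0.0, cfg.animal_pref_rot_sd_deg, size=cfg.n_animals)
    animal_lat = np.clip(
        cfg.base_latency_s
        + np.abs(rng.normal(0.0, cfg.animal_latency_sd_s, size=cfg.n_animals)),
        0.0, 0.5,
    )

    # deal each structure's unit budget across animals as evenly as possible
    per_animal = np.full((len(structures), cfg.n_animals), cfg.units_per_structure // cfg.n_animals)
    for k, sp in enumerate(structures):
        extra = cfg.units_per_structure - per_animal[k].sum()
        per_animal[k, rng.choice(cfg.n_animals, size=extra, replace=False)] += 1

    units: list[UnitRecord] = []
    uid = 0
    for a in range(cfg.n_animals):
        animal_id = f"animal{a:02d}"
        for p, layout in enumerate(probe_layouts):
            if not layout:
                continue
            probe_id = f"{animal_id}_probe{p}"
            for s_pos, sp in enumerate(layout):
                k = structures.index(sp)
                n_units = int(per_animal[k, a])
                span0 = s_pos * cfg.electrodes_per_structure_span
                electrodes = rng.integers(
                    span0, span0 + cfg.electrodes_per_structure_span, size=n_units
                )
                shape = max(0.1, sp.gamma_shape * animal_shape[a])
                params_a = replace(sp, gamma_shape=shape)
                # the rate profile is shared by all units of this
                # (structure, animal); build it once
                times, rates = _rate_profile(
                    params_a,
                    animal_rate[a],
                    stimuli,
                    animal_rot[a],
                    cfg.movie_rate_factor,
                    cfg.spontaneous_rate_factor,
                    animal_lat[a],
                )
                for e in electrodes:
                    spikes = _sample_renewal(times, rates, shape, rng)
                    units.append(
                        UnitRecord(
                            unit_id=f"u{uid:05d}",
                            animal_id=animal_id,
                            probe_id=probe_id,
                            electrode_index=int(e),
                            region=sp.region,
                            structure=None if sp.region == "midbrain" else sp.structure,
                            layer=None,
                            isi_violations=float(rng.uniform(0.0, 0.4)),
                            amplitude_cutoff=float(rng.uniform(0.0, 0.08)),
                            presence_ratio=float(rng.uniform(0.95, 1.0)),
                            spike_times_s=spikes,
                        )
                    )
                    uid += 1

    if cfg.label_noise_rate > 0:
        flip = rng.random(len(units)) < cfg.label_noise_rate
        names = [sp.structure for sp in structures]
        for i in np.flatnonzero(flip):
            u = units[i]
            current = u.structure or "MB"
            others = [s for s in names if s != current]
            new = by_name[others[rng.integers(len(others))]]
            units[i] = replace(
                u,
                region=new.region,
                structure=None if new.region == "midbrain" else new.structure,
            )

    # label noise can put conflicting labels on one site; nudge those units to
    # a free electrode on the same probe so Dataset invariants hold
    units = _resolve_site_conflicts(units, rng)

    return Dataset(
        units=tuple(units),
        stimuli=stimuli,
        hierarchy=hierarchy,
        provenance=f"synthetic seed={cfg.seed}",
    )


def _resolve_site_conflicts(units, rng):
    seen: dict[tuple[str, int], tuple] = {}
    used: dict[str, set[int]] = {}
    for u in units:
        used.setdefault(u.probe_id, set()).add(u.electrode_index)
    out = []
    for u in units:
        key = (u.probe_id, u.electrode_index)
        label = (u.region, u.structure)
        if seen.setdefault(key, label) != label:
            e = u.electrode_index
            while (u.probe_id, e) in seen and seen[(u.probe_id, e)] != label:
                e += 1
            u = replace(u, electrode_index=e)
            seen[(u.probe_id, e)] = label
            used[u.probe_id].add(e)
        out.append(u)
    return out
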