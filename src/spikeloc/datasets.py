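"""Core data types, tabular IO, and unit/class inclusion filters.

The package works on well-isolated single units ("units") recorded with
high-density linear probes.  Each unit carries its spike timestamps (seconds),
anatomical labels at two granularities (brain region and structure, plus an
optional cortical layer), its position along the probe as an integer electrode
index, and standard spike-sorting quality metrics.  Stimulus presentations are
described by an epoch table of half-open intervals ``[start_s, stop_s)``.

All times are seconds; all intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "UnitRecord",
    "StimulusEpochTable",
    "LabelHierarchy",
    "Dataset",
    "default_hierarchy",
    "load_dataset",
    "write_dataset",
    "filter_units",
    "filter_classes",
    "compute_isis",
    "task_labels",
]

#: Canonical drifting-gratings protocol parameters.
ORIENTATIONS_DEG = (0, 45, 90, 135, 180, 225, 270, 315)
TEMPORAL_FREQUENCIES_HZ = (1, 2, 4, 8, 15)

STIMULUS_CLASSES = ("drifting_gratings", "natural_movie", "spontaneous")

_UNITS_COLUMNS = [
    "unit_id",
    "animal_id",
    "probe_id",
    "electrode_index",
    "region",
    "structure",
    "layer",
    "isi_violations",
    "amplitude_cutoff",
    "presence_ratio",
]
_SPIKES_COLUMNS = ["unit_id", "spike_time_s"]
_STIMULI_COLUMNS = [
    "trial_id",
    "stimulus_class",
    "orientation_deg",
    "temporal_frequency_hz",
    "start_s",
    "stop_s",
]


class DatasetError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class UnitRecord:
    """One neuron: spike times plus anatomical, probe and quality metadata.

    ``structure`` and ``layer`` may be ``None`` (e.g. midbrain units are not
    subdivided; ambiguous structure assignments are modelled as missing and
    excluded from structure-level tasks while remaining usable for region
    tasks).
    """

    unit_id: str
    animal_id: str
    probe_id: str
    electrode_index: int
    region: str
    structure: str | None
    layer: str | None
    isi_violations: float
    amplitude_cutoff: float
    presence_ratio: float
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times_s, dtype=float)
        if st.ndim != 1:
            raise DatasetError(f"unit {self.unit_id}: spike_times_s must be 1-D")
        if st.size and not np.all(np.isfinite(st)):
            raise DatasetError(f"unit {self.unit_id}: non-finite spike time")
        if st.size and st[0] < 0:
            raise DatasetError(f"unit {self.unit_id}: negative spike time")
        if np.any(np.diff(st) <= 0):
            raise DatasetError(
                f"unit {self.unit_id}: spike times must be strictly increasing "
                "(unsorted or duplicate timestamps are rejected, not repaired)"
            )
        object.__setattr__(self, "spike_times_s", st)
        if self.electrode_index < 0:
            raise DatasetError(f"unit {self.unit_id}: electrode_index < 0")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass(frozen=True)
class StimulusEpochTable:
    """Trial intervals with condition parameters.

    Drifting-grating rows carry ``orientation_deg`` and
    ``temporal_frequency_hz``; movie and spontaneous rows carry neither.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in _STIMULI_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"stimuli table missing columns: {missing}")
        df = df[_STIMULI_COLUMNS].copy()
        bad = df["stop_s"] <= df["start_s"]
        if bad.any():
            raise DatasetError("stimulus epoch with stop_s <= start_s")
        unknown = set(df["stimulus_class"]) - set(STIMULUS_CLASSES)
        if unknown:
            raise DatasetError(f"unknown stimulus classes: {sorted(unknown)}")
        grat = df["stimulus_class"] == "drifting_gratings"
        if df.loc[grat, ["orientation_deg", "temporal_frequency_hz"]].isna().any().any():
            raise DatasetError("drifting-grating rows must carry orientation and frequency")
        if df.loc[~grat, ["orientation_deg", "temporal_frequency_hz"]].notna().any().any():
            raise DatasetError("non-grating rows must not carry grating parameters")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    def of_class(self, stimulus_class: str) -> "StimulusEpochTable":
        return StimulusEpochTable(self.df[self.df["stimulus_class"] == stimulus_class])

    def gratings_conditions(self) -> pd.DataFrame:
        """Unique (orientation, frequency) pairs with their trial counts."""
        g = self.of_class("drifting_gratings").df
        return (
            g.groupby(["orientation_deg", "temporal_frequency_hz"])
            .size()
            .rename("n_trials")
            .reset_index()
        )

    def span(self, stimulus_class: str | None = None) -> tuple[float, float]:
        df = self.df if stimulus_class is None else self.of_class(stimulus_class).df
        if df.empty:
            raise DatasetError(f"no epochs of class {stimulus_class!r}")
        return float(df["start_s"].min()), float(df["stop_s"].max())


@dataclass(frozen=True)
class LabelHierarchy:
    """Region/structure ontology plus named classification tasks.

    ``tasks`` maps a task name to the metadata attribute it reads
    (``region``, ``structure``, ``superstructure``, ``layer`` or
    ``hierarchy``) — see :func:`task_labels`.
    """

    region_structures: dict[str, tuple[str, ...]]
    superstructures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for region, structs in self.region_structures.items():
            for s in structs:
                if s in seen:
                    raise DatasetError(f"structure {s} mapped to both {seen[s]} and {region}")
                seen[s] = region

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.region_structures)

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(s for ss in self.region_structures.values() for s in ss)

    def region_of(self, structure: str) -> str:
        for region, structs in self.region_structures.items():
            if structure in structs:
                return region
        raise KeyError(structure)

    def structure_tasks(self) -> dict[str, str]:
        """Per-region structure tasks with >= 2 structures."""
        return {
            f"structures_{r}": r
            for r, ss in self.region_structures.items()
            if len(ss) >= 2
        }

    def task_names(self) -> tuple[str, ...]:
        return ("region", "structure", "superstructure", "layer", "hierarchy",
                *self.structure_tasks())


#: Secondary visual cortex: the pooled higher visual areas.
VISS_STRUCTURES = ("VISal", "VISam", "VISl", "VISpm", "VISrl")


def default_hierarchy() -> LabelHierarchy:
    """The canonical atlas: 4 regions, 18 named structures plus midbrain."""
    return LabelHierarchy(
        region_structures={
            "hippocampus": ("CA1", "CA3", "DG", "ProS", "SUB"),
            "midbrain": (),
            "thalamus": ("Eth", "LGd", "LP", "MGv", "PO", "SGN", "VPM"),
            "visual_cortex": ("VISal", "VISam", "VISl", "VISp", "VISpm", "VISrl"),
        },
        superstructures={**{s: "VISs" for s in VISS_STRUCTURES}, "VISp": "VISp"},
    )


@dataclass(frozen=True)
class Dataset:
    units: tuple[UnitRecord, ...]
    stimuli: StimulusEpochTable
    hierarchy: LabelHierarchy
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate unit_id")
        # anatomical consistency of each (probe, electrode) site
        site_label: dict[tuple[str, int], tuple] = {}
        for u in self.units:
            if u.region not in self.hierarchy.regions:
                raise DatasetError(f"unit {u.unit_id}: unknown region {u.region!r}")
            if u.structure is not None:
                if u.structure not in self.hierarchy.structures:
                    raise DatasetError(f"unit {u.unit_id}: unknown structure {u.structure!r}")
                if self.hierarchy.region_of(u.structure) != u.region:
                    raise DatasetError(
                        f"unit {u.unit_id}: structure {u.structure} is not in region {u.region}"
                    )
            key = (u.probe_id, u.electrode_index)
            label = (u.region, u.structure)
            if site_label.setdefault(key, label) != label:
                raise DatasetError(f"conflicting anatomical labels at electrode {key}")

    def __len__(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    @property
    def animal_ids(self) -> list[str]:
        return sorted({u.animal_id for u in self.units})

    def unit(self, unit_id: str) -> UnitRecord:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def subset(self, unit_ids) -> "Dataset":
        keep = set(unit_ids)
        return replace(self, units=tuple(u for u in self.units if u.unit_id in keep))

    def units_frame(self) -> pd.DataFrame:
        """Unit metadata (no spikes) as a DataFrame indexed by unit_id."""
        rows = []
        for u in self.units:
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "animal_id": u.animal_id,
                    "probe_id": u.probe_id,
                    "electrode_index": u.electrode_index,
                    "region": u.region,
                    "structure": u.structure,
                    "layer": u.layer,
                    "isi_violations": u.isi_violations,
                    "amplitude_cutoff": u.amplitude_cutoff,
                    "presence_ratio": u.presence_ratio,
                    "n_spikes": u.n_spikes,
                }
            )
        return pd.DataFrame(rows).set_index("unit_id", drop=False)


# ---------------------------------------------------------------------------
# task labels
# ---------------------------------------------------------------------------

def task_labels(ds: Dataset, task: str) -> pd.Series:
    """Per-unit class label for ``task``; NaN where the label is missing.

    Tasks: ``region`` (4 classes), ``structures_<region>`` (structures within
    one region), ``structure`` (all structures pooled), ``superstructure``
    (VISp vs VISs, visual-cortex units only), ``layer`` (cortical layers),
    ``hierarchy`` (structure labels with midbrain units labelled 'midbrain').
    """
    h = ds.hierarchy
    out = {}
    for u in ds.units:
        if task == "region":
            lab = u.region
        elif task == "structure":
            lab = u.structure
        elif task == "hierarchy":
            lab = "midbrain" if u.region == "midbrain" else u.structure
        elif task == "superstructure":
            lab = h.superstructures.get(u.structure) if u.structure else None
        elif task == "layer":
            lab = u.layer if u.region == "visual_cortex" else None
        elif task.startswith("structures_"):
            region = task[len("structures_"):]
            if region not in h.regions:
                raise DatasetError(f"unknown task {task!r}")
            lab = u.structure if u.region == region else None
        else:
            raise DatasetError(f"unknown task {task!r}")
        out[u.unit_id] = lab
    return pd.Series(out, name=task)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".parquet"):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _write_table(df: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".parquet"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def load_dataset(
    units_path,
    spikes_path,
    stimuli_path,
    hierarchy: LabelHierarchy | None = None,
    provenance: str = "",
) -> Dataset:
    """Read the three interchange tables and return a validated Dataset.

    Spike times are attached to units by ``unit_id``.  Rows in the spikes
    table whose ``unit_id`` is absent from the units table are an error, as
    are unsorted or duplicate spike timestamps (rejected, never repaired).
    """
    hierarchy = hierarchy or default_hierarchy()
    units_df = _read_table(units_path)
    spikes_df = _read_table(spikes_path)
    stimuli_df = _read_table(stimuli_path)

    for cols, df, name in (
        (_UNITS_COLUMNS, units_df, "units"),
        (_SPIKES_COLUMNS, spikes_df, "spikes"),
        (_STIMULI_COLUMNS, stimuli_df, "stimuli"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DatasetError(f"{name} table missing columns: {missing}")

    units_df = units_df.copy()
    units_df["unit_id"] = units_df["unit_id"].astype(str)
    spikes_df = spikes_df.copy()
    spikes_df["unit_id"] = spikes_df["unit_id"].astype(str)

    known = set(units_df["unit_id"])
    unknown = set(spikes_df["unit_id"]) - known
    if unknown:
        raise DatasetError(f"spikes table references unknown unit_ids: {sorted(unknown)[:5]}")

    grouped = {uid: g["spike_time_s"].to_numpy(float) for uid, g in spikes_df.groupby("unit_id")}

    def _opt(v):
        if pd.isna(v) or v == "":
            return None
        if isinstance(v, float) and v.is_integer():
            return str(int(v))
        return str(v)

    units = []
    for row in units_df.itertuples(index=False):
        units.append(
            UnitRecord(
                unit_id=str(row.unit_id),
                animal_id=str(row.animal_id),
                probe_id=str(row.probe_id),
                electrode_index=int(row.electrode_index),
                region=str(row.region),
                structure=_opt(row.structure),
                layer=_opt(row.layer),
                isi_violations=float(row.isi_violations),
                amplitude_cutoff=float(row.amplitude_cutoff),
                presence_ratio=float(row.presence_ratio),
                spike_times_s=grouped.get(str(row.unit_id), np.empty(0)),
            )
        )
    return Dataset(
        units=tuple(units),
        stimuli=StimulusEpochTable(stimuli_df),
        hierarchy=hierarchy,
        provenance=provenance,
    )


def write_dataset(ds: Dataset, units_path, spikes_path, stimuli_path) -> None:
    """Write the three interchange tables (CSV, or Parquet by extension)."""
    units_df = ds.units_frame().drop(columns="n_spikes").reset_index(drop=True)
    spikes_df = pd.DataFrame(
        {
            "unit_id": np.repeat(
                [u.unit_id for u in ds.units], [u.n_spikes for u in ds.units]
            ),
            "spike_time_s": np.concatenate(
                [u.spike_times_s for u in ds.units] or [np.empty(0)]
            ),
        }
    )
    _write_table(units_df, units_path)
    _write_table(spikes_df, spikes_path)
    _write_table(ds.stimuli.df, stimuli_path)


def load_dataset_nwb(nwb_path, hierarchy: LabelHierarchy | None = None) -> Dataset:
    """Adapter seam for NWB session files.  Not implemented here.

    A deployment with access to NWB recordings should convert them to the
    three interchange tables and call :func:`load_dataset`.
    """
    raise NotImplementedError(
        "NWB ingestion is an adapter seam: export units/spikes/stimuli tables "
        "and use load_dataset"
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def compute_isis(spike_times_s, window: tuple[float, float]) -> np.ndarray:
    """Interspike intervals of the spikes falling in half-open ``window``.

    Returns successive differences; length is (#in-window spikes) - 1 and may
    be zero.
    """
    start, stop = window
    st = np.asarray(spike_times_s, dtype=float)
    inwin = st[(st >= start) & (st < stop)]
    return np.diff(inwin)


def filter_units(ds: Dataset, analysis_window: tuple[float, float]) -> Dataset:
    """Apply the quality and firing-rate inclusion criteria.

    Keeps units with ISI violations < 0.5, amplitude cutoff < 0.1, presence
    ratio > 0.9 (strict), and a firing rate of at least 0.1 Hz over the
    analysis window (spike count / window duration).
    """
    start, stop = analysis_window
    if not stop > start:
        raise DatasetError("empty analysis window")
    duration = stop - start
    keep = []
    for u in ds.units:
        st = u.spike_times_s
        n = int(np.count_nonzero((st >= start) & (st < stop)))
        rate = n / duration
        if (
            u.isi_violations < 0.5
            and u.amplitude_cutoff < 0.1
            and u.presence_ratio > 0.9
            and rate >= 0.1
        ):
            keep.append(u.unit_id)
    return ds.subset(keep)


def filter_classes(ds: Dataset, task: str, min_units: int = 150) -> Dataset:
    """Drop units whose task label is missing or backed by < ``min_units``.

    The unit-count floor guarantees enough test units per class under the
    60/20/20 rotation.  Raises if fewer than two classes survive.
    """
    labels = task_labels(ds, task)
    counts = labels.value_counts(dropna=True)
    good = set(counts[counts >= min_units].index)
    if len(good) < 2:
        raise DatasetError(
            f"task {task!r}: {len(good)} classes with >= {min_units} units; need >= 2"
        )
    keep = labels[labels.isin(good)].index
    return ds.subset(keep)
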