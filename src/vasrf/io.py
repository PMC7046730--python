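"""File formats: spike/event tables (TSV), HRIR containers (HDF5), WAV, JSON.

The synthetic generator writes the same tabular spike and event files the
real-data path reads, so synthetic and recorded inputs are interchangeable
downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .hrtf import HrirGrid
from .stimuli import ChordStimulus

__all__ = [
    "read_spike_table",
    "write_spike_table",
    "read_event_table",
    "write_event_table",
    "save_hrir_grid",
    "load_hrir_grid",
    "save_chord",
    "load_chord",
    "write_wav",
    "write_json",
]


# ---------------------------------------------------------------------------
# Spike and event tables (TSV)
# ---------------------------------------------------------------------------

def read_spike_table(path) -> dict:
    """Read a tab-separated (neuron_id, time_s) table into sorted arrays.

    Returns ``{neuron_id: sorted times}``.  Negative times are rejected
    with their line number; an empty file yields an empty dict (with a
    warning).
    """
    import warnings

    path = Path(path)
    per_neuron: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                nid, t = line.split("\t")
                t = float(t)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed spike row "
                                 f"{line!r}") from None
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative spike time {t}")
            per_neuron.setdefault(nid, []).append(t)
    if not per_neuron:
        warnings.warn(f"{path}: empty spike table", stacklevel=2)
    return {nid: np.sort(np.asarray(ts)) for nid, ts in per_neuron.items()}


def write_spike_table(path, spikes_by_neuron: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# neuron_id\ttime_s\n")
        for nid in spikes_by_neuron:
            for t in np.asarray(spikes_by_neuron[nid]):
                fh.write(f"{nid}\t{t:.9f}\n")


def read_event_table(path):
    """(event_time_s, direction_index, condition) rows -> arrays."""
    times, dirs, conds = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                t, d, c = line.split("\t")
                times.append(float(t))
                dirs.append(int(d))
                conds.append(c)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed event row "
                                 f"{line!r}") from None
    return np.asarray(times), np.asarray(dirs, dtype=int), conds


def write_event_table(path, event_times, direction_indices, conditions) -> None:
    with open(path, "w") as fh:
        fh.write("# event_time_s\tdirection_index\tcondition\n")
        for t, d, c in zip(event_times, direction_indices, conditions):
            fh.write(f"{float(t):.9f}\t{int(d)}\t{c}\n")


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def save_hrir_grid(path, grid: HrirGrid) -> None:
    """Layout: /sample_rate, /directions (Nx2), /ir/left, /ir/right, /frame."""
    with h5py.File(path, "w") as f:
        f.create_dataset("sample_rate", data=float(grid.sample_rate))
        f.create_dataset("directions", data=grid.directions)
        g = f.create_group("ir")
        g.create_dataset("left", data=grid.ir_left)
        g.create_dataset("right", data=grid.ir_right)
        f.attrs["frame"] = grid.frame
        f.attrs["band"] = list(grid.band)


def load_hrir_grid(path) -> HrirGrid:
    with h5py.File(path, "r") as f:
        return HrirGrid(sample_rate=float(f["sample_rate"][()]),
                        directions=f["directions"][()],
                        ir_left=f["ir/left"][()], ir_right=f["ir/right"][()],
                        frame=str(f.attrs["frame"]),
                        band=tuple(f.attrs["band"]))


def save_chord(path, chord: ChordStimulus) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("patterns_left", data=chord.patterns_left)
        f.create_dataset("patterns_right", data=chord.patterns_right)
        f.create_dataset("frequencies_hz", data=chord.frequencies_hz)
        f.attrs.update(pattern_duration=chord.pattern_duration,
                       taper=chord.taper, n_repeats=chord.n_repeats,
                       seed=chord.seed)


def load_chord(path) -> ChordStimulus:
    with h5py.File(path, "r") as f:
        return ChordStimulus(
            patterns_left=f["patterns_left"][()],
            patterns_right=f["patterns_right"][()],
            frequencies_hz=f["frequencies_hz"][()],
            pattern_duration=float(f.attrs["pattern_duration"]),
            taper=float(f.attrs["taper"]),
            n_repeats=int(f.attrs["n_repeats"]), seed=int(f.attrs["seed"]))


# ---------------------------------------------------------------------------
# WAV and JSON
# ---------------------------------------------------------------------------

def write_wav(path, left, right, sample_rate: float) -> None:
    """Stereo float32 WAV, scaled to 90% full scale."""
    from scipy.io import wavfile

    data = np.column_stack([left, right]).astype(np.float64)
    peak = np.abs(data).max()
    if peak > 0:
        data = data / peak * 0.9
    wavfile.write(path, int(sample_rate), data.astype(np.float32))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
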