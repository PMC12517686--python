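"""Session data model and HDF5 persistence.

A session bundles simultaneously recorded signals on a common clock:
per-cell fluorescence traces sampled at the imaging rate (default 2 kHz),
one contralateral LFP channel at an integer multiple of the imaging rate
(default 8 kHz), and behavior tracking (linearized position on a one-way
track and running speed) resampled to the imaging rate.  Imaging frame 0
defines t = 0; sample i covers the half-open interval [i/fs, (i+1)/fs).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np


class FormatError(ValueError):
    """A session file is missing a required group/dataset/attribute."""


class AlignmentError(ValueError):
    """Sampling rates or lengths of the bundled signals are inconsistent."""


@dataclass
class CellTrace:
    cell_id: str
    raw_f: np.ndarray          # fluorescence, a.u., one value per imaging sample
    centroid_xy: np.ndarray    # ROI centroid, micrometers
    sampling_rate_hz: float = 2000.0

    def validate(self) -> None:
        if not np.all(np.isfinite(self.raw_f)):
            raise ValueError(f"cell {self.cell_id}: raw_f contains non-finite values")
        if np.shape(self.centroid_xy) != (2,) or not np.all(np.isfinite(self.centroid_xy)):
            raise ValueError(f"cell {self.cell_id}: centroid_xy must be a finite 2-vector")


@dataclass
class LfpTrace:
    samples: np.ndarray        # microvolts
    sampling_rate_hz: float = 8000.0

    def validate(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("lfp: samples contain non-finite values")


@dataclass
class BehaviorTrack:
    t: np.ndarray              # seconds, strictly increasing
    position_cm: np.ndarray    # linearized position on the one-way track
    speed_cm_s: np.ndarray
    track_length_cm: float = 90.0

    def validate(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("behavior: t must be strictly increasing")
        if np.any(self.position_cm < 0) or np.any(self.position_cm > self.track_length_cm):
            raise ValueError("behavior: position_cm outside [0, track_length_cm]")
        if np.any(self.speed_cm_s < 0):
            raise ValueError("behavior: speed_cm_s must be nonnegative")


@dataclass
class SessionBundle:
    cells: list[CellTrace]
    lfp: LfpTrace
    behavior: BehaviorTrack
    session_id: str
    duration_s: float
    extras: dict = field(default_factory=dict)

    @property
    def imaging_rate_hz(self) -> float:
        return self.cells[0].sampling_rate_hz

    @property
    def lfp_imaging_ratio(self) -> int:
        ratio = self.lfp.sampling_rate_hz / self.imaging_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise AlignmentError(
                f"lfp rate {self.lfp.sampling_rate_hz} is not an integer multiple "
                f"of imaging rate {self.imaging_rate_hz}"
            )
        return int(round(ratio))

    def validate(self) -> None:
        if not self.cells:
            raise ValueError("bundle has no cells")
        rates = {c.sampling_rate_hz for c in self.cells}
        lengths = {c.raw_f.size for c in self.cells}
        if len(rates) != 1 or len(lengths) != 1:
            raise AlignmentError("cell traces must share one sampling rate and length")
        for c in self.cells:
            c.validate()
        self.lfp.validate()
        self.behavior.validate()
        _ = self.lfp_imaging_ratio
        if self.behavior.t.size and (
            self.behavior.t[0] < 0 or self.behavior.t[-1] > self.duration_s
        ):
            raise ValueError("behavior timestamps outside [0, duration_s]")


def align_indices(t_event, target_rate_hz: float, duration_s: float | None = None):
    """Nearest-sample index of event time(s) at a target rate (half-up ties).

    With ``duration_s`` given, events outside [0, duration_s] raise.
    """
    t = np.asarray(t_event, dtype=float)
    if duration_s is not None and (np.any(t < 0) or np.any(t > duration_s)):
        raise ValueError("event time outside the recording")
    elif duration_s is None and np.any(t < 0):
        raise ValueError("event time before the recording start")
    idx = np.floor(t * float(target_rate_hz) + 0.5).astype(int)
    return int(idx) if np.isscalar(t_event) else idx


def save_session(bundle: SessionBundle, path, overwrite: bool = False):
    """Write a validated bundle to the HDF5 session layout; returns the path."""
    bundle.validate()
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = bundle.session_id
        f.attrs["duration_s"] = float(bundle.duration_s)
        f.attrs["imaging_rate_hz"] = float(bundle.imaging_rate_hz)
        f.attrs["lfp_rate_hz"] = float(bundle.lfp.sampling_rate_hz)
        f.attrs["track_length_cm"] = float(bundle.behavior.track_length_cm)
        g = f.create_group("cells")
        for c in bundle.cells:
            cg = g.create_group(c.cell_id)
            cg.create_dataset("raw_f", data=np.asarray(c.raw_f, dtype=np.float64))
            cg.create_dataset("centroid_xy", data=np.asarray(c.centroid_xy, dtype=np.float64))
        f.create_group("lfp").create_dataset(
            "samples", data=np.asarray(bundle.lfp.samples, dtype=np.float64)
        )
        bg = f.create_group("behavior")
        bg.create_dataset("t", data=np.asarray(bundle.behavior.t, dtype=np.float64))
        bg.create_dataset("position_cm", data=np.asarray(bundle.behavior.position_cm, dtype=np.float64))
        bg.create_dataset("speed_cm_s", data=np.asarray(bundle.behavior.speed_cm_s, dtype=np.float64))
    return path


def load_session(path) -> SessionBundle:
    """Read and validate a session bundle from the HDF5 layout."""
    with h5py.File(path, "r") as f:
        for key in ("cells", "lfp", "behavior"):
            if key not in f:
                raise FormatError(f"session file missing group '{key}'")
        for key in ("session_id", "duration_s", "imaging_rate_hz", "lfp_rate_hz",
                    "track_length_cm"):
            if key not in f.attrs:
                raise FormatError(f"session file missing attribute '{key}'")
        if "samples" not in f["lfp"]:
            raise FormatError("session file missing dataset 'lfp/samples'")
        imaging_rate = float(f.attrs["imaging_rate_hz"])
        cells = []
        for cid in sorted(f["cells"].keys()):
            cg = f["cells"][cid]
            for key in ("raw_f", "centroid_xy"):
                if key not in cg:
                    raise FormatError(f"session file missing dataset 'cells/{cid}/{key}'")
            cells.append(CellTrace(
                cell_id=cid,
                raw_f=cg["raw_f"][()],
                centroid_xy=cg["centroid_xy"][()],
                sampling_rate_hz=imaging_rate,
            ))
        lfp = LfpTrace(samples=f["lfp/samples"][()],
                       sampling_rate_hz=float(f.attrs["lfp_rate_hz"]))
        bg = f["behavior"]
        for key in ("t", "position_cm", "speed_cm_s"):
            if key not in bg:
                raise FormatError(f"session file missing dataset 'behavior/{key}'")
        behavior = BehaviorTrack(
            t=bg["t"][()], position_cm=bg["position_cm"][()],
            speed_cm_s=bg["speed_cm_s"][()],
            track_length_cm=float(f.attrs["track_length_cm"]),
        )
        bundle = SessionBundle(
            cells=cells, lfp=lfp, behavior=behavior,
            session_id=str(f.attrs["session_id"]),
            duration_s=float(f.attrs["duration_s"]),
        )
    bundle.validate()
    return bundle
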