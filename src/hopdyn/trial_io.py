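"""Reading, validating, synchronising and writing hopping-trial data.

A trial couples three inputs recorded simultaneously: reflective-marker
trajectories (200 Hz motion capture, TRC or long-form CSV), a force-plate
record (1000 Hz CSV with 3D ground reaction force and fore-aft centre of
pressure), and subject metadata.  On load the forces are baseline-corrected
and decimated onto the marker clock by boxcar averaging, which preserves
impulse — the quantity body-mass estimation depends on — rather than
waveform detail.

Lab-frame convention: x fore-aft (+ direction of travel), y vertical (+ up),
z lateral.  All downstream mechanics happen in the sagittal (x, y) plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .config import G, PipelineConfig
from .errors import PipelineError, PipelineWarning

REQUIRED_MARKERS = ("hip", "knee", "ankle", "mtp", "toe", "ilium", "tail")

#: markers forming the hindlimb chain from pelvis to toe tip
CHAIN_MARKERS = ("ilium", "hip", "knee", "ankle", "mtp", "toe")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialMetadata:
    animal_id: str
    trial_id: str
    body_mass: Optional[float] = None  # kg; may be estimated later
    species: str = ""

    def __post_init__(self):
        if self.body_mass is not None and self.body_mass <= 0:
            raise PipelineError("bad_metadata", "body_mass must be > 0")


@dataclass
class MarkerSet:
    """Synchronised 3D marker trajectories in metres, lab frame."""

    positions: Dict[str, np.ndarray]  # name -> (n, 3)
    rate: float  # Hz
    time: np.ndarray  # (n,) seconds, strictly increasing

    def __post_init__(self):
        n = len(self.time)
        for name, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (n, 3):
                raise PipelineError("bad_markers", f"{name}: shape {pos.shape} != ({n},3)")
            self.positions[name] = pos
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise PipelineError("bad_timebase", "marker time not strictly increasing")

    @property
    def names(self) -> List[str]:
        return list(self.positions)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class ForceRecord:
    """Ground reaction force and fore-aft centre of pressure."""

    grf: np.ndarray  # (n, 3) N: fx, fy, fz
    cop_x: np.ndarray  # (n,) m; NaN where unloaded
    rate: float  # Hz
    time: np.ndarray  # (n,) s

    def __post_init__(self):
        self.grf = np.asarray(self.grf, dtype=float)
        self.cop_x = np.asarray(self.cop_x, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.grf.shape != (len(self.time), 3):
            raise PipelineError("bad_forces", f"grf shape {self.grf.shape}")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise PipelineError("bad_timebase", "force time not strictly increasing")
        if len(self.time) and np.nanmin(self.grf[:, 1]) < -2.0:
            warnings.warn(
                f"vertical force dips to {np.nanmin(self.grf[:, 1]):.1f} N after "
                "baseline correction", PipelineWarning)

    @property
    def fy(self) -> np.ndarray:
        return self.grf[:, 1]


@dataclass
class Trial:
    """One hop: markers, forces resampled to the marker clock, metadata."""

    metadata: TrialMetadata
    markers: MarkerSet
    forces: ForceRecord  # on the marker clock
    forces_raw: Optional[ForceRecord] = None  # native-rate record
    forward: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self):
        if len(self.forces.time) != len(self.markers.time) or not np.allclose(
                self.forces.time, self.markers.time, atol=1e-9):
            raise PipelineError("bad_timebase", "markers and forces share no common clock")

    def sagittal(self, name: str) -> np.ndarray:
        """Marker trajectory projected onto the travel-direction sagittal
        plane: column 0 = fore-aft along ``forward``, column 1 = vertical."""
        p = self.markers.positions[name]
        x = p[:, 0] * self.forward[0] + p[:, 2] * self.forward[1]
        return np.column_stack([x, p[:, 1]])

    def sagittal_markers(self) -> Dict[str, np.ndarray]:
        return {name: self.sagittal(name) for name in self.markers.positions}


def travel_direction(markers: MarkerSet, pelvis: str = "ilium") -> np.ndarray:
    """Horizontal unit vector (x, z components) of net pelvis displacement."""
    p = markers.positions[pelvis]
    d = p[-1, [0, 2]] - p[0, [0, 2]]
    norm = np.hypot(*d)
    if norm < 1e-9:
        return np.array([1.0, 0.0])
    return d / norm


# ---------------------------------------------------------------------------
# marker file formats
# ---------------------------------------------------------------------------

def _fill_gaps(pos: np.ndarray, time: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    """Cubic-spline fill of NaN runs up to ``max_gap`` frames."""
    bad = np.any(np.isnan(pos), axis=1)
    if not bad.any():
        return pos
    # longest NaN run
    run, longest = 0, 0
    for b in bad:
        run = run + 1 if b else 0
        longest = max(longest, run)
    if longest > max_gap:
        raise PipelineError("marker_gap", f"{name}: gap of {longest} frames > {max_gap}")
    if bad[0] or bad[-1]:
        raise PipelineError("marker_gap", f"{name}: series starts or ends with a gap")
    good = ~bad
    out = pos.copy()
    for ax in range(3):
        cs = CubicSpline(time[good], pos[good, ax])
        out[bad, ax] = cs(time[bad])
    return out


def read_trc(path: str | Path) -> MarkerSet:
    """Read a Motion Analysis dialect TRC file (tab separated, 5 header rows,
    coordinates usually in mm)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise PipelineError("bad_trc", f"{path}: truncated file")
    hdr_keys = lines[1].split("\t")
    hdr_vals = lines[2].split("\t")
    hdr = dict(zip(hdr_keys, hdr_vals))
    rate = float(hdr.get("DataRate", 200.0))
    units = hdr.get("Units", "mm").strip()
    scale = {"mm": 1e-3, "m": 1.0}.get(units)
    if scale is None:
        raise PipelineError("unit_error", f"unknown TRC units {units!r}")
    label_row = lines[3].split("\t")
    names = [s.strip() for s in label_row[2:] if s.strip()]
    data = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        cells = ln.split("\t")
        row = [float(c) if c.strip() else np.nan for c in cells[1:]]
        data.append(row)
    arr = np.asarray(data, dtype=float)
    time = arr[:, 0]
    coords = arr[:, 1:]
    if coords.shape[1] < 3 * len(names):
        raise PipelineError("bad_trc", f"{path}: fewer coordinate columns than markers")
    positions = {
        name: coords[:, 3 * i:3 * i + 3] * scale for i, name in enumerate(names)
    }
    return MarkerSet(positions=positions, rate=rate, time=time)


def write_trc(markers: MarkerSet, path: str | Path) -> None:
    """Write markers as Motion Analysis dialect TRC (mm)."""
    path = Path(path)
    names = markers.names
    n = len(markers)
    head = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{markers.rate:g}\t{markers.rate:g}\t{n}\t{len(names)}\tmm\t"
        f"{markers.rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(len(names))),
    ]
    rows = []
    for i in range(n):
        cells = [str(i + 1), f"{markers.time[i]:.9f}"]
        for name in names:
            cells.extend(f"{v * 1e3:.9f}" for v in markers.positions[name][i])
        rows.append("\t".join(cells))
    path.write_text("\n".join(head + rows) + "\n")


def read_marker_csv(path: str | Path) -> MarkerSet:
    """Long-form CSV: columns time, marker, x, y, z (seconds and metres)."""
    df = pd.read_csv(path)
    need = {"time", "marker", "x", "y", "z"}
    if not need.issubset(df.columns):
        raise PipelineError("bad_markers", f"{path}: columns {sorted(df.columns)}")
    times = np.sort(df["time"].unique())
    positions = {}
    for name, g in df.groupby("marker"):
        g = g.sort_values("time")
        if len(g) != len(times):
            raise PipelineError("bad_markers", f"marker {name} has missing frames")
        positions[str(name)] = g[["x", "y", "z"]].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(times)) if len(times) > 1 else 0.0
    return MarkerSet(positions=positions, rate=float(round(rate, 6)), time=times)


def read_force_csv(path: str | Path) -> ForceRecord:
    """Force-plate CSV with columns time, fx, fy, fz, cop_x (s, N, m)."""
    df = pd.read_csv(path)
    need = {"time", "fx", "fy", "fz", "cop_x"}
    if not need.issubset(df.columns):
        raise PipelineError("bad_forces", f"{path}: columns {sorted(df.columns)}")
    time = df["time"].to_numpy(dtype=float)
    grf = df[["fx", "fy", "fz"]].to_numpy(dtype=float)
    cop = df["cop_x"].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(time)) if len(time) > 1 else 0.0
    return ForceRecord(grf=grf, cop_x=cop, rate=float(round(rate, 6)), time=time)


def write_force_csv(forces: ForceRecord, path: str | Path) -> None:
    df = pd.DataFrame({
        "time": forces.time,
        "fx": forces.grf[:, 0],
        "fy": forces.grf[:, 1],
        "fz": forces.grf[:, 2],
        "cop_x": forces.cop_x,
    })
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# synchronisation
# ---------------------------------------------------------------------------

def resample_forces(forces: ForceRecord, target_rate: float,
                    cop_threshold_n: float = 10.0) -> ForceRecord:
    """Anti-aliased decimation onto a ``target_rate`` clock.

    Each output sample is the boxcar average of the source samples within the
    half-open-centred interval of width ``1/target_rate`` — exact for linear
    signals and impulse-preserving for everything else.  The centre of
    pressure is averaged only over loaded source samples (vertical force
    above ``cop_threshold_n``); fully unloaded intervals get NaN CoP.
    """
    if target_rate > forces.rate + 1e-9:
        raise PipelineError("upsample_not_supported",
                            f"{target_rate} Hz > source {forces.rate} Hz")
    dt = 1.0 / target_rate
    t0, t1 = forces.time[0], forces.time[-1]
    n_out = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
    t_out = t0 + dt * np.arange(n_out)
    eps = 1e-12
    lo = np.searchsorted(forces.time, t_out - dt / 2 - eps, side="left")
    hi = np.searchsorted(forces.time, t_out + dt / 2 + eps, side="right")
    grf_out = np.empty((n_out, 3))
    cop_out = np.full(n_out, np.nan)
    loaded = forces.fy > cop_threshold_n
    for i in range(n_out):
        s = slice(lo[i], hi[i])
        grf_out[i] = forces.grf[s].mean(axis=0)
        m = loaded[s] & ~np.isnan(forces.cop_x[s])
        if m.any():
            cop_out[i] = forces.cop_x[s][m].mean()
    return ForceRecord(grf=grf_out, cop_x=cop_out, rate=target_rate, time=t_out)


def baseline_correct(forces: ForceRecord, contact_floor_n: float = 10.0,
                     window_s: float = 0.05,
                     guard_s: float = 0.01) -> ForceRecord:
    """Subtract the unloaded-plate mean over a pre-contact window.

    The window ends ``guard_s`` before the force first exceeds the contact
    floor, so the onset ramp does not leak into the baseline.
    """
    fy = forces.fy
    above = np.flatnonzero(fy > contact_floor_n)
    if len(above) == 0:
        return forces
    first = above[0]
    t_first = forces.time[first] - guard_s
    in_win = (forces.time < t_first) & (forces.time >= t_first - window_s)
    if in_win.sum() < 5:
        return forces
    offset = forces.grf[in_win].mean(axis=0)
    return ForceRecord(grf=forces.grf - offset, cop_x=forces.cop_x,
                       rate=forces.rate, time=forces.time)


# ---------------------------------------------------------------------------
# trial assembly
# ---------------------------------------------------------------------------

_MARKER_ALIASES = {
    "pelvis": "ilium", "asis": "ilium", "toe_tip": "toe", "phalanx": "toe",
    "tailbase": "tail", "tail_base": "tail",
}


def _canonical_markers(markers: MarkerSet, aliases: Optional[dict] = None) -> MarkerSet:
    table = dict(_MARKER_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    positions = {}
    for name, pos in markers.positions.items():
        key = name.lower()
        positions[table.get(key, key)] = pos
    missing = [m for m in REQUIRED_MARKERS if m not in positions]
    if missing:
        raise PipelineError("missing_marker", f"missing markers: {missing}")
    return MarkerSet(positions=positions, rate=markers.rate, time=markers.time)


def _check_units(markers: MarkerSet, forces: ForceRecord,
                 metadata: TrialMetadata) -> None:
    span = max(np.nanmax(np.abs(p)) for p in markers.positions.values())
    if span > 100.0:
        raise PipelineError("unit_error",
                            f"marker span {span:.0f} looks like mm (scale 1e-3)")
    loaded = forces.cop_x[~np.isnan(forces.cop_x)]
    if len(loaded) and np.median(np.abs(loaded)) > 50.0:
        raise PipelineError("unit_error", "cop_x looks like mm (scale 1e-3)")
    if metadata.body_mass is not None:
        peak = np.nanmax(forces.fy) if len(forces.time) else 0.0
        if 0 < peak < 0.5 * metadata.body_mass * G:
            raise PipelineError(
                "unit_error",
                f"peak vertical force {peak:.0f} N < 0.5 BW; forces may be kgf "
                f"(scale {G:g})")


def read_trial(marker_path: str | Path, force_path: str | Path,
               metadata: TrialMetadata,
               config: Optional[PipelineConfig] = None,
               marker_aliases: Optional[dict] = None) -> Trial:
    """Read, validate and synchronise one trial.

    Markers come from a TRC file (``.trc``) or long-form CSV; forces from a
    ``time,fx,fy,fz,cop_x`` CSV.  Forces are baseline-corrected against the
    pre-contact window and boxcar-decimated onto the marker clock.
    """
    config = config or PipelineConfig()
    marker_path = Path(marker_path)
    if marker_path.suffix.lower() == ".trc":
        raw = read_trc(marker_path)
    else:
        raw = read_marker_csv(marker_path)
    markers = _canonical_markers(raw, marker_aliases)
    markers = MarkerSet(
        positions={
            name: _fill_gaps(pos, markers.time, config.max_gap_frames, name)
            for name, pos in markers.positions.items()
        },
        rate=markers.rate, time=markers.time)
    forces = read_force_csv(force_path)
    if forces.rate + 1e-9 < markers.rate:
        raise PipelineError("bad_timebase",
                            f"force rate {forces.rate} < marker rate {markers.rate}")
    _check_units(markers, forces, metadata)
    forces = baseline_correct(forces, config.contact_floor_n,
                              config.baseline_window_s)
    synced = resample_forces(forces, markers.rate, config.contact_floor_n)
    n = min(len(markers), len(synced.time))
    markers = MarkerSet(
        positions={k: v[:n] for k, v in markers.positions.items()},
        rate=markers.rate, time=markers.time[:n])
    synced = ForceRecord(grf=synced.grf[:n], cop_x=synced.cop_x[:n],
                         rate=synced.rate, time=synced.time[:n])
    fwd = travel_direction(markers)
    return Trial(metadata=metadata, markers=markers, forces=synced,
                 forces_raw=forces, forward=fwd)


def write_trial(trial: Trial, marker_path: str | Path,
                force_path: str | Path) -> None:
    """Write a trial back to TRC + force CSV (uses the native-rate force
    record when available)."""
    write_trc(trial.markers, marker_path)
    write_force_csv(trial.forces_raw or trial.forces, force_path)


# ---------------------------------------------------------------------------
# results output
# ---------------------------------------------------------------------------

@dataclass
class ResultBundle:
    """Analysed-trial outputs ready for disk: per-trial scalar rows plus
    %-stance time-series tables, and the configuration that produced them."""

    scalars: List[dict] = field(default_factory=list)
    timeseries: Dict[str, pd.DataFrame] = field(default_factory=dict)
    config: Optional[PipelineConfig] = None

    def add(self, trial_id: str, scalars: dict, timeseries: pd.DataFrame) -> None:
        self.scalars.append({"trial_id": trial_id, **scalars})
        self.timeseries[trial_id] = timeseries


def write_results(bundle: ResultBundle, out_dir: str | Path) -> Path:
    """Write the bundle as CSV + JSON manifest; returns the manifest path.

    Output is deterministic for identical input: fixed column order, fixed
    float formatting, sorted manifest keys.
    """
    from . import __version__

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        files = []
        if bundle.scalars:
            df = pd.DataFrame(bundle.scalars)
            df.to_csv(out_dir / "per_hop_scalars.csv", index=False,
                      float_format="%.9g")
            files.append("per_hop_scalars.csv")
        for trial_id, ts in sorted(bundle.timeseries.items()):
            name = f"{trial_id}_timeseries.csv"
            ts.to_csv(out_dir / name, index=False, float_format="%.9g")
            files.append(name)
        manifest = {
            "software": "hopdyn",
            "version": __version__,
            "n_trials": len(bundle.scalars),
            "files": files,
            "config": bundle.config.to_dict() if bundle.config else None,
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest_path
    except OSError as exc:
        raise PipelineError("write_error", str(exc)) from exc
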