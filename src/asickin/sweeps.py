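"""Sweep data model, on-disk formats, and stimulus-epoch segmentation.

A *sweep* is one time-aligned record of membrane current together with the
solution (pH) command that produced it.  Blocks of sweeps sharing a grid and
protocol are the currency passed between every analysis stage: the synthetic
generators emit them, and the recovery / NSFA / kinetics modules consume them.

Two on-disk dialects are supported: a human-readable TSV with ``#key=value``
header lines (the canonical fixture format) and an HDF5 container for large
blocks.  Conventions: inward currents are negative; all index windows are
0-based half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RecordingMeta",
    "StimulusEpoch",
    "StimulusProtocol",
    "Sweep",
    "SweepBlock",
    "EpochWindow",
    "SweepFormatError",
    "read_sweep_block",
    "write_sweep_block",
    "segment_epochs",
    "stimulus_waveform",
]

EPOCH_LABELS = ("baseline", "conditioning", "interpulse", "test", "generic")


class SweepFormatError(ValueError):
    """Raised for malformed sweep files or invariant violations."""


@dataclass
class RecordingMeta:
    patch_id: str = "synthetic"
    holding_potential: float = -60.0  # mV
    reversal_potential: float | None = None  # mV
    sample_interval: float = 1e-4  # s
    construct_label: str = ""
    temperature_note: str | None = None

    def __post_init__(self) -> None:
        if not (self.sample_interval > 0):
            raise ValueError("sample_interval must be > 0")
        if not math.isfinite(self.holding_potential):
            raise ValueError("holding_potential must be finite")


@dataclass(frozen=True)
class StimulusEpoch:
    start: float  # s
    duration: float  # s
    level: float  # pH
    label: str = "generic"

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError("epoch duration must be > 0")
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class StimulusProtocol:
    epochs: tuple[StimulusEpoch, ...]
    rest_level: float = 8.0

    def __post_init__(self) -> None:
        epochs = tuple(self.epochs)
        object.__setattr__(self, "epochs", epochs)
        for a, b in zip(epochs, epochs[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError("epochs must be non-overlapping and time-ordered")

    @property
    def end(self) -> float:
        return self.epochs[-1].end if self.epochs else 0.0

    def first_nonrest(self) -> StimulusEpoch | None:
        for ep in self.epochs:
            if ep.level != self.rest_level:
                return ep
        return None

    def by_label(self, label: str) -> list[StimulusEpoch]:
        return [ep for ep in self.epochs if ep.label == label]

    def to_dict(self) -> dict:
        return {
            "rest_level": self.rest_level,
            "epochs": [
                {"start": e.start, "duration": e.duration, "level": e.level, "label": e.label}
                for e in self.epochs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            epochs=tuple(StimulusEpoch(**e) for e in d["epochs"]),
            rest_level=float(d["rest_level"]),
        )


def stimulus_waveform(protocol: StimulusProtocol, time: np.ndarray) -> np.ndarray:
    """Ideal square stimulus (pH vs time) for a protocol on a sample grid."""
    stim = np.full(time.shape, protocol.rest_level, dtype=float)
    for ep in protocol.epochs:
        mask = (time >= ep.start - 1e-12) & (time < ep.end - 1e-12)
        stim[mask] = ep.level
    return stim


@dataclass
class Sweep:
    time: np.ndarray  # s, uniform grid
    current: np.ndarray  # pA
    stimulus: np.ndarray  # pH on the same grid
    meta: RecordingMeta = field(default_factory=RecordingMeta)
    sweep_index: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValueError("sweep needs at least 2 samples")
        if self.current.size != n or self.stimulus.size != n:
            raise SweepFormatError("time, current and stimulus must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise ValueError("time grid must be uniform to 1 part in 1e6")

    @property
    def sample_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return int(self.time.size)


@dataclass
class SweepBlock:
    sweeps: list[Sweep]
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("SweepBlock requires at least one sweep")
        n = self.sweeps[0].n_samples
        dt = self.sweeps[0].sample_interval
        for sw in self.sweeps:
            if sw.n_samples != n:
                raise SweepFormatError("all sweeps in a block must share a grid length")
            if abs(sw.sample_interval - dt) > 1e-12 * dt:
                raise SweepFormatError("all sweeps must share the sample interval")

    @property
    def time(self) -> np.ndarray:
        return self.sweeps[0].time

    @property
    def meta(self) -> RecordingMeta:
        return self.sweeps[0].meta

    def current_matrix(self) -> np.ndarray:
        """Stack currents into a (n_sweeps, n_samples) matrix."""
        return np.stack([sw.current for sw in self.sweeps])

    def subset(self, indices: Sequence[int]) -> "SweepBlock":
        return SweepBlock(sweeps=[self.sweeps[i] for i in indices], protocol=self.protocol)

    def __len__(self) -> int:
        return len(self.sweeps)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def write_sweep_block(block: SweepBlock, path: str | Path, format: str = "tsv") -> None:
    """Write a block losslessly (1e-9 pA / 1e-9 s) in 'tsv' or 'container' form."""
    if not isinstance(block, SweepBlock) or len(block.sweeps) == 0:
        raise ValueError("refusing to write an empty sweep block")
    path = Path(path)
    if format == "tsv":
        _write_tsv(block, path)
    elif format == "container":
        _write_container(block, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_sweep_block(path: str | Path, format: str = "tsv") -> SweepBlock:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "container":
        return _read_container(path)
    raise ValueError(f"unknown format {format!r}")


def _write_tsv(block: SweepBlock, path: Path) -> None:
    meta = block.meta
    k = len(block.sweeps)
    lines = [
        f"#patch_id={meta.patch_id}",
        f"#holding_mV={meta.holding_potential!r}",
        f"#reversal_mV={'' if meta.reversal_potential is None else repr(meta.reversal_potential)}",
        f"#sample_interval_s={meta.sample_interval!r}",
        f"#sweep_count={k}",
        f"#construct_label={meta.construct_label}",
        f"#protocol={json.dumps(block.protocol.to_dict())}",
    ]
    header = ["time_s"] + [f"current_pA_s{j}" for j in range(k)] + ["stimulus_pH"]
    lines.append("\t".join(header))
    cur = block.current_matrix()
    t = block.time
    stim = block.sweeps[0].stimulus
    for irow in range(t.size):
        row = [repr(float(t[irow]))] + [repr(float(cur[j, irow])) for j in range(k)]
        row.append(repr(float(stim[irow])))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_tsv(path: Path) -> SweepBlock:
    meta_kv: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise SweepFormatError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, val = line[1:].partition("=")
                meta_kv[key] = val
            elif header is None:
                header = line.split("\t")
                if header[0] != "time_s" or header[-1] != "stimulus_pH":
                    raise SweepFormatError(f"{path}:{lineno}: bad column header {line!r}")
            else:
                cells = line.split("\t")
                if len(cells) != len(header):
                    raise SweepFormatError(
                        f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                    )
                rows.append(cells)
    if header is None or not rows:
        raise SweepFormatError(f"{path}: no data rows")
    try:
        data = np.array(rows, dtype=float)
    except ValueError as exc:
        raise SweepFormatError(f"{path}: non-numeric data cell ({exc})") from exc
    k = len(header) - 2
    declared = int(meta_kv.get("sweep_count", k))
    if declared != k:
        raise SweepFormatError(f"{path}: sweep_count={declared} but {k} current columns")
    rev = meta_kv.get("reversal_mV", "")
    meta = RecordingMeta(
        patch_id=meta_kv.get("patch_id", "unknown"),
        holding_potential=float(meta_kv.get("holding_mV", -60.0)),
        reversal_potential=float(rev) if rev else None,
        sample_interval=float(meta_kv["sample_interval_s"]),
        construct_label=meta_kv.get("construct_label", ""),
    )
    protocol = StimulusProtocol.from_dict(json.loads(meta_kv["protocol"]))
    time = data[:, 0]
    stim = data[:, -1]
    sweeps = [
        Sweep(time=time, current=data[:, 1 + j], stimulus=stim, meta=meta, sweep_index=j)
        for j in range(k)
    ]
    return SweepBlock(sweeps=sweeps, protocol=protocol)


def _write_container(block: SweepBlock, path: Path) -> None:
    import h5py

    meta = block.meta
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("block")
        grp.create_dataset("time", data=block.time)
        grp.create_dataset("current", data=block.current_matrix())
        grp.create_dataset("stimulus", data=block.sweeps[0].stimulus)
        grp.attrs["patch_id"] = meta.patch_id
        grp.attrs["holding_mV"] = meta.holding_potential
        if meta.reversal_potential is not None:
            grp.attrs["reversal_mV"] = meta.reversal_potential
        grp.attrs["sample_interval_s"] = meta.sample_interval
        grp.attrs["construct_label"] = meta.construct_label
        grp.attrs["protocol"] = json.dumps(block.protocol.to_dict())


def _read_container(path: Path) -> SweepBlock:
    import h5py

    with h5py.File(path, "r") as fh:
        grp = fh["block"]
        time = grp["time"][...]
        cur = grp["current"][...]
        stim = grp["stimulus"][...]
        meta = RecordingMeta(
            patch_id=str(grp.attrs["patch_id"]),
            holding_potential=float(grp.attrs["holding_mV"]),
            reversal_potential=(
                float(grp.attrs["reversal_mV"]) if "reversal_mV" in grp.attrs else None
            ),
            sample_interval=float(grp.attrs["sample_interval_s"]),
            construct_label=str(grp.attrs["construct_label"]),
        )
        protocol = StimulusProtocol.from_dict(json.loads(grp.attrs["protocol"]))
    sweeps = [
        Sweep(time=time, current=cur[j], stimulus=stim, meta=meta, sweep_index=j)
        for j in range(cur.shape[0])
    ]
    return SweepBlock(sweeps=sweeps, protocol=protocol)


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochWindow:
    start: int  # inclusive sample index
    end: int  # exclusive
    level: float  # median stimulus within the window


def segment_epochs(
    stimulus: np.ndarray,
    rest_level: float,
    threshold_fraction: float = 0.5,
    debounce: int = 5,
) -> list[EpochWindow]:
    """Detect non-rest stimulus windows on the command channel.

    A sample deviates when |stimulus - rest| exceeds ``threshold_fraction``
    of the largest step amplitude in the trace; deviations shorter than
    ``debounce`` samples are treated as glitches and ignored.  Returns
    ordered, non-overlapping half-open index windows.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.size < 2:
        raise ValueError("stimulus needs at least 2 samples")
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    dev = np.abs(stimulus - rest_level)
    amplitude = float(dev.max())
    if amplitude == 0.0:
        return []
    mask = dev >= threshold_fraction * amplitude
    windows: list[EpochWindow] = []
    for start, end in _true_runs(mask):
        if end - start < debounce:
            continue
        level = float(np.median(stimulus[start:end]))
        windows.append(EpochWindow(start=start, end=end, level=level))
    return windows


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]
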