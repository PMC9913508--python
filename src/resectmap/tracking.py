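"""Tool-tip tracking logs: the TSV log format, replay, and the brain-mask filter.

A log holds time-stamped tool-tip positions in world (RAS) millimeters,
one instrument per file, as streamed by a navigation platform at a nominal
15-30 samples/second.  The on-disk format is a self-describing UTF-8 TSV::

    # time_s	x_mm	y_mm	z_mm	instrument
    0.0	12.5	-3.25	40.0	cusa

Timestamps are stream-relative seconds; wall-clock epochs are re-zeroed on
parse.  The cerebrum filter drops samples recorded outside the brain (tool
entering/leaving the field), with a small Euclidean dilation margin to
avoid discarding cortical-surface carving due to mask discretization.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

from .volume import BinaryMask

__all__ = [
    "ToolTipSample",
    "TrackingLog",
    "parse_log",
    "write_log",
    "filter_by_brain_mask",
    "split_segments",
    "concat_logs",
    "replay",
    "log_from_transforms",
]

LOG_HEADER = "# time_s\tx_mm\ty_mm\tz_mm\tinstrument"

# Timestamps above this are assumed to be absolute epochs and re-zeroed.
_EPOCH_THRESHOLD_S = 1e8


class ToolTipSample(NamedTuple):
    time_s: float
    position: np.ndarray  # (3,) world mm
    instrument: str


@dataclass(eq=False)
class TrackingLog:
    """Ordered time-stamped tool-tip samples sharing one coordinate frame."""

    t: np.ndarray                      # (n,) seconds, non-decreasing
    xyz: np.ndarray                    # (n, 3) world mm
    instrument: np.ndarray             # (n,) labels
    nominal_rate: Optional[float] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3) if np.size(self.xyz) else np.zeros((0, 3))
        self.instrument = np.asarray(self.instrument, dtype=str).reshape(-1)
        n = len(self.t)
        if self.xyz.shape[0] != n or len(self.instrument) != n:
            raise ValueError("t, xyz and instrument must have equal lengths")
        if n and (not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xyz))):
            raise ValueError("log contains non-finite values")
        if n and np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if n and self.t[0] < 0:
            raise ValueError("timestamps must be >= 0")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, sel) -> "TrackingLog":
        return TrackingLog(self.t[sel], self.xyz[sel], self.instrument[sel], self.nominal_rate)

    def samples(self) -> Iterator[ToolTipSample]:
        for i in range(len(self)):
            yield ToolTipSample(float(self.t[i]), self.xyz[i].copy(), str(self.instrument[i]))

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def mean_rate_hz(self) -> float:
        """Average sampling density (samples/second) over the log span."""
        if len(self) < 2 or self.duration_s == 0:
            return 0.0
        return (len(self) - 1) / self.duration_s

    def __eq__(self, other):
        if not isinstance(other, TrackingLog):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.xyz, other.xyz)
            and np.array_equal(self.instrument, other.instrument)
        )


def empty_log() -> TrackingLog:
    return TrackingLog(np.zeros(0), np.zeros((0, 3)), np.zeros(0, dtype=str))


def parse_log(path: str) -> TrackingLog:
    """Parse a tool-tip TSV log; malformed lines raise with their line number."""
    ts, ps, inst = [], [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (4, 5):
                raise ValueError(f"{path}:{lineno}: expected 4 or 5 fields, got {len(fields)}: {line!r}")
            try:
                vals = [float(f) for f in fields[:4]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {line!r}") from exc
            if not all(np.isfinite(v) for v in vals):
                raise ValueError(f"{path}:{lineno}: non-finite value: {line!r}")
            ts.append(vals[0])
            ps.append(vals[1:4])
            inst.append(fields[4] if len(fields) == 5 else "tool")
    if not ts:
        return empty_log()
    t = np.asarray(ts, dtype=float)
    dec = np.nonzero(np.diff(t) < 0)[0]
    if dec.size:
        raise ValueError(f"{path}: decreasing timestamp at sample {dec[0] + 2}")
    if t[0] > _EPOCH_THRESHOLD_S:
        t = t - t[0]
    return TrackingLog(t, np.asarray(ps, dtype=float), np.asarray(inst, dtype=str))


def write_log(path: str, log: TrackingLog) -> None:
    """Write the TSV log format (floats at full shortest-round-trip precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(LOG_HEADER + "\n")
        for i in range(len(log)):
            x, y, z = (float(v) for v in log.xyz[i])
            fh.write(f"{float(log.t[i])!r}\t{x!r}\t{y!r}\t{z!r}\t{log.instrument[i]}\n")


def filter_by_brain_mask(log: TrackingLog, cerebrum: BinaryMask, margin_mm: float = 1.0) -> TrackingLog:
    """Keep samples inside the cerebrum mask dilated by ``margin_mm`` (Euclidean).

    The dilation is evaluated on the mask lattice: a sample is kept when the
    voxel containing its position lies within ``margin_mm`` (center-to-center
    Euclidean distance, via an exact distance transform) of a cerebrum voxel.
    Samples outside the mask grid entirely are dropped.  Order and
    timestamps are preserved; the filter is idempotent and monotone in the
    margin.
    """
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    if len(log) == 0:
        return log[np.zeros(0, dtype=bool)]
    if margin_mm == 0:
        region = cerebrum.voxels
    else:
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(~cerebrum.voxels, sampling=cerebrum.geometry.spacing)
        region = dist <= margin_mm
    cont = cerebrum.geometry.world_to_index(log.xyz)
    idx = np.rint(cont).astype(np.int64)
    inb = np.all((idx >= 0) & (idx < np.array(cerebrum.geometry.shape)), axis=1)
    keep = np.zeros(len(log), dtype=bool)
    sel = idx[inb]
    keep[inb] = region[sel[:, 0], sel[:, 1], sel[:, 2]]
    return log[keep]


def split_segments(log: TrackingLog, max_gap_s: float = 0.5, max_jump_mm: float = 10.0) -> list:
    """Split a log at temporal gaps > ``max_gap_s`` or spatial jumps > ``max_jump_mm``.

    Concatenating the returned segments reproduces the input exactly.
    """
    if max_gap_s <= 0 or max_jump_mm <= 0:
        raise ValueError("split thresholds must be > 0")
    if len(log) == 0:
        return []
    dt = np.diff(log.t)
    jump = np.linalg.norm(np.diff(log.xyz, axis=0), axis=1)
    breaks = np.nonzero((dt > max_gap_s) | (jump > max_jump_mm))[0] + 1
    bounds = np.concatenate([[0], breaks, [len(log)]])
    return [log[int(a):int(b)] for a, b in zip(bounds[:-1], bounds[1:])]


def concat_logs(segments: Sequence[TrackingLog]) -> TrackingLog:
    if not segments:
        return empty_log()
    return TrackingLog(
        np.concatenate([s.t for s in segments]),
        np.concatenate([s.xyz for s in segments]),
        np.concatenate([s.instrument for s in segments]),
        segments[0].nominal_rate,
    )


def replay(log: TrackingLog, speed_factor: Optional[float] = None) -> Iterator[ToolTipSample]:
    """Yield samples in time order, emulating the intraoperative stream.

    With ``speed_factor=None`` the replay is as-fast-as-possible; otherwise
    inter-sample wall-clock delays are the logged intervals divided by
    ``speed_factor`` (2.0 replays a 10 s log in a nominal 5 s).
    """
    if speed_factor is not None and speed_factor <= 0:
        raise ValueError("speed_factor must be > 0")
    prev_t = None
    for s in log.samples():
        if speed_factor is not None and prev_t is not None:
            time.sleep((s.time_s - prev_t) / speed_factor)
        prev_t = s.time_s
        yield s


def log_from_transforms(times, transforms, instrument: str = "tool") -> TrackingLog:
    """Build a log from 4x4 tracker transforms (OpenIGTLink TRANSFORM semantics).

    The tool-tip position is the translation column of each matrix.
    """
    mats = np.asarray(transforms, dtype=float)
    if mats.ndim != 3 or mats.shape[1:] != (4, 4):
        raise ValueError(f"expected (n, 4, 4) transforms, got {mats.shape}")
    xyz = mats[:, :3, 3]
    t = np.asarray(times, dtype=float)
    return TrackingLog(t, xyz, np.full(len(t), instrument, dtype=object).astype(str))
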