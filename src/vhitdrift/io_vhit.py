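"""Reading, writing and segmentation of three-column vHIT recordings.

A recording is a plain-text file with three whitespace- or tab-delimited
columns: time (s), head velocity (deg/s), eye velocity (deg/s), sampled at
a nominally uniform rate (250 Hz for the ICS Impulse device). Continuous
recordings are cut into fixed-length per-impulse windows around each
detected head impulse, and impulses are grouped into the three canal
stimulation protocols (Lateral, LARP, RALP) either from an explicit label
or from the conventional VOR<k> file numbering.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .errors import InputError, ProtocolError, RecordingParseError

PROTOCOLS = ("Lateral", "LARP", "RALP")

#: Default mapping from VOR file number to protocol, following the common
#: clinical session layout: Lateral VOR125-148, LARP VOR149-164,
#: RALP VOR165-181.
DEFAULT_PROTOCOL_RANGES: dict[str, tuple[int, int]] = {
    "Lateral": (125, 148),
    "LARP": (149, 164),
    "RALP": (165, 181),
}

_VOR_RE = re.compile(r"VOR(\d+)", re.IGNORECASE)


@dataclass
class Recording:
    """A synchronized time / head-velocity / eye-velocity recording.

    Parameters
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing.
    head_vel, eye_vel : ndarray
        Head and eye angular velocity in deg/s, same length as ``times``.
    sample_rate : float
        Nominal sampling rate in Hz (default 250). The median sampling
        interval must agree with ``1/sample_rate`` to within 1%.
    label : str or None
        Optional protocol tag (one of ``PROTOCOLS``).
    source_id : str
        Free-text identifier, e.g. ``"VOR165"``.
    """

    times: np.ndarray
    head_vel: np.ndarray
    eye_vel: np.ndarray
    sample_rate: float = 250.0
    label: str | None = None
    source_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.head_vel = np.asarray(self.head_vel, dtype=float)
        self.eye_vel = np.asarray(self.eye_vel, dtype=float)
        n = len(self.times)
        if not (len(self.head_vel) == len(self.eye_vel) == n):
            raise InputError("time, head and eye arrays must have equal length")
        if n < 2:
            raise InputError("a recording needs at least 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise InputError("times must be strictly increasing")
        nominal = 1.0 / self.sample_rate
        if abs(np.median(dt) - nominal) > 0.01 * nominal:
            raise InputError(
                f"median sampling interval {np.median(dt):.6g} s deviates more "
                f"than 1% from nominal {nominal:.6g} s"
            )
        if self.label is not None and self.label not in PROTOCOLS:
            raise InputError(f"unknown protocol label {self.label!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ImpulseWindow:
    """One trimmed head-impulse segment on a local (re-zeroed) time axis."""

    local_times: np.ndarray
    head_vel: np.ndarray
    eye_vel: np.ndarray
    protocol: str | None = None
    impulse_id: int = 0
    source_id: str = ""

    def __post_init__(self):
        self.local_times = np.asarray(self.local_times, dtype=float)
        self.head_vel = np.asarray(self.head_vel, dtype=float)
        self.eye_vel = np.asarray(self.eye_vel, dtype=float)
        if not (len(self.head_vel) == len(self.eye_vel) == len(self.local_times)):
            raise InputError("window arrays must have equal length")
        if len(self.local_times) and self.local_times[0] != 0.0:
            raise InputError("local time axis must start at 0")

    def __len__(self) -> int:
        return len(self.local_times)

    @property
    def duration(self) -> float:
        return float(self.local_times[-1]) if len(self) else 0.0


@dataclass
class ProtocolGrouping:
    """Mapping from VOR file number ranges to protocol names."""

    ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PROTOCOL_RANGES)
    )

    def protocol_for(self, number: int) -> str | None:
        for protocol, (lo, hi) in self.ranges.items():
            if lo <= number <= hi:
                return protocol
        return None


def read_recording(
    path: str | Path,
    sample_rate: float = 250.0,
    label: str | None = None,
    source_id: str | None = None,
) -> Recording:
    """Read a three-column plain-text recording.

    Lines starting with ``#`` and blank lines are skipped; a single leading
    non-numeric header row is tolerated. Any other malformed line raises
    :class:`RecordingParseError` naming its line number.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                values = tuple(float(f) for f in fields)
            except ValueError:
                if not rows and not header_seen:
                    header_seen = True  # one non-numeric header row allowed
                    continue
                raise RecordingParseError(
                    f"non-numeric field in {fields!r}", line_number=lineno
                ) from None
            if len(values) != 3:
                raise RecordingParseError(
                    f"expected 3 columns, found {len(values)}", line_number=lineno
                )
            rows.append(values)
    if len(rows) < 2:
        raise InputError(f"{path}: fewer than 2 data rows")
    data = np.array(rows, dtype=float)
    return Recording(
        times=data[:, 0],
        head_vel=data[:, 1],
        eye_vel=data[:, 2],
        sample_rate=sample_rate,
        label=label,
        source_id=source_id if source_id is not None else path.stem,
    )


def write_recording(rec: Recording | ImpulseWindow, path: str | Path) -> Path:
    """Write a recording or window in the three-column text format.

    Values are written with 6 significant digits, which round-trips through
    :func:`read_recording` at that precision.
    """
    path = Path(path)
    times = rec.local_times if isinstance(rec, ImpulseWindow) else rec.times
    with open(path, "w") as fh:
        fh.write("# time_s\thead_vel_deg_s\teye_vel_deg_s\n")
        for t, h, e in zip(times, rec.head_vel, rec.eye_vel):
            fh.write(f"{t:.6g}\t{h:.6g}\t{e:.6g}\n")
    return path


def segment_impulses(
    rec: Recording,
    threshold: float = 50.0,
    pre_peak: float = 0.25,
    window_length: float = 0.7,
    refractory: float = 0.5,
    protocol: str | None = None,
) -> list[ImpulseWindow]:
    """Cut a continuous recording into fixed-length impulse windows.

    Impulses are detected as local maxima of ``|head_vel|`` exceeding
    ``threshold`` deg/s, at least ``refractory`` seconds apart. Each window
    starts ``pre_peak`` seconds before the detected peak and spans
    ``window_length`` seconds, re-zeroed to a local time axis so the head
    peak sits near ``pre_peak``. Peaks whose window would overrun the
    recording are dropped. Returns an empty list when nothing crosses the
    threshold.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    fs = rec.sample_rate
    speed = np.abs(rec.head_vel)
    distance = max(1, int(round(refractory * fs)))
    peaks, _ = find_peaks(speed, height=threshold, distance=distance)
    n_pre = int(round(pre_peak * fs))
    n_win = int(round(window_length * fs)) + 1
    windows: list[ImpulseWindow] = []
    proto = protocol if protocol is not None else rec.label
    for k, p in enumerate(peaks):
        start = p - n_pre
        stop = start + n_win
        if start < 0 or stop > len(rec):
            continue
        windows.append(
            ImpulseWindow(
                local_times=rec.times[start:stop] - rec.times[start],
                head_vel=rec.head_vel[start:stop].copy(),
                eye_vel=rec.eye_vel[start:stop].copy(),
                protocol=proto,
                impulse_id=len(windows),
                source_id=rec.source_id,
            )
        )
    return windows


def assign_protocol(
    source_id: str,
    grouping: ProtocolGrouping | None = None,
    label: str | None = None,
) -> str:
    """Assign a protocol from an explicit label or a VOR<k> file number.

    An explicit ``label`` always wins. Otherwise the numeric part of a
    ``VOR<k>`` identifier is looked up in ``grouping`` (default: Lateral
    125-148, LARP 149-164, RALP 165-181).
    """
    if label is not None:
        if label not in PROTOCOLS:
            raise ProtocolError(f"unknown protocol label {label!r}")
        return label
    grouping = grouping or ProtocolGrouping()
    m = _VOR_RE.search(source_id)
    if m:
        protocol = grouping.protocol_for(int(m.group(1)))
        if protocol is not None:
            return protocol
    raise ProtocolError(
        f"cannot classify {source_id!r}: not in any protocol range and no label given"
    )


def write_impulse_windows(
    windows: list[ImpulseWindow], outdir: str | Path
) -> tuple[list[Path], Path]:
    """Write one 3-column file per window plus a grouping manifest CSV.

    Files are named ``<source>_impulse<k>.txt``; the manifest has columns
    impulse_id, source_id, protocol, filename.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["impulse_id", "source_id", "protocol", "filename"])
        for w in windows:
            name = f"{w.source_id or 'rec'}_impulse{w.impulse_id}.txt"
            write_recording(w, outdir / name)
            paths.append(outdir / name)
            writer.writerow([w.impulse_id, w.source_id, w.protocol or "", name])
    return paths, manifest


def read_impulse_windows(manifest: str | Path) -> list[ImpulseWindow]:
    """Load impulse windows listed in a grouping manifest CSV."""
    manifest = Path(manifest)
    base = manifest.parent
    windows: list[ImpulseWindow] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = read_recording(
                base / row["filename"], source_id=row["source_id"] or None
            )
            windows.append(
                ImpulseWindow(
                    local_times=rec.times - rec.times[0],
                    head_vel=rec.head_vel,
                    eye_vel=rec.eye_vel,
                    protocol=row["protocol"] or None,
                    impulse_id=int(row["impulse_id"]),
                    source_id=row["source_id"],
                )
            )
    return windows
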