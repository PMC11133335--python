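"""File dialects: recordings as delimited text or HDF5, reports as JSON.

Text recordings carry metadata in ``# key=value`` comment lines (``rate_hz``
is mandatory), a header row of channel labels, then one row per sample.
The HDF5 container stores ``/samples``, ``/rate`` and ``/phase_boundaries``
and round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocessing import ChangePointSet
from .recording import MultiChannelRecording

__all__ = [
    "read_recording",
    "write_recording",
    "write_changepoints",
    "read_changepoints",
    "write_json",
    "read_json",
]


def write_recording(recording: MultiChannelRecording, path: str | Path) -> Path:
    """Write a recording; format chosen by suffix (.h5/.hdf5 binary, else text)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            # track_times=False keeps the file byte-identical across reruns
            f.create_dataset("samples", data=recording.samples, track_times=False)
            f.create_dataset("rate", data=recording.rate, track_times=False)
            if recording.phase_boundaries is not None:
                f.create_dataset(
                    "phase_boundaries",
                    data=recording.phase_boundaries,
                    track_times=False,
                )
            f.attrs["group"] = recording.group
            f.attrs["channel_labels"] = [str(c) for c in recording.channel_labels]
        return path
    with open(path, "w") as f:
        f.write(f"# rate_hz={recording.rate!r}\n")
        f.write(f"# group={recording.group}\n")
        if recording.phase_boundaries is not None:
            f.write(
                "# phase_boundaries="
                + ",".join(str(int(b)) for b in recording.phase_boundaries)
                + "\n"
            )
        f.write(",".join(recording.channel_labels) + "\n")
        np.savetxt(f, recording.samples.T, delimiter=",", fmt="%.17g")
    return path


def read_recording(path: str | Path) -> MultiChannelRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return MultiChannelRecording(
                samples=f["samples"][()],
                rate=float(f["rate"][()]),
                channel_labels=[str(c) for c in f.attrs["channel_labels"]],
                group=str(f.attrs["group"]),
                phase_boundaries=(
                    f["phase_boundaries"][()] if "phase_boundaries" in f else None
                ),
            )
    meta: dict[str, str] = {}
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            cells = line.split(",")
            if labels is None:
                labels = [c.strip() for c in cells]
                continue
            if len(cells) != len(labels):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(labels)} columns, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                bad = next(i for i, c in enumerate(cells) if not _is_float(c))
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {cells[bad]!r} in column "
                    f"{bad + 1} ({labels[bad]})"
                ) from exc
    if "rate_hz" not in meta:
        raise ValueError(f"{path}: missing '# rate_hz=' metadata line")
    if labels is None or not rows:
        raise ValueError(f"{path}: empty recording (no sample rows)")
    boundaries = None
    if "phase_boundaries" in meta and meta["phase_boundaries"]:
        boundaries = np.array([int(b) for b in meta["phase_boundaries"].split(",")])
    return MultiChannelRecording(
        samples=np.array(rows).T,
        rate=float(meta["rate_hz"]),
        channel_labels=labels,
        group=meta.get("group", "synthetic"),
        phase_boundaries=boundaries,
    )


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_changepoints(cp_sets: list[ChangePointSet], path: str | Path) -> Path:
    """Change points as delimited text: channel, time_s, value."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("channel,time_s,value\n")
        for cp in cp_sets:
            for t, v in zip(cp.times, cp.values):
                f.write(f"{cp.channel_id},{float(t):.17g},{float(v):.17g}\n")
    return path


def read_changepoints(path: str | Path) -> list[ChangePointSet]:
    per_channel: dict[str, list[tuple[float, float]]] = {}
    with open(path) as f:
        header = f.readline()
        if not header.startswith("channel"):
            raise ValueError(f"{path}: missing change-point header")
        for line in f:
            ch, t, v = line.strip().split(",")
            per_channel.setdefault(ch, []).append((float(t), float(v)))
    out = []
    for ch, pts in per_channel.items():
        pts.sort()
        out.append(
            ChangePointSet(
                channel_id=ch,
                times=np.array([p[0] for p in pts]),
                values=np.array([p[1] for p in pts]),
                source_length=len(pts),
            )
        )
    return out


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_jsonify)
        f.write("\n")
    return path


def read_json(path: str | Path) -> dict:
    with open(path) as f:
        return json.load(f)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
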