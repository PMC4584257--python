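"""Readers/writers and run manifests shared by the command-line tools.

All delimited text is comma-separated UTF-8 with a header row; numbers
are written with full ``repr`` precision and a decimal point regardless
of locale (pandas defaults).  Spike-train files carry two columns,
``time_s`` and ``source_id``, sorted and strictly increasing per
source.  Run manifests are JSON documents recording the command, the
configuration snapshot, the seeds and the outputs, enough to re-execute
a run exactly.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stp import SpikeTrain

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "write_outcomes",
    "read_fit_targets",
    "write_fit_targets",
    "RunManifest",
]


def read_spike_trains(path: str | os.PathLike) -> list[SpikeTrain]:
    """Load spike trains from a (time_s, source_id) table.

    Rows may be interleaved across sources but must be sorted and
    strictly increasing within each source; violations report the
    offending file line (header = line 1).
    """
    frame = pd.read_csv(path)
    missing = {"time_s", "source_id"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    trains = []
    for source, group in frame.groupby("source_id", sort=True):
        times = group["time_s"].to_numpy(dtype=float)
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            bad = int(group.index[int(np.nonzero(diffs <= 0)[0][0]) + 1]) + 2
            raise ValueError(
                f"{path}: line {bad}: spike times of source {source!r} "
                "must be strictly increasing"
            )
        trains.append(SpikeTrain(times=times, id=str(source)))
    return trains


def write_spike_trains(path: str | os.PathLike, trains: list[SpikeTrain]) -> None:
    rows = [
        {"time_s": t, "source_id": train.id} for train in trains for t in train.times
    ]
    pd.DataFrame(rows, columns=["time_s", "source_id"]).to_csv(path, index=False)


def write_outcomes(path: str | os.PathLike, rows: list[dict]) -> None:
    """Protocol outcome table: (protocol_id, P_ratio, q_ratio, w_ratio)."""
    pd.DataFrame(rows, columns=["protocol_id", "P_ratio", "q_ratio", "w_ratio"]).to_csv(
        path, index=False
    )


def read_fit_targets(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"freq_hz", "delta_t_ms", "p_ratio", "q_ratio"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return frame


def write_fit_targets(path: str | os.PathLike, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Reproducibility record written at the end of every CLI run."""

    command: str
    config: dict
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    started_at: str = ""
    finished_at: str = ""

    def write(self, directory: str | os.PathLike) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        self.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        path = Path(directory) / "manifest.json"
        tmp = path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2, default=str))
        tmp.replace(path)  # atomic on POSIX
        return path
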