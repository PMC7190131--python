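"""Bundled survival datasets and CSV I/O.

The CSV dialect is minimal: comma-separated, UTF-8, a required header, and
columns ``time,event`` with ``event`` in {0, 1} (1 = failure observed,
0 = right-censored).  A single-column file with only ``time`` is read as
complete data.  Times are stored at the full precision printed in their
sources and are not re-rounded on write.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import SurvivalSample

__all__ = [
    "DatasetFixture",
    "read_survival_csv",
    "write_survival_csv",
    "format_plus_list",
    "load_fixture",
    "list_fixtures",
]

_FIXTURE_SHA256 = {
    "leukemia46": "f17660d74191b801bed221a3bdd2a4a203c16d3c7118155b4e22a5b635f1cb93",
}


@dataclass(frozen=True)
class DatasetFixture:
    """A named bundled dataset with provenance note."""

    name: str
    sample: SurvivalSample
    note: str


def read_survival_csv(path) -> SurvivalSample:
    """Read a ``time,event`` CSV (or single ``time`` column) as a sample.

    Raises descriptive errors on empty files, non-positive times and
    non-binary event codes.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if "time" not in frame.columns:
        raise ValueError(f"{path}: header must contain a 'time' column")
    times = frame["time"].to_numpy(dtype=float)
    if times.size == 0:
        raise ValueError(f"{path}: no observations")
    if np.any(times <= 0):
        raise ValueError(f"{path}: observation times must be strictly positive")
    if "event" in frame.columns:
        events = frame["event"].to_numpy()
        if not np.all(np.isin(events, (0, 1))):
            bad = sorted(set(events) - {0, 1})
            raise ValueError(f"{path}: event codes must be 0 or 1, found {bad}")
        events = events.astype(int)
        scheme = "complete" if np.all(events == 1) else "random"
    else:
        events = np.ones_like(times, dtype=int)
        scheme = "complete"
    return SurvivalSample(times=times, events=events, scheme=scheme)


def write_survival_csv(sample: SurvivalSample, path) -> None:
    """Write a sample as a ``time,event`` CSV; exact inverse of the reader."""
    if sample.times.size == 0:
        raise ValueError("refusing to write an empty sample")
    frame = pd.DataFrame({"time": sample.times, "event": sample.events})
    frame.to_csv(path, index=False, float_format="%.4f")


def format_plus_list(sample: SurvivalSample) -> str:
    """Render a censored sample in the plus-sign notation of printed data
    listings, where '+' marks right-censored observations."""
    parts = [
        f"{t:.4f}+" if e == 0 else f"{t:.4f}"
        for t, e in zip(sample.times, sample.events)
    ]
    return ", ".join(parts)


def _fixture_path(name: str):
    return resources.files("letdist.data").joinpath(f"{name}.csv")


def list_fixtures() -> list[str]:
    return sorted(_FIXTURE_SHA256)


def load_fixture(name: str) -> DatasetFixture:
    """Load a bundled dataset by name, verifying its checksum.

    ``leukemia46``: recurrence times (years) of leukemia for 46 patients who
    received autologous marrow transplants; 33 recurrences observed, 13
    randomly right-censored.
    """
    if name not in _FIXTURE_SHA256:
        raise KeyError(f"unknown fixture {name!r}; available: {list_fixtures()}")
    ref = _fixture_path(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name!r} failed checksum verification")
    with resources.as_file(ref) as p:
        sample = read_survival_csv(Path(p))
    notes = {
        "leukemia46": (
            "Recurrence of leukemia (years) for 46 autologous-marrow "
            "transplant patients; randomly right-censored (13 of 46)."
        )
    }
    return DatasetFixture(name=name, sample=sample, note=notes[name])
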