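"""Dataset containers and CSV + sidecar I/O for FMG recordings.

A subject's recording is a time-synchronized pair of matrices: the FMG
channels (force-sensing resistors worn in four bands on the arm) and the
six load-cell axes (Fx, Fy, Fz in N; Tx, Ty, Tz in Nm), annotated per
sample with a trial id and a session label.  The on-disk format is one CSV
per subject (``sample_index, trial_id, session_id, ch_001..ch_NNN, Fx..Tz``)
plus a JSON sidecar holding the band layout, the active-sensor mask, and
generation metadata.

Band positions are numbered 1 (wrist), 2 (forearm midway), 3 (forearm
muscle belly, the widest forearm circumference) and 4 (upper arm).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

AXES: tuple[str, ...] = ("Fx", "Fy", "Fz", "Tx", "Ty", "Tz")
FREE_SESSION = "free"
SESSIONS: tuple[str, ...] = AXES + (FREE_SESSION,)

#: Default per-band sensor counts, wrist -> upper arm.
DEFAULT_BAND_SIZES: tuple[int, ...] = (12, 16, 16, 16)


@dataclass(frozen=True)
class BandLayout:
    """Channel-to-band assignment plus the active-sensor mask.

    ``band_sizes`` lists the number of FSR channels per band position
    (1..4, ordered wrist -> midway -> muscle belly -> upper arm).  The
    default layout has 12 + 16 + 16 + 16 = 60 channels.  ``active_mask``
    marks which channels were actually in contact with the skin; inactive
    channels are dropped before any analysis.
    """

    band_sizes: tuple[int, ...] = DEFAULT_BAND_SIZES
    active_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.band_sizes):
            raise ConfigError("every band must contain at least one channel")
        if self.active_mask is None:
            object.__setattr__(
                self, "active_mask", tuple([True] * self.n_channels)
            )
        else:
            object.__setattr__(self, "active_mask", tuple(bool(a) for a in self.active_mask))
        if len(self.active_mask) != self.n_channels:
            raise ConfigError(
                f"active_mask length {len(self.active_mask)} != channel count {self.n_channels}"
            )
        bands = self.channel_bands
        for pos in range(1, len(self.band_sizes) + 1):
            idx = [i for i, b in enumerate(bands) if b == pos]
            if not any(self.active_mask[i] for i in idx):
                raise ConfigError(f"band {pos} has no active channel")

    @property
    def n_channels(self) -> int:
        return int(sum(self.band_sizes))

    @property
    def n_bands(self) -> int:
        return len(self.band_sizes)

    @property
    def channel_bands(self) -> tuple[int, ...]:
        """Band position (1-based) of every channel, in channel order."""
        out: list[int] = []
        for pos, size in enumerate(self.band_sizes, start=1):
            out.extend([pos] * size)
        return tuple(out)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(f"ch_{i + 1:03d}" for i in range(self.n_channels))

    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.active_mask, dtype=bool))


@dataclass(frozen=True)
class BandCombination:
    """A nonempty subset of band positions used as model input."""

    included_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(int(p) for p in self.included_positions)))
        if not pos:
            raise ConfigError("band combination must be nonempty")
        if any(p < 1 or p > 4 for p in pos):
            raise ConfigError(f"invalid band positions {pos}; must be within 1..4")
        object.__setattr__(self, "included_positions", pos)

    def __str__(self) -> str:
        return "+".join(str(p) for p in self.included_positions)


def enumerate_combinations() -> list[BandCombination]:
    """All 15 nonempty band subsets, ordered by size then lexicographically."""
    combos: list[BandCombination] = []
    for size in range(1, 5):
        for subset in itertools.combinations(range(1, 5), size):
            combos.append(BandCombination(subset))
    return combos


@dataclass
class SubjectDataset:
    """All trials of one subject: FMG matrix, 6-DoF labels, and indexing.

    ``fmg`` is samples x channels (raw, nonnegative sensor units) and
    ``labels`` is samples x 6 in the fixed axis order ``AXES``.
    ``channel_bands`` records the band position of each retained channel so
    band selection survives active-sensor masking.
    """

    fmg: np.ndarray
    labels: np.ndarray
    trial_id: np.ndarray
    session_id: np.ndarray
    layout: BandLayout
    channel_names: tuple[str, ...]
    channel_bands: tuple[int, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fmg = np.asarray(self.fmg, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.trial_id = np.asarray(self.trial_id)
        self.session_id = np.asarray(self.session_id, dtype=object)
        n = self.fmg.shape[0]
        if self.labels.shape != (n, len(AXES)):
            raise DataError(
                f"labels shape {self.labels.shape} does not match {n} samples x {len(AXES)} axes"
            )
        if len(self.trial_id) != n or len(self.session_id) != n:
            raise DataError("trial_id/session_id length must match sample count")
        if self.fmg.shape[1] != len(self.channel_names) or len(self.channel_names) != len(
            self.channel_bands
        ):
            raise DataError("channel bookkeeping does not match FMG column count")

    @property
    def n_samples(self) -> int:
        return int(self.fmg.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.fmg.shape[1])

    @property
    def trials(self) -> np.ndarray:
        return np.unique(self.trial_id)

    def _subset_rows(self, mask: np.ndarray) -> "SubjectDataset":
        return SubjectDataset(
            fmg=self.fmg[mask],
            labels=self.labels[mask],
            trial_id=self.trial_id[mask],
            session_id=self.session_id[mask],
            layout=self.layout,
            channel_names=self.channel_names,
            channel_bands=self.channel_bands,
            meta=dict(self.meta),
        )

    def select_trials(self, trials: Iterable[int]) -> "SubjectDataset":
        trials = set(int(t) for t in trials)
        mask = np.array([int(t) in trials for t in self.trial_id])
        if not mask.any():
            raise DataError(f"no samples for trials {sorted(trials)}")
        return self._subset_rows(mask)

    def select_sessions(self, sessions: Iterable[str]) -> "SubjectDataset":
        sessions = set(sessions)
        unknown = sessions - set(SESSIONS)
        if unknown:
            raise DataError(f"unknown session labels {sorted(unknown)}")
        mask = np.array([s in sessions for s in self.session_id])
        if not mask.any():
            raise DataError(f"no samples for sessions {sorted(sessions)}")
        return self._subset_rows(mask)

    def apply_mask(self) -> "SubjectDataset":
        """Drop inactive channels per the layout's active-sensor mask."""
        full = self.layout.channel_names
        if self.channel_names != full:
            return self  # mask already applied
        keep = self.layout.active_indices()
        return SubjectDataset(
            fmg=self.fmg[:, keep],
            labels=self.labels,
            trial_id=self.trial_id,
            session_id=self.session_id,
            layout=self.layout,
            channel_names=tuple(full[i] for i in keep),
            channel_bands=tuple(self.layout.channel_bands[i] for i in keep),
            meta=dict(self.meta),
        )


def select_bands(ds: SubjectDataset, combo: BandCombination) -> SubjectDataset:
    """Restrict the FMG matrix to channels of the included band positions."""
    keep = [i for i, b in enumerate(ds.channel_bands) if b in combo.included_positions]
    if not keep:
        raise DataError(f"band combination {combo} selects no channels")
    return SubjectDataset(
        fmg=ds.fmg[:, keep],
        labels=ds.labels,
        trial_id=ds.trial_id,
        session_id=ds.session_id,
        layout=ds.layout,
        channel_names=tuple(ds.channel_names[i] for i in keep),
        channel_bands=tuple(ds.channel_bands[i] for i in keep),
        meta=dict(ds.meta),
    )


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def save_dataset(ds: SubjectDataset, csv_path: str | Path) -> Path:
    """Write a subject to CSV plus a JSON sidecar; returns the CSV path.

    All channels in ``ds`` are written (call before masking to preserve the
    raw 60-channel recording); labels keep full float precision via repr.
    """
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"sample_index": np.arange(ds.n_samples)})
    df["trial_id"] = ds.trial_id.astype(int)
    df["session_id"] = ds.session_id.astype(str)
    for j, name in enumerate(ds.channel_names):
        df[name] = ds.fmg[:, j]
    for j, ax in enumerate(AXES):
        df[ax] = ds.labels[:, j]
    df.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "band_sizes": list(ds.layout.band_sizes),
        "active_mask": [bool(a) for a in ds.layout.active_mask],
        "channel_names": list(ds.channel_names),
        "channel_bands": list(ds.channel_bands),
        "meta": ds.meta,
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def load_dataset(csv_path: str | Path) -> SubjectDataset:
    """Load a subject CSV + sidecar and drop inactive channels per the mask."""
    csv_path = Path(csv_path)
    side = _sidecar_path(csv_path)
    if not csv_path.exists():
        raise DataError(f"dataset file not found: {csv_path}")
    if not side.exists():
        raise DataError(f"missing sidecar for {csv_path}: expected {side}")
    sidecar = json.loads(side.read_text())
    layout = BandLayout(
        band_sizes=tuple(sidecar["band_sizes"]),
        active_mask=tuple(sidecar["active_mask"]),
    )
    # tolerate comma- or tab-delimited files
    df = pd.read_csv(csv_path, sep=None, engine="python")
    expected = list(sidecar["channel_names"])
    missing = [c for c in expected + list(AXES) + ["sample_index", "trial_id", "session_id"] if c not in df.columns]
    if missing:
        raise DataError(f"dataset {csv_path} is missing columns {missing}")
    if len(expected) != layout.n_channels:
        raise DataError("sidecar channel list does not match band sizes")
    idx = df["sample_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise DataError("sample_index must be strictly increasing")
    ds = SubjectDataset(
        fmg=df[expected].to_numpy(dtype=float),
        labels=df[list(AXES)].to_numpy(dtype=float),
        trial_id=df["trial_id"].to_numpy(),
        session_id=df["session_id"].to_numpy(dtype=object),
        layout=layout,
        channel_names=tuple(expected),
        channel_bands=tuple(sidecar["channel_bands"]),
        meta=dict(sidecar.get("meta", {})),
    )
    return ds.apply_mask()
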