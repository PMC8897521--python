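"""In-memory and on-disk containers for epoched multi-channel EEG.

The canonical object is :class:`EpochSet`: a ``trials x channels x samples``
voltage array in microvolts with a millisecond time axis and a pandas
DataFrame of per-trial metadata aligned to the first axis.  Epochs serialize
to a portable HDF5 layout (datasets ``data``/``time_ms``/``channels`` plus the
trial table as JSON) and, for tiny fixtures, to a plain directory of CSV
files.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Epoched EEG: voltage array with time axis, channel labels and trial metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    channels
        Channel labels aligned to axis 1.  Labels must be unique.
    times
        Sample times in milliseconds relative to stimulus onset, aligned to
        axis 2; strictly increasing with a constant step of
        ``1000 / sfreq``.
    sfreq
        Sampling rate in Hz.
    trials
        Per-trial metadata aligned to axis 0 (one row per epoch).
    """

    data: np.ndarray
    channels: list[str]
    times: np.ndarray
    sfreq: float
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-dimensional (trials x channels x samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.channels) != n_channels:
            raise ValueError(
                f"channel labels ({len(self.channels)}) do not match data axis 1 ({n_channels})"
            )
        if len(set(self.channels)) != n_channels:
            raise ValueError("channel labels must be unique")
        if self.times.shape != (n_samples,):
            raise ValueError("time axis does not match data axis 2")
        if n_samples >= 2:
            steps = np.diff(self.times)
            expected = 1000.0 / self.sfreq
            if np.any(steps <= 0) or not np.allclose(steps, expected, rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must increase with constant step 1000/sfreq")
        if len(self.trials) == 0 and n_trials > 0:
            self.trials = pd.DataFrame(index=range(n_trials))
        if len(self.trials) != n_trials:
            raise ValueError(
                f"trial table ({len(self.trials)}) does not match data axis 0 ({n_trials})"
            )
        self.trials = self.trials.reset_index(drop=True)

    # -- basic introspection ------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def get_channel(self, label: str) -> np.ndarray:
        """Voltage traces for one channel, shape ``(n_trials, n_samples)``."""
        return self.data[:, self.channel_index(label), :]

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for a closed time window (both ends inclusive)."""
        lo, hi = window_ms
        if hi < lo:
            raise ValueError(f"window {window_ms} is empty")
        mask = (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)
        if not mask.any():
            raise ValueError(f"window {window_ms} contains no samples")
        return mask

    # -- selection ----------------------------------------------------------

    def select_trials(self, index) -> "EpochSet":
        """Subset trials by boolean mask or integer index, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            if index.shape != (self.n_trials,):
                raise ValueError("boolean mask length does not match trial count")
            index = np.flatnonzero(index)
        return EpochSet(
            data=self.data[index],
            channels=list(self.channels),
            times=self.times.copy(),
            sfreq=self.sfreq,
            trials=self.trials.iloc[index].reset_index(drop=True),
        )

    def drop_channels(self, labels) -> "EpochSet":
        keep = [i for i, ch in enumerate(self.channels) if ch not in set(labels)]
        return EpochSet(
            data=self.data[:, keep, :],
            channels=[self.channels[i] for i in keep],
            times=self.times.copy(),
            sfreq=self.sfreq,
            trials=self.trials.copy(),
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            channels=list(self.channels),
            times=self.times.copy(),
            sfreq=self.sfreq,
            trials=self.trials.copy(),
        )

    # -- serialization ------------------------------------------------------

    def to_hdf5(self, path) -> None:
        """Write to an HDF5 file (``data``, ``time_ms``, ``channels`` + JSON trial table)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", compression_opts=4)
            f.create_dataset("time_ms", data=self.times)
            f.create_dataset(
                "channels", data=np.array(self.channels, dtype=h5py.string_dtype())
            )
            f.attrs["sfreq"] = float(self.sfreq)
            f.attrs["trials_json"] = self.trials.to_json(orient="split")

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["time_ms"][()]
            channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
            sfreq = float(f.attrs["sfreq"])
            trials = pd.read_json(io.StringIO(f.attrs["trials_json"]), orient="split")
        return cls(data=data, channels=channels, times=times, sfreq=sfreq, trials=trials)

    def to_csv_dir(self, directory) -> None:
        """Plain-text fallback for tiny fixtures: one CSV per trial plus metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"sfreq": float(self.sfreq), "channels": self.channels,
                "time_ms": self.times.tolist(), "n_trials": self.n_trials}
        (directory / "meta.json").write_text(json.dumps(meta))
        self.trials.to_csv(directory / "trials.csv", index=False)
        for i in range(self.n_trials):
            pd.DataFrame(self.data[i].T, columns=self.channels).to_csv(
                directory / f"trial_{i:04d}.csv", index=False
            )

    @classmethod
    def from_csv_dir(cls, directory) -> "EpochSet":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        trials = pd.read_csv(directory / "trials.csv")
        data = np.stack(
            [
                pd.read_csv(directory / f"trial_{i:04d}.csv").to_numpy().T
                for i in range(meta["n_trials"])
            ]
        ) if meta["n_trials"] else np.zeros((0, len(meta["channels"]), len(meta["time_ms"])))
        return cls(
            data=data,
            channels=meta["channels"],
            times=np.asarray(meta["time_ms"]),
            sfreq=meta["sfreq"],
            trials=trials,
        )
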