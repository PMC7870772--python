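"""In-memory container and HDF5 round-trip for EEG epoch arrays.

Epochs are a (trials x electrodes x samples) float array in microvolts
with NaN marking missing samples, a uniform time axis in milliseconds
(relative to the response for response-locked data), channel names, and a
symmetric electrode-neighbour adjacency used for interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGEpochArray", "make_montage"]


@dataclass
class EEGEpochArray:
    data: np.ndarray  # trials x electrodes x samples, microvolts, NaN = missing
    time_ms: np.ndarray
    channel_names: list
    neighbours: list  # per-electrode lists of neighbour indices (symmetric)
    sample_rate: float
    trial_index: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be trials x electrodes x samples, got shape {self.data.shape}")
        if self.time_ms.shape[0] != self.data.shape[2]:
            raise ValueError("time axis length does not match sample count")
        steps = np.diff(self.time_ms)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("time axis must be strictly increasing and uniform")
        if len(steps) and not np.isclose(steps[0], 1000.0 / self.sample_rate):
            raise ValueError("time-axis step does not match sample_rate")
        for e, nbrs in enumerate(self.neighbours):
            for n in nbrs:
                if e not in self.neighbours[n]:
                    raise ValueError(f"neighbour metadata not symmetric at electrodes {e}/{n}")
        if self.trial_index is None:
            self.trial_index = np.arange(self.data.shape[0])
        self.trial_index = np.asarray(self.trial_index)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, data: np.ndarray, **kw) -> "EEGEpochArray":
        return replace(self, data=data, **kw)

    def to_hdf5(self, path) -> None:
        import h5py

        nmax = max((len(n) for n in self.neighbours), default=0)
        adj = np.full((self.n_electrodes, nmax), -1, dtype=np.int64)
        for e, nbrs in enumerate(self.neighbours):
            adj[e, : len(nbrs)] = sorted(nbrs)
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.data)
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset("trial_index", data=self.trial_index)
            f.create_dataset(
                "channel_names", data=np.array(self.channel_names, dtype=h5py.string_dtype())
            )
            f.create_dataset("neighbours", data=adj)
            f.attrs["sample_rate"] = self.sample_rate

    @classmethod
    def from_hdf5(cls, path) -> "EEGEpochArray":
        import h5py

        with h5py.File(path, "r") as f:
            adj = f["neighbours"][...]
            neighbours = [[int(v) for v in row if v >= 0] for row in adj]
            return cls(
                data=f["epochs"][...],
                time_ms=f["time_ms"][...],
                channel_names=[s.decode() if isinstance(s, bytes) else s for s in f["channel_names"][...]],
                neighbours=neighbours,
                sample_rate=float(f.attrs["sample_rate"]),
                trial_index=f["trial_index"][...],
            )


def make_montage(n_electrodes: int, seed: int = 12345):
    """Deterministic synthetic sensor layout on a disc.

    Electrodes are placed on a sunflower (Fibonacci) spiral; interior
    electrodes link to their 6 nearest neighbours and perimeter electrodes
    (outermost ring, ~the convex edge of the layout) to their 4 nearest,
    after which the adjacency is symmetrised.  Returns (positions (E, 2),
    neighbour lists).
    """
    i = np.arange(n_electrodes)
    r = np.sqrt((i + 0.5) / n_electrodes)
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))
    pos = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
    perimeter = r > np.quantile(r, 0.8)
    neighbours = [set() for _ in range(n_electrodes)]
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    for e in range(n_electrodes):
        k = 4 if perimeter[e] else 6
        k = min(k, n_electrodes - 1)
        for n in np.argsort(d2[e])[:k]:
            neighbours[e].add(int(n))
            neighbours[int(n)].add(e)
    return pos, [sorted(s) for s in neighbours]
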