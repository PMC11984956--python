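"""Core data carriers shared across the pipelines.

Images travel as :class:`ImageField` (channel-first raster with a physical
pixel size); single-molecule localization data travel as plain
:class:`pandas.DataFrame` objects with the column schema in
:data:`LOC_COLUMNS`; hierarchical (condition / replicate / cell)
measurements travel as :class:`NestedDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Column schema for localization tables. Coordinates are in nanometres,
#: ``crlb_xy_nm`` is the lateral Cramér–Rao lower bound reported by the
#: upstream fitter, ``channel`` is a small integer identifier.
LOC_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "photons", "crlb_xy_nm", "channel"]


def validate_localizations(locs: pd.DataFrame) -> pd.DataFrame:
    """Check a localization table against the standard schema.

    Returns the table unchanged; raises ``ValueError`` on missing columns,
    non-finite coordinates or negative frame indices.
    """
    missing = [c for c in LOC_COLUMNS if c not in locs.columns]
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    coords = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("localization coordinates must be finite")
    if (locs["frame"].to_numpy() < 0).any():
        raise ValueError("frame indices must be nonnegative")
    return locs


@dataclass
class ImageField:
    """Multi-channel 2D raster with physical pixel size.

    Parameters
    ----------
    data : ndarray, shape (n_channels, H, W)
        Intensity data, float or unsigned integer.
    pixel_size_nm : float
        Edge length of one pixel in nanometres.
    channel_names : sequence of str
        One name per channel, e.g. ``("CEP170", "POI")``.
    """

    data: np.ndarray
    pixel_size_nm: float
    channel_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("image data must be (channels, H, W)")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, name: str | int) -> np.ndarray:
        """Return one channel as a 2D float array."""
        if isinstance(name, (int, np.integer)):
            return np.asarray(self.data[int(name)], dtype=float)
        try:
            idx = list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {tuple(self.channel_names)}"
            ) from None
        return np.asarray(self.data[idx], dtype=float)


@dataclass
class NestedDataset:
    """Measurements for one condition, grouped replicate -> cell values.

    ``replicates`` is a list of per-replicate value lists; the hierarchy is
    what nested tests operate on (replicate means, never pooled cells).
    """

    condition: str
    replicates: list[list[float]]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate required")
        for rep in self.replicates:
            if len(rep) < 1:
                raise ValueError("each replicate needs at least one value")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def replicate_means(self) -> np.ndarray:
        return np.array([np.mean(rep) for rep in self.replicates], dtype=float)

    def all_values(self) -> np.ndarray:
        return np.concatenate([np.asarray(r, dtype=float) for r in self.replicates])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": self.condition, "replicate": i, "value": float(v)}
            for i, rep in enumerate(self.replicates)
            for v in rep
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str | None = None) -> "NestedDataset":
        """Build from a long table with condition/replicate/value columns."""
        if condition is not None:
            df = df[df["condition"] == condition]
        else:
            conds = df["condition"].unique()
            if len(conds) != 1:
                raise ValueError("frame holds multiple conditions; pass one")
            condition = conds[0]
        reps = [
            g["value"].astype(float).tolist()
            for _, g in df.groupby("replicate", sort=True)
        ]
        return cls(condition=str(condition), replicates=reps)
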