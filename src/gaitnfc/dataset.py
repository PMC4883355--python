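"""Labelled gait-signal datasets.

A :class:`GaitDataset` holds a dimensions x samples signal matrix (each
column one 100-sample hip-height window) plus a gait label per column.
The four gaits are coded 1..4 in the fixed order walk, sitting trot,
rising trot, canter; the scalar code is the regression target of the
neuro-fuzzy classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["GAITS", "DEFAULT_CLASS_CODES", "GaitDataset",
           "read_dataset", "write_dataset"]

#: Gait labels in canonical (code) order.
GAITS: tuple[str, ...] = ("walk", "sitting_trot", "rising_trot", "canter")

#: label -> integer class code, consecutive from 1.
DEFAULT_CLASS_CODES: dict[str, int] = {g: i + 1 for i, g in enumerate(GAITS)}


@dataclass
class GaitDataset:
    """Signal matrix with per-sample gait labels.

    Parameters
    ----------
    signals : ndarray, shape (n_dims, n_samples)
        Samples are columns (the table convention: a 100 x 160 study is
        160 windows of 100 frames each).
    labels : sequence of str
        One gait label per column.
    class_codes : dict
        label -> distinct consecutive integer codes starting at 1.
    """

    signals: np.ndarray
    labels: list[str]
    class_codes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CODES)
    )

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.labels = list(self.labels)
        if self.signals.shape[1] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for {self.signals.shape[1]} "
                "signal columns"
            )
        codes = sorted(self.class_codes.values())
        if codes != list(range(1, len(codes) + 1)):
            raise ValueError(
                "class codes must be distinct consecutive integers from 1"
            )
        unknown = set(self.labels) - set(self.class_codes)
        if unknown:
            raise ValueError(f"labels without a class code: {sorted(unknown)}")

    @property
    def n_dims(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def codes(self) -> np.ndarray:
        """Integer class code per column."""
        return np.array([self.class_codes[l] for l in self.labels], dtype=int)

    def select(self, indices: Sequence[int]) -> "GaitDataset":
        """Column subset as a new dataset (order as given)."""
        idx = np.asarray(indices, dtype=int)
        return GaitDataset(
            signals=self.signals[:, idx].copy(),
            labels=[self.labels[i] for i in idx],
            class_codes=dict(self.class_codes),
        )

    def counts(self) -> dict[str, int]:
        """Samples per gait label."""
        return {g: self.labels.count(g) for g in self.class_codes}

    def plot(self, ax=None, max_per_gait: int = 3):
        """Overlay a few signals per gait (one colour per gait)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for gait in self.class_codes:
            cols = [i for i, l in enumerate(self.labels) if l == gait]
            for j, i in enumerate(cols[:max_per_gait]):
                ax.plot(self.signals[:, i],
                        label=gait if j == 0 else None, alpha=0.7)
        ax.set_xlabel("frame")
        ax.set_ylabel("hip height")
        ax.legend()
        return ax


def write_dataset(data: GaitDataset, path: str | Path,
                  delimiter: str = ",") -> None:
    """Write signals as delimited text (columns = samples) with the labels
    in a sidecar file ``<path>.labels`` (one label per line)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gait signal matrix: rows=dimensions, columns=samples\n")
        for row in data.signals:
            fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")
    with open(path.with_suffix(path.suffix + ".labels"), "w") as fh:
        fh.write("\n".join(data.labels) + "\n")


def read_dataset(path: str | Path, delimiter: str = ",") -> GaitDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(v) for v in line.split(delimiter)])
    labels_path = path.with_suffix(path.suffix + ".labels")
    labels = [l for l in labels_path.read_text().splitlines() if l]
    return GaitDataset(signals=np.array(rows, dtype=float), labels=labels)
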