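"""Recording normalization and fixed-length epoch segmentation.

Each recording is z-scored over its full length (normalization precedes
segmentation) and then cut into non-overlapping 30 s epochs; a trailing
partial epoch is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthgen import BCGRecord, HC_LABEL, HPT_LABEL

__all__ = [
    "DegenerateSignalError",
    "Epoch",
    "EpochDataset",
    "zscore_normalize",
    "segment_epochs",
    "build_epoch_dataset",
]


class DegenerateSignalError(ValueError):
    """Raised for signals whose z-score is undefined (constant or empty)."""


@dataclass
class Epoch:
    """One fixed-length normalized segment, traceable to its recording."""

    subject_id: str
    label: str
    index: int  # 0-based position within the parent recording
    fs: float
    samples: np.ndarray


def zscore_normalize(record: BCGRecord, ddof: int = 1) -> BCGRecord:
    """Return a copy of ``record`` with samples mapped to (Q - mu) / sigma.

    mu and sigma are computed over the whole recording.  ``ddof=1`` gives
    the sample (n-1) standard deviation; pass ``ddof=0`` for the population
    form.  Raises :class:`DegenerateSignalError` for empty or constant input.
    """
    x = np.asarray(record.samples, dtype=float)
    if x.size < 2:
        raise DegenerateSignalError("z-score needs at least 2 samples")
    sigma = float(np.std(x, ddof=ddof))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise DegenerateSignalError("constant signal: standard deviation is zero")
    z = (x - float(np.mean(x))) / sigma
    return BCGRecord(record.subject_id, record.label, record.fs, z, dict(record.meta))


def segment_epochs(record: BCGRecord, epoch_s: float = 30.0) -> list[Epoch]:
    """Cut a recording into consecutive epochs of ``epoch_s`` seconds.

    Returns ``floor(n_samples / (epoch_s * fs))`` epochs; the trailing
    remainder is dropped.  A recording shorter than one epoch yields an
    empty list.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be > 0")
    epoch_len = int(round(epoch_s * record.fs))
    n_epochs = len(record.samples) // epoch_len
    return [
        Epoch(
            subject_id=record.subject_id,
            label=record.label,
            index=i,
            fs=record.fs,
            samples=record.samples[i * epoch_len : (i + 1) * epoch_len],
        )
        for i in range(n_epochs)
    ]


@dataclass
class EpochDataset:
    """All epochs of a dataset plus per-class counts."""

    epochs: list[Epoch]
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.counts.get(HC_LABEL, 0) + self.counts.get(HPT_LABEL, 0)

    def index_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": e.subject_id,
                "label": e.label,
                "epoch_index": e.index,
                "start_sample": e.index * len(e.samples),
            }
            for e in self.epochs
        ]
        return pd.DataFrame(rows, columns=["subject_id", "label", "epoch_index", "start_sample"])

    def write_index(self, path: str | Path) -> None:
        self.index_frame().to_csv(path, index=False)


def build_epoch_dataset(
    records: Sequence[BCGRecord],
    epoch_s: float = 30.0,
    normalize: bool = True,
) -> EpochDataset:
    """Normalize (optionally) and segment every recording; tally per class.

    Every record must carry an HC or HPT label.  The returned count table
    satisfies ``total == counts[HC] + counts[HPT]``.
    """
    epochs: list[Epoch] = []
    counts = {HC_LABEL: 0, HPT_LABEL: 0}
    for rec in records:
        if rec.label not in counts:
            raise ValueError(f"record {rec.subject_id!r} has unknown label {rec.label!r}")
        r = zscore_normalize(rec) if normalize else rec
        segs = segment_epochs(r, epoch_s)
        counts[rec.label] += len(segs)
        epochs.extend(segs)
    return EpochDataset(epochs=epochs, counts=counts)
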