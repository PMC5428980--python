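"""Container for a discrete, finite real-valued signal.

A signal is a function f on {1, 2, ..., n}: minute-level activity counts in
the intended application, but any finite real sequence is accepted.  Indices
are 1-based throughout the package to match the usual time-series convention
of "minute 1 .. minute n"; NumPy positions are an internal detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["Signal"]


@dataclass(frozen=True)
class Signal:
    """A finite real-valued sequence with optional provenance metadata.

    Parameters
    ----------
    values :
        Sequence of finite floats.  Stored as a read-only float64 array.
    sample_period :
        Duration of one sample in minutes.  Metadata only; no operation
        rescales by it.
    participant_id :
        Optional identifier of the subject the signal was recorded from.
    """

    values: np.ndarray
    sample_period: float = 1.0
    participant_id: Optional[str] = None

    def __init__(
        self,
        values: Sequence[float],
        sample_period: float = 1.0,
        participant_id: Optional[str] = None,
    ) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"signal must be one-dimensional, got shape {arr.shape}")
        if arr.size and not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(
                f"signal contains a non-finite value at 1-based index {bad + 1}"
            )
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "sample_period", float(sample_period))
        object.__setattr__(self, "participant_id", participant_id)

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, index: int) -> float:
        """Value at 1-based index ``index`` (1 <= index <= n)."""
        n = len(self)
        if not 1 <= index <= n:
            raise IndexError(f"1-based index {index} out of range [1, {n}]")
        return float(self.values[index - 1])

    def crop(self, length: int) -> "Signal":
        """First ``length`` samples as a new signal."""
        if length < 0:
            raise ValueError("length must be nonnegative")
        return Signal(
            self.values[:length],
            sample_period=self.sample_period,
            participant_id=self.participant_id,
        )
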