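"""Rectangular windowing of a signal into per-window persistence diagrams.

The signal is split into consecutive, equal-length, non-overlapping
segments (no tapering); a trailing partial window is dropped.  One
persistence diagram is computed per window, independently of all others:
there is no cross-window state and no boundary correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .persistence import PersistenceDiagram, compute_diagram
from .signal import Signal

__all__ = ["WindowConfig", "DiagramSequence", "segment", "windowed_diagrams"]

DEFAULT_WINDOW_LENGTH = 20


@dataclass(frozen=True)
class WindowConfig:
    """Windowing parameters.

    window_length : samples per window (default 20). A 7000-minute activity
    signal then yields 350 windows; lengths 15-25 behave comparably for
    minute-level counts.  The trailing remainder shorter than one window is
    always dropped.
    """

    window_length: int = DEFAULT_WINDOW_LENGTH

    def __post_init__(self) -> None:
        if int(self.window_length) != self.window_length or self.window_length < 2:
            raise ValueError(
                f"window_length must be an integer >= 2, got {self.window_length!r}"
            )
        object.__setattr__(self, "window_length", int(self.window_length))


@dataclass(frozen=True)
class DiagramSequence:
    """Ordered per-window persistence diagrams of one signal."""

    diagrams: Tuple[PersistenceDiagram, ...]
    window_length: int
    source_id: Optional[str] = None
    offsets: Tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.diagrams)

    def __getitem__(self, k: int) -> PersistenceDiagram:
        return self.diagrams[k]


def segment(signal: Signal, config: WindowConfig = WindowConfig()) -> List[Signal]:
    """Split a signal into floor(n / w) consecutive windows of exactly w samples.

    Concatenating the result reproduces the first floor(n/w)*w samples of
    the input.  Emits a warning when the signal is too short for even one
    window.
    """
    w = config.window_length
    n = len(signal)
    n_windows = n // w
    if n_windows == 0:
        warnings.warn(
            f"signal of length {n} is shorter than one window (w={w}); "
            "no windows produced",
            stacklevel=2,
        )
    return [
        Signal(
            signal.values[k * w : (k + 1) * w],
            sample_period=signal.sample_period,
            participant_id=signal.participant_id,
        )
        for k in range(n_windows)
    ]


def windowed_diagrams(
    signal: Signal, config: WindowConfig = WindowConfig()
) -> DiagramSequence:
    """One persistence diagram per rectangular window, in temporal order."""
    windows = segment(signal, config)
    w = config.window_length
    return DiagramSequence(
        diagrams=tuple(compute_diagram(win) for win in windows),
        window_length=w,
        source_id=signal.participant_id,
        offsets=tuple(k * w for k in range(len(windows))),
    )
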