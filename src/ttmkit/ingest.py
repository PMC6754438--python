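"""Frame-stack ingestion: demultiplexing and trace extraction.

The acquisition interleaves the three channels frame-by-frame (LED switching
at the full camera rate), so a 1000 fps recording carries each transient at
1000/3 ≈ 333.33 fps.  This module splits an interleaved stack into the three
per-channel stacks, extracts ROI-mean intensity traces, and computes a
frame-difference contraction trace.

The contraction quantifier is a deliberately minimal stand-in for
MUSCLEMOTION: sample *i* is the mean absolute pixel difference between frame
*i* and a fixed reference frame.  It is a monotone surrogate of motion
amplitude, not a validated displacement measure; see the methods note.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import InputError
from .traces import Trace

__all__ = ["FrameStack", "demultiplex", "intensity_trace", "contraction_trace", "read_tiff"]

DEFAULT_LAYOUT = ("AP", "Ca", "Co")


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of equally shaped 2-D intensity frames.

    ``layout`` names the channels in interleave order; a demultiplexed
    single-channel stack has a length-1 layout.  ``rate`` is frames/s for
    this stack (total acquisition rate for an interleaved stack).
    """

    frames: np.ndarray
    rate: float
    layout: tuple[str, ...] = DEFAULT_LAYOUT
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise InputError("frames must be a (n, h, w) array")
        if np.any(frames < 0):
            raise InputError("frame intensities must be non-negative")
        if not self.rate > 0:
            raise InputError("acquisition rate must be positive")
        if len(set(self.layout)) != len(self.layout):
            raise InputError("interleave layout must not repeat channels")
        if self.roi is not None:
            roi = np.asarray(self.roi, dtype=bool)
            if roi.shape != frames.shape[1:]:
                raise InputError("ROI mask shape must match frame shape")
            if not roi.any():
                raise InputError("ROI mask selects no pixels")
            object.__setattr__(self, "roi", roi)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def channel(self) -> str:
        if len(self.layout) != 1:
            raise InputError("stack is interleaved; demultiplex first")
        return self.layout[0]


def read_tiff(path: str | Path, rate: float,
              layout: tuple[str, ...] = DEFAULT_LAYOUT,
              roi: np.ndarray | None = None) -> FrameStack:
    """Load a multi-page grayscale TIFF as an interleaved FrameStack."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames.astype(float), rate=rate, layout=layout, roi=roi)


def demultiplex(stack: FrameStack) -> dict[str, FrameStack]:
    """Split an interleaved stack into one stack per channel.

    Frame *i* goes to channel ``layout[i mod k]``; a trailing incomplete
    cycle is dropped so every channel keeps the same number of frames.  Each
    output stack runs at ``rate / k``.
    """
    k = len(stack.layout)
    n = len(stack)
    if n < k:
        raise InputError(f"need at least {k} frames to demultiplex, got {n}")
    n_complete = n // k
    trimmed = stack.frames[: n_complete * k]
    out = {}
    for offset, channel in enumerate(stack.layout):
        out[channel] = FrameStack(
            trimmed[offset::k],
            rate=stack.rate / k,
            layout=(channel,),
            roi=stack.roi,
        )
    return out


def intensity_trace(stack: FrameStack, channel: str | None = None) -> Trace:
    """ROI-mean intensity per frame (whole frame when no ROI is set)."""
    if len(stack) == 0:
        raise InputError("empty frame stack")
    if stack.roi is not None:
        values = stack.frames[:, stack.roi].mean(axis=1)
    else:
        values = stack.frames.reshape(len(stack), -1).mean(axis=1)
    if channel is None:
        channel = stack.layout[0] if len(stack.layout) == 1 else "MA"
    return Trace(values, rate=stack.rate, channel=channel)


def contraction_trace(stack: FrameStack, reference: int = 0) -> Trace:
    """Frame-difference contraction surrogate.

    Sample *i* is the ROI-mean of ``|frame_i - frame_reference|``.  A
    motionless recording yields an all-zero trace; the result is invariant
    to adding a constant intensity offset to every frame.
    """
    n = len(stack)
    if n < 2:
        raise InputError("need at least 2 frames for a contraction trace")
    if not (-n <= reference < n):
        raise InputError(f"reference frame {reference} out of range")
    ref = stack.frames[reference]
    diff = np.abs(stack.frames - ref[None])
    if stack.roi is not None:
        values = diff[:, stack.roi].mean(axis=1)
    else:
        values = diff.reshape(n, -1).mean(axis=1)
    return Trace(values, rate=stack.rate, channel="Co")
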