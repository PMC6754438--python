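"""Uniformly sampled intensity / contraction time series."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InputError

__all__ = ["Trace"]


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled fluorescence or contraction signal.

    Parameters
    ----------
    values : array of sample values (a.u. or dimensionless).
    rate : sampling rate in samples/s (per-channel rate after demultiplexing,
        e.g. 1000/3 ≈ 333.33 for a 1000 fps three-channel acquisition).
    channel : one of "AP", "Ca", "Co", "MA".
    t0 : time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    channel: str = "AP"
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise InputError("a trace needs at least 2 samples in one dimension")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise InputError("sampling rate must be positive")

    # ---- basic geometry ---------------------------------------------------

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    @property
    def dt_ms(self) -> float:
        """Sample period in milliseconds."""
        return 1000.0 / self.rate

    def with_values(self, values: np.ndarray, channel: str | None = None) -> "Trace":
        return replace(
            self, values=np.asarray(values, dtype=float),
            channel=self.channel if channel is None else channel,
        )

    # ---- plain-text persistence ------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with ``time_s,value`` columns and metadata comments."""
        lines = [
            f"# channel={self.channel}",
            f"# fps={self.rate!r}",
            f"# t0={self.t0!r}",
            "time_s,value",
        ]
        for t, v in zip(self.times, self.values):
            lines.append(f"{t:.9g},{v:.9g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        channel, rate, t0 = "AP", None, 0.0
        times, values = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    if key == "channel":
                        channel = val
                    elif key == "fps":
                        rate = float(val)
                    elif key == "t0":
                        t0 = float(val)
                    continue
                if line.startswith("time_s"):
                    continue
                t, _, v = line.partition(",")
                times.append(float(t))
                values.append(float(v))
        if rate is None:
            if len(times) < 2:
                raise InputError(f"{path}: cannot infer sampling rate")
            rate = 1.0 / float(np.median(np.diff(times)))
            t0 = times[0]
        return cls(np.asarray(values), rate=rate, channel=channel, t0=t0)
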