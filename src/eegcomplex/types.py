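"""Shared dataclasses passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import CHANNELS_1020, GROUPS


@dataclass
class Recording:
    """One session of multichannel EEG-like data.

    ``data`` is channels x time; row order matches ``channels``.
    """

    subject_id: str
    session_id: str
    group: str
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x time matrix")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate_montage(self) -> None:
        """Require the exact 19-channel 10-20 montage (strict mode)."""
        if self.channels != CHANNELS_1020:
            raise ValueError(
                "recording does not carry the 19-channel 10-20 montage: "
                f"got {len(self.channels)} channels {list(self.channels)!r}"
            )


@dataclass
class SampEnParams:
    """Sample-entropy / multiscale settings: pattern length ``m``, tolerance
    as a fraction of the scale-1 SD, and the largest coarse-graining factor."""

    m: int = 2
    r_frac: float = 0.15
    max_scale: int = 20

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be > 0")
        if self.max_scale < 1:
            raise ValueError("max_scale must be >= 1")


@dataclass
class MSECurve:
    """Per-channel entropy-vs-scale curve; incomputable scales are flagged."""

    channel: str
    scales: np.ndarray
    entropy: np.ndarray
    r_abs: float
    undefined_scales: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.entropy = np.asarray(self.entropy, dtype=float)
        if self.scales.shape != self.entropy.shape:
            raise ValueError("scales and entropy must have equal length")
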