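"""Seeded synthetic cohort generator.

Produces EEG-like recordings as standardized white/pink (1/f) noise mixtures
plus a 12-symptom score table driven by a latent per-subject severity factor.
The pink-noise weight ``w`` controls the entropy-vs-scale geometry: pure white
noise loses sample entropy as the series is coarse-grained, while 1/f noise
keeps a flat curve, so group-graded weights on a subset of channels plant a
crossover between the group-mean curves without modelling any physiological
rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import CHANNELS_1020, GROUPS, GROUP_SEVERITY, NPI_SYMPTOMS
from .types import Recording

__all__ = ["CohortSpec", "pink_noise", "generate_channel_signal", "generate_cohort"]

#: Default latent severity grade per group; doubles as the pink weight on
#: effect channels.  Calibrated so the extreme contrast is easy and the
#: HC-vs-AD1 contrast is hard.
DEFAULT_MIX_WEIGHTS: dict[str, float] = {"HC": 0.2, "AD1": 0.35, "AD2": 0.5, "AD3": 0.8}

DEFAULT_GROUP_SIZES: dict[str, int] = {"HC": 15, "AD1": 15, "AD2": 69, "AD3": 24}


def _default_npi_loadings() -> np.ndarray:
    # Single latent factor; DEL/HAL/APA load strongly so the planted
    # feature<->symptom association is recoverable by CCA.
    loadings = np.array(
        [6.0, 5.0, 1.0, 1.0, 1.0, 4.0, 1.0, 0.5, 0.5, 1.0, 1.0, 1.0]
    )
    return loadings.reshape(12, 1)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults mirror the study geometry
    (123 subjects in four severity groups, 3 sessions of 10 s at 256 Hz,
    19-channel 10-20 montage)."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    sessions_per_subject: int = 3
    duration_s: float = 10.0
    fs: float = 256.0
    channels: tuple[str, ...] = CHANNELS_1020
    mix_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX_WEIGHTS)
    )
    baseline_weight: float = 0.3
    effect_channels: frozenset[str] = frozenset({"T5", "T6", "O1", "O2"})
    npi_loadings: np.ndarray = field(default_factory=_default_npi_loadings)
    severity_jitter_sd: float = 0.05
    #: SD of the per-subject offset on the baseline (non-effect) pink weight:
    #: a class-unrelated subject signature that is stable across a subject's
    #: sessions, mimicking individual variability.  It is what makes
    #: unregularized p>n logistic regression overfit under LOSO.
    baseline_jitter_sd: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.npi_loadings = np.atleast_2d(np.asarray(self.npi_loadings, dtype=float))
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"group_sizes: unknown group {g!r}")
            if n < 1:
                raise ValueError(f"group_sizes: group {g!r} must have >= 1 subject")
        if self.sessions_per_subject < 1:
            raise ValueError("sessions_per_subject must be >= 1")
        n = self.fs * self.duration_s
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be a positive integer")
        if len(self.channels) != 19 or len(set(self.channels)) != 19:
            raise ValueError("channels must be 19 unique labels")
        for g in self.group_sizes:
            w = self.mix_weights.get(g)
            if w is None:
                raise ValueError(f"mix_weights: missing group {g!r}")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"mix_weights: weight for {g!r} outside [0, 1]")
        if not 0.0 <= self.baseline_weight <= 1.0:
            raise ValueError("baseline_weight outside [0, 1]")
        unknown = set(self.effect_channels) - set(self.channels)
        if unknown:
            raise ValueError(f"effect_channels not in montage: {sorted(unknown)}")
        if self.npi_loadings.shape[0] != len(NPI_SYMPTOMS):
            raise ValueError(
                f"npi_loadings must have {len(NPI_SYMPTOMS)} rows, "
                f"got {self.npi_loadings.shape[0]}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate zero-variance signal")
    return x / sd


#: Amplitude-shaping exponent of the 1/f component.  0.5 gives textbook pink
#: noise (PSD slope -1); 0.65 (slope ~ -1.3) is the default because mixtures
#: against white noise then cross over near scale factor 6-7 instead of 3-4,
#: matching the geometry the downstream analysis assumes.
PINK_EXPONENT: float = 0.65


def pink_noise(
    n: int, seed: int | np.random.Generator, exponent: float = PINK_EXPONENT
) -> np.ndarray:
    """Zero-mean unit-variance noise with a ~1/f power spectral density.

    White Gaussian noise is shaped in the frequency domain with amplitude
    f^(-exponent) (DC removed), then standardized.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _as_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** -exponent
    shaped = np.fft.irfft(spec * amp, n=n)
    return _standardize(shaped)


def generate_channel_signal(
    n: int, w: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Standardized sqrt(1-w)*white + sqrt(w)*pink mixture.

    Higher ``w`` raises temporal correlation, which lowers scale-1 sample
    entropy and flattens the entropy-vs-scale curve.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _as_rng(seed)
    white = rng.standard_normal(n)
    pink = pink_noise(n, rng)
    return _standardize(np.sqrt(1.0 - w) * white + np.sqrt(w) * pink)


def _subject_table(spec: CohortSpec) -> list[tuple[str, str]]:
    """Deterministic (subject_id, group) list, grouped HC, AD1, AD2, AD3."""
    rows = []
    for g in GROUPS:
        if g not in spec.group_sizes:
            continue
        for i in range(spec.group_sizes[g]):
            rows.append((f"{g}_{i + 1:03d}", g))
    return rows


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate one Recording per subject x session plus the symptom table.

    Each subject carries a latent severity ``s`` = group grade + Gaussian
    jitter (clipped to [0, 1]).  Effect channels use pink weight ``s``;
    all other channels share ``baseline_weight``.  Symptom scores are
    ``npi_loadings @ s`` plus Gaussian noise, truncated at zero.  The whole
    cohort is a pure function of ``spec.seed``.
    """
    spec.validate()
    n = spec.n_samples
    subjects = _subject_table(spec)
    ss = np.random.SeedSequence(spec.seed)
    subj_seeds = ss.spawn(len(subjects))

    recordings: list[Recording] = []
    severities = np.empty(len(subjects))
    for si, ((subject_id, group), sseed) in enumerate(zip(subjects, subj_seeds)):
        rng = np.random.default_rng(sseed)
        s = float(
            np.clip(
                spec.mix_weights[group] + spec.severity_jitter_sd * rng.standard_normal(),
                0.0,
                1.0,
            )
        )
        severities[si] = s
        w_base = float(
            np.clip(
                spec.baseline_weight + spec.baseline_jitter_sd * rng.standard_normal(),
                0.0,
                1.0,
            )
        )
        for sess in range(1, spec.sessions_per_subject + 1):
            data = np.empty((len(spec.channels), n))
            for ci, ch in enumerate(spec.channels):
                w = s if ch in spec.effect_channels else w_base
                data[ci] = generate_channel_signal(n, w, rng)
            recordings.append(
                Recording(
                    subject_id=subject_id,
                    session_id=f"s{sess}",
                    group=group,
                    fs=spec.fs,
                    channels=spec.channels,
                    data=data,
                )
            )

    k = spec.npi_loadings.shape[1]
    npi_rng = np.random.default_rng(ss.spawn(1)[0])
    # Latent factor matrix: first factor is the severity, extra factors are
    # independent standard normal per subject.
    factors = np.column_stack(
        [severities]
        + [npi_rng.standard_normal(len(subjects)) for _ in range(k - 1)]
    )
    means = factors @ spec.npi_loadings.T
    scores = means + spec.noise_sd * npi_rng.standard_normal(means.shape)
    scores = np.clip(scores, 0.0, None)

    npi = pd.DataFrame(scores, columns=list(NPI_SYMPTOMS))
    npi.insert(0, "subject_id", [s for s, _ in subjects])
    npi.attrs["latent_severity"] = severities
    return recordings, npi
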