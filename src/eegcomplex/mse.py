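"""Coarse-graining, sample entropy, and multiscale-entropy feature extraction.

Sample entropy follows the Richman-Moorman convention: Chebyshev distance,
self-matches excluded, strict ``< r`` matching, and both template counts taken
over the same index range so the ratio is a proper conditional probability
(a constant series therefore scores exactly 0).  The tolerance is fixed once
per channel as ``r_frac x SD`` of the original (scale-1) series and reused at
every scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import detrend as _linear_detrend
from scipy.spatial import cKDTree

from .types import MSECurve, Recording, SampEnParams

__all__ = [
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "extract_features",
    "extract_feature_table",
    "feature_names",
]


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Average ``x`` over non-overlapping windows of length ``tau``.

    The trailing ``len(x) % tau`` samples are discarded.
    """
    x = np.asarray(x, dtype=float)
    tau = int(tau)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > x.size:
        raise ValueError(f"tau={tau} exceeds series length {x.size}")
    if tau == 1:
        return x.copy()
    n_win = x.size // tau
    return x[: n_win * tau].reshape(n_win, tau).mean(axis=1)


def _count_close_pairs(templates: np.ndarray, r_strict: float) -> int:
    """Unordered template pairs (k < l) with Chebyshev distance <= r_strict."""
    tree = cKDTree(templates)
    ordered = tree.count_neighbors(tree, r_strict, p=np.inf)
    return int(ordered - len(templates)) // 2


def sample_entropy(y: np.ndarray, m: int, r_abs: float) -> float:
    """-ln of the conditional template-matching probability; NaN if undefined.

    Both the m-length and (m+1)-length counts run over template start indices
    1..M-m, so every m-template that is counted has an (m+1)-extension.
    """
    y = np.asarray(y, dtype=float)
    m = int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    if r_abs <= 0:
        raise ValueError("r_abs must be > 0")
    big_m = y.size
    if big_m <= m + 1:
        raise ValueError(f"series length {big_m} must exceed m+1={m + 1}")
    # Largest float strictly below r_abs: "<= r_strict" == "< r_abs".
    r_strict = np.nextafter(r_abs, 0.0)
    templates_m1 = sliding_window_view(y, m + 1)          # (M-m) x (m+1)
    templates_m = templates_m1[:, :m]                     # same start indices
    n_m = _count_close_pairs(np.ascontiguousarray(templates_m), r_strict)
    if n_m == 0:
        return float("nan")
    n_m1 = _count_close_pairs(templates_m1, r_strict)
    if n_m1 == 0:
        return float("nan")
    return float(-np.log(n_m1 / n_m))


def mse_curve(x: np.ndarray, params: SampEnParams, channel: str = "") -> MSECurve:
    """Sample entropy of ``x`` at coarse-graining factors 1..max_scale."""
    x = np.asarray(x, dtype=float)
    m, t = params.m, params.max_scale
    min_len = (m + 2) * t
    if x.size < min_len:
        feasible = x.size // (m + 2)
        raise ValueError(
            f"series of length {x.size} too short for max_scale={t} "
            f"(needs >= {min_len}; maximal feasible scale is {feasible})"
        )
    sd = float(x.std())
    if sd == 0:
        raise ValueError("zero-variance series: tolerance r_abs would be 0")
    r_abs = params.r_frac * sd
    scales = np.arange(1, t + 1)
    entropy = np.full(t, np.nan)
    undefined: set[int] = set()
    for i, tau in enumerate(scales):
        value = sample_entropy(coarse_grain(x, int(tau)), m, r_abs)
        if np.isnan(value):
            undefined.add(int(tau))
        else:
            entropy[i] = value
    return MSECurve(
        channel=channel,
        scales=scales,
        entropy=entropy,
        r_abs=r_abs,
        undefined_scales=undefined,
    )


def feature_names(
    channels: tuple[str, ...], max_scale: int
) -> list[str]:
    """Channel-major, scale-minor feature naming: '<channel>_s<scale>'."""
    return [f"{ch}_s{tau}" for ch in channels for tau in range(1, max_scale + 1)]


def extract_features(
    rec: Recording, params: SampEnParams, detrend: bool = True
) -> pd.Series:
    """One row of the feature table: per-channel entropy curves concatenated
    in montage order.  Channels are linearly detrended before the SD that
    fixes the tolerance is computed.  Undefined entries stay NaN.
    """
    values = np.empty(len(rec.channels) * params.max_scale)
    for ci, ch in enumerate(rec.channels):
        x = rec.data[ci]
        if detrend:
            x = _linear_detrend(x)
        try:
            curve = mse_curve(x, params, channel=ch)
        except ValueError as exc:
            raise ValueError(f"channel {ch!r}: {exc}") from exc
        values[ci * params.max_scale : (ci + 1) * params.max_scale] = curve.entropy
    return pd.Series(
        values,
        index=feature_names(rec.channels, params.max_scale),
        name=(rec.subject_id, rec.session_id),
    )


def extract_feature_table(
    recordings: list[Recording],
    params: SampEnParams | None = None,
    detrend: bool = True,
) -> pd.DataFrame:
    """Feature table over sessions: metadata columns then the named features."""
    params = params or SampEnParams()
    rows = []
    meta = []
    for rec in recordings:
        rows.append(extract_features(rec, params, detrend=detrend))
        meta.append((rec.subject_id, rec.session_id, rec.group))
    features = pd.DataFrame(rows).reset_index(drop=True)
    table = pd.DataFrame(meta, columns=["subject_id", "session_id", "group"])
    return pd.concat([table, features], axis=1)
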