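"""Selection-frequency topographic maps.

A feature counts as selected in a fold when its fitted coefficient is
non-zero (above a float-dust threshold).  Per-feature frequencies are then
aggregated per channel over five scale-factor bins by taking the maximum
frequency within each bin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_BINS
from .montage import CHANNELS_1020, XY_1020
from .evalcv import CVResult

#: |beta| above this counts as selected; the solver produces exact zeros, so
#: this only guards accumulated float dust.
SELECTION_EPS = 1e-8

_FEATURE_RE = re.compile(r"^(?P<channel>[A-Za-z]+[0-9z]*)_s(?P<scale>[0-9]+)$")

__all__ = [
    "SelectionFrequencyMap",
    "selection_frequency",
    "bin_frequencies",
    "topomap_export",
    "read_topomap",
]


@dataclass
class SelectionFrequencyMap:
    channels: tuple[str, ...]
    bins: tuple[tuple[int, int], ...]
    values: np.ndarray  # channels x bins, in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channels), len(self.bins)):
            raise ValueError("values must be channels x bins")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        bin_labels = [f"{lo}-{hi}" for lo, hi in self.bins]
        return pd.DataFrame(self.values, index=list(self.channels), columns=bin_labels)


def parse_feature_name(name: str) -> tuple[str, int]:
    m = _FEATURE_RE.match(name)
    if not m:
        raise ValueError(f"feature name {name!r} is not of the form <channel>_s<scale>")
    return m.group("channel"), int(m.group("scale"))


def selection_frequency(cv: CVResult, feature_names: list[str] | None = None) -> pd.Series:
    """Fraction of folds in which each feature has a non-zero coefficient."""
    if not cv.folds:
        raise ValueError("CV result has no folds")
    names = feature_names if feature_names is not None else cv.feature_names
    counts = pd.Series(0.0, index=names)
    for fold in cv.folds:
        beta = fold.model.beta
        active = {cv.feature_names[j] for j in np.flatnonzero(np.abs(beta) > SELECTION_EPS)}
        counts[counts.index.isin(active)] += 1.0
    return counts / len(cv.folds)


def bin_frequencies(
    freqs: pd.Series,
    bins: tuple[tuple[int, int], ...] = DEFAULT_BINS,
    channels: tuple[str, ...] = CHANNELS_1020,
) -> SelectionFrequencyMap:
    """Aggregate per-feature frequencies into a channels x bins map; the
    value of a bin is the maximal frequency among its scale factors."""
    parsed: dict[tuple[str, int], float] = {}
    for name, f in freqs.items():
        ch, scale = parse_feature_name(str(name))
        parsed[(ch, scale)] = float(f)
    values = np.zeros((len(channels), len(bins)))
    for ci, ch in enumerate(channels):
        for bi, (lo, hi) in enumerate(bins):
            in_bin = [parsed[(ch, s)] for s in range(lo, hi + 1) if (ch, s) in parsed]
            values[ci, bi] = max(in_bin) if in_bin else 0.0
    return SelectionFrequencyMap(channels=tuple(channels), bins=tuple(bins), values=values)


def topomap_export(
    smap: SelectionFrequencyMap, path, png: str | None = None
) -> pd.DataFrame:
    """Write the map as a long CSV (channel, bin, value, x, y); optionally
    render a schematic scalp image (decorative only)."""
    rows = []
    for ci, ch in enumerate(smap.channels):
        x, y = XY_1020.get(ch, (np.nan, np.nan))
        for bi, (lo, hi) in enumerate(smap.bins):
            rows.append(
                {
                    "channel": ch,
                    "bin": f"{lo}-{hi}",
                    "value": smap.values[ci, bi],
                    "x": x,
                    "y": y,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    if png is not None:
        _render_png(smap, png)
    return df


def read_topomap(path) -> SelectionFrequencyMap:
    df = pd.read_csv(path)
    channels = tuple(dict.fromkeys(df["channel"]))
    bins = tuple(
        tuple(int(v) for v in b.split("-")) for b in dict.fromkeys(df["bin"])
    )
    values = np.zeros((len(channels), len(bins)))
    ci = {c: i for i, c in enumerate(channels)}
    bi = {f"{lo}-{hi}": i for i, (lo, hi) in enumerate(bins)}
    for _, row in df.iterrows():
        values[ci[row["channel"]], bi[row["bin"]]] = row["value"]
    return SelectionFrequencyMap(channels=channels, bins=bins, values=values)


def _render_png(smap: SelectionFrequencyMap, png: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(smap.bins), figsize=(3 * len(smap.bins), 3))
    for bi, ax in enumerate(np.atleast_1d(axes)):
        xs = [XY_1020[c][0] for c in smap.channels]
        ys = [XY_1020[c][1] for c in smap.channels]
        sc = ax.scatter(xs, ys, c=smap.values[:, bi], cmap="viridis", vmin=0, vmax=1, s=120)
        for c, x, y in zip(smap.channels, xs, ys):
            ax.annotate(c, (x, y), fontsize=6, ha="center", va="center")
        lo, hi = smap.bins[bi]
        ax.set_title(f"scales {lo}-{hi}")
        ax.set_aspect("equal")
        ax.axis("off")
    fig.colorbar(sc, ax=axes, shrink=0.7)
    fig.savefig(png, dpi=120)
    plt.close(fig)
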