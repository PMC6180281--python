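"""Readers and writers for recordings, cohorts, feature tables, and results.

CSV is the canonical interchange format.  Writers are deterministic; readers
reject malformed input rather than repairing it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .montage import NPI_SYMPTOMS
from .types import Recording

META_COLUMNS = ("subject_id", "session_id", "group")

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "save_cohort",
    "load_cohort",
    "write_feature_table",
    "read_feature_table",
    "read_npi",
]


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Rows = channels; first column is the channel label; no header line."""
    with open(path, "w") as fh:
        for ch, row in zip(rec.channels, rec.data):
            fh.write(ch + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_recording_csv(
    path: str | Path,
    fs: float,
    subject_id: str = "",
    session_id: str = "",
    group: str = "HC",
    strict: bool = True,
) -> Recording:
    """Parse a channels-x-time CSV; in strict mode the file must carry the
    exact 19-channel 10-20 montage."""
    path = Path(path)
    channels: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        label, _, rest = line.partition(",")
        label = label.strip()
        try:
            values = np.array([float(v) for v in rest.split(",")])
        except ValueError as exc:
            raise ValueError(
                f"{path.name}, row {lineno} (channel {label!r}): non-numeric cell"
            ) from exc
        channels.append(label)
        rows.append(values)
    if not rows:
        raise ValueError(f"{path.name}: empty recording file")
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path.name}: ragged rows, lengths {sorted(lengths)}")
    rec = Recording(
        subject_id=subject_id,
        session_id=session_id,
        group=group,
        fs=fs,
        channels=tuple(channels),
        data=np.vstack(rows),
    )
    if strict:
        rec.validate_montage()
    return rec


def save_cohort(
    recordings: list[Recording], npi: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write per-session CSVs, a cohort manifest, and the symptom table.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.session_id}.csv"
        write_recording_csv(rec, rec_dir / fname)
        manifest_rows.append(
            {
                "subject_id": rec.subject_id,
                "session_id": rec.session_id,
                "group": rec.group,
                "fs": rec.fs,
                "path": f"recordings/{fname}",
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    npi.to_csv(outdir / "npi.csv", index=False)
    return manifest_path


def load_cohort(manifest_path: str | Path, strict: bool = True) -> list[Recording]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    needed = {"subject_id", "session_id", "group", "fs", "path"}
    missing = needed - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    base = manifest_path.parent
    return [
        read_recording_csv(
            base / row["path"],
            fs=float(row["fs"]),
            subject_id=str(row["subject_id"]),
            session_id=str(row["session_id"]),
            group=str(row["group"]),
            strict=strict,
        )
        for _, row in manifest.iterrows()
    ]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Metadata columns first, then feature columns in their given
    (channel-major, scale-minor) order."""
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks metadata columns {missing}")
    dup = table.duplicated(subset=["subject_id", "session_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, session) rows: "
            f"{table.loc[dup, ['subject_id', 'session_id']].values.tolist()}"
        )
    feats = [c for c in table.columns if c not in META_COLUMNS]
    table[list(META_COLUMNS) + feats].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks metadata columns {missing}")
    dup = table.duplicated(subset=["subject_id", "session_id"])
    if dup.any():
        raise ValueError("duplicate (subject, session) rows in feature table")
    feats = [c for c in table.columns if c not in META_COLUMNS]
    if len(set(feats)) != len(feats):
        raise ValueError("duplicate feature column names")
    return table


def read_npi(path: str | Path) -> pd.DataFrame:
    npi = pd.read_csv(path)
    missing = [c for c in ("subject_id", *NPI_SYMPTOMS) if c not in npi.columns]
    if missing:
        raise ValueError(f"NPI table lacks columns {missing}")
    scores = npi[list(NPI_SYMPTOMS)].to_numpy(dtype=float)
    if (scores < 0).any():
        raise ValueError("NPI scores must be non-negative")
    return npi[["subject_id", *NPI_SYMPTOMS]]
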