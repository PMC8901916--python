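"""Reading recordings and manifests.

Delimited numeric matrices (rows = time samples, columns = channels) are
the primary interchange format; EDF files are read through ``mne`` when
it is installed.  A manifest CSV with columns ``subject_id, experiment,
path, label`` describes a cohort on disk.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExperimentMatrix

__all__ = ["read_channel_matrix", "read_manifest_dataset", "write_cohort"]


def read_channel_matrix(path, sampling_rate: float = 256.0):
    """Read a recording as (values, channel_labels).

    ``.edf`` files go through ``mne`` (optional dependency); anything else
    is parsed as a delimited numeric matrix whose header row, if present,
    names the channels.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:
            raise ImportError("reading EDF requires the optional dependency 'mne'") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data().T, tuple(raw.ch_names)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.columns.str.match(r"^[-+0-9.eE]+$").all():
        # no header: first row was data
        arr = np.loadtxt(path, delimiter="," if sep == "," else None, ndmin=2)
        return arr, tuple(f"ch{i}" for i in range(arr.shape[1]))
    return df.to_numpy(dtype=float), tuple(map(str, df.columns))


def read_manifest_dataset(manifest_path, sampling_rate: float = 256.0):
    """Load a cohort from a manifest CSV; returns (matrices, labels)."""
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    required = {"subject_id", "experiment", "path"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    matrices, labels = [], {}
    for _, row in man.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        values, channels = read_channel_matrix(p, sampling_rate)
        matrices.append(
            ExperimentMatrix(values, str(row["subject_id"]), str(row["experiment"]),
                             channels, sampling_rate)
        )
        if "label" in man.columns and pd.notna(row.get("label")):
            labels[str(row["subject_id"])] = str(row["label"])
    return matrices, labels


def write_cohort(cohort, out_dir) -> Path:
    """Write a cohort as per-recording CSVs plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in cohort.matrices:
        fname = f"{m.subject_id}_{m.experiment_id}.csv"
        pd.DataFrame(m.values, columns=list(m.channel_labels)).to_csv(out / fname, index=False)
        rows.append(
            {
                "subject_id": m.subject_id,
                "experiment": m.experiment_id,
                "path": fname,
                "label": cohort.labels.get(m.subject_id, ""),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
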