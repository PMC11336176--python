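"""Readers and writers for the pipeline's on-disk formats.

EEG blocks travel as plain TSV matrices (one file per participant:
channels x samples, header row of channel labels, one column per channel)
or as EDF (read via MNE). Tap onsets travel as CSV with columns
``participant_id, onset_seconds[, condition]``. Synchrony matrices, graphs
and results tables are written as labeled TSV plus JSON metadata, so every
artifact is diffable text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TapRecord
from .connectivity import SyncMatrices
from .preprocessing import DualRecording
from .surrogate import HyperbrainGraph


# ---------------------------------------------------------------- recordings

def write_recording_tsv(rec: DualRecording, path_p1, path_p2) -> None:
    """One TSV per participant: header of channel labels, samples as rows."""
    for path, block in zip((path_p1, path_p2), rec.participant_blocks):
        df = pd.DataFrame(block.T, columns=list(rec.channel_labels))
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_recording_tsv(
    path_p1, path_p2, sampling_rate: float, band_tag: str | None = None
) -> DualRecording:
    frames = [pd.read_csv(p, sep="\t") for p in (path_p1, path_p2)]
    labels = tuple(frames[0].columns)
    if tuple(frames[1].columns) != labels:
        raise ValueError("participant files disagree on channel labels")
    blocks = tuple(f.to_numpy(dtype=float).T for f in frames)
    return DualRecording(
        participant_blocks=blocks,
        sampling_rate=sampling_rate,
        channel_labels=labels,
        band_tag=band_tag,
    )


def read_recording_edf(path_p1, path_p2) -> DualRecording:
    """Load one dyad from two EDF files (channel sets must match)."""
    import mne

    raws = [mne.io.read_raw_edf(p, preload=True, verbose="error") for p in (path_p1, path_p2)]
    if raws[0].ch_names != raws[1].ch_names:
        raise ValueError("EDF files disagree on channel labels")
    if raws[0].info["sfreq"] != raws[1].info["sfreq"]:
        raise ValueError("EDF files disagree on sampling rate")
    n = min(r.n_times for r in raws)
    blocks = tuple(r.get_data()[:, :n] for r in raws)
    return DualRecording(
        participant_blocks=blocks,
        sampling_rate=float(raws[0].info["sfreq"]),
        channel_labels=tuple(raws[0].ch_names),
    )


# ----------------------------------------------------------------------- taps

def write_taps_csv(records: list[TapRecord], path) -> None:
    rows = []
    for rec in records:
        for t in rec.onsets:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "onset_seconds": t,
                    "condition": rec.condition or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_taps_csv(path) -> list[TapRecord]:
    """One TapRecord per participant_id found in the file, in file order."""
    df = pd.read_csv(path)
    records = []
    for pid, sub in df.groupby("participant_id", sort=False):
        cond = None
        if "condition" in sub.columns:
            vals = sub["condition"].dropna().unique()
            cond = str(vals[0]) if len(vals) == 1 and str(vals[0]) else None
        records.append(
            TapRecord(
                onsets=np.sort(sub["onset_seconds"].to_numpy(dtype=float)),
                participant_id=str(pid),
                condition=cond,
            )
        )
    return records


# -------------------------------------------------------------- sync matrices

def write_sync_matrices(sync: SyncMatrices, out_dir, metadata: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = list(sync.channel_labels)
    for name, mat in (("intra_1", sync.intra_1), ("intra_2", sync.intra_2), ("inter", sync.inter)):
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(
            out / f"{name}.tsv", sep="\t", float_format="%.8g"
        )
    meta = {"band": sync.band_tag, "n_samples_used": sync.n_samples_used}
    meta.update(metadata or {})
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))


# --------------------------------------------------------------------- graphs

def write_graph(graph: HyperbrainGraph, out_dir) -> None:
    """Labeled TSV adjacency + edge list + JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = list(graph.node_labels)
    pd.DataFrame(graph.adjacency, index=labels, columns=labels).to_csv(
        out / "adjacency.tsv", sep="\t"
    )
    ii, kk = np.nonzero(np.triu(graph.adjacency, k=1))
    pd.DataFrame({"node_i": [labels[i] for i in ii], "node_k": [labels[k] for k in kk]}).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    meta = {
        "band": graph.band_tag,
        "condition": graph.condition,
        "alpha_per_test": graph.alpha_per_test,
        "n_tests": graph.n_tests,
        "n_nodes": graph.n_nodes,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))


def read_graph(out_dir) -> HyperbrainGraph:
    out = Path(out_dir)
    df = pd.read_csv(out / "adjacency.tsv", sep="\t", index_col=0)
    meta = json.loads((out / "metadata.json").read_text())
    n = df.shape[0]
    return HyperbrainGraph(
        adjacency=df.to_numpy(dtype=int),
        node_labels=tuple(df.columns),
        module_of=np.repeat([1, 2], n // 2),
        band_tag=meta["band"],
        condition=meta.get("condition"),
        alpha_per_test=meta.get("alpha_per_test", float("nan")),
        n_tests=meta.get("n_tests", 0),
    )
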