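"""Plain-text I/O: waveform CSVs, delimited tables, tree artifacts.

Waveforms are stored one CSV per record (columns = leads I, II, V1–V6,
one row per sample) beside a metadata table; fitted trees are serialized
to a documented directory of delimited text + JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LEADS_8, EcgRecord, MedianBeat
from .tree import TreeModel

__all__ = [
    "write_waveform_csv", "read_waveform_csv",
    "write_median_beat_csv", "read_median_beat_csv",
    "save_tree", "load_tree",
]


def write_waveform_csv(rec: EcgRecord, path: str | Path) -> None:
    df = pd.DataFrame(rec.signal.T, columns=list(rec.lead_names))
    df.to_csv(path, index=False, float_format="%.5f")


def read_waveform_csv(path: str | Path, fs: float,
                      meta: dict | None = None,
                      record_id: str = "") -> EcgRecord:
    df = pd.read_csv(path)
    return EcgRecord(signal=df.to_numpy().T, fs=fs,
                     lead_names=tuple(df.columns),
                     meta=meta or {}, record_id=record_id)


def write_median_beat_csv(beat: MedianBeat, path: str | Path) -> None:
    df = pd.DataFrame(beat.beats.T, columns=list(LEADS_8))
    df.to_csv(path, index=False, float_format="%.5f")


def read_median_beat_csv(path: str | Path, fs: float = 400.0,
                         source_id: str = "") -> MedianBeat:
    df = pd.read_csv(path)
    return MedianBeat(beats=df.to_numpy().T, fs=fs, source_id=source_id)


def save_tree(model: TreeModel, path: str | Path) -> None:
    """Serialize a fitted tree: centroid table, edge list, sample table,
    hyperparameters + objective trace.

    The soft-assignment matrix is reduced to each sample's argmax
    centroid; reloading reconstructs a one-hot assignment.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ii, jj = np.nonzero(np.triu(model.B))
    pd.DataFrame({"i": ii, "j": jj}).to_csv(path / "edges.csv", index=False)
    cent = pd.DataFrame(model.Y, columns=["dim1", "dim2"])
    if model.centroid_branch is not None:
        cent["branch"] = model.centroid_branch
    if model.centroid_phenogroup is not None:
        cent["phenogroup"] = model.centroid_phenogroup
    cent.to_csv(path / "centroids.csv", index=False)
    samp = pd.DataFrame(model.Z, columns=["dim1", "dim2"])
    samp["centroid"] = model.sample_centroid
    for col, val in [("branch", model.branch_id),
                     ("phenogroup", model.phenogroup),
                     ("pseudotime_global", model.pseudotime_global),
                     ("pseudotime_branch", model.pseudotime_branch)]:
        if val is not None:
            samp[col] = val
    samp.to_csv(path / "samples.csv", index=False)
    np.savetxt(path / "basis_w.csv", model.W, delimiter=",")
    meta = {
        "hyperparams": {k: (int(v) if isinstance(v, (np.integer,)) else v)
                        for k, v in model.hyperparams.items()},
        "objective_trace": [float(o) for o in model.objective_trace],
        "converged": bool(model.converged),
        "center_node": model.center_node,
    }
    (path / "tree.json").write_text(json.dumps(meta, indent=1))


def load_tree(path: str | Path) -> TreeModel:
    path = Path(path)
    meta = json.loads((path / "tree.json").read_text())
    edges = pd.read_csv(path / "edges.csv")
    cent = pd.read_csv(path / "centroids.csv")
    samp = pd.read_csv(path / "samples.csv")
    K = len(cent)
    B = np.zeros((K, K), dtype=bool)
    B[edges["i"], edges["j"]] = True
    B |= B.T
    R = np.zeros((len(samp), K))
    R[np.arange(len(samp)), samp["centroid"].to_numpy()] = 1.0
    model = TreeModel(
        W=np.loadtxt(path / "basis_w.csv", delimiter=",", ndmin=2),
        Z=samp[["dim1", "dim2"]].to_numpy(),
        Y=cent[["dim1", "dim2"]].to_numpy(),
        B=B, R=R,
        hyperparams=meta["hyperparams"],
        objective_trace=meta["objective_trace"],
        converged=meta["converged"],
        center_node=meta.get("center_node"),
    )
    if "branch" in cent.columns:
        model.centroid_branch = cent["branch"].to_numpy()
    if "phenogroup" in cent.columns:
        model.centroid_phenogroup = cent["phenogroup"].to_numpy()
    if "branch" in samp.columns:
        model.branch_id = samp["branch"].to_numpy()
    if "phenogroup" in samp.columns:
        model.phenogroup = samp["phenogroup"].to_numpy()
    if "pseudotime_global" in samp.columns:
        model.pseudotime_global = samp["pseudotime_global"].to_numpy()
    if "pseudotime_branch" in samp.columns:
        model.pseudotime_branch = samp["pseudotime_branch"].to_numpy()
    return model
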