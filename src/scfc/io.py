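"""Delimited-text and JSON I/O for the package's data types.

SC matrices travel as tab-separated matrices with a header row and column
of region names (round-tripped byte-identically) plus a two-column atlas
sidecar; BOLD runs as tab-separated regions x timepoints tables whose first
line records the sampling interval; connectivity vectors as two-column
tables keyed by "i-j" / "i-j-k" id strings.  Reports are JSON, versioned
with a schema id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import LEFT, RegionAtlas
from .cohort import SCMatrix
from .fc import BOLDRun, ConnectivityVector

REPORT_SCHEMA = "scfc-report-1"


def write_sc(sc: SCMatrix, matrix_path, atlas_path=None) -> None:
    names = list(sc.atlas.names)
    df = pd.DataFrame(sc.weights, index=names, columns=names)
    df.to_csv(matrix_path, sep="\t")
    if atlas_path is not None:
        write_atlas(sc.atlas, atlas_path)


def write_atlas(atlas: RegionAtlas, path) -> None:
    df = pd.DataFrame({"region": list(atlas.names), "hemisphere": list(atlas.hemisphere)})
    df.to_csv(path, sep="\t", index=False)


def read_atlas(path) -> RegionAtlas:
    df = pd.read_csv(path, sep="\t", dtype=str)
    hemisphere = tuple(df["hemisphere"])
    n = len(hemisphere)
    h = n // 2
    # canonical pairing: position within hemisphere matches across sides
    left = [i for i, s in enumerate(hemisphere) if s == LEFT]
    right = [i for i, s in enumerate(hemisphere) if s != LEFT]
    pair = np.empty(n, dtype=int)
    for a, b in zip(left, right):
        pair[a], pair[b] = b, a
    if len(left) != h:
        raise ValueError("atlas sidecar must have equal hemispheres")
    return RegionAtlas(
        n_regions=n, hemisphere=hemisphere, homotopic_pair=pair, names=tuple(df["region"])
    )


def read_sc(matrix_path, atlas_path) -> SCMatrix:
    atlas = read_atlas(atlas_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if tuple(df.index) != atlas.names or tuple(df.columns) != atlas.names:
        raise ValueError("region names in matrix and atlas sidecar do not match")
    w = df.to_numpy(dtype=float)
    w = 0.5 * (w + w.T)  # undo round-trip asymmetry at printed precision
    nz = w[w > 0]
    thr = float(nz.min()) if nz.size else 0.0
    return SCMatrix(weights=w, atlas=atlas, threshold_applied=min(thr, 0.001))


def write_bold(run: BOLDRun, path, names=None) -> None:
    names = names or [f"r{i:03d}" for i in range(run.n_regions)]
    with open(path, "w") as fh:
        fh.write(f"# tr={run.tr}\tgsr={int(run.gsr_applied)}\n")
        pd.DataFrame(run.values, index=list(names)).to_csv(fh, sep="\t", header=False)


def read_bold(path) -> BOLDRun:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(item.split("=") for item in header.split("\t"))
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    return BOLDRun(
        values=df.to_numpy(dtype=float),
        tr=float(meta["tr"]),
        gsr_applied=bool(int(meta.get("gsr", 0))),
    )


def write_connectivity(vec: ConnectivityVector, path, k: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# measure={vec.measure}\tn_regions={vec.n_regions}"
            f"\twindow_size={vec.window_size or ''}\tk={k if k is not None else ''}\n"
        )
        n_base = len(vec.index)
        per_window = n_base // vec.n_windows if vec.measure == "dynFC" else n_base
        for p, (ids, v) in enumerate(zip(vec.index, vec.values)):
            key = "-".join(str(int(i)) for i in ids)
            if vec.measure == "dynFC":
                key = f"w{p // per_window}:{key}"
            fh.write(f"{key}\t{v:.10g}\n")


def read_connectivity(path) -> ConnectivityVector:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(item.split("=") for item in header.split("\t"))
        ids, vals = [], []
        for line in fh:
            key, v = line.rstrip("\n").split("\t")
            key = key.split(":", 1)[-1]
            ids.append(tuple(int(t) for t in key.split("-")))
            vals.append(float(v))
    return ConnectivityVector(
        values=np.array(vals),
        index=np.array(ids),
        measure=meta["measure"],
        n_regions=int(meta["n_regions"]),
        window_size=int(meta["window_size"]) if meta.get("window_size") else None,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    payload = {"schema": REPORT_SCHEMA}
    payload.update(_jsonable(report))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
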