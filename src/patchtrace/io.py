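"""Reading and writing movies, tables and lineage graphs.

Movies live on disk as one uncompressed TIFF per frame per channel, named
``<prefix><frame>_<channel>.tif`` (e.g. ``t007_g.tif``); frame numbers are
parsed numerically, so zero padding is optional. Stage outputs are plain
CSV; the lineage graph exports to GraphML and JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import networkx as nx
import numpy as np
import tifffile

from .frames import BinaryFrame, Frame

_FILE_RE = re.compile(r"^(?P<prefix>.*?)(?P<idx>\d+)_(?P<chan>[A-Za-z]+)\.tiff?$")


def write_movie(frames: list[Frame], directory, prefix: str = "t") -> None:
    """Write one TIFF per frame per channel under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame in frames:
        for chan, data in frame.channels.items():
            name = f"{prefix}{frame.time_index:03d}_{chan}.tif"
            tifffile.imwrite(directory / name, np.asarray(data))


def read_movie(path, channels: tuple[str, ...] = ("r", "g", "b")) -> list[Frame]:
    """Read a movie directory written in the per-frame-per-channel layout.

    Frames are ordered by their numeric index regardless of lexicographic
    file order. A gap in the frame indices or a missing channel file is a
    hard error naming the frame (and channel); all channels must share one
    shape.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such movie directory: {directory}")
    found: dict[int, dict[str, Path]] = {}
    for f in directory.iterdir():
        m = _FILE_RE.match(f.name)
        if m and m.group("chan") in channels:
            found.setdefault(int(m.group("idx")), {})[m.group("chan")] = f
    if not found:
        raise FileNotFoundError(f"no channel TIFFs found in {directory}")
    indices = sorted(found)
    expected = list(range(indices[0], indices[-1] + 1))
    missing = sorted(set(expected) - set(indices))
    if missing:
        raise FileNotFoundError(f"missing frame indices: {missing}")
    frames: list[Frame] = []
    shape = None
    for pos, idx in enumerate(indices):
        chans = {}
        for chan in channels:
            if chan not in found[idx]:
                raise FileNotFoundError(f"frame {idx}: missing channel {chan!r}")
            data = tifffile.imread(found[idx][chan])
            if shape is None:
                shape = data.shape
            elif data.shape != shape:
                raise ValueError(
                    f"frame {idx} channel {chan!r}: shape {data.shape} != {shape}"
                )
            chans[chan] = data
        frames.append(Frame(pos, chans))
    return frames


def write_masks(masks: list[BinaryFrame], directory, prefix: str = "mask") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in masks:
        name = f"{prefix}{m.time_index:03d}_m.tif"
        tifffile.imwrite(directory / name, m.mask.astype(np.uint8) * 255)


def assignment_to_dataframe(assignment, trajs):
    """One row per trajectory point: k, t, x, y, patch_id."""
    import pandas as pd

    rows = []
    for tr in trajs:
        for t, x, y in tr.points:
            rows.append(
                dict(k=tr.k, t=t, x=x, y=y, patch_id=assignment.assign[(tr.k, t)])
            )
    return pd.DataFrame(rows).sort_values(["t", "k"], ignore_index=True)


def graph_to_json_dict(graph: nx.MultiDiGraph) -> dict:
    return {
        "nodes": [
            dict(id=int(n), **{k: v for k, v in attrs.items()})
            for n, attrs in sorted(graph.nodes(data=True))
        ],
        "edges": [
            dict(source=int(u), target=int(v), **attrs)
            for u, v, attrs in sorted(
                graph.edges(data=True), key=lambda e: (e[2].get("t", 0), e[0], e[1])
            )
        ],
        "absorbed_events": graph.graph.get("absorbed_events", []),
        "pruned_flows": graph.graph.get("pruned_flows", []),
    }


def write_graph(graph: nx.MultiDiGraph, basepath) -> None:
    """Write the lineage graph as <basepath>.graphml and <basepath>.json."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    with open(basepath.with_suffix(".json"), "w") as fh:
        json.dump(graph_to_json_dict(graph), fh, indent=2)
    gml = graph.copy()
    for key in ("absorbed_events", "pruned_flows"):
        gml.graph[key] = json.dumps(graph.graph.get(key, []))
    nx.write_graphml(gml, basepath.with_suffix(".graphml"))
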