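"""Readers and writers for matrices, attributes, survival tables, graphs
and search reports.

Conventions: matrices are CSV/TSV with the sample id in the first column
and feature names in the header; attribute and survival tables join to the
matrix by sample id with strict one-to-one checking; every exported file
refers to samples by id, never by positional index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hotspot import RejectionReason
from .mapper import DataMatrix, MapperGraph
from .search import HotspotReport, SearchResult
from .stats import SurvivalData

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_attribute",
    "write_attribute",
    "read_survival",
    "write_survival",
    "write_graph_json",
    "write_graphml",
    "write_dendrogram_tsv",
    "write_report",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(path: str | Path) -> DataMatrix:
    """Load a samples-by-features CSV/TSV (id column first, feature header)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ValueError(f"{path}: missing value at sample {row!r}, column {col!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return DataMatrix(values=values, sample_ids=tuple(str(s) for s in df.index))


def write_matrix(data: DataMatrix, path: str | Path, feature_names=None) -> None:
    path = Path(path)
    cols = feature_names or [f"f{i}" for i in range(data.n_features)]
    df = pd.DataFrame(data.values, index=list(data.sample_ids), columns=cols)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def _aligned(df: pd.DataFrame, data: DataMatrix, path: Path) -> pd.DataFrame:
    ids = list(data.sample_ids)
    missing = set(ids) - set(df.index.astype(str))
    extra = set(df.index.astype(str)) - set(ids)
    if missing or extra:
        raise ValueError(
            f"{path}: sample ids do not match the matrix "
            f"(missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
        )
    df = df.copy()
    df.index = df.index.astype(str)
    return df.loc[ids]


def read_attribute(path: str | Path, data: DataMatrix) -> np.ndarray:
    """Load a (sample_id, value) table aligned to the matrix row order."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one value column")
    df = _aligned(df, data, path)
    values = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: missing attribute values")
    return values


def write_attribute(attr: np.ndarray, data: DataMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"attribute": np.asarray(attr, dtype=float)},
                      index=list(data.sample_ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def read_survival(path: str | Path, data: DataMatrix) -> SurvivalData:
    """Load (sample_id, time_months, event) aligned to the matrix row order."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    required = {"time_months", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df = _aligned(df, data, path)
    events = df["event"].to_numpy(dtype=float)
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValueError(f"{path}: event must be 0 or 1")
    return SurvivalData(df["time_months"].to_numpy(dtype=float), events.astype(bool))


def write_survival(survival: SurvivalData, data: DataMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"time_months": survival.times, "event": survival.events.astype(int)},
        index=list(data.sample_ids),
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def graph_to_dict(graph: MapperGraph) -> dict:
    return {
        "vertices": [
            {
                "id": v.id,
                "interval": v.interval_index,
                "members": sorted(v.members),
                "attr_mean": v.attr_mean,
            }
            for v in graph.vertices
        ],
        "edges": [
            {"u": u, "v": w, "gradient": grad}
            for (u, w), grad in sorted(graph.edges.items())
        ],
    }


def write_graph_json(graph: MapperGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph_to_dict(graph), indent=2))


def write_graphml(graph: MapperGraph, path: str | Path) -> None:
    import networkx as nx

    g = graph.to_networkx()
    # GraphML stores scalars only; member lists become a comma string
    for _, attrs in g.nodes(data=True):
        attrs["members"] = ",".join(str(m) for m in attrs["members"])
        if attrs.get("attr_mean") is None:
            attrs.pop("attr_mean", None)
    for _, _, attrs in g.edges(data=True):
        if attrs.get("gradient") is None:
            attrs.pop("gradient", None)
    nx.write_graphml(g, str(path))


def write_dendrogram_tsv(dendrogram, path: str | Path) -> None:
    lines = ["height\tleft\tright"]
    for merge in dendrogram.merges:
        left, right = merge.groups
        lines.append(
            f"{merge.height:.10g}\t{','.join(map(str, sorted(left)))}"
            f"\t{','.join(map(str, sorted(right)))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def report_to_dict(result: SearchResult, config: dict | None = None) -> dict:
    def hotspot_dict(h: HotspotReport) -> dict:
        rec = h.record
        return {
            "parameters": {
                "lens_seed": h.lens.seed,
                "lens_index": h.lens_index,
                "t": h.t,
                "p": h.p,
            },
            "hotspot": {
                "vertex_ids": sorted(rec.community.vertex_ids),
                "sample_ids": sorted(h.sample_ids),
                "S": rec.community.size,
                "attr_mean": rec.community.attr_mean,
            },
            "neighbourhood": {
                "S": rec.neighbourhood_size,
                "attr_mean": rec.neighbourhood_attr_mean,
            },
            "sigma2": rec.sigma2,
            "score": h.score,
            "logrank_p": h.logrank_p,
            "decision": "hotspot" if rec.is_hotspot else "non-hotspot",
            "rejection_reason": rec.rejection_reason.value,
        }

    return {
        "config": config or {},
        "lenses_tried": result.lenses_tried,
        "graphs_built": result.graphs_built,
        "best": hotspot_dict(result.best) if result.best else None,
        "all_hits": [hotspot_dict(h) for h in result.all_hits],
    }


def write_report(result: SearchResult, path: str | Path, config: dict | None = None) -> None:
    """Write the search report JSON; config and seeds are embedded verbatim
    so the run can be reproduced."""
    Path(path).write_text(json.dumps(report_to_dict(result, config), indent=2))
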