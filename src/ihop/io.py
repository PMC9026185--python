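"""Plain-text readers and writers for graph datasets.

Formats
-------
Edge list
    2-3 whitespace/tab-delimited columns ``src dst [weight]``; ``#`` starts
    a comment.  Node ids may be arbitrary strings or integers; they are
    remapped to contiguous 0-based ids with a persisted id-map.
Features
    TSV with a node-id column followed by ``f`` numeric columns, or a
    MatrixMarket coordinate file (rows are nodes in id order).
Labels
    TSV with a node-id column followed by ``l`` binary columns.
Splits
    One node id per line (train / val / test files).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread

from .graph import CCDataset, Graph

__all__ = ["load_dataset", "save_dataset", "write_id_map"]


class ParseError(ValueError):
    """Raised for malformed input lines; carries file and line number."""


def _read_tokenized(path):
    """Yield (lineno, tokens) for non-empty, non-comment lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            yield lineno, line.split()


def _read_edge_file(path):
    edges, weights = [], []
    for lineno, tok in _read_tokenized(path):
        if len(tok) not in (2, 3):
            raise ParseError(
                f"{path}:{lineno}: expected 2 or 3 columns, got {len(tok)}"
            )
        try:
            w = float(tok[2]) if len(tok) == 3 else 1.0
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad edge weight {tok[2]!r}") from exc
        edges.append((tok[0], tok[1]))
        weights.append(w)
    return edges, weights


def _read_table(path, kind):
    ids, rows = [], []
    width = None
    for lineno, tok in _read_tokenized(path):
        if len(tok) < 2:
            raise ParseError(f"{path}:{lineno}: {kind} row needs id + values")
        if width is None:
            width = len(tok)
        elif len(tok) != width:
            raise ParseError(
                f"{path}:{lineno}: ragged {kind} row ({len(tok)} != {width} columns)"
            )
        try:
            rows.append([float(v) for v in tok[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric {kind} value") from exc
        ids.append(tok[0])
    return ids, np.asarray(rows, dtype=np.float64)


def _read_split(path):
    return [tok[0] for _, tok in _read_tokenized(path)]


def _sort_key(raw_id: str):
    try:
        return (0, int(raw_id), "")
    except ValueError:
        return (1, 0, raw_id)


def load_dataset(
    edge_path,
    feature_path,
    label_path,
    split_paths: dict,
    task: str,
    row_normalize: bool = True,
    name: str | None = None,
) -> CCDataset:
    """Load and validate a collective-classification dataset from files.

    ``split_paths`` maps ``{"train": ..., "val": ..., "test": ...}`` to
    node-id list files.  The labeled set ``S`` is train + val.  The node
    universe is defined by the feature file; edge or split ids outside it
    are rejected.  Non-contiguous or non-integer ids are remapped (sorted
    numerically when possible) and the mapping is kept on the dataset.
    """
    feature_path = Path(feature_path)
    if feature_path.suffix in (".mtx", ".mm"):
        M = mmread(feature_path)
        X = np.asarray(M.todense() if sp.issparse(M) else M, dtype=np.float64)
        raw_ids = [str(i) for i in range(X.shape[0])]
    else:
        raw_ids, X = _read_table(feature_path, "feature")
        if len(set(raw_ids)) != len(raw_ids):
            raise ParseError(f"{feature_path}: duplicate node ids")

    order = sorted(range(len(raw_ids)), key=lambda i: _sort_key(raw_ids[i]))
    id_map = {raw_ids[i]: pos for pos, i in enumerate(order)}
    X = X[order]
    n = len(raw_ids)

    def _map(raw, where):
        if raw not in id_map:
            raise ValueError(f"{where}: unknown node id {raw!r}")
        return id_map[raw]

    edges_raw, weights = _read_edge_file(edge_path)
    edges = [(_map(u, edge_path), _map(v, edge_path)) for u, v in edges_raw]
    graph = Graph.from_edges(n, edges, weights)

    splits = {}
    for key in ("train", "val", "test"):
        ids = _read_split(split_paths[key])
        splits[key] = np.asarray(
            sorted({_map(r, split_paths[key]) for r in ids}), dtype=np.int64
        )
    S = np.union1d(splits["train"], splits["val"])
    U = np.setdiff1d(np.arange(n), S)
    if not set(splits["test"].tolist()) <= set(U.tolist()):
        raise ValueError("test nodes overlap the labeled (train/val) set")

    lab_ids, lab_rows = _read_table(label_path, "label")
    if not np.isin(lab_rows, (0.0, 1.0)).all():
        raise ParseError(f"{label_path}: label values must be 0/1")
    allowed = set(S.tolist()) | set(splits["test"].tolist())
    Y = np.zeros((n, lab_rows.shape[1]), dtype=np.float64)
    for raw, row in zip(lab_ids, lab_rows):
        node = _map(raw, label_path)
        if node not in allowed:
            raise ValueError(
                f"{label_path}: label row for node {raw!r} which is neither "
                "labeled (train/val) nor a test node"
            )
        Y[node] = row
    missing = [s for s in S.tolist() if not Y[s].any()]
    if missing and task == "multi-label":
        raise ValueError(f"labeled nodes without any label row/positives: {missing[:5]}")
    if task == "multi-class" and any(Y[s].sum() != 1 for s in S.tolist()):
        raise ValueError("every labeled node needs exactly one class label")

    ds = CCDataset(
        graph=graph, X=X, Y=Y, S=S, U=U, val=splits["val"], test=splits["test"],
        task=task, id_map=id_map, name=name or Path(edge_path).stem,
    )
    if row_normalize:
        ds.row_normalize_features()
    ds.validate()
    return ds


def save_dataset(ds: CCDataset, out_dir) -> dict:
    """Write a dataset to the standard plain-text files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "features": out / "features.tsv",
        "labels": out / "labels.tsv",
        "train": out / "train.txt",
        "val": out / "val.txt",
        "test": out / "test.txt",
    }
    with open(paths["edges"], "w") as fh:
        fh.write("# src\tdst\tweight\n")
        coo = ds.graph.A.tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            if i < j:
                fh.write(f"{i}\t{j}\t{w:g}\n")
    with open(paths["features"], "w") as fh:
        for i, row in enumerate(ds.X):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    labeled = sorted(set(ds.S.tolist()) | set(ds.test.tolist()))
    with open(paths["labels"], "w") as fh:
        for i in labeled:
            fh.write(str(i) + "\t" + "\t".join(str(int(v)) for v in ds.Y[i]) + "\n")
    train = np.setdiff1d(ds.S, ds.val)
    for key, nodes in (("train", train), ("val", ds.val), ("test", ds.test)):
        with open(paths[key], "w") as fh:
            fh.writelines(f"{i}\n" for i in nodes.tolist())
    return paths


def write_id_map(id_map: dict, path) -> None:
    """Persist an original-id -> internal-id mapping as TSV."""
    with open(path, "w") as fh:
        fh.write("# original_id\tinternal_id\n")
        for raw, internal in sorted(id_map.items(), key=lambda kv: kv[1]):
            fh.write(f"{raw}\t{internal}\n")
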