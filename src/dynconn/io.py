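"""Delimited-text input, and JSON/CSV/TSV result serialization.

Time-series input is delimited text with rows as time points and columns as
channels; the delimiter is auto-detected between comma and tab unless
forced.  Results round-trip losslessly through JSON: floats are written via
Python's shortest-round-trip repr, which preserves every bit.

All time indices in the result document are 1-based and inclusive.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DataValidationError
from .sparse_estimation import TimeSeriesMatrix
from .segmentation import SegmentationResult

__all__ = ["ResultDocument", "read_timeseries", "write_results", "read_results"]


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_timeseries(path, delimiter: str | None = None, header: str | bool = "auto") -> TimeSeriesMatrix:
    """Read a ``T x J`` delimited-text series (rows = time, columns = channels).

    ``header`` may be True, False, or "auto" (header assumed iff the first
    row contains a non-numeric cell).  Without a header, channels are named
    ``c1 .. cJ``.  Ragged rows, non-numeric and non-finite cells are
    rejected with their line and column location.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise DataValidationError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _detect_delimiter(text.splitlines()[0])

    rows = [row for row in csv.reader(text.splitlines(), delimiter=delimiter)]
    rows = [(lineno, row) for lineno, row in enumerate(rows, start=1) if any(c.strip() for c in row)]

    def _is_number(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    first_line, first_row = rows[0]
    if header == "auto":
        has_header = not all(_is_number(c) for c in first_row)
    else:
        has_header = bool(header)

    names: list[str] | None = None
    if has_header:
        names = [c.strip() for c in first_row]
        rows = rows[1:]
        if not rows:
            raise DataValidationError(f"{path}: no data rows below the header")

    width = len(rows[0][1])
    data = np.empty((len(rows), width), dtype=float)
    for r, (lineno, row) in enumerate(rows):
        if len(row) != width:
            raise DataValidationError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
        for c, cell in enumerate(row):
            try:
                value = float(cell)
            except ValueError:
                raise DataValidationError(
                    f"{path}: non-numeric value {cell.strip()!r} at line {lineno}, column {c + 1}"
                ) from None
            if not math.isfinite(value):
                raise DataValidationError(
                    f"{path}: non-finite value {cell.strip()!r} at line {lineno}, column {c + 1}"
                )
            data[r, c] = value

    if names is None:
        names = [f"c{k + 1}" for k in range(width)]
    if len(names) != width:
        raise DataValidationError(
            f"{path}: header has {len(names)} names for {width} columns"
        )
    return TimeSeriesMatrix(data, channel_names=names)


@dataclass
class ResultDocument:
    """Serializable snapshot of a segmentation result.

    ``metadata`` echoes the configuration and seed; ``segments`` holds one
    block per terminal segment with its 1-based inclusive bounds, sparse
    mean, sparse covariance, and binary adjacency; ``tree`` traces every
    node of the binary search (candidate location, gain, test outcome).
    """

    metadata: dict = field(default_factory=dict)
    change_points: list[int] = field(default_factory=list)
    segments: list[dict] = field(default_factory=list)
    tree: list[dict] = field(default_factory=list)
    channel_names: list[str] | None = None

    @classmethod
    def from_result(
        cls, result: SegmentationResult, metadata: dict | None = None
    ) -> "ResultDocument":
        segments = []
        for params, adj in zip(result.segments, result.graphs):
            segments.append(
                {
                    "start": int(params.start),
                    "end": int(params.end),
                    "mean": [float(v) for v in params.mean],
                    "cov": [[float(v) for v in row] for row in params.cov],
                    "adjacency": [[int(v) for v in row] for row in adj],
                }
            )
        tree = []
        for node in result.tree:
            tree.append(
                {
                    "start": int(node["start"]),
                    "end": int(node["end"]),
                    "parent": node["parent"],
                    "t0": None if node["t0"] is None else int(node["t0"]),
                    "gain": None if node["gain"] is None else float(node["gain"]),
                    "tested": bool(node["tested"]),
                    "significant": bool(node["significant"]),
                    "min_p": None if node["min_p"] is None else float(node["min_p"]),
                    "n_tests": int(node["n_tests"]),
                }
            )
        meta = dict(metadata or {})
        meta.setdefault("delta", int(result.delta))
        return cls(
            metadata=meta,
            change_points=[int(c) for c in result.change_points],
            segments=segments,
            tree=tree,
            channel_names=result.channel_names,
        )

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "change_points": self.change_points,
            "segments": self.segments,
            "tree": self.tree,
            "channel_names": self.channel_names,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ResultDocument":
        return cls(
            metadata=payload.get("metadata", {}),
            change_points=list(payload.get("change_points", [])),
            segments=list(payload.get("segments", [])),
            tree=list(payload.get("tree", [])),
            channel_names=payload.get("channel_names"),
        )


def write_results(
    result: SegmentationResult, outdir, metadata: dict | None = None
) -> ResultDocument:
    """Write ``results.json`` plus per-segment adjacency CSVs and edge-list TSVs.

    Adjacency files are ``segment_<k>_adjacency.csv`` (0/1 matrices); edge
    lists are ``segment_<k>_edges.tsv`` with columns channel_i, channel_j,
    covariance.  Returns the written :class:`ResultDocument`.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataValidationError(f"cannot create output directory {outdir}: {exc}") from exc

    doc = ResultDocument.from_result(result, metadata)
    (outdir / "results.json").write_text(json.dumps(doc.to_dict(), indent=1) + "\n")

    names = doc.channel_names
    for k, block in enumerate(doc.segments, start=1):
        adj = np.asarray(block["adjacency"], dtype=int)
        j = adj.shape[0]
        labels = names if names is not None else [f"c{x + 1}" for x in range(j)]
        with open(outdir / f"segment_{k:02d}_adjacency.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(labels)
            writer.writerows(adj.tolist())
        cov = np.asarray(block["cov"], dtype=float)
        with open(outdir / f"segment_{k:02d}_edges.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["channel_i", "channel_j", "covariance"])
            for a in range(j):
                for b in range(a + 1, j):
                    if adj[a, b]:
                        writer.writerow([labels[a], labels[b], repr(float(cov[a, b]))])
    return doc


def read_results(path) -> ResultDocument:
    """Read a ``results.json`` document back (lossless round trip)."""
    payload = json.loads(Path(path).read_text())
    return ResultDocument.from_dict(payload)
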