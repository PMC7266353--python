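"""Recorded genealogies: node/edge tables, traces, and their TSV round trip.

Node times are generations (0 = present, increasing into the past); edge
intervals are half-open and in Morgans on the axis the simulation ran on
(``spacer`` says how much inert gap that axis put between chromosomes).
Edges are stored grouped by parent with parents in nondecreasing time
order, and adjacent intervals of the same (parent, child) pair squashed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NODE_IS_CENSUS, NODE_IS_SAMPLE, TableBuilder
from .genome import GeneticMap

__all__ = ["Genealogy", "write_tables", "read_tables", "ParseError"]

_FORMAT_VERSION = "wfcoal-tables 1"


class ParseError(ValueError):
    def __init__(self, message, path=None, line=None):
        loc = f"{path}:{line}: " if path is not None else ""
        super().__init__(f"{loc}{message}")


@dataclass
class Genealogy:
    """A simulated genealogy plus the context needed to interpret it."""

    nodes: pd.DataFrame       # time, population, flags, individual
    edges: pd.DataFrame       # left, right, parent, child
    map: GeneticMap
    spacer: float             # inter-chromosome gap on the simulation axis
    trace: pd.DataFrame       # generation, lineages (may be empty)
    model: str = ""
    seed: int | None = None

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.nodes.index[(self.nodes["flags"].to_numpy() & NODE_IS_SAMPLE) != 0].to_numpy()

    @property
    def num_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def axis_length(self) -> float:
        return self.map.axis_length(self.spacer)

    def census_nodes(self, time: float | None = None) -> np.ndarray:
        mask = (self.nodes["flags"].to_numpy() & NODE_IS_CENSUS) != 0
        if time is not None:
            mask &= np.isclose(self.nodes.time.to_numpy(), time)
        return self.nodes.index[mask].to_numpy()

    def breakpoints(self) -> np.ndarray:
        """Sorted unique edge interval endpoints, including the axis ends."""
        pts = np.concatenate([
            self.edges.left.to_numpy(), self.edges.right.to_numpy(),
            [0.0, self.axis_length],
        ])
        return np.unique(pts)


def finalize_tables(builder: TableBuilder, genetic_map: GeneticMap, spacer: float,
                    trace_rows, model: str = "", seed: int | None = None) -> Genealogy:
    """Sort, squash and freeze a :class:`TableBuilder` into a Genealogy."""
    nodes = pd.DataFrame({
        "time": np.asarray(builder.node_time, dtype=float),
        "population": np.asarray(builder.node_population, dtype=np.int32),
        "flags": np.asarray(builder.node_flags, dtype=np.int32),
        "individual": np.asarray(builder.node_individual, dtype=np.int64),
    })
    edges = pd.DataFrame({
        "left": np.asarray(builder.edge_left, dtype=float),
        "right": np.asarray(builder.edge_right, dtype=float),
        "parent": np.asarray(builder.edge_parent, dtype=np.int64),
        "child": np.asarray(builder.edge_child, dtype=np.int64),
    })
    if len(edges):
        ptime = nodes.time.to_numpy()[edges.parent.to_numpy()]
        order = np.lexsort((edges.left.to_numpy(), edges.child.to_numpy(),
                            edges.parent.to_numpy(), ptime))
        edges = edges.iloc[order].reset_index(drop=True)
        edges = _squash(edges)
    trace = pd.DataFrame(trace_rows, columns=["generation", "lineages"])
    return Genealogy(nodes=nodes, edges=edges, map=genetic_map, spacer=spacer,
                     trace=trace, model=model, seed=seed)


def _squash(edges: pd.DataFrame) -> pd.DataFrame:
    left = edges.left.to_numpy()
    right = edges.right.to_numpy()
    parent = edges.parent.to_numpy()
    child = edges.child.to_numpy()
    keep_l, keep_r, keep_p, keep_c = [], [], [], []
    for i in range(len(edges)):
        if (keep_p and keep_p[-1] == parent[i] and keep_c[-1] == child[i]
                and keep_r[-1] == left[i]):
            keep_r[-1] = right[i]
        else:
            keep_l.append(left[i]); keep_r.append(right[i])
            keep_p.append(parent[i]); keep_c.append(child[i])
    return pd.DataFrame({"left": keep_l, "right": keep_r,
                         "parent": np.asarray(keep_p, dtype=np.int64),
                         "child": np.asarray(keep_c, dtype=np.int64)})


# ---------------------------------------------------------------------------
# TSV round trip

def _fmt(x: float) -> str:
    return repr(float(x))


def write_tables(g: Genealogy, path: str) -> None:
    """Write a genealogy to ``path`` (a directory) as deterministic TSVs."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "metadata.tsv"), "w") as f:
        f.write(f"# {_FORMAT_VERSION}\n")
        f.write("key\tvalue\n")
        f.write(f"spacer\t{_fmt(g.spacer)}\n")
        f.write(f"model\t{g.model}\n")
        f.write(f"seed\t{'' if g.seed is None else g.seed}\n")
        f.write(f"bp_per_morgan\t{_fmt(g.map.bp_per_morgan)}\n")
        f.write(f"hudson_spacer\t{_fmt(g.map.hudson_spacer)}\n")
        lens = ",".join(_fmt(x) for x in g.map.chromosome_lengths)
        f.write(f"chromosome_lengths\t{lens}\n")
    with open(os.path.join(path, "nodes.tsv"), "w") as f:
        f.write(f"# {_FORMAT_VERSION}\n")
        f.write("id\tflags\ttime\tpopulation\tindividual\n")
        for i, row in enumerate(g.nodes.itertuples(index=False)):
            f.write(f"{i}\t{row.flags}\t{_fmt(row.time)}\t{row.population}\t{row.individual}\n")
    with open(os.path.join(path, "edges.tsv"), "w") as f:
        f.write(f"# {_FORMAT_VERSION}\n")
        f.write("left\tright\tparent\tchild\n")
        for row in g.edges.itertuples(index=False):
            f.write(f"{_fmt(row.left)}\t{_fmt(row.right)}\t{row.parent}\t{row.child}\n")
    with open(os.path.join(path, "trace.tsv"), "w") as f:
        f.write(f"# {_FORMAT_VERSION}\n")
        f.write("generation\tlineages\n")
        for row in g.trace.itertuples(index=False):
            f.write(f"{_fmt(row.generation)}\t{int(row.lineages)}\n")


def _read_tsv(path: str, fname: str, columns) -> pd.DataFrame:
    full = os.path.join(path, fname)
    rows = []
    with open(full) as f:
        header = None
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if _FORMAT_VERSION not in line:
                    raise ParseError("unknown format version", full, lineno)
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header != list(columns):
                    raise ParseError(f"expected columns {list(columns)}, got {header}",
                                     full, lineno)
                continue
            if len(parts) != len(header):
                raise ParseError("wrong number of fields", full, lineno)
            rows.append(parts)
    if header is None:
        raise ParseError("missing header", full)
    return pd.DataFrame(rows, columns=header)


def read_tables(path: str) -> Genealogy:
    """Read a genealogy written by :func:`write_tables`."""
    meta_df = _read_tsv(path, "metadata.tsv", ["key", "value"])
    meta = dict(zip(meta_df.key, meta_df.value))
    gmap = GeneticMap(
        chromosome_lengths=tuple(float(x) for x in meta["chromosome_lengths"].split(",")),
        hudson_spacer=float(meta["hudson_spacer"]),
        bp_per_morgan=float(meta["bp_per_morgan"]),
    )
    nodes = _read_tsv(path, "nodes.tsv", ["id", "flags", "time", "population", "individual"])
    nodes = pd.DataFrame({
        "time": nodes.time.astype(float),
        "population": nodes.population.astype(np.int32),
        "flags": nodes["flags"].astype(np.int32),
        "individual": nodes.individual.astype(np.int64),
    })
    edges = _read_tsv(path, "edges.tsv", ["left", "right", "parent", "child"])
    edges = pd.DataFrame({
        "left": edges.left.astype(float), "right": edges.right.astype(float),
        "parent": edges.parent.astype(np.int64), "child": edges.child.astype(np.int64),
    })
    trace = _read_tsv(path, "trace.tsv", ["generation", "lineages"])
    trace = pd.DataFrame({
        "generation": trace.generation.astype(float),
        "lineages": trace.lineages.astype(np.int64),
    })
    seed = meta.get("seed", "")
    return Genealogy(nodes=nodes, edges=edges, map=gmap, spacer=float(meta["spacer"]),
                     trace=trace, model=meta.get("model", ""),
                     seed=None if seed == "" else int(seed))
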