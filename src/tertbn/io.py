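"""File formats: signed edge-list TSV, screen-record CSV, Pajek .net/.clu.

The edge-list dialect is a TSV with one header line ``source\ttarget\tsign``
(sign written ``+1``/``-1``) preceded by comment lines that make the
round-trip lossless::

    #target=TERT
    #nodes=AR,JUN,...      (full node list in index order)

Pajek files use 1-based vertex numbering with quoted labels (internal node
indices are 0-based; the writer owns that boundary).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .netcore import SCREEN_COLUMNS, SignedNetwork

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_screen_csv",
    "write_screen_csv",
    "write_pajek_network",
    "write_pajek_graph",
]


class EdgeListFormatError(ValueError):
    """Malformed edge-list file; message carries the offending line number."""


def write_edge_list(network: SignedNetwork, path) -> None:
    path = Path(path)
    lines = [
        f"#target={network.target}",
        "#nodes=" + ",".join(network.node_names),
        "source\ttarget\tsign",
    ]
    for it in network.interactions:
        sign = "+1" if it.sign == 1 else "-1"
        lines.append(f"{it.source}\t{it.target}\t{sign}")
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path) -> SignedNetwork:
    path = Path(path)
    target = "TERT"
    nodes: list[str] | None = None
    edges: list[tuple[str, str, int]] = []
    seen: dict[tuple[str, str], int] = {}
    header_done = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key == "target":
                target = value.strip()
            elif key == "nodes":
                nodes = [g.strip() for g in value.split(",") if g.strip()]
            continue
        if not header_done:
            cols = line.split("\t")
            if cols != ["source", "target", "sign"]:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected header 'source\\ttarget\\tsign'"
                )
            header_done = True
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise EdgeListFormatError(f"{path}:{lineno}: expected 3 fields")
        src, tgt, sign_tok = parts
        if sign_tok not in ("+1", "-1", "1"):
            raise EdgeListFormatError(
                f"{path}:{lineno}: malformed sign token {sign_tok!r}"
            )
        if (src, tgt) in seen:
            raise EdgeListFormatError(
                f"{path}:{lineno}: duplicate edge {src}->{tgt} "
                f"(first at line {seen[(src, tgt)]})"
            )
        seen[(src, tgt)] = lineno
        edges.append((src, tgt, 1 if sign_tok in ("+1", "1") else -1))

    if nodes is None:
        nodes = []
        for s, t, _ in edges:
            for g in (s, t):
                if g not in nodes:
                    nodes.append(g)
    declared = set(nodes)
    for lineno, (s, t, _) in zip(
        (seen[(s, t)] for s, t, _ in edges), edges
    ):
        for g in (s, t):
            if g not in declared:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: edge references undeclared node {g!r}"
                )
    return SignedNetwork(nodes, edges, target=target)


def write_screen_csv(records: pd.DataFrame, path) -> None:
    pd.DataFrame(records)[list(SCREEN_COLUMNS)].to_csv(path, index=False)


def read_screen_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: screen CSV missing columns {missing}")
    return df


def _pajek_lines(
    labels: Sequence[str], arcs: Iterable[tuple[int, int, int]]
) -> list[str]:
    lines = [f"*Vertices {len(labels)}"]
    lines += [f'{i + 1} "{lab}"' for i, lab in enumerate(labels)]
    lines.append("*Arcs")
    lines += [f"{s + 1} {t + 1} {w}" for s, t, w in arcs]
    return lines


def write_pajek_network(network: SignedNetwork, path, partition=None) -> None:
    """Write a signed network as Pajek .net; arc weights carry the signs."""
    arcs = [
        (network.index(it.source), network.index(it.target), it.sign)
        for it in network.interactions
    ]
    _write_pajek(list(network.node_names), arcs, path, partition)


def write_pajek_graph(
    labels: Sequence[str],
    arcs: Sequence[tuple[int, int, int]],
    ids: Sequence[int],
    path,
    partition=None,
) -> None:
    """Write a generic directed graph whose arcs reference external ids.

    ``ids`` gives the external id of each vertex in label order; arcs are
    (source_id, target_id, weight) triples re-indexed to Pajek's 1-based
    vertex numbers.
    """
    pos = {v: i for i, v in enumerate(ids)}
    rearcs = [(pos[s], pos[t], w) for s, t, w in arcs]
    _write_pajek(list(labels), rearcs, path, partition)


def _write_pajek(labels, arcs, path, partition) -> None:
    path = Path(path)
    path.write_text("\n".join(_pajek_lines(labels, arcs)) + "\n")
    if partition is not None:
        if len(partition) != len(labels):
            raise ValueError("partition length must match vertex count")
        clu = path.with_suffix(".clu")
        clu.write_text(
            "\n".join([f"*Vertices {len(partition)}"] + [str(int(p)) for p in partition])
            + "\n"
        )
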