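"""Structural-variant / copy-number integration and independence filtering.

Co-occurrence statistics must not count a copy alteration and the
rearrangement that created it as two independent events.  Two alterations in
one sample are *non-independent* when

(a) a single SV has one breakpoint within 5 kb of a boundary of the first
    alteration and its other breakpoint within 5 kb of a boundary of the
    second (e.g. an unbalanced translocation joining the end of an 11q13.3
    gain to the beginning of a 17q gain makes the translocation and both
    gains mutually non-independent), or
(b) a chain of SVs connects them, where consecutive breakpoints on each
    intervening chromosome lie 15 Mb or less apart.

Linkage is transitive (path connectivity in the per-sample graph).  SNVs and
indels are always independent of everything and never become graph nodes.

The hotspot t(11;17) is a translocation joining 17q at >= 30 Mb to 11q
between 60 and 80 Mb (GRCh37); bounds inclusive, breakpoint order
irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

SV_CNA_WINDOW_BP = 5_000
MAX_HOP_BP = 15_000_000

SV_TYPES = ("translocation", "deletion", "duplication", "inversion", "other")


@dataclass(frozen=True)
class SvRecord:
    """One structural variant: two breakpoints and a type."""

    sample: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    svtype: str = "other"

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("breakpoint positions must be >= 1")
        if self.chrom_a == self.chrom_b and self.pos_a == self.pos_b:
            raise ValueError("degenerate SV: both breakpoints identical")

    @property
    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chrom_a, self.pos_a), (self.chrom_b, self.pos_b))


@dataclass(frozen=True)
class Alteration:
    """A named alteration with genomic boundary points (CNA termini, or the
    breakpoints of a translocation event itself)."""

    id: str
    boundaries: tuple[tuple[str, int], ...] = field(default_factory=tuple)


def classify_t11_17(sv: SvRecord) -> bool:
    """Hotspot t(11;17): 17q at >= 30 Mb joined to 11q in [60, 80] Mb (inclusive)."""
    if sv.svtype != "translocation":
        warnings.warn("classify_t11_17 called on a non-translocation SV", stacklevel=2)
        return False

    def _is17(chrom: str, pos: int) -> bool:
        return chrom in ("17", "chr17") and pos >= 30_000_000

    def _is11(chrom: str, pos: int) -> bool:
        return chrom in ("11", "chr11") and 60_000_000 <= pos <= 80_000_000

    (ca, pa), (cb, pb) = sv.breakpoints
    return (_is17(ca, pa) and _is11(cb, pb)) or (_is17(cb, pb) and _is11(ca, pa))


def match_sv_to_cna(
    svs: Sequence[SvRecord],
    alterations: Sequence[Alteration],
    window: int = SV_CNA_WINDOW_BP,
) -> pd.DataFrame:
    """Match SV breakpoints to alteration boundaries within ``window`` bp
    (inclusive), same chromosome.  One row per (breakpoint, boundary) match."""
    rows = []
    for i, sv in enumerate(svs):
        for side, (chrom, pos) in zip("AB", sv.breakpoints):
            for alt in alterations:
                for b_chrom, b_pos in alt.boundaries:
                    if chrom == b_chrom and abs(pos - b_pos) <= window:
                        rows.append(
                            {
                                "sv_index": i,
                                "breakpoint": side,
                                "chrom": chrom,
                                "pos": pos,
                                "alteration": alt.id,
                                "boundary_pos": b_pos,
                                "distance": abs(pos - b_pos),
                            }
                        )
    return pd.DataFrame(
        rows,
        columns=["sv_index", "breakpoint", "chrom", "pos", "alteration", "boundary_pos", "distance"],
    )


def build_linkage_graph(
    svs: Sequence[SvRecord],
    alterations: Sequence[Alteration],
    window: int = SV_CNA_WINDOW_BP,
    max_hop: int = MAX_HOP_BP,
) -> nx.Graph:
    """Per-sample linkage graph over alteration ids.

    Nodes are alteration ids plus internal breakpoint nodes.  Edges: each
    SV's two breakpoints; breakpoints of different SVs on the same
    chromosome within ``max_hop`` (chaining); alteration boundaries to
    breakpoints within ``window``.  Two alterations are linked iff a path
    connects them; adding SVs can only add edges, never remove them.
    """
    g = nx.Graph()
    for alt in alterations:
        g.add_node(alt.id, kind="alteration")
    bp_nodes: list[tuple[tuple[str, int, int], str, int]] = []  # (node, chrom, pos)
    for i, sv in enumerate(svs):
        nodes = []
        for side, (chrom, pos) in zip((0, 1), sv.breakpoints):
            node = ("bp", i, side)
            g.add_node(node, kind="breakpoint")
            nodes.append(node)
            bp_nodes.append((node, chrom, pos))
        g.add_edge(*nodes, kind="sv")
    # chain breakpoints of different SVs on the same chromosome
    for idx, (node, chrom, pos) in enumerate(bp_nodes):
        for other, ochrom, opos in bp_nodes[idx + 1 :]:
            if node[1] == other[1]:
                continue  # same SV: already joined
            if chrom == ochrom and abs(pos - opos) <= max_hop:
                g.add_edge(node, other, kind="chain")
    # attach alteration boundaries
    for alt in alterations:
        for b_chrom, b_pos in alt.boundaries:
            for node, chrom, pos in bp_nodes:
                if chrom == b_chrom and abs(pos - b_pos) <= window:
                    g.add_edge(alt.id, node, kind="boundary")
    return g


def independent_pair_filter(graph: nx.Graph, pair: tuple[str, str]) -> str:
    """``linked`` iff the two alterations are connected by any path in the
    sample's linkage graph, else ``independent``."""
    a, b = pair
    for node in (a, b):
        if node not in graph:
            raise KeyError(f"unknown alteration id {node!r}")
    return "linked" if nx.has_path(graph, a, b) else "independent"


def linkage_edges_table(graph: nx.Graph) -> pd.DataFrame:
    """Tidy table of linked alteration pairs (transitive closure over components)."""
    alt_nodes = [n for n, d in graph.nodes(data=True) if d.get("kind") == "alteration"]
    rows = []
    for comp in nx.connected_components(graph):
        alts = sorted(n for n in comp if n in set(alt_nodes))
        for i, a in enumerate(alts):
            for b in alts[i + 1 :]:
                rows.append({"alteration_a": a, "alteration_b": b})
    return pd.DataFrame(rows, columns=["alteration_a", "alteration_b"])


def linked_lookup(graphs: dict[str, nx.Graph]):
    """Make a ``linked(sample, a, b) -> bool`` callable over per-sample graphs.

    Alterations absent from a sample's graph (e.g. SNV-level events, which
    are never graph nodes) are independent by definition.
    """

    def linked(sample: str, a: str, b: str) -> bool:
        g = graphs.get(sample)
        if g is None or a not in g or b not in g:
            return False
        return independent_pair_filter(g, (a, b)) == "linked"

    return linked


def svs_from_table(df: pd.DataFrame) -> list[SvRecord]:
    """Build SvRecords from a BEDPE-like table
    (sample, chrom_a, pos_a, chrom_b, pos_b, svtype)."""
    return [
        SvRecord(
            sample=str(r.sample),
            chrom_a=str(r.chrom_a),
            pos_a=int(r.pos_a),
            chrom_b=str(r.chrom_b),
            pos_b=int(r.pos_b),
            svtype=str(r.svtype),
        )
        for r in df.itertuples(index=False)
    ]
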