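"""Melanocytic nest calling.

A nest is a cluster of three or more confluent melanocytes. Confluence is
treated geometrically: two nucleus instances are confluent when their
pixel masks, each dilated by half the allowed gap, intersect — i.e. the
masks come within ``confluence_gap_um`` of each other. Nests are the
connected components of that confluence graph with at least
``min_cluster_size`` members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import NucleusInstance
from .errors import ConfigurationError


@dataclass
class NestConfig:
    min_cluster_size: int = 3
    confluence_gap_um: float = 1.0
    scope: str = "junctional_only"  # junctional_only | all_epidermal

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ConfigurationError("min_cluster_size must be >= 2")
        if self.confluence_gap_um < 0:
            raise ConfigurationError("confluence_gap_um must be non-negative")
        if self.scope not in ("junctional_only", "all_epidermal"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")


@dataclass
class NestCall:
    nest_id: int
    member_ids: list[int]
    centroid: tuple[float, float]
    arc_start_mm: float
    arc_end_mm: float

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def as_row(self) -> dict:
        return {
            "nest_id": self.nest_id,
            "member_ids": ";".join(str(m) for m in self.member_ids),
            "n_members": self.size,
            "arc_start_mm": self.arc_start_mm,
            "arc_end_mm": self.arc_end_mm,
        }


def _mask_pixels(labels: np.ndarray, label: int, bbox_pad: int) -> np.ndarray:
    ys, xs = np.nonzero(labels == label)
    return np.stack([xs, ys], axis=1)


def build_confluence_graph(
    instances: list[NucleusInstance],
    labels: np.ndarray,
    config: NestConfig | None = None,
    microns_per_pixel: float = 1.0,
) -> nx.Graph:
    """Graph with an edge between instances whose masks come within the gap.

    Candidate pairs are pruned with a centroid KD-tree; the exact test is
    the minimum pixel distance between the two masks, compared against
    ``confluence_gap_um`` (each mask conceptually dilated by half the gap).
    Monotone in the gap: enlarging it can only add edges.
    """
    config = config or NestConfig()
    if config.scope == "junctional_only":
        instances = [i for i in instances if i.junctional]
    g = nx.Graph()
    g.add_nodes_from(i.id for i in instances)
    if len(instances) < 2:
        return g
    gap_px = config.confluence_gap_um / microns_per_pixel
    pix = {i.id: _mask_pixels(labels, i.label, 0) for i in instances}
    radius = {k: np.max(np.linalg.norm(v - np.mean(v, axis=0), axis=1)) if len(v) else 0.0
              for k, v in pix.items()}
    cents = np.array([i.centroid for i in instances])
    tree = cKDTree(cents)
    rmax = max(radius.values(), default=0.0)
    pairs = tree.query_pairs(2 * rmax + gap_px + 2.0)
    for a, b in pairs:
        ia, ib = instances[a], instances[b]
        pa, pb = pix[ia.id], pix[ib.id]
        if len(pa) == 0 or len(pb) == 0:
            continue
        d = cKDTree(pa).query(pb)[0].min()
        # adjacent pixels are 1 apart; "touching" masks therefore have d <= 1
        if d <= gap_px + 1.0:
            g.add_edge(ia.id, ib.id)
    return g


def call_nests(
    graph: nx.Graph,
    instances: list[NucleusInstance],
    config: NestConfig | None = None,
) -> list[NestCall]:
    """Connected components of size >= min_cluster_size become nests."""
    config = config or NestConfig()
    by_id = {i.id: i for i in instances}
    calls: list[NestCall] = []
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    nid = 0
    for comp in comps:
        if len(comp) < config.min_cluster_size:
            continue
        nid += 1
        members = sorted(comp)
        pts = np.array([by_id[m].centroid for m in members])
        arcs = [by_id[m].arc_mm for m in members if np.isfinite(by_id[m].arc_mm)]
        calls.append(
            NestCall(
                nest_id=nid,
                member_ids=members,
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                arc_start_mm=float(min(arcs)) if arcs else float("nan"),
                arc_end_mm=float(max(arcs)) if arcs else float("nan"),
            )
        )
        for m in members:
            by_id[m].nest_id = nid
    return calls


def slide_nest_flag(nests: list[NestCall]) -> bool:
    """True iff at least one nest was called on the slide."""
    return len(nests) > 0


def combined_call(md_call: str, nest_flag: bool) -> bool:
    """Slide positivity from density OR nest presence (the combined rule)."""
    return md_call == "positive" or bool(nest_flag)


def find_nests(
    instances: list[NucleusInstance],
    labels: np.ndarray,
    config: NestConfig | None = None,
    microns_per_pixel: float = 1.0,
) -> list[NestCall]:
    """Convenience: build the confluence graph and call nests in one step."""
    config = config or NestConfig()
    scoped = [i for i in instances if i.junctional] if config.scope == "junctional_only" else instances
    g = build_confluence_graph(scoped, labels, config, microns_per_pixel)
    return call_nests(g, scoped, config)
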