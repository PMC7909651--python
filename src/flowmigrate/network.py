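"""Vessel-network data model and the two idealised geometries.

The networks are collections of directed line segments (directed along the
*initial* flow direction) meeting at nodes.  Two builders are provided:

* :func:`build_a_branch` -- a feeding vessel that splits into a short
  proximal branch and a longer distal branch which reconverge into a
  draining vessel (one flow-divergent and one flow-convergent bifurcation).
* :func:`build_y_branch` -- two inlet branches converging into a single
  draining stem (one flow-convergent bifurcation, no divergent one).

Mesh convention: each vessel is discretised independently and junction
endpoints are welded together.  At the flow-convergent junction of the
A-branch the two branch segments keep their own endpoint nodes -- the two
segments monitored for bifurcation loss -- identified hydraulically with the
draining vessel's first node (equal pressure, merged flow balance).  The
node-id count is therefore ``n_seg + 1`` (41 for the default A-branch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .params import GeometrySpec, ModelParams

#: branch labels used by the builders
A_BRANCH_LABELS = ("feeding", "proximal", "distal", "draining")
Y_BRANCH_LABELS = ("left", "right", "stem")


@dataclass
class Segment:
    """One vessel segment (a record view onto the network arrays)."""

    id: int
    upstream_node: int
    downstream_node: int
    n: int
    branch_label: str
    theta: float | None = None  # branch angle at a bifurcation (rad)


@dataclass
class VesselNetwork:
    """Directed segment network with per-segment cell counts.

    Internally the state lives in numpy arrays (``n``, ``seg_up``,
    ``seg_down``) for speed; :attr:`segments` materialises ``Segment``
    records on demand.
    """

    params: ModelParams
    seg_up: np.ndarray  # raw upstream node id per segment
    seg_down: np.ndarray  # raw downstream node id per segment
    n: np.ndarray  # current integer cell count per segment
    labels: list[str]
    node_ids: np.ndarray
    inlet_nodes: list[int]  # canonical ids
    outlet_node: int
    divergent_node: int | None
    convergent_node: int
    convergent_branch_segments: tuple[int, int]  # (branch 1, branch 2)
    theta: dict[int, float]
    branch_order: dict[str, list[int]]
    node_alias: dict[int, int] = field(default_factory=dict)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    default_inlet_flows: dict[int, float] | None = None  # y_branch, ratio != 1

    # -- derived topology (built once) -------------------------------------
    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.seg_up = np.asarray(self.seg_up, dtype=np.int64)
        self.seg_down = np.asarray(self.seg_down, dtype=np.int64)
        if np.any(self.seg_up == self.seg_down):
            raise ValueError("segment endpoints must differ")
        if np.any(self.n < 0):
            raise ValueError("cell counts must be non-negative")
        n_node = len(self.node_ids)
        canon = np.arange(n_node, dtype=np.int64)
        for alias, target in self.node_alias.items():
            canon[alias] = target
        self._canon = canon
        self._up_c = canon[self.seg_up]
        self._down_c = canon[self.seg_down]
        node_segments: dict[int, list[int]] = {}
        for s in range(self.n_seg):
            node_segments.setdefault(int(self._up_c[s]), []).append(s)
            node_segments.setdefault(int(self._down_c[s]), []).append(s)
        self._node_segments = node_segments
        bif = set()
        for v, segs in node_segments.items():
            if len(segs) == 3:
                bif.add(v)
        boundary = set(self.inlet_nodes) | {self.outlet_node}
        self._bifurcation_nodes = bif
        interior = [v for v in node_segments if v not in boundary]
        self._interior_nodes = interior
        for v in interior:
            if len(node_segments[v]) < 2:
                raise ValueError(f"interior node {v} touches < 2 segments")
        # segments incident to a bifurcation node (intercalation exemption)
        self._bifurcation_segments = frozenset(
            s for v in bif for s in node_segments[v]
        )

    # -- basic properties ---------------------------------------------------
    @property
    def n_seg(self) -> int:
        return len(self.seg_up)

    @property
    def n_node(self) -> int:
        return len(self.node_ids)

    @property
    def total_cells(self) -> int:
        return int(self.n.sum())

    @property
    def segments(self) -> list[Segment]:
        return [
            Segment(
                id=s,
                upstream_node=int(self.seg_up[s]),
                downstream_node=int(self.seg_down[s]),
                n=int(self.n[s]),
                branch_label=self.labels[s],
                theta=self.theta.get(s),
            )
            for s in range(self.n_seg)
        ]

    def canonical(self, node: int | np.ndarray) -> int | np.ndarray:
        """Resolve a node id through the junction identification."""
        return self._canon[node]

    @property
    def up_canonical(self) -> np.ndarray:
        return self._up_c

    @property
    def down_canonical(self) -> np.ndarray:
        return self._down_c

    @property
    def interior_nodes(self) -> list[int]:
        return list(self._interior_nodes)

    @property
    def bifurcation_nodes(self) -> set[int]:
        return set(self._bifurcation_nodes)

    @property
    def bifurcation_segments(self) -> frozenset[int]:
        """Segments incident to a bifurcation node."""
        return self._bifurcation_segments

    def node_segments(self, node: int) -> list[int]:
        return list(self._node_segments.get(int(self._canon[node]), []))

    @property
    def reentry_segment(self) -> int:
        """Segment adjacent to the outlet node (cells re-enter here)."""
        segs = self._node_segments[self.outlet_node]
        assert len(segs) == 1
        return segs[0]

    def copy(self) -> "VesselNetwork":
        """Independent copy sharing topology but not cell state."""
        out = VesselNetwork(
            params=self.params,
            seg_up=self.seg_up,
            seg_down=self.seg_down,
            n=self.n.copy(),
            labels=self.labels,
            node_ids=self.node_ids,
            inlet_nodes=list(self.inlet_nodes),
            outlet_node=self.outlet_node,
            divergent_node=self.divergent_node,
            convergent_node=self.convergent_node,
            convergent_branch_segments=self.convergent_branch_segments,
            theta=dict(self.theta),
            branch_order={k: list(v) for k, v in self.branch_order.items()},
            node_alias=dict(self.node_alias),
            geometry=self.geometry,
            default_inlet_flows=(
                dict(self.default_inlet_flows)
                if self.default_inlet_flows is not None
                else None
            ),
        )
        return out

    def reset_cells(self) -> None:
        self.n[:] = self.params.n0

    # -- export -------------------------------------------------------------
    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": np.arange(self.n_seg),
                "upstream_node": self.seg_up,
                "downstream_node": self.seg_down,
                "branch_label": self.labels,
                "length_m": np.full(self.n_seg, self.params.l_seg),
                "n_cells": self.n,
            }
        )

    def to_edge_csv(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, index=False)


def branch_segments(network: VesselNetwork, label: str) -> list[int]:
    """Segment ids of one branch, ordered upstream to downstream (t=0 flow)."""
    try:
        return list(network.branch_order[label])
    except KeyError:
        raise KeyError(
            f"branch label {label!r} not in network "
            f"(has {sorted(network.branch_order)})"
        ) from None


def build_a_branch(
    params: ModelParams, distal_multiplier: int = 2
) -> VesselNetwork:
    """Build the A-branch network: feeding -> (proximal | distal) -> draining.

    The distal branch is ``distal_multiplier`` times the proximal length; the
    proximal branch is twice the feeding/draining length.  For the default
    ``n_seg = 40`` and multiplier 2 the allocation is 5/10/20/5 segments.
    For other multipliers the feeding, draining and proximal counts are held
    fixed and the distal count becomes ``proximal * multiplier``.

    At the flow-convergent junction the proximal branch makes a -pi/2 angle
    with the draining vessel and the distal branch 0 (straight through).
    """
    if distal_multiplier < 2:
        raise ValueError("distal_multiplier must be >= 2")
    base, rem = divmod(params.n_seg, 8)
    if rem != 0 or base < 1:
        raise ValueError(
            "n_seg must be a positive multiple of 8 to realise the "
            "1:2:4:1 feeding:proximal:distal:draining segment ratios"
        )
    n_feed = n_drain = base
    n_prox = 2 * base
    n_dist = n_prox * distal_multiplier
    n_seg = n_feed + n_prox + n_dist + n_drain
    params = params.replace(n_seg=n_seg, n_node=n_seg + 1)

    seg_up: list[int] = []
    seg_down: list[int] = []
    labels: list[str] = []
    branch_order: dict[str, list[int]] = {lab: [] for lab in A_BRANCH_LABELS}

    def add_chain(label: str, nodes: list[int]) -> None:
        for a, b in zip(nodes[:-1], nodes[1:]):
            branch_order[label].append(len(seg_up))
            seg_up.append(a)
            seg_down.append(b)
            labels.append(label)

    inlet = 0
    divergent = n_feed
    add_chain("feeding", list(range(0, n_feed + 1)))
    # proximal: divergent -> interior -> convergent
    conv = n_feed + n_prox
    add_chain("proximal", [divergent] + list(range(n_feed + 1, conv + 1)))
    # distal: divergent -> interior -> convergent alias
    d0 = conv + 1
    conv_alias = d0 + n_dist - 1
    add_chain("distal", [divergent] + list(range(d0, conv_alias + 1)))
    # draining: convergent -> interior -> outlet
    outlet = conv_alias + n_drain
    add_chain("draining", [conv] + list(range(conv_alias + 1, outlet + 1)))

    prox_last = branch_order["proximal"][-1]
    dist_last = branch_order["distal"][-1]
    net = VesselNetwork(
        params=params,
        seg_up=np.array(seg_up),
        seg_down=np.array(seg_down),
        n=np.full(n_seg, params.n0, dtype=np.int64),
        labels=labels,
        node_ids=np.arange(n_seg + 1),
        inlet_nodes=[inlet],
        outlet_node=outlet,
        divergent_node=divergent,
        convergent_node=conv,
        convergent_branch_segments=(prox_last, dist_last),
        theta={prox_last: -math.pi / 2.0, dist_last: 0.0},
        branch_order=branch_order,
        node_alias={conv_alias: conv},
        geometry=GeometrySpec(type="a_branch", distal_multiplier=distal_multiplier),
    )
    return net


def build_y_branch(
    params: ModelParams,
    inlet_flow_ratio: float = 1.0,
    branch_segments: int = 10,
    stem_segments: int = 10,
) -> VesselNetwork:
    """Build the Y-branch network: two inlet branches merging into a stem.

    With ``inlet_flow_ratio == 1`` the default boundary condition is equal
    inlet pressures (initial wall shear stress equal in both branches).  For
    any other ratio the builder records prescribed inlet flows whose total
    matches the equal-pressure initial inflow and whose left:right split is
    the requested ratio.
    """
    if inlet_flow_ratio <= 0:
        raise ValueError("inlet_flow_ratio must be > 0")
    if branch_segments < 1 or stem_segments < 1:
        raise ValueError("branch/stem segment counts must be >= 1")
    n_b, n_s = branch_segments, stem_segments
    n_seg = 2 * n_b + n_s
    params = params.replace(n_seg=n_seg, n_node=n_seg + 1)

    seg_up: list[int] = []
    seg_down: list[int] = []
    labels: list[str] = []
    branch_order: dict[str, list[int]] = {lab: [] for lab in Y_BRANCH_LABELS}

    def add_chain(label: str, nodes: list[int]) -> None:
        for a, b in zip(nodes[:-1], nodes[1:]):
            branch_order[label].append(len(seg_up))
            seg_up.append(a)
            seg_down.append(b)
            labels.append(label)

    inlet_l = 0
    conv = n_b
    add_chain("left", list(range(0, n_b + 1)))
    inlet_r = n_b + 1
    add_chain("right", list(range(inlet_r, inlet_r + n_b)) + [conv])
    s0 = inlet_r + n_b
    outlet = s0 + n_s - 1
    add_chain("stem", [conv] + list(range(s0, outlet + 1)))

    left_last = branch_order["left"][-1]
    right_last = branch_order["right"][-1]
    net = VesselNetwork(
        params=params,
        seg_up=np.array(seg_up),
        seg_down=np.array(seg_down),
        n=np.full(n_seg, params.n0, dtype=np.int64),
        labels=labels,
        node_ids=np.arange(n_seg + 1),
        inlet_nodes=[inlet_l, inlet_r],
        outlet_node=outlet,
        divergent_node=None,
        convergent_node=conv,
        convergent_branch_segments=(left_last, right_last),
        theta={left_last: -math.pi / 4.0, right_last: math.pi / 4.0},
        branch_order=branch_order,
        geometry=GeometrySpec(
            type="y_branch",
            inlet_flow_ratio=inlet_flow_ratio,
            branch_segments=n_b,
            stem_segments=n_s,
        ),
    )
    if inlet_flow_ratio != 1.0:
        # Split the equal-pressure initial inflow by the requested ratio.
        from .flow import PressureBC, solve_flow

        state = solve_flow(net, PressureBC(params.p_in, params.p_out))
        q_total = sum(
            abs(state.q[net.node_segments(v)[0]]) for v in net.inlet_nodes
        )
        r = inlet_flow_ratio
        net.default_inlet_flows = {
            inlet_l: q_total * r / (1.0 + r),
            inlet_r: q_total * 1.0 / (1.0 + r),
        }
    return net


def build_network(params: ModelParams, geometry: GeometrySpec) -> VesselNetwork:
    """Dispatch on a :class:`GeometrySpec`."""
    if geometry.type == "a_branch":
        return build_a_branch(params, geometry.distal_multiplier)
    return build_y_branch(
        params,
        inlet_flow_ratio=geometry.inlet_flow_ratio,
        branch_segments=geometry.branch_segments,
        stem_segments=geometry.stem_segments,
    )
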