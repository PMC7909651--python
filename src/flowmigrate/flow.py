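"""Hagen-Poiseuille network flow solver.

Each vessel segment is a cylindrical resistor whose lumen diameter follows
from wrapping its ``n`` cells (lateral width ``w``) into a circle,
``d = n w / pi``.  Conductance then scales as ``n^4 w^4 / (128 pi^3 mu l)``;
a segment with no cells keeps an infinitesimal floor conductance
(1e-25 m^3/s/Pa) so the nodal system stays invertible.  Nodal pressures are
obtained from flow-balance (Kirchhoff) equations with either pressure or
prescribed-inlet-flow boundary conditions, and per-segment flow, pressure
drop and wall shear stress follow.

Sign convention: ``dp = p_downstream - p_upstream`` so that ``q = -G dp`` is
positive along the segment orientation under forward flow.  Wall shear
stress is stored as a magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .network import VesselNetwork

#: conductance assigned to a zero-lumen segment (m^3/s/Pa)
ZERO_LUMEN_CONDUCTANCE = 1e-25



# ---------------------------------------------------------------------------
# per-segment constitutive relations
# ---------------------------------------------------------------------------
def lumen_diameter(n, w):
    """Lumen diameter (m) of a segment holding ``n`` cells of width ``w``."""
    return np.multiply(n, w) / np.pi


def segment_conductance(n, w, mu, l_seg):
    """Segment flow conductance (m^3/s/Pa), with the zero-lumen floor."""
    n = np.asarray(n, dtype=float)
    g = n**4 * w**4 / (128.0 * np.pi**3 * mu * l_seg)
    return np.where(n >= 1, g, ZERO_LUMEN_CONDUCTANCE)


def resistance(n, w, mu, l_seg):
    """Segment flow resistance (Pa s/m^3); infinite lumen-free case signalled.

    Raises
    ------
    ZeroDivisionError
        If ``n == 0``; callers must use the conductance floor instead.
    """
    if np.any(np.asarray(n) < 1):
        raise ZeroDivisionError(
            "resistance is infinite for an empty segment; "
            "use segment_conductance (zero-lumen floor) instead"
        )
    n = np.asarray(n, dtype=float)
    return 128.0 * np.pi**3 * mu * l_seg / (n**4 * w**4)


def segment_wss(n, w, l_seg, dp):
    """Wall shear stress magnitude (Pa) from cell count and pressure drop."""
    return np.abs(np.multiply(n, w) * dp / (4.0 * np.pi * l_seg))


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PressureBC:
    """Dirichlet pressures at every inlet and at the outlet (Pa)."""

    p_in: float
    p_out: float


@dataclass(frozen=True)
class InletFlowBC:
    """Prescribed inlet flow(s) (m^3/s) with a Dirichlet outlet pressure.

    ``q_in`` is either a single float (one-inlet networks) or a mapping of
    inlet node id to prescribed inflow.
    """

    q_in: float | Mapping[int, float]
    p_out: float


# ---------------------------------------------------------------------------
# flow state
# ---------------------------------------------------------------------------
@dataclass
class FlowState:
    """Pressures, flows, pressure drops and wall shear for one instant."""

    p: np.ndarray  # per raw node id (Pa)
    q: np.ndarray  # per segment (m^3/s), sign along segment orientation
    dp: np.ndarray  # per segment, p_down - p_up (Pa)
    tau: np.ndarray  # per segment, magnitude (Pa)
    G: np.ndarray  # per segment (m^3/s/Pa)

    def max_relative_imbalance(self, network: "VesselNetwork") -> float:
        """Largest interior-node net flow relative to the largest |q|."""
        n_node = network.n_node
        net_flow = np.zeros(n_node)
        np.add.at(net_flow, network.up_canonical, -self.q)
        np.add.at(net_flow, network.down_canonical, self.q)
        interior = np.array(network.interior_nodes, dtype=int)
        scale = np.abs(self.q).max()
        if scale == 0.0:
            return float(np.abs(net_flow[interior]).max())
        return float(np.abs(net_flow[interior]).max() / scale)


def solve_flow(
    network: "VesselNetwork",
    bc: PressureBC | InletFlowBC | None = None,
) -> FlowState:
    """Solve the nodal flow-balance system for the current cell counts.

    Dirichlet pressures are imposed by row substitution; a prescribed inlet
    flow replaces that inlet's balance row with a source term.  The system
    is small (tens of nodes) and solved densely.
    """
    p = network.params
    if bc is None:
        if network.default_inlet_flows is not None:
            bc = InletFlowBC(q_in=network.default_inlet_flows, p_out=p.p_out)
        else:
            bc = PressureBC(p_in=p.p_in, p_out=p.p_out)

    G = segment_conductance(network.n, p.w, p.mu, p.l_seg)

    # degenerate no-driving-force cases have the exact constant solution;
    # return it directly so flow and shear are exactly zero
    if isinstance(bc, PressureBC) and bc.p_in == bc.p_out:
        n_seg = network.n_seg
        return FlowState(
            p=np.full(network.n_node, float(bc.p_in)),
            q=np.zeros(n_seg),
            dp=np.zeros(n_seg),
            tau=np.zeros(n_seg),
            G=G,
        )

    up = network.up_canonical
    down = network.down_canonical

    n_node = network.n_node
    used = np.zeros(n_node, dtype=bool)
    used[up] = True
    used[down] = True
    idx_of = -np.ones(n_node, dtype=int)
    idx_of[used] = np.arange(used.sum())
    N = int(used.sum())

    A = np.zeros((N, N))
    b = np.zeros(N)
    iu, idn = idx_of[up], idx_of[down]
    np.add.at(A, (iu, iu), G)
    np.add.at(A, (idn, idn), G)
    np.add.at(A, (iu, idn), -G)
    np.add.at(A, (idn, iu), -G)

    # boundary rows
    dirichlet: dict[int, float] = {}
    if isinstance(bc, PressureBC):
        for v in network.inlet_nodes:
            dirichlet[v] = bc.p_in
        dirichlet[network.outlet_node] = bc.p_out
    elif isinstance(bc, InletFlowBC):
        q_in = bc.q_in
        if not isinstance(q_in, Mapping):
            if len(network.inlet_nodes) != 1:
                raise ValueError(
                    "scalar q_in is ambiguous for a multi-inlet network; "
                    "pass a mapping of inlet node to flow"
                )
            q_in = {network.inlet_nodes[0]: float(q_in)}
        for v in network.inlet_nodes:
            if v not in q_in:
                raise ValueError(f"no prescribed flow for inlet node {v}")
            b[idx_of[v]] = q_in[v]
        dirichlet[network.outlet_node] = bc.p_out
    else:
        raise TypeError(f"unsupported boundary condition {bc!r}")
    for v, value in dirichlet.items():
        i = idx_of[v]
        A[i, :] = 0.0
        A[i, i] = 1.0
        b[i] = value

    p_solved = np.linalg.solve(A, b)
    if not np.all(np.isfinite(p_solved)):  # pragma: no cover
        raise ArithmeticError("flow solve produced non-finite pressures")

    pressures = np.zeros(n_node)
    pressures[used] = p_solved
    # fill aliased nodes with their canonical pressure
    for alias, target in network.node_alias.items():
        pressures[alias] = pressures[target]

    dp = pressures[network.canonical(network.seg_down)] - pressures[
        network.canonical(network.seg_up)
    ]
    q = -G * dp
    tau = segment_wss(network.n, p.w, p.l_seg, dp)
    return FlowState(p=pressures, q=q, dp=dp, tau=tau, G=G)
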