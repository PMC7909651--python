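"""One synchronous migration step: every cell moves one segment against flow.

All destinations are computed from the pre-step state and applied at once.
A cell's destination is the neighbouring segment on the side its segment's
flow comes from; at the flow-convergent junction two such segments exist
and each deciding cell applies the selected bifurcation rule.  At the
flow-divergent junction the paths merge (a single upstream choice).

Cells exiting at an inlet are routed by the cell boundary condition:
*periodic* re-injects them at the outlet the same step (total cell count is
conserved exactly), *dirichlet* admits at most ``n_fixed`` cells per step at
the outlet and discards the surplus.

Intercalation smoothing: a segment whose planned efflux exceeds its planned
(positive) influx retains one cell that step.  Segments incident to a
bifurcation node are exempt so the smoothing does not interfere with the
decision dynamics at junctions.  Retention acts on exchangeable integer
counts and therefore consumes no random draws; the only stochastic draws in
a step are the per-cell branch choices of BR3-BR5, taken in segment order
from the simulation's single RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import FlowState
from .network import VesselNetwork
from .rules import (
    BranchProbabilities,
    RuleSpec,
    br1_choice,
    br2_choice,
    branch_probabilities,
)

#: flows with magnitude below this (m^3/s) are treated as stagnant
FLOW_ZERO_TOL = 1e-30

#: destination sentinels
HOLD = -2
EXIT = -1


@dataclass(frozen=True)
class CellBC:
    """Cell boundary condition at the network inlet/outlet."""

    kind: str = "periodic"  # "periodic" | "dirichlet"
    n_fixed: int | None = None  # dirichlet: cells admitted per step

    def __post_init__(self) -> None:
        if self.kind not in ("periodic", "dirichlet"):
            raise ValueError(f"unknown cell BC kind {self.kind!r}")
        if self.n_fixed is not None and self.n_fixed < 0:
            raise ValueError("n_fixed must be >= 0")


@dataclass
class StepRecord:
    """What happened during one migration step."""

    probs: BranchProbabilities | None  # BR5 only
    k1: int  # deciding cells sent to branch 1
    k2: int  # deciding cells sent to branch 2
    retained: int  # cells held back by intercalation
    exited: int  # cells that left through the inlet(s)
    entered: int  # cells injected at the outlet


def migration_directions(
    network: VesselNetwork, flow: FlowState
) -> dict[int, list[int]]:
    """Map each moving segment to its candidate destination segment(s).

    A segment with |q| below :data:`FLOW_ZERO_TOL` holds its cells and is
    absent from the map.  A segment whose cells exit through an inlet maps
    to the empty list.
    """
    out: dict[int, list[int]] = {}
    q = flow.q
    up, down = network.up_canonical, network.down_canonical
    for s in range(network.n_seg):
        if abs(q[s]) <= FLOW_ZERO_TOL:
            continue
        exit_node = int(up[s]) if q[s] > 0 else int(down[s])
        sources = [
            t
            for t in network.node_segments(exit_node)
            if t != s and _flows_into(q, up, down, t, exit_node)
        ]
        if sources:
            out[s] = sources
        elif exit_node in network.inlet_nodes:
            out[s] = []
        # else: stagnant upstream side, cells hold -> omit
    return out


def _flows_into(q, up, down, t: int, v: int) -> bool:
    if q[t] > FLOW_ZERO_TOL:
        return int(down[t]) == v
    if q[t] < -FLOW_ZERO_TOL:
        return int(up[t]) == v
    return False


def intercalation_retention(outgoing: int, incoming: int) -> int:
    """Retention rule: 1 iff planned efflux exceeds positive planned influx."""
    return 1 if outgoing > incoming > 0 else 0


def step_migrate(
    network: VesselNetwork,
    flow: FlowState,
    rule: RuleSpec,
    bc: CellBC,
    rng: np.random.Generator | None,
) -> StepRecord:
    """Advance all cells one segment against flow (in place).

    Returns a :class:`StepRecord`; raises if a stochastic rule is selected
    without an RNG.  Under the periodic cell BC the total cell count is
    exactly conserved.
    """
    if rule.is_stochastic and rng is None:
        raise ValueError(f"rule {rule.rule_id} is stochastic and needs an rng")

    n = network.n
    S = network.n_seg
    dirs = migration_directions(network, flow)

    dest = np.full(S, HOLD, dtype=np.int64)
    decision_seg: int | None = None
    for s, sources in dirs.items():
        if not sources:
            dest[s] = EXIT
        elif len(sources) == 1:
            dest[s] = sources[0]
        else:
            if decision_seg is not None:  # pragma: no cover
                raise AssertionError("more than one decision segment in a step")
            decision_seg = s

    # --- branch decision at the flow-convergent junction -------------------
    b1, b2 = network.convergent_branch_segments
    probs: BranchProbabilities | None = None
    k1 = k2 = 0
    if decision_seg is not None:
        if set(dirs[decision_seg]) != {b1, b2}:  # pragma: no cover
            raise AssertionError(
                "decision candidates are not the registered convergent "
                "branch segments"
            )
        n_dec = int(n[decision_seg])
        if rule.rule_id == "BR1":
            choice = br1_choice(float(flow.tau[b1]), float(flow.tau[b2]))
            k1 = n_dec if choice == 1 else 0
        elif rule.rule_id == "BR2":
            choice = br2_choice(network.theta[b1], network.theta[b2])
            k1 = n_dec if choice == 1 else 0
        else:
            if rule.rule_id == "BR5":
                probs = branch_probabilities(
                    float(flow.tau[b1]),
                    float(flow.tau[b2]),
                    int(n[b1]),
                    int(n[b2]),
                    rule.alpha,
                )
                p1 = probs.P1
            else:
                p1 = rule.fixed_p1
            if n_dec > 0:
                k1 = int((rng.random(n_dec) < p1).sum())
        k2 = n_dec - k1

    # --- synchronous plan ---------------------------------------------------
    moving = dest != HOLD
    if decision_seg is not None:
        moving[decision_seg] = True
    planned_out = np.where(moving, n, 0)

    planned_in = np.zeros(S, dtype=np.int64)
    normal = moving.copy()
    if decision_seg is not None:
        normal[decision_seg] = False
    normal &= dest >= 0
    np.add.at(planned_in, dest[normal], planned_out[normal])
    if decision_seg is not None:
        planned_in[b1] += k1
        planned_in[b2] += k2
    exiting_planned = int(planned_out[dest == EXIT].sum())
    reentry = network.reentry_segment
    if bc.kind == "periodic":
        planned_in[reentry] += exiting_planned
    else:
        n_fixed = network.params.n0 if bc.n_fixed is None else bc.n_fixed
        planned_in[reentry] += min(exiting_planned, n_fixed)

    # --- intercalation (bifurcation-incident segments exempt) ---------------
    retained = np.zeros(S, dtype=np.int64)
    eligible = moving.copy()
    for s in network.bifurcation_segments:
        eligible[s] = False
    idx = np.nonzero(eligible)[0]
    retained[idx] = (planned_out[idx] > planned_in[idx]) & (planned_in[idx] > 0)

    moved = planned_out - retained

    # --- apply ---------------------------------------------------------------
    actual_in = np.zeros(S, dtype=np.int64)
    np.add.at(actual_in, dest[normal], moved[normal])
    if decision_seg is not None:
        actual_in[b1] += k1
        actual_in[b2] += k2
    exited = int(moved[dest == EXIT].sum())
    if bc.kind == "periodic":
        entered = exited
    else:
        n_fixed = network.params.n0 if bc.n_fixed is None else bc.n_fixed
        entered = min(exited, n_fixed)
    actual_in[reentry] += entered

    total_before = int(n.sum())
    n -= moved
    n += actual_in
    if np.any(n < 0):  # pragma: no cover
        raise AssertionError("negative cell count after migration step")
    if bc.kind == "periodic" and int(n.sum()) != total_before:  # pragma: no cover
        raise AssertionError("cell count not conserved under periodic BC")

    return StepRecord(
        probs=probs,
        k1=k1,
        k2=k2,
        retained=int(retained.sum()),
        exited=exited,
        entered=entered,
    )
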