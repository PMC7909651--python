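"""Couple flow and migration over time; record trajectories; detect loss.

A run alternates a flow solve with a synchronous migration step for
``floor(duration_days * 24 / dt)`` steps (43 steps for the default 6 days).
Step 0 of the trajectory is the pre-migration initial state.  The run
continues after a bifurcation loss (the conductance floor carries the dead
branch).

Two loss criteria are available.  The *segment* criterion fires on the
first step at which either branch segment incident to the flow-convergent
node holds zero cells -- the onset of regression, which under the
mechanistic rule is absorbing (an empty entry segment has zero shear and
zero cell number, hence zero entry probability).  The *branch* criterion
(default, used for ensemble statistics) fires once every segment of a
branch is empty, i.e. when the regression has run to completion; the two
describe the same absorbing event separated by the time the emptying wave
takes to traverse the branch.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .flow import FlowState, InletFlowBC, PressureBC, solve_flow
from .migration import CellBC, step_migrate
from .network import VesselNetwork
from .rules import RuleSpec, branch_probabilities

#: documented meta-seed from which ensemble seed lists are derived
DEFAULT_META_SEED = 19700101

#: relative tolerance for the per-step nodal flow-balance check
IMBALANCE_RTOL = 1e-10

_PROB_COLS = ("P1", "P2", "P_tau1", "P_tau2", "P_n1", "P_n2")


@dataclass
class LossEvent:
    """Bifurcation-loss record for one run."""

    occurred: bool = False
    loss_step: int | None = None
    loss_time_hr: float | None = None
    lost_branch: str | None = None  # branch-1 label, branch-2 label or "both"
    day_bin: int | None = None

    @staticmethod
    def day_of(time_hr: float) -> int:
        """Day bin of a loss time: (d-1)*24 < t <= d*24."""
        return max(1, math.ceil(time_hr / 24.0))


def detect_bifurcation_loss(network: VesselNetwork) -> str | None:
    """Segment-level loss check on the two convergent branch segments.

    Returns the label of the branch whose segment at the flow-convergent
    node is empty, ``"both"`` if both are, or None.
    """
    b1, b2 = network.convergent_branch_segments
    z1, z2 = network.n[b1] == 0, network.n[b2] == 0
    if z1 and z2:
        return "both"
    if z1:
        return network.labels[b1]
    if z2:
        return network.labels[b2]
    return None


@dataclass
class Trajectory:
    """Per-step record of one simulation run."""

    times: np.ndarray  # (S+1,) hours
    n: np.ndarray  # (S+1, n_seg) cells
    q: np.ndarray  # (S+1, n_seg) m^3/s
    dp: np.ndarray  # (S+1, n_seg) Pa, p_down - p_up
    tau: np.ndarray  # (S+1, n_seg) Pa, magnitude
    probs: np.ndarray  # (S+1, 6) BR5 components, NaN otherwise
    choices: np.ndarray  # (S, 2) per-step (k1, k2) branch assignments
    total_cells: np.ndarray  # (S+1,)
    network: VesselNetwork  # final state; topology for labels
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-segment per-step table."""
        S1, nseg = self.n.shape
        return pd.DataFrame(
            {
                "time_hr": np.repeat(self.times, nseg),
                "segment_id": np.tile(np.arange(nseg), S1),
                "n": self.n.ravel(),
                "q_m3s": self.q.ravel(),
                "dp_Pa": self.dp.ravel(),
                "tau_Pa": self.tau.ravel(),
            }
        )

    def probability_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(_PROB_COLS))
        df.insert(0, "time_hr", self.times)
        return df

    def write(self, directory: str | Path, stem: str = "trajectory") -> None:
        """Write the trajectory CSV and a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / f"{stem}.csv", index=False)
        (directory / f"{stem}.json").write_text(
            json.dumps(self.meta, indent=2, default=str) + "\n"
        )


def run_simulation(
    network: VesselNetwork,
    rule: RuleSpec,
    seed: int | None = None,
    cell_bc: CellBC | None = None,
    flow_bc: PressureBC | InletFlowBC | None = None,
    duration_days: float | None = None,
    check_invariants: bool = True,
    record: bool = True,
    loss_criterion: str = "branch",
) -> tuple[Trajectory | None, LossEvent]:
    """Run one simulation on a copy of ``network``.

    Parameters
    ----------
    network
        Initial network; not mutated (a copy is advanced).
    rule
        Bifurcation rule; stochastic rules require ``seed``.
    seed
        Seed for the single per-run RNG stream (numpy ``default_rng``).
    cell_bc
        Cell boundary condition; defaults to periodic.
    flow_bc
        Flow boundary condition; defaults to the network's own (pressure
        BCs, or the recorded inlet flows of a flow-ratio Y-branch).
    duration_days
        Simulated days; defaults to ``network.params.duration_days``.
    check_invariants
        Assert nodal flow balance and probability normalisation each step.
    record
        Keep the full trajectory (disable in large ensembles).
    loss_criterion
        ``"branch"`` (default): loss when a whole branch is empty;
        ``"segment"``: loss at the first empty convergent branch segment.

    Returns
    -------
    (trajectory, loss_event)
        ``trajectory`` is None when ``record`` is False.
    """
    if rule.is_stochastic and seed is None:
        raise ValueError(f"rule {rule.rule_id} requires a seed")
    if loss_criterion not in ("branch", "segment"):
        raise ValueError("loss_criterion must be 'branch' or 'segment'")
    net = network.copy()
    params = net.params
    cell_bc = cell_bc or CellBC("periodic")
    steps = params.n_steps(duration_days)
    rng = np.random.default_rng(seed) if seed is not None else None
    b1, b2 = net.convergent_branch_segments
    label1, label2 = net.labels[b1], net.labels[b2]
    branch1_segs = np.array(net.branch_order[label1])
    branch2_segs = np.array(net.branch_order[label2])

    def _loss_zeros() -> tuple[bool, bool]:
        if loss_criterion == "segment":
            return bool(net.n[b1] == 0), bool(net.n[b2] == 0)
        return (
            bool(net.n[branch1_segs].sum() == 0),
            bool(net.n[branch2_segs].sum() == 0),
        )

    if record:
        nseg = net.n_seg
        times = np.arange(steps + 1) * params.dt
        n_hist = np.empty((steps + 1, nseg), dtype=np.int64)
        q_hist = np.empty((steps + 1, nseg))
        dp_hist = np.empty((steps + 1, nseg))
        tau_hist = np.empty((steps + 1, nseg))
        probs_hist = np.full((steps + 1, 6), np.nan)
        choices = np.zeros((steps, 2), dtype=np.int64)
        totals = np.empty(steps + 1, dtype=np.int64)

    loss = LossEvent()

    def record_state(k: int, flow: FlowState) -> None:
        n_hist[k] = net.n
        q_hist[k] = flow.q
        dp_hist[k] = flow.dp
        tau_hist[k] = flow.tau
        totals[k] = net.n.sum()
        if rule.rule_id == "BR5" and (net.n[b1] + net.n[b2]) > 0:
            p = branch_probabilities(
                float(flow.tau[b1]), float(flow.tau[b2]),
                int(net.n[b1]), int(net.n[b2]), rule.alpha,
            )
            probs_hist[k] = (p.P1, p.P2, p.P_tau1, p.P_tau2, p.P_n1, p.P_n2)

    flow = solve_flow(net, flow_bc)
    if check_invariants:
        _check_step(net, flow)
    if record:
        record_state(0, flow)

    for k in range(1, steps + 1):
        rec = step_migrate(net, flow, rule, cell_bc, rng)
        flow = solve_flow(net, flow_bc)
        if check_invariants:
            _check_step(net, flow)
        if record:
            record_state(k, flow)
            choices[k - 1] = (rec.k1, rec.k2)
        if not loss.occurred:
            z1, z2 = _loss_zeros()
            if z1 or z2:
                loss.occurred = True
                loss.loss_step = k
                loss.loss_time_hr = k * params.dt
                loss.day_bin = LossEvent.day_of(loss.loss_time_hr)
                loss.lost_branch = "both" if (z1 and z2) else (label1 if z1 else label2)

    traj = None
    if record:
        traj = Trajectory(
            times=times,
            n=n_hist,
            q=q_hist,
            dp=dp_hist,
            tau=tau_hist,
            probs=probs_hist,
            choices=choices,
            total_cells=totals,
            network=net,
            meta={
                "rule": asdict(rule),
                "seed": seed,
                "geometry": asdict(net.geometry),
                "cell_bc": asdict(cell_bc),
                "flow_bc": repr(flow_bc) if flow_bc is not None else "network default",
                "duration_days": (
                    params.duration_days if duration_days is None else duration_days
                ),
                "steps": steps,
                "params": params.to_dict(),
                "loss_criterion": loss_criterion,
                "loss": asdict(loss),
            },
        )
    return traj, loss


def _check_step(net: VesselNetwork, flow: FlowState) -> None:
    """Per-step invariants: flow balance and the two shear-probability forms."""
    imbalance = flow.max_relative_imbalance(net)
    if imbalance > IMBALANCE_RTOL:
        raise AssertionError(
            f"nodal flow imbalance {imbalance:.3e} exceeds {IMBALANCE_RTOL:.0e}"
        )
    b1, b2 = net.convergent_branch_segments
    # shear-ratio form vs n*dp form of the shear probability
    t1, t2 = float(flow.tau[b1]), float(flow.tau[b2])
    a1 = float(net.n[b1]) * abs(float(flow.dp[b1]))
    a2 = float(net.n[b2]) * abs(float(flow.dp[b2]))
    if (t1 + t2) > 0 and (a1 + a2) > 0:
        if abs(t1 / (t1 + t2) - a1 / (a1 + a2)) > 1e-12:
            raise AssertionError(
                "shear-ratio and n*dp-ratio probability forms disagree"
            )


def generate_seeds(m: int, meta_seed: int = DEFAULT_META_SEED) -> np.ndarray:
    """A reproducible list of ``m`` seeds, uniform integers in [1, 1e9].

    The same list must be reused across every rule and alpha value of one
    sweep so that ensembles are paired.
    """
    if m < 1:
        raise ValueError("need at least one seed")
    rng = np.random.default_rng(meta_seed)
    return rng.integers(1, 10**9, size=m, endpoint=True)
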