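"""Ensemble sweeps and trajectory summaries.

The central experiment is the alpha sweep: for each weight alpha in a grid,
run the mechanistic rule (BR5) over a shared list of seeds and record if and
when each run loses the flow-convergent bifurcation.  Loss fractions over
time form the stability surface whose interior minimum identifies the rule
weightings that preserve bifurcations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .flow import InletFlowBC, PressureBC, lumen_diameter
from .migration import CellBC
from .network import VesselNetwork, branch_segments
from .rules import RuleSpec
from .simulate import Trajectory, run_simulation


@dataclass
class SweepResult:
    """Per-(alpha, seed) loss outcomes of a BR5 ensemble sweep."""

    table: pd.DataFrame  # alpha, seed, occurred, loss_step, loss_time_hr, lost_branch, day_bin
    duration_days: float
    dt: float
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def alphas(self) -> np.ndarray:
        return np.sort(self.table["alpha"].unique())

    def final_loss_fraction(self, alpha: float) -> float:
        sub = self._at(alpha)
        return float(sub["occurred"].mean())

    def loss_fraction_by_time(self, alpha: float) -> pd.DataFrame:
        """Cumulative fraction of runs lost by each step (monotone)."""
        sub = self._at(alpha)
        m = len(sub)
        steps = int(round(self.duration_days * 24.0 / self.dt + 1e-9))
        counts = np.zeros(steps + 1)
        lost = sub.loc[sub["occurred"], "loss_step"].astype(int)
        for step in lost:
            counts[step:] += 1
        return pd.DataFrame(
            {
                "time_hr": np.arange(steps + 1) * self.dt,
                "fraction_lost": counts / m,
            }
        )

    def loss_fraction_by_day(self, alpha: float, day: float) -> float:
        curve = self.loss_fraction_by_time(alpha)
        sel = curve["time_hr"] <= day * 24.0 + 1e-9
        return float(curve.loc[sel, "fraction_lost"].iloc[-1])

    def attribution(self, alpha: float) -> dict[str, float]:
        """Fraction of lost runs attributed to each branch.

        Computed over lost runs only; simultaneous losses count half-half.
        """
        sub = self._at(alpha)
        lost = sub[sub["occurred"]]
        if len(lost) == 0:
            return {}
        labels = [
            b for b in lost["lost_branch"].unique() if b != "both"
        ]
        out = {}
        n_both = float((lost["lost_branch"] == "both").sum())
        for lab in labels:
            out[lab] = float(
                ((lost["lost_branch"] == lab).sum() + 0.5 * n_both) / len(lost)
            )
        return out

    def day_bin_counts(self, alpha: float) -> pd.Series:
        sub = self._at(alpha)
        return (
            sub.loc[sub["occurred"], "day_bin"]
            .astype(int)
            .value_counts()
            .sort_index()
        )

    def modal_loss_day(self, alpha: float) -> int | None:
        counts = self.day_bin_counts(alpha)
        if counts.empty:
            return None
        return int(counts.idxmax())

    def loss_surface(self) -> pd.DataFrame:
        """Tidy (alpha, time_hr, fraction_lost) table over the whole grid."""
        frames = []
        for a in self.alphas:
            curve = self.loss_fraction_by_time(a)
            curve.insert(0, "alpha", a)
            frames.append(curve)
        return pd.concat(frames, ignore_index=True)

    def write(self, directory: str | Path, stem: str = "sweep") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / f"{stem}_summary.csv", index=False)
        self.loss_surface().to_csv(directory / f"{stem}_surface.csv", index=False)
        (directory / f"{stem}.json").write_text(
            json.dumps(self.meta, indent=2, default=str) + "\n"
        )

    def _at(self, alpha: float) -> pd.DataFrame:
        sub = self.table[np.isclose(self.table["alpha"], alpha)]
        if sub.empty:
            raise KeyError(f"alpha {alpha} not in sweep grid")
        return sub


def alpha_sweep(
    network: VesselNetwork,
    alphas: Sequence[float],
    seeds: Iterable[int],
    cell_bc: CellBC | None = None,
    flow_bc: PressureBC | InletFlowBC | None = None,
    duration_days: float | None = None,
    check_invariants: bool = False,
    progress: bool = False,
    loss_criterion: str = "branch",
) -> SweepResult:
    """Run the BR5 ensemble over an alpha grid with a shared seed list."""
    alphas = list(alphas)
    seeds = [int(s) for s in seeds]
    if not alphas or not seeds:
        raise ValueError("alpha grid and seed list must be non-empty")
    cell_bc = cell_bc or CellBC("periodic")
    rows = []
    for a in alphas:
        rule = RuleSpec("BR5", alpha=a)
        for seed in seeds:
            _, loss = run_simulation(
                network,
                rule,
                seed=seed,
                cell_bc=cell_bc,
                flow_bc=flow_bc,
                duration_days=duration_days,
                check_invariants=check_invariants,
                record=False,
                loss_criterion=loss_criterion,
            )
            rows.append(
                {
                    "alpha": a,
                    "seed": seed,
                    "occurred": loss.occurred,
                    "loss_step": loss.loss_step,
                    "loss_time_hr": loss.loss_time_hr,
                    "lost_branch": loss.lost_branch,
                    "day_bin": loss.day_bin,
                }
            )
        if progress:  # pragma: no cover
            frac = sum(r["occurred"] for r in rows if r["alpha"] == a) / len(seeds)
            print(f"alpha={a:.2f}: fraction lost {frac:.3f}")
    params = network.params
    days = params.duration_days if duration_days is None else duration_days
    return SweepResult(
        table=pd.DataFrame(rows),
        duration_days=days,
        dt=params.dt,
        meta={
            "alphas": alphas,
            "n_seeds": len(seeds),
            "duration_days": days,
            "cell_bc": cell_bc.kind,
            "geometry": network.geometry.type,
            "loss_criterion": loss_criterion,
        },
    )


# ---------------------------------------------------------------------------
# single-trajectory summaries
# ---------------------------------------------------------------------------
def _diameter_subset(traj: Trajectory, branch: str) -> list[int]:
    """Equal-size averaging subsets for the two branches.

    The subset size equals the shorter (proximal/left) branch's segment
    count; for the longer branch the segments adjacent to the
    flow-convergent node are used.
    """
    net = traj.network
    order = net.branch_order
    if branch not in order:
        raise KeyError(f"branch {branch!r} not in network")
    pair = (
        ("proximal", "distal") if "proximal" in order else ("left", "right")
    )
    size = min(len(order[pair[0]]), len(order[pair[1]]))
    segs = order[branch]
    if branch in pair and len(segs) > size:
        return segs[-size:]  # adjacent to the convergent node
    return segs


def mean_branch_diameter(traj: Trajectory, branch: str) -> pd.DataFrame:
    """Per-step mean lumen diameter (m) over a fixed branch subset."""
    segs = _diameter_subset(traj, branch)
    w = traj.network.params.w
    d = lumen_diameter(traj.n[:, segs], w).mean(axis=1)
    return pd.DataFrame({"time_hr": traj.times, "mean_diameter_m": d})


def probability_traces(traj: Trajectory) -> pd.DataFrame:
    """Per-step BR5 probability components (errors for other rules)."""
    if traj.meta.get("rule", {}).get("rule_id") != "BR5":
        raise ValueError("probability traces are defined for BR5 runs only")
    return traj.probability_frame()


def pressure_cellnumber_traces(traj: Trajectory, branch: str) -> pd.DataFrame:
    """Per-step cell number and pressure-drop magnitude of a branch's
    segment at the flow-convergent node."""
    net = traj.network
    b1, b2 = net.convergent_branch_segments
    by_label = {net.labels[b1]: b1, net.labels[b2]: b2}
    if branch not in by_label:
        raise KeyError(
            f"branch {branch!r} has no segment at the convergent node"
        )
    s = by_label[branch]
    return pd.DataFrame(
        {
            "time_hr": traj.times,
            "n": traj.n[:, s],
            "dp_Pa": np.abs(traj.dp[:, s]),
        }
    )


def oscillation_period(
    trace: np.ndarray, min_prominence_frac: float = 0.1
) -> float:
    """Dominant period (in steps) of an oscillating trace.

    Peaks are detected with a prominence threshold set relative to the
    trace's overall range, and the mean peak-to-peak spacing is returned.
    """
    trace = np.asarray(trace, dtype=float)
    span = float(trace.max() - trace.min())
    if span == 0.0:
        raise ValueError("trace is constant; no oscillation to measure")
    peaks, _ = signal.find_peaks(trace, prominence=min_prominence_frac * span)
    if len(peaks) < 2:
        raise ValueError("fewer than two peaks found; cannot measure period")
    return float(np.diff(peaks).mean())
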