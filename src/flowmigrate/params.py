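"""Model constants and configuration handling.

The default parameter set describes an idealised microvessel network during
developmental remodelling: 40 segments of 10 um, each initially holding 8
endothelial cells of 5 um lateral width, perfused by a 100 Pa pressure head
across blood of viscosity 3.5 mPa s.  Cells migrate against flow at 3 um/hr,
so one 3h20 time step moves a cell exactly one segment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

#: time step (hr) such that v * dt equals one segment length exactly
DEFAULT_DT_HR = 10.0 / 3.0


@dataclass(frozen=True)
class ModelParams:
    """Physical and numerical constants of the simulation.

    Units are SI (metres, Pascals, Pa s) except time, which is kept in hours
    because migration speed is quoted in um/hr.

    Attributes
    ----------
    n_seg, n_node : int
        Bookkeeping segment/node counts of the default network.  The node
        count follows the ``n_node == n_seg + 1`` mesh convention (each
        branch endpoint at the flow-convergent junction keeps its own node;
        see :mod:`flowmigrate.network`).
    l_seg : float
        Segment length (m); equal to the distance a cell migrates per step.
    n0 : int
        Initial number of cells seeded in every segment.
    v : float
        Cell migration speed (m/hr).
    w : float
        Lateral width of an endothelial cell (m).
    dt : float
        Time step (hr).  Must satisfy ``v * dt == l_seg``.
    p_in, p_out : float
        Inlet/outlet pressure boundary values (Pa).
    mu : float
        Dynamic viscosity of blood (Pa s), treated as Newtonian.
    duration_days : float
        Default simulated duration (days).
    """

    n_seg: int = 40
    n_node: int = 41
    l_seg: float = 1.0e-5
    n0: int = 8
    v: float = 3.0e-6
    w: float = 5.0e-6
    dt: float = DEFAULT_DT_HR
    p_in: float = 100.0
    p_out: float = 0.0
    mu: float = 0.0035
    duration_days: float = 6.0

    def __post_init__(self) -> None:
        for name in ("l_seg", "v", "w", "dt", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n0 < 1:
            raise ValueError("n0 must be at least 1")
        if self.n_seg < 1 or self.n_node != self.n_seg + 1:
            raise ValueError("need n_seg >= 1 and n_node == n_seg + 1")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be strictly positive")
        if abs(self.v * self.dt - self.l_seg) > 1e-9 * self.l_seg:
            raise ValueError(
                "v * dt must equal l_seg (one segment per migration step); "
                f"got {self.v * self.dt:.6g} != {self.l_seg:.6g}"
            )

    @property
    def steps_per_day(self) -> float:
        return 24.0 / self.dt

    def n_steps(self, duration_days: float | None = None) -> int:
        """Number of migration steps in ``duration_days`` (floor)."""
        days = self.duration_days if duration_days is None else duration_days
        return int(days * 24.0 / self.dt + 1e-9)

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass(frozen=True)
class GeometrySpec:
    """Which idealised network to build and its shape options."""

    type: str = "a_branch"  # "a_branch" | "y_branch"
    distal_multiplier: int = 2
    inlet_flow_ratio: float = 1.0
    branch_segments: int = 10  # y_branch only
    stem_segments: int = 10  # y_branch only

    def __post_init__(self) -> None:
        if self.type not in ("a_branch", "y_branch"):
            raise ValueError(f"unknown geometry type {self.type!r}")
        if self.distal_multiplier < 2:
            raise ValueError("distal_multiplier must be >= 2")
        if self.inlet_flow_ratio <= 0:
            raise ValueError("inlet_flow_ratio must be > 0")


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON configuration file.

    Recognised top-level keys: ``params`` (ModelParams fields), ``geometry``
    (GeometrySpec fields), ``rule`` (rule_id / fixed_p1 / alpha), ``cell_bc``
    (kind / n_fixed) and ``flow_bc`` (kind / q_in).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix == ".json":
        cfg = json.loads(text)
    else:  # fall back on YAML, a superset of JSON
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg
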