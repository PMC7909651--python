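"""Decision rules at the flow-convergent bifurcation.

Cells migrating up the draining vessel reach a junction where two paths
against the flow exist.  Five rules decide which branch each cell enters:

* BR1 -- deterministic: take the branch with the larger wall shear stress.
* BR2 -- deterministic: take the branch needing the smallest direction
  change (smallest branch angle magnitude).
* BR3 -- stochastic with fixed equal probabilities (P1 = 0.5).
* BR4 -- stochastic with fixed unequal probabilities (P1 = 0.7 favouring
  the high-flow branch).
* BR5 -- the mechanistic rule: branch probability is a weighted average of
  a shear-stress component and a cell-number component,
  ``P_i = alpha * P_tau_i + (1 - alpha) * P_n_i`` with
  ``P_tau_i = tau_i / (tau_1 + tau_2)`` and ``P_n_i = n_i / (n_1 + n_2)``.

Ties in BR1/BR2 fall to branch 2 (the literal else-clause of the piecewise
definitions).  In BR3-BR5 each deciding cell draws its own uniform r in
[0, 1) and picks branch 1 iff ``r < P1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

_log = logging.getLogger(__name__)

_PROB_ATOL = 1e-12

RULE_IDS = ("BR1", "BR2", "BR3", "BR4", "BR5")


@dataclass(frozen=True)
class BranchProbabilities:
    """Branch-entry probabilities and their shear/cell-number decomposition."""

    P1: float
    P2: float
    P_tau1: float
    P_tau2: float
    P_n1: float
    P_n2: float
    alpha: float

    def validate(self) -> None:
        pairs = (
            ("P", self.P1, self.P2),
            ("P_tau", self.P_tau1, self.P_tau2),
            ("P_n", self.P_n1, self.P_n2),
        )
        for name, a, b in pairs:
            if not (-_PROB_ATOL <= a <= 1 + _PROB_ATOL and -_PROB_ATOL <= b <= 1 + _PROB_ATOL):
                raise AssertionError(f"{name} components outside [0, 1]: {a}, {b}")
            if abs(a + b - 1.0) > _PROB_ATOL:
                raise AssertionError(f"{name}1 + {name}2 != 1 ({a + b})")
        recon = self.alpha * self.P_tau1 + (1.0 - self.alpha) * self.P_n1
        if abs(recon - self.P1) > _PROB_ATOL:
            raise AssertionError("P1 does not match its weighted decomposition")


@dataclass(frozen=True)
class RuleSpec:
    """Selected bifurcation rule and its parameters."""

    rule_id: str
    fixed_p1: float | None = None  # BR3/BR4
    alpha: float | None = None  # BR5

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"unknown rule {self.rule_id!r}; expected one of {RULE_IDS}")
        if self.rule_id in ("BR3", "BR4"):
            default = 0.5 if self.rule_id == "BR3" else 0.7
            p1 = default if self.fixed_p1 is None else self.fixed_p1
            if not 0.0 <= p1 <= 1.0:
                raise ValueError("fixed_p1 must lie in [0, 1]")
            object.__setattr__(self, "fixed_p1", p1)
        if self.rule_id == "BR5":
            if self.alpha is None:
                raise ValueError("BR5 requires alpha")
            if not 0.0 <= self.alpha <= 1.0:
                raise ValueError("alpha must lie in [0, 1]")

    @property
    def is_stochastic(self) -> bool:
        return self.rule_id in ("BR3", "BR4", "BR5")


def br1_choice(tau1: float, tau2: float) -> int:
    """Branch with the larger wall shear stress (ties -> branch 2)."""
    if tau1 < 0 or tau2 < 0:
        raise ValueError("shear stresses must be non-negative")
    return 1 if tau1 > tau2 else 2


def br2_choice(theta1: float, theta2: float) -> int:
    """Branch with the smaller direction change |theta| (ties -> branch 2)."""
    return 1 if abs(theta1) < abs(theta2) else 2


def br_fixed_choice(p1: float, r: float) -> int:
    """Fixed-probability draw: branch 1 iff ``r < p1``."""
    return 1 if r < p1 else 2


def shear_probability(tau1: float, tau2: float) -> tuple[float, float]:
    """Shear components ``tau_i / (tau_1 + tau_2)``.

    The no-flow degenerate case (both shears zero) returns (0.5, 0.5): the
    ratio is undefined and neither branch has a flow advantage.
    """
    total = tau1 + tau2
    if total <= 0.0:
        _log.warning("both branch shear stresses are zero; using (0.5, 0.5)")
        return (0.5, 0.5)
    return (tau1 / total, tau2 / total)


def number_probability(n1: float, n2: float) -> tuple[float, float]:
    """Cell-number components ``n_i / (n_1 + n_2)``."""
    total = n1 + n2
    if total <= 0:
        raise ValueError(
            "both branch segments are empty; the bifurcation is already "
            "lost and no decision should be requested"
        )
    return (n1 / total, n2 / total)


def combined_probability(
    ptau: tuple[float, float], pn: tuple[float, float], alpha: float
) -> BranchProbabilities:
    """Weighted average of the shear and cell-number components."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    p1 = alpha * ptau[0] + (1.0 - alpha) * pn[0]
    p2 = alpha * ptau[1] + (1.0 - alpha) * pn[1]
    probs = BranchProbabilities(
        P1=p1, P2=p2,
        P_tau1=ptau[0], P_tau2=ptau[1],
        P_n1=pn[0], P_n2=pn[1],
        alpha=alpha,
    )
    probs.validate()
    return probs


def branch_probabilities(
    tau1: float, tau2: float, n1: int, n2: int, alpha: float
) -> BranchProbabilities:
    """BR5 probabilities from the two branch segments at the junction.

    The inputs are the wall shear stress and cell number of the two branch
    segments directly incident to the flow-convergent node (not whole-branch
    aggregates).
    """
    return combined_probability(
        shear_probability(tau1, tau2), number_probability(n1, n2), alpha
    )


def br5_choice(probs: BranchProbabilities, r: float) -> int:
    """Mechanistic-rule draw: branch 1 iff ``r < P1``."""
    return 1 if r < probs.P1 else 2
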