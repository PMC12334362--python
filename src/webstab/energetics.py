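"""Equilibrium energetics of a mass-balanced food web.

Under mass balance, a consumer's annual production (P/B)·B equals the sum
of its losses to predation and to non-predation ("other") mortality, and
its total consumption is production divided by conversion efficiency:

    F*_j = (P/B)_j · B_j / e_j

That consumption is split among prey either by biomass-weighted preference
(ω_ij · B_i, normalized per consumer) or by realized diet fractions DC_ij.
Summing the resulting feeding rates over a prey's consumers gives its
predation mortality M_i; the remainder of its production, expressed as a
specific rate m_i = (P/B)_i − M_i/B_i ≥ 0, is its non-predation mortality
and ends up in the detritus pool together with all egested (unassimilated)
food.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .webmodel import FoodWeb, FunctionalGroup, WebValidationError

__all__ = [
    "FlowMatrix",
    "MortalityPartition",
    "DetritusBudget",
    "total_consumption",
    "partition_flows",
    "mortality_partition",
    "detritus_budget",
    "trophic_levels",
]

#: Relative tolerance for mass-balance checks.
BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class FlowMatrix:
    """Equilibrium feeding rates F*_ij (prey i rows × predator j columns,
    mass·area⁻¹·yr⁻¹) and per-predator totals F*_j, in web group order."""

    flows: np.ndarray
    totals: np.ndarray
    names: tuple[str, ...]

    @property
    def total_feeding(self) -> float:
        """F*_T: summed consumption of every predator, detritivory included."""
        return float(self.totals.sum())


@dataclass(frozen=True)
class MortalityPartition:
    """Per-group predation mortality M_i (mass·area⁻¹·yr⁻¹) and
    non-predation specific mortality m_i (yr⁻¹, stored as a magnitude ≥ 0).

    The detritus pool has no mortality; its entries are NaN.
    """

    predation: np.ndarray
    nonpred_rate: np.ndarray
    names: tuple[str, ...]


@dataclass(frozen=True)
class DetritusBudget:
    inflow_egestion: float
    inflow_mortality: float
    outflow_consumption: float
    implied_import: float

    def as_dict(self) -> dict[str, float]:
        return {
            "inflow_egestion": self.inflow_egestion,
            "inflow_mortality": self.inflow_mortality,
            "outflow_consumption": self.outflow_consumption,
            "implied_import": self.implied_import,
        }


def total_consumption(group: FunctionalGroup) -> float:
    """Total equilibrium consumption F*_j = (P/B)_j · B_j / e_j of a consumer."""
    if group.role != "consumer":
        raise WebValidationError(
            f"total consumption is defined for consumers only, "
            f"{group.name!r} is a {group.role}"
        )
    if not group.efficiency:
        raise WebValidationError(
            f"consumer {group.name!r}: efficiency must be positive"
        )
    return group.pb * group.biomass / group.efficiency


def partition_flows(web: FoodWeb) -> FlowMatrix:
    """Split each consumer's total consumption among its prey.

    Preference mode: F*_ij = ω_ij·B_i / Σ_k ω_kj·B_k · F*_j (biomass-weighted
    preferences; the detritus pool participates as prey with its biomass).
    Fraction mode: F*_ij = DC_ij · F*_j.
    """
    n = web.n
    flows = np.zeros((n, n))
    totals = np.zeros(n)
    for g in web.consumers:
        j = web.index(g.name)
        fj = total_consumption(g)
        totals[j] = fj
        prey = web.diet.prey_of(g.name)
        if web.diet.mode == "preference":
            weights = {
                p: w * web.group(p).biomass for p, w in prey.items()
            }
            denom = sum(weights.values())
            if denom <= 0:
                raise WebValidationError(
                    f"consumer {g.name!r}: preference weighting denominator "
                    "is zero"
                )
            shares = {p: w / denom for p, w in weights.items()}
        else:
            shares = prey  # fractions sum to 1 (validated upstream)
        for p, share in shares.items():
            flows[web.index(p), j] = share * fj
    return FlowMatrix(flows=flows, totals=totals, names=tuple(web.names))


def mortality_partition(web: FoodWeb, flows: FlowMatrix) -> MortalityPartition:
    """Split each living group's total mortality (P/B) into predation and
    non-predation parts.  Raises if predation exceeds production beyond
    tolerance (the web is not balanced)."""
    n = web.n
    predation = np.full(n, np.nan)
    m = np.full(n, np.nan)
    for g in web.living:
        i = web.index(g.name)
        mi_flow = float(flows.flows[i, :].sum())
        predation[i] = mi_flow
        rate = g.pb - mi_flow / g.biomass
        if rate < -BALANCE_RTOL * max(1.0, g.pb):
            raise WebValidationError(
                f"unbalanced web: predation on {g.name!r} "
                f"({mi_flow / g.biomass:.6g}/yr) exceeds its production "
                f"(P/B = {g.pb:.6g}/yr)"
            )
        m[i] = max(rate, 0.0)
    return MortalityPartition(
        predation=predation, nonpred_rate=m, names=tuple(web.names)
    )


def detritus_budget(
    web: FoodWeb, flows: FlowMatrix, mort: MortalityPartition
) -> DetritusBudget:
    """Detritus mass balance: egestion and carcass inflows versus
    detritivore consumption.

    ``implied_import`` is the allochthonous input required to close the
    budget (outflow minus inflows).  It is reported only: being a constant
    (density-independent) source it contributes nothing to the Jacobian.
    """
    egestion = sum(
        (1.0 - g.unassim) * flows.totals[web.index(g.name)]
        for g in web.consumers
    )
    mortality = sum(
        mort.nonpred_rate[web.index(g.name)] * g.biomass for g in web.living
    )
    d = web.index(web.detritus.name)
    outflow = float(flows.flows[d, :].sum())
    return DetritusBudget(
        inflow_egestion=float(egestion),
        inflow_mortality=float(mortality),
        outflow_consumption=outflow,
        implied_import=outflow - float(egestion) - float(mortality),
    )


def trophic_levels(web: FoodWeb, flows: FlowMatrix | None = None) -> np.ndarray:
    """Fractional trophic levels: producers and detritus at 1, each consumer
    one level above the consumption-weighted mean of its prey.

    Solved as the linear system (I − C)·TL = 1 where C_ji is consumer j's
    diet fraction of prey i (rows sum to ≤ 1 for consumers, 0 for basal
    groups).
    """
    if flows is None:
        flows = partition_flows(web)
    n = web.n
    A = np.eye(n)
    for g in web.consumers:
        j = web.index(g.name)
        tot = flows.totals[j]
        if tot <= 0:
            continue
        A[j, :] -= flows.flows[:, j] / tot
    try:
        levels = np.linalg.solve(A, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise WebValidationError(
            f"trophic-level system is singular: {exc}"
        ) from exc
    return levels
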