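"""Jacobian community-matrix construction from equilibrium flows.

Interaction strengths are Jacobian entries α_ij = effect of group j on
group i's growth rate at the mass-balance equilibrium (yr⁻¹).  For a
living predator–prey pair with equilibrium feeding rate F*_ij the classic
energetic estimates are

    α_ij = −F*_ij / B_j        (top-down effect of predator j on prey i)
    α_ji = +e_j · F*_ij / B_i  (bottom-up effect of prey i on predator j)

Two matrix variants are built:

* ``grazing`` — the phytoplankton-based web: the detritus pool interacts
  only through being eaten (its row holds the top-down term −F*_Dj/B_j for
  detritivores; its column the bottom-up term e_j·F*_Dj/B_D).
* ``detritus`` — additionally accounts for the fluxes *into* detritus.
  Every living group feeds the pool through its predators' egestion and its
  own non-predation mortality; detritivores also deplete it.  The aggregate
  effect of living group A on detritus is

      α_DA = −F*_DA/B_A + m_A + Σ_K (1 − ac_K) · F*_AK / B_A

  (feeding on detritus, carcass production, and egestion by A's consumers
  K).  For a group that eats no detritus the first term vanishes and the
  effect is non-negative.

The diagonal is parameterized separately: α_ii = −s·m_i for living groups
with a single dimensionless self-limitation strength s (the stability
index searched by :mod:`webstab.stability`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .energetics import FlowMatrix, MortalityPartition
from .webmodel import FoodWeb, WebValidationError

__all__ = [
    "CommunityMatrix",
    "pair_strengths",
    "detritus_effect_of_prey",
    "detritus_effect_of_detritivore",
    "build_matrix",
    "set_diagonal",
]

Variant = Literal["grazing", "detritus"]
DetritusDiagonal = Literal["zero", "donor"]


@dataclass(frozen=True)
class CommunityMatrix:
    """The community (Jacobian) matrix α with metadata.

    ``alpha[i, j]`` is the effect of group j on group i (yr⁻¹).  ``s`` is
    ``None`` until a diagonal has been imposed with :func:`set_diagonal`.
    """

    alpha: np.ndarray
    names: tuple[str, ...]
    variant: Variant
    living: np.ndarray  # boolean mask, True for living groups
    detritus_index: int
    s: float | None = None
    detritus_diagonal: DetritusDiagonal = "zero"
    detritus_selfrate: float = 0.0  # −Σ_j F*_Dj / B_D, used by "donor" policy
    full_derivative: bool = False

    @property
    def n(self) -> int:
        return len(self.names)

    def off_diagonal(self) -> np.ndarray:
        out = self.alpha.copy()
        np.fill_diagonal(out, 0.0)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.alpha, index=self.names, columns=self.names)


def pair_strengths(
    flow: float, prey_biomass: float, predator_biomass: float, efficiency: float
) -> tuple[float, float]:
    """Top-down and bottom-up interaction strengths of one feeding link.

    Returns ``(α_ij, α_ji) = (−F*_ij/B_j, e_j·F*_ij/B_i)``.
    """
    if prey_biomass <= 0 or predator_biomass <= 0:
        raise WebValidationError("biomasses must be positive")
    if flow < 0:
        raise WebValidationError("feeding rate must be non-negative")
    return -flow / predator_biomass, efficiency * flow / prey_biomass


def detritus_effect_of_prey(
    web: FoodWeb, flows: FlowMatrix, mort: MortalityPartition, name: str
) -> float:
    """Effect on detritus of a living group that consumes no detritus:
    egestion by its predators plus its own non-predation mortality,
    Σ_m (1−ac_m)·F*_Pm/B_P + m_P ≥ 0."""
    g = web.group(name)
    if not g.is_living:
        raise WebValidationError("the detritus pool has no effect on itself here")
    i = web.index(name)
    egestion = sum(
        (1.0 - web.group(pred).unassim) * flows.flows[i, web.index(pred)]
        for pred in web.diet.predators_of(name)
    )
    return egestion / g.biomass + float(mort.nonpred_rate[i])


def detritus_effect_of_detritivore(
    web: FoodWeb, flows: FlowMatrix, mort: MortalityPartition, name: str
) -> float:
    """Aggregate effect on detritus of living consumer A:
    −F*_DA/B_A + m_A + Σ_K (1−ac_K)·F*_AK/B_A.

    Negative when A's detritivory dominates its carcass and predator-egestion
    contributions; reduces exactly to :func:`detritus_effect_of_prey` when A
    eats no detritus.
    """
    g = web.group(name)
    if not g.is_living:
        raise WebValidationError("the detritus pool cannot be a detritivore")
    a = web.index(name)
    d = web.index(web.detritus.name)
    return -flows.flows[d, a] / g.biomass + detritus_effect_of_prey(
        web, flows, mort, name
    )


def build_matrix(
    web: FoodWeb,
    flows: FlowMatrix,
    mort: MortalityPartition,
    variant: Variant = "detritus",
    detritus_diagonal: DetritusDiagonal = "zero",
    full_derivative: bool = False,
) -> CommunityMatrix:
    """Build the off-diagonal community matrix for one variant.

    ``full_derivative=True`` adds to each consumer's detritus-row entry its
    own egestion response (1−ac_A)·F*_A/B_A, i.e. the exact partial
    derivative of the detritus balance equation; the default keeps the
    three-term aggregate described in the module docstring, which attributes
    a consumer's egestion to its prey's columns instead.
    """
    n = web.n
    d = web.index(web.detritus.name)
    alpha = np.zeros((n, n))
    living = np.array([g.is_living for g in web.groups])

    # living–living pairs plus the detritus column (bottom-up effect of the
    # pool on its consumers) — identical in both variants
    for g in web.consumers:
        j = web.index(g.name)
        for prey_name in web.diet.prey_of(g.name):
            i = web.index(prey_name)
            f = flows.flows[i, j]
            if f == 0.0:
                continue
            td, bu = pair_strengths(
                f, web.group(prey_name).biomass, g.biomass, g.efficiency
            )
            alpha[i, j] += td
            alpha[j, i] += bu

    # detritus row: effect of living groups on the pool
    if variant == "detritus":
        for g in web.living:
            i = web.index(g.name)
            if g.role == "consumer":
                val = detritus_effect_of_detritivore(web, flows, mort, g.name)
                if full_derivative:
                    val += (1.0 - g.unassim) * flows.totals[i] / g.biomass
            else:
                val = detritus_effect_of_prey(web, flows, mort, g.name)
            alpha[d, i] = val
    elif variant == "grazing":
        # only the predation (top-down) term survives; rebuild the row so the
        # pair loop above, which already wrote it, is the single source
        pass
    else:
        raise WebValidationError(f"unknown variant {variant!r}")

    np.fill_diagonal(alpha, 0.0)
    selfrate = -float(flows.flows[d, :].sum()) / web.detritus.biomass
    return CommunityMatrix(
        alpha=alpha,
        names=tuple(web.names),
        variant=variant,
        living=living,
        detritus_index=d,
        s=None,
        detritus_diagonal=detritus_diagonal,
        detritus_selfrate=selfrate,
        full_derivative=full_derivative,
    )


def set_diagonal(
    matrix: CommunityMatrix, s: float, mort: MortalityPartition
) -> CommunityMatrix:
    """Impose the self-limitation diagonal α_ii = −s·m_i on living groups.

    The detritus diagonal follows the matrix's configured policy: 0 by
    default (the pool has no mortality rate to scale), or the donor-control
    rate −Σ_j F*_Dj/B_D under ``"donor"``.  Setting is idempotent: each call
    replaces the diagonal outright.
    """
    if s < 0:
        raise WebValidationError(f"diagonal strength s must be >= 0, got {s}")
    alpha = matrix.off_diagonal()
    m = np.where(np.isnan(mort.nonpred_rate), 0.0, mort.nonpred_rate)
    diag = -s * m
    if matrix.detritus_diagonal == "donor":
        diag[matrix.detritus_index] = matrix.detritus_selfrate
    else:
        diag[matrix.detritus_index] = 0.0
    alpha[np.arange(matrix.n), np.arange(matrix.n)] = diag
    return replace(matrix, alpha=alpha, s=float(s))
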