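"""Synthetic mass-balanced food-web generator.

Emulates the inputs the pipeline expects from a balanced Ecopath run on a
shallow-lake ecosystem: a biomass pyramid across trophic layers, P/B
falling with trophic level, conversion efficiencies in the 0.1–0.3 range
typical of aquatic consumers, an unassimilated fraction of 0.2, one
detritus pool with widespread facultative detritivory, and feeding links
directed from lower to higher layers (cascade ordering).

Balance is guaranteed by construction: layers are finalized from the top
down, and each preyed group's P/B is derived from the specific predation
rate already imposed by the (fixed) layers above it, scaled by an
ecotrophic-efficiency margin, so non-predation mortality m_i is strictly
positive for every living group.  A fixed seed reproduces the web
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .webmodel import DietSpec, FoodWeb, FunctionalGroup, WebValidationError
from . import energetics

__all__ = ["SynthParams", "generate_synthetic_web"]


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the generator; defaults mimic a 12-group shallow-lake web.

    ``pb_ranges`` holds one (low, high) interval per layer, layer 0 being
    the producers; when fewer intervals than layers are given the last one
    is reused.  ``pyramid_ratio`` is the biomass ratio between successive
    layers.  ``detritivory`` is the probability that a consumer also feeds
    on the detritus pool (at least one detritivore is always present).
    ``connectance`` is the probability of each feasible extra feeding link
    beyond the guaranteed one-per-consumer.
    """

    n_groups: int = 12
    n_producers: int = 2
    n_consumer_layers: int = 3
    base_biomass: float = 100.0
    pyramid_ratio: float = 0.15
    pb_ranges: tuple[tuple[float, float], ...] = (
        (20.0, 60.0),   # producers
        (2.0, 10.0),    # primary consumers
        (0.8, 3.0),     # secondary consumers
        (0.3, 1.2),     # top layer
    )
    efficiency_range: tuple[float, float] = (0.1, 0.3)
    unassim: float = 0.2
    detritivory: float = 0.5
    connectance: float = 0.3
    mortality_margin: tuple[float, float] = (0.05, 1.0)
    seed: int = 0
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 3:
            raise WebValidationError("need at least producer+consumer+detritus")
        if self.n_producers < 1:
            raise WebValidationError("need at least one producer")
        if self.n_consumer_layers < 1:
            raise WebValidationError("need at least one consumer layer")
        if self.n_groups - 1 - self.n_producers < self.n_consumer_layers:
            raise WebValidationError(
                "not enough groups for the requested layer structure"
            )
        for lo, hi in (self.efficiency_range, self.mortality_margin,
                       *self.pb_ranges):
            if not (0 < lo <= hi):
                raise WebValidationError("ranges must be positive and ordered")
        if not (0 <= self.connectance <= 1 and 0 <= self.detritivory <= 1):
            raise WebValidationError("probabilities must lie in [0, 1]")


def _layer_sizes(params: SynthParams) -> list[int]:
    n_cons = params.n_groups - 1 - params.n_producers
    base, extra = divmod(n_cons, params.n_consumer_layers)
    # bottom-heavy: earlier consumer layers get the remainder
    return [params.n_producers] + [
        base + (1 if i < extra else 0)
        for i in range(params.n_consumer_layers)
    ]


def generate_synthetic_web(params: SynthParams) -> FoodWeb:
    """Generate one balanced web; deterministic under ``params.seed``.

    ``structure_seed`` (default: same as ``seed``) drives the *system*
    draws — topology, diet preferences, conversion efficiencies, mortality
    margins and top-layer production rates — on a stream separate from the
    *snapshot* draws (the standing biomasses).  Holding it fixed while
    varying ``seed`` yields webs sharing one parameterized ecosystem with
    shifting standing stocks: the synthetic analogue of repeated survey
    snapshots of a single lake, whose production rates rebalance to the
    biomass state.
    """
    rng = np.random.default_rng(params.seed)
    rng_struct = np.random.default_rng(
        params.seed if params.structure_seed is None else params.structure_seed
    )
    sizes = _layer_sizes(params)

    # roster, layer by layer
    names: list[str] = ["Detritus"]
    layer_of: dict[str, int] = {}
    for lay, size in enumerate(sizes):
        for k in range(size):
            nm = f"P{k+1}" if lay == 0 else f"C{lay}_{k+1}"
            names.append(nm)
            layer_of[nm] = lay
    living = names[1:]

    biomass = {"Detritus": params.base_biomass * rng.uniform(0.8, 2.0)}
    for nm in living:
        lay = layer_of[nm]
        biomass[nm] = (
            params.base_biomass
            * params.pyramid_ratio**lay
            * rng.uniform(0.5, 1.5)
        )
    eff = {
        nm: rng_struct.uniform(*params.efficiency_range)
        for nm in living
        if layer_of[nm] > 0
    }

    # feeding links: every consumer eats >= 1 group one layer down, extra
    # links to any strictly lower layer with prob = connectance, plus
    # facultative detritivory
    entries: dict[tuple[str, str], float] = {}
    consumers = [nm for nm in living if layer_of[nm] > 0]
    detritivores: list[str] = []
    for nm in consumers:
        lay = layer_of[nm]
        below = [p for p in living if layer_of[p] == lay - 1]
        lower = [p for p in living if layer_of[p] < lay]
        staple = below[int(rng_struct.integers(len(below)))]
        prey = {staple}
        for p in lower:
            if p != staple and rng_struct.random() < params.connectance:
                prey.add(p)
        if rng_struct.random() < params.detritivory:
            prey.add("Detritus")
            detritivores.append(nm)
        for p in sorted(prey):
            entries[(p, nm)] = rng_struct.uniform(0.2, 1.0)
    if not detritivores:
        nm = consumers[int(rng_struct.integers(len(consumers)))]
        entries[("Detritus", nm)] = rng_struct.uniform(0.2, 1.0)

    # P/B top-down so that m_i > 0 everywhere: a group's specific predation
    # rate depends only on predators in higher (already fixed) layers
    def pb_range(lay: int) -> tuple[float, float]:
        ranges = params.pb_ranges
        return ranges[min(lay, len(ranges) - 1)]

    pb: dict[str, float] = {}
    n_layers = len(sizes)
    for lay in range(n_layers - 1, -1, -1):
        # feeding of all higher-layer consumers is now fixed; accumulate the
        # predation each group in this layer suffers
        predation = {nm: 0.0 for nm in living if layer_of[nm] == lay}
        for pred in consumers:
            if layer_of[pred] <= lay or pred not in pb:
                continue
            f_tot = pb[pred] * biomass[pred] / eff[pred]
            prey_w = {
                p: entries[(p, pred)] * biomass[p]
                for (p, q) in entries
                if q == pred
            }
            denom = sum(prey_w.values())
            for p, w in prey_w.items():
                if p in predation:
                    predation[p] += w / denom * f_tot
        for nm in sorted(predation):
            draw = rng_struct.uniform(*pb_range(lay))
            margin = rng_struct.uniform(*params.mortality_margin)
            if predation[nm] > 0:
                # preyed groups: production follows the predation they
                # suffer, with ecotrophic efficiency 1/(1+margin) — the
                # high consumed fraction typical of balanced webs; the
                # remainder is non-predation mortality, so m_i > 0 always
                pb[nm] = (predation[nm] / biomass[nm]) * (1.0 + margin)
            else:
                # unpreyed (top or ungrazed) groups die only naturally
                pb[nm] = draw

    groups = [
        FunctionalGroup("Detritus", "detritus", biomass["Detritus"])
    ]
    for nm in living:
        if layer_of[nm] == 0:
            groups.append(
                FunctionalGroup(nm, "producer", biomass[nm], pb=pb[nm])
            )
        else:
            groups.append(
                FunctionalGroup(
                    nm, "consumer", biomass[nm], pb=pb[nm],
                    efficiency=eff[nm], unassim=params.unassim,
                )
            )
    web = FoodWeb(
        groups=tuple(groups),
        diet=DietSpec(mode="preference", entries=entries),
        period_label=f"synthetic-{params.seed}",
    )
    # close the detritus budget with a non-negative allochthonous import
    flows = energetics.partition_flows(web)
    mort = energetics.mortality_partition(web, flows)
    budget = energetics.detritus_budget(web, flows, mort)
    if budget.implied_import > 0:
        web = FoodWeb(
            groups=web.groups, diet=web.diet,
            detritus_import=budget.implied_import,
            period_label=web.period_label,
        )
    return web
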