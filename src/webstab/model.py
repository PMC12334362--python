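"""Model/Results facade over the analysis pipeline.

:class:`CommunityStability` bundles the pipeline — flow partition,
mortality split, community-matrix construction, required-diagonal-strength
search, loop-weight analysis — behind a ``fit()`` call returning a
:class:`StabilityResults` object with the estimates, diagnostics, and a
``summary()`` table.  Multi-period series are assembled with
:func:`fit_periods`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import energetics, indicators, interaction, loops, stability
from .interaction import CommunityMatrix, DetritusDiagonal, Variant
from .webmodel import Diagnostic, FoodWeb, read_foodweb, validate_foodweb

__all__ = ["CommunityStability", "StabilityResults", "fit_periods"]


class CommunityStability:
    """Local-stability model of a mass-balanced food web.

    Parameters
    ----------
    web
        Validated :class:`~webstab.webmodel.FoodWeb` snapshot.
    variant
        ``"detritus"`` (default) includes the egestion and carcass fluxes
        into the detritus pool; ``"grazing"`` keeps only feeding links.
    detritus_diagonal, full_derivative
        Passed through to :func:`webstab.interaction.build_matrix`.
    """

    def __init__(
        self,
        web: FoodWeb,
        variant: Variant = "detritus",
        detritus_diagonal: DetritusDiagonal = "zero",
        full_derivative: bool = False,
    ):
        self.web = web
        self.variant = variant
        self.detritus_diagonal = detritus_diagonal
        self.full_derivative = full_derivative
        self.diagnostics: list[Diagnostic] = validate_foodweb(web)
        errors = [d for d in self.diagnostics if d.severity == "error"]
        if errors:
            from .webmodel import WebValidationError

            raise WebValidationError("; ".join(d.message for d in errors))
        self.flows = energetics.partition_flows(web)
        self.mortality = energetics.mortality_partition(web, self.flows)
        self.matrix: CommunityMatrix = interaction.build_matrix(
            web, self.flows, self.mortality, variant=variant,
            detritus_diagonal=detritus_diagonal,
            full_derivative=full_derivative,
        )

    @classmethod
    def from_tables(
        cls, groups_path, diet_path, config_path=None, **kwargs
    ) -> "CommunityStability":
        return cls(read_foodweb(groups_path, diet_path, config_path), **kwargs)

    def fit(
        self, tol: float = 1e-4, cap: float = 1e6, loop_length: int = 3
    ) -> "StabilityResults":
        """Run the stability search and loop analysis."""
        res = stability.required_diagonal_strength(
            self.matrix, self.mortality, tol=tol, cap=cap
        )
        mlw, argmax = loops.max_loop_weight(self.matrix, k=loop_length)
        table = loops.loop_table(self.matrix, self.web, k=loop_length)
        return StabilityResults(
            model=self,
            stability=res,
            mlw=mlw,
            max_loop=argmax,
            loop_records=table,
            trophic_levels=pd.Series(
                energetics.trophic_levels(self.web, self.flows),
                index=self.web.names,
            ),
        )


@dataclass
class StabilityResults:
    """Fitted stability estimates for one web snapshot."""

    model: CommunityStability
    stability: stability.StabilityResult
    mlw: float
    max_loop: loops.LoopRecord
    loop_records: pd.DataFrame
    trophic_levels: pd.Series
    _bcbp: float | None = field(default=None, repr=False)

    @property
    def required_s(self) -> float:
        return self.stability.required_s

    @property
    def lambda_max(self) -> float:
        return self.stability.lambda_max_at_s

    @property
    def max_loop_label(self) -> str:
        return self.max_loop.label

    def bcbp(self, pairs=None) -> float:
        return indicators.bcbp(self.model.web, pairs)

    def summary(self) -> str:
        web = self.model.web
        lines = [
            "Community stability results",
            "===========================",
            f"period:                {web.period_label or '-'}",
            f"groups:                {web.n} ({len(web.consumers)} consumers, "
            f"1 detritus pool)",
            f"matrix variant:        {self.model.variant}",
            f"required s:            {self.required_s:.6g}",
            f"lambda_max at s*:      {self.lambda_max:.6g} /yr",
            f"search bracket:        [{self.stability.bracket[0]:.6g}, "
            f"{self.stability.bracket[1]:.6g}]",
            f"eigenvalue solves:     {self.stability.iterations}",
            f"max loop weight (k=3): {self.mlw:.6g}",
            f"heaviest loop:         {self.max_loop_label}",
            f"3-link loops:          {len(self.loop_records)}",
            f"trophic levels:        1 - "
            f"{float(self.trophic_levels.max()):.3f}",
            f"BCBP (all links):      {self.bcbp():.6g}",
        ]
        return "\n".join(lines)


def fit_periods(
    webs: Sequence[FoodWeb] | dict[str, FoodWeb],
    variant: Variant = "detritus",
    bcbp_pairs=None,
    pbr_pairs: Sequence[tuple[str, str]] = (),
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every period and assemble an indicator series.

    Returns one row per period with required_s, mlw, the heaviest loop's
    label, BCBP, and a ``pbr_<pred>_<prey>`` column per requested
    predator/prey biomass-ratio pair.
    """
    if isinstance(webs, dict):
        items = list(webs.items())
    else:
        items = [(w.period_label or str(i), w) for i, w in enumerate(webs)]
    rows = []
    for label, web in items:
        res = CommunityStability(web, variant=variant).fit(**fit_kwargs)
        row = {
            "period": label,
            "required_s": res.required_s,
            "mlw": res.mlw,
            "mlw_loop": res.max_loop_label,
            "bcbp": res.bcbp(bcbp_pairs),
        }
        for pred, prey in pbr_pairs:
            row[f"pbr_{pred}_{prey}"] = indicators.biomass_ratio(
                web, pred, prey
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("period")
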