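"""Domain types, validation and tabular I/O for food-web snapshots.

A :class:`FoodWeb` is a mass-balanced (Ecopath-style) snapshot of an
ecosystem for one period: a list of functional groups with bioenergetic
parameters, a diet structure (either preference weights or realized diet
fractions), and an optional allochthonous detritus import.  All downstream
computation — equilibrium flows, interaction strengths, loop weights,
stability — starts from this object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalGroup",
    "DietSpec",
    "FoodWeb",
    "Diagnostic",
    "WebValidationError",
    "read_foodweb",
    "validate_foodweb",
    "write_matrix",
    "read_matrix",
    "write_foodweb",
]

Role = Literal["producer", "consumer", "detritus"]

#: Default unassimilated (egested) fraction for consumers.  Standard value
#: for aquatic consumers in mass-balance models.
DEFAULT_UNASSIM = 0.2


class WebValidationError(ValueError):
    """Raised when a food-web description violates a structural invariant."""


@dataclass(frozen=True)
class FunctionalGroup:
    """One functional group (or the detritus pool) of a food web.

    Parameters
    ----------
    name
        Unique identifier, preserved as matrix row/column label.
    role
        ``"producer"``, ``"consumer"`` or ``"detritus"`` (exactly one
        detritus pool per web).
    biomass
        Equilibrium density ``B`` (mass · area⁻¹, e.g. t·km⁻²); must be > 0.
    pb
        Production/biomass ratio (yr⁻¹).  Under mass balance this equals the
        instantaneous total mortality rate.  Ignored for detritus.
    efficiency
        Conversion efficiency ``e`` in (0, 1]: fraction of consumption
        converted to production.  Required for consumers, ignored otherwise.
    unassim
        Unassimilated fraction ``ac`` in [0, 1): share of consumption egested
        to the detritus pool rather than assimilated.
    """

    name: str
    role: Role
    biomass: float
    pb: float = 0.0
    efficiency: float | None = None
    unassim: float = DEFAULT_UNASSIM

    def __post_init__(self) -> None:
        if self.role not in ("producer", "consumer", "detritus"):
            raise WebValidationError(
                f"group {self.name!r}: unknown role {self.role!r}"
            )
        if not np.isfinite(self.biomass) or self.biomass <= 0:
            raise WebValidationError(
                f"group {self.name!r}: biomass must be > 0, got {self.biomass}"
            )
        if self.role != "detritus":
            if self.pb < 0 or not np.isfinite(self.pb):
                raise WebValidationError(
                    f"group {self.name!r}: P/B must be >= 0, got {self.pb}"
                )
        if self.role == "consumer":
            if self.efficiency is None:
                raise WebValidationError(
                    f"consumer {self.name!r}: conversion efficiency is required"
                )
            if not (0 < self.efficiency <= 1):
                raise WebValidationError(
                    f"consumer {self.name!r}: efficiency must be in (0, 1], "
                    f"got {self.efficiency}"
                )
            if not (0 <= self.unassim < 1):
                raise WebValidationError(
                    f"consumer {self.name!r}: unassimilated fraction must be "
                    f"in [0, 1), got {self.unassim}"
                )

    @property
    def is_living(self) -> bool:
        return self.role != "detritus"


@dataclass(frozen=True)
class DietSpec:
    """Diet structure: who eats whom, and how much.

    ``mode="preference"`` stores prey-preference weights ω_ij ≥ 0; each
    consumer's realized diet is obtained downstream by weighting preferences
    with prey biomass.  ``mode="fraction"`` stores realized diet fractions
    DC_ij (each consumer's column sums to 1), the form exported by Ecopath.
    """

    mode: Literal["preference", "fraction"]
    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("preference", "fraction"):
            raise WebValidationError(f"unknown diet mode {self.mode!r}")
        for (prey, pred), w in self.entries.items():
            if w < 0 or not np.isfinite(w):
                raise WebValidationError(
                    f"diet entry {prey!r} -> {pred!r}: weight must be "
                    f">= 0 and finite, got {w}"
                )
            if prey == pred:
                raise WebValidationError(
                    f"group {prey!r}: self-feeding is not allowed"
                )

    def prey_of(self, predator: str) -> dict[str, float]:
        return {
            prey: w
            for (prey, pred), w in self.entries.items()
            if pred == predator and w > 0
        }

    def predators_of(self, prey: str) -> dict[str, float]:
        return {
            pred: w
            for (p, pred), w in self.entries.items()
            if p == prey and w > 0
        }


@dataclass(frozen=True)
class FoodWeb:
    """A validated food-web snapshot for one period.

    Group order is the input order and is preserved in every derived matrix,
    so loop labels and matrix exports are reproducible.
    """

    groups: tuple[FunctionalGroup, ...]
    diet: DietSpec
    detritus_import: float = 0.0
    period_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [g.name for g in self.groups]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise WebValidationError(f"duplicate group names: {sorted(dupes)}")
        n_det = sum(g.role == "detritus" for g in self.groups)
        if n_det != 1:
            raise WebValidationError(
                f"a web must contain exactly one detritus pool, found {n_det}"
            )
        known = set(names)
        for prey, pred in self.diet.entries:
            for nm in (prey, pred):
                if nm not in known:
                    raise WebValidationError(
                        f"diet references unknown group {nm!r}"
                    )
        by_name = {g.name: g for g in self.groups}
        for prey, pred in self.diet.entries:
            if by_name[pred].role != "consumer" and self.diet.entries[(prey, pred)] > 0:
                raise WebValidationError(
                    f"{by_name[pred].role} {pred!r} cannot have a diet"
                )
        for g in self.groups:
            if g.role == "consumer" and not self.diet.prey_of(g.name):
                raise WebValidationError(
                    f"consumer {g.name!r} has no prey in the diet table"
                )
        if self.diet.mode == "fraction":
            for g in self.groups:
                if g.role != "consumer":
                    continue
                tot = sum(self.diet.prey_of(g.name).values())
                if abs(tot - 1.0) > 1e-9:
                    raise WebValidationError(
                        f"diet fractions of consumer {g.name!r} sum to "
                        f"{tot:.12g}, expected 1"
                    )
        if self.detritus_import < 0:
            raise WebValidationError("detritus import must be >= 0")

    # -- indexing helpers -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def n(self) -> int:
        return len(self.groups)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no group named {name!r}") from None

    def group(self, name: str) -> FunctionalGroup:
        return self.groups[self.index(name)]

    @property
    def detritus(self) -> FunctionalGroup:
        return next(g for g in self.groups if g.role == "detritus")

    @property
    def consumers(self) -> list[FunctionalGroup]:
        return [g for g in self.groups if g.role == "consumer"]

    @property
    def living(self) -> list[FunctionalGroup]:
        return [g for g in self.groups if g.is_living]

    def reordered(self, names: Iterable[str]) -> "FoodWeb":
        """Same web with groups permuted into the given order."""
        names = list(names)
        if sorted(names) != sorted(self.names):
            raise WebValidationError("reordering must be a permutation")
        return replace(self, groups=tuple(self.group(n) for n in names))


@dataclass(frozen=True)
class Diagnostic:
    severity: Literal["error", "warning"]
    message: str
    group: str | None = None


# ---------------------------------------------------------------------------
# Readers / writers


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise WebValidationError(f"{path}: missing columns {missing}")


def read_foodweb(
    groups_path: str | Path,
    diet_path: str | Path,
    config_path: str | Path | None = None,
) -> FoodWeb:
    """Read a food web from a groups table, a long-form diet table and an
    optional JSON config.

    ``groups.csv`` columns: name, role, biomass, pb, efficiency, unassim
    (the last two optional; ``unassim`` defaults to 0.2 for consumers).
    ``diet.csv`` columns: prey, predator, value.  ``config.json`` keys:
    diet_mode ("preference"|"fraction"), detritus_import, period.
    """
    groups_path, diet_path = Path(groups_path), Path(diet_path)
    gdf = pd.read_csv(groups_path, float_precision="round_trip")
    _require_columns(gdf, ["name", "role", "biomass", "pb"], str(groups_path))

    cfg: dict = {}
    if config_path is not None:
        cfg = json.loads(Path(config_path).read_text())
    mode = cfg.get("diet_mode", "preference")

    groups = []
    for _, row in gdf.iterrows():
        role = str(row["role"]).strip().lower()
        eff = None
        if "efficiency" in gdf.columns and pd.notna(row.get("efficiency")):
            eff = float(row["efficiency"])
        ua = DEFAULT_UNASSIM
        if "unassim" in gdf.columns and pd.notna(row.get("unassim")):
            ua = float(row["unassim"])
        pb = float(row["pb"]) if pd.notna(row["pb"]) else 0.0
        groups.append(
            FunctionalGroup(
                name=str(row["name"]),
                role=role,  # type: ignore[arg-type]
                biomass=float(row["biomass"]),
                pb=pb if role != "detritus" else 0.0,
                efficiency=eff if role == "consumer" else None,
                unassim=ua,
            )
        )

    ddf = pd.read_csv(diet_path, float_precision="round_trip")
    _require_columns(ddf, ["prey", "predator", "value"], str(diet_path))
    entries = {
        (str(r["prey"]), str(r["predator"])): float(r["value"])
        for _, r in ddf.iterrows()
        if float(r["value"]) != 0.0
    }
    diet = DietSpec(mode=mode, entries=entries)

    return FoodWeb(
        groups=tuple(groups),
        diet=diet,
        detritus_import=float(cfg.get("detritus_import", 0.0)),
        period_label=str(cfg.get("period", "")),
    )


def write_foodweb(web: FoodWeb, groups_path: str | Path,
                  diet_path: str | Path, config_path: str | Path) -> None:
    """Write a web back to the three-file tabular form read by
    :func:`read_foodweb` (exact round trip)."""
    rows = []
    for g in web.groups:
        rows.append(
            dict(name=g.name, role=g.role, biomass=repr(g.biomass),
                 pb=repr(g.pb),
                 efficiency="" if g.efficiency is None else repr(g.efficiency),
                 unassim=repr(g.unassim))
        )
    pd.DataFrame(rows).to_csv(groups_path, index=False)
    drows = [
        dict(prey=prey, predator=pred, value=repr(v))
        for (prey, pred), v in sorted(web.diet.entries.items())
    ]
    pd.DataFrame(drows, columns=["prey", "predator", "value"]).to_csv(
        diet_path, index=False
    )
    Path(config_path).write_text(
        json.dumps(
            {
                "diet_mode": web.diet.mode,
                "detritus_import": web.detritus_import,
                "period": web.period_label,
            },
            indent=2,
        )
    )


def validate_foodweb(web: FoodWeb) -> list[Diagnostic]:
    """Full validation: structural invariants plus energetic balance.

    Returns an empty list iff the web is internally consistent: every
    group's production covers the predation it suffers (non-predation
    mortality non-negative) and the detritus budget closes.  An implied
    negative detritus import is reported as a warning, not an error.
    """
    from . import energetics  # deferred: energetics imports this module

    out: list[Diagnostic] = []
    try:
        flows = energetics.partition_flows(web)
    except WebValidationError as exc:
        return [Diagnostic("error", str(exc))]

    bal_tol = 1e-9
    for g in web.living:
        i = web.index(g.name)
        m_pred = float(flows.flows[i, :].sum())
        m_rate = g.pb - m_pred / g.biomass
        if m_rate < -bal_tol * max(1.0, g.pb):
            out.append(
                Diagnostic(
                    "error",
                    f"group {g.name!r}: predation losses "
                    f"({m_pred / g.biomass:.6g}/yr) exceed production "
                    f"(P/B={g.pb:.6g}/yr); non-predation mortality would be "
                    f"negative",
                    group=g.name,
                )
            )
    if any(d.severity == "error" for d in out):
        return out

    mort = energetics.mortality_partition(web, flows)
    budget = energetics.detritus_budget(web, flows, mort)
    if budget.implied_import < -1e-9 * max(1.0, budget.outflow_consumption):
        out.append(
            Diagnostic(
                "warning",
                "detritus inflows (egestion + mortality) exceed detritivore "
                f"consumption by {-budget.implied_import:.6g}; implied "
                "allochthonous import is negative",
                group=web.detritus.name,
            )
        )
    elif budget.implied_import > web.detritus_import + 1e-9 * max(
        1.0, budget.outflow_consumption
    ):
        out.append(
            Diagnostic(
                "warning",
                "detritivore consumption exceeds detritus inflows plus the "
                f"configured import by "
                f"{budget.implied_import - web.detritus_import:.6g}",
                group=web.detritus.name,
            )
        )
    return out


def write_matrix(matrix, path: str | Path) -> None:
    """Write a labeled matrix (CommunityMatrix or FlowMatrix) to CSV at full
    precision (17 significant digits, round-trip exact)."""
    arr, names = _matrix_payload(matrix)
    if arr.size == 0:
        raise WebValidationError("refusing to write an empty matrix")
    df = pd.DataFrame(arr, index=names, columns=names)
    df.to_csv(path)  # default float repr: shortest exact round trip


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labeled matrix CSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


def _matrix_payload(matrix) -> tuple[np.ndarray, list[str]]:
    if hasattr(matrix, "alpha"):
        return np.asarray(matrix.alpha, dtype=float), list(matrix.names)
    if hasattr(matrix, "flows"):
        return np.asarray(matrix.flows, dtype=float), list(matrix.names)
    raise TypeError(f"cannot export object of type {type(matrix).__name__}")
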