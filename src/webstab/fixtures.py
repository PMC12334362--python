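"""Packaged Baiyangdian Lake (BYD) case-study fixture.

The published loop-weight table for the BYD detritus food web — 40
three-link loops across five snapshot years (1958, 1980, 1993, 2009,
2019), plus the per-year maximum loop weight and required diagonal
strength — ships with the package, together with the 12-functional-group
roster.  The meiofauna abbreviation is normalized to ``Meio`` (the source
table prints both ``Meao`` and ``Meio`` for the same group).

The underlying per-year biomass/diet/Ecopath tables are published as a
supplement only; :func:`load_period_tables` ingests them once the user has
converted them to the package's tabular form, enabling a full-pipeline
rerun of the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .webmodel import FoodWeb, read_foodweb

__all__ = ["BydFixture", "byd_fixture", "load_period_tables"]

PERIODS = ("1958", "1980", "1993", "2009", "2019")


@dataclass(frozen=True)
class BydFixture:
    """Published loop-weight table plus roster for the BYD case study."""

    loop_weights: pd.DataFrame   # index: loop label, columns: years
    max_loop_weight: pd.Series   # per year
    required_s: pd.Series        # per year
    roster: pd.DataFrame         # abbrev, name, role, category

    @property
    def categories(self) -> dict[str, str]:
        return dict(zip(self.roster["abbrev"], self.roster["category"]))

    def root_category(self, label: str) -> str:
        """Root-node category of a loop label like ``"Detr > Zoop > FilF"``."""
        return self.categories[label.split(" > ")[0]]

    def loops_rooted_at(self, category: str) -> pd.DataFrame:
        mask = [
            self.root_category(lb) == category
            for lb in self.loop_weights.index
        ]
        return self.loop_weights[mask]

    def argmax_loop(self, year: str) -> str:
        return str(self.loop_weights[year].idxmax())


def _data(name: str):
    return resources.files("webstab").joinpath("data", name)


def byd_fixture() -> BydFixture:
    """Load the packaged loop-weight table and roster."""
    with resources.as_file(_data("byd_table2_loops.csv")) as p:
        loops = pd.read_csv(p)
    with resources.as_file(_data("byd_table2_summary.csv")) as p:
        summary = pd.read_csv(p, index_col=0)
    with resources.as_file(_data("byd_groups.csv")) as p:
        roster = pd.read_csv(p)
    lw = loops.set_index("loop")[list(PERIODS)].astype(float)
    return BydFixture(
        loop_weights=lw,
        max_loop_weight=summary.loc["max_loop_weight"].astype(float),
        required_s=summary.loc["required_s"].astype(float),
        roster=roster,
    )


def load_period_tables(root: str | Path) -> dict[str, FoodWeb]:
    """Ingest user-converted per-period web tables for a full-pipeline run.

    ``root`` contains one subdirectory per period, each holding
    ``groups.csv``, ``diet.csv`` and ``config.json`` in the format of
    :func:`webstab.webmodel.read_foodweb`.  Returns period label → web,
    sorted by label.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"no such directory: {root}")
    out: dict[str, FoodWeb] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        gp, dp, cp = sub / "groups.csv", sub / "diet.csv", sub / "config.json"
        for f in (gp, dp, cp):
            if not f.exists():
                raise FileNotFoundError(f"period {sub.name}: missing {f.name}")
        label = json.loads(cp.read_text()).get("period", sub.name)
        out[str(label)] = read_foodweb(gp, dp, cp)
    if not out:
        raise FileNotFoundError(f"{root} contains no period subdirectories")
    return out
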