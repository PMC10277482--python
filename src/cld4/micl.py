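"""Cell line manufacturability index (MI_CL): weighted-sum ranking.

The index aggregates m clones over n criteria:

    MI_CL,i = sum_j w_j * r_ij

with normalised weights ``w_j = raw_j / sum(raw)`` and dimensionless
ratings

    r_ij = (x_ij - x_j,worst) / (x_j,best - x_j,worst)

where best/worst are the campaign extremes of criterion j; for
``min_is_best`` criteria (e.g. lactate, aggregate, trisulfide bond) the
roles of best and worst are swapped.  Ratings and scores are bounded in
[0, 1]; a clone that is best on every criterion scores exactly 1.

Degenerate criteria (identical value for every clone) are excluded and
the weights renormalised over the remainder.  A clone missing a value on
some criterion has its weights renormalised over its observed criteria
and is flagged incomplete.  Ranking ties break lexicographically by clone
id, so rankings are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .features import FeatureTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Criterion:
    name: str
    feature: str
    direction: Literal["max_is_best", "min_is_best"]
    raw_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.raw_weight < 0:
            raise ValueError("raw_weight must be non-negative")
        if self.direction not in ("max_is_best", "min_is_best"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class CriteriaConfig:
    criteria: list[Criterion]

    def __post_init__(self) -> None:
        if not any(c.raw_weight > 0 for c in self.criteria):
            raise ValueError("at least one criterion must have positive weight")
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise ValueError("criterion names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CriteriaConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls._from_entries(raw["criteria"])

    @classmethod
    def _from_entries(cls, entries: list[dict]) -> "CriteriaConfig":
        return cls([Criterion(e["name"], e["feature"], e["direction"],
                              float(e.get("weight", 1.0))) for e in entries])

    def weights(self) -> pd.Series:
        """Normalised weights w_j (sum to 1)."""
        return normalize_weights(self.criteria)


@lru_cache(maxsize=1)
def default_criteria() -> CriteriaConfig:
    """The shipped 20-criterion registry (TSB end point at raw weight 3)."""
    text = resources.files("cld4.data").joinpath("criteria.yaml").read_text()
    return CriteriaConfig._from_entries(yaml.safe_load(text)["criteria"])


def normalize_weights(criteria: list[Criterion]) -> pd.Series:
    total = sum(c.raw_weight for c in criteria)
    if total <= 0:
        raise ValueError("all raw weights are zero")
    return pd.Series({c.name: c.raw_weight / total for c in criteria})


class DegenerateCriterionError(ValueError):
    pass


def rate_criterion(values: pd.Series,
                   direction: Literal["max_is_best", "min_is_best"]
                   ) -> pd.Series:
    """Linear best/worst rating of one criterion's raw values.

    The best clone rates 1, the worst 0.  Missing values stay missing.
    Raises DegenerateCriterionError when all observed values coincide.
    """
    obs = values.dropna()
    if len(obs) < 2:
        raise ValueError("need at least two clones with observed values")
    lo, hi = float(obs.min()), float(obs.max())
    if hi == lo:
        raise DegenerateCriterionError(
            f"criterion values are all equal ({lo}); rating undefined")
    if direction == "max_is_best":
        return (values - lo) / (hi - lo)
    return (hi - values) / (hi - lo)


@dataclass
class MICLResult:
    scores: pd.Series                 # MI_CL per clone, descending-rankable
    ratings: pd.DataFrame             # clones x criteria r_ij
    weights: pd.Series                # normalised w_j over included criteria
    ranking: list[str]                # clone ids, best first
    excluded_criteria: list[str] = field(default_factory=list)
    incomplete_clones: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"MI_CL": self.scores})
        out["rank"] = out["MI_CL"].rank(ascending=False, method="first"
                                        ).astype(int)
        out = out.join(self.ratings.add_prefix("r: "))
        return out.loc[self.ranking]


def compute_micl(table: FeatureTable, config: CriteriaConfig | None = None
                 ) -> MICLResult:
    """Rate every criterion, weight, sum and rank."""
    config = config or default_criteria()
    values = table.values
    ratings = {}
    excluded = []
    for crit in config.criteria:
        if crit.feature not in values.columns:
            raise KeyError(f"criterion {crit.name!r} needs missing feature "
                           f"{crit.feature!r}")
        try:
            ratings[crit.name] = rate_criterion(values[crit.feature],
                                                crit.direction)
        except DegenerateCriterionError as exc:
            log.warning("criterion %s excluded: %s", crit.name, exc)
            excluded.append(crit.name)
    if not ratings:
        raise ValueError("no usable criteria after degeneracy exclusion")
    included = [c for c in config.criteria if c.name not in excluded]
    w = normalize_weights(included)
    r = pd.DataFrame(ratings)[w.index]

    # per-clone renormalisation over observed criteria
    obs = r.notna()
    denom = obs.mul(w, axis=1).sum(axis=1)
    scores = r.fillna(0.0).mul(w, axis=1).sum(axis=1) / denom
    incomplete = sorted(r.index[~obs.all(axis=1)])
    if incomplete:
        log.warning("clones with missing criteria (renormalised): %s",
                    incomplete)
    order = sorted(scores.index, key=lambda cid: (-scores[cid], cid))
    return MICLResult(scores=scores, ratings=r, weights=w, ranking=order,
                      excluded_criteria=excluded,
                      incomplete_clones=incomplete)


def select_top(result: MICLResult, n: int) -> list[str]:
    """The n best clones by MI_CL (ties broken by clone id)."""
    if n < 0 or n > len(result.ranking):
        raise ValueError(f"cannot select top {n} of {len(result.ranking)} clones")
    return result.ranking[:n]
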