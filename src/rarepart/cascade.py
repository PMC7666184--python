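"""Species-removal cascade: rank by commonness, delete, re-partition.

The central procedure: rank the species of a community by total abundance,
remove them one at a time — rarest first or commonest first — down to half
of the original richness, re-apply the abundance transform to each reduced
matrix, and re-run the two-block variation partitioning at every step with
the environmental and spatial predictor blocks frozen at their
full-community selection.  The summary statistic of a cascade is

    ΔR² = component(step 0) − component(final step)

for a chosen partition component (default: the total adjusted explained
fraction a + b + c, so a positive ΔR² means removal hurt the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datamodel import CommunityMatrix, RunConfig
from .ordination import (
    HellingerTransformer,
    VarpartResult,
    _as_matrix,
    _Bases,
)

__all__ = [
    "RarityRanking",
    "CascadeTrace",
    "DominanceSummary",
    "RemovalCascade",
    "rank_species",
    "run_cascade",
    "delta_r2",
    "simpson_dominance",
]

DIRECTIONS = ("remove_rare_first", "remove_common_first")
COMPONENTS = ("explained_total", "frac_a", "frac_b", "frac_c", "frac_d")


@dataclass
class RarityRanking:
    """Species ordered rarest → commonest under the chosen criterion."""

    species_ids: list[str]
    criterion: str                       # "total_abundance" | "occupancy"
    tie_breaks: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CascadeTrace:
    direction: str
    steps: list[tuple[int, list[str], VarpartResult]]
    max_steps: int

    def component_path(self, component: str = "explained_total") -> np.ndarray:
        return np.array([res.component(component) for _, _, res in self.steps])

    @property
    def reference(self) -> VarpartResult:
        return self.steps[0][2]

    @property
    def final(self) -> VarpartResult:
        return self.steps[-1][2]


@dataclass
class DominanceSummary:
    simpson: float
    rank_abundance: np.ndarray


def rank_species(Y: CommunityMatrix, criterion: str = "total_abundance") -> RarityRanking:
    """Rank species from rarest to commonest.

    The default criterion is total abundance (column sums); ties are broken
    by occupancy (number of occupied sites), then by species label, so the
    ranking is deterministic.  ``criterion="occupancy"`` swaps the first two
    keys.
    """
    if criterion not in ("total_abundance", "occupancy"):
        raise ValueError(f"unknown rarity criterion: {criterion!r}")
    if Y.n_species < 2:
        raise ValueError("ranking needs at least 2 species")
    totals = Y.values.sum(axis=0)
    occupancy = (Y.values > 0).sum(axis=0)
    if criterion == "total_abundance":
        keys = list(zip(totals, occupancy, Y.species_ids))
    else:
        keys = list(zip(occupancy, totals, Y.species_ids))
    order = sorted(range(Y.n_species), key=lambda j: keys[j])
    ties = []
    for a, b in zip(order[:-1], order[1:]):
        if keys[a][0] == keys[b][0]:
            ties.append((Y.species_ids[a], Y.species_ids[b]))
    return RarityRanking(
        species_ids=[Y.species_ids[j] for j in order],
        criterion=criterion,
        tie_breaks=ties,
    )


def _centered_transform(values: np.ndarray, transformer: HellingerTransformer) -> np.ndarray:
    out = transformer.fit(values).transform(values)
    # re-centre exactly as varpart2 does, so step 0 is bitwise identical to a
    # standalone partition of the full community
    return out - out.mean(axis=0, keepdims=True)


def run_cascade(
    Y: CommunityMatrix,
    X,
    W,
    direction: str = "remove_rare_first",
    config: RunConfig | None = None,
    ranking: RarityRanking | None = None,
) -> CascadeTrace:
    """Remove species step by step and re-run the partition at each step.

    Step 0 is the full community; step s removes the first s species of the
    rarity ranking (``remove_rare_first``) or of its reversal
    (``remove_common_first``).  The transform is re-applied to every reduced
    matrix (site totals change), while the predictor blocks X and W stay
    frozen at their full-community selection.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    config = config or RunConfig()
    if ranking is None:
        ranking = rank_species(Y)
    order = list(ranking.species_ids)
    if direction == "remove_common_first":
        order = order[::-1]
    max_steps = int(np.floor(config.removal_fraction * Y.n_species))
    if max_steps < 1:
        raise ValueError("removal_fraction removes no species for this richness")

    bases = _Bases(_as_matrix(X), _as_matrix(W))
    transformer = HellingerTransformer(mode=config.transform)
    col = {s: j for j, s in enumerate(Y.species_ids)}

    steps: list[tuple[int, list[str], VarpartResult]] = []
    for s in range(max_steps + 1):
        removed = order[:s]
        keep = [j for j in range(Y.n_species) if Y.species_ids[j] not in set(removed)]
        vals = Y.values[:, keep]
        if config.transform == "hellinger" and np.all(vals.sum(axis=1) == 0):
            raise ValueError(f"all site totals zero at step {s} under hellinger")
        Yc = _centered_transform(vals, transformer)
        try:
            res = bases.varpart(Yc)
        except ValueError as exc:
            raise ValueError(f"variation partitioning failed at step {s}: {exc}") from exc
        steps.append((s, removed, res))
    return CascadeTrace(direction=direction, steps=steps, max_steps=max_steps)


def delta_r2(trace: CascadeTrace, component: str = "explained_total") -> float:
    """ΔR² of a cascade: component at step 0 minus component at the last step.

    ``component="explained_total"`` (default) is positive when removal
    reduced the explained fraction; ``component="frac_d"`` gives the literal
    before-minus-after residual difference (opposite sign).
    """
    if component not in COMPONENTS:
        raise KeyError(f"component must be one of {COMPONENTS}")
    if len(trace.steps) != trace.max_steps + 1:
        raise ValueError("incomplete cascade trace")
    return float(trace.reference.component(component) - trace.final.component(component))


def simpson_dominance(Y: CommunityMatrix | np.ndarray) -> DominanceSummary:
    """Simpson dominance λ = Σ pᵢ² over species relative total abundances.

    λ is the probability that two randomly drawn individuals are
    conspecific: 1/S for a perfectly even community of S species, 1 under
    single-species dominance.
    """
    values = Y.values if isinstance(Y, CommunityMatrix) else np.asarray(Y, dtype=float)
    totals = values.sum(axis=0)
    N = totals.sum()
    if N <= 0:
        raise ValueError("all-zero community matrix")
    p = totals / N
    return DominanceSummary(
        simpson=float(np.sum(p * p)),
        rank_abundance=np.sort(totals)[::-1],
    )


class RemovalCascade(BaseEstimator):
    """Removal-cascade analysis as an estimator.

    Parameters
    ----------
    direction : {"remove_rare_first", "remove_common_first"}
    component : str
        Partition component used for the ΔR² summary.
    criterion : {"total_abundance", "occupancy"}
        Rarity ranking criterion.
    config : RunConfig, optional

    Attributes
    ----------
    trace_ : CascadeTrace
    delta_r2_ : float
    ranking_ : RarityRanking
    """

    def __init__(
        self,
        direction: str = "remove_rare_first",
        component: str = "explained_total",
        criterion: str = "total_abundance",
        config: RunConfig | None = None,
    ):
        self.direction = direction
        self.component = component
        self.criterion = criterion
        self.config = config

    def fit(self, Y: CommunityMatrix, env, space):
        config = self.config or RunConfig()
        self.ranking_ = rank_species(Y, criterion=self.criterion)
        self.trace_ = run_cascade(
            Y, env, space, direction=self.direction, config=config, ranking=self.ranking_
        )
        self.delta_r2_ = delta_r2(self.trace_, component=self.component)
        return self

    def score(self, *args) -> float:
        check_is_fitted(self)
        return self.delta_r2_
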