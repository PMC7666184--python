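"""Stratified random-removal null model for the cascade ΔR² statistic.

The observed ΔR² from an ordered removal cascade is compared against the
distribution of ΔR² under *random* species removal that preserves the
community's relative-abundance structure: species are binned into abundance
strata (quantiles of log10(total + 1)), each null replicate optionally draws
a stratified subsample of the community, and then removes half of the
species with proportional allocation across strata (largest-remainder
rounding, uniform within stratum).  Repeating this ``nrep`` times yields the
null distribution; the permutation p-value uses the add-one convention
p = (1 + #{at least as extreme}) / (nrep + 1), so 999 repetitions bound p
below by 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datamodel import CommunityMatrix, RunConfig
from .ordination import HellingerTransformer, _as_matrix, _Bases

__all__ = [
    "StratifiedSubsample",
    "NullDistribution",
    "StratifiedNullModel",
    "stratified_subsample",
    "null_distribution",
    "p_value",
]


@dataclass
class StratifiedSubsample:
    species_ids: list[str]
    strata_bounds: np.ndarray
    per_stratum_counts: list[int]


@dataclass
class NullDistribution:
    deltas: np.ndarray
    observed: float
    p_value: float
    nrep: int
    seed: int
    component: str
    tail: str
    subsample_fraction: float = 1.0
    n_strata: int = 4


def _strata(totals: np.ndarray, n_strata: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign each species to an abundance stratum.

    Strata are quantile bins of log10(total + 1); degenerate (empty) bins
    collapse, so every returned stratum is non-empty.
    """
    logt = np.log10(totals + 1.0)
    qs = np.quantile(logt, np.linspace(0, 1, n_strata + 1))
    bounds = np.unique(qs)
    # assign by right-closed bins; clip into [0, n_bins-1]
    idx = np.searchsorted(bounds, logt, side="right") - 1
    idx = np.clip(idx, 0, len(bounds) - 2) if len(bounds) > 1 else np.zeros_like(idx, dtype=int)
    # re-label strata consecutively in abundance order
    labels = np.unique(idx)
    remap = {lab: i for i, lab in enumerate(labels)}
    return np.array([remap[i] for i in idx]), qs


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    if short > 0:
        frac = exact - base
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


def stratified_subsample(
    Y: CommunityMatrix,
    n_strata: int = 4,
    seed: int = 0,
    size: int | None = None,
) -> StratifiedSubsample:
    """Draw a species subsample preserving the abundance-stratum mix.

    Species are stratified on log10(total abundance + 1) quantiles; ``size``
    species (default: all of them) are allocated proportionally across
    strata with largest-remainder rounding and drawn uniformly without
    replacement within each stratum.  Deterministic given ``seed``.
    """
    S = Y.n_species
    if S < 2 * n_strata:
        raise ValueError(f"richness {S} too small for {n_strata} strata")
    totals = Y.values.sum(axis=0)
    strat, bounds = _strata(totals, n_strata)
    if size is None:
        size = S
    if not 1 <= size <= S:
        raise ValueError("subsample size out of range")
    rng = np.random.default_rng(seed)
    counts = np.bincount(strat)
    alloc = _largest_remainder(counts.astype(float), size)
    alloc = np.minimum(alloc, counts)
    # top up if capping left the draw short
    deficit = size - alloc.sum()
    while deficit > 0:
        room = counts - alloc
        j = int(np.argmax(room))
        take = min(deficit, room[j])
        alloc[j] += take
        deficit -= take
    chosen: list[int] = []
    for h in range(len(counts)):
        members = np.flatnonzero(strat == h)
        pick = rng.choice(members, size=alloc[h], replace=False)
        chosen.extend(pick.tolist())
    chosen.sort()
    return StratifiedSubsample(
        species_ids=[Y.species_ids[j] for j in chosen],
        strata_bounds=bounds,
        per_stratum_counts=alloc.tolist(),
    )


def p_value(observed: float, deltas: np.ndarray, tail: str = "two_sided") -> float:
    """Add-one permutation p-value of ``observed`` against null ``deltas``."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty null distribution")
    nrep = deltas.size
    if tail == "two_sided":
        count = int(np.sum(np.abs(deltas) >= abs(observed)))
    elif tail == "upper":
        count = int(np.sum(deltas >= observed))
    elif tail == "lower":
        count = int(np.sum(deltas <= observed))
    else:
        raise ValueError(f"unknown tail: {tail!r}")
    return (1 + count) / (nrep + 1)


def null_distribution(
    Y: CommunityMatrix,
    X,
    W,
    config: RunConfig | None = None,
    observed: float | None = None,
    component: str = "explained_total",
    subsample_fraction: float = 1.0,
) -> NullDistribution:
    """Null ΔR² distribution under stratified random species removal.

    Per replicate: draw a stratified species subsample (default: the full
    community), compute its reference partition, remove half of its species
    at random with proportional allocation across abundance strata,
    re-partition, and record the ΔR² of the configured component.  Replicate
    r uses an RNG stream derived from ``(seed, r)``, so the distribution is
    reproducible and insensitive to replicate order.  A replicate whose
    reduced matrix is degenerate is redrawn (at most 10 times).
    """
    config = config or RunConfig()
    n_strata = config.null_nstrata
    S = Y.n_species
    if S < 2 * n_strata:
        raise ValueError(f"richness {S} too small for {n_strata} strata")
    totals = Y.values.sum(axis=0)
    strat, _ = _strata(totals, n_strata)
    counts = np.bincount(strat)
    sub_size = S if subsample_fraction >= 1.0 else max(2 * n_strata, int(round(subsample_fraction * S)))

    bases = _Bases(_as_matrix(X), _as_matrix(W))
    transformer = HellingerTransformer(mode=config.transform)

    def _partition(col_idx: np.ndarray) -> float:
        vals = Y.values[:, col_idx]
        Yc = transformer.fit(vals).transform(vals)
        Yc = Yc - Yc.mean(axis=0, keepdims=True)
        return bases.varpart(Yc).component(component)

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.null_nrep)
    # with no subsampling the "before" partition is the same in every replicate
    before_full = _partition(np.arange(S)) if sub_size == S else None
    deltas = np.empty(config.null_nrep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(config.null_nrep):
            rng = np.random.default_rng(child_seeds[r])
            for attempt in range(11):
                try:
                    # stratified subsample of the community
                    if sub_size == S:
                        sub = np.arange(S)
                    else:
                        alloc = _largest_remainder(counts.astype(float), sub_size)
                        alloc = np.minimum(alloc, counts)
                        sub_list: list[int] = []
                        for h in range(len(counts)):
                            members = np.flatnonzero(strat == h)
                            sub_list.extend(
                                rng.choice(members, size=alloc[h], replace=False).tolist()
                            )
                        sub = np.sort(np.array(sub_list, dtype=int))
                    # stratified random removal of half the subsample
                    n_remove = int(np.floor(config.removal_fraction * sub.size))
                    sub_strat = strat[sub]
                    sub_counts = np.bincount(sub_strat, minlength=len(counts)).astype(float)
                    rm_alloc = _largest_remainder(
                        np.where(sub_counts > 0, sub_counts, 0.0), n_remove
                    )
                    rm_alloc = np.minimum(rm_alloc, sub_counts.astype(int))
                    removed: list[int] = []
                    for h in range(len(counts)):
                        members = sub[sub_strat == h]
                        if rm_alloc[h] > 0:
                            removed.extend(
                                rng.choice(members, size=rm_alloc[h], replace=False).tolist()
                            )
                    keep = np.setdiff1d(sub, np.array(removed, dtype=int))
                    before = before_full if sub.size == S else _partition(sub)
                    after = _partition(keep)
                    deltas[r] = before - after
                    break
                except ValueError:
                    if attempt == 10:
                        raise ValueError(
                            f"null replicate {r} degenerate after 10 redraws"
                        )
    if observed is None:
        p = float("nan")
    else:
        p = p_value(observed, deltas, tail=config.tail)
    return NullDistribution(
        deltas=deltas,
        observed=float("nan") if observed is None else float(observed),
        p_value=p,
        nrep=config.null_nrep,
        seed=config.seed,
        component=component,
        tail=config.tail,
        subsample_fraction=subsample_fraction,
        n_strata=n_strata,
    )


class StratifiedNullModel(BaseEstimator):
    """Null-model significance test for a removal cascade.

    ``fit(Y, env, space)`` runs the ordered cascade in the configured
    direction to obtain the observed ΔR², generates the stratified
    random-removal null distribution, and stores the permutation p-value.

    Attributes
    ----------
    observed_ : float
    null_ : NullDistribution
    p_value_ : float
    """

    def __init__(
        self,
        direction: str = "remove_rare_first",
        component: str = "explained_total",
        config: RunConfig | None = None,
        subsample_fraction: float = 1.0,
    ):
        self.direction = direction
        self.component = component
        self.config = config
        self.subsample_fraction = subsample_fraction

    def fit(self, Y: CommunityMatrix, env, space):
        from .cascade import RemovalCascade

        config = self.config or RunConfig()
        cascade = RemovalCascade(
            direction=self.direction, component=self.component, config=config
        ).fit(Y, env, space)
        self.trace_ = cascade.trace_
        self.observed_ = cascade.delta_r2_
        self.null_ = null_distribution(
            Y,
            env,
            space,
            config=config,
            observed=self.observed_,
            component=self.component,
            subsample_fraction=self.subsample_fraction,
        )
        self.p_value_ = self.null_.p_value
        return self

    def score(self, *args) -> float:
        check_is_fitted(self)
        return self.p_value_
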