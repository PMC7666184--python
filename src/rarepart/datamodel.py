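"""Tabular data types, CSV readers/writers, and run configuration.

All stages of the pipeline operate on three aligned tables: a site x species
abundance matrix (the community), a site x variable environmental matrix, and
site coordinates.  Each is a thin, validated wrapper around a numpy array
with ordered string labels; files are plain CSV (header row of column labels,
first column of site labels, "." decimal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rarepart")

__all__ = [
    "CommunityMatrix",
    "EnvMatrix",
    "SiteCoordinates",
    "RunConfig",
    "read_matrix",
    "align_sites",
    "write_trace",
    "read_trace",
]


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x).strip() for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return labels


@dataclass
class CommunityMatrix:
    """Site x species abundance table (non-negative reals, counts allowed)."""

    site_ids: list[str]
    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = _check_labels(self.site_ids, "site")
        self.species_ids = _check_labels(self.species_ids, "species")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError("values shape does not match labels")
        if self.n_sites < 3:
            raise ValueError("a community matrix needs at least 3 sites")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("community matrix contains missing or non-finite cells")
        if np.any(self.values < 0):
            raise ValueError("negative abundance in community matrix")
        if np.any(self.values.sum(axis=1) == 0):
            # Empty sites are not an error at construction, but most analyses
            # (Hellinger transform in particular) warn or fail on them.
            warnings.warn("community matrix has sites with zero total abundance")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.species_ids)

    def drop_species(self, species: Iterable[str]) -> "CommunityMatrix":
        drop = set(species)
        unknown = drop - set(self.species_ids)
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        keep = [j for j, s in enumerate(self.species_ids) if s not in drop]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return CommunityMatrix(
                list(self.site_ids),
                [self.species_ids[j] for j in keep],
                self.values[:, keep],
            )


@dataclass
class EnvMatrix:
    """Site x environmental-variable table; variables may mix units freely."""

    site_ids: list[str]
    var_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = _check_labels(self.site_ids, "site")
        self.var_ids = _check_labels(self.var_ids, "variable")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.var_ids)):
            raise ValueError("values shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "environmental matrix contains missing or non-finite cells; "
                "imputation is not performed — clean the input instead"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_vars(self) -> int:
        return len(self.var_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.var_ids)


@dataclass
class SiteCoordinates:
    """Per-site positions, either planar x/y or longitude/latitude degrees."""

    site_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    crs_mode: str = "planar"  # "planar" | "lonlat"

    def __post_init__(self) -> None:
        self.site_ids = _check_labels(self.site_ids, "site")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.crs_mode not in ("planar", "lonlat"):
            raise ValueError(f"unknown crs_mode: {self.crs_mode!r}")
        if self.x.shape != (len(self.site_ids),) or self.y.shape != (len(self.site_ids),):
            raise ValueError("coordinate arrays do not match site labels")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite coordinates")
        pts = np.column_stack([self.x, self.y])
        _, counts = np.unique(pts, axis=0, return_counts=True)
        if np.any(counts > 1):
            raise ValueError(
                "coincident sites in coordinates; spatial eigenvectors require "
                "distinct positions (no jitter is applied)"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y}, index=self.site_ids
        )


_TRANSFORMS = ("hellinger", "presence_absence", "none")
_TAILS = ("two_sided", "lower", "upper")


@dataclass
class RunConfig:
    """All tunable constants of the analysis chain in one place.

    Defaults follow the standard workflow: CV screening window [40, 80] %,
    PCA retention of >= 90 % variance, forward selection at alpha = 0.05 with
    999 permutations, species removal down to 50 % of the original richness,
    and 999 null-model repetitions.
    """

    seed: int = 0
    transform: str = "hellinger"
    cv_low: float = 40.0
    cv_high: float = 80.0
    pca_threshold: float = 0.90
    forward_alpha: float = 0.05
    forward_nperm: int = 999
    removal_fraction: float = 0.50
    null_nrep: int = 999
    null_nstrata: int = 4
    tail: str = "two_sided"

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"transform must be one of {_TRANSFORMS}")
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}")
        if not 0 < self.pca_threshold <= 1:
            raise ValueError("pca_threshold must be in (0, 1]")
        if not 0 < self.removal_fraction <= 1:
            raise ValueError("removal_fraction must be in (0, 1]")
        if self.removal_fraction > 0.5:
            warnings.warn(
                "removal_fraction > 0.5 removes more than half the community; "
                "the standard design stops at 50% of richness"
            )
        if self.null_nrep < 19:
            raise ValueError("null_nrep must be >= 19")
        if self.forward_nperm < 19:
            raise ValueError("forward_nperm must be >= 19")
        if not 0 < self.forward_alpha <= 1:
            raise ValueError("forward_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def read_matrix(path: str | Path, kind: str):
    """Read a labelled CSV table as one of the three matrix kinds.

    ``kind`` is one of ``"community"``, ``"env"``, ``"coords"``.  The file
    must have a header row of column labels and a first column of site
    labels; every data cell must parse as a number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.index.isna().any():
        raise ValueError("missing site label")
    try:
        values = df.to_numpy(dtype=str).astype(float) if df.size else np.empty((len(df), 0))
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
    site_ids = [str(s) for s in df.index]
    col_ids = [str(c) for c in df.columns]
    if kind == "community":
        return CommunityMatrix(site_ids, col_ids, values)
    if kind == "env":
        return EnvMatrix(site_ids, col_ids, values)
    if kind == "coords":
        cols = {c.lower(): i for i, c in enumerate(col_ids)}
        if "x" in cols and "y" in cols:
            mode = "planar"
            xi, yi = cols["x"], cols["y"]
        elif ("lon" in cols or "longitude" in cols) and ("lat" in cols or "latitude" in cols):
            mode = "lonlat"
            xi = cols.get("lon", cols.get("longitude"))
            yi = cols.get("lat", cols.get("latitude"))
        else:
            raise ValueError(
                "coordinate file needs columns x/y (planar) or lon/lat (geographic)"
            )
        return SiteCoordinates(site_ids, values[:, xi], values[:, yi], crs_mode=mode)
    raise ValueError(f"unknown matrix kind: {kind!r}")


def write_matrix(obj, path: str | Path) -> None:
    """Write any of the three table kinds back to CSV (full precision)."""
    df = obj.to_dataframe()
    df.index.name = "site"
    df.to_csv(path, float_format="%.17g")


def align_sites(
    community: CommunityMatrix, env: EnvMatrix, coords: SiteCoordinates
) -> tuple[CommunityMatrix, EnvMatrix, SiteCoordinates]:
    """Inner-join the three tables on site labels; the community's order wins.

    Labels present in only some tables are dropped (and logged).  Fewer than
    three shared sites is an error.
    """
    env_pos = {s: i for i, s in enumerate(env.site_ids)}
    coo_pos = {s: i for i, s in enumerate(coords.site_ids)}
    shared = [s for s in community.site_ids if s in env_pos and s in coo_pos]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared site labels across tables; need >= 3"
        )
    for name, table in (("community", community.site_ids),
                        ("env", env.site_ids),
                        ("coords", coords.site_ids)):
        dropped = sorted(set(table) - set(shared))
        if dropped:
            logger.info("align_sites: dropped from %s: %s", name, ", ".join(dropped))
    keep_c = [i for i, s in enumerate(community.site_ids) if s in env_pos and s in coo_pos]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        community2 = CommunityMatrix(
            shared, list(community.species_ids), community.values[keep_c]
        )
    env2 = EnvMatrix(
        shared, list(env.var_ids), env.values[[env_pos[s] for s in shared]]
    )
    coords2 = SiteCoordinates(
        shared,
        coords.x[[coo_pos[s] for s in shared]],
        coords.y[[coo_pos[s] for s in shared]],
        crs_mode=coords.crs_mode,
    )
    return community2, env2, coords2


_TRACE_COLUMNS = [
    "step",
    "direction",
    "species_removed",
    "frac_env_adj",
    "frac_space_adj",
    "frac_shared_adj",
    "frac_resid_adj",
    "r2_total_adj",
]


def write_trace(trace, path: str | Path) -> None:
    """Serialize a removal-cascade trace as CSV, one row per step.

    ``species_removed`` holds the species deleted at that step (empty at
    step 0).  Numeric fields are printed with enough digits to round-trip.
    """
    rows = []
    prev: list[str] = []
    for step_index, removed, result in trace.steps:
        new = [s for s in removed if s not in prev]
        rows.append(
            {
                "step": step_index,
                "direction": trace.direction,
                "species_removed": ";".join(new),
                "frac_env_adj": result.frac_a,
                "frac_space_adj": result.frac_c,
                "frac_shared_adj": result.frac_b,
                "frac_resid_adj": result.frac_d,
                "r2_total_adj": 1.0 - result.frac_d,
            }
        )
        prev = list(removed)
    df = pd.DataFrame(rows, columns=_TRACE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str | Path) -> pd.DataFrame:
    """Read a trace CSV back as a DataFrame with the canonical column order."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    return df[_TRACE_COLUMNS]
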