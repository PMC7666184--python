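"""Synthetic metacommunities with known environmental/spatial structure.

Every downstream stage — screening, selection, PCNM, partitioning, cascade,
null model — is exercisable against generated data with a known ground
truth.  The generator emulates the sampling design of a tropical stream
metacommunity study: on the order of a hundred sites, several dozen species
with a strongly right-skewed (lognormal) abundance distribution, a large
battery of partially correlated habitat variables built from a few latent
gradients, and spatially autocorrelated site positions and processes.

Model
-----
* Sites are uniform in the unit square, or clustered (Thomas-like process:
  Poisson parents with Gaussian offspring).
* Latent environmental gradients are Gaussian-kernel random fields over the
  sites, mixed with white noise according to ``spatial_share``; observed
  variables are noisy linear mixtures of the gradients, rescaled to
  heterogeneous means and spreads so that CV screening has real work to do.
* Species are env-driven (Gaussian niche response on the latent gradients),
  space-driven (their log-intensity is an independent spatial field), or
  pure noise.  Expected abundance of an env-driven species i at site s is

      mu_is = A_i * exp( - sum_g (z_gs - o_ig)^2 / (2 b_ig^2) )

  with maximum abundance A_i lognormal across species (sigma controls how
  dominated the community is), optimum o_ig and niche breadth b_ig.
* Counts are Poisson (default) or negative binomial (overdispersed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CommunityMatrix, EnvMatrix, SiteCoordinates

__all__ = [
    "SimulationTruth",
    "generate_sites",
    "generate_env",
    "generate_community",
    "simulate_metacommunity",
]

# fixed offsets deriving per-component RNG streams from one master seed
_SITE_STREAM, _ENV_STREAM, _COMM_STREAM, _TRUTH_STREAM = 11, 23, 37, 53


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a generated community."""

    species_optima: np.ndarray        # n_species x n_gradients
    niche_breadths: np.ndarray        # n_species x n_gradients, > 0
    max_abundances: np.ndarray        # n_species, lognormal(mu_logN, sigma_logN)
    env_loadings: np.ndarray          # per species: 1 env-driven, 0 otherwise
    space_loadings: np.ndarray        # per species: 1 space-driven, 0 otherwise
    spatial_range: float = 0.25       # autocorrelation range of spatial fields
    noise_model: str = "poisson"      # "poisson" | "negbin"
    negbin_k: float = 2.0             # negbin dispersion (smaller = noisier)
    mu_logN: float = 2.5
    sigma_logN: float = 1.5

    def __post_init__(self) -> None:
        if np.any(self.niche_breadths <= 0):
            raise ValueError("niche breadths must be positive")
        if np.any(self.max_abundances <= 0):
            raise ValueError("max abundances must be positive")
        both = self.env_loadings.astype(bool) & self.space_loadings.astype(bool)
        if np.any(both):
            raise ValueError("a species is either env-driven or space-driven, not both")
        if self.noise_model not in ("poisson", "negbin"):
            raise ValueError(f"unknown noise model: {self.noise_model!r}")

    @property
    def n_species(self) -> int:
        return self.max_abundances.size

    @property
    def n_gradients(self) -> int:
        return self.species_optima.shape[1]


def generate_sites(n_sites: int, seed: int = 0, clustered: bool = False) -> SiteCoordinates:
    """Planar site positions in the unit square.

    ``clustered=True`` uses a Thomas-like process: ~n/10 uniform parents,
    Gaussian offspring (sd 0.05) folded back into the square.  Coordinates
    are guaranteed distinct.
    """
    if n_sites < 10:
        raise ValueError("need at least 10 sites")
    rng = _rng(seed, _SITE_STREAM)
    if clustered:
        n_parents = max(3, n_sites // 10)
        parents = rng.uniform(0, 1, size=(n_parents, 2))
        assign = rng.integers(0, n_parents, size=n_sites)
        pts = parents[assign] + rng.normal(0, 0.05, size=(n_sites, 2))
        pts = np.abs(pts) % 2.0
        pts = np.where(pts > 1.0, 2.0 - pts, pts)  # reflect into [0, 1]
    else:
        pts = rng.uniform(0, 1, size=(n_sites, 2))
    # nudge exact duplicates apart (vanishingly rare with float64 uniforms)
    while len(np.unique(pts, axis=0)) < n_sites:
        pts += rng.normal(0, 1e-9, size=pts.shape)
    labels = [f"s{i + 1:03d}" for i in range(n_sites)]
    return SiteCoordinates(labels, pts[:, 0], pts[:, 1], crs_mode="planar")


def _spatial_field(
    coords: SiteCoordinates, rng: np.random.Generator, length_scale: float, n_fields: int = 1
) -> np.ndarray:
    """Standardized Gaussian-kernel random fields over the sites."""
    pts = np.column_stack([coords.x, coords.y])
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    K = np.exp(-d2 / (2.0 * length_scale**2)) + 1e-8 * np.eye(len(pts))
    L = np.linalg.cholesky(K)
    z = L @ rng.standard_normal((len(pts), n_fields))
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    return z


def generate_env(
    coords: SiteCoordinates,
    n_vars: int = 90,
    n_latent: int = 6,
    spatial_share: float = 0.5,
    seed: int = 0,
    length_scale: float = 0.25,
) -> tuple[EnvMatrix, np.ndarray]:
    """Correlated environmental battery from a few latent gradients.

    Each latent gradient is a mixture of a spatially autocorrelated field
    and white noise (weights sqrt(spatial_share) / sqrt(1 − spatial_share)).
    Observed variables are sparse linear mixtures of the gradients plus
    independent noise, then shifted/scaled to heterogeneous positive means
    so the battery spans the whole CV range.

    Returns the observed :class:`EnvMatrix` and the ``n_sites x n_latent``
    latent gradient matrix (the ground truth used by the community model).
    """
    if not 1 <= n_latent <= n_vars:
        raise ValueError("need n_vars >= n_latent >= 1")
    if not 0.0 <= spatial_share <= 1.0:
        raise ValueError("spatial_share must be in [0, 1]")
    rng = _rng(seed, _ENV_STREAM)
    n = coords.n_sites
    white = rng.standard_normal((n, n_latent))
    white = (white - white.mean(axis=0)) / white.std(axis=0)
    if spatial_share > 0:
        spat = _spatial_field(coords, rng, length_scale, n_latent)
        latent = np.sqrt(spatial_share) * spat + np.sqrt(1 - spatial_share) * white
    else:
        latent = white
    latent = (latent - latent.mean(axis=0)) / latent.std(axis=0)

    loadings = rng.normal(0, 1, size=(n_latent, n_vars))
    # make each variable load mostly on one gradient (block structure)
    main = rng.integers(0, n_latent, size=n_vars)
    loadings *= 0.3
    loadings[main, np.arange(n_vars)] = rng.normal(0, 1, size=n_vars) + np.sign(
        rng.standard_normal(n_vars)
    )
    obs = latent @ loadings + 0.5 * rng.standard_normal((n, n_vars))
    obs = (obs - obs.mean(axis=0)) / obs.std(axis=0)
    # heterogeneous units: sd spread over decades, mean set so that the
    # CV = 100*sd/mean distribution straddles the screening window
    sd = 10.0 ** rng.uniform(-1, 2, size=n_vars)
    target_cv = 10.0 ** rng.uniform(0.5, 2.5, size=n_vars)  # ~3 .. ~300 %
    mean = 100.0 * sd / target_cv
    obs = obs * sd + mean
    var_ids = [f"env{j + 1:03d}" for j in range(n_vars)]
    return EnvMatrix(list(coords.site_ids), var_ids, obs), latent


def default_truth(
    n_species: int,
    n_gradients: int = 2,
    env_fraction: float = 1.0,
    space_fraction: float = 0.0,
    sigma_logN: float = 1.5,
    mu_logN: float = 2.5,
    niche_breadth: float = 1.0,
    noise_model: str = "poisson",
    seed: int = 0,
    common_signal: bool = False,
) -> SimulationTruth:
    """Draw a SimulationTruth for ``n_species`` species.

    ``env_fraction`` and ``space_fraction`` set the shares of env-driven and
    space-driven species (the remainder is pure noise).  With
    ``common_signal=True`` the species' responsiveness is tied to abundance:
    the most abundant species carry the environmental signal and the rarest
    are noise — the configuration in which ordered removal directions
    diverge most strongly.
    """
    if env_fraction + space_fraction > 1.0 + 1e-12:
        raise ValueError("env_fraction + space_fraction must be <= 1")
    rng = _rng(seed, _TRUTH_STREAM)
    optima = rng.uniform(-2, 2, size=(n_species, n_gradients))
    breadths = np.full((n_species, n_gradients), float(niche_breadth)) * rng.uniform(
        0.8, 1.25, size=(n_species, n_gradients)
    )
    maxab = rng.lognormal(mean=mu_logN, sigma=sigma_logN, size=n_species)
    n_env = int(round(env_fraction * n_species))
    n_space = int(round(space_fraction * n_species))
    env_load = np.zeros(n_species)
    space_load = np.zeros(n_species)
    if common_signal:
        order = np.argsort(-maxab)  # commonest first
        env_load[order[:n_env]] = 1.0
        space_load[order[n_env:n_env + n_space]] = 1.0
    else:
        idx = rng.permutation(n_species)
        env_load[idx[:n_env]] = 1.0
        space_load[idx[n_env:n_env + n_space]] = 1.0
    return SimulationTruth(
        species_optima=optima,
        niche_breadths=breadths,
        max_abundances=maxab,
        env_loadings=env_load,
        space_loadings=space_load,
        noise_model=noise_model,
        sigma_logN=sigma_logN,
        mu_logN=mu_logN,
    )


def generate_community(
    coords: SiteCoordinates,
    gradients: np.ndarray,
    truth: SimulationTruth,
    seed: int = 0,
) -> CommunityMatrix:
    """Sample a site x species count matrix from the niche/space model.

    ``gradients`` is the latent gradient matrix returned by
    :func:`generate_env`.  Env-driven species follow Gaussian niche curves
    on the gradients; space-driven species get an independent spatially
    autocorrelated log-intensity; noise species are flat.  Counts come from
    the configured noise model.
    """
    gradients = np.asarray(gradients, dtype=float)
    n = coords.n_sites
    if gradients.shape[0] != n:
        raise ValueError("gradients and coordinates disagree on the number of sites")
    if gradients.shape[1] != truth.n_gradients:
        raise ValueError(
            f"truth expects {truth.n_gradients} gradients, got {gradients.shape[1]}"
        )
    rng = _rng(seed, _COMM_STREAM)
    S = truth.n_species
    log_mu = np.zeros((n, S))
    env_mask = truth.env_loadings.astype(bool)
    if env_mask.any():
        # Gaussian niche response on each gradient, multiplicative across gradients
        diff = gradients[:, None, :] - truth.species_optima[None, env_mask, :]
        expo = -0.5 * np.sum((diff / truth.niche_breadths[None, env_mask, :]) ** 2, axis=2)
        log_mu[:, env_mask] = expo
    space_mask = truth.space_loadings.astype(bool)
    if space_mask.any():
        fields = _spatial_field(coords, rng, truth.spatial_range, int(space_mask.sum()))
        log_mu[:, space_mask] = fields - 1.0  # centred field, damped mean
    mu = truth.max_abundances[None, :] * np.exp(log_mu)
    if truth.noise_model == "poisson":
        counts = rng.poisson(mu)
    else:
        k = truth.negbin_k
        lam = rng.gamma(shape=k, scale=mu / k)
        counts = rng.poisson(lam)
    # drop nothing: all-zero species are legitimate rare species
    species = [f"sp{j + 1:03d}" for j in range(S)]
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return CommunityMatrix(list(coords.site_ids), species, counts.astype(float))


def simulate_metacommunity(
    scenario: str = "mixed",
    n_sites: int = 120,
    n_species: int = 80,
    n_vars: int = 90,
    n_latent: int = 6,
    seed: int = 0,
    sigma_logN: float = 1.5,
    noise_model: str = "poisson",
) -> tuple[CommunityMatrix, EnvMatrix, SiteCoordinates, SimulationTruth, np.ndarray]:
    """One-call scenario generator used by tests, the CLI, and examples.

    Scenarios
    ---------
    ``env_only``      all species env-driven, gradients purely non-spatial
    ``space_only``    all species space-driven
    ``mixed``         60 % env-driven, 20 % space-driven, spatial gradients
    ``exchangeable``  species i.i.d. pure noise with equal expected abundance
    ``common_signal`` lognormal abundances; the commonest half carries the
                      environmental signal, the rarest half is noise

    Returns (community, env, coords, truth, latent_gradients).
    """
    known = ("env_only", "space_only", "mixed", "exchangeable", "common_signal")
    if scenario not in known:
        raise ValueError(f"scenario must be one of {known}")
    clustered = scenario == "mixed"
    coords = generate_sites(n_sites, seed=seed, clustered=clustered)
    spatial_share = {"env_only": 0.0, "space_only": 0.0, "exchangeable": 0.0}.get(scenario, 0.5)
    env, latent = generate_env(
        coords, n_vars=n_vars, n_latent=n_latent, spatial_share=spatial_share, seed=seed
    )
    n_gradients = 2
    if scenario == "env_only":
        truth = default_truth(
            n_species, n_gradients, env_fraction=1.0, space_fraction=0.0,
            sigma_logN=sigma_logN, noise_model=noise_model, seed=seed,
        )
    elif scenario == "space_only":
        truth = default_truth(
            n_species, n_gradients, env_fraction=0.0, space_fraction=1.0,
            sigma_logN=sigma_logN, noise_model=noise_model, seed=seed,
        )
    elif scenario == "mixed":
        truth = default_truth(
            n_species, n_gradients, env_fraction=0.6, space_fraction=0.2,
            sigma_logN=sigma_logN, noise_model=noise_model, seed=seed,
            common_signal=True,
        )
    elif scenario == "exchangeable":
        truth = default_truth(
            n_species, n_gradients, env_fraction=0.0, space_fraction=0.0,
            sigma_logN=0.0, noise_model=noise_model, seed=seed,
        )
    else:  # common_signal
        truth = default_truth(
            n_species, n_gradients, env_fraction=0.5, space_fraction=0.0,
            sigma_logN=sigma_logN, noise_model=noise_model, seed=seed,
            common_signal=True,
        )
    community = generate_community(coords, latent[:, :n_gradients], truth, seed=seed)
    return community, env, coords, truth, latent
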