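"""End-to-end analysis chain: screen → select → PCA → PCNM → partition.

`run_varpart_pipeline` wires the stages together exactly as a practitioner
would: CV-screen the environmental battery, forward-select surviving
variables against the transformed community, compress the selected set with
correlation-matrix PCA (retaining >= 90 % variance), build PCNM spatial
filters from the coordinates and forward-select them, then run the
two-block variation partitioning on the resulting predictor blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CommunityMatrix, EnvMatrix, RunConfig, SiteCoordinates, align_sites
from .ordination import TransformedResponse, VarpartResult, transform_response, varpart2
from .selection import PCAAxes, ScreeningReport, SelectionResult, cv_screen, forward_select, pca_reduce
from .spatial import PCNM, PCNMBasis

__all__ = ["PipelineResult", "run_varpart_pipeline"]


@dataclass
class PipelineResult:
    """All intermediate artefacts of the predictor-building chain."""

    screening: ScreeningReport
    env_selection: SelectionResult
    pca: PCAAxes | None
    pcnm: PCNMBasis
    pcnm_selection: SelectionResult
    env_block: np.ndarray          # n_sites x k PCA axis scores (may be empty)
    space_block: np.ndarray        # n_sites x k selected PCNM vectors (may be empty)
    varpart: VarpartResult
    transformed: TransformedResponse
    config: RunConfig


def run_varpart_pipeline(
    community: CommunityMatrix,
    env: EnvMatrix,
    coords: SiteCoordinates,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full predictor-reduction and partitioning chain."""
    config = config or RunConfig()
    community, env, coords = align_sites(community, env, coords)
    Yt = transform_response(community, mode=config.transform)

    # 1. CV screening of the environmental battery
    screening = cv_screen(env, cv_low=config.cv_low, cv_high=config.cv_high)
    kept_idx = [env.var_ids.index(v) for v in screening.kept]
    env_kept = env.values[:, kept_idx]

    # 2. forward selection of screened variables against the community
    env_selection = forward_select(
        Yt,
        env_kept,
        alpha=config.forward_alpha,
        nperm=config.forward_nperm,
        seed=config.seed,
        labels=screening.kept,
    )
    sel_idx = [screening.kept.index(v) for v in env_selection.order]
    env_selected = env_kept[:, sel_idx]

    # 3. PCA of the selected variables, axes to >= pca_threshold
    if env_selected.shape[1] >= 1:
        pca = pca_reduce(env_selected, threshold=config.pca_threshold)
        env_block = pca.scores
    else:
        pca = None
        env_block = np.empty((community.n_sites, 0))

    # 4. PCNM spatial filters + forward selection
    pcnm_est = PCNM().fit(coords)
    basis = pcnm_est.basis_
    pcnm_labels = [f"V{j + 1}" for j in range(basis.k)]
    pcnm_selection = forward_select(
        Yt,
        basis.vectors,
        alpha=config.forward_alpha,
        nperm=config.forward_nperm,
        seed=config.seed + 1,
        labels=pcnm_labels,
    )
    w_idx = [pcnm_labels.index(v) for v in pcnm_selection.order]
    space_block = basis.vectors[:, w_idx]

    # 5. two-block variation partitioning
    result = varpart2(Yt, env_block, space_block)

    return PipelineResult(
        screening=screening,
        env_selection=env_selection,
        pca=pca,
        pcnm=basis,
        pcnm_selection=pcnm_selection,
        env_block=env_block,
        space_block=space_block,
        varpart=result,
        transformed=Yt,
        config=config,
    )
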