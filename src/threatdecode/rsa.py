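"""Representational similarity of regional decoding contributions.

For region i with decoder weights w_i (the full-circuit decoder restricted
to the region's voxels) and participant n's paired maps, the regional
representation response is

    Y_{n,i} = w_i . (x_{n,i,CS+} - x_{n,i,CS-}) / v_i,

where v_i is the region's voxel count (size normalization). Y > 0 means the
region pushed the decision toward CS+. Correlating the Y columns across
participants for every region pair yields the 24 x 24 similarity matrix R,
embedded into 2-D by classical (Torgerson) MDS of D = 1 - R. Regions whose
participant-mean preference sign is uniform across the scored trial-blocks
form the consistent-CS+ / consistent-CS- communities; sign switches mark a
region as flexible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .conditions import (
    COMMUNITY_CSMINUS,
    COMMUNITY_CSPLUS,
    COMMUNITY_FLEXIBLE,
    ROBUST_CONTRASTS,
    Contrast,
)
from .datasets import BetaMapSet
from .decoding import CVConfig, DecoderModel, fit_decoder
from .masks import extract_features


@dataclass
class RegionalResponseMatrix:
    """Participants x regions contribution scores for one trial-block."""

    Y: np.ndarray
    region_ids: list[int]
    block: str = ""

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if not np.isfinite(self.Y).all():
            raise ValueError("regional responses must be finite")
        if self.Y.shape[1] != len(self.region_ids):
            raise ValueError("region ids do not match Y columns")


@dataclass
class SimilarityMatrix:
    R: np.ndarray
    embedding: np.ndarray
    region_ids: list[int]
    block: str = ""


@dataclass
class CommunityAssignment:
    community: dict[int, str]                 # region id -> community label
    preference_sign: pd.DataFrame             # regions x blocks, entries in {-1, 0, +1}


def regional_response(
    model: DecoderModel,
    dataset: BetaMapSet,
    atlas: RegionAtlas,
    contrast: Contrast,
    region_ids: list[int] | None = None,
) -> RegionalResponseMatrix:
    """Size-normalized per-region decision contributions.

    ``model`` must have been trained on the feature space formed by
    concatenating the listed regions' voxels in order (the layout
    :func:`threatdecode.masks.extract_features` produces for an
    ``(atlas, region_ids)`` selector).
    """
    region_ids = list(region_ids) if region_ids is not None else atlas.region_ids
    features = extract_features(dataset, (atlas, region_ids))
    if model.feature_space_id and features.feature_space_id != model.feature_space_id:
        raise ValueError("model was not trained on this region feature space")
    Xp, Xm = features.pairs(contrast)
    diff = Xp - Xm
    Y = np.empty((dataset.n_participants, len(region_ids)))
    start = 0
    for j, rid in enumerate(region_ids):
        v = atlas.voxel_indices_of(rid).size
        if v == 0:
            raise ValueError(f"region {rid} has no voxels in the feature space")
        sl = slice(start, start + v)
        Y[:, j] = diff[:, sl] @ model.w[sl] / v
        start += v
    return RegionalResponseMatrix(Y, region_ids, block=contrast.label)


def preference_response(
    dataset: BetaMapSet,
    atlas: RegionAtlas,
    contrast: Contrast,
    region_ids: list[int] | None = None,
) -> RegionalResponseMatrix:
    """Size-normalized mean regional activation difference (CS preference).

    P_{n,i} = sum_v (x_{n,i,CS+,v} - x_{n,i,CS-,v}) / v_i. Unlike the
    decoder-weighted response Y, this functional has a fixed orientation, so
    the sign of its participant mean indicates which CS the region activates
    to — the quantity the red/blue predictive-pattern maps display and the
    community assignment is built on. A decoder-weighted score cannot play
    this role: the weights align with the region's own mean difference, so
    w_i . (x+ - x-) is nonnegative in expectation for every region that
    helps the classification, whichever CS it prefers.
    """
    region_ids = list(region_ids) if region_ids is not None else atlas.region_ids
    features = extract_features(dataset, (atlas, region_ids))
    Xp, Xm = features.pairs(contrast)
    diff = Xp - Xm
    P = np.empty((dataset.n_participants, len(region_ids)))
    start = 0
    for j, rid in enumerate(region_ids):
        v = atlas.voxel_indices_of(rid).size
        P[:, j] = diff[:, start:start + v].sum(axis=1) / v
        start += v
    return RegionalResponseMatrix(P, region_ids, block=contrast.label)


def classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson MDS: eigendecomposition of the double-centered squared
    dissimilarities; axes ordered by eigenvalue, negative eigenvalues
    truncated at zero."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1][:n_components]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))


def similarity_and_embedding(Y: RegionalResponseMatrix) -> SimilarityMatrix:
    """Cross-participant Pearson similarity matrix with a 2-D MDS embedding.

    Constant Y columns have undefined correlations; the offending regions
    are dropped with a warning and absent from the result.
    """
    if Y.Y.shape[0] < 3:
        raise ValueError("need at least 3 participants for cross-participant correlation")
    sd = Y.Y.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [rid for rid, k in zip(Y.region_ids, keep) if not k]
        warnings.warn(f"dropping constant-response regions {dropped}", stacklevel=2)
    ids = [rid for rid, k in zip(Y.region_ids, keep) if k]
    R = np.corrcoef(Y.Y[:, keep].T)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    embedding = classical_mds(1.0 - R, n_components=2)
    return SimilarityMatrix(R, embedding, ids, block=Y.block)


def assign_communities(
    responses: dict[str, RegionalResponseMatrix] | list[RegionalResponseMatrix],
) -> CommunityAssignment:
    """Classify regions by their preference sign across scored trial-blocks.

    Preference per (region, block) is the sign of the participant-mean Y.
    All-positive -> consistent CS+; all-negative -> consistent CS-;
    otherwise (including any exact-zero mean) -> flexible.
    """
    if isinstance(responses, dict):
        blocks = list(responses.values())
    else:
        blocks = list(responses)
    if not blocks:
        raise ValueError("no regional responses given")
    ids = blocks[0].region_ids
    for b in blocks[1:]:
        if b.region_ids != ids:
            raise ValueError("all blocks must share one region order")
    signs = pd.DataFrame(
        {b.block: np.sign(b.Y.mean(axis=0)) for b in blocks}, index=ids
    )
    community = {}
    for rid in ids:
        row = signs.loc[rid].to_numpy()
        if np.all(row > 0):
            community[rid] = COMMUNITY_CSPLUS
        elif np.all(row < 0):
            community[rid] = COMMUNITY_CSMINUS
        else:
            community[rid] = COMMUNITY_FLEXIBLE
    return CommunityAssignment(community, signs)


def circuit_rsa(
    dataset: BetaMapSet,
    atlas: RegionAtlas,
    cv: CVConfig,
    contrasts: tuple[Contrast, ...] = ROBUST_CONTRASTS,
    region_ids: list[int] | None = None,
) -> tuple[dict[str, RegionalResponseMatrix], dict[str, SimilarityMatrix], CommunityAssignment]:
    """Full RSA pass over the scored trial-blocks.

    Per block: a decoder trained on the concatenated region feature space,
    its weighted regional responses Y (-> similarity matrix R and 2-D MDS
    embedding), and the fixed-orientation preference responses; the latter
    feed :func:`assign_communities` (see :func:`preference_response` for why
    preference cannot be read off Y's sign).
    """
    region_ids = list(region_ids) if region_ids is not None else atlas.region_ids
    responses: dict[str, RegionalResponseMatrix] = {}
    sims: dict[str, SimilarityMatrix] = {}
    prefs: dict[str, RegionalResponseMatrix] = {}
    for con in contrasts:
        model = fit_decoder(dataset, con, cv, selector=(atlas, region_ids))
        Y = regional_response(model, dataset, atlas, con, region_ids)
        responses[con.label] = Y
        sims[con.label] = similarity_and_embedding(Y)
        prefs[con.label] = preference_response(dataset, atlas, con, region_ids)
    return responses, sims, assign_communities(prefs)
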