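"""Synthetic cohorts with planted, ground-truth-coded threat/safety effects.

The generator emulates what the analysis assumes about real beta maps: for a
voxel v inside region i, under the trial-block contrast b,

    value = baseline + participant_effect_n
            + gain_s * (sign * delta_{i,b} / 2 * profile_v) + offset_s
            + Gaussian noise,

with sign +1 for the CS+ map and -1 for the CS- map, a scalar Gaussian
participant random effect shared by both maps (so forced choice must absorb
it), per-site multiplicative gain and additive offset on the signal, and
unit-Euclidean-norm within-region profiles. The group-mean CS+ - CS-
difference therefore converges to the planted delta as N grows.

Coding profiles assign each region to one of three communities — consistent
CS+, consistent CS-, or flexible (sign switches between phases) — mirroring
the community structure the representational-similarity stage must recover.

:func:`generate_bold_run` additionally produces raw series for the GLM
stage: HRF-convolved task prediction plus drift plus stationary AR(1) noise,
with motion confounds from a bounded random walk and optional spike volumes
that exceed the censoring threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .atlas import RegionAtlas
from .conditions import (
    ALL_CONTRASTS,
    COMMUNITY_CSMINUS,
    COMMUNITY_CSPLUS,
    COMMUNITY_FLEXIBLE,
    CS_PLUS,
    CS_PLUS_E,
    CS_PLUS_U,
    ROBUST_CONTRASTS,
    Condition,
    Contrast,
    all_conditions,
)
from .datasets import BetaMapSet
from .events import EventSchedule
from .glm import BoldRun, ConfoundSet, build_design_matrix


def bayes_forced_choice_accuracy(delta: float, noise_sd: float) -> float:
    """Generative forced-choice ceiling Phi(d/2) with d = sqrt(2) delta / sd.

    With a planted CS+ - CS- difference ``delta`` along a unit-norm profile
    and independent per-map voxel noise, the optimal decoder projects the
    paired difference onto the profile: N(delta, 2 sd^2), so the chance the
    CS+ map scores higher is Phi(delta / (sd sqrt(2))).
    """
    return float(norm.cdf(delta / (noise_sd * np.sqrt(2.0))))


def delta_for_bayes_d(d: float, noise_sd: float = 1.0) -> float:
    """The planted delta whose generative Bayes accuracy is Phi(d/2)."""
    return float(d * noise_sd / np.sqrt(2.0))


# --------------------------------------------------------------------------
# ground-truth coding
# --------------------------------------------------------------------------

def _condition_contrast_map() -> dict[Condition, tuple[Contrast, int]]:
    """Condition -> (its contrast, +-1 sign). Recall CS- maps to the E contrast."""
    out: dict[Condition, tuple[Contrast, int]] = {}
    for con in ALL_CONTRASTS:
        out[con.positive] = (con, +1)
        out.setdefault(con.negative, (con, -1))
    return out


@dataclass
class GroundTruthCoding:
    """Planted per-(region, trial-block) effects and nuisance structure."""

    region_ids: list[int]
    delta: np.ndarray                        # (R, len(ALL_CONTRASTS)), beta units
    profiles: dict[int, np.ndarray]          # region id -> unit-norm voxel weights
    noise_sd: float = 1.0
    participant_sd: float = 0.5
    baseline: float = 0.0
    site_gains: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    site_offsets: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    #: SD of the per-participant, per-community effect-size multiplier
    #: (1 + coupling * g_n,c). Shared within-community variability is what
    #: makes regional responses correlate across participants, i.e. what the
    #: cross-participant similarity analysis detects.
    community_coupling: float = 0.0
    contrasts: tuple[Contrast, ...] = ALL_CONTRASTS

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (len(self.region_ids), len(self.contrasts)):
            raise ValueError("delta must be (n_regions, n_contrasts)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for rid, prof in self.profiles.items():
            if abs(np.linalg.norm(prof) - 1.0) > 1e-8:
                raise ValueError(f"profile of region {rid} is not unit-norm")
        # recall CS- blocks are shared between the E and U contrasts, so their
        # planted deltas must agree for the generative model to be consistent
        for b in (1, 2):
            ie = self.contrasts.index(Contrast("recall", b, CS_PLUS_E))
            iu = self.contrasts.index(Contrast("recall", b, CS_PLUS_U))
            if not np.allclose(self.delta[:, ie], self.delta[:, iu]):
                raise ValueError(
                    f"recall TB{b}: CS+E and CS+U contrasts must share one delta"
                )

    def delta_of(self, contrast: Contrast) -> np.ndarray:
        return self.delta[:, self.contrasts.index(contrast)]

    def communities(self) -> dict[int, str]:
        """Planted community labels from the sign pattern over robust blocks."""
        cols = [self.contrasts.index(c) for c in ROBUST_CONTRASTS]
        out = {}
        for r, rid in enumerate(self.region_ids):
            signs = np.sign(self.delta[r, cols])
            if np.all(signs > 0):
                out[rid] = COMMUNITY_CSPLUS
            elif np.all(signs < 0):
                out[rid] = COMMUNITY_CSMINUS
            else:
                out[rid] = COMMUNITY_FLEXIBLE
        return out


def _make_profiles(atlas: RegionAtlas, seed: int = 0,
                   mean: float = 0.75) -> dict[int, np.ndarray]:
    """Unit-norm within-region voxel profiles with spatial heterogeneity.

    Entries are Gaussian around a positive mean, so most voxels follow the
    region's coding direction while some oppose it — the mixed red/blue
    texture real predictive patterns show. The net orientation is forced
    positive (sign flip if needed) so the region's summed response carries
    its community sign. Heterogeneity matters: a spatially uniform profile
    would make the planted signal collinear with participant-level offset
    maps, and the decoder would have to fight offset noise for exactly the
    direction that carries the signal.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for r in atlas.regions:
        prof = rng.standard_normal(r.size) + mean
        if prof.sum() < 0:
            prof = -prof
        out[r.id] = prof / np.linalg.norm(prof)
    return out


def null_coding(atlas: RegionAtlas, noise_sd: float = 1.0,
                participant_sd: float = 0.5, profile_seed: int = 0,
                **kw) -> GroundTruthCoding:
    """No planted effect anywhere: decoding must sit at chance."""
    delta = np.zeros((len(atlas.regions), len(ALL_CONTRASTS)))
    return GroundTruthCoding(atlas.region_ids, delta,
                             _make_profiles(atlas, profile_seed),
                             noise_sd, participant_sd, **kw)


def uniform_coding(atlas: RegionAtlas, delta: float, noise_sd: float = 1.0,
                   participant_sd: float = 0.5, profile_seed: int = 0,
                   **kw) -> GroundTruthCoding:
    """The same positive effect in every region at every trial-block."""
    d = np.full((len(atlas.regions), len(ALL_CONTRASTS)), float(delta))
    return GroundTruthCoding(atlas.region_ids, d,
                             _make_profiles(atlas, profile_seed),
                             noise_sd, participant_sd, **kw)


def dynamics_coding(atlas: RegionAtlas, delta: float, noise_sd: float = 1.0,
                    participant_sd: float = 0.5, profile_seed: int = 0,
                    **kw) -> GroundTruthCoding:
    """Full-strength conditioning, extinction decaying to zero after TB1,
    recall effects at TB1 only — the qualitative accuracy-vs-trial-block
    shape of the two-day experiment."""
    d = np.zeros((len(atlas.regions), len(ALL_CONTRASTS)))
    for j, con in enumerate(ALL_CONTRASTS):
        if con.phase == "conditioning":
            d[:, j] = delta
        elif con.block == 1:
            d[:, j] = delta
    return GroundTruthCoding(atlas.region_ids, d,
                             _make_profiles(atlas, profile_seed),
                             noise_sd, participant_sd, **kw)


def three_community_coding(
    atlas: RegionAtlas,
    delta: float,
    n_plus: int = 6,
    n_minus: int = 4,
    noise_sd: float = 1.0,
    participant_sd: float = 0.5,
    community_coupling: float = 0.5,
    profile_seed: int = 0,
    **kw,
) -> GroundTruthCoding:
    """Plant three region communities: ``n_plus`` consistently CS+,
    ``n_minus`` consistently CS-, the rest flexible (sign flips between
    phases, in two alternating patterns so flexible regions are not all
    identical). Members of a community share a participant-level effect-size
    factor (``community_coupling``), giving the correlated regional
    responses the similarity analysis groups into communities."""
    n_regions = len(atlas.regions)
    if n_plus + n_minus > n_regions:
        raise ValueError("more community members requested than regions")
    d = np.zeros((n_regions, len(ALL_CONTRASTS)))
    for j, con in enumerate(ALL_CONTRASTS):
        d[:n_plus, j] = delta
        d[n_plus:n_plus + n_minus, j] = -delta
        for r in range(n_plus + n_minus, n_regions):
            flavor = (r - n_plus - n_minus) % 2
            if flavor == 0:   # CS+ during conditioning, CS- afterwards
                d[r, j] = delta if con.phase == "conditioning" else -delta
            else:             # CS- during conditioning, CS+ afterwards
                d[r, j] = -delta if con.phase == "conditioning" else delta
    return GroundTruthCoding(atlas.region_ids, d,
                             _make_profiles(atlas, profile_seed),
                             noise_sd, participant_sd,
                             community_coupling=community_coupling, **kw)


CODING_PROFILES = {
    "null": null_coding,
    "uniform": uniform_coding,
    "dynamics": dynamics_coding,
    "three_community": three_community_coding,
}


# --------------------------------------------------------------------------
# beta-map cohorts
# --------------------------------------------------------------------------

def generate_beta_dataset(
    n_participants: int,
    atlas: RegionAtlas,
    coding: GroundTruthCoding,
    seed: int,
    conditions: tuple[Condition, ...] | None = None,
) -> BetaMapSet:
    """Sample a grid-backed cohort under the planted coding model.

    Participants are assigned round-robin to the coding's sites.
    Deterministic for a fixed seed.
    """
    for rid in coding.region_ids:
        atlas.voxel_indices_of(rid)  # raises if the coding names a missing region
    conditions = tuple(conditions) if conditions is not None else all_conditions()
    rng = np.random.default_rng(seed)
    n_sites = len(coding.site_gains)
    site = np.arange(n_participants) % n_sites
    V = atlas.n_voxels
    C = len(conditions)

    values = rng.standard_normal((n_participants, C, V)) * coding.noise_sd
    values += coding.baseline
    values += rng.standard_normal(n_participants)[:, None, None] * coding.participant_sd
    values += np.asarray(coding.site_offsets)[site][:, None, None]

    cond_map = _condition_contrast_map()
    gains = np.asarray(coding.site_gains)[site]          # (N,)
    communities = coding.communities()
    comm_index = {name: j for j, name in enumerate(sorted(set(communities.values())))}
    factors = np.ones((n_participants, len(comm_index)))
    if coding.community_coupling:
        factors += coding.community_coupling * rng.standard_normal(factors.shape)
    for r, rid in enumerate(coding.region_ids):
        vox = atlas.voxel_indices_of(rid)
        prof = coding.profiles[rid]
        mult = factors[:, comm_index[communities[rid]]]  # (N,)
        for ci, cond in enumerate(conditions):
            contrast, sign = cond_map[cond]
            d = coding.delta[r, coding.contrasts.index(contrast)]
            if d == 0.0:
                continue
            signal = sign * d / 2.0 * prof               # (v_i,)
            values[:, ci, vox] += (gains * mult)[:, None] * signal[None, :]

    participants = [f"sub-{i + 1:04d}" for i in range(n_participants)]
    return BetaMapSet(values, participants, list(conditions),
                      atlas.shape, atlas.affine, site)


def paired_cohort(
    n_participants: int,
    n_voxels: int,
    delta: float,
    seed: int,
    n_signal: int | None = None,
    noise_sd: float = 1.0,
    participant_sd: float = 0.5,
    site_gains=(1.0,),
    site_offsets=(0.0,),
    contrast: Contrast = Contrast("conditioning", 1, CS_PLUS),
) -> BetaMapSet:
    """Abstract (gridless) single-contrast cohort for decoding studies.

    The planted effect of total size ``delta`` spreads over a unit-norm
    profile on the first ``n_signal`` voxels (all voxels by default), so the
    generative forced-choice ceiling is
    :func:`bayes_forced_choice_accuracy`(delta, noise_sd).
    """
    rng = np.random.default_rng(seed)
    k = n_signal if n_signal is not None else n_voxels
    profile = np.zeros(n_voxels)
    profile[:k] = 1.0 / np.sqrt(k)
    site = np.arange(n_participants) % len(site_gains)
    gains = np.asarray(site_gains, float)[site]
    offsets = np.asarray(site_offsets, float)[site]

    conditions = [contrast.positive, contrast.negative]
    values = rng.standard_normal((n_participants, 2, n_voxels)) * noise_sd
    values += rng.standard_normal(n_participants)[:, None, None] * participant_sd
    values += offsets[:, None, None]
    signal = delta / 2.0 * profile
    values[:, 0, :] += gains[:, None] * signal
    values[:, 1, :] -= gains[:, None] * signal
    participants = [f"sub-{i + 1:04d}" for i in range(n_participants)]
    return BetaMapSet(values, participants, conditions, site=site)


# --------------------------------------------------------------------------
# raw BOLD runs
# --------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Noise model for simulated BOLD: stationary AR(1) + drift + motion."""

    ar1_rho: float = 0.4
    sd: float = 1.0
    drift_amplitude: float = 0.0
    motion_step_sd: float = 0.005
    motion_bound: float = 0.5
    spike_volumes: tuple[int, ...] = ()


def generate_bold_run(
    schedule: EventSchedule,
    true_betas: dict[str, np.ndarray],
    tr: float,
    noise: NoiseSpec,
    seed: int,
    n_vols: int | None = None,
    washout_s: float = 20.0,
) -> tuple[BoldRun, ConfoundSet]:
    """Simulate one run: design x true betas + drift + AR(1) noise.

    ``true_betas`` maps task-column labels (trial-block condition labels and
    optionally ``"shock"``) to (V,) maps; omitted columns contribute zero
    signal. Motion is a bounded Gaussian random walk; volumes listed in
    ``noise.spike_volumes`` get a 1.2 mm translation jump, pushing framewise
    displacement past the 0.9 mm censoring threshold.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_vols is None:
        n_vols = int(np.ceil((schedule.duration_s + washout_s) / tr))
    rng = np.random.default_rng(seed)

    V = len(next(iter(true_betas.values()))) if true_betas else 1
    design = build_design_matrix(schedule, None, tr, n_vols)
    B = np.zeros((len(design.names), V))
    for name, beta_map in true_betas.items():
        if name not in design.names:
            raise KeyError(f"unknown task column {name!r}")
        B[design.names.index(name)] = np.asarray(beta_map, float)
    task_cols = [design.names.index(nm) for nm in design.task_names + ["shock"]
                 if nm in design.names]
    series = design.matrix[:, task_cols] @ B[task_cols]

    if noise.drift_amplitude:
        drift = noise.drift_amplitude * np.linspace(-1.0, 1.0, n_vols)
        series = series + drift[:, None]

    if noise.sd > 0:
        innov_sd = noise.sd * np.sqrt(1.0 - noise.ar1_rho**2)
        eps = rng.standard_normal((n_vols, V))
        e = np.empty((n_vols, V))
        e[0] = eps[0] * noise.sd
        for t in range(1, n_vols):
            e[t] = noise.ar1_rho * e[t - 1] + innov_sd * eps[t]
        series = series + e

    steps = rng.standard_normal((n_vols, 6)) * noise.motion_step_sd
    steps[0] = 0.0
    motion = np.clip(np.cumsum(steps, axis=0), -noise.motion_bound, noise.motion_bound)
    for v in noise.spike_volumes:
        motion[v:, 0] += 1.2
    confounds = ConfoundSet.from_motion(motion)
    return BoldRun(series, tr, run_id=f"sim-{schedule.phase}-{seed}"), confounds


def ar1_noise_lag1_autocorr(noise_series: np.ndarray) -> float:
    """Pooled sample lag-1 autocorrelation (diagnostic helper)."""
    x = np.asarray(noise_series, float)
    x = x - x.mean(axis=0)
    return float((x[1:] * x[:-1]).sum() / (x[:-1] ** 2).sum())
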