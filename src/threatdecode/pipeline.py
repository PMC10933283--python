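"""File-based orchestration: simulate -> decode -> interpret -> circuit ->
rsa -> stats, with every stage reading and writing artifacts (NIfTI / TSV /
JSON) in one working directory so real preprocessed data can replace any
stage's input. A manifest records seeds, configuration, and outputs; a fixed
seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionAtlas, generate_synthetic_atlas
from .conditions import ALL_CONTRASTS, PHASES, ROBUST_CONTRASTS
from .datasets import BetaMapSet
from .decoding import CVConfig, apply_decoder, crossvalidate_decoding, fit_decoder
from .events import generate_event_schedule
from .masks import VoxelMask, exclude_with_neighborhood, select_top_voxels
from .patterns import permutation_voxel_significance
from .rsa import circuit_rsa
from .simulate import CODING_PROFILES, generate_beta_dataset
from .stats import binomial_two_sided, fdr_bh, permutation_test_accuracy

log = logging.getLogger("threatdecode")

STAGES = ("simulate", "decode", "interpret", "circuit", "rsa", "stats", "report")


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 0
    out_dir: str = "threatdecode-run"
    n_discovery: int = 40
    n_validation: int = 20
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_circuit_regions: int = 10
    n_extended_regions: int = 14
    coding_profile: str = "three_community"
    effect_delta: float = 1.0
    noise_sd: float = 1.0
    folds: int = 5
    repeats: int = 2
    grid_size: int = 5
    n_perm: int = 199
    n_boot: int = 10
    top_fraction: float = 0.10
    neighborhood_radius_voxels: float = 3.0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        for name, value in (("n_discovery", self.n_discovery),
                            ("n_validation", self.n_validation),
                            ("n_perm", self.n_perm), ("folds", self.folds),
                            ("repeats", self.repeats)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def cv(self) -> CVConfig:
        grid = tuple(np.linspace(0.01, 100.0, self.grid_size)) if self.grid_size > 1 else (1.0,)
        return CVConfig(k=self.folds, repeats=self.repeats, grid=grid, seed=self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _workdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out

def _load_atlas(out: Path) -> RegionAtlas:
    return RegionAtlas.load(out / "atlas.nii.gz", out / "regions.tsv")


def _save_mask(mask: VoxelMask, path: Path) -> None:
    nib.save(nib.Nifti1Image(mask.volume().astype(np.int16), mask.affine), str(path))


def stage_simulate(config: RunConfig) -> None:
    out = _workdir(config)
    atlas = generate_synthetic_atlas(config.grid_shape, config.n_circuit_regions,
                                     config.n_extended_regions, seed=config.seed)
    atlas.save(out / "atlas.nii.gz", out / "regions.tsv")
    for i, phase in enumerate(PHASES):
        generate_event_schedule(phase, seed=config.seed + i).save_events_tsv(
            out / f"events_{phase}.tsv"
        )
    factory = CODING_PROFILES[config.coding_profile]
    kwargs = {} if config.coding_profile == "null" else {"delta": config.effect_delta}
    coding = factory(atlas, noise_sd=config.noise_sd, **kwargs)
    discovery = generate_beta_dataset(config.n_discovery, atlas, coding,
                                      seed=config.seed + 11)
    validation = generate_beta_dataset(config.n_validation, atlas, coding,
                                       seed=config.seed + 12)
    discovery.save_nifti_dir(out / "betas_discovery")
    validation.save_nifti_dir(out / "betas_validation")
    log.info("simulate: %d + %d participants on grid %s",
             config.n_discovery, config.n_validation, config.grid_shape)


def _circuit_selector(atlas: RegionAtlas):
    return (atlas, [r.id for r in atlas.regions_in_set("threat_circuit")])


def _whole_brain_mask(config: RunConfig, atlas: RegionAtlas) -> VoxelMask:
    whole = VoxelMask.from_volume(np.ones(atlas.shape, bool), atlas.affine)
    circuit = VoxelMask.from_regions(
        atlas, [r.id for r in atlas.regions_in_set("threat_circuit")]
    )
    return exclude_with_neighborhood(whole, circuit, config.neighborhood_radius_voxels)


def stage_decode(config: RunConfig) -> None:
    out = _workdir(config)
    atlas = _load_atlas(out)
    discovery = BetaMapSet.load_nifti_dir(out / "betas_discovery")
    validation = BetaMapSet.load_nifti_dir(out / "betas_validation")
    cv = config.cv()
    rows = []
    for name, selector in (
        ("threat_circuit", _circuit_selector(atlas)),
        ("whole_brain_minus_circuit", _whole_brain_mask(config, atlas)),
    ):
        for con in ALL_CONTRASTS:
            res = crossvalidate_decoding(discovery, con, cv, selector=selector)
            model = fit_decoder(discovery, con, cv, selector=selector)
            ext = apply_decoder(model, validation, con, selector=selector)
            rows.append((name, res.block, res.contrast, res.accuracy, res.n,
                         ext.accuracy, ext.n))
            if name == "threat_circuit":
                model.save(out / f"model_{con.label.replace('/', '_')}.json")
    pd.DataFrame(rows, columns=["features", "block", "contrast", "cv_accuracy", "n",
                                "validation_accuracy", "n_validation"]).to_csv(
        out / "accuracy.tsv", sep="\t", index=False
    )
    log.info("decode: %d feature-set x contrast accuracies", len(rows))


def stage_interpret(config: RunConfig) -> None:
    """Whole-brain predictive patterns + permutation voxel significance for
    the robust trial-blocks (these p maps feed the extended-circuit stage)."""
    out = _workdir(config)
    atlas = _load_atlas(out)
    discovery = BetaMapSet.load_nifti_dir(out / "betas_discovery")
    mask = _whole_brain_mask(config, atlas)
    _save_mask(mask, out / "whole_brain_mask.nii.gz")
    mm = mask.mm_coordinates()
    for con in ROBUST_CONTRASTS:
        pat = permutation_voxel_significance(
            discovery, con, c=1.0, n_perm=config.n_perm,
            seed=config.seed + 100, selector=mask,
        )
        stem = con.label.replace("/", "_")
        frame = pd.DataFrame(
            {"voxel_index": mask.indices, "a": pat.a, "z": pat.z,
             "p": pat.p, "q": pat.q}
        )
        frame.to_csv(out / f"pattern_{stem}.tsv", sep="\t", index=False)
        sig = pat.significant()
        table = frame[sig].copy()
        table[["x_mm", "y_mm", "z_mm"]] = mm[sig]
        table.to_csv(out / f"pattern_{stem}_significant.tsv", sep="\t", index=False)
        maps = np.zeros((3, *atlas.shape))
        for j, vals in enumerate((pat.a, pat.z, pat.q)):
            maps[j].ravel()[mask.indices] = vals
        nib.save(nib.Nifti1Image(np.moveaxis(maps, 0, -1).astype(np.float32),
                                 atlas.affine),
                 str(out / f"pattern_{stem}.nii.gz"))
    log.info("interpret: patterns for %d robust blocks", len(ROBUST_CONTRASTS))


def stage_circuit(config: RunConfig) -> None:
    out = _workdir(config)
    atlas = _load_atlas(out)
    mask = VoxelMask.from_volume(
        np.asarray(nib.load(str(out / "whole_brain_mask.nii.gz")).dataobj) > 0,
        atlas.affine,
    )
    p_maps = []
    for con in ROBUST_CONTRASTS:
        frame = pd.read_csv(out / f"pattern_{con.label.replace('/', '_')}.tsv", sep="\t")
        p_maps.append(frame["p"].to_numpy())
    extended = select_top_voxels(np.stack(p_maps), mask, fraction=config.top_fraction)
    _save_mask(extended, out / "extended_circuit_mask.nii.gz")
    log.info("circuit: selected %d voxels (top %.0f%%)",
             extended.n_voxels, 100 * config.top_fraction)


def stage_rsa(config: RunConfig) -> None:
    out = _workdir(config)
    atlas = _load_atlas(out)
    discovery = BetaMapSet.load_nifti_dir(out / "betas_discovery")
    _, sims, communities = circuit_rsa(discovery, atlas, config.cv())
    first = next(iter(sims.values()))
    pd.DataFrame(first.R, index=first.region_ids, columns=first.region_ids).to_csv(
        out / "rsa_similarity.tsv", sep="\t"
    )
    pd.DataFrame(first.embedding, index=first.region_ids,
                 columns=["mds1", "mds2"]).to_csv(out / "rsa_embedding.tsv", sep="\t")
    table = communities.preference_sign.copy()
    table.insert(0, "community", [communities.community[r] for r in table.index])
    table.to_csv(out / "communities.tsv", sep="\t", index_label="region")
    log.info("rsa: %d regions over %d blocks", len(table), len(sims))


def stage_stats(config: RunConfig) -> None:
    out = _workdir(config)
    atlas = _load_atlas(out)
    discovery = BetaMapSet.load_nifti_dir(out / "betas_discovery")
    acc = pd.read_csv(out / "accuracy.tsv", sep="\t")
    cv = config.cv()
    selector = _circuit_selector(atlas)
    rows = []
    for con in ALL_CONTRASTS:
        perm = permutation_test_accuracy(discovery, con, cv, n_perm=config.n_perm,
                                         seed=config.seed + 200, selector=selector)
        sub = acc[(acc.features == "threat_circuit") & (acc.contrast == con.label)]
        v_acc = float(sub.validation_accuracy.iloc[0])
        n_v = int(sub.n_validation.iloc[0])
        k = int(round(v_acc * n_v))
        rows.append((con.label, perm.observed, perm.p, perm.report,
                     v_acc, binomial_two_sided(k, n_v)))
    frame = pd.DataFrame(rows, columns=["contrast", "cv_accuracy", "perm_p",
                                        "perm_report", "validation_accuracy",
                                        "binomial_p"])
    frame["perm_q"], _ = fdr_bh(frame["perm_p"].to_numpy())
    frame.to_csv(out / "stats.tsv", sep="\t", index=False)
    log.info("stats: permutation + binomial tests for %d contrasts", len(rows))


def stage_report(config: RunConfig) -> None:
    out = _workdir(config)
    artifacts = sorted(p.name for p in out.iterdir() if p.is_file())
    manifest = {
        "package": "threatdecode",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("report: manifest with %d artifacts", len(artifacts))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "decode": stage_decode,
    "interpret": stage_interpret,
    "circuit": stage_circuit,
    "rsa": stage_rsa,
    "stats": stage_stats,
    "report": stage_report,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in canonical order; returns the run dir."""
    out = _workdir(config)
    (out / "config.json").write_text(config.to_json())
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config)
        except FileNotFoundError as err:
            raise RuntimeError(
                f"stage {stage!r}: missing upstream artifact ({err.filename}); "
                "run the producing stage first"
            ) from err
    return out
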