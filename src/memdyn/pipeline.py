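"""Configuration and end-to-end orchestration.

A run is described by a YAML-serializable :class:`RunConfig`; stages execute
in dependency order (simulate → track → dynamics / quantify / order) and the
results are aggregated into a ``report.json`` validated by
:mod:`memdyn.report`.  Every stage draws its randomness from an independent
stream derived from the master seed and the stage name, so a fixed config +
seed reproduces the report byte for byte and adding a stage never perturbs
the others.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import endo_quant, io, membrane_order, simgen
from . import spt_dynamics as spt
from .core import INTERIOR, PM, NoiseModel, RegionMask
from .report import (
    EndoReport,
    GroupComparisonModel,
    GPPeakModel,
    OrderReport,
    PeakFitModel,
    PunctaQuantModel,
    Report,
    RGMModel,
    SpectralProfileModel,
    SptReport,
)

logger = logging.getLogger("memdyn")

STAGE_ORDER = ["simulate", "track", "dynamics", "quantify", "order"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Config models (YAML round-trippable)
# ---------------------------------------------------------------------------


class Calibration(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.05


class TirfConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_particles: int = 300
    n_frames: int = 50
    populations: list[list[float]] = Field(
        default_factory=lambda: [[1.0, 0.01396]]
    )  # [fraction, step sigma μm]
    psf_sigma_um: float = 0.125
    photon_scale: float = 2000.0
    background_level: float = 10.0
    field_size_px: list[int] = Field(default_factory=lambda: [256, 256])
    min_separation_um: float = 1.0
    localization_jitter_um: float = 0.0
    noise: str = "poisson"


class CellGroupConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = 10
    n_puncta: int = 46
    puncta_intensity: float = 200.0
    pm_mean_intensity: float = 200.0
    interior_mean_intensity: float = 30.0


class LambdaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    field_size_px: list[int] = Field(default_factory=lambda: [160, 160])
    pm_ordered_fraction: float = 0.8
    endosome_ordered_fraction: float = 0.4
    n_endosomes: int = 12
    noise: str = "poisson"


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tirf: Optional[TirfConfig] = None
    cell_groups: Optional[dict[str, CellGroupConfig]] = None
    lambda_stack: Optional[LambdaConfig] = None


class TrackConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    movie_path: Optional[str] = None  # default: the simulated movie
    psf_sigma_um: float = 0.125
    snr_threshold: float = 5.0
    max_step_um: float = 0.3
    max_gap: int = 1
    min_length: int = 5


class DynamicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tracks_path: Optional[str] = None
    n_fit_lags: int = 4
    bimodal: str = "auto"  # "auto" or "never"
    log_scale_diffusion: bool = True


class QuantifyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference_group: str = "control"
    psf_sigma_um: float = 0.125
    snr_threshold: float = 5.0


class OrderConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    g_factor: float = 1.0
    n_rois: int = 20
    roi_size_px: int = 3


class RunConfig(BaseModel):
    """Full pipeline configuration; round-trips losslessly through YAML."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(STAGE_ORDER))
    calibration: Calibration = Field(default_factory=Calibration)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    track: TrackConfig = Field(default_factory=TrackConfig)
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)
    order: OrderConfig = Field(default_factory=OrderConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def default_synthetic_config(seed: int = 0) -> RunConfig:
    """Config for the full reproduce-synthetic run: all stages, defaults."""
    cfg = RunConfig(seed=seed)
    cfg.simulate.tirf = TirfConfig(localization_jitter_um=0.02)
    cfg.simulate.cell_groups = {
        "control": CellGroupConfig(n_puncta=46),
        "treated": CellGroupConfig(n_puncta=65),
    }
    cfg.simulate.lambda_stack = LambdaConfig()
    return cfg


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


class PipelineState:
    """In-memory products passed between stages."""

    def __init__(self) -> None:
        self.movie = None
        self.truth_tracks: Optional[pd.DataFrame] = None
        self.tracks: Optional[pd.DataFrame] = None
        self.cells: Optional[dict[str, list]] = None  # label -> [(stack, mask, table)]
        self.lambda_stack = None
        self.lambda_mask: Optional[RegionMask] = None


def _noise(kind: str) -> NoiseModel:
    return NoiseModel("none") if kind == "none" else NoiseModel(kind)


def _run_simulate(cfg: RunConfig, state: PipelineState, out: Path) -> dict:
    params: dict = {}
    seed = stage_seed(cfg.seed, "simulate")
    if cfg.simulate.tirf is not None:
        t = cfg.simulate.tirf
        spec = simgen.TirfSimSpec(
            n_particles=t.n_particles,
            n_frames=t.n_frames,
            frame_interval_s=cfg.calibration.frame_interval_s,
            pixel_size_um=cfg.calibration.pixel_size_um,
            populations=tuple(
                simgen.Population(f, s) for f, s in t.populations
            ),
            psf_sigma_um=t.psf_sigma_um,
            photon_scale=t.photon_scale,
            background_level=t.background_level,
            field_size_px=tuple(t.field_size_px),
            min_separation_um=t.min_separation_um,
            localization_jitter_um=t.localization_jitter_um,
            noise_model=_noise(t.noise),
            seed=seed,
        )
        state.movie, state.truth_tracks = simgen.simulate_tirf_movie(spec)
        io.write_stack(out / "movie.tif", state.movie)
        io.write_tracks(out / "truth_tracks.csv", state.truth_tracks)
        params["tirf"] = t.model_dump(mode="json")
    if cfg.simulate.cell_groups:
        state.cells = {}
        for gi, (label, g) in enumerate(sorted(cfg.simulate.cell_groups.items())):
            group = []
            for ci in range(g.n_cells):
                spec = simgen.CellImageSimSpec(
                    n_puncta=g.n_puncta,
                    puncta_intensity=g.puncta_intensity,
                    pm_mean_intensity=g.pm_mean_intensity,
                    interior_mean_intensity=g.interior_mean_intensity,
                    pixel_size_um=cfg.calibration.pixel_size_um,
                    seed=stage_seed(seed, f"cell:{label}:{ci}"),
                )
                stack, mask, table = simgen.simulate_cell_image(spec)
                io.write_stack(out / f"cell_{label}_{ci:02d}.tif", stack)
                io.write_mask(out / f"cell_{label}_{ci:02d}_mask.tif", mask)
                group.append((stack, mask, table))
            state.cells[label] = group
        params["cell_groups"] = {
            k: v.model_dump(mode="json") for k, v in cfg.simulate.cell_groups.items()
        }
    if cfg.simulate.lambda_stack is not None:
        lc = cfg.simulate.lambda_stack
        spec = simgen.SpectralSimSpec(
            field_size_px=tuple(lc.field_size_px),
            n_endosomes=lc.n_endosomes,
            region_ordered_fraction={
                PM: lc.pm_ordered_fraction,
                INTERIOR: lc.endosome_ordered_fraction,
                3: 0.3,
            },
            pixel_size_um=cfg.calibration.pixel_size_um,
            noise_model=_noise(lc.noise),
            seed=stage_seed(seed, "lambda"),
        )
        state.lambda_stack, state.lambda_mask = simgen.simulate_lambda_stack(spec)
        io.write_stack(out / "lambda.tif", state.lambda_stack)
        io.write_mask(out / "lambda_mask.tif", state.lambda_mask)
        params["lambda_stack"] = lc.model_dump(mode="json")
    return params


def _run_track(cfg: RunConfig, state: PipelineState, out: Path) -> dict:
    t = cfg.track
    if state.movie is None:
        if t.movie_path is None:
            raise FileNotFoundError(
                "track stage needs a movie: run simulate or set track.movie_path"
            )
        state.movie = io.read_stack(t.movie_path)
    spots = spt.detect_spots_movie(
        state.movie, psf_sigma_um=t.psf_sigma_um, snr_threshold=t.snr_threshold
    )
    tracks = spt.link_trajectories(
        spots, max_step_um=t.max_step_um, max_gap=t.max_gap, min_length=t.min_length
    )
    state.tracks = tracks
    spots.to_csv(out / "spots.csv", index=False)
    io.write_tracks(out / "tracks.csv", tracks)
    logger.info("track: %d spots -> %d tracks", len(spots), tracks["track_id"].nunique() if len(tracks) else 0)
    return t.model_dump(mode="json")


def _run_dynamics(
    cfg: RunConfig, state: PipelineState, out: Path
) -> tuple[dict, SptReport]:
    d = cfg.dynamics
    if state.tracks is None:
        if d.tracks_path is None:
            raise FileNotFoundError(
                "dynamics stage needs tracks: run track or set dynamics.tracks_path"
            )
        state.tracks = io.read_tracks(d.tracks_path)
    tracks = state.tracks
    dt = cfg.calibration.frame_interval_s
    dtab = spt.diffusion_table(tracks, dt, n_fit_lags=d.n_fit_lags)
    dtab.to_csv(out / "diffusion.csv", index=False)
    mtab = spt.motion_range_table(tracks)
    mtab.to_csv(out / "motion_range.csv", index=False)

    allow = d.bimodal == "auto"
    usable = dtab[~dtab["negative_slope"] & (dtab["D_um2_s"] > 0)]
    report = SptReport(
        n_tracks=int(tracks["track_id"].nunique()) if len(tracks) else 0,
        n_diffusion_estimates=len(dtab),
        n_negative_slope=int(dtab["negative_slope"].sum()) if len(dtab) else 0,
    )
    if len(usable) >= 30:
        dfit = spt.fit_peak_histogram(
            usable["D_um2_s"], allow_bimodal=allow, log_scale=d.log_scale_diffusion
        )
        report.diffusion_peaks = PeakFitModel.from_fit(dfit)
        pd.DataFrame(
            {
                "bin_left": dfit.bin_edges[:-1],
                "bin_right": dfit.bin_edges[1:],
                "count": dfit.counts,
            }
        ).to_csv(out / "diffusion_histogram.csv", index=False)
    if len(mtab) >= 30:
        mfit = spt.fit_peak_histogram(
            mtab["motion_range_um"], allow_bimodal=allow, log_scale=False
        )
        report.motion_range_peaks = PeakFitModel.from_fit(mfit)
    (out / "peaks.json").write_text(
        json.dumps(
            {
                "diffusion": None
                if report.diffusion_peaks is None
                else report.diffusion_peaks.model_dump(mode="json"),
                "motion_range": None
                if report.motion_range_peaks is None
                else report.motion_range_peaks.model_dump(mode="json"),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return d.model_dump(mode="json"), report


def _run_quantify(
    cfg: RunConfig, state: PipelineState, out: Path
) -> tuple[dict, EndoReport]:
    q = cfg.quantify
    if not state.cells:
        raise FileNotFoundError(
            "quantify stage needs simulated cell groups (simulate.cell_groups)"
        )
    cells_report: dict[str, list[PunctaQuantModel]] = {}
    counts: dict[str, list[float]] = {}
    intensities: dict[str, list[float]] = {}
    rows = []
    for label, group in state.cells.items():
        quants = []
        for ci, (stack, mask, _table) in enumerate(group):
            pq = endo_quant.quantify_puncta(
                stack,
                mask,
                psf_sigma_um=q.psf_sigma_um,
                snr_threshold=q.snr_threshold,
                cell_id=f"{label}:{ci}",
            )
            quants.append(pq)
            rows.append(
                (
                    label,
                    pq.cell_id,
                    pq.n_puncta,
                    pq.mean_internal_intensity,
                    pq.relative_internal_intensity,
                    pq.pm_mean_intensity,
                )
            )
        cells_report[label] = [PunctaQuantModel.from_quant(p) for p in quants]
        counts[label] = [p.n_puncta for p in quants]
        intensities[label] = [
            p.relative_internal_intensity
            for p in quants
            if np.isfinite(p.relative_internal_intensity)
        ]
    pd.DataFrame(
        rows,
        columns=[
            "group",
            "cell_id",
            "n_puncta",
            "mean_internal_intensity",
            "relative_internal_intensity",
            "pm_mean_intensity",
        ],
    ).to_csv(out / "puncta.csv", index=False)

    report = EndoReport(cells=cells_report)
    ref = q.reference_group
    if ref in counts and all(len(v) >= 2 for v in counts.values()):
        report.comparison_counts = GroupComparisonModel.from_comparison(
            endo_quant.compare_groups(counts, reference=ref)
        )
    if ref in intensities and all(len(v) >= 2 for v in intensities.values()):
        report.comparison_intensity = GroupComparisonModel.from_comparison(
            endo_quant.compare_groups(intensities, reference=ref)
        )
    (out / "comparisons.json").write_text(
        json.dumps(report.model_dump(mode="json"), indent=1, sort_keys=True)
    )
    return q.model_dump(mode="json"), report


def _run_order(
    cfg: RunConfig, state: PipelineState, out: Path
) -> tuple[dict, OrderReport]:
    o = cfg.order
    if state.lambda_stack is None or state.lambda_mask is None:
        raise FileNotFoundError(
            "order stage needs a simulated λ-stack (simulate.lambda_stack)"
        )
    stack, mask = state.lambda_stack, state.lambda_mask
    profiles = membrane_order.extract_spectral_profiles(
        stack,
        mask,
        n_rois=o.n_rois,
        roi_shape_px=(o.roi_size_px, o.roi_size_px),
        regions=[PM, INTERIOR],
        seed=stage_seed(cfg.seed, "order"),
    )
    green = membrane_order.band_integrate(stack, membrane_order.GREEN_WINDOW_NM)
    red = membrane_order.band_integrate(stack, membrane_order.RED_WINDOW_NM)
    rgms = [
        membrane_order.compute_rgm(green, red, mask, region)
        for region in (PM, INTERIOR)
    ]
    gp = membrane_order.compute_gp_image(green, red, g_factor=o.g_factor)
    import tifffile

    tifffile.imwrite(out / "gp_image.tif", gp.gp.astype(np.float32))
    gp_fits = membrane_order.fit_region_gp_peaks(gp, mask, regions=[PM, INTERIOR])

    pd.DataFrame(
        [
            {
                "region": p.region,
                "peak_wavelength_nm": p.peak_wavelength_nm,
                **{
                    f"band_{int(b)}": v
                    for b, v in zip(p.band_centers_nm, p.mean_intensity)
                },
            }
            for p in profiles
        ]
    ).to_csv(out / "profiles.csv", index=False)
    pd.DataFrame(
        [
            {"region": r.region, "rgm": r.rgm, "i_660": r.i_660, "i_550": r.i_550}
            for r in rgms
        ]
    ).to_csv(out / "rgm.csv", index=False)
    report = OrderReport(
        profiles=[
            SpectralProfileModel(
                region=p.region, peak_wavelength_nm=p.peak_wavelength_nm
            )
            for p in profiles
        ],
        rgm=[
            RGMModel(region=r.region, rgm=r.rgm, i_660=r.i_660, i_550=r.i_550)
            for r in rgms
        ],
        gp_peaks=[GPPeakModel.from_fit(f) for f in gp_fits],
        g_factor=o.g_factor,
    )
    (out / "gp_peaks.json").write_text(
        json.dumps(
            [g.model_dump(mode="json") for g in report.gp_peaks],
            indent=1,
            sort_keys=True,
        )
    )
    return o.model_dump(mode="json"), report


def run_pipeline(config: RunConfig, out_dir) -> Report:
    """Execute the configured stages in dependency order; write report.json.

    Identical config + seed produce a byte-identical report.  Missing stage
    inputs fail fast with the offending path/requirement in the message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in config.stages]

    state = PipelineState()
    parameters: dict = {"calibration": config.calibration.model_dump(mode="json")}
    spt_report = endo_report = order_report = None

    for stage in stages:
        logger.info("stage %s (seed %d)", stage, stage_seed(config.seed, stage))
        if stage == "simulate":
            parameters["simulate"] = _run_simulate(config, state, out)
        elif stage == "track":
            parameters["track"] = _run_track(config, state, out)
        elif stage == "dynamics":
            parameters["dynamics"], spt_report = _run_dynamics(config, state, out)
        elif stage == "quantify":
            parameters["quantify"], endo_report = _run_quantify(config, state, out)
        elif stage == "order":
            parameters["order"], order_report = _run_order(config, state, out)

    report = Report(
        seed=config.seed,
        stages=stages,
        parameters=parameters,
        spt=spt_report,
        endo=endo_report,
        order=order_report,
    )
    (out / "report.json").write_text(report.to_json())
    return report
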