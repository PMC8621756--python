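"""Machine-readable report models.

The pipeline aggregates its results into a single ``report.json`` validated
by the pydantic models below.  The corresponding JSON schema is published at
``memdyn/schemas/report.schema.json`` (generated from these models; a test
keeps the two in sync).
"""

from __future__ import annotations

import json
import math
from importlib import resources
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict

from . import spt_dynamics as spt
from . import endo_quant, membrane_order


def _clean(x: Optional[float]) -> Optional[float]:
    """Map NaN/inf to None so the report is strict JSON."""
    if x is None:
        return None
    x = float(x)
    return x if math.isfinite(x) else None


class GaussianComponentModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    peak: float
    width: float
    weight: float


class PeakFitModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_components: int
    components: list[GaussianComponentModel]
    bic_1: float
    bic_2: Optional[float] = None
    r_squared: float
    log_scale: bool
    n_values: int

    @classmethod
    def from_fit(cls, fit: spt.PeakFit) -> "PeakFitModel":
        return cls(
            n_components=fit.n_components,
            components=[
                GaussianComponentModel(peak=c.peak, width=c.width, weight=c.weight)
                for c in fit.components
            ],
            bic_1=fit.bic_1,
            bic_2=fit.bic_2,
            r_squared=fit.r_squared,
            log_scale=fit.log_scale,
            n_values=fit.n_values,
        )


class SptReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_tracks: int
    n_diffusion_estimates: int
    n_negative_slope: int
    diffusion_peaks: Optional[PeakFitModel] = None
    motion_range_peaks: Optional[PeakFitModel] = None


class PunctaQuantModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cell_id: str
    n_puncta: int
    mean_internal_intensity: Optional[float] = None
    relative_internal_intensity: Optional[float] = None
    pm_mean_intensity: Optional[float] = None

    @classmethod
    def from_quant(cls, q: endo_quant.PunctaQuant) -> "PunctaQuantModel":
        return cls(
            cell_id=str(q.cell_id),
            n_puncta=q.n_puncta,
            mean_internal_intensity=_clean(q.mean_internal_intensity),
            relative_internal_intensity=_clean(q.relative_internal_intensity),
            pm_mean_intensity=_clean(q.pm_mean_intensity),
        )


class GroupStatsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    n: int
    mean: float
    sd: float
    percent_change: Optional[float] = None
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    significance: str = ""


class GroupComparisonModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference: str
    groups: list[GroupStatsModel]

    @classmethod
    def from_comparison(
        cls, c: endo_quant.GroupComparison
    ) -> "GroupComparisonModel":
        return cls(
            reference=c.reference,
            groups=[
                GroupStatsModel(
                    label=g.label,
                    n=g.n,
                    mean=g.mean,
                    sd=g.sd,
                    percent_change=_clean(g.percent_change),
                    t_statistic=_clean(g.t_statistic),
                    p_value=_clean(g.p_value),
                    significance=g.significance,
                )
                for g in c.groups
            ],
        )


class EndoReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cells: dict[str, list[PunctaQuantModel]]
    comparison_counts: Optional[GroupComparisonModel] = None
    comparison_intensity: Optional[GroupComparisonModel] = None


class SpectralProfileModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    region: int
    peak_wavelength_nm: float


class RGMModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    region: int
    rgm: float
    i_660: float
    i_550: float


class GPPeakModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    region: int
    peak: float
    width: float
    r_squared: float
    n_pixels: int

    @classmethod
    def from_fit(cls, f: membrane_order.GPHistogramFit) -> "GPPeakModel":
        return cls(
            region=f.region,
            peak=f.peak,
            width=f.width,
            r_squared=f.r_squared,
            n_pixels=f.n_pixels,
        )


class OrderReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    profiles: list[SpectralProfileModel]
    rgm: list[RGMModel]
    gp_peaks: list[GPPeakModel]
    g_factor: float


class Report(BaseModel):
    """Top-level pipeline report."""

    model_config = ConfigDict(extra="forbid")
    package: str = "memdyn"
    seed: int
    stages: list[str]
    parameters: dict[str, Any]
    spt: Optional[SptReport] = None
    endo: Optional[EndoReport] = None
    order: Optional[OrderReport] = None

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=1, sort_keys=True)


def published_schema() -> dict:
    """The JSON schema shipped with the package."""
    text = (
        resources.files("memdyn").joinpath("schemas/report.schema.json").read_text()
    )
    return json.loads(text)


def validate_report(data: dict) -> Report:
    """Validate a loaded report dict against the models (raises on failure)."""
    return Report.model_validate(data)
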