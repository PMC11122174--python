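"""Validated layout of the statistics report.

The report produced by :func:`orbitmorph.stats.build_stats_report` is a
plain dict; these pydantic models pin its schema (version 1).  A JSON
Schema rendering generated from the models is shipped under
``orbitmorph/schemas/stats_report_v1.json`` for non-Python consumers.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

__all__ = ["StatsReportModel", "validate_report"]


class NormalityCell(BaseModel):
    W: float
    p: float = Field(ge=0.0, le=1.0)


class TermCell(BaseModel):
    coef: float
    p: float = Field(ge=0.0, le=1.0)


class UnpairedCell(BaseModel):
    p_unpaired: float = Field(ge=0.0, le=1.0)


class PairedCell(BaseModel):
    p_unpaired: float = Field(ge=0.0, le=1.0)
    p_paired: float | None = None
    degenerate: bool = False


class GroupTests(BaseModel):
    male_vs_female: dict[str, UnpairedCell]  # side -> cell
    left_vs_right: dict[str, PairedCell]  # gender -> cell
    larger_vs_smaller: dict[str, PairedCell]


class StatsReportModel(BaseModel):
    """Schema version 1 of the cohort statistics report."""

    schema_version: int
    n_screened: int = Field(ge=0)
    n_retained: int = Field(ge=0)
    n_excluded: int = Field(ge=0)
    normality: dict[str, dict[str, dict[str, NormalityCell]]]
    group_tests: dict[str, GroupTests]
    volume_model: dict[str, dict[str, TermCell]]
    correlations: dict[str, dict[str, dict[str, float]]]
    gender_volume_difference_pct: float
    volume_area_ratio: dict[str, float]


def validate_report(report: dict) -> StatsReportModel:
    """Validate a report dict against the versioned schema; raises on error."""
    return StatsReportModel.model_validate(report)
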