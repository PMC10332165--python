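"""Indicator taxonomy for medical-resource equity analysis.

The default set mirrors the yearbook indicators commonly used for
provincial health-resource studies in China: material resources
(institutions and beds), human resources (technicians, physicians,
nurses, general practitioners) and financial resources (government
health expenditure).  The set is configuration, not a constant of the
methods: every pipeline stage accepts any list of
:class:`IndicatorDef`.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, field_validator

Category = Literal["material", "human", "financial"]


class IndicatorDef(BaseModel):
    """One resource indicator column of the regional panel.

    Parameters
    ----------
    id
        Short machine-readable code used as the CSV column name.
    label
        Human-readable display name.
    category
        One of ``material``, ``human``, ``financial``.
    units
        Free-text units (counts, persons, billion yuan, ...).
    """

    id: str
    label: str
    category: Category
    units: str = "count"

    @field_validator("id")
    @classmethod
    def _id_nonempty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("indicator id must be non-empty")
        return v


DEFAULT_INDICATORS: tuple[IndicatorDef, ...] = (
    IndicatorDef(id="health_institutions", label="Medical and health institutions", category="material", units="count"),
    IndicatorDef(id="tcm_institutions", label="Traditional Chinese medicine institutions", category="material", units="count"),
    IndicatorDef(id="medical_beds", label="Beds in medical and health institutions", category="material", units="count"),
    IndicatorDef(id="grassroots_beds", label="Beds in primary medical and health institutions", category="material", units="count"),
    IndicatorDef(id="health_technicians", label="Health technicians", category="human", units="persons"),
    IndicatorDef(id="practicing_physicians", label="Practicing (assistant) physicians", category="human", units="persons"),
    IndicatorDef(id="registered_nurses", label="Registered nurses", category="human", units="persons"),
    IndicatorDef(id="primary_health_technicians", label="Primary health technicians", category="human", units="persons"),
    IndicatorDef(id="general_practitioners", label="General practitioners", category="human", units="persons"),
    IndicatorDef(id="gov_health_expenditure", label="Government health expenditure", category="financial", units="billion yuan"),
)


def check_unique_ids(indicators) -> None:
    ids = [ind.id for ind in indicators]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate indicator ids: {dupes}")
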