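"""Deterministic risk-characterization arithmetic.

Everything downstream of the benchmark-dose fit: gas-phase unit
conversions, conversion of an animal point of departure (PoD) to a
human-equivalent value, composition of assessment factors (AFs),
derivation of acceptable daily exposure ranges, margin of exposure, and
the exposure-vs-acceptable verdict.

Rounding policy
---------------
Every reported intermediate (human-equivalent PoD, acceptable bounds)
is rounded half-up to 2 significant figures, and the *rounded* value
feeds the next reported step.  Full precision is used internally only
up to each reporting boundary.  This is the convention under which the
chain 14.2 ppm -> x0.25 -> 3.55 -> 3.6 ppm -> /450 -> 8 ppb (not 7.9)
is self-consistent.

Gas conversions default to benzene (MW 78.11 g/mol) at 20 degC and
101.3 kPa (molar volume 24.04 L/mol).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

__all__ = [
    "BENZENE_MW",
    "MOLAR_VOLUME_20C",
    "PoDRange",
    "ExposureAdjustment",
    "AssessmentFactor",
    "AssessmentFactorSet",
    "RiskAssessmentReport",
    "WORKER_ADJUSTMENT",
    "GENERAL_POPULATION_ADJUSTMENT",
    "WORKER_AFS",
    "GENERAL_POPULATION_AFS",
    "round_sig",
    "ppm_to_mgm3",
    "mgm3_to_ppm",
    "ugm3_to_ppb",
    "ppb_to_ugm3",
    "human_equivalent_pod",
    "compose_afs",
    "acceptable_range",
    "margin_of_exposure",
    "characterize_risk",
    "aggregate_exposure",
]

BENZENE_MW = 78.11  # g/mol
MOLAR_VOLUME_20C = 24.04  # L/mol at 20 degC, 101.3 kPa

AF_RATIONALES = ("interspecies_tk_td", "duration", "intraspecies", "severity", "other")


def round_sig(x: float, sig: int = 2) -> float:
    """Round half-up to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    q = Decimal(repr(x))
    shift = sig - 1 - math.floor(math.log10(abs(x)))
    return float(q.scaleb(shift).quantize(Decimal(1), rounding=ROUND_HALF_UP).scaleb(-shift))


@dataclass(frozen=True)
class PoDRange:
    """A point-of-departure interval, e.g. the BMCL–BMCU of a BMD fit."""

    lower: float
    upper: float
    basis: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper):
            raise ValueError(f"PoD range must satisfy 0 < lower <= upper, got {self}")


@dataclass(frozen=True)
class ExposureAdjustment:
    """Exposure-regimen scaling from animal study to human scenario.

    The animal PoD is multiplied by (animal_hours / human_hours) x
    (animal_equiv_volume / human_volume).  For a general-population
    scenario with activity assumed similar to the animals', the volume
    ratio is 1 and human hours are 24.
    """

    animal_hours_per_day: float
    human_hours_per_day: float
    animal_equiv_inhaled_volume: float = 1.0
    human_inhaled_volume: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "animal_hours_per_day",
            "human_hours_per_day",
            "animal_equiv_inhaled_volume",
            "human_inhaled_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.animal_hours_per_day > 24 or self.human_hours_per_day > 24:
            raise ValueError("hours per day cannot exceed 24")

    @property
    def factor(self) -> float:
        return (self.animal_hours_per_day / self.human_hours_per_day) * (
            self.animal_equiv_inhaled_volume / self.human_inhaled_volume
        )


@dataclass(frozen=True)
class AssessmentFactor:
    value: float
    rationale: str = "other"
    note: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"assessment factor must be > 0, got {self.value}")
        if self.rationale not in AF_RATIONALES:
            raise ValueError(f"unknown rationale {self.rationale!r}; use one of {AF_RATIONALES}")


@dataclass(frozen=True)
class AssessmentFactorSet:
    """An itemized set of multiplicative uncertainty factors."""

    factors: tuple[AssessmentFactor, ...] = ()
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        warns = [f"assessment factor {f.value} < 1 ({f.rationale})" for f in self.factors if f.value < 1]
        object.__setattr__(self, "warnings", tuple(warns))

    @property
    def composite(self) -> float:
        return math.prod(f.value for f in self.factors)


# Benzene case-study presets.  Illustrative values following one
# regulatory opinion's choices; not a recommendation or precedent.
WORKER_ADJUSTMENT = ExposureAdjustment(
    animal_hours_per_day=6.0,
    human_hours_per_day=8.0,
    animal_equiv_inhaled_volume=6.7,
    human_inhaled_volume=10.0,
)

GENERAL_POPULATION_ADJUSTMENT = ExposureAdjustment(
    animal_hours_per_day=6.0,
    human_hours_per_day=24.0,
)

WORKER_AFS = AssessmentFactorSet(
    (
        AssessmentFactor(2.5, "interspecies_tk_td", "interspecies TK/TD variability"),
        AssessmentFactor(6.0, "duration", "28-day study to chronic exposure"),
        AssessmentFactor(5.0, "intraspecies", "worker population variability"),
        AssessmentFactor(3.0, "severity", "severity of genotoxic effect"),
    )
)

GENERAL_POPULATION_AFS = AssessmentFactorSet(
    (
        AssessmentFactor(2.5, "interspecies_tk_td", "interspecies TK/TD variability"),
        AssessmentFactor(6.0, "duration", "28-day study to chronic exposure"),
        AssessmentFactor(10.0, "intraspecies", "general-population variability"),
        AssessmentFactor(3.0, "severity", "severity of genotoxic effect"),
    )
)


# ---------------------------------------------------------------------------
# Unit conversions


def ppm_to_mgm3(c_ppm: float, mw: float = BENZENE_MW, molar_volume: float = MOLAR_VOLUME_20C) -> float:
    """Gas-phase ppm (v/v) to mg/m3: c * MW / Vm.  Full precision."""
    if c_ppm < 0:
        raise ValueError("concentration must be >= 0")
    return c_ppm * mw / molar_volume


def mgm3_to_ppm(c_mgm3: float, mw: float = BENZENE_MW, molar_volume: float = MOLAR_VOLUME_20C) -> float:
    if c_mgm3 < 0:
        raise ValueError("concentration must be >= 0")
    return c_mgm3 * molar_volume / mw


def ugm3_to_ppb(c_ugm3: float, mw: float = BENZENE_MW, molar_volume: float = MOLAR_VOLUME_20C) -> float:
    """ug/m3 to ppb; numerically identical to mg/m3 -> ppm."""
    return mgm3_to_ppm(c_ugm3, mw, molar_volume)


def ppb_to_ugm3(c_ppb: float, mw: float = BENZENE_MW, molar_volume: float = MOLAR_VOLUME_20C) -> float:
    return ppm_to_mgm3(c_ppb, mw, molar_volume)


# ---------------------------------------------------------------------------
# PoD extrapolation and acceptable levels


def human_equivalent_pod(pod: PoDRange, adj: ExposureAdjustment) -> PoDRange:
    """Animal PoD to human-equivalent PoD, reported at 2 significant figures.

    Each bound is multiplied by the exposure-regimen factor
    (hours ratio x inhaled-volume ratio) and then rounded per the
    reporting policy, since the rounded value feeds the next step.
    """
    return PoDRange(
        lower=round_sig(pod.lower * adj.factor),
        upper=round_sig(pod.upper * adj.factor),
        basis=f"{pod.basis}; human-equivalent (x{adj.factor:.4g})".lstrip("; "),
    )


logger = logging.getLogger(__name__)


def compose_afs(afs: AssessmentFactorSet) -> float:
    """Product of the assessment factors (1 for an empty set, with a warning)."""
    if not afs.factors:
        logger.warning("empty assessment-factor set: composite AF defaults to 1")
    for w in afs.warnings:
        logger.warning(w)
    return afs.composite


def acceptable_range(pod_he: PoDRange, composite_af: float) -> tuple[float, float]:
    """Acceptable daily exposure range in ppb from a human-equivalent PoD.

    Each (already 2-sig-fig) PoD bound is divided by the composite AF,
    converted ppm -> ppb, and rounded to 2 significant figures.
    """
    if composite_af <= 0:
        raise ValueError("composite assessment factor must be > 0")
    return (
        round_sig(pod_he.lower / composite_af * 1000.0),
        round_sig(pod_he.upper / composite_af * 1000.0),
    )


def margin_of_exposure(pod: float, exposure: float) -> float:
    """PoD / exposure (same units).  Undefined at zero exposure."""
    if exposure <= 0:
        raise ValueError("margin of exposure undefined for non-positive exposure")
    return pod / exposure


def characterize_risk(
    acceptable: tuple[float, float], exposure: tuple[float, float]
) -> str:
    """Compare an exposure range against an acceptable range.

    "above" if the exposure lower bound exceeds the acceptable upper
    bound, "below" if the exposure upper bound is under the acceptable
    lower bound, else "within" (any overlap, including touching bounds).
    """
    (alo, ahi), (elo, ehi) = acceptable, exposure
    if alo > ahi or elo > ehi:
        raise ValueError("ranges must be ordered (lower <= upper)")
    if elo > ahi:
        return "above"
    if ehi < alo:
        return "below"
    return "within"


def aggregate_exposure(sources: Sequence[dict]) -> tuple[float, dict]:
    """Sum exposure contributions (ppb) across sources.

    Each source is ``{"label": str, "level": ppb}``; returns the total
    and the per-source breakdown.
    """
    breakdown = {}
    for s in sources:
        level = float(s["level"])
        if level < 0:
            raise ValueError(f"negative exposure for source {s.get('label')!r}")
        breakdown[s.get("label", f"source{len(breakdown)}")] = level
    return sum(breakdown.values()), breakdown


# ---------------------------------------------------------------------------
# Report


@dataclass(frozen=True)
class RiskAssessmentReport:
    """End-to-end record: PoD -> human-equivalent PoD -> acceptable range
    -> verdict against an exposure estimate."""

    pod: PoDRange
    adjustment: ExposureAdjustment
    af_set: AssessmentFactorSet
    pod_human_equivalent: PoDRange
    composite_af: float
    acceptable_ppb: tuple[float, float]
    exposure_ppb: tuple[float, float]
    verdict: str
    moe: Optional[float] = None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "pod_ppm": [self.pod.lower, self.pod.upper],
            "pod_basis": self.pod.basis,
            "adjustment": {
                "animal_hours_per_day": self.adjustment.animal_hours_per_day,
                "human_hours_per_day": self.adjustment.human_hours_per_day,
                "animal_equiv_inhaled_volume": self.adjustment.animal_equiv_inhaled_volume,
                "human_inhaled_volume": self.adjustment.human_inhaled_volume,
                "factor": self.adjustment.factor,
            },
            "assessment_factors": [
                {"value": f.value, "rationale": f.rationale, "note": f.note}
                for f in self.af_set.factors
            ],
            "composite_af": self.composite_af,
            "pod_human_equivalent_ppm": [
                self.pod_human_equivalent.lower,
                self.pod_human_equivalent.upper,
            ],
            "acceptable_daily_exposure_ppb": list(self.acceptable_ppb),
            "exposure_estimate_ppb": list(self.exposure_ppb),
            "verdict": self.verdict,
            "moe": self.moe,
            "notes": list(self.notes),
            "warnings": list(self.af_set.warnings),
        }

    def to_text(self) -> str:
        lines = [
            "Risk characterization",
            "=====================",
            f"Animal PoD:            {self.pod.lower}-{self.pod.upper} ppm ({self.pod.basis})",
            f"Regimen factor:        x{self.adjustment.factor:.4g}",
            f"Human-equivalent PoD:  {self.pod_human_equivalent.lower}-{self.pod_human_equivalent.upper} ppm",
            "Assessment factors:    "
            + " * ".join(f"{f.value:g} ({f.rationale})" for f in self.af_set.factors),
            f"Composite AF:          {self.composite_af:g}",
            f"Acceptable daily exp.: {self.acceptable_ppb[0]}-{self.acceptable_ppb[1]} ppb",
            f"Exposure estimate:     {self.exposure_ppb[0]}-{self.exposure_ppb[1]} ppb",
            f"Verdict:               exposure {self.verdict} the acceptable range",
        ]
        if self.moe is not None:
            lines.append(f"Margin of exposure:    {self.moe:g}")
        for n in self.notes:
            lines.append(f"Note: {n}")
        for w in self.af_set.warnings:
            lines.append(f"Warning: {w}")
        return "\n".join(lines)


CASE_STUDY_CAVEAT = (
    "Assessment-factor values are illustrative for this case study and "
    "should not be seen as setting a precedent."
)


def assess(
    pod: PoDRange,
    adjustment: ExposureAdjustment,
    af_set: AssessmentFactorSet,
    exposure_ppb: tuple[float, float],
    *,
    moe_exposure_ppm: Optional[float] = None,
) -> RiskAssessmentReport:
    """Run the full deterministic chain and assemble the report."""
    pod_he = human_equivalent_pod(pod, adjustment)
    composite = compose_afs(af_set)
    acceptable = acceptable_range(pod_he, composite)
    verdict = characterize_risk(acceptable, tuple(exposure_ppb))
    moe = None
    notes = [CASE_STUDY_CAVEAT]
    if moe_exposure_ppm is not None:
        moe = margin_of_exposure(pod_he.lower, moe_exposure_ppm)
        notes.append(
            "MOE shown for reference only; the benzene case study did not "
            "apply the MOE concept (genotoxicity considered secondary)."
        )
    return RiskAssessmentReport(
        pod=pod,
        adjustment=adjustment,
        af_set=af_set,
        pod_human_equivalent=pod_he,
        composite_af=composite,
        acceptable_ppb=acceptable,
        exposure_ppb=tuple(exposure_ppb),
        verdict=verdict,
        moe=moe,
        notes=tuple(notes),
    )
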