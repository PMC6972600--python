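"""Synthetic micronucleus dose–response studies.

Generates per-animal datasets with exactly the statistical structure the
fitting layer assumes: median responses on a sigmoidal curve (exponential
or Hill) and multiplicative lognormal noise, with strain-specific
background and potency.  This is deliberately the fitted likelihood with
no overdispersion or litter effects, so parameter-recovery and coverage
tests are well-posed.

The benzene-like fixture emulates two inhalation study designs: a
Diversity Outbred (DO) mouse study with doses 0/1/10/100 ppm and 75
animals per group over 28 days, and a smaller conventional-strain
(B6C3F1-like) study spanning 1–200 ppm.  The fixture's true parameters
are arbitrary — order-of-magnitude plausible for MN-RET% potency
(CED near 10 ppm) but not estimates of any real study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import (
    CriticalEffectSize,
    DoseGroup,
    DoseResponseDataset,
    ModelParams,
    predict,
)

__all__ = [
    "StudyDesign",
    "TrueParams",
    "generate_study",
    "to_summary",
    "benzene_like_fixture",
    "DO_LIKE_DESIGN",
    "B6C3F1_LIKE_DESIGN",
    "DO_LIKE_TRUTH",
    "B6C3F1_LIKE_TRUTH",
]


@dataclass(frozen=True)
class StudyDesign:
    """Dose levels, group size and exposure-regimen annotation of one study."""

    doses: tuple[float, ...]
    n_per_group: int
    covariate_label: str = ""
    hours_per_day: float = 6.0
    days_per_week: float = 5.0
    weeks: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if len(set(self.doses)) < 3:
            raise ValueError("a study design needs at least 3 distinct doses")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth model parameters paired with the CES used to define them."""

    params: ModelParams
    ces: CriticalEffectSize = field(default_factory=CriticalEffectSize)


def generate_study(
    design: StudyDesign, truth: TrueParams, seed: int
) -> DoseResponseDataset:
    """Simulate one individual-animal study under the lognormal model.

    Each animal's response is ``predict(truth, dose) * exp(eps)`` with
    ``eps ~ Normal(0, log_sd^2)``; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    groups = []
    for dose in design.doses:
        median = predict(truth.params, truth.ces, dose)
        resp = median * np.exp(rng.normal(0.0, truth.params.log_sd, design.n_per_group))
        groups.append(
            DoseGroup(dose=dose, covariate=design.covariate_label or None, responses=tuple(resp))
        )
    return DoseResponseDataset(
        tuple(groups),
        endpoint="MN-RET frequency (synthetic)",
        dose_units="ppm",
        response_units="%",
    )


def to_summary(data: DoseResponseDataset) -> DoseResponseDataset:
    """Collapse an individual-mode dataset to (n, mean, sd) summaries.

    Arithmetic mean and sample SD (ddof=1; 0 for singleton groups), so n
    and the mean round-trip exactly.
    """
    groups = []
    for g in data.groups:
        if g.is_summary:
            groups.append(g)
            continue
        r = np.asarray(g.responses)
        sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
        groups.append(
            DoseGroup(dose=g.dose, covariate=g.covariate, n=r.size, mean=float(r.mean()), sd=sd)
        )
    return DoseResponseDataset(tuple(groups), data.endpoint, data.dose_units, data.response_units)


# ---------------------------------------------------------------------------
# Benzene-like two-study fixture

DO_LIKE_DESIGN = StudyDesign(
    doses=(0.0, 1.0, 10.0, 100.0),
    n_per_group=75,
    covariate_label="DO",
    hours_per_day=6.0,
    days_per_week=5.0,
    weeks=4.0,
)

B6C3F1_LIKE_DESIGN = StudyDesign(
    doses=(0.0, 1.0, 10.0, 50.0, 100.0, 200.0),
    n_per_group=10,
    covariate_label="B6C3F1",
    hours_per_day=6.0,
    days_per_week=5.0,
    weeks=4.0,
)

# Arbitrary but plausible truths: distinct backgrounds, CEDs near 10 ppm,
# shared shape (c, d) and residual spread across strains.
DO_LIKE_TRUTH = TrueParams(
    ModelParams(family="exponential", a=0.25, ced=10.0, c=4.0, d=1.0, log_sd=0.3)
)

B6C3F1_LIKE_TRUTH = TrueParams(
    ModelParams(family="exponential", a=0.15, ced=14.0, c=4.0, d=1.0, log_sd=0.3)
)


def benzene_like_fixture(
    seed: int,
    *,
    n_b6: Optional[int] = None,
) -> list[DoseResponseDataset]:
    """Two synthetic studies mirroring the DO / B6C3F1 benzene designs.

    Returns ``[do_like, b6c3f1_like]`` individual-mode datasets with
    independent noise streams derived from ``seed``.
    """
    b6_design = B6C3F1_LIKE_DESIGN
    if n_b6 is not None:
        b6_design = StudyDesign(
            doses=b6_design.doses,
            n_per_group=n_b6,
            covariate_label=b6_design.covariate_label,
        )
    return [
        generate_study(DO_LIKE_DESIGN, DO_LIKE_TRUTH, seed),
        generate_study(b6_design, B6C3F1_LIKE_TRUTH, seed + 1_000_003),
    ]
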