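"""Continuous dose–response model families for benchmark-dose analysis.

Implements the four-parameter exponential and Hill families in their
CED (critical effect dose) parameterization, together with a lognormal
likelihood for individual-animal and group-summary data.  Responses are
strictly positive continuous measurements (here micronucleated
reticulocyte frequencies, in %); multiplicative noise is assumed, so all
likelihood arithmetic happens on the natural-log scale.

Model forms (increasing endpoint, background ``a``, maximum fold-change
``c > 1``, log-steepness ``d``):

* exponential:  y(x) = a * (c - (c - 1) * exp(-b * x**d))
* Hill:         y(x) = a * (1 + (c - 1) * x**d / (b**d + x**d))

The rate / half-max parameter ``b`` is never exposed: it is derived from
the CED, the dose at which the median response equals ``a * (1 + CES)``
for a stated critical effect size (CES, the fractional increase over
background that defines the benchmark dose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "ModelFamily",
    "ModelParams",
    "CriticalEffectSize",
    "DoseGroup",
    "DoseResponseDataset",
    "ParameterDomainError",
    "DataDomainError",
    "predict",
    "b_from_ced",
    "log_likelihood",
]

ModelFamily = Literal["exponential", "hill"]

_FAMILIES = ("exponential", "hill")


class ParameterDomainError(ValueError):
    """Raised when model parameters leave their admissible domain."""


class DataDomainError(ValueError):
    """Raised when the data violate the likelihood's assumptions."""


@dataclass(frozen=True)
class CriticalEffectSize:
    """Fractional increase over background defining the benchmark dose.

    ``ces = 0.5`` means the CED is the dose producing a 50% increase in
    the median response over the concurrent background.
    """

    ces: float = 0.5

    def __post_init__(self) -> None:
        if not (self.ces > 0.0 and math.isfinite(self.ces)):
            raise ParameterDomainError(f"CES must be positive and finite, got {self.ces}")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of a CED-parameterized continuous dose–response model.

    Parameters
    ----------
    family:
        ``"exponential"`` or ``"hill"``.
    a:
        Background (dose-0 median) response, in response units; > 0.
    ced:
        Critical effect dose, in dose units (ppm); > 0.
    c:
        Maximum fold-change over background at infinite dose; > 1 for an
        increasing endpoint.
    d:
        Log-steepness; > 0.
    log_sd:
        Residual SD of ln(response); > 0.
    """

    family: ModelFamily
    a: float
    ced: float
    c: float
    d: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterDomainError(f"unknown family {self.family!r}")
        for name in ("a", "ced", "log_sd", "d"):
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ParameterDomainError(f"{name} must be positive and finite, got {v}")
        if not (self.c > 1.0 and math.isfinite(self.c)):
            raise ParameterDomainError(f"c must exceed 1 (increasing endpoint), got {self.c}")


@dataclass(frozen=True)
class DoseGroup:
    """One exposure group: a dose, an optional covariate label, and data.

    Exactly one of ``responses`` (per-animal values) or the summary triple
    ``(n, mean, sd)`` must be supplied.
    """

    dose: float
    covariate: Optional[str] = None
    responses: Optional[tuple[float, ...]] = None
    n: Optional[int] = None
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dose < 0 or not math.isfinite(self.dose):
            raise DataDomainError(f"dose must be >= 0, got {self.dose}")
        has_ind = self.responses is not None
        has_sum = self.n is not None or self.mean is not None or self.sd is not None
        if has_ind == has_sum:
            raise DataDomainError(
                "each group needs per-animal responses or an (n, mean, sd) summary, not both"
            )
        if has_ind:
            object.__setattr__(self, "responses", tuple(float(r) for r in self.responses))
            if len(self.responses) < 1:
                raise DataDomainError("empty response list")
        else:
            if self.n is None or self.mean is None or self.sd is None:
                raise DataDomainError("summary mode requires all of n, mean, sd")
            if self.n < 1:
                raise DataDomainError(f"group n must be >= 1, got {self.n}")
            if self.mean <= 0:
                raise DataDomainError(f"summary mean must be > 0, got {self.mean}")
            if self.sd < 0:
                raise DataDomainError(f"summary sd must be >= 0, got {self.sd}")

    @property
    def is_summary(self) -> bool:
        return self.responses is None

    @property
    def size(self) -> int:
        return self.n if self.is_summary else len(self.responses)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Grouped continuous dose–response data, optionally covariate-labelled.

    All groups must be in the same mode (individual or summary).  Doses
    are air concentrations in ppm throughout the fitting layer; no unit
    conversion happens here.
    """

    groups: tuple[DoseGroup, ...]
    endpoint: str = ""
    dose_units: str = "ppm"
    response_units: str = "%"

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise DataDomainError("dataset has no groups")
        modes = {g.is_summary for g in self.groups}
        if len(modes) > 1:
            raise DataDomainError("mixed individual/summary groups in one dataset")

    @property
    def is_summary(self) -> bool:
        return self.groups[0].is_summary

    @property
    def covariate_levels(self) -> tuple[str, ...]:
        """Distinct covariate labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g.covariate if g.covariate is not None else "", None)
        return tuple(seen)

    def n_distinct_doses(self, level: Optional[str] = None) -> int:
        doses = {
            g.dose
            for g in self.groups
            if level is None or (g.covariate if g.covariate is not None else "") == level
        }
        return len(doses)

    def relabel(self, covariate: str) -> "DoseResponseDataset":
        """Return a copy with every group assigned the given covariate label."""
        groups = tuple(
            DoseGroup(
                dose=g.dose,
                covariate=covariate,
                responses=g.responses,
                n=g.n,
                mean=g.mean,
                sd=g.sd,
            )
            for g in self.groups
        )
        return DoseResponseDataset(groups, self.endpoint, self.dose_units, self.response_units)


# ---------------------------------------------------------------------------
# Model evaluation


def b_from_ced(params: ModelParams, ces: CriticalEffectSize) -> float:
    """Solve y(CED) = a * (1 + CES) for the internal rate/half-max parameter.

    exponential: b = -ln((c - 1 - ces) / (c - 1)) / ced**d
    Hill:        b = ced * ((c - 1 - ces) / ces)**(1/d)

    Raises
    ------
    ParameterDomainError
        If ``ces >= c - 1``, in which case the response never reaches
        ``a * (1 + ces)`` and the CED is undefined.
    """
    eps = ces.ces
    if eps >= params.c - 1.0:
        raise ParameterDomainError(
            f"CED undefined: CES={eps} must be below c-1={params.c - 1.0}"
        )
    if params.family == "exponential":
        return -math.log((params.c - 1.0 - eps) / (params.c - 1.0)) / params.ced**params.d
    return params.ced * ((params.c - 1.0 - eps) / eps) ** (1.0 / params.d)


def predict(params: ModelParams, ces: CriticalEffectSize, dose):
    """Median response at the given dose(s) under the CED parameterization.

    Accepts a scalar or array dose; returns the same shape.  Satisfies
    y(0) = a, y(ced) = a*(1+ces), y nondecreasing, y(inf) -> a*c.
    """
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise DataDomainError("dose must be >= 0")
    b = b_from_ced(params, ces)
    with np.errstate(divide="ignore"):
        xd = np.where(x > 0, x, 1.0) ** params.d
        xd = np.where(x > 0, xd, 0.0)
    if params.family == "exponential":
        y = params.a * (params.c - (params.c - 1.0) * np.exp(-b * xd))
    else:
        y = params.a * (1.0 + (params.c - 1.0) * xd / (b**params.d + xd))
    return float(y) if np.isscalar(dose) or np.ndim(dose) == 0 else y


# ---------------------------------------------------------------------------
# Lognormal likelihood via per-group sufficient statistics


def lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Arithmetic (mean, sd) -> log-scale (mu, sigma2), method of moments.

    mu = ln(m / sqrt(1 + s^2/m^2)),  sigma2 = ln(1 + s^2/m^2).
    """
    r = 1.0 + (sd / mean) ** 2
    return math.log(mean / math.sqrt(r)), math.log(r)


def group_log_stats(g: DoseGroup, offset: float = 0.0) -> tuple[int, float, float]:
    """(n, mean of ln response, sum of squared log deviations) for a group.

    For individual data these are the exact log-scale sufficient
    statistics.  For summary data the arithmetic mean/SD are converted by
    the lognormal method of moments and the within-group sum of squares
    is taken as n * sigma2 (denominator-n convention).
    """
    if g.is_summary:
        mu, s2 = lognormal_moments(g.mean + offset, g.sd)
        return g.n, mu, g.n * s2
    r = np.asarray(g.responses, dtype=float) + offset
    if np.any(r <= 0):
        raise DataDomainError(
            f"non-positive response at dose {g.dose}; configure a positive "
            "additive offset to fit such data"
        )
    lr = np.log(r)
    m = float(lr.mean())
    return len(r), m, float(((lr - m) ** 2).sum())


def log_likelihood(
    params: ModelParams,
    ces: CriticalEffectSize,
    data: DoseResponseDataset,
    offset: float = 0.0,
) -> float:
    """Lognormal log-likelihood of the dataset under one parameter set.

    Defined as the normal log-density of ln(response) about
    ln(predict(dose)) with SD ``log_sd`` (no change-of-variable Jacobian,
    so zero residuals give exactly -(N/2) ln(2 pi log_sd^2)).  Additive
    over groups and invariant to group order.  Covariate labels are
    ignored here; per-level parameters are the fitting layer's job.
    """
    total = 0.0
    s2 = params.log_sd**2
    for g in data.groups:
        n, m, ss = group_log_stats(g, offset)
        mu = math.log(predict(params, ces, g.dose) + offset)
        total += -0.5 * n * math.log(2.0 * math.pi * s2) - (ss + n * (m - mu) ** 2) / (2.0 * s2)
    return total
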