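"""Config-driven orchestration of the full case-study chain.

data -> combined BMD analysis -> human-equivalent PoD -> assessment
factors -> acceptable daily exposure range -> verdict, with CSV/JSON
I/O, logging, and an audit trail (the exact config and its hash are
embedded in every report, so re-running from the embedded config
reproduces the report bit-for-bit).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .fitting import (
    BMDResult,
    FitFailureError,
    ModelFit,
    combined_analysis,
)
from .models import (
    CriticalEffectSize,
    DataDomainError,
    DoseGroup,
    DoseResponseDataset,
)
from .risk import (
    GENERAL_POPULATION_ADJUSTMENT,
    GENERAL_POPULATION_AFS,
    WORKER_ADJUSTMENT,
    WORKER_AFS,
    AssessmentFactor,
    AssessmentFactorSet,
    ExposureAdjustment,
    PoDRange,
    RiskAssessmentReport,
    assess,
    mgm3_to_ppm,
    ugm3_to_ppb,
)
from .simulate import benzene_like_fixture

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "read_dataset",
    "write_dataset",
    "run_case_study",
    "config_hash",
]

logger = logging.getLogger("bmdrisk")

_IND_COLS = {"dose", "response"}
_SUM_COLS = {"dose", "n", "mean", "sd"}


class PipelineStageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, message: str, exit_code: int = 2):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


# ---------------------------------------------------------------------------
# Dataset I/O


def read_dataset(
    path: Union[str, Path],
    *,
    dose_units: str = "ppm",
    response_units: str = "%",
    endpoint: str = "",
) -> DoseResponseDataset:
    """Read a dataset CSV in either dialect.

    Individual dialect: columns dose, response [, covariate] — one row
    per animal.  Summary dialect: dose, n, mean, sd [, covariate] — one
    row per group.  A file containing both ``response`` and ``mean``
    columns is rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if "response" in cols and "mean" in cols:
        raise DataDomainError(f"{path}: both 'response' and 'mean' columns present; ambiguous dialect")
    if _IND_COLS <= cols:
        mode = "individual"
    elif _SUM_COLS <= cols:
        mode = "summary"
    else:
        raise DataDomainError(
            f"{path}: need columns {sorted(_IND_COLS)} (individual) or {sorted(_SUM_COLS)} (summary), got {sorted(cols)}"
        )
    has_cov = "covariate" in cols
    for i, row in df.iterrows():
        if row["dose"] < 0:
            raise DataDomainError(f"{path} row {i}: negative dose {row['dose']}")
        if mode == "summary" and row["n"] < 1:
            raise DataDomainError(f"{path} row {i}: group n must be >= 1, got {row['n']}")

    groups = []
    if mode == "summary":
        for i, row in df.iterrows():
            groups.append(
                DoseGroup(
                    dose=float(row["dose"]),
                    covariate=str(row["covariate"]) if has_cov else None,
                    n=int(row["n"]),
                    mean=float(row["mean"]),
                    sd=float(row["sd"]),
                )
            )
    else:
        keys = ["dose", "covariate"] if has_cov else ["dose"]
        for key, sub in df.groupby(keys, sort=True):
            dose = key[0] if has_cov else (key[0] if isinstance(key, tuple) else key)
            cov = str(key[1]) if has_cov else None
            groups.append(
                DoseGroup(dose=float(dose), covariate=cov, responses=tuple(sub["response"].astype(float)))
            )
    return DoseResponseDataset(tuple(groups), endpoint=endpoint, dose_units=dose_units, response_units=response_units)


def write_dataset(data: DoseResponseDataset, path: Union[str, Path]) -> None:
    """Write a dataset CSV in the dialect matching its mode."""
    rows = []
    has_cov = any(g.covariate is not None for g in data.groups)
    for g in data.groups:
        base = {"covariate": g.covariate} if has_cov else {}
        if g.is_summary:
            rows.append({"dose": g.dose, "n": g.n, "mean": g.mean, "sd": g.sd, **base})
        else:
            rows.extend({"dose": g.dose, "response": r, **base} for r in g.responses)
    # %.17g round-trips IEEE doubles exactly through text
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one case-study run."""

    datasets: tuple[str, ...] = ()  # CSV paths; empty -> synthetic fixture
    fixture_seed: int = 7
    families: tuple[str, ...] = ("exponential", "hill")
    ces: float = 0.5
    ci_level: float = 0.90
    covariate_selection: bool = True
    adjustment: str = "worker"  # worker | general | custom
    custom_adjustment: Optional[dict] = None
    afs: str = "worker"  # worker | general | custom
    custom_afs: tuple[dict, ...] = ()
    exposure_lower: float = 50.0
    exposure_upper: float = 100.0
    exposure_units: str = "ppb"  # ppb | ppm | ugm3
    pod_override: Optional[tuple[float, float]] = None
    pod_level: Optional[str] = None
    seed: int = 0
    n_starts: int = 20
    offset: float = 0.0
    output_dir: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.ces <= 5):
            raise ValueError(f"ces must be in (0, 5], got {self.ces}")
        if not (0.5 < self.ci_level < 0.999):
            raise ValueError(f"ci_level must be in (0.5, 0.999), got {self.ci_level}")
        for fam in self.families:
            if fam not in ("exponential", "hill"):
                raise ValueError(f"unknown family {fam!r}")
        if self.adjustment not in ("worker", "general", "custom"):
            raise ValueError(f"adjustment preset must be worker|general|custom, got {self.adjustment!r}")
        if self.afs not in ("worker", "general", "custom"):
            raise ValueError(f"afs preset must be worker|general|custom, got {self.afs!r}")
        if self.exposure_units not in ("ppb", "ppm", "ugm3"):
            raise ValueError(f"exposure units must be ppb|ppm|ugm3, got {self.exposure_units!r}")
        for p in self.datasets:
            if not Path(p).exists():
                raise FileNotFoundError(f"dataset file not found: {p}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("datasets", "families", "custom_afs"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("pod_override") is not None:
            d["pod_override"] = tuple(d["pod_override"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "datasets": list(self.datasets),
            "fixture_seed": self.fixture_seed,
            "families": list(self.families),
            "ces": self.ces,
            "ci_level": self.ci_level,
            "covariate_selection": self.covariate_selection,
            "adjustment": self.adjustment,
            "custom_adjustment": self.custom_adjustment,
            "afs": self.afs,
            "custom_afs": [dict(x) for x in self.custom_afs],
            "exposure_lower": self.exposure_lower,
            "exposure_upper": self.exposure_upper,
            "exposure_units": self.exposure_units,
            "pod_override": list(self.pod_override) if self.pod_override else None,
            "pod_level": self.pod_level,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "offset": self.offset,
            "log_level": self.log_level,
        }


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _resolve_adjustment(config: PipelineConfig) -> ExposureAdjustment:
    if config.adjustment == "worker":
        return WORKER_ADJUSTMENT
    if config.adjustment == "general":
        return GENERAL_POPULATION_ADJUSTMENT
    if not config.custom_adjustment:
        raise PipelineStageError("config", "custom adjustment selected but not provided")
    return ExposureAdjustment(**config.custom_adjustment)


def _resolve_afs(config: PipelineConfig) -> AssessmentFactorSet:
    if config.afs == "worker":
        return WORKER_AFS
    if config.afs == "general":
        return GENERAL_POPULATION_AFS
    return AssessmentFactorSet(tuple(AssessmentFactor(**x) for x in config.custom_afs))


def _exposure_ppb(config: PipelineConfig) -> tuple[float, float]:
    lo, hi = config.exposure_lower, config.exposure_upper
    if config.exposure_units == "ppm":
        return lo * 1000.0, hi * 1000.0
    if config.exposure_units == "ugm3":
        return ugm3_to_ppb(lo), ugm3_to_ppb(hi)
    return lo, hi


# ---------------------------------------------------------------------------
# Orchestration


def run_case_study(config: PipelineConfig) -> dict:
    """Execute the full chain described by ``config``.

    Returns a JSON-serializable report with the fitted models (both
    families when requested), the headline BMD result, the risk
    characterization, and the config/hash audit trail.  Intermediate
    artifacts are written to ``config.output_dir`` when set.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("case study start: seed=%d config=%s", config.seed, config_hash(config)[:12])

    fits: dict[str, ModelFit] = {}
    bmds: dict[str, BMDResult] = {}
    headline_family = None
    pod_source = "override" if config.pod_override else "bmd"

    if config.pod_override is None:
        try:
            if config.datasets:
                datasets = [read_dataset(p) for p in config.datasets]
            else:
                datasets = benzene_like_fixture(config.fixture_seed)
        except (DataDomainError, OSError) as e:
            raise PipelineStageError("data", str(e), exit_code=2) from e
        ces = CriticalEffectSize(config.ces)
        for family in config.families:
            try:
                bmd, fit = combined_analysis(
                    datasets,
                    family,
                    ces,
                    config.ci_level,
                    n_starts=config.n_starts if config.covariate_selection else 0,
                    seed=config.seed,
                    offset=config.offset,
                )
            except FitFailureError as e:
                raise PipelineStageError("fit", str(e), exit_code=3) from e
            except DataDomainError as e:
                raise PipelineStageError("fit", str(e), exit_code=2) from e
            fits[family] = fit
            bmds[family] = bmd
            logger.info("fitted %s: AIC=%.2f LL=%.2f", family, fit.aic, fit.log_lik)
        headline_family = min(fits, key=lambda f: fits[f].aic)
        bmd = bmds[headline_family]
        level = config.pod_level or bmd.levels[0]
        if level not in bmd.ced_hat:
            raise PipelineStageError("pod", f"covariate level {level!r} not in fit {list(bmd.levels)}")
        lo, hi = bmd.bmcl[level], bmd.bmcu[level]
        if lo is None or hi is None:
            raise PipelineStageError("pod", f"open profile interval for level {level!r}", exit_code=3)
        pod = PoDRange(lo, hi, basis=f"BMCL/BMCU (CES={config.ces:g}, {headline_family}, {level})")
    else:
        pod = PoDRange(*config.pod_override, basis="supplied PoD override")

    try:
        report_obj: RiskAssessmentReport = assess(
            pod,
            _resolve_adjustment(config),
            _resolve_afs(config),
            _exposure_ppb(config),
        )
    except ValueError as e:
        raise PipelineStageError("risk", str(e), exit_code=2) from e

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "pod_source": pod_source,
        "headline_family": headline_family,
        "fits": {f: fits[f].to_dict() for f in fits},
        "bmd": {f: bmds[f].to_dict() for f in bmds},
        "risk": report_obj.to_dict(),
        "risk_text": report_obj.to_text(),
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
        (out / "report.txt").write_text(report_obj.to_text() + "\n")
        logger.info("report written to %s", out / "report.json")
    logger.info("verdict: exposure %s the acceptable range", report_obj.verdict)
    return report
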