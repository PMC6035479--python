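"""Assembly of REM reports: per-source ranges, comparison measures, tables.

A report row per variation source (each declared covariate subset plus the
unexplained cluster variation, GCE) gives the 95% REM range in
square-bracket semantics — a description of the distribution — and REM(0.75)
/ REM(0.975) point values with round-bracket confidence intervals.  A
comparison block restates the cluster variation as MOR, PerSD and the
latent-scale ICC, with optional IOM ranges for user-specified covariate
patterns.  Effect values are rounded to 2 decimals and percentiles to whole
numbers for display; machine-readable output keeps full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MultilevelDataset
from .glmm import FittedMixedModel
from .measures import (
    BOUNDARY_SIGMA,
    EmpiricalRiskDistribution,
    NormalRandomEffect,
    icc_latent,
    iom,
    mor,
    mor_percentile,
    per_sd,
    percentile_equivalent,
    rem_empirical,
    rem_empirical_range,
    rem_random,
    rem_range,
)
from .uncertainty import IntervalEstimate, cluster_bootstrap, delta_ci_rem

__all__ = ["VariationSource", "REMReport", "compute_report", "model_from_estimates"]

try:
    __version__ = metadata.version("remvar")
except metadata.PackageNotFoundError:  # editable checkout without install
    __version__ = "0+unknown"


@dataclass
class VariationSource:
    """One row of the variation table (a covariate subset or the GCE)."""

    label: str
    dist: object  # RandomEffectDistribution | EmpiricalRiskDistribution
    range95: tuple[float, float]
    rem75: IntervalEstimate | None = None
    rem975: IntervalEstimate | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "range95": list(self.range95),
            "rem75": self.rem75.to_dict() if self.rem75 else None,
            "rem975": self.rem975.to_dict() if self.rem975 else None,
        }


@dataclass
class REMReport:
    """Full analysis report (sources + model + comparison + provenance)."""

    sources: list[VariationSource]
    model: dict
    table1: pd.DataFrame | None
    comparison: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sources": [s.to_dict() for s in self.sources],
            "model": self.model,
            "comparison": self.comparison,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    def sources_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        """Table-2-style frame: [range] and REM values with (CIs)."""
        rows = []
        for s in self.sources:
            row = {
                "source": s.label,
                "range95_low": s.range95[0],
                "range95_high": s.range95[1],
            }
            for name, est in (("rem75", s.rem75), ("rem975", s.rem975)):
                if est is not None:
                    row[name] = est.point
                    row[f"{name}_ci_low"] = est.low
                    row[f"{name}_ci_high"] = est.high
            rows.append(row)
        frame = pd.DataFrame(rows)
        if decimals is not None:
            num = frame.select_dtypes("number").columns
            frame[num] = frame[num].round(decimals)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.sources_frame(decimals=None).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj).__name__}")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def model_from_estimates(
    beta: dict[str, float],
    sigma_u: float,
    se_sigma_u: float = float("nan"),
    se_beta: dict[str, float] | None = None,
    family: str = "binomial",
) -> FittedMixedModel:
    """Build a measures-only model from published estimates (no raw data).

    Supports every closed-form measure and delta-method CI; empirical risk
    distributions and bootstrap CIs need the subject-level data and raise
    informative errors if attempted.
    """
    names = list(beta)
    b = pd.Series({k: float(v) for k, v in beta.items()})
    se = pd.Series(
        {k: float((se_beta or {}).get(k, np.nan)) for k in names}
    )
    vcov = pd.DataFrame(
        np.diag(np.r_[se.to_numpy() ** 2, se_sigma_u**2]),
        index=[*names, "sigma_u"],
        columns=[*names, "sigma_u"],
    )
    return FittedMixedModel(
        family=family,
        beta=b,
        sigma_u=float(sigma_u),
        se_beta=se,
        se_sigma_u=float(se_sigma_u),
        vcov=vcov,
        loglik=float("nan"),
        converged=True,
        boundary=sigma_u <= BOUNDARY_SIGMA,
        n_quad=0,
        message="constructed from user-supplied estimates",
        design=None,
    )


def _gce_source(
    model: FittedMixedModel,
    data: MultilevelDataset | None,
    ci: str,
    level: float,
    n_boot: int,
    seed: int | None,
) -> VariationSource:
    dist = model.random_effect
    rng95 = rem_range(dist, 0.95)
    ests = {}
    for name, a in (("rem75", 0.75), ("rem975", 0.975)):
        if model.boundary:
            ests[name] = IntervalEstimate(1.0, 1.0, 1.0, level, "degenerate")
        elif ci == "delta" or data is None:
            if np.isnan(model.se_sigma_u):
                ests[name] = None
            else:
                ests[name] = delta_ci_rem(model.sigma_u, model.se_sigma_u, a, level)
        else:
            ests[name] = cluster_bootstrap(
                data,
                lambda m, a=a: rem_random(m.random_effect, a),
                n_boot=n_boot,
                level=level,
                seed=seed,
                family=model.family,
                n_quad=max(model.n_quad, 7),
                fitted=model,
            )
    return VariationSource("unexplained cluster variation (GCE)", dist, rng95, **ests)


def _empirical_source(
    label: str,
    subset,
    model: FittedMixedModel,
    data: MultilevelDataset | None,
    ci: str,
    level: float,
    n_boot: int,
    seed: int | None,
) -> VariationSource:
    dist = model.risk_distribution(subset, label=label)
    rng95 = rem_empirical_range(dist, 0.95)
    ests: dict = {"rem75": None, "rem975": None}
    for name, a in (("rem75", 0.75), ("rem975", 0.975)):
        point = rem_empirical(dist, a)
        if ci == "bootstrap" and data is not None:
            ests[name] = cluster_bootstrap(
                data,
                lambda m, a=a, s=subset: rem_empirical(m.risk_distribution(s), a),
                n_boot=n_boot,
                level=level,
                seed=seed,
                family=model.family,
                n_quad=max(model.n_quad, 7),
                fitted=model,
            )
        else:  # no closed-form SE for empirical quantiles; point only
            ests[name] = IntervalEstimate(point, point, point, level, "none")
    return VariationSource(label, dist, rng95, **ests)


def compute_report(
    model: FittedMixedModel,
    data: MultilevelDataset | None = None,
    subsets: dict[str, object] | None = None,
    iom_patterns: dict[str, dict[str, float]] | None = None,
    ci: str = "delta",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
    provenance: dict | None = None,
) -> REMReport:
    """Assemble the full REM report for a fitted (or supplied) model.

    ``subsets`` maps row labels to covariate subsets (``"subject"``,
    ``"cluster"``, ``"all"``, a column name, or a list of columns); each
    becomes an empirical-risk row.  ``iom_patterns`` maps labels to
    covariate-value dicts for individual outcome measures.  ``ci`` selects
    ``"delta"`` or ``"bootstrap"`` intervals.
    """
    if ci not in ("delta", "bootstrap"):
        raise ValueError(f"ci must be 'delta' or 'bootstrap', got {ci!r}")
    if ci == "bootstrap" and data is None:
        raise ValueError("bootstrap CIs require the subject-level dataset")
    subsets = subsets or {}
    if subsets and model.design is None:
        raise ValueError(
            "empirical covariate-set REM requires subject-level data; "
            "a measures-only model has none"
        )

    sources = [
        _empirical_source(label, subset, model, data, ci, level, n_boot, seed)
        for label, subset in subsets.items()
    ]
    sources.append(_gce_source(model, data, ci, level, n_boot, seed))

    sigma = model.sigma_u
    comparison = {
        "mor": mor(sigma),
        "mor_rem_percentile": mor_percentile(),
        "per_sd_u": per_sd(sigma),
        "icc_latent": icc_latent(sigma),
    }
    if not model.boundary:
        pe = {}
        for name in model.beta.index:
            if name == "(Intercept)":
                continue
            p = percentile_equivalent(float(model.beta[name]), model.random_effect)
            pe[name] = {"percentile": p, "flipped": 1.0 - p}
        comparison["percentile_equivalents"] = pe
    if iom_patterns:
        iom_block = {}
        for label, pattern in iom_patterns.items():
            lp = float(model.beta.get("(Intercept)", 0.0))
            for name, value in pattern.items():
                lp += float(model.beta[name]) * value
            iom_block[label] = {
                "point": iom(lp, model.random_effect, 0.5, model.family),
                "low": iom(lp, model.random_effect, 0.025, model.family),
                "high": iom(lp, model.random_effect, 0.975, model.family),
            }
        comparison["iom"] = iom_block

    prov = {"software_version": __version__, "seed": seed}
    prov.update(provenance or {})
    return REMReport(
        sources=sources,
        model=model.to_dict(),
        table1=model.summary_table() if not np.isnan(model.se_beta).all() else None,
        comparison=comparison,
        provenance=prov,
    )
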