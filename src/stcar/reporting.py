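"""Posterior summaries in the study's reporting conventions.

Coefficient tables report the posterior median and the 2.5th/97.5th
percentiles pooled across chains; a coefficient is flagged significant
when that 95% credible interval excludes zero.  Because the response is
log emission intensity, a coefficient g is translated to an approximate
percent change in emissions for a covariate increment d by the linear
rule 100*g*d (e.g. a ULDI coefficient of 1.574 and an increment of 0.05
give 7.9%); the exact transformation 100*(exp(g*d)-1) is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import build_design  # noqa: F401  (re-exported: part of the reporting surface)
from .mcmc import PosteriorSamples

__all__ = [
    "CoefficientSummary",
    "EffectTranslation",
    "summarize",
    "effect_percent",
    "effect_translation",
    "temporal_trend",
    "spatial_pattern",
    "percent_increase",
    "build_design",
]


@dataclass
class CoefficientSummary:
    parameter: str
    median: float
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    significant: bool


@dataclass
class EffectTranslation:
    """Percent-change statement for a covariate increment ``delta``."""

    parameter: str
    delta: float
    percent_median: float
    percent_lower: float
    percent_upper: float

    def __str__(self) -> str:
        return (
            f"+{self.delta:g} in {self.parameter}: {self.percent_median}% "
            f"[{self.percent_lower}%, {self.percent_upper}%]"
        )


def summarize(
    samples: PosteriorSamples, round_decimals: int | None = 3
) -> pd.DataFrame:
    """Coefficient table: median, 2.5%, 97.5%, significance flag.

    Rows cover every regression coefficient plus tau2, sigma2, rho and
    lambda, in the order the fit named them.
    """
    params = samples.scalar_parameters()
    if next(iter(params.values())).size == 0:
        raise ValueError("no retained draws to summarize")
    rows = []
    for nm, draws in params.items():
        lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
        if round_decimals is not None:
            lo, med, hi = (round(v, round_decimals) for v in (lo, med, hi))
        rows.append(
            {
                "parameter": nm,
                "median": med,
                "lower": lo,
                "upper": hi,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def effect_percent(value: float, delta: float, scale: str = "linear") -> float:
    """Percent change in the response per ``delta`` covariate increment.

    ``linear`` (default) is 100*value*delta rounded to one decimal — the
    convention used for log-scale responses when coefficients are small;
    ``exp`` is the exact 100*(exp(value*delta)-1).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if scale == "linear":
        pct = 100.0 * value * delta
    elif scale == "exp":
        pct = 100.0 * (np.exp(value * delta) - 1.0)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return round(float(pct), 1)


def effect_translation(
    summary: pd.DataFrame, parameter: str, delta: float, scale: str = "linear"
) -> EffectTranslation:
    """Translate one summarized coefficient row into a percent statement."""
    row = summary.loc[parameter]
    return EffectTranslation(
        parameter=parameter,
        delta=delta,
        percent_median=effect_percent(row["median"], delta, scale),
        percent_lower=effect_percent(row["lower"], delta, scale),
        percent_upper=effect_percent(row["upper"], delta, scale),
    )


def percent_increase(initial: float, final: float) -> float:
    """Percent growth from ``initial`` to ``final``, one-decimal rounded."""
    if initial <= 0:
        raise ValueError("initial value must be positive")
    return round(100.0 * (final - initial) / initial, 1)


def temporal_trend(
    samples: PosteriorSamples, include_intercept: bool = False
) -> pd.DataFrame:
    """Per-year quartiles of the covariate-adjusted county estimates.

    For each year, the 25th/50th/75th percentiles across counties of the
    posterior median of psi_kt (optionally shifted by the posterior median
    intercept).  Columns: year, q25, q50, q75, with q25 <= q50 <= q75.
    """
    med = samples.psi_median()
    if include_intercept:
        med = med + np.median(samples.scalar_parameters()["intercept"])
    q = np.percentile(med, [25.0, 50.0, 75.0], axis=0)  # (3, T)
    return pd.DataFrame(
        {"year": samples.years, "q25": q[0], "q50": q[1], "q75": q[2]}
    )


def spatial_pattern(samples: PosteriorSamples, mode: str = "mean") -> pd.DataFrame:
    """Per-county latent-field estimate for choropleth mapping.

    ``mode='mean'`` time-averages the posterior medians of psi_kt;
    ``mode='last'`` uses the final year only.  The result joins to the
    polygon set on unit_id.
    """
    med = samples.psi_median()
    if mode == "mean":
        value = med.mean(axis=1)
    elif mode == "last":
        value = med[:, -1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame({"unit_id": samples.unit_ids, "value": value})
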