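"""Statistical-power cost of uncontrolled rhythmicity.

An uncontrolled cosine rhythm adds variance on top of the base
(rhythm-removed) variance of a biomarker:

    sigma2_total = sigma2_base + sigma2_rhythm + sigma2_cov

with sigma2_cov = 0 when the rhythm is independent of the base
variation.  For a two-group, equal-n, equal-variance, two-sided design
the per-group sample size and the Type II quantile are linked by

    n      = (Z_{alpha/2} + Z_beta)^2 * 2 * sigma2_total / d^2
    Z_beta = sqrt(n * d^2 / (2 * sigma2_total)) - Z_{alpha/2}

so inflating sigma2_total inflates n proportionally, or — at fixed n —
pushes Z_beta down and the Type II error rate beta up.

Two conventions for the rhythm variance of a cosine of z-score
amplitude A are exposed.  ``eq2_half`` is the variance sum law for a
cosine, sigma2_rhythm = A^2/2.  ``table3_full`` uses sigma2_rhythm =
A^2 and is the default: on z-scored data (total variance 1, controlled
variance 1 - sigma2_rhythm) it reproduces the published per-protein
increase-in-n and uncontrolled-beta percentages, which eq2_half does
not; see docs/methods.md for the audit.

On the unit-total-variance (z-score) formulation the two reported
columns are invariant to the effect size d, which therefore never
appears in them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import PopulationRhythmResult
from .errors import ConfigError

__all__ = [
    "VarianceConvention",
    "PowerParams",
    "VarianceDecomposition",
    "PowerAssessment",
    "total_variance",
    "required_n",
    "z_beta",
    "n_increase_pct",
    "beta_uncontrolled_pct",
    "build_table3",
    "assessments_to_frame",
    "power_curve",
    "round_half_up",
]


class VarianceConvention(str, enum.Enum):
    """How a cosine amplitude A maps to rhythm variance."""

    EQ2_HALF = "eq2-half"      # sigma2_rhythm = A^2 / 2 (variance sum law)
    TABLE3_FULL = "table3-full"  # sigma2_rhythm = A^2 (reproduces the published table)

    @classmethod
    def coerce(cls, value: "VarianceConvention | str") -> "VarianceConvention":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).replace("_", "-"))
        except ValueError:
            raise ConfigError(
                "variance_convention",
                f"must be one of {[m.value for m in cls]}, got {value!r}",
            ) from None


DEFAULT_CONVENTION = VarianceConvention.TABLE3_FULL


@dataclass(frozen=True)
class PowerParams:
    """Design parameters of the two-group comparison.

    alpha is the two-sided significance level, beta_baseline the Type II
    rate the study is designed for (0.20 = 80 % power), and
    effect_size_d the group mean difference in z-score units.
    """

    alpha: float = 0.05
    beta_baseline: float = 0.20
    effect_size_d: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha", f"must be in (0, 1), got {self.alpha}")
        if not (0 < self.beta_baseline < 1):
            raise ConfigError("beta_baseline", f"must be in (0, 1), got {self.beta_baseline}")
        if not (self.effect_size_d > 0):
            raise ConfigError("effect_size_d", f"must be > 0, got {self.effect_size_d}")

    @property
    def z_alpha_half(self) -> float:
        return float(stats.norm.ppf(1 - self.alpha / 2))

    @property
    def z_beta_baseline(self) -> float:
        return float(stats.norm.ppf(1 - self.beta_baseline))


@dataclass(frozen=True)
class VarianceDecomposition:
    """Additive variance components of a rhythmic biomarker."""

    sigma2_base: float
    sigma2_rhythm: float
    sigma2_cov: float = 0.0

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_base + self.sigma2_rhythm + self.sigma2_cov


@dataclass(frozen=True)
class PowerAssessment:
    """Power cost of one rhythmic protein (one row of the summary table).

    ``n_increase_pct`` and ``beta_uncontrolled_pct`` are kept unrounded;
    rounding to integer percent happens once, in the reporting layer.
    """

    protein_id: str
    period: float
    amplitude: float
    n_increase_pct: float
    beta_uncontrolled_pct: float
    decomposition: VarianceDecomposition


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf (23.5 -> 24)."""
    return int(math.floor(x + 0.5))


def _rhythm_variance(
    amplitude: float | Iterable[float], convention: VarianceConvention
) -> float:
    amps = np.atleast_1d(np.asarray(amplitude, dtype=float))
    if np.any(amps < 0):
        raise ConfigError("amplitude", "amplitudes must be >= 0")
    per = amps**2 / 2 if convention is VarianceConvention.EQ2_HALF else amps**2
    return float(per.sum())  # multiple components add their rhythm variances


def total_variance(
    sigma2_base: float,
    amplitude: float | Iterable[float],
    convention: VarianceConvention | str = DEFAULT_CONVENTION,
) -> VarianceDecomposition:
    """Decompose total variance into base + rhythm (covariance fixed at 0).

    ``amplitude`` may be a scalar or an iterable of component amplitudes
    whose rhythm variances add.
    """
    if sigma2_base < 0:
        raise ConfigError("sigma2_base", f"must be >= 0, got {sigma2_base}")
    convention = VarianceConvention.coerce(convention)
    return VarianceDecomposition(
        sigma2_base=float(sigma2_base),
        sigma2_rhythm=_rhythm_variance(amplitude, convention),
        sigma2_cov=0.0,
    )


def required_n(params: PowerParams, sigma2_total: float) -> tuple[float, int]:
    """Per-group n maintaining the designed power at the given total variance.

    Returns the real-valued n and its ceiling.  n scales linearly in
    sigma2_total, which is exactly how rhythm variance inflates the
    required cohort size.
    """
    if not (sigma2_total > 0):
        raise ConfigError("sigma2_total", f"must be > 0, got {sigma2_total}")
    n_real = (
        (params.z_alpha_half + params.z_beta_baseline) ** 2
        * 2.0
        * sigma2_total
        / params.effect_size_d**2
    )
    return n_real, math.ceil(n_real)


def z_beta(n: float, params: PowerParams, sigma2_total: float) -> tuple[float, float]:
    """Type II quantile and error rate at a fixed per-group n.

    Returns (Z_beta, beta) with beta the upper-tail standard normal
    probability of Z_beta.  Feeding the real-valued output of
    :func:`required_n` back recovers the baseline Z_beta exactly.
    """
    if not (n > 0):
        raise ConfigError("n", f"must be > 0, got {n}")
    if not (sigma2_total > 0):
        raise ConfigError("sigma2_total", f"must be > 0, got {sigma2_total}")
    zb = math.sqrt(n * params.effect_size_d**2 / (2.0 * sigma2_total)) - params.z_alpha_half
    return zb, float(stats.norm.sf(zb))


def _controlled_variance(
    amplitude: float | Iterable[float], convention: VarianceConvention
) -> float:
    # z-scored data: total variance fixed at 1; controlling the rhythm
    # removes sigma2_rhythm, leaving sigma2_base = 1 - sigma2_rhythm.
    s2r = _rhythm_variance(amplitude, convention)
    if s2r >= 1:
        raise ConfigError(
            "amplitude",
            f"rhythm variance {s2r:.3f} >= 1 is incompatible with unit total variance",
        )
    return 1.0 - s2r


def n_increase_pct(
    amplitude: float | Iterable[float],
    convention: VarianceConvention | str = DEFAULT_CONVENTION,
) -> float:
    """Percent increase in required n when the rhythm is left uncontrolled.

    On z-scored data the uncontrolled total variance is 1 and the
    controlled variance is 1 - sigma2_rhythm; because n is proportional
    to the variance, the increase is 100 * (1 / sigma2_base - 1),
    independent of alpha, beta and effect size.
    """
    convention = VarianceConvention.coerce(convention)
    s2b = _controlled_variance(amplitude, convention)
    return 100.0 * (1.0 / s2b - 1.0)


def beta_uncontrolled_pct(
    amplitude: float | Iterable[float],
    params: PowerParams = PowerParams(),
    convention: VarianceConvention | str = DEFAULT_CONVENTION,
) -> float:
    """Type II error rate (percent) if the rhythm is not controlled.

    n is fixed at the value achieving the baseline power under the
    controlled variance sigma2_base = 1 - sigma2_rhythm; the design is
    then evaluated at the uncontrolled variance 1, giving

        Z_beta = (Z_{alpha/2} + Z_{beta0}) * sqrt(sigma2_base) - Z_{alpha/2}

    and beta as its upper-tail normal probability.
    """
    convention = VarianceConvention.coerce(convention)
    s2b = _controlled_variance(amplitude, convention)
    n_real, _ = required_n(params, s2b)
    _, beta = z_beta(n_real, params, 1.0)
    return 100.0 * beta


def build_table3(
    results: Sequence[PopulationRhythmResult],
    params: PowerParams = PowerParams(),
    convention: VarianceConvention | str = DEFAULT_CONVENTION,
) -> list[PowerAssessment]:
    """Power assessments for every screen-passing protein x period.

    Rows are ordered by period group, then ascending p-value, matching
    the published layout (12 h panel before 24 h).
    """
    convention = VarianceConvention.coerce(convention)
    rows = sorted(
        (r for r in results if r.passes_screen),
        key=lambda r: (r.period, r.p_value, r.protein_id),
    )
    out = []
    for r in rows:
        s2b = _controlled_variance(r.pop_amplitude, convention)
        out.append(
            PowerAssessment(
                protein_id=r.protein_id,
                period=r.period,
                amplitude=r.pop_amplitude,
                n_increase_pct=n_increase_pct(r.pop_amplitude, convention),
                beta_uncontrolled_pct=beta_uncontrolled_pct(
                    r.pop_amplitude, params, convention
                ),
                decomposition=VarianceDecomposition(
                    sigma2_base=s2b, sigma2_rhythm=1.0 - s2b
                ),
            )
        )
    return out


def assessments_to_frame(
    assessments: Sequence[PowerAssessment], rounded: bool = True
) -> pd.DataFrame:
    """Tabulate power assessments; integer-percent rounding happens here only."""
    frame = pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in assessments],
            "period": [a.period for a in assessments],
            "amplitude_z": [a.amplitude for a in assessments],
            "n_increase_pct": [a.n_increase_pct for a in assessments],
            "beta_uncontrolled_pct": [a.beta_uncontrolled_pct for a in assessments],
        }
    )
    if rounded:
        for col in ("n_increase_pct", "beta_uncontrolled_pct"):
            frame[col] = frame[col].map(round_half_up)
    return frame


def power_curve(
    amplitude_grid: Iterable[float],
    params: PowerParams = PowerParams(),
    convention: VarianceConvention | str = DEFAULT_CONVENTION,
) -> pd.DataFrame:
    """Increase-in-n and uncontrolled-beta as functions of amplitude.

    Both columns are monotone non-decreasing in A and grow with A^2 to
    leading order.  Values are unrounded, ready for plotting.
    """
    convention = VarianceConvention.coerce(convention)
    grid = [float(a) for a in amplitude_grid]
    return pd.DataFrame(
        {
            "amplitude_z": grid,
            "n_increase_pct": [n_increase_pct(a, convention) for a in grid],
            "beta_pct": [beta_uncontrolled_pct(a, params, convention) for a in grid],
        }
    )
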