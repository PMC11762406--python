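"""Single-component cosinor fitting and population-mean rhythm inference.

Each individual's z-scored series is regressed on
``[1, cos(2*pi*t/tau), sin(2*pi*t/tau)]`` by ordinary least squares,
giving MESOR M, coefficients (beta, gamma), amplitude
``A = sqrt(beta^2 + gamma^2)`` and acrophase
``phi = (tau / 2*pi) * atan2(gamma, beta)`` mapped into [0, tau).

The population is summarized by the arithmetic mean of the individual
coefficient vectors.  The zero-amplitude hypothesis (no rhythm at period
tau) is tested with the classical population-mean cosinor statistic: a
Hotelling-type

    T^2 = k * (beta_bar, gamma_bar) S^{-1} (beta_bar, gamma_bar)^T

with S the sample covariance of the k per-subject (beta_i, gamma_i)
pairs, referred to F = ((k-2) / (2*(k-1))) * T^2 on (2, k-2) degrees of
freedom.

The screen runs this test per protein at each candidate period (24 h and
12 h by default) and flags proteins with p < 0.05 and population
amplitude > 0.1 (strict inequalities).  No protein-level multiplicity
correction is applied; an optional Benjamini-Hochberg column can be
emitted for the report but never gates the screen flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateCovarianceError, FitError
from .preprocess import ScaledSeriesSet, wrap_dlmo_hours

__all__ = [
    "IndividualCosinorFit",
    "PopulationRhythmResult",
    "ScreenOutcome",
    "fit_individual_cosinor",
    "population_cosinor_test",
    "screen_rhythmic",
    "results_to_frame",
    "polar_export",
]

DEFAULT_PERIODS: tuple[float, ...] = (24.0, 12.0)
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_AMP_THRESHOLD = 0.1


@dataclass(frozen=True)
class IndividualCosinorFit:
    """One subject's least-squares cosinor fit at a fixed period."""

    participant_id: str
    protein_id: str
    period: float
    mesor: float
    beta_coef: float
    gamma_coef: float
    amplitude: float
    acrophase: float
    n_points: int
    residual_ss: float

    def predict(self, times: np.ndarray) -> np.ndarray:
        w = 2 * np.pi / self.period
        t = np.asarray(times, dtype=float)
        return self.mesor + self.beta_coef * np.cos(w * t) + self.gamma_coef * np.sin(w * t)


@dataclass(frozen=True)
class PopulationRhythmResult:
    """Population-mean cosinor summary and zero-amplitude test for one protein x period."""

    protein_id: str
    period: float
    k_subjects: int
    pop_mesor: float
    pop_amplitude: float
    pop_acrophase: float
    p_value: float
    passes_screen: bool


@dataclass
class ScreenOutcome:
    """Results of a multi-period screen plus any per-protein fit failures."""

    results: list[PopulationRhythmResult]
    failures: list[dict]

    def passing(self) -> list[PopulationRhythmResult]:
        return [r for r in self.results if r.passes_screen]


def _amp_acrophase(beta: float, gamma: float, period: float) -> tuple[float, float]:
    amplitude = math.hypot(beta, gamma)
    acrophase = (period / (2 * math.pi)) * math.atan2(gamma, beta) % period
    return amplitude, acrophase


def fit_individual_cosinor(
    times,
    values,
    period: float,
    participant_id: str = "",
    protein_id: str = "",
) -> IndividualCosinorFit:
    """Ordinary least squares cosinor fit of one series at a fixed period.

    NaN values are dropped pairwise.  Requires >= 4 usable points and a
    full-rank design (times not all congruent modulo the period).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise FitError(f"times and values have mismatched shapes {t.shape} vs {y.shape}")
    keep = ~np.isnan(y) & ~np.isnan(t)
    t, y = t[keep], y[keep]
    if t.size < 4:
        raise FitError(
            f"cosinor fit needs >= 4 non-missing points, got {t.size} "
            f"(participant {participant_id!r}, protein {protein_id!r})"
        )
    w = 2 * np.pi / period
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise FitError(
            f"rank-deficient cosinor design at period {period} h: sampling times "
            f"are degenerate modulo the period "
            f"(participant {participant_id!r}, protein {protein_id!r})"
        )
    mesor, beta, gamma = (float(c) for c in coefs)
    amplitude, acrophase = _amp_acrophase(beta, gamma, period)
    resid = y - design @ coefs
    return IndividualCosinorFit(
        participant_id=participant_id,
        protein_id=protein_id,
        period=float(period),
        mesor=mesor,
        beta_coef=beta,
        gamma_coef=gamma,
        amplitude=amplitude,
        acrophase=acrophase,
        n_points=int(t.size),
        residual_ss=float(resid @ resid),
    )


def population_cosinor_test(
    fits: list[IndividualCosinorFit],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> PopulationRhythmResult:
    """Population-mean cosinor with the Hotelling-type zero-amplitude test.

    All fits must share one protein and period and come from k >= 3
    subjects.  Population MESOR/amplitude/acrophase derive from the mean
    coefficient vector; the p-value is F-distributed on (2, k-2) under
    the no-rhythm null.

    Raises
    ------
    FitError
        If k < 3 or the fits mix proteins/periods.
    DegenerateCovarianceError
        If the between-subject coefficient covariance is singular
        (e.g. identical noiseless subjects).
    """
    k = len(fits)
    if k < 3:
        raise FitError(f"population cosinor needs k >= 3 subjects, got {k}")
    proteins = {f.protein_id for f in fits}
    periods = {f.period for f in fits}
    if len(proteins) != 1 or len(periods) != 1:
        raise FitError(
            f"fits mix proteins {sorted(proteins)} or periods {sorted(periods)}"
        )
    protein_id, period = fits[0].protein_id, fits[0].period

    coefs = np.array([[f.beta_coef, f.gamma_coef] for f in fits])  # (k, 2)
    mean_vec = coefs.mean(axis=0)
    cov = np.cov(coefs, rowvar=False, ddof=1)
    # Guard against exact singularity (identical subjects) before inverting.
    if not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < 2:
        raise DegenerateCovarianceError(
            f"singular between-subject coefficient covariance for protein "
            f"{protein_id!r} at period {period} h (are subjects identical?)"
        )
    t2 = float(k * mean_vec @ np.linalg.solve(cov, mean_vec))
    f_stat = (k - 2) / (2 * (k - 1)) * t2
    p_value = float(stats.f.sf(f_stat, 2, k - 2))

    pop_mesor = float(np.mean([f.mesor for f in fits]))
    pop_amplitude, pop_acrophase = _amp_acrophase(mean_vec[0], mean_vec[1], period)
    return PopulationRhythmResult(
        protein_id=protein_id,
        period=period,
        k_subjects=k,
        pop_mesor=pop_mesor,
        pop_amplitude=pop_amplitude,
        pop_acrophase=pop_acrophase,
        p_value=p_value,
        passes_screen=(p_value < p_threshold) and (pop_amplitude > amp_threshold),
    )


def screen_rhythmic(
    data: ScaledSeriesSet,
    periods=DEFAULT_PERIODS,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> ScreenOutcome:
    """Run the population-mean cosinor screen at every candidate period.

    One :class:`PopulationRhythmResult` is produced per protein x period
    (a protein may pass at both 24 h and 12 h).  Per-protein failures
    (too few subjects, degenerate fits) do not abort the screen; they
    are collected in the outcome's ``failures`` list.
    """
    results: list[PopulationRhythmResult] = []
    failures: list[dict] = []
    for protein_id, prot_grp in data.series.groupby("protein_id", sort=True):
        for period in periods:
            try:
                fits = [
                    fit_individual_cosinor(
                        grp["dlmo_time"], grp["z_value"], period,
                        participant_id=str(pid), protein_id=str(protein_id),
                    )
                    for pid, grp in prot_grp.groupby("participant_id", sort=True)
                ]
                results.append(
                    population_cosinor_test(fits, p_threshold, amp_threshold)
                )
            except (FitError, DegenerateCovarianceError) as exc:
                failures.append(
                    {"protein_id": str(protein_id), "period": float(period), "error": str(exc)}
                )
    results.sort(key=lambda r: (r.period, r.p_value, r.protein_id))
    return ScreenOutcome(results=results, failures=failures)


def results_to_frame(
    results: list[PopulationRhythmResult], add_bh_column: bool = False
) -> pd.DataFrame:
    """Tabulate screen results: protein, period, acrophase, p-value, amplitude.

    ``acrophase_signed`` gives the (-tau/2, tau/2] display convention.
    With ``add_bh_column`` a Benjamini-Hochberg adjusted p-value is
    appended per period for reference only; it never affects
    ``passes_screen``.
    """
    frame = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "period": [r.period for r in results],
            "k_subjects": [r.k_subjects for r in results],
            "acrophase_dlmo_h": [r.pop_acrophase for r in results],
            "acrophase_signed": [
                wrap_dlmo_hours(r.pop_acrophase, r.period) for r in results
            ],
            "p_value": [r.p_value for r in results],
            "amplitude_z": [r.pop_amplitude for r in results],
            "passes_screen": [r.passes_screen for r in results],
        }
    )
    if add_bh_column and len(frame):
        adjusted = np.full(len(frame), np.nan)
        for _, idx in frame.groupby("period").groups.items():
            p = frame.loc[idx, "p_value"].to_numpy()
            adjusted[frame.index.get_indexer(idx)] = stats.false_discovery_control(p)
        frame["p_bh"] = adjusted
    return frame


def polar_export(results: list[PopulationRhythmResult]) -> pd.DataFrame:
    """Acrophase angle (radians) and amplitude radius for polar plotting."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "period": [r.period for r in results],
            "acrophase_dlmo_h": [r.pop_acrophase for r in results],
            "angle_rad": [2 * math.pi * r.pop_acrophase / r.period for r in results],
            "amplitude_z": [r.pop_amplitude for r in results],
        }
    )
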