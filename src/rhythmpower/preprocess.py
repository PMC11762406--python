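"""Data preparation: replicate averaging, missingness filter, z-scaling, DLMO time.

The stages reproduce the preparation applied to a DLMO-aligned plasma
proteome before rhythm screening: technical replicates are averaged,
proteins with more than 10 % missing cells are excluded, and each
(participant, protein) series is expressed as a participant z-score so
that amplitudes are comparable across proteins and the total series
variance is 1 — the convention the power module builds on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConstantSeriesError, FitError
from .simulate import RECORD_COLUMNS, CohortDataset

__all__ = [
    "ScaledSeriesSet",
    "average_replicates",
    "filter_missing_proteins",
    "zscore_per_participant",
    "clock_to_dlmo",
    "dlmo_to_clock",
    "wrap_dlmo_hours",
    "decimal_to_hhmm",
]


@dataclass
class ScaledSeriesSet:
    """Per-(participant, protein) z-scored series.

    ``series`` has columns participant_id, protein_id, dlmo_time,
    z_value, one row per retained non-missing sample; each series has
    sample mean 0 and sample sd 1 (ddof=1) whenever >= 2 points exist.
    ``provenance`` records, per (participant, protein), how many
    replicate-averaged points entered the series and how many missing
    cells were dropped.
    """

    series: pd.DataFrame
    provenance: pd.DataFrame


def average_replicates(dataset: CohortDataset) -> CohortDataset:
    """Collapse technical replicates to their arithmetic mean.

    A cell (participant, protein, timepoint) is missing in the output
    iff all of its replicates are missing; otherwise the mean of the
    non-missing replicates is used.  The output has ``replicate == 0``
    for every row.
    """
    grouped = (
        dataset.records.groupby(["participant_id", "protein_id", "dlmo_time"], sort=True)[
            "abundance"
        ]
        .mean()  # skips NaN; all-NaN -> NaN
        .reset_index()
    )
    grouped["replicate"] = 0
    return CohortDataset(
        records=grouped[RECORD_COLUMNS],
        dlmo_clock=dict(dataset.dlmo_clock),
        ground_truth=dataset.ground_truth,
    )


def filter_missing_proteins(
    dataset: CohortDataset, max_missing: float = 0.10
) -> tuple[CohortDataset, pd.DataFrame]:
    """Drop proteins whose missing fraction exceeds ``max_missing``.

    The fraction is computed on the replicate-averaged table across all
    (participant x timepoint) cells jointly.  The boundary is strict:
    a protein is dropped iff fraction > ``max_missing``, so 1 missing
    cell of 16 (6.25 %) is kept and 2 of 16 (12.5 %) are dropped at the
    default 10 % threshold.

    Returns the filtered dataset and a report frame with columns
    protein_id, missing_fraction, kept.
    """
    frac = (
        dataset.records["abundance"]
        .isna()
        .groupby(dataset.records["protein_id"], sort=True)
        .mean()
    )
    report = pd.DataFrame(
        {
            "protein_id": frac.index,
            "missing_fraction": frac.values,
            "kept": frac.values <= max_missing,
        }
    ).reset_index(drop=True)
    keep = set(report.loc[report["kept"], "protein_id"])
    records = dataset.records[dataset.records["protein_id"].isin(keep)].reset_index(drop=True)
    gt = dataset.ground_truth
    if gt is not None:
        gt = tuple(s for s in gt if s.protein_id in keep)
    filtered = CohortDataset(records=records, dlmo_clock=dict(dataset.dlmo_clock), ground_truth=gt)
    return filtered, report


def zscore_per_participant(dataset: CohortDataset) -> ScaledSeriesSet:
    """Express every (participant, protein) series as participant z-scores.

    Missing cells are dropped; the remaining values are centred to mean
    0 and scaled to sample sd 1 (ddof=1).  Z-scoring is idempotent.

    Raises
    ------
    ConstantSeriesError
        If a series is constant (sd = 0); the error names the
        participant and protein.
    FitError
        If a series has fewer than 2 non-missing values.
    """
    keys = ["participant_id", "protein_id"]
    records = dataset.records.sort_values(keys + ["dlmo_time"], kind="mergesort")
    n_total = records.groupby(keys, sort=True).size()
    obs = records.dropna(subset=["abundance"]).reset_index(drop=True)
    grouped = obs.groupby(keys, sort=True)["abundance"]
    stats = grouped.agg(n_points="count", mean="mean", sd="std")  # pandas std: ddof=1

    too_few = stats.index[stats["n_points"] < 2]
    if len(too_few):
        pid, prot = too_few[0]
        raise FitError(
            f"series for participant {pid!r}, protein {prot!r} has "
            f"{int(stats.loc[(pid, prot), 'n_points'])} non-missing values; need >= 2 to scale"
        )
    degenerate = stats.index[(stats["sd"] == 0) | ~np.isfinite(stats["sd"])]
    if len(degenerate):
        pid, prot = degenerate[0]
        raise ConstantSeriesError(str(pid), str(prot))

    z = (obs["abundance"] - grouped.transform("mean")) / grouped.transform("std")
    series = obs[keys + ["dlmo_time"]].copy()
    series["z_value"] = z.to_numpy(dtype=float)
    provenance = stats.reset_index()[keys + ["n_points"]]
    provenance["n_missing"] = (
        n_total.reindex(pd.MultiIndex.from_frame(provenance[keys])).to_numpy()
        - provenance["n_points"].to_numpy()
    )
    return ScaledSeriesSet(series=series.reset_index(drop=True), provenance=provenance)


# ---------------------------------------------------------------------------
# Clock <-> DLMO time
# ---------------------------------------------------------------------------

def clock_to_dlmo(clock_time: float, participant_dlmo_clock: float) -> float:
    """Hours elapsed since the participant's dim light melatonin onset.

    ``clock_time`` is in decimal hours and may exceed 24 for sequential
    sampling sessions (e.g. 27.77 for 03:46 the next day), which keeps
    the mapping monotone across a 30 h session.  A sample taken before
    DLMO yields a negative DLMO hour (20.77 with DLMO at 22.77 -> -2.0).
    """
    return float(clock_time) - float(participant_dlmo_clock)


def dlmo_to_clock(dlmo_hours: float, participant_dlmo_clock: float) -> float:
    """Inverse of :func:`clock_to_dlmo`; reduce modulo 24 for wall-clock display."""
    return float(dlmo_hours) + float(participant_dlmo_clock)


def wrap_dlmo_hours(dlmo_hours: float, period: float = 24.0) -> float:
    """Map a DLMO-hour (or acrophase) into the signed display range (-period/2, period/2]."""
    wrapped = -((-float(dlmo_hours) + period / 2) % period) + period / 2
    return period / 2 if wrapped == -period / 2 else wrapped


def decimal_to_hhmm(decimal_hours: float) -> str:
    """Render decimal hours as "HH:MM" (e.g. 22.77 -> "22:46").

    The input is normalised modulo 24; minutes are rounded to the
    nearest integer with correct carry (23.999 -> "00:00").
    """
    if not math.isfinite(decimal_hours):
        raise ValueError(f"decimal_hours must be finite, got {decimal_hours}")
    h = float(decimal_hours) % 24.0
    hours = int(h)
    minutes = round(60 * (h - hours))
    if minutes == 60:
        minutes = 0
        hours = (hours + 1) % 24
    return f"{hours:02d}:{minutes:02d}"
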