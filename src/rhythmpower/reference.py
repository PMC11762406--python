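"""Bundled reference screen results from a 10-participant constant-routine cohort.

Fifteen plasma proteins flagged as rhythmic (population-mean cosinor,
p < 0.05 and z-score amplitude > 0.1) in a two-hourly, 30 h, DLMO-aligned
sampling study: nine at the 12 h period and six at the 24 h period, with
plasminogen and fibrinogen alpha chain appearing at both.  These rows
serve as ready-made inputs for the power module — e.g. to rebuild the
per-protein increase-in-n / uncontrolled-beta table — without rerunning
the screen on raw data.

Acrophases are in DLMO hours under the signed display convention
(-tau/2, tau/2]; amplitudes are intra-individual z-scores.
"""

from __future__ import annotations

import pandas as pd

from .cosinor import PopulationRhythmResult

__all__ = ["REFERENCE_COHORT_SIZE", "reference_screen_results", "reference_frame"]

#: Participants in the reference cohort.
REFERENCE_COHORT_SIZE = 10

#: Mean cohort DLMO clock time (decimal hours) and its SD.
REFERENCE_DLMO_CLOCK = (22.77, 1.11)

# protein (gene), uniprot, period h, acrophase (signed DLMO h), p, amplitude (z)
_ROWS = [
    ("AZGP1", "P25311", 12.0, 4.4, 0.009, 0.28),
    ("ITIH2", "P19823", 12.0, 10.0, 0.019, 0.30),
    ("FGA", "P02671", 12.0, 7.9, 0.019, 0.30),
    ("KNG1", "P01042", 12.0, 5.0, 0.020, 0.23),
    ("APOA2", "P02652", 12.0, 10.1, 0.021, 0.27),
    ("IGK", "P0DOX7", 12.0, 3.7, 0.039, 0.27),
    ("PLG", "P00747", 12.0, 5.8, 0.039, 0.22),
    ("IGHM", "P01871", 12.0, 0.3, 0.042, 0.31),
    ("IGKC", "P01834", 12.0, 3.5, 0.049, 0.27),
    ("PLG", "P00747", 24.0, -0.9, 0.010, 0.37),
    ("APOC3", "P02656", 24.0, 7.5, 0.011, 0.41),
    ("FGA", "P02671", 24.0, -2.1, 0.025, 0.32),
    ("FGB", "P02675", 24.0, 0.0, 0.034, 0.31),
    ("CFH", "P08603", 24.0, 0.2, 0.042, 0.29),
    ("APOE", "P02649", 24.0, 5.4, 0.043, 0.37),
]


def reference_frame() -> pd.DataFrame:
    """The reference rhythmic-protein table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["protein_id", "uniprot_id", "period", "acrophase_signed", "p_value", "amplitude_z"],
    )


def reference_screen_results() -> list[PopulationRhythmResult]:
    """Reference rows as :class:`PopulationRhythmResult` objects.

    Acrophases are mapped back into [0, period); all rows pass the
    screen by construction.
    """
    return [
        PopulationRhythmResult(
            protein_id=gene,
            period=period,
            k_subjects=REFERENCE_COHORT_SIZE,
            pop_mesor=0.0,
            pop_amplitude=amplitude,
            pop_acrophase=acrophase % period,
            p_value=p,
            passes_screen=True,
        )
        for gene, _uniprot, period, acrophase, p, amplitude in _ROWS
    ]
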