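"""Small reference datasets for worked examples and validation.

These are published-style clinical reference values from breath-hold
six-echo GraSE myocardial T2 mapping at 1.5 T, shipped as plain numbers:
the 16-segment T2 profile of one healthy volunteer (a complete worked
example for the segmental aggregation rules) and the global T2 of five
patients with acute myocardial injury.  They serve as fixed inputs for
examples and round-trip checks — nothing in the package derives from
them at fit time.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["healthy_example_segments", "patient_cohort"]


def healthy_example_segments() -> pd.DataFrame:
    """Segmental myocardial T2 (ms) of one healthy volunteer.

    Sixteen AHA segments measured with the six-echo GraSE protocol
    (echo times 23.6-82.6 ms), one breath-hold per slice.  Columns:
    ``aha_id``, ``level``, ``name``, ``t2_ms``.
    """
    rows = [
        (1, "basal", "anterior", 50.1),
        (2, "basal", "anteroseptal", 51.6),
        (3, "basal", "inferoseptal", 47.6),
        (4, "basal", "inferior", 47.7),
        (5, "basal", "inferolateral", 45.0),
        (6, "basal", "anterolateral", 52.9),
        (7, "mid", "anterior", 55.5),
        (8, "mid", "anteroseptal", 57.1),
        (9, "mid", "inferoseptal", 50.2),
        (10, "mid", "inferior", 50.2),
        (11, "mid", "inferolateral", 54.6),
        (12, "mid", "anterolateral", 49.2),
        (13, "apical", "anterior", 54.7),
        (14, "apical", "septal", 54.8),
        (15, "apical", "inferior", 49.4),
        (16, "apical", "lateral", 54.9),
    ]
    return pd.DataFrame(rows, columns=["aha_id", "level", "name", "t2_ms"])


def patient_cohort() -> pd.DataFrame:
    """Global myocardial T2 of five patients with acute myocardial injury.

    Six-echo GraSE T2 mapping in two patients with acute myocarditis,
    two with acute myocardial infarction and one with takotsubo
    cardiomyopathy.  ``t2_global_ms`` / ``t2_global_sd_ms`` are each
    patient's global myocardial T2 mean and SD; healthy myocardium lies
    near 52 ms, so all five are prolonged.
    """
    rows = [
        (1, "acute diffuse myocarditis", "F", 42, 68.0, 2.4),
        (2, "acute myocardial infarction", "F", 53, 62.5, 13.1),
        (3, "takotsubo cardiomyopathy", "F", 44, 63.5, 6.0),
        (4, "acute myocarditis", "M", 28, 57.7, 8.7),
        (5, "acute myocardial infarction", "M", 68, 54.8, 4.1),
    ]
    return pd.DataFrame(
        rows,
        columns=["patient", "diagnosis", "sex", "age", "t2_global_ms", "t2_global_sd_ms"],
    )
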