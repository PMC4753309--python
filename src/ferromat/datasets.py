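"""Small published reference datasets used by the analyses.

These are field measurements printed in the source study's tables for
the two Norris Geyser Basin springs; they serve as inputs to summary
computations (e.g. the multi-year O2 flux mean) and as the reference
side of the primer-bias diagnostic.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "o2_flux_survey",
    "mature_mat_abundance_survey",
    "site_hydrodynamics",
]


def o2_flux_survey() -> pd.DataFrame:
    """Multi-year O2 microelectrode survey of the two springs.

    Columns: spring, temperature (C), sample date, net areal O2 flux
    (umol cm^-2 s^-1), penetration depth (um; midpoint when a range was
    reported), Thiele modulus (NaN where not determined).
    """
    return pd.DataFrame(
        [
            ("OSP", 75, "2013-05-21", 1.14e-4, 950.0, 28.0),
            ("OSP", 75, "2010-08-18", 1.41e-4, 750.0, 30.0),
            ("Beowulf", 68, "2011-07-06", 1.64e-4, 625.0, 60.0),
            ("Beowulf", 60, "2004-07-13", 5.0e-5, 500.0, float("nan")),
        ],
        columns=["spring", "temperature_c", "date", "flux_umol_cm2_s",
                 "penetration_um", "thiele_modulus"],
    )


def mature_mat_abundance_survey() -> pd.DataFrame:
    """Relative abundance (%) of phylotypes in mature Fe(III)-oxide mats.

    Amplicon (16S iTag) columns sit alongside random shotgun-sequencing
    estimates from matching samples; NaN marks phylotypes not detected
    by a method (amplicon dropout for *M. yellowstonensis* in Beowulf
    reflects the 515F primer mismatch, not absence).
    """
    data = {
        "taxon": [
            "M. yellowstonensis", "Hydrogenobaculum", "Geoarchaeota",
            "Novel archaeal group 2", "Thaumarchaeota",
            "Novel archaeal group 3", "Other Sulfolobales", "Nanoarchaeota",
        ],
        "osp_454": [10.3, 3.4, 43.4, 4, 0.4, 0.1, 2.5, 0.2],
        "osp_illumina": [16, 3, 33, 6, 0.4, 0.12, 4, 0.6],
        "osp_itag": [0.51, 24.2, 41, 24, 3, float("nan"), 3.3, float("nan")],
        "beowulf_sanger": [3.9, 2, 1, 26, 19, 4, 3.9, 0],
        "beowulf_454": [6.6, 1.2, 3, 38, 4.4, 3, 10, 0.1],
        "beowulf_illumina": [12, 4.3, 6, 27, 2, 5, 11, 0.6],
        "beowulf_itag": [float("nan"), 14, 4, 42, 3.2, 26, 8.5, float("nan")],
    }
    return pd.DataFrame(data).set_index("taxon")


def site_hydrodynamics() -> pd.DataFrame:
    """Channel velocity ranges and Reynolds numbers for the two springs."""
    return pd.DataFrame(
        [
            ("OSP", 2.0, 5.0, 1.5e3),
            ("Beowulf", 20.0, 30.0, 1.4e4),
        ],
        columns=["spring", "velocity_min_cm_s", "velocity_max_cm_s", "reynolds"],
    )
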