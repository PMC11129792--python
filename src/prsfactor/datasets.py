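"""Published UK Biobank summary tables for worked examples and checks.

These are aggregate counts and rates from a published UK Biobank analysis
of integrating a coronary-artery-disease PRS into SCORE2 risk prediction
(n = 432 981; 297 201 free of CVD at baseline). They are inputs to the
package's summary operations — e.g. reclassification shares and the
factor gradient are recomputed from the raw cell counts — not outputs of
this package.
"""

from __future__ import annotations

import pandas as pd

from .integration import ReclassificationTable


def ukb_reclassification_counts() -> ReclassificationTable:
    """SCORE2 vs 'SCORE2 x PRS-factor' reclassification of the event-free
    UK Biobank cohort: per-cell n and incident CVD rate (percent)."""
    cells = [
        ("low", "low", 113_447, 0.97),
        ("low", "intermediate", 13_868, 2.32),
        ("low", "high", 0, float("nan")),
        ("intermediate", "low", 28_453, 2.29),
        ("intermediate", "intermediate", 102_998, 4.08),
        ("intermediate", "high", 13_886, 8.08),
        ("high", "low", 0, float("nan")),
        ("high", "intermediate", 8_291, 6.87),
        ("high", "high", 16_258, 10.28),
    ]
    tab = pd.DataFrame(cells,
                       columns=["origin", "destination", "n", "incidence_pct"])
    return ReclassificationTable.from_counts(tab)


def ukb_prs_factor_table() -> pd.DataFrame:
    """Published mean CVD odds ratios per PRS tenth in the entire UK Biobank
    cohort (merged fifth/sixth tenths fixed at 1)."""
    rows = [
        ("1", 0.63, 0.60, 0.65),
        ("2", 0.72, 0.70, 0.74),
        ("3", 0.79, 0.76, 0.82),
        ("4", 0.87, 0.83, 0.90),
        ("5/6", 1.00, float("nan"), float("nan")),
        ("7", 1.07, 1.03, 1.11),
        ("8", 1.20, 1.18, 1.23),
        ("9", 1.37, 1.33, 1.41),
        ("10", 1.72, 1.67, 1.78),
    ]
    tab = pd.DataFrame(rows, columns=["prs_group", "mean_or", "ci_low",
                                      "ci_high"])
    return tab.set_index("prs_group")


def ukb_prevalence_by_score2_category() -> pd.DataFrame:
    """Published CVD prevalence (percent) by SCORE2 risk category."""
    rows = [("low", 128_652, 2.13), ("intermediate", 150_879, 7.63),
            ("high", 26_581, 16.07)]
    return pd.DataFrame(rows, columns=["category", "n", "cvd_pct"]) \
        .set_index("category")
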