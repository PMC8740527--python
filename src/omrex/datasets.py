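"""Published summary table from the 2018 Ocean Station Papa (EXPORTS)
remineralization experiments.

Eighteen incubations (four depths, diluted/undiluted treatments) with
initial and final DOC*, short- and long-term DOC* removal rates (OLS slope
± SE with n and two-tailed p), bacterioplankton production rates to
stationary phase under three biovolume→carbon conversions, and the growth
efficiencies reported where the resolvability gates passed.  Rates are in
µmol C L⁻¹ d⁻¹, concentrations in µmol C L⁻¹, efficiencies as fractions.

Cells printed as "p < 0.001" are stored as 0.0005; they are only ever
compared against the 0.05 significance gate.  Missing cells (unresolved
rates, ungated efficiencies) are NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_COLUMNS = [
    "depth_m", "start_date", "days_to_stationary", "days_to_final", "treatment",
    "doc0", "doc0_sd", "doc_final", "doc_final_sd",
    "short_rate", "short_rate_se", "short_n", "short_p",
    "long_rate", "long_n", "long_p",
    "bp_gundersen", "bp_gundersen_se",
    "bp_exports", "bp_exports_se",
    "bp_malfatti", "bp_malfatti_se",
    "bge_gundersen", "bge_gundersen_err",
    "bge_exports", "bge_exports_err",
    "bge_malfatti", "bge_malfatti_err",
]

_NA = float("nan")
_P_BELOW = 0.0005  # stands in for "p < 0.001"

_ROWS = [
    # depth date  stat fin trt   doc0        docf        short rate            long rate        BP (G, E, M)                                BGE (G, E, M)
    (5, "8/15", 6, 93, "diluted",   57.7, 0.4, 56.6, 0.5, 0.06, 0.04, 4, 0.21,  _NA, _NA, _NA,  0.09, 0.02, 0.12, 0.02, 0.16, 0.03, _NA, _NA, _NA, _NA, _NA, _NA),
    (5, "8/15", 6, 93, "undiluted", 60.4, 0.8, 56.3, 0.2, 0.14, 0.12, 4, 0.15,  0.015, 5, 0.007, 0.14, 0.01, 0.19, 0.01, 0.27, 0.02, _NA, _NA, _NA, _NA, _NA, _NA),
    (5, "8/18", 6, 90, "diluted",   57.7, 0.4, 56.0, 0.5, 0.05, 0.07, 3, 0.54,  0.014, 5, 0.03,  0.05, 0.01, 0.08, 0.02, 0.12, 0.03, _NA, _NA, _NA, _NA, _NA, _NA),
    (5, "8/18", 6, 90, "undiluted", 60.0, 0.3, 53.9, 0.4, 0.38, 0.01, 3, _P_BELOW, 0.046, 4, 0.04, 0.07, 0.01, 0.10, 0.01, 0.15, 0.01, 0.18, 0.02, 0.27, 0.03, 0.39, 0.04),
    (5, "8/23", 10, 85, "diluted",   57.8, 0.4, 57.0, 0.5, 0.08, 0.06, 3, 0.22,  _NA, _NA, _NA,  0.05, 0.01, 0.07, 0.01, 0.10, 0.01, _NA, _NA, _NA, _NA, _NA, _NA),
    (5, "8/23", 10, 85, "undiluted", 59.6, 0.4, 57.1, 0.7, 0.11, 0.02, 4, 0.005, 0.021, 6, 0.009, 0.03, 0.01, 0.05, 0.01, 0.07, 0.01, 0.27, 0.09, 0.45, 0.13, 0.68, 0.18),
    (5, "8/28", 9, 80, "diluted",   59.6, 0.5, 56.8, 0.4, 0.18, 0.03, 3, 0.003, 0.016, 6, 0.03,  0.03, 0.01, 0.07, 0.01, 0.11, 0.01, 0.26, 0.06, 0.38, 0.09, 0.55, 0.13),
    (5, "8/28", 9, 80, "undiluted", 61.2, 0.4, 56.8, 0.9, 0.22, 0.06, 3, 0.008, 0.031, 6, 0.01,  0.04, 0.00, 0.07, 0.01, 0.11, 0.01, 0.19, 0.05, 0.32, 0.09, 0.48, 0.13),
    (5, "8/31", 10, 77, "diluted",   59.8, 0.6, 55.0, 0.4, 0.19, 0.05, 4, 0.003, 0.044, 6, _P_BELOW, 0.03, 0.01, 0.05, 0.01, 0.07, 0.02, 0.18, 0.07, 0.27, 0.10, 0.39, 0.14),
    (5, "8/31", 10, 77, "undiluted", 59.3, 0.4, 54.3, 0.2, 0.24, 0.06, 4, 0.003, 0.039, 6, 0.01,  0.04, 0.01, 0.07, 0.01, 0.10, 0.01, 0.14, 0.05, 0.27, 0.07, 0.42, 0.11),
    (35, "8/23", 10, 85, "diluted",   58.0, 0.5, 56.5, 0.6, 0.09, 0.06, 3, 0.19,  0.018, 4, 0.02,  0.05, 0.01, 0.06, 0.01, 0.09, 0.01, _NA, _NA, _NA, _NA, _NA, _NA),
    (35, "8/23", 10, 85, "undiluted", 58.7, 0.5, 55.9, 0.9, 0.03, 0.02, 3, 0.29,  0.017, 5, 0.08,  0.02, 0.00, 0.03, 0.00, 0.05, 0.00, _NA, _NA, _NA, _NA, _NA, _NA),
    (50, "8/15", 10, 93, "diluted",   57.3, 0.4, 56.3, 0.6, 0.10, 0.02, 5, 0.003, 0.014, 5, 0.18,  0.03, 0.00, 0.04, 0.01, 0.05, 0.01, 0.25, 0.06, 0.35, 0.10, 0.47, 0.12),
    (50, "8/15", 10, 93, "undiluted", 56.9, 0.5, 54.7, 0.3, 0.16, 0.03, 5, 0.003, 0.021, 6, 0.05,  0.02, 0.01, 0.04, 0.01, 0.06, 0.01, 0.13, 0.05, 0.25, 0.07, 0.41, 0.11),
    (50, "8/28", 9, 80, "diluted",   56.9, 0.4, 54.0, 0.7, 0.12, 0.09, 3, 0.25,  0.023, 6, _P_BELOW, 0.01, 0.00, 0.01, 0.01, 0.01, 0.01, _NA, _NA, _NA, _NA, _NA, _NA),
    (50, "8/28", 9, 80, "undiluted", 58.6, 0.4, 56.9, 0.3, 0.20, 0.03, 3, _P_BELOW, 0.010, 6, 0.29, 0.02, 0.00, 0.02, 0.00, 0.03, 0.00, 0.25, 0.05, 0.33, 0.06, 0.46, 0.08),
    (95, "8/15", 10, 93, "diluted",   54.5, 0.3, 54.3, 0.5, 0.04, 0.03, 5, 0.49,  _NA, _NA, _NA,  0.01, 0.00, 0.01, 0.01, 0.01, 0.01, _NA, _NA, _NA, _NA, _NA, _NA),
    (95, "8/15", 10, 93, "undiluted", 54.2, 0.6, 52.4, 0.6, 0.13, 0.05, 5, 0.03,  0.007, 5, 0.005, 0.03, 0.00, 0.04, 0.00, 0.05, 0.00, 0.13, 0.05, 0.19, 0.08, 0.27, 0.11),
]


def osp_experiment_summary(conversion: str = "exports") -> pd.DataFrame:
    """The experiment summary table, one row per incubation.

    ``conversion`` selects which biovolume→carbon calibration populates the
    generic ``bp``/``bge`` columns used by
    :func:`omrex.rates.summarize_experiments` (``"exports"``,
    ``"gundersen"`` or ``"malfatti"``); the per-conversion columns are
    always present.
    """
    records = []
    for row in _ROWS:
        rec = dict(zip(_COLUMNS[:13], row[:13]))
        (rec["long_rate"], rec["long_n"], rec["long_p"]) = row[13:16]
        for i, name in enumerate(["gundersen", "exports", "malfatti"]):
            rec[f"bp_{name}"] = row[16 + 2 * i]
            rec[f"bp_{name}_se"] = row[17 + 2 * i]
            rec[f"bge_{name}"] = row[22 + 2 * i]
            rec[f"bge_{name}_err"] = row[23 + 2 * i]
        records.append(rec)
    df = pd.DataFrame(records)
    key = conversion.lower()
    if key not in ("exports", "gundersen", "malfatti"):
        raise KeyError(f"unknown conversion {conversion!r}")
    df["bp"] = df[f"bp_{key}"]
    df["bge"] = df[f"bge_{key}"]
    df["experiment_id"] = [
        f"{d}m_{s.replace('/', '-')}_{t[0].upper()}"
        for d, s, t in zip(df["depth_m"], df["start_date"], df["treatment"])
    ]
    df["long_rate"] = df["long_rate"].astype(float)
    return df
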