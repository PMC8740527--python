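"""Total hydrolyzable amino acids: composition, carbon, degradation indices.

After acid hydrolysis, 18 amino acids (16 protein amino acids plus the
non-protein gamma-aminobutyric acid and beta-alanine) are quantified in
nmol L⁻¹.  Three indicators summarize the diagenetic state of the organic
matter:

* mol% composition — each analyte as a percentage of the summed pool;
* THAA carbon — Σ conc_i · C_i / 1000, in µmol C L⁻¹, weighting each
  analyte by its carbon atoms;
* the degradation index (DI) — a weighted sum of standardized mol% values,
  DI = Σ_i [(mol%_i − ref_mean_i)/ref_sd_i] · coef_i, where lower scores
  indicate more degraded material; and the combined mol% of GABA +
  beta-alanine, which rises with degradation.

The DI factor coefficients and reference statistics are configuration with
a provenance label: the defaults shipped here are *synthetic illustrative
values* patterned after the protein-amino-acid degradation-index
literature (labile aromatics/branched chains load positive, Gly/Ser/Thr
negative); substitute the published coefficient table for real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError

#: default analyte set with carbon atoms per molecule
AMINO_ACID_CARBON: dict[str, int] = {
    "Asp": 4, "Glu": 5, "Ser": 3, "His": 6, "Gly": 2, "Thr": 4,
    "Arg": 6, "Ala": 3, "Tyr": 9, "Met": 5, "Val": 5, "Phe": 9,
    "Ile": 6, "Leu": 6, "Lys": 6, "Trp": 11, "GABA": 4, "B-Ala": 3,
}

NON_PROTEIN = ("GABA", "B-Ala")


@dataclass(frozen=True)
class DICoefficients:
    """Factor coefficients and reference mol% statistics for the DI.

    ``table`` maps amino acid → (factor_coefficient, reference_mean_molpct,
    reference_sd_molpct).  ``provenance`` documents where the numbers come
    from and is carried into reports.
    """

    table: dict[str, tuple[float, float, float]]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for aa, (_, _, sd) in self.table.items():
            if sd <= 0:
                raise ConfigurationError(f"DI reference sd for {aa} must be > 0")

    @property
    def amino_acids(self) -> list[str]:
        return list(self.table)


# Synthetic illustrative defaults (NOT a published coefficient set): signs
# follow the qualitative pattern of protein-AA degradation indices, with
# reference mol% loosely resembling marine hydrolyzable-AA pools.
DEFAULT_DI_COEFFICIENTS = DICoefficients(
    table={
        "Asp": (-0.10, 11.0, 2.0),
        "Glu": (0.12, 9.0, 1.8),
        "Ser": (-0.14, 8.0, 1.5),
        "His": (0.02, 1.5, 0.6),
        "Gly": (-0.18, 20.0, 4.0),
        "Thr": (-0.10, 6.5, 1.2),
        "Arg": (0.06, 4.0, 1.0),
        "Ala": (-0.04, 12.0, 2.2),
        "Tyr": (0.16, 1.5, 0.6),
        "Met": (0.10, 1.0, 0.5),
        "Val": (0.08, 6.0, 1.0),
        "Phe": (0.16, 3.0, 0.8),
        "Ile": (0.14, 4.0, 0.8),
        "Leu": (0.15, 6.5, 1.2),
        "Lys": (0.05, 5.0, 1.5),
        "Trp": (0.04, 0.8, 0.4),
    },
    provenance=(
        "synthetic illustrative defaults patterned after protein amino-acid "
        "degradation indices; replace with a published coefficient table for "
        "real data"
    ),
)


@dataclass(frozen=True)
class PhaseComparison:
    delta: float
    t_statistic: float
    p: float
    direction: str | None  # "more degraded" / "less degraded" / None


def _as_series(concentrations) -> pd.Series:
    s = pd.Series(concentrations, dtype=float)
    if (s < 0).any():
        raise ConfigurationError("concentrations must be >= 0")
    return s


def mol_percent(concentrations) -> pd.Series:
    """mol% of each analyte; values sum to 100."""
    s = _as_series(concentrations)
    total = s.sum()
    if total <= 0:
        raise ConfigurationError("all-zero profile: composition undefined")
    return 100.0 * s / total


def thaa_carbon(concentrations, carbon_atoms: dict[str, int] | None = None) -> float:
    """THAA in carbon units (µmol C L⁻¹) from nmol L⁻¹ concentrations."""
    s = _as_series(concentrations)
    if s.empty:
        raise ConfigurationError("empty profile")
    atoms = AMINO_ACID_CARBON if carbon_atoms is None else carbon_atoms
    missing = [aa for aa in s.index if aa not in atoms]
    if missing:
        raise ConfigurationError(f"no carbon count configured for {missing}")
    return float(sum(s[aa] * atoms[aa] for aa in s.index) / 1000.0)


def degradation_index(
    molpct, coefficients: DICoefficients | None = None
) -> float:
    """DI score from a mol% composition; lower = more degraded."""
    if coefficients is None:
        coefficients = DEFAULT_DI_COEFFICIENTS
    mp = pd.Series(molpct, dtype=float)
    missing = [aa for aa in coefficients.amino_acids if aa not in mp.index]
    if missing:
        raise ConfigurationError(f"mol% missing DI analytes {missing}")
    di = 0.0
    for aa, (coef, mean, sd) in coefficients.table.items():
        di += (mp[aa] - mean) / sd * coef
    return float(di)


def gaba_bala_molpct(molpct) -> float:
    """Combined mol% of the non-protein amino acids GABA and beta-alanine."""
    mp = pd.Series(molpct, dtype=float)
    total = 0.0
    for aa in NON_PROTEIN:
        if aa in mp.index:
            total += float(mp[aa])
        else:
            warnings.warn(f"{aa} absent from profile; counted as 0 mol%")
    return total


def indicators(concentrations, coefficients: DICoefficients | None = None,
               carbon_atoms: dict[str, int] | None = None) -> dict:
    """DI, mol% GABA+B-Ala and THAA carbon for one replicate profile."""
    mp = mol_percent(concentrations)
    return {
        "di_score": degradation_index(mp, coefficients),
        "gaba_bala_molpct": gaba_bala_molpct(mp),
        "thaa_c": thaa_carbon(concentrations, carbon_atoms),
    }


def compare_phases(
    values_a,
    values_b,
    higher_is_degraded: bool,
    alpha: float = 0.05,
) -> PhaseComparison:
    """Two-tailed two-sample t-test of an indicator between two phases.

    ``values_a``/``values_b`` are replicate indicator values (e.g. DI
    scores) for phase A (earlier) and B (later).  ``higher_is_degraded``
    states the direction of the indicator (True for mol% GABA+B-Ala, False
    for DI).  The direction flag is set only when p < alpha.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 replicates per phase")
    delta = float(b.mean() - a.mean())
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return PhaseComparison(0.0, 0.0, 1.0, None)
    t, p = stats.ttest_ind(b, a)
    direction = None
    if p < alpha and delta != 0:
        degraded = (delta > 0) == higher_is_degraded
        direction = "more degraded" if degraded else "less degraded"
    return PhaseComparison(delta, float(t), float(p), direction)


def indicator_table(
    thaa_long: pd.DataFrame,
    coefficients: DICoefficients | None = None,
    carbon_atoms: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per (experiment, phase, replicate) indicator values from a long table.

    ``thaa_long`` columns: experiment_id, phase, replicate, amino_acid,
    conc_nmol_l.
    """
    rows = []
    for (exp, phase, rep), grp in thaa_long.groupby(
        ["experiment_id", "phase", "replicate"]
    ):
        conc = grp.set_index("amino_acid")["conc_nmol_l"]
        ind = indicators(conc, coefficients, carbon_atoms)
        rows.append(
            {"experiment_id": exp, "phase": phase, "replicate": rep, **ind}
        )
    return pd.DataFrame(rows)
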