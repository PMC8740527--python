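"""Untargeted MS1 feature tables: blank filtering, z-scores, class changes.

Input is an aligned peak-area export (features × samples) with a
process-blank area and a coarse compound-class annotation per feature.
Features are kept when their maximum sample area exceeds a multiple
(default 3×) of the blank.  Per feature, areas are standardized across all
samples to z-scores (sample standard deviation, n−1); the change
Δz = z(stationary) − z(initial) measures how many standard deviations a
feature moved over an incubation, and Δz values are summarized per
compound class with a one-sample t-test against zero.  A correlation
screen relates per-feature Δz across experiments to a bioavailability
covariate (e.g. the initial degradation index).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError


def blank_filter(
    areas: pd.DataFrame, blank: pd.Series, factor: float = 3.0
) -> pd.DataFrame:
    """Keep features whose maximum sample area exceeds ``factor`` × blank.

    ``areas`` is features × samples; ``blank`` is indexed by feature (0
    allowed, in which case any positive area keeps the feature).
    """
    if factor <= 0:
        raise ValueError("blank factor must be positive")
    blank = blank.reindex(areas.index).fillna(0.0)
    keep = areas.max(axis=1) > factor * blank
    keep &= areas.max(axis=1) > 0
    return areas.loc[keep]


def zscore_matrix(areas: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize peak areas: per feature, mean 0 and sd 1 (ddof=1).

    Features constant across samples have no defined z-score; they are
    dropped with a warning.
    """
    if areas.shape[1] < 2:
        raise InsufficientDataError("z-scores need >= 2 samples")
    mu = areas.mean(axis=1)
    sd = areas.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) excluded from z-scoring"
        )
    z = areas.loc[~constant].sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    return z


def delta_z(
    z: pd.DataFrame,
    sample_phase: pd.Series,
    initial: str = "initial",
    stationary: str = "stationary",
) -> pd.Series:
    """Per-feature z-score change, mean z at stationary minus at initial."""
    phases = sample_phase.reindex(z.columns)
    init_cols = z.columns[phases == initial]
    stat_cols = z.columns[phases == stationary]
    if len(init_cols) == 0 or len(stat_cols) == 0:
        raise InsufficientDataError("need samples in both phases")
    return z[stat_cols].mean(axis=1) - z[init_cols].mean(axis=1)


def class_change_summary(
    dz: pd.Series, classes: pd.Series, min_class_size: int = 2
) -> pd.DataFrame:
    """Mean Δz, standard error and two-tailed p vs 0 per compound class.

    Classes with fewer than ``min_class_size`` features are reported
    without a p-value.  Zero-variance classes are handled exactly: p = 0
    for a nonzero mean, p = 1 for a zero mean.
    """
    classes = classes.reindex(dz.index)
    rows = []
    for cls, grp in dz.groupby(classes):
        vals = grp.to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        if n < min_class_size:
            p = float("nan")
        elif se == 0:
            p = 0.0 if mean != 0 else 1.0
        else:
            _, p = stats.ttest_1samp(vals, 0.0)
            p = float(p)
        rows.append(
            {"compound_class": cls, "n": n, "mean_delta_z": mean, "se": se, "p": p}
        )
    return pd.DataFrame(rows)


def correlate_feature_changes(
    dz_by_experiment: pd.DataFrame,
    covariate: pd.Series,
    classes: pd.Series | None = None,
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson screen of per-feature Δz against a covariate.

    ``dz_by_experiment`` is features × experiments (Δz per incubation);
    ``covariate`` is indexed by experiment (e.g. initial DI score or
    short-term DOC* removal rate).  Returns (per-feature frame with r, p, n
    and a significance flag; per-class counts of significant features).
    Raw p-values are used, matching the published screen; apply your own
    multiplicity correction downstream if desired.
    """
    cov = covariate.reindex(dz_by_experiment.columns)
    if cov.isna().any():
        raise InsufficientDataError("covariate missing for some experiments")
    if np.ptp(cov.to_numpy(dtype=float)) == 0:
        raise DegenerateDesignError("constant covariate: correlation undefined")
    rows = []
    for fid, row in dz_by_experiment.iterrows():
        ok = row.notna()
        n = int(ok.sum())
        if n < min_pairs:
            rows.append({"feature_id": fid, "r": float("nan"), "p": float("nan"), "n": n})
            continue
        x = cov[ok].to_numpy(dtype=float)
        y = row[ok].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            rows.append({"feature_id": fid, "r": float("nan"), "p": float("nan"), "n": n})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"feature_id": fid, "r": float(r), "p": float(p), "n": n})
    per_feature = pd.DataFrame(rows).set_index("feature_id")
    per_feature["significant"] = per_feature["p"] < alpha
    if classes is not None:
        cls = classes.reindex(per_feature.index)
        counts = (
            per_feature.groupby(cls)["significant"]
            .agg(n_significant="sum", n_tested="count")
            .reset_index()
            .rename(columns={"index": "compound_class"})
        )
        counts["n_significant"] = counts["n_significant"].astype(int)
    else:
        counts = pd.DataFrame(columns=["compound_class", "n_significant", "n_tested"])
    return per_feature, counts
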