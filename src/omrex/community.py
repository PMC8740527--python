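"""16S ASV community statistics: responders, diversity, indicator taxa.

Counts per sample are converted to relative abundances; the 100 most
abundant ASVs typically carry ~96 % of the reads.  A *responder* is an ASV
whose relative abundance rises at least threefold between the initial and
stationary phases of an incubation — log2 fold change ≥ log2(3) ≈ 1.58 —
with a detection-limit pseudocount (1/read depth) guarding against zeros.

Alpha diversity uses the Shannon–Wiener index H = −Σ p ln p (natural log by
default) with the classical large-sample variance

    var(H) = [Σ p (ln p)² − H²]/N + (S − 1)/(2N²),

and two samples are compared with Hutcheson's t-test,
t = (H₁ − H₂)/√(V₁+V₂) with Welch-style degrees of freedom.  Indicator
taxa for a sample grouping are scored with the group-size-corrected
point-biserial correlation ("r.g") between an ASV's abundances and group
membership, with a permutation p-value (two-sided on |r.g|).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError

#: threefold increase on the log2 scale
LOG2FC_THRESHOLD = math.log2(3.0)  # 1.585


@dataclass(frozen=True)
class DiversityResult:
    H: float
    variance: float
    n_reads: int
    n_asvs: int

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * math.sqrt(self.variance)
        return (self.H - half, self.H + half)


def relative_abundance(counts) -> pd.DataFrame | pd.Series:
    """Column-wise fractions; each sample must have positive total."""
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            raise InsufficientDataError("zero-total sample")
        return counts / total
    counts = pd.DataFrame(counts)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InsufficientDataError(f"zero-total sample(s): {bad}")
    return counts.div(totals, axis=1)


def rarefy(counts, depth: int, seed: int | None = None) -> pd.Series:
    """Subsample one sample's counts to a fixed depth without replacement.

    Provided for sensitivity checks; diversity is computed on non-rarefied
    counts by default.
    """
    c = pd.Series(counts).astype(int)
    total = int(c.sum())
    if depth > total:
        raise InsufficientDataError(f"cannot rarefy {total} reads to {depth}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(c)), c.to_numpy())
    picked = rng.choice(pool, size=depth, replace=False)
    out = np.bincount(picked, minlength=len(c))
    return pd.Series(out, index=c.index)


def top_n_asvs(ra: pd.DataFrame, n: int = 100) -> tuple[pd.Index, pd.Series]:
    """The n ASVs with highest mean relative abundance, plus coverage.

    Ties break by ASV id.  Returns (ordered index of the subset, per-sample
    coverage fraction of that subset).  n larger than the table is clipped
    with a warning.
    """
    if n > len(ra):
        import warnings

        warnings.warn(f"n={n} exceeds {len(ra)} ASVs; using all")
        n = len(ra)
    means = ra.mean(axis=1)
    # two-key sort: descending mean abundance, ties broken by ascending id
    df = pd.DataFrame({"mean": means, "asv": means.index.astype(str)})
    df = df.sort_values(["mean", "asv"], ascending=[False, True])
    top = df.index[:n]
    coverage = ra.loc[top].sum(axis=0)
    return top, coverage


def log2_fold_change(
    ra_initial,
    ra_stationary,
    pseudocount_initial: float = 0.0,
    pseudocount_stationary: float = 0.0,
    threshold: float = LOG2FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-ASV log2 fold change with responder flags.

    Pseudocounts (typically 1/read depth of the respective sample) are
    added to both phases' relative abundances; an ASV absent from both
    phases with zero pseudocounts yields NaN.  ``responder`` is True when
    log2fc >= ``threshold`` (default log2(3), a threefold increase).
    """
    ri = pd.Series(ra_initial, dtype=float) + pseudocount_initial
    rs = pd.Series(ra_stationary, dtype=float) + pseudocount_stationary
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(rs / ri)
    lfc = lfc.replace([np.inf, -np.inf], np.nan)
    out = pd.DataFrame(
        {
            "ra_initial": pd.Series(ra_initial, dtype=float),
            "ra_stationary": pd.Series(ra_stationary, dtype=float),
            "log2fc": lfc,
        }
    )
    out["responder"] = out["log2fc"] >= threshold
    out.loc[out["log2fc"].isna(), "responder"] = False
    return out


def shannon(counts, base: float = math.e) -> DiversityResult:
    """Shannon–Wiener H with its large-sample variance for one sample."""
    c = np.asarray(pd.Series(counts, dtype=float))
    c = c[c > 0]
    n = c.sum()
    if n <= 0:
        raise InsufficientDataError("empty sample")
    p = c / n
    log = np.log(p) / math.log(base)
    h = float(-(p * log).sum())
    s = len(p)
    var = float((np.sum(p * log**2) - h**2) / n + (s - 1) / (2 * n**2))
    return DiversityResult(H=h, variance=max(var, 0.0), n_reads=int(round(n)), n_asvs=s)


def hutcheson_t(div1: DiversityResult, div2: DiversityResult) -> dict:
    """Hutcheson's t-test for a difference between two Shannon indices."""
    v = div1.variance + div2.variance
    if v <= 0:
        raise DegenerateDesignError("zero combined variance")
    t = (div1.H - div2.H) / math.sqrt(v)
    df = v**2 / (
        div1.variance**2 / div1.n_reads + div2.variance**2 / div2.n_reads
    )
    p = 2 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def _rg_statistics(values: np.ndarray, membership: np.ndarray, weights: np.ndarray):
    """Group-equalized point-biserial correlation for each row of ``values``.

    ``weights`` give every group equal total weight, so unequal group sizes
    do not bias the statistic; with equal sizes this is the plain
    point-biserial (Pearson) correlation.  Rows with zero weighted variance
    return NaN.
    """
    w = weights / weights.sum()
    mx = values @ w
    xc = values - mx[:, None]
    m = membership.astype(float)
    mm = float(m @ w)
    mc = m - mm
    cov = (xc * mc[None, :]) @ w
    vx = (xc**2) @ w
    vm = float((mc**2) @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        rg = cov / np.sqrt(vx * vm)
    rg[vx == 0] = np.nan
    return rg


def indicator_rg(
    ra: pd.DataFrame,
    labels,
    group=None,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Indicator statistic and permutation p for each ASV × group.

    ``ra`` is ASVs × samples (relative abundances); ``labels`` assigns each
    sample to a group.  For every group (or just ``group``), the
    group-size-corrected point-biserial correlation r.g between abundance
    and membership is computed; significance comes from permuting the
    sample labels, comparing |r.g| (two-sided).  ``method="exhaustive"``
    enumerates all distinct label arrangements (p = #{|perm| ≥ |obs|}/N,
    which includes the identity, feasible for <= ~8 samples);
    ``"permutation"`` draws ``n_permutations`` random shuffles and reports
    (1 + #{|perm| ≥ |obs|})/(1 + n_permutations).  ``"auto"`` picks
    exhaustive when there are at most 5,040 arrangements.
    """
    labels = pd.Series(list(labels), index=ra.columns)
    groups = [group] if group is not None else sorted(labels.unique())
    if labels.nunique() < 2:
        raise DegenerateDesignError("need >= 2 groups")
    values = ra.to_numpy(dtype=float)
    lab = labels.to_numpy()
    sizes = labels.value_counts()
    weights = np.array([1.0 / sizes[g] for g in lab])

    n = len(lab)
    if method == "auto":
        n_arrangements = math.factorial(n) // math.prod(
            math.factorial(k) for k in sizes
        )
        method = "exhaustive" if n_arrangements <= 5040 else "permutation"

    rng = np.random.default_rng(seed)
    results = []
    for g in groups:
        member = lab == g
        obs = _rg_statistics(values, member, weights)
        abs_obs = np.abs(obs)
        exceed = np.zeros(values.shape[0])
        if method == "exhaustive":
            arrangements = sorted(set(itertools.permutations(lab)))
            for arr in arrangements:
                arr = np.array(arr)
                w = np.array([1.0 / sizes[a] for a in arr])
                stat = _rg_statistics(values, arr == g, w)
                exceed += np.abs(stat) >= abs_obs - 1e-12
            pvals = exceed / len(arrangements)
            n_used = len(arrangements)
        elif method == "permutation":
            for _ in range(n_permutations):
                idx = rng.permutation(n)
                stat = _rg_statistics(values, member[idx], weights[idx])
                exceed += np.abs(stat) >= abs_obs - 1e-12
            pvals = (1.0 + exceed) / (1.0 + n_permutations)
            n_used = n_permutations
        else:
            raise ValueError(f"unknown method {method!r}")
        for i, asv in enumerate(ra.index):
            results.append(
                {
                    "asv_id": asv,
                    "group": g,
                    "rg_statistic": float(obs[i]),
                    "permutation_p": float(pvals[i]) if np.isfinite(obs[i]) else float("nan"),
                    "n_permutations": n_used,
                }
            )
    return pd.DataFrame(results)
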