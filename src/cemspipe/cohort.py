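"""Clinical-side statistics for a CKD peptidomics cohort.

Covers the renal-function side of the analysis: MDRD eGFR from serum
creatinine, staging into eGFR bands, one-way GLM (unbalanced ANOVA) of
scores across stage groups, Pearson/Spearman correlations and OLS fits,
average-linkage patient clustering on peptide profiles, cluster-vs-
clinical comparisons, per-peptide eGFR correlations with multiplicity
correction, and selection of peptides varying monotonically across
stage groups.

Dialysis patients are excluded from every eGFR-based computation: their
serum creatinine varies with the dialysis schedule, so a creatinine-based
GFR estimate does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .matching import PeptideMatrix, presence_filter

#: Default eGFR band cutpoints (mL/min/1.73 m²): >60, 30–60, 15–30, <=15.
DEFAULT_STAGE_CUTPOINTS = (60.0, 30.0, 15.0)

_UMOL_PER_MGDL = 88.4  # creatinine unit conversion


@dataclass(frozen=True)
class AssociationResult:
    """One association statistic with its sample size and two-sided p."""

    kind: str  # "pearson_R" | "spearman_rho" | "glm_F"
    value: float
    n: int
    p_value: float
    df: tuple[int, int] | None = None
    note: str | None = None  # e.g. "constant input" when undefined


def mdrd_egfr(creatinine_umol_l, age_years, sex, black=False):
    """Simplified (abbreviated) MDRD estimate of GFR, mL/min/1.73 m².

    eGFR = 186 * (Scr[mg/dL])^-1.154 * age^-0.203 * 0.742 (female)
           * 1.210 (Black); serum creatinine is supplied in µmol/L and
    converted with 88.4 µmol/L per mg/dL.  Vectorized over inputs.
    """
    cr = np.asarray(creatinine_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(cr <= 0):
        raise ValidationError("creatinine must be positive")
    if np.any(age <= 0):
        raise ValidationError("age must be positive")
    female = np.asarray(
        [s in ("F", "f", "female") if isinstance(s, str) else bool(s) for s in np.atleast_1d(sex)]
    )
    black_arr = np.atleast_1d(np.asarray(black, dtype=bool))
    egfr = (
        186.0
        * (cr / _UMOL_PER_MGDL) ** (-1.154)
        * age ** (-0.203)
        * np.where(female, 0.742, 1.0)
        * np.where(black_arr, 1.210, 1.0)
    )
    if np.ndim(creatinine_umol_l) == 0 and np.ndim(age_years) == 0 and np.asarray(egfr).size == 1:
        return float(np.asarray(egfr).reshape(-1)[0])
    return egfr


def invert_mdrd_creatinine(egfr, age_years, sex, black=False):
    """Serum creatinine (µmol/L) that yields a target MDRD eGFR. Exact inverse."""
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(egfr <= 0):
        raise ValidationError("eGFR must be positive")
    female = np.asarray(
        [s in ("F", "f", "female") if isinstance(s, str) else bool(s) for s in np.atleast_1d(sex)]
    )
    black_arr = np.atleast_1d(np.asarray(black, dtype=bool))
    base = 186.0 * age ** (-0.203) * np.where(female, 0.742, 1.0) * np.where(black_arr, 1.210, 1.0)
    cr = _UMOL_PER_MGDL * (egfr / base) ** (-1.0 / 1.154)
    if np.ndim(egfr) == 0 and np.ndim(age_years) == 0 and np.asarray(cr).size == 1:
        return float(np.asarray(cr).reshape(-1)[0])
    return cr


def assign_stage_group(egfr, cutpoints: Sequence[float] = DEFAULT_STAGE_CUTPOINTS):
    """Map eGFR to an ordered group index 1..len(cutpoints)+1.

    With the default cutpoints (60, 30, 15): group 1 for eGFR > 60
    (stages I–II), 2 for 30 < eGFR <= 60 (III), 3 for 15 < eGFR <= 30
    (IV), 4 for eGFR <= 15 (V).  Upper bounds are inclusive so the bands
    are exhaustive and disjoint over the reals.
    """
    cps = tuple(cutpoints)
    if any(a <= b for a, b in zip(cps, cps[1:])):
        raise ValidationError("cutpoints must be strictly decreasing")
    e = np.asarray(egfr, dtype=float)
    if np.any(e < 0):
        raise ValidationError("eGFR must be non-negative")
    group = np.ones(e.shape, dtype=int)
    for cp in cps:
        group = group + (e <= cp)
    return int(group) if group.ndim == 0 else group


def glm_f_unbalanced(values, groups) -> AssociationResult:
    """One-way fixed-effects F test with unequal group sizes.

    F = (SSB/(k-1)) / (SSW/(N-k)); the p-value comes from the F(k-1, N-k)
    distribution.  This is the GLM analysis appropriate for unbalanced
    designs with a single factor.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if all(len(s) < 2 for s in samples):
        raise ValidationError("need at least one group with >= 2 values")
    F, p = stats.f_oneway(*samples)
    k, N = len(uniq), len(values)
    return AssociationResult(
        kind="glm_F", value=float(F), n=N, p_value=float(p), df=(k - 1, N - k)
    )


def correlate(x, y, method: str = "pearson") -> AssociationResult:
    """Pearson or Spearman correlation with pairwise-complete observations.

    Pairs with a missing value in either variable are dropped (the count
    reflects the pairs used).  A constant input yields an undefined
    coefficient, reported as a flagged NaN result rather than an error.
    Spearman uses average ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 complete pairs, got {n}")
    kind = {"pearson": "pearson_R", "spearman": "spearman_rho"}.get(method)
    if kind is None:
        raise ValidationError(f"unknown method {method!r}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return AssociationResult(kind=kind, value=float("nan"), n=n,
                                 p_value=float("nan"), note="constant input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return AssociationResult(kind=kind, value=float(r), n=n, p_value=float(p))


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_line(x, y) -> LineFit:
    """Ordinary least squares line y = a·x + b with R² = 1 − SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValidationError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        r2 = 0.0  # flat response: the line explains nothing beyond the mean
    else:
        pred = res.slope * x + res.intercept
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sstot
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=float(res.pvalue),
        n=len(x),
    )


def impute_matrix(matrix: PeptideMatrix, policy: str = "zero") -> pd.DataFrame:
    """Samples × peptides numeric table with missing cells filled.

    Zero-fill reflects the detection-limit interpretation of absence:
    an undetected peptide is below the limit, closer to zero than to the
    cohort mean.
    """
    X = matrix.intensities.to_numpy(dtype=float).T  # samples x peptides
    if policy == "zero":
        X = np.nan_to_num(X, nan=0.0)
    else:
        raise ValidationError(f"unknown imputation policy {policy!r}")
    return pd.DataFrame(X, index=matrix.sample_ids, columns=matrix.intensities.index)


def cluster_patients(
    matrix: PeptideMatrix,
    k: int = 4,
    impute: str = "zero",
    log_transform: bool = True,
) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage hierarchical clustering of patients.

    Per-patient peptide vectors (missing cells imputed, optionally
    log10(1+I)-transformed) are clustered agglomeratively with average
    linkage on standard Euclidean distances; the tree is cut into ``k``
    clusters.  Returns (assignments indexed by sample id, scipy linkage
    matrix).  Deterministic given the input order.
    """
    n = matrix.n_samples
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    X = impute_matrix(matrix, policy=impute).to_numpy()
    if log_transform:
        X = np.log10(1.0 + X)
    if n == 1:
        return pd.Series([1], index=matrix.sample_ids), np.empty((0, 4))
    Z = linkage(X, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.sample_ids), Z


def compare_clusters(
    patients: pd.DataFrame,
    assignments: pd.Series,
    variables: Sequence[str],
) -> pd.DataFrame:
    """Parametric and non-parametric tests between the two largest clusters.

    For each clinical variable, a Welch t test and a two-sided Wilcoxon
    rank-sum (Mann-Whitney U) compare the two largest clusters; missing
    values are dropped per variable.  Returns one row per variable with
    the statistics, p-values and per-cluster means.
    """
    counts = assignments.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least two clusters to compare")
    big = counts.sort_values(ascending=False).index[:2]
    ids1 = assignments.index[assignments == big[0]]
    ids2 = assignments.index[assignments == big[1]]
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValidationError("each compared cluster needs >= 2 members")

    rows = []
    for var in variables:
        a = pd.to_numeric(patients.loc[patients.index.isin(ids1), var], errors="coerce").dropna()
        b = pd.to_numeric(patients.loc[patients.index.isin(ids2), var], errors="coerce").dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append({"variable": var, "n1": len(a), "n2": len(b),
                         "mean1": np.nan, "mean2": np.nan, "t_stat": np.nan,
                         "t_p": np.nan, "ranksum_stat": np.nan, "ranksum_p": np.nan})
            continue
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
        if np.all(np.concatenate([a, b]) == a.iloc[0]):
            u_stat, u_p = np.nan, 1.0  # identical values: no evidence of a shift
        else:
            u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "variable": var,
                "n1": len(a),
                "n2": len(b),
                "mean1": float(a.mean()),
                "mean2": float(b.mean()),
                "t_stat": float(t_stat),
                "t_p": float(t_p),
                "ranksum_stat": float(u_stat) if np.isfinite(u_stat) else np.nan,
                "ranksum_p": float(u_p),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def per_peptide_egfr_correlation(
    matrix: PeptideMatrix,
    patients: pd.DataFrame,
    egfr_col: str = "egfr",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of every peptide with eGFR, with BH correction.

    Missing intensities are treated as zero (below detection limit).
    Dialysis patients must already be excluded (their eGFR is NaN and is
    dropped here).  Direction calls follow the renal-function reading:
    ρ < 0 (more peptide as eGFR falls) = "increased-with-CKD";
    ρ > 0 = "decreased-with-CKD".  Constant peptide rows are flagged and
    get no direction.  Benjamini-Hochberg adjusted p-values are reported
    alongside the raw ones.
    """
    common = [s for s in matrix.sample_ids if s in patients.index]
    egfr = pd.to_numeric(patients.loc[common, egfr_col], errors="coerce")
    keep = egfr.notna()
    ids = list(egfr.index[keep])
    if len(ids) < 3:
        raise ValidationError("need at least 3 patients with eGFR")
    e = egfr[keep].to_numpy(dtype=float)
    X = matrix.intensities[ids].to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)

    rows = []
    for ri, pid in enumerate(matrix.intensities.index):
        x = X[ri]
        if np.all(x == x[0]):
            rows.append({"peptide_id": pid, "rho": np.nan, "p": np.nan,
                         "direction": None, "flag": "constant", "n": len(ids)})
            continue
        rho, p = stats.spearmanr(x, e)
        direction = "increased-with-CKD" if rho < 0 else "decreased-with-CKD"
        rows.append({"peptide_id": pid, "rho": float(rho), "p": float(p),
                     "direction": direction, "flag": None, "n": len(ids)})
    out = pd.DataFrame(rows).set_index("peptide_id")
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    if mask.any():
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    return out


def monotone_peptides(
    matrix: PeptideMatrix,
    stage_groups: Mapping[str, int] | pd.Series,
    min_frac: float = 0.5,
) -> tuple[list[str], pd.DataFrame]:
    """Select peptides whose group-mean signal is monotone across stages.

    Applies the presence filter (strictly > ``min_frac`` of samples),
    computes the mean signal per ordered stage group with missing cells
    as zero, and keeps peptides whose group-mean sequence is non-strictly
    monotone (non-increasing or non-decreasing; ties allowed).  Returns
    the selected ids and the full heatmap-ready group-mean table.
    """
    groups = pd.Series(stage_groups)
    common = [s for s in matrix.sample_ids if s in groups.index]
    groups = groups.loc[common].astype(int)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("need at least 2 non-empty stage groups")

    filtered = presence_filter(matrix, min_frac=min_frac)
    X = filtered.intensities[common].to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    means = np.column_stack(
        [X[:, (groups == g).to_numpy()].mean(axis=1) for g in levels]
    )
    table = pd.DataFrame(
        means, index=filtered.intensities.index, columns=[f"group_{g}" for g in levels]
    )
    diffs = np.diff(means, axis=1)
    mono = np.all(diffs >= 0, axis=1) | np.all(diffs <= 0, axis=1)
    selected = list(table.index[mono])
    return selected, table
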