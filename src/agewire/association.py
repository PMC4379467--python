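"""Per-gene covariate association: ANCOVA, FDR control, direction calls,
cross-cohort merging, class enrichment and age-binned summaries.

Each gene's log2 expression y is modelled jointly on the two covariates,

    y = b0 + b1 * age + b2 * I(male) + e,

and b1, b2 are tested with two-sided t tests on n - 3 residual degrees of
freedom (equivalent to the per-term partial F test). A gene is called
significant for a covariate when its raw p-value is below the threshold
(default 0.001) AND its Benjamini-Hochberg q-value is at or below the FDR
(default 5%); FDR families are per cohort and per covariate. Spearman
correlation with age supplies the direction of significant age associations.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from agewire.errors import InputError

__all__ = [
    "fit_covariance_model",
    "benjamini_hochberg",
    "spearman_with_age",
    "associate_cohort",
    "call_significant",
    "merge_nonredundant",
    "class_proportion_test",
    "sex_difference_summary",
    "bin_ages",
    "bin_means",
    "hierarchical_clusters",
]


def _design_matrix(ages: np.ndarray, male: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(ages), ages, male.astype(float)])


def _validate_design(ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
    """Check the shared design; returns the male indicator."""
    sexes = np.asarray(sexes)
    levels = set(np.unique(sexes))
    if not levels <= {"male", "female"}:
        raise InputError(f"sex must be 'male'/'female', got {sorted(levels)}")
    if len(levels) < 2:
        raise InputError("singular design: only one sex present (covariate 'sex')")
    if np.var(ages) <= 0:
        raise InputError("singular design: age has zero variance (covariate 'age')")
    return sexes == "male"


def _ols_covariate_pvalues(
    Y: np.ndarray, ages: np.ndarray, male: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS of every row of Y on [1, age, I(male)].

    Returns (beta_age, beta_sex, p_age, p_sex). Rows with zero variance get
    NaNs (callers warn and skip them).
    """
    X = _design_matrix(np.asarray(ages, float), male)
    n, k = X.shape
    if n < 5:
        raise InputError(f"need n >= 5 samples, got {n}")
    df = n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv.T  # genes x k
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(s2, np.diag(xtx_inv)))
        t = B / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    constant = Y.var(axis=1) <= 0
    for arr in (B, p):
        arr[constant] = np.nan
    return B[:, 1], B[:, 2], p[:, 1], p[:, 2]


def fit_covariance_model(
    y: np.ndarray, ages: np.ndarray, sexes: np.ndarray
) -> tuple[float, float]:
    """ANCOVA p-values (p_age, p_sex) for a single gene."""
    y = np.asarray(y, dtype=float)
    male = _validate_design(np.asarray(ages, float), sexes)
    if y.var() <= 0:
        warnings.warn("zero-variance expression vector; gene skipped", stacklevel=2)
        return (float("nan"), float("nan"))
    _, _, p_age, p_sex = _ols_covariate_pvalues(y[None, :], ages, male)
    return float(p_age[0]), float(p_sex[0])


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values: q_(i) = min_{j>=i} m p_(j) / j, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _exact_spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided permutation p-value for Spearman rho at small n."""
    ranks = np.arange(1, n + 1, dtype=float)
    denom = n * (n**2 - 1)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        d2 = np.sum((ranks - ranks[list(perm)]) ** 2)
        r = 1.0 - 6.0 * d2 / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman_with_age(y: np.ndarray, ages: np.ndarray) -> tuple[float, float]:
    """Spearman rho of expression vs age with a two-sided p-value.

    p comes from the t approximation on n - 2 df for n > 9 and from exact
    permutation enumeration for n <= 9 (where the approximation is poor).
    """
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = y.size
    if n < 4:
        raise InputError(f"Spearman correlation needs n >= 4, got {n}")
    ry = stats.rankdata(y)
    ra = stats.rankdata(ages)
    if np.var(ry) <= 0 or np.var(ra) <= 0:
        warnings.warn("zero rank variance; Spearman rho undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    rho = float(np.corrcoef(ry, ra)[0, 1])
    if n <= 9:
        return rho, _exact_spearman_pvalue(rho, n)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), n - 2))


def associate_cohort(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    p_thresh: float = 0.001,
    fdr: float = 0.05,
    gate: str = "ancova",
) -> pd.DataFrame:
    """Full association table for one cohort.

    Columns: beta_age, beta_sex, p_age, p_sex, q_age, q_sex, rho, p_rho,
    q_rho, sig_age, sig_sex, direction. FDR correction is applied within
    this cohort, separately per covariate. ``gate`` selects whether the
    significance call for age requires the ANCOVA test alone (default) or
    additionally a significant Spearman correlation (``"both"``).
    """
    meta = meta.set_index("sample_id").loc[list(expr.columns)]
    ages = meta["age"].to_numpy(float)
    male = _validate_design(ages, meta["sex"].to_numpy())

    Y = expr.to_numpy(float)
    beta_age, beta_sex, p_age, p_sex = _ols_covariate_pvalues(Y, ages, male)
    constant = ~np.isfinite(p_age)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) skipped in association",
            stacklevel=2,
        )

    # Spearman, vectorised: Pearson correlation of within-row ranks vs age ranks.
    n = Y.shape[1]
    ry = stats.rankdata(Y, axis=1)
    ra = stats.rankdata(ages)
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    ra_c = ra - ra.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ry_c @ ra_c) / np.sqrt((ry_c**2).sum(axis=1) * (ra_c**2).sum())
    if n <= 9:
        p_rho = np.array([
            _exact_spearman_pvalue(r, n) if np.isfinite(r) else np.nan for r in rho
        ])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
        p_rho = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p_rho = np.where(np.abs(rho) >= 1.0, 0.0, p_rho)

    table = pd.DataFrame(
        {
            "beta_age": beta_age,
            "beta_sex": beta_sex,
            "p_age": p_age,
            "p_sex": p_sex,
            "rho": rho,
            "p_rho": p_rho,
        },
        index=expr.index,
    )
    for col in ("p_age", "p_sex", "p_rho"):
        q = np.full(len(table), np.nan)
        ok = np.isfinite(table[col].to_numpy())
        q[ok] = benjamini_hochberg(table[col].to_numpy()[ok])
        table[col.replace("p_", "q_")] = q
    return call_significant(table, p_thresh=p_thresh, fdr=fdr, gate=gate)


def call_significant(
    table: pd.DataFrame,
    p_thresh: float = 0.001,
    fdr: float = 0.05,
    gate: str = "ancova",
) -> pd.DataFrame:
    """Apply the significance rule: raw p < p_thresh AND BH q <= fdr
    (strict inequality at the p threshold), per covariate. Direction is
    sign(rho) for genes significant for age, else 0.
    """
    if gate not in ("ancova", "both"):
        raise InputError(f"gate must be 'ancova' or 'both', got {gate!r}")
    out = table.copy()
    sig_age = (out["p_age"] < p_thresh) & (out["q_age"] <= fdr)
    if gate == "both":
        sig_age &= (out["p_rho"] < p_thresh) & (out["q_rho"] <= fdr)
    out["sig_age"] = sig_age.fillna(False)
    out["sig_sex"] = ((out["p_sex"] < p_thresh) & (out["q_sex"] <= fdr)).fillna(False)
    out["direction"] = np.where(out["sig_age"], np.sign(out["rho"]), 0.0).astype(int)
    return out


def merge_nonredundant(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of significant (gene, covariate) pairs over cohorts.

    When cohorts disagree on direction, the cohort with the larger effect
    wins (|rho| for age, |beta_sex| for sex); an exact tie yields direction
    0 with a warning. Output columns: gene, covariate, direction, cohorts.
    """
    if not tables:
        raise InputError("merge_nonredundant needs at least one cohort table")
    records: dict[tuple[str, str], dict] = {}
    for cohort in sorted(tables):
        table = tables[cohort]
        for covariate, sig_col, eff_col in (
            ("age", "sig_age", "rho"),
            ("sex", "sig_sex", "beta_sex"),
        ):
            sub = table[table[sig_col].astype(bool)]
            for gene, row in sub.iterrows():
                effect = float(row[eff_col])
                key = (gene, covariate)
                rec = records.setdefault(
                    key, {"direction": 0, "magnitude": -1.0, "cohorts": set(), "tied": False}
                )
                rec["cohorts"].add(cohort)
                mag = abs(effect)
                direction = int(np.sign(effect))
                if mag > rec["magnitude"]:
                    rec["direction"] = direction
                    rec["magnitude"] = mag
                    rec["tied"] = False
                elif mag == rec["magnitude"] and direction != rec["direction"]:
                    rec["tied"] = True
    rows = []
    for (gene, covariate), rec in sorted(records.items()):
        direction = 0 if rec["tied"] else rec["direction"]
        if rec["tied"]:
            warnings.warn(
                f"direction tie for {gene}/{covariate}; reporting 0", stacklevel=2
            )
        rows.append(
            {
                "gene": gene,
                "covariate": covariate,
                "direction": direction,
                "cohorts": ",".join(sorted(rec["cohorts"])),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "covariate", "direction", "cohorts"])


def class_proportion_test(
    catalog: pd.DataFrame,
    merged: pd.DataFrame,
    class_a: str,
    class_b: str,
) -> float:
    """Two-sided Fisher exact p comparing the associated fraction between two
    gene classes. ``catalog`` maps symbol -> class; ``merged`` is the merged
    significant set (its ``gene`` column defines "associated").
    """
    assoc = set(merged["gene"])
    counts = {}
    for cls in (class_a, class_b):
        members = catalog.loc[catalog["class"] == cls, "symbol"]
        if members.empty:
            raise InputError(f"gene class {cls!r} is empty")
        k = int(members.isin(assoc).sum())
        counts[cls] = (k, len(members) - k)
    table = [list(counts[class_a]), list(counts[class_b])]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def sex_difference_summary(
    expr: pd.DataFrame, meta: pd.DataFrame, genes: Iterable[str]
) -> pd.DataFrame:
    """Per-gene male/female medians and a two-sided Mann-Whitney p-value."""
    meta = meta.set_index("sample_id").loc[list(expr.columns)]
    male_cols = meta.index[meta["sex"] == "male"]
    female_cols = meta.index[meta["sex"] == "female"]
    short = min(len(male_cols), len(female_cols)) < 2
    rows = []
    for gene in genes:
        mv = expr.loc[gene, male_cols].to_numpy(float)
        fv = expr.loc[gene, female_cols].to_numpy(float)
        rec = {
            "gene": gene,
            "median_male": float(np.median(mv)) if mv.size else np.nan,
            "median_female": float(np.median(fv)) if fv.size else np.nan,
        }
        if short:
            rec["p"] = np.nan
            rec["flag"] = "sex_group_too_small"
        else:
            method = "exact" if max(mv.size, fv.size) <= 25 else "asymptotic"
            rec["p"] = float(
                stats.mannwhitneyu(mv, fv, alternative="two-sided", method=method).pvalue
            )
            rec["flag"] = ""
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene")


_MAX_AGE = 120.0


def bin_ages(meta: pd.DataFrame, width: float = 20.0) -> pd.Series:
    """Half-open age bins [0, w), [w, 2w), ...; the last bin closes at 120."""
    if width <= 0:
        raise InputError(f"bin width must be > 0, got {width}")
    ages = meta["age"].to_numpy(float)
    if np.any((ages < 0) | (ages > _MAX_AGE)):
        raise InputError("ages must lie in [0, 120]")
    last = int(np.ceil(_MAX_AGE / width)) - 1
    idx = np.minimum(np.floor(ages / width).astype(int), last)
    labels = []
    for i in idx:
        lo, hi = i * width, (i + 1) * width
        closing = "]" if i == last else ")"
        labels.append(f"[{lo:g},{min(hi, _MAX_AGE):g}{closing}")
    return pd.Series(labels, index=meta["sample_id"].to_numpy(), name="age_bin")


def bin_means(expr: pd.DataFrame, bins: pd.Series) -> pd.DataFrame:
    """Gene x bin matrix of arithmetic means over member samples.

    Bins are ordered by their lower edge; a bin with no samples would simply
    be absent (an explicitly requested empty bin yields a NaN column).
    """
    bins = bins.loc[expr.columns]
    order = sorted(bins.unique(), key=lambda s: float(s.split(",")[0][1:]))
    out = pd.DataFrame(index=expr.index, columns=order, dtype=float)
    for label in order:
        cols = bins.index[bins == label]
        out[label] = expr[cols].mean(axis=1) if len(cols) else np.nan
    return out


def hierarchical_clusters(submatrix: pd.DataFrame, k: int) -> pd.Series:
    """Average-linkage agglomerative clustering with 1 - Pearson distance on
    row z-scores, cut to k clusters.

    Rows are processed in lexicographic gene order so the labelling is
    deterministic. Constant rows cannot be z-scored; they all go to a
    residual cluster labelled 0 with a warning.
    """
    if submatrix.shape[1] < 2:
        raise InputError("clustering needs >= 2 bins/columns")
    sub = submatrix.loc[sorted(submatrix.index)]
    values = sub.to_numpy(float)
    sd = values.std(axis=1)
    constant = sd <= 0
    labels = pd.Series(0, index=sub.index, dtype=int, name="cluster")
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) assigned to residual cluster 0",
            stacklevel=2,
        )
    active = values[~constant]
    if active.shape[0] == 0:
        return labels
    if active.shape[0] < k:
        raise InputError(f"need >= {k} non-constant rows, got {active.shape[0]}")
    z = (active - active.mean(axis=1, keepdims=True)) / active.std(axis=1, keepdims=True)
    corr = np.corrcoef(z)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    cut = fcluster(tree, t=k, criterion="maxclust")
    labels.loc[sub.index[~constant]] = cut
    return labels
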