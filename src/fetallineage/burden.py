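"""Mutation-burden extrapolation and mixed-effects comparisons.

Per-clone observed autosomal SNV counts are extrapolated to the whole
genome through the surveyed fraction (positions adequately covered in both
clone and matched bulk), converted to annual rates by the donor's age
since conception, and compared across cohorts and karyotypes with the
linear mixed models in :mod:`fetallineage.lmm`:

* ``rate`` model -- rate ~ cohort with a donor random intercept;
* ``trisomy`` model -- load ~ age + trisomy x cell type, donor random slope
  on age, separate residual variances for disomic and trisomic clones;
* ``early`` model -- the trisomy model without the age term, for mutations
  acquired before gastrulation.

Robustness utilities: leave-n-out refits, FDR-controlled outlier detection
on standardized residuals, the variance likelihood-ratio test, and the
rank-sum comparison of double-base-substitution counts.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import LMMResult, MixedModel, lr_test_variances

#: years per gestational week, for metadata given in weeks
YEARS_PER_WEEK = 7.0 / 365.25


# ---------------------------------------------------------------------------
# Extrapolation
# ---------------------------------------------------------------------------

def surveyed_fraction(clone_depths, bulk_depths, dp_min: int = 20):
    """Fraction of sampled positions with DP >= dp_min in both clone and bulk.

    Returns ``(fraction, se)`` with a binomial standard error over the
    position subsample.
    """
    clone_depths = np.asarray(clone_depths)
    bulk_depths = np.asarray(bulk_depths)
    if clone_depths.size == 0 or bulk_depths.size == 0:
        raise ValueError("empty depth input")
    if clone_depths.shape != bulk_depths.shape:
        raise ValueError("clone and bulk depth tracks must align")
    ok = (clone_depths >= dp_min) & (bulk_depths >= dp_min)
    f = float(ok.mean())
    se = math.sqrt(f * (1 - f) / ok.size)
    return f, se


def extrapolate_load(n_observed: float, fraction: float) -> float:
    """Whole-genome load n_observed / surveyed_fraction (linear in n)."""
    if not 0 < fraction <= 1:
        raise ValueError("surveyed fraction must be in (0, 1]")
    return n_observed / fraction


def burden_table(rows) -> pd.DataFrame:
    """Normalize a list of per-clone dicts into a burden table with
    extrapolated loads and annual rates."""
    df = pd.DataFrame(rows)
    df["extrapolated_load"] = [
        extrapolate_load(n, f) for n, f in zip(df["n_observed"], df["surveyed_fraction"])
    ]
    df["rate"] = df["extrapolated_load"] / df["age"]
    return df


# ---------------------------------------------------------------------------
# Model design helpers
# ---------------------------------------------------------------------------

def _require_groups(df: pd.DataFrame, col: str, min_donors: int = 2,
                    min_levels: int = 1):
    if df[col].nunique() < min_levels:
        raise ValueError(f"need at least {min_levels} levels of {col!r}")
    for level, sub in df.groupby(col):
        if sub["donor_id"].nunique() < min_donors:
            raise ValueError(
                f"group {col}={level!r} has fewer than {min_donors} donors; "
                "only descriptive output is possible")


def _trisomy_design(df: pd.DataFrame, with_age: bool):
    t21 = df["trisomy21"].astype(bool).to_numpy().astype(float)
    isc = (df["cell_type"].astype(str) == "ISC").to_numpy().astype(float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if with_age:
        cols.append(df["age"].to_numpy(dtype=float))
        names.append("age")
    cols += [t21, isc, t21 * isc]
    names += ["trisomy21", "cell_type_ISC", "trisomy21:cell_type_ISC"]
    X = np.column_stack(cols)
    # drop interaction / cell-type columns that are constant (single cell type)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0 or names[j] == "intercept"]
    return X[:, keep], [names[j] for j in keep]


@dataclass
class RateModelResult:
    lmm: LMMResult
    group_means: pd.DataFrame        # cohort-level fitted mean rates with CI
    contrasts: pd.DataFrame          # pairwise differences
    fold_changes: pd.DataFrame       # pairwise ratios with bootstrap CI


def fit_rate_model(df: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                   method: str = "reml") -> RateModelResult:
    """Mutation rate (load/age) against cohort with a donor random intercept.

    ``df`` needs columns rate, cohort, donor_id.  Reports per-cohort mean
    rates with 95% CI, all pairwise contrasts (two-tailed t) and
    fold-changes between fitted means with a parametric-bootstrap CI drawn
    from the fixed-effect covariance.
    """
    _require_groups(df, "cohort")
    levels = list(pd.unique(df["cohort"]))
    X = np.column_stack([(df["cohort"] == lv).to_numpy(float) for lv in levels])
    names = [f"cohort[{lv}]" for lv in levels]
    model = MixedModel(df["rate"].to_numpy(float), X, df["donor_id"].to_numpy(),
                       random="intercept", xnames=names)
    res = model.fit(method=method)

    df_b = max(df["donor_id"].nunique() - len(levels), 1)
    means = []
    for j, lv in enumerate(levels):
        c = np.zeros(len(levels))
        c[j] = 1.0
        row = res.contrast(c, df=df_b)
        row["cohort"] = lv
        means.append(row)
    contrasts = []
    for (i, a), (j, b) in itertools.combinations(enumerate(levels), 2):
        c = np.zeros(len(levels))
        c[i], c[j] = 1.0, -1.0
        row = res.contrast(c, df=df_b)
        row["comparison"] = f"{a} - {b}"
        contrasts.append(row)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(res.params.to_numpy(),
                                    res.cov_params.to_numpy(), size=n_boot)
    folds = []
    for (i, a), (j, b) in itertools.combinations(enumerate(levels), 2):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = draws[:, i] / draws[:, j]
        est = res.params.iloc[i] / res.params.iloc[j]
        lo, hi = np.nanpercentile(ratio, [2.5, 97.5])
        folds.append({"comparison": f"{a} / {b}", "fold": float(est),
                      "ci_low": float(lo), "ci_high": float(hi)})
    return RateModelResult(
        lmm=res,
        group_means=pd.DataFrame(means).set_index("cohort"),
        contrasts=pd.DataFrame(contrasts).set_index("comparison"),
        fold_changes=pd.DataFrame(folds).set_index("comparison"),
    )


def fit_trisomy_model(df: pd.DataFrame, method: str = "reml",
                      heteroscedastic: bool = True) -> LMMResult:
    """Extrapolated load ~ age + trisomy x cell type; donor random slope on
    age; separate residual variances for D21 and T21 clones."""
    _require_groups(df, "trisomy21", min_levels=2)
    X, names = _trisomy_design(df, with_age=True)
    vg = df["trisomy21"].map({False: "D21", True: "T21"}).to_numpy() \
        if heteroscedastic else None
    model = MixedModel(df["extrapolated_load"].to_numpy(float), X,
                       df["donor_id"].to_numpy(),
                       random=df["age"].to_numpy(float),
                       variance_groups=vg, xnames=names)
    res = model.fit(method=method)
    if not res.converged:
        raise RuntimeError(
            "trisomy model did not converge; consider a simplified model "
            "(single variance or random intercept)")
    return res


def fit_early_model(df: pd.DataFrame, method: str = "reml",
                    heteroscedastic: bool = True,
                    response: str = "early_load") -> LMMResult:
    """The trisomy model without the age term, fitted to pre-gastrulation
    (bulk-subclonal) mutation loads; donor random intercept."""
    _require_groups(df, "trisomy21", min_levels=2)
    X, names = _trisomy_design(df, with_age=False)
    vg = df["trisomy21"].map({False: "D21", True: "T21"}).to_numpy() \
        if heteroscedastic else None
    model = MixedModel(df[response].to_numpy(float), X,
                       df["donor_id"].to_numpy(), random="intercept",
                       variance_groups=vg, xnames=names)
    res = model.fit(method=method)
    if not res.converged:
        raise RuntimeError("early model did not converge")
    return res


def variance_lr_test(df: pd.DataFrame, model: str = "trisomy",
                     method: str = "reml"):
    """Compare the heteroscedastic model to a single-variance version by a
    likelihood-ratio test (chi-square df=1).

    REML fits are the default: the two models share their fixed effects, so
    the REML criteria are directly comparable, and the ML version of this
    test is anticonservative at cohort-sized samples.
    """
    fit = fit_trisomy_model if model == "trisomy" else fit_early_model
    het = fit(df, method=method, heteroscedastic=True)
    hom = fit(df, method=method, heteroscedastic=False)
    return lr_test_variances(het, hom)


def leave_n_out(df: pd.DataFrame, n: int, fit_fn=fit_trisomy_model,
                effects=None) -> pd.DataFrame:
    """Refit after removing every combination of ``n`` observations.

    Returns one row per successful combination with the p-value of each
    fixed effect; combinations emptying a compared group are skipped (the
    ``skipped`` attribute lists them).
    """
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    idx = list(df.index)
    rows = []
    skipped = []
    for combo in itertools.combinations(idx, n):
        sub = df.drop(list(combo))
        try:
            res = fit_fn(sub)
        except (ValueError, RuntimeError) as err:
            skipped.append({"combo": combo, "reason": str(err)})
            continue
        row = {"removed": combo}
        for eff in (effects or res.pvalues.index):
            row[f"p[{eff}]"] = float(res.pvalues[eff])
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    out.attrs["max_p"] = {c: float(out[c].max()) for c in out.columns
                          if c.startswith("p[")} if len(out) else {}
    return out


def detect_outliers(result: LMMResult, fdr_q: float = 0.05) -> pd.DataFrame:
    """Two-sided standard-normal tail odds of each standardized residual,
    Benjamini-Hochberg adjusted; flag where FDR < q."""
    z = np.abs(result.std_resid)
    p = 2 * stats.norm.sf(z)
    rejected, fdr, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    return pd.DataFrame({
        "std_resid": result.std_resid, "p": p, "fdr": fdr,
        "outlier": rejected & (fdr < fdr_q),
    })


def compare_dbs(d21_counts, t21_counts, exact_limit: int = 20000):
    """Wilcoxon rank-sum comparison of per-clone DBS counts.

    Small samples are handled by exact enumeration of the permutation
    distribution of the rank-sum statistic (midranks under ties; two-sided
    p doubles the smaller tail); larger samples use the normal
    approximation with continuity and tie correction.  Returns (U, p).
    """
    x = np.asarray(d21_counts, dtype=float)
    y = np.asarray(t21_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2

    if math.comb(n1 + n2, n1) <= exact_limit:
        stats_all = []
        for combo in itertools.combinations(range(n1 + n2), n1):
            stats_all.append(ranks[list(combo)].sum())
        stats_all = np.asarray(stats_all)
        le = float(np.mean(stats_all <= r1 + 1e-9))
        ge = float(np.mean(stats_all >= r1 - 1e-9))
        p = min(1.0, 2.0 * min(le, ge))
        return float(u1), float(p)

    mu = n1 * n2 / 2
    tie_counts = np.array([c for c in pd.Series(pooled).value_counts()])
    n = n1 + n2
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u1), 1.0
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return float(u1), p
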