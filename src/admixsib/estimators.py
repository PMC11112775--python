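"""Regression estimators for ancestry differences in mean phenotype and genotype.

Three models, all with age and sex as covariates:

* model 1a (individual level):  Y_i = a + bY*Q_i + bA*Age_i + bS*Sex_i + e_i.
  bY estimates the difference in mean phenotype value (Delta-Y) between the
  two ancestral populations; it absorbs any environmental difference.
* model 1b (sibling-pair differences):
  dy_j = a + bG*dQ_j + b1*dAge_j + b2*Age_j1 + b3*dSex_j + b4*Sex_j1 + e_j.
  bG estimates the difference in mean genotypic value (Delta-G): family-level
  environment cancels in the within-pair difference.
* model 2 (mixed model): y_ij = a + bW*(Q_ij - Qbar_j) + bB*Qbar_j
  + b_age*Age + b_sex*Sex + gamma_j + e_ij with a family random intercept.
  bW is the within-family (Delta-G) and bB the between-family (Delta-Y)
  estimate; the random intercept handles multiple pairs per family.

Effect sizes are reported per percentage point of ancestry (coef/100 with Q
on [0, 1]); p-values are computed on rank-based inverse-normal transformed
phenotypes, reproducing the dual reporting convention of admixture-ancestry
association tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri
from scipy.stats import rankdata

from .relatedness import SibPair

__all__ = [
    "EffectEstimate",
    "quantile_transform",
    "build_pair_diffs",
    "fit_model_1a",
    "fit_model_1b",
    "fit_model_2",
    "fdr_adjust",
    "multi_response_ols",
    "estimate_effects",
]


@dataclass
class EffectEstimate:
    """One fitted ancestry effect.

    ``coef``/``se`` are on the Q-in-[0,1] scale; ``effect_per_pct`` divides
    by 100 for reporting per percentage point of ancestry.
    """

    model: str  # 1a | 1b | 2-within | 2-between
    phenotype: str
    coef: float
    se: float
    p: float
    n: int
    scale: str = "raw"  # raw | transformed
    p_fdr: float | None = None

    @property
    def effect_per_pct(self) -> float:
        return self.coef / 100.0

    @property
    def se_per_pct(self) -> float:
        return self.se / 100.0


def quantile_transform(values: np.ndarray | pd.Series, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    z_i = Phi^-1((r_i - c) / (n - 2c + 1)) with average ranks for ties (tied
    inputs map to identical outputs).  Missing values propagate as NaN.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    xo = x[obs]
    if len(xo) < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.all(xo == xo[0]):
        raise ValueError("all values identical: quantile transform undefined")
    r = rankdata(xo, method="average")
    out[obs] = ndtri((r - c) / (len(xo) - 2 * c + 1))
    return out


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.sqrt(np.mean(resid**2)) < 1e-10 * max(1.0, np.abs(X[:, j]).max()):
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_model_1a(
    df: pd.DataFrame,
    pheno: str = "y",
    q_col: str = "q",
    age_col: str = "age",
    sex_col: str = "sex",
    scale: str = "raw",
) -> EffectEstimate:
    """OLS of phenotype on ancestry proportion, age and sex (Delta-Y estimate)."""
    d = df[[pheno, q_col, age_col, sex_col]].dropna()
    if len(d) < 3:
        raise ValueError("need at least 3 complete cases")
    X = sm.add_constant(d[[q_col, age_col, sex_col]].to_numpy(dtype=float), has_constant="add")
    _check_full_rank(X, ["const", q_col, age_col, sex_col])
    res = sm.OLS(d[pheno].to_numpy(dtype=float), X).fit()
    return EffectEstimate(
        model="1a", phenotype=pheno, coef=float(res.params[1]),
        se=float(res.bse[1]), p=float(res.pvalues[1]), n=len(d), scale=scale,
    )


def build_pair_diffs(
    pairs: Sequence[SibPair] | Sequence[tuple[str, str]],
    table: pd.DataFrame,
    pheno: str = "y",
    q_col: str = "q",
    age_col: str = "age",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Sibling-pair difference table for model 1b.

    ``table`` must be indexed by individual id.  Sibling 1 is the
    lexicographically smaller id, fixing the sign convention of all
    difference columns deterministically.
    """
    rows = []
    for p in pairs:
        a, b = (p.id1, p.id2) if isinstance(p, SibPair) else (p[0], p[1])
        s1, s2 = sorted((a, b))
        r1, r2 = table.loc[s1], table.loc[s2]
        rows.append(
            {
                "id1": s1,
                "id2": s2,
                "fid": getattr(p, "fid", None) or r1.get("fid"),
                "dy": r1[pheno] - r2[pheno],
                "dq": r1[q_col] - r2[q_col],
                "dage": r1[age_col] - r2[age_col],
                "age1": r1[age_col],
                "dsex": r1[sex_col] - r2[sex_col],
                "sex1": r1[sex_col],
            }
        )
    return pd.DataFrame(rows)


def fit_model_1b(pair_df: pd.DataFrame, scale: str = "raw", pheno: str = "y") -> EffectEstimate:
    """OLS of within-pair phenotype differences on ancestry differences (Delta-G)."""
    d = pair_df[["dy", "dq", "dage", "age1", "dsex", "sex1"]].dropna()
    if len(d) < 7:
        raise ValueError("need at least 7 complete pairs (6 parameters)")
    if np.all(d["dq"] == 0):
        raise ValueError("all ancestry differences are zero: Delta-G not identifiable")
    X = sm.add_constant(d[["dq", "dage", "age1", "dsex", "sex1"]].to_numpy(dtype=float), has_constant="add")
    _check_full_rank(X, ["const", "dq", "dage", "age1", "dsex", "sex1"])
    res = sm.OLS(d["dy"].to_numpy(dtype=float), X).fit()
    return EffectEstimate(
        model="1b", phenotype=pheno, coef=float(res.params[1]),
        se=float(res.bse[1]), p=float(res.pvalues[1]), n=len(d), scale=scale,
    )


def fit_model_2(
    df: pd.DataFrame,
    pheno: str = "y",
    q_col: str = "q",
    fid_col: str = "fid",
    age_col: str = "age",
    sex_col: str = "sex",
    scale: str = "raw",
) -> tuple[EffectEstimate, EffectEstimate]:
    """Family random-intercept mixed model (REML): within and between effects.

    Returns (within, between) effect estimates for the family-mean-centred
    ancestry (Delta-G) and the family mean ancestry (Delta-Y).  A singular or
    non-converging random-effect fit falls back, with a warning, to the
    sigma_gamma = 0 ordinary least squares fit.
    """
    d = df[[pheno, q_col, fid_col, age_col, sex_col]].dropna().copy()
    fam_sizes = d.groupby(fid_col)[pheno].size()
    if (fam_sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 families with at least 2 siblings")
    qbar = d.groupby(fid_col)[q_col].transform("mean")
    d["q_within"] = d[q_col] - qbar
    d["q_between"] = qbar
    y = d[pheno].to_numpy(dtype=float)
    X = sm.add_constant(d[["q_within", "q_between", age_col, sex_col]].to_numpy(dtype=float), has_constant="add")
    names = ["const", "q_within", "q_between", age_col, sex_col]
    _check_full_rank(X, names)

    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, X, groups=d[fid_col].to_numpy())
            res = md.fit(reml=True)
        if not np.all(np.isfinite(res.bse[1:3])):
            res = None
    except (np.linalg.LinAlgError, ValueError):
        res = None
    if res is None:
        warnings.warn(
            "mixed model singular or non-converged; falling back to sigma_gamma=0 OLS",
            stacklevel=2,
        )
        res = sm.OLS(y, X).fit()
    params = np.asarray(res.params)[:5]
    bse = np.asarray(res.bse)[:5]
    pvals = np.asarray(res.pvalues)[:5]
    within = EffectEstimate(
        model="2-within", phenotype=pheno, coef=float(params[1]),
        se=float(bse[1]), p=float(pvals[1]), n=len(d), scale=scale,
    )
    between = EffectEstimate(
        model="2-between", phenotype=pheno, coef=float(params[2]),
        se=float(bse[2]), p=float(pvals[2]), n=len(d), scale=scale,
    )
    return within, between


def fdr_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def multi_response_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and standard errors for many response vectors at once.

    ``X`` is (n, p); ``Y`` is (n, r).  Returns ``(B, SE)`` each of shape
    (p, r).  Used for replicate-heavy simulations where the design is fixed;
    coefficients are identical to fitting each column separately.
    """
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / max(n - p, 1)
    SE = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return B, SE


def estimate_effects(
    table: pd.DataFrame,
    pairs: Sequence[SibPair] | Sequence[tuple[str, str]],
    phenotypes: Sequence[str],
    q_col: str = "q",
    age_col: str = "age",
    sex_col: str = "sex",
    fid_col: str = "fid",
    include: Mapping[str, pd.Series] | None = None,
    run_model_2: bool = True,
) -> pd.DataFrame:
    """Fit all models for each phenotype and assemble a results table.

    Per phenotype and model the table reports the raw-scale effect per
    percentage point of ancestry with its SE, the p-value from the
    inverse-normal-transformed fit, and the FDR-adjusted p-value (adjusted
    across phenotypes within each model).  ``include`` optionally maps a
    phenotype to a boolean mask over ``table``'s index (e.g. declarative
    treatment-exclusion rules); individuals are transformed after masking,
    and pair differences use transformed individual values.
    """
    include = include or {}
    records = []
    for pheno in phenotypes:
        t = table if pheno not in include else table[include[pheno].reindex(table.index, fill_value=False)]
        t = t[t[pheno].notna()]
        tt = t.copy()
        tt[pheno] = quantile_transform(t[pheno])
        fits: dict[str, tuple[EffectEstimate, EffectEstimate]] = {}
        raw_1a = fit_model_1a(t, pheno, q_col, age_col, sex_col, scale="raw")
        trn_1a = fit_model_1a(tt, pheno, q_col, age_col, sex_col, scale="transformed")
        usable = [
            p for p in pairs
            if (p.id1 if isinstance(p, SibPair) else p[0]) in t.index
            and (p.id2 if isinstance(p, SibPair) else p[1]) in t.index
        ]
        raw_1b = fit_model_1b(
            build_pair_diffs(usable, t, pheno, q_col, age_col, sex_col), "raw", pheno)
        trn_1b = fit_model_1b(
            build_pair_diffs(usable, tt, pheno, q_col, age_col, sex_col), "transformed", pheno)
        model_fits = [("1a", raw_1a, trn_1a), ("1b", raw_1b, trn_1b)]
        if run_model_2:
            raw_2w, raw_2b = fit_model_2(t, pheno, q_col, fid_col, age_col, sex_col, "raw")
            trn_2w, trn_2b = fit_model_2(tt, pheno, q_col, fid_col, age_col, sex_col, "transformed")
            model_fits += [("2-within", raw_2w, trn_2w), ("2-between", raw_2b, trn_2b)]
        for tag, raw, trn in model_fits:
            records.append(
                {
                    "phenotype": pheno,
                    "model": tag,
                    "n": raw.n,
                    "effect_per_pct": raw.effect_per_pct,
                    "se_per_pct": raw.se_per_pct,
                    "effect_raw": raw.coef,
                    "se_raw": raw.se,
                    "p": trn.p,
                }
            )
    out = pd.DataFrame(records)
    out["p_fdr"] = np.nan
    for tag in out["model"].unique():
        m = out["model"] == tag
        out.loc[m, "p_fdr"] = fdr_adjust(out.loc[m, "p"].to_numpy())
    return out
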