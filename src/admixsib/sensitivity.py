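"""Simulation-based sensitivity analyses for the sibling Delta-G design.

Three perturbations of the generative model probe the estimators' robustness:

* ancestry-by-environment interaction, acting on the family mean sibling
  ancestry (expected: Delta-G unbiased, Delta-Y biased) or on each sibling's
  own ancestry (expected: Delta-G biased by exactly E_anc in the noiseless
  limit, small relative to its sampling spread at realistic dQ variance);
* participation bias, where a high phenotype (one's own, or one's mother's)
  lowers the chance of joining the study (expected: |Delta-Y| attenuated,
  Delta-G nearly unbiased, since only within-pair contrasts enter it);
* ancestry-estimation error, N(0, sigma_Qerror^2) added per individual
  before estimation (expected: classical errors-in-variables attenuation of
  Delta-G by Var(dQ) / (Var(dQ) + 2*sigma_Qerror^2)).

Each analysis simulates phenotypes on a fixed sibling population (any table
with family structure and ancestry proportions; by default a synthetic
admixed population filtered to informative sibling pairs), refits models 1a
and 1b per replicate, and reports the mean and spread of the estimates
against truth on a parameter grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .relatedness import SibPair, filter_admixed_pairs
from .simpop import Population, simulate_population

__all__ = [
    "SimGridResult",
    "default_sibling_data",
    "sim_env_interaction",
    "sim_participation_bias",
    "sim_q_error",
]


@dataclass
class SimGridResult:
    """Grid summary of a sensitivity simulation."""

    param_name: str
    table: pd.DataFrame  # one row per grid value
    truth: float  # true Delta-G
    n_reps: int
    seed: int


@dataclass
class _PairedDesign:
    """Fixed design matrices for replicate-heavy refits on one population."""

    q: np.ndarray
    mother_q: np.ndarray | None
    fam_index: np.ndarray  # family code per individual
    i1: np.ndarray  # row of sibling 1 per pair (lexicographic id order)
    i2: np.ndarray
    X1a: np.ndarray  # [1, Q, age, sex]
    X1b: np.ndarray  # [1, dq, dage, age1, dsex, sex1]
    pinv1a: np.ndarray
    pinv1b: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.i1)

    @property
    def dq(self) -> np.ndarray:
        return self.q[self.i1] - self.q[self.i2]


def _make_design(sibs: pd.DataFrame, pairs: Sequence[tuple[str, str]], q_col: str) -> _PairedDesign:
    sibs = sibs.reset_index(drop=True)
    loc = {iid: i for i, iid in enumerate(sibs["iid"])}
    i1 = np.array([loc[min(a, b)] for a, b in pairs])
    i2 = np.array([loc[max(a, b)] for a, b in pairs])
    q = sibs[q_col].to_numpy(dtype=float)
    age = sibs["age"].to_numpy(dtype=float)
    sex = sibs["sex"].to_numpy(dtype=float)
    X1a = np.column_stack([np.ones(len(sibs)), q, age, sex])
    X1b = np.column_stack(
        [np.ones(len(i1)), q[i1] - q[i2], age[i1] - age[i2], age[i1],
         sex[i1] - sex[i2], sex[i1]]
    )
    mother_q = (
        sibs["mother_q"].to_numpy(dtype=float) if "mother_q" in sibs else None
    )
    fam = pd.factorize(sibs["fid"])[0]
    return _PairedDesign(
        q=q, mother_q=mother_q, fam_index=fam, i1=i1, i2=i2,
        X1a=X1a, X1b=X1b,
        pinv1a=np.linalg.pinv(X1a), pinv1b=np.linalg.pinv(X1b),
    )


def default_sibling_data(
    n_families: int = 450, seed: int = 0
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """A synthetic admixed sibling population, filtered to informative pairs.

    Simulates the default two-way admixed population, keeps the siblings
    belonging to at least one retained admixed pair (true ancestry and true
    parental ancestry drive the filters), and returns the sibling table
    (iid, fid, sex, age, q_true, mother_q) plus the retained pair ids.
    """
    pop = simulate_population(n_families, seed=seed)
    ped = pop.pedigree_frame()
    q_true = ped["q_true"]
    candidates = [SibPair(a, b) for a, b in pop.sibling_pairs()]
    retained, _ = filter_admixed_pairs(candidates, q_true, pop.parent_q())
    keep_ids = sorted({p.id1 for p in retained} | {p.id2 for p in retained})
    sibs = ped.loc[keep_ids, ["iid", "fid", "sex", "age", "q_true"]].copy()
    mothers = {ind.iid: ind.mother for ind in pop.offspring}
    sibs["mother_q"] = [q_true[mothers[i]] for i in sibs["iid"]]
    return sibs.reset_index(drop=True), [(p.id1, p.id2) for p in retained]


def _resolve_data(
    sibs: pd.DataFrame | None,
    pairs: Sequence[tuple[str, str]] | None,
    q_col: str,
    seed: int,
) -> tuple[pd.DataFrame, Sequence[tuple[str, str]]]:
    if sibs is None:
        return default_sibling_data(seed=seed)
    if pairs is None:
        raise ValueError("pairs must accompany a user-supplied sibling table")
    return sibs, pairs


def sim_env_interaction(
    mode: str,
    e_anc_grid: Sequence[float] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0),
    n_reps: int = 10_000,
    dg: float = 1.0,
    sigma: float = 1.0,
    sibs: pd.DataFrame | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    q_col: str = "q_true",
    seed: int = 0,
) -> SimGridResult:
    """Bias of the Delta-Y (model 1a) and Delta-G (model 1b) estimators under
    an ancestry-by-environment interaction.

    Phenotypes per replicate: y ~ N(Q*dg + E_anc*Qbar_family, sigma^2) in
    family mode, or y ~ N(Q*dg + E_anc*Q, sigma^2) in individual mode.
    """
    if mode not in ("family", "individual"):
        raise ValueError(f"mode must be 'family' or 'individual', got {mode!r}")
    sibs, pairs = _resolve_data(sibs, pairs, q_col, seed)
    des = _make_design(sibs, pairs, q_col)
    qbar = pd.Series(des.q).groupby(des.fam_index).transform("mean").to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for e_anc in e_anc_grid:
        env = e_anc * (qbar if mode == "family" else des.q)
        mu = des.q * dg + env
        by = np.empty(n_reps)
        bg = np.empty(n_reps)
        chunk = max(1, min(n_reps, 200))
        done = 0
        while done < n_reps:
            r = min(chunk, n_reps - done)
            Y = mu[:, None] + sigma * rng.standard_normal((len(mu), r))
            by[done : done + r] = (des.pinv1a @ Y)[1]
            dY = Y[des.i1] - Y[des.i2]
            bg[done : done + r] = (des.pinv1b @ dY)[1]
            done += r
        rows.append(
            {
                "e_anc": e_anc,
                "mean_dy_hat": by.mean(), "sd_dy_hat": by.std(ddof=1),
                "mean_dg_hat": bg.mean(), "sd_dg_hat": bg.std(ddof=1),
                "bias_dy": by.mean() - dg, "bias_dg": bg.mean() - dg,
            }
        )
    return SimGridResult("e_anc", pd.DataFrame(rows), truth=dg, n_reps=n_reps, seed=seed)


def sim_participation_bias(
    threshold_quantiles: Sequence[float] = (0.5, 0.7, 0.9),
    dropout_prob: float = 0.2,
    mode: str = "self",
    n_reps: int = 500,
    dg: float = 1.0,
    sigma: float = 1.0,
    sibs: pd.DataFrame | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    q_col: str = "q_true",
    seed: int = 0,
) -> SimGridResult:
    """Bias of the estimators under phenotype-dependent non-participation.

    ``self`` mode: an individual whose phenotype exceeds the grid quantile's
    threshold fails to participate with probability ``dropout_prob``; to keep
    the number of individuals and pairs fixed, the non-participant is
    replaced by redrawing its phenotype until below the threshold (rejection
    sampling), and both models are fitted on the resulting sample.

    ``mother`` mode: participation depends on the mother's phenotype
    (simulated from her ancestry proportion under the same model); families
    whose mother exceeds the threshold drop out entirely with probability
    ``dropout_prob`` and their siblings and pairs are removed from both fits.
    """
    if mode not in ("self", "mother"):
        raise ValueError(f"mode must be 'self' or 'mother', got {mode!r}")
    for tq in threshold_quantiles:
        if not (0 < tq < 1):
            raise ValueError("threshold quantiles must lie strictly in (0, 1)")
    sibs, pairs = _resolve_data(sibs, pairs, q_col, seed)
    des = _make_design(sibs, pairs, q_col)
    if mode == "mother" and des.mother_q is None:
        raise ValueError("mother mode requires a 'mother_q' column")
    rng = np.random.default_rng(seed)
    n = len(des.q)
    rows = []
    for tq in threshold_quantiles:
        by = np.empty(n_reps)
        bg = np.empty(n_reps)
        for rep in range(n_reps):
            y = des.q * dg + sigma * rng.standard_normal(n)
            if mode == "self":
                thr = np.quantile(y, tq)
                redraw = (y > thr) & (rng.random(n) < dropout_prob)
                pending = np.flatnonzero(redraw)
                while len(pending):
                    y[pending] = des.q[pending] * dg + sigma * rng.standard_normal(len(pending))
                    pending = pending[y[pending] > thr]
                by[rep] = (des.pinv1a @ y)[1]
                bg[rep] = (des.pinv1b @ (y[des.i1] - y[des.i2]))[1]
            else:
                fam_mq = pd.Series(des.mother_q).groupby(des.fam_index).first().to_numpy()
                ym = fam_mq * dg + sigma * rng.standard_normal(len(fam_mq))
                thr = np.quantile(ym, tq)
                fam_drop = (ym > thr) & (rng.random(len(ym)) < dropout_prob)
                keep_ind = ~fam_drop[des.fam_index]
                keep_pair = keep_ind[des.i1] & keep_ind[des.i2]
                b1a, _ = np.linalg.lstsq(des.X1a[keep_ind], y[keep_ind], rcond=None)[:2]
                dY = (y[des.i1] - y[des.i2])[keep_pair]
                b1b, _ = np.linalg.lstsq(des.X1b[keep_pair], dY, rcond=None)[:2]
                by[rep], bg[rep] = b1a[1], b1b[1]
        rows.append(
            {
                "threshold_quantile": tq,
                "mean_dy_hat": by.mean(), "sd_dy_hat": by.std(ddof=1),
                "mean_dg_hat": bg.mean(), "sd_dg_hat": bg.std(ddof=1),
                "bias_dy": by.mean() - dg, "bias_dg": bg.mean() - dg,
            }
        )
    return SimGridResult(
        "threshold_quantile", pd.DataFrame(rows), truth=dg, n_reps=n_reps, seed=seed
    )


def sim_q_error(
    sigma_grid: Sequence[float] | None = None,
    n_reps: int = 10_000,
    dg: float = 1.0,
    sigma: float = 1.0,
    per_pair: bool = False,
    sibs: pd.DataFrame | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    q_col: str = "q_true",
    seed: int = 0,
) -> SimGridResult:
    """Attenuation of the Delta-G estimator under ancestry-estimation error.

    Phenotypes are generated from true ancestry; before fitting model 1b,
    independent N(0, sigma_Qerror^2) error is added to each individual's Q
    (or, with ``per_pair=True``, a single error to each pair's dQ).  Reports
    the mean estimate, the induced mean absolute error of dQ, and the
    closed-form attenuation factor Var(dQ)/(Var(dQ) + 2*sigma_Qerror^2)
    (per-individual mode) for comparison.

    Each replicate's phenotype and unit ancestry-noise draws are shared
    across the grid (common random numbers): the marginal distribution at
    every grid value is unchanged, while grid-to-grid comparisons of the
    mean estimate — the attenuation curve — have far less Monte-Carlo noise.
    """
    if sigma_grid is None:
        rng0 = np.random.default_rng(seed)
        sigma_grid = np.sort(rng0.uniform(0.0, 0.05, size=100))
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(sigma_grid < 0):
        raise ValueError("sigma_Qerror grid values must be >= 0")
    sibs, pairs = _resolve_data(sibs, pairs, q_col, seed)
    des = _make_design(sibs, pairs, q_col)
    rng = np.random.default_rng(seed)
    dq_true = des.dq
    var_dq = float(np.var(dq_true))
    n = len(des.q)
    n_pairs = des.n_pairs
    # Frisch-Waugh-Lovell: the model-1b slope on dq_hat equals the simple
    # regression of covariate-residualised dY on covariate-residualised
    # dq_hat; the covariate block is fixed, so residualisation is two matvecs
    covar = np.delete(des.X1b, 1, axis=1)
    Qc, _ = np.linalg.qr(covar)

    def resid(v: np.ndarray) -> np.ndarray:
        return v - Qc @ (Qc.T @ v)

    bg = np.empty((len(sigma_grid), n_reps))
    abs_err = np.empty((len(sigma_grid), n_reps))
    for rep in range(n_reps):
        y = des.q * dg + sigma * rng.standard_normal(n)
        dY_r = resid(y[des.i1] - y[des.i2])
        eta = rng.standard_normal(n_pairs if per_pair else n)
        for gi, sq in enumerate(sigma_grid):
            if per_pair:
                dq_hat = dq_true + sq * eta
            else:
                q_hat = des.q + sq * eta
                dq_hat = q_hat[des.i1] - q_hat[des.i2]
            dq_r = resid(dq_hat)
            bg[gi, rep] = float(dq_r @ dY_r) / float(dq_r @ dq_r)
            abs_err[gi, rep] = np.mean(np.abs(dq_hat - dq_true))
    rows = []
    for gi, sq in enumerate(sigma_grid):
        err_var = sq**2 if per_pair else 2 * sq**2
        rows.append(
            {
                "sigma_qerror": sq,
                "mean_dg_hat": bg[gi].mean(), "sd_dg_hat": bg[gi].std(ddof=1),
                "bias_dg": bg[gi].mean() - dg,
                "mean_abs_dq_error": abs_err[gi].mean(),
                "predicted_attenuation": var_dq / (var_dq + err_var),
                "empirical_attenuation": bg[gi].mean() / dg,
            }
        )
    return SimGridResult(
        "sigma_qerror", pd.DataFrame(rows), truth=dg, n_reps=n_reps, seed=seed
    )
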