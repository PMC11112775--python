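"""Variant QC and two-way admixture proportion estimation.

The admixture model is the standard K=2 binomial likelihood: individual i's
genotype at locus l is Binomial(2, pi_il) with

    pi_il = q_i * f1_l + (1 - q_i) * f2_l,

where q_i is the ancestry-1 proportion and f1/f2 the ancestral allele
frequencies.  The supervised estimator maximises this over q_i alone with
known frequencies; the unsupervised estimator runs block EM over all q's and
both frequency vectors, with component labels aligned to population 1 through
an anchor set of individuals of known ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .simpop import AncestralFreqs

__all__ = [
    "QCReport",
    "AdmixtureEstimate",
    "variant_qc",
    "estimate_admixture_supervised",
    "estimate_admixture_unsupervised",
]

_FREQ_EPS = 1e-6  # clamp for frequencies, avoids log(0)


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_removed_ld: int
    kept: np.ndarray  # boolean mask over input loci

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def _masked_freq(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus allele frequency and missing fraction; -1 codes missing."""
    miss = G < 0
    n_obs = (~miss).sum(axis=0)
    tot = np.where(miss, 0, G).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, tot / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return freq, miss.mean(axis=0)


def variant_qc(
    G: np.ndarray,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    ld_r2_max: float = 0.8,
    window: int = 50,
    step: int = 5,
) -> tuple[np.ndarray, QCReport]:
    """Filter loci on MAF, missingness and pairwise LD.

    Removes loci with minor-allele frequency below ``maf_min`` or missing-call
    fraction above ``miss_max``, then greedily prunes one locus of any pair
    with squared Pearson correlation above ``ld_r2_max`` inside a sliding
    window of ``window`` loci advanced by ``step`` (PLINK-style dialect).
    """
    if G.size == 0:
        raise ValueError("empty genotype matrix")
    n_ind, n_loci = G.shape
    freq, missfrac = _masked_freq(G)
    maf = np.minimum(freq, 1 - freq)
    bad_maf = (maf < maf_min) | np.isnan(maf)
    bad_miss = missfrac > miss_max
    keep = ~(bad_maf | bad_miss)

    # mean-impute missing for correlation computations
    Gf = G.astype(float)
    Gf[G < 0] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(Gf), np.nan, Gf), axis=0)
    Gi = np.where(np.isnan(Gf), col_mean, Gf)

    idx = np.flatnonzero(keep)
    removed_ld = np.zeros(n_loci, dtype=bool)
    start = 0
    while start < len(idx):
        win = idx[start : start + window]
        win = win[~removed_ld[win]]
        if len(win) > 1:
            X = Gi[:, win]
            sd = X.std(axis=0)
            ok = sd > 0
            if ok.sum() > 1:
                Xc = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
                R = (Xc.T @ Xc) / n_ind
                r2 = R**2
                sub = win[ok]
                for a in range(len(sub)):
                    if removed_ld[sub[a]]:
                        continue
                    for b in range(a + 1, len(sub)):
                        if not removed_ld[sub[b]] and r2[a, b] > ld_r2_max:
                            removed_ld[sub[b]] = True
        start += step
    keep &= ~removed_ld
    report = QCReport(
        n_input=n_loci,
        n_removed_maf=int(bad_maf.sum()),
        n_removed_missing=int((bad_miss & ~bad_maf).sum()),
        n_removed_ld=int(removed_ld.sum()),
        kept=keep,
    )
    return G[:, keep], report


@dataclass
class AdmixtureEstimate:
    """Estimated ancestry proportions (population 1) and model metadata."""

    q: np.ndarray
    f1: np.ndarray | None = None
    f2: np.ndarray | None = None
    loglik: float = np.nan
    loglik_path: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = True


def _loglik_matrix(G: np.ndarray, pi: np.ndarray) -> float:
    """Binomial log-likelihood, missing entries (-1) skipped; constants dropped."""
    obs = G >= 0
    g = np.where(obs, G, 0).astype(float)
    pi = np.clip(pi, _FREQ_EPS, 1 - _FREQ_EPS)
    ll = g * np.log(pi) + (2.0 - g) * np.log1p(-pi)
    return float(np.where(obs, ll, 0.0).sum())


def estimate_admixture_supervised(
    G: np.ndarray, freqs: AncestralFreqs
) -> AdmixtureEstimate:
    """Per-individual MLE of q with known ancestral frequencies.

    One-dimensional bounded likelihood maximisation over q in [0, 1] per
    individual; missing genotypes are skipped.
    """
    if G.ndim == 1:
        G = G[None, :]
    if G.shape[1] != freqs.n_loci:
        raise ValueError(
            f"genotypes have {G.shape[1]} loci but frequencies have {freqs.n_loci}"
        )
    f1 = np.clip(freqs.f1, _FREQ_EPS, 1 - _FREQ_EPS)
    f2 = np.clip(freqs.f2, _FREQ_EPS, 1 - _FREQ_EPS)
    q_hat = np.empty(G.shape[0])
    total_ll = 0.0
    for i, g in enumerate(G):
        obs = g >= 0
        gv, a, b = g[obs].astype(float), f1[obs], f2[obs]

        def neg_ll(q: float) -> float:
            pi = np.clip(q * a + (1 - q) * b, _FREQ_EPS, 1 - _FREQ_EPS)
            return -float(np.sum(gv * np.log(pi) + (2 - gv) * np.log1p(-pi)))

        res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-10})
        q_hat[i] = res.x
        total_ll -= res.fun
    return AdmixtureEstimate(q=q_hat, f1=freqs.f1, f2=freqs.f2, loglik=total_ll)


def estimate_admixture_unsupervised(
    G: np.ndarray,
    K: int = 2,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int | np.random.Generator = 0,
    anchors: np.ndarray | None = None,
    anchor_population: int = 2,
) -> AdmixtureEstimate:
    """Joint EM estimation of ancestry proportions and ancestral frequencies.

    Block EM for the K=2 binomial admixture likelihood, alternating updates
    of each individual's q and of both frequency vectors; stops when the
    log-likelihood gain drops below ``tol``.  Component labels are aligned so
    that the individuals in ``anchors`` belong to ``anchor_population``
    (mirroring the use of a reference panel of known ancestry); without
    anchors the labelling is deterministic but arbitrary (population 1 is the
    majority component) and a warning is issued.
    """
    if K != 2:
        raise ValueError("only K=2 is supported")
    if G.ndim != 2 or G.shape[0] < 2 or G.shape[1] < 2:
        raise ValueError("need >=2 individuals and >=2 loci")
    rng = np.random.default_rng(seed)
    n, L = G.shape
    obs = G >= 0
    g = np.where(obs, G, 0).astype(float)
    two = np.where(obs, 2.0, 0.0)
    n_obs = obs.sum(axis=1)
    if np.any(n_obs == 0):
        raise ValueError("individual with no observed genotypes")

    freq, _ = _masked_freq(G)
    if np.all((freq <= 0) | (freq >= 1) | np.isnan(freq)):
        raise ValueError("all loci monomorphic: admixture proportions are undefined")

    q = rng.uniform(0.2, 0.8, size=n)
    jitter = 0.1 * rng.standard_normal((2, L))
    f1 = np.clip(freq + jitter[0], _FREQ_EPS, 1 - _FREQ_EPS)
    f2 = np.clip(freq + jitter[1], _FREQ_EPS, 1 - _FREQ_EPS)

    def em_step(q: np.ndarray, f1: np.ndarray, f2: np.ndarray):
        pi = np.clip(q[:, None] * f1 + (1 - q[:, None]) * f2, _FREQ_EPS, 1 - _FREQ_EPS)
        # expected allele-copy counts attributed to each component
        a1 = g * (q[:, None] * f1 / pi)                      # '1' alleles from pop1
        a0 = (two - g) * (q[:, None] * (1 - f1) / (1 - pi))  # '0' alleles from pop1
        b1 = g * ((1 - q[:, None]) * f2 / pi)
        b0 = (two - g) * ((1 - q[:, None]) * (1 - f2) / (1 - pi))
        q_new = np.clip((a1 + a0).sum(axis=1) / (2.0 * n_obs), 0.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f1_new = a1.sum(axis=0) / np.maximum((a1 + a0).sum(axis=0), 1e-300)
            f2_new = b1.sum(axis=0) / np.maximum((b1 + b0).sum(axis=0), 1e-300)
        return (
            q_new,
            np.clip(f1_new, _FREQ_EPS, 1 - _FREQ_EPS),
            np.clip(f2_new, _FREQ_EPS, 1 - _FREQ_EPS),
        )

    def loglik(q: np.ndarray, f1: np.ndarray, f2: np.ndarray) -> float:
        return _loglik_matrix(G, q[:, None] * f1 + (1 - q[:, None]) * f2)

    def pack(q, f1, f2):
        return np.concatenate([q, f1, f2])

    def unpack(theta):
        return (
            np.clip(theta[:n], 0.0, 1.0),
            np.clip(theta[n : n + L], _FREQ_EPS, 1 - _FREQ_EPS),
            np.clip(theta[n + L :], _FREQ_EPS, 1 - _FREQ_EPS),
        )

    # SQUAREM-accelerated EM: each cycle takes two EM steps plus, when it
    # improves the likelihood, an extrapolated step; falling back to the
    # plain double EM step keeps the log-likelihood path non-decreasing.
    ll_path = [loglik(q, f1, f2)]
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        s1 = em_step(q, f1, f2)
        s2 = em_step(*s1)
        t0, t1, t2 = pack(q, f1, f2), pack(*s1), pack(*s2)
        r, v = t1 - t0, (t2 - t1) - (t1 - t0)
        v_norm = float(np.linalg.norm(v))
        ll2 = loglik(*s2)
        best, ll_new = s2, ll2
        if v_norm > 0:
            alpha = min(-1.0, -float(np.linalg.norm(r)) / v_norm)
            cand = unpack(t0 - 2 * alpha * r + alpha**2 * v)
            cand = em_step(*cand)  # stabilising EM step after extrapolation
            ll_cand = loglik(*cand)
            if ll_cand > ll2:
                best, ll_new = cand, ll_cand
        q, f1, f2 = best
        ll_path.append(ll_new)
        if ll_new - ll_path[-2] < tol:
            converged = True
            break

    if anchors is not None and len(anchors) > 0:
        anchor_q = float(np.mean(q[np.asarray(anchors)]))
        flip = anchor_q > 0.5 if anchor_population == 2 else anchor_q < 0.5
    else:
        warnings.warn(
            "no anchor individuals provided: component labels are arbitrary "
            "(population 1 set to the majority component)",
            stacklevel=2,
        )
        flip = float(np.mean(q)) < 0.5
    if flip:
        q, f1, f2 = 1 - q, f2, f1

    return AdmixtureEstimate(
        q=q, f1=f1, f2=f2, loglik=ll_path[-1],
        loglik_path=np.array(ll_path), n_iter=it, converged=converged,
    )
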