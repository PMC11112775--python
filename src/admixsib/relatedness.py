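"""Admixture-aware IBD estimation, sibling clustering and pair filtering.

Pairwise relatedness is summarised by (k0, k1, k2): the genome fractions at
which a pair shares 0, 1 or 2 alleles identical by descent.  Full siblings
expect (0.25, 0.5, 0.25).  In an admixed sample, ignoring ancestry inflates
apparent relatedness, so each individual's allele frequency at locus l is
taken as pi_il = q_i f1_l + (1 - q_i) f2_l before entering the standard
IBD-conditional genotype-pair probabilities.  The shared-allele frequency in
the IBD=1/IBD=2 terms uses the pair mean (pi_1 + pi_2)/2, a deliberate
simplification of haplotype-level joint ancestry/IBD models.

Sibling classification and the admixed-pair filters follow the study design:
a k1/k2 box selects full siblings (with a boundary rescue rule for pairs
already tied into a sibship), pairs in which both members carry >95% of the
same ancestry are uninformative and dropped, and candidate F1 pairs (both
members near 50/50 ancestry) are resolved through parental ancestry.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simpop import AncestralFreqs

__all__ = [
    "RelatednessEstimate",
    "SibPair",
    "pair_ibd_probs",
    "estimate_k",
    "estimate_k_pairs",
    "classify_full_siblings",
    "filter_admixed_pairs",
    "estimate_dq_error_from_f1",
]

_P_EPS = 1e-300


@dataclass
class RelatednessEstimate:
    id1: str
    id2: str
    k0: float
    k1: float
    k2: float
    loglik: float
    n_loci: int

    def __post_init__(self) -> None:
        k = np.array([self.k0, self.k1, self.k2])
        if np.any(k < -1e-9) or abs(k.sum() - 1) > 1e-6:
            raise ValueError("k0, k1, k2 must be a point on the probability simplex")


@dataclass
class SibPair:
    """One candidate full-sibling pair with its filter outcome."""

    id1: str
    id2: str
    fid: str | None = None
    status: str = "retained"  # retained | excluded-same-ancestry | excluded-F1 | unresolved
    rescued: bool = False
    dq: float | None = None  # Q(id1) - Q(id2)


def _genotype_probs(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities for observed genotypes."""
    return np.where(g == 0, (1 - p) ** 2, np.where(g == 1, 2 * p * (1 - p), p**2))


def _genotype_probs_given_shared(g: np.ndarray, s: int, p: np.ndarray) -> np.ndarray:
    """P(genotype | one allele IBD-shared equals s), other allele ~ Bernoulli(p)."""
    if s == 1:
        return np.where(g == 2, p, np.where(g == 1, 1 - p, 0.0))
    return np.where(g == 0, 1 - p, np.where(g == 1, p, 0.0))


def pair_ibd_probs(
    g1: np.ndarray, g2: np.ndarray, pi1: np.ndarray, pi2: np.ndarray
) -> np.ndarray:
    """Per-locus P(g1, g2 | IBD=m) for m = 0, 1, 2; shape (3, L).

    Individual-specific allele frequencies pi1/pi2 enter each individual's
    marginal; shared alleles are drawn at the pair-mean frequency.
    """
    pbar = 0.5 * (pi1 + pi2)
    p0 = _genotype_probs(g1, pi1) * _genotype_probs(g2, pi2)
    p1 = pbar * (
        _genotype_probs_given_shared(g1, 1, pi1) * _genotype_probs_given_shared(g2, 1, pi2)
    ) + (1 - pbar) * (
        _genotype_probs_given_shared(g1, 0, pi1) * _genotype_probs_given_shared(g2, 0, pi2)
    )
    p2 = np.where(g1 == g2, _genotype_probs(g1, pbar), 0.0)
    return np.stack([p0, p1, p2])


def _em_simplex_batch(
    P: np.ndarray, w: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted EM for many 3-component per-locus mixtures at once.

    ``P`` has shape (3, m, L); ``w`` is a (m, L) 0/1 observation mask.
    Returns (k, loglik) with shapes (m, 3) and (m,).  Each pair's
    log-likelihood path is non-decreasing (standard EM property).
    """
    m = P.shape[1]
    k_out = np.full((m, 3), 1.0 / 3.0)
    ll_out = np.full(m, -np.inf)
    # SQUAREM-accelerated EM on the still-unconverged subset only; the
    # extrapolated step is kept per pair only when it improves that pair's
    # log-likelihood, so each pair's path is monotone and stops at its own
    # convergence.
    idx = np.arange(m)
    P_act, w_act = P, w
    k = np.full((m, 3), 1.0 / 3.0)
    n_obs = w.sum(axis=1)
    ll_prev = np.full(m, -np.inf)

    def em_step(kk: np.ndarray) -> np.ndarray:
        mix = np.maximum((kk.T[:, :, None] * P_act).sum(axis=0), _P_EPS)
        resp = kk.T[:, :, None] * P_act / mix
        out = (resp * w_act).sum(axis=2).T / n_obs[:, None]
        out = np.maximum(out, 0)
        return out / out.sum(axis=1, keepdims=True)

    def loglik(kk: np.ndarray) -> np.ndarray:
        mix = np.maximum((kk.T[:, :, None] * P_act).sum(axis=0), _P_EPS)
        return (w_act * np.log(mix)).sum(axis=1)

    for _ in range(max_iter):
        k1 = em_step(k)
        k2 = em_step(k1)
        r = k1 - k
        v = k2 - 2 * k1 + k
        v_norm = np.linalg.norm(v, axis=1)
        r_norm = np.linalg.norm(r, axis=1)
        alpha = np.where(v_norm > 0, -r_norm / np.maximum(v_norm, 1e-300), -1.0)
        alpha = np.minimum(alpha, -1.0)
        cand = k - 2 * alpha[:, None] * r + alpha[:, None] ** 2 * v
        cand = np.clip(cand, 1e-12, None)
        cand /= cand.sum(axis=1, keepdims=True)
        cand = em_step(cand)  # stabilising EM step after extrapolation
        ll2 = loglik(k2)
        llc = loglik(cand)
        use_cand = llc > ll2
        k = np.where(use_cand[:, None], cand, k2)
        ll = np.where(use_cand, llc, ll2)
        k_out[idx] = k
        ll_out[idx] = ll
        done = ll - ll_prev < tol
        if done.all():
            break
        if done.any():
            keep = ~done
            idx, P_act, w_act = idx[keep], P_act[:, keep], w_act[keep]
            k, n_obs, ll = k[keep], n_obs[keep], ll[keep]
        ll_prev = ll
    return k_out, ll_out


def _em_simplex(
    P: np.ndarray, tol: float, max_iter: int
) -> tuple[tuple[float, float, float], float]:
    """EM for one 3-component per-locus mixture; returns (k, loglik)."""
    k, ll = _em_simplex_batch(
        P[:, None, :], np.ones((1, P.shape[1])), tol, max_iter
    )
    return (float(k[0, 0]), float(k[0, 1]), float(k[0, 2])), float(ll[0])


def estimate_k(
    g1: np.ndarray,
    g2: np.ndarray,
    q1: float,
    q2: float,
    freqs: AncestralFreqs,
    min_loci: int = 200,
    tol: float = 1e-6,
    max_iter: int = 1000,
    id1: str = "id1",
    id2: str = "id2",
) -> RelatednessEstimate:
    """Maximum-likelihood (k0, k1, k2) for one pair via EM on the simplex.

    Loci missing in either individual are skipped; fewer than ``min_loci``
    informative loci raises, since the estimate is unstable.
    """
    if g1.shape != g2.shape or g1.shape[0] != freqs.n_loci:
        raise ValueError("genotype vectors must share the frequency panel's loci")
    obs = (g1 >= 0) & (g2 >= 0)
    if int(obs.sum()) < min_loci:
        raise ValueError(
            f"only {int(obs.sum())} informative loci; need at least {min_loci}"
        )
    f1 = np.clip(freqs.f1[obs], 1e-6, 1 - 1e-6)
    f2 = np.clip(freqs.f2[obs], 1e-6, 1 - 1e-6)
    pi1 = np.clip(q1 * f1 + (1 - q1) * f2, 1e-6, 1 - 1e-6)
    pi2 = np.clip(q2 * f1 + (1 - q2) * f2, 1e-6, 1 - 1e-6)
    P = pair_ibd_probs(g1[obs], g2[obs], pi1, pi2)  # (3, L)
    k, ll = _em_simplex(P, tol, max_iter)
    return RelatednessEstimate(id1, id2, *k, loglik=ll, n_loci=int(obs.sum()))


def estimate_k_pairs(
    G: np.ndarray,
    q: np.ndarray,
    freqs: AncestralFreqs,
    pairs: Sequence[tuple[int, int]],
    ids: Sequence[str] | None = None,
    min_loci: int = 200,
    tol: float = 1e-6,
    max_iter: int = 1000,
    chunk_size: int = 256,
) -> pd.DataFrame:
    """Relatedness estimates for many index pairs from one genotype matrix.

    Pairs are processed in vectorised chunks; results are identical to
    calling :func:`estimate_k` per pair.
    """
    ids = list(ids) if ids is not None else [str(i) for i in range(G.shape[0])]
    f1 = np.clip(freqs.f1, 1e-6, 1 - 1e-6)
    f2 = np.clip(freqs.f2, 1e-6, 1 - 1e-6)
    pairs = list(pairs)
    rows = []
    for start in range(0, len(pairs), chunk_size):
        chunk = pairs[start : start + chunk_size]
        ii = np.array([p[0] for p in chunk])
        jj = np.array([p[1] for p in chunk])
        g1, g2 = G[ii], G[jj]
        w = ((g1 >= 0) & (g2 >= 0)).astype(float)
        n_obs = w.sum(axis=1).astype(int)
        low = n_obs < min_loci
        if np.any(low):
            bad = chunk[int(np.flatnonzero(low)[0])]
            raise ValueError(
                f"pair ({ids[bad[0]]}, {ids[bad[1]]}): only {n_obs[low][0]} "
                f"informative loci; need at least {min_loci}"
            )
        pi1 = np.clip(q[ii, None] * f1 + (1 - q[ii, None]) * f2, 1e-6, 1 - 1e-6)
        pi2 = np.clip(q[jj, None] * f1 + (1 - q[jj, None]) * f2, 1e-6, 1 - 1e-6)
        P = pair_ibd_probs(np.where(g1 < 0, 0, g1), np.where(g2 < 0, 0, g2), pi1, pi2)
        P = np.where(w[None, :, :] > 0, P, 1.0)  # masked loci contribute nothing
        k, ll = _em_simplex_batch(P, w, tol, max_iter)
        for c, (i, j) in enumerate(chunk):
            rows.append(
                (ids[i], ids[j], k[c, 0], k[c, 1], k[c, 2], ll[c], n_obs[c])
            )
    return pd.DataFrame(
        rows, columns=["id1", "id2", "k0", "k1", "k2", "loglik", "n_loci"]
    )


def _is_primary(k1: float, k2: float) -> bool:
    return 0.25 < k1 < 0.75 and 0.15 < k2 < 0.5


def _is_rescue(k1: float, k2: float) -> bool:
    return 0.4 < k1 < 0.6 and k2 > 0.125


def classify_full_siblings(
    estimates: pd.DataFrame | Iterable[RelatednessEstimate],
) -> list[SibPair]:
    """Full-sibling pairs from k1/k2 estimates, with the boundary rescue rule.

    Primary set: 0.25 < k1 < 0.75 and 0.15 < k2 < 0.5.  A boundary pair with
    0.4 < k1 < 0.6 and k2 > 0.125 is additionally accepted when both of its
    members already appear in a primary-set pair with some other individual.
    Sibships are the connected components of the resulting pair graph and a
    family id is assigned per component.
    """
    if not isinstance(estimates, pd.DataFrame):
        estimates = pd.DataFrame(
            [(e.id1, e.id2, e.k0, e.k1, e.k2) for e in estimates],
            columns=["id1", "id2", "k0", "k1", "k2"],
        )
    if estimates.empty:
        return []

    primary: list[tuple[str, str]] = []
    candidates: list[tuple[str, str]] = []
    for row in estimates.itertuples(index=False):
        if _is_primary(row.k1, row.k2):
            primary.append((row.id1, row.id2))
        elif _is_rescue(row.k1, row.k2):
            candidates.append((row.id1, row.id2))

    partners: dict[str, set[str]] = {}
    for a, b in primary:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    rescued = [
        (a, b)
        for a, b in candidates
        if partners.get(a, set()) - {b} and partners.get(b, set()) - {a}
    ]

    # connected components via union-find
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    accepted = primary + rescued
    for a, b in accepted:
        union(a, b)
    roots = sorted({find(a) for a, _ in accepted} | {find(b) for _, b in accepted})
    fid_of = {root: f"SIB{i + 1:04d}" for i, root in enumerate(roots)}
    out = [
        SibPair(id1=min(a, b), id2=max(a, b), fid=fid_of[find(a)], rescued=False)
        for a, b in primary
    ]
    out += [
        SibPair(id1=min(a, b), id2=max(a, b), fid=fid_of[find(a)], rescued=True)
        for a, b in rescued
    ]
    out.sort(key=lambda p: (p.fid, p.id1, p.id2))
    return out


def filter_admixed_pairs(
    pairs: Sequence[SibPair],
    q: Mapping[str, float],
    parent_q: Mapping[str, tuple[float, float]] | None = None,
    threshold: float = 0.95,
    central_band: tuple[float, float] = (0.40, 0.60),
    unresolved: str = "drop",
) -> tuple[list[SibPair], pd.DataFrame]:
    """Drop uninformative sibling pairs; keep pairs with usable ancestry contrast.

    A pair is excluded as ``same-ancestry`` when both members carry more than
    ``threshold`` of the same ancestry (Q both > threshold or both <
    1-threshold).  When both members' Q lies inside ``central_band`` the pair
    is a candidate F1 pair: its parental ancestry proportions (``parent_q``,
    keyed by either member's id) decide — one parent above ``threshold`` and
    the other below ``1-threshold`` marks an F1 pair, which is excluded since
    its true ancestry difference is exactly zero.  Candidate F1 pairs without
    parental information are flagged ``unresolved`` and dropped (default) or
    retained per ``unresolved``.

    Returns the retained pairs and a per-pair report.  The operation is
    idempotent and order-independent.
    """
    if unresolved not in ("drop", "retain"):
        raise ValueError("unresolved must be 'drop' or 'retain'")
    parent_q = parent_q or {}
    retained: list[SibPair] = []
    rows = []
    for p in sorted(pairs, key=lambda s: (s.id1, s.id2)):
        q1, q2 = float(q[p.id1]), float(q[p.id2])
        status = "retained"
        if (q1 > threshold and q2 > threshold) or (
            q1 < 1 - threshold and q2 < 1 - threshold
        ):
            status = "excluded-same-ancestry"
        elif (
            central_band[0] <= q1 <= central_band[1]
            and central_band[0] <= q2 <= central_band[1]
        ):
            pq = parent_q.get(p.id1) or parent_q.get(p.id2)
            if pq is None:
                status = "unresolved"
            else:
                qa, qb = float(pq[0]), float(pq[1])
                if (qa > threshold and qb < 1 - threshold) or (
                    qb > threshold and qa < 1 - threshold
                ):
                    status = "excluded-F1"
        kept = status == "retained" or (status == "unresolved" and unresolved == "retain")
        rows.append((p.id1, p.id2, q1, q2, status, kept))
        if kept:
            retained.append(
                SibPair(p.id1, p.id2, fid=p.fid, status=status,
                        rescued=p.rescued, dq=q1 - q2)
            )
    report = pd.DataFrame(
        rows, columns=["id1", "id2", "q1", "q2", "status", "kept"]
    )
    return retained, report


def estimate_dq_error_from_f1(
    f1_pairs: Sequence[SibPair] | Sequence[tuple[str, str]],
    q: Mapping[str, float],
) -> float:
    """Average error of the estimated sibling ancestry difference, from F1 pairs.

    Both members of an F1 pair have a true ancestry proportion of exactly 0.5,
    so the true within-pair difference is 0 and the mean absolute estimated
    difference |Q1 - Q2| over F1 pairs is a direct measure of estimation
    error.  (With independent N(0, sigma^2) errors per individual the
    statistic's expectation is 2*sigma/sqrt(pi).)
    """
    pairs = [
        (p.id1, p.id2) if isinstance(p, SibPair) else (p[0], p[1]) for p in f1_pairs
    ]
    if not pairs:
        raise ValueError("no F1 pairs supplied")
    return float(np.mean([abs(float(q[a]) - float(q[b])) for a, b in pairs]))
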