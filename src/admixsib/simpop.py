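"""Synthetic two-way admixed populations: pedigrees, tracts, genotypes, phenotypes.

This module generates the study conditions the sibling design assumes: a
population admixed between two ancestral groups (population 1 plays the role
of the majority ancestry, mean proportion ~0.71), organised into families of
two founder parents and two or more full siblings whose ancestry proportions
differ only through random recombination.  Ground truth — local-ancestry
tracts, true ancestry proportions Q_true, pedigree links — is retained so
that every downstream estimator can be checked against it.

Phenotypes are generated as

    y_ij = alpha + Q_ij * dG + env_ij + gamma_j + b_age*Age + b_sex*Sex + eps_ij

where ``env_ij`` is an optional ancestry-by-environment interaction acting on
the family mean ancestry (family mode) or the individual's own ancestry
(individual mode), ``gamma_j`` is a family random effect and ``eps_ij`` is
i.i.d. Gaussian noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneticMap, HaplotypeTracts, default_map, ibd_state_fractions, _simplify

__all__ = [
    "AncestralFreqs",
    "Individual",
    "Population",
    "PhenotypeGenConfig",
    "simulate_ancestral_freqs",
    "make_founder",
    "meiosis",
    "make_family",
    "simulate_population",
    "simulate_genotypes",
    "simulate_phenotypes",
]


@dataclass
class AncestralFreqs:
    """Per-locus allele frequencies in the two ancestral populations.

    Loci live on a :class:`GeneticMap`; ``chrom`` is the chromosome index and
    ``pos`` the position in Morgans, sorted within chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    fst: float
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        for arr in (self.f1, self.f2):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("allele frequencies must lie in [0, 1]")
        lengths = self.gmap.lengths
        if np.any(self.pos < 0) or np.any(self.pos > lengths[self.chrom]):
            raise ValueError("locus positions must lie within chromosome bounds")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("loci must be sorted by (chromosome, position)")

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def subset(self, idx: np.ndarray) -> "AncestralFreqs":
        return AncestralFreqs(
            self.chrom[idx], self.pos[idx], self.f1[idx], self.f2[idx],
            self.fst, self.gmap,
        )


def simulate_ancestral_freqs(
    n_loci: int,
    fst: float,
    gmap: GeneticMap | None = None,
    base_freq_dist: tuple[float, float] = (0.05, 0.95),
    seed: int | np.random.Generator = 0,
) -> AncestralFreqs:
    """Draw ancestral allele frequencies under the Balding-Nichols model.

    A shared base frequency ``p_l`` is drawn uniformly on ``base_freq_dist``;
    each population's frequency is then an independent
    ``Beta(p(1-fst)/fst, (1-p)(1-fst)/fst)`` draw (variance ``fst*p*(1-p)``).
    ``fst = 0`` gives identical frequencies in both populations.  Loci are
    placed uniformly at random on the map and sorted.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (0 <= fst < 1):
        raise ValueError(f"fst must be in [0, 1), got {fst}")
    gmap = gmap or default_map()
    rng = np.random.default_rng(seed)
    lo, hi = base_freq_dist
    p = rng.uniform(lo, hi, size=n_loci)
    if fst == 0:
        f1, f2 = p.copy(), p.copy()
    else:
        a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
        f1 = rng.beta(a, b)
        f2 = rng.beta(a, b)
    lengths = gmap.lengths
    chrom = rng.choice(gmap.n_chromosomes, size=n_loci, p=lengths / lengths.sum())
    pos = rng.uniform(0, lengths[chrom])
    order = np.lexsort((pos, chrom))
    return AncestralFreqs(chrom[order], pos[order], f1[order], f2[order], fst, gmap)


@dataclass
class Individual:
    """One person: pedigree links, covariates and two ancestry-labelled haplotypes.

    For offspring, ``origin_pat``/``origin_mat`` record, per transmitted
    gamete, which of the parent's two haplotypes (label 1 = that parent's
    paternal, 2 = maternal) each segment descends from.  These origin tracts
    carry the identity-by-descent ground truth and drive allelic inheritance
    in genotype simulation.
    """

    iid: str
    fid: str
    sex: int  # 0 = female, 1 = male
    age: float
    hap_pat: HaplotypeTracts
    hap_mat: HaplotypeTracts
    father: str | None = None
    mother: str | None = None
    origin_pat: HaplotypeTracts | None = None
    origin_mat: HaplotypeTracts | None = None

    def q_true(self, gmap: GeneticMap) -> float:
        """Morgan-weighted fraction of the genome from ancestral population 1."""
        return 0.5 * (
            self.hap_pat.label_fraction(gmap, 1) + self.hap_mat.label_fraction(gmap, 1)
        )


def make_founder(
    q_target: float,
    admix_generations: int = 5,
    gmap: GeneticMap | None = None,
    seed: int | np.random.Generator = 0,
    iid: str = "F0",
    fid: str = "FAM0",
    sex: int = 0,
    age: float = 50.0,
) -> Individual:
    """A founder whose haplotypes are stationary admixture mosaics.

    Tract boundaries follow a Poisson process with rate ``admix_generations``
    per Morgan; each segment's ancestry is population 1 with probability
    ``q_target``.  ``q_target`` of 0 or 1 yields single-ancestry haplotypes.
    """
    if not (0 <= q_target <= 1):
        raise ValueError("q_target must be in [0, 1]")
    if admix_generations < 1:
        raise ValueError("admix_generations must be >= 1")
    gmap = gmap or default_map()
    rng = np.random.default_rng(seed)

    def one_haplotype() -> HaplotypeTracts:
        if q_target in (0.0, 1.0):
            return HaplotypeTracts.uniform(gmap, 1 if q_target == 1.0 else 2)
        ends, labels = [], []
        for L in gmap.lengths:
            n_bp = rng.poisson(admix_generations * L)
            bp = np.sort(rng.uniform(0, L, size=n_bp))
            e = np.concatenate([bp, [L]])
            lab = np.where(rng.random(len(e)) < q_target, 1, 2).astype(np.int8)
            e, lab = _simplify(e, lab)
            ends.append(e)
            labels.append(lab)
        return HaplotypeTracts(ends, labels)

    return Individual(iid, fid, sex, age, one_haplotype(), one_haplotype())


def _crossover_pattern(
    gmap: GeneticMap, rng: np.random.Generator
) -> HaplotypeTracts:
    """A recombination pattern: which parental haplotype (1/2) each segment uses.

    Crossover counts are Poisson with mean equal to each chromosome's genetic
    length in Morgans, positions uniform, no interference (Haldane model);
    the starting haplotype is chosen with probability 1/2 per chromosome.
    """
    ends, labels = [], []
    for L in gmap.lengths:
        n_cross = rng.poisson(L)
        cross = np.sort(rng.uniform(0, L, size=n_cross))
        start = int(rng.integers(2))
        e = np.concatenate([cross, [L]])
        lab = (1 + (start + np.arange(len(e))) % 2).astype(np.int8)
        e, lab = _simplify(e, lab)
        ends.append(e)
        labels.append(lab)
    return HaplotypeTracts(ends, labels)


def _apply_pattern(
    pattern: HaplotypeTracts,
    hap1: HaplotypeTracts,
    hap2: HaplotypeTracts,
    gmap: GeneticMap,
) -> HaplotypeTracts:
    """Splice two parental haplotypes along a crossover pattern."""
    out_ends, out_labels = [], []
    haps = (hap1, hap2)
    for c in range(gmap.n_chromosomes):
        seg_ends: list[np.ndarray] = []
        seg_labels: list[np.ndarray] = []
        prev = 0.0
        for b, which in zip(pattern.ends[c], pattern.labels[c]):
            ends, labels = haps[which - 1].ends[c], haps[which - 1].labels[c]
            i0 = np.searchsorted(ends, prev, side="right")
            i1 = np.searchsorted(ends, b, side="left")
            seg_ends.append(np.concatenate([ends[i0:i1], [b]]))
            seg_labels.append(labels[i0 : i1 + 1])
            prev = b
        e, lab = _simplify(np.concatenate(seg_ends), np.concatenate(seg_labels))
        out_ends.append(e)
        out_labels.append(lab)
    return HaplotypeTracts(out_ends, out_labels)


def meiosis(
    parent: Individual,
    gmap: GeneticMap | None = None,
    seed: int | np.random.Generator = 0,
    return_pattern: bool = False,
) -> HaplotypeTracts | tuple[HaplotypeTracts, HaplotypeTracts]:
    """One gamete from ``parent`` under the Haldane model.

    Returns the gamete's ancestry tracts; with ``return_pattern=True`` also
    the crossover pattern (which parental haplotype each segment came from),
    which is the gamete's identity-by-descent ground truth.
    """
    gmap = gmap or default_map()
    rng = np.random.default_rng(seed)
    pattern = _crossover_pattern(gmap, rng)
    gamete = _apply_pattern(pattern, parent.hap_pat, parent.hap_mat, gmap)
    return (gamete, pattern) if return_pattern else gamete


@dataclass
class Population:
    """A simulated pedigree: founders plus offspring, with ground truth."""

    individuals: list[Individual]
    gmap: GeneticMap

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def offspring(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.father is not None]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.father is None]

    def by_id(self, iid: str) -> Individual:
        return next(ind for ind in self.individuals if ind.iid == iid)

    def pedigree_frame(self) -> pd.DataFrame:
        """Pedigree/truth table: iid, fid, father, mother, sex, age, q_true."""
        rows = [
            {
                "iid": ind.iid,
                "fid": ind.fid,
                "father": ind.father or "0",
                "mother": ind.mother or "0",
                "sex": ind.sex,
                "age": ind.age,
                "q_true": ind.q_true(self.gmap),
            }
            for ind in self.individuals
        ]
        return pd.DataFrame(rows).set_index("iid", drop=False)

    def sibling_pairs(self) -> list[tuple[str, str]]:
        """All unordered within-family full-sibling pairs (lexicographic order)."""
        fams: dict[str, list[str]] = {}
        for ind in self.offspring:
            fams.setdefault(ind.fid, []).append(ind.iid)
        pairs = []
        for sibs in fams.values():
            for a, b in itertools.combinations(sorted(sibs), 2):
                pairs.append((a, b))
        return pairs

    def parent_q(self) -> dict[str, tuple[float, float]]:
        """True (father_Q, mother_Q) per offspring id."""
        q = {ind.iid: ind.q_true(self.gmap) for ind in self.individuals}
        return {
            ind.iid: (q[ind.father], q[ind.mother])
            for ind in self.offspring
        }

    def ibd_truth(self, id1: str, id2: str) -> tuple[float, float, float]:
        """Exact (k0, k1, k2) for a full-sibling pair from crossover-pattern truth."""
        a, b = self.by_id(id1), self.by_id(id2)
        if a.father != b.father or a.mother != b.mother or a.father is None:
            raise ValueError("IBD truth is defined for full-sibling pairs only")
        return ibd_state_fractions(
            (a.origin_pat, a.origin_mat), (b.origin_pat, b.origin_mat), self.gmap
        )

    def tracts_frame(self) -> pd.DataFrame:
        """Truth tracts as a BED-like table (positions in centiMorgans)."""
        rows = []
        names = self.gmap.names
        for ind in self.individuals:
            for hap_name, hap in (("pat", ind.hap_pat), ("mat", ind.hap_mat)):
                for c in range(self.gmap.n_chromosomes):
                    starts = np.concatenate([[0.0], hap.ends[c][:-1]])
                    for s, e, lab in zip(starts, hap.ends[c], hap.labels[c]):
                        rows.append(
                            (ind.iid, names[c], 100 * s, 100 * e, hap_name, int(lab))
                        )
        return pd.DataFrame(
            rows, columns=["iid", "chrom", "start_cM", "end_cM", "haplotype", "ancestry"]
        )


def make_family(
    fid: str,
    father_q: float,
    mother_q: float,
    n_sibs: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    admix_generations: int = 5,
) -> list[Individual]:
    """Two founders with the given target ancestry proportions plus ``n_sibs`` offspring."""
    father = make_founder(father_q, admix_generations, gmap, rng,
                          iid=f"{fid}_P1", fid=fid, sex=1,
                          age=float(rng.uniform(40, 90)))
    mother = make_founder(mother_q, admix_generations, gmap, rng,
                          iid=f"{fid}_P2", fid=fid, sex=0,
                          age=float(rng.uniform(40, 90)))
    members = [father, mother]
    for s in range(n_sibs):
        hap_pat, origin_pat = meiosis(father, gmap, rng, return_pattern=True)
        hap_mat, origin_mat = meiosis(mother, gmap, rng, return_pattern=True)
        child = Individual(
            iid=f"{fid}_S{s + 1}",
            fid=fid,
            sex=int(rng.integers(2)),
            age=float(rng.uniform(18, 80)),
            hap_pat=hap_pat,
            hap_mat=hap_mat,
            father=father.iid,
            mother=mother.iid,
            origin_pat=origin_pat,
            origin_mat=origin_mat,
        )
        members.append(child)
    return members


def simulate_population(
    n_families: int,
    sibs_per_family: Mapping[int, float] | None = None,
    founder_fracs: tuple[float, float, float] = (0.20, 0.08, 0.72),
    admixed_q_beta: tuple[float, float] = (0.71 * 8, 0.29 * 8),
    admix_generations: int = 5,
    gmap: GeneticMap | None = None,
    seed: int | np.random.Generator = 0,
) -> Population:
    """Simulate families of two founders and >=2 full siblings each.

    ``founder_fracs`` gives the probabilities that a founder is unadmixed
    population 1, unadmixed population 2, or admixed with q drawn from
    ``Beta(*admixed_q_beta)`` (default mean 0.71).  The defaults yield a
    population mean ancestry-1 proportion near 0.71 and include
    unadmixed-unadmixed, F1-producing and admixed-admixed families, so all
    downstream sibling filters are exercised.  With the default map and
    admixture timing, most sibling pairs differ by less than 5 percentage
    points in true ancestry.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not np.isclose(sum(founder_fracs), 1.0):
        raise ValueError("founder_fracs must sum to 1")
    sibs_per_family = dict(sibs_per_family or {2: 0.80, 3: 0.15, 4: 0.05})
    if all(k < 2 for k in sibs_per_family):
        raise ValueError("sibs_per_family must allow families with >=2 siblings")
    gmap = gmap or default_map()
    rng = np.random.default_rng(seed)
    sizes = np.array(sorted(sibs_per_family))
    size_p = np.array([sibs_per_family[k] for k in sizes], dtype=float)
    size_p /= size_p.sum()

    def draw_founder_q() -> float:
        kind = rng.choice(3, p=founder_fracs)
        if kind == 0:
            return 1.0
        if kind == 1:
            return 0.0
        return float(rng.beta(*admixed_q_beta))

    individuals: list[Individual] = []
    for f in range(n_families):
        fid = f"FAM{f + 1:04d}"
        n_sibs = int(rng.choice(sizes, p=size_p))
        individuals.extend(
            make_family(fid, draw_founder_q(), draw_founder_q(), n_sibs,
                        gmap, rng, admix_generations)
        )
    return Population(individuals, gmap)


def _labels_at_loci(hap: HaplotypeTracts, freqs: AncestralFreqs) -> np.ndarray:
    lab = np.empty(freqs.n_loci, dtype=np.int8)
    for c in np.unique(freqs.chrom):
        m = freqs.chrom == c
        lab[m] = hap.labels_at(int(c), freqs.pos[m])
    return lab


def simulate_genotypes(
    individuals: Sequence[Individual] | "Population",
    freqs: AncestralFreqs,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Genotypes (0/1/2; -1 = missing) at the given loci, with allelic inheritance.

    Founder haplotypes receive allele copies drawn Bernoulli(f_a), where a is
    the ancestry of the carrying haplotype at that locus; offspring inherit
    their parents' actual alleles along the recorded crossover patterns, so
    identity-by-descent sharing between relatives is preserved in the
    genotypes.  Offspring whose parents are referenced but absent from the
    input raise an error (pass the whole population and slice rows instead).
    """
    if isinstance(individuals, Population):
        individuals = individuals.individuals
    rng = np.random.default_rng(seed)
    L = freqs.n_loci
    by_id = {ind.iid: ind for ind in individuals}
    hap_alleles: dict[tuple[str, str], np.ndarray] = {}

    def alleles_for(ind: Individual, side: str) -> np.ndarray:
        key = (ind.iid, side)
        if key in hap_alleles:
            return hap_alleles[key]
        hap = ind.hap_pat if side == "pat" else ind.hap_mat
        parent_id = ind.father if side == "pat" else ind.mother
        origin = ind.origin_pat if side == "pat" else ind.origin_mat
        if parent_id is None or origin is None:
            lab = _labels_at_loci(hap, freqs)
            p = np.where(lab == 1, freqs.f1, freqs.f2)
            a = (rng.random(L) < p).astype(np.int8)
        else:
            parent = by_id.get(parent_id)
            if parent is None:
                raise ValueError(
                    f"{ind.iid}: parent {parent_id} not among the provided individuals"
                )
            src = _labels_at_loci(origin, freqs)
            a = np.where(
                src == 1, alleles_for(parent, "pat"), alleles_for(parent, "mat")
            ).astype(np.int8)
        hap_alleles[key] = a
        return a

    G = np.empty((len(individuals), L), dtype=np.int8)
    # founders first so the rng consumption order is deterministic by pedigree depth
    for ind in sorted(individuals, key=lambda x: x.father is not None):
        alleles_for(ind, "pat")
        alleles_for(ind, "mat")
    for i, ind in enumerate(individuals):
        G[i] = alleles_for(ind, "pat") + alleles_for(ind, "mat")
    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = -1
    return G


@dataclass
class PhenotypeGenConfig:
    """Generative model for sibling phenotypes.

    ``dg`` is the difference in mean genotypic value between the ancestral
    populations, in phenotype units per unit ancestry proportion.  ``e_anc``
    is an ancestry-by-environment interaction acting on the family mean
    sibling ancestry (``mode='family'``) or each sibling's own ancestry
    (``mode='individual'``).
    """

    dg: float = 1.0
    intercept: float = 0.0
    sigma: float = 1.0
    sigma_family: float = 0.0
    e_anc: float = 0.0
    e_anc_mode: str = "none"  # none | family | individual
    beta_age: float = 0.0
    beta_sex: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.sigma_family < 0:
            raise ValueError("sigma and sigma_family must be >= 0")
        if self.e_anc_mode not in ("none", "family", "individual"):
            raise ValueError(f"unknown e_anc_mode {self.e_anc_mode!r}")
        if self.e_anc_mode == "none" and self.e_anc != 0:
            raise ValueError("e_anc != 0 requires e_anc_mode 'family' or 'individual'")


def simulate_phenotypes(
    sibs: pd.DataFrame,
    cfg: PhenotypeGenConfig,
    q_col: str = "q_true",
    pheno_col: str = "y",
) -> pd.DataFrame:
    """Draw phenotypes for a sibling table (columns iid, fid, sex, age, Q).

    Returns a copy of ``sibs`` with a phenotype column added.  The family
    environmental term uses the mean ancestry of the family's siblings.
    """
    rng = np.random.default_rng(cfg.seed)
    out = sibs.copy()
    q = out[q_col].to_numpy(dtype=float)
    qbar = out.groupby("fid")[q_col].transform("mean").to_numpy(dtype=float)
    if cfg.e_anc_mode == "family":
        env = cfg.e_anc * qbar
    elif cfg.e_anc_mode == "individual":
        env = cfg.e_anc * q
    else:
        env = 0.0
    fids = out["fid"].to_numpy()
    uniq, inv = np.unique(fids, return_inverse=True)
    gamma = cfg.sigma_family * rng.standard_normal(len(uniq))
    y = (
        cfg.intercept
        + q * cfg.dg
        + env
        + gamma[inv]
        + cfg.beta_age * out["age"].to_numpy(dtype=float)
        + cfg.beta_sex * out["sex"].to_numpy(dtype=float)
        + cfg.sigma * rng.standard_normal(len(out))
    )
    out[pheno_col] = y
    return out
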