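"""End-to-end pipeline: simulate -> QC -> ancestry -> relatedness -> filters -> estimates.

The pipeline is configured by a strict YAML schema (unknown keys rejected)
and writes every stage's output with the run seed, package version and a
config hash, so a re-run with the same seed and config reproduces the same
numbers.  Any stage failure halts the run with the stage name; outputs of
completed stages are left on disk.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import estimate_admixture_supervised, estimate_admixture_unsupervised, variant_qc
from .estimators import estimate_effects
from .io import config_hash, load_yaml_config, write_plink, write_q, write_tsv
from .relatedness import SibPair, classify_full_siblings, estimate_k_pairs, filter_admixed_pairs
from .simpop import (
    PhenotypeGenConfig,
    simulate_ancestral_freqs,
    simulate_genotypes,
    simulate_population,
    simulate_phenotypes,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

_SCHEMA: dict[str, set[str]] = {
    "seed": set(),
    "out_dir": set(),
    "simulate": {
        "n_families", "n_loci", "fst", "sibs_per_family", "founder_fracs",
        "admix_generations", "phenotype",
    },
    "qc": {"maf_min", "miss_max", "ld_r2_max", "window", "step"},
    "ancestry": {"mode", "tol", "max_iter"},
    "relatedness": {"min_loci", "max_pairs"},
    "sibpairs": {"threshold", "central_band", "unresolved"},
    "estimate": {"phenotypes", "run_model_2"},
}

_PHENO_KEYS = {
    "dg", "intercept", "sigma", "sigma_family", "e_anc", "e_anc_mode",
    "beta_age", "beta_sex",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    out_dir: str = "admixsib_out"
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    ancestry: dict = field(default_factory=lambda: {"mode": "supervised"})
    relatedness: dict = field(default_factory=dict)
    sibpairs: dict = field(default_factory=dict)
    estimate: dict = field(default_factory=lambda: {"phenotypes": ["y"]})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = load_yaml_config(path, allowed=_SCHEMA)
        sim = cfg.get("simulate", {})
        unknown = set(sim.get("phenotype", {})) - _PHENO_KEYS
        if unknown:
            raise ValueError(f"unknown phenotype config keys: {sorted(unknown)}")
        return cls(
            seed=int(cfg.get("seed", 0)),
            out_dir=str(cfg.get("out_dir", "admixsib_out")),
            simulate=sim,
            qc=cfg.get("qc", {}),
            ancestry=cfg.get("ancestry", {"mode": "supervised"}),
            relatedness=cfg.get("relatedness", {}),
            sibpairs=cfg.get("sibpairs", {}),
            estimate=cfg.get("estimate", {"phenotypes": ["y"]}),
        )

    def as_dict(self) -> dict:
        return {
            "seed": self.seed, "out_dir": self.out_dir, "simulate": self.simulate,
            "qc": self.qc, "ancestry": self.ancestry, "relatedness": self.relatedness,
            "sibpairs": self.sibpairs, "estimate": self.estimate,
        }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages on a simulated dataset; returns a result bundle.

    The bundle maps stage names to their main in-memory products; every stage
    also writes TSV/JSON artifacts under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": config_hash(config.as_dict()),
    }
    (out / "run_meta.json").write_text(json.dumps({**meta, "config": config.as_dict()}, indent=2))
    bundle: dict[str, Any] = {"meta": meta}
    rng = np.random.default_rng(config.seed)

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        sim = config.simulate
        pop = simulate_population(
            n_families=int(sim.get("n_families", 100)),
            sibs_per_family=sim.get("sibs_per_family"),
            founder_fracs=tuple(sim.get("founder_fracs", (0.20, 0.08, 0.72))),
            admix_generations=int(sim.get("admix_generations", 5)),
            seed=rng,
        )
        freqs = simulate_ancestral_freqs(
            n_loci=int(sim.get("n_loci", 2000)),
            fst=float(sim.get("fst", 0.12)),
            gmap=pop.gmap,
            seed=rng,
        )
        ped = pop.pedigree_frame()
        offspring = pop.offspring
        off_ids = [ind.iid for ind in offspring]
        all_ids = [ind.iid for ind in pop.individuals]
        G_all = simulate_genotypes(pop, freqs, seed=rng)
        G = G_all[[all_ids.index(i) for i in off_ids]]
        pheno_cfg = PhenotypeGenConfig(
            **sim.get("phenotype", {}), seed=int(rng.integers(2**31))
        )
        sib_table = ped.loc[off_ids].copy()
        sib_table = simulate_phenotypes(sib_table, pheno_cfg)
        write_tsv(out / "pedigree.tsv", ped.reset_index(drop=True))
        write_tsv(out / "phenotypes.tsv", sib_table.reset_index(drop=True))
        fam = pd.DataFrame(
            {
                "fid": [i.fid for i in offspring], "iid": off_ids,
                "father": [i.father for i in offspring],
                "mother": [i.mother for i in offspring],
                "sex": [i.sex for i in offspring],
            }
        )
        write_plink(out / "genotypes", G, fam)
        bundle[stage] = {"population": pop, "freqs": freqs, "genotypes": G,
                         "phenotypes": sib_table}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    # --- variant QC ---------------------------------------------------------
    stage = "qc"
    try:
        Gq, report = variant_qc(G, **{k: v for k, v in config.qc.items()})
        freqs_q = freqs.subset(np.flatnonzero(report.kept))
        (out / "qc_report.json").write_text(json.dumps({
            **meta, "n_input": report.n_input, "n_kept": report.n_kept,
            "removed_maf": report.n_removed_maf,
            "removed_missing": report.n_removed_missing,
            "removed_ld": report.n_removed_ld,
        }, indent=2))
        bundle[stage] = {"genotypes": Gq, "report": report}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- ancestry -----------------------------------------------------------
    stage = "ancestry"
    try:
        mode = config.ancestry.get("mode", "supervised")
        if mode == "supervised":
            est = estimate_admixture_supervised(Gq, freqs_q)
        elif mode == "unsupervised":
            q_true = ped.loc[off_ids, "q_true"].to_numpy()
            anchors = np.flatnonzero(q_true < 0.05)
            if len(anchors) == 0:
                anchors = np.array([int(np.argmin(q_true))])
            est = estimate_admixture_unsupervised(
                Gq,
                tol=float(config.ancestry.get("tol", 1e-6)),
                max_iter=int(config.ancestry.get("max_iter", 2000)),
                seed=rng, anchors=anchors, anchor_population=2,
            )
        else:
            raise ValueError(f"unknown ancestry mode {mode!r}")
        q_hat = pd.Series(est.q, index=off_ids, name="q")
        write_q(out / "ancestry.Q", est.q)
        bundle[stage] = {"estimate": est, "q": q_hat}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- relatedness --------------------------------------------------------
    stage = "relatedness"
    try:
        idx_pairs = list(itertools.combinations(range(len(off_ids)), 2))
        max_pairs = config.relatedness.get("max_pairs")
        if max_pairs is not None and len(idx_pairs) > int(max_pairs):
            sel = rng.choice(len(idx_pairs), size=int(max_pairs), replace=False)
            idx_pairs = [idx_pairs[i] for i in sorted(sel)]
        rel = estimate_k_pairs(
            Gq, q_hat.to_numpy(), freqs_q, idx_pairs, ids=off_ids,
            min_loci=int(config.relatedness.get("min_loci", 200)),
        )
        write_tsv(out / "relatedness.tsv", rel)
        bundle[stage] = {"estimates": rel}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- sibling identification & filtering ---------------------------------
    stage = "sibpairs"
    try:
        sib_pairs = classify_full_siblings(rel)
        retained, filt_report = filter_admixed_pairs(
            sib_pairs,
            q_hat,
            parent_q=pop.parent_q(),
            threshold=float(config.sibpairs.get("threshold", 0.95)),
            central_band=tuple(config.sibpairs.get("central_band", (0.40, 0.60))),
            unresolved=config.sibpairs.get("unresolved", "drop"),
        )
        write_tsv(out / "sibpairs.tsv", filt_report)
        bundle[stage] = {"pairs": retained, "report": filt_report}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- effect estimation ---------------------------------------------------
    stage = "estimate"
    try:
        tab = sib_table.copy()
        tab["q"] = q_hat
        results = estimate_effects(
            tab,
            retained,
            phenotypes=list(config.estimate.get("phenotypes", ["y"])),
            run_model_2=bool(config.estimate.get("run_model_2", True)),
        )
        write_tsv(out / "results.tsv", results)
        (out / "results.json").write_text(
            json.dumps({**meta, "results": results.to_dict(orient="records")}, indent=2)
        )
        bundle[stage] = {"results": results}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    return bundle
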