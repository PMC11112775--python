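"""File formats: PLINK .bed/.bim/.fam, ADMIXTURE .Q/.P, TSV tables, YAML config.

All tabular interchange is TSV with a header; genotype matrices can round-trip
through PLINK binary (variant-major .bed) or a plain dosage TSV.  Ancestry
proportions are stored on the [0, 1] scale everywhere; conversion to
percentage points happens only in reporting.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_plink",
    "read_plink",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_q",
    "read_q",
    "write_p",
    "read_p",
    "write_tsv",
    "read_tsv",
    "load_yaml_config",
    "config_hash",
]

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_VARIANT_MAJOR = 0x01

# 2-bit PLINK codes for A1-allele counts: g=2 -> 00, missing -> 01, g=1 -> 10, g=0 -> 11
_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)


def write_plink(prefix: str | Path, G: np.ndarray, fam: pd.DataFrame,
                bim: pd.DataFrame | None = None) -> None:
    """Write genotypes (individuals x loci; -1 = missing) as .bed/.bim/.fam.

    ``fam`` needs columns fid, iid, father, mother, sex (0=female, 1=male)
    and optionally phenotype; ``bim`` needs chrom, snp, cm, bp, a1, a2 (a
    default is generated if omitted).  The .bed is variant-major.
    """
    prefix = Path(prefix)
    n, L = G.shape
    if len(fam) != n:
        raise ValueError(".fam rows must match genotype rows")
    fam_out = pd.DataFrame(
        {
            "fid": fam["fid"],
            "iid": fam["iid"],
            "father": fam.get("father", pd.Series(["0"] * n)).fillna("0"),
            "mother": fam.get("mother", pd.Series(["0"] * n)).fillna("0"),
            # PLINK sex code: 1=male, 2=female
            "sex": fam["sex"].map({1: 1, 0: 2}).fillna(0).astype(int),
            "pheno": fam.get("pheno", pd.Series([-9] * n)),
        }
    )
    fam_out.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    if bim is None:
        bim = pd.DataFrame(
            {
                "chrom": np.ones(L, dtype=int),
                "snp": [f"snp{i + 1}" for i in range(L)],
                "cm": np.zeros(L),
                "bp": np.arange(1, L + 1),
                "a1": ["A"] * L,
                "a2": ["C"] * L,
            }
        )
    if len(bim) != L:
        raise ValueError(".bim rows must match genotype columns")
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    codes = np.empty((L, n), dtype=np.uint8)
    for g, c in _ENCODE.items():
        codes[(G.T == g)] = c
    n_bytes = (n + 3) // 4
    padded = np.zeros((L, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_VARIANT_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a variant-major PLINK fileset; returns (G, fam, bim).

    Genotypes are A1-allele counts with -1 for missing, aligned to .fam row
    and .bim column order.  Corrupt magic bytes, the sample-major dialect and
    truncated .bed files raise format errors naming the offending file.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    fam["sex"] = fam["sex"].map({1: 1, 2: 0}).fillna(-1).astype(int)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
    )
    n, L = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: bad magic bytes, not a PLINK .bed file")
    if raw[2] != _BED_VARIANT_MAJOR:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: sample-major .bed layout is not supported"
        )
    n_bytes = (n + 3) // 4
    if len(raw) - 3 != n_bytes * L:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: truncated or inconsistent with "
            f"{n} samples x {L} variants"
        )
    packed = np.frombuffer(raw[3:], dtype=np.uint8).reshape(L, n_bytes)
    codes = np.empty((L, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    G = _DECODE[codes[:, :n]].T.copy()
    return G, fam, bim


def write_genotypes_tsv(path: str | Path, G: np.ndarray, ids: list[str]) -> None:
    """Dosage matrix TSV: one row per individual, loci as columns."""
    df = pd.DataFrame(G, index=pd.Index(ids, name="iid"),
                      columns=[f"snp{i + 1}" for i in range(G.shape[1])])
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="iid")
    return df.to_numpy(dtype=np.int8), list(df.index.astype(str))


def write_q(path: str | Path, q: np.ndarray) -> None:
    """ADMIXTURE-style .Q: two whitespace-separated columns (pop1, pop2)."""
    np.savetxt(path, np.column_stack([q, 1 - np.asarray(q)]), fmt="%.6f")


def read_q(path: str | Path, pop1_col: int = 0) -> np.ndarray:
    """Read a K=2 .Q file; returns the population-1 proportion per row.

    Rows must sum to 1 within 1e-4; rows further off are renormalised with a
    warning.  Any column count other than 2 is an error.
    """
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape[1] != 2:
        raise ValueError(f"{path}: expected K=2 columns, found {mat.shape[1]}")
    sums = mat.sum(axis=1)
    off = np.abs(sums - 1) > 1e-4
    if np.any(off):
        warnings.warn(
            f"{path}: {int(off.sum())} row(s) do not sum to 1 within 1e-4; renormalising",
            stacklevel=2,
        )
        mat = mat / sums[:, None]
    return mat[:, pop1_col]


def write_p(path: str | Path, f1: np.ndarray, f2: np.ndarray) -> None:
    """ADMIXTURE-style .P: per-locus allele frequencies, one column per population."""
    np.savetxt(path, np.column_stack([f1, f2]), fmt="%.6f")


def read_p(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape[1] != 2:
        raise ValueError(f"{path}: expected K=2 columns, found {mat.shape[1]}")
    return mat[:, 0], mat[:, 1]


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def load_yaml_config(path: str | Path, allowed: Mapping[str, set[str]] | None = None) -> dict:
    """Load a YAML config; unknown sections/keys are rejected when a schema is given."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    if allowed is not None:
        for section, value in cfg.items():
            if section not in allowed:
                raise ValueError(f"{path}: unknown config section {section!r}")
            keys = allowed[section]
            if keys and isinstance(value, dict):
                unknown = set(value) - keys
                if unknown:
                    raise ValueError(
                        f"{path}: unknown keys in section {section!r}: {sorted(unknown)}"
                    )
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a config mapping, recorded in output artifacts."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
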