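"""PLINK text PED/MAP readers and writers, results TSV, power-grid config.

The input dialect is whitespace-delimited PLINK text: a MAP file with
(chromosome, snp id, genetic distance, bp position) per SNP and a PED file
with six leading columns (family, individual, father, mother, sex,
phenotype) followed by two allele fields per SNP.  Alleles are converted to
minor-allele counts per SNP: the minor allele is the less frequent allele in
the sample, with ties broken toward the lexicographically smaller allele;
"0" allele fields mean missing.  Phenotype coding must be declared ("01" for
0=control/1=case, "12" for PLINK's 1=control/2=case) and is never guessed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scan import PairTestResult, ScanResult
from .tables import MISSING, GenotypeMatrix

__all__ = [
    "ParseError",
    "read_ped_map",
    "write_ped_map",
    "write_results",
    "read_results",
    "write_truth",
    "read_power_grid",
]

RESULT_COLUMNS = [
    "snp_p", "chrom_p", "pos_p", "snp_q", "chrom_q", "pos_q",
    "joint_stat", "joint_df", "joint_p_raw", "joint_p_adj",
    "marginal_p_p", "marginal_p_q", "distance", "flags",
]


class ParseError(ValueError):
    """Malformed PED/MAP content, reported with a line number."""


def _read_map(map_path) -> tuple[list[str], list[str], list[int]]:
    chroms, ids, pos = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 MAP fields, got {len(fields)}")
            try:
                bp = int(fields[3])
            except ValueError as e:
                raise ParseError(f"{map_path}:{lineno}: bad bp position {fields[3]!r}") from e
            chroms.append(fields[0])
            ids.append(fields[1])
            pos.append(bp)
    if not ids:
        raise ParseError(f"{map_path}: empty MAP file")
    return chroms, ids, pos


def read_ped_map(ped_path, map_path, pheno_coding: str) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a PED/MAP pair into a GenotypeMatrix and a {0,1} phenotype vector.

    ``pheno_coding`` is "01" (0=control, 1=case) or "12" (1=control, 2=case);
    the missing phenotype code is "-9" under either coding, plus "0" under
    "12".
    """
    if pheno_coding not in {"01", "12"}:
        raise ParseError("pheno_coding must be '01' or '12'")
    chroms, ids, pos = _read_map(map_path)
    L = len(ids)
    pheno_map = ({"0": 0, "1": 1, "-9": MISSING} if pheno_coding == "01"
                 else {"1": 0, "2": 1, "0": MISSING, "-9": MISSING})

    rows, phenos = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * L:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * L} fields for {L} SNPs, "
                    f"got {len(fields)}")
            code = fields[5]
            if code not in pheno_map:
                raise ParseError(f"{ped_path}:{lineno}: unknown phenotype code {code!r} "
                                 f"for coding {pheno_coding!r}")
            phenos.append(pheno_map[code])
            rows.append(fields[6:])
    if not rows:
        raise ParseError(f"{ped_path}: empty PED file")

    alleles = np.array(rows, dtype=object).reshape(len(rows), L, 2)
    values = np.full((len(rows), L), MISSING, dtype=np.int8)
    for l in range(L):
        a = alleles[:, l, :]
        present = a != "0"
        half = present.sum(axis=1) == 1
        if half.any():
            bad = int(np.nonzero(half)[0][0]) + 1
            raise ParseError(f"{ped_path}: sample {bad}, SNP {ids[l]}: half-missing genotype")
        observed, counts = np.unique(a[present].astype(str), return_counts=True)
        if observed.size > 2:
            raise ParseError(f"{ped_path}: SNP {ids[l]} has more than two alleles: {list(observed)}")
        if observed.size == 0:
            continue  # all missing; stays MISSING
        if observed.size == 1:
            minor = None  # monomorphic: zero minor alleles everywhere
        else:
            # minor = less frequent; tie -> lexicographically smaller
            minor = sorted(zip(counts, observed))[0][1]
        full = present.all(axis=1)
        values[full, l] = 0 if minor is None else (a[full] == minor).sum(axis=1)
    G = GenotypeMatrix(values, np.array(ids, dtype=object),
                       np.array(chroms, dtype=object), np.array(pos, dtype=np.int64))
    return G, np.array(phenos, dtype=np.int8)


def write_ped_map(G: GenotypeMatrix, y, ped_path, map_path, pheno_coding: str = "12") -> None:
    """Write a GenotypeMatrix and phenotype as PLINK text PED/MAP.

    Major alleles are written as "A", minor as "B"; missing genotypes as
    "0 0".  Phenotypes use the requested coding.
    """
    if pheno_coding not in {"01", "12"}:
        raise ParseError("pheno_coding must be '01' or '12'")
    y = np.asarray(y)
    with open(map_path, "w") as fh:
        for l in range(G.n_snps):
            fh.write(f"{G.chrom[l]}\t{G.snp_ids[l]}\t0\t{G.pos[l]}\n")
    code = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}
    with open(ped_path, "w") as fh:
        for s in range(G.n_samples):
            ph = int(y[s])
            if ph == MISSING:
                pcode = "-9"
            else:
                pcode = str(ph) if pheno_coding == "01" else str(ph + 1)
            fields = [f"FAM{s + 1}", f"IND{s + 1}", "0", "0", "0", pcode]
            for l in range(G.n_snps):
                fields.extend(code[int(G.values[s, l])])
            fh.write(" ".join(fields) + "\n")


def _config_hash(meta: dict) -> str:
    return hashlib.sha256(json.dumps(meta, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_results(result: ScanResult, path, meta: dict | None = None) -> None:
    """Write the scan's reported pairs as a TSV with a commented header.

    The header records the package version, a hash of the configuration,
    the seed (when provided in ``meta``), L, L' and the number of pairs
    tested, so every output is traceable to its run.
    """
    from . import __version__

    meta = dict(meta or {})
    header = {
        "version": __version__,
        "config_hash": _config_hash(meta),
        **meta,
        "n_snps": result.n_snps,
        "n_kept": result.n_kept,
        "n_pairs_tested": result.n_pairs_tested,
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in result.pairs:
            d = dataclasses.asdict(r)
            d["distance"] = "NA" if r.distance is None else r.distance
            d["joint_stat"] = f"{r.joint_stat:.10g}"
            d["joint_p_raw"] = f"{r.joint_p_raw:.10g}"
            d["joint_p_adj"] = f"{r.joint_p_adj:.10g}"
            d["marginal_p_p"] = f"{r.marginal_p_p:.10g}"
            d["marginal_p_q"] = f"{r.marginal_p_q:.10g}"
            fh.write("\t".join(str(d[c]) for c in RESULT_COLUMNS) + "\n")


def read_results(path) -> pd.DataFrame:
    """Parse a results TSV back into a DataFrame (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_truth(truth: dict, path) -> None:
    """Sidecar TSV naming the causal columns and the generating model."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in truth.items():
            fh.write(f"{k}\t{v}\n")


def read_power_grid(path) -> dict:
    """Read a YAML power-grid configuration.

    Recognized keys: ``r2`` (list), ``maf`` (list), ``prevalence``, ``h2``,
    ``ld_sign``, ``n_cases``, ``n_controls``, ``n_null_snps``, ``alpha``.
    """
    with open(path) as fh:
        grid = yaml.safe_load(fh) or {}
    if not isinstance(grid, dict):
        raise ParseError(f"{path}: power grid must be a mapping")
    defaults = {
        "r2": [0.1, 0.3, 0.5, 0.7],
        "maf": [0.3],
        "prevalence": 0.1,
        "h2": 0.02,
        "ld_sign": "+",
        "n_cases": 500,
        "n_controls": 500,
        "n_null_snps": 98,
        "alpha": 0.05,
    }
    unknown = set(grid) - set(defaults)
    if unknown:
        raise ParseError(f"{path}: unknown power-grid keys {sorted(unknown)}")
    defaults.update(grid)
    return defaults
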