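"""Text-format I/O: GENEPOP, long-format CSV, and Structure export.

GENEPOP files use 3-digit allele codes (6 digits per diploid genotype);
population blocks correspond to barrier sides. The CSV snapshot format is
long: one row per individual x locus with columns
generation, replicate, id, sex, row, col, locus, allele1, allele2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_genepop(path, genotypes: np.ndarray, groups=None, locus_ids=None,
                  title="tortflow snapshot") -> None:
    genotypes = np.asarray(genotypes)
    n, L, _ = genotypes.shape
    if np.any(genotypes > 999) or np.any(genotypes < 0):
        raise ValueError("allele states must fit 3-digit GENEPOP codes")
    groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)
    locus_ids = locus_ids or [f"L{j + 1:02d}" for j in range(L)]
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in locus_ids:
            fh.write(name + "\n")
        for label in np.unique(groups):
            fh.write("POP\n")
            for i in np.nonzero(groups == label)[0]:
                codes = " ".join(
                    f"{genotypes[i, j, 0]:03d}{genotypes[i, j, 1]:03d}"
                    for j in range(L)
                )
                fh.write(f"ind{i}_{label} , {codes}\n")


def read_genepop(path):
    """Returns (genotypes (n, L, 2), groups, locus_ids)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        # loci may be one per line or comma-separated
        locus_ids.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    genotypes, groups = [], []
    pop = -1
    for ln in lines[i:]:
        if ln.strip().upper() == "POP":
            pop += 1
            continue
        if not ln.strip():
            continue
        _, _, geno_part = ln.partition(",")
        codes = geno_part.split()
        if len(codes) != len(locus_ids):
            raise ValueError("genotype row does not match locus count")
        row = [[int(c[: len(c) // 2]), int(c[len(c) // 2:])] for c in codes]
        genotypes.append(row)
        groups.append(pop)
    return (
        np.array(genotypes, dtype=np.int16),
        np.array(groups, dtype=int),
        locus_ids,
    )


def snapshot_to_dataframe(state, locus_ids=None) -> pd.DataFrame:
    """Long-format dataframe of a population state."""
    n, L, _ = state.genotypes.shape
    locus_ids = locus_ids or [loc.locus_id for loc in state.loci]
    rows = np.repeat(np.arange(n), L)
    return pd.DataFrame(
        {
            "generation": state.generation,
            "replicate": state.replicate,
            "id": rows,
            "sex": np.repeat(np.where(state.sex == 1, "male", "female"), L),
            "row": np.repeat(state.row, L),
            "col": np.repeat(state.col, L),
            "locus": np.tile(locus_ids, n),
            "allele1": state.genotypes[:, :, 0].ravel(),
            "allele2": state.genotypes[:, :, 1].ravel(),
        }
    )


def write_snapshot_csv(path, state, locus_ids=None) -> None:
    snapshot_to_dataframe(state, locus_ids).to_csv(path, index=False)


def write_structure(path, genotypes: np.ndarray, groups=None,
                    locus_ids=None) -> None:
    """Structure input: two rows per individual, one column per locus."""
    genotypes = np.asarray(genotypes)
    n, L, _ = genotypes.shape
    groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)
    locus_ids = locus_ids or [f"L{j + 1:02d}" for j in range(L)]
    with open(path, "w") as fh:
        fh.write("\t".join(locus_ids) + "\n")
        for i in range(n):
            for copy in (0, 1):
                alleles = "\t".join(str(genotypes[i, j, copy]) for j in range(L))
                fh.write(f"ind{i}\t{groups[i] + 1}\t{alleles}\n")
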