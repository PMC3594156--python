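"""Text-format I/O: PLINK .ped/.map dialect, sample annotations, frequencies.

The .map file carries one SNP per line (chrom, id, genetic distance, bp
position); the .ped file carries one sample per line with two allele
columns per SNP, ``0`` marking a missing allele. Because the standard
.ped/.map dialect has no slot for disease/phase/trait metadata, a
sample-annotation TSV travels alongside (sample id, disease, phase,
gender, subphenotype, one column per quantitative trait, ``NA`` for a
trait not measured).

The minor allele at each SNP is defined on the combined non-missing
sample across all cohorts — group MAFs downstream are reported against
this one fixed allele — with frequency ties broken by taking the
alphabetically first nucleotide as minor.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import MISSING, SAMPLE_COLUMNS, GenotypeMatrix

VALID_ALLELES = frozenset("ACGT")
MISSING_ALLELE = "0"


class PedMapParseError(ValueError):
    """Malformed .ped/.map input; message names the offending SNP/line."""


def read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    """Read a .map file into a SNP table (without allele columns)."""
    table = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str, "id": str, "pos": np.int64},
    )
    dup = table["id"].duplicated()
    if dup.any():
        raise PedMapParseError(
            f"duplicate SNP id {table.loc[dup, 'id'].iloc[0]!r} in {map_path}"
        )
    return table.drop(columns="cm")


def read_genotypes(
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
) -> GenotypeMatrix:
    """Read a .ped/.map pair plus sample annotations into a GenotypeMatrix.

    The three files must agree on SNP count/order and on sample ids.
    Raises :class:`PedMapParseError` on dimension mismatches, unknown
    allele symbols, or duplicate SNP ids.
    """
    snp_table = read_map(map_path)
    n_snps = len(snp_table)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PedMapParseError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_snps} "
                    f"fields for {n_snps} SNPs, found {len(fields)}"
                )
            sample_ids.append(fields[1])
            alleles = fields[6:]
            for k, a in enumerate(alleles):
                if a != MISSING_ALLELE and a not in VALID_ALLELES:
                    snp_id = snp_table["id"].iloc[k // 2]
                    raise PedMapParseError(
                        f"{ped_path} line {lineno}: unknown allele symbol "
                        f"{a!r} at SNP {snp_id}"
                    )
            allele_rows.append(alleles)

    alleles = np.array(allele_rows, dtype="U1").reshape(len(sample_ids), n_snps, 2)
    calls, minor, major = _encode_minor_counts(alleles, snp_table["id"])
    snp_table = snp_table.assign(allele_minor=minor, allele_major=major)
    snp_table = snp_table[["id", "chrom", "pos", "allele_minor", "allele_major"]]

    samples = pd.read_csv(annotation_path, sep="\t", dtype={"id": str}, na_values=["NA"])
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise PedMapParseError(f"{annotation_path} lacks columns {missing_cols}")
    if list(samples["id"]) != sample_ids:
        raise PedMapParseError(
            f"sample ids in {annotation_path} do not match {ped_path} "
            "(same ids in the same order are required)"
        )
    return GenotypeMatrix(calls=calls, snps=snp_table, samples=samples)


def _encode_minor_counts(
    alleles: np.ndarray, snp_ids: pd.Series
) -> tuple[np.ndarray, list[str], list[str]]:
    """Map per-sample allele pairs to minor-allele counts per SNP."""
    n_samples, n_snps, _ = alleles.shape
    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    minor_out: list[str] = []
    major_out: list[str] = []
    for j in range(n_snps):
        pair = alleles[:, j, :]
        observed = pair[pair != MISSING_ALLELE]
        symbols, counts = np.unique(observed, return_counts=True)
        if len(symbols) > 2:
            raise PedMapParseError(
                f"SNP {snp_ids.iloc[j]}: more than two alleles observed "
                f"({', '.join(symbols)})"
            )
        if len(symbols) == 0:
            minor_out.append(MISSING_ALLELE)
            major_out.append(MISSING_ALLELE)
            continue
        if len(symbols) == 1:
            major, minor = symbols[0], MISSING_ALLELE
        else:
            # less frequent allele is minor; alphabetical order breaks ties
            order = np.lexsort((symbols, counts))
            minor, major = symbols[order[0]], symbols[order[1]]
        nonmissing = (pair != MISSING_ALLELE).all(axis=1)
        calls[nonmissing, j] = (pair[nonmissing] == minor).sum(axis=1)
        minor_out.append(minor)
        major_out.append(major)
    return calls, minor_out, major_out


def write_genotypes(
    g: GenotypeMatrix,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
) -> None:
    """Write a GenotypeMatrix as .ped/.map plus the annotation TSV.

    Heterozygote allele pairs are emitted in alphabetical order so that a
    read/write cycle is byte-stable after one normalization pass.
    """
    map_table = g.snps[["chrom", "id", "pos"]].copy()
    map_table.insert(2, "cm", 0)
    map_table.to_csv(map_path, sep="\t", header=False, index=False)

    sex_code = g.samples["gender"].map({"male": "1", "female": "2"}).fillna("0")
    with open(ped_path, "w") as handle:
        for i in range(g.n_samples):
            sid = g.samples["id"].iloc[i]
            fields = [sid, sid, "0", "0", sex_code.iloc[i], "-9"]
            for j in range(g.n_snps):
                call = g.calls[i, j]
                minor = g.snps["allele_minor"].iloc[j]
                major = g.snps["allele_major"].iloc[j]
                if call == MISSING:
                    pair = (MISSING_ALLELE, MISSING_ALLELE)
                elif call == 0:
                    pair = (major, major)
                elif call == 2:
                    pair = (minor, minor)
                else:
                    pair = tuple(sorted((minor, major)))
                fields.extend(pair)
            handle.write(" ".join(fields) + "\n")

    g.samples.to_csv(annotation_path, sep="\t", index=False, na_rep="NA")


def write_normative_freqs(
    freqs: pd.DataFrame, path: str | os.PathLike
) -> None:
    """Write a normative-frequency table (snp_id, maf) as TSV."""
    freqs[["snp_id", "maf"]].to_csv(path, sep="\t", index=False)


def read_normative_freqs(path: str | os.PathLike) -> pd.Series:
    """Read a normative-frequency TSV into a snp_id -> MAF mapping."""
    table = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    return table.set_index("snp_id")["maf"]
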