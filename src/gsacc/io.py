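"""Plain-text readers/writers for genotypes and phenotypes.

Genotypes travel as TSV with one row per individual and one column per
locus, the header carrying locus positions in centimorgans.  Phenotypes
are a two-column TSV (id, value).  A minimal haploid VCF export is
provided for interoperability with variant tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GeneticMap, HaploidPopulation

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_vcf",
]


def write_genotypes_tsv(path, pop: HaploidPopulation) -> None:
    cols = [f"{100 * p:.6g}" for p in pop.map.positions]
    pd.DataFrame(pop.alleles, columns=cols).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path, chrom_length: float | None = None) -> HaploidPopulation:
    df = pd.read_csv(path, sep="\t")
    positions = np.array([float(c) for c in df.columns]) / 100.0
    length = chrom_length if chrom_length is not None else max(positions[-1], 1e-9)
    gmap = GeneticMap(positions, chrom_length=length)
    return HaploidPopulation(df.to_numpy(dtype=np.int8), gmap)


def write_phenotypes_tsv(path, values, ids=None) -> None:
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"ind{i}" for i in range(values.size)]
    pd.DataFrame({"id": ids, "value": values}).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError("phenotype TSV must have exactly two columns (id, value)")
    df.columns = ["id", "value"]
    return df


def write_vcf(path, pop: HaploidPopulation, chrom: str = "1") -> None:
    """Minimal haploid VCF (GT field only, positions in integer cM*1e4)."""
    samples = [f"ind{i}" for i in range(pop.n_individuals)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, pos in enumerate(pop.map.positions):
            # 1-based integer coordinate: position in 10^-4 cM units
            coord = int(round(pos * 1_000_000)) + 1
            gts = "\t".join(str(int(a)) for a in pop.alleles[:, j])
            fh.write(f"{chrom}\t{coord}\tlocus{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
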