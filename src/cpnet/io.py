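"""Readers/writers for cohort and network artifacts (TSV, VCF, SIF, GraphML).

All formats are plain text. The VCF writer emits a minimal GT-only file;
reading VCF dosages uses cyvcf2 when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .synthetic_data import GenotypeMatrix, ProteinMatrix, TraitTable, TruthNetwork

__all__ = [
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_vcf",
    "read_vcf_dosages",
    "write_protein_tsv",
    "write_annotation_tsv",
    "write_trait_tsv",
    "write_truth_edges_tsv",
    "write_edges_sif",
    "write_edges_graphml",
    "write_preprocess_sidecar",
    "read_ppi_table",
]


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_ids)
    df.insert(0, "individual", [f"IND{i:05d}" for i in range(genotypes.n_individuals)])
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path, chrom=None, pos=None, maf=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    snp_ids = np.array(df.columns[1:], dtype=object)
    dosages = df.iloc[:, 1:].to_numpy(dtype=np.int8)
    m = len(snp_ids)
    freq = dosages.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chrom=np.array(["1"] * m, dtype=object) if chrom is None else np.asarray(chrom),
        pos=np.arange(1, m + 1) * 10_000 if pos is None else np.asarray(pos),
        maf=np.minimum(freq, 1 - freq) if maf is None else np.asarray(maf),
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal single-sample-block VCF with GT only."""
    n = genotypes.n_individuals
    samples = [f"IND{i:05d}" for i in range(n)]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(genotypes.chrom), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(genotypes.n_snps):
            gts = "\t".join(gt_strings[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\t{genotypes.snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read GT dosages from a VCF via cyvcf2 (optional dependency)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    snp_ids, chrom, pos, rows = [], [], [], []
    for variant in vcf:
        snp_ids.append(variant.ID)
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
        rows.append(variant.gt_types.astype(np.int8))
    dosages = np.array(rows).T
    freq = dosages.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        maf=np.minimum(freq, 1 - freq),
    )


def write_protein_tsv(proteins: ProteinMatrix, path: str | Path) -> None:
    df = pd.DataFrame(proteins.values, columns=proteins.aptamer_ids)
    df.insert(0, "individual", [f"IND{i:05d}" for i in range(proteins.n_individuals)])
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_annotation_tsv(proteins: ProteinMatrix, path: str | Path) -> None:
    proteins.annotation().to_csv(path, sep="\t", index=False)


def write_trait_tsv(traits: TraitTable, path: str | Path) -> None:
    traits.data.to_csv(path, sep="\t", index=False)


def write_truth_edges_tsv(truth: TruthNetwork, path: str | Path) -> None:
    pd.DataFrame(
        {"parent": truth.edges[:, 0], "child": truth.edges[:, 1], "beta": truth.betas}
    ).to_csv(path, sep="\t", index=False)


def write_edges_sif(edges: pd.DataFrame, path: str | Path, relation: str = "causes") -> None:
    with open(path, "w") as fh:
        for a, b in zip(edges["a"], edges["b"]):
            fh.write(f"{a}\t{relation}\t{b}\n")


def write_edges_graphml(edges: pd.DataFrame, path: str | Path, levels: dict | None = None) -> None:
    g = nx.DiGraph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.a, row.b, pp=float(getattr(row, "pp", 1.0)))
    if levels:
        nx.set_node_attributes(g, {k: int(v) for k, v in levels.items() if k in g}, "level")
    nx.write_graphml(g, path)


def write_preprocess_sidecar(params, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)


def read_ppi_table(path: str | Path) -> pd.DataFrame:
    """HIPPIE-style tab format: two gene symbol columns + confidence score."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    return df.rename(columns={cols[0]: "gene_a", cols[1]: "gene_b", cols[2]: "confidence"})
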