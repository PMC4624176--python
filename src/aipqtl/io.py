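"""Readers and writers for the pipeline's plain-text formats.

Founder panels round-trip through a minimal VCF (homozygous 0/0 and 1/1
genotypes only) or a TSV matrix (site rows, line columns). Elution tables,
pool counts and Ct tables are headered TSV; gene models come from BED
(0-based half-open) or GFF3 (1-based inclusive, converted at the boundary);
interaction graphs are 3-column edge lists with optional GraphML export.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .candidates import GeneCatalog
from .simulate import DEFAULT_CHROMOSOMES, FounderPanel, GeneticMap

__all__ = [
    "write_panel_vcf",
    "read_panel_vcf",
    "write_panel_tsv",
    "read_panel_tsv",
    "read_table",
    "write_table",
    "read_gene_catalog",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
]

ELUTION_COLUMNS = ["id", "sex", "exposure", "replicate", "date", "minutes"]
POOL_COLUMNS = ["chrom", "pos", "alt_S", "d_S", "alt_R", "d_R"]
CT_COLUMNS = ["gene", "sex", "pool", "bio_rep", "tech_rep", "ct"]
EDGE_COLUMNS = ["gene_a", "gene_b", "type"]


def _genetic_map_for(chroms, lengths_bp=None) -> GeneticMap:
    lengths_cm, bp = {}, {}
    for c in chroms:
        default_bp, cm = DEFAULT_CHROMOSOMES.get(c, (0, 50.0))
        bp[c] = (lengths_bp or {}).get(c, default_bp)
        lengths_cm[c] = cm
    return GeneticMap(lengths_cm=lengths_cm, lengths_bp=bp)


def write_panel_vcf(panel: FounderPanel, path: str) -> None:
    """Write a founder panel as a minimal VCF (GT-only, homozygous calls)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=aipqtl\n")
        for chrom, bp in panel.genetic_map.lengths_bp.items():
            fh.write(f"##contig=<ID={chrom},length={bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.line_ids)
            + "\n"
        )
        for i, row in enumerate(panel.sites.itertuples(index=False)):
            gts = "\t".join("1/1" if a else "0/0" for a in panel.genotypes[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_panel_vcf(path: str) -> FounderPanel:
    """Read a founder panel from a minimal VCF of homozygous biallelic calls."""
    import pysam

    vf = pysam.VariantFile(path)
    line_ids = list(vf.header.samples)
    lengths_bp = {c: vf.header.contigs[c].length for c in vf.header.contigs}
    records, geno = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"site {rec.chrom}:{rec.pos} is not biallelic")
        alleles = []
        for sample in line_ids:
            gt = rec.samples[sample]["GT"]
            if gt == (0, 0):
                alleles.append(0)
            elif gt == (1, 1):
                alleles.append(1)
            else:
                raise ValueError(
                    f"heterozygous or missing call at {rec.chrom}:{rec.pos} ({sample})"
                )
        records.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
        geno.append(alleles)
    sites = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])
    gmap = _genetic_map_for(sites["chrom"].unique(), lengths_bp)
    return FounderPanel(
        line_ids=line_ids,
        sites=sites,
        genotypes=np.array(geno, dtype=np.int8),
        genetic_map=gmap,
    )


def write_panel_tsv(panel: FounderPanel, path: str) -> None:
    """TSV matrix dialect: chrom, pos, ref, alt, then one 0/1 column per line."""
    df = panel.sites.copy()
    for j, lid in enumerate(panel.line_ids):
        df[lid] = panel.genotypes[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str) -> FounderPanel:
    df = read_table(path, ["chrom", "pos", "ref", "alt"])
    line_ids = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    if not line_ids:
        raise ValueError(f"{path}: no line columns found")
    geno = df[line_ids].to_numpy(dtype=np.int8)
    sites = df[["chrom", "pos", "ref", "alt"]].copy()
    return FounderPanel(
        line_ids=line_ids,
        sites=sites,
        genotypes=geno,
        genetic_map=_genetic_map_for(sites["chrom"].unique()),
    )


def read_table(path: str, required_columns: list[str]) -> pd.DataFrame:
    """Headered TSV with schema validation; parse errors carry line numbers."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ValueError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_catalog(path: str) -> GeneCatalog:
    """Gene intervals from BED (0-based half-open) or GFF3 (1-based inclusive).

    The format is chosen by file extension; both converge on identical
    internal half-open 0-based coordinates.
    """
    import pyranges as pr

    lower = str(path).lower()
    if lower.endswith((".gff", ".gff3")):
        df = pr.read_gff3(path).df
        df = df[df["Feature"] == "gene"] if "Feature" in df.columns else df
        name_col = "ID" if "ID" in df.columns else "Name"
        table = pd.DataFrame(
            {
                "gene": df[name_col],
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
            }
        )
    elif lower.endswith(".bed"):
        df = pr.read_bed(path).df
        table = pd.DataFrame(
            {
                "gene": df["Name"],
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
            }
        )
    else:
        raise ValueError(f"{path}: expected a .bed, .gff or .gff3 file")
    return GeneCatalog(table.reset_index(drop=True))


def read_edge_list(path: str) -> pd.DataFrame:
    """3-column interaction edge list: gene_a, gene_b, type in {genetic, physical}."""
    df = read_table(path, EDGE_COLUMNS)
    bad = ~df["type"].isin(("genetic", "physical"))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: invalid interaction type at line(s) {lines}")
    return df


def write_edge_list(edges: pd.DataFrame, path: str) -> None:
    edges[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_graphml(graph, path: str) -> None:
    """GraphML export of an (extracted) interaction network."""
    import networkx as nx

    nx.write_graphml(graph, path)
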