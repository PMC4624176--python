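"""Variant-to-gene annotation and cross-analysis candidate-gene overlap.

Top associations from separate analyses (sex x exposure x mapping
population) rarely share individual variants, but genes recurrently tagged
across analyses are enriched for true positives. This module maps variants
to genes by interval overlap (gene body plus a flanking window), counts
genes tagged in multiple analyses, and attaches an empirical null by
permutation: each analysis's gene set is replaced by a size-matched uniform
draw from the universe of testable genes, and the multi-analysis overlap
count is recomputed. The add-one estimator p = (1 + #{perm >= obs})/(B + 1)
bounds the p-value away from zero.

Coordinates are half-open 0-based internally; GFF3 input (1-based
inclusive) is converted exactly once at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneCatalog",
    "annotate_variants",
    "overlap_count",
    "overlap_permutation_test",
    "cross_population_overlap",
]


class GeneCatalog:
    """Gene intervals, half-open 0-based, indexed for fast point queries."""

    def __init__(self, table: pd.DataFrame):
        """``table`` columns: gene, chrom, start, end (0-based half-open)."""
        if table.empty:
            raise ValueError("gene catalog is empty")
        bad = table[table["start"] > table["end"]]
        if len(bad):
            raise ValueError(f"malformed intervals for genes: {list(bad['gene'])}")
        if table["gene"].duplicated().any():
            raise ValueError("gene ids must be unique")
        self.table = table.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, grp in self.table.groupby("chrom"):
            tree = IntervalTree()
            for row in grp.itertuples(index=False):
                if row.end > row.start:
                    tree.addi(row.start, row.end, row.gene)
            self._trees[chrom] = tree

    def __len__(self) -> int:
        return len(self.table)

    def genes_at(self, chrom: str, pos0: int, window_bp: int = 0) -> list[str]:
        """Genes whose body +/- window contains the 0-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos0 - window_bp, pos0 + window_bp + 1)
        return sorted(h.data for h in hits)


def annotate_variants(
    variants: pd.DataFrame,
    catalog: GeneCatalog,
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Assign variants to every gene whose body +/- window covers them.

    ``variants`` needs columns ``chrom, pos`` with ``pos`` 1-based.
    Returns one row per (variant, gene) assignment; variants hitting no gene
    (gene deserts) get a single row with gene = NA.
    """
    rows = []
    for row in variants.itertuples(index=True):
        genes = catalog.genes_at(row.chrom, row.pos - 1, window_bp)
        if genes:
            rows.extend((row.Index, row.chrom, row.pos, g) for g in genes)
        else:
            rows.append((row.Index, row.chrom, row.pos, pd.NA))
    return pd.DataFrame(rows, columns=["variant", "chrom", "pos", "gene"])


def overlap_count(sets: dict[str, set], min_analyses: int = 2) -> list:
    """Genes appearing in at least ``min_analyses`` of the analysis sets."""
    if len(sets) < 2:
        raise ValueError("need >= 2 analysis sets")
    counts: dict = {}
    for s in sets.values():
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_analyses)


def overlap_permutation_test(
    sets: dict[str, set],
    universe: set,
    B: int = 1000,
    seed: int = 0,
    min_analyses: int = 2,
) -> dict:
    """Permutation null for the multi-analysis gene-overlap count.

    Each permutation redraws every analysis's set uniformly (size-preserving,
    without replacement) from ``universe`` and recounts genes shared by
    >= ``min_analyses`` analyses. Returns observed count, the permuted
    counts, and the add-one empirical p-value.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    universe_list = sorted(universe)
    for label, s in sets.items():
        if not s <= universe:
            raise ValueError(f"set {label!r} is not contained in the universe")
        if len(s) > len(universe_list):
            raise ValueError(f"set {label!r} larger than the universe")
    observed = len(overlap_count(sets, min_analyses))
    rng = np.random.default_rng(seed)
    sizes = {label: len(s) for label, s in sets.items()}
    perm_counts = np.empty(B, dtype=int)
    arr = np.array(universe_list, dtype=object)
    for b in range(B):
        perm = {
            label: set(rng.choice(arr, size=size, replace=False))
            for label, size in sizes.items()
        }
        perm_counts[b] = len(overlap_count(perm, min_analyses))
    p = (1 + int((perm_counts >= observed).sum())) / (B + 1)
    return {
        "observed": observed,
        "p_value": p,
        "B": B,
        "perm_counts": perm_counts,
        "genes": overlap_count(sets, min_analyses),
    }


def cross_population_overlap(dgrp_genes: set, xqtl_genes: set) -> dict:
    """Genes found by both mapping populations, with per-source provenance."""
    shared = set(dgrp_genes) & set(xqtl_genes)
    return {
        "shared": sorted(shared),
        "n_shared": len(shared),
        "only_dgrp": sorted(set(dgrp_genes) - shared),
        "only_xqtl": sorted(set(xqtl_genes) - shared),
    }
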