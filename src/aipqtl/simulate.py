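"""Forward simulation of an advanced intercross population (AIP) and its assays.

This module generates every input the analysis layers consume: a panel of
fully inbred founder lines segregating biallelic SNPs, a diploid outbred
population descended from those founders by random mating, inebriometer
elution phenotypes (alcohol knock-down times collected at fixed one-minute
intervals), pooled sequencing of phenotypic extremes, and small fixtures for
the network and qPCR modules.

Haplotypes are founder mosaics: each chromosome of each individual is an
ordered list of segments, each segment labelled with the founder line it
descends from. Recombination follows a Poisson crossover count on the genetic
map length with uniformly placed crossovers and no interference, and occurs
in female meiosis only by default (Drosophila males are achiasmatic).

All randomness flows from a single integer seed through
:func:`numpy.random.default_rng`; derived streams are spawned
deterministically so every operation is bit-reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "FounderPanel",
    "Population",
    "PhenotypeModel",
    "VarCompSpec",
    "make_founder_panel",
    "diallel_base_population",
    "advance_generations",
    "dosage_matrix",
    "simulate_elution",
    "simulate_dgrp_fly_data",
    "simulate_varcomp_array",
    "simulate_pool_seq",
    "make_fixture_network",
    "make_fixture_ct_table",
    "DEFAULT_CHROMOSOMES",
]

# Major D. melanogaster chromosome arms: (physical length bp, map length cM)
DEFAULT_CHROMOSOMES: dict[str, tuple[int, float]] = {
    "X": (22_400_000, 66.0),
    "2L": (23_000_000, 55.0),
    "2R": (21_100_000, 52.0),
    "3L": (24_500_000, 47.0),
    "3R": (27_900_000, 58.0),
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneticMap:
    """Linear physical-to-genetic map, one entry per chromosome.

    ``lengths_cm`` gives the total map length in centimorgans and
    ``lengths_bp`` the physical span; positions map to cM proportionally.
    """

    lengths_cm: dict[str, float]
    lengths_bp: dict[str, int]

    def to_cm(self, chrom: str, pos) -> np.ndarray:
        """Map 1-based bp position(s) to cM on ``chrom``."""
        return np.asarray(pos, dtype=float) / self.lengths_bp[chrom] * self.lengths_cm[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths_cm)


@dataclass
class FounderPanel:
    """Genotypes of fully inbred founder lines at biallelic SNP sites.

    Because the lines are fully homozygous each is represented by a single
    haploid allele (0 = ref, 1 = alt) per site. ``sites`` has columns
    ``chrom, pos, ref, alt`` with ``pos`` 1-based and strictly increasing
    within a chromosome; ``genotypes`` is an (n_sites, n_lines) 0/1 array.
    """

    line_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    genetic_map: GeneticMap

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.line_ids)):
            raise ValueError("genotype matrix shape does not match sites x lines")
        if not np.isin(self.genotypes, (0, 1)).all():
            raise ValueError("founder genotypes must be 0/1 (lines are fully homozygous)")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_cm(self) -> np.ndarray:
        """cM coordinate of every site, in site order."""
        out = np.empty(self.n_sites)
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            out[grp.index.to_numpy()] = self.genetic_map.to_cm(chrom, grp["pos"].to_numpy())
        return out


# A haplotype is {chrom: (founders, ends)} with parallel arrays: segment i
# descends from founders[i] and covers (ends[i-1], ends[i]] in cM, tiling
# [0, map length] without gaps.
Haplotype = dict[str, tuple[np.ndarray, np.ndarray]]


@dataclass
class Population:
    """Diploid individuals as pairs of founder-mosaic haplotypes."""

    individuals: list[tuple[Haplotype, Haplotype]]
    generation: int
    census_size: int

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if self.census_size != len(self.individuals):
            raise ValueError("census_size must equal the number of individuals")

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass
class PhenotypeModel:
    """Additive QTL model for inebriometer elution time.

    ``qtl_effects`` maps site index (row of the panel's site table) to the
    additive effect in minutes per alt allele. ``sex_effect`` is added for
    males; ``tolerance_shift`` is added under the second exposure (E2).
    Phenotypes are discretized to the upper edge of ``bin_width``-minute
    bins, emulating collection of eluting flies at fixed intervals.
    """

    grand_mean: float = 6.0
    qtl_effects: dict[int, float] = field(default_factory=dict)
    sex_effect: float = 0.0
    tolerance_shift: float = 0.0
    residual_sd: float = 1.0
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


@dataclass
class VarCompSpec:
    """Generating variance components for a balanced line x factor design.

    The model is Y = mu + L + F + LxF + Rep(LxF) + eps with Gaussian random
    effects; ``factor_effect`` is the fixed offset of the second factor
    level. Units are minutes (components in minutes squared).
    """

    sigma2_L: float
    sigma2_LxF: float
    sigma2_Rep: float
    sigma2_eps: float
    n_lines: int
    n_levels: int = 2
    n_reps: int = 2
    n_flies_per_rep: int = 70
    grand_mean: float = 7.0
    factor_effect: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sigma2_L", "sigma2_LxF", "sigma2_Rep", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_lines", "n_levels", "n_reps", "n_flies_per_rep"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# founder panel


def make_founder_panel(
    n_lines: int,
    n_sites_per_chrom: int,
    private_fraction: float = 0.3,
    seed: int = 0,
    chromosomes: dict[str, tuple[int, float]] | None = None,
) -> FounderPanel:
    """Simulate a panel of fully inbred founder lines.

    A ``private_fraction`` of sites carry the alt allele in exactly one line
    (private alleles — at intermediate frequency once the lines are
    intercrossed); the remainder carry it in a random nonempty proper subset
    of lines, so every site segregates in the panel.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 founder lines")
    if not 0 <= private_fraction <= 1:
        raise ValueError("private_fraction must be in [0, 1]")
    if n_sites_per_chrom == 0:
        raise ValueError("n_sites_per_chrom must be >= 1 (empty panel)")
    chromosomes = chromosomes or DEFAULT_CHROMOSOMES
    rng = np.random.default_rng(seed)

    records = []
    for chrom, (bp, _cm) in chromosomes.items():
        pos = np.sort(rng.choice(np.arange(1, bp + 1), size=n_sites_per_chrom, replace=False))
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            records.append((chrom, int(p), _BASES[ref], _BASES[alt]))
    sites = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])

    n_sites = len(sites)
    geno = np.zeros((n_sites, n_lines), dtype=np.int8)
    is_private = rng.random(n_sites) < private_fraction
    for i in range(n_sites):
        if is_private[i]:
            geno[i, rng.integers(n_lines)] = 1
        else:
            # nonempty proper subset, never of size 1 when avoidable so the
            # site is not accidentally private
            lo = 2 if n_lines > 2 else 1
            k = int(rng.integers(lo, n_lines))
            geno[i, rng.choice(n_lines, size=k, replace=False)] = 1

    gmap = GeneticMap(
        lengths_cm={c: cm for c, (_bp, cm) in chromosomes.items()},
        lengths_bp={c: bp for c, (bp, _cm) in chromosomes.items()},
    )
    return FounderPanel(
        line_ids=[f"L{i + 1:03d}" for i in range(n_lines)],
        sites=sites,
        genotypes=geno,
        genetic_map=gmap,
    )


def _whole_haplotype(founder: int, gmap: GeneticMap) -> Haplotype:
    return {
        c: (np.array([founder], dtype=np.int32), np.array([gmap.lengths_cm[c]]))
        for c in gmap.chromosomes
    }


def diallel_base_population(panel: FounderPanel, size: int, seed: int = 0) -> Population:
    """Generation-0 population from a partial diallel cross of the founders.

    Every unordered pair of distinct lines (no reciprocals, no within-line
    crosses) contributes equally many F1 individuals, so each founder
    contributes exactly 1/n_lines of all haplotypes.
    """
    pairs = list(itertools.combinations(range(panel.n_lines), 2))
    if size % len(pairs):
        raise ValueError(
            f"population size must be a multiple of {len(pairs)} "
            f"(number of distinct line pairs for {panel.n_lines} founders)"
        )
    per_pair = size // len(pairs)
    gmap = panel.genetic_map
    individuals = [
        (_whole_haplotype(i, gmap), _whole_haplotype(j, gmap))
        for i, j in pairs
        for _ in range(per_pair)
    ]
    return Population(individuals=individuals, generation=0, census_size=size)


# ---------------------------------------------------------------------------
# random mating with female-limited recombination


def _recombine_chrom(
    h1: tuple[np.ndarray, np.ndarray],
    h2: tuple[np.ndarray, np.ndarray],
    xovers: np.ndarray,
    length: float,
    start_on_first: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Mosaic of two homologous chromosomes switching at ``xovers`` (cM)."""
    bounds = np.concatenate(([0.0], xovers, [length]))
    founders: list[int] = []
    ends: list[float] = []
    cur = 0 if start_on_first else 1
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        f, e = (h1, h2)[cur]
        i0 = np.searchsorted(e, lo, side="right")
        i1 = np.searchsorted(e, hi, side="left")
        for k in range(i0, min(i1, len(e) - 1) + 1):
            seg_end = min(float(e[k]), hi)
            if founders and founders[-1] == f[k] and ends:
                ends[-1] = seg_end
            else:
                founders.append(int(f[k]))
                ends.append(seg_end)
            if seg_end >= hi:
                break
        cur ^= 1
    ends_arr = np.array(ends)
    ends_arr[-1] = length  # guard against float round-off at the telomere
    return np.array(founders, dtype=np.int32), ends_arr


def _gamete(parent: tuple[Haplotype, Haplotype], gmap: GeneticMap,
            rng: np.random.Generator, recombine: bool) -> Haplotype:
    h_a, h_b = parent
    out: Haplotype = {}
    for chrom in gmap.chromosomes:
        length = gmap.lengths_cm[chrom]
        first = bool(rng.integers(2))
        k = rng.poisson(length / 100.0) if (recombine and length > 0) else 0
        if k == 0:
            src = h_a if first else h_b
            out[chrom] = (src[chrom][0].copy(), src[chrom][1].copy())
        else:
            xo = np.sort(rng.uniform(0.0, length, size=k))
            out[chrom] = _recombine_chrom(h_a[chrom], h_b[chrom], xo, length, first)
    return out


def advance_generations(
    pop: Population,
    n_gen: int,
    panel: FounderPanel,
    seed: int = 0,
    offspring_per_generation: int | None = None,
    final_size: int | None = None,
    female_recombination_only: bool = True,
) -> Population:
    """Advance ``n_gen`` generations of random mating (selfing excluded).

    Each offspring draws two distinct parents uniformly; the dam's gamete
    recombines, the sire's does not unless ``female_recombination_only`` is
    False (achiasmatic males). ``final_size`` expands the last generation,
    e.g. to breed the cohort of flies that will be phenotyped.
    """
    if n_gen < 0:
        raise ValueError("n_gen must be >= 0")
    if not pop.individuals:
        raise ValueError("population is empty")
    if n_gen == 0:
        return pop
    rng = np.random.default_rng(seed)
    gmap = panel.genetic_map
    current = pop.individuals
    n = offspring_per_generation or pop.census_size
    for g in range(n_gen):
        size = final_size if (final_size and g == n_gen - 1) else n
        nxt = []
        for _ in range(size):
            i = int(rng.integers(len(current)))
            j = int(rng.integers(len(current) - 1))
            j += j >= i  # exclude selfing
            dam, sire = current[i], current[j]
            egg = _gamete(dam, gmap, rng, recombine=True)
            sperm = _gamete(sire, gmap, rng, recombine=not female_recombination_only)
            nxt.append((egg, sperm))
        current = nxt
    return Population(
        individuals=current,
        generation=pop.generation + n_gen,
        census_size=len(current),
    )


# ---------------------------------------------------------------------------
# genotype extraction


def _hap_alleles(hap: Haplotype, panel: FounderPanel, chrom: str,
                 cm: np.ndarray, rows: np.ndarray) -> np.ndarray:
    founders, ends = hap[chrom]
    idx = np.searchsorted(ends, cm, side="left")
    idx = np.minimum(idx, len(founders) - 1)
    return panel.genotypes[rows][np.arange(len(rows)), founders[idx]]


def dosage_matrix(pop_or_individuals, panel: FounderPanel,
                  site_rows: np.ndarray | None = None) -> np.ndarray:
    """Alt-allele dosage (0/1/2) for each individual at each panel site.

    Accepts a :class:`Population` or a list of individuals; ``site_rows``
    restricts to a subset of site-table rows.
    """
    individuals = pop_or_individuals.individuals if isinstance(pop_or_individuals, Population) \
        else list(pop_or_individuals)
    if site_rows is None:
        site_rows = np.arange(panel.n_sites)
    site_rows = np.asarray(site_rows)
    out = np.zeros((len(individuals), len(site_rows)), dtype=np.int8)
    chroms = panel.sites["chrom"].to_numpy()[site_rows]
    all_cm = panel.site_cm()[site_rows]
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        rows = site_rows[sel]
        cm = all_cm[sel]
        for k, (ha, hb) in enumerate(individuals):
            out[k, sel] = _hap_alleles(ha, panel, chrom, cm, rows) + _hap_alleles(
                hb, panel, chrom, cm, rows
            )
    return out


# ---------------------------------------------------------------------------
# phenotypes


def _discretize(minutes: np.ndarray, bin_width: float) -> np.ndarray:
    """Upper edge of each observation's collection interval, floored at one bin."""
    binned = np.ceil(minutes / bin_width) * bin_width
    return np.maximum(binned, bin_width)


def simulate_elution(
    pop_or_lines,
    model: PhenotypeModel,
    sex: str,
    exposure: str,
    n_flies: int,
    seed: int = 0,
    panel: FounderPanel | None = None,
    replicate: int = 1,
    date: str = "d1",
) -> pd.DataFrame:
    """Inebriometer elution times for ``n_flies`` flies.

    ``pop_or_lines`` is a :class:`Population` (flies are individuals, sampled
    without replacement) or a :class:`FounderPanel` (flies are drawn evenly
    from the homozygous lines). Returns an elution table with columns
    ``id, sex, exposure, replicate, date, minutes``.
    """
    if exposure not in ("E1", "E2"):
        raise ValueError(f"unknown exposure label {exposure!r} (expected E1 or E2)")
    if sex not in ("M", "F"):
        raise ValueError(f"unknown sex label {sex!r} (expected M or F)")
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    rng = np.random.default_rng(seed)

    qtl_rows = np.array(sorted(model.qtl_effects), dtype=int)
    effects = np.array([model.qtl_effects[i] for i in qtl_rows])

    if isinstance(pop_or_lines, Population):
        if panel is None:
            raise ValueError("panel is required when phenotyping a Population")
        if n_flies > len(pop_or_lines):
            raise ValueError("n_flies exceeds the population census")
        fly_idx = rng.choice(len(pop_or_lines), size=n_flies, replace=False)
        ids = [f"ind{i}" for i in fly_idx]
        if len(qtl_rows):
            inds = [pop_or_lines.individuals[i] for i in fly_idx]
            dos = dosage_matrix(inds, panel, qtl_rows).astype(float)
        else:
            dos = np.zeros((n_flies, 0))
    else:
        panel_in = pop_or_lines
        line_idx = np.arange(n_flies) % panel_in.n_lines
        ids = [panel_in.line_ids[i] for i in line_idx]
        dos = 2.0 * panel_in.genotypes[qtl_rows][:, line_idx].T if len(qtl_rows) else np.zeros(
            (n_flies, 0)
        )

    genetic = dos @ effects if len(qtl_rows) else 0.0
    value = (
        model.grand_mean
        + genetic
        + (model.sex_effect if sex == "M" else 0.0)
        + (model.tolerance_shift if exposure == "E2" else 0.0)
        + rng.normal(0.0, model.residual_sd, size=n_flies)
    )
    return pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "exposure": exposure,
            "replicate": replicate,
            "date": date,
            "minutes": _discretize(np.asarray(value, dtype=float), model.bin_width),
        }
    )


def simulate_varcomp_array(spec: VarCompSpec, seed: int = 0) -> np.ndarray:
    """Draw a balanced design as an (lines, levels, reps, flies) array."""
    rng = np.random.default_rng(seed)
    a, b, r, f = spec.n_lines, spec.n_levels, spec.n_reps, spec.n_flies_per_rep
    line = rng.normal(0, math.sqrt(spec.sigma2_L), size=(a, 1, 1, 1))
    inter = rng.normal(0, math.sqrt(spec.sigma2_LxF), size=(a, b, 1, 1))
    rep = rng.normal(0, math.sqrt(spec.sigma2_Rep), size=(a, b, r, 1))
    eps = rng.normal(0, math.sqrt(spec.sigma2_eps), size=(a, b, r, f))
    fixed = spec.factor_effect * np.arange(b).reshape(1, b, 1, 1)
    return spec.grand_mean + fixed + line + inter + rep + eps


def simulate_dgrp_fly_data(
    spec: VarCompSpec,
    seed: int = 0,
    factor_name: str = "sex",
    factor_levels: tuple[str, ...] = ("F", "M"),
) -> pd.DataFrame:
    """Per-fly elution table from the balanced line x factor mixed model.

    Emulates a reference-panel screen: two replicate inebriometer runs per
    line and factor level with a fixed number of flies each. Columns:
    ``line, <factor_name>, replicate, minutes``.
    """
    if len(factor_levels) != spec.n_levels:
        raise ValueError("factor_levels length must equal n_levels")
    arr = simulate_varcomp_array(spec, seed)
    a, b, r, f = arr.shape
    idx = pd.MultiIndex.from_product(
        [
            [f"line{i + 1:03d}" for i in range(a)],
            list(factor_levels),
            np.arange(1, r + 1),
            np.arange(f),
        ],
        names=["line", factor_name, "replicate", "_fly"],
    )
    df = pd.DataFrame({"minutes": arr.ravel()}, index=idx).reset_index()
    return df.drop(columns="_fly")


# ---------------------------------------------------------------------------
# pooled sequencing


def simulate_pool_seq(
    pop: Population,
    selected_ids: tuple,
    panel: FounderPanel,
    mean_depth: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled sequencing of the sensitive and resistant extreme pools.

    ``selected_ids`` is a ``(sensitive_ids, resistant_ids)`` pair of
    individual indices. Per site the true pool frequency is the mean alt
    dosage over the pool's chromosomes; sequencing depth is Poisson with the
    given mean and alt read counts are binomial. Sites monomorphic in the
    founder panel are excluded. Returns a pool-counts table with columns
    ``chrom, pos, alt_S, d_S, alt_R, d_R``.
    """
    sens_ids, res_ids = selected_ids
    if len(sens_ids) == 0 or len(res_ids) == 0:
        raise ValueError("both pools must be non-empty")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)

    from .xqtl import segregating_sites

    seg = segregating_sites(panel)
    rows = seg.index.to_numpy()
    out = {"chrom": seg["chrom"].to_numpy(), "pos": seg["pos"].to_numpy()}
    for label, ids in (("S", sens_ids), ("R", res_ids)):
        inds = [pop.individuals[i] for i in ids]
        dos = dosage_matrix(inds, panel, rows)
        freq = dos.sum(axis=0) / (2.0 * len(ids))
        depth = rng.poisson(mean_depth, size=len(rows))
        alt = rng.binomial(depth, freq)
        out[f"alt_{label}"] = alt
        out[f"d_{label}"] = depth
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# fixtures for the network and expression layers


def make_fixture_network(
    n_candidates: int,
    n_other: int,
    n_edges: int,
    seed: int = 0,
    planted_linkers: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Random typed edge list with optional planted candidate-linker-candidate paths.

    Returns ``(edges, candidates)`` where edges has columns
    ``gene_a, gene_b, type`` (type in {genetic, physical}). Planted linkers
    are named ``link{k}`` and each connects two distinct candidates, so the
    one-linker subnetwork extraction must recover them.
    """
    if min(n_candidates, n_other, n_edges) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    candidates = [f"cand{i}" for i in range(n_candidates)]
    others = [f"gene{i}" for i in range(n_other)]
    nodes = candidates + others
    rows: list[tuple[str, str, str]] = []
    seen: set[frozenset] = set()
    for _ in range(n_edges):
        if len(nodes) < 2:
            break
        a, b = rng.choice(len(nodes), size=2, replace=False)
        key = frozenset((nodes[a], nodes[b]))
        if key in seen:
            continue
        seen.add(key)
        rows.append((nodes[a], nodes[b], ("genetic", "physical")[int(rng.integers(2))]))
    for k in range(planted_linkers):
        if n_candidates < 2:
            raise ValueError("planted linkers need >= 2 candidates")
        linker = f"link{k}"
        c1, c2 = rng.choice(n_candidates, size=2, replace=False)
        rows.append((candidates[c1], linker, "genetic"))
        rows.append((linker, candidates[c2], "genetic"))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "type"])
    return edges, candidates


def make_fixture_ct_table(
    genes: list[str],
    n_bio_reps: int = 6,
    effect_sizes: dict[str, float] | None = None,
    seed: int = 0,
    reference: str = "Gpdh",
    n_tech_reps: int = 3,
    noise_sd: float = 0.3,
    sexes: tuple[str, ...] = ("M", "F"),
) -> pd.DataFrame:
    """qPCR Ct table for sensitive vs resistant pools with planted shifts.

    ``effect_sizes[gene]`` is the ddCt shift (cycles) of the resistant pool
    relative to the sensitive pool; positive values mean higher Ct (lower
    expression) in the resistant pool. The reference gene is included in
    every stratum. Columns: ``gene, sex, pool, bio_rep, tech_rep, ct``.
    """
    if n_bio_reps < 0 or n_tech_reps < 1:
        raise ValueError("replicate counts must be >= 0 (technical >= 1)")
    effect_sizes = effect_sizes or {}
    rng = np.random.default_rng(seed)
    rows = []
    for sex in sexes:
        for pool in ("sensitive", "resistant"):
            for rep in range(1, n_bio_reps + 1):
                ref_level = 20.0 + rng.normal(0, noise_sd)
                for gene in [reference] + [g for g in genes if g != reference]:
                    base = ref_level if gene == reference else 25.0 + rng.normal(0, noise_sd)
                    if gene != reference and pool == "resistant":
                        base += effect_sizes.get(gene, 0.0)
                    for tech in range(1, n_tech_reps + 1):
                        rows.append(
                            (gene, sex, pool, rep, tech, base + rng.normal(0, 0.05))
                        )
    return pd.DataFrame(
        rows, columns=["gene", "sex", "pool", "bio_rep", "tech_rep", "ct"]
    )
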