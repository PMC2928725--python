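"""Coalescent simulation of SNP panels with designated, MAF-conditioned QTLs.

The genome is a set of independent linkage groups, each a row of markers at
fixed recombination distances: the population-scaled recombination rate
between adjacent markers is ``rho_adjacent`` (default 1, i.e. 2Nr = 1).
Genealogies are generated by the coalescent with recombination (via msprime)
with time rescaled so branch lengths are in coalescent units — two lineages
coalesce at rate 1 — and one marginal tree is available at every marker.

Mutations are then superimposed by this module, not by the engine: every
marker receives exactly one mutation, placed on a branch of that marker's
marginal tree with probability proportional to branch length (infinite
sites), and the leaves below the branch carry the derived allele.  At the
two designated QTL markers the placement is *conditioned*: only branches
whose descendant count puts the resulting minor-allele frequency inside a
configured window (e.g. 1-10% or 20-30%) are eligible.  If a marginal tree
offers no eligible branch, the chromosome's genealogy is resampled with a
fresh sub-seed, so the MAF guarantee is never relaxed.

Haplotypes are paired in order (2k, 2k+1) into diploid individuals with
genotypes coded 0/1/2 = derived-allele count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import tskit

__all__ = [
    "SimConfig",
    "HaplotypePanel",
    "GenotypeMatrix",
    "ResampleNeeded",
    "simulate_genealogies",
    "place_mutations",
    "place_conditioned_mutation",
    "assemble_diploids",
    "simulate_panel",
]

logger = logging.getLogger(__name__)

#: a genealogy for one linkage group: a tree sequence whose marginal tree at
#: integer position p is the gene tree of marker p
Genealogy = tskit.TreeSequence


class ResampleNeeded(RuntimeError):
    """No branch of the marginal tree can satisfy the MAF window."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated population sample.

    ``qtl_positions`` are 0-based (chromosome, marker-within-chromosome)
    pairs; the default places the two trait loci at marker 50 of the first
    and second linkage groups (global 1-based positions 50 and 150), so they
    are unlinked to each other.  ``maf_window`` bounds the minor-allele
    frequency of the QTL columns as a fraction of the 2n haplotypes.
    """

    n_individuals: int
    n_chromosomes: int = 5
    markers_per_chromosome: int = 100
    rho_adjacent: float = 1.0
    qtl_positions: tuple[tuple[int, int], ...] = ((0, 49), (1, 49))
    maf_window: tuple[float, float] = (0.2, 0.3)
    genealogy_seed: int = 1
    mutation_seed: int = 2

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 diploid individuals")
        chroms = [c for c, _ in self.qtl_positions]
        if len(set(chroms)) != len(chroms):
            raise ValueError("QTL positions must lie on distinct chromosomes")
        for c, p in self.qtl_positions:
            if not (0 <= c < self.n_chromosomes and 0 <= p < self.markers_per_chromosome):
                raise ValueError(f"QTL position ({c}, {p}) outside the genome")
        low, high = self.maf_window
        if not 0.0 < low < high <= 0.5:
            raise ValueError("maf_window must satisfy 0 < low < high <= 0.5")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def global_marker(self, chrom: int, pos: int) -> int:
        return chrom * self.markers_per_chromosome + pos

    @property
    def qtl_markers(self) -> tuple[int, ...]:
        return tuple(self.global_marker(c, p) for c, p in self.qtl_positions)

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_chromosomes": self.n_chromosomes,
            "markers_per_chromosome": self.markers_per_chromosome,
            "rho_adjacent": self.rho_adjacent,
            "qtl_positions": [list(q) for q in self.qtl_positions],
            "maf_window": list(self.maf_window),
            "genealogy_seed": self.genealogy_seed,
            "mutation_seed": self.mutation_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "qtl_positions" in d:
            d["qtl_positions"] = tuple(tuple(q) for q in d["qtl_positions"])
        if "maf_window" in d:
            d["maf_window"] = tuple(d["maf_window"])
        return cls(**d)


@dataclass
class HaplotypePanel:
    """Binary haplotypes (2n x markers) with chromosome assignment."""

    haplotypes: np.ndarray  # (2n, M) uint8
    marker_chrom: np.ndarray  # (M,) chromosome index of each column
    marker_pos: np.ndarray  # (M,) 0-based marker index within its chromosome
    qtl_cols: tuple[int, ...]  # column indices of the designated QTLs
    n_resamples: int = 0  # genealogy regenerations forced by MAF conditioning

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.haplotypes.mean(axis=0)
        return np.minimum(p, 1.0 - p)


@dataclass
class GenotypeMatrix:
    """Diploid 0/1/2 genotypes (n x markers) derived from a haplotype panel."""

    genotypes: np.ndarray  # (n, M) uint8, derived-allele counts
    marker_chrom: np.ndarray
    marker_pos: np.ndarray
    qtl_cols: tuple[int, ...]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def qtl_genotypes(self) -> np.ndarray:
        return self.genotypes[:, list(self.qtl_cols)]


def _chromosome_seed(genealogy_seed: int, chrom: int, attempt: int) -> int:
    """Deterministic msprime seed for one chromosome's genealogy."""
    state = np.random.SeedSequence(
        entropy=genealogy_seed, spawn_key=(chrom, attempt)
    ).generate_state(1, dtype=np.uint32)[0]
    return int(state % (2**31 - 2)) + 1


def _sim_chromosome(config: SimConfig, chrom: int, attempt: int = 0) -> Genealogy:
    """One linkage group's genealogy, branch lengths in coalescent units.

    With ploidy 2 and population size 1/2 the pairwise coalescence rate is
    one per unit time, so the per-unit-length recombination rate equals the
    population-scaled rate between adjacent markers directly.
    """
    m = config.markers_per_chromosome
    return msprime.sim_ancestry(
        samples=config.n_individuals,
        ploidy=2,
        population_size=0.5,
        sequence_length=max(m, 2) if m > 1 else 1,
        recombination_rate=config.rho_adjacent if m > 1 else 0.0,
        random_seed=_chromosome_seed(config.genealogy_seed, chrom, attempt),
    )


def simulate_genealogies(config: SimConfig) -> list[Genealogy]:
    """Independent genealogies, one per chromosome, deterministic in the seed."""
    return [_sim_chromosome(config, c) for c in range(config.n_chromosomes)]


def _branches(tree: tskit.Tree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nodes below a branch, branch lengths, and descendant-leaf counts."""
    nodes = np.array(
        [u for u in tree.nodes() if tree.parent(u) != tskit.NULL], dtype=np.int64
    )
    lengths = np.array([tree.branch_length(u) for u in nodes])
    counts = np.array([tree.num_samples(u) for u in nodes], dtype=np.int64)
    return nodes, lengths, counts


def _mutate_on_node(tree: tskit.Tree, node: int, n_haplotypes: int) -> np.ndarray:
    col = np.zeros(n_haplotypes, dtype=np.uint8)
    col[np.fromiter(tree.samples(node), dtype=np.int64)] = 1
    return col


def place_conditioned_mutation(
    tree: tskit.Tree,
    maf_window: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Place one mutation whose minor-allele frequency lands in the window.

    Sampling is restricted to eligible branches (descendant count k with
    min(k, 2n-k)/2n inside the window) and proportional to branch length
    among them.  Raises :class:`ResampleNeeded` when no branch qualifies.
    """
    nh = tree.tree_sequence.num_samples
    nodes, lengths, counts = _branches(tree)
    # a branch is suitable when its descendant (derived-allele) count lands
    # in the window; with the window capped at 0.5 the derived allele is the
    # minor one, fixing the orientation of the genotype coding at the QTL
    freq = counts / nh
    low, high = maf_window
    eligible = (freq >= low) & (freq <= high)
    if not eligible.any():
        raise ResampleNeeded(
            f"no branch with minor-allele frequency in [{low}, {high}]"
        )
    weights = lengths * eligible
    node = nodes[rng.choice(len(nodes), p=weights / weights.sum())]
    return _mutate_on_node(tree, int(node), nh)


def place_mutations(
    genealogy: Genealogy,
    positions: np.ndarray,
    rng: np.random.Generator,
    conditioned: dict[int, tuple[float, float]] | None = None,
) -> np.ndarray:
    """One mutation per marker, branch sampled proportional to its length.

    ``positions`` are marker indices along the chromosome; ``conditioned``
    maps a position to a MAF window for the restricted placement.  Returns a
    (2n, len(positions)) binary matrix; every column is polymorphic because
    mutations never sit above the root.
    """
    conditioned = conditioned or {}
    nh = genealogy.num_samples
    positions = np.asarray(positions, dtype=np.int64)
    H = np.zeros((nh, len(positions)), dtype=np.uint8)
    order = np.argsort(positions)
    tree = tskit.Tree(genealogy)
    for out_idx in order:
        pos = positions[out_idx]
        tree.seek(min(pos, genealogy.sequence_length - 0.5))
        if int(pos) in conditioned:
            H[:, out_idx] = place_conditioned_mutation(tree, conditioned[int(pos)], rng)
        else:
            nodes, lengths, _ = _branches(tree)
            node = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
            H[:, out_idx] = _mutate_on_node(tree, int(node), nh)
    return H


def assemble_diploids(panel: HaplotypePanel) -> GenotypeMatrix:
    """Pair haplotypes (2k, 2k+1) into individual k; genotypes are allele sums."""
    H = panel.haplotypes
    if H.shape[0] % 2 != 0:
        raise ValueError("odd number of haplotypes cannot form diploids")
    G = (H[0::2, :] + H[1::2, :]).astype(np.uint8)
    return GenotypeMatrix(
        genotypes=G,
        marker_chrom=panel.marker_chrom.copy(),
        marker_pos=panel.marker_pos.copy(),
        qtl_cols=panel.qtl_cols,
    )


def simulate_panel(
    config: SimConfig,
    markers: list[int] | None = None,
    genealogies: list[Genealogy] | None = None,
    max_resamples: int = 100,
) -> HaplotypePanel:
    """Simulate a haplotype panel under ``config``.

    ``markers`` optionally restricts output to a subset of global marker
    indices (QTL markers are conditioned wherever they appear).  Passing
    precomputed ``genealogies`` reuses trees across settings, which is how
    replicated experiments hold genealogies (but not mutations) constant;
    chromosomes whose QTL tree cannot satisfy the MAF window are resampled
    with fresh sub-seeds and the count is recorded on the panel.
    """
    mpc = config.markers_per_chromosome
    if markers is None:
        markers = list(range(config.n_markers))
    markers = sorted(markers)
    qtl_globals = set(config.qtl_markers)

    chrom_of = np.array([m // mpc for m in markers], dtype=np.int64)
    pos_of = np.array([m % mpc for m in markers], dtype=np.int64)
    qtl_cols = tuple(i for i, m in enumerate(markers) if m in qtl_globals)

    columns: list[np.ndarray | None] = [None] * len(markers)
    n_resamples = 0
    for chrom in sorted(set(chrom_of.tolist())):
        sel = np.flatnonzero(chrom_of == chrom)
        positions = pos_of[sel]
        conditioned = {
            int(p): config.maf_window
            for p, m in zip(positions, np.asarray(markers)[sel])
            if int(m) in qtl_globals
        }
        genealogy = (
            genealogies[chrom] if genealogies is not None else _sim_chromosome(config, chrom)
        )
        for attempt in range(max_resamples + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=config.mutation_seed, spawn_key=(chrom, attempt)
                )
            )
            try:
                block = place_mutations(genealogy, positions, rng, conditioned)
                break
            except ResampleNeeded:
                n_resamples += 1
                logger.info(
                    "chromosome %d: resampling genealogy (attempt %d) to satisfy "
                    "MAF window %s", chrom, attempt + 1, config.maf_window,
                )
                genealogy = _sim_chromosome(config, chrom, attempt=attempt + 1)
        else:
            raise RuntimeError(
                f"could not satisfy MAF window {config.maf_window} on chromosome "
                f"{chrom} after {max_resamples} genealogy resamples"
            )
        for j, col in zip(sel, block.T):
            columns[j] = col

    H = np.column_stack(columns)
    return HaplotypePanel(
        haplotypes=H,
        marker_chrom=chrom_of,
        marker_pos=pos_of,
        qtl_cols=qtl_cols,
        n_resamples=n_resamples,
    )
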