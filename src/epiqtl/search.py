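"""Two-step BIC model selection over compatible haplotype blocks.

Dense marker maps carry heavy local linkage disequilibrium, so an exhaustive
multi-locus search over all markers is both redundant and intractable.  The
scan therefore proceeds in two steps:

1. Each chromosome is parsed left-to-right into *phylogenetically compatible
   blocks* — runs of markers in which every pair passes the four-gamete
   test, so a single gene tree could explain them without recombination.
   Within each block all one- and two-marker full (cell-means) models are
   fitted and the markers of the block's best model (minimum BIC) survive.
2. Over the union of surviving markers, every one-, two- and three-marker
   full model (plus the intercept-only null model) is fitted and the global
   minimum-BIC model is reported; its markers are the loci identified by
   the procedure.

Step 2 can alternatively search additive main-effects models (0/1/2 marker
coding, no interactions) for comparing search spaces on additive traits.
The scan is also packaged as :class:`TwoStepSelector`, an estimator-style
class with ``fit`` and trailing-underscore attributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .anova import score_subsets
from .coalsim import GenotypeMatrix, HaplotypePanel

__all__ = [
    "Block",
    "SelectionResult",
    "four_gamete_compatible",
    "genotype_four_gamete_compatible",
    "parse_blocks",
    "step1_reduce",
    "step2_select",
    "n_candidate_models",
    "TwoStepSelector",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Block:
    """A maximal run of pairwise four-gamete-compatible markers."""

    chromosome: int
    start: int  # first column index (into the panel), inclusive
    stop: int  # past-the-end column index
    markers: tuple[int, ...]  # column indices of member markers

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class SelectionResult:
    """Outcome of the two-step scan."""

    reduced_marker_set: tuple[int, ...]
    best_model: tuple[int, ...]  # empty tuple = intercept-only null model
    best_bic: float
    block_winners: dict[int, tuple[int, ...]] = field(default_factory=dict)
    n_step2_candidates: int = 0


def four_gamete_compatible(col_x: np.ndarray, col_y: np.ndarray) -> bool:
    """True iff at most 3 of the 4 gametic types {00, 01, 10, 11} occur.

    Under infinite sites, two markers mutated on one genealogy can show at
    most three haplotypes; all four prove a recombination between them.
    """
    codes = 2 * np.asarray(col_x, dtype=np.int8) + np.asarray(col_y, dtype=np.int8)
    return np.unique(codes).size < 4


def genotype_four_gamete_compatible(g_x: np.ndarray, g_y: np.ndarray) -> bool:
    """Conservative four-gamete test on unphased 0/1/2 genotypes.

    A gamete is *certain* only when it can be read off without phase: both
    loci homozygous give one gamete; one homozygous and one heterozygous
    give two; double heterozygotes are ambiguous and contribute nothing.
    The pair is declared incompatible only when all four gametes are
    certain, so phase ambiguity never splits a truly compatible pair.
    """
    gx = np.asarray(g_x, dtype=np.int8)
    gy = np.asarray(g_y, dtype=np.int8)
    seen = np.zeros(4, dtype=bool)
    hom_x, hom_y = gx != 1, gy != 1
    both = hom_x & hom_y
    if both.any():
        seen[(gx[both] & 2) + (gy[both] >> 1)] = True
    mx = hom_x & ~hom_y  # x homozygous, y heterozygous -> both y alleles
    if mx.any():
        seen[(gx[mx] & 2)] = True
        seen[(gx[mx] & 2) + 1] = True
    my = ~hom_x & hom_y
    if my.any():
        seen[(gy[my] >> 1)] = True
        seen[2 + (gy[my] >> 1)] = True
    return not seen.all()


def _incompatible_any(H: np.ndarray, block_cols: list[int], cand: int) -> bool:
    """Vectorized four-gamete check of one candidate against all block members."""
    X = H[:, block_cols].astype(np.int8)
    y = H[:, cand].astype(np.int8)
    codes = 2 * X + y[:, None]
    all_four = np.ones(X.shape[1], dtype=bool)
    for c in range(4):
        all_four &= (codes == c).any(axis=0)
        if not all_four.any():
            return False
    return bool(all_four.any())


def parse_blocks(panel: HaplotypePanel, chromosome: int | None = None) -> list[Block]:
    """Greedy left-to-right partition of each chromosome into compatible blocks.

    The current block is extended while the incoming marker is compatible
    with *every* marker already in the block; otherwise a new block starts
    at that marker.  Blocks tile each chromosome without overlap.
    """
    H = panel.haplotypes
    chroms = (
        [chromosome] if chromosome is not None else sorted(set(panel.marker_chrom.tolist()))
    )
    blocks: list[Block] = []
    for chrom in chroms:
        cols = np.flatnonzero(panel.marker_chrom == chrom)
        cols = cols[np.argsort(panel.marker_pos[cols])]
        if cols.size == 0:
            continue
        current: list[int] = [int(cols[0])]
        for c in cols[1:]:
            c = int(c)
            if _incompatible_any(H, current, c):
                blocks.append(
                    Block(chrom, current[0], current[-1] + 1, tuple(current))
                )
                current = [c]
            else:
                current.append(c)
        blocks.append(Block(chrom, current[0], current[-1] + 1, tuple(current)))
    return blocks


def _fittable_mask(G: np.ndarray) -> np.ndarray:
    """Markers with at least two observed genotype classes."""
    return (G != G[0, :]).any(axis=0)


def _pick_best(
    subsets: list[tuple[int, ...]], bics: np.ndarray
) -> tuple[tuple[int, ...], float]:
    """Minimum-BIC candidate; ties broken by fewer markers, then marker order."""
    order = sorted(
        range(len(subsets)), key=lambda i: (bics[i], len(subsets[i]), subsets[i])
    )
    best = order[0]
    return subsets[best], float(bics[best])


def _score_mixed_sizes(
    G: np.ndarray, y: np.ndarray, subsets: list[tuple[int, ...]]
) -> np.ndarray:
    """BIC for candidate subsets of mixed sizes (cell-means models)."""
    bics = np.empty(len(subsets))
    by_size: dict[int, list[int]] = {}
    for i, s in enumerate(subsets):
        by_size.setdefault(len(s), []).append(i)
    for size, idx in by_size.items():
        res = score_subsets(G, y, [subsets[i] for i in idx])
        bics[idx] = res["bic"]
    return bics


def _score_main_effects(
    G: np.ndarray, y: np.ndarray, subsets: list[tuple[int, ...]]
) -> np.ndarray:
    """BIC for additive main-effects models (intercept + 0/1/2 codings)."""
    n = y.shape[0]
    bics = np.empty(len(subsets))
    logn = np.log(n)
    ones = np.ones((n, 1))
    for i, s in enumerate(subsets):
        X = np.hstack([ones, G[:, list(s)].astype(float)])
        coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(res[0]) if res.size else float(((y - X @ coef) ** 2).sum())
        if rss <= 1e-12:
            bics[i] = -np.inf
        else:
            bics[i] = n * np.log(rss / n) + (rank + 1) * logn
    return bics


def step1_reduce(
    panel: HaplotypePanel,
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: np.ndarray,
    blocks: list[Block] | None = None,
) -> tuple[tuple[int, ...], dict[int, tuple[int, ...]]]:
    """Block-wise reduction: keep the markers of each block's best model.

    Within every block all one- and two-marker full models over the block's
    fittable markers are scored by BIC; the winning model's markers join the
    reduced set.  Blocks with no fittable marker contribute nothing.
    Returns the sorted reduced marker set and the per-block winners.
    """
    G = genotypes.genotypes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    y = np.asarray(phenotype, dtype=float)
    if blocks is None:
        blocks = parse_blocks(panel)
    fittable = _fittable_mask(G)
    reduced: set[int] = set()
    winners: dict[int, tuple[int, ...]] = {}
    for bi, block in enumerate(blocks):
        ms = [m for m in block.markers if fittable[m]]
        if not ms:
            logger.info("block %d (chrom %d) has no fittable markers", bi, block.chromosome)
            continue
        cands: list[tuple[int, ...]] = [(m,) for m in ms]
        cands += list(combinations(ms, 2))
        bics = _score_mixed_sizes(G, y, cands)
        best, _ = _pick_best(cands, bics)
        winners[bi] = best
        reduced.update(best)
    return tuple(sorted(reduced)), winners


def n_candidate_models(n_markers: int, max_size: int = 3) -> int:
    """Number of 1..max_size-marker models constructible from n markers."""
    from math import comb

    return sum(comb(n_markers, k) for k in range(1, max_size + 1))


def step2_select(
    reduced: tuple[int, ...],
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: np.ndarray,
    search_space: str = "full",
    max_model_size: int = 3,
) -> SelectionResult:
    """Exhaustive BIC search over all 1-, 2- and 3-marker models.

    The intercept-only null model competes as well (zero loci can win).
    ``search_space='full'`` fits cell-means models (main effects and all
    interactions jointly); ``'main_effects'`` fits additive-coding
    regressions without interactions.
    """
    if search_space not in ("full", "main_effects"):
        raise ValueError("search_space must be 'full' or 'main_effects'")
    if not reduced:
        raise ValueError("reduced marker set is empty")
    G = genotypes.genotypes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]

    markers = sorted(reduced)
    cands: list[tuple[int, ...]] = [()]
    for k in range(1, max_model_size + 1):
        cands += list(combinations(markers, k))
    bics = np.empty(len(cands))
    tss = float(((y - y.mean()) ** 2).sum())
    bics[0] = n * np.log(tss / n) + 2 * np.log(n)  # null: mean + error variance
    if search_space == "full":
        bics[1:] = _score_mixed_sizes(G, y, cands[1:])
    else:
        bics[1:] = _score_main_effects(G, y, cands[1:])
    best, best_bic = _pick_best(cands, bics)
    return SelectionResult(
        reduced_marker_set=tuple(markers),
        best_model=best,
        best_bic=best_bic,
        n_step2_candidates=len(cands),
    )


class TwoStepSelector:
    """Estimator-style interface to the two-step scan.

    Parameters
    ----------
    search_space : 'full' or 'main_effects'
        Model family used in the exhaustive step-2 search.
    max_model_size : int
        Largest marker subset considered in step 2 (default 3).

    After ``fit(panel, y)`` the fitted attributes are ``blocks_``,
    ``reduced_markers_``, ``selected_markers_`` (empty tuple when the null
    model wins), ``best_bic_`` and ``result_``.
    """

    def __init__(self, search_space: str = "full", max_model_size: int = 3):
        self.search_space = search_space
        self.max_model_size = max_model_size

    def get_params(self, deep: bool = True) -> dict:
        return {"search_space": self.search_space, "max_model_size": self.max_model_size}

    def set_params(self, **params) -> "TwoStepSelector":
        for k, v in params.items():
            if k not in ("search_space", "max_model_size"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: HaplotypePanel, y: np.ndarray, genotypes: GenotypeMatrix | None = None):
        """Run both steps on a haplotype panel and phenotype vector.

        Blocks are parsed on haplotypes; models are fitted on the diploid
        genotypes (assembled from the panel when not supplied).
        """
        from .coalsim import assemble_diploids

        if not isinstance(X, HaplotypePanel):
            raise TypeError("X must be a HaplotypePanel (haplotypes delimit blocks)")
        if genotypes is None:
            genotypes = assemble_diploids(X)
        y = np.asarray(y, dtype=float)
        self.blocks_ = parse_blocks(X)
        reduced, winners = step1_reduce(X, genotypes, y, blocks=self.blocks_)
        result = step2_select(
            reduced, genotypes, y,
            search_space=self.search_space,
            max_model_size=self.max_model_size,
        )
        result.block_winners = winners
        self.result_ = result
        self.reduced_markers_ = result.reduced_marker_set
        self.selected_markers_ = result.best_model
        self.best_bic_ = result.best_bic
        return self
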