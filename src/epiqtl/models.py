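"""Two-locus genetic models as constrained cell-means tables.

A two-locus diploid system defines a 3x3 Punnett square of genotypic means
``theta[i, j]``, with row index i = count of the minor ``a`` allele at locus A
(0 = AA, 1 = Aa, 2 = aa) and column index j the same for locus B.  The
additive model and five patterns of molecular epistasis are encoded as
equality constraints among the nine cell means: biologically, a masking
genotype (e.g. the ``bb`` homozygote under recessive epistasis) forces all
cells it covers to share one value.

All canonical tables are centered (the unweighted mean of the nine cells is
zero) and scaled so that the distance between the largest and smallest
genotypic mean equals a fixed phenotypic range (default 1.6, in units of the
residual standard deviation).  Holding the range fixed across models makes
power comparisons between additive and epistatic architectures meaningful:
the effect size is the same, only its arrangement over genotypes differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PATTERN_CODES",
    "EpistasisPattern",
    "GenotypeMeansTable",
    "GenotypeFrequencies",
    "get_pattern",
    "make_pattern_table",
    "check_pattern_constraints",
    "marginal_effects",
    "expected_r2",
]

PATTERN_CODES = ("a", "b", "c", "d", "e", "f")

#: default phenotypic range (max - min genotypic mean) in residual-SD units
DEFAULT_RANGE = 1.6

#: tolerance for centering / equality-constraint checks, phenotype units
ATOL = 1e-9

# cell-index groups that must share one mean value, per pattern.
# a: additive, unconstrained beyond additivity of the base.
# b: bb column masks the A locus (recessive epistasis).
# c: b plus dominance of A (AA == Aa) in the non-masked columns.
# d: both aa row and bb column mask the other locus; the two groups share
#    the (2, 2) corner and therefore merge into a single 5-cell group.
# e: two distinct values only: the 5-cell mask union vs the remaining 4 cells.
# f: additive-by-additive, theta[i, j] = delta * u_i * u_j with u = (1, 0, -1);
#    handled multiplicatively rather than by equality groups.
_GROUPS: dict[str, list[list[tuple[int, int]]]] = {
    "a": [],
    "b": [[(0, 2), (1, 2), (2, 2)]],
    "c": [[(0, 2), (1, 2), (2, 2)], [(0, 0), (1, 0)], [(0, 1), (1, 1)]],
    "d": [[(2, 0), (2, 1), (2, 2)], [(0, 2), (1, 2), (2, 2)]],
    "e": [
        [(2, 0), (2, 1), (2, 2), (0, 2), (1, 2)],
        [(0, 0), (0, 1), (1, 0), (1, 1)],
    ],
    "f": [],
}

_U = np.array([1.0, 0.0, -1.0])  # additive scores per genotype class


@dataclass(frozen=True)
class EpistasisPattern:
    """One of the six two-locus model codes and its equality constraints."""

    code: str
    constraint_set: tuple[tuple[tuple[int, int], ...], ...] = ()

    def __post_init__(self) -> None:
        if self.code not in PATTERN_CODES:
            raise ValueError(
                f"unknown pattern code {self.code!r}; expected one of {PATTERN_CODES}"
            )

    @property
    def is_additive_by_additive(self) -> bool:
        return self.code == "f"


def get_pattern(code: str) -> EpistasisPattern:
    """Return the :class:`EpistasisPattern` for a model code ``a``–``f``."""
    if code not in _GROUPS:
        raise ValueError(
            f"unknown pattern code {code!r}; expected one of {PATTERN_CODES}"
        )
    groups = tuple(tuple(g) for g in _merge_groups(_GROUPS[code]))
    return EpistasisPattern(code=code, constraint_set=groups)


def _merge_groups(groups: list[list[tuple[int, int]]]) -> list[list[tuple[int, int]]]:
    """Merge equality groups sharing a cell (equality is transitive)."""
    merged: list[set[tuple[int, int]]] = []
    for g in groups:
        g = set(g)
        overlapping = [m for m in merged if m & g]
        for m in overlapping:
            g |= m
            merged.remove(m)
        merged.append(g)
    return [sorted(m) for m in merged]


@dataclass(frozen=True)
class GenotypeMeansTable:
    """Centered 3x3 table of genotypic means for a two-locus model."""

    theta: np.ndarray
    pattern: EpistasisPattern
    range_target: float = DEFAULT_RANGE

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (3, 3):
            raise ValueError("theta must be a 3x3 array of genotypic means")
        object.__setattr__(self, "theta", theta)

    @property
    def range(self) -> float:
        return float(self.theta.max() - self.theta.min())

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern.code,
            "range": self.range_target,
            "theta": [[float(v) for v in row] for row in self.theta],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypeMeansTable":
        pattern = get_pattern(d["pattern"])
        rng_target = float(d.get("range", DEFAULT_RANGE))
        if "theta" in d and d["theta"] is not None:
            return cls(np.asarray(d["theta"], float), pattern, rng_target)
        return make_pattern_table(pattern, rng_target)


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Genotype-class frequencies at two independent loci.

    Entries are ordered by minor-allele count: (AA, Aa, aa) and (BB, Bb, bb).
    The joint frequency of cell (i, j) is the product ``locus_a[i] *
    locus_b[j]`` because the loci are unlinked.
    """

    locus_a: np.ndarray
    locus_b: np.ndarray

    def __post_init__(self) -> None:
        for name in ("locus_a", "locus_b"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,):
                raise ValueError(f"{name} must have 3 genotype-class entries")
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
            object.__setattr__(self, name, p)

    @classmethod
    def uniform(cls) -> "GenotypeFrequencies":
        w = np.full(3, 1.0 / 3.0)
        return cls(w, w.copy())

    @classmethod
    def from_minor_allele_freqs(cls, maf_a: float, maf_b: float) -> "GenotypeFrequencies":
        """Hardy–Weinberg genotype frequencies from per-locus minor-allele freqs."""

        def hw(m: float) -> np.ndarray:
            if not 0.0 <= m <= 0.5:
                raise ValueError("minor allele frequency must lie in [0, 0.5]")
            return np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2])

        return cls(hw(maf_a), hw(maf_b))

    def joint(self) -> np.ndarray:
        return np.outer(self.locus_a, self.locus_b)


def _additive_base() -> np.ndarray:
    # theta_ij = a(1 - i) + a(1 - j) with unit per-locus effect a = 1
    return np.add.outer(_U, _U)


def make_pattern_table(
    pattern: EpistasisPattern | str, range_target: float = DEFAULT_RANGE
) -> GenotypeMeansTable:
    """Construct the canonical cell-means table for a model pattern.

    Patterns ``a``–``e`` start from the additive base ``theta_ij =
    (1 - i) + (1 - j)``; each equality group is replaced by the unweighted
    mean of the base values it merges, then the table is recentered to sum
    zero and rescaled so ``max - min == range_target``.  Pattern ``f`` is the
    additive-by-additive surface ``delta * u_i * u_j`` with ``delta``
    chosen to hit the range.
    """
    if isinstance(pattern, str):
        pattern = get_pattern(pattern)
    if not range_target > 0:
        raise ValueError("range_target must be positive")

    if pattern.is_additive_by_additive:
        delta = range_target / 2.0
        theta = delta * np.outer(_U, _U)
        return GenotypeMeansTable(theta, pattern, range_target)

    theta = _additive_base()
    for group in pattern.constraint_set:
        idx = tuple(np.array(group).T)
        theta[idx] = theta[idx].mean()
    theta = theta - theta.mean()
    theta = theta * (range_target / (theta.max() - theta.min()))
    return GenotypeMeansTable(theta, pattern, range_target)


def check_pattern_constraints(table: GenotypeMeansTable, atol: float = ATOL) -> bool:
    """True iff ``table.theta`` satisfies its pattern's equality constraints."""
    theta = table.theta
    if table.pattern.is_additive_by_additive:
        expected = theta[0, 0] * np.outer(_U, _U)
        return bool(np.allclose(theta, expected, rtol=0.0, atol=atol))
    for group in table.pattern.constraint_set:
        idx = tuple(np.array(group).T)
        vals = theta[idx]
        if np.abs(vals - vals[0]).max() > atol:
            return False
    return True


def marginal_effects(
    table: GenotypeMeansTable, freqs: GenotypeFrequencies
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted marginal means of the rows (A) and columns (B).

    ``row_means[i] = sum_j q_j * theta[i, j]`` with ``q`` the locus-B
    genotype frequencies, and symmetrically for columns.  With uniform
    class weights these are the unweighted margins of the Punnett square.
    """
    row_means = table.theta @ freqs.locus_b
    col_means = freqs.locus_a @ table.theta
    return row_means, col_means


def expected_r2(
    table: GenotypeMeansTable, freqs: GenotypeFrequencies, error_sd: float = 1.0
) -> float:
    """Expected proportion of phenotypic variance explained by the QTL pair.

    Var_G = sum_ij p_i q_j (theta_ij - theta_bar)^2 with theta_bar the
    frequency-weighted mean; returns Var_G / (Var_G + error_sd^2).
    """
    if not error_sd > 0:
        raise ValueError("error_sd must be positive")
    w = freqs.joint()
    mean = float((w * table.theta).sum())
    var_g = float((w * (table.theta - mean) ** 2).sum())
    return var_g / (var_g + error_sd**2)
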