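"""Two-way fixed-effects ANOVA machinery: effects, ESS, power, fits, BIC.

The cell-means model ``y = theta[g_A, g_B] + e`` is equivalent to the factor
effects model ``y = mu + alpha_i + beta_j + gamma_ij + e`` under sum-to-zero
constraints.  For a balanced 3x3 design the expected sums of squares of the
A, B and interaction sources are simple quadratic forms in the effects, and
each source's F statistic follows a noncentral F whose noncentrality is the
source ESS divided by the error variance — which is what makes analytic
power statements about epistatic versus additive architectures possible.

Fitting is done in the "full model" sense used in multi-locus genome scans:
one mean per *observed* multi-locus genotype class, so main effects and all
interactions are absorbed jointly and empty cells reduce the model degrees
of freedom automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import GenotypeMeansTable

__all__ = [
    "FactorEffects",
    "EssTable",
    "ModelFit",
    "UnfittableModelError",
    "decompose_effects",
    "expected_ss",
    "analytic_power",
    "fit_full_model",
    "bic_score",
    "score_subsets",
]

#: rss at or below this (relative to tss) is treated as a perfect fit
_RSS_FLOOR = 1e-12


class UnfittableModelError(ValueError):
    """Raised when a marker set has fewer than 2 observed genotype classes."""


@dataclass(frozen=True)
class FactorEffects:
    """Sum-to-zero factor-effects parameterization of a 3x3 means table."""

    mu: float
    alpha: np.ndarray  # row (locus A) main effects
    beta: np.ndarray  # column (locus B) main effects
    gamma: np.ndarray  # 3x3 interaction (epistasis) effects

    def reconstruct(self) -> np.ndarray:
        """theta_ij = mu + alpha_i + beta_j + gamma_ij (exact identity)."""
        return self.mu + np.add.outer(self.alpha, self.beta) + self.gamma


@dataclass(frozen=True)
class EssTable:
    """Expected sums of squares for the balanced two-way design.

    The error-variance term common to all sources is omitted; only the
    systematic parts enter power comparisons.
    """

    ess_a: float
    ess_b: float
    ess_epistasis: float
    df_a: int = 2
    df_b: int = 2
    df_epistasis: int = 4

    @property
    def total_ess(self) -> float:
        return self.ess_a + self.ess_b + self.ess_epistasis


@dataclass(frozen=True)
class ModelFit:
    """One fitted full (cell-means) model for a marker set."""

    markers: tuple[int, ...]
    n: int
    n_classes: int
    rss: float
    tss: float
    f_stat: float
    p_value: float
    r2: float
    bic: float

    @property
    def df_model(self) -> int:
        return self.n_classes - 1

    @property
    def df_error(self) -> int:
        return self.n - self.n_classes

    def to_row(self) -> dict:
        """Flat record for TSV serialization (markers joined by ';')."""
        return {
            "markers": ";".join(str(m) for m in self.markers),
            "n": self.n,
            "n_classes": self.n_classes,
            "rss": self.rss,
            "tss": self.tss,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "r2": self.r2,
            "bic": self.bic,
        }


def decompose_effects(table: GenotypeMeansTable | np.ndarray) -> FactorEffects:
    """Unweighted factor-effects decomposition of a cell-means table."""
    theta = table.theta if isinstance(table, GenotypeMeansTable) else np.asarray(table, float)
    mu = float(theta.mean())
    alpha = theta.mean(axis=1) - mu
    beta = theta.mean(axis=0) - mu
    gamma = theta - mu - np.add.outer(alpha, beta)
    return FactorEffects(mu=mu, alpha=alpha, beta=beta, gamma=gamma)


def expected_ss(effects: FactorEffects, n_per_cell: int) -> EssTable:
    """Expected sums of squares for a balanced design with n_per_cell per cell.

    ESS_A = 3 n_c * sum_i alpha_i^2, ESS_B = 3 n_c * sum_j beta_j^2, and
    ESS_AB = n_c * sum_ij gamma_ij^2.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1 (balanced design)")
    return EssTable(
        ess_a=float(3 * n_per_cell * (effects.alpha**2).sum()),
        ess_b=float(3 * n_per_cell * (effects.beta**2).sum()),
        ess_epistasis=float(n_per_cell * (effects.gamma**2).sum()),
    )


def analytic_power(
    ess: float, df_num: int, df_err: int, error_var: float = 1.0, alpha_level: float = 0.05
) -> float:
    """Power of the F test with noncentrality lambda = ESS / error variance.

    Returns P(F' > F_crit) where F' ~ noncentral F(df_num, df_err, lambda)
    and F_crit is the central-F upper-alpha quantile.  Power is monotone
    increasing in the ESS, which is the analytic backbone of the claim that
    architectures with larger total ESS are easier to detect.
    """
    if df_num < 1 or df_err < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not error_var > 0:
        raise ValueError("error_var must be positive")
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must lie in (0, 1)")
    lam = ess / error_var
    fcrit = stats.f.isf(alpha_level, df_num, df_err)
    if lam == 0:
        return float(alpha_level)
    return float(stats.ncf.sf(fcrit, df_num, df_err, lam))


def _class_labels(genotypes: np.ndarray) -> tuple[np.ndarray, int]:
    """Integer class labels for the observed multi-locus genotype rows."""
    G = np.asarray(genotypes)
    if G.ndim == 1:
        G = G[:, None]
    _, labels = np.unique(G, axis=0, return_inverse=True)
    return labels.ravel(), int(labels.max()) + 1


def fit_full_model(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    markers: tuple[int, ...] | None = None,
) -> ModelFit:
    """Fit one mean per observed multi-locus genotype class.

    ``genotypes`` is an (n, k) array of 0/1/2 codes restricted to the marker
    set of interest; ``markers`` is an optional tuple of identifiers carried
    through to the result.  F = [(TSS - RSS)/(g - 1)] / [RSS/(n - g)] with g
    the number of observed classes; a perfect fit (RSS = 0) is capped at
    p = 0 with an infinite F.
    """
    y = np.asarray(phenotype, dtype=float)
    G = np.asarray(genotypes)
    if G.ndim == 1:
        G = G[:, None]
    n = y.shape[0]
    if G.shape[0] != n:
        raise ValueError("genotypes and phenotype have mismatched lengths")
    labels, g = _class_labels(G)
    if g < 2:
        raise UnfittableModelError(
            "marker set is monomorphic (single genotype class); cannot fit"
        )
    if n <= g:
        raise ValueError(f"need n > number of classes (n={n}, g={g})")

    counts = np.bincount(labels, minlength=g)
    sums = np.bincount(labels, weights=y, minlength=g)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((y**2).sum() - (sums**2 / counts).sum())
    rss = max(rss, 0.0)

    df_model, df_error = g - 1, n - g
    if rss <= _RSS_FLOOR * max(tss, 1.0):
        rss, f_stat, p_value, r2 = 0.0, np.inf, 0.0, 1.0
    else:
        f_stat = (tss - rss) / df_model / (rss / df_error)
        p_value = float(stats.f.sf(f_stat, df_model, df_error))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
    bic = bic_score(rss, n, g)
    if markers is None:
        markers = tuple(range(G.shape[1]))
    return ModelFit(
        markers=tuple(markers),
        n=n,
        n_classes=g,
        rss=rss,
        tss=tss,
        f_stat=float(f_stat),
        p_value=p_value,
        r2=float(r2),
        bic=bic,
    )


def bic_score(rss: float, n: int, n_mean_params: int) -> float:
    """BIC = n ln(RSS/n) + (g + 1) ln(n), counting the error variance.

    Lower is better; scores are comparable across models fit to the same n
    observations.  A zero RSS returns -inf (the model wins outright).
    """
    if rss <= 0:
        warnings.warn("RSS <= 0: returning -inf BIC sentinel", stacklevel=2)
        return -np.inf
    return float(n * np.log(rss / n) + (n_mean_params + 1) * np.log(n))


# ---------------------------------------------------------------------------
# batch scoring of many candidate marker subsets (exhaustive scans)
# ---------------------------------------------------------------------------

def score_subsets(
    G: np.ndarray,
    y: np.ndarray,
    subsets: list[tuple[int, ...]],
    columns: np.ndarray | None = None,
    chunk_size: int = 4096,
) -> dict[str, np.ndarray]:
    """Score many full (cell-means) models at once.

    ``subsets`` are tuples of marker ids; ``columns`` maps marker id to a
    column of ``G`` (identity when omitted).  Subsets must all have the same
    size.  Returns arrays ``rss``, ``n_classes``, ``bic``, ``f_stat``,
    ``p_value`` aligned with ``subsets``.  Each model's genotype classes are
    encoded in base 3 (entries must be 0/1/2), counts and sums accumulated
    with bincount, which keeps exhaustive searches over 10^5-10^6 candidate
    models tractable.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if not subsets:
        empty = np.empty(0)
        return {k: empty.copy() for k in ("rss", "n_classes", "bic", "f_stat", "p_value")}
    k = len(subsets[0])
    if any(len(s) != k for s in subsets):
        raise ValueError("all subsets in one batch must have the same size")
    if columns is None:
        cols = np.asarray(subsets, dtype=np.intp)
    else:
        columns = np.asarray(columns)
        cols = columns[np.asarray(subsets, dtype=np.intp)]

    Gu = np.ascontiguousarray(G, dtype=np.int64)
    yy = float((y**2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    n_cells = 3**k
    powers = 3 ** np.arange(k - 1, -1, -1, dtype=np.int64)

    m = len(subsets)
    rss = np.empty(m)
    g_out = np.empty(m, dtype=np.int64)
    for lo in range(0, m, chunk_size):
        hi = min(lo + chunk_size, m)
        b = hi - lo
        # codes: (b, n) base-3 multi-locus genotype class per individual
        codes = np.zeros((b, n), dtype=np.int64)
        for pos in range(k):
            codes += Gu[:, cols[lo:hi, pos]].T * powers[pos]
        flat = codes + (np.arange(b, dtype=np.int64) * n_cells)[:, None]
        counts = np.bincount(flat.ravel(), minlength=b * n_cells).reshape(b, n_cells)
        sums = np.bincount(
            flat.ravel(),
            weights=np.broadcast_to(y, (b, n)).ravel(),
            minlength=b * n_cells,
        ).reshape(b, n_cells)
        occupied = counts > 0
        g_out[lo:hi] = occupied.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            explained = np.where(occupied, sums**2 / np.where(occupied, counts, 1), 0.0)
        rss[lo:hi] = np.maximum(yy - explained.sum(axis=1), 0.0)

    df_model = g_out - 1
    df_error = n - g_out
    perfect = rss <= _RSS_FLOOR * max(tss, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = np.where(
            perfect | (df_model < 1) | (df_error < 1),
            np.inf,
            (tss - rss) / np.maximum(df_model, 1) / (rss / np.maximum(df_error, 1)),
        )
        p_value = np.where(
            np.isinf(f_stat), 0.0, stats.f.sf(f_stat, df_model, df_error)
        )
        bic = np.where(
            perfect, -np.inf, n * np.log(np.maximum(rss, _RSS_FLOOR) / n) + (g_out + 1) * np.log(n)
        )
    return {
        "rss": rss,
        "n_classes": g_out,
        "bic": bic,
        "f_stat": f_stat,
        "p_value": p_value,
    }
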