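"""Replicated simulation experiments: power, model selection and type-I error.

One *setting* is a (genetic model, sample size, MAF window) combination; a
study runs ``n_replicates`` independent population samples per setting and
summarizes:

* power — the proportion of replicates in which the full-model F test of
  the true two-QTL model rejects at ``alpha_level``;
* selection accuracy — the proportion in which the two-step BIC scan picks
  exactly the two specified QTLs, plus the distributions of the number of
  selected loci (0-3) and of correctly identified QTLs (0-2);
* false discovery rate — the average per-replicate proportion of selected
  loci that are not specified QTLs (zero-selection replicates contribute 0);
* type-I error — the proportion of all 1-/2-/3-marker full models over 30
  markers unlinked to the trait whose F test rejects.

Within a replicate index, genealogies are held constant across settings
(only mutations, allele-frequency conditioning and phenotype noise vary),
which removes unwanted genealogical variance from between-setting
comparisons.  Only exact QTL marker hits count as correct, so reported
detection rates are a lower bound (a linked neighbor of a QTL counts as a
false discovery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .anova import ModelFit, fit_full_model, score_subsets
from .coalsim import GenotypeMatrix, SimConfig, assemble_diploids, simulate_panel
from .models import make_pattern_table
from .pheno import PhenotypeConfig, generate_phenotypes
from .search import SelectionResult, TwoStepSelector

__all__ = [
    "ExperimentConfig",
    "ReplicateRecord",
    "ExperimentSummary",
    "run_replicate",
    "estimate_power",
    "selection_metrics",
    "type1_scan",
    "run_power_study",
    "run_type1_study",
    "run_experiment",
    "summary_frame",
]

logger = logging.getLogger(__name__)

#: named minor-allele-frequency windows used throughout the study
MAF_WINDOWS = {"low": (0.01, 0.10), "high": (0.20, 0.30)}


@dataclass(frozen=True)
class ExperimentConfig:
    sample_sizes: tuple[int, ...] = (100, 500, 1000)
    maf_windows: tuple[str, ...] = ("low", "high")
    patterns: tuple[str, ...] = ("a", "b", "c", "d", "e", "f")
    n_replicates: int = 50
    alpha_level: float = 0.05
    range_target: float = 1.6
    error_sd: float = 1.0
    base_seed: int = 0
    run_scan: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for w in self.maf_windows:
            if w not in MAF_WINDOWS:
                raise ValueError(f"unknown MAF window {w!r}; use {list(MAF_WINDOWS)}")


@dataclass
class ReplicateRecord:
    pattern: str
    n: int
    maf_window: str
    replicate: int
    true_fit: ModelFit
    true_qtls: tuple[int, ...]
    selection: SelectionResult | None = None
    n_resamples: int = 0

    @property
    def n_selected(self) -> int:
        return 0 if self.selection is None else len(self.selection.best_model)

    @property
    def n_correct(self) -> int:
        if self.selection is None:
            return 0
        return len(set(self.selection.best_model) & set(self.true_qtls))


@dataclass
class ExperimentSummary:
    pattern: str
    n: int
    maf_window: str
    n_replicates: int
    power: float
    mean_r2: float
    accuracy: float | None = None
    loci_count_dist: dict[int, float] | None = None
    correct_count_dist: dict[int, float] | None = None
    fdr: float | None = None


def _seed(base: int, *key: int) -> int:
    """Deterministic 31-bit sub-seed for a labelled stream."""
    state = np.random.SeedSequence(entropy=base, spawn_key=tuple(key)).generate_state(1)
    return int(state[0] % (2**31 - 1))


def _sim_config(
    n: int, maf_window: str, rep: int, base_seed: int, **genome
) -> SimConfig:
    # genealogy seed depends on (n, replicate) only: constant across patterns
    # and MAF windows; mutation seed additionally keys on the window.
    wid = sorted(MAF_WINDOWS).index(maf_window)
    return SimConfig(
        n_individuals=n,
        maf_window=MAF_WINDOWS[maf_window],
        genealogy_seed=_seed(base_seed, 1, n, rep),
        mutation_seed=_seed(base_seed, 2, n, rep, wid),
        **genome,
    )


def run_replicate(
    pattern: str,
    n: int,
    maf_window: str,
    replicate: int,
    base_seed: int = 0,
    range_target: float = 1.6,
    error_sd: float = 1.0,
    run_scan: bool = False,
    search_space: str = "full",
    **genome,
) -> ReplicateRecord:
    """Simulate one population sample and analyze it.

    When ``run_scan`` is false only the two QTL columns are generated (the
    true-model fit needs nothing else), which keeps pure power studies
    cheap; the full 500-marker panel is generated for scans.
    """
    config = _sim_config(n, maf_window, replicate, base_seed, **genome)
    markers = None if run_scan else list(config.qtl_markers)
    panel = simulate_panel(config, markers=markers)
    genotypes = assemble_diploids(panel)

    table = make_pattern_table(pattern, range_target)
    qtl_a, qtl_b = genotypes.qtl_cols
    pheno_cfg = PhenotypeConfig(
        table=table,
        qtl_a=qtl_a,
        qtl_b=qtl_b,
        error_sd=error_sd,
        seed=_seed(base_seed, 3, n, replicate, sorted(MAF_WINDOWS).index(maf_window),
                   ord(pattern)),
    )
    y = generate_phenotypes(genotypes, pheno_cfg)
    true_fit = fit_full_model(
        genotypes.genotypes[:, [qtl_a, qtl_b]], y, markers=(qtl_a, qtl_b)
    )

    selection = None
    if run_scan:
        selector = TwoStepSelector(search_space=search_space)
        selector.fit(panel, y, genotypes=genotypes)
        selection = selector.result_
    return ReplicateRecord(
        pattern=pattern,
        n=n,
        maf_window=maf_window,
        replicate=replicate,
        true_fit=true_fit,
        true_qtls=(qtl_a, qtl_b),
        selection=selection,
        n_resamples=panel.n_resamples,
    )


def estimate_power(records: list[ReplicateRecord], alpha_level: float = 0.05) -> float:
    """Proportion of replicates whose true-model F test has p < alpha."""
    if not records:
        raise ValueError("need at least one replicate record")
    return float(np.mean([r.true_fit.p_value < alpha_level for r in records]))


def selection_metrics(records: list[ReplicateRecord]) -> dict:
    """Accuracy, loci-count and correct-loci distributions, and FDR.

    Accuracy counts only replicates whose best model is exactly the true
    QTL pair.  FDR is the replicate-average of (selected non-QTL loci /
    selected loci), with zero-selection replicates contributing 0.
    """
    recs = [r for r in records if r.selection is not None]
    if not recs:
        raise ValueError("no records carry a selection result")
    m = len(recs)
    accuracy = np.mean(
        [set(r.selection.best_model) == set(r.true_qtls) for r in recs]
    )
    loci_counts = np.array([r.n_selected for r in recs])
    correct_counts = np.array([r.n_correct for r in recs])
    fdr_terms = [
        (r.n_selected - r.n_correct) / r.n_selected if r.n_selected else 0.0
        for r in recs
    ]
    return {
        "n_replicates": m,
        "accuracy": float(accuracy),
        "loci_count_dist": {k: float((loci_counts == k).mean()) for k in range(4)},
        "correct_count_dist": {k: float((correct_counts == k).mean()) for k in range(3)},
        "fdr": float(np.mean(fdr_terms)),
        "n_zero_selected": int((loci_counts == 0).sum()),
    }


def _evenly_spaced(indices: np.ndarray, k: int = 10) -> np.ndarray:
    """k evenly spaced picks from an ordered index array (ends included)."""
    m = indices.size
    if m < k:
        raise ValueError(f"chromosome has {m} markers, need {k}")
    picks = np.round(np.arange(k) * (m - 1) / (k - 1)).astype(int)
    return indices[picks]


def type1_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    alpha_level: float = 0.05,
    markers_per_chromosome: int = 10,
    max_model_size: int = 3,
) -> tuple[float, int]:
    """Rejection rate of full-model F tests over markers unlinked to the trait.

    Ten evenly spaced markers are taken from each chromosome that carries
    no QTL; every 1-, 2- and 3-marker full model over those markers is
    fitted (4525 models for 30 markers).  Returns the proportion of models
    with p < alpha and the number of models fitted.  Monomorphic picks are
    replaced by the nearest fittable marker on the same chromosome.
    """
    G = genotypes.genotypes
    y = np.asarray(phenotype, dtype=float)
    qtl_chroms = {int(genotypes.marker_chrom[c]) for c in genotypes.qtl_cols}
    null_chroms = sorted(set(genotypes.marker_chrom.tolist()) - qtl_chroms)
    if not null_chroms:
        raise ValueError("no chromosome is free of QTLs")
    fittable = (G != G[0, :]).any(axis=0)

    chosen: list[int] = []
    for chrom in null_chroms:
        cols = np.flatnonzero(genotypes.marker_chrom == chrom)
        cols = cols[np.argsort(genotypes.marker_pos[cols])]
        for c in _evenly_spaced(cols, markers_per_chromosome):
            if not fittable[c]:
                options = cols[fittable[cols]]
                if options.size == 0:
                    raise ValueError(f"chromosome {chrom} is entirely monomorphic")
                repl = int(options[np.argmin(np.abs(options - c))])
                logger.info("marker %d monomorphic; using neighbor %d", c, repl)
                c = repl
            chosen.append(int(c))

    n_reject = 0
    n_models = 0
    for k in range(1, max_model_size + 1):
        subsets = list(combinations(chosen, k))
        res = score_subsets(G, y, subsets)
        n_reject += int((res["p_value"] < alpha_level).sum())
        n_models += len(subsets)
    return n_reject / n_models, n_models


def run_power_study(
    patterns: tuple[str, ...] = ("a", "b", "c", "d", "e", "f"),
    n: int = 500,
    maf_window: str = "high",
    n_replicates: int = 50,
    base_seed: int = 0,
    alpha_level: float = 0.05,
    range_target: float = 1.6,
    error_sd: float = 1.0,
    run_scan: bool = False,
    **genome,
) -> dict[str, list[ReplicateRecord]]:
    """Replicated records per pattern at one (n, MAF window) setting."""
    records: dict[str, list[ReplicateRecord]] = {p: [] for p in patterns}
    for rep in range(n_replicates):
        for pattern in patterns:
            records[pattern].append(
                run_replicate(
                    pattern, n, maf_window, rep,
                    base_seed=base_seed,
                    range_target=range_target,
                    error_sd=error_sd,
                    run_scan=run_scan,
                    **genome,
                )
            )
    return records


def run_type1_study(
    n_replicates: int = 10,
    n: int = 100,
    pattern: str = "a",
    maf_window: str = "high",
    base_seed: int = 0,
    alpha_level: float = 0.05,
    range_target: float = 1.6,
    error_sd: float = 1.0,
    **genome,
) -> list[float]:
    """Per-replicate rejection proportions over the 30 null markers.

    The trait is generated from the QTLs on their own chromosomes; the
    scanned markers sit on the chromosomes without any trait locus, so
    every fitted model is a true null despite the phenotype carrying a
    genetic signal.
    """
    proportions = []
    for rep in range(n_replicates):
        config = _sim_config(n, maf_window, rep, base_seed, **genome)
        panel = simulate_panel(config)
        genotypes = assemble_diploids(panel)
        table = make_pattern_table(pattern, range_target)
        qtl_a, qtl_b = genotypes.qtl_cols
        y = generate_phenotypes(
            genotypes,
            PhenotypeConfig(
                table=table, qtl_a=qtl_a, qtl_b=qtl_b, error_sd=error_sd,
                seed=_seed(base_seed, 3, n, rep, 0, ord(pattern)),
            ),
        )
        prop, _ = type1_scan(genotypes, y, alpha_level=alpha_level)
        proportions.append(prop)
    return proportions


def run_experiment(config: ExperimentConfig) -> list[ReplicateRecord]:
    """Run the full factorial of patterns x sample sizes x MAF windows."""
    records: list[ReplicateRecord] = []
    for n in config.sample_sizes:
        for window in config.maf_windows:
            by_pattern = run_power_study(
                patterns=config.patterns,
                n=n,
                maf_window=window,
                n_replicates=config.n_replicates,
                base_seed=config.base_seed,
                alpha_level=config.alpha_level,
                range_target=config.range_target,
                error_sd=config.error_sd,
                run_scan=config.run_scan,
            )
            for recs in by_pattern.values():
                records.extend(recs)
    return records


def summary_frame(
    records: list[ReplicateRecord], alpha_level: float = 0.05
) -> pd.DataFrame:
    """Per-setting summary table (power, mean r2, selection metrics)."""
    rows = []
    keys = sorted({(r.pattern, r.n, r.maf_window) for r in records})
    for pattern, n, window in keys:
        recs = [
            r for r in records
            if (r.pattern, r.n, r.maf_window) == (pattern, n, window)
        ]
        row = {
            "pattern": pattern,
            "n": n,
            "maf_window": window,
            "n_replicates": len(recs),
            "power": estimate_power(recs, alpha_level),
            "mean_r2": float(np.mean([r.true_fit.r2 for r in recs])),
        }
        if any(r.selection is not None for r in recs):
            row.update(
                {
                    k: v
                    for k, v in selection_metrics(recs).items()
                    if k in ("accuracy", "fdr")
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
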