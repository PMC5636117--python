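"""Permutation/subsampling test for a candidate pattern's carrier count.

The study-design test repeatedly draws ``subsample_size`` cases (without
replacement within a replicate) from the full case cohort and counts how
many carry the pattern, building the distribution of carrier counts across
replicates.  Because sampling is from the cases only, the counts are exactly
hypergeometric(N = n_cases, K = total carriers, n = subsample_size); the
test is a subsampling stability check rather than a case/control label
permutation.  A conventional label-swap null is provided separately as an
extension (:func:`label_swap_null_counts`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix
from .search import GenotypePattern


@dataclass
class PermutationConfig:
    n_permutations: int = 1000
    subsample_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.subsample_size < 1:
            raise ValueError("subsample_size must be >= 1")


def carrier_mask(matrix: GenotypeMatrix,
                 pattern: GenotypePattern) -> np.ndarray:
    """Boolean per-sample carriage of the pattern (missing call = not carrier)."""
    sub = matrix.calls[:, list(pattern.snp_indices)]
    return (sub == np.array(pattern.genotype_codes, dtype=np.int8)).all(axis=1)


def permuted_carrier_counts(cases: GenotypeMatrix, pattern: GenotypePattern,
                            config: PermutationConfig) -> np.ndarray:
    """Carrier counts over ``n_permutations`` random case subsamples.

    Each replicate draws ``subsample_size`` distinct cases; reproducible
    given ``config.seed``.
    """
    n = cases.n_samples
    if config.subsample_size > n:
        raise ValueError(
            f"subsample_size {config.subsample_size} exceeds case count {n}")
    mask = carrier_mask(cases, pattern)
    rng = np.random.default_rng(config.seed)
    counts = np.empty(config.n_permutations, dtype=np.int64)
    for i in range(config.n_permutations):
        idx = rng.choice(n, size=config.subsample_size, replace=False)
        counts[i] = int(mask[idx].sum())
    return counts


def label_swap_null_counts(cases: GenotypeMatrix, controls: GenotypeMatrix,
                           pattern: GenotypePattern,
                           config: PermutationConfig) -> np.ndarray:
    """Extension: carrier counts among pseudo-cases under label permutation.

    Pools both cohorts, randomly relabels ``n_cases`` samples as cases per
    replicate, and counts pattern carriers among them — a conventional null
    for "how many case carriers would arise if labels were uninformative".
    """
    pooled = np.concatenate([carrier_mask(cases, pattern),
                             carrier_mask(controls, pattern)])
    n_cases = cases.n_samples
    rng = np.random.default_rng(config.seed)
    counts = np.empty(config.n_permutations, dtype=np.int64)
    for i in range(config.n_permutations):
        idx = rng.choice(pooled.size, size=n_cases, replace=False)
        counts[i] = int(pooled[idx].sum())
    return counts


def distribution_summary(counts: np.ndarray, observed: int) -> dict:
    """Histogram plus mean/sd and the observed count's empirical quantile.

    The quantile uses the <=-rank convention: fraction of replicates with a
    count at or below ``observed``.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    lo, hi = int(counts.min()), int(counts.max())
    bins = np.arange(lo, hi + 2)
    hist, _ = np.histogram(counts, bins=bins)
    return {
        "histogram": {int(b): int(h) for b, h in zip(bins[:-1], hist)},
        "mean": float(counts.mean()),
        "sd": float(counts.std(ddof=0)),
        "observed": int(observed),
        "quantile": float((counts <= observed).mean()),
        "n_replicates": int(counts.size),
    }
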