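"""Label-swapped ("inverse") pattern search over the healthy cohort.

The inverse analysis asks whether genotype combination patterns exclusive
to healthy individuals behave like the case-exclusive ones: controls are
treated as "patients" with prevalence ``1 - p_disease`` (99.53% for a
disease prevalence of 4.7 per mille) and the product-frequency window is
applied as absolute bounds (default 0.01 to 0.2, the same multipliers
0.01/0.2 scaled by a prevalence of ~1).  It is a thin parameterization of
the forward engine with the cohort roles swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .resampling import carrier_mask
from .search import CandidateCGCP, GenotypePattern, PrevalenceModel, \
    SearchConfig, search_cgcp, summarize_frequency_distribution


def inverse_prevalence_model(p_disease: float = 0.0047,
                             lower: float = 0.01,
                             upper: float = 0.2) -> PrevalenceModel:
    """Prevalence model for the healthy-as-patient analysis.

    Prevalence is ``1 - p_disease``; the absolute frequency window
    ``(lower, upper)`` is expressed through the model's multipliers so that
    ``lower_bound == lower`` and ``upper_bound == upper`` exactly.
    """
    p = 1.0 - p_disease
    return PrevalenceModel(p=p, lower_mult=lower / p, upper_mult=upper / p)


def make_inverse_config(r: int, p_disease: float = 0.0047,
                        min_carriers: int = 1,
                        lower: float = 0.01, upper: float = 0.2,
                        **kwargs) -> SearchConfig:
    """SearchConfig for the inverse analysis (min_carriers defaults to 1)."""
    return SearchConfig(
        r=r, min_carriers=min_carriers,
        prevalence_model=inverse_prevalence_model(p_disease, lower, upper),
        **kwargs)


def inverse_search(cases: GenotypeMatrix, controls: GenotypeMatrix,
                   config: SearchConfig) -> list[CandidateCGCP]:
    """Search for control-exclusive patterns under the inverse prevalence.

    Exactly the forward search with the cohort roles swapped: genotype
    frequencies take alpha from controls and beta from cases, exclusivity
    is enforced against the cases, and carriers are controls.
    """
    return search_cgcp(controls, cases, config)


def pooled_joint_frequency(pattern: GenotypePattern, cases: GenotypeMatrix,
                           controls: GenotypeMatrix) -> float:
    """Raw joint carriage frequency of a pattern in the pooled cohort.

    Alternative frequency reading to the per-SNP product form; carriers over
    samples with complete calls at the pattern SNPs.
    """
    masks = [carrier_mask(m, pattern) for m in (cases, controls)]
    complete = [
        (m.calls[:, list(pattern.snp_indices)] != MISSING).all(axis=1)
        for m in (cases, controls)
    ]
    n_carr = int(sum(mk.sum() for mk in masks))
    n_complete = int(sum(c.sum() for c in complete))
    if n_complete == 0:
        raise ValueError("no sample has complete calls at the pattern SNPs")
    return n_carr / n_complete


def frequency_by_r_report(
        results_by_r: dict[int, list[CandidateCGCP]]) -> pd.DataFrame:
    """Per-r summary of candidate product frequencies (mean/min/max/count)."""
    rows = []
    for r in sorted(results_by_r):
        s = summarize_frequency_distribution(results_by_r[r])
        rows.append({"r": r, "n_candidates": s.count, "mean_frequency": s.mean,
                     "min_frequency": s.min, "max_frequency": s.max})
    return pd.DataFrame(rows,
                        columns=["r", "n_candidates", "mean_frequency",
                                 "min_frequency", "max_frequency"])
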