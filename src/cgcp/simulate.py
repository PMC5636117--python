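"""Synthetic case-control genotype cohorts with planted case-only patterns.

Background genotypes are drawn independently per SNP from Hardy-Weinberg
proportions ``((1-q)^2, 2q(1-q), q^2)`` at a minor-allele frequency sampled
uniformly from ``maf_range`` — the structure the search assumes of QC-passed
genotyping data (no linkage disequilibrium, no population structure).
Requested patterns are then planted by overwriting the genotypes of
randomly chosen cases so that the pattern's prevalence-weighted product
frequency lands in a requested band, and any control coincidentally
carrying a planted tuple has one of its genotypes flipped, guaranteeing
exact case-exclusivity.  Missingness is applied last, never at a planted
carrier's pattern SNPs, so planted carriage survives.  All randomness flows
from a single seed; identical configs reproduce byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product as iter_product
from pathlib import Path

import numpy as np

from .genotype_io import (MISSING, GenotypeMatrix, SNPRecord, tally_counts)
from .search import GenotypePattern, PrevalenceModel, population_frequency

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"),
                 ("C", "G"), ("C", "T"), ("G", "T")]


class GenerationError(RuntimeError):
    """Requested cohort cannot be generated (infeasible planting)."""


@dataclass(frozen=True)
class PlantSpec:
    """One pattern to plant: r SNPs, carrier count, product-frequency band."""

    r: int
    n_carriers: int
    band: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0.0 < lo < hi <= 1.0:
            raise ValueError(f"invalid frequency band {self.band}")
        if self.r < 1 or self.n_carriers < 1:
            raise ValueError("r and n_carriers must be >= 1")


@dataclass
class SimulationConfig:
    n_snps: int = 20
    n_cases: int = 500
    n_controls: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    planted_patterns: list[PlantSpec] = field(default_factory=list)
    prevalence_model: PrevalenceModel = field(
        default_factory=lambda: PrevalenceModel(p=0.0047))
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError(f"maf_range must lie within [0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.missing_rate <= 0.1:
            raise ValueError("missing_rate must be in [0, 0.1]")
        for spec in self.planted_patterns:
            if spec.n_carriers > self.n_cases:
                raise GenerationError(
                    f"cannot plant {spec.n_carriers} carriers in "
                    f"{self.n_cases} cases")
        if sum(s.r for s in self.planted_patterns) > self.n_snps:
            raise GenerationError(
                "planted patterns need more disjoint SNPs than available")


@dataclass
class PlantedPattern:
    pattern: GenotypePattern
    rsids: tuple[str, ...]
    carrier_ids: list[str]
    product_frequency: float  # realized, post-missingness


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort: the planted patterns."""

    patterns: list[PlantedPattern]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "seed": self.seed,
            "patterns": [
                {
                    "snp_indices": list(p.pattern.snp_indices),
                    "genotype_codes": list(p.pattern.genotype_codes),
                    "rsids": list(p.rsids),
                    "carrier_ids": p.carrier_ids,
                    "product_frequency": p.product_frequency,
                }
                for p in self.patterns
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            patterns=[
                PlantedPattern(
                    pattern=GenotypePattern(tuple(d["snp_indices"]),
                                            tuple(d["genotype_codes"])),
                    rsids=tuple(d["rsids"]),
                    carrier_ids=list(d["carrier_ids"]),
                    product_frequency=d["product_frequency"],
                )
                for d in payload["patterns"]
            ],
            seed=payload["seed"],
        )


def _cohort_frequencies(calls: np.ndarray) -> np.ndarray:
    """(n_snps, 3) genotype fractions over non-missing calls per SNP."""
    out = np.empty((calls.shape[1], 3))
    for j in range(calls.shape[1]):
        col = calls[:, j]
        counts = np.array([(col == c).sum() for c in (0, 1, 2)], float)
        out[j] = counts / counts.sum()
    return out


def _tuple_products(alpha: np.ndarray, beta: np.ndarray,
                    subset: tuple[int, ...],
                    model: PrevalenceModel) -> np.ndarray:
    """Product frequency of all 3^r genotype tuples on a SNP subset."""
    F = population_frequency(alpha, beta, model)
    prod = F[subset[0]]
    for j in subset[1:]:
        prod = np.multiply.outer(prod, F[j]).ravel()
    return prod


def _carries(calls: np.ndarray, pattern: GenotypePattern) -> np.ndarray:
    sub = calls[:, list(pattern.snp_indices)]
    return (sub == np.array(pattern.genotype_codes, dtype=np.int8)).all(axis=1)


def plant_patterns(case_calls: np.ndarray, ctrl_calls: np.ndarray,
                   config: SimulationConfig,
                   rng: np.random.Generator) -> list[tuple[GenotypePattern, np.ndarray]]:
    """Plant each requested pattern in-place; returns (pattern, carrier rows).

    SNP subsets are drawn disjointly across patterns.  A genotype tuple is
    accepted when its product frequency under the forward prevalence model
    (from the current, pre-missingness frequencies) lies in the spec's band;
    controls carrying a planted tuple are repaired by flipping one genotype.
    """
    model = config.prevalence_model
    pool = list(range(case_calls.shape[1]))
    planted: list[tuple[GenotypePattern, np.ndarray]] = []

    for spec in config.planted_patterns:
        lo, hi = spec.band
        chosen = None
        for _ in range(200):  # subset proposals
            subset = tuple(sorted(rng.choice(pool, size=spec.r,
                                             replace=False).tolist()))
            alpha = _cohort_frequencies(case_calls)
            beta = _cohort_frequencies(ctrl_calls)
            prods = _tuple_products(alpha, beta, subset, model)
            ok = np.nonzero((prods > lo) & (prods < hi))[0]
            if ok.size:
                key = int(rng.choice(ok))
                codes = tuple(int(d)
                              for d in np.unravel_index(key, (3,) * spec.r))
                chosen = GenotypePattern(subset, codes)
                break
        if chosen is None:
            raise GenerationError(
                f"no genotype tuple with product frequency in {spec.band} "
                f"found for r={spec.r} after 200 subset proposals")
        for s in chosen.snp_indices:
            pool.remove(s)
        carriers = rng.choice(case_calls.shape[0], size=spec.n_carriers,
                              replace=False)
        case_calls[np.ix_(carriers, list(chosen.snp_indices))] = \
            np.array(chosen.genotype_codes, dtype=np.int8)
        planted.append((chosen, np.sort(carriers)))

    # Repair controls until none carries any planted tuple.  A flip at one
    # pattern's SNP cannot create carriage of another (disjoint SNP sets),
    # but the loop guards the invariant regardless.
    for _ in range(100):
        dirty = False
        for pattern, _ in planted:
            hit = np.nonzero(_carries(ctrl_calls, pattern))[0]
            for row in hit:
                dirty = True
                k = int(rng.integers(pattern.r))
                col = pattern.snp_indices[k]
                old = ctrl_calls[row, col]
                shift = 1 + int(rng.integers(2))
                ctrl_calls[row, col] = (old + shift) % 3
        if not dirty:
            break
    else:
        raise GenerationError("could not clear control carriage of planted tuples")
    return planted


def _apply_missingness(calls: np.ndarray, rate: float,
                       protect: np.ndarray | None,
                       rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    mask = rng.random(calls.shape) < rate
    if protect is not None:
        mask &= ~protect
    calls[mask] = MISSING


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, list[SNPRecord], SimulationTruth]:
    """Generate a case/control cohort with the configured planted truth.

    The realized product frequency recorded in the truth is recomputed from
    the final (post-missingness) matrices; if missingness drift pushes a
    planted pattern outside its requested band the generation is retried
    with a seed-derived sub-stream, and a :class:`GenerationError` is raised
    after repeated failures.
    """
    for attempt in range(5):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, attempt]))
        try:
            return _simulate_once(config, rng)
        except _BandDrift:
            continue
    raise GenerationError(
        "planted product frequencies kept drifting out of band; "
        "widen the band or lower missing_rate")


class _BandDrift(Exception):
    pass


def _simulate_once(config, rng):
    n, m_case, m_ctrl = config.n_snps, config.n_cases, config.n_controls
    mafs = rng.uniform(*config.maf_range, size=n)
    # allele_b carries the minor allele: HWE probs for codes (0, 1, 2)
    probs = np.stack([(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs ** 2],
                     axis=1)
    cum = probs.cumsum(axis=1)

    def draw(m):
        u = rng.random((m, n))
        calls = np.empty((m, n), dtype=np.int8)
        for j in range(n):
            calls[:, j] = np.searchsorted(cum[j], u[:, j], side="right")
        np.clip(calls, 0, 2, out=calls)
        return calls

    case_calls = draw(m_case)
    ctrl_calls = draw(m_ctrl)

    case_ids = [f"case_{i+1:05d}" for i in range(m_case)]
    ctrl_ids = [f"ctrl_{i+1:05d}" for i in range(m_ctrl)]
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=n)
    records = [
        SNPRecord(rsid=f"rs{100001 + j}", allele_a=_ALLELE_PAIRS[k][0],
                  allele_b=_ALLELE_PAIRS[k][1])
        for j, k in enumerate(pair_idx)
    ]

    planted = plant_patterns(case_calls, ctrl_calls, config, rng)

    protect = np.zeros_like(case_calls, dtype=bool)
    for pattern, rows in planted:
        protect[np.ix_(rows, list(pattern.snp_indices))] = True
    _apply_missingness(case_calls, config.missing_rate, protect, rng)
    _apply_missingness(ctrl_calls, config.missing_rate, None, rng)

    # realized truth from the final matrices
    alpha = _cohort_frequencies(case_calls)
    beta = _cohort_frequencies(ctrl_calls)
    truth_patterns = []
    for spec, (pattern, rows) in zip(config.planted_patterns, planted):
        pf = 1.0
        for i, c in zip(pattern.snp_indices, pattern.genotype_codes):
            pf *= float(population_frequency(alpha[i, c], beta[i, c],
                                             config.prevalence_model))
        lo, hi = spec.band
        if not lo < pf < hi:
            raise _BandDrift
        if _carries(ctrl_calls, pattern).any():
            raise GenerationError("control carries a planted tuple")
        truth_patterns.append(PlantedPattern(
            pattern=pattern,
            rsids=tuple(records[i].rsid for i in pattern.snp_indices),
            carrier_ids=[case_ids[i] for i in rows],
            product_frequency=pf,
        ))

    records = tally_counts(records, case_calls, ctrl_calls)
    cases = GenotypeMatrix(case_ids, records, case_calls)
    controls = GenotypeMatrix(ctrl_ids, records, ctrl_calls)
    return cases, controls, records, SimulationTruth(truth_patterns,
                                                     config.seed)
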