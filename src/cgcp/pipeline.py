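"""End-to-end pipeline: QC -> forward search -> permutation -> inverse.

``run_pipeline`` composes the stages over one genotype table and writes a
self-describing output directory:

* ``qc_report.tsv`` — per-SNP MAF/HWE decisions
* ``candidates_r{r}.tsv`` — surviving candidate patterns per r
* ``top_candidates.tsv`` — per r, the best bounded candidate and the
  maximum-carrier case-exclusive pattern with the bounds disabled (the two
  readings of "top")
* ``permutation_r{r}.tsv`` / ``..._summary.json`` — subsampling test of
  each top bounded candidate
* ``inverse_r{r}.tsv`` — control-exclusive patterns under the inverse
  prevalence
* ``manifest.json`` — parameters, seeds, input checksum, stage timings and
  candidate counts; enough to reproduce the run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genotype_io import GenotypeMatrix, qc_filter, read_genotype_table
from .inverse import frequency_by_r_report, inverse_search, make_inverse_config
from .resampling import PermutationConfig, distribution_summary, \
    permuted_carrier_counts
from .search import (PrevalenceModel, SearchConfig, candidates_to_frame,
                     count_pattern_space, search_cgcp)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str
    out_dir: str
    r_values: list[int] = field(default_factory=lambda: [3, 4, 5])
    prevalence: float = 0.0047
    lower_mult: float = 0.01
    upper_mult: float = 0.2
    maf_min: float = 0.05
    hwe_control_min: float = 0.01
    hwe_case_min: float = 1e-4
    min_carriers: int = 8
    run_inverse: bool = True
    inverse_min_carriers: int = 1
    inverse_lower: float = 0.01
    inverse_upper: float = 0.2
    n_permutations: int = 1000
    subsample_size: int = 1000
    seed: int = 0
    allow_heavy: bool = False
    heavy_guard: int = 50_000_000  # pattern-space size needing allow_heavy

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    manifest: dict = {
        "cgcp_version": __version__,
        "parameters": asdict(config),
        "input_sha256": _sha256(Path(config.genotypes)),
        "stages": {},
        "incomplete": True,
    }
    manifest_path = out / "manifest.json"

    def _stage(name):
        manifest["stages"][name] = {"seconds": None}
        return time.perf_counter()

    def _done(name, start, **info):
        manifest["stages"][name].update(
            seconds=round(time.perf_counter() - start, 3), **info)
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    # --- QC -------------------------------------------------------------
    t = _stage("qc")
    cases, controls, records = read_genotype_table(config.genotypes)
    passing, report = qc_filter(records, config.maf_min,
                                config.hwe_control_min, config.hwe_case_min)
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    keep = [i for i, rec in enumerate(records)
            if rec.rsid in {p.rsid for p in passing}]
    cases = cases.select_snps(keep)
    controls = controls.select_snps(keep)
    _done("qc", t, n_snps_in=len(records), n_snps_pass=len(keep))
    logger.info("QC: %d/%d SNPs pass", len(keep), len(records))

    model = PrevalenceModel(config.prevalence, config.lower_mult,
                            config.upper_mult)
    n = cases.n_snps
    top_rows = []

    # --- forward search per r -------------------------------------------
    for r in config.r_values:
        space = count_pattern_space(n, r)
        if space > config.heavy_guard and not config.allow_heavy:
            raise RuntimeError(
                f"r={r} pattern space {space} exceeds heavy_guard "
                f"{config.heavy_guard}; rerun with allow_heavy")
        t = _stage(f"search_r{r}")
        cands = search_cgcp(cases, controls, SearchConfig(
            r=r, prevalence_model=model, min_carriers=config.min_carriers))
        candidates_to_frame(cands, cases.snps).to_csv(
            out / f"candidates_r{r}.tsv", sep="\t", index=False)
        unfiltered = search_cgcp(cases, controls, SearchConfig(
            r=r, prevalence_model=model, min_carriers=config.min_carriers,
            apply_bounds=False))
        for label, pool in (("bounded", cands), ("unbounded_max", unfiltered)):
            if pool:
                best = pool[0]
                top_rows.append({
                    "r": r, "selection": label,
                    "rsids": ",".join(cases.snps[i].rsid
                                      for i in best.pattern.snp_indices),
                    "genotype_string": "".join(
                        cases.snps[i].genotype_string(c)
                        for i, c in zip(best.pattern.snp_indices,
                                        best.pattern.genotype_codes)),
                    "n_case_carriers": best.n_case_carriers,
                    "product_frequency": best.product_frequency,
                })
        _done(f"search_r{r}", t, pattern_space=space,
              n_candidates=len(cands), empty=not cands)

        # --- permutation of the top bounded candidate -------------------
        if cands:
            t = _stage(f"permutation_r{r}")
            sub = min(config.subsample_size, cases.n_samples)
            if sub < config.subsample_size:
                logger.warning("subsample_size clamped to case count %d", sub)
            pconf = PermutationConfig(config.n_permutations, sub, config.seed)
            counts = permuted_carrier_counts(cases, cands[0].pattern, pconf)
            pd.DataFrame({"replicate": range(1, len(counts) + 1),
                          "carrier_count": counts}).to_csv(
                out / f"permutation_r{r}.tsv", sep="\t", index=False)
            summary = distribution_summary(counts, cands[0].n_case_carriers)
            summary["seed"] = config.seed
            summary["subsample_size"] = sub
            (out / f"permutation_r{r}_summary.json").write_text(
                json.dumps(summary, indent=2) + "\n")
            _done(f"permutation_r{r}", t, subsample_size=sub)

    pd.DataFrame(top_rows, columns=["r", "selection", "rsids",
                                    "genotype_string", "n_case_carriers",
                                    "product_frequency"]).to_csv(
        out / "top_candidates.tsv", sep="\t", index=False)

    # --- inverse analysis ------------------------------------------------
    if config.run_inverse:
        inv_by_r = {}
        for r in config.r_values:
            t = _stage(f"inverse_r{r}")
            inv = inverse_search(cases, controls, make_inverse_config(
                r=r, p_disease=config.prevalence,
                min_carriers=config.inverse_min_carriers,
                lower=config.inverse_lower, upper=config.inverse_upper))
            inv_by_r[r] = inv
            candidates_to_frame(inv, cases.snps).to_csv(
                out / f"inverse_r{r}.tsv", sep="\t", index=False)
            _done(f"inverse_r{r}", t, n_candidates=len(inv), empty=not inv)
        frequency_by_r_report(inv_by_r).to_csv(
            out / "inverse_frequency_by_r.tsv", sep="\t", index=False)

    manifest["incomplete"] = False
    manifest["total_seconds"] = round(time.perf_counter() - t0, 3)
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
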