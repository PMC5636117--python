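"""Genotype matrix I/O, per-SNP QC and genotype frequencies.

Genotypes are coded per SNP as ``0`` (homozygous for ``allele_a``), ``1``
(heterozygous) and ``2`` (homozygous for ``allele_b``), with ``allele_a``
always the alphabetically first of the two observed alleles so that a call
written "GC" and one written "CG" receive the same code.  Missing calls are
stored as :data:`MISSING`.

The on-disk dialect is a plain TSV with header
``sample_id<TAB>phenotype<TAB><rsid1><TAB>...``, phenotype in
``{case, control}``, genotypes as two-character allele strings, and missing
calls written as ``NN``, ``--`` or the empty string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING: int = -1
_MISSING_STRINGS = {"NN", "--", ""}
_VALID_ALLELES = set("ACGT")


class GenotypeParseError(ValueError):
    """Malformed input file (wrong row length, bad phenotype, ...)."""


class GenotypeDataError(ValueError):
    """Structurally valid input with inconsistent genotype content."""


@dataclass
class SNPRecord:
    """One biallelic SNP with per-cohort genotype counts.

    ``case_counts``/``control_counts`` are ``(n_AA, n_AB, n_BB)`` triples in
    genotype-code order (AA = homozygous ``allele_a``).
    """

    rsid: str
    allele_a: str
    allele_b: str
    case_counts: tuple[int, int, int] = (0, 0, 0)
    control_counts: tuple[int, int, int] = (0, 0, 0)
    n_missing_case: int = 0
    n_missing_control: int = 0

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise GenotypeDataError(f"{self.rsid}: alleles must differ")
        for a in (self.allele_a, self.allele_b):
            if a not in _VALID_ALLELES:
                raise GenotypeDataError(f"{self.rsid}: invalid allele {a!r}")
        if self.allele_a > self.allele_b:
            raise GenotypeDataError(
                f"{self.rsid}: allele_a must sort before allele_b"
            )
        if any(c < 0 for c in (*self.case_counts, *self.control_counts,
                               self.n_missing_case, self.n_missing_control)):
            raise GenotypeDataError(f"{self.rsid}: negative count")

    def counts(self, cohort: str) -> tuple[int, int, int]:
        if cohort == "case":
            return self.case_counts
        if cohort == "control":
            return self.control_counts
        raise ValueError(f"unknown cohort {cohort!r}")

    def genotype_string(self, code: int) -> str:
        """Two-character allele rendering of a genotype code.

        Homozygotes are doubled; heterozygotes rendered allele_a+allele_b.
        """
        if code == 0:
            return self.allele_a * 2
        if code == 1:
            return self.allele_a + self.allele_b
        if code == 2:
            return self.allele_b * 2
        raise ValueError(f"invalid genotype code {code}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs coded genotype calls for one cohort."""

    sample_ids: list[str]
    snps: list[SNPRecord]
    calls: np.ndarray  # int8, shape (n_samples, n_snps), MISSING = -1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise GenotypeDataError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeDataError("duplicate sample ids")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise GenotypeDataError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def select_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP columns (records shared)."""
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )


@dataclass
class GenotypeFrequencies:
    """Per-SNP genotype frequencies: ``alpha`` in cases, ``beta`` in controls.

    Both arrays have shape ``(n_snps, 3)`` and each row sums to 1 over the
    cohort's non-missing calls.
    """

    alpha: np.ndarray
    beta: np.ndarray


def encode_genotype(text: str, record: SNPRecord) -> int:
    """Map a two-character genotype string to a code for ``record``.

    Heterozygote order is normalized ("GC" == "CG").  Raises
    :class:`GenotypeDataError` for alleles outside the SNP's pair.
    """
    if text in _MISSING_STRINGS:
        return MISSING
    if len(text) != 2:
        raise GenotypeDataError(f"{record.rsid}: bad genotype string {text!r}")
    for ch in text:
        if ch not in (record.allele_a, record.allele_b):
            raise GenotypeDataError(
                f"{record.rsid}: allele {ch!r} not in "
                f"{{{record.allele_a},{record.allele_b}}}"
            )
    n_b = sum(ch == record.allele_b for ch in text)
    return n_b  # 0 = aa, 1 = het, 2 = bb


def _infer_records(rsids: Sequence[str], columns: list[list[str]],
                   alleles: dict[str, tuple[str, str]] | None) -> list[SNPRecord]:
    records = []
    for rsid, col in zip(rsids, columns):
        if alleles and rsid in alleles:
            a, b = sorted(alleles[rsid])
        else:
            seen = sorted({ch for g in col if g not in _MISSING_STRINGS
                           for ch in g})
            if len(seen) != 2:
                raise GenotypeDataError(
                    f"{rsid}: observed {len(seen)} distinct allele(s) "
                    f"{seen}; supply alleles explicitly for monomorphic or "
                    "multi-allelic columns"
                )
            a, b = seen
        records.append(SNPRecord(rsid=rsid, allele_a=a, allele_b=b))
    return records


def _tally(record: SNPRecord, codes: np.ndarray, cohort: str) -> SNPRecord:
    counts = tuple(int((codes == c).sum()) for c in (0, 1, 2))
    n_miss = int((codes == MISSING).sum())
    if cohort == "case":
        return replace(record, case_counts=counts, n_missing_case=n_miss)
    return replace(record, control_counts=counts, n_missing_control=n_miss)


def tally_counts(records: Iterable[SNPRecord], cases: np.ndarray,
                 controls: np.ndarray) -> list[SNPRecord]:
    """Fill per-cohort genotype counts of each record from call matrices."""
    out = []
    for j, rec in enumerate(records):
        rec = _tally(rec, cases[:, j], "case")
        rec = _tally(rec, controls[:, j], "control")
        out.append(rec)
    return out


def read_genotype_table(
    path: str | Path,
    dialect: str = "tsv",
    alleles: dict[str, tuple[str, str]] | None = None,
    sample_sheet: str | Path | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, list[SNPRecord]]:
    """Read a genotype table, splitting samples into case/control matrices.

    Parameters
    ----------
    path
        Input file.  ``dialect="tsv"`` expects the package's TSV dialect;
        ``dialect="vcf"`` reads a minimal biallelic-SNP VCF (GT field only)
        and requires ``sample_sheet`` (two-column TSV: sample_id, phenotype).
    alleles
        Optional rsid -> (allele, allele) map; otherwise alleles are
        inferred from the observed genotype strings (TSV only).
    """
    if dialect == "vcf":
        return _read_vcf(path, sample_sheet)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "phenotype":
            raise GenotypeParseError(
                f"{path}: header must start 'sample_id\\tphenotype\\t<rsid>...'"
            )
        rsids = header[2:]
        sample_ids: list[str] = []
        phenotypes: list[str] = []
        raw_rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            if fields[1] not in ("case", "control"):
                raise GenotypeParseError(
                    f"{path}:{lineno}: phenotype must be case/control, "
                    f"got {fields[1]!r}"
                )
            sample_ids.append(fields[0])
            phenotypes.append(fields[1])
            raw_rows.append(fields[2:])

    columns = [[row[j] for row in raw_rows] for j in range(len(rsids))]
    records = _infer_records(rsids, columns, alleles)

    calls = np.empty((len(sample_ids), len(rsids)), dtype=np.int8)
    for i, row in enumerate(raw_rows):
        for j, text in enumerate(row):
            try:
                calls[i, j] = encode_genotype(text, records[j])
            except GenotypeDataError as exc:
                raise GenotypeDataError(
                    f"sample {sample_ids[i]}: {exc}"
                ) from None

    case_mask = np.array([p == "case" for p in phenotypes])
    case_calls = calls[case_mask]
    ctrl_calls = calls[~case_mask]
    records = tally_counts(records, case_calls, ctrl_calls)

    cases = GenotypeMatrix(
        [s for s, m in zip(sample_ids, case_mask) if m], records, case_calls)
    controls = GenotypeMatrix(
        [s for s, m in zip(sample_ids, case_mask) if not m], records,
        ctrl_calls)
    return cases, controls, records


def _read_vcf(path, sample_sheet):
    from cyvcf2 import VCF

    if sample_sheet is None:
        raise ValueError("VCF input requires a sample sheet (sample_id, phenotype)")
    sheet = pd.read_csv(sample_sheet, sep="\t", header=None,
                        names=["sample_id", "phenotype"], dtype=str)
    pheno = dict(zip(sheet.sample_id, sheet.phenotype))

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pheno]
    if unknown:
        raise GenotypeDataError(f"samples missing from sheet: {unknown[:5]}")

    records: list[SNPRecord] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise GenotypeDataError(f"{var.ID}: only biallelic SNPs supported")
        a, b = sorted((var.REF, var.ALT[0]))
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        codes[gt == 1] = 1
        if var.ALT[0] == b:
            codes[gt == 0] = 0
            codes[gt == 3] = 2
        else:
            codes[gt == 0] = 2
            codes[gt == 3] = 0
        records.append(SNPRecord(rsid=var.ID or f"{var.CHROM}:{var.POS}",
                                 allele_a=a, allele_b=b))
        cols.append(codes)

    calls = np.column_stack(cols) if cols else np.empty((len(samples), 0), np.int8)
    case_mask = np.array([pheno[s] == "case" for s in samples])
    records = tally_counts(records, calls[case_mask], calls[~case_mask])
    cases = GenotypeMatrix([s for s, m in zip(samples, case_mask) if m],
                           records, calls[case_mask])
    controls = GenotypeMatrix([s for s, m in zip(samples, case_mask) if not m],
                              records, calls[~case_mask])
    return cases, controls, records


def write_genotype_table(path: str | Path, cases: GenotypeMatrix,
                         controls: GenotypeMatrix) -> None:
    """Write both cohorts back to the TSV dialect (missing as ``--``)."""
    path = Path(path)
    records = cases.snps
    with path.open("w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(r.rsid for r in records)
                 + "\n")
        for matrix, label in ((cases, "case"), (controls, "control")):
            for i, sid in enumerate(matrix.sample_ids):
                cells = [
                    "--" if c == MISSING else records[j].genotype_string(int(c))
                    for j, c in enumerate(matrix.calls[i])
                ]
                fh.write(f"{sid}\t{label}\t" + "\t".join(cells) + "\n")


def compute_maf(record: SNPRecord, cohort: str) -> float:
    """Minor allele frequency in one cohort, in [0, 0.5]."""
    n_aa, n_ab, n_bb = record.counts(cohort)
    total = n_aa + n_ab + n_bb
    if total == 0:
        raise GenotypeDataError(
            f"{record.rsid}: no non-missing {cohort} calls, MAF undefined")
    f = (2 * n_aa + n_ab) / (2 * total)
    return min(f, 1.0 - f)


def hwe_test(counts: tuple[int, int, int]) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg.

    Expected genotype counts are derived from the allele frequency estimated
    from the observed counts.  Monomorphic input returns p = 1 by convention
    (no departure is testable).
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise GenotypeDataError("HWE test needs a positive total count")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    records: Sequence[SNPRecord],
    maf_min: float = 0.05,
    hwe_control_min: float = 0.01,
    hwe_case_min: float = 1e-4,
) -> tuple[list[SNPRecord], pd.DataFrame]:
    """Apply the MAF and Hardy-Weinberg QC rules.

    A SNP is retained when MAF > ``maf_min`` in BOTH cohorts, HWE p >
    ``hwe_control_min`` in controls and HWE p > ``hwe_case_min`` in cases.
    Returns the passing records and a per-SNP report frame (columns: rsid,
    maf_case, maf_control, hwe_p_case, hwe_p_control, status, reason).
    """
    rows = []
    passing = []
    for rec in records:
        maf_case = compute_maf(rec, "case")
        maf_ctrl = compute_maf(rec, "control")
        p_case = hwe_test(rec.case_counts)
        p_ctrl = hwe_test(rec.control_counts)
        reasons = []
        if maf_case <= maf_min:
            reasons.append("MAF(case)")
        if maf_ctrl <= maf_min:
            reasons.append("MAF(control)")
        if p_ctrl <= hwe_control_min:
            reasons.append("HWE(control)")
        if p_case <= hwe_case_min:
            reasons.append("HWE(case)")
        status = "pass" if not reasons else "fail"
        if not reasons:
            passing.append(rec)
        rows.append({
            "rsid": rec.rsid, "maf_case": maf_case, "maf_control": maf_ctrl,
            "hwe_p_case": p_case, "hwe_p_control": p_ctrl,
            "status": status, "reason": ";".join(reasons),
        })
    return passing, pd.DataFrame(rows)


def genotype_frequencies(case: GenotypeMatrix,
                         control: GenotypeMatrix) -> GenotypeFrequencies:
    """Per-SNP genotype frequencies over non-missing calls in each cohort."""
    if [r.rsid for r in case.snps] != [r.rsid for r in control.snps]:
        raise GenotypeDataError("case/control matrices have different SNP lists")

    def _freqs(matrix: GenotypeMatrix, label: str) -> np.ndarray:
        out = np.empty((matrix.n_snps, 3))
        for j in range(matrix.n_snps):
            col = matrix.calls[:, j]
            counts = np.array([(col == c).sum() for c in (0, 1, 2)], float)
            total = counts.sum()
            if total == 0:
                raise GenotypeDataError(
                    f"{matrix.snps[j].rsid}: no non-missing {label} calls")
            out[j] = counts / total
        return out

    return GenotypeFrequencies(alpha=_freqs(case, "case"),
                               beta=_freqs(control, "control"))
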