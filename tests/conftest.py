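import numpy as np
import pytest

from cgcp.genotype_io import GenotypeMatrix, SNPRecord, tally_counts

_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


def random_cohort(rng, n_snps, n_cases, n_controls, missing_rate=0.05):
    """Unstructured random genotype matrices for oracle-style tests."""
    case = rng.integers(0, 3, (n_cases, n_snps)).astype(np.int8)
    ctrl = rng.integers(0, 3, (n_controls, n_snps)).astype(np.int8)
    if missing_rate:
        case[rng.random(case.shape) < missing_rate] = -1
        ctrl[rng.random(ctrl.shape) < missing_rate] = -1
    records = [
        SNPRecord(f"rs{j:05d}", *_PAIRS[j % len(_PAIRS)])
        for j in range(n_snps)
    ]
    records = tally_counts(records, case, ctrl)
    cases = GenotypeMatrix([f"case_{i:04d}" for i in range(n_cases)],
                           records, case)
    controls = GenotypeMatrix([f"ctrl_{i:04d}" for i in range(n_controls)],
                              records, ctrl)
    return cases, controls


def matrices_from_codes(case_rows, ctrl_rows, n_snps=None):
    """Build aligned cohort matrices from explicit genotype-code rows."""
    case = np.array(case_rows, dtype=np.int8)
    ctrl = np.array(ctrl_rows, dtype=np.int8)
    n_snps = n_snps or case.shape[1]
    records = [SNPRecord(f"rs{j:05d}", "A", "C") for j in range(n_snps)]
    records = tally_counts(records, case, ctrl)
    cases = GenotypeMatrix([f"case_{i}" for i in range(case.shape[0])],
                           records, case)
    controls = GenotypeMatrix([f"ctrl_{i}" for i in range(ctrl.shape[0])],
                              records, ctrl)
    return cases, controls


@pytest.fixture
def tiny_tsv(tmp_path):
    """Six samples, two SNPs, one missing call (hand-countable)."""
    text = "\n".join([
        "sample_id\tphenotype\trs1\trs2",
        "s1\tcase\tCC\tAG",
        "s2\tcase\tCG\tAA",
        "s3\tcase\tGC\tGG",
        "s4\tcontrol\tGG\tAG",
        "s5\tcontrol\t--\tAA",
        "s6\tcontrol\tCG\tGG",
    ]) + "\n"
    path = tmp_path / "tiny.tsv"
    path.write_text(text)
    return path
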