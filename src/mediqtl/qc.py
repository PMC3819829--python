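"""Sample- and SNP-level genotype quality control.

Three SNP filters are applied, in the spirit of standard GWAS practice:
genotyping call rate, an exact Hardy-Weinberg equilibrium test, and a
minor-allele-frequency floor.  All thresholds are strict ("less than"):
a SNP sitting exactly on a threshold is kept.  Sample call-rate filtering
happens first and SNP statistics are computed on the post-sample-filter
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .io import GenotypeMatrix

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def sample_call_rate_filter(g: GenotypeMatrix, min_rate: float = 0.95) -> GenotypeMatrix:
    """Drop samples whose fraction of non-missing genotypes is below ``min_rate``.

    The inequality is strict: a sample at exactly ``min_rate`` is kept.
    """
    if not (0.0 < min_rate <= 1.0):
        raise ValueError(f"min_rate must be in (0, 1], got {min_rate!r}")
    if g.n_snps == 0:
        return g
    rates = 1.0 - np.isnan(g.dose).mean(axis=1)
    keep = rates >= min_rate
    if not keep.any():
        raise ValueError("sample call-rate filter removed every sample")
    dropped = [g.sample_ids[i] for i in np.flatnonzero(~keep)]
    if dropped:
        log.info("sample call-rate filter removed %d samples: %s",
                 len(dropped), ", ".join(dropped[:10]))
    return g.subset_samples(np.flatnonzero(keep))


def minor_allele_frequency(doses) -> float:
    """MAF of a dose vector: min(f, 1-f) with f = sum(dose) / (2 * non-missing)."""
    d = np.asarray(doses, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("cannot compute MAF: all genotypes missing")
    f = float(d[ok].sum()) / (2.0 * int(ok.sum()))
    return min(f, 1.0 - f)


def genotype_counts(doses) -> tuple[int, int, int]:
    """(ref-hom, het, alt-hom) counts of a dose vector, ignoring missing."""
    d = np.asarray(doses, dtype=float)
    return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def hwe_exact_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over every attainable
    heterozygote count, the conditional probabilities of tables at most as
    probable as the observed one.  Symmetric in the two homozygote counts.
    """
    if min(n_ref_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    n_rare = min(2 * n_ref_hom + n_het, 2 * n_alt_hom + n_het)
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable table
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log P(het | n, allele counts) up to a shared constant
    logp = hets * LN2 - (
        gammaln(rare_hom + 1) + gammaln(hets + 1) + gammaln(common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


def hwe_chisq_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg test (asymptotic alternative)."""
    if min(n_ref_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    p = (2 * n_ref_hom + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_ref_hom, n_het, n_alt_hom], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


@dataclass
class SnpQcReport:
    snp_id: str
    call_rate: float
    maf: float
    hwe_p: float
    passed: bool
    fail_reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.fail_reasons) == 0):
            raise ValueError("passed flag inconsistent with fail_reasons")


def snp_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 0.001,
    maf_min: float = 0.10,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, list[SnpQcReport]]:
    """Remove SNPs failing any of the call-rate / HWE / MAF criteria.

    All three comparisons are strict: a SNP is removed when call rate is
    below ``call_rate_min``, when the HWE p-value is below ``hwe_alpha``
    (the test is "significant"), or when MAF is below ``maf_min``.
    """
    if not (0.0 < call_rate_min <= 1.0):
        raise ValueError("call_rate_min must be in (0, 1]")
    if not (0.0 < hwe_alpha < 1.0):
        raise ValueError("hwe_alpha must be in (0, 1)")
    if not (0.0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    hwe = hwe_exact_test if hwe_method == "exact" else hwe_chisq_test

    reports: list[SnpQcReport] = []
    keep: list[int] = []
    n = g.n_samples
    for j, snp_id in enumerate(g.snp_ids):
        d = g.dose[:, j]
        n_ok = int((~np.isnan(d)).sum())
        call_rate = n_ok / n if n else 0.0
        reasons: list[str] = []
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        if n_ok == 0:
            reports.append(SnpQcReport(snp_id, 0.0, np.nan, np.nan, False,
                                       tuple(reasons)))
            continue
        hwe_p = hwe(*genotype_counts(d))
        if hwe_p < hwe_alpha:
            reasons.append("hwe")
        maf = minor_allele_frequency(d)
        if maf < maf_min:
            reasons.append("maf")
        passed = not reasons
        if passed:
            keep.append(j)
        reports.append(SnpQcReport(snp_id, call_rate, maf, hwe_p, passed,
                                   tuple(reasons)))
    if not keep:
        raise ValueError("SNP filter removed every SNP")
    log.info("SNP filter kept %d of %d SNPs", len(keep), g.n_snps)
    return g.subset_snps(np.asarray(keep)), reports


def write_qc_report(reports: list[SnpQcReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tcall_rate\tmaf\thwe_p\tpass\tfail_reasons\n")
        for r in reports:
            fh.write(
                f"{r.snp_id}\t{r.call_rate:.6g}\t{r.maf:.6g}\t{r.hwe_p:.6g}\t"
                f"{str(r.passed).lower()}\t{','.join(r.fail_reasons) or '.'}\n"
            )
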