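"""By-chance false-discovery-rate estimate for the genome-wide trio scan.

Under a global null, the expected number of tests reaching a fixed p-value
threshold alpha is (number of tests) x alpha.  The by-chance FDR is that
expectation divided by the observed number of significant results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


def chance_fdr(n_tests: int, alpha: float, n_significant: int) -> float:
    """(n_tests * alpha) / n_significant; expected-by-chance over observed.

    Returns 0.0 for the degenerate 0/0 case and NaN (flagged undefined)
    when nothing is significant but the expected count is positive.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    if n_significant < 0:
        raise ValueError("n_significant must be >= 0")
    expected = n_tests * alpha
    if n_significant == 0:
        return 0.0 if expected == 0.0 else math.nan
    return expected / n_significant


@dataclass
class ScanSummary:
    """Counts of significant trios / distinct SNPs / distinct probes plus the FDR."""

    n_tests: int
    alpha: float
    n_significant_trios: int
    n_significant_snps: int
    n_significant_probes: int
    fdr: float

    def __post_init__(self) -> None:
        if self.n_significant_snps > self.n_significant_trios:
            raise ValueError("distinct SNPs cannot exceed trio count")
        if self.n_significant_probes > self.n_significant_trios:
            raise ValueError("distinct probes cannot exceed trio count")


def summarize_scan(results: Iterable, alpha: float, n_tests: int,
                   use_permutation_p: bool = False) -> ScanSummary:
    """Count trios with p < alpha, their distinct SNPs and probes, attach the FDR."""
    n_trios = 0
    snps: set[str] = set()
    probes: set[str] = set()
    for r in results:
        p = r.p_permutation if use_permutation_p else r.sobel.p_analytic
        if p is not None and not math.isnan(p) and p < alpha:
            n_trios += 1
            snps.add(r.snp_id)
            probes.add(r.probe_id)
    return ScanSummary(
        n_tests=n_tests,
        alpha=alpha,
        n_significant_trios=n_trios,
        n_significant_snps=len(snps),
        n_significant_probes=len(probes),
        fdr=chance_fdr(n_tests, alpha, n_trios),
    )


def write_scan_summary(summary: ScanSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("n_tests\talpha\tn_sig_trios\tn_sig_snps\tn_sig_probes\tfdr\n")
        fdr = "NA" if math.isnan(summary.fdr) else f"{summary.fdr:.6g}"
        fh.write(
            f"{summary.n_tests}\t{summary.alpha:g}\t{summary.n_significant_trios}\t"
            f"{summary.n_significant_snps}\t{summary.n_significant_probes}\t{fdr}\n"
        )
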