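"""eQTL scan, trans-eQTL hotspot detection and hotspot-mediation overlap.

A hotspot is a SNP associated (at the pair-level significance cutoff) with
at least ``min_probes`` transcripts genome-wide, suggesting a master
regulator.  Hotspot enrichment is scored by an exact upper-tail binomial
test of the per-SNP count of significant probes against a null per-pair
significance probability, Bonferroni-corrected over all SNPs tested.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.stats import binom, t as t_dist

from .io import ExpressionMatrix, GenotypeMatrix
from .mediation import _MIN_TRIO_N

log = logging.getLogger(__name__)


@dataclass
class EqtlRecord:
    snp_id: str
    probe_id: str
    beta: float
    p: float
    cis: bool | None = None  # None = unknown annotation


@dataclass
class Hotspot:
    snp_id: str
    n_significant_probes: int
    enrichment_p_raw: float
    enrichment_p_bonferroni: float
    enrichment_score: float  # -log10 of the corrected p


@dataclass
class OverlapResult:
    hotspot_snp_ids: tuple[str, ...]
    n_overlap_trios: int
    n_overlap_snps: int
    n_overlap_probes: int

    def __post_init__(self) -> None:
        if self.n_overlap_snps > len(self.hotspot_snp_ids):
            raise ValueError("overlap SNPs cannot exceed the number of hotspots")


def _eqtl_snp(x: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-probe slope, t-test p and n for expression ~ dose of one SNP."""
    base = ~np.isnan(x)
    V = (~np.isnan(M)) & base[:, None]
    Vf = V.astype(float)
    xz = np.where(base, x, 0.0)
    Mz = np.where(V, M, 0.0)
    n = base.astype(float) @ Vf
    sx = xz @ Vf
    sxx = (xz * xz) @ Vf
    sm = base.astype(float) @ Mz
    smm = base.astype(float) @ (Mz * Mz)
    sxm = xz @ Mz
    with np.errstate(divide="ignore", invalid="ignore"):
        cxx = sxx - sx * sx / n
        cmm = smm - sm * sm / n
        cxm = sxm - sx * sm / n
        beta = cxm / cxx
        rss = np.maximum(0.0, cmm - beta * cxm)
        se2 = rss / (n - 2) / cxx
        tstat = np.where(se2 > 0, beta / np.sqrt(se2), np.inf * np.sign(beta))
    p = 2.0 * t_dist.sf(np.abs(tstat), df=np.maximum(n - 2, 1))
    bad = (n < _MIN_TRIO_N) | ~(cxx > 0.0)
    beta = np.where(bad, np.nan, beta)
    p = np.where(bad, np.nan, p)
    return beta, p, n


def eqtl_scan(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    p_cutoff: float = 1e-5,
    emit_all: bool = False,
) -> Iterator[EqtlRecord]:
    """Simple-regression eQTL scan of every SNP x probe pair, SNP-major order.

    Each probe is regressed on the SNP dose; records with p < ``p_cutoff``
    are emitted (all records when ``emit_all``).  Uses the same linear-model
    statistics as the mediation scan's step-2 fit, with a t-test p-value.
    """
    if g.sample_ids != e.sample_ids:
        raise ValueError("genotype and expression samples are not aligned")
    if not (0.0 < p_cutoff <= 1.0):
        raise ValueError("p_cutoff must be in (0, 1]")
    for j in range(g.n_snps):
        beta, p, _n = _eqtl_snp(g.dose[:, j], e.values)
        if emit_all:
            emit = np.arange(e.n_probes)
        else:
            with np.errstate(invalid="ignore"):
                emit = np.flatnonzero(p < p_cutoff)
        for k in emit:
            yield EqtlRecord(
                snp_id=g.snp_ids[j],
                probe_id=e.probe_ids[k],
                beta=float(beta[k]),
                p=float(p[k]),
            )


def classify_cis_trans(snp_chrom, snp_pos, probe_chrom, probe_pos,
                       window: int = 1_000_000) -> bool | None:
    """cis iff same chromosome and |snp_pos - probe_pos| <= window (inclusive).

    Returns None (unknown) when any coordinate is missing.
    """
    def _missing(v) -> bool:
        if v is None:
            return True
        if isinstance(v, float) and math.isnan(v):
            return True
        return str(v) in ("", "nan", "NA")

    if any(_missing(v) for v in (snp_chrom, snp_pos, probe_chrom, probe_pos)):
        log.debug("missing annotation; cis/trans unknown")
        return None
    if str(snp_chrom) != str(probe_chrom):
        return False
    return abs(float(snp_pos) - float(probe_pos)) <= window


def annotate_cis_trans(records: Iterable[EqtlRecord], snp_ann: pd.DataFrame,
                       probe_ann: pd.DataFrame, window: int = 1_000_000) -> list[EqtlRecord]:
    """Fill the ``cis`` flag of each record from (id, chrom, pos) annotation maps."""
    out = []
    for r in records:
        sc = snp_ann["chrom"].get(r.snp_id)
        sp = snp_ann["pos"].get(r.snp_id)
        pc = probe_ann["chrom"].get(r.probe_id)
        pp = probe_ann["pos"].get(r.probe_id)
        r.cis = classify_cis_trans(sc, sp, pc, pp, window=window)
        out.append(r)
    return out


def detect_hotspots(
    records: Iterable[EqtlRecord],
    min_probes: int,
    n_probes_total: int,
    p0: float,
    n_snps_tested: int,
) -> list[Hotspot]:
    """SNPs with >= ``min_probes`` significant probes, scored by exact binomial enrichment.

    ``records`` must already be filtered at the pair-level significance
    cutoff.  The enrichment p is the exact upper tail
    P(K >= k | n_probes_total, p0); the Bonferroni multiplier is
    ``n_snps_tested`` (the whole scan family) and the score is -log10 of
    the corrected p (capped at 1).
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0!r}")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if n_snps_tested < 1:
        raise ValueError("n_snps_tested must be >= 1")
    counts = Counter(r.snp_id for r in records)
    hotspots = []
    for snp_id, k in sorted(counts.items()):
        if k < min_probes:
            continue
        p_raw = float(binom.sf(k - 1, n_probes_total, p0))
        p_bonf = min(1.0, p_raw * n_snps_tested)
        score = -math.log10(max(p_bonf, 1e-300))
        hotspots.append(
            Hotspot(
                snp_id=snp_id,
                n_significant_probes=int(k),
                enrichment_p_raw=p_raw,
                enrichment_p_bonferroni=p_bonf,
                enrichment_score=score,
            )
        )
    log.info("detected %d hotspots (>= %d probes)", len(hotspots), min_probes)
    return hotspots


def overlap_hotspots_with_mediation(hotspots: list[Hotspot], trios: Iterable) -> OverlapResult:
    """Restrict significant mediation trios to hotspot SNPs and count the triple.

    ``trios`` must already be filtered at the trio significance cutoff.
    Reports (trio count, distinct hotspot SNPs, distinct mediator probes).
    """
    hotspot_ids = tuple(h.snp_id for h in hotspots)
    members = set(hotspot_ids)
    n_trios = 0
    snps: set[str] = set()
    probes: set[str] = set()
    for t in trios:
        if t.snp_id in members:
            n_trios += 1
            snps.add(t.snp_id)
            probes.add(t.probe_id)
    return OverlapResult(
        hotspot_snp_ids=hotspot_ids,
        n_overlap_trios=n_trios,
        n_overlap_snps=len(snps),
        n_overlap_probes=len(probes),
    )


# ---------------------------------------------------------------------------
# tabular output


def write_eqtl_records(records: Iterable[EqtlRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tprobe_id\tbeta\tp\tcis\n")
        for r in records:
            cis = "NA" if r.cis is None else str(r.cis).lower()
            fh.write(f"{r.snp_id}\t{r.probe_id}\t{r.beta:.10g}\t{r.p:.10g}\t{cis}\n")


def read_eqtl_records(path: str | Path) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "probe_id": str},
                     na_values=["NA"], keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        cis = None if pd.isna(row.cis) else str(row.cis) == "true"
        out.append(EqtlRecord(snp_id=row.snp_id, probe_id=row.probe_id,
                              beta=float(row.beta), p=float(row.p), cis=cis))
    return out


def write_hotspots(hotspots: list[Hotspot], path: str | Path,
                   snp_ann: pd.DataFrame | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tn_sig_probes\tenrichment_p_raw\t"
                 "enrichment_p_bonf\tscore\n")
        for h in hotspots:
            chrom = pos = "NA"
            if snp_ann is not None and h.snp_id in snp_ann.index:
                chrom = str(snp_ann["chrom"].get(h.snp_id))
                pos = str(int(snp_ann["pos"].get(h.snp_id)))
            fh.write(
                f"{h.snp_id}\t{chrom}\t{pos}\t{h.n_significant_probes}\t"
                f"{h.enrichment_p_raw:.10g}\t{h.enrichment_p_bonferroni:.10g}\t"
                f"{h.enrichment_score:.10g}\n"
            )


def read_hotspots(path: str | Path) -> list[Hotspot]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str},
                     na_values=["NA"], keep_default_na=False)
    return [
        Hotspot(
            snp_id=row.snp_id,
            n_significant_probes=int(row.n_sig_probes),
            enrichment_p_raw=float(row.enrichment_p_raw),
            enrichment_p_bonferroni=float(row.enrichment_p_bonf),
            enrichment_score=float(row.score),
        )
        for row in df.itertuples(index=False)
    ]


def write_overlap(result: OverlapResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("n_hotspots\tn_overlap_trios\tn_overlap_snps\tn_overlap_probes\n")
        fh.write(
            f"{len(result.hotspot_snp_ids)}\t{result.n_overlap_trios}\t"
            f"{result.n_overlap_snps}\t{result.n_overlap_probes}\n"
        )
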