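"""Mediation analysis of SNP -> transcript -> phenotype trios.

The model is the classic four-step mediation setup: with genotype dose X,
transcript level M and quantitative phenotype Y,

    step 1:  Y = a1 + b1*X            (total effect)
    step 2:  M = a2 + b2*X            (X -> M path)
    step 3:  Y = a3 + b3*M            (zero-order M -> Y)
    step 4:  Y = a4 + b4*M + b5*X     (M -> Y adjusted for X)

The indirect (mediated) effect is the product b2*b4.  Its delta-method
standard error is sqrt(b2^2*se4^2 + b4^2*se2^2) and the Sobel statistic is
the ratio of the product to that standard error, referred to a standard
normal.  A permutation alternative compares the observed product to
products of coefficients refitted after independently permuting Y (in the
step-4 regression) and M (in the step-2 regression).

The genome-wide scan fits steps 2 and 4 for every SNP x probe pair with
per-trio complete-case handling, vectorized across probes within each SNP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import norm, t as t_dist

from .config import RunConfig
from .io import ExpressionMatrix, GenotypeMatrix
from .normalize import AdjustedVector

log = logging.getLogger(__name__)

_MIN_TRIO_N = 5  # complete cases needed for the two-predictor fit + 1


@dataclass
class SimpleFit:
    """OLS fit of a one-predictor regression."""

    intercept: float
    slope: float
    slope_se: float
    n_used: int


@dataclass
class TwoPredictorFit:
    """OLS fit of y on an intercept, the mediator m and the predictor x."""

    intercept: float
    slope_m: float
    slope_m_se: float
    slope_x: float
    slope_x_se: float
    n_used: int


@dataclass
class SobelResult:
    indirect: float
    se: float
    z: float
    p_analytic: float


@dataclass
class PermutationNull:
    """Null products b2+ * b4+ from coefficient permutation."""

    products: np.ndarray
    B: int
    seed: object

    def __post_init__(self) -> None:
        self.products = np.asarray(self.products, dtype=float)
        if self.products.shape != (self.B,):
            raise ValueError("products length must equal B")


@dataclass
class TrioResult:
    snp_id: str
    probe_id: str
    beta2: float
    beta4: float
    beta5: float
    sobel: SobelResult
    p_permutation: float | None = None


def _complete(*vectors: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("input vectors must have equal lengths")
    ok = ~np.any([np.isnan(a) for a in arrs], axis=0)
    return tuple(a[ok] for a in arrs)


def simple_regression(x, y) -> SimpleFit:
    """OLS of y on an intercept and x, with the residual-based slope SE (n-2 df)."""
    x, y = _complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("predictor has zero variance")
    sxy = float((x - xm) @ (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    rss = max(0.0, float(((y - ym) ** 2).sum()) - slope * sxy)
    se = math.sqrt(rss / (n - 2) / sxx)
    return SimpleFit(intercept=intercept, slope=slope, slope_se=se, n_used=n)


def slope_pvalue(fit: SimpleFit) -> float:
    """Two-sided t-test p-value of the slope of a simple regression."""
    if fit.slope_se == 0.0:
        return 1.0 if fit.slope == 0.0 else 0.0
    return float(2.0 * t_dist.sf(abs(fit.slope / fit.slope_se), df=fit.n_used - 2))


def two_predictor_regression(x, m, y) -> TwoPredictorFit:
    """OLS of y on an intercept, m and x, with n-3 df standard errors."""
    x, m, y = _complete(x, m, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete triples, have {n}")
    xc = x - x.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    cxx = float(xc @ xc)
    cmm = float(mc @ mc)
    cxm = float(xc @ mc)
    det = cmm * cxx - cxm * cxm
    if det <= 0.0 or cxx == 0.0 or cmm == 0.0:
        raise ValueError("design matrix is rank deficient (x and m collinear or constant)")
    cym = float(yc @ mc)
    cxy = float(yc @ xc)
    b4 = (cym * cxx - cxy * cxm) / det
    b5 = (cmm * cxy - cxm * cym) / det
    rss = max(0.0, float(yc @ yc) - b4 * cym - b5 * cxy)
    sigma2 = rss / (n - 3)
    return TwoPredictorFit(
        intercept=float(y.mean() - b4 * m.mean() - b5 * x.mean()),
        slope_m=b4,
        slope_m_se=math.sqrt(sigma2 * cxx / det),
        slope_x=b5,
        slope_x_se=math.sqrt(sigma2 * cmm / det),
        n_used=n,
    )


def sobel_statistic(b2: float, se2: float, b4: float, se4: float) -> SobelResult:
    """Delta-method test of the indirect effect b2*b4.

    SE = sqrt(b2^2*se4^2 + b4^2*se2^2); z = (b2*b4)/SE against N(0, 1).
    """
    if se2 < 0 or se4 < 0:
        raise ValueError("standard errors must be non-negative")
    indirect = b2 * b4
    se = math.sqrt(b2 * b2 * se4 * se4 + b4 * b4 * se2 * se2)
    if se == 0.0:
        if indirect == 0.0:
            return SobelResult(indirect=0.0, se=0.0, z=0.0, p_analytic=1.0)
        z = math.inf if indirect > 0 else -math.inf
        return SobelResult(indirect=indirect, se=0.0, z=z, p_analytic=0.0)
    z = indirect / se
    return SobelResult(indirect=indirect, se=se, z=z,
                       p_analytic=float(2.0 * norm.sf(abs(z))))


def permutation_null(x, m, y, B: int, seed) -> PermutationNull:
    """Null distribution of b2+ * b4+ under independent permutation of y and m.

    Each iteration permutes y and refits the step-4 regression of the
    permuted y on (x, m) for b4+, independently permutes m and refits the
    step-2 regression of the permuted m on x for b2+, and records the
    product.  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x, m, y = _complete(x, m, y)
    n = len(x)
    if n < _MIN_TRIO_N:
        raise ValueError(f"need >= {_MIN_TRIO_N} complete triples, have {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("predictor has zero variance")
    # Frisch-Waugh: the m coefficient in y ~ 1 + m + x equals the simple
    # regression of y on the residual of m given (1, x).
    mc = m - m.mean()
    rm = mc - (float(xc @ mc) / sxx) * xc
    srr = float(rm @ rm)
    if srr == 0.0:
        raise ValueError("m is collinear with x")
    rng = np.random.default_rng(seed)
    yz = y - y.mean()
    perm_y = yz[np.argsort(rng.random((B, n)), axis=1)]
    perm_m = mc[np.argsort(rng.random((B, n)), axis=1)]
    b4p = perm_y @ rm / srr
    b2p = perm_m @ xc / sxx
    return PermutationNull(products=b2p * b4p, B=B, seed=seed)


def permutation_pvalue(observed: float, null: PermutationNull) -> float:
    """Two-sided add-one permutation p: (1 + #{|null| >= |obs|}) / (B + 1)."""
    count = int((np.abs(null.products) >= abs(observed)).sum())
    return (1 + count) / (null.B + 1)


# ---------------------------------------------------------------------------
# vectorized per-SNP block statistics


def _snp_stats(x: np.ndarray, M: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Step-2 and step-4 statistics of one SNP against every probe column.

    Complete cases are handled per trio: a sample enters the pair (SNP,
    probe j) only when its dose, probe value and phenotype are all present.
    Returns per-probe arrays; entries are NaN for degenerate pairs
    (too few samples, zero dose variance, collinearity).
    """
    base = ~(np.isnan(x) | np.isnan(y))
    V = (~np.isnan(M)) & base[:, None]
    Vf = V.astype(float)
    xz = np.where(base, x, 0.0)
    yz = np.where(base, y, 0.0)
    Mz = np.where(V, M, 0.0)

    n = base.astype(float) @ Vf
    sx = xz @ Vf
    sxx = (xz * xz) @ Vf
    sy = yz @ Vf
    syy = (yz * yz) @ Vf
    sxy = (xz * yz) @ Vf
    sm = base.astype(float) @ Mz
    smm = base.astype(float) @ (Mz * Mz)
    sxm = xz @ Mz
    sym = yz @ Mz

    with np.errstate(divide="ignore", invalid="ignore"):
        cxx = sxx - sx * sx / n
        cyy = syy - sy * sy / n
        cxy = sxy - sx * sy / n
        cmm = smm - sm * sm / n
        cxm = sxm - sx * sm / n
        cym = sym - sy * sm / n

        det = cmm * cxx - cxm * cxm
        valid = (n >= _MIN_TRIO_N) & (cxx > 0.0) & (cmm > 0.0) & (det > 0.0)

        b2 = cxm / cxx
        rss2 = np.maximum(0.0, cmm - b2 * cxm)
        se2 = np.sqrt(rss2 / (n - 2) / cxx)

        b4 = (cym * cxx - cxy * cxm) / det
        b5 = (cmm * cxy - cxm * cym) / det
        rss4 = np.maximum(0.0, cyy - b4 * cym - b5 * cxy)
        sigma2 = rss4 / (n - 3)
        se4 = np.sqrt(sigma2 * cxx / det)
        se5 = np.sqrt(sigma2 * cmm / det)

        indirect = b2 * b4
        se_ind = np.sqrt(b2 * b2 * se4 * se4 + b4 * b4 * se2 * se2)
        z = np.where(se_ind > 0, indirect / se_ind, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(se_ind > 0, p, np.where(indirect == 0.0, 1.0, 0.0))
    bad = ~valid
    out = {"b2": b2, "se2": se2, "b4": b4, "se4": se4, "b5": b5, "se5": se5,
           "indirect": indirect, "se_ind": se_ind, "z": z, "p": p, "n": n}
    for key in out:
        if key != "n":
            out[key] = np.where(bad, np.nan, out[key])
    return out


def _as_values(y, sample_ids: list[str]) -> np.ndarray:
    if isinstance(y, AdjustedVector):
        if y.sample_ids != sample_ids:
            raise ValueError("phenotype samples are not aligned with the genotype matrix")
        return y.values
    y = np.asarray(y, dtype=float)
    if y.shape != (len(sample_ids),):
        raise ValueError("phenotype length does not match the sample count")
    return y


def scan_trios(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    y,
    cfg: RunConfig | None = None,
) -> Iterator[TrioResult]:
    """Genome-wide mediation scan over every SNP x probe pair.

    Inputs must already be sample-aligned, QC'd and normalized.  For each
    pair the step-2 and step-4 regressions are fitted and the Sobel result
    computed; when ``cfg.permutations`` > 0 a permutation p-value is added
    for pairs whose analytic p falls below ``cfg.trio_p_cutoff``
    (screen-then-permute).  Results stream in deterministic SNP-major
    order; only significant trios are emitted unless ``cfg.emit_all``.
    Processing is chunked in blocks of ``cfg.block_size`` SNPs; the output
    is independent of the block size.
    """
    cfg = cfg or RunConfig()
    if g.sample_ids != e.sample_ids:
        raise ValueError("genotype and expression samples are not aligned")
    yv = _as_values(y, g.sample_ids)
    n_snps = g.n_snps
    block = cfg.block_size
    for start in range(0, n_snps, block):
        for j in range(start, min(start + block, n_snps)):
            x = g.dose[:, j]
            st = _snp_stats(x, e.values, yv)
            if cfg.emit_all:
                emit = np.arange(e.n_probes)
            else:
                with np.errstate(invalid="ignore"):
                    emit = np.flatnonzero(st["p"] < cfg.trio_p_cutoff)
            for k in emit:
                p_perm = None
                p_ana = float(st["p"][k])
                if (
                    cfg.permutations > 0
                    and np.isfinite(p_ana)
                    and p_ana < cfg.trio_p_cutoff
                ):
                    seed = np.random.SeedSequence((cfg.seed, j, int(k)))
                    null = permutation_null(
                        x, e.values[:, k], yv, cfg.permutations, seed
                    )
                    p_perm = permutation_pvalue(float(st["indirect"][k]), null)
                yield TrioResult(
                    snp_id=g.snp_ids[j],
                    probe_id=e.probe_ids[k],
                    beta2=float(st["b2"][k]),
                    beta4=float(st["b4"][k]),
                    beta5=float(st["b5"][k]),
                    sobel=SobelResult(
                        indirect=float(st["indirect"][k]),
                        se=float(st["se_ind"][k]),
                        z=float(st["z"][k]),
                        p_analytic=p_ana,
                    ),
                    p_permutation=p_perm,
                )
        if (start // block) % 10 == 0:
            log.debug("trio scan: %d/%d SNPs done", min(start + block, n_snps), n_snps)
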