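"""Synthetic genotype-expression-phenotype datasets with known architecture.

The generator emulates a liver-cohort-style study: a couple of hundred
samples, SNPs in Hardy-Weinberg proportions across 22 autosomes, a
continuous expression matrix, one quantitative enzyme-activity phenotype
and age/sex covariates.  Mediated trios (SNP -> probe -> phenotype),
trans-eQTL hotspot SNPs driving many probes, and direct SNP effects can be
planted with known effect sizes, and the full ground truth is returned so
scans can be scored for true and false positives.

Effects are linear-additive with Gaussian noise, the model family the
mediation regressions assume; array-level artifacts and linkage
disequilibrium between SNPs are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenotypeMatrix, PhenotypeTable

N_CHROMS = 22
_AGE_LOW, _AGE_HIGH = 20.0, 80.0
_AGE_SD = (_AGE_HIGH - _AGE_LOW) / np.sqrt(12.0)


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset; defaults give a null study."""

    n_samples: int = 200
    n_snps: int = 500
    n_probes: int = 1000
    maf_range: tuple[float, float] = (0.10, 0.50)
    planted_trios: list[tuple[int, int, float, float]] = field(default_factory=list)
    # (snp index, probe index, beta2 true, beta4 true)
    hotspot_spec: list[tuple[int, list[int], float]] = field(default_factory=list)
    # (snp index, probe indices, per-probe effect size)
    direct_effects: list[tuple[int, float]] = field(default_factory=list)
    # (snp index, beta5 true)
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    age_effect: float = 0.2   # phenotype SD per SD of age
    sex_effect: float = 0.4   # phenotype shift for sex == 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must be in [0, 0.5)")
        if min(self.n_samples, self.n_snps, self.n_probes) < 1:
            raise ValueError("n_samples, n_snps and n_probes must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for si, pi, *_ in self.planted_trios:
            if not (0 <= si < self.n_snps and 0 <= pi < self.n_probes):
                raise ValueError(f"planted trio index ({si}, {pi}) out of range")
        for si, probes, _eff in self.hotspot_spec:
            if not 0 <= si < self.n_snps:
                raise ValueError(f"hotspot SNP index {si} out of range")
            if any(not 0 <= pj < self.n_probes for pj in probes):
                raise ValueError("hotspot probe index out of range")
        for si, _b in self.direct_effects:
            if not 0 <= si < self.n_snps:
                raise ValueError(f"direct-effect SNP index {si} out of range")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, sufficient to score any scan."""

    spec: SimulationSpec
    mafs: np.ndarray
    complete_dose: np.ndarray          # doses before missingness masking
    snp_ids: list[str]
    probe_ids: list[str]
    age: np.ndarray
    sex: np.ndarray

    def true_trio_ids(self) -> set[tuple[str, str]]:
        return {
            (self.snp_ids[si], self.probe_ids[pi])
            for si, pi, b2, b4 in self.spec.planted_trios
            if b2 != 0.0 and b4 != 0.0
        }

    def true_eqtl_ids(self) -> set[tuple[str, str]]:
        pairs = {
            (self.snp_ids[si], self.probe_ids[pi])
            for si, pi, b2, _b4 in self.spec.planted_trios
            if b2 != 0.0
        }
        for si, probes, eff in self.spec.hotspot_spec:
            if eff != 0.0:
                pairs |= {(self.snp_ids[si], self.probe_ids[pj]) for pj in probes}
        return pairs

    def score_pairs(self, found: set[tuple[str, str]], truth: set[tuple[str, str]]
                    ) -> tuple[int, int]:
        """(true positives, false positives) of a discovered pair set."""
        tp = len(found & truth)
        return tp, len(found) - tp


def _coordinates(n: int, prefix: str, spacing: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Spread n features over 22 chromosomes with evenly spaced 1-based positions."""
    ids = [f"{prefix}{i}" for i in range(n)]
    chrom_idx = np.arange(n) % N_CHROMS + 1
    pos = (np.arange(n) // N_CHROMS + 1) * spacing
    chroms = np.asarray([str(c) for c in chrom_idx], dtype=object)
    return ids, chroms, pos.astype(int)


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw per-SNP MAFs uniformly in ``maf_range`` and doses from HWE proportions.

    Missingness is sprinkled independently at ``missing_rate``.  The
    pre-masking doses are kept on the returned object (attribute
    ``_complete_dose``) so downstream phenotype simulation can use the true
    genotypes.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    mafs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    dose = rng.binomial(2, mafs[None, :], size=(spec.n_samples, spec.n_snps)).astype(float)
    complete = dose.copy()
    if spec.missing_rate > 0:
        mask = rng.random(dose.shape) < spec.missing_rate
        dose[mask] = np.nan
    snp_ids, chroms, pos = _coordinates(spec.n_snps, "snp", 100_000)
    g = GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(spec.n_samples)],
        snp_ids=snp_ids,
        dose=dose,
        snp_chrom=chroms,
        snp_pos=pos,
    )
    g._complete_dose = complete  # type: ignore[attr-defined]
    g._mafs = mafs               # type: ignore[attr-defined]
    return g


def simulate_expression_and_phenotype(
    g: GenotypeMatrix, spec: SimulationSpec
) -> tuple[ExpressionMatrix, PhenotypeTable, SimulationTruth]:
    """Generate expression and phenotype from the planted architecture.

    probe_j = sum(planted beta2 * dose) + hotspot effects + N(0, noise_sd^2);
    phenotype = sum(planted beta4 * probe) + sum(direct beta5 * dose)
                + age/sex effects + N(0, noise_sd^2).
    """
    if g.n_snps != spec.n_snps or g.n_samples != spec.n_samples:
        raise ValueError("genotype matrix inconsistent with the simulation spec")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    dose = getattr(g, "_complete_dose", None)
    if dose is None:
        # observed doses with missing entries imputed at the per-SNP mean
        dose = g.dose.copy()
        mu = np.nanmean(dose, axis=0)
        idx = np.where(np.isnan(dose))
        dose[idx] = mu[idx[1]]

    n, P = spec.n_samples, spec.n_probes
    E = rng.normal(0.0, spec.noise_sd, size=(n, P))
    for si, pi, b2, _b4 in spec.planted_trios:
        E[:, pi] += b2 * dose[:, si]
    for si, probes, eff in spec.hotspot_spec:
        for pj in probes:
            E[:, pj] += eff * dose[:, si]

    age = rng.uniform(_AGE_LOW, _AGE_HIGH, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    y = rng.normal(0.0, spec.noise_sd, size=n)
    for si, pi, _b2, b4 in spec.planted_trios:
        y += b4 * E[:, pi]
    for si, b5 in spec.direct_effects:
        y += b5 * dose[:, si]
    y += spec.age_effect * (age - (_AGE_LOW + _AGE_HIGH) / 2.0) / _AGE_SD
    y += spec.sex_effect * sex

    probe_ids, pchrom, ppos = _coordinates(P, "probe", 130_000)
    e = ExpressionMatrix(
        sample_ids=list(g.sample_ids),
        probe_ids=probe_ids,
        values=E,
        probe_chrom=pchrom,
        probe_pos=ppos,
    )
    pt = PhenotypeTable(sample_ids=list(g.sample_ids), trait=y, age=age, sex=sex)
    truth = SimulationTruth(
        spec=spec,
        mafs=getattr(g, "_mafs", np.full(spec.n_snps, np.nan)),
        complete_dose=dose,
        snp_ids=list(g.snp_ids),
        probe_ids=probe_ids,
        age=age,
        sex=sex,
    )
    return e, pt, truth


def simulate_dataset(
    spec: SimulationSpec, outdir: str | Path | None = None
) -> tuple[GenotypeMatrix, ExpressionMatrix, PhenotypeTable, SimulationTruth]:
    """Generate a full dataset; optionally write the pipeline's TSV inputs."""
    g = simulate_genotypes(spec)
    e, p, truth = simulate_expression_and_phenotype(g, spec)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genotype_tsv(g, outdir / "genotypes.tsv")
        write_expression_tsv(e, outdir / "expression.tsv")
        write_phenotype_tsv(p, outdir / "phenotype.tsv")
        write_annotation_tsv(g.snp_ids, g.snp_chrom, g.snp_pos,
                             outdir / "snp_annotation.tsv")
        write_annotation_tsv(e.probe_ids, e.probe_chrom, e.probe_pos,
                             outdir / "probe_annotation.tsv")
    return g, e, p, truth


# ---------------------------------------------------------------------------
# TSV writers matching the io readers (features in rows, samples in columns)


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(g.sample_ids) + "\n")
        for j, snp in enumerate(g.snp_ids):
            row = ["NA" if np.isnan(v) else str(int(v)) for v in g.dose[:, j]]
            fh.write(snp + "\t" + "\t".join(row) + "\n")


def write_expression_tsv(e: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\t" + "\t".join(e.sample_ids) + "\n")
        for j, probe in enumerate(e.probe_ids):
            row = ["NA" if np.isnan(v) else format(v, ".10g") for v in e.values[:, j]]
            fh.write(probe + "\t" + "\t".join(row) + "\n")


def write_phenotype_tsv(p: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttrait\tage\tsex\n")
        for i, s in enumerate(p.sample_ids):
            trait = "NA" if np.isnan(p.trait[i]) else format(p.trait[i], ".10g")
            fh.write(f"{s}\t{trait}\t{p.age[i]:.10g}\t{int(p.sex[i])}\n")


def write_annotation_tsv(ids, chroms, pos, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\n")
        for i, c, x in zip(ids, chroms, pos):
            fh.write(f"{i}\t{c}\t{int(x)}\n")
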