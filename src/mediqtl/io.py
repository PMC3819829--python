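"""Readers, writers and in-memory containers for the formats the pipeline touches.

Matrix TSV dialect: features (SNPs or probes) as rows, samples as columns,
header row of sample ids, first column the feature id.  Genotypes are
gene-dose coded 0/1/2 (count of alternate alleles); "NA", "" and "." all
denote missing.  Annotation maps are three-column TSVs (id, chrom, pos),
coordinates 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING_TOKENS = frozenset({"NA", "", ".", "na", "NaN", "nan"})


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs gene-dose matrix (values 0/1/2, NaN = missing)."""

    sample_ids: list[str]
    snp_ids: list[str]
    dose: np.ndarray
    snp_chrom: np.ndarray | None = None  # chromosome label per SNP
    snp_pos: np.ndarray | None = None    # 1-based bp position per SNP

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dose shape {self.dose.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.snp_ids, "SNP")
        bad = ~(np.isnan(self.dose) | np.isin(self.dose, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype dose must be 0/1/2/missing; found "
                f"{self.dose[i, j]!r} at sample {self.sample_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r}"
            )
        for arr_name in ("snp_chrom", "snp_pos"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (len(self.snp_ids),):
                    raise ValueError(f"{arr_name} length mismatch")
                setattr(self, arr_name, arr)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            dose=self.dose[idx, :],
        )

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            snp_ids=[self.snp_ids[j] for j in idx],
            dose=self.dose[:, idx],
            snp_chrom=None if self.snp_chrom is None else self.snp_chrom[idx],
            snp_pos=None if self.snp_pos is None else self.snp_pos[idx],
        )


@dataclass
class ExpressionMatrix:
    """Samples x probes continuous expression matrix."""

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    probe_chrom: np.ndarray | None = None
    probe_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.probe_ids)} probes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.probe_ids, "probe")
        if self.values.size and np.isnan(self.values).all(axis=0).any():
            j = int(np.isnan(self.values).all(axis=0).argmax())
            raise ValueError(f"probe {self.probe_ids[j]!r} is entirely missing")
        for arr_name in ("probe_chrom", "probe_pos"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (len(self.probe_ids),):
                    raise ValueError(f"{arr_name} length mismatch")
                setattr(self, arr_name, arr)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx, :],
        )


@dataclass
class PhenotypeTable:
    """One quantitative trait per sample plus the age/sex covariates."""

    sample_ids: list[str]
    trait: np.ndarray
    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        self.trait = np.asarray(self.trait, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex)
        for name in ("trait", "age", "sex"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one value per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, idx: np.ndarray) -> "PhenotypeTable":
        idx = np.asarray(idx)
        return PhenotypeTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            trait=self.trait[idx],
            age=self.age[idx],
            sex=self.sex[idx],
        )


# ---------------------------------------------------------------------------
# readers


def _read_matrix_tsv(path: str | Path, what: str) -> tuple[list[str], list[str], np.ndarray]:
    """Parse a features-in-rows TSV; returns (sample_ids, feature_ids, samples x features)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.name is None and df.shape[1] == 0:
        raise ValueError(f"{path}: malformed header line (no sample columns)")
    sample_ids = [str(c) for c in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: malformed header line: duplicate sample ids")
    feature_ids = [str(i) for i in df.index]
    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(raw[i, j]).strip()
            if tok in MISSING_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError:
                    raise ValueError(
                        f"{path}: invalid {what} token {tok!r} at row "
                        f"{feature_ids[i]!r} (line {i + 2}), column "
                        f"{sample_ids[j]!r}"
                    ) from None
    return sample_ids, feature_ids, values.T


def read_genotype_matrix(path: str | Path, fmt: str = "tsv") -> GenotypeMatrix:
    """Read a gene-dose genotype matrix from TSV (SNPs as rows) or VCF.

    VCF records are converted to alternate-allele dose; multi-allelic records
    are skipped with a warning and "./." genotypes become missing.
    """
    if fmt == "tsv":
        sample_ids, snp_ids, dose = _read_matrix_tsv(path, "genotype")
        ok = np.isnan(dose) | np.isin(dose, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok.T)[0]  # back to file orientation
            raise ValueError(
                f"{path}: invalid genotype value {dose[j, i]!r} at row "
                f"{snp_ids[i]!r} (line {i + 2}), column {sample_ids[j]!r}: "
                "expected 0, 1, 2 or NA"
            )
        return GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_ids, dose=dose)
    if fmt == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    cols: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dose_map = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning(
                "skipping multi-allelic record %s:%s (%d ALT alleles)",
                var.CHROM, var.POS, len(var.ALT),
            )
            continue
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        cols.append(dose_map[np.asarray(var.gt_types)])
    vcf.close()
    if not cols:
        dose = np.empty((len(sample_ids), 0))
    else:
        dose = np.column_stack(cols)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        dose=dose,
        snp_chrom=np.asarray(chroms, dtype=object),
        snp_pos=np.asarray(poss, dtype=int),
    )


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probes-in-rows expression TSV; entirely-missing probes are dropped."""
    sample_ids, probe_ids, values = _read_matrix_tsv(path, "expression")
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        dropped = [probe_ids[j] for j in np.flatnonzero(all_missing)]
        log.warning("dropping %d entirely-missing probes: %s",
                    len(dropped), ", ".join(dropped[:5]))
        keep = np.flatnonzero(~all_missing)
        probe_ids = [probe_ids[j] for j in keep]
        values = values[:, keep]
    return ExpressionMatrix(sample_ids=sample_ids, probe_ids=probe_ids, values=values)


def read_phenotype_table(path: str | Path, trait: str = "trait") -> PhenotypeTable:
    """Read the per-sample trait/age/sex table (columns: sample_id, trait, age, sex)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", trait, "age", "sex"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return PhenotypeTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        trait=df[trait].to_numpy(dtype=float),
        age=df["age"].to_numpy(dtype=float),
        sex=df["sex"].to_numpy(),
    )


def read_annotation_map(path: str | Path) -> pd.DataFrame:
    """Read an (id, chrom, pos) map; returns a DataFrame indexed by id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: annotation map needs columns id, chrom, pos")
    df.columns = ["id", "chrom", "pos"] + list(df.columns[3:])
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    return df.set_index("id")


def attach_snp_annotation(g: GenotypeMatrix, ann: pd.DataFrame) -> GenotypeMatrix:
    sub = ann.reindex(g.snp_ids)
    missing = sub["pos"].isna()
    if missing.any():
        log.warning("%d SNPs lack annotation; their coordinates are unknown",
                    int(missing.sum()))
    chrom = sub["chrom"].to_numpy(dtype=object)
    pos = sub["pos"].to_numpy(dtype=float)
    return replace(g, snp_chrom=chrom, snp_pos=pos)


def attach_probe_annotation(e: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    sub = ann.reindex(e.probe_ids)
    chrom = sub["chrom"].to_numpy(dtype=object)
    pos = sub["pos"].to_numpy(dtype=float)
    return replace(e, probe_chrom=chrom, probe_pos=pos)


# ---------------------------------------------------------------------------
# sample alignment


def align_samples(
    g: GenotypeMatrix, e: ExpressionMatrix, p: PhenotypeTable
) -> tuple[GenotypeMatrix, ExpressionMatrix, PhenotypeTable]:
    """Restrict all three inputs to their shared samples, in one shared order.

    The shared order is the genotype sample order filtered to the
    intersection, so aligning already-aligned inputs is the identity.
    """
    common = set(g.sample_ids) & set(e.sample_ids) & set(p.sample_ids)
    if not common:
        raise ValueError("no samples shared between genotype, expression and phenotype")
    order = [s for s in g.sample_ids if s in common]
    log.info("aligned to %d shared samples", len(order))

    def idx(ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(ids)}
        return np.asarray([pos[s] for s in order])

    return (
        g.subset_samples(idx(g.sample_ids)),
        e.subset_samples(idx(e.sample_ids)),
        p.subset_samples(idx(p.sample_ids)),
    )


# ---------------------------------------------------------------------------
# writers


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return format(float(x), ".10g")


TRIO_COLUMNS = (
    "snp_id", "probe_id", "beta2", "beta4", "beta5",
    "sobel_z", "p_analytic", "p_permutation",
)


def write_trio_results(results: Iterable, path: str | Path) -> None:
    """Write trio records as TSV with the fixed 8-column schema."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRIO_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    (
                        r.snp_id,
                        r.probe_id,
                        _fmt(r.beta2),
                        _fmt(r.beta4),
                        _fmt(r.beta5),
                        _fmt(r.sobel.z),
                        _fmt(r.sobel.p_analytic),
                        _fmt(r.p_permutation),
                    )
                )
                + "\n"
            )


def read_trio_results(path: str | Path):
    """Read back a trio TSV as a list of TrioResult records."""
    from .mediation import SobelResult, TrioResult

    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "probe_id": str},
                     na_values=["NA"], keep_default_na=False)
    if list(df.columns) != list(TRIO_COLUMNS):
        raise ValueError(f"{path}: unexpected trio columns {list(df.columns)}")
    out = []
    for row in df.itertuples(index=False):
        b2, b4 = float(row.beta2), float(row.beta4)
        z = float(row.sobel_z)
        indirect = b2 * b4
        se = abs(indirect / z) if (z != 0.0 and np.isfinite(z)) else np.nan
        out.append(
            TrioResult(
                snp_id=row.snp_id,
                probe_id=row.probe_id,
                beta2=b2,
                beta4=b4,
                beta5=float(row.beta5),
                sobel=SobelResult(
                    indirect=indirect, se=se, z=z,
                    p_analytic=float(row.p_analytic),
                ),
                p_permutation=None if pd.isna(row.p_permutation) else float(row.p_permutation),
            )
        )
    return out
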