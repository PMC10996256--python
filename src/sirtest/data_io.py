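"""Data model, validation and IO for genotype/phenotype tables.

Genotypes are minor-allele counts in {0, 1, 2} for n individuals at k SNPs;
phenotypes are q continuous traits on the same individuals.  Both are stored
as plain delimited text (header row of column ids, first column of sample
ids) so that a write/read round trip is exact up to float formatting.  VCF
input is supported for genotypes via cyvcf2 (alternate-allele dosages from
the GT field, optionally flipped to minor-allele counts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sirtest")

MissingPolicy = Literal["drop", "error", "mean"]


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x k matrix of minor-allele counts with sample and SNP identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError("genotype values must be a 2-D matrix")
        n, k = values.shape
        if n < 2 or k < 1:
            raise ValidationError(f"need n >= 2 individuals and k >= 1 SNPs, got {n}x{k}")
        bad = ~np.isin(values, (0, 1, 2))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"genotype entry {values[i, j]!r} at sample {self.sample_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r} is not in {{0, 1, 2}}"
            )
        object.__setattr__(self, "values", values.astype(np.int64))
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample ids"))
        object.__setattr__(self, "snp_ids", _check_ids(self.snp_ids, "SNP ids"))
        if len(self.sample_ids) != n or len(self.snp_ids) != k:
            raise ValidationError("id lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.snp_ids)


@dataclass(frozen=True)
class PhenotypeMatrix:
    """n x q matrix of continuous traits with sample and trait identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    trait_ids: list[str]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("phenotype values must be a 2-D matrix")
        if not np.isfinite(values).all():
            i, j = map(int, np.argwhere(~np.isfinite(values))[0])
            raise ValidationError(
                f"non-finite phenotype at sample {self.sample_ids[i]!r}, "
                f"trait {self.trait_ids[j]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample ids"))
        object.__setattr__(self, "trait_ids", _check_ids(self.trait_ids, "trait ids"))
        if len(self.sample_ids) != values.shape[0] or len(self.trait_ids) != values.shape[1]:
            raise ValidationError("id lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.trait_ids)


@dataclass(frozen=True)
class RunConfig:
    """Run-wide settings: nominal level, permutation count, slicing strategy.

    ``target_slice_size`` and ``min_slice_size`` only matter under
    relatedness slicing; ``min_slice_size`` defaults to 5 so that every merged
    slice holds at least five individuals.
    """

    alpha: float = 0.05
    n_permutations: int = 1000
    slicing: Literal["exhaustive", "relatedness"] = "exhaustive"
    target_slice_size: int = 10
    min_slice_size: int = 5
    d0: int = 1
    seed: int = 0
    exhaustive_cap: int = 3**10

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.min_slice_size < 2:
            raise ValidationError("min_slice_size must be >= 2")
        if self.d0 < 1:
            raise ValidationError("d0 must be >= 1")
        if self.slicing not in ("exhaustive", "relatedness"):
            raise ValidationError(f"unknown slicing strategy {self.slicing!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON; keys map 1:1 onto fields."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_matrix(
    path: str | Path,
    kind: Literal["genotype", "phenotype"],
    missing: MissingPolicy = "drop",
) -> GenotypeMatrix | PhenotypeMatrix:
    """Read a delimited genotype or phenotype table.

    The file must have a header row of column ids and sample ids in the first
    column.  Missing entries are handled per ``missing``: ``drop`` removes the
    affected rows (complete-case analysis, the default), ``error`` raises, and
    ``mean`` imputes the column mean (rounded to the nearest valid count for
    genotypes).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample ids in first column")
    na_mask = df.isna()
    if kind == "phenotype":
        for col in df.columns:
            nonnum = pd.to_numeric(df[col], errors="coerce")
            bad = nonnum.isna() & ~na_mask[col]
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValidationError(
                    f"{path}: non-numeric phenotype {df[col][bad].iloc[0]!r} "
                    f"at sample {row!r}, trait {col!r}"
                )
            df[col] = nonnum
        na_mask = df.isna()
    if na_mask.any().any():
        n_bad = int(na_mask.any(axis=1).sum())
        if missing == "error":
            i, j = np.argwhere(na_mask.values)[0]
            raise ValidationError(
                f"{path}: missing value at sample {df.index[i]!r}, column {df.columns[j]!r}"
            )
        if missing == "drop":
            logger.info("%s: dropping %d rows with missing values", path, n_bad)
            df = df.loc[~na_mask.any(axis=1)]
        else:  # mean
            logger.info("%s: mean-imputing %d rows", path, n_bad)
            means = df.astype(float).mean()
            if kind == "genotype":
                means = means.round().clip(0, 2)
            df = df.fillna(means)
    ids = [str(x) for x in df.index]
    cols = [str(c) for c in df.columns]
    if kind == "genotype":
        values = df.to_numpy()
        if not np.issubdtype(np.asarray(values).dtype, np.number):
            raise ValidationError(f"{path}: non-numeric genotype entries")
        fv = values.astype(float)
        if not np.all(fv == np.round(fv)):
            i, j = map(int, np.argwhere(fv != np.round(fv))[0])
            raise ValidationError(
                f"{path}: non-integer genotype {fv[i, j]} at sample {ids[i]!r}, SNP {cols[j]!r}"
            )
        return GenotypeMatrix(fv.astype(np.int64), ids, cols)
    return PhenotypeMatrix(df.to_numpy(dtype=float), ids, cols)


def write_matrix(mat: GenotypeMatrix | PhenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    # %.17g preserves doubles exactly, so write -> read round-trips
    mat.to_frame().to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def read_vcf_dosages(
    path: str | Path,
    missing: MissingPolicy = "error",
    flip_to_minor: bool = False,
) -> GenotypeMatrix:
    """Read biallelic GT dosages (alternate-allele counts) from a VCF.

    Multi-allelic sites are skipped with a warning.  ``flip_to_minor`` recodes
    columns whose alternate-allele frequency exceeds 0.5 as 2 - dosage, so the
    counts refer to the minor allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d", rec.CHROM, rec.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012=False maps hom-alt to 3)
        dosage = np.array([a + b if a >= 0 and b >= 0 else -1
                           for a, b, *_ in rec.genotypes], dtype=float)
        dosage[dosage < 0] = np.nan
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        rows.append(dosage)
    vcf.close()
    if not rows:
        raise ValidationError(f"{path}: no usable biallelic sites")
    values = np.column_stack(rows)
    nan = np.isnan(values)
    if nan.any():
        if missing == "error":
            i, j = map(int, np.argwhere(nan)[0])
            raise ValidationError(
                f"{path}: missing GT for sample {samples[i]!r} at {snp_ids[j]!r}"
            )
        if missing == "drop":
            keep = ~nan.any(axis=1)
            logger.info("%s: dropping %d samples with missing GT", path, int((~keep).sum()))
            values, samples = values[keep], [s for s, k in zip(samples, keep) if k]
        else:
            col_mean = np.nanmean(values, axis=0)
            values = np.where(nan, np.round(col_mean).clip(0, 2), values)
    if flip_to_minor:
        freq = values.mean(axis=0) / 2.0
        flip = freq > 0.5
        values[:, flip] = 2 - values[:, flip]
        if flip.any():
            logger.info("flipped %d columns to minor-allele counts", int(flip.sum()))
    return GenotypeMatrix(values.astype(np.int64), samples, snp_ids)


def align_samples(
    G: GenotypeMatrix, Y: PhenotypeMatrix
) -> tuple[GenotypeMatrix, PhenotypeMatrix]:
    """Restrict both matrices to the shared samples, in G's row order."""
    common = [s for s in G.sample_ids if s in set(Y.sample_ids)]
    if not common:
        raise ValidationError("no samples shared between genotype and phenotype tables")
    dropped = (G.n - len(common)) + (Y.n - len(common))
    if dropped:
        logger.info("align_samples: dropped %d unmatched rows", dropped)
    gi = [G.sample_ids.index(s) for s in common]
    yi = {s: i for i, s in enumerate(Y.sample_ids)}
    G2 = GenotypeMatrix(G.values[gi], common, G.snp_ids)
    Y2 = PhenotypeMatrix(Y.values[[yi[s] for s in common]], common, Y.trait_ids)
    return G2, Y2
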