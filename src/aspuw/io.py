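"""Readers, writers and validated in-memory containers.

All tabular artifacts are TSV with a header row.  Conventions:

* samples table: ``sample_id``, ``family_id``, ``phenotype``, then one
  column per covariate (an explicit ``intercept`` column is expected in
  the covariate set used for modelling);
* methylation matrix: rows are CpG sites (first column ``cpg_id``),
  columns are samples — the common array-export orientation;
* CpG manifest: ``cpg_id``, ``chrom``, ``pos``;
* genotype matrix: rows are SNPs (first column ``snp_id``), columns are
  samples, additive coding 0/1/2, missing values allowed (``NA``);
* gene annotation: BED, 0-based half-open, columns chrom/start/end/name.

Sample columns of the methylation and genotype files are aligned to the
sample table by ``sample_id``, never by position.  Loaders reject
malformed values instead of coercing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ValidationError

__all__ = [
    "SampleFrame",
    "MethylationMatrix",
    "GenotypeMatrix",
    "GeneAnnotation",
    "read_samples",
    "write_samples",
    "read_methylation",
    "write_methylation",
    "read_genotypes",
    "write_genotypes",
    "read_genes",
    "write_genes",
    "read_matrix",
    "write_matrix",
    "write_results",
]


@dataclass
class SampleFrame:
    """Per-individual phenotype, family labels and covariates.

    Parameters
    ----------
    data
        One row per individual with columns ``sample_id``, ``family_id``,
        optionally ``phenotype``, and the covariate columns.
    covariates
        Names of the covariate columns forming the fixed-effect design
        matrix (include ``intercept`` explicitly).
    """

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        required = {"sample_id", "family_id"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"samples table missing columns: {sorted(missing)}")
        ids = self.data["sample_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValidationError(f"duplicate sample_ids: {dups[:5]}")
        for c in self.covariates:
            if c not in self.data.columns:
                raise ValidationError(f"covariate column {c!r} not in samples table")
        if self.covariates:
            X = self.exog
            if not np.all(np.isfinite(X)):
                raise ValidationError("non-finite covariate values")
            # rank is only meaningful once there are at least q rows
            if self.n >= self.q and np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValidationError("covariate matrix is rank deficient")
        if "phenotype" in self.data.columns:
            ph = pd.to_numeric(self.data["phenotype"], errors="coerce")
            if ph.notna().any() and ph.isna().any():
                bad = self.data.loc[ph.isna(), "sample_id"].tolist()
                raise ValidationError(f"missing phenotype for samples {bad[:5]}")

    # -- convenience accessors -------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def q(self) -> int:
        return len(self.covariates)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy()

    @property
    def family_ids(self) -> np.ndarray:
        return self.data["family_id"].to_numpy()

    @property
    def endog(self) -> np.ndarray:
        """Phenotype vector y."""
        if "phenotype" not in self.data.columns:
            raise ValidationError("samples table has no phenotype column")
        y = pd.to_numeric(self.data["phenotype"], errors="coerce").to_numpy(float)
        if np.isnan(y).any():
            raise ValidationError("phenotype contains missing values")
        return y

    @property
    def exog(self) -> np.ndarray:
        """Fixed-effect design matrix X (n x q)."""
        return self.data[self.covariates].to_numpy(float)

    def with_phenotype(self, y: np.ndarray) -> "SampleFrame":
        data = self.data.copy()
        data["phenotype"] = np.asarray(y, float)
        return SampleFrame(data, list(self.covariates))


@dataclass
class MethylationMatrix:
    """Beta-values (n samples x p CpGs) with a positional manifest."""

    values: np.ndarray  # n x p, all in [0, 1]
    manifest: pd.DataFrame  # cpg_id, chrom, pos
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.values.ndim != 2:
            raise ValidationError("methylation values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match matrix rows")
        if len(self.manifest) != p:
            raise ValidationError("manifest length does not match matrix columns")
        for col in ("cpg_id", "chrom", "pos"):
            if col not in self.manifest.columns:
                raise ValidationError(f"manifest missing column {col!r}")
        if self.manifest["cpg_id"].duplicated().any():
            raise ValidationError("duplicate cpg_ids in manifest")
        if (self.manifest["pos"].to_numpy() < 0).any():
            raise ValidationError("negative CpG positions in manifest")
        bad = ~np.isfinite(self.values) | (self.values < 0) | (self.values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta-value outside [0,1] at sample {self.sample_ids[i]!r}, "
                f"CpG {self.manifest['cpg_id'].iloc[j]!r}: {self.values[i, j]}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def cpg_ids(self) -> np.ndarray:
        return self.manifest["cpg_id"].to_numpy()

    def subset(self, col_idx) -> "MethylationMatrix":
        idx = np.asarray(col_idx)
        return MethylationMatrix(
            self.values[:, idx],
            self.manifest.iloc[idx].reset_index(drop=True),
            self.sample_ids,
        )


@dataclass
class GenotypeMatrix:
    """Additive-coded SNP genotypes (n samples x m SNPs), NaN = missing."""

    values: np.ndarray
    snp_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.snp_ids = np.asarray(self.snp_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValidationError("genotype matrix shape does not match id vectors")
        vals = self.values[~np.isnan(self.values)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("genotypes must be coded 0/1/2 (or missing)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval, BED semantics: 0-based half-open [start, end)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_samples(path, covariates: list[str] | None = None) -> SampleFrame:
    """Read the samples TSV.

    If ``covariates`` is None, every column other than sample_id,
    family_id and phenotype is treated as a covariate.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str})
    if covariates is None:
        covariates = [
            c for c in df.columns if c not in ("sample_id", "family_id", "phenotype")
        ]
    return SampleFrame(df, list(covariates))


def write_samples(path, frame: SampleFrame) -> None:
    cols = ["sample_id", "family_id"]
    if "phenotype" in frame.data.columns:
        cols.append("phenotype")
    cols += [c for c in frame.covariates if c not in cols]
    frame.data[cols].to_csv(path, sep="\t", index=False)


def _align_sample_columns(df: pd.DataFrame, id_col: str, samples: SampleFrame):
    """Reorder sample columns of a features-by-samples table to match
    ``samples``; raise AlignmentError naming any unmatched ID."""
    have = [c for c in df.columns if c != id_col]
    want = [str(s) for s in samples.sample_ids]
    missing = sorted(set(want) - set(have))
    extra = sorted(set(have) - set(want))
    if missing or extra:
        parts = []
        if extra:
            parts.append(f"unknown sample_ids in matrix file: {extra[:5]}")
        if missing:
            parts.append(f"sample_ids absent from matrix file: {missing[:5]}")
        raise AlignmentError("; ".join(parts))
    return df[want]


def read_methylation(path, manifest_path, samples: SampleFrame) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str})
    if "cpg_id" not in df.columns:
        raise ValidationError("methylation file must have a cpg_id column")
    manifest = pd.read_csv(
        manifest_path, sep="\t", dtype={"cpg_id": str, "chrom": str, "pos": int}
    )
    aligned = _align_sample_columns(df, "cpg_id", samples)
    values = aligned.to_numpy(float).T  # -> samples x CpGs
    man = manifest.set_index("cpg_id").loc[df["cpg_id"]].reset_index()
    return MethylationMatrix(values, man, samples.sample_ids)


def write_methylation(path, manifest_path, meth: MethylationMatrix) -> None:
    out = pd.DataFrame(meth.values.T, columns=[str(s) for s in meth.sample_ids])
    out.insert(0, "cpg_id", meth.cpg_ids)
    out.to_csv(path, sep="\t", index=False)
    meth.manifest.to_csv(manifest_path, sep="\t", index=False)


def read_genotypes(path, samples: SampleFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if "snp_id" not in df.columns:
        raise ValidationError("genotype file must have a snp_id column")
    aligned = _align_sample_columns(df, "snp_id", samples)
    values = aligned.to_numpy(float).T
    return GenotypeMatrix(values, df["snp_id"].to_numpy(), samples.sample_ids)


def write_genotypes(path, geno: GenotypeMatrix) -> None:
    out = pd.DataFrame(geno.values.T, columns=[str(s) for s in geno.sample_ids])
    out.insert(0, "snp_id", geno.snp_ids)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_genes(path) -> list[GeneAnnotation]:
    """Read a 4-column BED file (chrom, start, end, gene_id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "start": int, "end": int, "gene_id": str},
    )
    if df["gene_id"].isna().any():
        raise ValidationError("BED file must have 4 columns (chrom start end name)")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene_ids in BED: {dups[:5]}")
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def write_genes(path, genes: list[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a square matrix TSV with sample IDs as header and first column.

    Returns (matrix, sample_ids).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError("matrix file row and column IDs differ")
    return df.to_numpy(float), df.index.to_numpy()


def write_matrix(path, matrix: np.ndarray, sample_ids) -> None:
    ids = [str(s) for s in sample_ids]
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def write_results(path, scan_result) -> None:
    """Write a genome-scan results table as TSV."""
    scan_result.table.to_csv(path, sep="\t", index=False)
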