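"""Input tables, validation, and expression preprocessing.

TSV conventions: expression is genes x samples with a header row of sample
ids and gene ids in the first column; genotypes are markers x samples coded
either ``A/H/B`` or dosage ``0/1/2`` (0 -> A, 1 -> H, 2 -> B); the gene map has
columns ``gene_id``, ``chrom``, ``pos``.  Chromosomes are integers, with 0
reserved for the mitochondrial genome and -1 for unplaced scaffolds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: integer genotype codes used internally
GENO_A, GENO_H, GENO_B, GENO_NA = 0, 1, 2, -1

CODE_TO_LABEL = {GENO_A: "A", GENO_H: "H", GENO_B: "B", GENO_NA: "NA"}
LABEL_TO_CODE = {"A": GENO_A, "H": GENO_H, "B": GENO_B}
DOSAGE_TO_CODE = {"0": GENO_A, "1": GENO_H, "2": GENO_B}

#: tokens treated as missing genotype calls
MISSING_TOKENS = {"NA", "", ".", "nan", "NaN"}


class ProcessingState(str, Enum):
    """Whether an expression matrix holds raw counts or residualized values."""

    RAW_COUNTS = "raw_counts"
    RESIDUALIZED = "residualized"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a processing state.

    ``values`` has shape (p_genes, n_samples).  In ``RAW_COUNTS`` state all
    entries must be nonnegative integers; in ``RESIDUALIZED`` state every gene
    row has (numerically) zero mean across samples.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    state: ProcessingState = ProcessingState.RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.state = ProcessingState(self.state)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if p != len(self.gene_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        if self.state is ProcessingState.RAW_COUNTS:
            bad = (self.values < 0) | (self.values % 1 != 0)
            if bad.any():
                j, k = np.argwhere(bad)[0]
                raise ValueError(
                    "raw counts must be nonnegative integers; offending cell "
                    f"gene {self.gene_ids[j]!r}, sample {self.sample_ids[k]!r} "
                    f"= {self.values[j, k]!r}"
                )
        else:
            row_means = self.values.mean(axis=1) if n else np.zeros(p)
            if p and np.abs(row_means).max() > 1e-6:
                raise ValueError("residualized rows must have zero mean")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Column indices of the given sample ids (error on unknown id)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message detail
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [lookup[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx], list(gene_ids), list(self.sample_ids), self.state
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        if self.state is ProcessingState.RAW_COUNTS:
            df = df.astype(int)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def load_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV of raw read counts.

    The header row holds sample ids; the first column holds gene ids.
    Duplicate ids and non-integer counts are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene id")
    _check_unique(sample_ids, "sample id")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression entry ({exc})") from None
    bad = ~np.isfinite(values) | (values < 0) | (values % 1 != 0)
    if bad.any():
        j, k = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-integer or negative count at gene {gene_ids[j]!r}, "
            f"sample {sample_ids[k]!r}: {df.iat[j, k]!r}"
        )
    expr = ExpressionMatrix(values, gene_ids, sample_ids, ProcessingState.RAW_COUNTS)
    logger.info("loaded expression: %d genes x %d samples", expr.n_genes, expr.n_samples)
    return expr


@dataclass
class Covariates:
    """Per-sample covariate table (numeric columns and/or factors).

    Factor (non-numeric) columns are one-hot encoded with the first level
    dropped, so the design stays full rank once an intercept is added.
    """

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        _check_unique(list(self.table.index), "covariate sample id")

    @classmethod
    def from_tsv(cls, path) -> "Covariates":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def design_matrix(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, list[str]]:
        """Encoded design (without intercept) aligned to the given samples."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"covariates missing for samples: {missing[:5]}")
        sub = self.table.loc[list(sample_ids)]
        numeric = sub.select_dtypes(include=[np.number])
        factors = sub.drop(columns=numeric.columns)
        parts = [numeric]
        if factors.shape[1]:
            parts.append(pd.get_dummies(factors.astype(str), drop_first=True, dtype=float))
        enc = pd.concat(parts, axis=1)
        if enc.isna().any().any():
            col = enc.columns[enc.isna().any()][0]
            raise ValueError(f"missing covariate values in column {col!r}")
        return enc.to_numpy(dtype=float), list(enc.columns)


def preprocess(
    expr: ExpressionMatrix,
    cov: Covariates | None = None,
    top_k: int | None = None,
    scale: float = 1e6,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Normalize, residualize against covariates, and keep the top-k genes.

    Pipeline: counts-per-``scale`` library-size normalization, then
    ``log2(x + pseudocount)``, then per-gene least-squares residualization on
    the covariates (with intercept), then ranking genes by post-normalization
    mean and subsetting to the ``top_k`` highest.  Already-residualized input
    skips the normalization step, which makes the operation idempotent.

    Returns a ``RESIDUALIZED`` matrix whose retained rows all have zero mean.
    """
    p, n = expr.values.shape
    if top_k is None:
        top_k = p
    if not 1 <= top_k <= p:
        raise ValueError(f"top_k={top_k} out of range [1, {p}]")

    if expr.state is ProcessingState.RAW_COUNTS:
        libsize = expr.values.sum(axis=0)
        if (libsize <= 0).any():
            bad = int(np.argmax(libsize <= 0))
            raise ValueError(f"sample {expr.sample_ids[bad]!r} has zero library size")
        logd = np.log2(expr.values / libsize * scale + pseudocount)
    else:
        logd = expr.values.copy()

    design = np.ones((n, 1))
    if cov is not None:
        enc, names = cov.design_matrix(expr.sample_ids)
        keep = enc.std(axis=0) > 0
        dropped = [nm for nm, k in zip(names, keep) if not k]
        if dropped:
            logger.warning("dropping constant covariate column(s): %s", dropped)
        enc = enc[:, keep]
        design = np.hstack([design, enc])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate design matrix is rank-deficient")

    coef, *_ = np.linalg.lstsq(design, logd.T, rcond=None)
    resid = logd - (design @ coef).T

    means = logd.mean(axis=1)
    order = sorted(range(p), key=lambda j: (-means[j], expr.gene_ids[j]))
    selected = sorted(order[:top_k])  # keep original row order
    out = ExpressionMatrix(
        resid[selected],
        [expr.gene_ids[j] for j in selected],
        list(expr.sample_ids),
        ProcessingState.RESIDUALIZED,
    )
    logger.info("preprocess: kept %d/%d genes", out.n_genes, p)
    return out


@dataclass
class GenotypeMatrix:
    """Markers x samples genotype codes with an optional marker map.

    ``codes`` is an int8 matrix over {0 (A), 1 (H), 2 (B), -1 (missing)}.
    """

    codes: np.ndarray
    marker_ids: list[str]
    sample_ids: list[str]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D matrix")
        m, n = self.codes.shape
        if m != len(self.marker_ids) or n != len(self.sample_ids):
            raise ValueError("genotype shape does not match marker/sample ids")
        _check_unique(self.marker_ids, "marker id")
        _check_unique(self.sample_ids, "sample id")
        valid = np.isin(self.codes, (GENO_A, GENO_H, GENO_B, GENO_NA))
        if not valid.all():
            i, k = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code at marker {self.marker_ids[i]!r}, "
                f"sample {self.sample_ids[k]!r}"
            )
        all_missing = (self.codes == GENO_NA).all(axis=1)
        if n and all_missing.any():
            i = int(np.argmax(all_missing))
            raise ValueError(f"marker {self.marker_ids[i]!r} has no non-missing genotypes")
        for arr_name in ("chrom", "pos"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=int)
                if arr.shape != (m,):
                    raise ValueError(f"marker {arr_name} must have length {m}")
                setattr(self, arr_name, arr)

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def reorder_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        """Align sample columns to the given id order (sets must match)."""
        if set(sample_ids) != set(self.sample_ids):
            raise ValueError("genotype and expression sample id sets differ")
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in sample_ids]
        return replace(self, codes=self.codes[:, idx], sample_ids=list(sample_ids))

    def to_tsv(self, path, coding: str = "AHB") -> None:
        if coding == "AHB":
            mapping = np.array(["A", "H", "B"], dtype=object)
        elif coding == "dosage012":
            mapping = np.array(["0", "1", "2"], dtype=object)
        else:
            raise ValueError(f"unknown coding {coding!r}")
        out = np.where(self.codes >= 0, mapping[np.clip(self.codes, 0, 2)], "NA")
        df = pd.DataFrame(out, index=self.marker_ids, columns=self.sample_ids)
        df.index.name = "marker_id"
        df.to_csv(path, sep="\t")


def load_genotypes(path, coding: str = "AHB") -> GenotypeMatrix:
    """Read a markers x samples genotype TSV.

    ``coding="AHB"`` accepts tokens A/H/B; ``coding="dosage012"`` maps
    0 -> A, 1 -> H, 2 -> B.  Tokens in :data:`MISSING_TOKENS` become missing.
    Any other token is a hard error naming the marker and sample.
    """
    if coding == "AHB":
        mapping = LABEL_TO_CODE
    elif coding == "dosage012":
        mapping = DOSAGE_TO_CODE
    else:
        raise ValueError(f"unknown genotype coding {coding!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    marker_ids = [str(m) for m in df.index]
    sample_ids = [str(s) for s in df.columns]
    codes = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy(dtype=object)
    for (i, k), token in np.ndenumerate(raw):
        token = str(token).strip()
        if token in MISSING_TOKENS:
            codes[i, k] = GENO_NA
        elif token in mapping:
            codes[i, k] = mapping[token]
        else:
            raise ValueError(
                f"{path}: unknown genotype token {token!r} at marker "
                f"{marker_ids[i]!r}, sample {sample_ids[k]!r}"
            )
    geno = GenotypeMatrix(codes, marker_ids, sample_ids)
    logger.info("loaded genotypes: %d markers x %d samples", geno.n_markers, geno.n_samples)
    return geno


def load_marker_map(path) -> pd.DataFrame:
    """Read a marker map TSV with columns marker_id, chrom, pos."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    required = {"marker_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: marker map needs columns {sorted(required)}")
    _check_unique(list(df["marker_id"]), "marker id")
    return df.set_index("marker_id")


def with_marker_map(geno: GenotypeMatrix, mmap: pd.DataFrame) -> GenotypeMatrix:
    """Attach chromosome/position columns from a marker map."""
    missing = [m for m in geno.marker_ids if m not in mmap.index]
    if missing:
        raise ValueError(f"marker map missing markers: {missing[:5]}")
    sub = mmap.loc[geno.marker_ids]
    return replace(
        geno,
        chrom=sub["chrom"].to_numpy(dtype=int),
        pos=sub["pos"].to_numpy(dtype=int),
    )


@dataclass
class GeneMap:
    """Gene locations: gene_id -> (chrom, pos).

    Chromosome coding: positive integers for regular chromosomes, 0 for the
    mitochondrial genome, -1 for unplaced scaffolds.  Positions are 1-based
    and used for ordering only.
    """

    table: pd.DataFrame  # indexed by gene_id with columns chrom, pos

    def __post_init__(self) -> None:
        required = {"chrom", "pos"}
        if not required <= set(self.table.columns):
            raise ValueError(f"gene map needs columns {sorted(required)}")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        _check_unique(list(self.table.index), "gene id")
        if (self.table["pos"] < 0).any():
            raise ValueError("gene positions must be >= 0")

    @classmethod
    def from_tsv(cls, path) -> "GeneMap":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        if "gene_id" not in df.columns:
            raise ValueError(f"{path}: gene map needs a gene_id column")
        return cls(df.set_index("gene_id"))

    def to_tsv(self, path) -> None:
        out = self.table.reset_index()
        out = out.rename(columns={out.columns[0]: "gene_id"})
        out.to_csv(path, sep="\t", index=False)

    def chrom_of(self, gene_ids: Sequence[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise ValueError(f"gene map missing genes: {missing[:5]}")
        return self.table.loc[list(gene_ids), "chrom"].to_numpy(dtype=int)
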