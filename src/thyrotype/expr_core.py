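"""Expression-matrix containers, file I/O and shared normalization primitives.

The pipeline works on a dense gene x sample matrix tagged with its unit
(``counts``, ``normlog``, ``fpkm`` or ``zscore``), a per-gene genomic
annotation (with chromosome-arm assignment) and a per-sample metadata table.
Counts are normalized with median-of-ratios size factors and a
``log2(count / factor + 1)`` transform — a declared, monotone stand-in for a
regularized-log transform; every downstream stage (median-centering,
variance ranking, PCA, K-means, signature scoring) needs only that the
transform is monotone and variance-tamed.

Genomic coordinates are stored 0-based half-open internally; GTF input
(1-based closed) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("thyrotype")

VALID_UNITS = ("counts", "normlog", "fpkm", "zscore")

#: autosomal chromosome arms; the five acrocentric short arms carry no
#: annotated protein-coding genes and are listed for completeness only.
ACROCENTRIC_P = ("13p", "14p", "15p", "21p", "22p")
AUTOSOME_ARMS = tuple(
    f"{c}{a}" for c in range(1, 23) for a in ("p", "q")
)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Dense gene x sample matrix with a unit tag.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    unit
        One of ``counts``, ``normlog``, ``fpkm``, ``zscore``.
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise DataError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene id(s): {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample id(s): {dup}")
        if self.unit in ("counts", "fpkm") and (self.values.to_numpy() < 0).any():
            raise DataError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise DataError(f"unknown sample id(s): {missing}")
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.unit)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise DataError(f"unknown gene id(s): {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)


ANNOTATION_COLUMNS = ["chromosome", "start", "end", "strand", "biotype", "length", "arm"]


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (index = gene_id, 0-based half-open)."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise DataError(f"annotation missing column(s): {missing}")
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene id(s) in annotation: {dup}")
    if (ann["start"] >= ann["end"]).any():
        bad = ann.index[ann["start"] >= ann["end"]].tolist()
        raise DataError(f"start >= end for gene(s): {bad}")
    if (ann["length"] <= 0).any():
        raise DataError("non-positive gene length in annotation")
    bad_arm = ~ann.apply(
        lambda r: str(r["arm"]).startswith(str(r["chromosome"]).removeprefix("chr")),
        axis=1,
    )
    if bad_arm.any():
        raise DataError(
            f"arm inconsistent with chromosome for gene(s): {ann.index[bad_arm].tolist()}"
        )
    return ann


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_counts(path, dialect: str = "tsv", strict: bool = True) -> ExpressionMatrix:
    """Read a gene x sample count matrix.

    ``tsv``: first column = gene id, header = sample ids.
    ``mtx``: MatrixMarket triplet at *path* with sibling index files
    ``<path>.genes.txt`` and ``<path>.samples.txt`` (one id per line).
    """
    path = str(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.columns.size == 0:
            raise DataError(f"{path}: no sample columns found")
    elif dialect == "mtx":
        mat = scipy.io.mmread(path)
        genes = _read_index_file(path + ".genes.txt")
        samples = _read_index_file(path + ".samples.txt")
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if arr.shape != (len(genes), len(samples)):
            raise DataError(
                f"{path}: matrix shape {arr.shape} does not match index files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(arr, index=genes, columns=samples)
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate gene id(s): {dup}")
    vals = df.to_numpy()
    if strict and not np.allclose(vals, np.round(vals)):
        raise DataError(f"{path}: non-integer counts in strict mode")
    logger.info("read_counts: %d genes x %d samples from %s", *df.shape, path)
    return ExpressionMatrix(df.astype(float), unit="counts")


def _read_index_file(path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise DataError(f"{path}: empty index file")
    return ids


def write_counts(m: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    path = str(path)
    if dialect == "tsv":
        out = m.values
        if m.unit == "counts":
            out = out.round().astype(int)
        out.to_csv(path, sep="\t", index_label="gene_id")
    elif dialect == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values.to_numpy()))
        with open(path + ".genes.txt", "w") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with open(path + ".samples.txt", "w") as fh:
            fh.write("\n".join(m.sample_ids) + "\n")
    else:
        raise DataError(f"unknown dialect {dialect!r}")


def read_annotation(path, dialect: str = "bed") -> pd.DataFrame:
    """Read a gene annotation table.

    ``bed``: BED-like TSV with header
    ``gene_id chromosome start end strand biotype length arm``
    (0-based half-open, stored as-is).
    ``gtf``: GTF ``gene`` features (1-based closed, converted to 0-based
    half-open) with ``gene_id``, ``gene_biotype``, ``gene_length`` and
    ``arm`` attributes.
    """
    path = str(path)
    if dialect == "bed":
        ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    elif dialect == "gtf":
        rows = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = _parse_gtf_attributes(f[8])
                gid = attrs.get("gene_id")
                if gid is None:
                    raise DataError(f"{path}: gene feature without gene_id")
                if gid in rows:
                    raise DataError(f"{path}: duplicate gene id {gid!r}")
                start1, end1 = int(f[3]), int(f[4])
                rows[gid] = {
                    "chromosome": f[0],
                    "start": start1 - 1,  # GTF is 1-based closed
                    "end": end1,
                    "strand": f[6],
                    "biotype": attrs.get("gene_biotype", ""),
                    "length": int(attrs.get("gene_length", end1 - start1 + 1)),
                    "arm": attrs.get("arm", ""),
                }
        ann = pd.DataFrame.from_dict(rows, orient="index")
        ann.index.name = "gene_id"
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    logger.info("read_annotation: %d genes from %s (%s)", len(ann), path, dialect)
    return validate_annotation(ann)


def _parse_gtf_attributes(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def write_annotation(ann: pd.DataFrame, path, dialect: str = "bed") -> None:
    path = str(path)
    if dialect == "bed":
        ann.to_csv(path, sep="\t", index_label="gene_id")
    elif dialect == "gtf":
        with open(path, "w") as fh:
            for gid, r in ann.iterrows():
                attrs = (
                    f'gene_id "{gid}"; gene_biotype "{r.biotype}"; '
                    f'gene_length "{int(r.length)}"; arm "{r.arm}";'
                )
                fh.write(
                    "\t".join(
                        [
                            str(r.chromosome), "thyrotype", "gene",
                            str(int(r.start) + 1), str(int(r.end)),
                            ".", str(r.strand), ".", attrs,
                        ]
                    )
                    + "\n"
                )
    else:
        raise DataError(f"unknown dialect {dialect!r}")


def read_samples(path) -> pd.DataFrame:
    """Read the sample metadata TSV (index = sample_id)."""
    tbl = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "role" not in tbl.columns:
        raise DataError(f"{path}: metadata must have a 'role' column")
    bad = ~tbl["role"].isin(["tumor", "normal"])
    if bad.any():
        raise DataError(f"{path}: invalid role(s): {tbl['role'][bad].unique().tolist()}")
    if "matched_normal_id" in tbl.columns:
        refs = tbl["matched_normal_id"].dropna()
        refs = refs[refs.astype(str).str.len() > 0]
        normals = set(tbl.index[tbl["role"] == "normal"])
        dangling = [r for r in refs if r not in normals]
        if dangling:
            raise DataError(f"{path}: matched_normal_id references non-normals: {dangling}")
    logger.info("read_samples: %d samples from %s", len(tbl), path)
    return tbl


# ---------------------------------------------------------------------------
# Normalization primitives
# ---------------------------------------------------------------------------

def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For every gene with a positive geometric mean across samples, the ratio
    count/geomean is formed; a sample's factor is the median ratio. A single
    sample gets factor 1 by convention.
    """
    if m.unit != "counts":
        raise DataError(f"size_factors requires counts, got {m.unit!r}")
    counts = m.values.to_numpy(dtype=float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=m.sample_ids, name="size_factor")
    with np.errstate(divide="ignore"):
        loggeo = np.mean(np.log(counts), axis=1)  # -inf where any zero
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise DataError("no gene has positive counts in every sample")
    ratios = np.log(counts[usable]) - loggeo[usable, None]
    factors = np.exp(np.median(ratios, axis=0))
    if not (factors > 0).all():
        raise DataError("non-positive size factor computed")
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def normlog(m: ExpressionMatrix, factors: pd.Series | None = None, pseudocount: float = 1.0) -> ExpressionMatrix:
    """``log2(count / size_factor + pseudocount)`` — the rlog stand-in."""
    if m.unit != "counts":
        raise DataError(f"normlog requires counts, got {m.unit!r}")
    if factors is None:
        factors = size_factors(m)
    f = np.asarray([factors[s] for s in m.sample_ids], dtype=float)
    if (f <= 0).any():
        raise DataError("size factors must be positive")
    vals = np.log2(m.values.to_numpy(dtype=float) / f[None, :] + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids), unit="normlog"
    )


def fpkm(m: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    """Fragments per kilobase per million: ``count * 1e9 / (length * library)``."""
    if m.unit != "counts":
        raise DataError(f"fpkm requires counts, got {m.unit!r}")
    missing = [g for g in m.gene_ids if g not in ann.index]
    if missing:
        raise DataError(f"gene(s) missing from annotation: {missing[:5]}")
    lengths = ann.loc[m.gene_ids, "length"].to_numpy(dtype=float)
    if (lengths <= 0).any() or np.isnan(lengths).any():
        raise DataError("missing or non-positive gene length")
    totals = m.values.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise DataError("sample with zero total counts")
    vals = m.values.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids), unit="fpkm"
    )


def median_center(m: ExpressionMatrix, axis: str = "genes") -> ExpressionMatrix:
    """Subtract the median along *axis*.

    ``genes``: each gene row is centered across samples (the signature-score
    convention). ``samples``: each sample column is centered across genes.
    Even-length medians use the mean-of-middle-two convention.
    """
    vals = m.values.to_numpy(dtype=float)
    if axis == "genes":
        if vals.shape[1] == 0:
            raise DataError("cannot median-center an empty sample axis")
        vals = vals - np.median(vals, axis=1, keepdims=True)
    elif axis == "samples":
        if vals.shape[0] == 0:
            raise DataError("cannot median-center an empty gene axis")
        vals = vals - np.median(vals, axis=0, keepdims=True)
    else:
        raise DataError(f"unknown axis {axis!r}")
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids), unit="zscore"
    )
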