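"""Arm-level copy-number inference from expression: jointly regulated blocks.

A chromosome arm whose genes are coherently over- or under-expressed
relative to normal tissue (a "jointly regulated block", JRB) is read as an
arm-level amplification or deletion. The chain:

1. keep autosomal protein-coding genes with mean FPKM >= 1.5 across all
   samples, sorted by chromosomal coordinate;
2. ``Z = (log FPKM - mu) / sigma`` per gene, with mu/sigma the mean and
   standard deviation of log FPKM across the reference normals;
3. ``ZZ = (Z - mu_i) / sigma_i`` per tumor sample i, with mu_i/sigma_i the
   sample's own mean/sd of Z across genes — removing per-sample global
   shifts so that only *relative* arm displacement remains;
4. per sample, each arm's value is the median ZZ over its genes, centered
   by subtracting the median across arms; arms at >= +0.5 are called
   overexpressed (amplified), <= -0.5 underexpressed (deleted).

Z is invariant to the logarithm base (the base cancels in (log x - mu)/
sigma), so natural log is used throughout. Arms with fewer than
``min_genes`` surviving genes are no-calls and are excluded from the
cross-arm median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expr_core import DataError, ExpressionMatrix

logger = logging.getLogger("thyrotype")

CALL_OVER = "overexpressed"
CALL_UNDER = "underexpressed"
CALL_NEUTRAL = "neutral"
CALL_NONE = "no-call"

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


@dataclass
class NormalReferenceStats:
    """Per-gene log-FPKM mean/sd over the reference normals."""

    mu: pd.Series
    sigma: pd.Series
    n_reference: int
    pseudo: float

    @property
    def usable_genes(self) -> pd.Index:
        return self.mu.index[self.sigma > 0.0]


@dataclass
class ArmCallMatrix:
    values: pd.DataFrame        # sample x arm centered median ZZ (NaN = no-call)
    calls: pd.DataFrame         # sample x arm call strings
    genes_per_arm: pd.Series    # arm -> number of genes used


def jrb_gene_filter(
    m: ExpressionMatrix, ann: pd.DataFrame, min_mean_fpkm: float = 1.5
) -> list:
    """Autosomal protein-coding genes with mean FPKM >= threshold, sorted
    by (chromosome, start)."""
    if m.unit != "fpkm":
        raise DataError(f"jrb_gene_filter requires fpkm, got {m.unit!r}")
    genes = [g for g in m.gene_ids if g in ann.index]
    sub = ann.loc[genes]
    mean_fpkm = m.values.loc[genes].mean(axis=1)
    keep = sub.index[
        sub["chromosome"].astype(str).isin(AUTOSOMES)
        & (sub["biotype"] == "protein_coding")
        & (mean_fpkm >= min_mean_fpkm)
    ]
    if keep.empty:
        raise DataError("no gene survives the JRB expression filter")

    def chrom_key(c: str):
        return int(str(c).removeprefix("chr"))

    ordered = sorted(
        keep, key=lambda g: (chrom_key(sub.at[g, "chromosome"]), sub.at[g, "start"])
    )
    logger.info("jrb_gene_filter: %d / %d genes kept", len(ordered), len(genes))
    return ordered


def build_reference(
    m_normals: ExpressionMatrix, pseudo: float = 0.1
) -> NormalReferenceStats:
    """Per-gene mean and sd of log(FPKM + pseudo) across reference normals.

    Genes with zero variance across normals are flagged (sigma = 0) and
    must be excluded from scoring.
    """
    if m_normals.unit != "fpkm":
        raise DataError(f"build_reference requires fpkm, got {m_normals.unit!r}")
    logx = np.log(m_normals.values.to_numpy(dtype=float) + pseudo)
    mu = pd.Series(logx.mean(axis=1), index=m_normals.gene_ids, name="mu")
    n = logx.shape[1]
    sd = logx.std(axis=1, ddof=1) if n > 1 else np.zeros(len(mu))
    sd[sd < 1e-12] = 0.0  # identical normals up to float noise
    sigma = pd.Series(sd, index=m_normals.gene_ids, name="sigma")
    n_flagged = int((sigma == 0.0).sum())
    if n_flagged:
        logger.info("build_reference: %d gene(s) with sigma = 0 flagged", n_flagged)
    return NormalReferenceStats(mu=mu, sigma=sigma, n_reference=n, pseudo=pseudo)


def zz_transform(
    m_tumors: ExpressionMatrix, ref: NormalReferenceStats
) -> pd.DataFrame:
    """Doubly standardized expression: reference Z, then per-sample Z of Z.

    Returns a gene x tumor DataFrame with per-sample mean 0 and sd 1
    (sd with denominator n-1).
    """
    if m_tumors.unit != "fpkm":
        raise DataError(f"zz_transform requires fpkm, got {m_tumors.unit!r}")
    genes = [g for g in m_tumors.gene_ids if g in ref.usable_genes]
    if not genes:
        raise DataError("no gene with positive reference sigma")
    logx = np.log(m_tumors.values.loc[genes].to_numpy(dtype=float) + ref.pseudo)
    mu = ref.mu.loc[genes].to_numpy()
    sigma = ref.sigma.loc[genes].to_numpy()
    z = (logx - mu[:, None]) / sigma[:, None]
    mu_i = z.mean(axis=0)
    sigma_i = z.std(axis=0, ddof=1)
    bad = sigma_i == 0.0
    if bad.any():
        names = [m_tumors.sample_ids[j] for j in np.flatnonzero(bad)]
        raise DataError(f"sample(s) with zero Z-score variance: {names}")
    zz = (z - mu_i[None, :]) / sigma_i[None, :]
    return pd.DataFrame(zz, index=genes, columns=m_tumors.sample_ids)


def call_arms(
    zz: pd.DataFrame,
    ann: pd.DataFrame,
    min_genes: int = 10,
    threshold: float = 0.5,
) -> ArmCallMatrix:
    """Median ZZ per arm, centered across arms, thresholded at +-threshold.

    Arms with fewer than *min_genes* genes are no-calls and excluded from
    the per-sample cross-arm median. Fewer than 3 callable arms is an
    error: median-centering across arms would be meaningless.
    """
    arm_of = ann.loc[[g for g in zz.index if g in ann.index], "arm"]
    arms = list(dict.fromkeys(arm_of))
    genes_per_arm = arm_of.value_counts().reindex(arms).fillna(0).astype(int)
    callable_arms = [a for a in arms if genes_per_arm[a] >= min_genes]
    if len(callable_arms) < 3:
        raise DataError(
            f"only {len(callable_arms)} arm(s) with >= {min_genes} genes; "
            "cross-arm median-centering is meaningless"
        )
    samples = list(zz.columns)
    medians = pd.DataFrame(
        {
            a: zz.loc[arm_of.index[arm_of == a]].median(axis=0)
            for a in callable_arms
        },
        index=samples,
    )
    centered = medians.sub(medians.median(axis=1), axis=0)
    calls = pd.DataFrame(CALL_NEUTRAL, index=samples, columns=callable_arms)
    calls = calls.mask(centered >= threshold, CALL_OVER)
    calls = calls.mask(centered <= -threshold, CALL_UNDER)
    # re-attach no-call arms for a complete matrix
    values = centered.reindex(columns=arms)
    all_calls = calls.reindex(columns=arms).fillna(CALL_NONE)
    return ArmCallMatrix(values=values, calls=all_calls, genes_per_arm=genes_per_arm)


def jrb_pipeline(
    m_fpkm: ExpressionMatrix,
    ann: pd.DataFrame,
    normal_ids,
    tumor_ids,
    min_mean_fpkm: float = 1.5,
    pseudo: float = 0.1,
    min_genes: int = 10,
    threshold: float = 0.5,
) -> ArmCallMatrix:
    """Filter -> reference -> ZZ -> arm calls, end to end."""
    genes = jrb_gene_filter(m_fpkm, ann, min_mean_fpkm=min_mean_fpkm)
    sub = m_fpkm.subset_genes(genes)
    ref = build_reference(sub.subset_samples(normal_ids), pseudo=pseudo)
    zz = zz_transform(sub.subset_samples(tumor_ids), ref)
    return call_arms(zz, ann, min_genes=min_genes, threshold=threshold)


def write_arm_calls(result: ArmCallMatrix, path, bed_path=None, ann=None) -> None:
    """Long-format TSV (sample, arm, centered_value, call, n_genes), plus an
    optional whole-arm BED of non-neutral calls."""
    rows = []
    for sid in result.values.index:
        for arm in result.values.columns:
            rows.append(
                {
                    "sample": sid,
                    "arm": arm,
                    "centered_value": result.values.at[sid, arm],
                    "call": result.calls.at[sid, arm],
                    "n_genes": int(result.genes_per_arm.get(arm, 0)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        if ann is None:
            raise DataError("BED output requires the gene annotation")
        with open(bed_path, "w") as fh:
            for sid in result.calls.index:
                for arm in result.calls.columns:
                    call = result.calls.at[sid, arm]
                    if call in (CALL_OVER, CALL_UNDER):
                        sub = ann[ann["arm"] == arm]
                        chrom = sub["chromosome"].iloc[0]
                        fh.write(
                            f"{chrom}\t{int(sub['start'].min())}\t"
                            f"{int(sub['end'].max())}\t{sid}:{arm}:{call}\n"
                        )
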