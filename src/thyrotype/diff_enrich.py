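"""Differential expression thresholds, positional enrichment, oncocytic helpers.

Differentially expressed genes (DEGs) are classified by fixed thresholds on
three statistics per gene: the log2 fold change between groups (computed on
size-factor-normalized means with a pseudocount), the baseMean (mean of
size-factor-normalized counts over both groups) and the Benjamini-Hochberg
q-value. Classes:

* ``up``:            q < 0.05, LFC >= 1,  baseMean >= 100
* ``down``:          q < 0.05, LFC <= -1, baseMean >= 100
* ``moderate-down``: q < 0.05, -1 < LFC < 0
* ``ns``:            everything else

Moderately downregulated genes are the readout of an arm-level deletion:
one lost copy halves dosage (LFC around -0.6 when averaged over carriers),
so a deleted arm announces itself by positional over-representation of the
moderate-down class on that arm (one-sided hypergeometric per arm, BH
across arms).

Per-gene p-values come from a two-sided Welch t-test on normalized log
values — a declared stand-in with a hook for an external count-model test;
the thresholds above are the implemented content.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_core import DataError, ExpressionMatrix, normlog, size_factors

logger = logging.getLogger("thyrotype")

Q_CUT = 0.05
LFC_CUT = 1.0
BASEMEAN_CUT = 100.0


def deg_stats(
    m_counts: ExpressionMatrix,
    group_a,
    group_b,
    pseudocount: float = 1.0,
    test: str = "welch",
    test_fn=None,
) -> pd.DataFrame:
    """Per-gene (lfc, baseMean, p, q) for group A versus group B.

    ``lfc`` is log2((meanA + pc) / (meanB + pc)) of size-factor-normalized
    counts; positive values mean higher expression in group A. ``test_fn``
    may supply an external per-gene count-model test taking the two
    normalized count blocks and returning a p-value vector.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataError("each group needs at least 2 samples")
    if m_counts.unit != "counts":
        raise DataError(f"deg_stats requires counts, got {m_counts.unit!r}")
    both = group_a + group_b
    sub = m_counts.subset_samples(both)
    factors = size_factors(sub)
    norm = sub.values.div(factors, axis=1)
    base_mean = norm.mean(axis=1)
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    if test_fn is not None:
        p = np.asarray(test_fn(norm[group_a], norm[group_b]), dtype=float)
    elif test == "welch":
        nl = normlog(sub, factors).values
        p = stats.ttest_ind(
            nl[group_a], nl[group_b], axis=1, equal_var=False
        ).pvalue
    else:
        raise DataError(f"unknown test {test!r}")
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "lfc": lfc,
            "baseMean": base_mean,
            "p": p,
            "q": q,
        },
        index=sub.gene_ids,
    )
    out.index.name = "gene_id"
    return out


def classify_deg(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the threshold ``class`` column (up / down / moderate-down / ns)."""
    out = records.copy()
    sig = out["q"] < Q_CUT
    big = out["baseMean"] >= BASEMEAN_CUT
    cls = np.full(len(out), "ns", dtype=object)
    cls[(sig & big & (out["lfc"] >= LFC_CUT)).to_numpy()] = "up"
    cls[(sig & big & (out["lfc"] <= -LFC_CUT)).to_numpy()] = "down"
    cls[(sig & (out["lfc"] > -LFC_CUT) & (out["lfc"] < 0)).to_numpy()] = "moderate-down"
    out["class"] = cls
    return out


def positional_enrichment(
    gene_set, arm_membership: pd.Series, universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of *gene_set* per arm.

    Parameters
    ----------
    gene_set
        Genes of interest (restricted to the universe).
    arm_membership
        gene_id -> arm for the universe genes.
    universe
        Background genes (typically all genes surviving the expression
        filter), not the whole annotation.

    Returns a frame (arm, overlap, arm_size, p, q) sorted by p.
    """
    universe = [g for g in universe if g in arm_membership.index]
    hits = set(gene_set) & set(universe)
    n_univ, n_hits = len(universe), len(hits)
    arms = arm_membership.loc[universe]
    rows = []
    for arm in sorted(arms.unique()):
        arm_genes = set(arms.index[arms == arm])
        overlap = len(arm_genes & hits)
        # P(X >= overlap), X ~ Hypergeom(N=n_univ, K=arm_size, n=n_hits)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, len(arm_genes), n_hits))
        rows.append({"arm": arm, "overlap": overlap, "arm_size": len(arm_genes), "p": p})
    out = pd.DataFrame(rows)
    if n_hits == 0:
        out["p"] = 1.0
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "arm"], kind="stable").reset_index(drop=True)


def gene_pair_correlation(
    m: ExpressionMatrix, gene_a: str, gene_b: str, samples=None
) -> float:
    """Pearson r between two genes' expression over a sample subset."""
    samples = list(samples) if samples is not None else m.sample_ids
    x = m.values.loc[gene_a, samples].to_numpy(dtype=float)
    y = m.values.loc[gene_b, samples].to_numpy(dtype=float)
    if len(x) < 3:
        raise DataError("need at least 3 samples for a correlation")
    return float(stats.pearsonr(x, y)[0])


def flag_overexpressed(
    m: ExpressionMatrix, gene: str, samples=None, z_cut: float = 2.0
) -> list:
    """Samples whose normalized-log value for *gene* exceeds the cohort
    mean by more than ``z_cut`` standard deviations."""
    if m.unit != "normlog":
        raise DataError(f"flag_overexpressed requires normlog, got {m.unit!r}")
    samples = list(samples) if samples is not None else m.sample_ids
    vals = m.values.loc[gene, samples].astype(float)
    mu, sd = vals.mean(), vals.std(ddof=1)
    if sd == 0:
        return []
    return [s for s in samples if vals[s] > mu + z_cut * sd]
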