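"""Gene-signature scores: thyroid differentiation score (TDS) and ERK score.

Both scores follow the same recipe: take normalized log expression of a
fixed gene panel, median-center each panel gene across the *tumor* samples
(normals never enter the centering), then average over the panel genes
present in the matrix. The TDS panel holds thyroid metabolism and function
genes (16 by default); a low TDS means loss of thyroid differentiation. The
ERK panel holds MAPK-pathway genes (52 by default); a high ERK score
proxies MAPK activation, the hallmark of BRAF-driven tumors.

Panel membership is configuration, not code: panels ship as plain text
files (one gene id per line, ``#`` comments) and synthetic cohorts use
generator-defined panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expr_core import DataError, ExpressionMatrix

logger = logging.getLogger("thyrotype")


@dataclass
class GenePanel:
    """Named, ordered gene list."""

    name: str
    gene_ids: list

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataError(f"panel {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError(f"panel {self.name!r} has duplicate gene ids")

    @classmethod
    def from_file(cls, path, name=None) -> "GenePanel":
        ids = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    ids.append(line)
        return cls(name=name or str(path), gene_ids=ids)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# panel: {self.name}\n")
            fh.write("\n".join(self.gene_ids) + "\n")


@dataclass
class SignatureScore:
    """Per-sample score for one panel."""

    panel: str
    scores: pd.Series       # index = tumor sample ids
    n_genes_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.scores.index,
                "panel": self.panel,
                "score": self.scores.to_numpy(),
                "n_genes_used": self.n_genes_used,
            }
        )


def signature_score(
    m: ExpressionMatrix, panel: GenePanel, samples=None
) -> SignatureScore:
    """Mean of median-centered normalized log expression over a gene panel.

    Parameters
    ----------
    m
        Normalized-log expression matrix.
    panel
        Gene panel; panel genes absent from the matrix are dropped and the
        count actually used is reported in ``n_genes_used``.
    samples
        The tumor subset to score; centering medians are computed over
        exactly these samples. Defaults to all columns of *m*.
    """
    if m.unit != "normlog":
        raise DataError(f"signature_score requires normlog values, got {m.unit!r}")
    if samples is None:
        samples = m.sample_ids
    samples = list(samples)
    if not samples:
        raise DataError("no samples to score")
    present = [g for g in panel.gene_ids if g in m.values.index]
    if not present:
        raise DataError(f"no gene of panel {panel.name!r} present in matrix")
    dropped = len(panel.gene_ids) - len(present)
    if dropped:
        logger.warning("panel %s: %d gene(s) absent from matrix", panel.name, dropped)
    sub = m.values.loc[present, samples].to_numpy(dtype=float)
    centered = sub - np.median(sub, axis=1, keepdims=True)
    scores = pd.Series(centered.mean(axis=0), index=samples, name=panel.name)
    return SignatureScore(panel=panel.name, scores=scores, n_genes_used=len(present))


def write_scores(scores: list[SignatureScore], path) -> None:
    pd.concat([s.to_frame() for s in scores]).to_csv(path, sep="\t", index=False)
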