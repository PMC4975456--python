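"""Synthetic thyroid-tumor RNA-seq cohorts with known planted structure.

The generator emits everything the analysis pipeline consumes — a count
matrix, gene annotation (GTF and BED-like dialects), sample metadata,
variant and fusion candidate tables — together with ground-truth labels, so
that subtyping, signature scoring, arm-level CNV inference, driver
filtration and the DEG/enrichment loop can all be validated without any
external download.

Generative model
----------------
Counts are negative-binomial: gene g in sample j has mean
``exp(b_g) * s_j * 2**E_gj`` where ``b_g ~ Normal(base_mean_log)`` is a
log-normal base expression level, ``s_j`` is a log-normal library-size
factor, and ``E_gj`` (log2 units) sums the planted programs:

* molecular-subtype programs — each of BRAF-like / RAS-like / NBNR carries
  its own gene panel shifted by ``effect_sizes['program']``; BRAF-like
  tumors additionally shift the MAPK (ERK) panel up and the thyroid
  differentiation (TDS) panel down;
* an immunoglobulin panel shifted up in lymphocytic-thyroiditis (LT)
  flagged tumors — the clustering confound;
* an oncocytic mitochondrial-biogenesis panel (designated ESRRA/PPARGC1A
  genes plus a TCA-cycle set) shifted up in oncocytic tumors, which are
  drawn from the NBNR subtype only;
* arm-level dosage shifts applied to every gene on a planted CNV arm.

Normal samples carry no tumor programs. Programs are multiplicative on the
mean (additive in log space), matching how the downstream arm-block and DEG
stages measure effects. The variance is ``mu + dispersion * mu**2``.

Defaults mirror the study cohort this pipeline is designed around: 180
tumors, 81 paired normals, a ~29% LT rate, three molecular subtypes, and a
22q-deletion CNV plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expr_core import (
    ACROCENTRIC_P,
    AUTOSOME_ARMS,
    DataError,
    ExpressionMatrix,
    validate_annotation,
    write_annotation,
    write_counts,
)

SUBTYPES = ("BRAF-like", "RAS-like", "NBNR")

#: default planted arms: every autosome arm with annotated coding genes
DEFAULT_ARMS = tuple(a for a in AUTOSOME_ARMS if a not in ACROCENTRIC_P)

#: driver genes planted per subtype, with the class used for cluster naming
SUBTYPE_DRIVERS = {
    "BRAF-like": [
        ("BRAF", "BRAF", "BRAF-class"),
        ("CCDC6-RET", "fusion", "BRAF-class"),
        ("ETV6-NTRK3", "fusion", "BRAF-class"),
    ],
    "RAS-like": [
        ("NRAS", "H/K/NRAS", "RAS-class"),
        ("HRAS", "H/K/NRAS", "RAS-class"),
        ("KRAS", "H/K/NRAS", "RAS-class"),
        ("STRN-ALK", "fusion", "RAS-class"),
    ],
    "NBNR": [
        ("DICER1", "other-small", "other"),
        ("EIF1AX", "other-small", "other"),
        ("IDH1", "other-small", "other"),
        ("PTEN", "other-small", "other"),
        ("SOS1", "other-small", "other"),
        ("SPOP", "other-small", "other"),
        ("PAX8-PPARG", "fusion", "other"),
        (None, "driver-unknown", "unknown"),
    ],
}

DRIVER_PROTEIN_CHANGE = {
    "BRAF": "p.V600E", "NRAS": "p.Q61R", "HRAS": "p.Q61R", "KRAS": "p.Q61R",
    "DICER1": "p.E1705Q", "EIF1AX": "p.R13C", "IDH1": "p.R132C",
    "PTEN": "p.V343E", "SOS1": "p.N233Y", "SPOP": "p.P94R",
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; ``seed`` fully determines output."""

    n_tumors: int = 180
    n_normals: int = 81
    n_genes: int = 3000
    arms: tuple = DEFAULT_ARMS
    subtype_fractions: dict = field(
        default_factory=lambda: {"BRAF-like": 0.45, "RAS-like": 0.35, "NBNR": 0.20}
    )
    base_mean_log: tuple = (5.0, 1.5)  # natural-log mean/sd of base expression
    #: curated panels (signature, program, immunoglobulin, oncocytic genes)
    #: are well-expressed genes in real tissue; they draw from a higher,
    #: tighter base-mean stratum
    panel_base_mean_log: tuple = (6.0, 0.8)
    dispersion: float = 0.05
    library_sd: float = 0.15  # sd of log library-size factors
    panel_sizes: dict = field(
        default_factory=lambda: {"tds": 16, "erk": 52, "ig": 91, "oncocytic": 30}
    )
    program_size: int = 60  # genes per subtype expression program
    effect_sizes: dict = field(
        default_factory=lambda: {
            "program": 1.0,   # log2FC of each subtype program
            "erk": 1.0,       # ERK panel up in BRAF-like
            "tds": -1.0,      # TDS panel down in BRAF-like
            "ig": 4.0,        # immunoglobulin panel up in LT tumors
            "oncocytic": 2.0, # mitochondrial panel up in oncocytic tumors
        }
    )
    lt_fraction: float = 0.29
    oncocytic_fraction: float = 0.05  # of tumors; restricted to NBNR
    cnv_plan: list = field(default_factory=lambda: [("22q", -0.6, 0.15)])
    frac_chrx: float = 0.02       # genes placed on Xq (JRB filter fodder)
    frac_noncoding: float = 0.05  # lincRNA biotype (JRB filter fodder)
    seed: int = 0

    def validate(self, arm_set=None) -> None:
        for name in ("n_tumors", "n_normals", "n_genes", "program_size"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        total = sum(self.subtype_fractions.get(s, 0.0) for s in SUBTYPES)
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"subtype_fractions must sum to 1, got {total}")
        arms = set(arm_set if arm_set is not None else self.arms)
        for arm, lfc, frac in self.cnv_plan:
            if arm not in arms:
                raise DataError(f"cnv_plan arm {arm!r} not in annotation")
            if not 0.0 <= frac <= 1.0:
                raise DataError(f"cnv_plan carrier fraction {frac} outside [0, 1]")


@dataclass
class CohortTruth:
    """Ground truth: one row per tumor sample plus the per-arm dosage matrix."""

    samples: pd.DataFrame   # index: tumor id; subtype, driver_gene, driver_label,
                            # driver_class, lt, oncocytic
    arm_cnv: pd.DataFrame   # tumors x arms, planted dosage in log2 units
    panels: dict            # panel name -> list of gene ids

    def __post_init__(self) -> None:
        for sid, row in self.samples.iterrows():
            cls, label = row["driver_class"], row["driver_label"]
            if row["subtype"] == "BRAF-like" and cls != "BRAF-class":
                raise DataError(f"{sid}: BRAF-like tumor without a BRAF-class driver")
            if row["subtype"] == "RAS-like" and cls != "RAS-class":
                raise DataError(f"{sid}: RAS-like tumor without a RAS-class driver")
            if label == "driver-unknown" and row["driver_gene"] is not None:
                raise DataError(f"{sid}: driver-unknown with a driver gene")


# ---------------------------------------------------------------------------
# Gene universe and annotation
# ---------------------------------------------------------------------------

def _panel_gene_ids(config: CohortConfig) -> dict:
    p = config.panel_sizes
    onc = max(int(p.get("oncocytic", 30)), 3)
    panels = {
        "tds": [f"TDS{i:02d}" for i in range(1, p.get("tds", 16) + 1)],
        "erk": [f"ERK{i:02d}" for i in range(1, p.get("erk", 52) + 1)],
        "ig": [f"IGHV{i:03d}" for i in range(1, p.get("ig", 91) + 1)],
        "oncocytic": ["ESRRA", "PPARGC1A"] + [f"TCA{i:02d}" for i in range(1, onc - 1)],
        "braf_prog": [f"BRFP{i:03d}" for i in range(1, config.program_size + 1)],
        "ras_prog": [f"RASP{i:03d}" for i in range(1, config.program_size + 1)],
        "nbnr_prog": [f"NBNP{i:03d}" for i in range(1, config.program_size + 1)],
    }
    return panels


def _build_universe(config: CohortConfig, rng: np.random.Generator):
    """Gene ids, panels, and annotation with arm placement and coordinates."""
    panels = _panel_gene_ids(config)
    panel_genes = [g for genes in panels.values() for g in genes]
    if len(set(panel_genes)) != len(panel_genes):
        raise DataError("panel gene ids overlap")
    n_filler = config.n_genes - len(panel_genes)
    if n_filler < 0:
        raise DataError(f"n_genes={config.n_genes} too small for panels ({len(panel_genes)})")
    filler = [f"G{i:05d}" for i in range(n_filler)]
    gene_ids = panel_genes + filler

    n_x = int(round(config.frac_chrx * config.n_genes))
    n_nc = int(round(config.frac_noncoding * config.n_genes))
    autosome_arms = list(config.arms)

    # chrX genes drawn from filler only, so panels stay autosomal
    x_set = set(rng.choice(filler, size=min(n_x, len(filler)), replace=False)) if n_x else set()
    # deterministic shuffled placement so panels spread across arms
    order = rng.permutation(len(gene_ids))
    arm_of, k = {}, 0
    for gi in order:
        gid = gene_ids[gi]
        if gid in x_set:
            arm_of[gid] = "Xq"
        else:
            arm_of[gid] = autosome_arms[k % len(autosome_arms)]
            k += 1
    # non-coding biotype: drawn from filler genes only, so panels stay coding
    nc_pool = [g for g in filler if g not in x_set]
    nc_set = set(rng.choice(nc_pool, size=min(n_nc, len(nc_pool)), replace=False)) if n_nc else set()

    rows = []
    per_arm_counter: dict[str, int] = {}
    lengths = np.exp(rng.uniform(np.log(500), np.log(100000), size=len(gene_ids)))
    for gid, length in zip(gene_ids, lengths):
        arm = arm_of[gid]
        chrom = arm[:-1]
        i = per_arm_counter.get(arm, 0)
        per_arm_counter[arm] = i + 1
        # p arm occupies [0, 5e7), q arm [5e7, 1.5e8); 200 kb gene spacing
        base = 0 if arm.endswith("p") else 50_000_000
        start = base + i * 200_000
        rows.append(
            {
                "gene_id": gid,
                "chromosome": f"chr{chrom}",
                "start": start,
                "end": start + int(length),
                "strand": "+" if rng.random() < 0.5 else "-",
                "biotype": "lincRNA" if gid in nc_set else "protein_coding",
                "length": int(length),
                "arm": arm,
            }
        )
    ann = pd.DataFrame(rows).set_index("gene_id")
    return gene_ids, panels, validate_annotation(ann)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig):
    """Generate (counts, annotation, sample table, truth) for one cohort.

    Returns
    -------
    tuple of (ExpressionMatrix, pandas.DataFrame, pandas.DataFrame, CohortTruth)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids, panels, ann = _build_universe(config, rng)
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    tumor_ids = [f"T{i:03d}" for i in range(1, config.n_tumors + 1)]
    normal_ids = [f"N{i:03d}" for i in range(1, config.n_normals + 1)]
    sample_ids = tumor_ids + normal_ids

    # --- truth assignment -------------------------------------------------
    fr = config.subtype_fractions
    n_braf = int(round(fr["BRAF-like"] * config.n_tumors))
    n_ras = int(round(fr["RAS-like"] * config.n_tumors))
    subtype = (
        ["BRAF-like"] * n_braf
        + ["RAS-like"] * n_ras
        + ["NBNR"] * (config.n_tumors - n_braf - n_ras)
    )
    subtype = list(rng.permutation(subtype))

    drivers = []
    for st in subtype:
        choices = SUBTYPE_DRIVERS[st]
        gene, label, cls = choices[rng.integers(len(choices))]
        drivers.append((gene, label, cls))

    lt = rng.random(config.n_tumors) < config.lt_fraction
    onc = np.zeros(config.n_tumors, dtype=bool)
    nbnr_idx = [i for i, s in enumerate(subtype) if s == "NBNR"]
    n_onc = min(int(round(config.oncocytic_fraction * config.n_tumors)), len(nbnr_idx))
    if n_onc:
        onc[rng.choice(nbnr_idx, size=n_onc, replace=False)] = True

    arm_cnv = pd.DataFrame(
        0.0, index=tumor_ids, columns=list(dict.fromkeys(ann["arm"]))
    )
    for arm, lfc, frac in config.cnv_plan:
        n_car = int(round(frac * config.n_tumors))
        if n_car:
            carriers = rng.choice(config.n_tumors, size=n_car, replace=False)
            arm_cnv.iloc[carriers, arm_cnv.columns.get_loc(arm)] = lfc

    truth_samples = pd.DataFrame(
        {
            "subtype": subtype,
            "driver_gene": [d[0] for d in drivers],
            "driver_label": [d[1] for d in drivers],
            "driver_class": [d[2] for d in drivers],
            "lt": lt,
            "oncocytic": onc,
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    truth = CohortTruth(samples=truth_samples, arm_cnv=arm_cnv, panels=panels)

    # --- expression model -------------------------------------------------
    base_log = rng.normal(config.base_mean_log[0], config.base_mean_log[1], size=n_genes)
    panel_rows = [gene_pos[g] for genes in panels.values() for g in genes]
    base_log[panel_rows] = rng.normal(
        config.panel_base_mean_log[0], config.panel_base_mean_log[1], size=len(panel_rows)
    )
    lib = np.exp(rng.normal(0.0, config.library_sd, size=len(sample_ids)))

    eff = np.zeros((n_genes, len(sample_ids)))  # log2 units
    es = config.effect_sizes

    def bump(gene_list, sample_idx, lfc):
        rows = [gene_pos[g] for g in gene_list]
        eff[np.ix_(rows, sample_idx)] += lfc

    st_panel = {"BRAF-like": "braf_prog", "RAS-like": "ras_prog", "NBNR": "nbnr_prog"}
    for st in SUBTYPES:
        idx = [i for i, s in enumerate(subtype) if s == st]
        if idx:
            bump(panels[st_panel[st]], idx, es["program"])
    braf_idx = [i for i, s in enumerate(subtype) if s == "BRAF-like"]
    if braf_idx:
        bump(panels["erk"], braf_idx, es["erk"])
        bump(panels["tds"], braf_idx, es["tds"])
    lt_idx = np.flatnonzero(lt).tolist()
    if lt_idx:
        bump(panels["ig"], lt_idx, es["ig"])
    onc_idx = np.flatnonzero(onc).tolist()
    if onc_idx:
        bump(panels["oncocytic"], onc_idx, es["oncocytic"])
    for arm in arm_cnv.columns:
        col = arm_cnv[arm].to_numpy()
        car = np.flatnonzero(col != 0.0)
        if car.size:
            arm_genes = ann.index[ann["arm"] == arm].tolist()
            for j in car:
                bump(arm_genes, [j], col[j])

    mu = np.exp(base_log)[:, None] * lib[None, :] * np.exp2(eff)
    if config.dispersion > 0:
        n_param = 1.0 / config.dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    else:
        counts = rng.poisson(mu)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=gene_ids, columns=sample_ids),
        unit="counts",
    )

    # --- sample metadata --------------------------------------------------
    hist_map = {
        "BRAF-like": ["cPTC", "cPTC", "cPTC", "FVPTC-I"],
        "RAS-like": ["FVPTC-E", "miFTC", "FA", "FVPTC-I"],
        "NBNR": ["FA", "FA", "miFTC", "FVPTC-E"],
    }
    sex = np.where(rng.random(len(sample_ids)) < 131 / 180, "F", "M")
    age = np.clip(rng.normal(47, 13, size=len(sample_ids)).round(), 18, 90)
    meta = pd.DataFrame(
        {
            "role": ["tumor"] * config.n_tumors + ["normal"] * config.n_normals,
            "histology": [
                hist_map[s][rng.integers(4)] for s in subtype
            ] + [""] * config.n_normals,
            "lt": lt.tolist() + [False] * config.n_normals,
            "age": age.astype(int),
            "sex": sex,
            "menopause": [
                bool(s == "F" and a >= 50) for s, a in zip(sex, age)
            ],
            "smoking": (rng.random(len(sample_ids)) < 0.15),
            "drinking": (rng.random(len(sample_ids)) < 0.30),
            "matched_normal_id": [
                normal_ids[i] if i < config.n_normals else ""
                for i in range(config.n_tumors)
            ] + [""] * config.n_normals,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return matrix, ann, meta, truth


# ---------------------------------------------------------------------------
# Variant / fusion tables
# ---------------------------------------------------------------------------

DEFAULT_DECOY_RATES = {
    "high_maf": 0.15,          # population-common variant
    "silent": 0.15,            # synonymous change
    "non_driver_gene": 0.15,   # nonsilent but outside the driver list
    "low_discordant": 0.15,    # fusion with < 2 discordant pairs
    "close_intrachromosomal": 0.15,  # same-chromosome partners < 100 kb apart
    "in_normal": 0.15,         # fusion also seen in a normal sample
}

#: synthetic loci for fusion partner placement (chromosome, position)
_FUSION_LOCI = {
    "CCDC6-RET": (("chr10", 61_600_000), ("chr10", 43_600_000)),
    "ETV6-NTRK3": (("chr12", 12_000_000), ("chr15", 88_400_000)),
    "STRN-ALK": (("chr2", 37_000_000), ("chr2", 29_400_000)),
    "PAX8-PPARG": (("chr2", 113_900_000), ("chr3", 12_300_000)),
}


def generate_alteration_tables(truth: CohortTruth, decoy_rates=None, seed: int = 0):
    """Build variant and fusion candidate tables from cohort truth.

    Every tumor with a known driver receives exactly one true record; decoy
    records of each requested class are added at per-tumor Bernoulli rates.
    """
    rates = dict(DEFAULT_DECOY_RATES if decoy_rates is None else decoy_rates)
    rng = np.random.default_rng(seed)
    var_rows, fus_rows = [], []

    for sid, row in truth.samples.iterrows():
        gene, label = row["driver_gene"], row["driver_label"]
        if label in ("BRAF", "H/K/NRAS", "other-small"):
            var_rows.append(
                {
                    "sample": sid, "gene": gene,
                    "hgvs_p": DRIVER_PROTEIN_CHANGE.get(gene, "p.?"),
                    "consequence": "nonsynonymous",
                    "maf_exac": 0.0, "maf_1kg": 0.0, "maf_esp": 0.0,
                    "in_driver_list": True,
                }
            )
        elif label == "fusion":
            (ca, pa), (cb, pb) = _FUSION_LOCI[gene]
            a, b = gene.split("-")
            fus_rows.append(
                {
                    "sample": sid, "geneA": a, "geneB": b,
                    "chromA": ca, "posA": pa, "chromB": cb, "posB": pb,
                    "discordant_pairs": int(rng.integers(2, 60)),
                    "found_in_normal": False,
                }
            )

    for sid in truth.samples.index:
        if rng.random() < rates.get("high_maf", 0):
            var_rows.append(
                {
                    "sample": sid, "gene": "EGFR", "hgvs_p": "p.R521K",
                    "consequence": "nonsynonymous",
                    "maf_exac": 0.02, "maf_1kg": 0.05, "maf_esp": 0.05,
                    "in_driver_list": True,
                }
            )
        if rng.random() < rates.get("silent", 0):
            var_rows.append(
                {
                    "sample": sid, "gene": "CHEK2", "hgvs_p": "p.L56L",
                    "consequence": "silent",
                    "maf_exac": 0.0, "maf_1kg": 0.0, "maf_esp": 0.0,
                    "in_driver_list": True,
                }
            )
        if rng.random() < rates.get("non_driver_gene", 0):
            var_rows.append(
                {
                    "sample": sid, "gene": "TTN", "hgvs_p": "p.A2T",
                    "consequence": "nonsynonymous",
                    "maf_exac": 0.0, "maf_1kg": 0.0, "maf_esp": 0.0,
                    "in_driver_list": False,
                }
            )
        if rng.random() < rates.get("low_discordant", 0):
            fus_rows.append(
                {
                    "sample": sid, "geneA": "FGFR2", "geneB": "WARS",
                    "chromA": "chr10", "posA": 123_200_000,
                    "chromB": "chr14", "posB": 100_800_000,
                    "discordant_pairs": 1, "found_in_normal": False,
                }
            )
        if rng.random() < rates.get("close_intrachromosomal", 0):
            fus_rows.append(
                {
                    "sample": sid, "geneA": "NEIGH1", "geneB": "NEIGH2",
                    "chromA": "chr1", "posA": 10_000_000,
                    "chromB": "chr1", "posB": 10_050_000,
                    "discordant_pairs": 8, "found_in_normal": False,
                }
            )
        if rng.random() < rates.get("in_normal", 0):
            fus_rows.append(
                {
                    "sample": sid, "geneA": "HACL1", "geneB": "COLQ",
                    "chromA": "chr3", "posA": 15_600_000,
                    "chromB": "chr3", "posB": 15_500_000,
                    "discordant_pairs": 5, "found_in_normal": True,
                }
            )

    var_cols = ["sample", "gene", "hgvs_p", "consequence",
                "maf_exac", "maf_1kg", "maf_esp", "in_driver_list"]
    fus_cols = ["sample", "geneA", "geneB", "chromA", "posA", "chromB", "posB",
                "discordant_pairs", "found_in_normal"]
    variants = pd.DataFrame(var_rows, columns=var_cols)
    fusions = pd.DataFrame(fus_rows, columns=fus_cols)
    return variants, fusions


# ---------------------------------------------------------------------------
# On-disk cohort bundle
# ---------------------------------------------------------------------------

def write_cohort(outdir, matrix, ann, meta, truth, variants=None, fusions=None) -> dict:
    """Write every external-format artifact of a cohort; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts_tsv": out / "counts.tsv",
        "counts_mtx": out / "counts.mtx",
        "annotation_bed": out / "genes.bed.tsv",
        "annotation_gtf": out / "genes.gtf",
        "metadata": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    write_counts(matrix, paths["counts_tsv"], dialect="tsv")
    write_counts(matrix, paths["counts_mtx"], dialect="mtx")
    ann.to_csv(paths["annotation_bed"], sep="\t", index_label="gene_id")
    write_annotation(ann, paths["annotation_gtf"], dialect="gtf")
    meta.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    truth_json = {
        "samples": truth.samples.reset_index().to_dict(orient="records"),
        "arm_cnv": {
            sid: {a: v for a, v in row.items() if v != 0.0}
            for sid, row in truth.arm_cnv.iterrows()
        },
        "panels": truth.panels,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1, default=str)
    if variants is not None:
        paths["variants"] = out / "variants.tsv"
        variants.to_csv(paths["variants"], sep="\t", index=False)
    if fusions is not None:
        paths["fusions"] = out / "fusions.tsv"
        fusions.to_csv(paths["fusions"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
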