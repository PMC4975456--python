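"""Cohort summarization: contingency tables, group tests, pipeline driver.

Reproduces the reporting style of a clinical risk-factor table: per driver
group, a categorical variable is shown as numerator/denominator with the
percentage rounded half-up to two decimals; the omnibus test is Pearson's
chi-square, switching to Fisher's exact test (2x2) when any expected count
is below 5; pairwise post-hoc comparisons are Bonferroni-adjusted (p times
the number of pairwise comparisons, capped at 1). Continuous variables are
shown as mean +- sd with t-test/ANOVA omnibus and Bonferroni pairwise
tests; covariate-adjusted analyses delegate to logistic/linear regression.

Denominators may vary per variable (missing data), so every cell keeps its
own numerator and denominator.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("thyrotype")


def percent(num: int, den: int, digits: int = 2) -> float:
    """Percentage rounded half-up, the convention of clinical tables."""
    if den == 0:
        raise ValueError("zero denominator")
    exact = Decimal(100) * Decimal(num) / Decimal(den)
    return float(exact.quantize(Decimal(10) ** -digits, rounding=ROUND_HALF_UP))


def _omnibus(table: np.ndarray) -> tuple[str, float]:
    """Chi-square, or Fisher's exact on 2x2 tables with expected counts < 5."""
    table = np.asarray(table)
    keep = table.sum(axis=1) > 0
    table = table[keep]
    if table.shape[0] < 2:
        return "none", float("nan")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        if table.shape == (2, 2):
            return "fisher", float(stats.fisher_exact(table)[1])
        warnings.warn("expected counts < 5 in a >2x2 table; using chi-square", stacklevel=2)
    return "chi2", float(stats.chi2_contingency(table, correction=False)[1])


@dataclass
class ContingencyReport:
    variable: str
    cells: pd.DataFrame          # per group: num, den, percent
    test: str
    p: float
    pairwise: dict               # (group_a, group_b) -> Bonferroni-adjusted p
    n_comparisons: int


def contingency_from_counts(variable: str, counts: dict) -> ContingencyReport:
    """Build a report from explicit {group: (numerator, denominator)} counts.

    Printed tables can be fed straight in; the omnibus and post-hoc tests
    are computed on the (num, den-num) table.
    """
    groups = [g for g, (n, d) in counts.items() if d > 0]
    dropped = [g for g in counts if g not in groups]
    if dropped:
        warnings.warn(f"empty group(s) excluded: {dropped}", stacklevel=2)
    cells = pd.DataFrame(
        {
            "num": [counts[g][0] for g in groups],
            "den": [counts[g][1] for g in groups],
        },
        index=pd.Index(groups, name="group"),
    )
    cells["percent"] = [percent(n, d) for n, d in zip(cells["num"], cells["den"])]
    table = np.column_stack([cells["num"], cells["den"] - cells["num"]])
    test, p = _omnibus(table)
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        sub = np.array(
            [
                [counts[a][0], counts[a][1] - counts[a][0]],
                [counts[b][0], counts[b][1] - counts[b][0]],
            ]
        )
        _, p_ab = _omnibus(sub)
        pairwise[(a, b)] = min(1.0, p_ab * m) if np.isfinite(p_ab) else float("nan")
    return ContingencyReport(
        variable=variable, cells=cells, test=test, p=p,
        pairwise=pairwise, n_comparisons=m,
    )


def contingency(
    metadata: pd.DataFrame, groups: pd.Series, variable: str
) -> ContingencyReport:
    """Contingency report for a boolean metadata column across groups.

    Missing values shrink that group's denominator, preserving per-row
    denominators.
    """
    common = metadata.index.intersection(groups.index)
    col = metadata.loc[common, variable]
    grp = groups.loc[common]
    counts = {}
    for g in pd.unique(grp):
        vals = col[grp == g].dropna()
        counts[g] = (int(vals.astype(bool).sum()), int(len(vals)))
    return contingency_from_counts(variable, counts)


@dataclass
class ContinuousReport:
    variable: str
    stats_table: pd.DataFrame    # per group: n, mean, sd
    test: str
    p: float
    pairwise: dict


def continuous_compare(
    metadata: pd.DataFrame, groups: pd.Series, variable: str
) -> ContinuousReport:
    """Mean +- sd per group with t-test (2 groups) or one-way ANOVA
    omnibus and Bonferroni-adjusted pairwise Welch t-tests."""
    common = metadata.index.intersection(groups.index)
    col = pd.to_numeric(metadata.loc[common, variable], errors="coerce")
    grp = groups.loc[common]
    names = [g for g in pd.unique(grp) if col[grp == g].dropna().size >= 2]
    series = {g: col[grp == g].dropna().to_numpy(dtype=float) for g in names}
    tbl = pd.DataFrame(
        {
            "n": [len(series[g]) for g in names],
            "mean": [series[g].mean() for g in names],
            "sd": [series[g].std(ddof=1) for g in names],
        },
        index=pd.Index(names, name="group"),
    )
    if len(names) < 2:
        return ContinuousReport(variable, tbl, "none", float("nan"), {})
    if len(names) == 2:
        test = "t"
        p = float(stats.ttest_ind(series[names[0]], series[names[1]]).pvalue)
    else:
        test = "anova"
        p = float(stats.f_oneway(*[series[g] for g in names]).pvalue)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    pairwise = {
        (a, b): min(1.0, float(stats.ttest_ind(series[a], series[b], equal_var=False).pvalue) * m)
        for a, b in pairs
    }
    return ContinuousReport(variable, tbl, test, p, pairwise)


def adjusted_categorical_p(
    metadata: pd.DataFrame, groups: pd.Series, variable: str, covariates=("age", "sex")
) -> float:
    """Age/sex-adjusted p for a binary variable via logistic regression
    (likelihood-ratio test on the group terms)."""
    import statsmodels.api as sm

    common = metadata.index.intersection(groups.index)
    df = metadata.loc[common, list(covariates) + [variable]].copy()
    df["group"] = groups.loc[common]
    df = df.dropna()
    y = df[variable].astype(bool).astype(int)
    x_cov = pd.get_dummies(df[list(covariates)], drop_first=True, dtype=float)
    x_cov = sm.add_constant(x_cov)
    x_full = pd.concat(
        [x_cov, pd.get_dummies(df["group"], drop_first=True, dtype=float)], axis=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.Logit(y, x_full).fit(disp=0)
        null = sm.Logit(y, x_cov).fit(disp=0)
    lr = 2 * (full.llf - null.llf)
    df_diff = x_full.shape[1] - x_cov.shape[1]
    return float(stats.chi2.sf(lr, df_diff))


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration (synthetic simulate -> report)."""

    outdir: str = "thyrotype_run"
    seed: int = 0
    n_tumors: int = 180
    n_normals: int = 81
    n_genes: int = 3000
    n_variable_genes: int = 500
    k: int = 3
    cnv_plan: list = field(default_factory=lambda: [("22q", -0.6, 0.15)])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate -> normalize -> score -> subtype -> JRB -> filter -> DEG ->
    report, writing every stage's outputs plus a manifest of file hashes.

    Returns the manifest dict. A stage failure is re-raised with the stage
    name attached; outputs of completed stages persist.
    """
    from . import diff_enrich, expr_core, jrb_cnv, mutation_filters
    from . import signatures as sig
    from . import subtyping as sub
    from . import synthetic_data as syn

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}
    stage = "simulate"
    try:
        cc = syn.CohortConfig(
            n_tumors=config.n_tumors,
            n_normals=config.n_normals,
            n_genes=config.n_genes,
            cnv_plan=config.cnv_plan,
            seed=config.seed,
        )
        counts, ann, meta, truth = syn.generate_cohort(cc)
        variants, fusions = syn.generate_alteration_tables(truth, seed=config.seed)
        syn.write_cohort(out / "cohort", counts, ann, meta, truth, variants, fusions)
        manifest["stages"].append(stage)

        stage = "normalize"
        factors = expr_core.size_factors(counts)
        nl = expr_core.normlog(counts, factors)
        fk = expr_core.fpkm(counts, ann)
        tumors = meta.index[meta["role"] == "tumor"].tolist()
        normals = meta.index[meta["role"] == "normal"].tolist()
        manifest["stages"].append(stage)

        stage = "filter"
        v = mutation_filters.filter_snv_indel(variants)
        f = mutation_filters.filter_fusions(fusions)
        v.to_csv(out / "variants_filtered.tsv", sep="\t", index=False)
        f.to_csv(out / "fusions_filtered.tsv", sep="\t", index=False)
        driver_groups = mutation_filters.assign_driver_groups(tumors, v, f)
        manifest["stages"].append(stage)

        stage = "score"
        tds = sig.signature_score(nl, sig.GenePanel("TDS", truth.panels["tds"]), tumors)
        erk = sig.signature_score(nl, sig.GenePanel("ERK", truth.panels["erk"]), tumors)
        sig.write_scores([tds, erk], out / "scores.tsv")
        manifest["stages"].append(stage)

        stage = "subtype"
        res = sub.subtype_cohort(
            nl,
            truth.samples["driver_class"],
            n_genes=config.n_variable_genes,
            exclude=truth.panels["ig"],
            k=config.k,
            seed=config.seed,
        )
        pd.DataFrame({"cluster": res.clusters, "subtype": res.labels}).to_csv(
            out / "subtypes.tsv", sep="\t", index_label="sample_id"
        )
        res.embedding.to_csv(out / "embedding.tsv", sep="\t", index_label="sample_id")
        manifest["stages"].append(stage)

        stage = "jrb"
        arm_result = jrb_cnv.jrb_pipeline(fk, ann, normals, tumors)
        jrb_cnv.write_arm_calls(
            arm_result, out / "arms.tsv", bed_path=out / "arms.bed", ann=ann
        )
        manifest["stages"].append(stage)

        stage = "deg"
        deleted_arm = config.cnv_plan[0][0] if config.cnv_plan else None
        if deleted_arm is not None:
            carriers = truth.arm_cnv.index[truth.arm_cnv[deleted_arm] != 0].tolist()
            others = [t for t in tumors if t not in carriers]
            if len(carriers) >= 2 and len(others) >= 2:
                deg = diff_enrich.classify_deg(
                    diff_enrich.deg_stats(counts, carriers, others)
                )
                deg.to_csv(out / "deg.tsv", sep="\t")
                univ = jrb_cnv.jrb_gene_filter(fk, ann)
                enr = diff_enrich.positional_enrichment(
                    deg.index[deg["class"] == "moderate-down"],
                    ann["arm"],
                    univ,
                )
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "report"
        rep = contingency(meta.loc[tumors], driver_groups, "lt")
        rep.cells.to_csv(out / "report_lt.tsv", sep="\t")
        age = continuous_compare(meta.loc[tumors], driver_groups, "age")
        age.stats_table.to_csv(out / "report_age.tsv", sep="\t")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete: %d stages, %d files", len(manifest["stages"]), len(manifest["files"]))
    return manifest
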