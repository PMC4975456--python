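"""Driver SNV/indel filtration, fusion filtration and exclusivity tests.

SNV/indel candidates pass when they are (1) absent or rare in population
databases (ExAC MAF <= 1e-4; 1000 Genomes and ESP6500 MAF <= 0.01, all
inclusive; a missing frequency counts as 0 — absence from population
databases is evidence of rarity), (2) nonsilent (nonsynonymous, splice-site
or frameshift indel; stop-gain/loss are treated as nonsilent too), and
(3) located in a supplied driver-gene list (COSMIC/TCGA membership is an
input flag, never fetched). Fusion candidates pass when they are absent
from normals, supported by >= 2 discordant read pairs, and either
inter-chromosomal or >= 100 kb apart. Each failing record carries exactly
one primary reason: the first violated criterion in the order above.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("thyrotype")

MAF_THRESHOLDS = {"maf_exac": 0.0001, "maf_1kg": 0.01, "maf_esp": 0.01}
NONSILENT = {"nonsynonymous", "splice-site", "frameshift-indel",
             "stop-gain", "stop-loss"}
MIN_DISCORDANT_PAIRS = 2
MIN_INTRACHROM_DISTANCE = 100_000

PASS = "pass"


def filter_snv_indel(records: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``verdict`` column (``pass`` or ``fail(<reason>)``).

    Reason order: population_frequency, consequence, not_in_driver_list.
    Idempotent; the input frame is not modified.
    """
    out = records.copy()
    verdicts = []
    for _, r in out.iterrows():
        reason = None
        for col, thr in MAF_THRESHOLDS.items():
            maf = r.get(col)
            maf = 0.0 if maf is None or (isinstance(maf, float) and np.isnan(maf)) else float(maf)
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"{col}={maf} outside [0, 1]")
            if maf > thr:
                reason = "population_frequency"
                break
        if reason is None and r["consequence"] not in NONSILENT:
            reason = "consequence"
        if reason is None and not bool(r["in_driver_list"]):
            reason = "not_in_driver_list"
        verdicts.append(PASS if reason is None else f"fail({reason})")
    out["verdict"] = verdicts
    logger.info(
        "filter_snv_indel: %d / %d pass", int((out["verdict"] == PASS).sum()), len(out)
    )
    return out


def filter_fusions(records: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``verdict`` column to fusion candidates.

    Reason order: found_in_normal, discordant_pairs, breakpoint_distance.
    """
    out = records.copy()
    verdicts = []
    for _, r in out.iterrows():
        if bool(r["found_in_normal"]):
            verdicts.append("fail(found_in_normal)")
        elif int(r["discordant_pairs"]) < MIN_DISCORDANT_PAIRS:
            verdicts.append("fail(discordant_pairs)")
        elif (
            str(r["chromA"]) == str(r["chromB"])
            and abs(int(r["posA"]) - int(r["posB"])) < MIN_INTRACHROM_DISTANCE
        ):
            verdicts.append("fail(breakpoint_distance)")
        else:
            verdicts.append(PASS)
    out["verdict"] = verdicts
    logger.info(
        "filter_fusions: %d / %d pass", int((out["verdict"] == PASS).sum()), len(out)
    )
    return out


def read_variants(path) -> pd.DataFrame:
    """Read the variant TSV, or a minimal VCF whose INFO field carries
    ``GENE``, ``HGVSP``, ``CSQ`` (consequence), the three MAF keys and
    ``DRIVER`` flags, with the sample id in a ``SAMPLE`` key."""
    path = str(path)
    if path.endswith(".vcf"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                info = dict(
                    kv.split("=", 1) if "=" in kv else (kv, "1")
                    for kv in fields[7].split(";")
                    if kv
                )
                rows.append(
                    {
                        "sample": info.get("SAMPLE", ""),
                        "gene": info.get("GENE", ""),
                        "hgvs_p": info.get("HGVSP", ""),
                        "consequence": info.get("CSQ", "other"),
                        "maf_exac": float(info["MAF_EXAC"]) if "MAF_EXAC" in info else np.nan,
                        "maf_1kg": float(info["MAF_1KG"]) if "MAF_1KG" in info else np.nan,
                        "maf_esp": float(info["MAF_ESP"]) if "MAF_ESP" in info else np.nan,
                        "in_driver_list": info.get("DRIVER", "0") in ("1", "true", "True"),
                    }
                )
        return pd.DataFrame(rows)
    return pd.read_csv(path, sep="\t")


def exclusivity_table(altered: pd.DataFrame, gene_a: str, gene_b: str) -> dict:
    """Co-occurrence 2x2 and one-sided Fisher p for a co-occurrence deficit.

    Parameters
    ----------
    altered
        Boolean sample x gene alteration flags.
    """
    a = altered[gene_a].astype(bool)
    b = altered[gene_b].astype(bool)
    both = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    table = np.array([[both, only_a], [only_b, neither]])
    p = float(stats.fisher_exact(table, alternative="less")[1])
    return {
        "both": both, "only_a": only_a, "only_b": only_b, "neither": neither,
        "p": p,
    }


# precedence when one sample carries several passing alterations
_GROUP_PRECEDENCE = ("fusion", "BRAF", "H/K/NRAS", "other-small")
_RAS_GENES = {"NRAS", "HRAS", "KRAS"}


def _variant_group(gene: str) -> str:
    if gene == "BRAF":
        return "BRAF"
    if gene in _RAS_GENES:
        return "H/K/NRAS"
    return "other-small"


def assign_driver_group(
    sample_id: str, variants: pd.DataFrame, fusions: pd.DataFrame
) -> str:
    """Driver group of one sample from its *passing* records.

    Precedence fusion > BRAF > H/K/NRAS > other-small (alterations are
    expected to be mutually exclusive, so co-occurrence triggers a
    warning); no passing record -> driver-unknown.
    """
    groups = set()
    v = variants[(variants["sample"] == sample_id) & (variants["verdict"] == PASS)]
    groups.update(_variant_group(g) for g in v["gene"])
    f = fusions[(fusions["sample"] == sample_id) & (fusions["verdict"] == PASS)]
    if len(f):
        groups.add("fusion")
    if not groups:
        return "driver-unknown"
    if len(groups) > 1:
        warnings.warn(
            f"sample {sample_id}: multiple driver classes {sorted(groups)}; "
            "applying precedence",
            stacklevel=2,
        )
    for g in _GROUP_PRECEDENCE:
        if g in groups:
            return g
    return "driver-unknown"


def assign_driver_groups(
    sample_ids, variants: pd.DataFrame, fusions: pd.DataFrame
) -> pd.Series:
    return pd.Series(
        {s: assign_driver_group(s, variants, fusions) for s in sample_ids},
        name="driver_group",
    )
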