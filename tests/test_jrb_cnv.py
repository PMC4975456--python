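import math
import statistics

import numpy as np
import pandas as pd
import pytest

import thyrotype as tt
from thyrotype.expr_core import DataError
from thyrotype.jrb_cnv import CALL_NEUTRAL, CALL_NONE, CALL_OVER, CALL_UNDER


def fpkm_matrix(arr, genes, samples):
    return tt.ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=samples, dtype=float), unit="fpkm"
    )


def make_annotation(arm_of: dict) -> pd.DataFrame:
    rows = []
    counters: dict = {}
    for g, arm in arm_of.items():
        i = counters.get(arm, 0)
        counters[arm] = i + 1
        base = 0 if arm.endswith("p") else 50_000_000
        rows.append(
            {
                "gene_id": g,
                "chromosome": f"chr{arm[:-1]}",
                "start": base + i * 10_000,
                "end": base + i * 10_000 + 1_000,
                "strand": "+",
                "biotype": "protein_coding",
                "length": 1000,
                "arm": arm,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


class TestGeneFilter:
    def test_boundary_chrx_and_hand_fixture(self):
        genes = [f"g{i}" for i in range(10)]
        arm_of = {g: "1q" for g in genes[:8]}
        ann = make_annotation(arm_of)
        extra = make_annotation({"g8": "2p"})
        ann = pd.concat([ann, extra])
        xrow = make_annotation({"g9": "1q"})
        xrow["chromosome"] = "chrX"
        xrow["arm"] = "Xq"
        ann = pd.concat([ann, xrow])
        ann.loc["g7", "biotype"] = "lincRNA"
        means = [1.5, 1.49, 0.0, 10.0, 2.0, 1.6, 3.0, 5.0, 2.0, 100.0]
        arr = np.tile(np.array(means)[:, None], (1, 4))
        m = fpkm_matrix(arr, genes, [f"s{j}" for j in range(4)])
        kept = tt.jrb_gene_filter(m, ann)
        # g0 at exactly 1.5 kept (inclusive); g1 below; g2 zero; g7 non-coding;
        # g9 on chrX dropped; sorted by (chromosome, start)
        assert kept == ["g0", "g3", "g4", "g5", "g6", "g8"]

    def test_empty_result_is_error(self):
        ann = make_annotation({"g0": "1p"})
        m = fpkm_matrix([[0.1]], ["g0"], ["s0"])
        with pytest.raises(DataError):
            tt.jrb_gene_filter(m, ann)


class TestReference:
    def test_identical_normals_flag_sigma_zero(self):
        m = fpkm_matrix([[2.0, 2.0, 2.0]], ["g"], ["n1", "n2", "n3"])
        ref = tt.build_reference(m)
        assert (ref.sigma == 0.0).all()
        assert len(ref.usable_genes) == 0

    def test_two_normal_closed_form(self):
        m = fpkm_matrix([[1.0, 3.0]], ["g"], ["n1", "n2"])
        ref = tt.build_reference(m, pseudo=0.0)
        assert ref.mu["g"] == pytest.approx((math.log(1) + math.log(3)) / 2)
        assert ref.sigma["g"] == pytest.approx(
            statistics.stdev([math.log(1), math.log(3)])
        )

    def test_mu_recovered_on_simulated_lognormal_normals(self):
        rng = np.random.default_rng(0)
        true_mu, true_sd, n = 2.0, 0.5, 200
        vals = np.exp(rng.normal(true_mu, true_sd, size=(1, n)))
        m = fpkm_matrix(vals, ["g"], [f"n{j}" for j in range(n)])
        ref = tt.build_reference(m, pseudo=0.0)
        se = true_sd / math.sqrt(n)
        assert abs(ref.mu["g"] - true_mu) < 4 * se


class TestZZTransform:
    def test_hand_computed_single_sample(self):
        normals = fpkm_matrix(
            [[1.0, 3.0], [2.0, 8.0], [1.0, 9.0], [4.0, 16.0]],
            ["g1", "g2", "g3", "g4"],
            ["n1", "n2"],
        )
        ref = tt.build_reference(normals, pseudo=0.0)
        tumor = fpkm_matrix([[9.0], [4.0], [3.0], [8.0]], ["g1", "g2", "g3", "g4"], ["t1"])
        zz = tt.zz_transform(tumor, ref)
        # oracle with plain python
        z = []
        for g, x in zip(["g1", "g2", "g3", "g4"], [9.0, 4.0, 3.0, 8.0]):
            z.append((math.log(x) - ref.mu[g]) / ref.sigma[g])
        mu_i, sd_i = statistics.mean(z), statistics.stdev(z)
        for g, zi in zip(["g1", "g2", "g3", "g4"], z):
            assert zz.at[g, "t1"] == pytest.approx((zi - mu_i) / sd_i)
        assert zz["t1"].mean() == pytest.approx(0.0, abs=1e-9)
        assert zz["t1"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_tumor_equal_to_reference_mean_is_degenerate(self):
        normals = fpkm_matrix(
            np.exp(np.array([[1.0, 3.0], [0.0, 2.0]])), ["g1", "g2"], ["n1", "n2"]
        )
        ref = tt.build_reference(normals, pseudo=0.0)
        tumor = fpkm_matrix(np.exp([[2.0], [1.0]]), ["g1", "g2"], ["t1"])  # = mu
        with pytest.raises(DataError, match="zero Z-score variance"):
            tt.zz_transform(tumor, ref)

    def test_z_invariant_to_log_base(self):
        # (log_b x - mu_b) / sigma_b is base-free: verify ZZ values match a
        # base-10 reimplementation
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(1, 0.5, size=(6, 5)))
        genes = [f"g{i}" for i in range(6)]
        normals = fpkm_matrix(vals[:, :3], genes, ["n1", "n2", "n3"])
        tumors = fpkm_matrix(vals[:, 3:], genes, ["t1", "t2"])
        ref = tt.build_reference(normals, pseudo=0.0)
        zz = tt.zz_transform(tumors, ref)
        log10 = np.log10(vals)
        mu10 = log10[:, :3].mean(axis=1)
        sd10 = log10[:, :3].std(axis=1, ddof=1)
        z10 = (log10[:, 3:] - mu10[:, None]) / sd10[:, None]
        zz10 = (z10 - z10.mean(axis=0)) / z10.std(axis=0, ddof=1)
        assert np.allclose(zz.to_numpy(), zz10)


class TestCallArms:
    def _uniform_zz(self, n_arms=5, genes_per_arm=12, n_samples=3, shift=None,
                    noise=1.0):
        rng = np.random.default_rng(2)
        genes, arms = [], {}
        for a in range(n_arms):
            for i in range(genes_per_arm):
                g = f"a{a}g{i}"
                genes.append(g)
                arms[g] = f"{a + 1}q"
        zz = pd.DataFrame(
            rng.normal(scale=noise, size=(len(genes), n_samples)),
            index=genes,
            columns=[f"t{j}" for j in range(n_samples)],
        )
        if shift:
            arm, delta = shift
            sel = [g for g in genes if arms[g] == arm]
            zz.loc[sel] += delta
        return zz, make_annotation(arms)

    def test_equal_arms_all_neutral_and_centered_zero(self):
        genes = [f"g{i}" for i in range(30)]
        arms = {g: f"{1 + i % 3}q" for i, g in enumerate(genes)}
        zz = pd.DataFrame(1.7, index=genes, columns=["t1", "t2"])
        res = tt.call_arms(zz, make_annotation(arms), min_genes=5)
        assert (res.values.to_numpy() == 0.0).all()
        assert (res.calls.to_numpy() == CALL_NEUTRAL).all()

    def test_shifted_arm_called_over(self):
        zz, ann = self._uniform_zz(n_arms=10, shift=("3q", 1.2), noise=0.1)
        res = tt.call_arms(zz, ann, min_genes=5)
        assert (res.calls["3q"] == CALL_OVER).all()
        other = res.calls.drop(columns="3q")
        assert (other == CALL_NEUTRAL).to_numpy().all()

    def test_small_arms_are_no_call_and_min_arm_guard(self):
        zz, ann = self._uniform_zz(n_arms=4)
        tiny = pd.DataFrame(
            {"t0": [0.1], "t1": [0.2], "t2": [0.0]}, index=["tinyg"]
        )
        ann2 = pd.concat([ann, make_annotation({"tinyg": "9p"})])
        res = tt.call_arms(pd.concat([zz, tiny]), ann2, min_genes=5)
        assert (res.calls["9p"] == CALL_NONE).all()
        with pytest.raises(DataError, match="meaningless"):
            tt.call_arms(zz, ann, min_genes=13)

    def test_per_sample_median_of_centered_values_is_zero(self):
        zz, ann = self._uniform_zz(n_arms=7)
        res = tt.call_arms(zz, ann, min_genes=5)
        med = res.values.median(axis=1)
        assert np.allclose(med.to_numpy(), 0.0)


def brute_force_jrb(fpkm_df, ann, normals, tumors, pseudo=0.1, min_genes=10,
                    threshold=0.5, min_mean_fpkm=1.5):
    """Independent plain-python JRB implementation used as an oracle."""
    genes = [
        g
        for g in fpkm_df.index
        if str(ann.at[g, "chromosome"]).removeprefix("chr").isdigit()
        and ann.at[g, "biotype"] == "protein_coding"
        and statistics.mean(fpkm_df.loc[g]) >= min_mean_fpkm
    ]
    genes.sort(key=lambda g: (int(str(ann.at[g, "chromosome"]).removeprefix("chr")),
                              ann.at[g, "start"]))
    mu, sd = {}, {}
    for g in genes:
        logs = [math.log(fpkm_df.at[g, n] + pseudo) for n in normals]
        mu[g] = statistics.mean(logs)
        sd[g] = statistics.stdev(logs)
    genes = [g for g in genes if sd[g] > 0]
    values, calls = {}, {}
    arms = sorted(set(ann.loc[genes, "arm"]), key=lambda a: genes.index(
        next(g for g in genes if ann.at[g, "arm"] == a)))
    callable_arms = [a for a in arms
                     if sum(ann.at[g, "arm"] == a for g in genes) >= min_genes]
    for t in tumors:
        z = {g: (math.log(fpkm_df.at[g, t] + pseudo) - mu[g]) / sd[g] for g in genes}
        mu_i = statistics.mean(z.values())
        sd_i = statistics.stdev(z.values())
        zz = {g: (z[g] - mu_i) / sd_i for g in genes}
        med = {
            a: statistics.median([zz[g] for g in genes if ann.at[g, "arm"] == a])
            for a in callable_arms
        }
        center = statistics.median(med.values())
        for a in callable_arms:
            v = med[a] - center
            values[(t, a)] = v
            calls[(t, a)] = (
                CALL_OVER if v >= threshold else CALL_UNDER if v <= -threshold else CALL_NEUTRAL
            )
    return values, calls


class TestPipelineOracle:
    def test_matches_brute_force_elementwise(self):
        rng = np.random.default_rng(8)
        n_arms, gpa = 10, 20  # 200 genes
        genes, arm_of = [], {}
        for a in range(n_arms):
            arm = f"{a + 1}{'p' if a % 2 else 'q'}"
            for i in range(gpa):
                g = f"g{a:02d}_{i:02d}"
                genes.append(g)
                arm_of[g] = arm
        ann = make_annotation(arm_of)
        vals = np.exp(rng.normal(1.5, 0.8, size=(len(genes), 11)))
        samples = [f"n{j}" for j in range(6)] + [f"t{j}" for j in range(5)]
        fpkm_df = pd.DataFrame(vals, index=genes, columns=samples)
        m = fpkm_matrix(vals, genes, samples)
        normals, tumors = samples[:6], samples[6:]
        res = tt.jrb_pipeline(m, ann, normals, tumors)
        values, calls = brute_force_jrb(fpkm_df, ann, normals, tumors)
        assert set(res.values.columns) == {a for (_, a) in values}
        for (t, a), v in values.items():
            assert res.values.at[t, a] == pytest.approx(v, abs=1e-10)
            assert res.calls.at[t, a] == calls[(t, a)]


class TestPlantedRecovery:
    def test_sensitivity_and_false_call_rate(self):
        sens_hit = sens_tot = 0
        fp_hit = fp_tot = 0
        for seed in range(20):
            cfg = tt.CohortConfig(
                n_tumors=50, n_normals=30, n_genes=39 * 50,
                effect_sizes={"program": 0, "erk": 0, "tds": 0, "ig": 0, "oncocytic": 0},
                lt_fraction=0.0, oncocytic_fraction=0.0,
                frac_chrx=0.0, frac_noncoding=0.0,
                cnv_plan=[("5q", -0.6, 0.2)], seed=seed,
            )
            counts, ann, meta, truth = tt.generate_cohort(cfg)
            tumors = meta.index[meta["role"] == "tumor"].tolist()
            normals = meta.index[meta["role"] == "normal"].tolist()
            res = tt.jrb_pipeline(tt.fpkm(counts, ann), ann, normals, tumors)
            carriers = set(truth.arm_cnv.index[truth.arm_cnv["5q"] != 0])
            sens_hit += (res.calls.loc[list(carriers), "5q"] == CALL_UNDER).sum()
            sens_tot += len(carriers)
            others = [a for a in res.calls.columns if a != "5q"]
            non_carriers = [t for t in tumors if t not in carriers]
            fp_hit += (res.calls.loc[tumors, others] != CALL_NEUTRAL).to_numpy().sum()
            fp_hit += (res.calls.loc[non_carriers, "5q"] != CALL_NEUTRAL).sum()
            fp_tot += len(tumors) * len(others) + len(non_carriers)
        assert sens_hit / sens_tot >= 0.9
        assert fp_hit / fp_tot <= 0.05

    def test_calls_invariant_to_gene_order(self):
        cfg = tt.CohortConfig(
            n_tumors=10, n_normals=8, n_genes=600,
            effect_sizes={"program": 0, "erk": 0, "tds": 0, "ig": 0, "oncocytic": 0},
            lt_fraction=0.0, cnv_plan=[("3p", 0.8, 0.3)], seed=4,
        )
        counts, ann, meta, _ = tt.generate_cohort(cfg)
        tumors = meta.index[meta["role"] == "tumor"].tolist()
        normals = meta.index[meta["role"] == "normal"].tolist()
        fk = tt.fpkm(counts, ann)
        res = tt.jrb_pipeline(fk, ann, normals, tumors)
        shuffled = tt.ExpressionMatrix(fk.values.sample(frac=1, random_state=0), unit="fpkm")
        res2 = tt.jrb_pipeline(shuffled, ann, normals, tumors)
        pd.testing.assert_frame_equal(
            res.values.sort_index(axis=1), res2.values.sort_index(axis=1)
        )
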