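"""TMM normalization, NB dispersion and GLM testing, replication criteria."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lincsig.io_formats import ExpressionMatrix
from lincsig.replication_de import (
    load_table2,
    nb_dispersion,
    nb_test,
    replication_filter,
    tmm_factors,
)
from lincsig.synthdata import SimulationTruth, gen_annotation, gen_count_cohort


def brute_force_tmm(df, ref_col, trim_m=0.30, trim_a=0.05):
    """Plain-loop transcription of the doubly-trimmed weighted-mean definition."""
    lib = df.sum(axis=0)
    logf = {}
    for s in df.columns:
        if s == ref_col:
            logf[s] = 0.0
            continue
        M, A, W = [], [], []
        for g in df.index:
            x, r = df.loc[g, s], df.loc[g, ref_col]
            if x > 0 and r > 0:
                m = np.log2((x / lib[s]) / (r / lib[ref_col]))
                a = 0.5 * np.log2((x / lib[s]) * (r / lib[ref_col]))
                v = (lib[s] - x) / (lib[s] * x) + (lib[ref_col] - r) / (lib[ref_col] * r)
                M.append(m), A.append(a), W.append(1.0 / v)
        M, A, W = map(np.array, (M, A, W))
        n = len(M)
        rm, ra = stats.rankdata(M), stats.rankdata(A)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = (W[keep] * M[keep]).sum() / W[keep].sum()
        logf[s] = f if abs(f) > 1e-6 else 0.0
    factors = pd.Series({s: 2.0 ** v for s, v in logf.items()})
    return factors / np.exp(np.mean(np.log(factors)))


def _counts_df(arr, prefix="s"):
    return pd.DataFrame(
        np.asarray(arr),
        index=[f"g{i}" for i in range(np.asarray(arr).shape[0])],
        columns=[f"{prefix}{j}" for j in range(np.asarray(arr).shape[1])],
    )


class TestTMM:
    def test_identical_columns_unit_factors(self):
        df = _counts_df([[10, 10], [20, 20], [5, 5], [100, 100]])
        np.testing.assert_allclose(tmm_factors(df), [1.0, 1.0])

    def test_pure_library_size_scaling_unit_factors(self):
        col = np.array([13, 210, 7, 55, 1000, 3])
        df = _counts_df(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_factors(df), [1.0, 1.0], atol=1e-12)

    def test_six_gene_worked_example_matches_definition(self, rng):
        df = _counts_df(rng.integers(1, 500, size=(6, 3)))
        ref = df.columns[0]
        got = tmm_factors(df, ref=ref)
        want = brute_force_tmm(df, ref)
        np.testing.assert_allclose(got.to_numpy(), want.to_numpy(), atol=1e-10)

    def test_larger_random_instance_matches_definition(self, rng):
        df = _counts_df(rng.integers(0, 2000, size=(80, 5)))
        ref = df.columns[2]
        np.testing.assert_allclose(
            tmm_factors(df, ref=ref).to_numpy(),
            brute_force_tmm(df, ref).to_numpy(),
            atol=1e-10,
        )

    def test_invariant_to_global_integer_rescaling(self, rng):
        df = _counts_df(rng.integers(1, 300, size=(40, 4)))
        np.testing.assert_allclose(
            tmm_factors(df).to_numpy(), tmm_factors(df * 3).to_numpy(), atol=1e-9
        )

    def test_all_zero_sample_is_error_naming_sample(self):
        df = _counts_df([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            tmm_factors(df)

    def test_matches_edger_reference_implementation(self, tmp_path, rng):
        """Cross-check against the Bioconductor TMM implementation."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = _counts_df(rng.integers(0, 1000, size=(200, 4)))
        csv = tmp_path / "counts.csv"
        df.to_csv(csv)
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.csv('{csv}', row.names=1));"
            "f <- calcNormFactors(x, method='TMM', refColumn=1);"
            "cat(f, sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        if out.returncode != 0:
            pytest.skip(f"edgeR unavailable: {out.stderr[-200:]}")
        ref_factors = np.array([float(v) for v in out.stdout.split()])
        ours = tmm_factors(df, ref=df.columns[0]).to_numpy()
        np.testing.assert_allclose(ours, ref_factors, rtol=1e-6)


class TestNBDispersion:
    def test_poisson_counts_give_small_common_dispersion(self, rng):
        mu = rng.uniform(200, 2000, size=60)
        counts = rng.poisson(mu[:, None] * np.ones((1, 50)))
        common, _ = nb_dispersion(_counts_df(counts), ["a"] * 25 + ["b"] * 25)
        assert common < 0.05

    def test_nb_dispersion_recovered_in_band(self, rng):
        phi = 0.4
        mu = rng.uniform(100, 1000, size=80)[:, None] * np.ones((1, 50))
        counts = rng.poisson(rng.gamma(1 / phi, phi * mu))
        common, _ = nb_dispersion(_counts_df(counts), ["a"] * 25 + ["b"] * 25)
        assert 0.25 <= common <= 0.6

    def test_constant_duplicated_column_floored_at_zero(self):
        df = _counts_df(np.tile([[50], [80]], (1, 6)))
        _, per_feat = nb_dispersion(df, ["a"] * 3 + ["b"] * 3, shrink=0.0)
        np.testing.assert_allclose(per_feat, 0.0)


class TestNBTest:
    def test_identical_groups_lr_near_zero(self, rng):
        base = rng.poisson(200, size=(10, 12))
        counts = _counts_df(np.column_stack([base, base]))
        groups = ["tumor"] * 12 + ["adjacent"] * 12
        res = nb_test(counts, groups, dispersion=0.1, offsets=np.zeros(24))
        assert (res["lr_stat"] < 1e-6).all()
        np.testing.assert_allclose(res["p_raw"], 1.0, atol=1e-3)

    def test_poisson_limit_agrees_with_poisson_glm(self, rng):
        import statsmodels.api as sm

        mu = rng.uniform(300, 3000, size=15)
        grp_effect = np.array([2.0] * 5 + [1.0] * 10)
        y = rng.poisson(np.outer(mu * grp_effect, np.ones(40)) * np.r_[np.ones(20) * 1.0, np.ones(20)][None, :])
        counts = _counts_df(rng.poisson(np.outer(mu, np.ones(40))))
        groups = np.array(["tumor"] * 20 + ["adjacent"] * 20)
        res = nb_test(counts, groups, dispersion=1e-8, offsets=np.zeros(40))
        X = np.column_stack([np.ones(40), (groups == "tumor").astype(float)])
        for i, g in enumerate(counts.index):
            m1 = sm.GLM(counts.loc[g].to_numpy(), X, family=sm.families.Poisson()).fit()
            m0 = sm.GLM(counts.loc[g].to_numpy(), np.ones((40, 1)), family=sm.families.Poisson()).fit()
            lr_pois = 2 * (m1.llf - m0.llf)
            assert res.loc[g, "lr_stat"] == pytest.approx(lr_pois, rel=0.1, abs=0.05)

    def test_planted_log2fc_recovered_on_nb_cohort(self):
        catalog, _ = gen_annotation(30, 30, seed=1)
        feats = list(catalog)
        truth = SimulationTruth(de_log2fc={f: 1.0 for f in feats[:10]})
        counts, sheet = gen_count_cohort(catalog, 50, 0, truth, dispersion=0.2, seed=2)
        samples = [s for s in counts.samples if sheet.df.loc[s, "tissue"] in ("tumor", "adjacent")]
        res = nb_test(
            counts.subset(samples=samples),
            sheet.df.loc[samples, "tissue"],
            covariates=sheet.df.loc[samples, ["age", "race", "batch"]],
        )
        errs = (res.loc[feats[:10], "log2fc"] - 1.0).abs()
        assert errs.median() < 0.15

    def test_sample_order_invariance(self, rng):
        counts = _counts_df(rng.poisson(100, size=(6, 30)))
        groups = np.array(["tumor"] * 15 + ["adjacent"] * 15)
        res1 = nb_test(counts, groups, dispersion=0.1, offsets=np.zeros(30))
        perm = rng.permutation(30)
        res2 = nb_test(
            counts.iloc[:, perm], groups[perm], dispersion=0.1, offsets=np.zeros(30)
        )
        np.testing.assert_allclose(res1["lr_stat"], res2["lr_stat"], rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="module")
def table2():
    return load_table2()


class TestReplicationFilter:

    def _verdicts(self, t2, **kw):
        return replication_filter(
            t2[["discovery_log2fc"]].rename(columns={"discovery_log2fc": "log2fc"}),
            t2[["paired_log2fc", "paired_p"]].rename(
                columns={"paired_log2fc": "log2fc", "paired_p": "p"}
            ),
            t2[["tvn_log2fc", "tvn_p"]].rename(
                columns={"tvn_log2fc": "log2fc", "tvn_p": "p"}
            ),
            **kw,
        )

    def test_all_37_pass_paired_rule(self, table2):
        v = self._verdicts(table2)
        assert len(v) == 37 and int(v["passes_paired"].sum()) == 37

    def test_30_of_37_pass_tumor_vs_normal(self, table2):
        v = self._verdicts(table2)
        assert int(v["passes_tumor_vs_normal"].sum()) == 30

    def test_meg3_fails_tumor_vs_normal(self, table2):
        v = self._verdicts(table2)
        assert not v.loc["ENSG00000214548", "passes_tumor_vs_normal"]
        assert v.loc["ENSG00000214548", "passes_paired"]

    def test_rerun_bit_identical(self, table2):
        pd.testing.assert_frame_equal(self._verdicts(table2), self._verdicts(table2))

    def test_missing_feature_excluded_with_warning(self, table2):
        with pytest.warns(UserWarning, match="missing"):
            v = replication_filter(
                table2[["discovery_log2fc"]].rename(columns={"discovery_log2fc": "log2fc"}),
                table2[["paired_log2fc", "paired_p"]]
                .rename(columns={"paired_log2fc": "log2fc", "paired_p": "p"})
                .iloc[:-2],
                table2[["tvn_log2fc", "tvn_p"]].rename(
                    columns={"tvn_log2fc": "log2fc", "tvn_p": "p"}
                ),
            )
        assert len(v) == 35
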