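import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episig.core_io import BetaMatrix, EpisigError, SampleSheet
from episig.signature import (
    DiffMethResult,
    ModerationParams,
    bh_adjust,
    build_design,
    delta_beta,
    direction_summary,
    fit_linear_models,
    geneset_enrichment,
    hypergeom_upper,
    island_shore_enrichment,
    map_cpgs_to_genes,
    moderate_variances,
    run_differential,
    select_signature,
)


def two_group_sheet(n_case, n_control):
    rows = []
    for i in range(n_case):
        rows.append((f"C{i}", "case", "discovery_case", "F" if i % 2 else "M", 10.0 + i))
    for i in range(n_control):
        rows.append(
            (f"K{i}", "control", "discovery_control", "M" if i % 2 else "F", 12.0 + i)
        )
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "group", "role", "sex", "age_years"])
    )


class TestDesign:
    def test_full_covariate_design_has_ten_columns(self):
        sheet = two_group_sheet(8, 26)
        # 6-type composition with the dominant type dropped, as in covariate_block
        props = pd.DataFrame(
            np.random.default_rng(0).dirichlet(np.ones(6), size=34)[:, :5],
            index=sheet.sample_ids,
            columns=["CD4T", "CD8T", "NK", "Bcell", "Mono"],
        )
        residuals = pd.Series(
            np.random.default_rng(1).normal(size=34), index=sheet.sample_ids
        )
        design = build_design(sheet, cell_props=props, residuals=residuals)
        assert design.shape == (34, 10)
        assert list(design.columns[:4]) == ["intercept", "group", "age_years", "sex"]

    def test_single_sex_cohort_is_rank_deficient(self):
        rows = [
            ("A", "case", "discovery_case", "M", 5.0),
            ("B", "case", "discovery_case", "M", 6.0),
            ("C", "control", "discovery_control", "M", 7.0),
            ("D", "control", "discovery_control", "M", 8.0),
        ]
        sheet = SampleSheet(
            pd.DataFrame(rows, columns=["sample_id", "group", "role", "sex", "age_years"])
        )
        with pytest.raises(EpisigError, match="sex"):
            build_design(sheet)

    def test_covariates_disabled_gives_two_columns(self):
        design = build_design(two_group_sheet(3, 3), include_covariates=False)
        assert list(design.columns) == ["intercept", "group"]


class TestLinearFits:
    def test_two_group_coef_is_difference_of_means(self, rng):
        sheet = two_group_sheet(4, 4)
        vals = rng.uniform(0.2, 0.8, size=(5, 8))
        beta = BetaMatrix(
            pd.DataFrame(vals, index=[f"cg{i}" for i in range(5)], columns=sheet.sample_ids)
        )
        design = build_design(sheet, include_covariates=False)
        fits = fit_linear_models(beta, design)
        expected = vals[:, :4].mean(axis=1) - vals[:, 4:].mean(axis=1)
        assert fits["coef"].to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_constant_probe_has_zero_coef_and_sigma(self):
        sheet = two_group_sheet(3, 3)
        beta = BetaMatrix(
            pd.DataFrame(
                np.full((1, 6), 0.5), index=["cgconst"], columns=sheet.sample_ids
            )
        )
        fits = fit_linear_models(beta, build_design(sheet, include_covariates=False))
        assert fits.loc["cgconst", "coef"] == pytest.approx(0.0, abs=1e-12)
        assert fits.loc["cgconst", "sigma"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_lstsq_oracle_with_covariate(self, rng):
        # 6 samples, design with one numeric covariate, solved independently
        sheet = two_group_sheet(3, 3)
        design = build_design(sheet, include_covariates=False)
        design["age"] = [3.0, 9.0, 5.0, 2.0, 7.0, 11.0]
        y = rng.uniform(0.1, 0.9, size=6)
        beta = BetaMatrix(
            pd.DataFrame(y[None, :], index=["cg0"], columns=sheet.sample_ids)
        )
        fits = fit_linear_models(beta, design)
        X = design.to_numpy()
        b_or, res_or, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fits.loc["cg0", "coef"] == pytest.approx(b_or[1], abs=1e-10)
        assert fits.loc["cg0", "sigma"] ** 2 * fits.loc["cg0", "df_residual"] == (
            pytest.approx(float(res_or[0]), abs=1e-10)
        )

    def test_missing_values_fit_on_complete_cases(self):
        sheet = two_group_sheet(3, 3)
        vals = np.array([[0.8, 0.7, np.nan, 0.2, 0.3, 0.25]])
        beta = BetaMatrix(
            pd.DataFrame(vals, index=["cg0"], columns=sheet.sample_ids)
        )
        fits = fit_linear_models(beta, build_design(sheet, include_covariates=False))
        assert fits.loc["cg0", "df_residual"] == 3  # 5 complete cases - 2 params
        assert fits.loc["cg0", "coef"] == pytest.approx(0.75 - 0.25)


class TestModeration:
    def _fits(self, rng, n_probes=200, n=12, df=10):
        coef = rng.normal(0, 0.05, n_probes)
        sigma = np.sqrt(
            stats.invgamma.rvs(4.0, scale=3.0 * 0.002, size=n_probes, random_state=42)
        )
        return pd.DataFrame(
            {
                "coef": coef,
                "sigma": sigma,
                "df_residual": float(df),
                "unscaled_sd": 0.5,
            },
            index=[f"cg{i}" for i in range(n_probes)],
        )

    def test_infinite_prior_pools_all_variances(self, rng):
        fits = self._fits(rng)
        params, out = moderate_variances(fits, prior_df=np.inf)
        expected = fits["coef"] / (np.sqrt(params.s0_sq) * fits["unscaled_sd"])
        assert out["moderated_t"].to_numpy() == pytest.approx(
            expected.to_numpy(), rel=1e-12
        )

    def test_zero_prior_df_equals_ordinary_t(self, rng):
        fits = self._fits(rng)
        _, out = moderate_variances(fits, prior_df=0.0)
        ordinary = fits["coef"] / (fits["sigma"] * fits["unscaled_sd"])
        assert out["moderated_t"].to_numpy() == pytest.approx(
            ordinary.to_numpy(), rel=1e-12
        )
        p_ord = 2 * stats.t.sf(np.abs(ordinary), fits["df_residual"])
        assert out["p"].to_numpy() == pytest.approx(p_ord, rel=1e-12)

    def test_null_pvalues_uniform(self):
        # no signal: moderated p-values should be uniform on [0, 1]
        rng = np.random.default_rng(7)
        n, probes = 20, 5000
        sheet = two_group_sheet(10, 10)
        vals = np.clip(rng.normal(0.5, 0.04, size=(probes, n)), 0, 1)
        beta = BetaMatrix(
            pd.DataFrame(
                vals, index=[f"cg{i}" for i in range(probes)], columns=sheet.sample_ids
            )
        )
        fits = fit_linear_models(beta, build_design(sheet, include_covariates=False))
        _, out = moderate_variances(fits)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_raw_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(13)
        probes = 10_000
        sheet = two_group_sheet(10, 10)
        vals = np.clip(rng.normal(0.5, 0.04, size=(probes, 20)), 0, 1)
        beta = BetaMatrix(
            pd.DataFrame(
                vals, index=[f"cg{i}" for i in range(probes)], columns=sheet.sample_ids
            )
        )
        fits = fit_linear_models(beta, build_design(sheet, include_covariates=False))
        _, out = moderate_variances(fits)
        frac = float((out["p"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06
        # and BH keeps the false-discovery set essentially empty under the null
        q = bh_adjust(out["p"].to_numpy())
        assert (q < 0.05).mean() < 0.001

    def test_all_zero_variances_error(self):
        fits = pd.DataFrame(
            {
                "coef": [0.0] * 12,
                "sigma": [0.0] * 12,
                "df_residual": [5.0] * 12,
                "unscaled_sd": [0.5] * 12,
            }
        )
        with pytest.raises(EpisigError):
            moderate_variances(fits)


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_matches_bruteforce_definition(self, rng):
        # q_i = min over p_j >= p_i of m * p_j / rank_j
        for _ in range(5):
            p = rng.uniform(size=20)
            q = bh_adjust(p)
            m = len(p)
            order = np.argsort(p)
            ranks = np.empty(m)
            ranks[order] = np.arange(1, m + 1)
            brute = np.array(
                [
                    min(m * pj / rj for pj, rj in zip(p, ranks) if pj >= pi)
                    for pi in p
                ]
            )
            brute = np.minimum(brute, 1.0)
            assert q == pytest.approx(brute)

    def test_out_of_range_p_errors(self):
        with pytest.raises(EpisigError):
            bh_adjust([0.5, 1.2])


class TestDeltaBeta:
    def test_direct_computation_on_toy(self):
        sheet = two_group_sheet(2, 2)
        vals = np.array(
            [
                [0.8, 0.8, 0.6, 0.6],
                [0.5, 0.5, 0.5, 0.5],
                [0.1, 0.3, 0.4, 0.6],
                [0.9, 0.7, 0.2, 0.4],
                [0.35, 0.45, 0.15, 0.25],
            ]
        )
        beta = BetaMatrix(
            pd.DataFrame(vals, index=[f"cg{i}" for i in range(5)], columns=sheet.sample_ids)
        )
        db = delta_beta(beta, sheet)
        assert db.to_numpy() == pytest.approx([0.2, 0.0, -0.3, 0.5, 0.2])

    def test_probe_missing_in_whole_group_is_nan(self):
        sheet = two_group_sheet(2, 2)
        vals = np.array([[np.nan, np.nan, 0.5, 0.6]])
        beta = BetaMatrix(pd.DataFrame(vals, index=["cg0"], columns=sheet.sample_ids))
        with pytest.warns(UserWarning, match="entire group"):
            db = delta_beta(beta, sheet)
        assert np.isnan(db.iloc[0])


def make_result(probes, qs, dbs):
    table = pd.DataFrame(
        {
            "coef": dbs,
            "delta_beta": dbs,
            "sigma": 0.01,
            "df_residual": 10.0,
            "unscaled_sd": 0.5,
            "moderated_t": 1.0,
            "p": qs,
            "q": qs,
            "direction": np.where(np.asarray(dbs) > 0, "hyper", "hypo"),
        },
        index=probes,
    )
    return DiffMethResult(table=table, params=ModerationParams(5.0, 1e-4))


class TestSelection:
    def test_passing_probe_selected(self):
        res = make_result(["a"], [0.04], [0.15])
        assert select_signature(res) == ["a"]

    def test_boundary_delta_excluded_by_strict_inequality(self):
        res = make_result(["a", "b"], [0.04, 0.04], [0.10, 0.15])
        assert select_signature(res) == ["b"]

    def test_boundary_q_excluded_by_strict_inequality(self):
        res = make_result(["a"], [0.05], [0.2])
        with pytest.warns(UserWarning, match="empty signature"):
            assert select_signature(res) == []

    def test_sorted_by_q_then_effect_then_id(self):
        # a and b tie on (q, |delta beta|): probe id breaks the tie
        res = make_result(
            ["d", "c", "b", "a"], [0.02, 0.01, 0.01, 0.01], [0.30, 0.20, 0.25, 0.25]
        )
        assert select_signature(res) == ["a", "b", "c", "d"]

    def test_selection_invariant_to_probe_and_sample_order(self, rng, small_sim):
        from episig.core_io import align

        disc = small_sim.sheet.discovery()
        beta = align(small_sim.beta, disc)
        design = build_design(disc, include_covariates=False)
        r1 = run_differential(beta, disc, design)
        s1 = select_signature(r1)

        perm_probes = list(rng.permutation(beta.probe_ids))
        perm_samples = list(rng.permutation(list(disc.sample_ids)))
        beta2 = beta.subset_probes(perm_probes).subset_samples(perm_samples)
        disc2 = disc.subset(perm_samples)  # sheet rows follow the permuted order
        design2 = build_design(disc2, include_covariates=False)
        r2 = run_differential(beta2, disc2, design2)
        s2 = select_signature(r2)
        assert set(s1) == set(s2)

    def test_planted_effects_reestimated_accurately(self, small_sim, small_run):
        # delta-beta recovery at n = 8 vs 26: mean absolute error < 0.02
        truth = small_sim.truth["signature"]
        est = small_run.diff.table["delta_beta"].reindex(truth.index)
        mae = float((est - truth["delta_beta"]).abs().mean())
        assert mae < 0.02

    def test_direction_summary_fractions(self):
        res = make_result(["a", "b", "c", "d"], [0.01] * 4, [0.2, 0.3, 0.15, -0.2])
        sig = select_signature(res)
        frac_hyper, frac_hypo = direction_summary(res, sig)
        assert (frac_hyper, frac_hypo) == (0.75, 0.25)
        with pytest.raises(EpisigError):
            direction_summary(res, [])


class TestHypergeometric:
    def test_closed_form_small_case(self):
        # N=10, K=5, n=4, k=4: p = C(5,4)/C(10,4) = 5/210
        assert hypergeom_upper(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_no_enrichment_gives_large_p(self):
        p = hypergeom_upper(1000, 370, 100, 37)
        assert 0.4 <= p <= 1.0

    def test_matches_summation_oracle_at_n20(self):
        from math import comb

        N, K, n = 20, 8, 6
        for k in range(0, min(K, n) + 1):
            oracle = sum(
                comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
            ) / comb(N, n)
            assert hypergeom_upper(N, K, n, k) == pytest.approx(oracle, rel=1e-12)

    def test_island_shore_enrichment_on_manifest(self, small_sim):
        man = small_sim.manifest
        background = list(man.probe_ids)
        signature = [
            p
            for p in background
            if man.table.loc[p, "island_relation"] in ("Island", "Shore")
        ][:30]
        rec = island_shore_enrichment(signature, man, background)
        assert rec.k == 30 and rec.n == 30
        assert rec.p < 1e-6  # all-island foreground is strongly enriched

    def test_signature_outside_background_errors(self, small_sim):
        man = small_sim.manifest
        bg = list(man.probe_ids)[:100]
        with pytest.raises(EpisigError, match="not in background"):
            island_shore_enrichment([list(man.probe_ids)[200]], man, bg)


class TestGeneMapping:
    def test_distance_rules(self, tmp_path):
        from episig.core_io import read_manifest
        from episig.synth import make_degenerate_fixtures

        paths = make_degenerate_fixtures(tmp_path)
        man = read_manifest(paths["boundary_manifest"])
        mapping = map_cpgs_to_genes(["cgNEAR", "cgFAR"], man, max_distance=10_000)
        # gene starts exactly 10 kb from cgNEAR: inclusive boundary maps it
        assert mapping.per_cpg["cgNEAR"] == ["NEARGENE"]
        # cgFAR's gene is 50 kb away
        assert mapping.per_cpg["cgFAR"] == []

    def test_gene_counts_and_multi_hits(self, small_sim):
        man = small_sim.manifest
        probes = [p for p in man.probe_ids if man.table.loc[p, "genes"]][:50]
        mapping = map_cpgs_to_genes(probes, man)
        assert set(mapping.multi_hit_genes) <= set(mapping.genes)
        for gl in mapping.per_cpg.values():
            assert gl == sorted(set(gl))


class TestGenesetEnrichment:
    UNIVERSE = [f"G{i}" for i in range(20)]

    def test_fully_contained_term_has_smallest_p(self):
        fg = ["G0", "G1", "G2", "G3"]
        sets = {
            "contained": {"G0", "G1", "G2", "G3"},
            "half": {"G0", "G1", "G10", "G11"},
            "none": {"G10", "G11", "G12", "G13"},
        }
        df = geneset_enrichment(fg, sets, self.UNIVERSE)
        assert df.index[0] == "contained"
        assert df["p"].loc["contained"] == df["p"].min()

    def test_min_hits_filter_excludes_small_terms(self):
        fg = ["G0", "G1"]
        sets = {"tiny": {"G0", "G1"}}
        df = geneset_enrichment(fg, sets, self.UNIVERSE, min_hits=3)
        assert df.loc["tiny", "k"] == 2
        assert not df.loc["tiny", "reported"]

    def test_p_matches_closed_form_on_toy_universe(self):
        from math import comb

        fg = ["G0", "G1", "G2", "G3", "G4"]
        sets = {"term": {"G0", "G1", "G2", "G10"}}
        df = geneset_enrichment(fg, sets, self.UNIVERSE)
        N, K, n, k = 20, 4, 5, 3
        oracle = sum(
            comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
        ) / comb(N, n)
        assert df.loc["term", "p"] == pytest.approx(oracle, rel=1e-12)

    def test_empty_background_errors(self):
        with pytest.raises(EpisigError):
            geneset_enrichment(["G1"], {"t": {"G1"}}, [])
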