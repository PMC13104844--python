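import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ppikit.allele_enrichment import (
    MutationRecord,
    bin_by_lir,
    category_rates,
    cochran_armitage,
    conservation_analysis,
    enrichment_rates,
    global_align,
    map_mutation,
    within_gene_permutation,
)
from ppikit.synthetic_fixtures import MutationSpec, make_mutation_dataset


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

def brute_force_align_score(a, b, match=1, mismatch=-1, gap=-1):
    """Exhaustive recursion over all global alignments (tiny inputs only)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -10**9
        if i < len(a) and j < len(b):
            best = max(best, (match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestGlobalAlign:
    def test_identical(self):
        pairs, score = global_align("ACDE", "ACDE")
        assert score == 4
        assert pairs == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_insertion_example(self):
        pairs, _ = global_align("ACDE", "ACXDE")
        mapping = {i: j for i, j in pairs if i is not None and j is not None}
        assert mapping[2] == 3  # D (0-based 2) maps to position 4 (0-based 3)

    def test_empty_vs_nonempty(self):
        pairs, score = global_align("", "ACD")
        assert score == -3
        assert pairs == [(None, 0), (None, 1), (None, 2)]

    def test_optimal_score_vs_exhaustive(self, rng):
        letters = "ACDG"
        for _ in range(15):
            a = "".join(rng.choice(list(letters), size=int(rng.integers(1, 6))))
            b = "".join(rng.choice(list(letters), size=int(rng.integers(1, 6))))
            _, score = global_align(a, b)
            assert score == brute_force_align_score(a, b)

    def test_alignment_score_consistent_with_pairs(self, rng):
        a, b = "ACDEFG", "ACDFG"
        pairs, score = global_align(a, b)
        total = 0
        for i, j in pairs:
            if i is None or j is None:
                total -= 1
            else:
                total += 1 if a[i] == b[j] else -1
        assert total == score

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            global_align("AC1", "ACD")


class TestMapMutation:
    def test_exact_match(self):
        rec = MutationRecord("g", 3, "D", "N")
        res = map_mutation(rec, "ACDEF")
        assert res.accepted and res.position == 3

    def test_nterminal_insertion_shift(self):
        rec = MutationRecord("g", 2, "C", "Y")
        res = map_mutation(rec, "GACDEF", annotation_sequence="ACDEF")
        assert res.accepted and res.position == 3

    def test_mismatch_rejected(self):
        rec = MutationRecord("g", 2, "W", "Y")
        res = map_mutation(rec, "ACDEF", annotation_sequence="ACDEF")
        assert not res.accepted and res.reason == "ref-mismatch"

    def test_out_of_range(self):
        rec = MutationRecord("g", 99, "A", "V")
        assert map_mutation(rec, "ACDEF").reason == "out-of-range"

    def test_position_landing_on_gap(self):
        # annotation has an extra C-terminal residue absent from the model
        rec = MutationRecord("g", 6, "W", "Y")
        res = map_mutation(rec, "ACDEF", annotation_sequence="ACDEFW")
        assert not res.accepted

    def test_record_validation(self):
        with pytest.raises(ValueError):
            MutationRecord("g", 0, "A", "V")
        with pytest.raises(ValueError):
            MutationRecord("g", 1, "A", "A")


# ---------------------------------------------------------------------------
# Binning and rates
# ---------------------------------------------------------------------------

def table_from_values(values, mutated=None, gene="g1"):
    n = len(values)
    return pd.DataFrame(
        {
            "gene": [gene] * n,
            "position": np.arange(1, n + 1),
            "aa": ["A"] * n,
            "lir_pct": values,
            "clir_pct": [0.0] * n,
            "phylop": [np.nan] * n,
            "mutated": mutated if mutated is not None else [False] * n,
        }
    )


class TestBinByLir:
    def test_spec_example_one_per_quartile(self):
        binned = bin_by_lir(table_from_values([0, 0, 10, 20, 30, 40]))
        assert binned["lir_bin"].tolist() == ["Zero", "Zero", "Q1", "Q2", "Q3", "Q4"]
        # oracle: percentile edges of the nonzero values
        edges = np.percentile([10, 20, 30, 40], [25, 50, 75])
        assert np.allclose(edges, [17.5, 25.0, 32.5])

    def test_degenerate_all_equal_nonzero(self):
        binned = bin_by_lir(table_from_values([0, 5, 5, 5]))
        assert binned["lir_bin"].tolist() == ["Zero", "Q1", "Q1", "Q1"]

    def test_zero_residue_never_moves_edges(self, rng):
        vals = rng.uniform(1, 100, 40).tolist()
        b1 = bin_by_lir(table_from_values(vals + [0.0]))
        b2 = bin_by_lir(table_from_values(vals + [0.0, 0.0, 0.0]))
        assert b1["lir_bin"].iloc[:40].tolist() == b2["lir_bin"].iloc[:40].tolist()

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            binned = bin_by_lir(table_from_values([0.0, 0.0]))
        assert (binned["lir_bin"] == "Zero").all()

    def test_domain_only_restricts(self):
        t = table_from_values([0, 0, 10, 20, 30, 40])
        binned = bin_by_lir(t, domain_only=True)
        assert len(binned) == 4
        assert "Zero" not in binned["lir_bin"].tolist()

    def test_partition_conserves_totals(self, rng):
        t = table_from_values(np.where(rng.random(200) < 0.3, 0.0, rng.uniform(0, 100, 200)))
        binned = bin_by_lir(t)
        counts = binned.groupby("lir_bin", observed=False).size()
        assert counts.sum() == len(t)


class TestEnrichmentRates:
    def test_fold_six(self):
        t = pd.concat(
            [
                table_from_values([0.0] * 1000, [True] + [False] * 999),
                table_from_values([90.0] * 1000, [True] * 6 + [False] * 994, gene="g2"),
            ],
            ignore_index=True,
        )
        binned = bin_by_lir(t)
        rates = enrichment_rates(binned)
        assert rates.loc["Zero", "rate"] == pytest.approx(0.001)
        assert rates.loc["Q1", "fold_vs_zero"] == pytest.approx(6.0)

    def test_no_mutations(self):
        rates = enrichment_rates(bin_by_lir(table_from_values([0, 10, 20, 30, 40])))
        assert (rates["rate"].dropna() == 0).all()
        assert rates["fold_vs_zero"].isna().all()

    def test_counting_oracle(self, rng):
        vals = np.where(rng.random(300) < 0.4, 0.0, rng.uniform(0, 100, 300))
        mut = rng.random(300) < 0.05
        binned = bin_by_lir(table_from_values(vals, mut))
        rates = enrichment_rates(binned)
        for label in ["Zero", "Q1", "Q2", "Q3", "Q4"]:
            sel = binned["lir_bin"] == label
            assert rates.loc[label, "n_residues"] == int(sel.sum())
            assert rates.loc[label, "n_mutated"] == int((sel & binned["mutated"]).sum())
        assert rates["n_residues"].sum() == 300

    def test_category_split(self):
        t = pd.DataFrame(
            {
                "gene": ["g"] * 6,
                "position": range(1, 7),
                "aa": ["A"] * 6,
                "lir_pct": [0, 0, 50, 50, 80, 80],
                "clir_pct": [0, 0, 0, 0, 40, 40],
                "phylop": [np.nan] * 6,
                "mutated": [False, True, False, True, True, True],
            }
        )
        cats = category_rates(t)
        assert cats.loc["No LIR", "rate"] == pytest.approx(0.5)
        assert cats.loc["LIR-cLIR", "rate"] == pytest.approx(0.5)
        assert cats.loc["cLIR", "rate"] == pytest.approx(1.0)
        assert cats["n_residues"].sum() == 6


# ---------------------------------------------------------------------------
# Trend test
# ---------------------------------------------------------------------------

class TestCochranArmitage:
    def test_flat_rates_near_zero(self):
        z, p = cochran_armitage([10, 10, 10], [1000, 1000, 1000])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_direct_formula_oracle(self):
        m = np.array([1.0, 2.0, 3.0])
        n = np.array([100.0, 100.0, 100.0])
        s = np.array([0.0, 1.0, 2.0])
        # independent evaluation of the trend statistic
        N, M = n.sum(), m.sum()
        pbar = M / N
        T = np.sum(s * (m - n * pbar))
        var = pbar * (1 - pbar) * (N / (N - 1)) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
        z_expected = T / np.sqrt(var)
        z, _ = cochran_armitage(m, n)
        assert z == pytest.approx(z_expected, abs=1e-12)

    def test_reversal_antisymmetry(self):
        z1, _ = cochran_armitage([1, 2, 8], [100, 100, 100])
        z2, _ = cochran_armitage([8, 2, 1], [100, 100, 100])
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            cochran_armitage([0, 0], [0, 0])
        with pytest.raises(ValueError):
            cochran_armitage([5], [10])

    def test_hypergeometric_variance_matches_simulation(self, rng):
        # null: M mutations dropped among N residues without replacement
        n = np.array([50, 80, 120])
        M, N = 25, int(n.sum())
        s = np.arange(3.0)
        bins = np.repeat(s, n)
        sims = np.empty(4000)
        for k in range(4000):
            chosen = rng.choice(N, M, replace=False)
            m = np.array([(bins[chosen] == v).sum() for v in s])
            sims[k] = np.sum(s * (m - n * M / N))
        pbar = M / N
        var_formula = pbar * (1 - pbar) * (N / (N - 1)) * (
            np.sum(n * s**2) - np.sum(n * s) ** 2 / N
        )
        assert sims.var() == pytest.approx(var_formula, rel=0.1)


# ---------------------------------------------------------------------------
# Within-gene permutation
# ---------------------------------------------------------------------------

class TestWithinGenePermutation:
    def test_constant_statistic_p_one(self):
        # one gene, every residue in the same bin -> statistic degenerate
        t = table_from_values([10.0] * 20, [True] * 3 + [False] * 17)
        binned = bin_by_lir(t)
        res = within_gene_permutation(binned, n_perm=200, seed=0)
        assert res.p == pytest.approx(1.0)

    def test_planted_trend_hits_floor(self):
        table, _, _ = make_mutation_dataset(
            MutationSpec(seed=2, n_genes=40, n_residues=150, beta0=-5.0, beta1=0.06)
        )
        binned = bin_by_lir(table, field="clir_pct")
        res = within_gene_permutation(binned, n_perm=999, seed=3)
        assert res.p == pytest.approx(1.0 / 1000.0)

    def test_counts_preserved(self, rng):
        table, _, _ = make_mutation_dataset(MutationSpec(seed=4, n_genes=5, n_residues=50))
        binned = bin_by_lir(table)
        res = within_gene_permutation(binned, n_perm=50, seed=1, return_null=True)
        assert res.null is not None and len(res.null) == 50
        # total mutation count conservation is implicit in the count-based
        # sampler: per-gene draws are multivariate hypergeometric with the
        # gene's mutation count as sample size
        assert res.n_perm == 50

    def test_seeded_reproducible(self):
        table, _, _ = make_mutation_dataset(MutationSpec(seed=6, n_genes=10, n_residues=80))
        binned = bin_by_lir(table)
        r1 = within_gene_permutation(binned, n_perm=300, seed=7)
        r2 = within_gene_permutation(binned, n_perm=300, seed=7)
        assert r1.p == r2.p and r1.observed == r2.observed

    def test_permutation_matches_bruteforce_loop(self, rng):
        # independent oracle: permute explicitly per gene with rng.choice
        table, _, _ = make_mutation_dataset(MutationSpec(seed=8, n_genes=4, n_residues=40))
        binned = bin_by_lir(table)
        from ppikit.allele_enrichment import _trend_z_from_counts

        k = 5
        codes = binned["lir_bin"].cat.codes.to_numpy()
        totals = np.bincount(codes, minlength=k)
        obs = _trend_z_from_counts(
            np.bincount(codes[binned["mutated"]], minlength=k)[None, :], totals
        )[0]
        r = np.random.default_rng(0)
        null = []
        for _ in range(2000):
            counts = np.zeros(k, dtype=int)
            for _, sub in binned.groupby("gene", sort=False):
                m_g = int(sub["mutated"].sum())
                idx = r.choice(len(sub), m_g, replace=False)
                counts += np.bincount(sub["lir_bin"].cat.codes.to_numpy()[idx], minlength=k)
            null.append(_trend_z_from_counts(np.array([counts]), totals)[0])
        p_oracle = (1 + np.sum(np.array(null) >= obs)) / 2001
        res = within_gene_permutation(binned, n_perm=2000, seed=123)
        assert res.observed == pytest.approx(obs, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=0.05)

    def test_invalid_args(self):
        t = bin_by_lir(table_from_values([0, 10, 20, 30, 40]))
        with pytest.raises(ValueError):
            within_gene_permutation(t, n_perm=0)
        with pytest.raises(ValueError):
            within_gene_permutation(t, statistic="nope", n_perm=10)


# ---------------------------------------------------------------------------
# Conservation stratification and regression
# ---------------------------------------------------------------------------

class TestConservationAnalysis:
    def test_parameter_recovery_independent_phylop(self):
        spec = MutationSpec(seed=10, n_genes=60, n_residues=300, beta0=-5.0,
                            beta1=0.04, beta2=0.0)
        table, _, truth = make_mutation_dataset(spec)
        res = conservation_analysis(table)
        se = res.bse_adjusted[1]
        assert abs(res.beta_clir_adjusted - truth["beta1"]) < 3 * se
        assert abs(res.beta_phylop) < 0.3
        assert res.converged and not res.penalized

    def test_phylop_effect_recovered(self):
        spec = MutationSpec(seed=11, n_genes=60, n_residues=300, beta0=-5.5,
                            beta1=0.03, beta2=0.5)
        table, _, truth = make_mutation_dataset(spec)
        res = conservation_analysis(table)
        se2 = res.bse_adjusted[2]
        assert abs(res.beta_phylop - truth["beta2"]) < 3 * se2
        assert res.p_phylop < 0.01

    def test_attenuation_with_correlated_confounder(self):
        spec = MutationSpec(seed=12, n_genes=60, n_residues=300, beta0=-5.5,
                            beta1=0.03, beta2=0.8, phylop_clir_rho=0.5)
        table, _, _ = make_mutation_dataset(spec)
        res = conservation_analysis(table)
        # adjusting for the correlated covariate shrinks the clir coefficient
        assert res.beta_clir_adjusted < res.beta_clir_only
        assert res.attenuation > 0.05

    def test_constant_clir_rejected(self):
        t = table_from_values([10.0] * 50, [True] * 2 + [False] * 48)
        t["phylop"] = np.linspace(0, 3, 50)
        with pytest.raises(ValueError, match="constant"):
            conservation_analysis(t)

    def test_strata_counts_partition(self):
        table, _, _ = make_mutation_dataset(MutationSpec(seed=13, n_genes=20, n_residues=100))
        res = conservation_analysis(table)
        total = (res.strata["n_interface"] + res.strata["n_noninterface"]).sum()
        assert total == len(table)

    def test_grid_search_oracle_small_table(self):
        # clir-only logit fit vs brute-force likelihood maximization on a grid
        rng = np.random.default_rng(14)
        clir = rng.uniform(0, 100, 400)
        y = rng.random(400) < expit(-3.0 + 0.025 * clir)
        t = pd.DataFrame(
            {
                "gene": "g",
                "position": np.arange(1, 401),
                "aa": "A",
                "lir_pct": clir,
                "clir_pct": clir,
                "phylop": rng.normal(2, 1, 400),
                "mutated": y,
            }
        )
        res = conservation_analysis(t)

        def loglik(b0, b1):
            eta = b0 + b1 * clir
            return np.sum(y * eta - np.log1p(np.exp(eta)))

        b0_grid = np.linspace(-5, -1, 81)
        b1_grid = np.linspace(0.0, 0.06, 121)
        best = max(itertools.product(b0_grid, b1_grid), key=lambda ab: loglik(*ab))
        assert res.beta_clir_only == pytest.approx(best[1], abs=0.001)
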