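import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curvepool import (
    CohortScenario,
    IC50Table,
    MutationTable,
    expression_association,
    mutation_association,
    run_biomarker_scan,
    simulate_cohort,
    spearman,
    wilcoxon_rank_sum,
)

from _oracles import spearman_rho_bruteforce, wilcoxon_exact_p


class TestWilcoxonRankSum:
    def test_separated_groups_exact_p(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_null_symmetric(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_matches_enumeration_oracle_small_sizes(self, rng):
        for n_a in range(1, 6):
            for n_b in range(1, 6):
                values = rng.permutation(np.arange(1, n_a + n_b + 1, dtype=float))
                a, b = values[:n_a], values[n_a:]
                _, p = wilcoxon_rank_sum(a, b)
                assert p == pytest.approx(wilcoxon_exact_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        rho, _ = spearman([1, 2, 3], [1, 3, 2])
        assert rho == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_undefined(self):
        rho, p = spearman([1, 2, 3], [5, 5, 5])
        assert math.isnan(rho) and math.isnan(p)

    def test_matches_bruteforce_rank_formula(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            xs = rng.normal(size=n)
            ys = rng.normal(size=n)
            rho, _ = spearman(xs, ys)
            assert rho == pytest.approx(spearman_rho_bruteforce(xs, ys), abs=1e-12)

    @given(xs=st.lists(st.integers(-100, 100), min_size=4, max_size=20, unique=True),
           data=st.data())
    @settings(derandomize=True, max_examples=100)
    def test_invariant_under_monotone_transform(self, xs, data):
        # integer inputs keep the transforms strictly monotone in floats
        ys = data.draw(
            st.lists(st.integers(-100, 100), min_size=len(xs), max_size=len(xs),
                     unique=True)
        )
        rho, _ = spearman(xs, ys)
        rho_t, _ = spearman(np.exp(np.asarray(xs) / 50.0),
                            [float(y) ** 3 + y for y in ys])
        assert rho_t == pytest.approx(rho, abs=1e-9)


def _ic50_table(values, drug="D1", cancer_type="pan"):
    return IC50Table(
        records=pd.DataFrame(
            {
                "drug_id": drug,
                "cell_line_id": [f"CL{i}" for i in range(len(values))],
                "cancer_type": cancer_type,
                "ic50_log2": values,
            }
        )
    )


def _mut_table(gene, mutant_cells):
    return MutationTable(
        calls=pd.DataFrame({"gene": gene, "cell_line": sorted(mutant_cells)})
    )


class TestMutationAssociation:
    def test_insufficient_mutants_skipped(self, rng):
        table = _ic50_table(rng.normal(size=59))
        muts = _mut_table("G1", [f"CL{i}" for i in range(9)])
        result = mutation_association(table, muts, "D1", "G1")
        assert not result.tested
        assert result.skipped_reason == "insufficient mutants"
        assert (result.n_mut, result.n_wt) == (9, 50)

    def test_boundary_ten_ten_tested(self, rng):
        table = _ic50_table(rng.normal(size=20))
        muts = _mut_table("G1", [f"CL{i}" for i in range(10)])
        result = mutation_association(table, muts, "D1", "G1")
        assert result.tested and result.p_value is not None

    def test_effect_direction_and_size(self):
        values = np.concatenate([np.zeros(10) - 2.0, np.zeros(10)])
        table = _ic50_table(values)
        muts = _mut_table("G1", [f"CL{i}" for i in range(10)])
        result = mutation_association(table, muts, "D1", "G1")
        assert result.effect_size == pytest.approx(-2.0)
        assert result.rank_biserial == pytest.approx(-1.0)
        assert result.p_value < 0.001

    def test_missing_drug_raises(self, rng):
        table = _ic50_table(rng.normal(size=20))
        with pytest.raises(KeyError):
            mutation_association(table, _mut_table("G1", []), "NOPE", "G1")

    def test_planted_shift_power(self):
        """A −2 log2 shift in 20/20 mutants with noise sd 0.5 is detected
        (p < 0.01, negative effect) in at least 95% of 100 simulations."""
        hits = 0
        for seed in range(100):
            scn = CohortScenario(
                n_cell_lines=40,
                mutation_effects={"GENE": -2.0},
                n_null_genes=0,
                mutation_prevalence=0.5,
                ic50_noise_sd=0.5,
                seed=seed,
            )
            ic50, muts, _ = simulate_cohort(scn)
            result = mutation_association(ic50, muts, "DRUG1", "GENE")
            if result.tested and result.p_value < 0.01 and result.effect_size < 0:
                hits += 1
        assert hits >= 95


class TestExpressionAssociation:
    def _expr(self, tpm_rows):
        cells = [f"CL{i}" for i in range(len(next(iter(tpm_rows.values()))))]
        return pd.DataFrame(tpm_rows, index=cells).T

    def test_background_expression_skipped(self, rng):
        table = _ic50_table(rng.normal(size=12))
        tpm = np.full(12, 0.2)
        tpm[:4] = 5.0  # only 4 cell lines at TPM >= 1
        expr = self._expr({"G1": tpm})
        result = expression_association(table, expr, "D1", "G1")
        assert result.skipped_reason == "background expression"

    def test_insufficient_overlap_skipped(self, rng):
        table = _ic50_table(rng.normal(size=9))
        expr = self._expr({"G1": np.full(9, 10.0)})
        result = expression_association(table, expr, "D1", "G1")
        assert result.skipped_reason == "insufficient cell lines"

    def test_gate_boundaries_pass(self, rng):
        table = _ic50_table(rng.normal(size=10))
        tpm = np.full(10, 0.5)
        tpm[:5] = 1.0  # exactly 5 at TPM >= 1, exactly 10 cells
        result = expression_association(table, self._expr({"G1": tpm}), "D1", "G1")
        assert result.tested

    def test_missing_gene_raises(self, rng):
        table = _ic50_table(rng.normal(size=12))
        with pytest.raises(KeyError):
            expression_association(table, self._expr({"G1": np.ones(12)}), "D1", "G2")

    def test_planted_monotone_power(self):
        """IC50 rising with expression rank (n=30) yields positive rho with
        p < 0.05 in at least 95% of 100 simulations."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            n = 30
            tpm = np.exp(rng.normal(2.0, 1.0, n))
            ranks = np.argsort(np.argsort(tpm)).astype(float)
            ic = 0.5 * ranks + rng.normal(0.0, 2.0, n)
            table = _ic50_table(ic)
            result = expression_association(table, self._expr({"G1": tpm}), "D1", "G1")
            if result.tested and result.effect_size > 0 and result.p_value < 0.05:
                hits += 1
        assert hits >= 95


class TestBiomarkerScan:
    def test_all_below_gates_zero_tests(self, rng):
        scn = CohortScenario(n_cell_lines=8, n_null_genes=3, seed=1)
        ic50, muts, expr = simulate_cohort(scn)
        table = run_biomarker_scan(ic50, muts=muts, expr=expr)
        assert len(table) > 0
        assert table["p_value"].isna().all()
        assert table["skipped_reason"].notna().all()

    def test_bh_identity_single_test(self, rng):
        ic50 = _ic50_table(rng.normal(size=20))
        muts = _mut_table("G1", [f"CL{i}" for i in range(10)])
        tpm = np.exp(rng.normal(2, 1, 20))
        expr = pd.DataFrame([tpm], index=["G2"], columns=[f"CL{i}" for i in range(20)])
        table = run_biomarker_scan(ic50, muts=muts, expr=expr, genes=["G1", "G2"])
        tested = table[table["p_value"].notna()]
        assert len(tested) == 2  # one mutation + one expression test
        assert (tested["q_value"] == tested["p_value"]).all()

    def test_gate_logic_never_violated(self):
        scn = CohortScenario(
            n_cell_lines=25, n_null_genes=20, mutation_prevalence=0.3, seed=3
        )
        ic50, muts, expr = simulate_cohort(scn)
        table = run_biomarker_scan(ic50, muts=muts, expr=expr)
        tested = table[table["p_value"].notna()]
        mutation = tested[tested["test_type"] == "mutation"]
        assert (mutation["n_mut"] >= 10).all() and (mutation["n_wt"] >= 10).all()
        expression = tested[tested["test_type"] == "expression"]
        assert (expression["n_cells"] >= 10).all()

    def test_cancer_type_filter_applied_before_gates(self, rng):
        # 30 lines overall, but only 15 in the restricted type: the same
        # gene passes pan-cancer and fails within the type
        records = pd.DataFrame(
            {
                "drug_id": "D1",
                "cell_line_id": [f"CL{i}" for i in range(30)],
                "cancer_type": ["lung"] * 15 + ["breast"] * 15,
                "ic50_log2": rng.normal(size=30),
            }
        )
        ic50 = IC50Table(records=records)
        muts = _mut_table("G1", [f"CL{i}" for i in range(12)])
        pan = mutation_association(ic50, muts, "D1", "G1")
        assert pan.tested
        lung = mutation_association(ic50, muts, "D1", "G1", cancer_type="lung")
        assert not lung.tested
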