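"""Tests for comparative stability analytics.

Cliff's delta and the Mann-Whitney machinery are checked against brute-force
all-pairs oracles; matrix operations are checked on hand-built databases and
on parameter-recovery simulations with known injected effects.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_formula_db
from ndegron.analytics import (
    GROUPS,
    cliffs_delta,
    conditional_matrix,
    contrast,
    crosstab_bulky_negative,
    delta_matrix,
    enrichment_logo,
    group_count,
    group_enrichment,
    mean_psi_matrix,
    metap_comparison,
    net_charge,
    p1p2_enrichment,
    rank_low_psi_pairs,
    star_annotation,
    subset_contrast,
)
from ndegron.genetics import AA_ALPHABET
from ndegron.model import sample_motifs


def brute_force_delta(x, y):
    """All-pairs Cliff's delta oracle."""
    x = np.asarray(x)[:, None]
    y = np.asarray(y)[None, :]
    return ((x > y).sum() - (x < y).sum()) / (x.size * y.size)


class TestCliffsDelta:
    def test_complete_separation(self):
        assert cliffs_delta([3, 3, 3], [1, 1, 1]) == pytest.approx(1.0)
        assert cliffs_delta([1, 1, 1], [3, 3, 3]) == pytest.approx(-1.0)

    def test_identical_samples(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_overlapping_small_sample(self):
        # 9 ordered pairs: 1 greater, 6 lesser, 2 ties
        assert cliffs_delta([1, 2, 3], [2, 3, 4]) == pytest.approx(-5 / 9)
        assert brute_force_delta([1, 2, 3], [2, 3, 4]) == pytest.approx(-5 / 9)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n1 = int(rng.integers(1, 100))
            n2 = int(rng.integers(1, min(100, 10_000 // n1) + 1))
            x = rng.choice(np.linspace(1, 4, 13), size=n1)  # heavy ties
            y = rng.choice(np.linspace(1, 4, 13), size=n2)
            assert cliffs_delta(x, y) == pytest.approx(
                brute_force_delta(x, y), abs=1e-12
            )

    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=25),
        st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=25),
    )
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence_property(self, x, y):
        assert cliffs_delta(x, y) == pytest.approx(brute_force_delta(x, y), abs=1e-12)


class TestContrast:
    def test_identical_samples_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        res = contrast(x, x)
        assert res.delta == pytest.approx(0.0)
        assert res.p > 0.9
        assert res.annotation == "ns"

    def test_exact_and_asymptotic_agree_at_n8(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(loc=0.5, size=8)
            from scipy.stats import mannwhitneyu

            exact = mannwhitneyu(x, y, method="exact").pvalue
            asym = mannwhitneyu(x, y, method="asymptotic").pvalue
            assert asym == pytest.approx(exact, rel=0.10)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            contrast([], [1, 2])

    def test_star_annotation_bands(self):
        assert star_annotation(0.2, 0.9) == "ns"
        assert star_annotation(0.01, 0.1) == "*"
        assert star_annotation(0.01, 0.3) == "**"
        assert star_annotation(0.01, 0.6) == "***"
        assert star_annotation(0.01, 0.8) == "****"
        assert star_annotation(0.01, 1.0) == "****"

    def test_subset_contrast_on_formula_db(self):
        motifs = sample_motifs(np.random.default_rng(2), 2000)
        db = make_formula_db(motifs, lambda m: 2.0 if m[0] == "F" else 3.5)
        res = subset_contrast(db, lambda m: m[0] == "F", lambda m: m[0] == "A")
        assert res.delta == pytest.approx(-1.0)
        assert res.mean_diff == pytest.approx(-1.5)
        assert res.annotation == "****"


class TestMatrices:
    def test_single_motif_matrix(self):
        db = make_formula_db(["FAAAA"], lambda m: 2.0)
        matrix = mean_psi_matrix(db)
        assert matrix.cell("F", 1) == 2.0
        for p in (2, 3, 4, 5):
            assert matrix.cell("A", p) == 2.0
        assert np.isnan(matrix.cell("C", 1))
        assert matrix.n.loc["C", "P1"] == 0

    def test_matrix_invariant_to_motif_order(self):
        motifs = sample_motifs(np.random.default_rng(4), 300)
        db1 = make_formula_db(motifs, net_charge)
        db2 = make_formula_db(list(reversed(motifs)), net_charge)
        pd.testing.assert_frame_equal(
            mean_psi_matrix(db1).values, mean_psi_matrix(db2).values
        )

    def test_delta_identity_and_antisymmetry(self):
        motifs = sample_motifs(np.random.default_rng(5), 500)
        a = mean_psi_matrix(make_formula_db(motifs, lambda m: 3.0))
        b = mean_psi_matrix(make_formula_db(motifs, net_charge))
        zero = delta_matrix(a, a)
        assert np.allclose(zero.values.to_numpy(), 0.0)
        ab = delta_matrix(a, b).values.to_numpy()
        ba = delta_matrix(b, a).values.to_numpy()
        assert np.allclose(ab, -ba, equal_nan=True)

    def test_delta_propagates_empty_cells(self):
        a = mean_psi_matrix(make_formula_db(["FAAAA"], lambda m: 2.0))
        b = mean_psi_matrix(make_formula_db(["CAAAA"], lambda m: 3.0))
        d = delta_matrix(a, b)
        assert np.isnan(d.cell("F", 1)) and np.isnan(d.cell("C", 1))
        assert d.cell("A", 2) == pytest.approx(-1.0)

    def test_genotype_difference_recovers_injected_effect(self, recovery_pair):
        delta = delta_matrix(
            mean_psi_matrix(recovery_pair["WT"]),
            mean_psi_matrix(recovery_pair["CLPS_KO"]),
        )
        assert delta.cell("F", 1) == pytest.approx(-1.0, abs=0.1)
        others = delta.values.copy()
        others.loc["F", "P1"] = np.nan
        assert np.nanmax(np.abs(others.to_numpy())) < 0.1


class TestConditionalMatrix:
    def test_condition_restricts_and_reduces_positions(self):
        motifs = sample_motifs(np.random.default_rng(6), 2000)
        # interaction: E at P3 only matters when P1 is C
        db = make_formula_db(
            motifs,
            lambda m: 3.0 - (0.8 if (m[0] == "C" and m[2] == "E") else 0.0),
        )
        cond = conditional_matrix(db, 1, "C")
        assert cond.positions == ["P2", "P3", "P4", "P5"]
        background = np.nanmean(cond.values["P3"].drop("E").to_numpy())
        assert cond.cell("E", 3) < background - 0.5
        # and invisible without the condition on P1
        uncond = conditional_matrix(db, 1, "A")
        assert uncond.cell("E", 3) == pytest.approx(
            np.nanmean(uncond.values["P3"].drop("E").to_numpy()), abs=0.05
        )

    def test_absent_residue_gives_empty_matrix(self):
        db = make_formula_db(["AAAAA", "CCCCC"], lambda m: 3.0)
        cond = conditional_matrix(db, 1, "W")
        assert cond.values.isna().all().all()

    def test_p1_conditions_partition_the_database(self):
        motifs = sample_motifs(np.random.default_rng(7), 800)
        db = make_formula_db(motifs, lambda m: 3.0)
        total = sum(
            int(conditional_matrix(db, 1, aa).n["P2"].sum()) for aa in AA_ALPHABET
        )
        assert total == len(db)


class TestSequenceProperties:
    @pytest.mark.parametrize(
        "motif,charge", [("FDEDE", -4), ("FRKAA", 2), ("AAAAA", 0), ("HHHHH", 0)]
    )
    def test_net_charge(self, motif, charge):
        assert net_charge(motif) == charge

    def test_net_charge_position_mask(self):
        assert net_charge("RDEDE", positions=(2, 3, 4, 5)) == -4
        assert net_charge("RDEDE") == -3

    def test_group_count_examples(self):
        assert group_count("FFAAA", "Bulky", positions=(1, 2)) == 2
        assert group_count("LGSGS", frozenset("GS"), positions=(2, 3, 4, 5)) == 4
        assert group_count("MKVNP", frozenset(AA_ALPHABET)) == 5

    def test_group_presets_are_standard_residues(self):
        for members in GROUPS.values():
            assert members <= set(AA_ALPHABET)
        assert GROUPS["Negative"] == set("DE")
        assert GROUPS["CanonicalDestabilizing"] == set("FLWYRK")


class TestEnrichment:
    def test_logo_identity(self):
        motifs = sample_motifs(np.random.default_rng(8), 400)
        db = make_formula_db(motifs, lambda m: 3.0)
        logo = enrichment_logo(db, db)
        values = logo.values.to_numpy()
        assert np.allclose(values[~np.isnan(values)], 1.0)

    def test_single_motif_subset_fold(self):
        balanced = [aa * 5 for aa in AA_ALPHABET]
        background = make_formula_db(balanced, lambda m: 3.0)
        subset = make_formula_db(["FFFFF"], lambda m: 1.5)
        logo = enrichment_logo(subset, background)
        assert logo.cell("F", 1) == pytest.approx(20.0)

    def test_background_weighted_mean_fold_is_one(self):
        rng = np.random.default_rng(9)
        background = make_formula_db(sample_motifs(rng, 1000), lambda m: 3.0)
        subset = make_formula_db(sample_motifs(rng, 200), lambda m: 2.0)
        from ndegron.analytics import _position_frequencies

        f_bg = _position_frequencies(background.records["motif"])
        logo = enrichment_logo(subset, background).values
        weighted = (logo.fillna(0) * f_bg).sum()
        assert np.allclose(weighted.to_numpy(), 1.0, atol=1e-12)

    def test_p1p2_matrix_shape_and_neutral_pair(self):
        motifs = sample_motifs(np.random.default_rng(10), 6000)
        # stability independent of P1/P2 -> enrichment ~0 everywhere defined
        rng = np.random.default_rng(0)
        psi_map = {m: rng.choice([1.5, 3.5]) for m in motifs}
        db = make_formula_db(motifs, psi_map.get)
        mat = p1p2_enrichment(db)
        assert mat.shape == (20, 20)
        assert mat.size == 400
        assert abs(np.nanmean(mat.to_numpy())) < 0.2

    def test_destabilizing_pair_count(self):
        destabilizing = GROUPS["CanonicalDestabilizing"]
        labels = [
            (p1, p2)
            for p1 in AA_ALPHABET
            for p2 in AA_ALPHABET
            if p1 in destabilizing and p2 in destabilizing
        ]
        assert len(labels) == 36

    def test_rank_low_psi_pairs(self):
        motifs = sample_motifs(np.random.default_rng(12), 4000)
        db = make_formula_db(
            motifs, lambda m: 1.5 if m[:2] == "FQ" else (3.6 if m[0] == "A" else 3.0)
        )
        if not (db.records["motif"].str[:2] == "FQ").any():
            pytest.skip("sample lacks FQ dipeptide")
        ranked = rank_low_psi_pairs(db, k=5)
        assert ranked.iloc[0]["pair"] == "FQ"

    def test_group_enrichment_detects_overrepresentation(self):
        rng = np.random.default_rng(13)
        background = make_formula_db(sample_motifs(rng, 2000), lambda m: 3.0)
        subset = make_formula_db(
            ["F" + m[1:] for m in sample_motifs(rng, 500)], lambda m: 2.0
        )
        enr = group_enrichment(subset, background)
        assert enr.loc["Bulky", "P1"] > 0.5


class TestMetapComparison:
    def test_null_model_shows_no_shift(self):
        motifs = sample_motifs(np.random.default_rng(14), 8000)
        db = make_formula_db(motifs, lambda m: 3.0)
        result = metap_comparison(db)
        assert (result["diff"].abs() < 1e-9).all()
        assert len(result) <= 20

    def test_destabilizing_p1_effect_reverses_after_shift(self):
        # F destabilizes only at P1: the Met-extended form hides it
        motifs = sample_motifs(np.random.default_rng(15), 12_000)
        db = make_formula_db(
            motifs, lambda m: 3.5 - (1.0 if m[0] == "F" else 0.0)
        )
        result = metap_comparison(db).set_index("X")
        if "F" not in result.index:
            pytest.skip("sample lacks matched M-F windows")
        assert result.loc["F", "diff"] > 0.5
        neutral = result.drop(index=["F", "M"], errors="ignore")["diff"]
        assert (neutral.abs() < 0.2).all()

    def test_requires_met_motifs(self):
        db = make_formula_db(["AAAAA"], lambda m: 3.0)
        with pytest.raises(ValueError):
            metap_comparison(db)


class TestCrosstab:
    def test_reference_cell_is_zero(self):
        motifs = sample_motifs(np.random.default_rng(16), 3000)
        db = make_formula_db(motifs, lambda m: 3.0)
        table, _ = crosstab_bulky_negative(db)
        assert table.loc[0, 0] == pytest.approx(0.0)

    def test_additive_bulky_effect_recovered(self):
        motifs = sample_motifs(np.random.default_rng(17), 20_000)
        db = make_formula_db(
            motifs, lambda m: 3.5 - 0.3 * group_count(m, "Bulky", (2, 3, 4, 5))
        )
        table, stats = crosstab_bulky_negative(db)
        assert table.loc[2, 0] == pytest.approx(-0.6, abs=0.05)
        assert stats[(2, 0)].p < 0.05

    def test_cell_counts_partition_filtered_motifs(self):
        motifs = sample_motifs(np.random.default_rng(18), 2000)
        db = make_formula_db(motifs, lambda m: 3.0)
        p1_filter = lambda m: m[0] not in GROUPS["CanonicalDestabilizing"]
        _, stats = crosstab_bulky_negative(db, p1_filter)
        kept = db.records["motif"].map(p1_filter)
        tail = (2, 3, 4, 5)
        sub = db.records.loc[kept, "motif"]
        ref_n = sum(
            1 for m in sub
            if group_count(m, "Bulky", tail) == 0 and group_count(m, "Negative", tail) == 0
        )
        total = ref_n + sum(r.n1 for r in stats.values())
        assert total == kept.sum()
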