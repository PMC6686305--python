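import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempocc.matrix_io import (
    AbundanceMatrix,
    GuildTable,
    MatrixParseError,
    binarize,
    characteristics,
    exclude_rare,
    impute_tracing,
    read_matrix,
    split_by_guild,
    strip_degenerate,
    write_matrix,
)

from .conftest import random_abundance


class TestReadWrite:
    def test_reads_toy_file_with_tracing_cell(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text(
            "species,1990,1991,1992,1993\n"
            "tit,1.2,0,0.8,1.5\n"
            "warbler,0,2.0,2.4,0\n"
            "woodpecker,0,+,+,0\n"
        )
        m = read_matrix(f, plot_size_ha=25.0)
        assert m.species_ids == ["tit", "warbler", "woodpecker"]
        assert m.year_labels == [1990, 1991, 1992, 1993]
        assert m.tracing_flags[2, 1] and m.tracing_flags[2, 2]
        assert not m.tracing_flags[:2].any()
        assert m.values[2, 1] == 0.0  # pending imputation

    def test_tab_delimited_autodetect(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("species\t2000\t2001\na\t1\t0\nb\t0\t2\n")
        m = read_matrix(f, 10.0)
        assert m.values.tolist() == [[1.0, 0.0], [0.0, 2.0]]

    @pytest.mark.parametrize(
        "body,fragment",
        [
            ("a,1,-1\nb,0,2\n", "negative"),
            ("a,1,2\na,0,2\n", "duplicate"),
            ("a,1,x\nb,0,2\n", "not numeric"),
        ],
    )
    def test_parse_errors_name_the_offence(self, tmp_path, body, fragment):
        f = tmp_path / "bad.csv"
        f.write_text("species,2000,2001\n" + body)
        with pytest.raises(MatrixParseError, match=fragment):
            read_matrix(f, 10.0)

    def test_round_trip_is_exact(self, tmp_path, rng):
        for k in range(10):
            m = random_abundance(rng, S=5, T=6)
            path = tmp_path / f"rt{k}.csv"
            write_matrix(m, path)
            back = read_matrix(path, m.plot_size_ha, m.dataset_id)
            np.testing.assert_array_equal(back.values, m.values)
            assert back.species_ids == m.species_ids
            assert back.year_labels == m.year_labels


class TestImputeTracing:
    def test_constants_by_size_class(self, toy_matrix):
        for cls, expected in [
            ("small", 0.1),
            ("medium_raptor_corvid", 0.05),
            ("large_raptor", 0.004),
        ]:
            out = impute_tracing(toy_matrix, {"woodpecker": cls})
            assert out.values[2, 1] == expected
            assert out.values[2, 2] == expected
            assert out.values[2, 0] == 0.0 and out.values[2, 3] == 0.0

    def test_non_tracing_cells_unchanged(self, toy_matrix):
        out = impute_tracing(toy_matrix, {"woodpecker": "small"})
        np.testing.assert_array_equal(
            out.values[~toy_matrix.tracing_flags],
            toy_matrix.values[~toy_matrix.tracing_flags],
        )

    def test_no_tracing_is_identity(self, rng):
        m = random_abundance(rng)
        out = impute_tracing(m, {})
        np.testing.assert_array_equal(out.values, m.values)

    def test_missing_size_class_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="woodpecker"):
            impute_tracing(toy_matrix, {})


class TestBinarize:
    def test_threshold_and_idempotence(self):
        m = AbundanceMatrix(["a", "b"], [1, 2], [[0.1, 0.0], [2.3, 0.004]])
        b = binarize(m)
        assert b.values.tolist() == [[1, 0], [1, 1]]
        assert binarize(b).values.tolist() == b.values.tolist()

    def test_zero_row_is_retained(self):
        m = AbundanceMatrix(["a", "b"], [1, 2], [[0.0, 0.0], [1.0, 1.0]])
        assert binarize(m).values[0].tolist() == [0, 0]


class TestCharacteristics:
    def test_direct_arithmetic(self):
        m = AbundanceMatrix(["a", "b"], [1, 2], [[1, 0], [0, 1]], plot_size_ha=10)
        c = characteristics(m)
        assert c.prop_zeros == 0.5
        assert c.matrix_size == 4
        assert (c.n_species, c.n_years) == (2, 2)
        assert c.mean_density == 0.5
        m2 = AbundanceMatrix(["a", "b"], [1, 2], [[2, 2], [2, 2]])
        c2 = characteristics(m2)
        assert c2.prop_zeros == 0.0 and c2.cv_density == 0.0

    def test_matches_independent_recomputation(self, rng):
        for _ in range(100):
            m = random_abundance(rng, S=6, T=8)
            c = characteristics(m)
            v = m.values
            assert c.prop_zeros == pytest.approx(np.mean(v == 0))
            assert c.mean_density == pytest.approx(v.mean())
            assert c.cv_density == pytest.approx(v.std() / v.mean())

    def test_all_zero_matrix_errors(self):
        m = AbundanceMatrix(["a", "b"], [1, 2], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="CV"):
            characteristics(m)


class TestSplitByGuild:
    def test_partition_with_singleton(self, rng):
        m = random_abundance(rng, S=5, T=6)
        guilds = GuildTable(
            guild={
                "sp0": "foliage_forager",
                "sp1": "foliage_forager",
                "sp2": "ground_forager",
                "sp3": "ground_forager",
                "sp4": "raptor",
            }
        )
        parts = split_by_guild(m, guilds)
        assert sorted(parts) == ["foliage_forager", "ground_forager", "raptor"]
        assert parts["foliage_forager"].n_species == 2
        assert parts["raptor"].n_species == 1  # not analyzable

    def test_single_guild_is_identity(self, rng):
        m = random_abundance(rng, S=4)
        guilds = GuildTable(guild={s: "omnivore" for s in m.species_ids})
        (only,) = split_by_guild(m, guilds).values()
        np.testing.assert_array_equal(only.values, m.values)

    def test_unmapped_species_listed(self, rng):
        m = random_abundance(rng, S=4)
        guilds = GuildTable(guild={"sp0": "omnivore", "sp1": "omnivore"})
        with pytest.raises(ValueError, match="sp2"):
            split_by_guild(m, guilds)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(assignment=st.lists(st.sampled_from(["omnivore", "raptor", "water_forager"]),
                               min_size=5, max_size=5))
    def test_rows_partition_exactly(self, assignment):
        m = random_abundance(np.random.default_rng(0), S=5, T=6)
        guilds = GuildTable(guild=dict(zip(m.species_ids, assignment)))
        parts = split_by_guild(m, guilds)
        collected = sorted(s for p in parts.values() for s in p.species_ids)
        assert collected == sorted(m.species_ids)


class TestExcludeRare:
    def test_drops_tracing_rows(self, toy_matrix):
        out = exclude_rare(toy_matrix)
        assert out.species_ids == ["tit", "warbler"]

    def test_identity_without_tracing(self, rng):
        m = random_abundance(rng)
        np.testing.assert_array_equal(exclude_rare(m).values, m.values)

    def test_errors_when_too_few_remain(self):
        flags = np.array([[True, False], [False, False], [False, True]])
        m = AbundanceMatrix(
            ["a", "b", "c"], [1, 2], [[0.1, 0], [1, 1], [0, 0.1]], tracing_flags=flags
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            exclude_rare(m)

    def test_fill_increases_after_exclusion(self, rng):
        from tempocc.synthetic import calibrated_config, generate_matrix

        for seed in range(5):
            g = np.random.default_rng(seed)
            m, _ = generate_matrix(calibrated_config(n_tracing=4), g)
            before = characteristics(m).prop_zeros
            after = characteristics(exclude_rare(m)).prop_zeros
            assert after <= before


def test_strip_degenerate_removes_zero_marginals():
    m = AbundanceMatrix(
        ["a", "b", "c"], [1, 2, 3], [[1, 0, 2], [0, 0, 0], [3, 0, 1]]
    )
    with pytest.warns(UserWarning, match="stripping"):
        out = strip_degenerate(m)
    assert out.species_ids == ["a", "c"]
    assert out.year_labels == [1, 3]
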