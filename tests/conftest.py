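import numpy as np
import pytest

from tempocc.matrix_io import AbundanceMatrix, GuildTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """3 species x 4 years with one tracing species."""
    values = np.array(
        [
            [1.2, 0.0, 0.8, 1.5],
            [0.0, 2.0, 2.4, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    flags = np.zeros_like(values, dtype=bool)
    flags[2, [1, 2]] = True
    return AbundanceMatrix(
        species_ids=["tit", "warbler", "woodpecker"],
        year_labels=[1990, 1991, 1992, 1993],
        values=values,
        tracing_flags=flags,
        plot_size_ha=25.0,
        dataset_id="toy",
    )


@pytest.fixture
def toy_guilds():
    return GuildTable(
        guild={
            "tit": "foliage_forager",
            "warbler": "foliage_forager",
            "woodpecker": "trunk_forager",
        },
        size_class={"woodpecker": "small"},
    )


def random_abundance(rng, S=6, T=8, zero_frac=0.35):
    vals = rng.gamma(1.2, 1.0, size=(S, T))
    vals[rng.random((S, T)) < zero_frac] = 0.0
    # keep every row and column occupied so null models stay non-degenerate
    for i in range(S):
        if vals[i].sum() == 0:
            vals[i, rng.integers(T)] = rng.gamma(1.2, 1.0)
    for j in range(T):
        if vals[:, j].sum() == 0:
            vals[rng.integers(S), j] = rng.gamma(1.2, 1.0)
    return AbundanceMatrix(
        species_ids=[f"sp{i}" for i in range(S)],
        year_labels=list(range(2000, 2000 + T)),
        values=vals,
        dataset_id="random",
    )
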