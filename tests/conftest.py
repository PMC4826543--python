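import numpy as np
import pytest

import epidesign as ed
from epidesign.core import Label


@pytest.fixture(scope="session")
def small_pool():
    """A small planted-motif pool: 120 positives / 240 negatives."""
    cfg = ed.SyntheticConfig(n_pos=120, n_neg=240, seed=7)
    return ed.generate_pool(cfg)


@pytest.fixture(scope="session")
def small_split(small_pool):
    pos, neg = ed.build_pools(small_pool)
    return ed.make_train_test_split(pos, neg, 60, 120, seed=1)


@pytest.fixture(scope="session")
def mini_model(small_split):
    """A small but informative trained ensemble (3 members, tiny grids)."""
    specs = [
        s
        for s in ed.default_ensemble_specs(
            c_grid=(1.0, 8.0), gamma_grid=(2.0**-11, 2.0**-7), cv_folds=3
        )
        if s.name in ("k_spectrum", "bounded_range", "local_composition")
    ]
    return ed.fit_ensemble(specs, small_split.train, seed=3)


def labels_of(records):
    return [1 if r.label is Label.POSITIVE else 0 for r in records]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptides(rng, n, length, alphabet=ed.DEFAULT_ALPHABET, prefix="p"):
    symbols = np.array(list(alphabet.symbols))
    return [
        ed.Peptide(id=f"{prefix}{i}", sequence="".join(rng.choice(symbols, size=length)))
        for i in range(n)
    ]
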