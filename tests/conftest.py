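import numpy as np
import pytest

from dcnet.preprocess import ExpressionMatrix
from dcnet.synthdata import ModulePlant, gen_module_expression


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng):
    """12 genes x 20 samples: two correlated triples plus noise genes."""
    base1 = rng.standard_normal(20)
    base2 = rng.standard_normal(20)
    rows = [base1 + 0.3 * rng.standard_normal(20) for _ in range(3)]
    rows += [base2 + 0.3 * rng.standard_normal(20) for _ in range(3)]
    rows += [rng.standard_normal(20) for _ in range(6)]
    return ExpressionMatrix([f"g{i}" for i in range(12)],
                            [f"s{j}" for j in range(20)], np.array(rows))


@pytest.fixture(scope="session")
def planted():
    """A planted-module expression matrix with its true labels."""
    plant = ModulePlant(module_sizes=(40, 30), n_background=20,
                        n_samples=60, within_corr=0.8, seed=3)
    expr, labels = gen_module_expression(plant)
    return plant, expr, labels
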