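import numpy as np
import pytest

import nanoform as nf


@pytest.fixture(scope="session")
def factors():
    return nf.pln_factors()


@pytest.fixture(scope="session")
def design():
    return nf.pln_design()


@pytest.fixture(scope="session")
def size_model(design):
    return nf.fit_quadratic(design, "particle_size")


@pytest.fixture(scope="session")
def ee_model(design):
    return nf.fit_quadratic(design, "ee")


@pytest.fixture(scope="session")
def goals():
    return nf.pln_goals()


def normal_equations_fit(coded, y):
    """Independent OLS oracle: explicit 10x10 normal-equations solve."""
    coded = np.asarray(coded, float)
    x1, x2, x3 = coded[:, 0], coded[:, 1], coded[:, 2]
    X = np.column_stack(
        [np.ones(len(coded)), x1, x2, x3, x1 * x2, x1 * x3, x2 * x3,
         x1**2, x2**2, x3**2]
    )
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
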