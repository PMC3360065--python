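import numpy as np
import pytest

from sirnarank.features import build_default_schema
from sirnarank.multitask import StackedDesign


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def small_gaussian_design():
    """Small dense multi-task problem with a planted 5-row support.

    Gaussian features keep the solver tests independent of the sequence
    encoder; column 0 is the constant/intercept column.
    """
    rng = np.random.default_rng(42)
    d, tasks, s = 30, 3, 5
    support = np.array([3, 7, 11, 19, 25])
    beta = rng.uniform(0.5, 1.0, size=(s, tasks)) * np.sign(rng.standard_normal((s, 1)))
    X, y = [], []
    for j, n in enumerate((120, 90, 60)):
        Xj = rng.standard_normal((n, d))
        Xj[:, 0] = 1.0
        yj = 0.4 + Xj[:, support] @ beta[:, j] + rng.normal(0, 0.05, n)
        X.append(Xj)
        y.append(yj)
    design = StackedDesign(X, y)
    return design, support, beta


@pytest.fixture()
def write_tsv(tmp_path):
    def _write(rows, header=("sequence", "efficacy"), name="data.tsv"):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
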