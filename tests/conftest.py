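import numpy as np
import pytest

from jsofs import DatasetTable, SynthConfig, generate

#: 8-feature subset of the schema used by the small-p selection studies
P8_FEATURES = ("age", "sex", "cp", "trestbps", "chol", "thalach", "exang", "oldpeak")
INFORMATIVE = ("cp", "thalach", "oldpeak")


def make_p8_table(seed: int, n_per_class: int = 150, effect_size: float = 2.0,
                  categorical_shift: float | None = None) -> DatasetTable:
    kw = {}
    if categorical_shift is not None:
        kw["categorical_shift"] = categorical_shift
    return generate(SynthConfig(
        n_disease=n_per_class, n_healthy=n_per_class,
        features=P8_FEATURES, informative=INFORMATIVE,
        effect_size=effect_size, seed=seed, **kw,
    ))


@pytest.fixture(scope="session")
def table_p8() -> DatasetTable:
    """n=300, p=8 synthetic table with 3 informative features (d=2)."""
    return make_p8_table(seed=11)


@pytest.fixture(scope="session")
def cleveland_1025() -> DatasetTable:
    """Full-schema synthetic cohort mirroring the 526/499 composition."""
    return generate(SynthConfig(seed=7))


@pytest.fixture
def leaky_table(table_p8) -> DatasetTable:
    """Copy of the p=8 table where the 'sex' column equals the label."""
    t = table_p8.copy()
    t.features[:, t.names.index("sex")] = t.labels
    return t


class OracleStub:
    """Protocol-test classifier that reads the true class out of column 0."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.asarray(X)[:, 0].astype(int)


@pytest.fixture
def oracle_stub() -> OracleStub:
    return OracleStub()


@pytest.fixture
def uci_303_table() -> DatasetTable:
    """303-row table with 4 missing ca cells and 2 missing thal cells
    (disjoint rows), mirroring the original cohort's null pattern."""
    t = generate(SynthConfig(n_disease=139, n_healthy=164, seed=5))
    ca, thal = t.names.index("ca"), t.names.index("thal")
    t.features[[3, 57, 111, 200], ca] = np.nan
    t.features[[10, 250], thal] = np.nan
    return t
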