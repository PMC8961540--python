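import numpy as np
import pandas as pd
import pytest

from glycorisk import default_cohort_spec, generate_cohort, to_frame


@pytest.fixture(scope="session")
def male_cohort_500() -> pd.DataFrame:
    """Default male spec, 500 subjects per stratum, seed=1 (shared, read-only)."""
    spec = default_cohort_spec("M", n_per_stratum=500, seed=1)
    return to_frame(generate_cohort(spec))


@pytest.fixture(scope="session")
def small_male_cohort() -> pd.DataFrame:
    spec = default_cohort_spec("M", n_per_stratum=120, seed=2)
    return to_frame(generate_cohort(spec))


def random_closed_composition(rng: np.random.Generator, n_parts: int = 46,
                              n_rows: int | None = None) -> np.ndarray:
    """Strictly positive composition(s) closed to 100."""
    shape = (n_rows, n_parts) if n_rows else (n_parts,)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=shape)
    return 100.0 * raw / raw.sum(axis=-1, keepdims=True)


def make_logratio_cohort(
    n: int = 400,
    n_peaks: int = 12,
    num_peak: int = 0,
    den_peak: int = 1,
    beta: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic compositional cohort whose outcome depends only on
    ln(GP_a / GP_b); the independent ground truth for selection tests."""
    rng = np.random.default_rng(seed)
    comp = random_closed_composition(rng, n_peaks, n)
    signal = np.log(comp[:, num_peak]) - np.log(comp[:, den_peak])
    signal = (signal - signal.mean()) / signal.std()
    prob = 1.0 / (1.0 + np.exp(-(beta * signal)))
    y = (rng.random(n) < prob).astype(int)
    labels = [f"GP{i + 1:02d}" for i in range(n_peaks)]
    df = pd.DataFrame(comp, columns=labels)
    df["risk"] = np.where(y == 1, "risk", "non-risk")
    df["age"] = rng.normal(50, 10, n)
    df["smoker"] = (rng.random(n) < 0.25).astype(int)
    return df
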