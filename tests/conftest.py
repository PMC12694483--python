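import pandas as pd
import pytest

from nbudget import load_reference_components

# Published two-year trial report values (balance kg/ha, ANLR %) keyed by
# (pattern, n_rate, year); None marks the undefined zero-rate loss rate.
PRINTED_BUDGET = {
    ("FP", 0, 2023): (-88.69, None), ("FP", 0, 2024): (-111.01, None),
    ("FP", 80, 2023): (-11.53, -14.41), ("FP", 80, 2024): (-37.59, -46.99),
    ("FP", 160, 2023): (53.42, 33.39), ("FP", 160, 2024): (40.02, 25.01),
    ("FP", 240, 2023): (142.25, 59.279), ("FP", 240, 2024): (118.24, 49.27),
    ("JM", 0, 2023): (-81.96, None), ("JM", 0, 2024): (-104.14, None),
    ("JM", 80, 2023): (-12.03, -15.04), ("JM", 80, 2024): (-35.37, -44.21),
    ("JM", 160, 2023): (40.53, 25.33), ("JM", 160, 2024): (23.89, 14.93),
    ("JM", 240, 2023): (150.09, 62.54), ("JM", 240, 2024): (125.89, 52.45),
    ("PM", 0, 2023): (-93.62, None), ("PM", 0, 2024): (-115.16, None),
    ("PM", 80, 2023): (-33.80, -42.25), ("PM", 80, 2024): (-55.51, -69.39),
    ("PM", 160, 2023): (9.73, 6.08), ("PM", 160, 2024): (1.84, 1.15),
    ("PM", 240, 2023): (124.94, 52.06), ("PM", 240, 2024): (99.83, 41.59),
}


@pytest.fixture(scope="session")
def reference_components() -> pd.DataFrame:
    return load_reference_components()
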