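import numpy as np
import pytest

from coldfold import StabilityParams

# printed thermodynamic table for wild-type yeast frataxin and the three
# single E->S mutants: (dH kcal/mol, dCp kcal/K/mol, Tm degC) with the
# printed derived values (dS kcal/K/mol, Tc degC, folding %)
TABLE1 = {
    "Wt":   {"dH": 19.2, "dCp": 2.24, "Tm_C": 33.6, "dS": 0.063, "Tc_C": 16.8, "folding_pct": 61},
    "E89":  {"dH": 29.5, "dCp": 1.73, "Tm_C": 37.2, "dS": 0.095, "Tc_C": 4.1,  "folding_pct": 80},
    "E112": {"dH": 30.0, "dCp": 1.73, "Tm_C": 37.3, "dS": 0.097, "Tc_C": 3.7,  "folding_pct": 80},
    "E103": {"dH": 31.3, "dCp": 1.69, "Tm_C": 38.9, "dS": 0.10,  "Tc_C": 3.1,  "folding_pct": 83},
}


@pytest.fixture(scope="session")
def table1():
    return TABLE1


@pytest.fixture(scope="session")
def wt_params():
    row = TABLE1["Wt"]
    return StabilityParams.from_celsius(row["dH"], row["dCp"], row["Tm_C"])


def random_valid_params(rng: np.random.Generator) -> StabilityParams:
    """A physically plausible parameter triple for property tests."""
    return StabilityParams(
        dH=float(rng.uniform(5.0, 100.0)),
        dCp=float(rng.uniform(0.5, 8.0)),
        Tm=float(rng.uniform(295.0, 360.0)),
    )
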