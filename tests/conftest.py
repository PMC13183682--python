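import numpy as np
import pandas as pd
import pytest

from exondef import (KineticParameters, SyntheticConfig,
                     default_truth_parameters)


@pytest.fixture(scope="session")
def truth_params() -> KineticParameters:
    return default_truth_parameters()


@pytest.fixture(scope="session")
def one_step_params() -> KineticParameters:
    return KineticParameters(k1=0.05, k3=0.04, k2=0.02, kspli=0.2, kret=0.003,
                             kincl=0.0015, kskip=0.002, kdr1=0.001, kdr2=0.0012)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_mutants=40)


def random_parameters(rng: np.random.Generator, variant: str) -> KineticParameters:
    """Strictly positive random rate set, log-uniform over [1e-3, 1]."""
    v = 10.0 ** rng.uniform(-3, 0, size=12)
    kw = dict(k1=v[0], k3=v[1], kspli=v[2], kret=v[3], kincl=v[4],
              kskip=v[5], kdr1=v[6], kdr2=v[7])
    if variant == "one_step":
        kw["k2"] = v[8]
    else:
        kw["k2a"], kw["k2b"] = v[8], v[9]
    return KineticParameters(**kw)


def six_lsv_table() -> pd.DataFrame:
    """Hand-constructed six-LSV toy table: one violation per filter rule.

    lsv A, B: compliant (3 events, one IR, non-IR span difference > 300 nt,
    lowest-two event frequencies >= 1%, >= 10 total reads).  lsv C: only two
    events.  lsv D: three events but no IR.  lsv E: non-IR span difference
    200 nt (alternative splice-site mimic).  lsv F: lowest two events sum to
    0.5%.  Total read counts: A = 60, B = 45, so coverage cutoffs 50+ drop B
    and 80+ drop both.
    """
    rows = [
        # lsv_id, start, end, is_ir, frequency, median_count
        ("A", 1000, 1400, False, 0.50, 30),
        ("A", 1000, 2400, False, 0.30, 20),
        ("A", 1000, 1001, True, 0.20, 10),
        ("B", 5000, 5500, False, 0.45, 20),
        ("B", 5000, 5900, False, 0.35, 15),
        ("B", 5000, 5001, True, 0.20, 10),
        ("C", 9000, 9400, False, 0.70, 40),
        ("C", 9000, 9001, True, 0.30, 20),
        ("D", 12000, 12400, False, 0.45, 30),
        ("D", 12000, 13000, False, 0.35, 20),
        ("D", 12000, 12800, False, 0.20, 10),
        ("E", 15000, 15400, False, 0.55, 30),
        ("E", 15000, 15600, False, 0.25, 20),
        ("E", 15000, 15001, True, 0.20, 10),
        ("F", 18000, 18400, False, 0.995, 200),
        ("F", 18000, 19400, False, 0.004, 1),
        ("F", 18000, 18001, True, 0.001, 1),
    ]
    return pd.DataFrame(rows, columns=["lsv_id", "junction_start",
                                       "junction_end", "is_ir", "frequency",
                                       "median_count"])


@pytest.fixture()
def lsv_fixture() -> pd.DataFrame:
    return six_lsv_table()
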