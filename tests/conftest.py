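"""Shared fixtures: seed-fixed synthetic runs reused across test modules."""

from pathlib import Path

import pytest

import matreg
from matreg import SimulationDesign, simulate_expression

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_run():
    """Default 1000-gene design, simulated and analysed end to end."""
    design = SimulationDesign(n_genes=1000, seed=1)
    probes, truth = simulate_expression(design)
    result = matreg.run_de(probes)
    assignments = matreg.classify_table(result["comparison_table"])
    return {
        "design": design,
        "probes": probes,
        "truth": truth,
        **result,
        "assignments": assignments,
    }


@pytest.fixture(scope="session")
def null_run():
    """1500 genes with no planted effects: the calibration reference."""
    design = SimulationDesign(
        n_genes=1500, seed=3, class_proportions={"none": 1.0}, nonexpressed_fraction=0.0
    )
    probes, truth = simulate_expression(design)
    result = matreg.run_de(probes)
    return {"design": design, "truth": truth, **result}


@pytest.fixture(scope="session")
def table1():
    from matreg.io import _numeric, _read_tsv

    df = _read_tsv(DATA / "table1.tsv", decimal_comma=True)
    df["fc"] = _numeric(df, "fc", decimal_comma=True)
    return df


@pytest.fixture(scope="session")
def table2():
    from matreg.io import _numeric, _read_tsv

    df = _read_tsv(DATA / "table2.tsv", decimal_comma=True)
    for col in ("fc_fpr1_side", "fc_fmr1_side"):
        df[col] = _numeric(df, col, decimal_comma=True)
    return df
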