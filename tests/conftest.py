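import numpy as np
import pandas as pd
import pytest

from nmrcube import (
    AxisSpec,
    PeakRow,
    PeaklistTable,
    Series,
    TitrationSimSpec,
    simulate_titration,
)

NOISELESS = TitrationSimSpec(
    noise_sd_shift_h=0.0, noise_sd_shift_x=0.0, noise_sd_height=0.0,
)


@pytest.fixture(scope="session")
def noiseless_titration():
    """7-point, 100-residue fast-exchange titration without noise."""
    return simulate_titration(NOISELESS)


@pytest.fixture(scope="session")
def noisy_titration():
    """Same titration at the default noise levels."""
    return simulate_titration(TitrationSimSpec())


@pytest.fixture()
def titration_series(noisy_titration):
    """The titration wrapped as an x-axis Series (reference first)."""
    tables, _ = noisy_titration
    labels = tuple(tables)
    return Series(
        along="x",
        fixed={"y": "wt", "z": "apo"},
        labels=labels,
        tables=[tables[lbl] for lbl in labels],
        numeric_values=tuple(float(lbl) for lbl in labels),
    )


@pytest.fixture()
def tiny_table():
    """Three-residue table with one sidechain pair entry."""
    return PeaklistTable([
        PeakRow(14, "F", "N", "H", 121.3, 8.11, height=1.1e7, volume=2.2e7),
        PeakRow(18, "Q", "N", "H", 119.9, 8.43, height=1.3e7, volume=2.6e7),
        PeakRow(18, "Q", "ND2a", "HD2a", 112.5, 7.52, height=6.0e6,
                volume=1.2e7),
        PeakRow(22, "F", "N", "H", 117.2, 9.01, height=0.9e7, volume=1.8e7),
    ])


def make_axes(nx, ny, nz):
    return {
        "x": AxisSpec("x", tuple(str(i) for i in range(nx))),
        "y": AxisSpec("y", tuple(f"y{i}" for i in range(ny))),
        "z": AxisSpec("z", tuple(f"z{i}" for i in range(nz))),
    }


def one_row_table():
    return PeaklistTable([PeakRow(1, "A", "N", "H", 120.0, 8.0)])
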