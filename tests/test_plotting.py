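"""Figure templates: sidecar fidelity and file production.

Pixel content is never asserted; the test surface is the sidecar CSV (which
must contain exactly the plotted values) and figure-file existence.
"""

import numpy as np
import pandas as pd
import pytest

from nmrcube import (
    PeakRow,
    PeaklistTable,
    PlotConfig,
    PlotError,
    Series,
    compute_observables,
    pad_tables,
    render,
    render_all,
    simulate_pre_pair,
    stack,
)
from nmrcube.observables import ObservableConfig, dpre, gaussian_smooth
from nmrcube.plotting import TEMPLATES


@pytest.fixture(scope="module")
def titration_results(request):
    from nmrcube import TitrationSimSpec, simulate_titration
    tables, truth = simulate_titration(TitrationSimSpec())
    labels = tuple(tables)
    seq = dict(zip(truth["residue_number"], truth["residue_type"]))
    from nmrcube import scan_series
    series = Series(along="x", fixed={"y": "wt", "z": "apo"},
                    labels=labels, tables=[tables[k] for k in labels])
    padded = pad_tables(series, scan_series(series, seq))
    return compute_observables(padded), labels, truth


@pytest.fixture(scope="module")
def dpre_result():
    from nmrcube import PreSimSpec
    dia, para, predicted, _ = simulate_pre_pair(
        PreSimSpec(deviation_regions=((60, 70, 0.4),)))
    series = Series(along="z", fixed={"y": "wt", "x": "0"},
                    labels=("dia", "para"), tables=[dia, para])
    padded = pad_tables(series)
    results = compute_observables(padded, predicted_pre=predicted)
    return results[-1], predicted


class TestBarTemplates:
    @pytest.mark.parametrize("template",
                             ["bar_extended", "bar_compacted",
                              "bar_vertical"])
    def test_bar_count_equals_universe_and_sidecar_matches(
            self, template, titration_results, tmp_path):
        results, labels, truth = titration_results
        last = results[-1]
        fig, sidecar = render(
            template, last,
            PlotConfig(template=template, threshold=0.05),
            tmp_path / template)
        assert fig.exists() and fig.stat().st_size > 0
        side = pd.read_csv(sidecar)
        assert len(side) == len(last)            # one bar per residue
        want = last.frame["csp"].to_numpy()
        assert np.allclose(side["csp"].to_numpy(), want, equal_nan=True)
        # red bars exactly at missing residues
        missing_in_side = set(
            side.loc[side["status"] == "missing", "residue_number"])
        missing_in_data = set(
            last.frame.loc[last.frame["status"] == "missing",
                           "residue_number"])
        assert missing_in_side == missing_in_data


class TestScatterTemplates:
    def test_shift_map_sidecar(self, titration_results, tmp_path):
        results, labels, _ = titration_results
        fig, sidecar = render("scatter_shift_map", results[-1],
                              out_path=tmp_path / "map")
        side = pd.read_csv(sidecar)
        assert {"delta_h", "delta_x"} <= set(side.columns)
        assert len(side) == len(results[-1])

    def test_trajectory_covers_all_points(self, titration_results,
                                          tmp_path):
        results, labels, _ = titration_results
        fig, sidecar = render("scatter_trajectory", results,
                              labels=labels, out_path=tmp_path / "traj")
        side = pd.read_csv(sidecar)
        assert set(side["point"].astype(str)) == set(labels)


class TestHeatMap:
    def test_sidecar_equals_matrix_cell_for_cell(self, dpre_result,
                                                 tmp_path):
        para, _ = dpre_result
        sources = {"wt": para, "mut": para}
        table = stack(sources, "smoothed_dpre", "z", "y")
        fig, sidecar = render("heat_map", table,
                              out_path=tmp_path / "heat")
        side = pd.read_csv(sidecar).set_index("residue_number")
        assert np.allclose(side.to_numpy(), table.matrix.to_numpy(),
                           equal_nan=True)


class TestDpreProfile:
    def test_overlay_sidecar_columns(self, dpre_result, tmp_path):
        para, predicted = dpre_result
        fig, sidecar = render("dpre_profile", para, predicted=predicted,
                              out_path=tmp_path / "dpre")
        side = pd.read_csv(sidecar)
        assert {"observed_ratio", "predicted_ratio", "dpre",
                "smoothed_dpre"} <= set(side.columns)
        got = side.set_index("residue_number")["dpre"]
        want = para.frame.set_index("residue_number")["dpre"]
        assert np.allclose(got, want, equal_nan=True)


class TestResidueEvolution:
    def test_one_column_per_series_point(self, titration_results, tmp_path):
        results, labels, _ = titration_results
        xs = [float(lbl) for lbl in labels]
        fig, sidecar = render("residue_evolution", results, x_values=xs,
                              out_path=tmp_path / "evo",
                              config=PlotConfig(template="residue_evolution",
                                                max_subplots=20))
        side = pd.read_csv(sidecar)
        assert len(side.columns) == len(labels) + 1   # + residue_number


class TestRenderContracts:
    def test_empty_data_refused(self, tmp_path):
        with pytest.raises(PlotError, match="nothing to plot"):
            render("bar_extended", PeaklistTable([]),
                   out_path=tmp_path / "x")

    def test_missing_column_named(self, tmp_path):
        table = PeaklistTable([PeakRow(1, "A", "N", "H", 120.0, 8.0)])
        with pytest.raises(PlotError, match="csp"):
            render("bar_extended", table, out_path=tmp_path / "x")

    def test_unknown_template_rejected(self):
        with pytest.raises(PlotError, match="unknown template"):
            PlotConfig(template="pie_chart")

    def test_render_all_counts_and_continues_on_failure(
            self, titration_results, tmp_path, caplog):
        results, labels, _ = titration_results
        requests = [
            dict(template="bar_extended", data=results[-1],
                 out_path=tmp_path / "ok"),
            dict(template="bar_extended", data=PeaklistTable([]),
                 out_path=tmp_path / "bad"),
        ]
        with caplog.at_level("ERROR"):
            produced = render_all(requests)
        assert len(produced) == 1
        assert any("failed" in r.message for r in caplog.records)

    def test_no_templates_selected_yields_zero_figures(self, caplog):
        with caplog.at_level("INFO"):
            assert render_all([]) == []
        assert any("zero figures" in r.message for r in caplog.records)

    def test_sidecars_bit_identical_across_runs(self, titration_results,
                                                tmp_path):
        results, labels, _ = titration_results
        _, s1 = render("bar_extended", results[-1], out_path=tmp_path / "a")
        _, s2 = render("bar_extended", results[-1], out_path=tmp_path / "b")
        assert s1.read_bytes() == s2.read_bytes()
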