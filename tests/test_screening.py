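import numpy as np
import pytest

from spectraqc import (
    ScanAverages,
    ScreeningConfig,
    average_scans,
    builtin_registry,
    detailed_index_report,
    fit_model,
    flag_by_range,
    remove_plots,
    scatter_table,
    screen_sris,
    screen_wavelengths,
)
from spectraqc.errors import LookupError

from conftest import make_dataset, make_responses


def _averages(matrix, wavelengths=None):
    matrix = np.asarray(matrix, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(matrix.shape[1], dtype=float) + 400.0
    n = matrix.shape[0]
    return ScanAverages(
        wavelengths=np.asarray(wavelengths, dtype=float),
        plot_ids=list(range(1, n + 1)),
        codes=[f"G{i}" for i in range(1, n + 1)],
        values=matrix,
    )


class TestScreenWavelengths:
    def test_impossible_cutoff_gives_empty_report(self):
        rng = np.random.default_rng(0)
        avg = _averages(rng.uniform(0.1, 0.9, size=(12, 4)))
        responses = make_responses(rng.normal(size=12))
        report = screen_wavelengths(
            avg, responses, ScreeningConfig(("poly1",), "R2", 1.1, "above")
        )
        assert report.table.empty

    def test_generating_band_passes_r2_cutoff(self):
        rng = np.random.default_rng(1)
        avg = _averages(rng.uniform(0.1, 0.9, size=(30, 5)))
        y = 2.0 * avg.values[:, 2] + rng.normal(0, 0.02, size=30)
        report = screen_wavelengths(
            avg, make_responses(y), ScreeningConfig(("poly1",), "R2", 0.3, "above")
        )
        assert 402.0 in set(report.table.wavelength_nm)
        best = report.table.sort_values("R2").iloc[-1]
        assert best.wavelength_nm == 402.0

    def test_constant_response_is_skipped_not_reported(self):
        rng = np.random.default_rng(2)
        avg = _averages(rng.uniform(0.1, 0.9, size=(10, 3)))
        report = screen_wavelengths(
            avg,
            make_responses(np.full(10, 5.0)),
            ScreeningConfig(("poly1",), "R2", 0.0, "above"),
        )
        assert report.table.empty
        assert (report.skipped.reason == "degenerate-response").all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        avg = _averages(rng.uniform(0.1, 0.9, size=(15, 4)))
        y = avg.values[:, 1] * 3 + rng.normal(0, 0.1, size=15)
        config = ScreeningConfig(("poly1", "poly2"), "R2", 0.2, "above")
        report = screen_wavelengths(avg, make_responses(y), config)
        expected = set()
        for j, wl in enumerate(avg.wavelengths):
            for model in config.models:
                fit = fit_model(avg.values[:, j], y, model)
                if fit.r2 > 0.2:
                    expected.add((float(wl), model))
        got = set(zip(report.table.wavelength_nm, report.table.model))
        assert got == expected


class TestScreenSRIs:
    def _trial(self, n=60, noise=0.02, seed=4):
        rng = np.random.default_rng(seed)
        wl = np.asarray([445.0, 531.0, 550.0, 670.0, 800.0, 900.0, 970.0])
        r670 = rng.uniform(0.05, 0.15, size=n)
        r800 = rng.uniform(0.3, 0.6, size=n)
        matrix = np.column_stack(
            [
                rng.uniform(0.02, 0.06, size=n),  # 445
                rng.uniform(0.05, 0.1, size=n),  # 531
                rng.uniform(0.08, 0.14, size=n),  # 550
                r670,
                r800,
                rng.uniform(0.3, 0.6, size=n),  # 900
                rng.uniform(0.25, 0.5, size=n),  # 970
            ]
        )
        ndvi = (r800 - r670) / (r800 + r670)
        y = 3.0 + 6.0 * ndvi + rng.normal(0, noise, size=n)
        return _averages(matrix, wl), make_responses(y), ndvi

    def test_cutoff_above_one_empty(self):
        avg, responses, _ = self._trial()
        report = screen_sris(avg, responses, ("poly1",), 1.0001)
        assert report.table.empty

    def test_ndvi_driven_trait_found_with_poly1_best(self):
        avg, responses, _ = self._trial(n=100, noise=0.01)
        report = screen_sris(avg, responses, ("poly1", "poly2"), 0.9)
        ndvi_rows = report.table[report.table.sri == "NDVI"]
        assert len(ndvi_rows) == 1
        row = ndvi_rows.iloc[0]
        assert row.best_adjR2 >= 0.9
        # poly2 nests poly1 so either can win on adjR2; both blocks reported
        assert row.poly1_adjR2 >= 0.9

    def test_best_block_dominates_model_blocks(self):
        avg, responses, _ = self._trial()
        report = screen_sris(avg, responses, ("poly1", "poly2", "exponential"), -10.0)
        for _, row in report.table.iterrows():
            for model in ("poly1", "poly2", "exponential"):
                adj = row[f"{model}_adjR2"]
                if not np.isnan(adj):
                    assert adj <= row.best_adjR2 + 1e-12

    def test_unbounded_cutoff_is_full_cross_product(self):
        from spectraqc import BandMatchPolicy, match_band

        avg, responses, _ = self._trial()
        report = screen_sris(avg, responses, ("poly1",), -np.inf)
        policy = BandMatchPolicy()
        computable = {
            d.name
            for d in builtin_registry()
            if all(
                match_band(avg.wavelengths, b, policy) is not None
                for b in d.bands
            )
        }
        # every index whose bands all exist on the 7-band grid appears
        assert set(report.table.sri) == computable
        assert "NDVI" in computable and "SR" in computable and "WI" in computable
        assert "PRI" not in computable  # its 570 nm band is off this grid

    def test_all_missing_index_in_skip_log(self):
        avg, responses, _ = self._trial()
        avg.values[:, 4] = np.nan  # kill the 800 nm band -> NDVI missing
        report = screen_sris(avg, responses, ("poly1",), -np.inf)
        assert "NDVI" not in set(report.table.sri)
        skipped = report.skipped
        assert (
            (skipped.predictor == "NDVI") & (skipped.reason == "all-missing-index")
        ).any()


class TestOutlierLoop:
    def _setup(self):
        rng = np.random.default_rng(5)
        wl = np.asarray([670.0, 800.0])
        r670 = rng.uniform(0.05, 0.1, size=10)
        r800 = rng.uniform(0.4, 0.6, size=10)
        r800[3:6] *= 0.3  # depressed NIR block -> low NDVI
        matrix = np.column_stack([r670, r800])
        values = np.repeat(matrix, 2, axis=0)
        ds = make_dataset(values, wavelengths=wl, k=2)
        responses = make_responses(rng.uniform(2, 8, size=10))
        return ds, responses

    def test_scatter_table_covers_every_scan(self):
        ds, responses = self._setup()
        table = scatter_table(average_scans(ds), responses, "NDVI", "Yield")
        assert len(table) == ds.n_scans

    def test_flag_by_range_recovers_depressed_block(self):
        ds, responses = self._setup()
        table = scatter_table(average_scans(ds), responses, "NDVI", "Yield")
        inside = table.index_value[3:6].max()
        outside = table.index_value.drop(index=[3, 4, 5]).min()
        separator = (inside + outside) / 2
        assert flag_by_range(table, "index", "lt", separator) == [4, 5, 6]

    def test_flag_predicates(self):
        ds, responses = self._setup()
        table = scatter_table(average_scans(ds), responses, "NDVI", "Yield")
        assert flag_by_range(table, "index", "gt", 1e9) == []
        assert flag_by_range(table, "index", "between", -1e9, 1e9) == list(
            range(1, 11)
        )

    def test_missing_never_matches(self):
        ds, responses = self._setup()
        ds = remove_plots(ds, [1])
        table = scatter_table(average_scans(ds), responses, "NDVI", "Yield")
        assert 1 not in flag_by_range(table, "index", "between", -1e9, 1e9)

    def test_remove_plots_preserves_blocks_and_is_idempotent(self):
        ds, responses = self._setup()
        once = remove_plots(ds, [2, 7])
        assert once.n_scans == ds.n_scans
        assert np.all(np.isnan(once.scan_values(2)))
        twice = remove_plots(once, [2, 7])
        assert np.array_equal(once.values, twice.values, equal_nan=True)
        with pytest.raises(LookupError):
            remove_plots(ds, [99])

    def test_read_only_report_generators(self):
        ds, responses = self._setup()
        before = ds.values.copy()
        avg = average_scans(ds)
        scatter_table(avg, responses, "NDVI", "Yield")
        detailed_index_report(avg, responses, ["NDVI", "SR"], ["Yield"])
        screen_sris(avg, responses, ("poly1",), 0.99)
        assert np.array_equal(ds.values, before)


class TestDetailedIndexReport:
    def test_rows_and_consistency_with_scatter(self):
        rng = np.random.default_rng(6)
        wl = np.asarray([670.0, 800.0])
        values = np.repeat(rng.uniform(0.1, 0.7, size=(10, 2)), 2, axis=0)
        ds = make_dataset(values, wavelengths=wl, k=2)
        responses = make_responses(rng.uniform(2, 8, size=10))
        avg = average_scans(ds)
        report = detailed_index_report(avg, responses, ["NDVI"], ["Yield"])
        assert len(report) == 10
        table = scatter_table(avg, responses, "NDVI", "Yield")
        assert np.allclose(report.NDVI, table.index_value)
        assert np.allclose(report.Yield, responses.variable("Yield"))

    def test_unknown_names_raise(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(rng.uniform(0.1, 0.7, size=(4, 2)),
                          wavelengths=[670.0, 800.0], k=2)
        responses = make_responses(rng.uniform(size=2))
        avg = average_scans(ds)
        with pytest.raises(LookupError):
            detailed_index_report(avg, responses, ["NOPE"], ["Yield"])
        with pytest.raises(LookupError):
            detailed_index_report(avg, responses, ["NDVI"], ["NOPE"])
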