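"""Single-population integrate-and-fire dynamics and background drive."""

import numpy as np
import pytest

from cbgtsim.core import (
    BackgroundSpec,
    CellParams,
    ConfigError,
    IntegrationDivergedError,
    PopulationState,
    ReceptorParams,
    background_drive,
    lif_steady_rate,
    population_rate,
    step_population,
)


@pytest.fixture
def cell():
    return CellParams()


@pytest.fixture
def recept():
    return ReceptorParams()


class TestStepPopulation:
    def test_leak_relaxes_monotonically_toward_rest(self, cell, recept):
        st = PopulationState.zeros(1, cell)
        st.V[:] = -60.0  # above rest, below threshold
        prev = st.V[0]
        for _ in range(2000):
            step_population(st, cell, recept)
            assert st.V[0] <= prev + 1e-12
            prev = st.V[0]
        assert st.V[0] == pytest.approx(cell.V_rest, abs=0.05)

    def test_leak_time_constant_matches_taum(self, cell, recept):
        st = PopulationState.zeros(1, cell)
        st.V[:] = -60.0
        for _ in range(int(cell.Taum / st.dt)):  # one membrane time constant
            step_population(st, cell, recept)
        expected = cell.V_rest + (-60.0 - cell.V_rest) * np.exp(-1.0)
        assert st.V[0] == pytest.approx(expected, abs=0.05)

    def test_threshold_crossing_spikes_and_resets(self, cell, recept):
        st = PopulationState.zeros(3, cell)
        st.V[:] = [cell.V_thresh, cell.V_thresh + 5.0, -60.0]
        step_population(st, cell, recept)
        assert list(st.spiked) == [True, True, False]
        assert st.V[0] == cell.V_reset and st.V[1] == cell.V_reset

    def test_no_spike_within_refractory_period(self, cell, recept):
        st = PopulationState.zeros(1, cell)
        spike_times = []
        for _ in range(20000):
            step_population(st, cell, recept, external_current=2.0)
            if st.spiked[0]:
                spike_times.append(st.t)
        isi = np.diff(spike_times)
        assert len(spike_times) > 10
        assert isi.min() >= cell.refractory - 1e-9

    @pytest.mark.parametrize("current", [0.6, 0.9, 1.2])
    def test_fi_curve_matches_closed_form_within_2pct(self, cell, recept, current):
        st = PopulationState.zeros(1, cell, dt=0.1)
        n_spikes = 0
        for _ in range(50000):  # 5 s
            step_population(st, cell, recept, external_current=current)
            n_spikes += int(st.spiked[0])
        simulated = n_spikes / 5.0
        expected = lif_steady_rate(cell, current)
        assert simulated == pytest.approx(expected, rel=0.02)

    def test_subthreshold_current_never_spikes(self, cell, recept):
        st = PopulationState.zeros(1, cell)
        assert lif_steady_rate(cell, 0.3) == 0.0
        for _ in range(20000):
            step_population(st, cell, recept, external_current=0.3)
            assert not st.spiked[0]

    def test_nonfinite_state_raises_named_error(self, cell, recept):
        st = PopulationState.zeros(2, cell)
        st.V[1] = np.nan
        with pytest.raises(IntegrationDivergedError, match="FSI"):
            step_population(st, cell, recept, label="FSI")

    def test_invalid_cell_params_rejected(self):
        with pytest.raises(ConfigError):
            CellParams(Taum=-1.0)
        with pytest.raises(ConfigError):
            CellParams(V_reset=-40.0, V_thresh=-50.0)


class TestBackgroundDrive:
    def test_zero_rate_gives_zero_drive(self, rng):
        spec = BackgroundSpec(rate=0.0, efficacy=0.01)
        assert np.all(background_drive(spec, rng, dt=1.0, n_neurons=50) == 0)

    def test_mean_events_per_step(self, rng):
        # 100 spikes/s, one connection, 1 ms step -> 0.1 events/step
        spec = BackgroundSpec(rate=100.0, efficacy=0.01, n_connections=1)
        draws = np.concatenate(
            [background_drive(spec, rng, dt=1.0, n_neurons=1000) for _ in range(100)]
        )
        assert draws.mean() == pytest.approx(0.1, abs=3 * draws.std() / np.sqrt(draws.size))

    def test_n_connections_multiplies_rate(self, rng):
        spec = BackgroundSpec(rate=100.0, efficacy=0.01, n_connections=5)
        draws = background_drive(spec, rng, dt=1.0, n_neurons=100000)
        assert draws.mean() == pytest.approx(0.5, rel=0.05)

    def test_same_seed_bit_identical(self):
        spec = BackgroundSpec(rate=200.0, efficacy=0.01)
        a = background_drive(spec, np.random.default_rng(7), dt=0.1, n_neurons=100)
        b = background_drive(spec, np.random.default_rng(7), dt=0.1, n_neurons=100)
        assert np.array_equal(a, b)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            BackgroundSpec(rate=-1.0, efficacy=0.01)

    def test_drive_never_negative(self, rng):
        spec = BackgroundSpec(rate=0.5, efficacy=0.01)  # heavily truncated regime
        draws = background_drive(spec, rng, dt=1.0, n_neurons=10000)
        assert draws.min() >= 0


class TestPopulationRate:
    def test_count_to_rate_arithmetic(self):
        # 10 neurons, 3 spikes in one 10 ms bin -> 30 spikes/s
        raster = np.zeros((100, 10), dtype=bool)
        raster[5, 0] = raster[20, 3] = raster[90, 9] = True
        trace = population_rate(raster, window=10.0, dt=0.1)
        assert trace.shape == (1,)
        assert trace[0] == pytest.approx(30.0)

    def test_empty_raster_gives_zero_trace(self):
        raster = np.zeros((500, 8), dtype=bool)
        assert np.all(population_rate(raster, window=5.0, dt=0.1) == 0)

    def test_rate_integrates_back_to_spike_count(self, rng):
        raster = rng.random((2000, 15)) < 0.01
        window = 5.0
        trace = population_rate(raster, window=window, dt=0.1)
        recovered = trace.sum() * (window / 1000.0) * 15
        assert recovered == pytest.approx(raster.sum())

    def test_invalid_window_rejected(self):
        with pytest.raises(ConfigError):
            population_rate(np.zeros((10, 2)), window=0.0, dt=0.1)
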