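"""Series orchestration: happy path, fault injection, parameter bookkeeping."""

from dataclasses import replace

import numpy as np
import pytest

from nmrbot import (
    AdaptationRule,
    FaultInjectingBackend,
    ManifestValidationError,
    Resonance,
    RunConfig,
    SampleSpec,
    SeriesOptions,
    SimulatedSpectrometer,
    SyntheticSample,
    UnknownParameterSetError,
    apply_ns_multiplier,
    aqueous_metabolite_sample,
    default_profile,
    format_folder_name,
    hsqc_demo_sample,
    load_parameter_set,
    organic_sample,
    run_series,
    solvent_offset_prescan,
    water_standard_sample,
)


def two_sample_rack():
    return {
        "A1": organic_sample("org_a"),
        "A2": aqueous_metabolite_sample("mix_b"),
    }


def two_sample_config(**options):
    return RunConfig(
        samples=(
            SampleSpec("org_a", "CDCl3", "A1", ("PROTON", "C13CPD")),
            SampleSpec("mix_b", "H2O+D2O", "A2", ("PROTON", "C13CPD")),
        ),
        options=SeriesOptions(**options),
    )


class TestRunSeries:
    def test_happy_path_counts_and_folders(self, tmp_path, profile):
        backend = SimulatedSpectrometer(profile, two_sample_rack())
        result = run_series(two_sample_config(), backend, tmp_path, seed=1)
        assert result.counts() == {"completed": 4, "failed": 0, "skipped": 0}
        assert [s.status for s in result.sample_results] == ["completed"] * 2
        series_dir = tmp_path / "series"
        folders = {p.name for p in series_dir.iterdir() if p.is_dir()}
        assert folders == {"org_a_1", "mix_b_2"}
        for folder in folders:
            assert (series_dir / folder / "audit.txt").exists()
            assert (series_dir / folder / "1" / "spectrum.txt").exists()
            assert (series_dir / folder / "1" / "params.json").exists()
        assert (series_dir / "series_audit.txt").exists()

    def test_injected_experiment_fault_fails_one_continues_rest(self, profile):
        backend = FaultInjectingBackend(
            SimulatedSpectrometer(profile, two_sample_rack()),
            fail_method="acquire", fail_call=2,
        )
        result = run_series(two_sample_config(), backend, None, seed=1)
        statuses = [(s, st) for s, _, _, st in result.outcome_table()]
        assert statuses == [
            ("org_a", "completed"), ("org_a", "failed"),
            ("mix_b", "completed"), ("mix_b", "completed"),
        ]
        assert any(e.level == "error" for e in result.audit_events)

    def test_insert_fault_skips_sample_series_continues(self, profile):
        backend = FaultInjectingBackend(
            SimulatedSpectrometer(profile, two_sample_rack()),
            fail_method="insert", fail_call=1,
        )
        result = run_series(two_sample_config(), backend, None, seed=1)
        assert result.sample_results[0].status == "skipped"
        assert result.sample_results[1].status == "completed"
        assert result.counts() == {"completed": 2, "failed": 0, "skipped": 2}

    def test_missing_rack_position_skips_sample(self, profile):
        backend = SimulatedSpectrometer(profile, {"A1": organic_sample("org_a")})
        result = run_series(two_sample_config(), backend, None, seed=1)
        assert result.sample_results[0].status == "completed"
        assert result.sample_results[1].status == "skipped"

    def test_determinism_same_config_and_seed(self, profile):
        outcomes = []
        for _ in range(2):
            backend = SimulatedSpectrometer(profile, two_sample_rack())
            result = run_series(two_sample_config(), backend, None, seed=7)
            outcomes.append(
                (result.outcome_table(), result.audit_signature(),
                 [o.modifications for s in result.sample_results
                  for o in s.outcomes])
            )
        assert outcomes[0] == outcomes[1]

    def test_identical_spectra_for_identical_seed(self, profile):
        traces = []
        for _ in range(2):
            backend = SimulatedSpectrometer(profile, two_sample_rack())
            result = run_series(two_sample_config(), backend, None, seed=3)
            traces.append(
                result.sample_results[0].outcomes[0].spectrum.intensity
            )
        assert np.array_equal(traces[0], traces[1])

    def test_invalid_config_refused_before_any_acquisition(self, profile):
        config = RunConfig(
            samples=(SampleSpec("s1", "D2O", "A1", ()),)  # no experiments
        )
        backend = SimulatedSpectrometer(profile, two_sample_rack())
        with pytest.raises(ManifestValidationError):
            run_series(config, backend, None, seed=1)

    def test_unhandled_backend_fault_aborts_with_partial_result(self, profile):
        class ExplodingBackend(SimulatedSpectrometer):
            def acquire(self, params, seed):
                if self.state.inserted_sample.name == "mix_b":
                    raise RuntimeError("power supply died")
                return super().acquire(params, seed)

        backend = ExplodingBackend(profile, two_sample_rack())
        result = run_series(two_sample_config(), backend, None, seed=1)
        assert result.series_errors
        assert any(e.level == "fatal" for e in result.audit_events)
        # conservation still holds: every configured experiment has an outcome
        assert sum(result.counts().values()) == 4

    def test_outcome_conservation_under_every_single_fault(self, profile):
        total = 4
        for method, calls in [("acquire", 4), ("insert", 2), ("lock", 2)]:
            for k in range(1, calls + 1):
                backend = FaultInjectingBackend(
                    SimulatedSpectrometer(profile, two_sample_rack()),
                    fail_method=method, fail_call=k,
                )
                result = run_series(two_sample_config(), backend, None, seed=1)
                assert sum(result.counts().values()) == total


class TestWaterStandard:
    def config(self, use_ws):
        samples = [
            SampleSpec("mix_b", "H2O+D2O", "A2", ("PROTON",)),
            SampleSpec("org_a", "CDCl3", "A1", ("PROTON",)),
        ]
        if use_ws:
            samples.insert(
                0, SampleSpec("water", "H2O+D2O", "A9", (), is_water_standard=True)
            )
        return RunConfig(
            samples=tuple(samples),
            options=SeriesOptions(use_water_standard=use_ws),
        )

    def rack(self):
        return {
            "A9": water_standard_sample(),
            "A2": aqueous_metabolite_sample("mix_b"),
            "A1": organic_sample("org_a"),
        }

    def test_water_standard_runs_first_and_only_shims(self, profile):
        backend = SimulatedSpectrometer(profile, self.rack())
        result = run_series(self.config(True), backend, None, seed=1)
        ws = result.sample_results[0]
        assert ws.name == "water" and ws.outcomes == ()
        assert ws.final_shim_quality == pytest.approx(
            profile.shim_routines["3d"].floor
        )

    def test_preshim_never_worsens_subsequent_shim_state(self, profile):
        shim_with = {}
        for use_ws in (False, True):
            backend = SimulatedSpectrometer(profile, self.rack())
            result = run_series(self.config(use_ws), backend, None, seed=1)
            shim_with[use_ws] = [
                s.final_shim_quality
                for s in result.sample_results
                if not s.name == "water"
            ]
        for with_ws, without in zip(shim_with[True], shim_with[False]):
            assert with_ws <= without


class TestParameterModifications:
    def test_load_parameter_set_verbatim_and_with_prosol(self, profile):
        library = profile.parameter_sets
        params, mods = load_parameter_set("PROTON", library, use_prosol=False)
        assert params == library["PROTON"] and mods == []
        params, mods = load_parameter_set(
            "PROTON", library, use_prosol=True, profile=profile
        )
        assert (params.pulse_length, params.pulse_power) == profile.prosol["1H"]
        assert [m.kind for m in mods] == ["prosol"]

    def test_unknown_parameter_set_raises(self, profile):
        with pytest.raises(UnknownParameterSetError):
            load_parameter_set("NOEXP", profile.parameter_sets)

    def test_unknown_set_fails_experiment_but_series_continues(self, profile):
        config = RunConfig(
            samples=(SampleSpec("org_a", "CDCl3", "A1", ("NOEXP", "PROTON")),)
        )
        backend = SimulatedSpectrometer(profile, {"A1": organic_sample("org_a")})
        result = run_series(config, backend, None, seed=1)
        assert [st for _, _, _, st in result.outcome_table()] == [
            "failed", "completed"
        ]

    def test_ns_multiplier_arithmetic(self, profile):
        params = profile.parameter_sets["PROTON"]
        assert params.ns == 8
        multiplied, mods = apply_ns_multiplier(params, 4)
        assert multiplied.ns == 32
        assert replace(multiplied, ns=8) == params  # nothing else changed
        same, mods1 = apply_ns_multiplier(params, 1)
        assert same == params and mods1 == []

    def test_ns_multiplier_improves_snr_as_sqrt(self, profile):
        """S/N scales as sqrt(multiplier) on the simulated backend."""
        sample = SyntheticSample(
            "s", "D2O", resonances={"1H": (Resonance(4.7, 5.0, 1.5),)}
        )
        base = RunConfig(
            samples=(SampleSpec("s", "D2O", "A1", ("PROTON",)),)
        )
        snr = {}
        for mult in (1, 16):
            config = replace(
                base,
                samples=(replace(base.samples[0], ns_multiplier=mult),),
            )
            values = []
            for seed in range(30):
                backend = SimulatedSpectrometer(profile, {"A1": sample})
                result = run_series(config, backend, None, seed=seed)
                spec = result.sample_results[0].outcomes[0].spectrum
                values.append(np.max(spec.intensity) / spec.noise_sigma)
            snr[mult] = np.mean(values)
        assert snr[16] / snr[1] == pytest.approx(4.0, rel=0.10)

    def test_modification_ledger_explains_every_difference(self, profile):
        """Stored params vs acquired-with params: each delta maps to exactly
        one recorded modification."""
        config = RunConfig(
            samples=(
                SampleSpec("mix_b", "H2O+D2O", "A2", ("PROTON",),
                           ns_multiplier=4),
            ),
            options=SeriesOptions(
                use_prosol=True,
                find_solvent_offset=True,
                use_gain_optimization=True,
            ),
        )
        backend = SimulatedSpectrometer(
            profile, {"A2": aqueous_metabolite_sample("mix_b")}
        )
        result = run_series(config, backend, None, seed=5)
        outcome = result.sample_results[0].outcomes[0]
        assert outcome.status == "completed"
        kinds = [m.kind for m in outcome.modifications]
        assert kinds == ["prosol", "ns_multiplier", "solvent_offset", "gain"]
        stored = profile.parameter_sets["PROTON"]
        acquired = outcome.params
        assert acquired.ns == stored.ns * 4
        assert (acquired.pulse_length, acquired.pulse_power) == profile.prosol["1H"]
        assert acquired.dims[0].offset != stored.dims[0].offset
        assert acquired.receiver_gain != "auto"
        # nothing changed without a ledger entry
        reverted = replace(
            acquired,
            ns=stored.ns,
            pulse_length=stored.pulse_length,
            pulse_power=stored.pulse_power,
            receiver_gain=stored.receiver_gain,
        ).with_dim(1, sw=stored.dims[0].sw, offset=stored.dims[0].offset)
        assert reverted == stored


class TestFolderNames:
    def sample(self):
        return SampleSpec("lysate", "D2O", "B2", ("PROTON",))

    def test_token_substitution(self):
        assert format_folder_name(self.sample(), "{name}_{index}", 3) == "lysate_3"
        assert format_folder_name(
            self.sample(), "{rack}_{solvent}_{index}", 1
        ) == "B2_D2O_1"

    def test_unsafe_characters_sanitized(self):
        sample = replace(self.sample(), name="crude/extract 1")
        assert "/" not in format_folder_name(sample, "{name}_{index}", 1)
        assert " " not in format_folder_name(sample, "{name}_{index}", 1)

    def test_collisions_get_numeric_suffix(self):
        existing: set[str] = set()
        first = format_folder_name(self.sample(), "{name}", 1, existing=existing)
        second = format_folder_name(self.sample(), "{name}", 2, existing=existing)
        third = format_folder_name(self.sample(), "{name}", 3, existing=existing)
        assert first == "lysate"
        assert second == "lysate_2"
        assert third == "lysate_3"


class TestSolventOffsetPrescan:
    def test_offset_applied_to_every_later_1h_dimension(self, profile):
        truth = 4.72
        config = RunConfig(
            samples=(
                SampleSpec("mix", "H2O+D2O", "A2", ("PROTON", "HSQC")),
            ),
            options=SeriesOptions(find_solvent_offset=True),
        )
        backend = SimulatedSpectrometer(
            profile, {"A2": aqueous_metabolite_sample("mix", solvent_shift=truth)}
        )
        result = run_series(config, backend, None, seed=2)
        step = 20.0 / 4095  # pre-scan digital resolution
        for outcome in result.sample_results[0].outcomes:
            assert outcome.status == "completed"
            h_dims = [d for d in outcome.params.dims if d.nucleus == "1H"]
            for dim in h_dims:
                assert abs(dim.offset - truth) <= step

    def test_no_peak_keeps_defaults_with_warning(self, profile):
        # empty 1H spectrum: nothing above threshold
        quiet = SyntheticSample("blank", "D2O")
        config = RunConfig(
            samples=(SampleSpec("blank", "D2O", "A1", ("PROTON",)),),
            options=SeriesOptions(find_solvent_offset=True),
        )
        backend = SimulatedSpectrometer(profile, {"A1": quiet})
        result = run_series(config, backend, None, seed=2)
        outcome = result.sample_results[0].outcomes[0]
        assert outcome.status == "completed"
        stored = profile.parameter_sets["PROTON"]
        assert outcome.params.dims[0].offset == stored.dims[0].offset
        assert any(
            e.level == "warning" and "no solvent peak" in e.message
            for e in result.audit_events
        )

    def test_disabled_option_adds_no_extra_acquisition(self, profile):
        acquisitions = {}
        for enabled in (False, True):
            config = RunConfig(
                samples=(SampleSpec("mix", "H2O+D2O", "A2", ("PROTON",)),),
                options=SeriesOptions(find_solvent_offset=enabled),
            )
            backend = FaultInjectingBackend(
                SimulatedSpectrometer(
                    profile, {"A2": aqueous_metabolite_sample("mix")}
                ),
                fail_method="acquire", fail_call=99,
            )
            run_series(config, backend, None, seed=2)
            acquisitions[enabled] = backend.calls["acquire"]
        assert acquisitions[False] == 1
        assert acquisitions[True] == 2

    def test_prescan_function_recovers_truth(self, profile):
        backend = SimulatedSpectrometer(
            profile, {"A2": aqueous_metabolite_sample("mix", solvent_shift=4.72)}
        )
        backend.insert("A2")
        backend.lock("H2O+D2O")
        offset = solvent_offset_prescan(
            backend, profile.parameter_sets["PROTON_QUICK"], seed=0
        )
        assert offset == pytest.approx(4.72, abs=20.0 / 4095)


class TestAdaptiveSWIntegration:
    def test_13c_1d_drives_hsqc_indirect_window(self, profile):
        sample = hsqc_demo_sample()
        rule = AdaptationRule("C13CPD", "13C", ("HSQC",), 2)
        config = RunConfig(
            samples=(SampleSpec("hsqc_demo", "D2O", "A5", ("C13CPD", "HSQC")),),
            options=SeriesOptions(sw_adaptation=(rule,)),
        )
        backend = SimulatedSpectrometer(profile, {"A5": sample})
        result = run_series(config, backend, None, seed=4)
        c1d, hsqc = result.sample_results[0].outcomes
        assert c1d.status == "completed" and hsqc.status == "completed"
        adapted = hsqc.params.dims[1]
        default = profile.parameter_sets["HSQC"].dims[1]
        assert adapted.sw < default.sw
        c_shifts = [c.c_shift for c in sample.correlations]
        assert adapted.offset == pytest.approx(
            (max(c_shifts) + min(c_shifts)) / 2, abs=0.5
        )
        assert any(m.kind == "adapted_sw" for m in hsqc.modifications)
        # all crosspeaks inside the adapted window: no folding
        lo = adapted.offset - adapted.sw / 2
        hi = adapted.offset + adapted.sw / 2
        assert all(lo <= c <= hi for c in c_shifts)
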