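"""Synthetic-cohort generator: geometry, spectra, forward model, artifacts."""

import numpy as np
import pytest
from scipy import signal as sg

from megspect import synth
from megspect.atlas import BAND_EDGES_HZ, region_labels
from megspect.preproc import RawRecording


class TestGeometry:
    def test_default_partition_covers_all_regions(self):
        sensors, head = synth.make_geometry(160, 1000, 68, seed=1)
        assert sensors.n_channels == 160
        assert head.n_vertices == 1000
        counts = np.bincount(head.vertex_region, minlength=68)
        assert counts.min() >= 1
        assert head.region_names == region_labels(68)

    def test_seeded_determinism(self):
        a = synth.make_geometry(32, 100, 10, seed=7)
        b = synth.make_geometry(32, 100, 10, seed=7)
        assert np.array_equal(a[1].vertices, b[1].vertices)
        assert np.array_equal(a[1].normals, b[1].normals)
        assert np.array_equal(a[0].positions, b[0].positions)
        c = synth.make_geometry(32, 100, 10, seed=8)
        assert not np.array_equal(a[1].normals, c[1].normals)

    def test_one_vertex_per_region_when_counts_match(self):
        _, head = synth.make_geometry(8, 8, 8, seed=2)
        assert np.bincount(head.vertex_region, minlength=8).tolist() == [1] * 8

    def test_sensors_outside_vertices_inside(self):
        sensors, head = synth.make_geometry(64, 250, 68, seed=3)
        assert np.all(np.linalg.norm(sensors.positions, axis=1) > head.sphere_radius)
        assert np.all(
            np.linalg.norm(head.vertices, axis=1) < head.sphere_radius
        )
        assert np.allclose(
            np.linalg.norm(sensors.orientations, axis=1), 1.0, atol=1e-9
        )
        assert np.allclose(np.linalg.norm(head.normals, axis=1), 1.0, atol=1e-9)

    def test_more_regions_than_vertices_rejected(self):
        with pytest.raises(ValueError, match="n_regions"):
            synth.make_geometry(8, 10, 11, seed=0)

    def test_symmetric_region_labels_pair_across_midline(self):
        _, head = synth.make_geometry(16, 200, 68, seed=4)
        lh = head.region_vertices("lh_supramarginal")
        rh = head.region_vertices("rh_supramarginal")
        assert len(lh) > 0 and len(rh) > 0
        # mirrored patches sit at opposite x on average
        assert head.vertices[lh][:, 0].mean() * head.vertices[rh][:, 0].mean() < 0


class TestSourceSimulation:
    def test_zero_amplitude_table_gives_zero_sources(self, tiny_geometry):
        _, head = tiny_geometry
        table = synth.default_amplitude_table(head.region_names, ad_effects={})
        table[:] = 0.0
        spec = synth.CohortSpec(
            n_ad=2, n_nc=2, duration=4, amplitude_table=table, source_floor_rms=0.0
        )
        src = synth.simulate_source_timecourses(spec, head, "NC", "EC", 1)
        assert np.all(src.values == 0)

    def test_single_region_alpha1_peaks_in_band(self, tiny_geometry):
        _, head = tiny_geometry
        target = head.region_names[3]
        table = synth.default_amplitude_table(head.region_names, ad_effects={})
        table[:] = 0.0
        table.loc[(slice(None), slice(None), "alpha1", target)] = 1e-9
        spec = synth.CohortSpec(
            n_ad=2,
            n_nc=2,
            duration=30,
            amplitude_table=table,
            source_floor_rms=0.0,
            between_subject_cv=0.0,
        )
        src = synth.simulate_source_timecourses(spec, head, "NC", "EC", 3)
        members = head.region_vertices(target)
        f, p = sg.welch(src.values[members], fs=spec.sampling_rate, nperseg=512)
        lo, hi = BAND_EDGES_HZ["alpha1"]
        peak = f[np.argmax(p.mean(axis=0))]
        assert lo <= peak <= hi
        others = np.setdiff1d(np.arange(head.n_vertices), members)
        assert np.abs(src.values[others]).max() == 0

    def test_ec_activity_exceeds_eo_in_every_region(self, tiny_geometry):
        """Eyes-closed absolute activity beats eyes-open region by region
        under the default amplitude table (alpha blocking on eye opening)."""
        _, head = tiny_geometry
        spec = synth.CohortSpec(n_ad=2, n_nc=2, duration=30)
        ec = synth.simulate_source_timecourses(spec, head, "NC", "EC", 9)
        eo = synth.simulate_source_timecourses(spec, head, "NC", "EO", 9)
        for i in range(len(head.region_names)):
            members = head.vertex_region == i
            assert (
                np.abs(ec.values[members]).mean() > np.abs(eo.values[members]).mean()
            )

    def test_unknown_labels_rejected(self, tiny_geometry):
        _, head = tiny_geometry
        spec = synth.CohortSpec(n_ad=2, n_nc=2, duration=4)
        with pytest.raises(ValueError, match="group"):
            synth.simulate_source_timecourses(spec, head, "XX", "EC", 1)
        with pytest.raises(ValueError, match="condition"):
            synth.simulate_source_timecourses(spec, head, "AD", "closed", 1)

    def test_band_amplitude_raises_sensor_band_power_monotonically(
        self, tiny_geometry
    ):
        """Sensor-level power in a band grows with the simulated source
        amplitude of that band (3 amplitude levels)."""
        sensors, head = tiny_geometry
        from megspect.sourceest import compute_lead_field

        L = compute_lead_field(head, sensors)
        target = head.region_names[1]
        powers = []
        for amp in (0.5e-9, 1.0e-9, 2.0e-9):
            table = synth.default_amplitude_table(head.region_names, ad_effects={})
            table.loc[(slice(None), "EC", "theta2", target)] = amp
            spec = synth.CohortSpec(
                n_ad=2,
                n_nc=2,
                duration=20,
                amplitude_table=table,
                between_subject_cv=0.0,
            )
            src = synth.simulate_source_timecourses(spec, head, "NC", "EC", 17)
            rec = synth.project_to_sensors(src, head, sensors, L)
            f, p = sg.welch(rec.values, fs=spec.sampling_rate, nperseg=512)
            lo, hi = BAND_EDGES_HZ["theta2"]
            sel = (f >= lo) & (f <= hi)
            powers.append(p[:, sel].sum())
        assert powers[0] < powers[1] < powers[2]


class TestForwardProjection:
    def test_zero_sources_zero_recording(self, tiny_geometry, leadfield_tiny=None):
        sensors, head = tiny_geometry
        from megspect.sourceest import compute_lead_field

        L = compute_lead_field(head, sensors)
        src = synth.SourceActivityMatrix(
            values=np.zeros((head.n_vertices, 50)), sampling_rate=100.0
        )
        rec = synth.project_to_sensors(src, head, sensors, L)
        assert np.all(rec.values == 0)

    def test_linearity_and_single_vertex_column(self, tiny_geometry, rng):
        sensors, head = tiny_geometry
        from megspect.sourceest import compute_lead_field

        L = compute_lead_field(head, sensors)
        values = rng.standard_normal((head.n_vertices, 40)) * 1e-9
        src = synth.SourceActivityMatrix(values=values, sampling_rate=100.0)
        src2 = synth.SourceActivityMatrix(values=2 * values, sampling_rate=100.0)
        r1 = synth.project_to_sensors(src, head, sensors, L)
        r2 = synth.project_to_sensors(src2, head, sensors, L)
        assert np.allclose(r2.values, 2 * r1.values, rtol=1e-12)

        only = np.zeros_like(values)
        tc = rng.standard_normal(40) * 1e-9
        only[17] = tc
        rec = synth.project_to_sensors(
            synth.SourceActivityMatrix(values=only, sampling_rate=100.0),
            head,
            sensors,
            L,
        )
        assert np.allclose(rec.values, np.outer(L.values[:, 17], tc), rtol=1e-12)

    def test_dimension_mismatch_rejected(self, tiny_geometry):
        sensors, head = tiny_geometry
        from megspect.sourceest import LeadFieldMatrix

        bad = LeadFieldMatrix(values=np.ones((sensors.n_channels, 3)))
        src = synth.SourceActivityMatrix(
            values=np.zeros((head.n_vertices, 10)), sampling_rate=100.0
        )
        with pytest.raises(ValueError, match="lead field"):
            synth.project_to_sensors(src, head, sensors, bad)


class TestNoiseAndArtifacts:
    def _rec(self, n_ch=4, fs=50.0, dur=120.0):
        return RawRecording(
            values=np.zeros((n_ch, int(fs * dur))), sampling_rate=fs
        )

    def test_noiseless_identity(self):
        rec = self._rec()
        out, events = synth.add_noise_and_artifacts(rec, 0.0, 0.0, 1e-12, seed=1)
        assert np.array_equal(out.values, rec.values)
        assert events == []

    def test_poisson_event_count_calibration(self):
        """3 events/min on 2 minutes: mean count over 200 seeds within
        3 standard errors of 6."""
        rec = self._rec()
        counts = [
            len(synth.add_noise_and_artifacts(rec, 0.0, 3.0, 1e-12, seed=s)[1])
            for s in range(200)
        ]
        mean = np.mean(counts)
        se = np.sqrt(6.0 / 200)
        assert abs(mean - 6.0) < 3 * se

    def test_artifact_amplitude_exceeds_rejection_threshold(self):
        rec = self._rec(dur=60.0)
        out, events = synth.add_noise_and_artifacts(
            rec, 0.0, 10.0, 12e-12, seed=3
        )
        assert events
        for ev in events:
            window = out.values[ev.channel, ev.onset_sample : ev.onset_sample + ev.n_samples]
            assert np.abs(window).max() > 10e-12
        # 100 ms boxcar width
        assert events[0].n_samples == int(round(0.1 * rec.sampling_rate))


class TestCohort:
    def test_bundle_shape_and_determinism(self):
        spec = synth.CohortSpec(n_ad=2, n_nc=2, duration=10, seed=21)
        kw = {"n_channels": 16, "n_vertices": 80, "n_regions": 8}
        a = synth.generate_cohort(spec, geometry_kwargs=kw)
        assert len(a.subjects) == 4
        assert len(a.recordings) == 8  # 4 subjects x EC/EO
        assert set(g for _, g in a.recordings) == {"EC", "EO"}
        b = synth.generate_cohort(spec, geometry_kwargs=kw)
        for key in a.recordings:
            assert np.array_equal(a.recordings[key].values, b.recordings[key].values)
        assert a.true_amplitudes.equals(b.true_amplitudes)

    def test_default_cohort_sizes(self):
        spec = synth.CohortSpec()
        assert spec.n_ad + spec.n_nc == 47
        ids, groups, _ = synth._cohort_roster(spec)
        assert groups.count("AD") == 20 and groups.count("NC") == 27

    def test_truth_draw_matches_generated_cohort(self):
        spec = synth.CohortSpec(n_ad=2, n_nc=2, duration=4, seed=9)
        kw = {"n_channels": 8, "n_vertices": 16, "n_regions": 8}
        cohort = synth.generate_cohort(spec, geometry_kwargs=kw)
        _, truth = synth.draw_cohort_truth(spec, cohort.head.region_names)
        assert truth.equals(cohort.true_amplitudes)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            synth.CohortSpec(n_ad=1, n_nc=5)
        with pytest.raises(ValueError):
            synth.CohortSpec(duration=10.3, sampling_rate=3.0)
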