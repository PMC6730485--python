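"""Synthetic cohort generator: paradigm arithmetic, determinism, forward
model consistency, and latent-structure recovery."""

import numpy as np
import pytest
from scipy import signal as spsig

from nirsnet import (
    GroupProfile,
    NoiseSpec,
    default_profiles,
    degraded_connectivity,
    derive_subject_seed,
    fc_matrix,
    make_default_schedule,
    mbll_convert,
    optical_density,
    simulate_cohort,
    simulate_subject,
    uniform_connectivity,
)

FS = 7.81


class TestDefaultSchedule:
    def test_task_session_totals_342_seconds(self, schedule):
        blocks = schedule.task_blocks()
        assert len(blocks) == 9
        t0, t1 = schedule.segments["task"]
        assert t1 - t0 == pytest.approx(342.0)
        assert all(dur == pytest.approx(24.0) for _, dur in blocks)

    def test_resting_state_is_240_seconds(self, schedule):
        t0, t1 = schedule.segments["resting"]
        assert (t0, t1) == (0.0, 240.0)

    def test_trials_nonoverlapping_and_ordered(self, schedule):
        onsets = schedule.task_onsets()
        assert np.all(np.diff(onsets) == pytest.approx(38.0))

    def test_trial_phases_present(self, schedule):
        conds = {e.condition for e in schedule.entries}
        assert conds == {"ready", "encode", "retain", "probe", "rest"}

    def test_post_rest_30_seconds(self, schedule):
        t0, t1 = schedule.segments["post_rest"]
        assert t1 - t0 == pytest.approx(30.0)


class TestSimulateSubject:
    def test_null_profile_gives_null_hemoglobin(self, montage, schedule):
        prof = GroupProfile(
            label="null",
            activation_amplitude=0.0,
            active_channels=(),
            latent_connectivity=uniform_connectivity(20, 0.0),
            noise=NoiseSpec.silent(),
            background_sd=0.0,
        )
        rec, _ = simulate_subject(prof, montage, schedule, seed=0)
        od = optical_density(rec.intensity)
        h = mbll_convert(od, fs=rec.fs)
        assert np.abs(h.hbo).max() < 1e-12
        assert np.abs(h.hbr).max() < 1e-12

    def test_same_seed_bit_identical(self, montage, schedule):
        prof = default_profiles()[0]
        r1, _ = simulate_subject(prof, montage, schedule, seed=77)
        r2, _ = simulate_subject(prof, montage, schedule, seed=77)
        assert np.array_equal(r1.intensity, r2.intensity)

    def test_different_seeds_differ(self, montage, schedule):
        prof = default_profiles()[0]
        r1, _ = simulate_subject(prof, montage, schedule, seed=1)
        r2, _ = simulate_subject(prof, montage, schedule, seed=2)
        assert not np.array_equal(r1.intensity, r2.intensity)

    def test_forward_inverse_round_trip(self, montage, schedule, quiet_profile):
        rec, truth = simulate_subject(quiet_profile, montage, schedule, seed=5)
        s = rec.segment_slice("resting")
        od = optical_density(rec.intensity, baseline=(s.start, s.stop))
        h = mbll_convert(od, fs=rec.fs)
        evoked = truth.regressor[:, None] * truth.amplitudes[None, :]
        assert np.abs(h.hbo - evoked).max() < 1e-9
        assert np.abs(h.hbr + evoked / 3.0).max() < 1e-9

    def test_block_average_peak_recovers_amplitude(self, montage, schedule, quiet_profile):
        """The block-average peak equals the amplitude times the epoch peak
        of the dHRF itself (the forward oracle for trial-overlap effects)."""
        from nirsnet import block_average

        rec, truth = simulate_subject(quiet_profile, montage, schedule, seed=3)
        h = mbll_convert(optical_density(rec.intensity), fs=rec.fs)
        ba = block_average(h.hbo[:, 0], schedule, FS)
        oracle = block_average(truth.regressor, schedule, FS)
        expected_peak = 0.4 * oracle.mean.max()
        assert ba.mean.max() == pytest.approx(expected_peak, rel=0.05)
        # trial overlap distorts the single-trial peak by no more than ~15%
        assert oracle.mean.max() == pytest.approx(1.0, rel=0.15)

    def test_noiseless_background_correlation_converges(self, montage):
        """Empirical correlation of a long noiseless background approaches
        the latent matrix (tested at 10x the resting-state length)."""
        latent = degraded_connectivity(20, 0.5, {9: 0.1})
        prof = GroupProfile(
            label="bg",
            activation_amplitude=0.0,
            active_channels=(),
            latent_connectivity=latent,
            noise=NoiseSpec.silent(),
            background_sd=0.2,
        )
        from nirsnet import EventEntry, EventSchedule

        long_sched = EventSchedule(
            entries=[EventEntry(0.0, 2400.0, "rest")],
            segments={"resting": (0.0, 2400.0)},
        )
        rec, _ = simulate_subject(prof, montage, long_sched, seed=21)
        h = mbll_convert(optical_density(rec.intensity), fs=rec.fs)
        m = fc_matrix(h.hbo)
        iu = np.triu_indices(20, k=1)
        err = np.abs(m.values[iu] - latent[iu]).mean()
        assert err <= 0.05

    def test_non_psd_latent_rejected(self, montage, schedule):
        bad = uniform_connectivity(20, 0.5)
        bad[0, 1] = bad[1, 0] = -0.9
        with pytest.raises(ValueError, match="positive semi-definite"):
            GroupProfile(
                label="bad",
                activation_amplitude=0.1,
                active_channels=(0,),
                latent_connectivity=bad,
            )

    def test_low_sampling_rate_rejected(self, montage, schedule):
        prof = default_profiles()[0]
        with pytest.raises(ValueError, match="cannot represent"):
            simulate_subject(prof, montage, schedule, fs=2.0, seed=0)

    def test_empty_schedule_rejected(self, montage):
        from nirsnet import EventSchedule

        prof = default_profiles()[0]
        with pytest.raises(ValueError, match="empty"):
            simulate_subject(prof, montage, EventSchedule(entries=[]), seed=0)

    def test_noise_bands_lie_outside_analysis_band(self, montage, schedule):
        """With the default NoiseSpec, most noise power is outside
        0.026-0.15 Hz, so the band-pass raises the evoked-signal SNR."""
        prof = GroupProfile(
            label="noise",
            activation_amplitude=0.0,
            active_channels=(),
            latent_connectivity=uniform_connectivity(20, 0.0),
            background_sd=0.0,
        )
        rec, _ = simulate_subject(prof, montage, schedule, seed=8)
        h = mbll_convert(optical_density(rec.intensity), fs=rec.fs)
        f, pxx = spsig.welch(h.hbo[:, 0], fs=FS, nperseg=1024)
        in_band = (f >= 0.026) & (f <= 0.15)
        assert pxx[~in_band].sum() > pxx[in_band].sum()


class TestSimulateCohort:
    def test_counts_and_manifest(self, montage, short_schedule):
        profs = default_profiles()[:2]
        cohort = simulate_cohort(profs, 3, montage, short_schedule, seed=1)
        assert cohort.n_subjects == 6
        man = cohort.manifest()
        assert set(man["groups"]) == {"HC", "MCI-1"}
        listed = [s["seed"] for g in man["groups"].values() for s in g]
        assert len(listed) == 6

    def test_subject_seeds_distinct(self):
        seeds = {
            derive_subject_seed(0, label, i)
            for label in ("HC", "MCI-0", "MCI-1", "MCI-2")
            for i in range(11)
        }
        assert len(seeds) == 44
        assert all(0 <= s < 2**31 for s in seeds)

    def test_duplicate_labels_rejected(self, montage, short_schedule):
        p = default_profiles()[0]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort([p, p], 2, montage, short_schedule, seed=0)

    def test_minimum_group_size_enforced(self, montage, short_schedule):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_cohort(default_profiles()[:1], 1, montage, short_schedule, seed=0)

    def test_amplitude_ordering_recovered_downstream(self, montage, schedule):
        """HC (0.4 uM) vs MCI-0 (0.1 uM): the group difference in mean task
        dHbO is significant in a two-sample test (light version; the full
        Monte-Carlo power check runs with the acceptance suite)."""
        from nirsnet import block_average, preprocess_recording, two_sample_t

        profs = [p for p in default_profiles() if p.label in ("HC", "MCI-0")]
        cohort = simulate_cohort(profs, 5, montage, schedule, seed=4)
        means = {}
        for label, subs in cohort.groups.items():
            vals = []
            for rec, _ in subs:
                h = preprocess_recording(rec)
                ba = block_average(h.hbo, schedule, FS)
                tw = (ba.time >= 0) & (ba.time <= 24)
                vals.append(ba.mean[np.ix_(tw, list(profs[0].active_channels))].mean())
            means[label] = np.asarray(vals)
        assert means["HC"].mean() > means["MCI-0"].mean()
        assert two_sample_t(means["HC"], means["MCI-0"]).p < 0.01


class TestDefaultProfiles:
    def test_group_ordering_encoded(self):
        profs = {p.label: p for p in default_profiles()}
        amps = [profs[k].activation_amplitude for k in ("HC", "MCI-1", "MCI-2", "MCI-0")]
        assert amps == sorted(amps, reverse=True)
        mean_r = {
            k: profs[k].latent_connectivity[np.triu_indices(20, k=1)].mean()
            for k in profs
        }
        assert mean_r["HC"] > mean_r["MCI-1"] > mean_r["MCI-2"] > mean_r["MCI-0"]

    def test_latent_matrices_valid_correlations(self):
        for p in default_profiles():
            lat = p.latent_connectivity
            assert np.allclose(lat, lat.T)
            assert np.allclose(np.diag(lat), 1.0)
            assert np.linalg.eigvalsh(lat).min() > -1e-10
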