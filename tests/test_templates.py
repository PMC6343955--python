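"""Woody alignment, template projection, threshold calibration, and
sensory-template derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neopain import (
    BackgroundCalibration,
    EvokedTemplate,
    NoStimulusComponentError,
    SensoryTemplatePCA,
    TemplateProjector,
    calibrate_threshold,
    call_occurrence,
    detect_noxious_specific,
    make_noxious_template,
    project_template,
    synth_epoch,
    woody_align,
)
from neopain.preprocess import EpochedTrial
from neopain.templates import save_template, load_template

FS = 500.0


def woody_oracle(segment, reference, J):
    """Independent exhaustive-search Pearson alignment with the documented
    tie-break (smallest |shift|, then negative)."""
    L = len(reference)
    best_c, best_lag = -np.inf, 0
    # maximise correlation; ties -> smaller |lag|, then the negative one
    for lag in sorted(range(-J, J + 1), key=lambda s: (abs(s), s)):
        win = segment[J + lag : J + lag + L]
        if np.std(win) == 0 or np.std(reference) == 0:
            c = -np.inf
        else:
            c = np.corrcoef(win, reference)[0, 1]
        if c > best_c:
            best_c, best_lag = c, lag
    return best_lag


def make_trial(post, fs=FS, t_pre=1.0, channels=("Cz",)):
    """Single-channel trial whose post-stimulus part is ``post``."""
    n_pre = int(t_pre * fs)
    data = np.zeros((len(channels), n_pre + len(post)))
    data[0, n_pre:] = post
    times = np.arange(-n_pre, len(post)) / fs
    return EpochedTrial(
        data=data, times=times, fs=fs, stimulus="noxious", channels=list(channels)
    )


class TestWoody:
    def test_self_alignment_gives_zero_shift(self, nox_template):
        ref = nox_template.waveform
        J = 25
        seg = np.concatenate([np.zeros(J), ref, np.zeros(J)])
        aligned, shift = woody_align(seg, ref, FS, 50.0)
        assert shift == 0.0
        np.testing.assert_allclose(aligned, ref)

    @pytest.mark.parametrize("delay_ms", [20.0, -20.0])
    def test_known_delay_recovered_with_sign_convention(self, nox_template, delay_ms):
        # positive shift = data later than template
        ref = nox_template.waveform
        J = 25
        d = int(delay_ms / 1000 * FS)
        seg = np.zeros(ref.size + 2 * J)
        seg[J + d : J + d + ref.size] = ref
        _, shift = woody_align(seg, ref, FS, 50.0)
        assert shift == pytest.approx(delay_ms)

    def test_shift_saturates_at_jitter_boundary(self, nox_template):
        ref = nox_template.waveform
        J, d = 25, int(0.080 * FS)  # true delay 80 ms, jitter 50 ms
        seg = np.zeros(ref.size + 2 * J)
        place = J + d
        seg[place:] = ref[: seg.size - place]  # event 80 ms late, truncated
        _, shift = woody_align(seg, ref, FS, 50.0)
        assert abs(shift) == pytest.approx(50.0)

    def test_insufficient_context_rejected(self, nox_template):
        with pytest.raises(ValueError, match="too short"):
            woody_align(nox_template.waveform, nox_template.waveform, FS, 50.0)

    def test_alignment_never_worse_than_zero_shift(self, rng, nox_template):
        ref = nox_template.waveform
        J = 25
        for _ in range(50):
            seg = rng.standard_normal(ref.size + 2 * J)
            aligned, _ = woody_align(seg, ref, FS, 50.0)
            c_aligned = np.corrcoef(aligned, ref)[0, 1]
            c_zero = np.corrcoef(seg[J : J + ref.size], ref)[0, 1]
            assert c_aligned >= c_zero - 1e-12

    def test_matches_exhaustive_oracle_on_random_segments(self, rng, nox_template):
        ref = nox_template.waveform
        J = 25
        for _ in range(200):
            seg = rng.standard_normal(ref.size + 2 * J)
            _, shift = woody_align(seg, ref, FS, 50.0)
            assert int(shift / 1000 * FS) == woody_oracle(seg, ref, J)


class TestProjection:
    def test_zero_data_gives_zero_magnitude(self, nox_template):
        tr = make_trial(np.zeros(600))
        out = project_template(tr, nox_template)
        assert out.magnitude == 0.0

    def test_scaled_template_recovers_coefficient(self, nox_template):
        post = np.zeros(600)
        post[200:350] = 2.5 * nox_template.waveform  # exactly at 400-700 ms
        out = project_template(tr := make_trial(post), nox_template)
        assert out.shift_ms == 0.0
        assert out.magnitude == pytest.approx(2.5, abs=1e-9)

    def test_orthogonal_component_does_not_leak(self, rng, nox_template):
        # Gram-Schmidt-built orthogonal waveform; explicit inner-product
        # oracle (alignment held at zero shift so the algebra is exact)
        w = nox_template.waveform
        q = rng.standard_normal(w.size)
        q -= np.dot(q, w) * w
        q /= np.linalg.norm(q)
        post = np.zeros(600)
        post[200:350] = w + 0.5 * q
        out = project_template(make_trial(post), nox_template, max_jitter_ms=0.0)
        assert out.shift_ms == 0.0
        assert out.magnitude == pytest.approx(1.0, abs=1e-6)

    def test_linear_in_amplitude_at_fixed_shift(self, nox_template):
        post = np.zeros(600)
        post[200:350] = nox_template.waveform
        m1 = project_template(make_trial(post), nox_template)
        m3 = project_template(make_trial(3.0 * post), nox_template)
        assert m3.shift_ms == m1.shift_ms
        assert m3.magnitude == pytest.approx(3.0 * m1.magnitude, rel=1e-12)


class TestThreshold:
    def test_degenerate_distribution(self):
        cal = calibrate_threshold([4.2] * 12)
        assert cal.threshold == pytest.approx(4.2)

    def test_interpolated_percentile_of_one_to_ten(self):
        cal = calibrate_threshold(np.arange(1.0, 11.0), percentile=80)
        assert cal.threshold == pytest.approx(8.2)

    def test_too_few_backgrounds_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            calibrate_threshold([1.0, 2.0])

    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=10, max_size=60),
        st.floats(1.0, 99.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_sort_and_interpolate_oracle(self, mags, pct):
        cal = calibrate_threshold(mags, percentile=pct)
        srt = np.sort(np.asarray(mags, dtype=float))
        h = (len(srt) - 1) * pct / 100.0
        lo, frac = int(np.floor(h)), h - np.floor(h)
        oracle = srt[lo] + frac * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])
        assert cal.threshold == pytest.approx(oracle, rel=1e-12, abs=1e-9)

    @given(st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=10, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_duplicating_maximum_never_lowers_threshold(self, mags):
        base = calibrate_threshold(mags).threshold
        boosted = calibrate_threshold(list(mags) + [max(mags)]).threshold
        assert boosted >= base - 1e-12

    def test_occurrence_is_strictly_above(self):
        cal = BackgroundCalibration(magnitudes=np.arange(10.0), percentile=80.0)
        thr = cal.threshold
        assert not call_occurrence(thr, cal)
        assert call_occurrence(thr + 1e-9, cal)


class TestDetection:
    def test_zero_noise_mature_noxious_occurs(self, quiet_spec, cz_spec, nox_template):
        bg = [synth_epoch(cz_spec, "background", 4, seed=900 + i) for i in range(30)]
        proj = TemplateProjector(nox_template).fit(bg)
        tr = synth_epoch(quiet_spec, "noxious", 4, seed=1)
        out = proj.predict([tr])[0]
        assert out.occurred
        assert out.threshold_used == proj.threshold_

    def test_innocuous_mature_epoch_not_called_noxious(self, cz_spec, nox_template):
        bg = [synth_epoch(cz_spec, "background", 4, seed=900 + i) for i in range(60)]
        proj = TemplateProjector(nox_template).fit(bg)
        hits = 0
        for i in range(30):
            tr = synth_epoch(cz_spec, "innocuous", 4, seed=300 + i)
            if proj.predict([tr])[0].occurred:
                hits += 1
        # SEP energy lies outside the 400-700 ms window; call rate stays at
        # the background level, far below noxious sensitivity
        assert hits / 30 <= 0.4

    def test_detect_composition_equals_parts(self, cz_spec, nox_template):
        bg = [synth_epoch(cz_spec, "background", 4, seed=50 + i) for i in range(20)]
        mags = TemplateProjector(nox_template).fit(bg).background_magnitudes_
        cal = calibrate_threshold(mags)
        tr = synth_epoch(cz_spec, "noxious", 4, seed=7)
        direct = detect_noxious_specific(tr, nox_template, cal)
        manual = project_template(tr, nox_template)
        assert direct.magnitude == manual.magnitude
        assert direct.occurred == call_occurrence(manual.magnitude, cal)


class TestSensoryDerivation:
    def _trials(self, rng, coeffs, waveform, noise=0.02, fs=FS):
        trials = []
        for c in coeffs:
            post = rng.standard_normal(600) * noise
            post[50:150] += c * waveform  # 100-300 ms window
            trials.append(make_trial(post, fs=fs))
        return trials

    @staticmethod
    def _bump(fs=FS):
        t = np.arange(100) / fs
        w = np.exp(-((t - 0.1) ** 2) / (2 * 0.03**2))
        return w / np.linalg.norm(w)

    def test_planted_component_recovered(self, rng):
        w = self._bump()
        coeffs = np.r_[rng.uniform(3, 5, 12), rng.uniform(0.0, 0.2, 12)]
        labels = ["lance"] * 12 + ["background"] * 12
        tpl = SensoryTemplatePCA().fit(
            self._trials(rng, coeffs, w), labels
        ).template_
        assert abs(np.corrcoef(tpl.waveform, w)[0, 1]) > 0.95
        assert tpl.waveform[np.argmax(np.abs(tpl.waveform))] > 0

    def test_no_stimulus_structure_raises_selection_error(self, rng):
        # stimulated trials are exact copies of background trials, so no
        # component's weights can separate the groups
        bg = self._trials(rng, rng.uniform(1, 2, 10), self._bump(), noise=0.05)
        stim = [
            make_trial(tr.data[0, tr.stim_index :].copy()) for tr in bg
        ]
        with pytest.raises(NoStimulusComponentError):
            SensoryTemplatePCA().fit(bg + stim, ["background"] * 10 + ["lance"] * 10)

    def test_background_only_input_rejected(self, rng):
        trials = self._trials(rng, np.ones(10), self._bump())
        with pytest.raises(ValueError, match="background"):
            SensoryTemplatePCA().fit(trials, ["background"] * 10)

    def test_modality_linked_component_selected_over_larger_variance(self, rng):
        # two orthogonal planted components; the high-variance one is shared
        # by all trials, only the weaker one separates the modalities
        w1 = self._bump()
        t = np.arange(100) / FS
        w2 = np.sin(2 * np.pi * 25 * t)
        w2 -= np.dot(w2, w1) * w1
        w2 /= np.linalg.norm(w2)
        rng_local = np.random.default_rng(42)
        trials, labels = [], []
        for i in range(24):
            stimulated = i < 12
            a = rng_local.normal(0, 6.0)  # shared, dominates variance
            b = (3.0 if stimulated else 0.0) + rng_local.normal(0, 0.3)
            post = rng_local.standard_normal(600) * 0.02
            post[50:150] += a * w1 + b * w2
            trials.append(make_trial(post))
            labels.append("lance" if stimulated else "background")
        est = SensoryTemplatePCA().fit(trials, labels)
        assert abs(np.corrcoef(est.template_.waveform, w2)[0, 1]) > 0.95
        assert est.selected_component_ != 0  # second by variance, yet selected


def test_template_json_roundtrip(tmp_path, nox_template):
    p = tmp_path / "tpl.json"
    save_template(p, nox_template)
    back = load_template(p)
    np.testing.assert_allclose(back.waveform, nox_template.waveform)
    assert back.window_ms == nox_template.window_ms
    assert back.kind == nox_template.kind


def test_template_normalised_and_length_checked(fs):
    with pytest.raises(ValueError, match="length"):
        EvokedTemplate(np.ones(10), (400.0, 700.0), fs, "noxious_specific")
    t = EvokedTemplate(np.ones(150), (400.0, 700.0), fs, "noxious_specific")
    assert np.linalg.norm(t.waveform) == pytest.approx(1.0)
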