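"""Group statistics: t-tests, Bonferroni, peak measures, channel tables."""

import numpy as np
import pytest
from scipy import stats as sps

from p300sttc.simulate import p300_template
from p300sttc.stats import (
    bonferroni,
    channel_stats,
    peak_measures,
    subject_average,
    topography_values,
    ttest_ind,
)
from tests.conftest import make_epochs


class TestSubjectAverage:
    def test_single_trial_average_is_identity(self, rng):
        data = rng.standard_normal((3, 2, 20))
        ep = make_epochs(data, subject_ids=["a", "b", "c"])
        avg, subjects, _ = subject_average(ep)
        assert subjects == ["a", "b", "c"]
        assert np.allclose(avg, data)

    def test_duplicated_trials_unchanged(self, rng):
        x = rng.standard_normal((1, 2, 20))
        data = np.concatenate([x, x, x])
        ep = make_epochs(data, subject_ids=["a", "a", "a"])
        avg, _, _ = subject_average(ep)
        assert np.allclose(avg[0], x[0])

    def test_matches_loop(self, rng):
        data = rng.standard_normal((6, 2, 10))
        sids = ["a", "b", "a", "b", "a", "b"]
        ep = make_epochs(data, subject_ids=sids)
        avg, subjects, _ = subject_average(ep)
        for i, s in enumerate(subjects):
            manual = np.mean([data[j] for j in range(6) if sids[j] == s], axis=0)
            assert np.allclose(avg[i], manual)


class TestTTest:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p, d = ttest_ind(a, a)
        assert t == 0 and p == pytest.approx(1.0) and d == 0

    def test_shifted_samples_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        c = 1.7
        t, p, d = ttest_ind(a + c, a)
        sp = a.std(ddof=1)  # pooled sd equals either sample's sd here
        assert d == pytest.approx(c / sp)
        assert t == pytest.approx(c / (sp * np.sqrt(2 / 3)))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=4))

    def test_sign_convention_first_minus_second(self):
        t, _, d = ttest_ind([1.0, 2.0, 3.0], [5.0, 6.0, 7.0])
        assert t < 0 and d < 0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ttest_ind([1.0], [1.0, 2.0])

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_ind([2.0, 2.0], [3.0, 3.0])


class TestBonferroni:
    def test_direct_formula(self):
        out = bonferroni([0.004] + [0.5] * 9)
        assert out[0] == pytest.approx(0.04)

    def test_capped_at_one(self):
        assert np.all(bonferroni([0.5] * 10) == 1.0)

    def test_zero_stays_zero(self):
        assert np.all(bonferroni([0.0, 0.0]) == 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestPeakMeasures:
    def test_noiseless_template_latency(self):
        t = np.arange(-100, 600, 4.0)
        wave = p300_template(312.0, 5.0, 45.0, t)
        pm = peak_measures(wave[None, None, :], t)
        assert pm.latency[0, 0] == 312.0
        assert pm.amplitude[0, 0] == pytest.approx(5.0)

    def test_monotone_decreasing_picks_window_start(self):
        t = np.arange(-100, 600, 4.0)
        wave = -t  # strictly decreasing
        pm = peak_measures(wave[None, None, :], t, (250.0, 500.0))
        assert pm.latency[0, 0] == 252.0  # first sample inside the closed window

    def test_matches_argmax_loop(self, rng):
        t = np.arange(-100, 600, 4.0)
        avg = rng.standard_normal((3, 4, t.size))
        pm = peak_measures(avg, t, (250.0, 500.0))
        w = (t >= 250) & (t <= 500)
        for s in range(3):
            for c in range(4):
                k = np.argmax(avg[s, c, w])
                assert pm.latency[s, c] == t[w][k]
                assert pm.amplitude[s, c] == avg[s, c, w][k]

    def test_window_outside_axis_rejected(self, rng):
        t = np.arange(-100, 600, 4.0)
        with pytest.raises(ValueError):
            peak_measures(rng.standard_normal((1, 1, t.size)), t, (700, 900))


def _two_group_epochs(rng, effect=0.0, latency_shift=0.0, n_per_group=6, noise=1.0):
    """Per-subject single-trial epochs with an optional group effect at ch0."""
    t = np.arange(-100, 600, 4.0)
    data, sids, groups = [], [], []
    for g, (amp, lat) in (("PTSD", (2.0 - effect, 312.0 + latency_shift)),
                          ("HC", (2.0, 312.0))):
        for s in range(n_per_group):
            base = noise * rng.standard_normal((3, t.size))
            base[0] += p300_template(lat, amp, 45.0, t)
            data.append(base)
            sids.append(f"{g}{s}")
            groups.append(g)
    return make_epochs(np.array(data), subject_ids=sids, groups=groups)


class TestChannelStats:
    def test_identical_groups_rarely_significant(self, rng):
        ep = _two_group_epochs(rng, effect=0.0)
        table = channel_stats(ep)
        # null construction: corrected significance should be absent here
        assert table["significant_m"].sum() == 0

    def test_injected_effect_detected_at_negligible_noise(self, rng):
        # a sliver of noise keeps the pooled variance finite; the injected
        # amplitude/latency effects dominate it by orders of magnitude
        ep = _two_group_epochs(rng, effect=1.5, latency_shift=100.0, noise=0.01)
        table = channel_stats(ep).set_index("channel")
        assert bool(table.loc["ch0", "significant_m"])
        assert bool(table.loc["ch0", "significant_l"])
        # attenuated PTSD: negative t with the PTSD-minus-HC convention
        assert table.loc["ch0", "t_m"] < 0

    def test_column_layout(self, rng):
        table = channel_stats(_two_group_epochs(rng))
        for col in ("channel", "p_m", "t_m", "d_m", "p_a", "p_l"):
            assert col in table.columns

    def test_trial_permutation_invariance(self, rng):
        ep = _two_group_epochs(rng, effect=1.0)
        perm = rng.permutation(ep.n_trials)
        table1 = channel_stats(ep)
        table2 = channel_stats(ep.select(perm))
        assert np.allclose(table1["p_m"], table2["p_m"])
        assert np.allclose(table1["p_l"], table2["p_l"])

    def test_small_group_rejected(self, rng):
        ep = _two_group_epochs(rng, n_per_group=1)
        with pytest.raises(ValueError):
            channel_stats(ep)


class TestTopography:
    def test_identical_groups_near_zero_difference(self, rng):
        ep = _two_group_epochs(rng, effect=0.0, noise=0.0)
        tv = topography_values(ep)
        assert np.allclose(tv["difference"], 0.0, atol=1e-12)

    def test_attenuated_ptsd_gives_positive_difference(self, rng):
        ep = _two_group_epochs(rng, effect=1.0, noise=0.0)
        tv = topography_values(ep).set_index("channel")
        assert tv.loc["ch0", "difference"] > 0  # HC minus PTSD

    def test_matches_loop(self, rng):
        ep = _two_group_epochs(rng, effect=0.7)
        tv = topography_values(ep)
        avg, _, groups = subject_average(ep)
        groups = np.asarray(groups)
        w = (ep.t_axis >= 250) & (ep.t_axis <= 500)
        manual_hc = avg[groups == "HC"][:, :, w].mean(axis=(0, 2))
        assert np.allclose(tv["HC"], manual_hc)
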