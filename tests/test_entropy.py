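"""Unit tests for the phase-space entropy estimators."""

import math
import shutil
import subprocess

import numpy as np
import pytest

from rangeen import (
    EmbeddingConfig,
    TimeSeries,
    apen,
    chebyshev_distance,
    embed,
    match_counts,
    pairwise_distance_matrix,
    range_distance,
    rangeen_a,
    rangeen_b,
    sampen,
)

import reference


class TestEmbed:
    def test_windows_and_count(self):
        t = embed([1, 2, 3, 4], 2)
        assert t.templates.tolist() == [[1, 2], [2, 3], [3, 4]]
        assert len(t) == 3

    def test_m1_degenerate(self):
        t = embed(np.arange(7.0), 1)
        assert len(t) == 7
        assert t.templates.shape == (7, 1)

    def test_constant_signal(self):
        t = embed([5, 5, 5, 5, 5], 3)
        assert len(t) == 3
        assert np.all(t.templates == 5)

    def test_too_short_error_names_n_and_m(self):
        with pytest.raises(ValueError, match="N=3.*m=3"):
            embed([1.0, 2.0, 3.0], 3)


class TestDistances:
    def test_chebyshev_examples(self):
        assert chebyshev_distance((0, 0), (1, 3)) == 3
        assert chebyshev_distance((1.5, -2), (1.5, -2)) == 0

    def test_chebyshev_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            chebyshev_distance((0, 0), (1, 2, 3))

    def test_range_hand_example(self):
        # diffs (1, 3): (3 - 1) / (3 + 1)
        assert range_distance((0, 0), (1, 3)) == 0.5

    def test_range_equal_elementwise_diffs(self):
        assert range_distance((0, 0), (2, 2)) == 0.0

    def test_range_identical_undefined(self):
        assert range_distance((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)) is None

    def test_range_m2_reduces_to_simple_form(self, rng):
        for _ in range(50):
            a, b, c, d = rng.standard_normal(4)
            hi = max(abs(a - c), abs(b - d))
            lo = min(abs(a - c), abs(b - d))
            expected = None if hi + lo == 0 else (hi - lo) / (hi + lo)
            assert range_distance((a, b), (c, d)) == expected

    def test_range_offset_and_scale_invariance(self, rng):
        for _ in range(50):
            a = rng.standard_normal(4)
            b = rng.standard_normal(4)
            d = range_distance(a, b)
            # power-of-two scaling is bitwise exact in floating point
            assert range_distance(4.0 * a, 4.0 * b) == d
            assert range_distance(-0.5 * a, -0.5 * b) == d
            # offsets and general scalars are invariant to rounding error
            assert range_distance(a + 3.25, b + 3.25) == pytest.approx(d, rel=1e-12)
            assert range_distance(5.0 * a, 5.0 * b) == pytest.approx(d, rel=1e-12)

    def test_dimension_monotonicity_both_distances(self, rng):
        for _ in range(100):
            a = rng.standard_normal(5)
            b = rng.standard_normal(5)
            for m in (2, 3, 4):
                assert chebyshev_distance(a[: m + 1], b[: m + 1]) >= chebyshev_distance(
                    a[:m], b[:m]
                )
                d_lo = range_distance(a[:m], b[:m])
                d_hi = range_distance(a[: m + 1], b[: m + 1])
                assert d_hi >= d_lo


class TestMatchCounts:
    def test_constant_signal_chebyshev_all_match(self):
        t = embed([2.0] * 8, 2)
        mc = match_counts(t, r=0.0, distance="chebyshev", mode="include_self")
        assert np.all(mc.counts == len(t))

    def test_range_r_ge_1_exclude_self(self, rng):
        x = rng.standard_normal(30)
        t = embed(x, 2)
        mc = match_counts(t, r=1.0, distance="range", mode="exclude_self")
        assert np.all(mc.counts == len(t) - 1)

    def test_toy_set_matches_enumeration(self, rng):
        x = rng.standard_normal(12)
        t = embed(x, 3)
        temps = reference.naive_templates(list(x), 3)
        for r in (0.1, 0.4, 0.9):
            for distance, dist_fn in (
                ("chebyshev", reference.naive_chebyshev),
                ("range", reference.naive_range),
            ):
                mc = match_counts(t, r, distance, "exclude_self")
                for i, a in enumerate(temps):
                    expected = 0
                    for j, b in enumerate(temps):
                        if i == j:
                            continue
                        d = dist_fn(a, b)
                        if d is not None and d <= r:
                            expected += 1
                    assert mc.counts[i] == expected

    def test_counts_nondecreasing_in_r(self, rng):
        t = embed(rng.standard_normal(40), 2)
        grid = np.linspace(0.0, 1.2, 13)
        for distance in ("chebyshev", "range"):
            prev = None
            for r in grid:
                c = match_counts(t, r, distance, "include_self").counts
                if prev is not None:
                    assert np.all(c >= prev)
                prev = c

    def test_undefined_pairs_tallied(self):
        # duplicate templates: (1,2) appears twice
        t = embed([1.0, 2.0, 1.0, 2.0], 2)
        mc = match_counts(t, r=0.5, distance="range", mode="exclude_self")
        # off-diagonal undefined pairs: (0,2) and (2,0)
        assert mc.n_excluded_pairs == 2


class TestEstimators:
    def test_constant_signal_apen_sampen_zero(self):
        x = [3.0] * 12
        assert apen(x, m=2, r=0.5).value == 0.0
        assert sampen(x, m=2, r=0.5).value == 0.0

    def test_constant_signal_rangeen_undefined(self):
        x = [3.0] * 12
        assert rangeen_a(x, m=2, r=0.5).value is None
        assert rangeen_b(x, m=2, r=0.5).value is None

    def test_apen_always_defined(self, small_signals):
        for x in small_signals:
            for r in (0.0, 0.01, 0.2):
                assert apen(x, m=2, r=r).value is not None

    def test_sampen_nonnegative_when_defined(self, small_signals):
        for x in small_signals:
            ev = sampen(x, m=2, r=0.2)
            if ev.value is not None:
                assert ev.value >= 0
            ev = rangeen_b(x, m=2, r=0.3)
            if ev.value is not None:
                assert ev.value >= 0

    @pytest.mark.parametrize("m,r", [(1, 0.3), (2, 0.2), (3, 0.5)])
    def test_oracle_equivalence(self, small_signals, m, r):
        """All four estimators agree with the naive triple-loop reference."""
        for x in small_signals:
            xs = list(x)
            pairs = [
                (apen(x, m=m, r=r).value, reference.naive_apen(xs, m, r)),
                (sampen(x, m=m, r=r).value, reference.naive_sampen(xs, m, r)),
                (rangeen_a(x, m=m, r=r).value, reference.naive_rangeen_a(xs, m, r)),
                (rangeen_b(x, m=m, r=r).value, reference.naive_rangeen_b(xs, m, r)),
            ]
            for got, want in pairs:
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, rel=1e-12)

    def test_sd_correction_equals_prescaling(self, rng):
        x = 7.3 * rng.standard_normal(60) + 2.0
        scaled = x / x.std()
        assert apen(x, m=2, r=0.2, sd_correction=True).value == pytest.approx(
            apen(scaled, m=2, r=0.2).value, rel=1e-12
        )
        assert sampen(x, m=2, r=0.2, sd_correction=True).value == pytest.approx(
            sampen(scaled, m=2, r=0.2).value, rel=1e-12
        )

    def test_rangeen_terminal_zero(self, rng):
        x = rng.standard_normal(200)
        assert rangeen_a(x, m=2, r=1.0).value == 0.0
        assert rangeen_b(x, m=2, r=1.0).value == 0.0

    def test_rangeen_scale_invariance_exact(self, rng):
        x = rng.standard_normal(100)
        for c in (5.0, 0.1, 4.0):
            assert rangeen_a(c * x, m=2, r=0.3).value == rangeen_a(x, m=2, r=0.3).value
            assert rangeen_b(c * x, m=2, r=0.3).value == rangeen_b(x, m=2, r=0.3).value

    def test_rangeen_a_undefined_at_tiny_r_matches_bruteforce(self, rng):
        """At very small r some templates have no neighbour: the fast
        path and a brute-force census agree on how many."""
        x = rng.standard_normal(40)
        r = 1e-4
        from numpy.lib.stride_tricks import sliding_window_view
        from rangeen.entropy import TemplateSet

        t = TemplateSet(sliding_window_view(np.asarray(x), 2), 2, len(x))
        dm = pairwise_distance_matrix(t, "range")
        fast_zero = int(np.sum(np.count_nonzero(dm <= r, axis=1) == 0))
        temps = reference.naive_templates(list(x), 2)
        slow_zero = 0
        for i, a in enumerate(temps):
            cnt = 0
            for j, b in enumerate(temps):
                d = reference.naive_range(a, b)
                if d is not None and d <= r:
                    cnt += 1
            slow_zero += cnt == 0
        assert fast_zero == slow_zero > 0
        assert rangeen_a(x, m=2, r=r).value is None

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            apen([1.0, 2.0, 3.0], m=2, r=0.2)
        with pytest.raises(ValueError, match="too short"):
            rangeen_b([1.0, 2.0, 3.0], m=2, r=0.2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EmbeddingConfig(m=0)
        with pytest.raises(ValueError):
            EmbeddingConfig(r=-0.1)
        with pytest.raises(ValueError):
            EmbeddingConfig(delay=2)

    def test_timeseries_validation(self):
        with pytest.raises(ValueError, match="finite"):
            TimeSeries(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            TimeSeries(np.array([]))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_cross_check_against_pracma(tmp_path):
    """ApEn and SampEn agree with R pracma's independent implementations."""
    rng = np.random.default_rng(2024)
    x = np.round(rng.standard_normal(80), 6)
    sig = tmp_path / "sig.txt"
    sig.write_text("\n".join(f"{v:.6f}" for v in x) + "\n")
    script = tmp_path / "check.R"
    script.write_text(
        "library(pracma)\n"
        f"x <- scan('{sig}')\n"
        "cat(sprintf('%.12f %.12f', sample_entropy(x, edim=2, r=0.2, tau=1),"
        " approx_entropy(x, edim=2, r=0.2)))\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    r_sampen, r_apen = map(float, out.stdout.split())
    assert sampen(x, m=2, r=0.2).value == pytest.approx(r_sampen, abs=1e-10)
    assert apen(x, m=2, r=0.2).value == pytest.approx(r_apen, abs=1e-10)
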