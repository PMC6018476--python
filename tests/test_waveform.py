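"""Synthetic TCD trace generation, statistics, scaling and round trip."""

import numpy as np
import pytest

from hemolat.waveform import (
    TraceFormatError,
    VelocityTrace,
    extract_cycle_stats,
    read_trace,
    scale_trace,
    synth_cardiac_waveform,
    write_trace,
)


def test_jitter_free_trace_contract():
    """Without jitter or noise, every cycle is exactly mean_cycle long and
    the global maximum equals the requested peak exactly."""
    tr = synth_cardiac_waveform(
        peak_velocity=1.50, n_cycles=6, mean_cycle=0.894,
        cycle_jitter_sd=0.0, quantization_noise=0.0, seed=1,
    )
    stats = extract_cycle_stats(tr)
    assert stats.mean_cycle_length == pytest.approx(0.894, abs=1e-12)
    assert stats.min_cycle_length == pytest.approx(stats.max_cycle_length, abs=1e-12)
    assert stats.vmax == 1.50
    assert tr.velocities.max() == 1.50


def test_inflow_regime_trace():
    """Peak 1.50 m/s / mean cycle 0.894 s (the measured inflow regime)."""
    tr = synth_cardiac_waveform(peak_velocity=1.50, n_cycles=6,
                                mean_cycle=0.894, seed=7)
    stats = extract_cycle_stats(tr)
    assert stats.vmax == pytest.approx(1.50, abs=1e-9)
    assert stats.min_cycle_length <= stats.mean_cycle_length <= stats.max_cycle_length
    assert abs(stats.mean_cycle_length - 0.894) < 0.15


def test_determinism_same_seed():
    a = synth_cardiac_waveform(seed=42, quantization_noise=0.0064)
    b = synth_cardiac_waveform(seed=42, quantization_noise=0.0064)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.velocities, b.velocities)
    c = synth_cardiac_waveform(seed=43, quantization_noise=0.0064)
    assert not np.array_equal(a.velocities, c.velocities)


def test_quantization_noise_bounded():
    clean = synth_cardiac_waveform(seed=5, cycle_jitter_sd=0.0)
    noisy = synth_cardiac_waveform(seed=5, cycle_jitter_sd=0.0,
                                   quantization_noise=0.0064)
    assert np.all(np.abs(noisy.velocities - clean.velocities) <= 0.0064)


def test_generator_mean_cycle_statistics():
    """Over 200 seeded realizations with 0.05 s jitter, the empirical mean
    cycle length is within 2 standard errors of the requested mean."""
    means = []
    for seed in range(200):
        tr = synth_cardiac_waveform(n_cycles=6, mean_cycle=0.894,
                                    cycle_jitter_sd=0.05, seed=seed)
        means.append(extract_cycle_stats(tr).mean_cycle_length)
    se = 0.05 / np.sqrt(6 * 200)
    assert abs(np.mean(means) - 0.894) < 2 * se


def test_parameter_validation():
    with pytest.raises(ValueError):
        synth_cardiac_waveform(diastolic_fraction=1.5)
    with pytest.raises(ValueError):
        synth_cardiac_waveform(peak_velocity=-1.0)
    with pytest.raises(ValueError):
        synth_cardiac_waveform(n_cycles=0)


def test_extract_stats_from_explicit_marks():
    """Cycle marks at 0, 0.87, 1.842 s give lengths 0.870 and 0.972."""
    times = np.array([0.0, 0.4, 0.87, 1.3, 1.842])
    tr = VelocityTrace(times=times, velocities=np.full(5, 1.0),
                       cycle_marks=np.array([0, 2, 4]))
    stats = extract_cycle_stats(tr)
    assert stats.min_cycle_length == pytest.approx(0.870)
    assert stats.max_cycle_length == pytest.approx(0.972)


def test_extract_stats_needs_two_marks():
    tr = VelocityTrace(times=np.array([0.0, 1.0]), velocities=np.ones(2),
                       cycle_marks=np.array([0]))
    with pytest.raises(ValueError, match="two cycle marks"):
        extract_cycle_stats(tr)


def test_scale_trace_halving_and_inverse():
    tr = synth_cardiac_waveform(peak_velocity=1.50, seed=3, cycle_jitter_sd=0.0)
    half = scale_trace(tr, 0.5)
    assert half.velocities.max() == pytest.approx(0.75)
    assert np.array_equal(half.times, tr.times)
    back = scale_trace(half, 2.0)
    assert np.allclose(back.velocities, tr.velocities, rtol=1e-15)
    with pytest.raises(ValueError):
        scale_trace(tr, 0.0)


def test_write_read_round_trip(tmp_path):
    tr = synth_cardiac_waveform(seed=11, quantization_noise=0.0064,
                                depth_label="63 mm")
    path = tmp_path / "trace.tsv"
    write_trace(tr, path)
    back = read_trace(path)
    assert np.array_equal(back.times, tr.times)
    assert np.array_equal(back.velocities, tr.velocities)
    assert np.array_equal(back.cycle_marks, tr.cycle_marks)
    assert back.depth_label == "63 mm"


def test_read_rejects_missing_header(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("1.0\t2.0\n3.0\t4.0\n")
    with pytest.raises(TraceFormatError, match="header"):
        read_trace(path)


def test_read_rejects_non_monotone_times(tmp_path):
    path = tmp_path / "bad2.tsv"
    path.write_text("time_s\tvelocity_m_s\n0.0\t1.0\n0.5\t1.0\n0.4\t1.0\n")
    with pytest.raises(TraceFormatError, match="monotone"):
        read_trace(path)


def test_cycle_stats_table_export(tmp_path):
    """Stats for several depths export as a labelled delimited table."""
    import pandas as pd

    from hemolat.waveform import write_cycle_stats

    stats = {}
    for depth, peak in [("49", 1.43), ("63 (inflow)", 1.50)]:
        tr = synth_cardiac_waveform(peak_velocity=peak, n_cycles=6,
                                    cycle_jitter_sd=0.0, seed=2)
        stats[depth] = extract_cycle_stats(tr)
    path = tmp_path / "table1.tsv"
    write_cycle_stats(stats, path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    assert list(df.columns) == ["49", "63 (inflow)"]
    assert df.loc["vmaxTCD [m/s]", "49"] == pytest.approx(1.43)
    assert "Mean cycle length [s]" in df.index


def test_sample_count_arithmetic():
    """Six 0.9 s cycles at 100 Hz produce ~540 samples (+1 closing)."""
    tr = synth_cardiac_waveform(n_cycles=6, mean_cycle=0.9,
                                cycle_jitter_sd=0.0, sample_rate=100.0, seed=0)
    assert len(tr) == 6 * 90 + 1
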