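"""Binned densities, normalization, peak calling, interval masses, comparison."""

import numpy as np
import pytest

from distalblock import Component, SyntheticSpec, sample_ensemble
from distalblock.exceptions import (
    EmptyProfileError,
    NormalizationError,
    UndefinedRatioError,
)
from distalblock.profiles import (
    Peak,
    build_hist2d,
    build_pdf,
    compare_sets,
    find_peaks,
    interval_mass,
    normalize_by_reference,
    population_ratio,
)
from distalblock.structure_io import extract_records, records_to_frame


def test_build_pdf_hand_arithmetic():
    """Three lengths in one 0.05 A bin: count 3, density 3/(3*0.05) = 20."""
    p = build_pdf([5.21, 5.23, 5.24], 0.05, feature="dblock")
    assert p.counts.tolist() == [3]
    assert p.edges == pytest.approx([5.20, 5.25])
    assert p.density == pytest.approx([20.0])


def test_build_pdf_angle_boundary_and_grid():
    p = build_pdf([359.999, 0.0, 2.5], 5.0, feature="phi", limits=(0.0, 360.0))
    assert p.counts.size == 72
    assert p.counts[71] == 1   # 359.999 in [355, 360)
    assert p.counts[0] == 2
    assert p.counts.sum() == p.n_total == 3


def test_build_pdf_uniform_grid_equal_densities():
    values = np.arange(2.5, 360.0, 5.0)  # one per bin
    p = build_pdf(values, 5.0, limits=(0.0, 360.0))
    assert np.all(p.counts == 1)
    assert np.allclose(p.density, p.density[0])
    assert p.density.sum() * p.bin_width == pytest.approx(1.0)


def test_build_pdf_empty_raises():
    with pytest.raises(EmptyProfileError):
        build_pdf([], 5.0)
    with pytest.raises(EmptyProfileError):
        build_pdf([float("nan")], 5.0)


def test_build_pdf_permutation_invariant():
    rng = np.random.default_rng(0)
    values = rng.uniform(3.0, 7.0, 500)
    p1 = build_pdf(values, 0.05)
    p2 = build_pdf(rng.permutation(values), 0.05)
    assert np.array_equal(p1.counts, p2.counts)


def test_normalize_reference_peaks_at_exactly_one():
    p = build_pdf([1.0, 1.0, 1.6, 2.3], 0.5)
    t, r = normalize_by_reference(p, p, ref_id="self")
    assert r.values.max() == 1.0  # exact, not approximate
    assert np.array_equal(t.values, r.values)


def test_normalize_target_can_exceed_one():
    # target concentrates all mass where the reference has half its mass
    ref = build_pdf([1.1, 1.1, 1.6, 1.6], 0.5)
    tgt = build_pdf([1.1, 1.1, 1.1, 1.1], 0.5)
    t, r = normalize_by_reference(tgt, ref)
    assert r.values.max() == 1.0
    assert t.values.max() == pytest.approx(2.0)


def test_normalize_requires_matching_grids():
    a = build_pdf([1.0], 0.5)
    b = build_pdf([1.0], 0.25)
    with pytest.raises(ValueError):
        normalize_by_reference(a, b)


def test_normalize_zero_reference_rejected():
    p = build_pdf([1.0], 0.5)
    zero = type(p)(feature=p.feature, bin_width=p.bin_width, anchor=p.anchor,
                   edges=p.edges, counts=np.zeros_like(p.counts), n_total=1)
    with pytest.raises(NormalizationError):
        normalize_by_reference(p, zero)


def test_hist2d_single_conformation_single_cell():
    h = build_hist2d([298.0] * 7, [5.71] * 7)
    assert h.counts.sum() == 7
    assert h.ratio.max() == 1.0
    assert (h.ratio > 0).sum() == 1


def test_hist2d_population_ratio_arithmetic():
    # 50 observations in one cell, 9 in another: ratio 18%
    phi = [300.0] * 50 + [60.0] * 9
    dbl = [5.7] * 50 + [5.7] * 9
    h = build_hist2d(phi, dbl)
    modal = h.modal_cell
    other = (int(60.0 // 5), modal[1])
    assert population_ratio(h, other) == pytest.approx(0.18)
    assert population_ratio(h, modal) == 1.0
    empty = (0, 0)
    assert population_ratio(h, empty) == 0.0


def test_population_ratio_empty_denominator():
    h = build_hist2d([10.0, 20.0], [5.0, 5.0])
    empty_cell = (0, 0)  # in-grid but unpopulated
    assert h.counts[empty_cell] == 0
    with pytest.raises(UndefinedRatioError):
        population_ratio(h, h.modal_cell, empty_cell)


def test_hist2d_empty_raises():
    with pytest.raises(EmptyProfileError):
        build_hist2d([], [])
    with pytest.raises(EmptyProfileError):
        build_hist2d([np.nan], [5.0])


def test_find_peaks_edge_cases():
    assert find_peaks(np.ones(6)) == [Peak(0.0, 1.0)]          # flat: leftmost
    assert find_peaks(np.arange(5.0)) == [Peak(4.0, 4.0)]      # monotone: max
    plateau = np.array([0.0, 2.0, 2.0, 1.0, 0.0])
    assert find_peaks(plateau) == [Peak(1.0, 2.0)]             # leftmost of tie


def test_find_peaks_prominence_threshold():
    vals = np.array([0.0, 1.0, 0.98, 1.01, 0.0])  # middle dip of 3% only
    peaks = find_peaks(vals, min_prominence=0.05)
    assert len(peaks) == 1 and peaks[0].center == 3.0  # global max always kept
    peaks = find_peaks(vals, min_prominence=0.01)
    assert len(peaks) == 2


def test_find_peaks_orders_by_height():
    vals = np.array([0.0, 3.0, 0.0, 5.0, 0.0, 4.0, 0.0])
    centers = [p.center for p in find_peaks(vals)]
    assert centers == [3.0, 5.0, 1.0]


def test_find_peaks_recovers_mixture_modes(block_table):
    """Two-component ensemble: peaks land within one 0.05 A bin of the
    sigma=0 component lengths."""
    comps = [Component(-62, -41, (180, 180, 180, 180), 0.5, 5.0),
             Component(-62, -41, (180, 180, 60, 180), 0.5, 5.0)]
    ideal = [sample_ensemble(SyntheticSpec("LYS", [Component(-62, -41, c.chis)],
                                           1, 1))[1]["dblock"][0]
             for c in comps]
    assert abs(ideal[0] - ideal[1]) >= 0.4
    spec = SyntheticSpec("LYS", comps, n_samples=4000, seed=5)
    _, truth = sample_ensemble(spec)
    pdf = build_pdf(truth["dblock"], 0.05, feature="dblock")
    npdf, _ = normalize_by_reference(pdf, pdf)
    peaks = find_peaks(npdf)
    assert len(peaks) == 2
    for target in ideal:
        assert min(abs(p.center - target) for p in peaks) <= 0.05


def test_interval_mass():
    values = np.arange(0.025, 1.0, 0.05)  # uniform, one per bin over (0, 1)
    p = build_pdf(values, 0.05)
    assert interval_mass(p, 0.0, 1.0) == pytest.approx(1.0)
    assert interval_mass(p, 0.0, 0.5) == pytest.approx(0.5)
    assert interval_mass(p, 2.0, 3.0) == 0.0
    # partial bin split proportionally
    assert interval_mass(p, 0.0, 0.025) == pytest.approx(0.025)
    with pytest.raises(ValueError):
        interval_mass(p, 1.0, 0.5)


def _lys_frame(components, n, seed, block_table):
    spec = SyntheticSpec("LYS", components, n_samples=n, seed=seed)
    structures, _ = sample_ensemble(spec)
    return records_to_frame(
        [r for s in structures
         for r in extract_records([s], block_table, "sim")])


def test_compare_sets_identical_sets_no_exceedance(block_table):
    frame = _lys_frame([Component(-62, -41, (180, 180, 180, 180), 1.0, 5.0)],
                       600, 21, block_table)
    report = compare_sets(frame, frame, "LYS")
    assert report.comparable
    assert report.exceedance == []
    fc = report.features["dblock"]
    assert np.array_equal(fc.npdf_a.values, fc.npdf_b.values)


def test_compare_sets_shifted_mixture_reports_exceedance(block_table):
    trans = Component(-62, -41, (180, 180, 180, 180), 1.0, 5.0)
    frame_a = _lys_frame([trans], 1500, 31, block_table)
    folded = Component(-62, -41, (180, 180, 60, 180), 0.4, 5.0)
    frame_b = _lys_frame([Component(-62, -41, (180, 180, 180, 180), 0.6, 5.0),
                          folded], 1500, 32, block_table)
    report = compare_sets(frame_a, frame_b, "LYS")
    assert report.exceedance
    shifted_mode = _lys_frame([Component(-62, -41, folded.chis)], 1, 1,
                              block_table)["dblock"][0]
    assert any(e.lo - 0.05 <= shifted_mode <= e.hi + 0.05
               for e in report.exceedance)
    covering = [e for e in report.exceedance
                if e.lo - 0.05 <= shifted_mode <= e.hi + 0.05]
    assert all(e.mass_b > e.mass_a for e in covering)
    # B moved mass off A's mode, so B's npdf at the mode is below 1
    fc = report.features["dblock"]
    mode_bin = int(np.argmax(fc.npdf_a.values))
    assert fc.npdf_b.values[mode_bin] < 1.0


def test_compare_sets_missing_residue_type(block_table):
    frame = _lys_frame([Component(-62, -41, (180, 180, 180, 180))], 5, 1,
                       block_table)
    report = compare_sets(frame, frame[frame["res_type"] == "GLY"], "LYS")
    assert not report.comparable
    assert "absent" in report.reason
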