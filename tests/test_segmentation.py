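"""Segmentation chain: quality gate, vessel handling, filtering, Canny and
boundary tracing accuracy/invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octinl import (
    AcquisitionModel,
    BScan,
    PhantomSpec,
    QualityThresholds,
    canny_boundaries,
    detect_vessel_shadows,
    make_layer_geometry,
    multiscale_median_filter,
    quality_check,
    remove_vessels,
    render_bscan,
    segment_bscan,
)
from octinl.sampling import sample_grid
from octinl.protocol import RadialProtocol

from conftest import BOUNDARIES, FOVEAL_EXCLUSION_UM


@pytest.fixture(scope="module")
def phantom():
    return make_layer_geometry(seed=0)


@pytest.fixture(scope="module")
def full_acq():
    """Full-width acquisition for the per-column specificity checks."""
    return AcquisitionModel(ascan_count=1536, depth_px=320)


# ---------------------------------------------------------------------------
# quality gate


class TestQualityGate:
    def test_good_scan_passes(self, phantom, acq):
        scan, _, _ = render_bscan(phantom, 0, acq, seed=0)
        rep = quality_check(scan)
        assert rep.passed
        assert rep.snr_db > 25.0
        assert rep.centration_offset_um < 100.0
        assert 0.9 < rep.brightness_uniformity < 1.1

    def test_noise_raised_to_20db_fails(self, phantom):
        """Raise the vitreous background until the SNR estimator reads
        ~20 dB; the 25 dB gate must then fail the scan."""
        lo, hi = 0.05, 0.6
        snr = None
        for _ in range(30):
            bg = 0.5 * (lo + hi)
            acq_noisy = AcquisitionModel(
                ascan_count=384, depth_px=176, background_level=bg
            )
            ph = make_layer_geometry(
                PhantomSpec(reflectivity={**phantom.layer_reflectivity,
                                          "vitreous": bg}),
                seed=0,
            )
            scan, _, _ = render_bscan(ph, 0, acq_noisy, seed=1)
            snr = quality_check(scan).snr_db
            if snr > 20.0:
                lo = bg
            else:
                hi = bg
            if abs(snr - 20.0) < 0.5:
                break
        assert abs(snr - 20.0) < 1.5
        rep = quality_check(scan)
        assert not rep.passed

    def test_displaced_pit_fails_centration(self, acq):
        ph = make_layer_geometry(PhantomSpec(fovea_center_um=1000.0), seed=0)
        scan, _, _ = render_bscan(ph, 0, acq, seed=0)
        rep = quality_check(scan, QualityThresholds(centration_limit_um=500.0))
        assert rep.centration_offset_um > 800.0
        assert not rep.passed

    def test_zero_background_variance_gives_inf_snr(self):
        img = np.full((80, 64), 0.02)
        img[40:70, :] = 0.8
        scan = BScan(pixels=img, axial_um_per_px=3.9, lateral_um_per_px=11.7)
        rep = quality_check(scan)
        assert rep.snr_db == np.inf


# ---------------------------------------------------------------------------
# vessel shadows


class TestVesselShadows:
    def test_clean_scan_flags_nothing(self, phantom, acq_clean):
        scan, _, _ = render_bscan(phantom, 0, acq_clean, seed=0)
        assert len(detect_vessel_shadows(scan)) == 0

    def test_injected_shadows_recalled_with_low_false_rate(self, phantom, full_acq):
        shadows = ((-1500.0, 35.0, 0.5), (400.0, 30.0, 0.5), (1200.0, 40.0, 0.5))
        scan, _, _ = render_bscan(phantom, 0, full_acq, seed=3, shadows=shadows)
        flagged = np.zeros(full_acq.ascan_count, dtype=bool)
        flagged[detect_vessel_shadows(scan)] = True
        x = full_acq.x_um()
        gt = np.zeros_like(flagged)
        for x0, w, _ in shadows:
            gt |= np.abs(x - x0) <= w / 2
        assert (flagged & gt).sum() / gt.sum() >= 0.90
        assert (flagged & ~gt).sum() / (~gt).sum() <= 0.01

    def test_gain_invariance(self, phantom, full_acq):
        shadows = ((600.0, 40.0, 0.5),)
        scan, _, _ = render_bscan(phantom, 0, full_acq, seed=3, shadows=shadows)
        scaled = BScan(
            pixels=np.clip(scan.pixels * 0.7, 0, 1),
            axial_um_per_px=scan.axial_um_per_px,
            lateral_um_per_px=scan.lateral_um_per_px,
        )
        assert np.array_equal(
            detect_vessel_shadows(scan), detect_vessel_shadows(scaled)
        )


class TestRemoveVessels:
    def _ramp_scan(self):
        ramp = np.tile(np.linspace(0.1, 0.9, 64), (48, 1))
        return BScan(pixels=ramp, axial_um_per_px=3.9, lateral_um_per_px=11.7)

    def test_empty_set_is_identity(self):
        scan = self._ramp_scan()
        out = remove_vessels(scan, np.array([], dtype=int))
        assert np.array_equal(out.pixels, scan.pixels)

    def test_linear_ramp_restored_exactly(self):
        scan = self._ramp_scan()
        out = remove_vessels(scan, np.array([20]))
        assert np.allclose(out.pixels[:, 20], scan.pixels[:, 20], atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 62), min_size=1, max_size=10, unique=True))
    def test_unflagged_columns_bit_identical(self, cols):
        scan = self._ramp_scan()
        rng = np.random.default_rng(0)
        noisy = BScan(
            pixels=np.clip(scan.pixels + rng.normal(0, 0.05, scan.pixels.shape),
                           0, 1),
            axial_um_per_px=3.9,
            lateral_um_per_px=11.7,
        )
        out = remove_vessels(noisy, np.array(cols))
        good = np.setdiff1d(np.arange(64), cols)
        assert np.array_equal(out.pixels[:, good], noisy.pixels[:, good])

    def test_edge_run_nearest_neighbour(self):
        scan = self._ramp_scan()
        out = remove_vessels(scan, np.array([0, 1]))
        assert np.allclose(out.pixels[:, 0], scan.pixels[:, 2])


# ---------------------------------------------------------------------------
# filtering and edges


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((32, 32), 0.4)
        assert np.array_equal(multiscale_median_filter(img), img)

    def test_impulse_removed(self):
        img = np.full((32, 32), 0.2)
        img[16, 16] = 1.0
        out = multiscale_median_filter(img, sizes=(3,))
        assert out[16, 16] == 0.2

    def test_sequential_composition(self):
        rng = np.random.default_rng(0)
        img = np.clip(
            np.tile((np.arange(64) > 32).astype(float), (48, 1))
            + rng.normal(0, 0.2, (48, 64)),
            0,
            1,
        )
        combined = multiscale_median_filter(img, sizes=(3, 7))
        stepwise = multiscale_median_filter(
            multiscale_median_filter(img, sizes=(3,)), sizes=(7,)
        )
        assert np.array_equal(combined, stepwise)

    @pytest.mark.parametrize("sizes", [(4,), (2, 3), ((3, 4),), (1,)])
    def test_bad_sizes_rejected(self, sizes):
        with pytest.raises(ValueError):
            multiscale_median_filter(np.zeros((8, 8)), sizes=sizes)


class TestCanny:
    def test_single_step_edge_localized(self):
        img = np.zeros((64, 48))
        img[30:, :] = 0.8
        edges = canny_boundaries(img)
        rows = np.nonzero(edges)[0]
        assert len(rows) > 0
        assert np.all(np.abs(rows - 29.5) <= 1.5)

    def test_constant_image_empty(self):
        assert not canny_boundaries(np.full((32, 32), 0.3)).any()

    def test_phantom_boundary_coverage(self, phantom, acq_clean):
        """>= 95 % of columns of every boundary have an edge within 2 px."""
        scan, truth, _ = render_bscan(phantom, 0, acq_clean, seed=0)
        edges = canny_boundaries(scan.pixels)
        x = acq_clean.x_um()
        keep = np.abs(x) > FOVEAL_EXCLUSION_UM
        rows = np.arange(scan.depth_px)[:, None]
        for name in BOUNDARIES:
            d = truth[name]
            near = (np.abs(rows - d[None, :] + 0.5) <= 2.0) & edges
            covered = near.any(axis=0)[keep]
            assert covered.mean() >= 0.95, name


# ---------------------------------------------------------------------------
# tracing


class TestTracing:
    def test_ordering_invariant_everywhere(self, seg_batch):
        # ordering is asserted inside LayerBoundaries construction; here we
        # re-check the traced output of the whole batch explicitly
        for label in ("clean", "speckle"):
            errs, _ = seg_batch[label]
            assert (errs.mae_px >= 0).all()

    def test_noise_free_accuracy(self, seg_batch):
        errs, _ = seg_batch["clean"]
        per_boundary = errs.groupby("boundary").mae_px.mean()
        assert (per_boundary <= 1.0).all(), per_boundary
        assert errs.max_px.max() <= 3.0

    def test_speckle_accuracy(self, seg_batch):
        errs, _ = seg_batch["speckle"]
        per_boundary = errs.groupby("boundary").mae_px.mean()
        assert (per_boundary <= 2.0).all(), per_boundary

    def test_gain_invariance_of_boundaries(self, phantom, acq):
        scan, _, _ = render_bscan(phantom, 0, acq, seed=4)
        base = segment_bscan(scan)
        for gain in (0.5, 1.5):
            scaled = BScan(
                pixels=np.clip(scan.pixels * gain, 0, 1),
                axial_um_per_px=scan.axial_um_per_px,
                lateral_um_per_px=scan.lateral_um_per_px,
            )
            other = segment_bscan(scaled)
            for name in BOUNDARIES:
                mad = np.abs(other.depths[name] - base.depths[name]).mean()
                assert mad <= 1.0, (gain, name, mad)

    def test_vessel_robustness_on_grid(self, phantom, acq):
        """5 injected shadows change 36-point thickness by <= 2 um RMS."""
        from octinl import render_eye

        protocol = RadialProtocol()
        shadows = tuple(
            (x0, 40.0, 0.5) for x0 in (-1700.0, -900.0, 700.0, 1300.0, 1900.0)
        )
        grids = {}
        for label, sh in (("clean", None), ("shadowed", [shadows] * 6)):
            scans, _, _ = render_eye(
                phantom, acq, seed=11, shadows_per_slice=sh
            )
            lbs = [segment_bscan(s) for s in scans]
            grids[label] = sample_grid(
                lbs, protocol, acq.axial_um_per_px, acq.lateral_um_per_px
            ).table
        merged = grids["clean"].merge(
            grids["shadowed"],
            on=["line", "ecc_index", "ecc_um", "layer"],
            suffixes=("_a", "_b"),
        )
        diff = merged.thickness_um_a - merged.thickness_um_b
        rms = float(np.sqrt((diff**2).mean()))
        assert rms <= 2.0, rms

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_tracing_never_crosses_on_noise(self, seed):
        """Pure-noise input: tracing stays ordered and in-bounds (it may be
        meaningless, but it must be well-formed)."""
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (96, 128))
        scan = BScan(pixels=img, axial_um_per_px=3.9, lateral_um_per_px=11.7)
        lb = segment_bscan(scan)
        d = lb.depths
        assert np.all(d["ILM"] <= d["RNFL_GCLIPL"] + 1e-9)
        assert np.all(d["RNFL_GCLIPL"] <= d["GCLIPL_INL"] + 1e-9)
        assert np.all(d["GCLIPL_INL"] <= d["INL_OPL"] + 1e-9)
        for name in BOUNDARIES:
            assert d[name].min() >= 0 and d[name].max() <= 96
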