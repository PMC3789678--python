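"""Thickness grid sampling: exactness, completeness, mirroring, rotation,
and end-to-end recovery against generator truth."""

import numpy as np
import pandas as pd
import pytest

from octinl import (
    PhantomSpec,
    RadialProtocol,
    eye_summary,
    make_layer_geometry,
    render_eye,
    sample_grid,
    segment_bscan,
)
from octinl.sampling import LAYER_PAIRS, grid_truth_from_phantom
from octinl.segmentation import LayerBoundaries

from conftest import LAYERS


def _flat_boundaries(n_cols=384, ilm=60.0, rnfl=8.0, gcl=25.0, inl=10.0):
    """Synthetic perfectly-flat traced boundaries (no segmentation involved)."""
    ones = np.ones(n_cols)
    return LayerBoundaries(
        depths={
            "ILM": ilm * ones,
            "RNFL_GCLIPL": (ilm + rnfl) * ones,
            "GCLIPL_INL": (ilm + rnfl + gcl) * ones,
            "INL_OPL": (ilm + rnfl + gcl + inl) * ones,
        },
        provenance=np.zeros(n_cols, dtype=bool),
        failed={n: False for n in
                ("ILM", "RNFL_GCLIPL", "GCLIPL_INL", "INL_OPL")},
        fovea_column=(n_cols - 1) / 2,
    )


def test_constant_thickness_sampled_exactly():
    protocol = RadialProtocol()
    lbs = [_flat_boundaries() for _ in range(6)]
    grid = sample_grid(lbs, protocol, 3.9, 11.71875)
    assert len(grid.table) == 36 * 3
    for layer, px in (("RNFL", 8.0), ("GCLIPL", 25.0), ("INL", 10.0)):
        vals = grid.layer_values(layer)
        assert len(vals) == 36
        assert np.allclose(vals, px * 3.9, atol=1e-9)


def test_grid_complete_and_beyond_edge_invalid():
    protocol = RadialProtocol(eccentricities_um=(750.0, 1500.0, 2250.0))
    lbs = [_flat_boundaries(n_cols=120) for _ in range(6)]  # short scan
    grid = sample_grid(lbs, protocol, 3.9, 11.71875)
    pairs = grid.table.groupby(["line", "ecc_index"]).ngroups
    assert pairs == 36
    # 120 columns cover only ~703 um per half-line: everything is off-scan
    assert not grid.table.valid.any()


def test_eye_summary_masking_and_exclusion():
    protocol = RadialProtocol()
    lbs = [_flat_boundaries() for _ in range(6)]
    grid = sample_grid(lbs, protocol, 3.9, 11.71875)
    t = grid.table
    assert eye_summary(grid).analyzable
    # invalidate one point -> mean over the remaining 35
    mask = (t.line == 1) & (t.ecc_index == 1)
    t.loc[mask, "valid"] = False
    s = eye_summary(grid)
    assert s.n_invalid == 1 and s.analyzable
    assert np.isclose(s.mean_um["RNFL"], 8.0 * 3.9)
    # invalidate 7 points -> fewer than 30 remain -> unanalyzable
    for line in range(2, 8):
        t.loc[(t.line == line) & (t.ecc_index == 1), "valid"] = False
    assert not eye_summary(grid).analyzable


def test_left_eye_mirrored_to_template(acq_clean):
    """An OS scan set yields the same per-line values as the OD rendering
    of the same asymmetric phantom."""
    scale = np.ones(12)
    scale[[4, 5, 6, 7, 8]] = 0.6  # nasal GCL/IPL loss on the template
    ph = make_layer_geometry(
        PhantomSpec(line_scale={"GCLIPL": scale}, undulation_frac=0.0), seed=0
    )
    protocol = ph.protocol
    grids = {}
    for lat in ("OD", "OS"):
        scans, _, _ = render_eye(ph, acq_clean, seed=1, laterality=lat)
        lbs = [segment_bscan(s) for s in scans]
        grids[lat] = sample_grid(
            lbs, protocol, acq_clean.axial_um_per_px,
            acq_clean.lateral_um_per_px, laterality=lat,
        ).table
    m = grids["OD"].merge(
        grids["OS"], on=["line", "ecc_index", "ecc_um", "layer"],
        suffixes=("_od", "_os"),
    )
    assert np.allclose(m.thickness_um_od, m.thickness_um_os, atol=1.0)
    # and nasal GCL/IPL really is thinner than temporal on both
    g = grids["OD"]
    gcl = g[g.layer == "GCLIPL"]
    nasal = gcl[gcl.line.isin([5, 6, 7, 8, 9])].thickness_um.mean()
    temporal = gcl[gcl.line.isin([11, 12, 1, 2, 3])].thickness_um.mean()
    assert nasal < 0.75 * temporal


def test_rotational_consistency():
    """Rotating the thickness field by 30 deg permutes grid entries by one
    line index without changing the multiset of values (1 um tolerance)."""
    rng_scale = 1.0 + 0.3 * np.sin(np.arange(12) * 2.6)
    base = make_layer_geometry(
        PhantomSpec(line_scale={"GCLIPL": rng_scale}, undulation_frac=0.0),
        seed=0,
    )
    rolled = make_layer_geometry(
        PhantomSpec(line_scale={"GCLIPL": np.roll(rng_scale, 1)},
                    undulation_frac=0.0),
        seed=0,
    )
    t_base = grid_truth_from_phantom(base)
    t_roll = grid_truth_from_phantom(rolled)
    for layer in LAYERS:
        a = t_base[t_base.layer == layer]
        b = t_roll[t_roll.layer == layer]
        for ecc in (750.0, 1500.0, 2250.0):
            va = a[a.ecc_um == ecc].set_index("line").thickness_um
            vb = b[b.ecc_um == ecc].set_index("line").thickness_um
            for line in range(1, 13):
                rolled_line = line % 12 + 1
                assert abs(vb[rolled_line] - va[line]) <= 1.0


def test_end_to_end_grid_recovery(seg_batch):
    """Sampled grids match generator truth within 2 um RMS; near-unbiased."""
    _, grids = seg_batch["speckle"]
    rms = float(np.sqrt((grids.err_um**2).mean()))
    assert rms <= 2.0, rms
    signed = grids.groupby("layer").err_um.mean()
    assert (signed.abs() <= 1.0).all(), signed


def test_cohort_mean_recovery(seg_batch):
    """Noise-free batch: per-layer grid means recover phantom targets closely."""
    _, grids = seg_batch["clean"]
    bias = grids.groupby("layer").err_um.mean()
    assert (bias.abs() <= 0.5).all(), bias
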