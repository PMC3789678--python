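"""Shared fixtures: reduced-size acquisition models and cached batches of
rendered + segmented phantoms reused across accuracy tests.

Images are rendered at 384 A-scans x 176 depth pixels (full 4.5 mm radial
geometry, coarser lateral sampling) so the accuracy suites stay fast;
boundary errors are expressed in pixels and thickness errors in um, both of
which are meaningful at this scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from octinl import (
    AcquisitionModel,
    CystSpec,
    PhantomSpec,
    RadialProtocol,
    inject_cysts_into_eye,
    make_layer_geometry,
    render_eye,
    segment_bscan,
    sample_grid,
    detect_microcysts,
    merge_eye_cysts,
)
from octinl.render import random_shadows
from octinl.sampling import grid_truth_from_phantom

TEST_ASCANS = 384
TEST_DEPTH = 176

#: columns within this distance of the fovea are excluded from accuracy
#: evaluation (the protocol itself excludes the central points because the
#: inner layers converge and are indistinct there)
FOVEAL_EXCLUSION_UM = 600.0

BOUNDARIES = ("ILM", "RNFL_GCLIPL", "GCLIPL_INL", "INL_OPL")
LAYERS = ("RNFL", "GCLIPL", "INL")


@pytest.fixture(scope="session")
def acq() -> AcquisitionModel:
    return AcquisitionModel(ascan_count=TEST_ASCANS, depth_px=TEST_DEPTH)


@pytest.fixture(scope="session")
def acq_clean() -> AcquisitionModel:
    return AcquisitionModel(
        ascan_count=TEST_ASCANS, depth_px=TEST_DEPTH, speckle_shape=None
    )


def _phantom_for_seed(seed: int):
    """Phantoms spanning healthy to severely thinned anatomy."""
    rng = np.random.default_rng(seed)
    frac = seed / 19 if seed < 20 else rng.random()
    targets = {
        "RNFL": 32.2 - frac * (32.2 - 22.7) + rng.normal(0, 1.0),
        "GCLIPL": 98.1 - frac * (98.1 - 54.2) + rng.normal(0, 3.0),
        "INL": 39.6 + frac * (53.8 - 39.6) + rng.normal(0, 1.5),
    }
    targets = {k: max(v, 5.0) for k, v in targets.items()}
    return make_layer_geometry(PhantomSpec(target_um=targets), seed=seed)


def _evaluate_phantom(phantom, acq_model, seed):
    """Render + segment all slices; per-boundary errors and the sampled grid."""
    protocol = phantom.protocol
    scans, truths, _ = render_eye(phantom, acq_model, seed=seed)
    lbs = [segment_bscan(s) for s in scans]
    x = acq_model.x_um()
    keep = np.abs(x) > FOVEAL_EXCLUSION_UM
    err_rows = []
    for k, (lb, truth) in enumerate(zip(lbs, truths)):
        for name in BOUNDARIES:
            e = (lb.depths[name] - truth[name])[keep]
            err_rows.append(
                {"slice": k, "boundary": name,
                 "mae_px": float(np.abs(e).mean()),
                 "max_px": float(np.abs(e).max()),
                 "bias_px": float(e.mean())}
            )
    grid = sample_grid(
        lbs, protocol, acq_model.axial_um_per_px, acq_model.lateral_um_per_px
    )
    truth_grid = grid_truth_from_phantom(phantom, protocol)
    merged = grid.table.merge(
        truth_grid, on=["line", "ecc_index", "ecc_um", "layer"],
        suffixes=("", "_true"),
    )
    merged["err_um"] = merged.thickness_um - merged.thickness_um_true
    return pd.DataFrame(err_rows), merged


@pytest.fixture(scope="session")
def seg_batch(acq, acq_clean):
    """20 seeded phantoms rendered noise-free and at default speckle.

    Returns ``{"clean": (errors, grids), "speckle": (errors, grids)}`` with
    ``errors`` a per-(phantom, slice, boundary) DataFrame and ``grids`` the
    concatenated sampled-vs-true grid tables.
    """
    out = {}
    for label, model in (("clean", acq_clean), ("speckle", acq)):
        err_frames, grid_frames = [], []
        for seed in range(20):
            phantom = _phantom_for_seed(seed)
            errs, grid = _evaluate_phantom(phantom, model, seed=1000 + seed)
            errs["phantom"] = seed
            grid["phantom"] = seed
            err_frames.append(errs)
            grid_frames.append(grid)
        out[label] = (
            pd.concat(err_frames, ignore_index=True),
            pd.concat(grid_frames, ignore_index=True),
        )
    return out


@pytest.fixture(scope="session")
def cyst_eyes(acq):
    """Six seeded severely-affected eyes with injected microcysts.

    Returns per-eye dicts with plans, rendered scans, truth masks, traced
    boundaries and merged detections.
    """
    eyes = []
    severe = {"RNFL": 22.7, "GCLIPL": 54.2, "INL": 53.8}
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        phantom = make_layer_geometry(PhantomSpec(target_um=severe), seed=seed)
        phantom, plans = inject_cysts_into_eye(phantom, CystSpec(), rng)
        shadows = [random_shadows(rng) for _ in range(6)]
        scans, truths, masks = render_eye(
            phantom, acq, seed=200 + seed, cysts=plans, shadows_per_slice=shadows
        )
        lbs = [segment_bscan(s) for s in scans]
        sets = [detect_microcysts(s, lb) for s, lb in zip(scans, lbs)]
        eyes.append(
            {
                "phantom": phantom,
                "plans": plans,
                "scans": scans,
                "truth": truths,
                "masks": masks,
                "boundaries": lbs,
                "detections": merge_eye_cysts(sets),
            }
        )
    return eyes
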