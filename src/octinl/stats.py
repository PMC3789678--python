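"""Cohort-level statistics: group comparisons, correlations, inter-eye
asymmetry and the 36-point topographic deviation analysis.

Conventions (also stated in every output header):

* group t-tests are unpaired two-sample Student tests with pooled variance
  (Welch available as an option), two-sided, no multiple-testing correction;
* the asymmetry of a layer is (affected-eye mean - fellow-eye mean) in um,
  so a thinner affected-eye GCL/IPL yields a negative delta;
* topographic deviations are control - affected for RNFL and GCL/IPL
  (thinning positive) and affected - control for the INL (increase
  positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

LAYERS = ("RNFL", "GCLIPL", "INL")


@dataclass
class TTestResult:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    note: str = ""


def group_compare(
    a, b, equal_var: bool = True
) -> TTestResult:
    """Two-sample Student t-test (pooled variance by default) on per-eye means.

    Two identical zero-variance samples report t=0, p=1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 eyes per group")
    note = ""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(
                float(a.mean()), 0.0, len(a), float(b.mean()), 0.0, len(b),
                0.0, 1.0, note="zero variance in both groups; p=1 by convention",
            )
        note = "zero variance in both groups"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        float(res.statistic), float(res.pvalue), note,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t transform.

    Raises on zero variance in either vector (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# asymmetry analysis


@dataclass
class AsymmetryResult:
    records: pd.DataFrame  # subject, dRNFL_um, dGCLIPL_um, dINL_um, has_cysts
    r: float | None
    p: float | None
    n_excluded_binocular: int
    n_dropped_missing_fellow: int
    note: str = ""


def asymmetry_analysis(eye_table: pd.DataFrame) -> AsymmetryResult:
    """Per-subject affected-minus-fellow differences and their correlation.

    ``eye_table`` needs one row per eye with columns ``subject``, ``role``
    ("ON"/"fellow"), ``binocular``, ``has_cysts`` and ``<layer>_um`` means.
    Binocular subjects are excluded; subjects missing a fellow eye are
    dropped with a count.  The headline statistic is Pearson's r between
    the GCL/IPL and INL asymmetries; with zero-variance differences it is
    reported as undefined (None), not fabricated.
    """
    on = eye_table[eye_table.role == "ON"].set_index("subject")
    fellow = eye_table[eye_table.role == "fellow"].set_index("subject")
    n_binoc = int(on.binocular.sum()) if "binocular" in on else 0
    eligible = on[~on.binocular] if "binocular" in on else on
    common = eligible.index.intersection(fellow.index)
    dropped = len(eligible) - len(common)
    rows = []
    for sid in common:
        rows.append(
            {
                "subject": sid,
                **{
                    f"d{l}_um": float(eligible.loc[sid, f"{l}_um"]
                                      - fellow.loc[sid, f"{l}_um"])
                    for l in LAYERS
                },
                "has_cysts": bool(eligible.loc[sid, "has_cysts"])
                if "has_cysts" in eligible
                else False,
            }
        )
    rec = pd.DataFrame(rows)
    if len(rec) < 3:
        raise ValueError("need at least 3 eligible subjects for asymmetry analysis")
    try:
        r, p = pearson_r(rec.dGCLIPL_um, rec.dINL_um)
        note = ""
    except ValueError as e:
        r = p = None
        note = f"correlation undefined: {e}"
    return AsymmetryResult(rec, r, p, n_binoc, dropped, note)


# ---------------------------------------------------------------------------
# topographic deviation analysis


@dataclass
class DeviationResult:
    table: pd.DataFrame  # line, ecc_um, layer, deviation_um, n_control, n_on
    r: float | None
    p: float | None
    n_points: int
    quadrant_means: pd.DataFrame  # layer x quadrant mean deviation
    sign_convention: str = (
        "RNFL/GCLIPL deviation = control - affected (thinning positive); "
        "INL deviation = affected - control (increase positive)"
    )


def pointwise_deviation(
    control_grids: pd.DataFrame,
    on_grids: pd.DataFrame,
    protocol=None,
    min_eyes: int = 2,
) -> DeviationResult:
    """36-point topographic group deviation map and its cross-layer coupling.

    Inputs are long-format grid tables over eyes (columns ``subject``,
    ``line``, ``ecc_um``, ``layer``, ``thickness_um``, ``valid``).  Points
    with fewer than ``min_eyes`` valid eyes in either group are dropped from
    the cross-layer correlation (and reported via ``n_points``).
    The correlation pairs GCL/IPL thinning with INL increase over the grid
    points, using signed differences.
    """
    if protocol is None:
        from .protocol import RadialProtocol

        protocol = RadialProtocol()

    def point_means(df):
        v = df[df.valid]
        g = v.groupby(["line", "ecc_um", "layer"]).thickness_um.agg(["mean", "count"])
        return g

    gc = point_means(control_grids)
    go = point_means(on_grids)
    rows = []
    for key in sorted(set(gc.index) & set(go.index)):
        line, ecc, layer = key
        mc, nc = gc.loc[key]
        mo, no = go.loc[key]
        if nc < min_eyes or no < min_eyes:
            continue
        dev = (mc - mo) if layer in ("RNFL", "GCLIPL") else (mo - mc)
        rows.append(
            {
                "line": int(line),
                "ecc_um": float(ecc),
                "layer": layer,
                "deviation_um": float(dev),
                "n_control": int(nc),
                "n_on": int(no),
                "quadrant": protocol.quadrant_of_line(int(line)),
                "nasal": protocol.is_nasal(int(line)),
            }
        )
    table = pd.DataFrame(rows)
    piv = table.pivot_table(
        index=["line", "ecc_um"], columns="layer", values="deviation_um"
    )
    r = p = None
    n_points = 0
    if {"GCLIPL", "INL"} <= set(piv.columns):
        both = piv[["GCLIPL", "INL"]].dropna()
        n_points = len(both)
        if n_points >= 3 and both.GCLIPL.std() > 0 and both.INL.std() > 0:
            r, p = pearson_r(both.GCLIPL, both.INL)
    quad = (
        table.groupby(["layer", "quadrant"]).deviation_um.mean().unstack()
        if len(table)
        else pd.DataFrame()
    )
    return DeviationResult(table, r, p, n_points, quad)


# ---------------------------------------------------------------------------
# covariates and subgroups


def covariate_correlation(eye_table: pd.DataFrame, covariate: str,
                          layer: str = "INL") -> tuple[float, float]:
    """Pearson correlation of a layer's per-eye mean against a covariate."""
    on = eye_table[eye_table.role == "ON"]
    if on[covariate].isna().any():
        raise ValueError(f"covariate {covariate} missing for some subjects")
    return pearson_r(on[f"{layer}_um"], on[covariate])


@dataclass
class SubgroupResult:
    per_layer: dict[str, TTestResult]
    r_full: float | None
    p_full: float | None
    r_excluding: float | None
    p_excluding: float | None
    n_positive: int
    n_negative: int
    note: str = ""


def subgroup_compare(eye_table: pd.DataFrame) -> SubgroupResult:
    """Cyst-positive vs cyst-negative affected eyes, plus correlation stability.

    Splits affected eyes by ``has_cysts``, compares each layer with the
    pooled-variance t-test, and re-runs the GCL/IPL-INL correlation over
    affected eyes with and without the cyst-positive eyes — both from the
    same immutable table.  A subgroup of size 1 is refused (insufficient n).
    """
    on = eye_table[eye_table.role == "ON"]
    pos = on[on.has_cysts]
    neg = on[~on.has_cysts]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both subgroups must be non-empty")
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"insufficient n for subgroup comparison (positive={len(pos)}, "
            f"negative={len(neg)})"
        )
    per_layer = {
        l: group_compare(pos[f"{l}_um"], neg[f"{l}_um"]) for l in LAYERS
    }

    def safe_r(df):
        try:
            return pearson_r(df.GCLIPL_um, df.INL_um)
        except ValueError:
            return None, None

    r_full, p_full = safe_r(on)
    r_excl, p_excl = safe_r(neg)
    return SubgroupResult(
        per_layer, r_full, p_full, r_excl, p_excl, len(pos), len(neg)
    )


def layer_correlations(eye_table: pd.DataFrame, role: str) -> pd.DataFrame:
    """All pairwise layer-mean correlations within one eye role/group."""
    sel = eye_table[eye_table.role == role]
    rows = []
    pairs = [("RNFL", "GCLIPL"), ("RNFL", "INL"), ("GCLIPL", "INL")]
    for a, b in pairs:
        r, p = pearson_r(sel[f"{a}_um"], sel[f"{b}_um"])
        rows.append({"layer_a": a, "layer_b": b, "r": r, "p": p, "n": len(sel)})
    return pd.DataFrame(rows)
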