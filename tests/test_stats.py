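"""Cohort statistics: textbook-formula oracles, hand fixtures, asymmetry,
topographic deviation, covariates and subgroup bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from octinl import (
    RadialProtocol,
    asymmetry_analysis,
    covariate_correlation,
    group_compare,
    pearson_r,
    pointwise_deviation,
    subgroup_compare,
)
from octinl.stats import LAYERS


# --- independent textbook oracles ------------------------------------------


def pooled_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


# --- t-test ------------------------------------------------------------------


def test_hand_fixture_t_statistic():
    res = group_compare([1, 2, 3], [4, 5, 6])
    assert res.t == pytest.approx(-3.674, abs=5e-4)


def test_identical_groups_t0_p1():
    res = group_compare([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    assert res.t == 0.0 and res.p == 1.0
    assert "convention" in res.note


def test_t_matches_oracle_on_random_fixtures():
    rng = np.random.default_rng(0)
    for _ in range(100):
        a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(3, 40))
        b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(3, 40))
        res = group_compare(a, b)
        assert res.t == pytest.approx(pooled_t_oracle(a, b), rel=1e-10)


def test_group_separation_recovered():
    """Groups drawn from distinct INL distributions: means recovered within
    0.5 um and the test rejects at alpha = 0.01."""
    rng = np.random.default_rng(1)
    ctrl = rng.normal(39.6, 3.0, 500)
    on = rng.normal(42.9, 6.0, 500)
    res = group_compare(ctrl, on)
    assert abs(res.mean_a - 39.6) < 0.5
    assert abs(res.mean_b - 42.9) < 0.5
    assert res.p < 0.01


# --- Pearson r ---------------------------------------------------------------


def test_perfect_linear_r_is_1():
    x = np.arange(10.0)
    r, p = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)


def test_hand_fixture_r_06():
    r, _ = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
    assert r == pytest.approx(0.6, abs=1e-12)


def test_null_correlation_is_small():
    rng = np.random.default_rng(2)
    r, _ = pearson_r(rng.normal(size=10_000), rng.normal(size=10_000))
    assert abs(r) < 0.03


def test_zero_variance_raises():
    with pytest.raises(ValueError, match="zero variance"):
        pearson_r([1.0, 1.0, 1.0], [1, 2, 3])


def test_r_matches_oracle_on_random_fixtures():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(3, 50))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + rng.uniform(-1, 1) * x
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), rel=1e-10, abs=1e-12)


# --- asymmetry ---------------------------------------------------------------


def _eye_table(on_vals, fellow_vals, has_cysts=None, binocular=None):
    rows = []
    n = len(on_vals)
    has_cysts = has_cysts or [False] * n
    binocular = binocular or [False] * n
    for i in range(n):
        for role, vals in (("ON", on_vals), ("fellow", fellow_vals)):
            rows.append(
                {
                    "subject": f"P{i}",
                    "role": role,
                    "RNFL_um": vals[i][0],
                    "GCLIPL_um": vals[i][1],
                    "INL_um": vals[i][2],
                    "has_cysts": has_cysts[i] and role == "ON",
                    "binocular": binocular[i],
                }
            )
    return pd.DataFrame(rows)


def test_identical_eyes_give_undefined_correlation():
    vals = [(30.0 + i, 90.0 - i, 40.0) for i in range(5)]
    res = asymmetry_analysis(_eye_table(vals, vals))
    assert np.allclose(res.records[["dRNFL_um", "dGCLIPL_um", "dINL_um"]], 0.0)
    assert res.r is None and "undefined" in res.note


def test_binocular_subjects_excluded():
    rng = np.random.default_rng(0)
    on = [tuple(rng.normal([28, 69, 43], 1)) for _ in range(6)]
    fellow = [tuple(rng.normal([32, 98, 40], 1)) for _ in range(6)]
    res = asymmetry_analysis(
        _eye_table(on, fellow, binocular=[True] + [False] * 5)
    )
    assert res.n_excluded_binocular == 1
    assert len(res.records) == 5


def test_asymmetry_recovers_generative_coupling():
    """Delta-model cohort with corr(dGCLIPL, dINL) = -0.75 at n = 200:
    the recovered r lies inside the exact 95% CI of the target."""
    from octinl.cohort import CohortSpec, draw_paired_eyes

    spec = CohortSpec(
        n_per_group=200,
        eye_model="delta",
        delta_sds={"RNFL": 4.0, "GCLIPL": 10.0, "INL": 4.0},
        delta_corr=[[1.0, 0.6, -0.5], [0.6, 1.0, -0.75], [-0.5, -0.75, 1.0]],
        rng_seed=4,
    )
    on, fellow = draw_paired_eyes(spec, 200, np.random.default_rng(4))
    table = _eye_table([tuple(v) for v in on], [tuple(v) for v in fellow])
    res = asymmetry_analysis(table)
    z = np.arctanh(res.r)
    half = 1.96 / np.sqrt(200 - 3)
    assert np.arctanh(-0.75) == pytest.approx(z, abs=half)


def test_cyst_exclusion_rerun_is_reproducible():
    rng = np.random.default_rng(5)
    n = 40
    on = [tuple(rng.normal([28, 69, 43], [2, 8, 4])) for _ in range(n)]
    fellow = [tuple(rng.normal([32, 98, 40], [2, 5, 3])) for _ in range(n)]
    cysts = [i < 5 for i in range(n)]
    table = _eye_table(on, fellow, has_cysts=cysts)
    res_all = asymmetry_analysis(table)
    res_neg = asymmetry_analysis(
        pd.concat([
            table[(table.subject.isin([f"P{i}" for i in range(5, n)]))]
        ])
    )
    # both values are computable and the re-run is bit-identical
    again = asymmetry_analysis(table)
    assert res_all.r == again.r
    assert res_neg.r is not None and res_all.r is not None


# --- topographic deviation ---------------------------------------------------


def _grid_table(values_by_line_ecc, subjects, layer_values):
    """Build a long grid table; layer_values(line, ecc, layer, subj) -> um."""
    protocol = RadialProtocol()
    rows = []
    for s in subjects:
        for line, j, ecc in protocol.grid_points():
            for layer in LAYERS:
                rows.append(
                    {
                        "subject": s,
                        "line": line,
                        "ecc_um": ecc,
                        "layer": layer,
                        "thickness_um": layer_values(line, ecc, layer, s),
                        "valid": True,
                    }
                )
    return pd.DataFrame(rows)


def test_identical_groups_zero_deviation():
    f = lambda line, ecc, layer, s: {"RNFL": 32.0, "GCLIPL": 98.0, "INL": 40.0}[layer]
    g = _grid_table(None, ["a", "b", "c"], f)
    res = pointwise_deviation(g, g.copy())
    assert np.allclose(res.table.deviation_um, 0.0)
    assert res.r is None  # zero variance -> no correlation reported


def test_constructed_linear_coupling_gives_r_minus_1():
    """INL increase built proportional to GCL/IPL loss point-by-point."""
    rng = np.random.default_rng(0)
    loss = {
        (line, ecc): rng.uniform(5, 30)
        for line, _, ecc in RadialProtocol().grid_points()
    }

    def ctrl(line, ecc, layer, s):
        return {"RNFL": 32.0, "GCLIPL": 98.0, "INL": 40.0}[layer]

    def on(line, ecc, layer, s):
        if layer == "GCLIPL":
            return 98.0 - loss[(line, ecc)]
        if layer == "INL":
            return 40.0 + 0.3 * loss[(line, ecc)]
        return 28.0

    gc = _grid_table(None, ["c1", "c2"], ctrl)
    go = _grid_table(None, ["p1", "p2"], on)
    res = pointwise_deviation(gc, go)
    assert res.n_points == 36
    assert res.r == pytest.approx(1.0, abs=0.01)  # thinning vs increase align
    # signed deviations: thinning positive, increase positive
    t = res.table
    assert (t[t.layer == "GCLIPL"].deviation_um > 0).all()
    assert (t[t.layer == "INL"].deviation_um > 0).all()


def test_nasal_only_loss_shows_nasal_temporal_asymmetry():
    nasal = {4, 5, 6, 7, 8, 9}

    def ctrl(line, ecc, layer, s):
        return {"RNFL": 32.0, "GCLIPL": 98.0, "INL": 40.0}[layer]

    def on(line, ecc, layer, s):
        if layer == "GCLIPL" and line in nasal:
            return 70.0
        return ctrl(line, ecc, layer, s)

    res = pointwise_deviation(
        _grid_table(None, ["c1", "c2"], ctrl), _grid_table(None, ["p1", "p2"], on)
    )
    t = res.table[res.table.layer == "GCLIPL"]
    assert t[t.nasal].deviation_um.mean() > t[~t.nasal].deviation_um.mean() + 20


# --- covariates and subgroups ------------------------------------------------


def _summaries(n=40, seed=0, cysts=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append(
            {
                "subject": f"P{i}",
                "role": "ON",
                "RNFL_um": rng.normal(28, 4),
                "GCLIPL_um": rng.normal(69, 14),
                "INL_um": rng.normal(43, 6),
                "has_cysts": i < cysts,
                "duration_on_to_oct_months": rng.gamma(1.3, 38),
            }
        )
    return pd.DataFrame(rows)


def test_covariate_self_correlation_and_null():
    df = _summaries(n=1000, seed=1)
    df["self"] = df.INL_um
    r, _ = covariate_correlation(df, "self")
    assert r == pytest.approx(1.0)
    r_null, _ = covariate_correlation(df, "duration_on_to_oct_months")
    assert abs(r_null) < 0.07


def test_constant_covariate_raises():
    df = _summaries(n=20, seed=2)
    df["const"] = 51.0
    with pytest.raises(ValueError, match="zero variance"):
        covariate_correlation(df, "const")


def test_subgroup_sign_recovery_and_bookkeeping():
    rng = np.random.default_rng(3)
    df = _summaries(n=36, seed=3, cysts=5)
    # cyst-positive eyes drawn from a thicker-INL stratum
    df.loc[df.has_cysts, "INL_um"] = rng.normal(53.8, 6, 5)
    df.loc[df.has_cysts, "GCLIPL_um"] = rng.normal(54.2, 6, 5)
    res = subgroup_compare(df)
    assert res.per_layer["INL"].mean_a > res.per_layer["INL"].mean_b
    assert res.n_positive == 5 and res.n_negative == 31
    assert res.r_full is not None and res.r_excluding is not None
    again = subgroup_compare(df)
    assert res.r_full == again.r_full and res.r_excluding == again.r_excluding


def test_subgroup_size_one_refused():
    df = _summaries(n=10, seed=4, cysts=1)
    with pytest.raises(ValueError, match="insufficient n"):
        subgroup_compare(df)


def test_subgroup_null_false_positive_rate():
    """Identical strata: non-significant INL difference in >= 90 % of
    seeded replicates at n = 36."""
    hits = 0
    reps = 200
    for seed in range(reps):
        df = _summaries(n=36, seed=1000 + seed, cysts=5)
        res = subgroup_compare(df)
        hits += res.per_layer["INL"].p >= 0.05
    assert hits / reps >= 0.90
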