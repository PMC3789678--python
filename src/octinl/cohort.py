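"""Paired-eye cohort simulation with configurable group statistics.

Per-subject layer thickness targets (RNFL, GCL/IPL, INL) are drawn from a
group-specific multivariate normal (truncated at 1 um) with configurable
means, SDs and inter-layer correlation; affected-eye/fellow-eye pairs are
coupled by one of two models:

``shared_latent``
    both eyes share a fraction ``eye_coupling`` of their latent variance,
    so the within-subject correlation of each layer across eyes equals
    ``eye_coupling`` (with coupling 1 and identical eye specs the two eyes
    are identical draws);
``delta``
    the fellow eye is drawn from its own distribution and the affected eye
    is fellow + a correlated difference, which puts the inter-eye
    *asymmetry* correlation structure directly under control (useful when
    the asymmetry correlation itself is the generative target).

A fixed fraction of affected eyes receives INL microcysts: the count is
deterministic (``round(prevalence x n)``), the assignment is random under
the seed.  Optionally every eye is rendered into a radial scan set with
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import MEASURED_LAYERS, PhantomSpec, RetinaPhantom, make_layer_geometry
from .protocol import RadialProtocol
from .render import (
    AcquisitionModel,
    CystPlan,
    CystSpec,
    inject_cysts_into_eye,
    random_shadows,
    render_eye,
)

LAYER_ORDER = MEASURED_LAYERS  # ("RNFL", "GCLIPL", "INL")

#: group-level parameters of a healthy-control-like population
CONTROL_PARAMS = {
    "means": {"RNFL": 32.2, "GCLIPL": 98.1, "INL": 39.6},
    "sds": {"RNFL": 2.0, "GCLIPL": 5.0, "INL": 3.0},
    "corr": [[1.0, 0.14, 0.03], [0.14, 1.0, 0.65], [0.03, 0.65, 1.0]],
}

#: group-level parameters of an optic-neuritis-like population
ON_PARAMS = {
    "means": {"RNFL": 27.8, "GCLIPL": 69.3, "INL": 42.9},
    "sds": {"RNFL": 4.0, "GCLIPL": 14.0, "INL": 6.0},
    "corr": [[1.0, 0.80, -0.61], [0.80, 1.0, -0.44], [-0.61, -0.44, 1.0]],
}

#: the microcyst-bearing stratum: severe RGC loss with a markedly thicker INL
CYST_STRATUM_PARAMS = {
    "means": {"RNFL": 22.7, "GCLIPL": 54.2, "INL": 53.8},
    "sds": {"RNFL": 4.0, "GCLIPL": 6.0, "INL": 6.0},
    "corr": [[1.0, 0.80, -0.61], [0.80, 1.0, -0.44], [-0.61, -0.44, 1.0]],
}


def _as_corr(mat) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    if m.shape != (len(LAYER_ORDER),) * 2:
        raise ValueError("correlation matrix must be 3x3 (RNFL, GCLIPL, INL)")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError("correlation matrix must be positive semi-definite")
    return m


@dataclass
class GroupParams:
    means: dict[str, float]
    sds: dict[str, float]
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.corr = _as_corr(self.corr)
        if any(self.sds[l] <= 0 for l in LAYER_ORDER):
            raise ValueError("SDs must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "GroupParams":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]), corr=d["corr"])


@dataclass
class CohortSpec:
    n_per_group: int = 36
    control: GroupParams = field(
        default_factory=lambda: GroupParams.from_dict(CONTROL_PARAMS)
    )
    on: GroupParams = field(default_factory=lambda: GroupParams.from_dict(ON_PARAMS))
    fellow: GroupParams | None = None  # defaults to control parameters
    eye_model: str = "shared_latent"  # or "delta"
    eye_coupling: float = 0.7
    delta_sds: dict[str, float] | None = None
    delta_corr: np.ndarray | None = None
    cyst_prevalence: float = 5.0 / 36.0
    cyst_spec: CystSpec = field(default_factory=CystSpec)
    #: cyst-designated eyes are redrawn from this severe stratum (set to None
    #: to keep their original draw)
    cyst_stratum: GroupParams | None = field(
        default_factory=lambda: GroupParams.from_dict(CYST_STRATUM_PARAMS)
    )
    n_binocular: int = 0
    duration_on_to_oct_months: tuple[float, float] = (51.0, 44.0)  # mean, sd
    duration_ms_months: tuple[float, float] = (52.0, 44.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fellow is None:
            self.fellow = GroupParams.from_dict(CONTROL_PARAMS)
        if not 0.0 <= self.cyst_prevalence <= 1.0:
            raise ValueError("cyst_prevalence must be in [0, 1]")
        if not 0.0 <= self.eye_coupling <= 1.0:
            raise ValueError("eye_coupling must be in [0, 1]")
        if self.eye_model not in ("shared_latent", "delta"):
            raise ValueError("eye_model must be 'shared_latent' or 'delta'")
        if self.eye_model == "delta":
            if self.delta_sds is None or self.delta_corr is None:
                raise ValueError("delta eye model needs delta_sds and delta_corr")
            self.delta_corr = _as_corr(self.delta_corr)


@dataclass
class EyeData:
    role: str  # "control" | "ON" | "fellow"
    laterality: str
    truth_um: dict[str, float]
    has_cysts: bool = False
    phantom: RetinaPhantom | None = None
    cyst_plans: list[CystPlan] = field(default_factory=list)
    scans: list | None = None
    boundary_truth: list | None = None
    cyst_masks: list | None = None


@dataclass
class SubjectRecord:
    subject: str
    group: str  # "control" | "ON"
    age: float
    sex: str
    eyes: dict[str, EyeData]
    duration_on_to_oct_months: float | None = None
    duration_ms_months: float | None = None
    binocular: bool = False


def _chol(corr: np.ndarray) -> np.ndarray:
    # tiny jitter tolerates numerically semi-definite matrices
    return np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))


def _scale(z: np.ndarray, p: GroupParams) -> np.ndarray:
    sds = np.array([p.sds[l] for l in LAYER_ORDER])
    mus = np.array([p.means[l] for l in LAYER_ORDER])
    return np.clip(mus + z * sds, 1.0, None)  # truncated at 1 um


def draw_group(n: int, params: GroupParams, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, 3) truncated-MVN layer thickness targets for single eyes."""
    L = _chol(params.corr)
    z = rng.standard_normal((n, len(LAYER_ORDER))) @ L.T
    return _scale(z, params)


def draw_paired_eyes(
    spec: CohortSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (affected, fellow) thickness targets, (n, 3) each."""
    if spec.eye_model == "shared_latent":
        rho = spec.eye_coupling
        L_on, L_f = _chol(spec.on.corr), _chol(spec.fellow.corr)
        zs = rng.standard_normal((n, 3))
        z1 = rng.standard_normal((n, 3))
        z2 = rng.standard_normal((n, 3))
        a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
        on = _scale((a * zs + b * z1) @ L_on.T, spec.on)
        fellow = _scale((a * zs + b * z2) @ L_f.T, spec.fellow)
        return on, fellow
    # delta model: affected = fellow + correlated difference
    fellow = draw_group(n, spec.fellow, rng)
    d_mu = np.array(
        [spec.on.means[l] - spec.fellow.means[l] for l in LAYER_ORDER]
    )
    d_sd = np.array([spec.delta_sds[l] for l in LAYER_ORDER])
    Ld = _chol(spec.delta_corr)
    delta = d_mu + (rng.standard_normal((n, 3)) @ Ld.T) * d_sd
    return np.clip(fellow + delta, 1.0, None), fellow


def _truncated_duration(rng, mean: float, sd: float, lo: float = 3.0) -> float:
    # gamma-shaped: durations are positive and right-skewed
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return float(max(lo, rng.gamma(shape, scale)))


def simulate_cohort(
    spec: CohortSpec,
    render: bool = False,
    acq: AcquisitionModel | None = None,
    protocol: RadialProtocol | None = None,
    phantom_kwargs: dict | None = None,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Simulate a control + affected cohort; optionally render every eye.

    Returns the subject records and a ground-truth table with one row per
    analyzed eye (columns: subject, group, role, laterality, the three
    layer targets, has_cysts, durations).
    """
    protocol = protocol or RadialProtocol()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_per_group

    ctrl_draws = draw_group(n, spec.control, rng)
    on_draws, fellow_draws = draw_paired_eyes(spec, n, rng)

    n_cyst = int(round(spec.cyst_prevalence * n))
    cyst_eyes = set(rng.choice(n, size=n_cyst, replace=False).tolist()) if n_cyst else set()
    if cyst_eyes and spec.cyst_stratum is not None:
        stratum = draw_group(len(cyst_eyes), spec.cyst_stratum, rng)
        for j, i in enumerate(sorted(cyst_eyes)):
            on_draws[i] = stratum[j]

    records: list[SubjectRecord] = []
    rows = []
    phantom_kwargs = phantom_kwargs or {}

    def build_eye(role, lat, truth, has_cysts, eye_rng):
        eye = EyeData(
            role=role,
            laterality=lat,
            truth_um={l: float(truth[i]) for i, l in enumerate(LAYER_ORDER)},
            has_cysts=has_cysts,
        )
        if render:
            pspec = PhantomSpec(target_um=dict(eye.truth_um), **phantom_kwargs)
            phantom = make_layer_geometry(
                pspec, seed=int(eye_rng.integers(2**31)), protocol=protocol
            )
            plans: list[CystPlan] = []
            if has_cysts:
                phantom, plans = inject_cysts_into_eye(
                    phantom, spec.cyst_spec, eye_rng
                )
            shadows = [
                random_shadows(eye_rng) for _ in range(protocol.n_slices)
            ]
            scans, truths, masks = render_eye(
                phantom,
                acq,
                seed=int(eye_rng.integers(2**31)),
                cysts=plans,
                shadows_per_slice=shadows,
                laterality=lat,
            )
            eye.phantom = phantom
            eye.cyst_plans = plans
            eye.scans = scans
            eye.boundary_truth = truths
            eye.cyst_masks = masks
        return eye

    if render and acq is None:
        raise ValueError("render=True needs an AcquisitionModel")

    for i in range(n):
        sid = f"C{i + 1:03d}"
        lat = "OD" if rng.random() < 0.5 else "OS"
        eye = build_eye("control", lat, ctrl_draws[i], False, rng)
        rec = SubjectRecord(
            subject=sid,
            group="control",
            age=float(np.clip(rng.normal(39.5, 10.7), 18, 70)),
            sex="F" if rng.random() < 27 / 36 else "M",
            eyes={"control": eye},
        )
        records.append(rec)

    for i in range(n):
        sid = f"P{i + 1:03d}"
        on_lat = "OD" if rng.random() < 0.5 else "OS"
        fellow_lat = "OS" if on_lat == "OD" else "OD"
        has_cysts = i in cyst_eyes
        binocular = i < spec.n_binocular
        on_eye = build_eye("ON", on_lat, on_draws[i], has_cysts, rng)
        fellow_eye = build_eye("fellow", fellow_lat, fellow_draws[i], False, rng)
        rec = SubjectRecord(
            subject=sid,
            group="ON",
            age=float(np.clip(rng.normal(39.5, 9.8), 18, 70)),
            sex="F" if rng.random() < 28 / 36 else "M",
            eyes={"ON": on_eye, "fellow": fellow_eye},
            duration_on_to_oct_months=_truncated_duration(
                rng, *spec.duration_on_to_oct_months
            ),
            duration_ms_months=_truncated_duration(rng, *spec.duration_ms_months),
            binocular=binocular,
        )
        records.append(rec)

    for rec in records:
        for role, eye in rec.eyes.items():
            rows.append(
                {
                    "subject": rec.subject,
                    "group": rec.group,
                    "role": role,
                    "laterality": eye.laterality,
                    **{f"{l}_um": eye.truth_um[l] for l in LAYER_ORDER},
                    "has_cysts": eye.has_cysts,
                    "binocular": rec.binocular,
                    "duration_on_to_oct_months": rec.duration_on_to_oct_months,
                    "duration_ms_months": rec.duration_ms_months,
                }
            )
    return records, pd.DataFrame(rows)
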