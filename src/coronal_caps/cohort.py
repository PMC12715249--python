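"""Seeded phantom-brain cohort generation.

Real cohorts for three-class dementia studies (CN / MCI / AD) come from
access-controlled archives, so this module generates geometric head
phantoms carrying the statistical structure the downstream analysis
assumes: three diagnostic classes at clinical prevalence proportions
(43.3% AD, 34.3% MCI, 22.5% CN), class-graded hippocampal shrinkage and
ventricular enlargement, T1-like tissue contrast (WM > GM > CSF),
additive noise, and optional motion/bias-field artifacts for QC testing.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import BrainVolume

CLASSES = ("CN", "MCI", "AD")

# phantom label codes
LBL_AIR, LBL_SCALP, LBL_GM, LBL_WM, LBL_VENTRICLE, LBL_HIPPOCAMPUS = 0, 1, 2, 3, 4, 5

AGE_GROUPS = ("<70", "70-80", ">80")


def age_group_of(age: float) -> str:
    """Deterministic age banding: <70, 70-80 inclusive, >80."""
    if age < 70:
        return "<70"
    if age <= 80:
        return "70-80"
    return ">80"


def largest_remainder(n: int, proportions) -> np.ndarray:
    """Apportion ``n`` items to categories by the largest-remainder method.

    Floors of n*p are assigned first; remaining seats go to the largest
    fractional remainders (ties broken by category order).
    """
    p = np.asarray(proportions, dtype=float)
    if n < 0:
        raise ValueError("n must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    quotas = n * p
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # stable sort => ties resolved by category order
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


@dataclass
class PatientRecord:
    patient_id: str
    diagnosis: str
    age: float
    sex: str
    scanner_id: str
    scan_ids: list[str]

    def __post_init__(self) -> None:
        if self.diagnosis not in CLASSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")

    @property
    def age_group(self) -> str:
        return age_group_of(self.age)


@dataclass
class PhantomParams:
    """Geometry and intensity parameters of one rendered head phantom.

    ``hippocampus_scale`` (<= 1) shrinks the two hippocampal blobs;
    ``ventricle_scale`` (>= 1) enlarges the ventricular cavities — the
    two structural axes along which dementia severity is graded.
    Intensities must satisfy the T1 ordering WM > GM (cortical) > CSF.
    """

    volume_shape: tuple[int, int, int] = (96, 112, 96)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    hippocampus_scale: float = 1.0
    ventricle_scale: float = 1.0
    cortical_mean_intensity: float = 80.0
    wm_mean_intensity: float = 120.0
    csf_mean_intensity: float = 30.0
    noise_sd: float = 3.0
    motion_severity: float = 0.0
    bias_field_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.hippocampus_scale <= 1):
            raise ValueError("hippocampus_scale must be in (0, 1]")
        if self.ventricle_scale < 1:
            raise ValueError("ventricle_scale must be >= 1")
        if not (self.wm_mean_intensity > self.cortical_mean_intensity > self.csf_mean_intensity):
            raise ValueError("intensity ordering must be WM > cortical > CSF")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.motion_severity <= 1):
            raise ValueError("motion_severity must be in [0, 1]")
        if self.bias_field_amplitude < 0:
            raise ValueError("bias_field_amplitude must be nonnegative")


#: default class-graded atrophy: direction from dementia pathophysiology
#: (hippocampal shrinkage, ventricular enlargement with severity); the
#: magnitudes are package defaults large enough for a tiny classifier.
DEFAULT_CLASS_EFFECTS: dict[str, dict[str, float]] = {
    "CN": {"hippocampus_scale": 1.0, "ventricle_scale": 1.0},
    "MCI": {"hippocampus_scale": 0.85, "ventricle_scale": 1.15},
    "AD": {"hippocampus_scale": 0.70, "ventricle_scale": 1.30},
}

# class-conditional age distributions (mean, sd); AD skews older
_AGE_PARAMS = {"CN": (72.0, 6.0), "MCI": (74.0, 6.0), "AD": (77.0, 6.0)}


@dataclass
class CohortSpec:
    n_patients: int = 100
    class_proportions: tuple[float, float, float] = (0.225, 0.342, 0.433)  # (CN, MCI, AD)
    scans_per_patient: int = 1
    base_params: PhantomParams = field(default_factory=PhantomParams)
    class_effect_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_EFFECTS.items()}
    )
    anatomy_jitter_sd: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if len(p) != 3 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must be a 3-vector summing to 1, got {p}")
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients (one per class after rounding)")
        if self.scans_per_patient < 1:
            raise ValueError("scans_per_patient must be positive")


def _ellipsoid(grid_mm, center_mm, semi_axes_mm) -> np.ndarray:
    x, y, z = grid_mm
    cx, cy, cz = center_mm
    ax, ay, az = semi_axes_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def render_phantom(params: PhantomParams, seed: int) -> BrainVolume:
    """Render one head phantom.

    The phantom is an ellipsoidal head (scalp tier) containing a brain
    compartment with a cortical GM shell and WM core, two CSF ventricular
    cavities scaled by ``ventricle_scale``, and two hippocampal blobs
    (GM intensity, embedded in WM for contrast) scaled by
    ``hippocampus_scale``. Gaussian noise of sd ``noise_sd`` is added
    everywhere. The ground-truth label map travels on ``labels``.
    """
    shape = tuple(int(s) for s in params.volume_shape)
    spacing = np.asarray(params.voxel_spacing_mm, dtype=float)
    extent = np.asarray(shape) * spacing
    if np.any(extent < np.array([120.0, 140.0, 120.0])):
        raise ValueError(
            f"volume extent {tuple(extent)} mm too small to contain the head structures"
        )
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)]
    grid = np.meshgrid(*axes, indexing="ij")  # mm, centered

    labels = np.zeros(shape, dtype=np.int8)
    head_semi = extent * np.array([0.40, 0.42, 0.40])
    brain_semi = head_semi * 0.86
    wm_semi = brain_semi * np.array([0.72, 0.74, 0.72])

    labels[_ellipsoid(grid, (0, 0, 0), head_semi)] = LBL_SCALP
    labels[_ellipsoid(grid, (0, 0, 0), brain_semi)] = LBL_GM
    labels[_ellipsoid(grid, (0, 0, 0), wm_semi)] = LBL_WM
    # deep structures sit at fixed fractions of the WM core so they stay
    # embedded in WM (image contrast) at any supported volume size; their
    # absolute sizes in mm scale only with the atrophy parameters
    vs = params.ventricle_scale
    vent_semi = np.array([7.0, 20.0, 11.0]) * vs
    vent_center = wm_semi * np.array([0.25, 0.08, 0.25])
    for sx in (-1, 1):
        c = (sx * vent_center[0], vent_center[1], vent_center[2])
        labels[_ellipsoid(grid, c, vent_semi)] = LBL_VENTRICLE
    hs = params.hippocampus_scale
    hip_semi = np.array([8.0, 16.0, 7.0]) * hs
    hip_center = wm_semi * np.array([0.55, -0.20, -0.45])
    for sx in (-1, 1):
        c = (sx * hip_center[0], hip_center[1], hip_center[2])
        labels[_ellipsoid(grid, c, hip_semi)] = LBL_HIPPOCAMPUS

    intensity = {
        LBL_AIR: 0.0,
        LBL_SCALP: 0.85 * params.cortical_mean_intensity,
        LBL_GM: params.cortical_mean_intensity,
        LBL_WM: params.wm_mean_intensity,
        LBL_VENTRICLE: params.csf_mean_intensity,
        LBL_HIPPOCAMPUS: params.cortical_mean_intensity,
    }
    data = np.zeros(shape, dtype=np.float64)
    for lbl, val in intensity.items():
        data[labels == lbl] = val

    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, params.noise_sd, size=shape)

    origin = tuple(int(round(c)) for c in (np.asarray(shape) - 1) / 2.0)
    vol = BrainVolume(data=data, spacing=tuple(spacing), origin=origin, labels=labels)

    if params.bias_field_amplitude > 0:
        vol = inject_artifact(vol, "bias_field", params.bias_field_amplitude, seed=seed + 1)
    if params.motion_severity > 0:
        vol = inject_artifact(vol, "motion_ghost", params.motion_severity, seed=seed + 2)
    return vol


ARTIFACT_KINDS = ("motion_ghost", "bias_field", "noise_burst")

#: motion ghost replica amplitude at severity 1 (fraction of the source
#: intensity); the QC motion-score estimator is calibrated to this scale.
GHOST_FULL_AMPLITUDE = 0.5


def inject_artifact(volume: BrainVolume, kind: str, severity: float, seed: int) -> BrainVolume:
    """Return a modified copy of ``volume`` carrying one acquisition artifact.

    ``motion_ghost`` adds a half-FOV-shifted attenuated replica along the
    phase-encode (posterior-anterior) axis; ``bias_field`` multiplies by a
    smooth low-order polynomial field; ``noise_burst`` adds extra Gaussian
    noise. ``severity`` = 0 returns the input unchanged.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; choose from {ARTIFACT_KINDS}")
    if not (0.0 <= severity <= 1.0):
        raise ValueError("severity must be in [0, 1]")
    out = volume.copy()
    if severity == 0.0:
        return out
    data = out.data
    if kind == "motion_ghost":
        shift = data.shape[1] // 2
        ghost = np.roll(data, shift, axis=1)
        out = replace(out, data=data + GHOST_FULL_AMPLITUDE * severity * ghost)
    elif kind == "bias_field":
        axes = [np.linspace(-1.0, 1.0, n) for n in data.shape]
        u, v, w = np.meshgrid(*axes, indexing="ij")
        fld = 0.45 * u + 0.35 * v * w + 0.45 * (w * w - 0.5)
        # normalize over the head-ish central region so severity controls
        # the modulation actually seen by tissue, not the cube corners
        central = u * u + v * v + w * w <= 0.85**2
        fld = fld / np.percentile(np.abs(fld[central]), 98)
        out = replace(out, data=data * (1.0 + 0.5 * severity * fld))
    else:  # noise_burst
        rng = np.random.default_rng(seed)
        fg_mean = np.mean(data[data > 0.25 * np.percentile(data, 98)])
        out = replace(out, data=data + rng.normal(0.0, 0.2 * severity * fg_mean, data.shape))
    return out


def _phantom_params_for(spec: CohortSpec, diagnosis: str, rng: np.random.Generator) -> PhantomParams:
    eff = spec.class_effect_table.get(diagnosis, {})
    params = replace(spec.base_params, **eff)
    if spec.anatomy_jitter_sd > 0:
        jh = float(np.exp(rng.normal(0.0, spec.anatomy_jitter_sd)))
        jv = float(np.exp(rng.normal(0.0, spec.anatomy_jitter_sd)))
        params = replace(
            params,
            hippocampus_scale=min(1.0, params.hippocampus_scale * jh),
            ventricle_scale=max(1.0, params.ventricle_scale * jv),
        )
    return params


def generate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], dict[str, BrainVolume]]:
    """Generate a full cohort: patient records plus one volume per scan.

    Per-class patient counts follow largest-remainder apportionment of
    ``n_patients`` by ``class_proportions``; each patient's scans are
    rendered with that diagnosis's effect parameters (plus a small
    per-patient anatomical jitter). Identical spec + seed gives
    bit-identical output.
    """
    counts = largest_remainder(spec.n_patients, spec.class_proportions)
    ss = np.random.SeedSequence(spec.seed)
    demo_rng = np.random.default_rng(ss.spawn(1)[0])

    patients: list[PatientRecord] = []
    volumes: dict[str, BrainVolume] = {}
    idx = 0
    for cls, n_cls in zip(CLASSES, counts):
        mu, sd = _AGE_PARAMS[cls]
        for _ in range(n_cls):
            idx += 1
            pid = f"P{idx:04d}"
            age = float(np.clip(demo_rng.normal(mu, sd), 55.0, 95.0))
            sex = "F" if demo_rng.random() < 0.5 else "M"
            scanner = f"SC{demo_rng.integers(1, 4)}"
            params = _phantom_params_for(spec, cls, demo_rng)
            scan_ids = []
            for s in range(spec.scans_per_patient):
                sid = f"{pid}_S{s + 1:02d}"
                scan_seed = int(np.random.SeedSequence([spec.seed, idx, s]).generate_state(1)[0] % (2**31))
                volumes[sid] = render_phantom(params, seed=scan_seed)
                scan_ids.append(sid)
            patients.append(
                PatientRecord(
                    patient_id=pid, diagnosis=cls, age=age, sex=sex,
                    scanner_id=scanner, scan_ids=scan_ids,
                )
            )
    return patients, volumes


def cohort_table(patients: list[PatientRecord]) -> pd.DataFrame:
    """One row per scan: patient_id, scan_id, diagnosis, age, age_group, sex, scanner_id."""
    rows = [
        {
            "patient_id": p.patient_id,
            "scan_id": sid,
            "diagnosis": p.diagnosis,
            "age": round(p.age, 1),
            "age_group": p.age_group,
            "sex": p.sex,
            "scanner_id": p.scanner_id,
        }
        for p in patients
        for sid in p.scan_ids
    ]
    return pd.DataFrame(rows)


def save_cohort(patients: list[PatientRecord], volumes: dict[str, BrainVolume], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_table(patients).to_csv(out / "cohort.csv", index=False)
    for sid, vol in volumes.items():
        vol.to_nifti(out / f"{sid}.nii.gz")
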