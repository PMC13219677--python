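"""Synthetic cohort generator.

No public lung-ablation CT collection carries the applicator geometry and
paired landmarks this pipeline needs, so the package ships a generator that
emulates the statistical structure such cohorts show, at the scale of a
single-probe, single-burn microwave cohort:

* patient-level clustering — most patients contribute one ablation, some
  two or three (default 70/25/5%);
* treatment settings concentrated on 65 W at 2, 4, 5 and 6 min, with the
  observed relative frequencies of those four settings;
* right-skewed, heavy-tailed ablation volumes — a lognormal multiplier on
  the vendor-predicted volume, with a patient-level random intercept;
* elongated, non-ellipsoidal, front-narrower shapes — an egg-like body of
  revolution r(u) ∝ sqrt(1-u^2)(1-eps*u) whose taper parameter eps is
  solved from the requested front/back max-width ratio, plus a smooth
  low-order (degree 2-4) spherical-harmonic radial perturbation so shapes
  stay connected and watertight, like segmented lesions;
* tip offset — the distance the zone extends past the applicator tip,
  lognormal with median 6 mm;
* tissue contraction — mean landmark-distance shrinkage generated as a
  linear function of follow-up interval plus noise (median ≈ 2.5 mm at a
  30-day follow-up under defaults), realised by displacing post-procedure
  landmarks toward the zone centroid with exp(-d/20 mm) distance
  attenuation and 0.3 mm isotropic noise.  The per-ablation displacement
  scale is calibrated so the noise-free mean pairwise distance change
  equals the target, which is what makes the target a recoverable truth.

Every generated quantity is recorded in a truth table; downstream recovery
tests read the truth rather than re-deriving constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import eval_legendre

from .core import ApplicatorLine, MaskVolume
from .contraction import LandmarkSet
from .vendor import VendorTable, default_vendor_table, interpolate_vendor

__all__ = ["CohortSpec", "simulate_records", "simulate_ablation_mask",
           "simulate_landmarks", "simulate_cohort"]


@dataclass
class CohortSpec:
    """Generator knobs; defaults are the cohort conditions being emulated."""

    n_patients: int = 72
    # P(1, 2, 3 ablations per patient)
    ablations_per_patient: tuple = (0.70, 0.25, 0.05)
    # (power W, duration min) -> weight; the four most common settings
    setting_weights: dict = field(default_factory=lambda: {
        (65.0, 5.0): 18, (65.0, 6.0): 17, (65.0, 4.0): 14, (65.0, 2.0): 11,
    })
    # lognormal volume multiplier on the vendor volume, split into a
    # patient-level intercept and a residual: total sd = 0.5 on log scale
    sigma_log_volume: float = 0.5
    sigma_patient: float = 0.2
    # injectable fixed effects of the log observed/vendor volume discrepancy
    discrepancy_intercept: float = 0.0
    beta_followup: float = 0.0
    beta_contraction: float = 0.0
    beta_log_tumor: float = 0.0
    beta_log_energy: float = 0.0
    # geometry
    front_back_ratio: float = 0.9         # front max width / back max width
    tip_offset_median_mm: float = 6.0
    tip_offset_sigma_log: float = 0.45    # lognormal -> IQR approx 4.4-8.1 mm
    lobulation_amplitude: float = 0.08    # relative radial perturbation (rms)
    # contraction truth model: mm = a + b * followup_days + noise
    contraction_intercept_mm: float = 1.0
    contraction_slope_per_day: float = 0.05
    contraction_noise_sd_mm: float = 1.5
    # covariates
    followup_mean_days: float = 30.0
    followup_sd_days: float = 8.0
    tumor_volume_log_mean: float = 5.73   # lognormal: mean 420, sd ~390 mm^3
    tumor_volume_log_sd: float = 0.79
    landmark_range: tuple = (3, 10)
    landmark_noise_sd_mm: float = 0.3
    # native world grid the masks are written on (anisotropic, like thin-slice CT)
    world_spacing: tuple = (0.8, 0.8, 1.25)
    world_shape: tuple = (128, 128, 82)

    def __post_init__(self) -> None:
        if abs(sum(self.ablations_per_patient) - 1.0) > 1e-9:
            raise ValueError("ablations-per-patient probabilities must sum to 1")
        if self.sigma_log_volume < 0 or self.sigma_patient < 0:
            raise ValueError("log-volume sigmas must be non-negative")
        if not (0 < self.front_back_ratio <= 1):
            raise ValueError("front/back ratio must lie in (0, 1]")
        if self.sigma_patient > self.sigma_log_volume:
            raise ValueError("patient-level sigma cannot exceed the total sigma")


# ---------------------------------------------------------------------------
# record level


_NODULE_CLASSES = (("solid", 0.86), ("subsolid", 0.07), ("cavitary", 0.07))
_VESSEL_CLASSES = (("<2mm", 0.315), ("2-3mm", 0.279), (">3mm", 0.406))


def _categorical(rng, table):
    names = [n for n, _ in table]
    probs = np.array([p for _, p in table])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def simulate_records(
    spec: CohortSpec,
    rng: np.random.Generator,
    vendor_table: VendorTable | None = None,
) -> pd.DataFrame:
    """Draw per-ablation metadata and record-level truth (no voxels).

    The returned frame carries the analytic observed volume
    ``volume_cm3 = vendor x exp(log-discrepancy)`` alongside the vendor
    prediction and the true contraction, so statistical recovery can be
    studied without voxelising masks.
    """
    table = vendor_table or default_vendor_table()
    settings = list(spec.setting_weights)
    w = np.array([spec.setting_weights[s] for s in settings], dtype=float)
    w /= w.sum()
    sigma_resid = np.sqrt(spec.sigma_log_volume**2 - spec.sigma_patient**2)

    rows = []
    aid = 0
    for p in range(spec.n_patients):
        patient_id = f"P{p:03d}"
        n_abl = rng.choice([1, 2, 3], p=spec.ablations_per_patient)
        u_patient = rng.normal(0.0, spec.sigma_patient)
        for _ in range(n_abl):
            power, duration = settings[rng.choice(len(settings), p=w)]
            pred = interpolate_vendor(table, power, duration, extrapolate=True)
            followup = max(7.0, rng.normal(spec.followup_mean_days, spec.followup_sd_days))
            tumor_vol = float(np.exp(rng.normal(
                spec.tumor_volume_log_mean, spec.tumor_volume_log_sd)))
            energy = power * duration
            contraction = (
                spec.contraction_intercept_mm
                + spec.contraction_slope_per_day * followup
                + rng.normal(0.0, spec.contraction_noise_sd_mm)
            )
            log_disc = (
                spec.discrepancy_intercept
                + spec.beta_followup * followup
                + spec.beta_contraction * contraction
                + spec.beta_log_tumor * np.log(tumor_vol)
                + spec.beta_log_energy * np.log(energy)
                + u_patient
                + rng.normal(0.0, sigma_resid)
            )
            tip_offset = float(np.exp(rng.normal(
                np.log(spec.tip_offset_median_mm), spec.tip_offset_sigma_log)))
            rows.append({
                "ablation_id": f"A{aid:03d}",
                "patient_id": patient_id,
                "power_w": power,
                "duration_min": duration,
                "energy_wmin": energy,
                "followup_days": round(followup),
                "tumor_volume_mm3": tumor_vol,
                "nodule_class": _categorical(rng, _NODULE_CLASSES),
                "location": "central" if rng.random() < 0.21 else "peripheral",
                "pleura_within_5mm": bool(rng.random() < 0.42),
                "vessel_class": _categorical(rng, _VESSEL_CLASSES),
                "vendor_length_mm": pred.length_mm,
                "vendor_width_mm": pred.width_mm,
                "vendor_tip_to_edge_mm": pred.tip_to_edge_mm,
                "vendor_volume_cm3": pred.volume_cm3,
                "true_log_discrepancy": float(log_disc),
                "volume_cm3": float(pred.volume_cm3 * np.exp(log_disc)),
                "true_contraction_mm": float(contraction),
                "contraction_mm": float(contraction),
                "true_tip_to_edge_mm": tip_offset,
                "true_front_back_ratio": spec.front_back_ratio,
            })
            aid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# voxel level


def _taper_from_ratio(ratio: float) -> float:
    """Solve the egg taper eps so front/back max width = ratio.

    The body of revolution r(u) = sqrt(1-u^2)(1-eps*u), u in [-1, 1] with
    u = +1 the front (distal) pole, has its widest section behind the
    mid-slice for eps > 0: front max width is r(0) = 1, back max width is
    R(eps) = max_u r(u) > 1, so the ratio is 1/R(eps).
    """
    if ratio >= 1.0:
        return 0.0

    def R(eps):
        u = (1.0 - np.sqrt(1.0 + 8.0 * eps**2)) / (4.0 * eps)
        return np.sqrt(1.0 - u * u) * (1.0 - eps * u)

    return float(brentq(lambda e: R(e) - 1.0 / ratio, 1e-9, 20.0))


class _SphericalField:
    """Smooth random band-limited field on the sphere (degrees 2-4).

    A sum of Legendre polynomials P_l(n . v) over random axes v spans
    exactly the degree-l spherical harmonics; the field is normalised to
    unit rms over a probe set of directions.
    """

    def __init__(self, rng: np.random.Generator, degrees=(2, 3, 4)):
        self.terms = []
        for l in degrees:
            for _ in range(2 * l + 1):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                self.terms.append((l, v, rng.normal()))
        probe = rng.normal(size=(256, 3))
        probe /= np.linalg.norm(probe, axis=1, keepdims=True)
        rms = np.sqrt(np.mean(self._raw(probe) ** 2))
        self.scale = 1.0 / rms if rms > 0 else 0.0

    def _raw(self, dirs: np.ndarray) -> np.ndarray:
        out = np.zeros(len(dirs))
        for l, v, w in self.terms:
            out += w * eval_legendre(l, dirs @ v)
        return out

    def __call__(self, dirs: np.ndarray) -> np.ndarray:
        return self._raw(dirs) * self.scale


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def simulate_ablation_mask(
    spec: CohortSpec,
    record: dict | pd.Series,
    rng: np.random.Generator,
):
    """Voxelise one synthetic ablation zone in a random world orientation.

    Returns (MaskVolume, ApplicatorLine, truth dict).  The base shape is the
    vendor ellipsoid at the record's setting, volume-scaled by the record's
    discrepancy multiplier, tapered front/back, lobulated, and anchored so
    its distal pole sits the drawn tip offset beyond the applicator tip.
    """
    rec = dict(record)
    length = float(rec["vendor_length_mm"])
    vendor_vol_mm3 = float(rec["vendor_volume_cm3"]) * 1000.0
    m = float(np.exp(rec["true_log_discrepancy"]))
    ratio = float(rec.get("true_front_back_ratio", spec.front_back_ratio))
    t2e = float(rec["true_tip_to_edge_mm"])

    a = 0.5 * length * m ** (1.0 / 3.0)
    eps = _taper_from_ratio(ratio)
    # transverse scale from the exact egg volume V = 4/3 pi a b^2 (1 + eps^2/5)
    b = np.sqrt(m * vendor_vol_mm3 / (4.0 / 3.0 * np.pi * a * (1.0 + eps**2 / 5.0)))
    zc = t2e - a  # egg centre offset along the applicator axis (ACCS z)

    field = _SphericalField(rng) if spec.lobulation_amplitude > 0 else None
    amp = spec.lobulation_amplitude

    # world frame: random orientation, tip jittered near the grid centre
    Q = _random_rotation(rng)          # rows = ACCS basis vectors in world
    tip = rng.uniform(-4.0, 4.0, size=3)
    spacing = np.array(spec.world_spacing, dtype=float)
    shape = np.array(spec.world_shape, dtype=int)
    origin = tip - (shape - 1) / 2.0 * spacing  # tip near the grid centre

    # bounding box around the zone to keep voxelisation cheap
    r_reach = max(abs(zc) + a, b * 2.0) * (1.0 + 3.0 * amp) + 2.0
    lo = np.maximum(np.floor((tip - r_reach - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((tip + r_reach - origin) / spacing).astype(int) + 1, shape)
    idx = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = idx * spacing + origin
    accs = (world - tip) @ Q.T          # ACCS coordinates of voxel centres

    rel = accs - np.array([0.0, 0.0, zc])
    u = rel[:, 2] / a
    rho = np.hypot(rel[:, 0], rel[:, 1])
    with np.errstate(invalid="ignore"):
        r_base = b * np.sqrt(np.clip(1.0 - u * u, 0.0, None)) * (1.0 - eps * u)
    if field is not None:
        norms = np.linalg.norm(rel, axis=1)
        dirs = rel / np.where(norms > 1e-9, norms, 1.0)[:, None]
        r_base = r_base * np.clip(1.0 + amp * field(dirs), 0.5, None)
    inside = (np.abs(u) <= 1.0) & (rho <= r_base)

    voxels = np.zeros(tuple(shape), dtype=np.uint8)
    voxels[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = 1
    if voxels.sum() == 0:
        raise RuntimeError("generated shape produced an empty mask")

    mask = MaskVolume(voxels=voxels, spacing=spacing, origin=origin,
                      direction=np.eye(3))
    applicator = ApplicatorLine(tip=tip, direction=Q[2])
    truth = {
        **{k: rec[k] for k in rec},
        "true_semi_axis_a_mm": a,
        "true_transverse_b_mm": b,
        "true_taper_eps": eps,
        "true_centre_offset_mm": zc,
    }
    return mask, applicator, truth


def simulate_landmarks(
    spec: CohortSpec,
    mask: MaskVolume,
    truth: dict,
    rng: np.random.Generator,
):
    """Place pre/post landmark sets around a zone, encoding its contraction.

    Pre landmarks sit 5-25 mm outside the zone surface in random directions
    from the centroid.  Post landmarks are displaced toward the centroid
    with magnitude proportional to exp(-surface distance / 20 mm); the
    overall scale is calibrated so the noise-free mean pairwise distance
    change equals the record's true contraction, then isotropic Gaussian
    noise (default sigma 0.3 mm) is added.
    """
    from scipy.spatial.distance import pdist

    target = float(truth["true_contraction_mm"])
    n = int(rng.integers(spec.landmark_range[0], spec.landmark_range[1] + 1))

    fg = np.argwhere(mask.voxels)
    centroid = mask.voxel_to_world(fg.mean(axis=0))
    vol_mm3 = mask.n_foreground * float(np.prod(mask.spacing))
    r_eff = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)

    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    d_surf = rng.uniform(5.0, 25.0, size=n)
    radii = r_eff + d_surf
    pre_pts = centroid + dirs * radii[:, None]

    atten = np.exp(-d_surf / 20.0)

    def realized(scale: float) -> float:
        post = pre_pts - (scale * atten)[:, None] * dirs
        return float(np.mean(pdist(pre_pts) - pdist(post)))

    # the realized change is almost (not exactly) linear in the scale:
    # start from the linear solution and polish with Newton steps
    g1 = realized(1.0)
    scale = target / g1 if abs(g1) > 1e-12 else 0.0
    for _ in range(4):
        g = realized(scale)
        if abs(g - target) < 1e-9:
            break
        h = 1e-3 * max(abs(scale), 1.0)
        slope = (realized(scale + h) - g) / h
        if abs(slope) < 1e-12:
            break
        scale -= (g - target) / slope
    post_pts = pre_pts - (scale * atten)[:, None] * dirs
    post_pts = post_pts + rng.normal(0.0, spec.landmark_noise_sd_mm, size=post_pts.shape)

    labels = [f"L{i:02d}" for i in range(n)]
    aid = str(truth.get("ablation_id", ""))
    pre = LandmarkSet(labels=labels, points=pre_pts, role="pre", ablation_id=aid)
    post = LandmarkSet(labels=labels, points=post_pts, role="post", ablation_id=aid)
    return pre, post


def simulate_cohort(
    spec: CohortSpec,
    out_dir,
    seed: int = 0,
    vendor_table: VendorTable | None = None,
    with_landmarks: bool = True,
) -> pd.DataFrame:
    """Generate a full cohort on disk: masks, markups, manifest and truth.

    Writes, under ``out_dir``: one NIfTI mask and one applicator fiducial
    file per ablation (plus pre/post landmark files when requested), a
    ``manifest.csv`` tying them to the metadata, and a ``truth.csv`` with
    every generating parameter.  Fully reproducible from ``seed``.
    """
    from pathlib import Path

    from .io import write_mask, write_markups_fcsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records = simulate_records(spec, rng, vendor_table)

    manifest_rows, truth_rows = [], []
    for _, rec in records.iterrows():
        mask, applicator, truth = simulate_ablation_mask(spec, rec, rng)
        aid = rec["ablation_id"]
        mask_path = out / f"{aid}_mask.nii.gz"
        app_path = out / f"{aid}_applicator.fcsv"
        write_mask(mask, mask_path)
        shaft = applicator.tip - 20.0 * applicator.direction
        write_markups_fcsv(
            ["shaft", "tip"], np.stack([shaft, applicator.tip]), app_path)
        row = {
            "ablation_id": aid,
            "patient_id": rec["patient_id"],
            "mask": mask_path.name,
            "applicator": app_path.name,
            "landmarks_pre": "",
            "landmarks_post": "",
            "power_w": rec["power_w"],
            "duration_min": rec["duration_min"],
            "followup_days": rec["followup_days"],
            "tumor_volume_mm3": rec["tumor_volume_mm3"],
            "nodule_class": rec["nodule_class"],
            "location": rec["location"],
            "pleura_within_5mm": rec["pleura_within_5mm"],
            "vessel_class": rec["vessel_class"],
        }
        if with_landmarks:
            pre, post = simulate_landmarks(spec, mask, truth, rng)
            pre_path = out / f"{aid}_landmarks_pre.fcsv"
            post_path = out / f"{aid}_landmarks_post.fcsv"
            write_markups_fcsv(pre.labels, pre.points, pre_path)
            write_markups_fcsv(post.labels, post.points, post_path)
            row["landmarks_pre"] = pre_path.name
            row["landmarks_post"] = post_path.name
        manifest_rows.append(row)
        truth_rows.append(truth)

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return manifest
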