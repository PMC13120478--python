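"""Synthetic cohorts of ILM surfaces and GCIPL thickness maps.

The generator emulates the statistical structure the analysis pipeline
assumes: a foveal-pit thickness topography (near-zero pit, annular peak
near 1 mm, peripheral decay), group means of 75.9 µm (healthy, SD 6.2)
versus 62.9 µm (MS, SD 5.4), MS thinning concentrated in a horseshoe-shaped
annulus around the fovea with a temporal angular gap, smooth per-subject
anatomical warps of both surface and thickness map, and i.i.d. measurement
noise.  Between-eye SD is injected at the subject level (one scalar per
eye) so the across-eye variance of map means matches the group SDs.

Every draw is reproducible from (config, seed); ground-truth warps are
recorded for registration-recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import EyeSide, Label, SubjectRecord, ThicknessGrid, write_grid, write_manifest

__all__ = [
    "CohortConfig",
    "healthy_profile",
    "apply_ms_effect",
    "sample_subject",
    "generate_cohort",
    "make_split",
    "write_cohort",
]


@dataclass
class CohortConfig:
    """Study-condition parameters of the simulated cohort."""

    n_healthy_eyes: int = 37
    n_ms_eyes: int = 35
    grid_shape: tuple[int, int] = (131, 131)  # (height, width) lattice points
    pixel_pitch: float | None = None  # mm/px; default 6 mm / (width − 1)
    healthy_mean: float = 75.9
    healthy_sd: float = 6.2
    ms_mean: float = 62.9
    ms_sd: float = 5.4
    horseshoe_r_inner: float = 0.5  # mm
    horseshoe_r_outer: float = 2.5  # mm
    horseshoe_gap_deg: float = 90.0  # angular width of the spared wedge
    horseshoe_gap_dir_deg: float = 180.0  # wedge centre; 180° = temporal for OD
    horseshoe_taper: float = 0.25  # mm, smooth edge width
    anatomy_jitter: float = 0.2  # mm, smooth warp amplitude
    jitter_corr_mm: float = 1.5  # mm, warp correlation length
    noise_sd: float = 3.0  # µm
    ilm_dome_um: float = 300.0  # dome amplitude over the scanned field
    left_eye_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_healthy_eyes, self.n_ms_eyes) < 0:
            raise ValueError("cohort sizes must be non-negative")
        if min(self.healthy_sd, self.ms_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if min(self.healthy_mean, self.ms_mean) <= 0:
            raise ValueError("group means must be positive")
        if self.pixel_pitch is None:
            self.pixel_pitch = 6.0 / (self.grid_shape[1] - 1)


def _radius_mm(shape: tuple[int, int], pitch: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - cx) * pitch
    dy = (yy - cy) * pitch
    return np.hypot(dx, dy), dx, dy


def healthy_profile(
    grid_shape: tuple[int, int], pixel_pitch: float, target_mean: float = 75.9
) -> ThicknessGrid:
    """Deterministic radial foveal-pit template rescaled to ``target_mean``.

    Thin at the foveal centre, annular peak near 1 mm radius, gentle decay
    toward the periphery — the canonical macular GCIPL topography.
    """
    r, _, _ = _radius_mm(grid_shape, pixel_pitch)
    r_peak = 1.0
    base, amp = 3.0, 100.0
    prof = base + amp * (r / r_peak) * np.exp(1.0 - r / r_peak)
    prof *= target_mean / prof.mean()
    return ThicknessGrid(prof, pixel_pitch, EyeSide.RIGHT, "GCIPL")


def _smoothstep(edge0: float, edge1: float, x: np.ndarray) -> np.ndarray:
    u = np.clip((x - edge0) / max(edge1 - edge0, 1e-9), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _horseshoe_weight(cfg: CohortConfig) -> np.ndarray:
    """[0, 1] weight of the horseshoe annulus minus its angular gap.

    Exactly zero outside the annulus and inside the angular gap, with a
    smoothstep taper of width ``horseshoe_taper`` at every edge.
    """
    r, dx, dy = _radius_mm(cfg.grid_shape, cfg.pixel_pitch)
    t = max(cfg.horseshoe_taper, 1e-6)
    radial = _smoothstep(cfg.horseshoe_r_inner, cfg.horseshoe_r_inner + t, r) * (
        1.0 - _smoothstep(cfg.horseshoe_r_outer - t, cfg.horseshoe_r_outer, r)
    )
    theta = np.degrees(np.arctan2(-dy, dx))  # image y grows downward
    dtheta = np.abs((theta - cfg.horseshoe_gap_dir_deg + 180.0) % 360.0 - 180.0)
    half_gap = cfg.horseshoe_gap_deg / 2.0
    r_mid = 0.5 * (cfg.horseshoe_r_inner + cfg.horseshoe_r_outer)
    t_deg = np.degrees(t / r_mid)
    angular = _smoothstep(half_gap, half_gap + t_deg, dtheta)
    return radial * angular


def apply_ms_effect(healthy: ThicknessGrid, cfg: CohortConfig) -> ThicknessGrid:
    """Thin the horseshoe so the map mean drops from healthy_mean to ms_mean."""
    w = _horseshoe_weight(cfg)
    hv = healthy.values
    wm = float((hv * w).mean())
    drop = cfg.healthy_mean - cfg.ms_mean
    if drop > wm:
        raise ValueError("requested mean drop infeasible: horseshoe would go negative")
    scale = drop / wm
    values = hv * (1.0 - scale * w)
    return ThicknessGrid(values, healthy.pixel_pitch, healthy.eye_side, healthy.layer_tag)


def _smooth_displacement(
    shape: tuple[int, int], amplitude_px: float, corr_px: float, rng: np.random.Generator
) -> np.ndarray:
    """(2, h, w) Gaussian-correlated displacement field with RMS ≈ amplitude."""
    disp = rng.standard_normal((2, *shape))
    disp = ndimage.gaussian_filter(disp, sigma=(0, corr_px, corr_px), mode="reflect")
    rms = np.sqrt(np.mean(disp**2))
    if rms > 0 and amplitude_px > 0:
        disp *= amplitude_px / rms
    else:
        disp[:] = 0.0
    return disp


def _warp(values: np.ndarray, disp: np.ndarray) -> np.ndarray:
    h, w = values.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(
        values, [yy + disp[0], xx + disp[1]], order=1, mode="nearest"
    )


def _ilm_dome(cfg: CohortConfig) -> np.ndarray:
    r, _, _ = _radius_mm(cfg.grid_shape, cfg.pixel_pitch)
    half_field = cfg.pixel_pitch * (cfg.grid_shape[1] - 1) / 2.0
    return cfg.ilm_dome_um * np.exp(-(r**2) / (2.0 * (0.8 * half_field) ** 2))


def class_template(cfg: CohortConfig, label: Label) -> ThicknessGrid:
    healthy = healthy_profile(cfg.grid_shape, cfg.pixel_pitch, cfg.healthy_mean)
    if Label(label) == Label.MS:
        return apply_ms_effect(healthy, cfg)
    return healthy


def sample_subject(
    cfg: CohortConfig,
    label: Label,
    rng: np.random.Generator,
    eye_id: str = "eye",
    subject_id: str = "subj",
) -> tuple[SubjectRecord, dict]:
    """Draw one eye: warped, scaled, noisy thickness map + matching ILM surface.

    Returns the record (right-eye orientation unless the draw assigns a left
    eye) and a ground-truth dict with the subject scalar and the displacement
    field statistics.
    """
    label = Label(label)
    template = class_template(cfg, label)
    mean_c, sd_c = (
        (cfg.healthy_mean, cfg.healthy_sd)
        if label == Label.HEALTHY
        else (cfg.ms_mean, cfg.ms_sd)
    )
    scalar = rng.normal(mean_c, sd_c) / mean_c
    scalar = max(scalar, 0.05)

    amp_px = cfg.anatomy_jitter / cfg.pixel_pitch
    corr_px = cfg.jitter_corr_mm / cfg.pixel_pitch
    disp = _smooth_displacement(cfg.grid_shape, amp_px, corr_px, rng)

    thick = _warp(template.values * scalar, disp)
    if cfg.noise_sd > 0:
        thick = thick + rng.normal(0.0, cfg.noise_sd, size=thick.shape)
    thick = np.clip(thick, 0.0, None)
    ilm = _warp(_ilm_dome(cfg), disp)

    side = EyeSide.LEFT if rng.random() < cfg.left_eye_fraction else EyeSide.RIGHT
    tv, iv = thick, ilm
    if side == EyeSide.LEFT:
        tv, iv = tv[:, ::-1].copy(), iv[:, ::-1].copy()

    rec = SubjectRecord(
        subject_id=subject_id,
        eye_id=eye_id,
        label=label,
        thickness=ThicknessGrid(tv, cfg.pixel_pitch, side, "GCIPL"),
        ilm=ThicknessGrid(iv, cfg.pixel_pitch, side, "ILM_elevation"),
    )
    truth = {
        "scalar": float(scalar),
        "disp_rms_px": float(np.sqrt(np.mean(disp**2))),
        "displacement": disp,
    }
    return rec, truth


def generate_cohort(cfg: CohortConfig) -> tuple[list[SubjectRecord], list[dict]]:
    """All eyes of the cohort, healthy first, reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    records, truths = [], []
    for i in range(cfg.n_healthy_eyes):
        rec, tr = sample_subject(cfg, Label.HEALTHY, rng, eye_id=f"H{i:03d}", subject_id=f"HS{i:03d}")
        records.append(rec)
        truths.append(tr)
    for i in range(cfg.n_ms_eyes):
        rec, tr = sample_subject(cfg, Label.MS, rng, eye_id=f"M{i:03d}", subject_id=f"MS{i:03d}")
        records.append(rec)
        truths.append(tr)
    return records, truths


def make_split(
    records: list[SubjectRecord],
    n_train_healthy: int = 28,
    n_train_ms: int = 26,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Seeded random train/test split by eye; returns (train_idx, test_idx)."""
    rng = np.random.default_rng(seed)
    healthy = [i for i, r in enumerate(records) if r.label == Label.HEALTHY]
    ms = [i for i, r in enumerate(records) if r.label == Label.MS]
    if n_train_healthy > len(healthy) or n_train_ms > len(ms):
        raise ValueError("training split exceeds cohort size")
    tr_h = list(rng.choice(healthy, size=n_train_healthy, replace=False))
    tr_m = list(rng.choice(ms, size=n_train_ms, replace=False))
    train = sorted(int(i) for i in tr_h + tr_m)
    test = sorted(set(range(len(records))) - set(train))
    return train, list(test)


def write_cohort(
    records: list[SubjectRecord],
    truths: list[dict],
    out_dir: str | Path,
    format: str = "delimited_text",
) -> Path:
    """Write grids + manifest (+ ground-truth sidecar JSON); returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".npz" if format == "binary_container" else ".csv"
    rows, truth_json = [], {}
    for rec, tr in zip(records, truths):
        tp = out / f"{rec.eye_id}_gcipl{ext}"
        ip = out / f"{rec.eye_id}_ilm{ext}"
        write_grid(rec.thickness, tp, format)
        write_grid(rec.ilm, ip, format)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "eye_id": rec.eye_id,
                "label": rec.label.value,
                "side": rec.thickness.eye_side.value,
                "thickness_path": tp.name,
                "ilm_path": ip.name,
            }
        )
        truth_json[rec.eye_id] = {
            "scalar": tr["scalar"],
            "disp_rms_px": tr["disp_rms_px"],
        }
    manifest = out / "manifest.csv"
    write_manifest(rows, manifest)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    return manifest
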