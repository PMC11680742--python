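"""Synthetic 8-channel head phantom: transmit fields, tissues, SAR model.

The generator emulates the qualitative structure of measured 7T data: an
ellipsoidal head with concentric WM/GM/CSF compartments, azimuthally
arranged transmit channels whose circularly polarized (CP) combination
shows central brightening, a smooth off-resonance field with one localized
hotspot, and a compressed local-SAR model of random Hermitian PSD
virtual-observation-point (VOP) matrices calibrated against a reference CP
pulse.  Everything is deterministic for a fixed seed.

The ``brightening`` parameter controls how strongly the per-channel field
magnitude decays away from each channel and how fast its phase rolls;
``brightening = 1`` yields spatially uniform channel fields (hence a
uniform CP combination), and the default produces a center-to-edge CP
ratio of at least 1.3, as seen with real head coils at 7T.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .sta_core import (GAMMA, KTPointsPulse, SequenceTiming, TransmitSetup,
                       cp_weights, flip_angle_map)
from .safety import SafetyModel, sar_quadratic

__all__ = [
    "PhantomConfig",
    "SafetyConfig",
    "TissueParams",
    "TissueModel",
    "DEFAULT_TISSUES",
    "generate_phantom",
    "generate_safety_model",
    "write_phantom",
]

LABEL_CODES = {"background": 0, "csf": 1, "gm": 2, "wm": 3}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}


# --------------------------------------------------------------------------
# Tissue model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueParams:
    """Two-pool relaxation/exchange parameters of one tissue class.

    Rates in s^-1, times in s.  ``m0s`` is the semisolid pool fraction
    (``m0f = 1 - m0s``); the reverse exchange rate is derived from detailed
    balance, ``k_fs * m0f = k_sf * m0s``, so the pair is always consistent.
    """

    r1f: float
    r1s: float = 3.0
    k_fs: float = 0.0
    m0s: float = 0.0
    t2s: float = 10e-6
    t2f: float = 0.05
    lineshape: str = "gaussian"

    def __post_init__(self) -> None:
        if min(self.r1f, self.r1s, self.k_fs) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.m0s < 1.0:
            raise ValueError("m0s must lie in [0, 1)")
        if self.m0s == 0.0 and self.k_fs != 0.0:
            raise ValueError("k_fs must vanish when there is no semisolid "
                             "pool (detailed balance)")

    @property
    def m0f(self) -> float:
        return 1.0 - self.m0s

    @property
    def k_sf(self) -> float:
        """Reverse exchange rate from detailed balance (0 if no pool)."""
        if self.m0s == 0.0:
            return 0.0
        return self.k_fs * self.m0f / self.m0s


#: Default tissue parameters.  These are config defaults of the phantom,
#: not ground truth for any subject.
DEFAULT_TISSUES: dict[str, TissueParams] = {
    "wm": TissueParams(r1f=0.5, r1s=3.0, k_fs=2.0, m0s=0.13, t2f=0.03),
    "gm": TissueParams(r1f=0.45, r1s=3.0, k_fs=1.0, m0s=0.07, t2f=0.05),
    "csf": TissueParams(r1f=0.25, r1s=3.0, k_fs=0.0, m0s=0.0, t2f=2.0),
}


@dataclass
class TissueModel:
    """Voxelwise tissue labels plus per-label two-pool parameters."""

    labels: np.ndarray                       # (N,) int codes
    params: dict[str, TissueParams]
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int).ravel()
        for name in self.params:
            if name not in LABEL_CODES:
                raise ValueError(f"unknown tissue label {name!r}")

    def param_map(self, attr: str) -> np.ndarray:
        """Per-voxel array of one tissue parameter (0 in background)."""
        out = np.zeros(self.labels.size, float)
        for name, p in self.params.items():
            out[self.labels == LABEL_CODES[name]] = getattr(p, attr)
        return out

    def label_mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_CODES[name]


# --------------------------------------------------------------------------
# Phantom configuration and generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic head phantom."""

    seed: int
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    fov: float = 0.240                       # m, isotropic
    n_channels: int = 8
    brightening: float = 1.8
    coil_radius: float = 0.15                # m
    channel_amplitude: float = 0.0075        # uT/V per channel at isocenter
    b0_range_hz: float = 150.0
    hotspot_sigma: float = 0.018             # m
    head_axes: tuple[float, float, float] = (0.72, 0.86, 0.78)
    shell_radii: tuple[float, float] = (0.78, 0.92)   # wm|gm and gm|csf
    channel_jitter: float = 0.1
    tissues: tuple[tuple[str, TissueParams], ...] = tuple(
        DEFAULT_TISSUES.items())

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 8:
            raise ValueError("grid must be at least 8 voxels per axis")
        if self.fov <= 0:
            raise ValueError("degenerate FOV")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.brightening < 1.0:
            raise ValueError("brightening must be >= 1")


def _grid_coords(grid_shape, fov) -> np.ndarray:
    """RAS voxel-center coordinates (N, 3), meters, grid-centered."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * (fov / n) for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def generate_phantom(config: PhantomConfig) -> tuple[TransmitSetup,
                                                     TissueModel]:
    """Build the synthetic head phantom.

    Returns a :class:`TransmitSetup` (fields, off-resonance, mask, unit
    weights inside the mask) and a :class:`TissueModel` with concentric
    CSF/GM/WM compartments.  Bit-identical for identical config + seed.
    """
    rng = np.random.default_rng(config.seed)
    r = _grid_coords(config.grid_shape, config.fov)
    half = config.fov / 2.0
    semi = np.array(config.head_axes) * half

    rho = np.sqrt(np.sum((r / semi) ** 2, axis=1))
    mask = rho <= 1.0
    if not mask.any():
        raise ValueError("zero-volume head mask")

    # isocenter at the mask centroid
    r = r - r[mask].mean(axis=0)

    labels = np.zeros(r.shape[0], int)
    labels[mask] = LABEL_CODES["csf"]
    labels[mask & (rho <= config.shell_radii[1])] = LABEL_CODES["gm"]
    labels[mask & (rho <= config.shell_radii[0])] = LABEL_CODES["wm"]

    # --- per-channel transmit fields --------------------------------------
    nch = config.n_channels
    b = config.brightening - 1.0
    phi = 2.0 * np.pi * np.arange(nch) / nch
    cx = config.coil_radius * np.cos(phi)
    cy = config.coil_radius * np.sin(phi)

    gains = config.channel_amplitude * (
        1.0 + config.channel_jitter * b * rng.standard_normal(nch))
    psi = 0.2 * b * rng.standard_normal(nch)
    # decay length and phase roll chosen so the default brightening gives a
    # clearly center-bright CP combination
    kappa_a = 6.0      # 1/m, log-magnitude slope per unit (brightening-1)
    kappa_p = 18.0     # rad/m phase roll per unit (brightening-1)

    u = r / half       # normalized coordinates for smooth perturbations
    sens = np.empty((nch, r.shape[0]), complex)
    for q in range(nch):
        d = np.sqrt((r[:, 0] - cx[q]) ** 2 + (r[:, 1] - cy[q]) ** 2
                    + (0.6 * r[:, 2]) ** 2)
        dd = d - config.coil_radius
        c_mag = rng.standard_normal(3)
        c_ph = rng.standard_normal(3)
        pert_mag = 0.05 * b * (u @ c_mag)
        pert_ph = 0.2 * b * (u @ c_ph)
        mag = gains[q] * np.exp(-kappa_a * b * dd + pert_mag)
        phase = phi[q] + psi[q] - kappa_p * b * dd + pert_ph
        sens[q] = mag * np.exp(1j * phase)

    # --- off-resonance: smooth low-order field + one Gaussian hotspot -----
    c1 = rng.standard_normal(3)
    c2 = rng.standard_normal((3, 3))
    c2 = (c2 + c2.T) / 2.0
    smooth = u @ c1 + np.einsum("ni,ij,nj->n", u, c2, u)
    smax = np.abs(smooth[mask]).max()
    smooth = smooth / smax if smax > 0 else smooth
    center = rng.uniform(-0.4, 0.4, size=3) * semi
    hot_sign = rng.choice([-1.0, 1.0])
    hot = hot_sign * np.exp(-np.sum((r - center) ** 2, axis=1)
                            / (2.0 * config.hotspot_sigma ** 2))
    db0 = 0.55 * smooth + 0.75 * hot
    peak = np.abs(db0[mask]).max()
    if peak > 0:
        db0 = db0 * (config.b0_range_hz / peak)

    setup = TransmitSetup(
        voxel_coords=r,
        sensitivities=sens,
        delta_b0=db0,
        mask=mask,
        grid_shape=tuple(config.grid_shape),
    )
    tissue = TissueModel(labels=labels, params=dict(config.tissues),
                         grid_shape=tuple(config.grid_shape))
    return setup, tissue


def cp_field(setup: TransmitSetup) -> np.ndarray:
    """CP-combined |B1+| over in-mask voxels, uT/V of common drive."""
    w = cp_weights(setup.n_channels)
    return np.abs(w @ setup.sensitivities[:, setup.mask])


# --------------------------------------------------------------------------
# Safety model generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SafetyConfig:
    """Parameters of the synthetic SAR model and hardware limits."""

    seed: int
    n_vop: int = 8
    sar_10g_max: float = 20.0
    sar_global_max: float | None = None
    p_max: float = 24.0
    v_max: float = 207.0
    g_amp_max: float = 30e-3
    g_slew_max: float = 80.0
    cp_sar_fraction: float = 0.25
    cp_alpha_des: float = np.deg2rad(15.0)
    global_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.n_vop < 1:
            raise ValueError("need at least one VOP")
        if not 0.0 < self.cp_sar_fraction <= 1.0:
            raise ValueError("cp_sar_fraction must lie in (0, 1]")


def reference_cp_pulse(setup: TransmitSetup, alpha_des: float,
                       tr: float = 8e-3,
                       subpulse_duration: float = 200e-6) -> KTPointsPulse:
    """Single-rectangle CP pulse with the weighted-least-squares optimal
    amplitude for the flip-angle target ``alpha_des`` (rad)."""
    timing = SequenceTiming(tr=tr, subpulse_duration=subpulse_duration,
                            blip_duration=0.0, n_subpulses=1,
                            dt=min(subpulse_duration, 10e-6))
    w = cp_weights(setup.n_channels)
    unit = KTPointsPulse(rf=w[:, None], blip_moments=np.zeros((0, 3)),
                         timing=timing)
    a = flip_angle_map(unit, setup)               # rad per volt
    wt = setup.weights[setup.mask]
    c = float(np.sum(wt * a) * alpha_des / np.sum(wt * a ** 2))
    return unit.scaled(c)


def generate_safety_model(config: SafetyConfig, setup: TransmitSetup,
                          tr: float = 8e-3) -> SafetyModel:
    """Random Hermitian-PSD SAR model calibrated against a CP pulse.

    Q matrices are built as ``A A^H`` from seeded complex Gaussians and
    scaled jointly so the reference CP rectangular pulse reaching the
    15-degree target sits at ``cp_sar_fraction`` of the 10 g local SAR
    limit; the global-SAR matrix is scaled to ``global_fraction`` of the
    reference pulse's local SAR.
    """
    rng = np.random.default_rng(config.seed)
    nch = setup.n_channels

    def _psd() -> np.ndarray:
        a = rng.standard_normal((nch, nch)) + 1j * rng.standard_normal((nch,
                                                                        nch))
        return a @ a.conj().T / nch

    vops_raw = np.array([_psd() for _ in range(config.n_vop)])
    q_raw = _psd()

    ref = reference_cp_pulse(setup, config.cp_alpha_des, tr=tr)
    per_vop = np.array([sar_quadratic(ref, v) for v in vops_raw])
    scale = config.cp_sar_fraction * config.sar_10g_max / per_vop.max()
    vops = vops_raw * scale

    sar_g_raw = sar_quadratic(ref, q_raw)
    target_g = config.global_fraction * config.cp_sar_fraction \
        * config.sar_10g_max
    q_global = q_raw * (target_g / sar_g_raw)

    return SafetyModel(
        q_global=q_global,
        vops=vops,
        sar_10g_max=config.sar_10g_max,
        sar_global_max=config.sar_global_max,
        p_max=config.p_max,
        v_max=config.v_max,
        g_amp_max=config.g_amp_max,
        g_slew_max=config.g_slew_max,
    )


# --------------------------------------------------------------------------
# On-disk representation
# --------------------------------------------------------------------------

def _affine(setup: TransmitSetup) -> np.ndarray:
    """RAS affine (mm) mapping voxel indices to scanner coordinates."""
    shape = setup.grid_shape
    r = setup.voxel_coords.reshape(*shape, 3) * 1000.0
    aff = np.eye(4)
    for i in range(3):
        idx0 = [0, 0, 0]
        idx1 = [0, 0, 0]
        idx1[i] = 1
        aff[:3, i] = r[tuple(idx1)] - r[tuple(idx0)] if shape[i] > 1 else 0.0
    aff[:3, 3] = r[0, 0, 0]
    return aff


def write_phantom(setup: TransmitSetup, tissue: TissueModel,
                  outdir) -> None:
    """Write the phantom as NIfTI volumes (magnitude+phase per channel,
    off-resonance, mask, tissue labels)."""
    import os

    import nibabel as nib

    os.makedirs(outdir, exist_ok=True)
    aff = _affine(setup)
    shape = setup.grid_shape

    def save(arr, name):
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32).reshape(shape),
                                 aff), os.path.join(outdir, name))

    for q in range(setup.n_channels):
        save(np.abs(setup.sensitivities[q]), f"b1_mag_ch{q}.nii.gz")
        save(np.angle(setup.sensitivities[q]), f"b1_phase_ch{q}.nii.gz")
    save(setup.delta_b0, "db0_hz.nii.gz")
    save(setup.mask.astype(np.float32), "mask.nii.gz")
    save(tissue.labels.astype(np.float32), "tissue_labels.nii.gz")
    with open(os.path.join(outdir, "tissues.json"), "w") as fh:
        json.dump({name: vars(p) | {"k_sf": p.k_sf}
                   for name, p in tissue.params.items()}, fh, indent=1)
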