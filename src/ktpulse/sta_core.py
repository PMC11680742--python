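"""Small-tip-angle (STA) forward model for kT-points parallel-transmit pulses.

This module contains the linear physics used by the pulse optimizer:
excitation k-space for blipped gradient trains, the STA system matrix,
flip-angle and sequence-B1rms maps, rectangular-train shape factors and
the analytic lower bound on the B1rms required to reach a given
on-resonance flip angle.

Conventions
-----------
* ``GAMMA`` is the proton gyromagnetic ratio in rad s^-1 T^-1.
* Transmit sensitivities are stored in uT/V, RF amplitudes in volts,
  B1rms maps in uT, flip angles in radians.
* Off-resonance is stored in Hz; the system-matrix phase uses
  ``exp(i 2*pi*dB0*(t - tau))``.
* RF time samples exist only where RF can be non-zero: gradient-blip gaps
  carry no columns of the system matrix.  The excitation k-space is
  sampled at the RF samples only and is piecewise constant (one value per
  subpulse); the final subpulse sits at k = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAMMA",
    "SequenceTiming",
    "TransmitSetup",
    "KTPointsPulse",
    "ShapeFactors",
    "cp_weights",
    "excitation_kspace",
    "system_matrix",
    "flip_angle_map",
    "b1rms_map",
    "pulse_shape_factors",
    "kt_waveform",
    "beta_min",
    "kt_beta_min",
    "nrmse",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA = 2.6752218744e8


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceTiming:
    """Timing of a repeating spoiled gradient-echo excitation block.

    The RF pulse is a train of ``n_subpulses`` ideal rectangular subpulses
    of ``subpulse_duration`` seconds separated by ``blip_duration`` gaps
    during which gradient blips play and the RF is off.
    """

    tr: float = 8e-3
    subpulse_duration: float = 200e-6
    blip_duration: float = 100e-6
    n_subpulses: int = 5
    dt: float = 10e-6

    def __post_init__(self) -> None:
        if self.n_subpulses < 1:
            raise ValueError("n_subpulses must be >= 1")
        if self.subpulse_duration <= 0 or self.dt <= 0:
            raise ValueError("durations must be positive")
        if self.n_subpulses > 1 and self.blip_duration <= 0:
            raise ValueError("blip_duration must be positive")
        n = self.subpulse_duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt must divide subpulse_duration")
        if self.tr <= self.tau:
            raise ValueError("TR must exceed the total pulse duration")

    @property
    def tau(self) -> float:
        """Total pulse duration (subpulses + blip gaps), seconds."""
        return (self.n_subpulses * self.subpulse_duration
                + (self.n_subpulses - 1) * self.blip_duration)

    @property
    def samples_per_subpulse(self) -> int:
        return round(self.subpulse_duration / self.dt)

    @property
    def n_time_samples(self) -> int:
        """Number of RF-on samples (blip gaps carry no samples)."""
        return self.n_subpulses * self.samples_per_subpulse

    @property
    def sample_times(self) -> np.ndarray:
        """Times of every RF-on sample (right edge of each dt bin),
        seconds from pulse start; the final sample sits exactly at tau."""
        nsps = self.samples_per_subpulse
        starts = np.arange(self.n_subpulses) * (self.subpulse_duration
                                                + self.blip_duration)
        within = (np.arange(nsps) + 1.0) * self.dt
        return (starts[:, None] + within[None, :]).ravel()

    @property
    def sample_subpulse_index(self) -> np.ndarray:
        """Subpulse index of every RF-on sample."""
        return np.repeat(np.arange(self.n_subpulses), self.samples_per_subpulse)

    def to_dict(self) -> dict:
        return {
            "tr_s": self.tr,
            "subpulse_duration_s": self.subpulse_duration,
            "blip_duration_s": self.blip_duration,
            "n_subpulses": self.n_subpulses,
            "dt_s": self.dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceTiming":
        return cls(tr=d["tr_s"], subpulse_duration=d["subpulse_duration_s"],
                   blip_duration=d["blip_duration_s"],
                   n_subpulses=d["n_subpulses"], dt=d["dt_s"])


@dataclass
class TransmitSetup:
    """Spatial half of the STA forward model.

    Arrays are flattened over the full grid (C order).  ``mask`` selects the
    voxels that enter any computation; ``weights`` is the diagonal of the
    error-weight matrix and is forced to zero outside the mask.

    Parameters
    ----------
    voxel_coords
        (N, 3) voxel-center positions in meters, relative to isocenter.
    sensitivities
        (N_ch, N) complex transmit sensitivities, uT/V.
    delta_b0
        (N,) off-resonance, Hz.
    mask
        (N,) boolean.
    weights
        (N,) non-negative error weights; defaults to 1 inside the mask.
    grid_shape
        Original 3-D shape, or ``None`` for non-gridded (e.g. clustered)
        setups.
    """

    voxel_coords: np.ndarray
    sensitivities: np.ndarray
    delta_b0: np.ndarray
    mask: np.ndarray
    weights: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None
    m0: float = 1.0

    def __post_init__(self) -> None:
        self.voxel_coords = np.atleast_2d(np.asarray(self.voxel_coords, float))
        self.sensitivities = np.atleast_2d(np.asarray(self.sensitivities,
                                                      complex))
        self.delta_b0 = np.asarray(self.delta_b0, float).ravel()
        self.mask = np.asarray(self.mask, bool).ravel()
        n = self.voxel_coords.shape[0]
        if self.sensitivities.shape[1] != n or self.delta_b0.size != n \
                or self.mask.size != n:
            raise ValueError("inconsistent voxel counts in TransmitSetup")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if not np.all(np.isfinite(self.sensitivities)):
            raise ValueError("non-finite transmit sensitivities")
        if self.weights is None:
            self.weights = self.mask.astype(float)
        else:
            self.weights = np.asarray(self.weights, float).ravel()
            if self.weights.size != n:
                raise ValueError("weights size mismatch")
            if (self.weights < 0).any():
                raise ValueError("weights must be non-negative")
            self.weights = np.where(self.mask, self.weights, 0.0)

    @property
    def n_channels(self) -> int:
        return self.sensitivities.shape[0]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked(self) -> "TransmitSetup":
        """Compact copy retaining only in-mask voxels (no grid)."""
        m = self.mask
        return TransmitSetup(
            voxel_coords=self.voxel_coords[m],
            sensitivities=self.sensitivities[:, m],
            delta_b0=self.delta_b0[m],
            mask=np.ones(int(m.sum()), bool),
            weights=self.weights[m],
            grid_shape=None,
            m0=self.m0,
        )

    def embed(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Place per-masked-voxel values back onto the 3-D grid."""
        if self.grid_shape is None:
            raise ValueError("setup has no grid to embed into")
        out = np.full(self.mask.size, fill, dtype=np.asarray(values).dtype)
        out[self.mask] = values
        return out.reshape(self.grid_shape)


@dataclass
class KTPointsPulse:
    """A kT-points pulse: per-channel subpulse amplitudes and blip moments.

    ``rf`` is (N_ch, n_subpulses) complex volts (one constant amplitude per
    rectangular subpulse); ``blip_moments`` is (n_subpulses-1, 3) excitation
    k-space increments in rad/m realized by the inter-subpulse gradient
    blips.
    """

    rf: np.ndarray
    blip_moments: np.ndarray
    timing: SequenceTiming

    def __post_init__(self) -> None:
        self.rf = np.atleast_2d(np.asarray(self.rf, complex))
        self.blip_moments = np.asarray(self.blip_moments, float).reshape(-1, 3) \
            if np.size(self.blip_moments) else np.zeros((0, 3))
        if self.rf.shape[1] != self.timing.n_subpulses:
            raise ValueError("rf must have one column per subpulse")
        if self.blip_moments.shape[0] != self.timing.n_subpulses - 1:
            raise ValueError("need n_subpulses - 1 blip moments")

    @property
    def n_channels(self) -> int:
        return self.rf.shape[0]

    def per_sample_rf(self) -> np.ndarray:
        """Expand to (N_ch, N_t) per-RF-sample amplitudes, volts."""
        return np.repeat(self.rf, self.timing.samples_per_subpulse, axis=1)

    def scaled(self, c: complex) -> "KTPointsPulse":
        return replace(self, rf=self.rf * c)

    def to_json(self, path=None) -> str:
        d = {
            "rf_V": [[[float(v.real), float(v.imag)] for v in row]
                     for row in self.rf],
            "blip_moments_rad_per_m": self.blip_moments.tolist(),
            "timing": self.timing.to_dict(),
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "KTPointsPulse":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        rf = np.array([[complex(re, im) for re, im in row]
                       for row in d["rf_V"]])
        return cls(rf=rf, blip_moments=np.array(d["blip_moments_rad_per_m"]),
                   timing=SequenceTiming.from_dict(d["timing"]))


@dataclass(frozen=True)
class ShapeFactors:
    """Normalized-waveform integrals of a unit-duration, unit-amplitude
    envelope: ``p1`` is its mean, ``p2`` the mean of its squared modulus."""

    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p2 <= 1.0 + 1e-12):
            raise ValueError("p2 must lie in (0, 1]")
        if abs(self.p1) > np.sqrt(self.p2) + 1e-12:
            raise ValueError("|p1| <= sqrt(p2) violated (Cauchy-Schwarz)")


def cp_weights(n_channels: int) -> np.ndarray:
    """Circularly polarized drive weights, ``exp(-i 2 pi q / N_ch)``."""
    q = np.arange(n_channels)
    return np.exp(-2j * np.pi * q / n_channels)


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------

def excitation_kspace(pulse: KTPointsPulse) -> np.ndarray:
    """Excitation k-space at every RF sample, rad/m, shape (N_t, 3).

    k(t) is minus the remaining gradient-moment integral, so the last
    subpulse sits at k = 0 and subpulse j accumulates the negatives of all
    subsequent blip moments.  Within each subpulse k is constant (no
    gradients during RF-on intervals).
    """
    k_sub = subpulse_kspace(pulse.blip_moments, pulse.timing.n_subpulses)
    return k_sub[pulse.timing.sample_subpulse_index]


def subpulse_kspace(blip_moments: np.ndarray, n_subpulses: int) -> np.ndarray:
    """Per-subpulse k-space locations, shape (n_subpulses, 3), rad/m."""
    blips = np.asarray(blip_moments, float).reshape(-1, 3)
    k = np.zeros((n_subpulses, 3))
    if blips.shape[0]:
        # reversed cumulative sum: k_j = -sum_{p >= j} dk_p
        k[:-1] = -np.cumsum(blips[::-1], axis=0)[::-1]
    return k


def system_matrix(setup: TransmitSetup, timing: SequenceTiming,
                  k: np.ndarray) -> np.ndarray:
    """STA system matrix over in-mask voxels, shape (N_masked, N_t).

    ``A[m, n] = i * GAMMA * m0 * dt * exp(i 2 pi dB0_m (t_n - tau))
    * exp(i r_m . k_n)``.  Units: rad per Tesla of combined field, i.e.
    multiplying by the per-sample combined B1+ in Tesla and summing over
    samples yields the transverse magnetization phase-area (flip angle
    after taking the modulus and dividing by m0).
    """
    k = np.asarray(k, float)
    if k.shape != (timing.n_time_samples, 3):
        raise ValueError("k must have one 3-vector per RF sample")
    m = setup.mask
    t = timing.sample_times
    phase_b0 = 2.0 * np.pi * np.outer(setup.delta_b0[m], t - timing.tau)
    phase_k = setup.voxel_coords[m] @ k.T
    return (1j * GAMMA * setup.m0 * timing.dt
            * np.exp(1j * (phase_b0 + phase_k)))


def flip_angle_map(pulse: KTPointsPulse, setup: TransmitSetup,
                   A: np.ndarray | None = None) -> np.ndarray:
    """STA flip-angle map over in-mask voxels, radians.

    ``alpha_m = | sum_q s_q(r_m) (A b_q)_m | / m0`` with sensitivities
    converted from uT/V to T/V.  Linear in the overall RF scale.
    """
    timing = pulse.timing
    if A is None:
        A = system_matrix(setup, timing, excitation_kspace(pulse))
    b = pulse.per_sample_rf()                       # (N_ch, N_t) volts
    s = setup.sensitivities[:, setup.mask] * 1e-6   # (N_ch, N_masked) T/V
    z = np.einsum("qm,mn,qn->m", s, A, b, optimize=True)
    return np.abs(z) / setup.m0


def b1rms_map(pulse: KTPointsPulse, setup: TransmitSetup) -> np.ndarray:
    """Sequence B1rms map over in-mask voxels, uT.

    ``beta_m = sqrt((1/TR) sum_n dt |sum_q s_q(r_m) b_q(t_n)|^2)``; the
    squared modulus of the complex combined field makes beta real.
    Independent of the blip moments.
    """
    timing = pulse.timing
    s = setup.sensitivities[:, setup.mask]          # uT/V
    f = s.T @ pulse.rf                              # (N_masked, n_sub) uT
    return np.sqrt(timing.subpulse_duration / timing.tr
                   * np.sum(np.abs(f) ** 2, axis=1))


# --------------------------------------------------------------------------
# Shape factors and the B1rms lower bound
# --------------------------------------------------------------------------

def pulse_shape_factors(waveform: np.ndarray) -> ShapeFactors:
    """Shape factors of a unit-amplitude envelope sampled uniformly over
    the pulse duration: ``p1 = mean(w)``, ``p2 = mean(|w|^2)``."""
    w = np.asarray(waveform)
    if w.size == 0:
        raise ValueError("empty waveform")
    if not np.isclose(np.max(np.abs(w)), 1.0, atol=1e-9):
        raise ValueError("waveform must be normalized to unit amplitude")
    p1 = float(np.mean(np.real(w)))
    p2 = float(np.mean(np.abs(w) ** 2))
    return ShapeFactors(p1=p1, p2=p2)


def kt_waveform(timing: SequenceTiming) -> np.ndarray:
    """Unit-amplitude binary envelope of the kT-points train, sampled at
    ``dt`` over the full duration tau (blip gaps are zeros)."""
    nsps = timing.samples_per_subpulse
    nblip = round(timing.blip_duration / timing.dt)
    chunks = []
    for j in range(timing.n_subpulses):
        chunks.append(np.ones(nsps))
        if j < timing.n_subpulses - 1:
            chunks.append(np.zeros(nblip))
    return np.concatenate(chunks)


def beta_min(alpha_des: float, shape: ShapeFactors, tr: float,
             tau: float) -> float:
    """Minimum sequence B1rms (uT) able to produce an on-resonance flip
    angle ``alpha_des`` (rad) with the given envelope shape.

    ``beta_min = alpha_des * sqrt(p2) / (GAMMA * p1 * sqrt(TR * tau))``.
    Invariant under zero-padding of the envelope (tau, p1, p2 referred to
    the same support).
    """
    if alpha_des < 0:
        raise ValueError("alpha_des must be >= 0")
    if shape.p1 <= 0:
        raise ValueError("p1 must be positive: waveform produces no "
                         "on-resonance flip")
    b_tesla = alpha_des * np.sqrt(shape.p2) / (GAMMA * shape.p1
                                               * np.sqrt(tr * tau))
    return float(b_tesla * 1e6)


def kt_beta_min(alpha_des: float, timing: SequenceTiming) -> float:
    """`beta_min` for the rectangular kT-points train of ``timing``, uT."""
    shape = pulse_shape_factors(kt_waveform(timing))
    return beta_min(alpha_des, shape, timing.tr, timing.tau)


def nrmse(x: np.ndarray, x_des, weights: np.ndarray | None = None) -> float:
    """Weighted root-mean-square error of ``x`` about the target,
    normalized by the weighted norm of the target."""
    x = np.asarray(x, float)
    xd = np.broadcast_to(np.asarray(x_des, float), x.shape)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    denom = float(np.sum(w * xd ** 2))
    if denom <= 0:
        raise ValueError("target has zero weighted norm")
    return float(np.sqrt(np.sum(w * (x - xd) ** 2) / denom))
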