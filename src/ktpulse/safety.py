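"""Hardware and SAR constraint evaluation for parallel-transmit pulses.

Local SAR uses a virtual-observation-point (VOP) compressed model: a list
of Hermitian positive-semidefinite channel-correlation matrices whose
time-averaged quadratic forms upper-bound the 10 g-averaged SAR.  Per-channel
average power is defined as forward power into a 50 Ohm load,
``P_q = mean_TR(|v_q(t)|^2) / (2 * 50)`` — note this definition rescales
what a given P_max limit means and is stated here deliberately.
Gradient feasibility is expressed on blip *moments*: each inter-subpulse
blip is a symmetric triangle/trapezoid, so the amplitude and slew limits
reduce exactly to a per-axis box bound on the achievable moment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .sta_core import GAMMA, KTPointsPulse, SequenceTiming

__all__ = [
    "SafetyModel",
    "ConstraintReport",
    "sar_quadratic",
    "local_sar",
    "channel_power",
    "max_blip_moment",
    "constraint_report",
]

#: Load impedance used in the forward-power definition, Ohm.
Z0 = 50.0

_HERM_TOL = 1e-10


def _check_hermitian_psd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, complex)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    scale = max(np.linalg.norm(m), 1.0)
    if np.linalg.norm(m - m.conj().T) > 1e-9 * scale:
        raise ValueError(f"{name} is not Hermitian")
    ev = np.linalg.eigvalsh(m)
    if ev.min() < -_HERM_TOL * scale:
        raise ValueError(f"{name} is not positive semidefinite")
    return m


@dataclass
class SafetyModel:
    """SAR matrices and hardware limits.

    ``q_global`` and every VOP are Hermitian PSD N_ch x N_ch matrices in
    W kg^-1 V^-2.  ``sar_global_max`` is optional (disabled when None,
    since regulatory first-level mode fixes no single universal number).
    """

    q_global: np.ndarray
    vops: np.ndarray
    sar_10g_max: float = 20.0       # W/kg
    sar_global_max: float | None = None
    p_max: float = 24.0             # W per channel
    v_max: float = 207.0            # V per channel
    g_amp_max: float = 30e-3        # T/m
    g_slew_max: float = 80.0        # T/m/s

    def __post_init__(self) -> None:
        self.q_global = _check_hermitian_psd(self.q_global, "Q_global")
        vops = np.asarray(self.vops, complex)
        if vops.ndim != 3 or vops.shape[0] < 1:
            raise ValueError("need at least one VOP matrix")
        for i in range(vops.shape[0]):
            _check_hermitian_psd(vops[i], f"VOP[{i}]")
        self.vops = vops

    @property
    def n_channels(self) -> int:
        return self.q_global.shape[0]

    @property
    def n_vop(self) -> int:
        return self.vops.shape[0]

    def to_json(self, path=None) -> str:
        def cplx(m):
            return [[[float(v.real), float(v.imag)] for v in row]
                    for row in np.asarray(m)]

        d = {
            "q_global_W_per_kg_V2": cplx(self.q_global),
            "vops_W_per_kg_V2": [cplx(v) for v in self.vops],
            "limits": {
                "sar_10g_max_W_per_kg": self.sar_10g_max,
                "sar_global_max_W_per_kg": self.sar_global_max,
                "p_max_W": self.p_max,
                "v_max_V": self.v_max,
                "g_amp_max_T_per_m": self.g_amp_max,
                "g_slew_max_T_per_m_s": self.g_slew_max,
            },
        }
        s = json.dumps(d)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "SafetyModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)

        def uncplx(m):
            return np.array([[complex(re, im) for re, im in row] for row in m])

        lim = d["limits"]
        return cls(
            q_global=uncplx(d["q_global_W_per_kg_V2"]),
            vops=np.array([uncplx(v) for v in d["vops_W_per_kg_V2"]]),
            sar_10g_max=lim["sar_10g_max_W_per_kg"],
            sar_global_max=lim["sar_global_max_W_per_kg"],
            p_max=lim["p_max_W"],
            v_max=lim["v_max_V"],
            g_amp_max=lim["g_amp_max_T_per_m"],
            g_slew_max=lim["g_slew_max_T_per_m_s"],
        )


@dataclass
class ConstraintReport:
    """Every operational constraint evaluated for one pulse."""

    sar_global: float
    sar_local_max: float
    sar_local_argmax: int
    sar_local_per_vop: np.ndarray
    power_per_channel: np.ndarray
    peak_voltage_per_channel: np.ndarray
    blip_feasible: np.ndarray        # (n_blips,) bool
    margins: dict = field(default_factory=dict)
    all_satisfied: bool = False

    def to_json(self, path=None) -> str:
        d = {
            "sar_global_W_per_kg": self.sar_global,
            "sar_local_max_W_per_kg": self.sar_local_max,
            "sar_local_argmax_vop": int(self.sar_local_argmax),
            "sar_local_per_vop_W_per_kg": self.sar_local_per_vop.tolist(),
            "power_per_channel_W": self.power_per_channel.tolist(),
            "peak_voltage_per_channel_V":
                self.peak_voltage_per_channel.tolist(),
            "blip_feasible": self.blip_feasible.tolist(),
            "margins": {k: float(v) for k, v in self.margins.items()},
            "all_satisfied": bool(self.all_satisfied),
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def margin_table(self) -> str:
        lines = [f"{'constraint':24s} {'margin':>10s}"]
        for k, v in self.margins.items():
            lines.append(f"{k:24s} {v:10.4f}")
        lines.append(f"all satisfied: {self.all_satisfied}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Constraint primitives
# --------------------------------------------------------------------------

def sar_quadratic(pulse: KTPointsPulse, q: np.ndarray,
                  tr: float | None = None) -> float:
    """Time-averaged SAR quadratic form, ``(1/TR) sum_n dt b^H Q b``.

    With subpulse-constant RF this is
    ``(subpulse_duration/TR) * sum_j b_j^H Q b_j``.
    """
    q = np.asarray(q, complex)
    if np.linalg.norm(q - q.conj().T) > 1e-9 * max(np.linalg.norm(q), 1.0):
        raise ValueError("Q must be Hermitian")
    tr = pulse.timing.tr if tr is None else tr
    b = pulse.rf  # (N_ch, n_sub)
    val = np.einsum("qj,qp,pj->", b.conj(), q, b).real
    return float(pulse.timing.subpulse_duration / tr * val)


def local_sar(pulse: KTPointsPulse,
              safety: SafetyModel) -> tuple[float, np.ndarray]:
    """Max and per-VOP local SAR, W/kg."""
    if safety.n_vop < 1:
        raise ValueError("empty VOP list")
    per_vop = np.array([sar_quadratic(pulse, v) for v in safety.vops])
    return float(per_vop.max()), per_vop


def channel_power(pulse: KTPointsPulse,
                  timing: SequenceTiming | None = None) -> np.ndarray:
    """Duty-averaged forward power per channel, W.

    ``P_q = (1/TR) sum_n dt |b_q(t_n)|^2 / (2 Z0)``.
    """
    timing = pulse.timing if timing is None else timing
    e = np.sum(np.abs(pulse.rf) ** 2, axis=1) * timing.subpulse_duration
    return e / timing.tr / (2.0 * Z0)


def max_blip_moment(blip_duration: float, g_amp_max: float,
                    g_slew_max: float) -> float:
    """Largest per-axis k-space increment (rad/m) a symmetric
    triangle/trapezoid blip can realize within ``blip_duration``."""
    if blip_duration < 0 or g_amp_max <= 0 or g_slew_max <= 0:
        raise ValueError("blip parameters must be positive")
    if blip_duration == 0:
        return 0.0
    ramp_peak = g_slew_max * blip_duration / 2.0
    if ramp_peak <= g_amp_max:
        area = blip_duration ** 2 * g_slew_max / 4.0       # triangle
    else:
        area = g_amp_max * (blip_duration - g_amp_max / g_slew_max)
    return float(GAMMA * area)


def constraint_report(pulse: KTPointsPulse,
                      safety: SafetyModel) -> ConstraintReport:
    """Evaluate every constraint and its relative margin, (limit-value)/limit."""
    sar_g = sar_quadratic(pulse, safety.q_global)
    sar_l_max, per_vop = local_sar(pulse, safety)
    power = channel_power(pulse)
    vpeak = np.abs(pulse.rf).max(axis=1)
    dk_max = max_blip_moment(pulse.timing.blip_duration, safety.g_amp_max,
                             safety.g_slew_max)
    blip_ok = (np.abs(pulse.blip_moments) <= dk_max + 1e-9).all(axis=1) \
        if pulse.blip_moments.size else np.ones(0, bool)

    margins = {}
    if safety.sar_global_max is not None:
        margins["sar_global"] = (safety.sar_global_max - sar_g) \
            / safety.sar_global_max
    margins["sar_local"] = (safety.sar_10g_max - sar_l_max) \
        / safety.sar_10g_max
    margins["power"] = (safety.p_max - power.max()) / safety.p_max
    margins["voltage"] = (safety.v_max - vpeak.max()) / safety.v_max
    if pulse.blip_moments.size:
        worst = np.abs(pulse.blip_moments).max()
        margins["blip_moment"] = (dk_max - worst) / dk_max if dk_max > 0 \
            else -np.inf
    ok = all(v >= 0 for v in margins.values())
    return ConstraintReport(
        sar_global=float(sar_g),
        sar_local_max=sar_l_max,
        sar_local_argmax=int(np.argmax(per_vop)),
        sar_local_per_vop=per_vop,
        power_per_channel=power,
        peak_voltage_per_channel=vpeak,
        blip_feasible=np.asarray(blip_ok, bool),
        margins=margins,
        all_satisfied=ok,
    )
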