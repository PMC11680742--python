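"""Hybrid flip-angle / B1rms kT-points pulse optimization.

The design variable is the stack of per-channel complex subpulse
amplitudes (as interleaved real/imaginary parts) and the inter-subpulse
gradient-blip moments.  The cost is the convex combination of *squared*
normalized errors

    (1 - lambda) * NRMSE(alpha)^2 + lambda * NRMSE(beta)^2,

minimized subject to local/global SAR quadratic forms, per-channel average
power, peak voltage, and per-axis box bounds on the blip moments (exact
for symmetric triangle/trapezoid blips).  A multi-start strategy with
seeded random initializations guards against the non-convexity introduced
by the magnitude target; reported maps and errors are always recomputed on
the full (uncompressed) voxel set.

lambda = 0 reproduces a pure flip-angle design; lambda = 1 a pure-B1rms
(saturation-homogeneity) design, for which the blips are retained but
irrelevant.  Reported NRMSE values are the square roots of the two cost
terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .safety import (ConstraintReport, SafetyModel, constraint_report,
                     max_blip_moment)
from .sta_core import (GAMMA, KTPointsPulse, SequenceTiming, ShapeFactors,
                       TransmitSetup, cp_weights, kt_beta_min, nrmse)

__all__ = [
    "DesignSpec",
    "DesignResult",
    "cp_pulse",
    "rf_shim_mls",
    "cluster_compress",
    "hybrid_design",
    "pareto_sweep",
    "log_lambda_grid",
]


@dataclass(frozen=True)
class DesignSpec:
    """Targets and solver settings of one hybrid design."""

    alpha_des: float                 # rad
    beta_des: float = 0.0            # uT
    lam: float = 0.5
    n_starts: int = 10
    seed: int = 0
    n_clusters: int = 500            # 0 disables voxel compression
    maxiter: int = 500
    ftol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.beta_des < 0:
            raise ValueError("beta_des must be >= 0")
        if self.n_starts < 1:
            raise ValueError("need at least one start")


@dataclass
class DesignResult:
    """Optimized pulse with achieved maps, errors and provenance."""

    pulse: KTPointsPulse
    alpha_map: np.ndarray            # rad, over in-mask voxels (full setup)
    beta_map: np.ndarray             # uT
    nrmse_alpha: float
    nrmse_beta: float
    cost: float
    constraints: ConstraintReport | None
    start_costs: list = field(default_factory=list)
    start_index: int = 0
    converged: bool = True
    mode: str = "hybrid"


def _result(pulse, setup, alpha_des, beta_des, lam, safety, **kw):
    from .sta_core import b1rms_map, flip_angle_map

    wt = setup.weights[setup.mask]
    amap = flip_angle_map(pulse, setup)
    bmap = b1rms_map(pulse, setup)
    na = nrmse(amap, alpha_des, wt)
    nb = nrmse(bmap, beta_des, wt) if beta_des > 0 else np.nan
    cost = (1.0 - lam) * na ** 2 + (lam * nb ** 2 if lam > 0 else 0.0)
    rep = constraint_report(pulse, safety) if safety is not None else None
    return DesignResult(pulse=pulse, alpha_map=amap, beta_map=bmap,
                        nrmse_alpha=na, nrmse_beta=nb, cost=cost,
                        constraints=rep, **kw)


# --------------------------------------------------------------------------
# Baselines: CP mode and magnitude-least-squares RF shimming
# --------------------------------------------------------------------------

def _single_subpulse_timing(tr: float, subpulse_duration: float = 200e-6,
                            dt: float = 10e-6) -> SequenceTiming:
    return SequenceTiming(tr=tr, subpulse_duration=subpulse_duration,
                          blip_duration=0.0, n_subpulses=1, dt=dt)


def cp_pulse(setup: TransmitSetup, alpha_des: float,
             timing: SequenceTiming | None = None,
             safety: SafetyModel | None = None) -> DesignResult:
    """Circularly polarized single-rectangle pulse with the closed-form
    amplitude minimizing the weighted flip-angle MSE.

    With per-volt CP flip angles ``a_m`` the optimal real amplitude is
    ``c* = sum(W a alpha_des) / sum(W a^2)``.
    """
    from .sta_core import flip_angle_map

    timing = timing or _single_subpulse_timing(8e-3)
    w = cp_weights(setup.n_channels)
    unit = KTPointsPulse(rf=np.repeat(w[:, None], timing.n_subpulses, axis=1),
                         blip_moments=np.zeros((timing.n_subpulses - 1, 3)),
                         timing=timing)
    a = flip_angle_map(unit, setup)
    if np.allclose(a, 0.0):
        raise ValueError("CP combined field is identically zero")
    wt = setup.weights[setup.mask]
    c = float(np.sum(wt * a) * alpha_des / np.sum(wt * a ** 2))
    return _result(unit.scaled(c), setup, alpha_des, 0.0, 0.0, safety,
                   mode="cp", start_costs=[], converged=True)


def rf_shim_mls(setup: TransmitSetup, alpha_des: float,
                timing: SequenceTiming | None = None, seed: int = 0,
                n_starts: int = 10, n_iter: int = 60,
                safety: SafetyModel | None = None) -> DesignResult:
    """Static RF shim by magnitude least squares (variable exchange).

    A single-rectangle pulse with free per-channel complex weights; each
    iteration re-phases the target to the current field phase and solves
    the resulting weighted linear least squares, so the objective is
    monotone non-increasing.  The best of ``n_starts`` runs is returned
    (start 0 is the optimally scaled CP mode).
    """
    from .sta_core import system_matrix, excitation_kspace

    timing = timing or _single_subpulse_timing(8e-3)
    if timing.n_subpulses != 1:
        raise ValueError("RF shimming uses a single-subpulse structure")
    nch = setup.n_channels
    blips = np.zeros((0, 3))
    probe = KTPointsPulse(rf=np.ones((nch, 1)), blip_moments=blips,
                          timing=timing)
    A = system_matrix(setup, timing, excitation_kspace(probe))
    # alpha_m(w) = |G_m . w|, G = diag-sens row-sums of A per channel
    s = setup.sensitivities[:, setup.mask] * 1e-6
    g = (s * A.sum(axis=1)[None, :]).T          # (N, N_ch), complex rad/V
    wt = setup.weights[setup.mask]
    sw = np.sqrt(wt)

    rng = np.random.default_rng(seed)
    best = None
    histories = []
    for istart in range(n_starts):
        if istart == 0:
            w0 = cp_weights(nch)
            a = np.abs(g @ w0)
            w = w0 * (np.sum(wt * a) * alpha_des / np.sum(wt * a ** 2))
        else:
            w = (rng.standard_normal(nch) + 1j * rng.standard_normal(nch))
            a = np.abs(g @ w)
            w = w * (np.sum(wt * a) * alpha_des / np.sum(wt * a ** 2))
        hist = []
        for _ in range(n_iter):
            z = g @ w
            hist.append(float(np.sum(wt * (np.abs(z) - alpha_des) ** 2)))
            target = alpha_des * np.exp(1j * np.angle(z))
            w, *_ = np.linalg.lstsq(sw[:, None] * g, sw * target, rcond=None)
        z = g @ w
        cost = float(np.sum(wt * (np.abs(z) - alpha_des) ** 2))
        hist.append(cost)
        histories.append(hist)
        if best is None or cost < best[0]:
            best = (cost, w, istart)
    pulse = KTPointsPulse(rf=best[1][:, None], blip_moments=blips,
                          timing=timing)
    res = _result(pulse, setup, alpha_des, 0.0, 0.0, safety, mode="shim",
                  start_costs=[h[-1] for h in histories],
                  start_index=best[2], converged=True)
    res.iteration_history = histories[best[2]]
    return res


# --------------------------------------------------------------------------
# Voxel compression
# --------------------------------------------------------------------------

def cluster_compress(setup: TransmitSetup, n_clusters: int,
                     seed: int = 0) -> tuple[TransmitSetup, np.ndarray]:
    """Compress in-mask voxels by k-means on standardized feature vectors
    [Re s_q, Im s_q (all q), dB0, x, y, z].

    The compressed setup carries the cluster centroids (un-standardized)
    and uses the summed voxel weights (cluster sizes for unit weights) as
    its error weights, so the weighted objective approximates the full
    one.  Returns the compressed setup and the per-masked-voxel cluster
    index.
    """
    from sklearn.cluster import KMeans

    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    compact = setup.masked()
    n = compact.n_masked
    if n_clusters > n:
        raise ValueError("more clusters than masked voxels")

    s = compact.sensitivities
    feats = np.concatenate([s.real.T, s.imag.T,
                            compact.delta_b0[:, None],
                            compact.voxel_coords], axis=1)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd

    if n_clusters == n:
        labels = np.arange(n)
        centers = feats
    else:
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=4)
        labels = km.fit_predict(z)
        centers = km.cluster_centers_ * sd + mu

    nch = compact.n_channels
    sens_c = (centers[:, :nch] + 1j * centers[:, nch:2 * nch]).T
    db0_c = centers[:, 2 * nch]
    coords_c = centers[:, 2 * nch + 1:]
    wsum = np.bincount(labels, weights=compact.weights,
                       minlength=n_clusters)
    comp = TransmitSetup(voxel_coords=coords_c, sensitivities=sens_c,
                         delta_b0=db0_c, mask=np.ones(n_clusters, bool),
                         weights=wsum, grid_shape=None, m0=compact.m0)
    return comp, labels


# --------------------------------------------------------------------------
# Hybrid optimization
# --------------------------------------------------------------------------

class _HybridObjective:
    """Cost, analytic gradient and constraints on a (possibly compressed)
    setup.  Parameter vector: [Re rf, Im rf, blip moments], with rf
    flattened channel-major."""

    def __init__(self, setup: TransmitSetup, safety: SafetyModel,
                 spec: DesignSpec, timing: SequenceTiming,
                 include_beta: bool | None = None):
        self.timing = timing
        self.spec = spec
        self.safety = safety
        m = setup.mask
        self.s_ut = setup.sensitivities[:, m]            # uT/V
        self.s_t = self.s_ut * 1e-6
        self.r = setup.voxel_coords[m]
        self.wt = setup.weights[m]
        self.nch = setup.n_channels
        self.nsub = timing.n_subpulses
        self.nblip = self.nsub - 1
        self.nrf = self.nch * self.nsub

        t = timing.sample_times
        sub_idx = timing.sample_subpulse_index
        ph = np.exp(2j * np.pi * np.outer(setup.delta_b0[m],
                                          t - timing.tau))
        # per-subpulse off-resonance sums E_mj
        self.E = np.stack([ph[:, sub_idx == j].sum(axis=1)
                           for j in range(self.nsub)], axis=1)
        self.pref = 1j * GAMMA * timing.dt               # rad per T
        self.duty = timing.subpulse_duration / timing.tr
        self.sumw = float(self.wt.sum())
        self.norm_a = spec.alpha_des ** 2 * self.sumw
        lam = spec.lam
        self.include_beta = (lam > 0) if include_beta is None \
            else include_beta
        self.norm_b = spec.beta_des ** 2 * self.sumw if self.include_beta \
            else 1.0
        self.lam = lam
        self.dk_max = max_blip_moment(timing.blip_duration,
                                      safety.g_amp_max, safety.g_slew_max)

    # -- parameter packing -------------------------------------------------
    def pack(self, rf: np.ndarray, blips: np.ndarray) -> np.ndarray:
        return np.concatenate([rf.real.ravel(), rf.imag.ravel(),
                               np.asarray(blips, float).ravel()])

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nrf = self.nrf
        rf = (x[:nrf] + 1j * x[nrf:2 * nrf]).reshape(self.nch, self.nsub)
        blips = x[2 * nrf:].reshape(self.nblip, 3)
        return rf, blips

    def bounds(self):
        b = [(None, None)] * (2 * self.nrf)
        b += [(-self.dk_max, self.dk_max)] * (3 * self.nblip)
        return b

    # -- forward maps ------------------------------------------------------
    def _fields(self, rf, blips):
        from .sta_core import subpulse_kspace

        f_ut = self.s_ut.T @ rf                          # (N, nsub) uT
        k = subpulse_kspace(blips, self.nsub)            # (nsub, 3)
        theta = self.r @ k.T                             # (N, nsub)
        kmat = self.pref * self.E * np.exp(1j * theta)   # K_mj
        z = np.sum(kmat * (f_ut * 1e-6), axis=1)         # complex, rad
        return f_ut, kmat, z

    def maps(self, x):
        rf, blips = self.unpack(x)
        f_ut, _, z = self._fields(rf, blips)
        alpha = np.abs(z)
        beta = np.sqrt(self.duty * np.sum(np.abs(f_ut) ** 2, axis=1))
        return alpha, beta

    # -- cost and gradient -------------------------------------------------
    def cost_grad(self, x):
        rf, blips = self.unpack(x)
        f_ut, kmat, z = self._fields(rf, blips)
        alpha = np.abs(z)
        lam = self.lam

        cost = 0.0
        grad_re = np.zeros((self.nch, self.nsub))
        grad_im = np.zeros((self.nch, self.nsub))
        grad_bl = np.zeros((self.nblip, 3))

        # flip-angle term
        da = alpha - self.spec.alpha_des
        cost_a = float(np.sum(self.wt * da ** 2) / self.norm_a)
        cost += (1.0 - lam) * cost_a
        ga = 2.0 * self.wt * da / self.norm_a            # d cost_a / d alpha
        zn = np.where(alpha > 0, alpha, 1.0)
        zhat = np.conj(z) / zn                           # z*/|z|
        vmat = (ga * zhat)[:, None] * kmat * 1e-6        # (N, nsub)
        ca = np.einsum("mj,qm->qj", vmat, self.s_ut, optimize=True)
        grad_re += (1.0 - lam) * ca.real
        grad_im += (1.0 - lam) * (-ca.imag)
        if self.nblip:
            tmat = kmat * (f_ut * 1e-6)                  # K_mj F_mj
            smat = np.cumsum(tmat, axis=1)[:, :-1]       # S_mp, p=0..nblip-1
            im_part = np.imag(zhat[:, None] * smat)      # Im(z* S)
            gb = np.einsum("m,mp,ma->pa", ga, im_part, self.r,
                           optimize=True)
            grad_bl += (1.0 - lam) * gb

        # B1rms term
        if self.include_beta:
            beta = np.sqrt(self.duty * np.sum(np.abs(f_ut) ** 2, axis=1))
            db = beta - self.spec.beta_des
            cost_b = float(np.sum(self.wt * db ** 2) / self.norm_b)
            cost += lam * cost_b
            gbeta = 2.0 * self.wt * db / self.norm_b
            bn = np.where(beta > 0, beta, 1.0)
            coef = (gbeta * self.duty / bn)[:, None] * np.conj(f_ut)
            cb = np.einsum("mj,qm->qj", coef, self.s_ut, optimize=True)
            grad_re += lam * cb.real
            grad_im += lam * (-cb.imag)

        grad = np.concatenate([grad_re.ravel(), grad_im.ravel(),
                               grad_bl.ravel()])
        return cost, grad

    # -- constraints -------------------------------------------------------
    def _sar_fun_jac(self, q_list, limit):
        duty = self.duty

        def fun(x):
            rf, _ = self.unpack(x)
            vals = np.array([np.einsum("qj,qp,pj->", rf.conj(), q, rf).real
                             for q in q_list])
            return limit - duty * vals

        def jac(x):
            rf, _ = self.unpack(x)
            rows = []
            for q in q_list:
                qb = q @ rf                              # (nch, nsub)
                g_re = -duty * 2.0 * qb.real
                g_im = -duty * 2.0 * qb.imag
                rows.append(np.concatenate([g_re.ravel(), g_im.ravel(),
                                            np.zeros(3 * self.nblip)]))
            return np.array(rows)

        return fun, jac

    def constraints(self):
        cons = []
        f, j = self._sar_fun_jac(list(self.safety.vops),
                                 self.safety.sar_10g_max)
        cons.append({"type": "ineq", "fun": f, "jac": j})
        if self.safety.sar_global_max is not None:
            f, j = self._sar_fun_jac([self.safety.q_global],
                                     self.safety.sar_global_max)
            cons.append({"type": "ineq", "fun": f, "jac": j})

        duty, nrf, nblip = self.duty, self.nrf, self.nblip
        nch, nsub = self.nch, self.nsub
        pmax, vmax2 = self.safety.p_max, self.safety.v_max ** 2

        def p_fun(x):
            rf, _ = self.unpack(x)
            return pmax - duty * np.sum(np.abs(rf) ** 2, axis=1) / 100.0

        def p_jac(x):
            rf, _ = self.unpack(x)
            out = np.zeros((nch, 2 * nrf + 3 * nblip))
            for q in range(nch):
                g = np.zeros((nch, nsub))
                g[q] = -duty * 2.0 * rf[q].real / 100.0
                out[q, :nrf] = g.ravel()
                g[q] = -duty * 2.0 * rf[q].imag / 100.0
                out[q, nrf:2 * nrf] = g.ravel()
            return out

        cons.append({"type": "ineq", "fun": p_fun, "jac": p_jac})

        def v_fun(x):
            rf, _ = self.unpack(x)
            return vmax2 - (np.abs(rf) ** 2).ravel()

        def v_jac(x):
            rf, _ = self.unpack(x)
            out = np.zeros((nrf, 2 * nrf + 3 * nblip))
            idx = np.arange(nrf)
            out[idx, idx] = -2.0 * rf.real.ravel()
            out[idx, nrf + idx] = -2.0 * rf.imag.ravel()
            return out

        cons.append({"type": "ineq", "fun": v_fun, "jac": v_jac})
        return cons

    def feasible_scale(self, rf: np.ndarray) -> float:
        """Largest c <= 1 keeping c*rf strictly inside all RF limits."""
        scale = 1.0
        vmax = np.abs(rf).max()
        if vmax > 0:
            scale = min(scale, 0.98 * self.safety.v_max / vmax)
        duty = self.duty
        p = duty * np.sum(np.abs(rf) ** 2, axis=1).max() / 100.0
        if p > 0:
            scale = min(scale, 0.98 * np.sqrt(self.safety.p_max / p))
        sar = max(np.einsum("qj,qp,pj->", rf.conj(), q, rf).real * duty
                  for q in self.safety.vops)
        if sar > 0:
            scale = min(scale,
                        0.98 * np.sqrt(self.safety.sar_10g_max / sar))
        if self.safety.sar_global_max is not None:
            sg = duty * np.einsum("qj,qp,pj->", rf.conj(),
                                  self.safety.q_global, rf).real
            if sg > 0:
                scale = min(scale,
                            0.98 * np.sqrt(self.safety.sar_global_max / sg))
        return min(scale, 1.0)


def _initial_starts(obj: _HybridObjective, spec: DesignSpec,
                    rng: np.random.Generator):
    """Random complex RF scaled to land near alpha_des in the weighted
    least-squares sense; blip moments uniform within 20% of the box."""
    for _ in range(spec.n_starts):
        rf = (rng.standard_normal((obj.nch, obj.nsub))
              + 1j * rng.standard_normal((obj.nch, obj.nsub)))
        blips = rng.uniform(-0.2, 0.2, size=(obj.nblip, 3)) * obj.dk_max
        alpha, _ = obj.maps(obj.pack(rf, blips))
        denom = np.sum(obj.wt * alpha ** 2)
        if denom > 0:
            c = np.sum(obj.wt * alpha) * spec.alpha_des / denom
            rf = rf * c
        rf = rf * obj.feasible_scale(rf)
        yield rf, blips


_FEAS_TOL = 1e-6


def _is_feasible(rep: ConstraintReport) -> bool:
    return all(v >= -_FEAS_TOL for v in rep.margins.values())


def _snap_feasible(obj: _HybridObjective, rf: np.ndarray,
                   blips: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove solver-tolerance-level constraint violations: clip blips to
    their box and shrink the RF onto the tightest quadratic limit.  A
    no-op (up to ~1e-9 relative) for strictly feasible solutions."""
    blips = np.clip(blips, -obj.dk_max, obj.dk_max)
    scale = obj.feasible_scale(rf) / 0.98       # undo the headroom factor
    if scale < 1.0:
        rf = rf * scale * (1.0 - 1e-12)
    return rf, blips


def hybrid_design(setup: TransmitSetup, safety: SafetyModel,
                  spec: DesignSpec, timing: SequenceTiming | None = None,
                  mode: str = "hybrid") -> DesignResult:
    """Constrained multi-start hybrid design (SLSQP with analytic
    gradients of the cost and every constraint).

    ``mode``: "hybrid" uses the dual cost weighted by ``spec.lam``;
    "fa" optimizes the flip-angle term alone; "push" the B1rms term alone.
    Ties across starts break on cost, then on lower local SAR.  Maps and
    errors in the returned result are recomputed on the full setup.
    """
    timing = timing or SequenceTiming()
    if mode == "fa":
        spec = DesignSpec(**{**vars(spec), "lam": 0.0})
    elif mode == "push":
        spec = DesignSpec(**{**vars(spec), "lam": 1.0})
    elif mode != "hybrid":
        raise ValueError(f"unknown design mode {mode!r}")

    if 0.0 < spec.lam < 1.0 and spec.beta_des > 0:
        bmin = kt_beta_min(spec.alpha_des, timing)
        if spec.beta_des < bmin:
            warnings.warn(
                f"beta_des = {spec.beta_des:.3f} uT below the lower bound "
                f"beta_min = {bmin:.3f} uT: both targets cannot be met "
                "simultaneously", stacklevel=2)

    design_setup = setup
    if spec.n_clusters and spec.n_clusters < setup.n_masked:
        design_setup, _ = cluster_compress(setup, spec.n_clusters,
                                           seed=spec.seed)

    obj = _HybridObjective(design_setup, safety, spec, timing,
                           include_beta=(spec.lam > 0))
    cons = obj.constraints()
    bounds = obj.bounds()
    rng = np.random.default_rng(spec.seed)

    best = None
    start_costs = []
    for istart, (rf0, blips0) in enumerate(_initial_starts(obj, spec, rng)):
        x0 = obj.pack(rf0, blips0)
        res = minimize(obj.cost_grad, x0, jac=True, method="SLSQP",
                       bounds=bounds, constraints=cons,
                       options={"maxiter": spec.maxiter,
                                "ftol": spec.ftol})
        rf, blips = _snap_feasible(obj, *obj.unpack(res.x))
        pulse = KTPointsPulse(rf=rf, blip_moments=blips, timing=timing)
        rep = constraint_report(pulse, safety)
        feas = _is_feasible(rep)
        start_costs.append(float(res.fun))
        key = (not feas, float(res.fun), rep.sar_local_max)
        if best is None or key < best[0]:
            best = (key, pulse, rep, istart, bool(res.success) and feas)

    _, pulse, rep, istart, converged = best
    out = _result(pulse, setup, spec.alpha_des,
                  spec.beta_des if spec.lam > 0 else 0.0,
                  spec.lam, safety, mode=mode, start_costs=start_costs,
                  start_index=istart, converged=converged)
    # report NRMSE(beta) even for pure-FA designs when a target exists
    if spec.beta_des > 0 and not np.isfinite(out.nrmse_beta):
        wt = setup.weights[setup.mask]
        out.nrmse_beta = nrmse(out.beta_map, spec.beta_des, wt)
    return out


# --------------------------------------------------------------------------
# Sweep drivers
# --------------------------------------------------------------------------

def log_lambda_grid(n: int = 51, eps: float = 1e-3) -> np.ndarray:
    """Grid over [0, 1] with endpoints included and logarithmic spacing
    denser near the bounds, sparser in the middle."""
    if n < 2:
        raise ValueError("need at least two lambda values")
    if n == 2:
        return np.array([0.0, 1.0])
    half = (n - 1) // 2
    lo = np.logspace(np.log10(eps), np.log10(0.5), half)
    hi = 1.0 - lo[::-1]
    inner = np.unique(np.concatenate([lo, hi]))
    grid = np.concatenate([[0.0], inner, [1.0]])
    # trim duplicates introduced by the midpoint when n is even
    if grid.size > n:
        mid = grid.size // 2
        grid = np.delete(grid, mid)
    return grid


def pareto_sweep(setup: TransmitSetup, safety: SafetyModel,
                 alpha_des: float, beta_grid, lambda_grid,
                 timing: SequenceTiming | None = None, seed: int = 0,
                 n_starts: int = 10, n_clusters: int = 500) -> pd.DataFrame:
    """Run one hybrid design per (beta_des, lambda) grid point.

    Returns a tidy table of targets, achieved NRMSE pair, cost, SAR and
    constraint margins, plus a ``pareto`` flag marking the non-dominated
    (NRMSE_alpha, NRMSE_beta) points within each beta_des.  Deterministic
    for a fixed seed.
    """
    timing = timing or SequenceTiming()
    beta_grid = np.atleast_1d(np.asarray(beta_grid, float))
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, float))
    if beta_grid.size == 0 or lambda_grid.size == 0:
        raise ValueError("empty sweep grid")

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ib, bdes in enumerate(beta_grid):
            for il, lam in enumerate(lambda_grid):
                spec = DesignSpec(alpha_des=alpha_des, beta_des=float(bdes),
                                  lam=float(lam), n_starts=n_starts,
                                  seed=seed + 1000 * ib + il,
                                  n_clusters=n_clusters)
                res = hybrid_design(setup, safety, spec, timing)
                rows.append({
                    "beta_des_ut": float(bdes),
                    "lambda": float(lam),
                    "nrmse_alpha": res.nrmse_alpha,
                    "nrmse_beta": res.nrmse_beta,
                    "cost": res.cost,
                    "sar_local_W_per_kg": res.constraints.sar_local_max,
                    "margin_sar_local": res.constraints.margins["sar_local"],
                    "margin_voltage": res.constraints.margins["voltage"],
                    "margin_power": res.constraints.margins["power"],
                    "converged": res.converged,
                })
    df = pd.DataFrame(rows)
    df["pareto"] = False
    for bdes, grp in df.groupby("beta_des_ut"):
        pts = grp[["nrmse_alpha", "nrmse_beta"]].to_numpy()
        dom = np.zeros(len(grp), bool)
        for i in range(len(grp)):
            others = np.delete(pts, i, axis=0)
            dom[i] = not np.any(np.all(others <= pts[i], axis=1)
                                & np.any(others < pts[i], axis=1))
        df.loc[grp.index, "pareto"] = dom
    return df
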