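"""Steady-state two-pool z-spectrum model and constrained nonlinear fitting.

Under sustained off-resonance saturation the coupled free/restricted
longitudinal system reaches a steady state in which the normalized free-pool
longitudinal magnetization is an algebraic function of the pool parameters
and the two saturation rates Wf (direct) and Wr (lineshape-mediated).  With
the restricted-pool R1 fixed at 1/s (it is not identifiable from z-spectra)
and the free-pool R1 constrained by the observed, B1-corrected T1, four free
parameters remain: the pool size ratio f, the exchange rate krf, and the two
transverse relaxation times T2f and T2r.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from nmmt.physics import (
    Lineshape,
    SaturationPoint,
    TwoPoolParams,
    lineshape_G,
    rate_Wf,
    rate_Wr,
    uT_to_rad_per_s,
)


@dataclass
class ZSpectrum:
    """Sampled normalized MT signal over (amplitude, offset) pairs for one ROI.

    ``mt_norm`` is the MT-weighted signal normalized to the unsaturated
    baseline (MTnorm = 1 - MTR/100), one value per saturation condition.
    """

    roi_label: str
    amplitudes_uT: np.ndarray  # CWPE amplitude per sample
    offsets_hz: np.ndarray
    mt_norm: np.ndarray
    t1_obs: float  # observed (B1-corrected) T1, s
    b1_scale: float = 1.0
    b0_shift: float = 0.0

    def __post_init__(self):
        self.amplitudes_uT = np.asarray(self.amplitudes_uT, dtype=float)
        self.offsets_hz = np.asarray(self.offsets_hz, dtype=float)
        self.mt_norm = np.asarray(self.mt_norm, dtype=float)
        n = len(self.mt_norm)
        if not (len(self.amplitudes_uT) == len(self.offsets_hz) == n):
            raise ValueError("amplitude, offset and signal arrays must be equal length")
        pairs = set(zip(self.amplitudes_uT.tolist(), self.offsets_hz.tolist()))
        if len(pairs) != n:
            raise ValueError("duplicate (amplitude, offset) samples")
        if np.any(self.mt_norm <= 0) or np.any(self.mt_norm > 1.05):
            raise ValueError("mt_norm values must lie in (0, 1.05]")

    def __len__(self) -> int:
        return len(self.mt_norm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi_label,
                "amplitude_uT": self.amplitudes_uT,
                "offset_hz": self.offsets_hz,
                "mt_norm": self.mt_norm,
            }
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        t1_obs: float,
        roi: str | None = None,
        b1_scale: float = 1.0,
        b0_shift: float = 0.0,
    ) -> "ZSpectrum":
        if roi is not None:
            df = df[df["roi"] == roi]
        else:
            roi = str(df["roi"].iloc[0])
        return cls(
            roi_label=roi,
            amplitudes_uT=df["amplitude_uT"].to_numpy(),
            offsets_hz=df["offset_hz"].to_numpy(),
            mt_norm=df["mt_norm"].to_numpy(),
            t1_obs=t1_obs,
            b1_scale=b1_scale,
            b0_shift=b0_shift,
        )


@dataclass
class QmtFitConfig:
    """Optimizer settings for the constrained two-pool fit."""

    lineshape: Lineshape = Lineshape.SUPER_LORENTZIAN
    R1r: float = 1.0  # fixed, 1/s
    # bounds: f (ratio), krf (1/s), T2f (s), T2r (s)
    f_bounds: tuple[float, float] = (0.001, 0.40)
    krf_bounds: tuple[float, float] = (0.1, 100.0)
    t2f_bounds: tuple[float, float] = (0.020, 0.400)
    t2r_bounds: tuple[float, float] = (1e-6, 50e-6)
    n_starts: int = 8
    multistart_seed: int = 1234
    extra_starts: tuple[tuple[float, float, float, float], ...] = ()
    min_offset_hz: float = 50.0


@dataclass
class QmtFitResult:
    params: TwoPoolParams
    estimates: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    n_starts: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "roi_params": json.loads(self.params.to_json()),
                "estimates": self.estimates,
                "stderr": self.stderr,
                "rss": self.rss,
                "converged": self.converged,
                "n_starts": self.n_starts,
            }
        )


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def mz_steady_state(
    params: TwoPoolParams,
    point: SaturationPoint,
    kind: Lineshape | str = Lineshape.SUPER_LORENTZIAN,
    min_offset_hz: float = 50.0,
) -> float:
    """Normalized steady-state longitudinal free-pool signal, in (0, 1].

    Algebraic solution of the coupled two-pool longitudinal system with the
    saturation rates Wr (restricted pool, lineshape) and Wf (free pool,
    direct).  Zero amplitude returns exactly 1.
    """
    if point.omega1_cwpe == 0.0:
        return 1.0
    Wr = rate_Wr(point, params.T2r, kind, min_offset_hz)
    Wf = rate_Wf(point, params.T2f)
    kfr = params.kfr
    krf = params.krf
    R1f, R1r = params.R1f, params.R1r
    num = R1r * kfr / R1f + Wr + R1r + krf
    den = (kfr / R1f) * (R1r + Wr) + (1.0 + Wf / R1f) * (Wr + R1r + krf)
    return num / den


def _recovery_rates(R1f: float, R1r: float, krf: float, f: float) -> tuple[float, float]:
    """Both longitudinal recovery rates (slow, fast) of the exchange system."""
    kfr = f * krf
    S = R1f + kfr + R1r + krf  # trace of the (negated) rate matrix
    D = (R1f + kfr) * (R1r + krf) - kfr * krf
    disc = math.sqrt(max(S * S - 4.0 * D, 0.0))
    return (S - disc) / 2.0, (S + disc) / 2.0


def constrain_R1f(
    t1_obs: float,
    R1r: float,
    krf: float,
    f: float,
    bracket: tuple[float, float] = (1e-3, 20.0),
) -> float:
    """Solve for the free-pool R1 given the observed (B1-corrected) T1.

    The observed T1 is identified with the slow recovery eigenvalue of the
    coupled longitudinal exchange system; R1f is found by bracketed
    root-finding so that this eigenvalue equals 1/t1_obs.
    """
    if t1_obs <= 0:
        raise ValueError("t1_obs must be positive")
    if R1r <= 0 or krf < 0 or not 0 < f < 1:
        raise ValueError("invalid rate parameters")
    target = 1.0 / t1_obs

    def g(R1f: float) -> float:
        return _recovery_rates(R1f, R1r, krf, f)[0] - target

    lo, hi = bracket
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    if glo * ghi > 0:
        raise ValueError(
            f"no R1f in ({lo}, {hi}) 1/s yields a slow recovery rate of "
            f"{target:.4f} 1/s (bracket values {glo:.4g}, {ghi:.4g})"
        )
    return optimize.brentq(g, lo, hi, xtol=1e-13, rtol=1e-15)


def apply_b1_b0(
    point: SaturationPoint, b1_scale: float, b0_shift: float, inverse: bool = False
) -> SaturationPoint:
    """Map a nominal saturation point to the effective one (or back).

    Forward: amplitude is multiplied by the B1 scale and the offset shifted
    by the B0 error.  Pure bookkeeping, exactly invertible.
    """
    if not 0.3 < b1_scale < 1.7:
        raise ValueError(f"b1_scale {b1_scale} outside plausible range (0.3, 1.7)")
    if inverse:
        return SaturationPoint(point.omega1_cwpe / b1_scale, point.delta - b0_shift)
    return SaturationPoint(point.omega1_cwpe * b1_scale, point.delta + b0_shift)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("f", "krf", "T2f", "T2r")


def _spectrum_points(spec: ZSpectrum) -> list[SaturationPoint]:
    pts = []
    for amp, off in zip(spec.amplitudes_uT, spec.offsets_hz):
        nominal = SaturationPoint(uT_to_rad_per_s(amp), off)
        pts.append(apply_b1_b0(nominal, spec.b1_scale, spec.b0_shift))
    return pts


def _forward(
    x: np.ndarray, points: list[SaturationPoint], t1_obs: float, cfg: QmtFitConfig
) -> np.ndarray:
    f, krf, t2f, t2r = x
    R1f = constrain_R1f(t1_obs, cfg.R1r, krf, f)
    p = TwoPoolParams(R1f=R1f, R1r=cfg.R1r, T2f=t2f, T2r=t2r, krf=krf, f=f)
    return np.array(
        [mz_steady_state(p, pt, cfg.lineshape, cfg.min_offset_hz) for pt in points]
    )


def _starts(cfg: QmtFitConfig) -> np.ndarray:
    lo = np.array([cfg.f_bounds[0], cfg.krf_bounds[0], cfg.t2f_bounds[0], cfg.t2r_bounds[0]])
    hi = np.array([cfg.f_bounds[1], cfg.krf_bounds[1], cfg.t2f_bounds[1], cfg.t2r_bounds[1]])
    sampler = qmc.LatinHypercube(d=4, seed=cfg.multistart_seed)
    unit = sampler.random(cfg.n_starts)
    # geometric interpolation: the box spans orders of magnitude
    pts = np.exp(np.log(lo) + unit * (np.log(hi) - np.log(lo)))
    if cfg.extra_starts:
        pts = np.vstack([pts, np.array(cfg.extra_starts)])
    return pts


def fit_z_spectrum(spec: ZSpectrum, config: QmtFitConfig | None = None) -> QmtFitResult:
    """Fit the constrained two-pool model to one ROI z-spectrum.

    Free parameters are (f, krf, T2f, T2r); R1r is fixed and R1f is
    re-derived from the observed T1 at every iterate.  Deterministic
    multistart (fixed-seed Latin hypercube over the bound box, geometric
    spacing); ties among minima broken by lowest residual, then lowest f.
    """
    cfg = config or QmtFitConfig()
    if len(spec) < 6:
        raise ValueError("need at least 6 z-spectrum samples to fit 4 parameters")
    if spec.t1_obs is None or spec.t1_obs <= 0:
        raise ValueError("a positive observed T1 is required for the R1f constraint")
    points = _spectrum_points(spec)
    target = spec.mt_norm
    lo = np.array([cfg.f_bounds[0], cfg.krf_bounds[0], cfg.t2f_bounds[0], cfg.t2r_bounds[0]])
    hi = np.array([cfg.f_bounds[1], cfg.krf_bounds[1], cfg.t2f_bounds[1], cfg.t2r_bounds[1]])

    def resid(x: np.ndarray) -> np.ndarray:
        return _forward(x, points, spec.t1_obs, cfg) - target

    best = None
    any_converged = False
    starts = _starts(cfg)
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                x_scale=np.array([0.05, 10.0, 0.1, 1e-5]),
            )
        except ValueError:
            continue
        rss = float(2.0 * sol.cost)
        key = (round(rss, 14), sol.x[0])
        if sol.success:
            any_converged = True
        if best is None or key < best[0]:
            best = (key, sol, rss)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    _, sol, rss = best

    f, krf, t2f, t2r = sol.x
    R1f = constrain_R1f(spec.t1_obs, cfg.R1r, krf, f)
    params = TwoPoolParams(R1f=R1f, R1r=cfg.R1r, T2f=t2f, T2r=t2r, krf=krf, f=f)
    # asymptotic standard errors from the Jacobian at the optimum
    stderr = {k: float("nan") for k in _PARAM_NAMES}
    n, p = len(target), 4
    if n > p and rss > 0:
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = np.linalg.inv(JTJ) * rss / (n - p)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            stderr = dict(zip(_PARAM_NAMES, se.tolist()))
        except np.linalg.LinAlgError:
            pass
    return QmtFitResult(
        params=params,
        estimates=dict(zip(_PARAM_NAMES, sol.x.tolist())),
        stderr=stderr,
        rss=rss,
        converged=any_converged,
        n_starts=len(starts),
    )


def t1_obs_from_params(params: TwoPoolParams) -> float:
    """Observed T1 implied by a parameter set (inverse slow recovery rate)."""
    slow, _ = _recovery_rates(params.R1f, params.R1r, params.krf, params.f)
    return 1.0 / slow
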