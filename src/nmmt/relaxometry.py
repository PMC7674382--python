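"""Voxelwise relaxometry: MTR, mono-exponential T2*, MP2RAGE-style T1.

Also implements the phantom heating-drift correction: during a long phantom
session RF power deposition warms the gel and drifts T1, which shows up as
an approximately linear signal change across the interleaved unsaturated
(TFL) acquisitions; that trend is estimated from the TFL series and divided
out of each MT-weighted acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import optimize


@dataclass
class VolumeGrid:
    """A 3D intensity volume with orientation metadata and an acquisition tag."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tag: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VolumeGrid expects a 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path, tag: str = "") -> "VolumeGrid":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.dataobj, dtype=float), affine=img.affine, tag=tag)


@dataclass
class EchoTrain:
    """Multi-echo GRE volumes with strictly increasing echo times (ms)."""

    echoes: list[tuple[float, VolumeGrid]]

    def __post_init__(self):
        if len(self.echoes) < 2:
            raise ValueError("need at least 2 echoes to fit a decay")
        tes = [te for te, _ in self.echoes]
        if np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be strictly increasing")
        shapes = {v.data.shape for _, v in self.echoes}
        if len(shapes) != 1:
            raise ValueError("echo volumes must share one grid")

    @property
    def tes_ms(self) -> np.ndarray:
        return np.array([te for te, _ in self.echoes], dtype=float)

    @property
    def stack(self) -> np.ndarray:
        return np.stack([v.data for _, v in self.echoes], axis=0)


# nominal multi-echo GRE grid of the 3 T protocol, ms
PAPER_TES_MS = (2.73, 7.65, 13.61, 21.86)


# ---------------------------------------------------------------------------
# MTR
# ---------------------------------------------------------------------------

def mtr_map(tfl: VolumeGrid, mt: VolumeGrid) -> tuple[VolumeGrid, int]:
    """Voxelwise magnetization transfer ratio (TFL - MT)/TFL x 100, percent.

    Voxels with non-positive baseline are set to NaN; their count is
    returned alongside the map.  MTnorm = 1 - MTR/100 is the exact inverse.
    """
    if tfl.data.shape != mt.data.shape:
        raise ValueError("TFL and MT volumes must share one grid")
    bad = tfl.data <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = (tfl.data - mt.data) / tfl.data * 100.0
    mtr[bad] = np.nan
    return _nan_volume(mtr, tfl.affine, "MTR"), int(bad.sum())


def _nan_volume(data: np.ndarray, affine: np.ndarray, tag: str) -> VolumeGrid:
    # bypass the finite-value check: masked voxels are NaN by design
    v = VolumeGrid.__new__(VolumeGrid)
    v.data = np.asarray(data, dtype=float)
    v.affine = affine
    v.tag = tag
    return v


def mtnorm_from_mtr(mtr_percent: np.ndarray) -> np.ndarray:
    """MTnorm = 1 - MTR/100 (normalized MT signal)."""
    return 1.0 - np.asarray(mtr_percent, dtype=float) / 100.0


# ---------------------------------------------------------------------------
# T2*
# ---------------------------------------------------------------------------

def _loglinear_t2star(tes_ms: np.ndarray, stack: np.ndarray, valid: np.ndarray):
    ln = np.where(valid, np.log(np.where(stack > 0, stack, 1.0)), 0.0)
    X = np.column_stack([np.ones_like(tes_ms), -tes_ms])
    flat = ln.reshape(len(tes_ms), -1)
    coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
    s0 = np.exp(coef[0]).reshape(stack.shape[1:])
    rate = coef[1].reshape(stack.shape[1:])  # 1/ms
    with np.errstate(divide="ignore"):
        t2s = np.where(rate > 0, 1.0 / np.where(rate > 0, rate, 1.0), np.inf)
    return s0, t2s


def fit_t2star(echoes: EchoTrain, method: str = "nls") -> tuple[VolumeGrid, VolumeGrid, int]:
    """Voxelwise mono-exponential S0*exp(-TE/T2*) fit.

    ``loglinear`` solves the log-domain least squares in closed form;
    ``nls`` (default) refines it by nonlinear least squares per voxel,
    which is less biased under Rician noise.  Voxels with any non-positive
    echo are masked (NaN) and counted.  Returns (S0 map, T2* map in ms,
    n masked voxels).
    """
    if method not in ("loglinear", "nls"):
        raise ValueError(f"unknown method {method!r}")
    tes = echoes.tes_ms
    stack = echoes.stack
    bad = np.any(stack <= 0, axis=0)
    valid = ~bad
    s0, t2s = _loglinear_t2star(tes, stack, np.broadcast_to(valid, stack.shape))
    if method == "nls":
        idx = np.argwhere(valid)
        for i, j, k in idx:
            y = stack[:, i, j, k]
            p0 = (max(s0[i, j, k], y.max()), float(np.clip(t2s[i, j, k], 1.0, 500.0)))
            try:
                popt, _ = optimize.curve_fit(
                    lambda te, a, t2: a * np.exp(-te / t2), tes, y, p0=p0, maxfev=2000
                )
                s0[i, j, k], t2s[i, j, k] = popt
            except RuntimeError:
                pass  # keep loglinear value
    s0 = np.where(valid, s0, np.nan)
    t2s = np.where(valid, t2s, np.nan)
    aff = echoes.echoes[0][1].affine
    return _nan_volume(s0, aff, "S0"), _nan_volume(t2s, aff, "T2star_ms"), int(bad.sum())


# ---------------------------------------------------------------------------
# MP2RAGE T1
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mp2rageProtocol:
    """Timing of a double-inversion gradient-echo (MP2RAGE) acquisition.

    Defaults follow the 3 T protocol (TR 5000 ms, TI 750/2570 ms, flips
    5/4 degrees); the flash-block repetition time and the number of
    excitations per block are configurable.
    """

    tr_s: float = 5.0
    ti1_s: float = 0.75
    ti2_s: float = 2.57
    flip1_deg: float = 5.0
    flip2_deg: float = 4.0
    n_gre: int = 176
    tr_flash_s: float = 5.8e-3
    inv_efficiency: float = 0.96


def mp2rage_index(t1_s: float, proto: Mp2rageProtocol, b1: float = 1.0) -> float:
    """Forward MP2RAGE signal index S1*S2/(S1^2 + S2^2) for one T1 and B1.

    Propagates the longitudinal magnetization through the steady-state
    cycle (inversion, recovery, two flash blocks, recovery) and evaluates
    both gradient-echo signals at their k-space-centre excitations.  The
    per-voxel B1 scale multiplies both flip angles.
    """
    a1 = math.radians(proto.flip1_deg * b1)
    a2 = math.radians(proto.flip2_deg * b1)
    n = proto.n_gre
    ta = proto.ti1_s - (n / 2) * proto.tr_flash_s
    tb = proto.ti2_s - proto.ti1_s - n * proto.tr_flash_s
    tc = proto.tr_s - proto.ti2_s - (n / 2) * proto.tr_flash_s
    if min(ta, tb, tc) < 0:
        raise ValueError("inconsistent MP2RAGE timing (negative gap)")
    E1 = math.exp(-proto.tr_flash_s / t1_s)

    def relax(mz, t):
        e = math.exp(-t / t1_s)
        return mz * e + (1.0 - e)

    def block(mz, cosa, npulse):
        g = E1 * cosa
        if npulse == 0:
            return mz
        gn = g**npulse
        return mz * gn + (1.0 - E1) * (1.0 - gn) / (1.0 - g)

    # one full cycle as an affine map mz -> A*mz + B; fixed point = steady state
    def cycle(mz):
        mz = -proto.inv_efficiency * mz
        mz = relax(mz, ta)
        mz = block(mz, math.cos(a1), n)
        mz = relax(mz, tb)
        mz = block(mz, math.cos(a2), n)
        mz = relax(mz, tc)
        return mz

    c0, c1 = cycle(0.0), cycle(1.0)
    A = c1 - c0
    mz_ss = c0 / (1.0 - A) if abs(1.0 - A) > 1e-15 else 0.0

    # propagate to each block's centre excitation
    mz = -proto.inv_efficiency * mz_ss
    mz = relax(mz, ta)
    mz_c1 = block(mz, math.cos(a1), n // 2)
    s1 = math.sin(a1) * mz_c1
    mz = block(mz, math.cos(a1), n)
    mz = relax(mz, tb)
    mz_c2 = block(mz, math.cos(a2), n // 2)
    s2 = math.sin(a2) * mz_c2
    denom = s1 * s1 + s2 * s2
    return s1 * s2 / denom if denom > 0 else 0.0


@dataclass
class T1LookupTable:
    """Monotone map between the MP2RAGE index and T1, per B1 scale.

    The dictionary holds index(T1) curves on a regular T1 grid for a set of
    B1 scales; within the invertible T1 range the curve is strictly
    monotone and inverted by linear interpolation, so lookup error is
    bounded by the grid step.
    """

    proto: Mp2rageProtocol = field(default_factory=Mp2rageProtocol)
    t1_grid_s: np.ndarray = field(
        default_factory=lambda: np.arange(0.35, 4.5001, 0.005)
    )
    b1_grid: np.ndarray = field(default_factory=lambda: np.arange(0.7, 1.3001, 0.05))
    # upper end chosen below the turnaround of the flattest (low-B1) curve
    valid_t1_range_s: tuple[float, float] = (0.5, 3.2)

    def __post_init__(self):
        self.t1_grid_s = np.asarray(self.t1_grid_s, dtype=float)
        self.b1_grid = np.asarray(self.b1_grid, dtype=float)
        self._index = np.array(
            [
                [mp2rage_index(t1, self.proto, b1) for t1 in self.t1_grid_s]
                for b1 in self.b1_grid
            ]
        )
        lo, hi = self.valid_t1_range_s
        sel = (self.t1_grid_s >= lo) & (self.t1_grid_s <= hi)
        for row in self._index[:, sel]:
            d = np.diff(row)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(
                    "MP2RAGE index is not strictly monotone over the valid T1 "
                    "range for this protocol; lookup would be ill-defined"
                )
        self._sel = sel

    def index_of(self, t1_s: float, b1: float = 1.0) -> float:
        """Forward index at an exact (T1, B1) via the signal model."""
        return mp2rage_index(t1_s, self.proto, b1)

    def lookup(self, index: float, b1: float = 1.0) -> tuple[float, bool]:
        """Invert the dictionary at the nearest tabulated B1.

        Returns (T1 in s, clipped flag); out-of-range indices clip to the
        nearest end of the valid T1 range.
        """
        i = int(np.argmin(np.abs(self.b1_grid - b1)))
        t1s = self.t1_grid_s[self._sel]
        idxs = self._index[i, self._sel]
        if idxs[0] > idxs[-1]:  # make increasing for interp
            idxs, t1s = idxs[::-1], t1s[::-1]
        clipped = bool(index <= idxs[0] or index >= idxs[-1])
        return float(np.interp(index, idxs, t1s)), clipped


def mp2rage_t1(
    index_vol: VolumeGrid, table: T1LookupTable, b1_map: VolumeGrid | None = None
) -> tuple[VolumeGrid, int, int]:
    """Per-voxel T1 lookup of an MP2RAGE index volume with B1 correction.

    Returns (T1 map in s, n voxels clipped out of range, n voxels whose B1
    fell outside the dictionary span and used the nearest entry).
    """
    b1 = b1_map.data if b1_map is not None else np.ones_like(index_vol.data)
    if b1.shape != index_vol.data.shape:
        raise ValueError("B1 map must share the index grid")
    out = np.empty_like(index_vol.data)
    n_clip = 0
    n_b1_out = int(np.sum((b1 < table.b1_grid[0]) | (b1 > table.b1_grid[-1])))
    it = np.nditer(index_vol.data, flags=["multi_index"])
    for val in it:
        t1, clipped = table.lookup(float(val), float(b1[it.multi_index]))
        out[it.multi_index] = t1
        n_clip += clipped
    return _nan_volume(out, index_vol.affine, "T1_s"), n_clip, n_b1_out


def index_volume_from_inversions(inv1: VolumeGrid, inv2: VolumeGrid) -> VolumeGrid:
    """Combine two inversion images into the B1-robust MP2RAGE index."""
    s1, s2 = inv1.data, inv2.data
    denom = s1 * s1 + s2 * s2
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(denom > 0, s1 * s2 / np.where(denom > 0, denom, 1.0), 0.0)
    return _nan_volume(idx, inv1.affine, "MP2RAGE_index")


# ---------------------------------------------------------------------------
# Heating drift
# ---------------------------------------------------------------------------

def heating_drift_correct(
    tfl_series: list[tuple[float, float | np.ndarray]],
    mt_series: list[tuple[float, float | np.ndarray]],
    mode: str = "ratio",
) -> list[tuple[float, float | np.ndarray]]:
    """Remove the linear heating trend seen in the unsaturated TFL series.

    A straight line is fitted to the TFL observations (ROI means or maps)
    against session time; each MT observation is then divided by the trend
    prediction at its timestamp, normalized to the trend value at the first
    TFL timestamp (``ratio`` mode, default, preserves MTR's ratio
    structure), or has the trend increment subtracted (``subtract`` mode).
    A zero-slope series is returned unchanged in both modes.
    """
    if len(tfl_series) < 2:
        raise ValueError("need at least 2 TFL observations to estimate a drift")
    if mode not in ("ratio", "subtract"):
        raise ValueError(f"unknown drift mode {mode!r}")
    times = np.array([t for t, _ in tfl_series], dtype=float)
    vals = np.array([np.mean(v) for _, v in tfl_series], dtype=float)
    slope, intercept = np.polyfit(times, vals, 1)
    t0 = times[0]
    ref = slope * t0 + intercept

    out = []
    for t, v in mt_series:
        trend = slope * t + intercept
        if mode == "ratio":
            out.append((t, v / (trend / ref)))
        else:
            out.append((t, v - (trend - ref)))
    return out
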