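"""ROI summarization, phantom regressions, young/old group models, FDR.

The MT-weighted turbo-flash scan is non-quantitative, so ROI means are
normalized to a pons reference region before group modelling.  Group
differences are assessed per (ROI, scan) with an ordinary least-squares
model of z-scored intensity on age group plus a motion confound (average
edge strength, AES), with Benjamini-Hochberg adjustment across the family
of tests.  The phantom analysis regresses ROI intensity on melanin
concentration and melanin model (agar as reference level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from nmmt.relaxometry import VolumeGrid


@dataclass
class ROIMask:
    """Integer voxel mask for one labelled region on a named grid."""

    label: str
    mask: np.ndarray  # boolean
    grid: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class GroupRecord:
    """One subject's ROI summary for the young/old comparison."""

    subject: str
    group: str  # "young" | "old"
    roi: str
    scan: str  # "T1" | "MTw"
    value: float
    aes: float

    def __post_init__(self):
        if self.group not in ("young", "old"):
            raise ValueError(f"unknown group {self.group!r}")


def records_to_frame(records: list[GroupRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "group": [r.group for r in records],
            "roi": [r.roi for r in records],
            "scan": [r.scan for r in records],
            "value": [r.value for r in records],
            "aes": [r.aes for r in records],
        }
    )


def roi_summary(vol: VolumeGrid, roi: ROIMask) -> tuple[float, float, int]:
    """Arithmetic mean, sample SD and count over in-mask finite voxels."""
    if vol.data.shape != roi.mask.shape:
        raise ValueError("volume and mask must share one grid")
    vals = vol.data[roi.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.label!r} contains no finite voxels")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd, int(vals.size)


def normalize_to_reference(roi_mean: float, pons_mean: float) -> float:
    """Ratio of an ROI mean to the pons reference mean (scanner gain cancels)."""
    if pons_mean <= 0:
        raise ValueError("reference mean must be positive")
    return roi_mean / pons_mean


# ---------------------------------------------------------------------------
# Phantom regression
# ---------------------------------------------------------------------------

@dataclass
class PhantomRegressionResult:
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    r_squared: float
    t_concentration: float
    p_concentration: float
    t_sepia_vs_agar: float
    p_sepia_vs_agar: float
    t_dam_vs_agar: float
    p_dam_vs_agar: float
    model: object = field(repr=False, default=None)


def phantom_regression(table: pd.DataFrame) -> PhantomRegressionResult:
    """OLS of layer signal on melanin concentration + melanin model.

    Expects columns ``model`` (sepia/dam/agar), ``concentration`` (mg/ml)
    and ``signal``.  The melanin model enters as a categorical with agar as
    the reference level, so its t statistics are the sepia-vs-agar and
    dam-vs-agar contrasts; concentration enters as a continuous slope.
    """
    req = {"model", "concentration", "signal"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    if table["concentration"].nunique() < 3:
        raise ValueError("need at least 3 distinct concentrations")
    levels = set(table["model"])
    if not {"sepia", "dam", "agar"}.issubset(levels):
        raise ValueError("all three model levels (sepia, dam, agar) must be present")
    if np.ptp(table["signal"].to_numpy(dtype=float)) == 0.0:
        # degenerate constant signal: no variance, no effects
        return PhantomRegressionResult(
            f_stat=0.0, f_pvalue=1.0, df_model=3, df_resid=len(table) - 4,
            r_squared=0.0, t_concentration=0.0, p_concentration=1.0,
            t_sepia_vs_agar=0.0, p_sepia_vs_agar=1.0,
            t_dam_vs_agar=0.0, p_dam_vs_agar=1.0,
        )
    fit = smf.ols(
        "signal ~ concentration + C(model, Treatment(reference='agar'))", data=table
    ).fit()
    names = fit.params.index
    rank = np.linalg.matrix_rank(fit.model.exog)
    if rank < fit.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design; aliased terms among {list(names)}")
    sep = "C(model, Treatment(reference='agar'))[T.sepia]"
    dam = "C(model, Treatment(reference='agar'))[T.dam]"
    return PhantomRegressionResult(
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        t_concentration=float(fit.tvalues["concentration"]),
        p_concentration=float(fit.pvalues["concentration"]),
        t_sepia_vs_agar=float(fit.tvalues[sep]),
        p_sepia_vs_agar=float(fit.pvalues[sep]),
        t_dam_vs_agar=float(fit.tvalues[dam]),
        p_dam_vs_agar=float(fit.pvalues[dam]),
        model=fit,
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def group_comparison(
    records: list[GroupRecord] | pd.DataFrame,
    standardize: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Young/old linear models per (ROI, scan) with AES confound and FDR.

    For each (ROI, scan) cell the intensity is z-scored across subjects
    (switchable), then regressed on group (old vs young) and the AES motion
    metric.  Raw p values of the group term are Benjamini-Hochberg adjusted
    across the whole (ROI x scan) family.  Returns a table with one row per
    test: estimate (old - young, in SD units when standardized), t value,
    raw and adjusted p, and the 95% confidence interval.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df["group"].nunique() < 2:
        raise ValueError("both groups must be present")
    rows = []
    for (roi, scan), cell in df.groupby(["roi", "scan"], sort=True):
        y = cell["value"].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            # degenerate cell: identical intensities carry no group signal
            rows.append(
                {
                    "roi": roi, "scan": scan, "estimate": 0.0, "t_value": 0.0,
                    "p_raw": 1.0, "ci_low": 0.0, "ci_high": 0.0,
                }
            )
            continue
        if standardize:
            y = (y - y.mean()) / y.std(ddof=1)
        X = sm.add_constant(
            np.column_stack(
                [(cell["group"] == "old").to_numpy(dtype=float), cell["aes"].to_numpy(dtype=float)]
            )
        )
        fit = sm.OLS(y, X).fit()
        ci = fit.conf_int(alpha=0.05)[1]
        rows.append(
            {
                "roi": roi,
                "scan": scan,
                "estimate": float(fit.params[1]),
                "t_value": float(fit.tvalues[1]),
                "p_raw": float(fit.pvalues[1]),
                "ci_low": float(ci[0]),
                "ci_high": float(ci[1]),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = benjamini_hochberg(out["p_raw"].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    return out


def benjamini_hochberg(p_raw: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment (monotone, clipped at 1)."""
    _, p_adj, _, _ = multipletests(np.asarray(p_raw, dtype=float), method="fdr_bh")
    return p_adj


# ---------------------------------------------------------------------------
# Motion metric
# ---------------------------------------------------------------------------

def average_edge_strength(vol: VolumeGrid, edge_fraction: float = 0.1) -> float:
    """Mean gradient magnitude over detected edge voxels (a.u.).

    Gradient-based surrogate for the average-edge-strength motion metric:
    edges are voxels whose central-difference gradient magnitude exceeds
    ``edge_fraction`` of the volume maximum; the AES is the mean magnitude
    over those voxels.  Blur spreads and weakens edges, so motion-degraded
    volumes score lower.  A constant volume returns 0.
    """
    if vol.data.ndim != 3:
        raise ValueError("AES expects a 3D volume")
    grads = np.gradient(vol.data)
    mag = np.sqrt(sum(g * g for g in grads))
    mx = float(np.nanmax(mag))
    if mx == 0.0 or not np.isfinite(mx):
        return 0.0
    edges = mag > edge_fraction * mx
    return float(mag[edges].mean())
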