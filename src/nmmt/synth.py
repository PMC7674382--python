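"""Synthetic-data generators with known ground truth for every pipeline stage.

Emulates the study's four data sources: (1) a layered agar/melanin phantom
with concentration-dependent T1/T2* and no melanin-driven MT modulation;
(2) in vivo-like z-spectra from the two-pool steady-state model at the
3-amplitude x 7-offset sampling grid; (3) 9-point transient saturation
timelines across subjects; (4) a young/old two-group ROI dataset with an
LC T1 elongation and null MT-weighted effects.  Magnitude data carry
Rician noise; every generator records its full generative truth and is
bit-reproducible from (spec, seed).

Seed scheme: per-object random streams are derived from the master seed
with ``numpy.random.SeedSequence(master, spawn_key=(stream,))`` where
``stream`` is a documented integer counter, so generators are independent
and individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nmmt.physics import SaturationPoint, TwoPoolParams, uT_to_rad_per_s
from nmmt.relaxometry import (
    Mp2rageProtocol,
    EchoTrain,
    PAPER_TES_MS,
    VolumeGrid,
    mp2rage_index,
)
from nmmt.roi_stats import GroupRecord, ROIMask
from nmmt.steady_state import ZSpectrum, apply_b1_b0, mz_steady_state, t1_obs_from_params
from nmmt.transient import (
    DEFAULT_SATURATION_INIT,
    PAPER_DELAYS_S,
    TransientState,
    TransientTimeline,
    simulate_transient,
)

#: CWPE amplitudes as printed in the acquisition protocol, microtesla.
#: These are mutually inconsistent with any single power-averaging
#: convention (their ratios to the peak amplitudes differ), and are far too
#: weak to produce the saturation the measured z-spectra show; they are
#: kept available verbatim but are not the generator default.
PRINTED_CWPE_UT = (0.061, 0.107, 0.153)
#: peak amplitudes of the three MT pulse-train blocks, microtesla
TRAIN_PEAKS_UT = (2.215, 4.430, 6.740)
#: nominal frequency offsets of the z-spectrum protocol, Hz
PAPER_OFFSETS_HZ = (210.0, 430.0, 860.0, 1280.0, 1710.0, 4280.0, 10000.0)

_default_cwpe: tuple[float, ...] | None = None


def default_cwpe_uT() -> tuple[float, ...]:
    """Default saturation amplitudes: the package's own CWPE convention
    (RMS over the train duration) applied to the protocol's 20-pulse
    gaussian-sinc train at each of the three peak amplitudes."""
    global _default_cwpe
    if _default_cwpe is None:
        from nmmt.physics import PulseTrain, cwpe_amplitude

        _default_cwpe = tuple(
            cwpe_amplitude(
                PulseTrain(
                    n_pulses=20,
                    pulse_duration=5.12e-3,
                    pulse_interval=10e-3,
                    peak_amplitude=peak,
                )
            )
            for peak in TRAIN_PEAKS_UT
        )
    return _default_cwpe


def child_rng(master_seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-object generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(stream,)))


def rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    """Rician-distributed magnitude: |signal + complex Gaussian noise|."""
    signal = np.asarray(signal, dtype=float)
    if sigma == 0.0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(re * re + im * im)


@dataclass
class SyntheticTruth:
    """Full generative record serialized beside each synthetic output."""

    kind: str
    seed: int
    payload: dict

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "payload": self.payload},
            default=_jsonable,
            indent=2,
        )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomLayerSpec:
    """One agar layer, optionally doped with a melanin model.

    MTnorm is set to the agar value for every layer: the phantom showed no
    melanin-driven MT modulation, and the generator reproduces that null by
    construction.
    """

    model: str  # "sepia" | "dam" | "agar"
    concentration: float  # mg/ml
    t1_ms: float
    t2s_ms: float
    mtnorm: float

    def __post_init__(self):
        if self.model not in ("sepia", "dam", "agar"):
            raise ValueError(f"unknown melanin model {self.model!r}")
        if not 0.0 <= self.concentration <= 3.0:
            raise ValueError("concentration must be within 0-3 mg/ml")


#: ground-truth concentration dependence: linear T1 decrease from the
#: agar-like 2000 ms down to 1400 ms at 3 mg/ml, and a weaker T2* decrease
T1_AGAR_MS = 2000.0
T1_SLOPE_MS_PER_MGML = -200.0
T2S_AGAR_MS = 70.0
T2S_SLOPE_MS_PER_MGML = -8.0
AGAR_MTNORM = 0.80


def default_phantom_layers() -> list[PhantomLayerSpec]:
    """The constructed layer set: 0.6-3.0 mg/ml in 0.6 steps per model,
    minus the two lost layers (0.6 mg/ml dam, 1.2 mg/ml sepia), with an
    agar reference layer between doped layers."""
    concs = {
        "sepia": [0.6, 1.8, 2.4, 3.0],
        "dam": [1.2, 1.8, 2.4, 3.0],
    }
    layers: list[PhantomLayerSpec] = []

    def mk(model, c):
        return PhantomLayerSpec(
            model=model,
            concentration=c,
            t1_ms=T1_AGAR_MS + T1_SLOPE_MS_PER_MGML * c,
            t2s_ms=T2S_AGAR_MS + T2S_SLOPE_MS_PER_MGML * c,
            mtnorm=AGAR_MTNORM,
        )

    doped = [mk(m, c) for m in ("sepia", "dam") for c in concs[m]]
    for i, layer in enumerate(doped):
        layers.append(layer)
        if i % 2 == 1:  # interleave agar reference layers
            layers.append(mk("agar", 0.0))
    return layers


@dataclass
class PhantomVolumes:
    tfl: VolumeGrid
    mt: dict[tuple[float, float], VolumeGrid]  # (amplitude_uT, offset_hz) -> volume
    echoes: EchoTrain
    mp2rage_index: VolumeGrid
    layer_masks: list[ROIMask]
    layers: list[PhantomLayerSpec]
    truth: SyntheticTruth


def make_phantom(
    layers: list[PhantomLayerSpec] | None = None,
    shape_xy: int = 16,
    slices_per_layer: int = 3,
    radius_fraction: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
    mt_conditions: tuple[tuple[float, float], ...] = ((0.153, 860.0),),
    proto: Mp2rageProtocol | None = None,
    tfl_tr_ms: float = 538.0,
    tfl_te_ms: float = 4.08,
    layer_t1_jitter_ms: float = 0.0,
    layer_t2s_jitter_ms: float = 0.0,
) -> PhantomVolumes:
    """Cylindrical layered phantom volume set with Rician noise.

    Layers stack along z (``slices_per_layer`` slices each, assigned
    sequentially so they cannot overlap); in-plane the tube is a disc of
    ``radius_fraction`` times the half-width.  Signals follow the
    relaxometry forward models: the TFL baseline carries T1 and T2*
    weighting, each MT volume is the TFL scaled by the layer's MTnorm
    (equal across layers by default -> zero melanin/agar MTR contrast), the
    echo train decays mono-exponentially with the layer T2*, and the
    MP2RAGE index volume follows the double-inversion signal model.
    """
    layers = layers if layers is not None else default_phantom_layers()
    if not layers:
        raise ValueError("need at least one layer")
    if layer_t1_jitter_ms or layer_t2s_jitter_ms:
        # layer-preparation variability (the doped concentrations were only
        # approximated); the jittered values become the layer ground truth
        jrng = child_rng(seed, 2)
        layers = [
            dataclasses.replace(
                l,
                t1_ms=l.t1_ms + jrng.normal(0.0, layer_t1_jitter_ms),
                t2s_ms=l.t2s_ms + jrng.normal(0.0, layer_t2s_jitter_ms),
            )
            for l in layers
        ]
    proto = proto or Mp2rageProtocol()
    nz = slices_per_layer * len(layers)
    shape = (shape_xy, shape_xy, nz)
    yy, xx = np.mgrid[0:shape_xy, 0:shape_xy]
    c = (shape_xy - 1) / 2.0
    disc = (xx - c) ** 2 + (yy - c) ** 2 <= (radius_fraction * shape_xy / 2.0) ** 2

    t1 = np.zeros(shape)
    t2s = np.zeros(shape)
    mtn = np.zeros(shape)
    masks = []
    for i, layer in enumerate(layers):
        z0, z1 = i * slices_per_layer, (i + 1) * slices_per_layer
        m = np.zeros(shape, dtype=bool)
        m[:, :, z0:z1] = disc[:, :, None]
        t1[m] = layer.t1_ms
        t2s[m] = layer.t2s_ms
        mtn[m] = layer.mtnorm
        masks.append(ROIMask(label=f"{layer.model}_{layer.concentration:.1f}_{i}", mask=m, grid="phantom"))

    inside = t1 > 0
    pd_ = np.where(inside, 1000.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_tr = np.where(inside, 1.0 - np.exp(-tfl_tr_ms / np.where(inside, t1, 1.0)), 0.0)
        e_te = np.where(inside, np.exp(-tfl_te_ms / np.where(inside, t2s, 1.0)), 0.0)
    tfl_clean = pd_ * e_tr * e_te

    rng = child_rng(seed, 0)
    aff = np.eye(4)
    tfl = VolumeGrid(rician(rng, tfl_clean, noise_sd), aff, tag="TFL")
    mt = {
        cond: VolumeGrid(rician(rng, tfl_clean * mtn, noise_sd), aff, tag=f"MT_{cond}")
        for cond in mt_conditions
    }
    echo_vols = []
    for te in PAPER_TES_MS:
        with np.errstate(divide="ignore"):
            s = np.where(inside, pd_ * np.exp(-te / np.where(inside, t2s, 1.0)), 0.0)
        echo_vols.append((te, VolumeGrid(rician(rng, s, noise_sd), aff, tag=f"echo_{te}")))
    echoes = EchoTrain(echo_vols)

    idx = np.zeros(shape)
    for layer, m in zip(layers, masks):
        idx[m.mask] = mp2rage_index(layer.t1_ms / 1e3, proto, b1=1.0)
    idx_noisy = idx if noise_sd == 0 else idx + rng.normal(0, noise_sd / 1000.0, shape)
    mp2 = VolumeGrid(idx_noisy, aff, tag="MP2RAGE_index")

    truth = SyntheticTruth(
        kind="phantom",
        seed=seed,
        payload={
            "layers": [dataclasses.asdict(l) for l in layers],
            "noise_sd": noise_sd,
            "shape": shape,
            "mt_conditions": list(mt_conditions),
            "tfl_tr_ms": tfl_tr_ms,
            "tfl_te_ms": tfl_te_ms,
        },
    )
    return PhantomVolumes(tfl, mt, echoes, mp2, masks, layers, truth)


# ---------------------------------------------------------------------------
# Z-spectra
# ---------------------------------------------------------------------------

def make_z_spectra(
    params: TwoPoolParams,
    amplitudes_uT: tuple[float, ...] | None = None,
    offsets_hz: tuple[float, ...] = PAPER_OFFSETS_HZ,
    noise_sd: float = 0.0,
    n_averages: int = 1,
    seed: int = 0,
    b1_scale: float = 1.0,
    b0_shift: float = 0.0,
    roi_label: str = "ROI",
) -> tuple[ZSpectrum, SyntheticTruth]:
    """Two-pool steady-state z-spectrum on an amplitude x offset grid.

    Each sample is the mean of ``n_averages`` Rician-noise magnitude draws
    at SD ``noise_sd``, emulating an ROI-mean spectrum over that many
    voxels (the experiment fits ROI means, not single voxels, to reach
    adequate SNR); values are clipped into (0, 1.05].  The observed T1 is
    the inverse slow recovery eigenvalue of the generative system, i.e.
    exactly what a relaxometry measurement of this tissue would return.
    """
    if amplitudes_uT is None:
        amplitudes_uT = default_cwpe_uT()
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    amps, offs, vals = [], [], []
    rng = child_rng(seed, 1)
    for a in amplitudes_uT:
        for d in offsets_hz:
            nominal = SaturationPoint(uT_to_rad_per_s(a), d)
            eff = apply_b1_b0(nominal, b1_scale, b0_shift)
            vals.append(mz_steady_state(params, eff))
            amps.append(a)
            offs.append(d)
    clean = np.array(vals)
    if noise_sd == 0.0:
        noisy = clean.copy()
    else:
        draws = rician(rng, np.tile(clean, (n_averages, 1)), noise_sd)
        noisy = draws.mean(axis=0)
    noisy = np.clip(noisy, 1e-6, 1.05)
    t1_obs = t1_obs_from_params(params)
    spec = ZSpectrum(
        roi_label=roi_label,
        amplitudes_uT=np.array(amps),
        offsets_hz=np.array(offs),
        mt_norm=noisy,
        t1_obs=t1_obs,
        b1_scale=b1_scale,
        b0_shift=b0_shift,
    )
    truth = SyntheticTruth(
        kind="z_spectrum",
        seed=seed,
        payload={
            "params": json.loads(params.to_json()),
            "t1_obs_s": t1_obs,
            "noise_sd": noise_sd,
            "n_averages": n_averages,
            "b1_scale": b1_scale,
            "b0_shift": b0_shift,
            "clean_mt_norm": clean,
            "amplitudes_uT": list(amplitudes_uT),
            "offsets_hz": list(offsets_hz),
        },
    )
    return spec, truth


# ---------------------------------------------------------------------------
# Transient cohort
# ---------------------------------------------------------------------------

def make_transient_cohort(
    params: TwoPoolParams,
    delays: np.ndarray = PAPER_DELAYS_S,
    noise_sd: float = 0.0,
    n_subjects: int = 5,
    seed: int = 0,
    init: TransientState = DEFAULT_SATURATION_INIT,
) -> tuple[TransientTimeline, SyntheticTruth]:
    """Noisy per-subject transient timelines plus the across-subject median.

    Noise is Rician on the underlying longitudinal magnitude Mz/M0 =
    1 - s_f, then mapped back to fractional saturation.  Per-subject
    streams derive deterministically from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    clean = simulate_transient(params, init, delays).s_f
    stack = np.empty((n_subjects, len(clean)))
    for s in range(n_subjects):
        rng = child_rng(seed, 100 + s)
        mz = rician(rng, 1.0 - clean, noise_sd)
        stack[s] = 1.0 - mz
    tl = TransientTimeline.median_of(stack, np.asarray(delays, dtype=float))
    truth = SyntheticTruth(
        kind="transient_cohort",
        seed=seed,
        payload={
            "params": json.loads(params.to_json()),
            "init": {"s_f": init.s_f, "s_r": init.s_r},
            "noise_sd": noise_sd,
            "n_subjects": n_subjects,
            "delays_s": np.asarray(delays),
            "clean_s_f": clean,
        },
    )
    return tl, truth


# ---------------------------------------------------------------------------
# Young/old group cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffectSpec:
    """Old-minus-young mean shifts injected by the cohort generator.

    Defaults emulate the study's finding pattern: an LC T1 elongation of
    1.2 pooled SD in the older group, and null effects for SN T1 and both
    Pons-normalized MT-weighted intensities.
    """

    lc_t1_shift_ms: float = 96.0  # 1.2 x the 80 ms young-group SD
    sn_t1_shift_ms: float = 0.0
    lc_mtw_shift: float = 0.0
    sn_mtw_shift: float = 0.0


#: young-group baselines: (mean, SD) per (ROI, scan)
GROUP_BASELINES = {
    ("LC", "T1"): (1871.0, 80.0),  # ms
    ("SN", "T1"): (1416.0, 35.0),
    ("LC", "MTw"): (1.09, 0.05),  # pons-normalized, a.u.
    ("SN", "MTw"): (1.06, 0.08),
}

#: AES (mean, SD) per group; the older group moves more -> blurrier -> lower
AES_DISTRIBUTIONS = {"young": (1.0, 0.05), "old": (0.9, 0.08)}


def make_group_cohort(
    n_young: int = 24,
    n_old: int = 15,
    effects: GroupEffectSpec = GroupEffectSpec(),
    aes_distributions: dict = AES_DISTRIBUTIONS,
    aes_coupling: float = 0.0,
    seed: int = 0,
) -> tuple[list[GroupRecord], SyntheticTruth]:
    """Two-group ROI dataset with known injected effects.

    Each subject contributes one record per (ROI, scan).  ``aes_coupling``
    adds a linear AES dependence to every intensity (in SD units per AES
    unit) so the confound can be made active; it defaults to inert.
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("both groups must be non-empty")
    shifts = {
        ("LC", "T1"): effects.lc_t1_shift_ms,
        ("SN", "T1"): effects.sn_t1_shift_ms,
        ("LC", "MTw"): effects.lc_mtw_shift,
        ("SN", "MTw"): effects.sn_mtw_shift,
    }
    rng = child_rng(seed, 200)
    records: list[GroupRecord] = []
    for group, n in (("young", n_young), ("old", n_old)):
        aes_mu, aes_sd = aes_distributions[group]
        for i in range(n):
            sid = f"{group}-{i:02d}"
            aes = float(rng.normal(aes_mu, aes_sd))
            for (roi, scan), (mu, sd) in GROUP_BASELINES.items():
                mean = mu + (shifts[(roi, scan)] if group == "old" else 0.0)
                val = float(
                    rng.normal(mean, sd) + aes_coupling * sd * (aes - 1.0)
                )
                records.append(
                    GroupRecord(subject=sid, group=group, roi=roi, scan=scan, value=val, aes=aes)
                )
    truth = SyntheticTruth(
        kind="group_cohort",
        seed=seed,
        payload={
            "n_young": n_young,
            "n_old": n_old,
            "effects": dataclasses.asdict(effects),
            "baselines": {f"{r}_{s}": v for (r, s), v in GROUP_BASELINES.items()},
            "aes_distributions": aes_distributions,
            "aes_coupling": aes_coupling,
        },
    )
    return records, truth
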