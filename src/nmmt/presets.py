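"""Representative in vivo two-pool parameter sets for LC, SN and pons.

Fitted ROI values from a 3 T brainstem qMT experiment (four young adults):
one fully-specified single-subject LC set and the three ROI means.  The
restricted-pool R1 is fixed at 1/s throughout (not identifiable from
z-spectra); the free-pool R1 follows from the observed T1 through the
slow-eigenvalue constraint, so each preset is completely determined by
(T1_obs, T2f, T2r, krf, f).
"""

from __future__ import annotations

from dataclasses import dataclass

from nmmt.physics import TwoPoolParams
from nmmt.steady_state import constrain_R1f


@dataclass(frozen=True)
class RoiPreset:
    name: str
    t1_obs_s: float
    t2f_ms: float
    t2r_us: float
    krf_hz: float
    f_percent: float

    def params(self, R1r: float = 1.0) -> TwoPoolParams:
        f = self.f_percent / 100.0
        R1f = constrain_R1f(self.t1_obs_s, R1r, self.krf_hz, f)
        return TwoPoolParams(
            R1f=R1f,
            R1r=R1r,
            T2f=self.t2f_ms * 1e-3,
            T2r=self.t2r_us * 1e-6,
            krf=self.krf_hz,
            f=f,
        )


#: single-subject locus coeruleus set (participant with unambiguous values)
LC_SUBJECT1 = RoiPreset(
    name="LC_subject1", t1_obs_s=1.56, t2f_ms=154.46, t2r_us=10.75,
    krf_hz=7.03, f_percent=4.93,
)

#: ROI means across the four participants; krf for LC derived from the
#: mean kfr (0.31 Hz) and mean f via krf = kfr / f
LC_MEAN = RoiPreset(
    name="LC", t1_obs_s=1.415, t2f_ms=150.0, t2r_us=11.55,
    krf_hz=0.31 / 0.0515, f_percent=5.15,
)
SN_MEAN = RoiPreset(
    name="SN", t1_obs_s=0.9975, t2f_ms=118.25, t2r_us=16.51,
    krf_hz=4.34, f_percent=14.54,
)
PONS_MEAN = RoiPreset(
    name="Pons", t1_obs_s=1.09, t2f_ms=108.56, t2r_us=14.13,
    krf_hz=8.12, f_percent=10.53,
)

ROI_PRESETS = {p.name: p for p in (LC_SUBJECT1, LC_MEAN, SN_MEAN, PONS_MEAN)}
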