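"""Transvalvular pressure waveforms.

The demonstrator is driven by the pressure difference between inlet
(atrial side) and outlet (ventricular side), prescribed as a continuous
piecewise-linear schedule in mmHg.  The default schedule reproduces the
three physiological phase anchors of a mitral cycle — about +10 mmHg
across the open valve during diastolic filling, roughly -80 mmHg just
after closure, and -150 mmHg at full systolic load — on a compressed
time axis suited to the desk-scale 2D channel (the anchor pressures, not
the clinical timings, are the fixed points; see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..laws import MMHG_TO_KPA

__all__ = ["PressureWaveform", "default_mitral_waveform", "MMHG_TO_CGS"]

#: 1 mmHg in dyn/cm^2.
MMHG_TO_CGS = MMHG_TO_KPA * 1.0e4


@dataclass(frozen=True)
class PressureWaveform:
    """Piecewise-linear pressure difference vs time.

    ``anchors`` is a sequence of ``(t_s, dp_mmHg)`` pairs with strictly
    increasing times; the waveform holds its end values outside the
    anchored interval.  Positive values drive forward (inlet -> outlet)
    flow.
    """

    anchors: tuple[tuple[float, float], ...]

    def __init__(self, anchors) -> None:
        pts = tuple((float(t), float(p)) for t, p in anchors)
        if len(pts) < 2:
            raise ValueError("need at least two anchor points")
        ts = np.array([t for t, _ in pts])
        if np.any(np.diff(ts) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        object.__setattr__(self, "anchors", pts)

    def __call__(self, t) -> np.ndarray | float:
        """Pressure difference in mmHg at time ``t`` (s)."""
        ts = np.array([a[0] for a in self.anchors])
        ps = np.array([a[1] for a in self.anchors])
        out = np.interp(t, ts, ps)
        return float(out) if np.ndim(t) == 0 else out

    def in_cgs(self, t) -> float:
        """Pressure difference in dyn/cm^2."""
        return self(t) * MMHG_TO_CGS

    def reversal_time(self) -> float | None:
        """First zero crossing from positive to non-positive, if any."""
        ts = np.array([a[0] for a in self.anchors])
        tt = np.linspace(ts[0], ts[-1], 4096)
        pp = self(tt)
        sign = pp > 0.0
        idx = np.where(sign[:-1] & ~sign[1:])[0]
        if idx.size == 0:
            return None
        i = int(idx[0])
        # linear interpolation of the crossing
        t0, t1, p0, p1 = tt[i], tt[i + 1], pp[i], pp[i + 1]
        return float(t0 + (t1 - t0) * p0 / (p0 - p1)) if p0 != p1 else float(t0)


def default_mitral_waveform(
    t_open: float = 0.008,
    t_fwd_end: float = 0.025,
    t_closed: float = 0.04,
    t_loaded: float = 0.065,
    p_open_mmhg: float = 10.0,
    p_closed_mmhg: float = -80.0,
    p_loaded_mmhg: float = -150.0,
) -> PressureWaveform:
    """Anchored mitral waveform: +10 mmHg filling, -80 just closed, -150 loaded."""
    return PressureWaveform(
        [
            (0.0, 0.0),
            (t_open, p_open_mmhg),
            (t_fwd_end, p_open_mmhg),
            (t_closed, p_closed_mmhg),
            (t_loaded, p_loaded_mmhg),
        ]
    )
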