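"""Pattern features of a single growth curve.

The seven archetypal coculture patterns (unimpeded logistic growth; full
killing; killing-then-regrowth variants; impaired-growth variants) are told
apart by a handful of scalar features of the adjusted OD trace: final OD,
lag duration, time to stationary phase, peak OD, and whether the culture
regrew after phage suppression.  These features drive the semantic labelling
of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import GrowthCurve

__all__ = ["PatternFeatures", "extract_pattern_features"]

#: sentinel for "stationary phase never reached / undefined"
T_STATIONARY_UNDEFINED = float("nan")


@dataclass(frozen=True)
class PatternFeatures:
    """Scalar descriptors of one adjusted OD600 curve.

    final_od
        Mean of the last three timepoints (absorbance).
    lag_h
        Last grid time before the OD first exceeds ``od_thresh``; the full
        span if it never does.
    t_stationary_h
        First time the OD reaches 95% of ``final_od``; NaN when the curve
        never grew.
    regrowth
        True when the culture was suppressed by phage and later recovered —
        either a rise–fall–rise around the thresholds, or an initial
        suppression of at least 2 h followed by growth.
    regrowth_onset_h
        First grid time the OD exceeds ``od_thresh`` after the suppressed
        phase (NaN when ``regrowth`` is False).
    max_od
        Peak absorbance over the whole trace.
    """

    final_od: float
    lag_h: float
    t_stationary_h: float
    regrowth: bool
    regrowth_onset_h: float
    max_od: float


def _detect_regrowth(t: np.ndarray, od: np.ndarray, od_thresh: float,
                     kill_thresh: float) -> tuple[bool, float]:
    above = od > od_thresh
    if not above.any():
        return False, T_STATIONARY_UNDEFINED

    first_above = int(np.argmax(above))
    # Pattern A: grew above od_thresh, was killed below kill_thresh, grew again.
    after = od[first_above:]
    below = after < kill_thresh
    if below.any():
        dip = first_above + int(np.argmax(below))
        re_above = od[dip:] > od_thresh
        if re_above.any():
            return True, float(t[dip + int(np.argmax(re_above))])

    # Pattern B: started suppressed (below od_thresh, no net growth for >= 2 h)
    # and only later rose above od_thresh.  The no-growth condition keeps
    # slow-but-steady impaired growers from being flagged.
    i2h = int(np.searchsorted(t, 2.0))
    if i2h < t.size and od[0] < od_thresh:
        suppressed = np.all(od[: i2h + 1] < od_thresh)
        no_growth = od[i2h] <= 1.1 * od[0] + 1e-3
        if suppressed and no_growth and t[first_above] >= 2.0:
            return True, float(t[first_above])
    return False, T_STATIONARY_UNDEFINED


def extract_pattern_features(curve: GrowthCurve, od_thresh: float = 0.1,
                             kill_thresh: float = 0.1) -> PatternFeatures:
    """Compute :class:`PatternFeatures` for one (adjusted) curve.

    Thresholds are in absorbance units; the 0.1 default sits midway between
    the adjusted baseline and the 0.2 "successful infection" endpoint bound.
    """
    t = curve.grid.times
    od = curve.od

    final_od = float(np.mean(od[-3:]))
    max_od = float(np.max(od))

    above = od > od_thresh
    if above.any():
        first_above = int(np.argmax(above))
        lag_h = float(t[max(first_above - 1, 0)])
    else:
        lag_h = float(t[-1])

    if final_od > 0:
        at_stat = od >= 0.95 * final_od
        t_stationary = float(t[int(np.argmax(at_stat))]) if at_stat.any() else T_STATIONARY_UNDEFINED
    else:
        t_stationary = T_STATIONARY_UNDEFINED

    regrowth, onset = _detect_regrowth(t, od, od_thresh, kill_thresh)

    return PatternFeatures(
        final_od=final_od,
        lag_h=lag_h,
        t_stationary_h=t_stationary,
        regrowth=regrowth,
        regrowth_onset_h=onset,
        max_od=max_od,
    )
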