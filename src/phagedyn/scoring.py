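"""Virulence scoring of coculture curves against their phage-free control.

Two AUC-ratio scores quantify how much a phage suppressed bacterial growth:

* **PhageScore** — ``100 * (AUC_control - AUC_treatment) / AUC_control``
  over the full 22-h incubation.
* **Local virulence score** — the same ratio, but integrating only up to
  the timepoint before the phage-free control reaches its maximum OD
  (i.e. until the control's stationary phase), so late regrowth in the
  control cannot dilute the early killing signal.

Both are 100 for a complete kill (treatment AUC 0), 0 for no effect, and
may be negative when the treated culture outgrows the control — negatives
are retained, not clipped.  Endpoint infectivity is classified from the
final OD: < 0.2 successful, 0.2–0.5 somewhat successful, > 0.5 failed.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from .curves import CombinationKey, GrowthCurve, PlateExperiment, require_adjusted

__all__ = [
    "ScoreResult",
    "auc_trapezoid",
    "stationary_cutoff_index",
    "phage_score",
    "local_virulence_score",
    "classify_endpoint",
    "score_plate",
    "score_correlation",
    "aggregate_scores",
]


@dataclass(frozen=True)
class ScoreResult:
    key: CombinationKey
    auc_full: float
    auc_local: float
    phage_score: float
    virulence_score: float
    endpoint_od: float
    endpoint_category: str


def auc_trapezoid(curve: GrowthCurve, t_cut_index: int | None = None) -> float:
    """Composite-trapezoid area under the curve over [t0, t_cut] (absorbance·h)."""
    n = len(curve.grid)
    if t_cut_index is None:
        t_cut_index = n - 1
    if not 0 < t_cut_index < n:
        raise IndexError(f"t_cut_index {t_cut_index} out of range (1..{n - 1})")
    sl = slice(0, t_cut_index + 1)
    return float(np.trapezoid(curve.od[sl], curve.grid.times[sl]))


def stationary_cutoff_index(control: GrowthCurve) -> int:
    """Grid index of the timepoint before the control's (first) maximum OD.

    Ties in a plateaued control are broken by the first occurrence of the
    maximum, so a noisy plateau cannot push the cutoff arbitrarily late.
    The minimum returned index is 1 (an AUC needs at least one interval).
    """
    if np.max(control.od) <= 0:
        raise ValueError("control did not grow (all-zero curve)")
    imax = int(np.argmax(control.od))
    return max(imax - 1, 1)


def _auc_ratio(treatment: GrowthCurve, control: GrowthCurve,
               t_cut_index: int | None) -> float:
    if treatment.grid != control.grid:
        raise ValueError("treatment and control must share the time grid")
    auc_ctrl = auc_trapezoid(control, t_cut_index)
    if auc_ctrl <= 0:
        raise ValueError("control AUC is zero; cannot form the score ratio")
    auc_trt = auc_trapezoid(treatment, t_cut_index)
    return 100.0 * (auc_ctrl - auc_trt) / auc_ctrl


def phage_score(treatment: GrowthCurve, control: GrowthCurve) -> float:
    """PhageScore over the full study period (percent)."""
    return _auc_ratio(treatment, control, None)


def local_virulence_score(treatment: GrowthCurve, control: GrowthCurve) -> float:
    """Local virulence score: the AUC ratio truncated at the control's
    stationary phase (percent)."""
    return _auc_ratio(treatment, control, stationary_cutoff_index(control))


def classify_endpoint(endpoint_od: float) -> str:
    if endpoint_od < 0:
        raise ValueError(f"endpoint OD must be >= 0, got {endpoint_od}")
    if endpoint_od < 0.2:
        return "successful"
    if endpoint_od <= 0.5:
        return "somewhat_successful"
    return "failed"


def score_plate(plate: PlateExperiment) -> list[ScoreResult]:
    """Score every treatment well of an adjusted plate against its own
    phage-free control (per-replicate convention; aggregation is separate)."""
    controls = plate.wells("bacteria_control")
    if not controls:
        raise ValueError("plate has no bacteria_control well")
    control = controls[0]
    require_adjusted(control, "scoring")
    cut = stationary_cutoff_index(control)

    results = []
    for trt in plate.wells("treatment"):
        require_adjusted(trt, "scoring")
        results.append(
            ScoreResult(
                key=trt.key,
                auc_full=auc_trapezoid(trt),
                auc_local=auc_trapezoid(trt, cut),
                phage_score=phage_score(trt, control),
                virulence_score=local_virulence_score(trt, control),
                endpoint_od=trt.endpoint_od,
                endpoint_category=classify_endpoint(trt.endpoint_od),
            )
        )
    return results


def score_correlation(results) -> float:
    """Sample Pearson correlation between PhageScore and virulence score."""
    ps = np.array([r.phage_score for r in results], dtype=float)
    vs = np.array([r.virulence_score for r in results], dtype=float)
    if ps.size < 3:
        raise ValueError("need at least 3 score pairs")
    if not (np.all(np.isfinite(ps)) and np.all(np.isfinite(vs))):
        raise ValueError("scores must be finite")
    if np.std(ps) == 0 or np.std(vs) == 0:
        raise ValueError("zero variance in a score vector")
    return float(np.corrcoef(ps, vs)[0, 1])


def aggregate_scores(results) -> pd.DataFrame:
    """Per-combination mean, standard error and n of both scores, and the
    replicate-averaged endpoint OD with its infectivity category."""
    groups: dict[tuple, list[ScoreResult]] = defaultdict(list)
    for r in results:
        groups[r.key.combination].append(r)
    rows = []
    for (phage, bact, moi), rs in sorted(groups.items()):
        ps = np.array([r.phage_score for r in rs])
        vs = np.array([r.virulence_score for r in rs])
        eo = np.array([r.endpoint_od for r in rs])
        n = len(rs)
        se = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        mean_ep = float(np.mean(eo))
        rows.append(
            {
                "phage_id": phage,
                "bacterium_id": bact,
                "moi": moi,
                "n": n,
                "phage_score_mean": float(np.mean(ps)),
                "phage_score_se": se(ps),
                "virulence_score_mean": float(np.mean(vs)),
                "virulence_score_se": se(vs),
                "endpoint_od_mean": mean_ep,
                "endpoint_category": classify_endpoint(max(mean_ep, 0.0)),
            }
        )
    return pd.DataFrame(rows)
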