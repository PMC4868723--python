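"""Per-marker ROC analysis: AUC, DeLong confidence intervals, optimal
cutoffs, and paired comparison of two markers on the same subjects.

The AUC is the Mann–Whitney statistic (ties count one half). Variances
come from DeLong's structural components: the placement value of a case
is the fraction of controls it beats, and vice versa; the AUC variance is
the sum of the two placement variances over their group sizes. With
complete separation all placements are constant, the variance is zero and
the confidence interval degenerates to [1, 1]. The optimal cutoff scans
every midpoint between adjacent distinct scores (plus the two infinite
corners) and jointly maximizes sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: orientation of a marker relative to the tumor class
HIGHER_IN_CASES = "higher-in-cases"
LOWER_IN_CASES = "lower-in-cases"


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    direction: str


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def _placements(cases: np.ndarray, controls: np.ndarray):
    """DeLong placement values (per case, per control) and the AUC."""
    psi = (cases[:, None] > controls[None, :]).astype(float)
    psi += 0.5 * (cases[:, None] == controls[None, :])
    v10 = psi.mean(axis=1)  # per case
    v01 = psi.mean(axis=0)  # per control
    return v10, v01, float(psi.mean())


def auc(scores, labels) -> float:
    """Mann–Whitney AUC of a marker for the tumor class (ties = 1/2).

    Missing scores are excluded pairwise. Values below 0.5 indicate a
    marker lower in cases; no reorientation is applied here.
    """
    cases, controls = _split(scores, labels)
    _, _, a = _placements(cases, controls)
    return a


def delong_ci(scores, labels, level: float = 0.95) -> RocResult:
    """AUC with a DeLong confidence interval (clipped to [0, 1])."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    cases, controls = _split(scores, labels)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("need at least 2 samples per class for a DeLong CI")
    v10, v01, a = _placements(cases, controls)
    var = v10.var(ddof=1) / cases.size + v01.var(ddof=1) / controls.size
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return RocResult(
        auc=a,
        ci_low=float(np.clip(a - half, 0, 1)),
        ci_high=float(np.clip(a + half, 0, 1)),
        threshold=np.nan,
        sensitivity=np.nan,
        specificity=np.nan,
        direction=HIGHER_IN_CASES,
    )


def best_cutoff(scores, labels, direction: str = HIGHER_IN_CASES):
    """Threshold jointly maximizing sensitivity and specificity.

    Candidates are the midpoints between adjacent distinct scores plus
    ±inf. For ``higher-in-cases`` a sample is called a case when its score
    is >= the threshold, for ``lower-in-cases`` when <=. Ties on
    sensitivity + specificity prefer higher specificity, then the lower
    threshold. Returns ``(threshold, sensitivity %, specificity %)``.
    """
    if direction not in (HIGHER_IN_CASES, LOWER_IN_CASES):
        raise ValueError(f"unknown direction {direction!r}")
    cases, controls = _split(scores, labels)
    pooled = np.unique(np.r_[cases, controls])
    mids = (pooled[:-1] + pooled[1:]) / 2 if pooled.size > 1 else np.empty(0)
    candidates = np.r_[-np.inf, mids, np.inf]

    if direction == HIGHER_IN_CASES:
        sens = np.array([(cases >= t).mean() for t in candidates])
        spec = np.array([(controls < t).mean() for t in candidates])
    else:
        sens = np.array([(cases <= t).mean() for t in candidates])
        spec = np.array([(controls > t).mean() for t in candidates])

    youden = sens + spec
    # maximize youden, then specificity, then prefer the lower threshold
    order = np.lexsort((candidates, -spec, -youden))
    i = order[0]
    return float(candidates[i]), float(100 * sens[i]), float(100 * spec[i])


def compare_auc_delong(scores_a, scores_b, labels, paired: bool = True):
    """DeLong test of AUC(a) − AUC(b); two-sided.

    ``paired=True`` (default) assumes both markers are scored on the same
    subjects and uses the covariance of the placement values; the unpaired
    variant sums the two independent DeLong variances. Returns
    ``(delta_auc, z, p_value)``.
    """
    labels = np.asarray(labels, dtype=int)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape != labels.shape:
        raise ValueError("markers must be scored on the same samples")
    if paired:
        ok = ~(np.isnan(sa) | np.isnan(sb))
        ca, na = _split(sa[ok], labels[ok])
        cb, nb = _split(sb[ok], labels[ok])
        v10a, v01a, aa = _placements(ca, na)
        v10b, v01b, ab = _placements(cb, nb)
        m, n = ca.size, na.size
        s10 = np.cov(v10a, v10b, ddof=1)
        s01 = np.cov(v01a, v01b, ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        ra = delong_ci(sa, labels)
        rb = delong_ci(sb, labels)
        aa, ab = ra.auc, rb.auc
        za = (ra.ci_high - ra.auc) / stats.norm.ppf(0.975)
        zb = (rb.ci_high - rb.auc) / stats.norm.ppf(0.975)
        var = za**2 + zb**2
    delta = aa - ab
    if var <= 0:
        return float(delta), 0.0 if delta == 0 else np.inf, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(p)


def roc_table(ds) -> pd.DataFrame:
    """Per-metabolite ROC summary, sorted by AUC descending.

    Each marker is auto-oriented so its AUC is >= 0.5 and the orientation
    recorded; degenerate metabolites (a class entirely missing, constant
    scores with one class absent, ...) become flagged rows rather than
    aborting the table.
    """
    rows = []
    for j, name in enumerate(ds.metabolite_names):
        scores = ds.values[:, j]
        try:
            raw = auc(scores, ds.labels)
            direction = HIGHER_IN_CASES if raw >= 0.5 else LOWER_IN_CASES
            oriented = scores if direction == HIGHER_IN_CASES else -scores
            res = delong_ci(oriented, ds.labels)
            thr, sens, spec = best_cutoff(scores, ds.labels, direction)
            rows.append({
                "metabolite": name, "auc": res.auc, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "threshold": thr, "sensitivity": sens,
                "specificity": spec, "direction": direction, "error": "",
            })
        except ValueError as exc:
            rows.append({
                "metabolite": name, "auc": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "threshold": np.nan, "sensitivity": np.nan,
                "specificity": np.nan, "direction": "", "error": str(exc),
            })
    table = pd.DataFrame(rows)
    return table.sort_values(
        "auc", ascending=False, kind="stable", na_position="last"
    ).reset_index(drop=True)
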