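"""Subject-level AHI agreement statistics.

AHI = detected events per hour of sleep; agreement between estimated and
reference AHI is summarized with Bland-Altman bias/limits, Spearman rank
correlation, ICC(2,1) (two-way random effects, absolute agreement, single
rater) with an F-based 95% CI, and severity classification
(confusion/accuracy/Cohen's kappa) with and without near-boundary
double-labeling (NBL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import EventList, Hypnogram
from .synthgen import SEVERITY_CLASSES, severity_of

BOUNDARIES = (5.0, 15.0, 30.0)

#: default NBL half-widths: 10% of each boundary (events/h); the original
#: scorer-disagreement-derived widths are not published, so these are
#: configurable everywhere they are used
DEFAULT_NBL_ZONES: dict[float, float] = {5.0: 0.5, 15.0: 1.5, 30.0: 3.0}


@dataclass
class AhiPair:
    subject_id: str
    ahi_est: float
    ahi_ref: float
    age: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.ahi_est < 0 or self.ahi_ref < 0:
            raise ValueError("AHI values must be non-negative")


@dataclass
class NBLZones:
    half_widths: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_NBL_ZONES))

    def __post_init__(self) -> None:
        hw = dict(self.half_widths)
        bounds = sorted(hw)
        for b, w in hw.items():
            if w < 0:
                raise ValueError("zone half-widths must be non-negative")
        for a, b in zip(bounds, bounds[1:]):
            if a + hw[a] > b - hw[b]:
                raise ValueError("NBL zones must not overlap")
        self.half_widths = hw


def compute_ahi(detected_events: EventList | int, hypnogram: Hypnogram) -> float:
    """Events per hour of sleep (sleep time from non-wake epochs)."""
    n = detected_events if isinstance(detected_events, int) else len(detected_events)
    tst_h = hypnogram.total_sleep_time_s() / 3600.0
    if tst_h <= 0:
        raise ValueError("total sleep time is zero; AHI undefined")
    return n / tst_h


def bland_altman(pairs: Sequence[AhiPair]) -> dict[str, float]:
    """Bias = mean(est - ref); LoA = bias +/- 1.96 * sample SD of diffs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    d = np.array([p.ahi_est - p.ahi_ref for p in pairs])
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "sd": sd,
        "loa_half_width": 1.96 * sd,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
    }


def spearman_r(
    pairs: Sequence[AhiPair], subgroup_max_ref: float | None = None
) -> dict[str, float | None]:
    """Average-rank Spearman correlation, optionally on AHI_ref < cutoff."""
    if subgroup_max_ref is not None:
        pairs = [p for p in pairs if p.ahi_ref < subgroup_max_ref]
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    est = np.array([p.ahi_est for p in pairs])
    ref = np.array([p.ahi_ref for p in pairs])
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        return {"r": None, "p": None, "n": len(pairs)}
    res = stats.spearmanr(est, ref)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": len(pairs)}


def icc_two_way(pairs: Sequence[AhiPair], alpha: float = 0.05) -> dict[str, float | None]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Closed-form mean squares with the McGraw & Wong F-distribution CI.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 pairs")
    data = np.array([[p.ahi_est, p.ahi_ref] for p in pairs], dtype=float)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return {"icc": None, "ci_lower": None, "ci_upper": None}
    icc = (msr - mse) / denom
    if icc >= 1.0 - 1e-15:  # perfect agreement; CI collapses
        return {"icc": 1.0, "ci_lower": 1.0, "ci_upper": 1.0}

    # McGraw & Wong (1996) CI for ICC(A,1)
    r = icc
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return {"icc": float(icc), "ci_lower": float(lower), "ci_upper": float(upper)}


# ---------------------------------------------------------------------------
# severity classification


@dataclass(frozen=True)
class SeverityLabel:
    primary: str
    twin: str | None = None

    def __post_init__(self) -> None:
        if self.twin is not None:
            i = SEVERITY_CLASSES.index(self.primary)
            j = SEVERITY_CLASSES.index(self.twin)
            if abs(i - j) != 1:
                raise ValueError("twin class must be adjacent to the primary class")

    def classes(self) -> set[str]:
        return {self.primary} | ({self.twin} if self.twin else set())


def severity_class(ahi: float, zones: NBLZones | None = None) -> SeverityLabel:
    """Class by the canonical 5/15/30 thresholds (boundary -> upper class);
    with zones, an AHI within a zone also carries the adjacent class."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    primary = severity_of(ahi)
    twin = None
    if zones is not None:
        for bnd, hw in zones.half_widths.items():
            if hw > 0 and abs(ahi - bnd) <= hw:
                below, above = (severity_of(bnd - 1e-9), severity_of(bnd))
                twin = below if primary == above else above
                break
    return SeverityLabel(primary, twin)


def _confusion(ref: Sequence[str], est: Sequence[str]) -> np.ndarray:
    cm = np.zeros((4, 4), dtype=int)
    idx = {c: i for i, c in enumerate(SEVERITY_CLASSES)}
    for r, e in zip(ref, est):
        cm[idx[r], idx[e]] += 1
    return cm


def kappa_from_confusion(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1))) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def severity_report(
    pairs: Sequence[AhiPair], zones: NBLZones | None = None
) -> dict[str, object]:
    """Confusion / accuracy / kappa, plain and with NBL.

    With NBL a subject whose reference AHI lies in a boundary zone is in
    agreement if the estimate matches either adjacent class; kappa is then
    computed on the resolved reference assignment (twin-matched subjects
    counted in the matching class).
    """
    zones = zones or NBLZones()
    ref = [severity_class(p.ahi_ref).primary for p in pairs]
    est = [severity_class(p.ahi_est).primary for p in pairs]
    if len(set(ref)) < 2:
        raise ValueError("need at least 2 reference classes present")
    cm = _confusion(ref, est)
    out: dict[str, object] = {
        "classes": list(SEVERITY_CLASSES),
        "confusion": cm.tolist(),
        "accuracy": float(np.trace(cm) / cm.sum()),
        "kappa": float(kappa_from_confusion(cm)),
        "nbl_zones": {str(k): v for k, v in zones.half_widths.items()},
    }
    ref_nbl = []
    for p, e in zip(pairs, est):
        lab = severity_class(p.ahi_ref, zones)
        ref_nbl.append(e if e in lab.classes() else lab.primary)
    cm_nbl = _confusion(ref_nbl, est)
    out["confusion_nbl"] = cm_nbl.tolist()
    out["accuracy_nbl"] = float(np.trace(cm_nbl) / cm_nbl.sum())
    out["kappa_nbl"] = float(kappa_from_confusion(cm_nbl))
    return out


def covariate_error_correlation(pairs: Sequence[AhiPair]) -> dict[str, dict[str, float | None]]:
    """Spearman R between |AHI_ref - AHI_est| and each covariate."""
    err = np.array([abs(p.ahi_ref - p.ahi_est) for p in pairs])
    out: dict[str, dict[str, float | None]] = {}
    for name in ("age", "bmi"):
        vals = [getattr(p, name) for p in pairs]
        if any(v is None for v in vals):
            continue
        v = np.asarray(vals, dtype=float)
        if np.ptp(err) == 0 or np.ptp(v) == 0:
            out[name] = {"r": None, "p": None}
        else:
            res = stats.spearmanr(err, v)
            out[name] = {"r": float(res.statistic), "p": float(res.pvalue)}
    return out
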