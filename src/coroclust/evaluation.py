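"""Plaque-level scoring of calls against ground truth.

Each lesion is the unit of analysis.  A truth lesion counts as a true
positive when some call of the *same type* overlaps its centerline
interval by at least ``min_overlap_mm`` (greedy one-to-one matching by
overlap, ties to the more proximal lesion); unmatched truth lesions are
false negatives, unmatched calls false positives.  Plaque-level true
negatives have no natural unit, so the lesion-free centerline is tiled
into disjoint 10 mm segments and each tile containing no call counts as
a TN — this makes specificity computable and scale-stable, and the tile
length is a parameter.

Also provided: symmetric Hausdorff distance between voxel sets in mm,
the FFR significance rule (FFR <= 0.80, inclusive), concordance counts
between predicted significance and FFR-derived significance, and the
paired two-sided t test with a 95% confidence interval used to compare
two algorithms' per-case F1 scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.spatial.distance import directed_hausdorff

from .lesion_calling import PlaqueCall
from .phantom import FFRRecord, LesionAnnotation

__all__ = [
    "ConfusionCounts",
    "match_calls_to_truth",
    "detection_metrics",
    "hausdorff_mm",
    "ffr_significant",
    "ffr_concordance",
    "paired_compare",
    "PairedComparison",
    "matched_hausdorff_mm",
]

PLAQUE_TYPES = ("calcified", "soft", "mixed")
FFR_SIGNIFICANCE_THRESHOLD = 0.80


@dataclass
class ConfusionCounts:
    """Per-plaque-type TP/FN/FP/TN at the lesion level."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    matches: list[tuple[int, int]] = field(default_factory=list)  # (truth id, call id)

    def of(self, plaque_type: str) -> dict[str, int]:
        return self.counts.setdefault(
            plaque_type, {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
        )

    def pooled(self) -> dict[str, int]:
        out = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
        for c in self.counts.values():
            for k in out:
                out[k] += c[k]
        return out


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def match_calls_to_truth(calls: list[PlaqueCall], truth: LesionAnnotation,
                         min_overlap_mm: float = 1.0,
                         tile_mm: float = 10.0,
                         type_strict: bool = True) -> ConfusionCounts:
    """Greedy one-to-one matching of calls to truth lesions by interval
    overlap; fills per-type confusion counts including tiled TNs."""
    intervals = sorted((les.interval_mm for les in truth.lesions),
                       key=lambda iv: iv[0])
    for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
        if b0 > a1:
            raise ValueError("overlapping truth lesions (invalid annotation)")

    cc = ConfusionCounts()
    for t in PLAQUE_TYPES:
        cc.of(t)

    pairs = []
    for les in truth.lesions:
        for call in calls:
            if type_strict and call.type != les.type:
                continue
            ov = _overlap(les.interval_mm, call.interval_mm)
            if ov >= min_overlap_mm:
                pairs.append((ov, les.interval_mm[0], les.id, call.id, les.type))
    # greedy by overlap (desc), ties -> more proximal truth lesion
    pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    matched_truth: set[int] = set()
    matched_call: set[int] = set()
    for ov, _, tid, cid, ttype in pairs:
        if tid in matched_truth or cid in matched_call:
            continue
        matched_truth.add(tid)
        matched_call.add(cid)
        cc.matches.append((tid, cid))
        cc.of(ttype)["tp"] += 1

    for les in truth.lesions:
        if les.id not in matched_truth:
            cc.of(les.type)["fn"] += 1
    for call in calls:
        if call.id not in matched_call:
            cc.of(call.type)["fp"] += 1

    # TN: disjoint 10 mm tiles of lesion-free centerline containing no call
    total = truth.centerline_length_mm
    free_segments = []
    cursor = 0.0
    for iv in intervals:
        if iv[0] > cursor:
            free_segments.append((cursor, iv[0]))
        cursor = max(cursor, iv[1])
    if cursor < total:
        free_segments.append((cursor, total))
    tn = 0
    for a, b in free_segments:
        n_tiles = int((b - a) // tile_mm)
        for t in range(n_tiles):
            tile = (a + t * tile_mm, a + (t + 1) * tile_mm)
            if not any(_overlap(tile, c.interval_mm) > 0 for c in calls):
                tn += 1
    # negatives are shared across types: each type's specificity uses the
    # same lesion-free tiling
    for t in PLAQUE_TYPES:
        cc.of(t)["tn"] = tn
    return cc


def _rate(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


def detection_metrics(cc: ConfusionCounts) -> dict[str, dict]:
    """Sensitivity/specificity/precision/F1 (percent) per plaque type.

    Any 0/0 rate is reported as 0 with a ``degenerate`` flag listing the
    affected metrics.
    """
    out: dict[str, dict] = {}
    items = list(cc.counts.items()) + [("all", cc.pooled())]
    for ptype, c in items:
        tp, fn, fp, tn = c["tp"], c["fn"], c["fp"], c["tn"]
        sens, d1 = _rate(tp, tp + fn)
        spec, d2 = _rate(tn, tn + fp)
        prec, d3 = _rate(tp, tp + fp)
        if prec + sens > 0:
            f1 = 2.0 * prec * sens / (prec + sens)
            d4 = False
        else:
            f1, d4 = 0.0, True
        flags = [n for n, d in zip(("sensitivity", "specificity",
                                    "precision", "f1"), (d1, d2, d3, d4)) if d]
        out[ptype] = {"sensitivity": sens, "specificity": spec,
                      "precision": prec, "f1": f1,
                      "counts": dict(c), "degenerate": flags}
    return out


def hausdorff_mm(pred_voxels: np.ndarray, truth_voxels: np.ndarray,
                 spacing) -> float:
    """Symmetric Hausdorff distance between voxel-center point sets (mm)."""
    a = np.asarray(pred_voxels, dtype=np.float64)
    b = np.asarray(truth_voxels, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("Hausdorff distance needs nonempty voxel sets")
    s = np.asarray(spacing, dtype=np.float64)
    a_mm = a * s[None, :]
    b_mm = b * s[None, :]
    d_ab = directed_hausdorff(a_mm, b_mm)[0]
    d_ba = directed_hausdorff(b_mm, a_mm)[0]
    return float(max(d_ab, d_ba))


def matched_hausdorff_mm(calls: list[PlaqueCall], truth: LesionAnnotation,
                         cc: ConfusionCounts, spacing) -> dict[int, float]:
    """Hausdorff distance (mm) per matched (truth, call) pair, by truth id."""
    call_by_id = {c.id: c for c in calls}
    truth_by_id = {l.id: l for l in truth.lesions}
    return {
        tid: hausdorff_mm(call_by_id[cid].voxels, truth_by_id[tid].voxels, spacing)
        for tid, cid in cc.matches
    }


def ffr_significant(ffr: float) -> bool:
    """Hemodynamic significance: FFR <= 0.80 (threshold inclusive)."""
    if not 0.0 < ffr <= 1.0:
        raise ValueError(f"FFR must be in (0, 1], got {ffr}")
    return ffr <= FFR_SIGNIFICANCE_THRESHOLD


def ffr_concordance(calls: list[PlaqueCall], truth: LesionAnnotation,
                    ffr_records: list[FFRRecord],
                    min_overlap_mm: float = 1.0) -> dict[str, int]:
    """Concordance between predicted significance and FFR significance.

    Each FFR-measured truth lesion is matched to the overlapping call
    with the greatest interval overlap (any type); the lesion counts as
    predicted-significant when that call is flagged significant.
    """
    ffr_by_id = {r.lesion_id: r.ffr for r in ffr_records}
    out = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for les in truth.lesions:
        if les.id not in ffr_by_id:
            continue
        truth_sig = ffr_significant(ffr_by_id[les.id])
        best, best_ov = None, 0.0
        for call in calls:
            ov = _overlap(les.interval_mm, call.interval_mm)
            if ov >= min_overlap_mm and ov > best_ov:
                best, best_ov = call, ov
        pred_sig = bool(best is not None and best.predicted_significant)
        key = {(True, True): "tp", (True, False): "fn",
               (False, True): "fp", (False, False): "tn"}[(truth_sig, pred_sig)]
        out[key] += 1
    return out


@dataclass
class PairedComparison:
    t: float
    p: float
    df: int
    mean_diff: float
    ci95: tuple[float, float]
    degenerate: bool = False


def paired_compare(f1_a, f1_b) -> PairedComparison:
    """Paired two-sided t test on per-case differences ``a - b`` with a
    95% CI of the mean difference.

    With zero-variance differences: t = 0 / p = 1 when the mean is also
    zero, otherwise an infinite-t surrogate with p = 0 (flagged
    degenerate).
    """
    a = np.asarray(f1_a, dtype=np.float64)
    b = np.asarray(f1_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired comparison needs >= 2 cases")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return PairedComparison(t=0.0, p=1.0, df=df, mean_diff=0.0,
                                    ci95=(0.0, 0.0), degenerate=True)
        t = float(np.inf) if md > 0 else float(-np.inf)
        return PairedComparison(t=t, p=0.0, df=df, mean_diff=md,
                                ci95=(md, md), degenerate=True)
    se = sd / np.sqrt(n)
    t = md / se
    p = float(2.0 * sstats.t.sf(abs(t), df))
    tcrit = float(sstats.t.ppf(0.975, df))
    return PairedComparison(t=float(t), p=p, df=df, mean_diff=md,
                            ci95=(md - tcrit * se, md + tcrit * se))
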