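"""Turn a semantically ordered clustering into discrete plaque calls.

Calling logic (defaults in :class:`CallingParams`):

* **calcified** — maximal 26-connected components of the calcified-role
  cluster whose centerline extent is at least ``min_lesion_mm``;
* **soft** — maximal contiguous centerline runs (length >=
  ``min_lesion_mm``) where the cross-section's majority cluster lies in
  the two narrowest width ranks, the radius deviation from the expected
  healthy profile is at least ``soft_deviation_min``, and the run is not
  majority-calcified; the run's narrow-rank voxels form the lesion;
* **mixed** — a calcified and a soft candidate whose centerline
  intervals lie within ``merge_gap_mm`` of each other merge into one
  mixed call.

The expected healthy radius at an arc length is the isotonic (monotone
nonincreasing proximal -> distal) regression of an upper envelope of the
observed radii (a moving 90th percentile over a 5 mm window), so focal
narrowings do not drag the baseline down.  A call's severity is the
maximum radius deviation over its interval; calls with severity >=
``sig_severity_min`` (default 0.50, i.e. >=50% diameter stenosis) are
flagged as predicted hemodynamically significant.  That geometric rule
is an explicit operationalization choice: the reference standard for
significance is invasive FFR, which imaging alone cannot measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.isotonic import IsotonicRegression

from .clustering import ClusterLabeling
from .skeleton import Skeleton

__all__ = [
    "RadiusDeviationProfile",
    "PlaqueCall",
    "CallingParams",
    "expected_radius_profile",
    "call_lesions",
    "calls_to_json",
    "calls_to_label_volume",
]


@dataclass
class RadiusDeviationProfile:
    """Observed vs expected radius per skeleton point, ordered by arc."""

    point_index: np.ndarray   # skeleton point indices, sorted by arc
    arc_mm: np.ndarray
    observed_mm: np.ndarray
    expected_mm: np.ndarray

    @property
    def deviation(self) -> np.ndarray:
        return 1.0 - self.observed_mm / self.expected_mm


@dataclass
class PlaqueCall:
    id: int
    type: str
    voxels: np.ndarray                     # (n, 3) voxel coordinates
    interval_mm: tuple[float, float]
    severity: float
    predicted_significant: bool

    def __post_init__(self) -> None:
        if len(self.voxels) == 0:
            raise ValueError("a plaque call needs a nonempty voxel set")
        if not 0.0 <= self.severity < 1.0:
            raise ValueError("severity must be in [0, 1)")


@dataclass
class CallingParams:
    min_lesion_mm: float = 2.0
    soft_deviation_min: float = 0.25
    merge_gap_mm: float = 2.0
    sig_severity_min: float = 0.50
    n_narrow_ranks: int = 2
    calcified_hu_threshold: float = 500.0


def expected_radius_profile(arc_mm: np.ndarray, radii_mm: np.ndarray,
                            point_index: np.ndarray | None = None,
                            window_mm: float = 5.0,
                            envelope_percentile: float = 90.0,
                            ) -> RadiusDeviationProfile:
    """Isotonic upper-envelope fit of the healthy radius along arc length.

    Points must be ordered (or orderable) proximal -> distal; at least 3
    points are required.
    """
    arc = np.asarray(arc_mm, dtype=np.float64)
    obs = np.asarray(radii_mm, dtype=np.float64)
    if arc.shape != obs.shape or arc.ndim != 1:
        raise ValueError("arc lengths and radii must be 1-D and aligned")
    if arc.size < 3:
        raise ValueError("need at least 3 skeleton points to fit a profile")
    order = np.argsort(arc, kind="stable")
    arc_s, obs_s = arc[order], obs[order]
    # moving upper envelope
    env = np.empty_like(obs_s)
    half = window_mm / 2.0
    lo = np.searchsorted(arc_s, arc_s - half, side="left")
    hi = np.searchsorted(arc_s, arc_s + half, side="right")
    for i in range(arc_s.size):
        env[i] = np.percentile(obs_s[lo[i]:hi[i]], envelope_percentile)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    expected = iso.fit_transform(arc_s, env)
    expected = np.maximum(expected, 1e-9)
    idx = (np.asarray(point_index)[order] if point_index is not None
           else order)
    return RadiusDeviationProfile(point_index=np.asarray(idx),
                                  arc_mm=arc_s, observed_mm=obs_s,
                                  expected_mm=expected)


def _runs(flags: np.ndarray, arc: np.ndarray, max_gap_mm: float):
    """Maximal runs of flagged points, split where arc gaps are large."""
    runs = []
    cur: list[int] = []
    for i, f in enumerate(flags):
        if f and (not cur or arc[i] - arc[cur[-1]] <= max_gap_mm):
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = [i] if f else []
    if cur:
        runs.append(cur)
    return runs


def _interval_gap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(a[0], b[0]) - min(a[1], b[1])


def call_lesions(labeling: ClusterLabeling, table: pd.DataFrame,
                 skel: Skeleton, profile: RadiusDeviationProfile,
                 params: CallingParams | None = None,
                 grid_shape: tuple[int, int, int] | None = None,
                 ) -> list[PlaqueCall]:
    """Produce typed plaque calls from a semantically ordered labeling."""
    params = params or CallingParams()
    if labeling.semantic is None:
        raise ValueError("labeling has no semantic roles "
                         "(run order_clusters_semantic first)")
    labels = labeling.labels
    roles = labeling.semantic
    calc_label = next((l for l, r in roles.items() if r == "calcified"), None)
    width_rank = {l: int(r.split("_")[-1]) for l, r in roles.items()
                  if r.startswith("width_rank_")}
    if not width_rank:
        raise ValueError("semantic roles contain no width ranks")
    max_rank = max(width_rank.values())
    narrow_labels = {l for l, rk in width_rank.items()
                     if rk > max_rank - params.n_narrow_ranks}

    coords = table[["x", "y", "z"]].to_numpy(dtype=np.int64)
    arcs = table["arc_mm"].to_numpy()
    owners = table["skel_index"].to_numpy(dtype=np.int64)

    dev_by_point = dict(zip(profile.point_index.tolist(),
                            profile.deviation.tolist()))

    candidates: list[dict] = []

    # (a) calcified candidates: 26-connected components of the calcified role
    if calc_label is not None:
        sel = labels == calc_label
        if sel.any():
            if grid_shape is None:
                grid_shape = tuple(coords.max(axis=0) + 2)
            vol = np.zeros(grid_shape, dtype=np.uint8)
            vol[tuple(coords[sel].T)] = 1
            lab_vol, n_comp = ndimage.label(vol, structure=np.ones((3, 3, 3)))
            comp_of = lab_vol[tuple(coords[sel].T)]
            sel_idx = np.flatnonzero(sel)
            for c in range(1, n_comp + 1):
                rows = sel_idx[comp_of == c]
                a = (float(arcs[rows].min()), float(arcs[rows].max()))
                if a[1] - a[0] >= params.min_lesion_mm:
                    candidates.append({"type": "calcified", "rows": rows,
                                       "interval": a})

    # (b) soft candidates: narrow-majority, high-deviation centerline runs
    point_ids = profile.point_index
    arc_p = profile.arc_mm
    majority = {}
    for p in point_ids.tolist():
        rows = np.flatnonzero(owners == p)
        if rows.size:
            counts = np.bincount(labels[rows])
            majority[p] = int(counts.argmax())
    step = np.median(np.diff(arc_p)) if arc_p.size > 1 else 1.0
    flags = np.zeros(arc_p.size, dtype=bool)
    for i, p in enumerate(point_ids.tolist()):
        maj = majority.get(p)
        flags[i] = (
            maj is not None
            and maj in narrow_labels
            and dev_by_point.get(p, 0.0) >= params.soft_deviation_min
        )
    for run in _runs(flags, arc_p, max_gap_mm=max(3.0 * step, 1.0)):
        pts = point_ids[run]
        a = (float(arc_p[run[0]]), float(arc_p[run[-1]]))
        if a[1] - a[0] < params.min_lesion_mm:
            continue
        in_run = np.isin(owners, pts)
        if calc_label is not None and in_run.any():
            calc_frac = float((labels[in_run] == calc_label).mean())
            if calc_frac > 0.5:
                continue
        rows = np.flatnonzero(in_run & np.isin(labels, list(narrow_labels)))
        if rows.size == 0:
            continue
        candidates.append({"type": "soft", "rows": rows, "interval": a})

    # (c) merge adjacent calcified + soft candidates into mixed calls
    candidates.sort(key=lambda c: c["interval"][0])
    merged = True
    while merged:
        merged = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                a, b = candidates[i], candidates[j]
                if {a["type"], b["type"]} == {"calcified", "soft"} and \
                        _interval_gap(a["interval"], b["interval"]) <= params.merge_gap_mm:
                    a["type"] = "mixed"
                    a["rows"] = np.unique(np.concatenate([a["rows"], b["rows"]]))
                    a["interval"] = (min(a["interval"][0], b["interval"][0]),
                                     max(a["interval"][1], b["interval"][1]))
                    del candidates[j]
                    merged = True
                    break
            if merged:
                break

    # (d) severity and significance per call
    calls: list[PlaqueCall] = []
    for cid, cand in enumerate(sorted(candidates, key=lambda c: c["interval"][0])):
        a = cand["interval"]
        in_int = (arc_p >= a[0] - 1e-9) & (arc_p <= a[1] + 1e-9)
        severity = float(np.clip(profile.deviation[in_int].max(initial=0.0),
                                 0.0, 1.0 - 1e-9))
        calls.append(PlaqueCall(
            id=cid, type=cand["type"], voxels=coords[cand["rows"]],
            interval_mm=a, severity=severity,
            predicted_significant=severity >= params.sig_severity_min,
        ))
    return calls


def calls_to_json(calls: list[PlaqueCall]) -> str:
    payload = [
        {
            "id": c.id,
            "type": c.type,
            "n_voxels": int(len(c.voxels)),
            "interval_mm": [round(float(v), 4) for v in c.interval_mm],
            "severity": round(float(c.severity), 4),
            "predicted_significant": bool(c.predicted_significant),
            "voxels": np.asarray(c.voxels).tolist(),
        }
        for c in calls
    ]
    return json.dumps(payload, indent=2)


TYPE_CODES = {"calcified": 1, "soft": 2, "mixed": 3}


def calls_to_label_volume(calls: list[PlaqueCall], shape) -> np.ndarray:
    """Typed label volume: 0 background, 1 calcified, 2 soft, 3 mixed."""
    vol = np.zeros(shape, dtype=np.int16)
    for c in calls:
        vol[tuple(np.asarray(c.voxels).T)] = TYPE_CODES[c.type]
    return vol
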