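"""Data-driven areas of interest from pooled fixation centroids.

Per picture, fixation centroids pooled over a sample of subjects (at most
200, sampled with a recorded seed when more are available) are clustered
with flat-kernel mean shift.  Each surviving mode becomes a circular
interest AOI; a second pass on the fixations falling outside every
interest AOI yields the areas of no interest used as control targets in
guided viewing.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import MeanShift

from .types import AOI, AOISet

DEFAULT_BANDWIDTH_DEG = 2.0
DEFAULT_MIN_CLUSTER_FRAC = 0.05
MIN_POOLED_FIXATIONS = 10


def _sorted_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("pooled fixations must be an (n, 2) array of degrees")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def _mean_shift_modes(
    pts: np.ndarray, bandwidth_deg: float, min_cluster_frac: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Flat-kernel mean shift; returns (mode, member_points) per cluster
    holding at least ``min_cluster_frac`` of the points.  Modes closer
    than bandwidth/2 are merged (weighted by member count)."""
    ms = MeanShift(bandwidth=bandwidth_deg, bin_seeding=False, cluster_all=True)
    ms.fit(pts)
    centers = ms.cluster_centers_
    labels = ms.labels_
    # merge near-duplicate modes
    merged: list[list[int]] = []
    used = np.zeros(len(centers), dtype=bool)
    for i in range(len(centers)):
        if used[i]:
            continue
        group = [i]
        used[i] = True
        for j in range(i + 1, len(centers)):
            if not used[j] and np.hypot(*(centers[i] - centers[j])) < bandwidth_deg / 2:
                group.append(j)
                used[j] = True
        merged.append(group)
    out = []
    for group in merged:
        member_mask = np.isin(labels, group)
        members = pts[member_mask]
        if len(members) < min_cluster_frac * len(pts):
            continue
        mode = members.mean(axis=0) if len(group) > 1 else centers[group[0]]
        out.append((np.asarray(mode, float), members))
    # deterministic ordering: by descending member count, then position
    out.sort(key=lambda mm: (-len(mm[1]), mm[0][0], mm[0][1]))
    return out


def derive_aois(
    fixations_pooled,
    bandwidth_deg: float = DEFAULT_BANDWIDTH_DEG,
    min_cluster_frac: float = DEFAULT_MIN_CLUSTER_FRAC,
    picture_id: str = "pic",
) -> AOISet:
    """Interest AOIs from pooled fixation centroids (degrees).

    AOI radius is max(bandwidth, RMS distance of cluster members to the
    mode).  Points are sorted internally, so the result does not depend on
    input order.
    """
    pts = _sorted_points(fixations_pooled)
    if len(pts) < MIN_POOLED_FIXATIONS:
        raise ValueError(
            f"need at least {MIN_POOLED_FIXATIONS} pooled fixations, got {len(pts)}"
        )
    aois = []
    for mode, members in _mean_shift_modes(pts, bandwidth_deg, min_cluster_frac):
        rms = float(np.sqrt(np.mean(np.sum((members - mode) ** 2, axis=1))))
        aois.append(
            AOI(
                centroid_deg=(float(mode[0]), float(mode[1])),
                radius_deg=max(bandwidth_deg, rms),
                kind="interest",
            )
        )
    return AOISet(picture_id, aois)


def derive_no_interest_centroids(
    fixations_pooled,
    aoi_set: AOISet,
    bandwidth_deg: float = DEFAULT_BANDWIDTH_DEG,
    min_required: int | None = None,
) -> AOISet:
    """Append no-interest centroids: mean-shift modes of the pooled
    fixations lying outside every interest AOI.

    ``min_required`` defaults to AOIs_pic - 1 (the number of control
    targets a guided-viewing path needs).
    """
    pts = _sorted_points(fixations_pooled)
    outside = np.array(
        [
            p
            for p in pts
            if not any(a.contains(p[0], p[1]) for a in aoi_set.interest)
        ]
    )
    if min_required is None:
        min_required = max(aoi_set.aois_pic - 1, 1)
    if len(outside) < MIN_POOLED_FIXATIONS:
        raise ValueError(
            "too few fixations outside interest AOIs "
            f"({len(outside)}); enlarge the pooled fixation sample"
        )
    modes = _mean_shift_modes(outside, bandwidth_deg, min_cluster_frac=0.0)
    extra = []
    for mode, members in modes:
        if any(a.contains(mode[0], mode[1]) for a in aoi_set.interest):
            continue  # no-interest centroids must lie outside interest AOIs
        rms = float(np.sqrt(np.mean(np.sum((members - mode) ** 2, axis=1))))
        extra.append(
            AOI(
                centroid_deg=(float(mode[0]), float(mode[1])),
                radius_deg=max(bandwidth_deg, rms),
                kind="no_interest",
            )
        )
    if len(extra) < min_required:
        raise ValueError(
            f"found {len(extra)} no-interest centroids, need {min_required}; "
            "enlarge the pooled fixation sample"
        )
    return AOISet(aoi_set.picture_id, list(aoi_set.aois) + extra)


def assign_fixations(fixations_deg, aoi_set: AOISet) -> list[int]:
    """Label each fixation with the index (within ``aoi_set.interest``) of
    the nearest interest AOI whose radius covers it, or -1.

    Ties (equal distance within float tolerance) go to the lower index.
    """
    interest = aoi_set.interest
    labels = []
    for p in np.asarray(fixations_deg, dtype=float):
        best = -1
        best_d = np.inf
        for idx, a in enumerate(interest):
            d = float(np.hypot(p[0] - a.centroid_deg[0], p[1] - a.centroid_deg[1]))
            if d <= a.radius_deg and d < best_d - 1e-12:
                best = idx
                best_d = d
        labels.append(best)
    return labels


def sample_pooled_subjects(
    subject_ids: list[str], max_subjects: int = 200, seed: int = 0
) -> list[str]:
    """The subject sample whose fixations are pooled per picture: all
    subjects when at most ``max_subjects``, otherwise a seeded random
    sample of that size."""
    if len(subject_ids) <= max_subjects:
        return list(subject_ids)
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(subject_ids), size=max_subjects, replace=False)
    return [subject_ids[i] for i in sorted(picked)]
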