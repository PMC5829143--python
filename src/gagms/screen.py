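"""Cross-run feature alignment and untreated/treated ratio screening.

Untargeted negative-mode LC-MS runs of diseased (untreated) versus
enzyme-treated tissue are compared per feature: features with matching
m/z and retention time across runs are aligned, per-group mean peak
areas are formed with a detection-floor substitution (100 instrument
arbitrary units for analytes below the level of detection), and the
untreated/treated area ratio classifies each feature into fold-change
classes.  When a treated replicate was floored the ratio is only a lower
bound, and is flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem import MassConstants
from .compositions import LADDER_STEPS, ladder_families

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "AlignedFeature",
    "ScreenHit",
    "align_features",
    "screen_ratios",
    "summarize_screen",
    "SCAN_RANGE",
    "CLASS_LABELS",
]

#: Full-scan acquisition window (Da) of the discovery method.
SCAN_RANGE: tuple[float, float] = (370.0, 1500.0)

CLASS_LABELS = (
    "enriched>20000",
    "enriched>10000",
    "enriched>1000",
    "depleted>1000",
    "unchanged",
)

GROUPS = ("untreated", "treated", "control")


@dataclass(frozen=True)
class Feature:
    """One detected feature in one run.

    ``area`` is the integrated peak area in instrument arbitrary units;
    None marks a not-detected entry.
    """

    run_id: str
    group: str
    mz: float
    rt: float  # minutes
    area: float | None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")
        if self.area is not None and self.area < 0:
            raise ValueError("area must be >= 0 or not-detected")


@dataclass
class AlignedFeature:
    """A cross-run consensus feature: median m/z and rt over its members."""

    mz: float
    rt: float
    members: list[Feature]

    @property
    def n_members(self) -> int:
        return len(self.members)

    def group_areas(self, group: str) -> dict[str, float | None]:
        """run_id → area for members of one group."""
        return {f.run_id: f.area for f in self.members if f.group == group}


@dataclass
class ScreenHit:
    """One screened feature with its enrichment ratio and class."""

    feature: AlignedFeature
    mean_untreated: float
    mean_treated: float
    ratio: float
    lower_bound: bool  # True when a treated replicate was floored
    fold_class: str

    def ratio_str(self) -> str:
        return ("≥" if self.lower_bound else "") + f"{self.ratio:.6g}"


def align_features(
    features: list[Feature],
    mz_tol_ppm: float = 10.0,
    rt_tol: float = 0.2,
) -> list[AlignedFeature]:
    """Greedy single-linkage clustering of per-run features.

    Seeds are taken in descending area order (not-detected last); each
    seed absorbs every unassigned feature within the m/z and rt windows
    of the seed.  A feature joins at most one cluster — when it would fit
    several, the earlier (higher-area) seed keeps it, which also breaks
    ties toward the nearest m/z since candidate pairs are gathered
    seed-first.  Deterministic for a given input list.
    """
    if not features:
        raise ValueError("no features to align")
    if mz_tol_ppm <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")

    order = sorted(
        range(len(features)),
        key=lambda i: (-(features[i].area or 0.0), features[i].mz, features[i].rt),
    )
    by_mz = sorted(range(len(features)), key=lambda i: features[i].mz)
    mzs = [features[i].mz for i in by_mz]

    assigned = [False] * len(features)
    clusters: list[AlignedFeature] = []
    import bisect

    for seed_idx in order:
        if assigned[seed_idx]:
            continue
        seed = features[seed_idx]
        window = mz_tol_ppm * 1e-6 * seed.mz
        lo = bisect.bisect_left(mzs, seed.mz - window)
        hi = bisect.bisect_right(mzs, seed.mz + window)
        cand = [
            by_mz[j] for j in range(lo, hi)
            if not assigned[by_mz[j]]
            and abs(features[by_mz[j]].rt - seed.rt) <= rt_tol
        ]
        # nearest-first within the window (m/z distance, then rt distance)
        cand.sort(key=lambda i: (abs(features[i].mz - seed.mz),
                                 abs(features[i].rt - seed.rt)))
        members = []
        for i in cand:
            assigned[i] = True
            members.append(features[i])
        clusters.append(
            AlignedFeature(
                mz=float(np.median([f.mz for f in members])),
                rt=float(np.median([f.rt for f in members])),
                members=members,
            )
        )
    clusters.sort(key=lambda c: (c.mz, c.rt))
    return clusters


def _filled_means(
    af: AlignedFeature, group: str, runs: list[str], floor: float
) -> tuple[float, bool, int]:
    """Group mean after floor substitution.

    Returns (mean, any_floored, n_detected).  Runs with no member or a
    not-detected member contribute the floor.
    """
    areas = af.group_areas(group)
    filled = []
    floored = False
    detected = 0
    for run in runs:
        a = areas.get(run)
        if a is None or a < floor:
            filled.append(floor)
            floored = True
        else:
            filled.append(a)
            detected += 1
    return float(np.mean(filled)), floored, detected


def classify_ratio(ratio: float, thresholds=(1000.0, 10000.0, 20000.0)) -> str:
    """Fold-change class, strict '>' at every boundary.

    Enrichment classes nest (a >20000 feature is reported in its highest
    class); depletion mirrors the lowest threshold symmetrically.
    """
    t1, t2, t3 = sorted(thresholds)
    if ratio > t3:
        return "enriched>20000"
    if ratio > t2:
        return "enriched>10000"
    if ratio > t1:
        return "enriched>1000"
    if ratio < 1.0 / t1:
        return "depleted>1000"
    return "unchanged"


def screen_ratios(
    aligned: list[AlignedFeature],
    floor: float = 100.0,
    thresholds: tuple[float, float, float] = (1000.0, 10000.0, 20000.0),
    runs: dict[str, list[str]] | None = None,
) -> list[ScreenHit]:
    """Untreated/treated ratio per aligned feature, with floor substitution.

    ``runs`` maps group → expected run ids; by default it is inferred as
    the union of runs observed across all aligned features, so a feature
    wholly absent from a run is treated as not-detected there.  Features
    not detected in any replicate of either group are dropped (logged).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if runs is None:
        runs = {"untreated": set(), "treated": set()}
        for af in aligned:
            for f in af.members:
                if f.group in runs:
                    runs[f.group].add(f.run_id)
        runs = {g: sorted(r) for g, r in runs.items()}
    if not runs.get("untreated") or not runs.get("treated"):
        raise ValueError("need at least one untreated and one treated run")

    hits: list[ScreenHit] = []
    for af in aligned:
        mean_u, floored_u, det_u = _filled_means(af, "untreated", runs["untreated"], floor)
        mean_t, floored_t, det_t = _filled_means(af, "treated", runs["treated"], floor)
        if det_u == 0 and det_t == 0:
            logger.info(
                "dropping feature m/z %.4f rt %.2f: below detection in all "
                "replicates of both groups", af.mz, af.rt,
            )
            continue
        ratio = mean_u / mean_t
        hits.append(
            ScreenHit(
                feature=af,
                mean_untreated=mean_u,
                mean_treated=mean_t,
                ratio=ratio,
                lower_bound=floored_t,
                fold_class=classify_ratio(ratio, thresholds),
            )
        )
    return hits


def summarize_screen(
    hits: list[ScreenHit],
    ladder_tol: float = 0.01,
) -> dict:
    """Per-class counts plus mass-ladder families of the enriched set.

    Neutral masses of enriched features are reconstructed from consensus
    m/z assuming singly deprotonated ions, then grouped by the
    ±176.032 / ±79.957 Da ladder steps.
    """
    counts = {label: 0 for label in CLASS_LABELS}
    for h in hits:
        counts[h.fold_class] += 1
    enriched = [h for h in hits if h.fold_class.startswith("enriched")]
    neutral = sorted(
        round(h.feature.mz + MassConstants.PROTON, 4) for h in enriched
    )
    families = ladder_families(neutral, LADDER_STEPS, ladder_tol)
    return {
        "class_counts": counts,
        "n_enriched": len(enriched),
        "enriched_neutral_masses": neutral,
        "ladder_families": families,
    }
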