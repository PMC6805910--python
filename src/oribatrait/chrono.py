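"""Branching-time profiles of dated trees and overlays of dated floral events.

Internal-node ages of an ultrametric tree are binned into half-open 5-my
intervals ``[t, t + 5)`` measured back from the present.  Against that
histogram, dated aboveground events (vascular-plant emergence, major
Carboniferous biome changes, the first angiosperm fossils) are labelled
"gap", "rise" or "typical" according to whether local branching frequency
around the event falls below the 25th or above the 75th percentile of bin
counts — a descriptive operationalization of visually matching radiation
gaps to floral turnover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .treeio import DatedTree

__all__ = [
    "BranchingProfile",
    "EventTimeline",
    "default_timeline",
    "branching_histogram",
    "interval_fraction",
    "event_overlay",
    "annotate_shift_times",
]


@dataclass(frozen=True)
class BranchingProfile:
    """Internal-node ages (mya) with their fixed-width histogram."""

    ages: np.ndarray
    bin_width: float
    edges: np.ndarray  # len(counts)+1 edges, 0 .. ceil(root/width)*width
    counts: np.ndarray  # count of ages in [edges[i], edges[i+1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_young": self.edges[:-1],
                "age_old": self.edges[1:],
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class EventTimeline:
    """Dated aboveground events: (name, oldest age, youngest age) in mya.

    Point events carry equal old/young ages; interval events (e.g. a stage
    given as a range) are represented by their midpoint in overlay
    distance computations.  Sorted oldest-first.
    """

    events: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for name, old, young in self.events:
            if old < young:
                raise ValueError(f"event {name!r}: age_old {old} < age_young {young}")
            if young < 0:
                raise ValueError(f"event {name!r}: negative age")
        ordered = tuple(sorted(self.events, key=lambda e: -(e[1] + e[2]) / 2))
        object.__setattr__(self, "events", ordered)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTimeline":
        events = []
        for _, row in df.iterrows():
            old = float(row["age_old"])
            young = float(row["age_young"]) if "age_young" in df.columns and pd.notna(row.get("age_young")) else old
            events.append((str(row["name"]), old, young))
        return cls(tuple(events))

    def midpoints(self) -> np.ndarray:
        return np.array([(old + young) / 2 for _, old, young in self.events])


def default_timeline() -> EventTimeline:
    """Major aboveground floral events used for the overlay (mya)."""
    return EventTimeline(
        (
            ("vascular plants and primitive roots", 425.0, 425.0),
            ("Devonian-Mississippian boundary", 359.0, 359.0),
            ("Mississippian-Pennsylvanian boundary", 318.0, 318.0),
            ("Kasimovian biome change", 307.0, 303.0),
            ("first angiosperm fossils", 124.0, 124.0),
        )
    )


def branching_histogram(
    tree_or_ages: DatedTree | np.ndarray, bin_width: float = 5.0
) -> BranchingProfile:
    """Histogram of internal-node ages in half-open ``[t, t + width)`` bins.

    Bins cover ``[0, ceil(root_age / width) * width)``; counts always sum
    to the number of internal nodes (n - 1 on a binary tree).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(tree_or_ages, DatedTree):
        ages = tree_or_ages.node_ages()
    else:
        ages = np.asarray(tree_or_ages, dtype=float)
    if len(ages) == 0:
        raise ValueError("no branching times")
    if np.any(ages < 0) or not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite and >= 0")
    n_bins = max(1, math.ceil(ages.max() / bin_width))
    if ages.max() == n_bins * bin_width:  # root exactly on the last edge
        n_bins += 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(ages / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return BranchingProfile(ages=ages, bin_width=float(bin_width), edges=edges, counts=counts)


def interval_fraction(
    profile_or_ages: BranchingProfile | np.ndarray, t_old: float, t_young: float
) -> float:
    """Fraction of branching events with age in ``[t_young, t_old)``."""
    if isinstance(profile_or_ages, BranchingProfile):
        ages = profile_or_ages.ages
    else:
        ages = np.asarray(profile_or_ages, dtype=float)
    if len(ages) == 0:
        raise ValueError("no branching times")
    if not t_old > t_young or t_young < 0:
        raise ValueError("need t_old > t_young >= 0")
    return float(np.mean((ages >= t_young) & (ages < t_old)))


def event_overlay(
    profile: BranchingProfile,
    timeline: EventTimeline,
    window: float = 10.0,
) -> pd.DataFrame:
    """Label each dated event "gap" / "rise" / "typical" for this profile.

    The branching count in the half-open window ``[mid - w, mid + w)``
    around the event midpoint is rescaled to a per-bin-width rate and
    compared to the 25th and 75th percentiles of the profile's bin counts:
    below the 25th -> "gap", above the 75th -> "rise", otherwise "typical".
    (Half-open, like the histogram bins, so a perfectly flat profile gives
    the same rate at every midpoint.)
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    q25, q75 = np.percentile(profile.counts, [25, 75])
    rows = []
    for (name, old, young), mid in zip(timeline.events, timeline.midpoints()):
        near = int(np.sum((profile.ages >= mid - window) & (profile.ages < mid + window)))
        rate = near * profile.bin_width / (2 * window)
        if rate < q25:
            label = "gap"
        elif rate > q75:
            label = "rise"
        else:
            label = "typical"
        rows.append(
            {
                "event": name,
                "age_old": old,
                "age_young": young,
                "age_mid": mid,
                "branchings_within_window": near,
                "rate_per_bin": rate,
                "q25_bin_count": q25,
                "q75_bin_count": q75,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def annotate_shift_times(
    shift_report, tree: DatedTree, trait_name: str = "trait"
) -> pd.DataFrame:
    """Map flagged shift nodes to their divergence times on the dated tree.

    Returns one row per flagged node with its age (mya), for merging
    across traits onto the branching-time plot.
    """
    ages = tree.node_ages()
    n = tree.n_tips
    rows = []
    for _, rec in shift_report.flagged.iterrows():
        node = int(rec["node"])
        if not n <= node < 2 * n - 1:
            raise KeyError(f"node {node} is not an internal node of this tree")
        rows.append(
            {
                "trait": trait_name,
                "node": node,
                "node_name": rec["node_name"],
                "age_mya": float(ages[node - n]),
                "p_value": float(rec["p_value"]),
            }
        )
    return pd.DataFrame(rows, columns=["trait", "node", "node_name", "age_mya", "p_value"])
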