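"""Stable-isotope trophic-level scoring for soil communities.

Within each habitat, species mean d15N (baseline-normalized, per-mil) is
ordered and cut into four trophic groups spaced ~3.4 per-mil apart — the
canonical per-trophic-level 15N enrichment.  Group 0 anchors at the
community minimum (specialist lichen feeders), groups 1 and 2 are primary
and secondary decomposers, group 3 predators and scavengers.  A species'
score is ``group + decimal`` where the decimal encodes its relative
position inside the group, so scores span [0.0, 3.99]: 0.0 is the lowest
d15N in the community, 3.99 the highest value inside the predator group.
Species measured in several habitats get the mean of their per-habitat
scores.

d13C is carried through (it separates carbon sources) but never enters the
score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "TROPHIC_SPACING",
    "SCORE_MAX",
    "GROUP_NAMES",
    "IsotopeTable",
    "normalize_baseline",
    "species_habitat_means",
    "assign_trophic_levels",
    "combine_species_scores",
    "score_isotope_table",
]

#: Per-trophic-level d15N enrichment (per-mil) separating adjacent groups.
TROPHIC_SPACING = 3.4

#: Scores are clamped to [0.0, SCORE_MAX]; values beyond the fourth group
#: width above the minimum still belong to the predator/scavenger group.
SCORE_MAX = 3.99

GROUP_NAMES = {
    0: "specialist lichen feeder",
    1: "primary decomposer",
    2: "secondary decomposer",
    3: "predator/scavenger",
}

_REQUIRED_COLUMNS = (
    "species",
    "habitat",
    "d13C",
    "d15N",
    "baseline_d13C",
    "baseline_d15N",
)


@dataclass(frozen=True)
class IsotopeTable:
    """Per-measurement isotope records with their habitat baselines.

    One row per measurement: species, habitat, d13C, d15N and the habitat's
    baseline for both isotopes (all per-mil).  ``normalized`` records
    whether values are already baseline-subtracted — normalizing twice
    would silently shift every score, so it is guarded.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"isotope table missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("isotope table is empty")
        for col in ("d13C", "d15N"):
            if not np.all(np.isfinite(self.data[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite values in column {col}")

    @classmethod
    def read_tsv(cls, path: str | Path, normalized: bool = False) -> "IsotopeTable":
        return cls(pd.read_csv(path, sep="\t"), normalized=normalized)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def habitats(self) -> list[str]:
        return sorted(self.data["habitat"].unique())


def normalize_baseline(table: IsotopeTable) -> IsotopeTable:
    """Subtract each record's habitat baseline from both isotope values."""
    if table.normalized:
        raise ValueError("table is already baseline-normalized")
    for iso in ("d13C", "d15N"):
        bad = table.data.loc[~np.isfinite(table.data[f"baseline_{iso}"]), "habitat"]
        if len(bad):
            raise ValueError(
                f"missing {iso} baseline for habitat(s): {sorted(bad.unique())}"
            )
    out = table.data.copy()
    out["d13C"] = out["d13C"] - out["baseline_d13C"]
    out["d15N"] = out["d15N"] - out["baseline_d15N"]
    return IsotopeTable(out, normalized=True)


def species_habitat_means(table: IsotopeTable) -> pd.DataFrame:
    """Mean normalized d13C/d15N per (species, habitat), with record counts."""
    if not table.normalized:
        raise ValueError("normalize the table before averaging (normalize_baseline)")
    g = table.data.groupby(["species", "habitat"], sort=True)
    out = g.agg(d13C=("d13C", "mean"), d15N=("d15N", "mean"), n=("d15N", "size"))
    return out.reset_index()


def assign_trophic_levels(
    d15n: pd.Series,
    spacing: float = TROPHIC_SPACING,
    decimal: Literal["continuous", "rank"] = "continuous",
) -> pd.DataFrame:
    """Score one community from per-species mean normalized d15N.

    With ``d = d15N - min(d15N)``, the integer group is
    ``min(3, floor(d / spacing))`` and the continuous decimal is the
    fractional position inside the group, ``(d - spacing*group)/spacing``,
    capped at 0.99.  Scores are non-decreasing in d15N, equal for ties, and
    clamped to [0.0, 3.99].  ``decimal="rank"`` replaces the fractional
    distance with the species' dense rank inside its group scaled to
    [0, 0.99] — order-preserving but insensitive to spacing within a group.
    """
    if len(d15n) == 0:
        raise ValueError("empty community")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    y = d15n.astype(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite d15N values")
    d = y - y.min()
    group = np.minimum(3, np.floor(d / spacing)).astype(int)
    if decimal == "continuous":
        frac = np.minimum(0.99, (d - spacing * group) / spacing)
    elif decimal == "rank":
        frac = pd.Series(0.0, index=y.index)
        for g in np.unique(group):
            members = d[group == g].rank(method="dense") - 1
            denom = max(members.max(), 1.0)
            frac[group == g] = np.minimum(0.99, 0.99 * members / denom)
    else:
        raise ValueError(f"unknown decimal mode {decimal!r}")
    score = group + frac
    return pd.DataFrame(
        {"d15N": y, "group": group, "score": score},
        index=y.index,
    )


def combine_species_scores(per_habitat: pd.DataFrame) -> pd.DataFrame:
    """Average per-habitat scores into one score per species.

    Expects columns ``species``, ``habitat``, ``score`` (and optionally
    ``group``).  The combined group is the integer part of the mean score;
    ``group_disagreement`` flags species whose habitats place them in
    different integer groups.
    """
    for col in ("species", "habitat", "score"):
        if col not in per_habitat.columns:
            raise ValueError(f"per-habitat score frame missing column {col!r}")
    g = per_habitat.groupby("species", sort=True)
    combined = g.agg(
        score=("score", "mean"),
        n_habitats=("habitat", "nunique"),
        n_measurements=("score", "size"),
    )
    combined["group"] = np.minimum(3, np.floor(combined["score"])).astype(int)
    if "group" in per_habitat.columns:
        spread = per_habitat.groupby("species")["group"].nunique()
        combined["group_disagreement"] = spread.reindex(combined.index) > 1
    else:
        combined["group_disagreement"] = False
    combined["group_name"] = combined["group"].map(GROUP_NAMES)
    return combined.reset_index()


def score_isotope_table(
    table: IsotopeTable,
    spacing: float = TROPHIC_SPACING,
    decimal: Literal["continuous", "rank"] = "continuous",
) -> pd.DataFrame:
    """Full scoring pipeline: normalize, average, score per habitat, combine.

    Returns one row per species with the combined score in [0.0, 3.99],
    the integer trophic group, and bookkeeping columns.
    """
    normalized = table if table.normalized else normalize_baseline(table)
    means = species_habitat_means(normalized)
    pieces = []
    for hab, sub in means.groupby("habitat", sort=True):
        scored = assign_trophic_levels(
            sub.set_index("species")["d15N"], spacing=spacing, decimal=decimal
        )
        scored = scored.reset_index().rename(columns={"index": "species"})
        scored["habitat"] = hab
        pieces.append(scored)
    per_habitat = pd.concat(pieces, ignore_index=True)
    return combine_species_scores(per_habitat)
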