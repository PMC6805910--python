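"""End-to-end analysis: signal, shifts, trophic scores, branching profile.

Given a dated tree, a morphology table (body length/width, micrometres), an
isotope table and a dated-event table, this runs the full comparative
analysis: Blomberg's K and Pagel's lambda per trait, independent-contrast
shift detection with node ages, trophic-level scoring, and the
branching-time histogram with the floral-event overlay.  Morphological
traits are analyzed on the tree matched to the morphology table; trophic
level is analyzed on a tree pruned to the isotope-scored species, so
missing isotope data cannot bias the signal estimates.

All stochastic stages (permutation tests) draw from substreams of one
pipeline seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .treeio import DatedTree, read_newick
from .phylosignal import k_permutation_test, pagel_lambda, align_trait
from .contrasts import detect_shifts
from .trophic import IsotopeTable, score_isotope_table
from .chrono import (
    EventTimeline,
    branching_histogram,
    default_timeline,
    event_overlay,
    annotate_shift_times,
)
from .synthetic_data import substreams

__all__ = ["PipelineConfig", "run_pipeline", "derive_morph_traits", "read_trait_table"]


@dataclass
class PipelineConfig:
    """Paths and options for one pipeline run (loadable from YAML)."""

    tree: str
    output_dir: str
    traits: Optional[str] = None  # morphology TSV: species, length_um, width_um
    isotopes: Optional[str] = None  # isotope TSV, one row per measurement
    events: Optional[str] = None  # TSV: name, age_old[, age_young]; default timeline if absent
    seed: int = 0
    n_replicates: int = 9999
    alpha: float = 0.05
    bin_width: float = 5.0
    overlay_window: float = 10.0
    log10_size: bool = False
    trophic_decimal: str = "continuous"
    shift_mode: str = "per-node"
    shift_correction: Optional[str] = None
    run_signal: bool = True
    run_shifts: bool = True
    run_trophic: bool = True
    run_chrono: bool = True
    normalize_names: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _canonical(name: str) -> str:
    return name.strip().lower().replace("_", " ")


def read_trait_table(path: str | Path, normalize_names: bool = False) -> pd.DataFrame:
    """Morphology table: one row per species with length/width in micrometres."""
    df = pd.read_csv(path, sep="\t")
    required = {"species"}
    if not required <= set(df.columns):
        raise ValueError(f"trait table needs columns {sorted(required)}")
    if normalize_names:
        df["species"] = df["species"].map(_canonical)
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
        raise ValueError(f"duplicate species in trait table: {dupes}")
    return df.set_index("species")


def derive_morph_traits(
    table: pd.DataFrame, log10_size: bool = False
) -> tuple[pd.Series, pd.Series]:
    """Body size and body form from a length/width table.

    Size is mean body length (micrometres; optionally log10), form is the
    length/width ratio — dimensionless, >1 elongated, ~1 globular.
    """
    for col in ("length_um", "width_um"):
        if col not in table.columns:
            raise ValueError(f"trait table needs column {col!r}")
        bad = table.index[table[col] <= 0].tolist()
        if bad:
            raise ValueError(f"nonpositive {col} for species: {bad}")
    size = table["length_um"].astype(float)
    ratio = (table["length_um"] / table["width_um"]).astype(float)
    if log10_size:
        size = np.log10(size)
    size.name = "body_size"
    ratio.name = "body_ratio"
    return size, ratio


def _species_match_report(tree: DatedTree, x: pd.Series, label: str) -> dict:
    tree_set = set(tree.labels)
    trait_set = set(x.dropna().index)
    return {
        "trait": label,
        "n_tree": len(tree_set),
        "n_trait": len(trait_set),
        "n_matched": len(tree_set & trait_set),
        "only_in_tree": sorted(tree_set - trait_set),
        "only_in_trait": sorted(trait_set - tree_set),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; write TSV/JSON reports; return them in memory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = read_newick(config.tree)
    streams = {
        name: ss
        for name, ss in zip(
            ("signal_size", "signal_ratio", "signal_tl",
             "shift_size", "shift_ratio", "shift_tl"),
            substreams(config.seed, 6),
        )
    }

    results: dict = {"match_reports": []}
    traits: dict[str, pd.Series] = {}
    if config.traits and (config.run_signal or config.run_shifts):
        table = read_trait_table(config.traits, config.normalize_names)
        size, ratio = derive_morph_traits(table, log10_size=config.log10_size)
        traits["body_size"] = size
        traits["body_ratio"] = ratio

    trophic_scores = None
    if config.isotopes and config.run_trophic:
        iso = IsotopeTable.read_tsv(config.isotopes)
        trophic_scores = score_isotope_table(
            iso, decimal=config.trophic_decimal  # type: ignore[arg-type]
        )
        trophic_scores.to_csv(out / "trophic_scores.tsv", sep="\t", index=False)
        results["trophic_scores"] = trophic_scores
        tl = trophic_scores.set_index("species")["score"]
        tl.name = "trophic_level"
        if config.run_signal or config.run_shifts:
            traits["trophic_level"] = tl

    stream_key = {"body_size": "size", "body_ratio": "ratio", "trophic_level": "tl"}
    signal_rows = []
    shift_frames = []
    shift_ages = []
    for name, x in traits.items():
        # trophic level is scored for fewer species than morphology; each
        # trait is analyzed on the tree pruned to its own coverage
        sub_tree, vec = align_trait(tree, x)
        key = stream_key[name]
        if config.run_signal:
            k_res = k_permutation_test(
                sub_tree, vec, n_replicates=config.n_replicates,
                seed=streams[f"signal_{key}"],
            )
            l_res = pagel_lambda(sub_tree, vec)
            signal_rows.append(
                {
                    "trait": name,
                    "n_species": k_res.n_species,
                    "K": k_res.estimate,
                    "P_K": k_res.p_value,
                    "lambda": l_res.estimate,
                    "P_lambda": l_res.p_value,
                    "n_replicates": k_res.n_replicates,
                }
            )
        if config.run_shifts:
            report = detect_shifts(
                sub_tree, vec, n_replicates=config.n_replicates,
                alpha=config.alpha, seed=streams[f"shift_{key}"],
                correction=config.shift_correction,  # type: ignore[arg-type]
                mode=config.shift_mode,  # type: ignore[arg-type]
            )
            ann = annotate_shift_times(report, sub_tree, trait_name=name)
            shift_ages.append(ann)
            tbl = report.table.copy()
            tbl.insert(0, "trait", name)
            ages = sub_tree.node_ages()
            tbl["age_mya"] = ages[tbl["node"].to_numpy() - sub_tree.n_tips]
            shift_frames.append(tbl)

    if signal_rows:
        signal_table = pd.DataFrame(signal_rows)
        signal_table.to_csv(out / "signal.tsv", sep="\t", index=False)
        results["signal"] = signal_table
    if shift_frames:
        shifts = pd.concat(shift_frames, ignore_index=True)
        shifts.to_csv(out / "shifts.tsv", sep="\t", index=False)
        results["shifts"] = shifts
        shift_age_table = (
            pd.concat(shift_ages, ignore_index=True)
            if shift_ages
            else pd.DataFrame()
        )
        shift_age_table.to_csv(out / "shift_times.tsv", sep="\t", index=False)
        results["shift_times"] = shift_age_table

    if config.run_chrono:
        profile = branching_histogram(tree, bin_width=config.bin_width)
        profile.to_frame().to_csv(out / "branching_histogram.tsv", sep="\t", index=False)
        if config.events:
            timeline = EventTimeline.from_frame(pd.read_csv(config.events, sep="\t"))
        else:
            timeline = default_timeline()
        overlay = event_overlay(profile, timeline, window=config.overlay_window)
        overlay.to_csv(out / "event_overlay.tsv", sep="\t", index=False)
        results["branching_profile"] = profile
        results["event_overlay"] = overlay

    for name, x in traits.items():
        results["match_reports"].append(_species_match_report(tree, x, name))

    manifest = {
        "package": "oribatrait",
        "version": __version__,
        "python": sys.version.split()[0],
        "config": asdict(config),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
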