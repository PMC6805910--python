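"""Generators for trees, traits, and isotope communities.

These produce inputs with the statistical structure the downstream analyses
assume: ultrametric Yule trees, continuous traits evolved by Brownian
motion (optionally with Pagel-lambda attenuation or clade-level mean
shifts), and multi-habitat stable-isotope communities in which d15N climbs
~3.4 per-mil per trophic level above a habitat baseline.

Every generator is a pure function of its arguments and a seed; the same
seed gives bit-identical output.  A single pipeline seed is expanded into
independent per-stage substreams via :func:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .treeio import DatedTree, lambda_transform
from .trophic import IsotopeTable, TROPHIC_SPACING

__all__ = [
    "CommunitySpec",
    "SimConfig",
    "simulate_yule",
    "simulate_bm",
    "simulate_lambda",
    "simulate_clade_shift",
    "simulate_isotope_communities",
    "default_community_spec",
    "simulate_bundle",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def substreams(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Split one user seed into ``n`` independent child streams."""
    return np.random.SeedSequence(seed).spawn(n)


# --------------------------------------------------------------------- trees


def simulate_yule(
    n_tips: int,
    *,
    birth_rate: float = 1.0,
    root_age: float | None = None,
    seed=None,
    label_prefix: str = "sp",
) -> DatedTree:
    """Pure-birth (Yule) tree, optionally rescaled to an exact root age.

    Lineages split after exponential waiting times (total rate
    ``birth_rate * k`` with *k* extant lineages) and the splitting lineage
    is chosen uniformly.  After the last split an extra exponential tail is
    drawn so terminal branches are never zero.  If ``root_age`` is given
    (my), all branch lengths are rescaled so the root sits exactly at that
    age — a conditioning shortcut adequate for generating test topologies.
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs n_tips >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _rng(seed)

    # grow the topology as linked slots first, then index into arrays;
    # active lineages are leaves-to-be
    class _Lin:
        __slots__ = ("t0", "node")

        def __init__(self, t0: float):
            self.t0 = t0
            self.node: object = None

    class _Split:
        __slots__ = ("left", "right", "t")

        def __init__(self, left, right, t):
            self.left, self.right, self.t = left, right, t

    t = 0.0
    root_left, root_right = _Lin(0.0), _Lin(0.0)
    active = [root_left, root_right]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        parent = active[i]
        a, b = _Lin(t), _Lin(t)
        parent.node = _Split(a, b, t)
        active[i] = a
        active.append(b)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    total = t

    # index tips in birth order of active list for determinism
    labels = [f"{label_prefix}{i + 1}" for i in range(n_tips)]
    for lin, lab in zip(active, labels):
        lin.node = lab

    scale = 1.0 if root_age is None else root_age / total

    tip_ids: dict[str, int] = {lab: i for i, lab in enumerate(labels)}
    rows: list[tuple[int, int]] = []
    blen = np.zeros(2 * n_tips - 1)

    def build(lin: _Lin, t_end: float) -> int:
        """Return node id of the subtree for this lineage slot."""
        node = lin.node
        if isinstance(node, str):
            nid = tip_ids[node]
            blen[nid] = (t_end - lin.t0) * scale
            return nid
        assert isinstance(node, _Split)
        left = build(node.left, t_end)
        # left/right order preserved from split
        right = build(node.right, t_end)
        nid = n_tips + len(rows)
        rows.append((left, right))
        blen[nid] = (node.t - lin.t0) * scale
        return nid

    # the root joins the two initial lineages at time 0
    left = build(root_left, total)
    right = build(root_right, total)
    rows.append((left, right))
    return DatedTree(tuple(labels), np.asarray(rows, dtype=np.intp), blen)


# --------------------------------------------------------------------- traits


def simulate_bm(
    tree: DatedTree,
    sigma2: float,
    root_state: float = 0.0,
    seed=None,
    trait_name: str = "trait",
) -> pd.Series:
    """Brownian-motion trait: independent Gaussian increments per branch
    with variance ``sigma2 * branch_length``, accumulated root-to-tip."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = _rng(seed)
    inc = rng.normal(0.0, np.sqrt(sigma2 * tree.blen))
    inc[tree.root] = 0.0
    value = np.zeros(tree.n_nodes)
    value[tree.root] = root_state
    n = tree.n_tips
    for k in range(n - 2, -1, -1):
        node = n + k
        value[tree.children[k]] = value[node] + inc[tree.children[k]]
    return pd.Series(value[:n], index=list(tree.labels), name=trait_name)


def simulate_lambda(
    tree: DatedTree,
    lam: float,
    sigma2: float,
    root_state: float = 0.0,
    seed=None,
    trait_name: str = "trait",
) -> pd.Series:
    """Trait drawn from the Pagel-lambda model: multivariate normal with
    covariance ``sigma2 * lambda_transform(vcv, lam)`` and mean root_state."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = _rng(seed)
    C = lambda_transform(tree.vcv(), lam)
    # C is PSD (PD for lam < 1 on trees with positive terminal branches);
    # draw via Cholesky with a relative jitter fallback for the PSD edge.
    S = sigma2 * C
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        S = S + np.eye(len(S)) * (1e-12 * np.trace(S) / len(S))
        L = np.linalg.cholesky(S)
    z = rng.standard_normal(tree.n_tips)
    return pd.Series(
        root_state + L @ z, index=list(tree.labels), name=trait_name
    )


def simulate_clade_shift(
    tree: DatedTree,
    node: int,
    offset: float,
    sigma2: float,
    root_state: float = 0.0,
    seed=None,
    trait_name: str = "trait",
) -> pd.Series:
    """Brownian trait plus a constant mean offset for every tip descending
    from ``node`` — the generating model for shift-detection power tests."""
    if not 0 <= node < tree.n_nodes:
        raise KeyError(f"node {node} not in tree (0..{tree.n_nodes - 1})")
    x = simulate_bm(tree, sigma2, root_state, seed=seed, trait_name=trait_name)
    shifted = tree.descendant_tips(node)
    vals = x.to_numpy().copy()
    vals[shifted] += offset
    return pd.Series(vals, index=x.index, name=trait_name)


# ----------------------------------------------------------------- isotopes


@dataclass(frozen=True)
class CommunitySpec:
    """Blueprint for a synthetic multi-habitat isotope compilation.

    ``true_tl`` maps species to their true trophic level in [0, 3.99];
    ``baselines`` maps habitat to (baseline d13C, baseline d15N) in per-mil;
    ``membership`` maps habitat to the species measured there.  d15N of a
    measurement is ``baseline + 3.4 * true_tl + N(0, noise_sd)``; d13C is
    baseline plus noise (it is carried through but does not define the
    trophic score).
    """

    true_tl: Mapping[str, float]
    baselines: Mapping[str, tuple[float, float]]
    membership: Mapping[str, Sequence[str]]
    noise_sd: float = 0.25
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not self.true_tl or not self.baselines:
            raise ValueError("community spec needs species and habitats")
        for sp, tl in self.true_tl.items():
            if not 0.0 <= tl <= 3.99:
                raise ValueError(f"true trophic level of {sp} outside [0, 3.99]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for hab, members in self.membership.items():
            unknown = set(members) - set(self.true_tl)
            if unknown:
                raise ValueError(f"habitat {hab} lists unknown species {sorted(unknown)}")


def default_community_spec(
    n_species: int = 70,
    n_habitats: int = 4,
    noise_sd: float = 0.25,
    seed=None,
) -> CommunitySpec:
    """Community at the scale of published soil-mite isotope compilations:
    70 species spread over 4 habitats, true trophic levels spanning
    specialist lichen feeders (0) to predators/scavengers (3)."""
    rng = _rng(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]
    # levels cover all four groups, most species are decomposers (groups 1-2)
    groups = rng.choice(4, size=n_species, p=[0.1, 0.35, 0.35, 0.2])
    within = rng.uniform(0.0, 0.99, size=n_species)
    true_tl = {sp: float(g + w) for sp, g, w in zip(species, groups, within)}
    habitats = ["forest_soil", "dead_wood", "dry_grassland", "peatland"][:n_habitats]
    baselines = {
        hab: (float(rng.uniform(-28.0, -24.0)), float(rng.uniform(-4.0, 4.0)))
        for hab in habitats
    }
    membership = {}
    for hab in habitats:
        k = max(2, int(round(n_species * rng.uniform(0.4, 0.8))))
        membership[hab] = sorted(
            rng.choice(species, size=min(k, n_species), replace=False).tolist()
        )
    # ensure every species occurs somewhere
    assigned = set().union(*membership.values())
    left_over = [sp for sp in species if sp not in assigned]
    if left_over:
        membership[habitats[0]] = sorted(set(membership[habitats[0]]) | set(left_over))
    return CommunitySpec(true_tl, baselines, membership, noise_sd=noise_sd)


def simulate_isotope_communities(spec: CommunitySpec, seed=None) -> IsotopeTable:
    """Raw (un-normalized) isotope records for each habitat in the spec."""
    rng = _rng(seed)
    rows = []
    for hab in spec.baselines:
        base_c, base_n = spec.baselines[hab]
        for sp in spec.membership.get(hab, ()):
            tl = spec.true_tl[sp]
            for _ in range(spec.n_replicates):
                d15n = base_n + TROPHIC_SPACING * tl + rng.normal(0.0, spec.noise_sd)
                d13c = base_c + rng.normal(0.0, spec.noise_sd)
                rows.append(
                    {
                        "species": sp,
                        "habitat": hab,
                        "d13C": d13c,
                        "d15N": d15n,
                        "baseline_d13C": base_c,
                        "baseline_d15N": base_n,
                    }
                )
    return IsotopeTable(pd.DataFrame(rows), normalized=False)


# ----------------------------------------------------------------- bundling


@dataclass(frozen=True)
class SimConfig:
    """One-stop configuration for a full synthetic study bundle."""

    seed: int
    n_tips: int = 110
    root_age: float = 400.0
    sigma2: float = 1.0
    lam: float = 1.0
    shift_nodes: Mapping[int, float] = field(default_factory=dict)
    n_species_isotope: int = 70
    n_habitats: int = 4
    isotope_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.root_age <= 0 or self.sigma2 <= 0:
            raise ValueError("root_age and sigma2 must be > 0")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")


def simulate_bundle(config: SimConfig):
    """Full synthetic study: tree, morphology table, isotope table.

    Body length and length/width ratio evolve by Brownian motion on a log10
    scale (sizes stay positive and rate is proportional on the natural
    scale), seeded around a 300-um, moderately elongated ancestor; optional
    clade-level mean shifts from ``config.shift_nodes`` are applied to log
    length.  Isotope species are mapped onto the first tree tips so the
    trophic stage can be analyzed on a pruned phylogeny.

    Returns ``(tree, traits_df, isotope_table)``; everything is a pure
    function of the config (one seed expands into per-stage substreams).
    """
    s_tree, s_size, s_ratio, s_iso_spec, s_iso = substreams(config.seed, 5)
    tree = simulate_yule(config.n_tips, root_age=config.root_age, seed=s_tree)
    log_len = simulate_bm(tree, sigma2=0.002, root_state=np.log10(300.0), seed=s_size)
    for node, offset in config.shift_nodes.items():
        shifted = tree.descendant_tips(int(node))
        log_len.iloc[shifted] += offset
    log_ratio = simulate_bm(
        tree, sigma2=0.0005, root_state=np.log10(1.8), seed=s_ratio
    )
    length = (10.0 ** log_len).round(1)
    width = (length / (10.0 ** log_ratio)).round(1)
    traits = pd.DataFrame(
        {
            "species": list(tree.labels),
            "length_um": length.to_numpy(),
            "width_um": width.to_numpy(),
        }
    )
    spec = default_community_spec(
        n_species=min(config.n_species_isotope, config.n_tips),
        n_habitats=config.n_habitats,
        noise_sd=config.isotope_noise_sd,
        seed=s_iso_spec,
    )
    remap = dict(zip(sorted(spec.true_tl), list(tree.labels)[: len(spec.true_tl)]))
    iso = simulate_isotope_communities(spec, seed=s_iso)
    data = iso.data.copy()
    data["species"] = data["species"].map(remap)
    return tree, traits, IsotopeTable(data, normalized=False)
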