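"""Multispecies-coalescent simulator for ITS-like species complexes.

Generates datasets with the statistical structure the threshold analysis
assumes: gene genealogies embedded in a species tree under the
multispecies coalescent (MSC), sequences evolved along the genealogy with
region-specific rates (variable ITS1/ITS2 spacers around a conserved 5.8S),
and database-style degradation (single-spacer truncations, IUPAC
ambiguities, substitutions planted inside the conserved domain).

Units follow the BP&P convention: both the population-size parameter θ and
the species divergence times τ are expressed in expected substitutions per
site, so no separate mutation rate exists.  Within one population, k
lineages coalesce after an exponential waiting time with rate k(k−1)/θ
(a pair coalesces with mean θ/2); lineages that have not coalesced when
the population ends at its parent's τ pass to the parent population.
Hyperparameters for θ and τ can be drawn from an inverse-gamma IG(α, β)
parameterised by shape α and *scale* β, mean β/(α−1) — stated explicitly
because IG conventions vary.

No indels are simulated: the true alignment is the simulator's output and
gaps arise only from truncation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import Alignment, SequenceRecord, SpeciesMap, SampleInfo, write_fasta, write_metadata
from .io import ROLE_QUERY, ROLE_REFERENCE
from .diagnostics import (
    FLAG_DOMAIN_DEVIANT,
    FLAG_FULL_LENGTH,
    FLAG_PARTIAL_ITS1,
    FLAG_PARTIAL_ITS2,
)

FLAG_AMBIGUATED = "ambiguated"

#: IUPAC ambiguity codes containing each base (used when ambiguating)
_AMBIG_FOR_BASE = {
    "A": "RWMDHVN",
    "C": "YSMBHVN",
    "G": "RSKBDVN",
    "T": "YWKBDHN",
}

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# species tree


@dataclass
class SpeciesNode:
    """Node of the species tree; ``tau`` is the node height (leaves at 0)."""

    label: str
    tau: float
    theta: float
    children: list["SpeciesNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SpeciesTreeModel:
    """Rooted, ultrametric, binary species tree with per-branch θ.

    ``theta`` on an internal node is the ancestral population parameter;
    when unspecified at construction it defaults to the descendant value.
    """

    root: SpeciesNode

    def validate(self) -> None:
        def walk(node: SpeciesNode) -> None:
            if node.theta <= 0:
                raise ValueError(f"theta must be > 0 at node {node.label!r}")
            if node.is_leaf:
                if node.tau != 0.0:
                    raise ValueError(
                        f"leaf {node.label!r} at height {node.tau}; tree must be ultrametric"
                    )
                return
            if len(node.children) != 2:
                raise ValueError(f"node {node.label!r} is not binary")
            for child in node.children:
                if node.tau <= child.tau:
                    raise ValueError(
                        f"parent height {node.tau} not above child {child.label!r} ({child.tau})"
                    )
                walk(child)

        walk(self.root)

    def leaves(self) -> list[SpeciesNode]:
        out: list[SpeciesNode] = []

        def walk(node: SpeciesNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def clades(self) -> set[frozenset[str]]:
        """Leaf-label sets of all internal nodes (topology fingerprint)."""
        out: set[frozenset[str]] = set()

        def walk(node: SpeciesNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            tips = frozenset().union(*(walk(c) for c in node.children))
            out.add(tips)
            return tips

        walk(self.root)
        return out

    def to_newick(self) -> str:
        """Newick with τ as node heights (branch lengths derived) and θ in
        ``[&theta=...]`` comments."""

        def walk(node: SpeciesNode, parent_tau: float | None) -> str:
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(walk(c, node.tau) for c in node.children) + ")" + node.label
            comment = f"[&theta={node.theta:g}]"
            if parent_tau is None:
                return f"{body}{comment};"
            return f"{body}{comment}:{parent_tau - node.tau:g}"

        return walk(self.root, None)

    @classmethod
    def from_dict(cls, spec: Mapping, default_theta: float = 0.0005) -> "SpeciesTreeModel":
        """Build from a nested mapping: ``{label, tau, theta, children: [...]}``.

        ``tau`` defaults to 0 (leaf); ``theta`` to ``default_theta``."""

        def walk(d: Mapping) -> SpeciesNode:
            return SpeciesNode(
                label=d.get("label", ""),
                tau=float(d.get("tau", 0.0)),
                theta=float(d.get("theta", default_theta)),
                children=[walk(c) for c in d.get("children", [])],
            )

        model = cls(walk(spec))
        model.validate()
        return model

    def scaled(self, factor: float) -> "SpeciesTreeModel":
        """Copy with every node height multiplied by ``factor``."""

        def walk(node: SpeciesNode) -> SpeciesNode:
            return SpeciesNode(node.label, node.tau * factor, node.theta,
                               [walk(c) for c in node.children])

        return SpeciesTreeModel(walk(self.root))

    def with_theta(self, theta: float) -> "SpeciesTreeModel":
        def walk(node: SpeciesNode) -> SpeciesNode:
            return SpeciesNode(node.label, node.tau, theta, [walk(c) for c in node.children])

        return SpeciesTreeModel(walk(self.root))


EUROPEAN_COMPLEX = ("albonigra", "ambusta", "nigrifacta", "ustulata", "sp1")


def albonigra_like_model(theta: float = 0.0005, depth_scale: float = 1.0) -> SpeciesTreeModel:
    """Five-species European complex preset.

    Topology mirrors the complex's multi-locus tree: (albonigra, sp1)
    sister to (ambusta, (nigrifacta, ustulata)).  Heights (0.010–0.015
    substitutions/site) and θ = 0.0005 are calibrated so within-species
    p-distance stays well below 0.5 % and between-species distance is
    >= ~2 % — the distance structure observed for the complex, since no
    point estimates are published.
    """
    s = depth_scale
    leaf = lambda name: SpeciesNode(name, 0.0, theta)
    node = lambda name, tau, a, b: SpeciesNode(name, tau * s, theta, [a, b])
    root = node(
        "root",
        0.015,
        node("alb_sp1", 0.011, leaf("albonigra"), leaf("sp1")),
        node(
            "amb_nig_ust",
            0.012,
            leaf("ambusta"),
            node("nig_ust", 0.010, leaf("nigrifacta"), leaf("ustulata")),
        ),
    )
    model = SpeciesTreeModel(root)
    model.validate()
    return model


def tight_complex_model(theta: float = 0.0005) -> SpeciesTreeModel:
    """Shallower variant (closest split 0.0035) whose between-species
    distances straddle ~1 %, so clusters merge inside the UNITE grid."""
    leaf = lambda name: SpeciesNode(name, 0.0, theta)
    root = SpeciesNode(
        "root", 0.0075, theta,
        [
            SpeciesNode("alb_sp1", 0.005, theta, [leaf("albonigra"), leaf("sp1")]),
            SpeciesNode(
                "amb_nig_ust", 0.006, theta,
                [
                    leaf("ambusta"),
                    SpeciesNode("nig_ust", 0.0035, theta, [leaf("nigrifacta"), leaf("ustulata")]),
                ],
            ),
        ],
    )
    model = SpeciesTreeModel(root)
    model.validate()
    return model


def sample_inverse_gamma(
    alpha: float, beta: float, rng: np.random.Generator, size: int | None = None
):
    """Draw from IG(shape α, scale β); mean β/(α−1) for α > 1."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("inverse-gamma parameters must be positive")
    return beta / rng.gamma(alpha, 1.0, size)


# ---------------------------------------------------------------------------
# gene genealogy


@dataclass
class GeneNode:
    id: str
    time: float
    children: list["GeneNode"] = field(default_factory=list)
    species: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GeneGenealogy:
    """Rooted binary genealogy over sampled lineages, times in
    expected-substitution units (same scale as τ)."""

    root: GeneNode
    tip_species: dict[str, str]

    def tips(self) -> list[GeneNode]:
        out: list[GeneNode] = []

        def walk(node: GeneNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    @property
    def tmrca(self) -> float:
        return self.root.time

    def clades(self) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()

        def walk(node: GeneNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.id])
            tips = frozenset().union(*(walk(c) for c in node.children))
            out.add(tips)
            return tips

        walk(self.root)
        return out

    def species_clades(self) -> set[frozenset[str]]:
        """Clades with tip ids replaced by species labels (for topology
        comparison against the species tree with one sample per species)."""
        return {
            frozenset(self.tip_species[t] for t in clade) for clade in self.clades()
        }

    def to_newick(self) -> str:
        def walk(node: GeneNode, parent_time: float | None) -> str:
            if node.is_leaf:
                body = node.id
            else:
                body = "(" + ",".join(walk(c, node.time) for c in node.children) + ")"
            if parent_time is None:
                return body + ";"
            return f"{body}:{parent_time - node.time:g}"

        return walk(self.root, None)


def simulate_genealogy(
    model: SpeciesTreeModel,
    samples_per_species: Mapping[str, int],
    seed: int | np.random.Generator,
) -> GeneGenealogy:
    """Simulate one gene genealogy under the MSC.

    Within each population the waiting time to the next coalescence among k
    lineages is Exp(k(k−1)/θ); survivors pass to the parent population at
    its τ.  Fully reproducible for a given seed.
    """
    model.validate()
    if not samples_per_species:
        raise ValueError("empty samples_per_species map")
    leaf_labels = set(model.leaf_labels())
    unknown = set(samples_per_species) - leaf_labels
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    if any(n < 1 for n in samples_per_species.values()):
        raise ValueError("sample counts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counter = 0
    tip_species: dict[str, str] = {}

    def coalesce_in(
        lineages: list[GeneNode], theta: float, t_start: float, t_end: float
    ) -> list[GeneNode]:
        nonlocal counter
        t = t_start
        lineages = list(lineages)
        while len(lineages) >= 2:
            k = len(lineages)
            t = t + rng.exponential(theta / (k * (k - 1)))
            if t >= t_end:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            counter += 1
            parent = GeneNode(f"anc{counter}", t, [lineages[i], lineages[j]])
            del lineages[j], lineages[i]
            lineages.append(parent)
        return lineages

    def process(node: SpeciesNode, t_end: float) -> list[GeneNode]:
        if node.is_leaf:
            n = samples_per_species.get(node.label, 0)
            incoming = []
            for i in range(n):
                tip_id = f"{node.label}_{i + 1:02d}"
                tip_species[tip_id] = node.label
                incoming.append(GeneNode(tip_id, 0.0, species=node.label))
        else:
            incoming = []
            for child in node.children:
                incoming.extend(process(child, node.tau))
        return coalesce_in(incoming, node.theta, node.tau, t_end)

    survivors = process(model.root, np.inf)
    if len(survivors) != 1:
        raise RuntimeError("root population did not fully coalesce")  # pragma: no cover
    return GeneGenealogy(survivors[0], tip_species)


# ---------------------------------------------------------------------------
# sequence evolution


@dataclass(frozen=True)
class Region:
    name: str
    length: int
    rate: float = 1.0


@dataclass(frozen=True)
class SubstitutionModel:
    """JC69 by default; HKY adds a transition/transversion ratio κ and
    non-uniform base frequencies (order A, C, G, T)."""

    name: str = "JC69"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.name not in ("JC69", "HKY"):
            raise ValueError(f"unknown substitution model {self.name!r}")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or min(self.base_freqs) <= 0:
            raise ValueError("base frequencies must be positive and sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """Normalised instantaneous rate matrix (mean rate 1 at equilibrium)."""
        pi = np.asarray(self.base_freqs)
        q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j] * (self.kappa if (i, j) in transitions else 1.0)
                if self.name == "JC69":
                    rate = pi[j]
                q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale


@dataclass(frozen=True)
class LocusSpec:
    """Ordered, contiguous regions with relative rate multipliers."""

    regions: tuple[Region, ...]
    substitution: SubstitutionModel = SubstitutionModel()

    def __post_init__(self) -> None:
        if any(r.length <= 0 for r in self.regions):
            raise ValueError("region lengths must be positive")
        if any(r.rate < 0 for r in self.regions):
            raise ValueError("region rate multipliers must be non-negative")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.regions)

    def region_map(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        pos = 0
        for r in self.regions:
            out[r.name] = (pos, pos + r.length)
            pos += r.length
        return out

    def site_rates(self) -> np.ndarray:
        return np.concatenate([np.full(r.length, r.rate) for r in self.regions])


def default_locus(include_lsu: bool = False, its2_length: int = 230) -> LocusSpec:
    """ITS1 (220, x1.0) + 5.8S (160, x0.1) + ITS2 (x1.0), optionally a
    partial LSU tail (300, x0.2)."""
    regions = [Region("ITS1", 220, 1.0), Region("5.8S", 160, 0.1), Region("ITS2", its2_length, 1.0)]
    if include_lsu:
        regions.append(Region("LSU-partial", 300, 0.2))
    return LocusSpec(tuple(regions))


def _jc_mutate(seq: np.ndarray, dist: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One JC69 step: per-site branch lengths ``dist`` (subs/site)."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * dist / 3.0))
    hit = rng.random(seq.size) < p_change
    out = seq.copy()
    # a changed site moves to one of the three other bases uniformly
    out[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _hky_mutate(
    seq: np.ndarray,
    branch: float,
    locus: LocusSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    from scipy.linalg import expm

    out = seq.copy()
    q = locus.substitution.rate_matrix()
    pos = 0
    for region in locus.regions:
        sl = slice(pos, pos + region.length)
        pos += region.length
        b = branch * region.rate
        if b == 0:
            continue
        p = expm(q * b)
        p = np.clip(p, 0, None)
        p /= p.sum(axis=1, keepdims=True)
        chunk = out[sl]
        for base in range(4):
            sites = np.nonzero(chunk == base)[0]
            if sites.size:
                chunk[sites] = rng.choice(4, size=sites.size, p=p[base])
        out[sl] = chunk
    return out


def evolve_sequences(
    genealogy: GeneGenealogy,
    locus: LocusSpec,
    seed: int | np.random.Generator,
) -> Alignment:
    """Evolve sequences site-independently along the genealogy.

    The root sequence is drawn from the model's equilibrium frequencies;
    there are no indels, so the output *is* the true alignment.
    """
    if locus.total_length == 0:
        raise ValueError("locus has zero total length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = locus.total_length
    site_rates = locus.site_rates()
    model = locus.substitution
    root_seq = rng.choice(4, size=length, p=np.asarray(model.base_freqs))

    tip_seqs: dict[str, np.ndarray] = {}

    def walk(node: GeneNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            tip_seqs[node.id] = seq
            return
        for child in node.children:
            branch = node.time - child.time
            if model.name == "JC69":
                child_seq = _jc_mutate(seq, branch * site_rates, rng)
            else:
                child_seq = _hky_mutate(seq, branch, locus, rng)
            walk(child, child_seq)

    walk(genealogy.root, root_seq)
    records = [
        SequenceRecord(tip_id, "".join(_BASES[tip_seqs[tip_id]]), source="synthetic")
        for tip_id in sorted(tip_seqs)
    ]
    return Alignment(records, locus.region_map())


# ---------------------------------------------------------------------------
# degradation


@dataclass(frozen=True)
class DegradationSpec:
    """Database-style damage applied per record.

    Each record is truncated to a single spacer with probability
    ``p_partial_its1`` / ``p_partial_its2`` (mutually exclusive draws);
    independently ambiguated (each base replaced, at ``ambiguity_rate`` per
    site, by an IUPAC code containing it) with probability ``p_ambiguate``;
    and independently given substitutions inside the conserved domain at
    ``domain_substitution_rate`` per site with probability
    ``p_domain_deviant``.
    """

    p_partial_its1: float = 0.0
    p_partial_its2: float = 0.0
    p_ambiguate: float = 0.0
    ambiguity_rate: float = 0.05
    p_domain_deviant: float = 0.0
    domain_substitution_rate: float = 0.02
    domain_region: str = "5.8S"

    def __post_init__(self) -> None:
        for name in (
            "p_partial_its1", "p_partial_its2", "p_ambiguate",
            "ambiguity_rate", "p_domain_deviant", "domain_substitution_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.p_partial_its1 + self.p_partial_its2 > 1.0:
            raise ValueError("partial-truncation probabilities sum above 1")


def truncate_to_region(seq: str, region_map: Mapping[str, tuple[int, int]], keep: str) -> str:
    """Keep one region's columns; every other column becomes '?' (missing)."""
    start, end = region_map[keep]
    return "?" * start + seq[start:end] + "?" * (len(seq) - end)


def ambiguate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Replace bases, at ``rate`` per site, by an IUPAC code containing them."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"ambiguity rate {rate} outside [0, 1]")
    chars = list(seq)
    for i, ch in enumerate(chars):
        if ch in _AMBIG_FOR_BASE and rng.random() < rate:
            codes = _AMBIG_FOR_BASE[ch]
            chars[i] = codes[rng.integers(len(codes))]
    return "".join(chars)


def perturb_domain(
    seq: str,
    region_map: Mapping[str, tuple[int, int]],
    region: str,
    rate: float,
    rng: np.random.Generator,
) -> str:
    """Substitute bases inside ``region`` at ``rate`` per site."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"domain substitution rate {rate} outside [0, 1]")
    start, end = region_map[region]
    chars = list(seq)
    for i in range(start, end):
        if chars[i] in "ACGT" and rng.random() < rate:
            others = [b for b in "ACGT" if b != chars[i]]
            chars[i] = others[rng.integers(3)]
    return "".join(chars)


def degrade(
    alignment: Alignment,
    spec: DegradationSpec,
    seed: int | np.random.Generator,
) -> tuple[Alignment, dict[str, tuple[str, ...]]]:
    """Apply the degradation spec; return the damaged alignment and
    per-record flags (full_length | partial:* | ambiguated | domain_deviant)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    region_map = alignment.region_map
    records: list[SequenceRecord] = []
    flags: dict[str, tuple[str, ...]] = {}
    for rec in alignment.records:
        seq = rec.seq
        rec_flags: list[str] = []
        u = rng.random()
        if u < spec.p_partial_its1 and "ITS1" in region_map:
            seq = truncate_to_region(seq, region_map, "ITS1")
            rec_flags.append(FLAG_PARTIAL_ITS1)
        elif u < spec.p_partial_its1 + spec.p_partial_its2 and "ITS2" in region_map:
            seq = truncate_to_region(seq, region_map, "ITS2")
            rec_flags.append(FLAG_PARTIAL_ITS2)
        if rng.random() < spec.p_ambiguate:
            seq = ambiguate(seq, spec.ambiguity_rate, rng)
            rec_flags.append(FLAG_AMBIGUATED)
        if rng.random() < spec.p_domain_deviant and spec.domain_region in region_map:
            seq = perturb_domain(seq, region_map, spec.domain_region,
                                 spec.domain_substitution_rate, rng)
            rec_flags.append(FLAG_DOMAIN_DEVIANT)
        if not rec_flags:
            rec_flags = [FLAG_FULL_LENGTH]
        flags[rec.id] = tuple(rec_flags)
        records.append(SequenceRecord(rec.id, seq, rec.description, rec.source))
    return Alignment(records, dict(region_map)), flags


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class DatasetConfig:
    """Everything needed to regenerate a dataset byte-for-byte.

    ``tree`` is a preset name ("albonigra_like" | "tight_complex") or a
    nested node mapping accepted by ``SpeciesTreeModel.from_dict``.  When
    ``theta_prior`` / ``tau_prior`` = (α, β) are given, θ (shared across
    branches) and the root height (internal heights rescaled
    proportionally) are drawn from IG(α, β) before simulation.
    """

    seed: int = 0
    tree: str | dict = "albonigra_like"
    theta: float | None = None
    samples_per_species: int | dict[str, int] = 4
    include_lsu: bool = False
    its2_length: int = 230
    substitution: str = "JC69"
    kappa: float = 2.0
    theta_prior: tuple[float, float] | None = None
    tau_prior: tuple[float, float] | None = None
    degradation: DegradationSpec = field(default_factory=DegradationSpec)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatasetConfig":
        d = dict(d)
        if "degradation" in d and isinstance(d["degradation"], Mapping):
            d["degradation"] = DegradationSpec(**d["degradation"])
        for key in ("theta_prior", "tau_prior"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("theta_prior", "tau_prior"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def build_model(self, rng: np.random.Generator) -> SpeciesTreeModel:
        if isinstance(self.tree, str):
            if self.tree == "albonigra_like":
                model = albonigra_like_model()
            elif self.tree == "tight_complex":
                model = tight_complex_model()
            else:
                raise ValueError(f"unknown species-tree preset {self.tree!r}")
        else:
            model = SpeciesTreeModel.from_dict(self.tree)
        if self.theta is not None:
            model = model.with_theta(self.theta)
        if self.theta_prior is not None:
            model = model.with_theta(float(sample_inverse_gamma(*self.theta_prior, rng)))
        if self.tau_prior is not None:
            new_root = float(sample_inverse_gamma(*self.tau_prior, rng))
            model = model.scaled(new_root / model.root.tau)
        model.validate()
        return model

    def build_locus(self) -> LocusSpec:
        locus = default_locus(include_lsu=self.include_lsu, its2_length=self.its2_length)
        if self.substitution != "JC69":
            locus = LocusSpec(
                locus.regions, SubstitutionModel(self.substitution, kappa=self.kappa)
            )
        return locus

    def sample_counts(self, model: SpeciesTreeModel) -> dict[str, int]:
        if isinstance(self.samples_per_species, int):
            return {lab: self.samples_per_species for lab in model.leaf_labels()}
        return dict(self.samples_per_species)


@dataclass
class DatasetResult:
    alignment: Alignment
    truth: pd.DataFrame
    species_map: SpeciesMap
    model: SpeciesTreeModel
    genealogy: GeneGenealogy
    config: DatasetConfig


def generate_dataset(
    config: DatasetConfig, outdir: str | Path | None = None
) -> DatasetResult:
    """Simulate genealogy -> sequences -> degradation; optionally write
    FASTA, truth TSV, species-tree Newick and the config as JSON.

    Deterministic for a given config + seed (identical bytes on re-run).
    Records that were degraded become role=query in the truth table; clean
    records are reference.
    """
    rng = np.random.default_rng(config.seed)
    model = config.build_model(rng)
    counts = config.sample_counts(model)
    genealogy = simulate_genealogy(model, counts, rng)
    locus = config.build_locus()
    clean = evolve_sequences(genealogy, locus, rng)
    damaged, flags = degrade(clean, config.degradation, rng)

    rows = []
    samples: dict[str, SampleInfo] = {}
    for rec in damaged.records:
        species = genealogy.tip_species[rec.id]
        rec_flags = flags[rec.id]
        role = ROLE_REFERENCE if rec_flags == (FLAG_FULL_LENGTH,) else ROLE_QUERY
        rows.append(
            {
                "id": rec.id,
                "species": species,
                "role": role,
                "flags": ",".join(rec_flags),
                "seed": config.seed,
            }
        )
        samples[rec.id] = SampleInfo(species=species, role=role, flags=rec_flags)
    truth = pd.DataFrame(rows, columns=["id", "species", "role", "flags", "seed"])
    result = DatasetResult(damaged, truth, SpeciesMap(samples), model, genealogy, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(damaged.records, outdir / "alignment.fasta")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        (outdir / "species_tree.nwk").write_text(model.to_newick() + "\n")
        (outdir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    return result
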