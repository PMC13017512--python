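"""Synthetic admixture-graph data generator.

Allele frequencies drift along a directed acyclic population graph: the root
frequency is drawn from a configurable law (default uniform on [0.05, 0.95])
and each edge applies Balding–Nichols drift — the child frequency is Beta
distributed with mean equal to the parent frequency and variance
``F · p(1 − p)`` for drift magnitude F. Admixture events set a node's
frequency to a fixed linear mixture of two parents. Genotypes are then
sampled binomially per sample with coverage-driven missingness: read depth is
Poisson(mean_depth) and zero depth yields a missing call.

Exact first and second moments of all node frequencies are available in
closed form (``expected_f2``/``expected_f3``/``expected_f4``), which the test
suite uses as an independent oracle for the f-statistic estimators.

Named presets mirror the inferred structure of Palaeolithic/early-Holocene
dog populations: a western/eastern Eurasian dog split with Near Eastern wolf
admixture into a Near Eastern dog lineage (default fraction 0.04), a
two-way western/eastern Mesolithic dog mixture, coupled human/dog site
similarity histories with spatial/temporal structure, and related-pair panels
for kinship testing. Every preset returns a machine-readable truth record of
its generating parameters. Default per-edge drift magnitudes (0.005–0.15)
are package constants chosen to produce f-statistic magnitudes typical of
canid panels; fixing the seed reproduces every panel bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coancestry import distance_matrices, standardize_offdiag
from .errors import ConfigurationError, InvariantError
from .genodata import GenotypePanel, MISSING, make_samples, make_sites

__all__ = [
    "DriftEdge",
    "AdmixtureEvent",
    "AdmixtureGraph",
    "SampleSpec",
    "simulate_frequencies",
    "sample_panel",
    "expected_f2",
    "expected_f3",
    "expected_f4",
    "expected_heterozygosity",
    "preset_wolf_admixture",
    "preset_mesolithic_mix",
    "preset_coupled_history",
    "preset_related_pair",
]

UNIFORM_ROOT = (0.05, 0.95)


@dataclass(frozen=True)
class DriftEdge:
    parent: str
    child: str
    drift: float  # Fst-like magnitude in [0, 1)


@dataclass(frozen=True)
class AdmixtureEvent:
    child: str
    parent_a: str
    parent_b: str
    fraction: float  # weight on parent_a


@dataclass
class AdmixtureGraph:
    """Population graph with drift edges and two-parent admixture events."""

    edges: list[DriftEdge]
    admixtures: list[AdmixtureEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        children = [e.child for e in self.edges] + [a.child for a in self.admixtures]
        if len(set(children)) != len(children):
            raise InvariantError("each node may have one parent or one admixture event")
        for e in self.edges:
            if e.drift < 0:
                raise InvariantError("drift must be non-negative")
        for a in self.admixtures:
            if not 0.0 <= a.fraction <= 1.0:
                raise InvariantError("admixture fraction must lie in [0, 1]")
        parents = {e.parent for e in self.edges}
        parents |= {a.parent_a for a in self.admixtures} | {a.parent_b for a in self.admixtures}
        roots = parents - set(children)
        if len(roots) != 1:
            raise InvariantError(f"graph must have exactly one root, found {sorted(roots)}")
        self._root = roots.pop()
        self._order = self._topological_order()

    @property
    def root(self) -> str:
        return self._root

    @property
    def nodes(self) -> list[str]:
        return list(self._order)

    def _topological_order(self) -> list[str]:
        deps: dict[str, set[str]] = {}
        for e in self.edges:
            deps.setdefault(e.child, set()).add(e.parent)
        for a in self.admixtures:
            deps.setdefault(a.child, set()).update((a.parent_a, a.parent_b))
        order = [self._root]
        placed = {self._root}
        pending = dict(deps)
        while pending:
            ready = [c for c, ps in pending.items() if ps <= placed]
            if not ready:
                raise InvariantError("graph contains a cycle")
            for c in sorted(ready):
                order.append(c)
                placed.add(c)
                del pending[c]
        return order

    def leaves(self) -> list[str]:
        parents = {e.parent for e in self.edges}
        parents |= {a.parent_a for a in self.admixtures} | {a.parent_b for a in self.admixtures}
        return [n for n in self.nodes if n not in parents]


def simulate_frequencies(
    graph: AdmixtureGraph,
    n_snps: int,
    rng: np.random.Generator,
    root_law: tuple[float, float] = UNIFORM_ROOT,
) -> dict[str, np.ndarray]:
    """Draw per-site allele frequencies for every node of the graph."""
    if n_snps <= 0:
        raise ConfigurationError("n_snps must be positive")
    lo, hi = root_law
    freqs: dict[str, np.ndarray] = {graph.root: rng.uniform(lo, hi, n_snps)}
    edge_by_child = {e.child: e for e in graph.edges}
    admix_by_child = {a.child: a for a in graph.admixtures}
    for node in graph.nodes[1:]:
        if node in edge_by_child:
            e = edge_by_child[node]
            p = freqs[e.parent]
            F = e.drift
            if F >= 1.0:
                warnings.warn("drift >= 1 clipped to 0.999")
                F = 0.999
            if F == 0.0:
                freqs[node] = p.copy()
            else:
                pc = np.clip(p, 1e-9, 1 - 1e-9)
                scale = (1.0 - F) / F
                freqs[node] = rng.beta(pc * scale, (1.0 - pc) * scale)
        else:
            a = admix_by_child[node]
            freqs[node] = a.fraction * freqs[a.parent_a] + (1 - a.fraction) * freqs[a.parent_b]
    return freqs


# ---------------------------------------------------------------------------
# Closed-form moments (independent oracle for f-statistics)
# ---------------------------------------------------------------------------

def _moment_table(
    graph: AdmixtureGraph, root_law: tuple[float, float] = UNIFORM_ROOT
) -> dict[tuple[str, str], float]:
    """E[x·y] for every pair of node frequencies, by topological recursion.

    For a Balding–Nichols edge, E[c | p] = p and
    E[c² | p] = (1 − F)·p² + F·p; a node is conditionally independent of all
    non-descendants given its parent(s), so cross-moments propagate directly.
    """
    lo, hi = root_law
    mean = (lo + hi) / 2.0
    second = mean**2 + (hi - lo) ** 2 / 12.0
    m2: dict[tuple[str, str], float] = {}
    m1: dict[str, float] = {}

    def get(x: str, y: str) -> float:
        return m2[(x, y)] if (x, y) in m2 else m2[(y, x)]

    def put(x: str, y: str, v: float) -> None:
        m2[(x, y)] = v
        m2[(y, x)] = v

    root = graph.root
    m1[root] = mean
    put(root, root, second)
    seen = [root]
    edge_by_child = {e.child: e for e in graph.edges}
    admix_by_child = {a.child: a for a in graph.admixtures}
    for node in graph.nodes[1:]:
        if node in edge_by_child:
            e = edge_by_child[node]
            F = min(e.drift, 0.999)
            m1[node] = m1[e.parent]
            for x in seen:
                put(node, x, get(e.parent, x))
            put(node, node, (1 - F) * get(e.parent, e.parent) + F * m1[e.parent])
        else:
            a = admix_by_child[node]
            f = a.fraction
            m1[node] = f * m1[a.parent_a] + (1 - f) * m1[a.parent_b]
            for x in seen:
                put(node, x, f * get(a.parent_a, x) + (1 - f) * get(a.parent_b, x))
            put(
                node,
                node,
                f**2 * get(a.parent_a, a.parent_a)
                + 2 * f * (1 - f) * get(a.parent_a, a.parent_b)
                + (1 - f) ** 2 * get(a.parent_b, a.parent_b),
            )
        seen.append(node)
    return m2


def expected_f2(graph: AdmixtureGraph, a: str, b: str, root_law=UNIFORM_ROOT) -> float:
    """E[(p_a − p_b)²] over population frequencies."""
    m2 = _moment_table(graph, root_law)
    return m2[(a, a)] - 2 * m2[(a, b)] + m2[(b, b)]


def expected_f3(graph: AdmixtureGraph, a: str, b: str, c: str, root_law=UNIFORM_ROOT) -> float:
    """E[(p_c − p_a)(p_c − p_b)] with vertex c."""
    m2 = _moment_table(graph, root_law)
    return m2[(c, c)] - m2[(c, a)] - m2[(c, b)] + m2[(a, b)]


def expected_f4(
    graph: AdmixtureGraph, a: str, b: str, c: str, d: str, root_law=UNIFORM_ROOT
) -> float:
    """E[(p_a − p_b)(p_c − p_d)]."""
    m2 = _moment_table(graph, root_law)
    return m2[(a, c)] - m2[(a, d)] - m2[(b, c)] + m2[(b, d)]


def expected_heterozygosity(graph: AdmixtureGraph, node: str, root_law=UNIFORM_ROOT) -> float:
    """E[p(1 − p)] at a node (useful for finite-sample bias terms)."""
    lo, hi = root_law
    mean = (lo + hi) / 2.0
    m2 = _moment_table(graph, root_law)
    return mean - m2[(node, node)]


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSpec:
    """How to sample individuals from one population node."""

    population: str
    n: int = 1
    ploidy: int = 1
    mean_depth: float | None = 5.0  # None = complete coverage
    species: str = "dog"
    latitude: float = np.nan
    longitude: float = np.nan
    age_bp: float = 0.0


def sample_panel(
    frequencies: dict[str, np.ndarray],
    specs: Sequence[SampleSpec],
    rng: np.random.Generator,
    n_chrom: int = 20,
    spacing_bp: int = 10_000,
) -> GenotypePanel:
    """Sample a genotype panel from per-population frequencies.

    Sites are laid out evenly across ``n_chrom`` chromosomes at
    ``spacing_bp`` intervals (all flagged transversions, ref A / alt C). Per
    sample and site, read depth is Poisson(mean_depth); zero depth gives
    MISSING, otherwise the call is Binomial(ploidy, freq).
    """
    n_snps = len(next(iter(frequencies.values())))
    per_chrom = int(np.ceil(n_snps / n_chrom))
    idx = np.arange(n_snps)
    chrom = (idx // per_chrom + 1).astype(str)
    pos = (idx % per_chrom + 1) * spacing_bp
    sites = make_sites(chrom, pos, ["A"] * n_snps, ["C"] * n_snps,
                       [f"snp{i}" for i in idx])

    cols, ids, pops, species, ploidies, lats, lons, ages, covs = ([] for _ in range(9))
    for spec in specs:
        freq = frequencies[spec.population]
        for k in range(spec.n):
            call = rng.binomial(spec.ploidy, freq).astype(np.int8)
            if spec.mean_depth is not None and np.isfinite(spec.mean_depth):
                depth = rng.poisson(spec.mean_depth, n_snps)
                call = np.where(depth > 0, call, np.int8(MISSING)).astype(np.int8)
                covs.append(spec.mean_depth)
            else:
                covs.append(np.nan)
            cols.append(call)
            ids.append(f"{spec.population}_{k + 1}")
            pops.append(spec.population)
            species.append(spec.species)
            ploidies.append(spec.ploidy)
            lats.append(spec.latitude)
            lons.append(spec.longitude)
            ages.append(spec.age_bp)
    calls = np.column_stack(cols) if cols else np.empty((n_snps, 0), dtype=np.int8)
    samples = make_samples(
        ids, pops, species=species, ploidy=ploidies,
        latitude=lats, longitude=lons, age_bp=ages, coverage=covs,
    )
    return GenotypePanel(sites, samples, calls)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def wolf_admixture_graph(wolf_fraction: float = 0.04) -> AdmixtureGraph:
    """Canid graph: coyote outgroup, wolves, western/eastern dogs, and a
    Near Eastern dog receiving ``wolf_fraction`` ancestry from the Near
    Eastern wolf lineage (the remainder from the western dog lineage)."""
    edges = [
        DriftEdge("root", "Coyote", 0.12),
        DriftEdge("root", "canid", 0.06),
        DriftEdge("canid", "wolf_anc", 0.02),
        DriftEdge("wolf_anc", "Eurasian_wolf", 0.04),
        DriftEdge("wolf_anc", "NE_wolf_anc", 0.03),
        DriftEdge("NE_wolf_anc", "Wezmeh", 0.02),
        DriftEdge("canid", "dog_anc", 0.08),
        DriftEdge("dog_anc", "Zhokhov", 0.05),
        DriftEdge("dog_anc", "west_anc", 0.03),
        DriftEdge("west_anc", "Pinarbasi", 0.02),
        DriftEdge("west_anc", "GoughsCave", 0.02),
        DriftEdge("west_anc", "Basenji", 0.05),
        DriftEdge("west_anc", "west_src", 0.005),
        DriftEdge("NE_dog_mix", "NE_dog", 0.01),
    ]
    admix = [AdmixtureEvent("NE_dog_mix", "NE_wolf_anc", "west_src", wolf_fraction)]
    return AdmixtureGraph(edges, admix)


WOLF_ADMIXTURE_ROLES = {
    "outgroup": "Coyote",
    "eastern_dog": "Zhokhov",
    "western_dog": "Pinarbasi",
    "ne_wolf": "Wezmeh",
    "target": "NE_dog",
}


def preset_wolf_admixture(
    n_snps: int = 100_000, seed: int = 0, wolf_fraction: float = 0.04
) -> tuple[GenotypePanel, dict]:
    """Panel from the canid admixture graph with a wolf→dog admixture event.

    The default fraction of 0.04 (96% western-dog / 4% Near-Eastern-wolf)
    matches the preset graph's headline configuration. The truth record
    carries every generating parameter and the role map used by the
    F4-ratio analysis.
    """
    graph = wolf_admixture_graph(wolf_fraction)
    rng = np.random.default_rng(seed)
    freqs = simulate_frequencies(graph, n_snps, rng)
    specs = [
        SampleSpec("Coyote", n=2, ploidy=2, mean_depth=20.0, species="outgroup"),
        SampleSpec("Eurasian_wolf", n=3, ploidy=1, mean_depth=5.0, species="wolf"),
        SampleSpec("Wezmeh", n=3, ploidy=1, mean_depth=5.0, species="wolf"),
        SampleSpec("Zhokhov", n=3, ploidy=1, mean_depth=5.0, species="dog"),
        SampleSpec("Pinarbasi", n=3, ploidy=1, mean_depth=5.0, species="dog"),
        SampleSpec("GoughsCave", n=3, ploidy=1, mean_depth=5.0, species="dog"),
        SampleSpec("Basenji", n=2, ploidy=2, mean_depth=20.0, species="dog"),
        SampleSpec("NE_dog", n=3, ploidy=1, mean_depth=5.0, species="dog"),
    ]
    panel = sample_panel(freqs, specs, rng)
    truth = {
        "preset": "wolfmix",
        "wolf_fraction": wolf_fraction,
        "n_snps": n_snps,
        "seed": seed,
        "roles": dict(WOLF_ADMIXTURE_ROLES),
        "edges": [(e.parent, e.child, e.drift) for e in graph.edges],
        "admixtures": [
            (a.child, a.parent_a, a.parent_b, a.fraction) for a in graph.admixtures
        ],
    }
    return panel, truth


def mesolithic_graph(west_fraction: float = 0.562) -> AdmixtureGraph:
    edges = [
        DriftEdge("root", "Coyote", 0.12),
        DriftEdge("root", "canid", 0.05),
        DriftEdge("canid", "wolf1", 0.06),
        DriftEdge("canid", "wolf_b", 0.02),
        DriftEdge("wolf_b", "wolf2", 0.04),
        DriftEdge("wolf_b", "wolf_c", 0.02),
        DriftEdge("wolf_c", "wolf3", 0.03),
        DriftEdge("canid", "dog_anc", 0.08),
        DriftEdge("dog_anc", "west_anc", 0.08),
        DriftEdge("west_anc", "Pinarbasi", 0.02),
        DriftEdge("west_anc", "west_src", 0.005),
        DriftEdge("dog_anc", "east_anc", 0.08),
        DriftEdge("east_anc", "Zhokhov", 0.02),
        DriftEdge("east_anc", "east_src", 0.005),
        DriftEdge("east_anc", "dingo_anc", 0.005),
        DriftEdge("dingo_anc", "Dingo", 0.03),
        DriftEdge("dingo_anc", "AmericanDog", 0.03),
        DriftEdge("Meso_mix", "Mesolithic", 0.01),
    ]
    admix = [AdmixtureEvent("Meso_mix", "west_src", "east_src", west_fraction)]
    return AdmixtureGraph(edges, admix)


MESOLITHIC_SOURCES = ["Pinarbasi", "Zhokhov"]
MESOLITHIC_RIGHTS = ["wolf1", "wolf2", "wolf3", "Dingo", "AmericanDog", "Coyote"]


def preset_mesolithic_mix(
    n_snps: int = 100_000, seed: int = 0, west_fraction: float = 0.562
) -> tuple[GenotypePanel, dict]:
    """Two-way western/eastern Eurasian dog mixture with reference wolves.

    The default western fraction of 0.562 is the mean western-Eurasian dog
    ancestry of the Mesolithic study condition. Reference ("right")
    populations comprise three wolves, a dingo-role and an American-dog-role
    eastern offshoot, and the coyote outgroup — enough for a well-posed
    two-source fit.
    """
    if not 0.0 <= west_fraction <= 1.0:
        raise ConfigurationError("west_fraction must lie in [0, 1]")
    graph = mesolithic_graph(west_fraction)
    rng = np.random.default_rng(seed)
    freqs = simulate_frequencies(graph, n_snps, rng)
    specs = [
        SampleSpec("Coyote", n=2, ploidy=2, mean_depth=20.0, species="outgroup"),
        SampleSpec("wolf1", n=3, ploidy=1, mean_depth=5.0, species="wolf"),
        SampleSpec("wolf2", n=3, ploidy=1, mean_depth=5.0, species="wolf"),
        SampleSpec("wolf3", n=3, ploidy=1, mean_depth=5.0, species="wolf"),
        SampleSpec("Dingo", n=2, ploidy=2, mean_depth=20.0, species="dog"),
        SampleSpec("AmericanDog", n=2, ploidy=2, mean_depth=20.0, species="dog"),
        SampleSpec("Pinarbasi", n=3, ploidy=1, mean_depth=5.0, species="dog"),
        SampleSpec("Zhokhov", n=3, ploidy=1, mean_depth=5.0, species="dog"),
        SampleSpec("Mesolithic", n=3, ploidy=1, mean_depth=5.0, species="dog"),
    ]
    panel = sample_panel(freqs, specs, rng)
    truth = {
        "preset": "mesolithic_mix",
        "west_fraction": west_fraction,
        "n_snps": n_snps,
        "seed": seed,
        "target": "Mesolithic",
        "sources": list(MESOLITHIC_SOURCES),
        "references": list(MESOLITHIC_RIGHTS),
        "period": "Mesolithic",
    }
    return panel, truth


def preset_coupled_history(
    n_sites: int = 35,
    rho: float = 0.40,
    seed: int = 0,
    space_weight: float = 0.4,
    time_weight: float = 0.3,
    latent_dim: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Coupled human/dog similarity matrices over archaeological sites.

    Site coordinates are drawn uniformly in a Europe-sized box (lat 35–60,
    lon −10–40) and ages uniformly over 1,500–16,000 BP. Human and dog
    similarity matrices are linear mixtures of a shared latent Gram matrix S,
    the negated standardized spatial/temporal distance matrices, and
    independent symmetric noise:

        H = √|ρ|·S − b·Zs − c·Zt + √(1−|ρ|)·E_h
        D = sign(ρ)√|ρ|·S − b·Zs − c·Zt + √(1−|ρ|)·E_d

    Because S, Zs, Zt, E are mutually independent with unit off-diagonal
    variance, the population partial correlation of H and D given space and
    time is exactly ρ.

    Returns (human, dog, spatial_km, temporal_years, truth); the truth record
    includes the site metadata table.
    """
    if n_sites < 10:
        raise ConfigurationError("n_sites must be at least 10")
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame(
        {
            "site": [f"site{i:02d}" for i in range(n_sites)],
            "latitude": rng.uniform(35.0, 60.0, n_sites),
            "longitude": rng.uniform(-10.0, 40.0, n_sites),
            "age_bp": rng.uniform(1_500.0, 16_000.0, n_sites),
        }
    )
    spatial, temporal = distance_matrices(meta)
    zs = standardize_offdiag(spatial)
    zt = standardize_offdiag(temporal)

    G = rng.normal(size=(n_sites, latent_dim)) / np.sqrt(latent_dim)
    S = standardize_offdiag(G @ G.T)

    def sym_noise() -> np.ndarray:
        E = rng.normal(size=(n_sites, n_sites))
        E = np.triu(E, k=1)
        E = E + E.T
        return E

    a = np.sqrt(abs(rho))
    e = np.sqrt(1.0 - abs(rho))
    human = a * S - space_weight * zs - time_weight * zt + e * sym_noise()
    dog = np.sign(rho) * a * S - space_weight * zs - time_weight * zt + e * sym_noise()
    # final z-transform mirrors the analysis convention; the partial
    # correlation given space and time is unchanged and remains rho
    human = standardize_offdiag(human)
    dog = standardize_offdiag(dog)
    truth = {
        "preset": "coupled_history",
        "rho": rho,
        "n_sites": n_sites,
        "seed": seed,
        "space_weight": space_weight,
        "time_weight": time_weight,
        "latent_dim": latent_dim,
        "site_meta": meta,
    }
    return human, dog, spatial, temporal, truth


def preset_related_pair(
    theta_target: float = 0.25,
    n_snps: int = 20_000,
    mean_depth: float = 2.0,
    seed: int = 0,
    n_unrelated: int = 8,
) -> tuple[GenotypePanel, dict]:
    """Panel with one related pair among unrelated individuals.

    The pair is built by copying one individual's haploid calls into the
    other at a fraction of sites equal to ``theta_target``: at copied sites
    the pairwise mismatch is zero, so the expected median-normalized
    relatedness of the pair equals the copying fraction (the unrelated pairs
    set the median).
    """
    if not 0.0 <= theta_target <= 0.5:
        raise ConfigurationError("theta_target must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*UNIFORM_ROOT, n_snps)
    specs = [
        SampleSpec("unrel", n=n_unrelated, ploidy=1, mean_depth=mean_depth),
        SampleSpec("rel", n=2, ploidy=1, mean_depth=mean_depth),
    ]
    panel = sample_panel({"unrel": p, "rel": p}, specs, rng)
    ia = list(panel.samples["sample_id"]).index("rel_1")
    ib = list(panel.samples["sample_id"]).index("rel_2")
    copy_mask = rng.random(n_snps) < theta_target
    a, b = panel.calls[:, ia], panel.calls[:, ib]
    both = (a != MISSING) & (b != MISSING) & copy_mask
    panel.calls[both, ib] = a[both]
    truth = {
        "preset": "related_pair",
        "theta_target": theta_target,
        "pair": ("rel_1", "rel_2"),
        "copy_fraction": theta_target,
        "n_snps": n_snps,
        "mean_depth": mean_depth,
        "seed": seed,
    }
    return panel, truth
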