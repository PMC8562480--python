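"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a diet-manipulation microbiome study:
a pure-birth phylogeny whose tips carry Brownian-motion niche traits, a
dietary-species-richness (DSR) design of eight groups, nutrient variables
with prescribed U / inverted-U / linear / flat responses to DSR, and
communities assembled either neutrally (uniform draws from the taxon pool)
or by habitat filtering on the match between a taxon's trait and the
sample's environment.  Every generator is bit-reproducible for a fixed seed.

Default design mirrors the study scale: 8 DSR levels x 10 samples and a
983-taxon pool; all sizes are parameters.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .containers import OtuTable, PhyloTree, SampleMetadata

__all__ = [
    "AssemblySpec",
    "ShapeSpec",
    "SHAPE_NAMES",
    "simulate_tree",
    "evolve_niche_traits",
    "generate_metadata",
    "assemble_communities",
    "generate_response_table",
    "generate_study",
]

SHAPE_NAMES = ("U", "inverted-U", "positive", "negative", "none")


@dataclasses.dataclass
class ShapeSpec:
    """Prescribed response of a variable to the DSR level.

    ``shape`` is one of ``U``, ``inverted-U``, ``positive``, ``negative`` or
    ``none``; ``amplitude`` scales the curve, ``vertex`` (DSR units) places
    the turning point of the quadratic shapes, ``noise_sd`` is the SD of
    additive Gaussian noise.
    """

    shape: str
    amplitude: float = 1.0
    vertex: float = 5.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_NAMES:
            raise ValueError(
                f"unknown shape {self.shape!r}; expected one of {SHAPE_NAMES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def mean(self, dsr: np.ndarray) -> np.ndarray:
        """Noise-free response at the given DSR levels."""
        x = np.asarray(dsr, dtype=float)
        if self.shape == "U":
            return self.amplitude * (x - self.vertex) ** 2
        if self.shape == "inverted-U":
            return -self.amplitude * (x - self.vertex) ** 2
        if self.shape == "positive":
            return self.amplitude * x
        if self.shape == "negative":
            return -self.amplitude * x
        return np.zeros_like(x)

    def validate_against_levels(self, dsr_levels: Sequence[int]) -> None:
        if self.shape in ("U", "inverted-U"):
            lo, hi = min(dsr_levels), max(dsr_levels)
            if not (lo <= self.vertex <= hi):
                raise ValueError(
                    f"vertex {self.vertex} outside DSR range [{lo}, {hi}] "
                    f"for shape {self.shape!r}")


@dataclasses.dataclass
class AssemblySpec:
    """Design of a synthetic community-assembly experiment.

    ``mode`` selects neutral (uniform) or habitat-filtering assembly;
    ``filter_strength`` is the filtering kernel SD in units of the trait SD
    (smaller = stronger filtering).  ``seq_depth`` reads are drawn per sample
    from lognormal relative abundances of the selected taxa.
    """

    mode: str = "neutral"
    n_taxa_pool: int = 983
    n_samples_per_group: int = 10
    dsr_levels: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    richness_per_sample: int = 100
    filter_strength: float = 0.25
    seq_depth: int = 10_000
    abundance_lognormal_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "filtering"):
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if self.richness_per_sample > self.n_taxa_pool:
            raise ValueError("richness_per_sample exceeds n_taxa_pool")
        if self.seq_depth < self.richness_per_sample:
            raise ValueError("seq_depth below richness_per_sample")
        if self.filter_strength <= 0:
            raise ValueError("filter_strength must be positive")


# ---------------------------------------------------------------------------
# Tree and traits
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Simulate a pure-birth (Yule, birth rate 1) tree scaled to unit height.

    Forward-time simulation: the root splits into two lineages at time 0;
    with k lineages the next speciation arrives after Exponential(k) time on
    a uniformly chosen lineage.  After the n-th lineage appears the process
    runs for one further Exponential(n) waiting time before sampling, so
    every tip branch is strictly positive.  All branch lengths are divided
    by the total elapsed time, giving an ultrametric tree of height 1 with
    tips labelled ``OTU_1`` ... ``OTU_n``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(int(seed))
    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    active: list[list] = []  # [node, branch start time]
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append([child, 0.0])
    k = 2
    while k < n_taxa:
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, start = active[i]
        node.edge.length = t - start
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active[i] = [left, t]
        active.append([right, t])
        k += 1
    t += rng.exponential(1.0 / n_taxa)
    for i, (node, start) in enumerate(active, start=1):
        node.edge.length = t - start
        node.taxon = taxa.new_taxon(f"OTU_{i}")
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / t
    tree.seed_node.edge.length = None
    return PhyloTree(tree)


def evolve_niche_traits(tree: PhyloTree, bm_sd: float, seed: int) -> pd.Series:
    """Evolve a Brownian-motion trait down the tree.

    The root value is 0; each child value is its parent's plus
    ``Normal(0, bm_sd^2 * branch_length)``.  Returns one real per tip,
    indexed by tip label.  BM on a tree guarantees phylogenetic signal:
    closely related tips have similar traits.
    """
    if bm_sd <= 0:
        raise ValueError("bm_sd must be positive")
    rng = np.random.default_rng(int(seed))
    values: dict[int, float] = {id(tree.tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if id(node) not in values:  # non-root
            parent_val = values[id(node.parent_node)]
            step = rng.normal(0.0, bm_sd * np.sqrt(node.edge.length))
            values[id(node)] = parent_val + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="trait").loc[list(tree.tip_labels)]


# ---------------------------------------------------------------------------
# Metadata and features
# ---------------------------------------------------------------------------

def _shape_column(spec: ShapeSpec, dsr: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    base = spec.mean(dsr)
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=len(dsr))
    return base


def generate_metadata(spec: AssemblySpec,
                      nutrient_shapes: Mapping[str, ShapeSpec],
                      seed: int) -> SampleMetadata:
    """Generate per-sample metadata with prescribed nutrient-DSR responses.

    Produces ``n_samples_per_group`` samples per DSR level with ids
    ``S001``...; each nutrient column equals its shape's mean at the
    sample's DSR level plus Gaussian noise.
    """
    if not spec.dsr_levels:
        raise ValueError("dsr_levels must be nonempty")
    for name, ss in nutrient_shapes.items():
        ss.validate_against_levels(spec.dsr_levels)
    rng = np.random.default_rng(int(seed))
    dsr = np.repeat(list(spec.dsr_levels), spec.n_samples_per_group)
    ids = [f"S{i + 1:03d}" for i in range(len(dsr))]
    data = pd.DataFrame({"dsr_level": dsr}, index=ids)
    data["group"] = [f"DSR{v}" for v in dsr]
    for name, ss in nutrient_shapes.items():
        data[name] = _shape_column(ss, dsr, rng)
    return SampleMetadata(data, env_vars=tuple(nutrient_shapes))


def generate_response_table(metadata: SampleMetadata,
                            specs: Sequence[ShapeSpec],
                            seed: int) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a samples x features table with known response shapes.

    Returns the feature table (columns ``F001``...) and the ground-truth
    shape label per feature.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    dsr = metadata.dsr_level.to_numpy(dtype=float)
    for ss in specs:
        ss.validate_against_levels(metadata.dsr_level.tolist())
    rng = np.random.default_rng(int(seed))
    cols = {}
    labels = {}
    for j, ss in enumerate(specs, start=1):
        fid = f"F{j:03d}"
        cols[fid] = _shape_column(ss, dsr, rng)
        labels[fid] = ss.shape
    table = pd.DataFrame(cols, index=metadata.data.index)
    return table, pd.Series(labels, name="true_shape")


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def assemble_communities(tree: PhyloTree,
                         traits: pd.Series,
                         metadata: SampleMetadata,
                         env_driver: str | None,
                         spec: AssemblySpec) -> OtuTable:
    """Draw communities from the taxon pool, neutrally or by filtering.

    For each sample, ``richness_per_sample`` taxa are drawn without
    replacement.  Neutral mode draws uniformly.  Filtering mode weights
    taxon ``i`` by ``exp(-(trait_i - scaled_env)^2 / (2 sigma^2))`` where
    ``scaled_env`` is the sample's ``env_driver`` z-scored and mapped onto
    the trait mean/SD, and ``sigma = filter_strength * SD(traits)``.
    Selected taxa receive lognormal relative abundances and a multinomial
    draw of ``seq_depth`` reads.

    Weighted sampling without replacement uses the Gumbel-top-k scheme,
    which is numerically stable for arbitrarily strong filtering: in the
    ``filter_strength -> 0`` limit each sample contains exactly the taxa
    whose traits are nearest its environment value.
    """
    pool = list(tree.tip_labels)
    if spec.n_taxa_pool != len(pool):
        pool = pool[: spec.n_taxa_pool]
        if len(pool) < spec.n_taxa_pool:
            raise ValueError("tree has fewer tips than n_taxa_pool")
    missing = [t for t in pool if t not in traits.index]
    if spec.mode == "filtering" and missing:
        raise ValueError(f"traits missing for taxa: {missing[:5]}")

    if spec.mode == "filtering":
        if env_driver is None or env_driver not in metadata.data.columns:
            raise ValueError(f"env_driver {env_driver!r} not in metadata")
        env = metadata.env(env_driver).to_numpy(dtype=float)
        tr = traits.loc[pool].to_numpy(dtype=float)
        t_mean, t_sd = tr.mean(), tr.std()
        e_sd = env.std()
        z = (env - env.mean()) / e_sd if e_sd > 0 else np.zeros_like(env)
        scaled_env = t_mean + z * (t_sd if t_sd > 0 else 1.0)
        sigma = spec.filter_strength * (t_sd if t_sd > 0 else 1.0)
        trait_arr = tr

    rng = np.random.default_rng(int(spec.seed))
    n_pool = len(pool)
    counts = np.zeros((len(metadata.data), n_pool), dtype=int)
    for k in range(len(metadata.data)):
        if spec.mode == "neutral":
            chosen = rng.choice(n_pool, size=spec.richness_per_sample,
                                replace=False)
        else:
            logw = -((trait_arr - scaled_env[k]) ** 2) / (2.0 * sigma ** 2)
            keys = logw + rng.gumbel(size=n_pool)
            chosen = np.argpartition(-keys, spec.richness_per_sample - 1)[
                : spec.richness_per_sample]
        rel = rng.lognormal(0.0, spec.abundance_lognormal_sd,
                            size=spec.richness_per_sample)
        rel = rel / rel.sum()
        reads = rng.multinomial(spec.seq_depth, rel)
        counts[k, chosen] = reads
    table = pd.DataFrame(counts, index=metadata.data.index, columns=pool)
    return OtuTable(table, is_relative=False)


# ---------------------------------------------------------------------------
# One-call study generator
# ---------------------------------------------------------------------------

#: nutrient response shapes emulating the study's Fig-1-style gradient:
#: sugars/starch peak mid-gradient, fiber/tannin/fat dip there, protein flat.
DEFAULT_NUTRIENT_SHAPES: dict[str, ShapeSpec] = {
    "glucose": ShapeSpec("inverted-U", amplitude=1.0, vertex=5.0, noise_sd=1.0),
    "resistant_starch": ShapeSpec("inverted-U", amplitude=0.8, vertex=5.0,
                                  noise_sd=1.0),
    "fiber": ShapeSpec("U", amplitude=1.0, vertex=5.0, noise_sd=1.0),
    "tannin": ShapeSpec("U", amplitude=0.6, vertex=5.0, noise_sd=1.0),
    "fat": ShapeSpec("U", amplitude=0.5, vertex=5.0, noise_sd=1.0),
    "fos": ShapeSpec("positive", amplitude=0.5, noise_sd=1.0),
    "crude_protein": ShapeSpec("none", noise_sd=1.0),
}


def generate_study(spec: AssemblySpec,
                   bm_sd: float = 1.0,
                   nutrient_shapes: Mapping[str, ShapeSpec] | None = None,
                   env_driver: str = "glucose",
                   ) -> tuple[PhyloTree, pd.Series, SampleMetadata, OtuTable]:
    """Generate a complete synthetic study from one :class:`AssemblySpec`.

    Sub-seeds for the tree, traits, metadata and communities are spawned
    from ``spec.seed`` so the components are independent but jointly
    reproducible.
    """
    if nutrient_shapes is None:
        nutrient_shapes = DEFAULT_NUTRIENT_SHAPES
    ss = np.random.SeedSequence(int(spec.seed))
    s_tree, s_trait, s_meta, s_comm = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4))
    tree = simulate_tree(spec.n_taxa_pool, seed=s_tree)
    traits = evolve_niche_traits(tree, bm_sd=bm_sd, seed=s_trait)
    metadata = generate_metadata(spec, nutrient_shapes, seed=s_meta)
    comm_spec = dataclasses.replace(spec, seed=s_comm)
    table = assemble_communities(tree, traits, metadata, env_driver, comm_spec)
    return tree, traits, metadata, table
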