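"""Forward simulation of per-individual HSC phylogenies with clonal
hematopoiesis, and derived genotype matrices / variant frequency spectra
with known ground truth.

The generative model:

* ``n_lineages`` primary HSC lineages are established by a burst of
  bifurcations inside a short embryonic window and then persist to the
  individual's age, each replenishing by asymmetric division without
  producing further sampled offspring lineages.
* Clonal-hematopoiesis (CH) founding events arrive as a Poisson process
  whose intensity ρ(t) = ch_rate·exp(ch_age_coeff·t) grows with age.  A
  founding event converts one primary lineage into a clade of secondary
  HSCs; the clade's tips *replace* other primary lineages, so the sampled
  tip count stays constant while phylogenetic diversity decays.
* Somatic mutations accrue clock-like along every branch as
  Poisson(mutation_rate × branch length in years); ~17 single-nucleotide
  alterations per lineage per year.

Every mutation on a branch subtending c of the n sampled tips appears in
the cell population at fraction c/n and hence at VAF = c/(2n).  The
ground-truth diversity decay of an individual is the sum, over shared
(non-tip) branches above the detection threshold, of (VAF) × (mutations on
the branch) — identical by construction to the VAF-sum metric computed on
the noise-free spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trees import PhylogenyTree, TreeNode
from .vfs import DEFAULT_VAF_THRESHOLD, VFS, VariantSource

__all__ = [
    "SimulationParams",
    "SimulatedIndividual",
    "simulate_individual",
    "simulate_cohort",
    "calibrated_cohort",
    "true_decay",
]

_MATRIX_AUTO_CELL_LIMIT = 2_000_000


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the HSC cohort generator.

    Defaults: 300 sampled lineages (within the 224–453 per-person range of
    published colony-seq cohorts), 17 mutations/lineage/year, a 0.1-year
    embryonic diversification window, and a CH founding intensity
    ρ(t) = 3e-4·exp(0.084·t) per year whose exponent matches the empirical
    exponential growth of the decay metric with age.  Clade sizes are drawn
    as Beta(1, 9) fractions of the lineage pool (mean 10%), and a new clade's
    internal splits spread over ``clade_spread`` years after founding.
    """

    n_lineages: int = 300
    mutation_rate: float = 17.0
    embryonic_window: float = 0.1
    ch_rate: float = 3e-4
    ch_age_coeff: float = 0.084
    clade_frac_alpha: float = 1.0
    clade_frac_beta: float = 9.0
    clade_spread: float = 1.0
    seed: int = 0
    clade_size_distribution: Callable[[np.random.Generator, int], int] | None = None

    def __post_init__(self) -> None:
        if self.n_lineages < 2:
            raise ValueError("n_lineages must be >= 2")
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be positive")
        if self.ch_rate < 0:
            raise ValueError("ch_rate must be non-negative")


@dataclass
class SimulatedIndividual:
    """One synthetic subject: phylogeny, genotype matrix, VFS, and truth."""

    sample_id: str
    age: float
    tree: PhylogenyTree
    matrix: pd.DataFrame | None
    vfs: VFS
    true_decay: float
    ch_events: list[tuple[float, int]]
    log: list[str] = field(default_factory=list)


def _build_embryonic_caterpillar(
    n: int, window: float, rng: np.random.Generator
) -> tuple[TreeNode, list[TreeNode]]:
    """Strictly binary caterpillar of n tips with split times inside the
    embryonic window (near-zero internal branches, newick-portable)."""
    times = np.sort(rng.uniform(0.0, window, size=n - 1))
    root = TreeNode(0.0, times[0])
    cur = root
    tips: list[TreeNode] = []
    for k in range(n - 1):
        tip = TreeNode(times[k], np.nan, label=f"L{k}")
        cur.add_child(tip)
        tips.append(tip)
        if k < n - 2:
            nxt = TreeNode(times[k], times[k + 1])
            cur.add_child(nxt)
            cur = nxt
        else:
            last = TreeNode(times[k], np.nan, label=f"L{n - 1}")
            cur.add_child(last)
            tips.append(last)
    return root, tips


def _prune_tip(root: TreeNode, tip: TreeNode) -> TreeNode:
    """Remove a tip and splice its parent's remaining edge; returns the
    (possibly new) root."""
    parent = tip.parent
    parent.children.remove(tip)
    only = parent.children[0]
    only.t_start = parent.t_start
    only.parent = parent.parent
    if parent.parent is None:
        return only
    parent.parent.children[parent.parent.children.index(parent)] = only
    return root


def _ch_event_times(
    age: float, window: float, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson founding times on (window, age) with intensity
    ρ(t) = ch_rate·exp(ch_age_coeff·t), by inversion."""
    if params.ch_rate == 0 or age <= window:
        return np.array([])
    c = params.ch_age_coeff
    if c > 0:
        total = params.ch_rate * (np.exp(c * age) - np.exp(c * window)) / c
    else:
        total = params.ch_rate * (age - window)
    n_events = rng.poisson(total)
    if n_events == 0:
        return np.array([])
    u = rng.uniform(size=n_events)
    if c > 0:
        lo, hi = np.exp(c * window), np.exp(c * age)
        times = np.log(lo + u * (hi - lo)) / c
    else:
        times = window + u * (age - window)
    return np.sort(times)


def _draw_clade_size(params: SimulationParams, rng: np.random.Generator) -> int:
    if params.clade_size_distribution is not None:
        return int(params.clade_size_distribution(rng, params.n_lineages))
    frac = rng.beta(params.clade_frac_alpha, params.clade_frac_beta)
    return max(2, int(round(frac * params.n_lineages)))


def _attach_clade(
    founder: TreeNode, t_f: float, size: int, age: float,
    spread: float, event_idx: int,
) -> TreeNode:
    """Convert a primary tip into a CH clade of ``size`` tips founded at
    ``t_f``; returns the clade root (which keeps the founder's edge start)."""
    clade_root = TreeNode(founder.t_start, t_f, parent=founder.parent)
    founder.parent.children[founder.parent.children.index(founder)] = clade_root
    spread_eff = min(spread, 0.9 * (age - t_f))
    if spread_eff <= 0 or size < 3:
        split_ts = t_f + 1e-9 * np.arange(size - 1)
    else:
        split_ts = t_f + spread_eff * np.arange(size - 1) / max(size - 2, 1)
    split_ts = np.minimum(split_ts, age - 1e-12)
    cur = clade_root
    cur.t_end = split_ts[0]
    for k in range(size - 1):
        cur.add_child(TreeNode(split_ts[k], age, label=f"S{event_idx}_{k}"))
        if k < size - 2:
            nxt = TreeNode(split_ts[k], split_ts[k + 1])
            cur.add_child(nxt)
            cur = nxt
        else:
            cur.add_child(TreeNode(split_ts[k], age, label=f"S{event_idx}_{size - 1}"))
    return clade_root


def _place_mutations(
    tree: PhylogenyTree, rate: float, rng: np.random.Generator,
    tip_mutations: bool,
) -> tuple[list[TreeNode], np.ndarray]:
    """Draw Poisson mutation counts per edge and assign variant ids.

    Counts are drawn for every edge; ids for tip-private variants are only
    materialised when ``tip_mutations`` is set (they sit below the VAF
    threshold by construction and can be omitted for speed).
    """
    nodes = list(tree.nodes())
    lengths = np.array([n.length for n in nodes], dtype=float)
    counts = rng.poisson(rate * np.clip(lengths, 0.0, None))
    for idx, node in enumerate(nodes):
        k = int(counts[idx])
        if k == 0 or (node.is_tip and not tip_mutations):
            node.mutations = []
            continue
        node.mutations = [f"e{idx}m{j}" for j in range(k)]
    return nodes, counts


def true_decay(tree: PhylogenyTree, threshold: float = DEFAULT_VAF_THRESHOLD) -> float:
    """Ground-truth diversity decay Σ f_i·n_i over shared branches.

    Sums, over non-tip branches whose carrier fraction f satisfies
    VAF = f/2 >= threshold, the product of that VAF and the number of
    mutations on the branch.  Mirrors the VAF-sum metric on the noise-free
    spectrum exactly (tip variants sit below the threshold whenever
    n_lineages >= 1/(2·threshold)).
    """
    counts = tree.tip_counts()
    n = tree.n_tips
    total = 0.0
    for node in tree.nodes():
        if node.is_tip:
            continue
        vaf = 0.5 * counts[node] / n
        if vaf >= threshold:
            total += vaf * len(node.mutations)
    return total


def _vfs_from_tree(
    tree: PhylogenyTree, nodes: list[TreeNode], counts: np.ndarray,
    sample_id: str, age: float, tip_mutations: bool,
) -> VFS:
    tip_count = tree.tip_counts()
    n = tree.n_tips
    carriers = np.array([tip_count[nd] for nd in nodes], dtype=float)
    emit = counts > 0
    if not tip_mutations:
        is_tip = np.array([nd.is_tip for nd in nodes])
        emit &= ~is_tip
    reps = counts[emit].astype(int)
    vafs = np.repeat(0.5 * carriers[emit] / n, reps)
    mut_cells = np.repeat(carriers[emit], reps)
    ids = np.concatenate(
        [np.array(nodes[i].mutations, dtype=object)
         for i in np.flatnonzero(emit)]
    ) if emit.any() else np.array([], dtype=object)
    return VFS(
        sample_id=sample_id,
        variant_ids=ids,
        mutant=mut_cells,
        nonmutant=n - mut_cells,
        vaf=vafs,
        source=np.array([VariantSource.COLONY.value] * len(ids), dtype=object),
        age=age,
    )


def _matrix_from_tree(tree: PhylogenyTree, vfs: VFS) -> pd.DataFrame:
    tips = tree.tips()
    tip_index = {t.label: i for i, t in enumerate(tips)}
    data = np.zeros((len(tips), len(vfs)), dtype=np.int8)
    col = 0
    for node in tree.nodes():
        k = len(node.mutations)
        if k == 0:
            continue
        rows = [tip_index[lab] for lab in tree.tip_labels_under(node)]
        data[np.ix_(rows, range(col, col + k))] = 1
        col += k
    columns = []
    for node in tree.nodes():
        columns.extend(node.mutations)
    df = pd.DataFrame(data, index=[t.label for t in tips], columns=columns)
    return df[list(vfs.variant_ids)]


def simulate_individual(
    age: float,
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
    forced_ch_events: Sequence[tuple[float, int]] | None = None,
    tip_mutations: bool = True,
    build_matrix: "bool | str" = "auto",
) -> SimulatedIndividual:
    """Simulate one individual's HSC phylogeny, genotype matrix, and VFS.

    ``forced_ch_events`` replaces the stochastic founding process with an
    explicit list of (founding time, clade size) pairs.  ``build_matrix``
    may be True, False or "auto" (build only when lineages × variants stays
    under two million cells).  Deterministic given the generator state.
    """
    params = params or SimulationParams()
    if age <= 0:
        raise ValueError("age must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.n_lineages < int(np.ceil(1.0 / (2 * DEFAULT_VAF_THRESHOLD))):
        warnings.warn(
            f"n_lineages={params.n_lineages} < 1/(2*threshold): single-tip "
            "variants will not sit below the default 1% VAF threshold",
            stacklevel=2,
        )
    n = params.n_lineages
    window = min(params.embryonic_window, 0.5 * age)
    root, primary = _build_embryonic_caterpillar(n, window, rng)
    for tip in primary:
        tip.t_end = age
    pool = list(primary)
    log: list[str] = []
    ch_events: list[tuple[float, int]] = []
    if forced_ch_events is not None:
        events = [(float(t), int(s)) for t, s in forced_ch_events]
    else:
        events = [(float(t), None) for t in _ch_event_times(age, window, params, rng)]
    for event_idx, (t_f, forced_size) in enumerate(sorted(events)):
        if len(pool) < 3:
            log.append(f"event at t={t_f:.3g} skipped: primary pool exhausted")
            continue
        size = forced_size
        if size is None:
            size = _draw_clade_size(params, rng)
            tries = 0
            while size > len(pool) and tries < 20:
                log.append(f"clade size {size} exceeds {len(pool)} available "
                           "primary lineages; resampled")
                size = _draw_clade_size(params, rng)
                tries += 1
            if size > len(pool):
                log.append(f"event at t={t_f:.3g} skipped after resampling")
                continue
        elif size > len(pool):
            raise ValueError(
                f"forced clade size {size} exceeds {len(pool)} available "
                "primary lineages"
            )
        founder_idx = int(rng.integers(len(pool)))
        founder = pool.pop(founder_idx)
        replace_idx = rng.choice(len(pool), size=size - 1, replace=False)
        for i in sorted(replace_idx, reverse=True):
            victim = pool.pop(int(i))
            root = _prune_tip(root, victim)
        _attach_clade(founder, t_f, size, age, params.clade_spread, event_idx)
        ch_events.append((t_f, size))
    tree = PhylogenyTree(root, age=age)
    nodes, counts = _place_mutations(tree, params.mutation_rate, rng, tip_mutations)
    sid = sample_id or f"sim_age{age:g}"
    vfs = _vfs_from_tree(tree, nodes, counts, sid, age, tip_mutations)
    decay = true_decay(tree)
    matrix = None
    want_matrix = build_matrix is True or (
        build_matrix == "auto"
        and tip_mutations
        and n * len(vfs) <= _MATRIX_AUTO_CELL_LIMIT
    )
    if want_matrix:
        matrix = _matrix_from_tree(tree, vfs)
    return SimulatedIndividual(
        sample_id=sid, age=age, tree=tree, matrix=matrix, vfs=vfs,
        true_decay=decay, ch_events=ch_events, log=log,
    )


def simulate_cohort(
    ages: Sequence[float],
    params: SimulationParams | None = None,
    seed: int | None = None,
    tip_mutations: bool = True,
    build_matrix: "bool | str" = "auto",
) -> list[SimulatedIndividual]:
    """Simulate a cohort with independent per-individual substreams."""
    ages = list(ages)
    if not ages:
        raise ValueError("cohort requires at least one age")
    params = params or SimulationParams()
    root_seed = params.seed if seed is None else seed
    streams = np.random.SeedSequence(root_seed).spawn(len(ages))
    out = []
    for i, (age, ss) in enumerate(zip(ages, streams)):
        out.append(
            simulate_individual(
                age, params, rng=np.random.default_rng(ss),
                sample_id=f"sim{i}_age{age:g}",
                tip_mutations=tip_mutations, build_matrix=build_matrix,
            )
        )
    return out


def calibrated_cohort(
    a: float,
    b: float,
    ages: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Draw (age, λ) pairs directly from the exponential age model.

    λ_i = exp(a + b·age_i + ε_i), ε ~ N(0, noise_sigma²).  Bypasses tree
    simulation for fast, exactly calibrated model-fitting tests.
    """
    if b <= 0:
        raise ValueError("slope b must be positive")
    ages = np.asarray(list(ages), dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=len(ages)) if noise_sigma > 0 \
        else np.zeros(len(ages))
    lams = np.exp(a + b * ages + noise)
    return list(zip(ages.tolist(), lams.tolist()))
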