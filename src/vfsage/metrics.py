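"""Diversity-decay metrics and classical population-diversity statistics.

The central quantity is the VAF-sum decay metric λ: after removing
tip-lineage variants (VAF < 1%), λ = Σ_k μ_k where μ_k is the VAF of
variant k.  Because clonal expansions place shared variants at elevated
frequencies, λ grows with the loss of HSC phylogenetic diversity and needs
neither a phylogeny nor clonal-structure inference.

The cluster-based metric γ = Σ_i f_i·n_i (cluster mean frequency × member
count) is the same quantity computed through an explicit subclonal
clustering; when cluster means are exact member means and nothing is
excluded, γ equals λ identically.

For comparison, classical statistics are provided: Nei's π, Tajima's D and
Fay & Wu's H on binary somatic alignments (reference state = ancestral, so
every variant allele is derived), Hill numbers on cluster frequencies, a
lineages-through-time Shannon diversity on the phylogeny, and the largest
VAF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSet, cluster_vafs
from .trees import PhylogenyTree
from .vfs import DEFAULT_VAF_THRESHOLD, VFS, filter_tip_variants

__all__ = [
    "MetricReport",
    "lambda_metric",
    "gamma_metric",
    "pi_metric",
    "pi_from_matrix",
    "tajimas_d",
    "fay_wu_h",
    "hill_number",
    "hill_numbers",
    "shannon_ltt",
    "largest_vaf",
    "metric_report",
    "metric_correlations",
]


def lambda_metric(vfs: VFS, threshold: float = DEFAULT_VAF_THRESHOLD) -> float:
    """Sum of VAFs over variants surviving the tip-variant threshold.

    Returns 0 for an empty post-filter spectrum.
    """
    filtered = filter_tip_variants(vfs, threshold)
    return float(filtered.vaf.sum())


def gamma_metric(clusters: ClusterSet) -> float:
    """Cluster-based decay metric: Σ mean frequency × size over non-excluded
    clusters."""
    return float(sum(c.mean_vaf * c.size for c in clusters.included))


def largest_vaf(vfs: VFS) -> float:
    """Maximum VAF among retained variants; a proxy for the single most
    expanded clone."""
    if len(vfs) == 0:
        raise ValueError("largest VAF undefined for an empty spectrum")
    return float(vfs.vaf.max())


# ---------------------------------------------------------------------------
# Nei's pi
# ---------------------------------------------------------------------------

def pi_metric(vfs: VFS, n_lineages: int) -> float:
    """Within-population average heterozygosity summed over variant sites.

    The lineage-level carrier fraction of a heterozygous somatic variant is
    p = 2·VAF (colony-seq VAFs are half cell fractions); per site the
    unbiased estimator 2·p·(1−p)·n/(n−1) is used and summed over sites.
    """
    if n_lineages < 2:
        raise ValueError("pi requires at least two lineages")
    if len(vfs) == 0:
        return 0.0
    p = np.minimum(2.0 * vfs.vaf, 1.0)
    n = n_lineages
    return float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1)))


def _site_counts(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele count and genotyped-lineage count with
    per-site (pairwise) deletion of missing entries."""
    values = matrix.to_numpy(dtype=float)
    derived = np.nansum(values == 1, axis=0).astype(float)
    called = np.sum(~np.isnan(values), axis=0).astype(float)
    return derived, called


def pi_from_matrix(matrix: pd.DataFrame) -> float:
    """π from a binary genotype matrix: mean pairwise difference summed over
    sites, with per-site deletion of missing entries.

    Equals ``pi_metric`` on the matrix-derived VFS when no data are missing.
    """
    derived, called = _site_counts(matrix)
    usable = called >= 2
    x, n = derived[usable], called[usable]
    # x·(n−x) differing pairs out of C(n,2) at each site
    return float(np.sum(2.0 * x * (n - x) / (n * (n - 1))))


# ---------------------------------------------------------------------------
# Tajima's D and Fay & Wu's H on binary somatic alignments
# ---------------------------------------------------------------------------

def _check_binary_matrix(matrix: pd.DataFrame, min_lineages: int) -> tuple[np.ndarray, np.ndarray]:
    n_rows = matrix.shape[0]
    if n_rows < min_lineages:
        raise ValueError(f"at least {min_lineages} lineages required, got {n_rows}")
    derived, called = _site_counts(matrix)
    seg = (derived >= 1) & (derived < called) & (called >= 2)
    if not seg.any():
        raise ValueError("statistic undefined: no segregating sites")
    return derived[seg], called[seg]


def tajimas_d(matrix: pd.DataFrame) -> float:
    """Tajima's D on a binary alignment (rows = lineages, columns = sites).

    θ_π comes from per-site pairwise differences, θ_W from the segregating
    site count and the harmonic number a1; the difference is normalised by
    Tajima's variance estimate computed from the nominal lineage count.
    """
    x, n_site = _check_binary_matrix(matrix, min_lineages=4)
    n = matrix.shape[0]
    s = len(x)
    theta_pi = float(np.sum(2.0 * x * (n_site - x) / (n_site * (n_site - 1))))
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    theta_w = s / a1
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        raise ValueError("statistic undefined: zero variance estimate")
    return float((theta_pi - theta_w) / np.sqrt(var))


def fay_wu_h(matrix: pd.DataFrame) -> float:
    """Fay & Wu's (unnormalised) H = θ_π − θ_H on a binary alignment.

    The reference state is ancestral by the somatic convention (all variant
    alleles are derived), so no outgroup polarisation is needed.  θ_H
    weights by squared derived-allele count: Σ 2·x²/(n(n−1)) per site.
    """
    x, n_site = _check_binary_matrix(matrix, min_lineages=4)
    theta_pi = float(np.sum(2.0 * x * (n_site - x) / (n_site * (n_site - 1))))
    theta_h = float(np.sum(2.0 * x**2 / (n_site * (n_site - 1))))
    return theta_pi - theta_h


# ---------------------------------------------------------------------------
# Hill numbers on cluster frequencies
# ---------------------------------------------------------------------------

def hill_number(clusters: ClusterSet, q: int) -> float:
    """Hill number of order q on normalised cluster mean frequencies.

    q=0 is cluster richness, q=1 the exponential of Shannon entropy, q=2 the
    inverse Simpson concentration; the family is non-increasing in q.
    """
    freqs = np.array([c.mean_vaf for c in clusters.included], dtype=float)
    if freqs.size == 0:
        raise ValueError("Hill numbers undefined for an empty cluster set")
    if freqs.sum() <= 0:
        raise ValueError("Hill numbers undefined: zero total frequency")
    p = freqs / freqs.sum()
    if q == 0:
        return float(len(p))
    if q == 1:
        p = p[p > 0]
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2:
        return float(1.0 / np.sum(p**2))
    raise ValueError("q must be 0, 1 or 2")


def hill_numbers(clusters: ClusterSet) -> dict[int, float]:
    return {q: hill_number(clusters, q) for q in (0, 1, 2)}


# ---------------------------------------------------------------------------
# Lineages-through-time Shannon diversity
# ---------------------------------------------------------------------------

def _ltt_changepoint(
    splits: np.ndarray, age: float,
    horizon: float = 5.0, n_grid: int = 512,
) -> float | None:
    """Plateau changepoint of the log lineages-through-time curve.

    log N(t) is evaluated on a uniform time grid (split events are too
    unevenly spaced for stable local differences) and the cut is the grid
    point with the most negative discrete second difference — the sharpest
    deceleration of diversification.  Candidates are restricted to the
    first ``horizon`` years, where the embryonic plateau lives; later
    bursts are clonal expansions, not the end of embryogenesis.
    """
    grid = np.linspace(0.0, age, n_grid)
    counts = 1 + np.searchsorted(splits, grid, side="right")
    log_n = np.log(counts.astype(float))
    d2 = log_n[2:] - 2 * log_n[1:-1] + log_n[:-2]
    interior = grid[1:-1]
    allowed = (d2 < 0) & (interior <= horizon)
    if not allowed.any():
        return None
    candidates = np.flatnonzero(allowed)
    bend = candidates[np.argmin(d2[candidates])]
    # The plateau starts just after the sharpest bend: cut at the right
    # neighbour of the grid point with maximal negative curvature.
    return float(grid[min(bend + 2, n_grid - 1)])


def shannon_ltt(tree: PhylogenyTree, fallback_time: float = 2.5) -> float:
    """Shannon diversity of the clades founded before the LTT plateau.

    The lineages-through-time curve of an HSC phylogeny rises steeply during
    embryonic diversification and then plateaus (typically at two to three
    years of age).  The plateau changepoint is the most negative discrete
    second difference of log lineage count over a uniform time grid,
    restricted to early life (see :func:`_ltt_changepoint`); if no such
    deceleration exists the cut falls back to ``fallback_time`` (clamped
    inside the tree span).  The tree is cut at that time and −Σ c_i·ln c_i
    is returned over the tip fractions c_i of the crossing lineages.
    """
    n_tips = tree.n_tips
    if n_tips < 2:
        raise ValueError("Shannon LTT diversity requires at least 2 tips")
    cut = _ltt_changepoint(tree.split_times(), tree.age)
    if cut is None:
        cut = fallback_time
    if not 0 < cut < tree.age:
        cut = tree.age / 2.0
    # Evaluate membership just after the cut so splits at the cut time count.
    eps = min(1e-9, (tree.age - cut) / 2.0)
    clades = tree.lineages_at(cut + eps)
    counts_map = tree.tip_counts()
    fracs = np.array([counts_map[c] / n_tips for c in clades], dtype=float)
    return float(-np.sum(fracs * np.log(fracs)))


# ---------------------------------------------------------------------------
# Per-individual report and cross-metric regression
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """All decay/diversity statistics for one individual.

    Fields requiring inputs that were not supplied (a genotype matrix for
    D/H, a tree for the LTT Shannon index) are ``None``.
    """

    sample_id: str
    age: float | None
    lambda_value: float
    gamma_value: float | None = None
    pi_value: float | None = None
    tajimas_d: float | None = None
    fay_wu_h: float | None = None
    hill_q0: float | None = None
    hill_q1: float | None = None
    hill_q2: float | None = None
    shannon_ltt: float | None = None
    largest_vaf: float | None = None


def metric_report(
    vfs: VFS,
    matrix: pd.DataFrame | None = None,
    tree: PhylogenyTree | None = None,
    clusters: ClusterSet | None = None,
    threshold: float = DEFAULT_VAF_THRESHOLD,
    n_lineages: int | None = None,
    seed: int = 0,
) -> MetricReport:
    """Compute every available metric for one individual's inputs."""
    filtered = filter_tip_variants(vfs, threshold)
    lam = float(filtered.vaf.sum())
    if clusters is None and len(filtered) >= 1:
        clusters = cluster_vafs(filtered, seed=seed)
    gamma = gamma_metric(clusters) if clusters is not None else None
    hills = {}
    if clusters is not None and clusters.included:
        hills = hill_numbers(clusters)
    if n_lineages is None and matrix is not None:
        n_lineages = matrix.shape[0]
    pi_val = pi_metric(filtered, n_lineages) if n_lineages is not None else None
    d_val = h_val = None
    if matrix is not None and matrix.shape[0] >= 4:
        try:
            d_val = tajimas_d(matrix)
            h_val = fay_wu_h(matrix)
        except ValueError:
            pass  # no segregating sites: statistics undefined for this sample
    shd = shannon_ltt(tree) if tree is not None else None
    return MetricReport(
        sample_id=vfs.sample_id,
        age=vfs.age,
        lambda_value=lam,
        gamma_value=gamma,
        pi_value=pi_val,
        tajimas_d=d_val,
        fay_wu_h=h_val,
        hill_q0=hills.get(0),
        hill_q1=hills.get(1),
        hill_q2=hills.get(2),
        shannon_ltt=shd,
        largest_vaf=largest_vaf(filtered) if len(filtered) else None,
    )


_COMPARISON_FIELDS = [
    "gamma_value", "pi_value", "tajimas_d", "fay_wu_h",
    "hill_q0", "hill_q1", "hill_q2", "shannon_ltt", "largest_vaf",
]


def metric_correlations(
    reports: Sequence[MetricReport],
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ordinary-least-squares R² of each comparison metric against λ.

    One row per metric with columns ``metric``, ``r_squared``, ``n``, and
    ``note``; a metric that is constant across individuals (or observed in
    fewer than three) has an undefined R², reported as NaN with a note.
    """
    if len(reports) < 3:
        raise ValueError("regression requires at least 3 individuals")
    lam = np.array([r.lambda_value for r in reports], dtype=float)
    rows = []
    for name in (metrics if metrics is not None else _COMPARISON_FIELDS):
        values = np.array(
            [getattr(r, name) if getattr(r, name) is not None else np.nan
             for r in reports], dtype=float)
        ok = ~np.isnan(values)
        note = ""
        if ok.sum() < 3:
            r2 = np.nan
            note = "fewer than 3 observations"
        elif np.ptp(values[ok]) == 0 or np.ptp(lam[ok]) == 0:
            r2 = np.nan
            note = "constant vector: R² undefined"
        else:
            res = stats.linregress(lam[ok], values[ok])
            r2 = res.rvalue**2
        rows.append({"metric": name, "r_squared": r2, "n": int(ok.sum()),
                     "note": note})
    return pd.DataFrame(rows)
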