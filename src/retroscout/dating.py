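"""Retrocopy-parent divergence counting, molecular-clock dating, and
bootstrap clustering of variant presence profiles.

A retrocopy is a molecular fossil of its parent's mRNA at insertion time:
substitutions between the two, divided by aligned length, give a per-site
divergence d = S/L which the clock converts to years as
``age = d / (k_lin * mu) * g`` with mu in substitutions/site/generation and
g the generation time in years. ``k_lin`` is 1 when all divergence is
attributed to the retrocopy lineage (the default) and 2 when both lineages
are assumed to drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode

from Bio import Align

# clock defaults: horse pedigree mutation rate and generation time
DEFAULT_MU = 7.24e-9  # substitutions/site/generation
DEFAULT_GENERATION_TIME = 8.0  # years
DEFAULT_K_LIN = 1


@dataclass(frozen=True)
class DivergenceRecord:
    pair_id: str
    substitutions: int
    aligned_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.substitutions <= self.aligned_length:
            raise ValueError("require 0 <= S <= L")

    @property
    def divergence(self) -> float:
        return self.substitutions / self.aligned_length


@dataclass(frozen=True)
class AgeEstimate:
    record: DivergenceRecord
    mu: float = DEFAULT_MU
    generation_time: float = DEFAULT_GENERATION_TIME
    k_lin: int = DEFAULT_K_LIN

    @property
    def age_years(self) -> float:
        d = self.record.divergence
        return d / (self.k_lin * self.mu) * self.generation_time

    @property
    def age_mya(self) -> float:
        return self.age_years / 1e6


# ---------------------------------------------------------------------------
# Divergence counting
# ---------------------------------------------------------------------------

_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=-1,
    open_gap_score=-2, extend_gap_score=-2,
)


def count_divergence(
    retro_seq: str,
    parent_seq: str,
    pair_id: str = "pair",
    alignment: Sequence[tuple[str, str]] | None = None,
) -> DivergenceRecord:
    """Substitutions and ungapped length between retrocopy and parent.

    Accepts a precomputed pairwise alignment as two equal-length gapped
    strings; otherwise performs Needleman-Wunsch (match 1 / mismatch -1 /
    gap -2). Gap columns count toward neither S nor L, so the measure is
    symmetric in its two inputs.
    """
    if alignment is not None:
        a, b = alignment
    else:
        if not retro_seq or not parent_seq:
            raise ValueError("sequences must be non-empty")
        aln = _ALIGNER.align(retro_seq, parent_seq)[0]
        a, b = str(aln[0]), str(aln[1])
    if len(a) != len(b):
        raise ValueError("aligned strings differ in length")
    S = L = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        L += 1
        if x != y:
            S += 1
    if L == 0:
        raise ValueError("alignment has zero ungapped columns")
    return DivergenceRecord(pair_id, S, L)


def estimate_age(
    record: DivergenceRecord,
    mu: float = DEFAULT_MU,
    generation_time: float = DEFAULT_GENERATION_TIME,
    k_lin: int = DEFAULT_K_LIN,
) -> AgeEstimate:
    if mu <= 0 or generation_time <= 0:
        raise ValueError("mu and generation_time must be > 0")
    if k_lin not in (1, 2):
        raise ValueError("k_lin must be 1 or 2")
    return AgeEstimate(record, mu, generation_time, k_lin)


def aggregate_ages(
    estimates: Sequence[AgeEstimate],
) -> dict[str, float | tuple[float, float] | None]:
    """Mean, Student-t 95% CI and range of per-haplotype age estimates."""
    if not estimates:
        raise ValueError("no estimates to aggregate")
    ages = np.array([e.age_years for e in estimates], dtype=float)
    mean = float(ages.mean())
    out: dict = {"mean": mean, "range": (float(ages.min()), float(ages.max())),
                 "n": len(ages)}
    if len(ages) >= 2:
        se = ages.std(ddof=1) / math.sqrt(len(ages))
        if se == 0:
            out["ci95"] = (mean, mean)
        else:
            tq = stats.t.ppf(0.975, len(ages) - 1)
            out["ci95"] = (mean - tq * se, mean + tq * se)
    else:
        out["ci95"] = None
    return out


# ---------------------------------------------------------------------------
# Variant-profile clustering with bootstrap support
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    tree: TreeNode  # Newick-serializable; internal node names = support
    support: dict[frozenset[str], float]  # leaf set -> bootstrap fraction
    linkage: np.ndarray
    labels: tuple[str, ...]

    def newick(self) -> str:
        return str(self.tree).strip()


def _clades_from_linkage(Z: np.ndarray, labels: Sequence[str]) -> set[frozenset[str]]:
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    clades: set[frozenset[str]] = set()
    for i, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        if 1 < len(merged) < n:
            clades.add(merged)
    return clades


def cluster_profiles(
    matrix: Mapping[str, Sequence[int]] | "np.ndarray",
    labels: Sequence[str] | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> ClusterResult:
    """Euclidean average-linkage clustering with ordinary bootstrap support.

    Rows are sequences (parent genes and retrocopies), columns variant
    sites, entries 0/1 allele presence. Support of an internal node is the
    fraction of column-resampled replicates whose tree contains the same
    leaf set. Deterministic for a fixed seed.
    """
    if isinstance(matrix, Mapping):
        labels = list(matrix)
        X = np.asarray([matrix[k] for k in labels], dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [f"row{i}" for i in range(X.shape[0])]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows to cluster")
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    if np.all(pdist(X) == 0):
        raise ValueError("constant matrix: all pairwise distances are zero")
    # row order must not matter: cluster a canonically sorted copy
    order = np.argsort(np.array(labels, dtype=object))
    labels_s = [labels[i] for i in order]
    Xs = X[order]
    Z = hierarchy.linkage(Xs, method="average", metric="euclidean")
    ref_clades = _clades_from_linkage(Z, labels_s)
    rng = np.random.default_rng(seed)
    counts = {c: 0 for c in ref_clades}
    ncol = Xs.shape[1]
    for _ in range(n_bootstrap):
        cols = rng.integers(0, ncol, size=ncol)
        Xb = Xs[:, cols]
        if np.all(pdist(Xb) == 0):
            continue
        Zb = hierarchy.linkage(Xb, method="average", metric="euclidean")
        boot = _clades_from_linkage(Zb, labels_s)
        for c in ref_clades & boot:
            counts[c] += 1
    support = {c: counts[c] / n_bootstrap for c in ref_clades}
    tree = TreeNode.from_linkage_matrix(Z, labels_s)
    for node in tree.non_tips():
        leafset = frozenset(t.name for t in node.tips())
        if leafset in support:
            node.name = f"{support[leafset]:.2f}"
    return ClusterResult(tree, support, Z, tuple(labels_s))
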