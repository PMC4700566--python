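"""Allele frequencies, Nei distance, UPGMA trees, polymorphism and Evanno ΔK.

Genetic dissimilarity between groups (accessions or populations) is Nei's
(1972) standard distance D = -ln(J_xy / sqrt(J_x * J_y)) computed over
shared markers; trees are built by UPGMA with a deterministic smallest-label
tie-break and serialized as Newick.  ΔK follows Evanno et al. (2005): the
absolute second difference of structure-run log-likelihoods across K,
normalized by the replicate standard deviation at K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "allele_freqs",
    "nei_distance",
    "nei_distance_matrix",
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "upgma",
    "cut_clusters",
    "polymorphism_rate",
    "evanno_delta_k",
]


@dataclass(frozen=True)
class GenotypePanel:
    """A diversity panel: accessions x markers.

    ``calls`` holds dosages as float (codominant: 0/1/2 copies of the
    alternate allele; dominant: 0/1 band presence) with ``nan`` for missing.
    ``marker_ploidy`` is 2 for codominant dosage markers and 1 for dominant
    band states, used as the allele-count denominator.
    """

    accessions: tuple[str, ...]
    markers: tuple[str, ...]
    calls: np.ndarray
    marker_ploidy: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.accessions), len(self.markers)):
            raise ValueError("calls matrix does not match accession/marker lists")
        if len(self.accessions) != len(set(self.accessions)):
            raise ValueError("duplicate accession codes")
        if self.marker_ploidy.shape != (len(self.markers),):
            raise ValueError("marker_ploidy must have one entry per marker")


def allele_freqs(
    panel: GenotypePanel, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Alternate-allele (or band-presence) frequency per group per marker.

    Codominant markers: dosage sum / (2 * n non-missing); dominant markers:
    presence count / n non-missing.  A marker with no data in a group gets
    ``nan`` (flagged absent).  Rows are groups, columns markers; a parallel
    ``n_<group>`` attribute is not kept — sample sizes are returned in the
    DataFrame ``attrs['n_used']``.
    """
    groups = sorted(set(grouping.values()))
    acc_index = {a: i for i, a in enumerate(panel.accessions)}
    freqs = np.full((len(groups), len(panel.markers)), np.nan)
    n_used = np.zeros((len(groups), len(panel.markers)), dtype=int)
    for gi, g in enumerate(groups):
        rows = [acc_index[a] for a, grp in grouping.items() if grp == g]
        if not rows:
            raise ValueError(f"empty group {g!r}")
        sub = panel.calls[rows]
        n = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            f = np.nansum(sub, axis=0) / (panel.marker_ploidy * n)
        f[n == 0] = np.nan
        freqs[gi] = f
        n_used[gi] = n
    out = pd.DataFrame(freqs, index=groups, columns=panel.markers)
    out.attrs["n_used"] = pd.DataFrame(n_used, index=groups, columns=panel.markers)
    return out


def _identity_sums(px: np.ndarray, py: np.ndarray) -> tuple[float, float, float]:
    """Mean single-locus identities J_xy, J_x, J_y over shared markers.

    Markers are biallelic/two-state: the allele-frequency vector at a locus
    is (p, 1-p), so sum_a x_a y_a = px*py + (1-px)*(1-py).
    """
    shared = ~np.isnan(px) & ~np.isnan(py)
    if not np.any(shared):
        raise ValueError("no shared markers with data in both groups")
    x, y = px[shared], py[shared]
    j_xy = float(np.mean(x * y + (1 - x) * (1 - y)))
    j_x = float(np.mean(x * x + (1 - x) * (1 - x)))
    j_y = float(np.mean(y * y + (1 - y) * (1 - y)))
    return j_xy, j_x, j_y


def nei_distance(px: np.ndarray, py: np.ndarray) -> float:
    """Nei (1972) standard genetic distance between two frequency rows.

    D = -ln(J_xy / sqrt(J_x * J_y)); markers missing in either group are
    excluded from all three means.  Complete non-identity (J_xy = 0) yields
    the +infinity sentinel.
    """
    j_xy, j_x, j_y = _identity_sums(np.asarray(px, float), np.asarray(py, float))
    if j_xy == 0.0:
        return math.inf
    return -math.log(j_xy / math.sqrt(j_x * j_y))


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.array_equal(v[finite], v.T[finite.T]):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(v[finite] < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)


def nei_distance_matrix(freqs: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Nei distances between the rows of a frequency table."""
    labels = tuple(freqs.index)
    p = freqs.to_numpy(float)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(p[i], p[j])
    return DistanceMatrix(labels, d)


@dataclass
class TreeNode:
    name: str | None
    height: float
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return [l for c in self.children for l in c.leaves()]

    def newick(self) -> str:
        return self._newick_rec(parent_height=None) + ";"

    def _newick_rec(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            body = "(" + ",".join(
                c._newick_rec(self.height) for c in self.children
            ) + ")"
        if parent_height is None:
            return body
        return f"{body}:{_fmt(parent_height - self.height)}"


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class Tree:
    """UPGMA result: rooted binary ultrametric tree plus the merge history.

    ``linkage`` is a scipy-compatible (n-1, 4) matrix (child1, child2,
    merge distance, cluster size) enabling cophenetic checks and k-cluster
    cuts.
    """

    root: TreeNode
    labels: tuple[str, ...]
    linkage: np.ndarray

    def newick(self) -> str:
        return self.root.newick()

    def cophenetic(self) -> np.ndarray:
        """Pairwise cophenetic distances (twice the merge height)."""
        n = len(self.labels)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        d = np.zeros((n, n))
        for k, (a, b, dist, _) in enumerate(self.linkage):
            ma, mb = members.pop(int(a)), members.pop(int(b))
            for i in ma:
                for j in mb:
                    d[i, j] = d[j, i] = dist
            members[n + k] = ma + mb
        return d


def upgma(dist: DistanceMatrix) -> Tree:
    """UPGMA agglomeration with deterministic smallest-label tie-breaking.

    The closest pair of clusters is merged at node height d/2; distances to
    the merged cluster are size-weighted averages.  Among equally close
    pairs the pair whose smallest member labels sort first (as strings)
    wins, making the tree invariant to input order.  Infinite distances are
    refused: cap them explicitly (e.g. replace +inf with a finite ceiling)
    before tree building.
    """
    if dist.n < 2:
        raise ValueError("need at least two taxa")
    if not np.all(np.isfinite(dist.values)):
        raise ValueError(
            "infinite distance in matrix; cap infinite Nei distances before UPGMA"
        )
    n = dist.n
    d = {(i, j): float(dist.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=dist.labels[i], height=0.0) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    minlab = {i: dist.labels[i] for i in range(n)}
    active = set(range(n))
    linkage = np.zeros((n - 1, 4))

    for step in range(n - 1):
        best = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                min(minlab[kv[0][0]], minlab[kv[0][1]]),
                max(minlab[kv[0][0]], minlab[kv[0][1]]),
            ),
        )
        (i, j), dij = best
        new = n + step
        first, second = sorted((i, j), key=lambda c: minlab[c])
        nodes[new] = TreeNode(
            name=None, height=dij / 2.0, children=(nodes[first], nodes[second])
        )
        linkage[step] = (i, j, dij, sizes[i] + sizes[j])
        for k in active - {i, j}:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(k, new)] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        del d[(i, j)]
        sizes[new] = sizes.pop(i) + sizes.pop(j)
        minlab[new] = min(minlab.pop(i), minlab.pop(j))
        active -= {i, j}
        active.add(new)

    return Tree(root=nodes[n + n - 2], labels=dist.labels, linkage=linkage)


def cut_clusters(tree: Tree, k: int) -> dict[str, int]:
    """Membership after stopping the agglomeration at k clusters."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b, _, _ = tree.linkage[step]
        members[n + step] = members.pop(int(a)) + members.pop(int(b))
    out: dict[str, int] = {}
    for cluster_id, (_, leaf_idx) in enumerate(sorted(members.items())):
        for i in leaf_idx:
            out[tree.labels[i]] = cluster_id
    return out


def polymorphism_rate(panel: GenotypePanel, accessions: Sequence[str]) -> float:
    """Fraction of markers showing >= 2 distinct non-missing states in a group."""
    if not accessions:
        raise ValueError("empty group")
    idx = [panel.accessions.index(a) for a in accessions]
    sub = panel.calls[idx]
    poly = 0
    for col in sub.T:
        states = np.unique(col[~np.isnan(col)])
        if len(states) >= 2:
            poly += 1
    return poly / len(panel.markers)


def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """ΔK per interior K from structure-run log-likelihood summaries.

    ``runs`` needs columns K, replicate, ln_prob.  For each K with both
    neighbours present, replicates are aligned by replicate id and
    ΔK(K) = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd(L(K)), with the
    sample standard deviation (ddof=1) over the replicates at K.  K values
    lacking a neighbour are omitted; a zero replicate sd is an error for
    that K.
    """
    required = {"K", "replicate", "ln_prob"}
    if not required <= set(runs.columns):
        raise ValueError(f"need columns {sorted(required)}")
    by_k = {
        int(k): g.set_index("replicate")["ln_prob"]
        for k, g in runs.groupby("K")
    }
    rows = []
    for k in sorted(by_k):
        if k - 1 not in by_k or k + 1 not in by_k:
            continue
        here = by_k[k]
        if len(here) < 2:
            raise ValueError(f"K={k}: need >= 2 replicates for a finite sd")
        sd = float(here.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"K={k}: zero replicate standard deviation")
        reps = here.index.intersection(by_k[k - 1].index).intersection(
            by_k[k + 1].index
        )
        if len(reps) > 0:
            second = (
                by_k[k + 1].loc[reps] - 2.0 * here.loc[reps] + by_k[k - 1].loc[reps]
            )
            num = float(second.abs().mean())
        else:  # replicate ids don't align across K: fall back to means
            num = abs(
                float(by_k[k + 1].mean()) - 2.0 * float(here.mean())
                + float(by_k[k - 1].mean())
            )
        rows.append({"K": k, "delta_k": num / sd})
    return pd.DataFrame(rows, columns=["K", "delta_k"])
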