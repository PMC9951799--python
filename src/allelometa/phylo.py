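"""Phylogenetic distances and correlation structure for species random effects.

A user-supplied Newick tree over every grass and recipient species provides
two quantities: the patristic distance between a species pair (the covariate
behind the phylogenetic-distance smooth, log-scaled as log(1+PD) so that
conspecific pairs at PD=0 stay defined) and the tip-by-tip correlation matrix
A of shared evolutionary history that constrains the tree-linked species
random effects, u ~ MVN(0, tau^2 A).

For a pair of tips x, y with root-to-tip depths D_x, D_y the shared branch
length is (D_x + D_y - PD(x,y)) / 2, and

    A(x, y) = shared / sqrt(D_x * D_y)

which has unit diagonal for any tree; on an ultrametric tree it reduces to
shared depth over tree height.  Non-ultrametric trees are accepted with a
warning (the geometric-mean scaling keeps the diagonal at one).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

DIAGONAL_JITTER = 1e-8


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, thinly wrapping dendropy."""

    tree: dendropy.Tree

    @property
    def leaves(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class DistanceCovariate:
    """Patristic distances between all tip pairs and their log scale."""

    species_order: list[str]
    pd_matrix: np.ndarray  # symmetric, zero diagonal

    def distance(self, a: str, b: str) -> float:
        i, j = self.species_order.index(a), self.species_order.index(b)
        return float(self.pd_matrix[i, j])

    def log_distance(self, a: str, b: str) -> float:
        return log_scaled_distance(self.distance(a, b))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pd_matrix, index=self.species_order,
                            columns=self.species_order)


@dataclass
class PhyloCovariance:
    """Phylogenetic correlation matrix A with unit diagonal."""

    species_order: list[str]
    A: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.species_order,
                            columns=self.species_order)


def parse_newick(text: str, strict_lengths: bool = False) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    With ``strict_lengths=True`` a missing branch length anywhere in the tree
    is an error; otherwise missing lengths default to zero.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"could not parse Newick tree: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf names in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if strict_lengths:
                raise ValueError(
                    f"missing branch length above node {edge.head_node}")
            edge.length = 0.0
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def check_coverage(phylo: Phylogeny, species: set[str]) -> None:
    """Fail loudly if any species in the effect table is absent from the tree."""
    missing = sorted(species - set(phylo.leaves))
    if missing:
        raise ValueError(f"species absent from tree: {missing}")


def patristic_matrix(phylo: Phylogeny) -> DistanceCovariate:
    """All-pairs patristic distances (sum of branch lengths along tip paths)."""
    pdm = phylo.tree.phylogenetic_distance_matrix()
    taxa = sorted(phylo.tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceCovariate(labels, M)


def _tip_depths(phylo: Phylogeny) -> dict[str, float]:
    depths: dict[str, float] = {}
    depths_by_node: dict[int, float] = {}
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is None:
            depths_by_node[id(node)] = 0.0
        else:
            el = node.edge.length or 0.0
            depths_by_node[id(node)] = depths_by_node[id(node.parent_node)] + el
        if node.is_leaf():
            depths[node.taxon.label] = depths_by_node[id(node)]
    return depths


def phylo_correlation(phylo: Phylogeny) -> PhyloCovariance:
    """Correlation matrix of shared root-to-tip branch lengths, unit diagonal."""
    dist = patristic_matrix(phylo)
    depths = _tip_depths(phylo)
    dvec = np.array([depths[s] for s in dist.species_order])
    if np.any(dvec <= 0):
        raise ValueError("all tips must have positive root-to-tip depth")
    if np.ptp(dvec) > 1e-6 * dvec.max():
        warnings.warn("tree is not ultrametric; correlations use the "
                      "geometric-mean tip-depth scaling", stacklevel=2)
    shared = (dvec[:, None] + dvec[None, :] - dist.pd_matrix) / 2.0
    A = shared / np.sqrt(np.outer(dvec, dvec))
    np.fill_diagonal(A, 1.0)
    A = (A + A.T) / 2.0
    eig_min = np.linalg.eigvalsh(A).min()
    if eig_min < -1e-8:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {eig_min:g})")
    return PhyloCovariance(dist.species_order, A)


def log_scaled_distance(pd_value):
    """Log-scale a patristic distance as log(1 + PD); defined at PD = 0."""
    arr = np.asarray(pd_value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("patristic distances must be >= 0")
    out = np.log1p(arr)
    return float(out) if np.isscalar(pd_value) or arr.ndim == 0 else out


def jittered(A: np.ndarray, jitter: float = DIAGONAL_JITTER) -> np.ndarray:
    """Add a small diagonal jitter ahead of factorization."""
    return A + jitter * np.eye(A.shape[0])
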