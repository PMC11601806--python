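"""Jukes-Cantor likelihoods on single trees.

Implements the classical ingredients the subsplit-DAG searches are built on:
the Jukes-Cantor transition matrix in closed form, Felsenstein's pruning
algorithm with per-site log scaling of partial likelihood vectors (PLVs),
and coordinate-wise Brent branch-length optimization of an arbitrary
objective.

Model assumptions: stationary root frequencies of 1/4 per nucleotide, a
single rate category (no across-site rate variation), and sites independent
and identically distributed, so the tree log likelihood is the sum of
per-site log likelihoods.  IUPAC ambiguity codes and gaps are treated as
fully ambiguous observations (partial vector of ones), the standard
convention of pruning implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._config import OptimizerConfig
from .subsplits import SubsplitError, TaxonSet
from .treeio import EdgeKey, Tree, _Node

NUCLEOTIDES = "ACGT"

#: IUPAC nucleotide codes mapped to their compatible-base indicator vectors.
_AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT", "X": "ACGT",
}

_CODES = "".join(_AMBIGUITY)
_CODE_INDEX = {c: i for i, c in enumerate(_CODES)}
_PARTIALS_TABLE = np.zeros((len(_CODES), 4))
for _c, _bases in _AMBIGUITY.items():
    for _b in _bases:
        _PARTIALS_TABLE[_CODE_INDEX[_c], NUCLEOTIDES.index(_b)] = 1.0


class PhyloError(ValueError):
    pass


@dataclass
class Alignment:
    """A gapless-or-not DNA alignment: one equal-length sequence per taxon."""

    taxa: TaxonSet
    codes: np.ndarray  # (n_taxa, n_sites) uint8 indices into the code table

    def __post_init__(self) -> None:
        if self.codes.shape[0] != self.taxa.n:
            raise PhyloError("one sequence per taxon is required")

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def leaf_partials(self, taxon_index: int) -> np.ndarray:
        """(n_sites, 4) observation indicator vectors for one taxon."""
        return _PARTIALS_TABLE[self.codes[taxon_index]]

    def sequence(self, taxon_index: int) -> str:
        return "".join(_CODES[c] for c in self.codes[taxon_index])

    @classmethod
    def from_sequences(
        cls, sequences: dict[str, str], taxa: Optional[TaxonSet] = None
    ) -> "Alignment":
        if not sequences:
            raise PhyloError("empty alignment")
        if taxa is None:
            taxa = TaxonSet(tuple(sorted(sequences)))
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise PhyloError(f"unequal sequence lengths: {sorted(lengths)}")
        n_sites = lengths.pop()
        codes = np.zeros((taxa.n, n_sites), dtype=np.uint8)
        for label in taxa.labels:
            if label not in sequences:
                raise PhyloError(f"no sequence for taxon {label!r}")
            seq = sequences[label].upper()
            try:
                codes[taxa.index(label)] = [_CODE_INDEX[c] for c in seq]
            except KeyError as exc:
                raise PhyloError(
                    f"unrecognized base {exc.args[0]!r} in sequence for "
                    f"{label!r}"
                ) from None
        return cls(taxa, codes)

    @classmethod
    def from_fasta(
        cls, path, taxa: Optional[TaxonSet] = None
    ) -> "Alignment":
        from Bio import SeqIO

        sequences = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in sequences:
                raise PhyloError(f"duplicate FASTA record {record.id!r}")
            sequences[record.id] = str(record.seq)
        return cls.from_sequences(sequences, taxa)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, label in enumerate(self.taxa.labels):
                fh.write(f">{label}\n{self.sequence(i)}\n")


# ---------------------------------------------------------------------------
# Jukes-Cantor model
# ---------------------------------------------------------------------------

def jc_transition_matrix(t: float) -> np.ndarray:
    """JC69 transition probability matrix for branch length `t`.

    Diagonal 1/4 + (3/4) e^{-4t/3}, off-diagonal 1/4 - (1/4) e^{-4t/3};
    rows sum to one.  `t` is in expected substitutions per site.
    """
    if t < 0:
        raise PhyloError(f"negative branch length: {t}")
    decay = np.exp(-4.0 * t / 3.0)
    off = 0.25 - 0.25 * decay
    matrix = np.full((4, 4), off)
    np.fill_diagonal(matrix, 0.25 + 0.75 * decay)
    return matrix


# ---------------------------------------------------------------------------
# Felsenstein pruning
# ---------------------------------------------------------------------------

def _require_length(tree: Tree, key: EdgeKey) -> float:
    v = tree.lengths.get(key)
    if v is None:
        raise PhyloError(f"unset (sentinel) branch length on edge {key!r}")
    return v


def tree_log_likelihood(
    tree: Tree, aln: Alignment, per_site: bool = False
) -> float | np.ndarray:
    """Log likelihood of an alignment on a tree under JC69.

    Post-order PLV recursion with per-node, per-site rescaling; scaling
    factors accumulate additively in log space, keeping deep trees and
    short branches away from underflow.  Returns the summed log likelihood,
    or the per-site vector when `per_site` is set.
    """
    if tree.taxa != aln.taxa:
        raise PhyloError("tree and alignment taxon sets differ")
    topo = tree.topology
    by_mask = {
        k.child.union.mask: _require_length(tree, k)
        for k in topo.edge_keys()
        if not k.parent.is_rho
    }
    n_sites = aln.n_sites

    def plv(node: _Node) -> tuple[np.ndarray, np.ndarray]:
        """Returns (partials (K,4), log-scale (K,)) for the subtree."""
        if node.children is None:
            return aln.leaf_partials(node.taxon), np.zeros(n_sites)
        out = np.ones((n_sites, 4))
        logscale = np.zeros(n_sites)
        for child in node.children:
            child_plv, child_scale = plv(child)
            matrix = jc_transition_matrix(by_mask[child.mask])
            out *= child_plv @ matrix.T
            logscale += child_scale
        top = out.max(axis=1)
        safe = np.where(top > 0, top, 1.0)
        out /= safe[:, None]
        with np.errstate(divide="ignore"):
            logscale += np.log(np.where(top > 0, safe, 0.0))
        return out, logscale

    root_plv, root_scale = plv(topo.root)
    with np.errstate(divide="ignore"):
        site_ll = np.log(0.25 * root_plv.sum(axis=1)) + root_scale
    return site_ll if per_site else float(site_ll.sum())


# ---------------------------------------------------------------------------
# Branch-length optimization
# ---------------------------------------------------------------------------

def brent_maximize(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    xatol: float,
) -> tuple[float, float]:
    """Bounded Brent maximization; returns (argmax, max)."""
    res = minimize_scalar(
        lambda x: -f(x), bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x), float(-res.fun)


def optimize_branch_lengths(
    objective: Callable[[dict[EdgeKey, float]], float],
    edges: Sequence[EdgeKey],
    init: dict[EdgeKey, float],
    config: Optional[OptimizerConfig] = None,
) -> dict[EdgeKey, float]:
    """Coordinate-ascent Brent optimization of `objective` over edge lengths.

    One branch length at a time is optimized with the others held fixed,
    sweeping the edges in the given order until the largest change in a
    sweep falls below the tolerance.  The objective value never decreases
    between sweeps: a Brent proposal that does not improve the current
    value is discarded.
    """
    cfg = config or OptimizerConfig()
    current = dict(init)
    f_current = objective(current)
    if not np.isfinite(f_current):
        raise PhyloError("objective is not finite at the initial lengths")
    for _ in range(cfg.max_sweeps):
        max_change = 0.0
        for edge in edges:
            def line(x: float, _edge=edge) -> float:
                trial = dict(current)
                trial[_edge] = x
                value = objective(trial)
                if np.isnan(value):
                    raise PhyloError(
                        f"objective is not finite while optimizing {_edge!r}"
                    )
                return value

            x_new, f_new = brent_maximize(
                line, cfg.min_branch_length, cfg.max_branch_length, cfg.xatol
            )
            if f_new > f_current:
                max_change = max(max_change, abs(x_new - current[edge]))
                current[edge] = x_new
                f_current = f_new
        if max_change < cfg.tol:
            break
    return current
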