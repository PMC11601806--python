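"""Tunable numerical settings shared by the likelihood and search code."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class OptimizerConfig:
    """Coordinate-wise Brent branch-length optimization settings.

    Bounds are in substitutions/site.  A sweep optimizes each coordinate
    once; sweeps repeat until the largest per-coordinate change falls below
    `tol` or `max_sweeps` is reached.
    """

    min_branch_length: float = 1e-6
    max_branch_length: float = 10.0
    tol: float = 1e-4
    max_sweeps: int = 5
    xatol: float = 1e-5  # Brent line-search absolute tolerance


@dataclass
class SearchConfig:
    """Settings for the top-pruning and generalized-pruning searches."""

    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    #: initial length for new edges with no pre-NNI counterpart edge
    default_branch_length: float = 0.1
    #: in the top-pruning NNI score, also optimize non-central new edges of
    #: the best known tree (default: central edge only)
    optimize_all_new_edges: bool = False
    #: verify that input tree lists are ordered by decreasing likelihood
    verify_tree_order: bool = False
    #: hard cap for brute-force topology enumeration oracles
    enumeration_cap: int = 100_000
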