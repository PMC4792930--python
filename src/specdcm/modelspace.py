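"""Enumeration of binary directed-graph model specifications and their
reduction under biological-plausibility rules.

A model is a binary adjacency matrix: entry ``[i, j] = 1`` means the
directed influence of node ``j`` on node ``i`` is a free parameter.  The
full space over ``n`` nodes has ``2**(n*n)`` members; plausibility rules
(mandatory self-connections, no isolated node, sagittal symmetry,
homotopic links bidirectional-or-absent, required links) cut it down.
For three nodes, self-connections plus connectedness leave 54 models.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inversion import PriorSpec

__all__ = [
    "ModelSpec",
    "ModelSpace",
    "PlausibilityRules",
    "enumerate_full",
    "apply_rules",
    "to_prior",
]


@dataclass
class ModelSpec:
    """One binary adjacency specification with labelled nodes."""

    adjacency: np.ndarray
    labels: list[str]
    laterality: list[str] | None = None  # "left" / "right" / "midline"

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if len(self.labels) != n:
            raise ValueError("labels must match adjacency size")
        if self.laterality is not None and len(self.laterality) != n:
            raise ValueError("laterality must match adjacency size")


@dataclass
class ModelSpace:
    """An ordered collection of binary adjacency matrices."""

    models: list[np.ndarray]
    labels: list[str]
    laterality: list[str] | None = None

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def specs(self) -> list[ModelSpec]:
        return [ModelSpec(m, self.labels, self.laterality) for m in self.models]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "laterality": self.laterality,
            "models": [m.astype(int).tolist() for m in self.models],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelSpace":
        payload = json.loads(Path(path).read_text())
        return cls(models=[np.asarray(m, dtype=int) for m in payload["models"]],
                   labels=payload["labels"], laterality=payload.get("laterality"))


@dataclass
class PlausibilityRules:
    """Filtering rules applied to a model space.

    ``connectivity`` selects the reading of "connected": ``"isolated"``
    (default; no node may lack both incoming and outgoing between-node
    links — the weakest reading, and the only one that leaves 54 of the
    512 three-node models), ``"weak"`` or ``"strong"`` graph
    connectivity of the off-diagonal digraph.
    """

    require_self: bool = True
    require_connected: bool = True
    connectivity: str = "isolated"
    sagittal_symmetry: bool = False
    bilateral_homotopic_only: list[tuple[int, int]] = field(default_factory=list)
    required_links: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.connectivity not in ("isolated", "weak", "strong"):
            raise ValueError("connectivity must be 'isolated', 'weak' or 'strong'")


def enumerate_full(n: int, labels: list[str] | None = None,
                   laterality: list[str] | None = None) -> ModelSpace:
    """All ``2**(n*n)`` binary adjacency matrices over ``n`` nodes.

    Guarded to ``1 <= n <= 5``; the output order is lexicographic in the
    row-major flattened adjacency.
    """
    if not 1 <= n <= 5:
        raise ValueError("n must be between 1 and 5")
    labels = labels or [f"node_{i}" for i in range(n)]
    models = [np.array(bits, dtype=int).reshape(n, n)
              for bits in itertools.product((0, 1), repeat=n * n)]
    return ModelSpace(models=models, labels=labels, laterality=laterality)


def _mirror_permutation(laterality: list[str]) -> np.ndarray:
    """Permutation swapping each left node with its right homotope.

    Nodes are paired in order of appearance: the k-th "left" node maps to
    the k-th "right" node; "midline" nodes map to themselves.
    """
    left = [i for i, t in enumerate(laterality) if t == "left"]
    right = [i for i, t in enumerate(laterality) if t == "right"]
    if len(left) != len(right):
        raise ValueError("unbalanced left/right laterality tags")
    perm = np.arange(len(laterality))
    for a, b in zip(left, right):
        perm[a], perm[b] = b, a
    return perm


def _node_isolated(adj: np.ndarray, i: int) -> bool:
    off = adj.copy()
    np.fill_diagonal(off, 0)
    return off[i].sum() == 0 and off[:, i].sum() == 0


def _connected(adj: np.ndarray, mode: str) -> bool:
    n = adj.shape[0]
    if n == 1:
        return True
    off = adj.copy()
    np.fill_diagonal(off, 0)
    if mode == "isolated":
        return all(not _node_isolated(adj, i) for i in range(n))
    reach = off.astype(bool)
    if mode == "weak":
        reach = reach | reach.T
    # transitive closure by repeated squaring
    closure = reach | np.eye(n, dtype=bool)
    for _ in range(int(np.ceil(np.log2(n))) + 1):
        closure = closure | (closure @ closure)
    return bool(closure.all())


def _passes(adj: np.ndarray, rules: PlausibilityRules,
            mirror: np.ndarray | None) -> bool:
    if rules.require_self and not np.all(np.diag(adj) == 1):
        return False
    if rules.require_connected and not _connected(adj, rules.connectivity):
        return False
    if rules.sagittal_symmetry:
        if mirror is None:
            raise ValueError("sagittal_symmetry requires laterality tags")
        if not np.array_equal(adj, adj[np.ix_(mirror, mirror)]):
            return False
    for i, j in rules.bilateral_homotopic_only:
        if adj[i, j] != adj[j, i]:
            return False
    for i, j in rules.required_links:
        if adj[i, j] == 0 and adj[j, i] == 0:
            return False
    return True


def apply_rules(space: ModelSpace, rules: PlausibilityRules) -> ModelSpace:
    """Members of ``space`` satisfying every enabled rule, in
    lexicographic order of the flattened adjacency."""
    n = len(space.labels)
    for i, j in list(rules.bilateral_homotopic_only) + list(rules.required_links):
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"rule references unknown node index ({i}, {j})")
    mirror = None
    if rules.sagittal_symmetry:
        if space.laterality is None:
            raise ValueError("sagittal_symmetry requires laterality tags")
        mirror = _mirror_permutation(space.laterality)
    kept = [m for m in space.models if _passes(m, rules, mirror)]
    kept.sort(key=lambda m: tuple(m.ravel()))
    if not kept:
        warnings.warn("no models survive the plausibility rules", stacklevel=2)
    return ModelSpace(models=kept, labels=space.labels,
                      laterality=space.laterality)


def to_prior(model: ModelSpec | np.ndarray, defaults: PriorSpec) -> PriorSpec:
    """Translate a binary adjacency into a prior: off-diagonal couplings
    with adjacency 0 get a zero-mean, zero-variance (switched-off) prior;
    everything else inherits the defaults."""
    adj = model.adjacency if isinstance(model, ModelSpec) else np.asarray(model, int)
    n = adj.shape[0]
    means = defaults.means.copy()
    variances = defaults.variances.copy()
    pos = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if adj[i, j] == 0:
                means[pos] = 0.0
                variances[pos] = 0.0
            pos += 1
    return PriorSpec(means=means, variances=variances, names=list(defaults.names))
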