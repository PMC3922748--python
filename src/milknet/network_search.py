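"""Inductive causation on posterior samples of a residual covariance matrix.

Searching for causal structure among traits in a mixed-model setting uses
the *residual* covariance matrix of a multi-trait animal model — the trait
covariances conditional on genetic and systematic confounders — rather
than raw data.  Every statistical decision is made on the posterior
distribution of a partial correlation: for each trait pair and each
conditioning subset of the remaining traits, one partial-correlation draw
is computed per posterior covariance sample, and the pair is declared
conditionally *dependent* whenever the highest-posterior-density (HPD)
interval of those draws excludes zero.

The three IC steps then are:

1. **Skeleton** — place an undirected edge between two traits iff they are
   dependent conditional on *every* subset of the other traits; record the
   separating sets of non-adjacent pairs.
2. **Colliders** — for every unshielded triple ``i – m – j`` (``i``, ``j``
   non-adjacent), orient ``i → m ← j`` iff ``m`` belongs to no recorded
   separating set of ``(i, j)``.
3. **Propagation** — orient remaining undirected edges whenever the
   orientation follows unambiguously, i.e. would otherwise create a new
   unshielded collider or a directed cycle (Meek rules R1 and R2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PDAG",
    "SeparationRecord",
    "OrientationConflictError",
    "partial_correlation",
    "posterior_partial_correlations",
    "PartialCorrelationPosterior",
    "hpd_interval",
    "count_ic_tests",
    "ic_skeleton",
    "orient_colliders",
    "propagate_orientations",
]


class OrientationConflictError(RuntimeError):
    """Two unshielded triples demand opposite orientations of one edge."""


# ---------------------------------------------------------------------------
# partial correlations
# ---------------------------------------------------------------------------

def partial_correlation(
    sigma: np.ndarray, i: int, j: int, S: tuple[int, ...] | list[int] = ()
) -> float:
    """Partial correlation of variables ``i`` and ``j`` given the set ``S``.

    Computed from the inverse ``Ω`` of the covariance submatrix over
    ``{i, j} ∪ S`` as ``-Ω_ij / sqrt(Ω_ii Ω_jj)``; with empty ``S`` this is
    the marginal correlation.

    Raises
    ------
    ValueError
        If indices overlap, or the submatrix is numerically singular (the
        message carries the condition number).
    """
    S = tuple(S)
    idx = (i, j) + S
    if len(set(idx)) != len(idx):
        raise ValueError(f"indices must be distinct, got i={i}, j={j}, S={S}")
    sub = np.asarray(sigma, dtype=float)[np.ix_(idx, idx)]
    cond = np.linalg.cond(sub)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"singular covariance submatrix (condition number {cond:.3e})")
    omega = np.linalg.inv(sub)
    return float(-omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1]))


@dataclass
class PartialCorrelationPosterior:
    """Posterior partial-correlation draws for every (pair, subset) in a plan.

    ``draws[(i, j, S)]`` holds one value per retained posterior covariance
    sample; draws whose submatrix was singular or produced a non-finite
    value are excluded and counted in ``n_excluded``.
    """

    traits: tuple[str, ...]
    draws: dict[tuple[int, int, tuple[int, ...]], np.ndarray]
    n_excluded: dict[tuple[int, int, tuple[int, ...]], int]
    n_samples: int

    def get(self, i: int, j: int, S: tuple[int, ...] | list[int] = ()) -> np.ndarray:
        i, j = min(i, j), max(i, j)
        return self.draws[(i, j, tuple(sorted(S)))]

    @property
    def n_series(self) -> int:
        return len(self.draws)

    def pairs(self) -> list[tuple[int, int]]:
        return sorted({(i, j) for i, j, _ in self.draws})

    def subsets_for(self, i: int, j: int) -> list[tuple[int, ...]]:
        i, j = min(i, j), max(i, j)
        return sorted(
            (S for a, b, S in self.draws if (a, b) == (i, j)), key=lambda S: (len(S), S)
        )

    def total_excluded(self) -> int:
        return sum(self.n_excluded.values())


def posterior_partial_correlations(
    samples,
    max_cond_size: int | None = None,
) -> PartialCorrelationPosterior:
    """Evaluate the full IC testing plan on posterior covariance samples.

    Parameters
    ----------
    samples:
        A :class:`~milknet.mixed_model.PosteriorCovarianceSamples` (its
        ``r0`` draws are used) or a bare ``(m, t, t)`` array of covariance
        draws paired with trait names via ``samples.traits``.
    max_cond_size:
        Cap on the conditioning-set size; default ``t - 2`` (full
        enumeration over all subsets of the remaining traits).
    """
    if hasattr(samples, "r0"):
        sigmas = np.asarray(samples.r0, dtype=float)
        traits = tuple(samples.traits)
    else:  # pragma: no cover - convenience path
        raise TypeError("samples must expose .r0 and .traits")
    m, t, _ = sigmas.shape
    if m < 30:
        warnings.warn(
            f"only {m} posterior samples; HPD decisions will be coarse", stacklevel=2
        )
    cap = t - 2 if max_cond_size is None else min(max_cond_size, t - 2)

    draws: dict[tuple[int, int, tuple[int, ...]], np.ndarray] = {}
    excluded: dict[tuple[int, int, tuple[int, ...]], int] = {}
    for i, j in combinations(range(t), 2):
        others = [v for v in range(t) if v != i and v != j]
        for size in range(cap + 1):
            for S in combinations(others, size):
                idx = (i, j) + S
                sub = sigmas[:, idx][:, :, idx]
                rho = _batched_partial_corr(sub)
                ok = np.isfinite(rho) & (np.abs(rho) <= 1 + 1e-8)
                draws[(i, j, S)] = np.clip(rho[ok], -1.0, 1.0)
                excluded[(i, j, S)] = int(m - ok.sum())
    return PartialCorrelationPosterior(
        traits=traits, draws=draws, n_excluded=excluded, n_samples=m
    )


def _batched_partial_corr(sub: np.ndarray) -> np.ndarray:
    """Partial correlation of the first two indices for a stack of matrices."""
    try:
        omega = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        omega = np.full_like(sub, np.nan)
        for m in range(sub.shape[0]):
            try:
                omega[m] = np.linalg.inv(sub[m])
            except np.linalg.LinAlgError:
                pass
    denom = omega[:, 0, 0] * omega[:, 1, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        return -omega[:, 0, 1] / np.sqrt(denom)


# ---------------------------------------------------------------------------
# HPD intervals and decision counts
# ---------------------------------------------------------------------------

def hpd_interval(draws: np.ndarray, content: float) -> tuple[float, float]:
    """Shortest interval containing ``ceil(content * N)`` sorted draws.

    The Chen–Shao estimator: slide a window of that many order statistics
    and keep the narrowest (ties broken by the lowest window start).
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 draws for an HPD interval, got {n}")
    if not 0 < content <= 1:
        raise ValueError(f"content must be in (0, 1], got {content}")
    m = int(np.ceil(content * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))  # argmin returns the first minimum: lowest start
    return float(x[j]), float(x[j + m - 1])


def count_ic_tests(t: int) -> tuple[int, int, int]:
    """Size of the full IC testing plan for ``t`` traits.

    Returns ``(n_pairs, n_subsets_per_pair, n_total)`` with
    ``n_pairs = t(t-1)/2`` and ``n_subsets_per_pair = 2^(t-2)`` (all subsets
    of the remaining traits, the empty set included).
    """
    if t < 2:
        raise ValueError(f"need at least two traits, got {t}")
    n_pairs = t * (t - 1) // 2
    n_subsets = 2 ** (t - 2)
    return n_pairs, n_subsets, n_pairs * n_subsets


# ---------------------------------------------------------------------------
# PDAG
# ---------------------------------------------------------------------------

@dataclass
class SeparationRecord:
    """For each non-adjacent pair, the subsets that rendered it independent."""

    sets: dict[tuple[int, int], list[tuple[int, ...]]] = field(default_factory=dict)

    def separators(self, i: int, j: int) -> list[tuple[int, ...]]:
        return self.sets.get((min(i, j), max(i, j)), [])

    def in_any_separator(self, i: int, j: int, m: int) -> bool:
        return any(m in S for S in self.separators(i, j))


class PDAG:
    """Partially directed acyclic graph over named traits.

    Each pair holds at most one edge, marked either ``undirected`` or
    directed ``a -> b``; the directed part must stay acyclic.
    """

    def __init__(self, nodes, provenance: float | None = None):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._edges: dict[frozenset, tuple[str, str] | None] = {}
        self.provenance = provenance

    # -- construction -----------------------------------------------------
    def add_undirected(self, a: str, b: str) -> None:
        self._check(a, b)
        self._edges[frozenset((a, b))] = None

    def orient(self, a: str, b: str) -> None:
        """Mark the existing edge between ``a`` and ``b`` as ``a -> b``."""
        self._check(a, b)
        key = frozenset((a, b))
        if key not in self._edges:
            raise KeyError(f"no edge between {a!r} and {b!r}")
        current = self._edges[key]
        if current is not None and current != (a, b):
            raise OrientationConflictError(
                f"edge {a!r}-{b!r} already oriented {current[0]!r}->{current[1]!r}"
            )
        self._edges[key] = (a, b)

    def _check(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self edge on {a!r}")
        for v in (a, b):
            if v not in self.nodes:
                raise KeyError(f"unknown node {v!r}")

    # -- queries ----------------------------------------------------------
    def is_adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._edges

    def mark(self, a: str, b: str):
        return self._edges[frozenset((a, b))]

    def neighbors(self, a: str) -> list[str]:
        return sorted(
            next(iter(key - {a}))
            for key in self._edges
            if a in key
        )

    def edges(self) -> list[tuple[str, str, str]]:
        """Sorted ``(from, to, mark)`` triples; undirected pairs sorted."""
        out = []
        for key, mark in self._edges.items():
            if mark is None:
                a, b = sorted(key)
                out.append((a, b, "undirected"))
            else:
                out.append((mark[0], mark[1], "directed"))
        return sorted(out)

    def undirected_edges(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, m in self.edges() if m == "undirected"]

    def directed_edges(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, m in self.edges() if m == "directed"]

    def skeleton(self) -> set[frozenset]:
        return set(self._edges)

    def unshielded_colliders(self) -> set[tuple[str, str, str]]:
        """Triples ``(i, m, j)`` with ``i -> m <- j`` and ``i``, ``j`` non-adjacent."""
        out = set()
        incoming: dict[str, list[str]] = {}
        for a, b in self.directed_edges():
            incoming.setdefault(b, []).append(a)
        for m, parents in incoming.items():
            for i, j in combinations(sorted(parents), 2):
                if not self.is_adjacent(i, j):
                    out.add((i, m, j))
        return out

    def directed_part_is_acyclic(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges())
        return nx.is_directed_acyclic_graph(g)

    def copy(self) -> "PDAG":
        new = PDAG(self.nodes, self.provenance)
        new._edges = dict(self._edges)
        return new

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PDAG)
            and set(self.nodes) == set(other.nodes)
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return f"PDAG({len(self.nodes)} nodes, {len(self._edges)} edges)"

    # -- serialisation ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (a, b, m, "" if self.provenance is None else self.provenance)
            for a, b, m in self.edges()
        ]
        df = pd.DataFrame(rows, columns=["from", "to", "mark", "hpd_content"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, nodes=None) -> "PDAG":
        df = pd.read_csv(path, sep="\t", dtype={"from": str, "to": str, "mark": str})
        if nodes is None:
            nodes = sorted(set(df["from"]).union(df["to"]))
        prov = None
        if "hpd_content" in df.columns and len(df):
            vals = pd.to_numeric(df["hpd_content"], errors="coerce").dropna().unique()
            prov = float(vals[0]) if len(vals) else None
        pdag = cls(nodes, provenance=prov)
        for a, b, mark in df[["from", "to", "mark"]].itertuples(index=False):
            pdag.add_undirected(a, b)
            if mark == "directed":
                pdag.orient(a, b)
        return pdag

    def to_dot(self, path: str | Path | None = None) -> str:
        lines = ["digraph pdag {"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for a, b, mark in self.edges():
            style = " [dir=none]" if mark == "undirected" else ""
            lines.append(f'  "{a}" -> "{b}"{style};')
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# IC steps
# ---------------------------------------------------------------------------

def ic_skeleton(
    pcp: PartialCorrelationPosterior, content: float = 0.95
) -> tuple[PDAG, SeparationRecord]:
    """IC step 1: undirected skeleton from HPD dependence decisions.

    An edge joins ``i`` and ``j`` iff the HPD interval (at the requested
    content) of every conditioning subset's partial-correlation posterior
    excludes zero; for non-adjacent pairs all zero-covering subsets are
    recorded as separating sets.
    """
    traits = pcp.traits
    pdag = PDAG(traits, provenance=content)
    record = SeparationRecord()
    for i, j in pcp.pairs():
        separators = []
        for S in pcp.subsets_for(i, j):
            lo, hi = hpd_interval(pcp.get(i, j, S), content)
            if lo <= 0.0 <= hi:
                separators.append(S)
        if separators:
            record.sets[(i, j)] = separators
        else:
            pdag.add_undirected(traits[i], traits[j])
    return pdag, record


def orient_colliders(skeleton: PDAG, record: SeparationRecord) -> PDAG:
    """IC step 2: orient unshielded triples into colliders.

    For every triple ``i – m – j`` with ``i``, ``j`` non-adjacent, orient
    ``i -> m <- j`` iff ``m`` appears in *no* recorded separating set of
    ``(i, j)``.  Conflicting demands on a single edge abort with a report
    listing the triples involved.
    """
    traits = skeleton.nodes
    tidx = {v: n for n, v in enumerate(traits)}
    pdag = skeleton.copy()
    proposals: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    for m in traits:
        nbrs = pdag.neighbors(m)
        for i, j in combinations(nbrs, 2):
            if pdag.is_adjacent(i, j):
                continue
            if not record.in_any_separator(tidx[i], tidx[j], tidx[m]):
                for tail in (i, j):
                    proposals.setdefault((tail, m), []).append((i, m, j))
    conflicts = [
        (a, b, proposals[(a, b)], proposals[(b, a)])
        for (a, b) in proposals
        if (b, a) in proposals and a < b
    ]
    if conflicts:
        report = "; ".join(
            f"edge {a}-{b}: triples {fwd} vs {rev}" for a, b, fwd, rev in conflicts
        )
        raise OrientationConflictError(f"conflicting collider orientations: {report}")
    for a, b in proposals:
        pdag.orient(a, b)
    return pdag


def propagate_orientations(pdag: PDAG) -> PDAG:
    """IC step 3: orient what follows unambiguously (Meek rules R1 and R2).

    R1: if ``a -> b`` and ``b – c`` with ``a``, ``c`` non-adjacent, then
    ``b -> c`` (anything else creates a new unshielded collider).
    R2: if ``a -> b -> c`` and ``a – c``, then ``a -> c`` (anything else
    creates a cycle).  Applied to a fixpoint; the result keeps the directed
    part acyclic and introduces no new unshielded colliders.
    """
    if not pdag.directed_part_is_acyclic():
        raise ValueError("input PDAG has a directed cycle")
    before = pdag.unshielded_colliders()
    out = pdag.copy()
    changed = True
    while changed:
        changed = False
        directed = out.directed_edges()
        parents: dict[str, set[str]] = {}
        children: dict[str, set[str]] = {}
        for a, b in directed:
            children.setdefault(a, set()).add(b)
            parents.setdefault(b, set()).add(a)
        for a, b in directed:
            # R1
            for c in out.neighbors(b):
                if c != a and out.mark(b, c) is None and not out.is_adjacent(a, c):
                    out.orient(b, c)
                    changed = True
        for a in out.nodes:
            # R2: a -> b -> c with a - c undirected
            for b in children.get(a, ()):
                for c in children.get(b, ()):
                    if c != a and out.is_adjacent(a, c) and out.mark(a, c) is None:
                        out.orient(a, c)
                        changed = True
    if not out.directed_part_is_acyclic():
        raise OrientationConflictError("orientation propagation created a cycle")
    new = out.unshielded_colliders() - before
    if new:
        raise OrientationConflictError(
            f"orientation propagation created unshielded colliders: {sorted(new)}"
        )
    return out
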