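"""Pedigrees and the numerator relationship matrix.

The additive genetic covariance between individuals in a pedigreed
population is proportional to the numerator relationship matrix **A**,
whose entry ``A[i, j]`` is twice the kinship coefficient between ``i`` and
``j`` and whose diagonal is ``1 + F_i`` with ``F_i`` the inbreeding
coefficient.  **A** is built here with the tabular (recursive) method,
which is exact and comfortably fast for pedigrees up to tens of thousands
of animals.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Pedigree",
    "PedigreeError",
    "parse_pedigree",
    "build_numerator_relationship_matrix",
    "inbreeding_coefficients",
]

#: Sentinel used internally for an unknown parent.
UNKNOWN = None


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles)."""


@dataclass(frozen=True)
class Pedigree:
    """An ordered pedigree: parents always precede their offspring.

    Attributes
    ----------
    records:
        List of ``(animal, sire, dam)`` tuples in topological order; an
        unknown parent is ``None``.
    """

    records: tuple[tuple[str, str | None, str | None], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {a: i for i, (a, _, _) in enumerate(self.records)}
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def animals(self) -> list[str]:
        return [a for a, _, _ in self.records]

    def index_of(self, animal: str) -> int:
        return self._index[animal]

    @property
    def generation_depth(self) -> int:
        """Longest ancestor chain length (founder generation = 1)."""
        depth: dict[str, int] = {}
        for animal, sire, dam in self.records:
            pdepth = [depth[p] for p in (sire, dam) if p is not None]
            depth[animal] = 1 + max(pdepth, default=0)
        return max(depth.values(), default=0)

    def founders(self) -> list[str]:
        return [a for a, s, d in self.records if s is None and d is None]

    def subset_to_ancestors(self, animals: list[str]) -> "Pedigree":
        """Prune to the given animals and all of their ancestors."""
        keep: set[str] = set()
        parent = {a: (s, d) for a, s, d in self.records}
        stack = [a for a in animals]
        while stack:
            a = stack.pop()
            if a in keep:
                continue
            keep.add(a)
            stack.extend(p for p in parent[a] if p is not None)
        return Pedigree(tuple(r for r in self.records if r[0] in keep))

    def to_frame(self, missing_code: str = "0") -> pd.DataFrame:
        return pd.DataFrame(
            [
                (a, s if s is not None else missing_code, d if d is not None else missing_code)
                for a, s, d in self.records
            ],
            columns=["animal", "sire", "dam"],
        )


def _toposort(
    rows: list[tuple[str, str | None, str | None]]
) -> list[tuple[str, str | None, str | None]]:
    """Kahn's algorithm, preserving input order among ready animals."""
    parents = {a: (s, d) for a, s, d in rows}
    children: dict[str, list[str]] = {a: [] for a in parents}
    indeg = {a: 0 for a in parents}
    for a, s, d in rows:
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    order = [a for a, _, _ in rows if indeg[a] == 0]
    head = 0
    while head < len(order):
        a = order[head]
        head += 1
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
    if len(order) < len(rows):
        stuck = next(a for a in indeg if indeg[a] > 0)
        raise PedigreeError(
            f"pedigree contains a cycle involving animal {stuck!r}"
        )
    return [(a, *parents[a]) for a in order]


def parse_pedigree(
    source: str | Path | io.TextIOBase | pd.DataFrame,
    missing_parent: str = "0",
) -> Pedigree:
    """Parse a delimited pedigree table into a topologically ordered pedigree.

    Parameters
    ----------
    source:
        Path, file-like object or DataFrame with columns
        ``animal, sire, dam`` (header required for text input; comma or tab
        delimited).
    missing_parent:
        Code marking an unknown parent; empty strings are always treated as
        unknown.

    Returns
    -------
    Pedigree
        Records in parents-before-offspring order, regardless of input
        order.  Parent ids never defined as animals are auto-inserted as
        founders with a logged warning.

    Raises
    ------
    PedigreeError
        On duplicate animal ids or a pedigree cycle.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        return Pedigree(())

    def decode(v: object) -> str | None:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        v = str(v).strip()
        return None if v in ("", missing_parent) else v

    rows: list[tuple[str, str | None, str | None]] = []
    seen: set[str] = set()
    for animal, sire, dam in df[["animal", "sire", "dam"]].itertuples(index=False):
        a = str(animal).strip()
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
        rows.append((a, decode(sire), decode(dam)))

    undeclared = [
        p for _, s, d in rows for p in (s, d) if p is not None and p not in seen
    ]
    if undeclared:
        uniq = sorted(set(undeclared))
        msg = f"{len(uniq)} parent id(s) never declared as animals; inserted as founders: {uniq[:5]}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        rows = [(p, None, None) for p in uniq] + rows
        seen.update(uniq)

    return Pedigree(tuple(_toposort(rows)))


def inbreeding_coefficients(ped: Pedigree) -> dict[str, float]:
    """Inbreeding coefficient of every animal, F_i = kinship(sire_i, dam_i).

    Uses memoized recursive kinship (``φ(a,a) = ½(1 + F_a)``,
    ``φ(a,b) = ½(φ(s_a,b) + φ(d_a,b))`` for the later-born ``a``), so only
    the ancestor pairs actually needed are visited — unlike the tabular
    method this never allocates the full matrix.
    """
    import sys

    parents = {a: (s, d) for a, s, d in ped.records}
    order = {a: i for i, (a, _, _) in enumerate(ped.records)}
    memo: dict[tuple[str, str], float] = {}
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * len(ped) + 100))

    def kin(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if order[a] < order[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        s, d = parents[a]
        if a == b:
            val = 0.5 * (1.0 + kin(s, d))
        else:
            val = 0.5 * (kin(s, b) + kin(d, b))
        memo[key] = val
        return val

    return {a: kin(*parents[a]) for a in parents}


def build_numerator_relationship_matrix(ped: Pedigree) -> pd.DataFrame:
    """Build **A** by the tabular method.

    For animals in topological order, with unknown parents contributing
    zero relationship::

        A[i, j] = 0.5 * (A[sire_i, j] + A[dam_i, j])   for j < i
        A[i, i] = 1 + 0.5 * A[sire_i, dam_i]

    Returns
    -------
    pandas.DataFrame
        Symmetric positive-definite matrix indexed by animal id in
        pedigree order; diagonal entries are ``1 + F`` (founders exactly 1).
    """
    n = len(ped)
    A = np.zeros((n, n))
    idx = ped.index_of
    for i, (_, sire, dam) in enumerate(ped.records):
        si = idx(sire) if sire is not None else -1
        di = idx(dam) if dam is not None else -1
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        inbreeding = 0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + inbreeding
    return pd.DataFrame(A, index=ped.animals, columns=ped.animals)
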