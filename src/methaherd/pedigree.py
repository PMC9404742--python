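"""Pedigrees and the numerator relationship matrix.

The additive genetic covariance between animals in an animal model is
``A * sigma_a^2``, where A is the numerator relationship matrix: ``a_ij`` is
twice the coancestry (kinship) of i and j, and the diagonal is ``1 + F_i``
with ``F_i`` the inbreeding coefficient.  This module parses pedigree CSV
files, topologically orders them (parents before offspring), prunes them to a
fixed number of ancestral generations, and builds A (dense, tabular method),
per-animal inbreeding (Meuwissen & Luo's diagonal algorithm) and the sparse
A-inverse (Henderson's rules with inbreeding) needed by the mixed-model
equations.

Unknown parents are treated as unrelated, non-inbred members of the base
population.  Identifiers are arbitrary non-empty strings.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "RelationshipMatrix",
    "NrmInverse",
    "read_pedigree",
    "prune_generations",
    "build_nrm",
    "build_nrm_inverse",
    "inbreeding",
]

#: token(s) interpreted as "parent unknown" when reading CSV files
DEFAULT_UNKNOWN_TOKENS = ("0", "", ".", "NA")

UNKNOWN = -1


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree row: an animal and its (possibly unknown) parents."""

    animal: str
    sire: str | None = None
    dam: str | None = None

    def __post_init__(self) -> None:
        if not self.animal:
            raise ValueError("animal identifier must be non-empty")
        if self.animal == self.sire or self.animal == self.dam:
            raise ValueError(f"animal {self.animal!r} is its own parent")


class Pedigree:
    """A topologically ordered pedigree.

    Internally animals are coded ``0..n-1`` in an order where every known
    parent precedes its offspring; ``sire``/``dam`` hold parent codes with
    ``-1`` for unknown.  The class is immutable in spirit: all operations
    return new objects.
    """

    def __init__(self, ids: list[str], sire: np.ndarray, dam: np.ndarray):
        self.ids = list(ids)
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate animal identifiers in pedigree")
        n = len(self.ids)
        for arr, which in ((self.sire, "sire"), (self.dam, "dam")):
            if arr.shape != (n,):
                raise ValueError(f"{which} array has wrong length")
            bad = np.nonzero(arr >= np.arange(n))[0]
            if bad.size:
                raise ValueError(
                    f"pedigree not topologically sorted at animal "
                    f"{self.ids[bad[0]]!r} (parents must come first)"
                )
        self._index = {a: i for i, a in enumerate(self.ids)}

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal: str) -> bool:
        return animal in self._index

    def index(self, animal: str) -> int:
        return self._index[animal]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Pedigree)
            and self.ids == other.ids
            and np.array_equal(self.sire, other.sire)
            and np.array_equal(self.dam, other.dam)
        )

    def __repr__(self) -> str:
        return f"Pedigree(n={len(self)})"

    # -- derived quantities ------------------------------------------------
    @property
    def generation(self) -> np.ndarray:
        """Generation index: 0 for founders, else 1 + max(parent generations)."""
        gen = np.zeros(len(self), dtype=np.int64)
        for i in range(len(self)):
            g = 0
            if self.sire[i] >= 0:
                g = gen[self.sire[i]] + 1
            if self.dam[i] >= 0:
                g = max(g, gen[self.dam[i]] + 1)
            gen[i] = g
        return gen

    def records(self) -> list[PedigreeRecord]:
        out = []
        for i, a in enumerate(self.ids):
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 else None
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 else None
            out.append(PedigreeRecord(a, s, d))
        return out

    def to_frame(self, unknown: str = "0") -> pd.DataFrame:
        ids = np.asarray(self.ids, dtype=object)
        name = lambda arr: np.where(arr >= 0, ids[np.clip(arr, 0, None)], unknown)
        return pd.DataFrame(
            {"animal": ids, "sire": name(self.sire), "dam": name(self.dam)}
        )

    def write_csv(self, path, unknown: str = "0") -> None:
        self.to_frame(unknown).to_csv(path, index=False)

    @classmethod
    def from_parent_map(
        cls, parents: dict[str, tuple[str | None, str | None]]
    ) -> "Pedigree":
        """Build a sorted pedigree from ``{animal: (sire, dam)}``.

        Animals appearing only as parents are inserted as founders.  Raises on
        cycles (naming an animal on the cycle) and on self-parenting.
        """
        parents = dict(parents)
        for a, (s, d) in list(parents.items()):
            if a in (s, d):
                raise ValueError(f"animal {a!r} is its own parent (cycle)")
            for p in (s, d):
                if p is not None and p not in parents:
                    parents[p] = (None, None)

        children: dict[str, list[str]] = {a: [] for a in parents}
        indeg = {a: 0 for a in parents}
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
        # Kahn's algorithm with a heap on the identifier: deterministic,
        # parents-before-offspring, invariant under input row permutation.
        ready = [a for a, k in indeg.items() if k == 0]
        heapq.heapify(ready)
        ids: list[str] = []
        while ready:
            a = heapq.heappop(ready)
            ids.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(ready, c)
        if len(ids) != len(parents):
            stuck = next(a for a, k in indeg.items() if k > 0)
            raise ValueError(f"pedigree cycle detected involving animal {stuck!r}")
        pos = {a: i for i, a in enumerate(ids)}
        code = lambda p: UNKNOWN if p is None else pos[p]
        sire = np.array([code(parents[a][0]) for a in ids], dtype=np.int64)
        dam = np.array([code(parents[a][1]) for a in ids], dtype=np.int64)
        return cls(ids, sire, dam)


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with per-animal inbreeding."""

    ids: list[str]
    matrix: np.ndarray  # (n, n), symmetric, diag = 1 + F
    inbreeding: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.inbreeding is None:
            self.inbreeding = np.diag(self.matrix) - 1.0


@dataclass
class NrmInverse:
    """Sparse inverse of A, plus by-products of its construction.

    ``log_det_A`` is sum(log d_i) over the Mendelian-sampling variance
    fractions d_i (A = TDT' with unit-triangular T), needed by the REML
    log-likelihood.
    """

    ids: list[str]
    matrix: sp.csr_matrix
    inbreeding: np.ndarray
    log_det_A: float


# ---------------------------------------------------------------------------
# construction and I/O


def read_pedigree(path, unknown: str | tuple[str, ...] = DEFAULT_UNKNOWN_TOKENS) -> Pedigree:
    """Read a ``animal,sire,dam`` CSV and return a topologically sorted Pedigree.

    Parameters
    ----------
    path : str or file-like
        CSV with header columns ``animal``, ``sire``, ``dam``.
    unknown : str or tuple of str
        Token(s) marking an unknown parent (besides empty cells).

    Animals referenced only as parents are inserted as founders.  Duplicate
    animal rows and pedigree cycles are hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"animal", "sire", "dam"} - set(df.columns)
    if missing:
        raise ValueError(f"pedigree CSV lacks columns: {sorted(missing)}")
    tokens = {unknown} if isinstance(unknown, str) else set(unknown)
    tokens.add("")

    def clean(v: str) -> str | None:
        v = v.strip()
        return None if v in tokens else v

    parents: dict[str, tuple[str | None, str | None]] = {}
    for a, s, d in zip(df["animal"], df["sire"], df["dam"]):
        a = a.strip()
        if not a or a in tokens:
            raise ValueError("empty or missing animal identifier in pedigree CSV")
        if a in parents:
            raise ValueError(f"duplicate animal id {a!r} in pedigree CSV")
        parents[a] = (clean(s), clean(d))
        if a in parents[a]:
            raise ValueError(f"animal {a!r} is its own parent (cycle)")
    return Pedigree.from_parent_map(parents)


def prune_generations(ped: Pedigree, focal, g: int = 6) -> Pedigree:
    """Keep focal animals plus ancestors within ``g`` parent-links.

    Parents of retained animals that fall outside the cut become unknown.
    ``g=0`` keeps the focal animals only.  One parent-link counts one
    generation.  The default of six generations matches common practice for
    deep national pedigrees.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    focal = set(focal)
    if not focal:
        raise ValueError("focal set must be non-empty")
    unknown_focal = focal - set(ped.ids)
    if unknown_focal:
        raise ValueError(f"focal animals not in pedigree: {sorted(unknown_focal)[:5]}")

    depth = {ped.index(a): 0 for a in focal}
    frontier = list(depth)
    for step in range(1, g + 1):
        nxt = []
        for i in frontier:
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0 and p not in depth:
                    depth[int(p)] = step
                    nxt.append(int(p))
        frontier = nxt
    keep = sorted(depth)
    kmap = {old: new for new, old in enumerate(keep)}

    def remap(arr):
        return np.array(
            [kmap.get(int(p), UNKNOWN) if p >= 0 else UNKNOWN for p in arr[keep]],
            dtype=np.int64,
        )

    return Pedigree([ped.ids[i] for i in keep], remap(ped.sire), remap(ped.dam))


def build_nrm(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    ``a_ij = 0.5 * (a_{j,s(i)} + a_{j,d(i)})`` for j before i, and
    ``a_ii = 1 + 0.5 * a_{s(i),d(i)}``; an unknown parent contributes 0.
    O(n^2) memory — intended for moderate pedigrees (tests, desk-scale runs);
    the mixed-model pipeline only ever needs the sparse inverse.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(list(ped.ids), A, np.diag(A) - 1.0)


def inbreeding(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding F and Mendelian-sampling variance fractions d (Meuwissen-Luo).

    ``d_i`` is 1 for founders, ``0.75 - 0.25 F_p`` with one known parent p,
    and ``0.5 - 0.25 (F_s + F_d)`` with both known.  ``a_ii`` is accumulated
    as ``sum_j L_ij^2 d_j`` by walking ancestors in decreasing code order,
    so the cost is n times the ancestor-path size rather than n^2.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, dm = sire[i], dam[i]
        if s < 0 and dm < 0:
            continue
        if s < 0:
            d[i] = 0.75 - 0.25 * F[dm]
        elif dm < 0:
            d[i] = 0.75 - 0.25 * F[s]
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        coef = {int(i): 1.0}
        aii = 0.0
        while coef:
            k = max(coef)
            c = coef.pop(k)
            aii += c * c * d[k]
            for p in (sire[k], dam[k]):
                if p >= 0:
                    coef[int(p)] = coef.get(int(p), 0.0) + 0.5 * c
        F[i] = aii - 1.0
    return F, d


def build_nrm_inverse(ped: Pedigree) -> NrmInverse:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    Never forms A densely, so it scales to tens of thousands of animals.
    For animal i with parents s, d and Mendelian fraction d_i, alpha = 1/d_i
    is added at (i,i), -alpha/2 at (i,parent), and alpha/4 between parents.
    """
    F, d = inbreeding(ped)
    n = len(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / d[i]
        add(i, i, alpha)
        known = [int(p) for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        for p in known:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in known:
            for q in known:
                add(p, q, 0.25 * alpha)
    Ainv = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n), dtype=np.float64)
    )
    return NrmInverse(list(ped.ids), Ainv, F, float(np.log(d).sum()))
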