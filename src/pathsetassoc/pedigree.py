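"""Pedigrees and the numerator (additive) relationship matrix.

The numerator relationship matrix **A** holds the expected additive genetic
relationship between every pair of pedigree members: a_ij is twice the
kinship coefficient, the diagonal is 1 + F_i where F_i is the inbreeding
coefficient. Fitted as the covariance structure of the polygenic effect,
``u ~ N(0, A * sigma_a2)``, it controls for population structure in
single-marker association models.

A is built with Henderson's tabular method: processing animals so that
parents precede offspring,

    a_ii = 1 + 0.5 * a(sire_i, dam_i)
    a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))   for j earlier than i,

with terms for unknown parents set to zero. Storage is dense; pedigrees of
a few thousand animals pose no difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "Pedigree",
    "NumeratorRelationshipMatrix",
    "build_A",
]

#: codes accepted as "parent unknown" in input files
UNKNOWN_CODES = {"0", "", ".", "NA", "nan", None}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, missing parents)."""


@dataclass
class Pedigree:
    """An ordered pedigree: animal ids plus integer parent indices.

    ``sire[i]`` / ``dam[i]`` index into ``ids``; ``-1`` marks an unknown
    parent. Records are stored in topological order (parents before
    offspring), which :meth:`from_records` establishes on load.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.ids) == self.sire.size == self.dam.size):
            raise PedigreeError("ids, sire and dam must have equal length")
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            seen: set[str] = set()
            dup = next(a for a in self.ids if a in seen or seen.add(a))
            raise PedigreeError(f"duplicate animal id: {dup!r}")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = np.flatnonzero(par >= np.arange(len(self.ids)))
            if bad.size:
                i = int(bad[0])
                raise PedigreeError(
                    f"{name} of {self.ids[i]!r} does not precede it; pedigree not topologically ordered"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    @property
    def is_founder(self) -> np.ndarray:
        """Boolean mask: True where both parents are unknown."""
        return (self.sire < 0) & (self.dam < 0)

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build a pedigree from ``(animal_id, sire_id, dam_id)`` triples.

        Parent ids matching one of the unknown codes ("0", "", ".", "NA")
        are treated as unknown. The records are topologically sorted, so
        input order is free; a parental cycle raises :class:`PedigreeError`
        naming the cycle, as does a parent id that never appears as an
        animal.
        """
        triples = []
        for rec in records:
            a, s, d = (str(x).strip() if x is not None else "" for x in rec)
            s = None if s in UNKNOWN_CODES else s
            d = None if d in UNKNOWN_CODES else d
            triples.append((a, s, d))

        ids_in = [a for a, _, _ in triples]
        if len(set(ids_in)) != len(ids_in):
            seen: set[str] = set()
            dup = next(a for a in ids_in if a in seen or seen.add(a))
            raise PedigreeError(f"duplicate animal id: {dup!r}")
        known = set(ids_in)
        for a, s, d in triples:
            for p in (s, d):
                if p is not None and p not in known:
                    raise PedigreeError(
                        f"parent {p!r} of animal {a!r} has no pedigree record; "
                        "code unknown parents as 0"
                    )

        order_in = {a: k for k, (a, _, _) in enumerate(triples)}
        graph = nx.DiGraph()
        graph.add_nodes_from(ids_in)
        for a, s, d in triples:
            for p in (s, d):
                if p is not None:
                    graph.add_edge(p, a)
        try:
            # keyed by input position so the sort is stable and reproducible
            order = list(nx.lexicographical_topological_sort(graph, key=order_in.get))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(graph)
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise PedigreeError(f"pedigree contains an ancestry cycle: {path}") from None

        pos = {a: i for i, a in enumerate(order)}
        parents = {a: (s, d) for a, s, d in triples}
        sire = np.array([pos[parents[a][0]] if parents[a][0] is not None else -1 for a in order])
        dam = np.array([pos[parents[a][1]] if parents[a][1] is not None else -1 for a in order])
        return cls(order, sire, dam)

    @classmethod
    def read_tsv(cls, path) -> "Pedigree":
        """Read a 3-column pedigree TSV (id, sire, dam; 0 = unknown), header optional."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if list(df.columns[:3]) != ["id", "sire", "dam"]:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, header=None)
        return cls.from_records(df.iloc[:, :3].itertuples(index=False, name=None))

    def to_frame(self) -> pd.DataFrame:
        sire_ids = ["0" if s < 0 else self.ids[s] for s in self.sire]
        dam_ids = ["0" if d < 0 else self.ids[d] for d in self.dam]
        return pd.DataFrame({"id": self.ids, "sire": sire_ids, "dam": dam_ids})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def drop_animal(self, animal_id: str) -> "Pedigree":
        """Remove an animal that has no descendants in the pedigree."""
        i = self.index_of(animal_id)
        if np.any(self.sire == i) or np.any(self.dam == i):
            raise PedigreeError(f"{animal_id!r} has descendants and cannot be dropped")
        keep = [a for a in self.ids if a != animal_id]
        frame = self.to_frame().set_index("id").loc[keep].reset_index()
        return Pedigree.from_records(frame.itertuples(index=False, name=None))


@dataclass
class NumeratorRelationshipMatrix:
    """Dense expected additive relationship matrix, indexed by animal id."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        self._index = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def inbreeding(self) -> pd.Series:
        """Per-animal inbreeding coefficient F_i = a_ii - 1."""
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids, name="F")

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def reindex(self, ids) -> "NumeratorRelationshipMatrix":
        """Submatrix for (a subset/reordering of) the animals."""
        idx = np.array([self._index[a] for a in ids])
        return NumeratorRelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path) -> "NumeratorRelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(list(df.index), df.to_numpy())


def build_A(pedigree: Pedigree) -> NumeratorRelationshipMatrix:
    """Numerator relationship matrix by Henderson's tabular method.

    Unknown parents contribute nothing, so founders with both parents
    unknown get a diagonal of exactly 1 and zero relationship to earlier
    animals. Runs in O(n^2) with a vectorised row update.
    """
    n = pedigree.n
    a = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += a[s, :i]
        if d >= 0:
            row += a[d, :i]
        row *= 0.5
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return NumeratorRelationshipMatrix(list(pedigree.ids), a)
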