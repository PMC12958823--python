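"""Pedigree container with validation and topological ordering."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an unknown parent.
UNKNOWN = ""


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Records of (individual, sire, dam, genetic group).

    Unknown parents are encoded as the empty string. The constructor
    validates uniqueness of ids, known-parent references, and acyclicity,
    and caches a topological order in which parents precede offspring.
    """

    table: pd.DataFrame
    _order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = ["id", "sire", "dam", "group"]
        missing = set(required) - set(self.table.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns: {sorted(missing)}")
        self.table = self.table[required].astype(
            {"id": str, "sire": str, "dam": str, "group": str}
        ).reset_index(drop=True)
        ids = self.table["id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()[:10]
            raise PedigreeError(f"duplicate individual ids: {dupes}")
        known = set(ids)
        for col in ("sire", "dam"):
            bad = [p for p in self.table[col] if p != UNKNOWN and p not in known]
            if bad:
                raise PedigreeError(f"unknown {col} ids referenced: {bad[:10]}")
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        parents = {
            row.id: [p for p in (row.sire, row.dam) if p != UNKNOWN]
            for row in self.table.itertuples()
        }
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for root in parents:
            if root in state:
                continue
            stack = [(root, iter(parents[root]))]
            state[root] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 0:
                        raise PedigreeError(f"pedigree loop involving '{p}'")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(parents[p])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    order.append(node)
                    stack.pop()
        return order

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def topological_order(self) -> list[str]:
        """Individual ids with every parent preceding its offspring."""
        return list(self._order)

    def parents_of(self, individual: str) -> tuple[str, str]:
        row = self.table.loc[self.table["id"] == individual]
        if row.empty:
            raise KeyError(individual)
        return str(row["sire"].iloc[0]), str(row["dam"].iloc[0])

    def founders(self) -> list[str]:
        t = self.table
        mask = (t["sire"] == UNKNOWN) & (t["dam"] == UNKNOWN)
        return t.loc[mask, "id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def numerator_relationship(self) -> tuple[np.ndarray, list[str]]:
        """Additive (numerator) relationship matrix by the tabular method.

        Processes individuals in topological order; unknown parents are
        treated as unrelated, non-inbred founders. Returns (A, ids) with
        ids in the pedigree's input order.
        """
        order = self._order
        pos = {ind: k for k, ind in enumerate(order)}
        n = len(order)
        sire_idx = np.full(n, -1)
        dam_idx = np.full(n, -1)
        for row in self.table.itertuples():
            k = pos[row.id]
            if row.sire != UNKNOWN:
                sire_idx[k] = pos[row.sire]
            if row.dam != UNKNOWN:
                dam_idx[k] = pos[row.dam]
        A = np.zeros((n, n))
        for i in range(n):
            s, d = sire_idx[i], dam_idx[i]
            a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
            A[i, i] = 1.0 + 0.5 * a_sd
            rel = np.zeros(i)
            if s >= 0:
                rel += 0.5 * A[s, :i]
            if d >= 0:
                rel += 0.5 * A[d, :i]
            A[i, :i] = rel
            A[:i, i] = rel
        # back to input order
        perm = [pos[i] for i in self.ids]
        return A[np.ix_(perm, perm)], self.ids
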