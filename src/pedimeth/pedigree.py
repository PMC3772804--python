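"""Pedigree parsing and additive genetic relationship matrices.

The polygenic models in this package parameterize the covariance of the
additive genetic effect as sigma_g^2 * A, where A is the numerator
(additive) relationship matrix: A[i,j] is twice the kinship coefficient
between i and j, i.e. the expected fraction of additive genetic effects
shared identically by descent. For non-inbred pedigrees A[i,i] = 1,
parent-offspring and full siblings share 0.5, grandparent-grandchild /
avuncular / half-sib / double-first-cousin pairs share 0.25, and the value
halves with each further degree of relationship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "additive_relationship",
    "pair_degree_census",
    "DEGREE_BINS",
    "REPORTING_DEGREE_TABLE",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (bad reference, cycle, lone parent)."""


#: Expected additive relationship per degree of relationship (2^-degree).
DEGREE_BINS: dict[str, float] = {
    "mz_twin": 1.0,
    "1st": 0.5,
    "2nd": 0.25,
    "3rd": 0.125,
    "4th": 0.0625,
    "5th": 0.03125,
    "6th": 0.015625,
}

#: Coefficients as conventionally printed in family-study reports for
#: distant relatives. The 3rd-6th degree entries do not follow the exact
#: halving series; they are kept verbatim for reporting/labelling only and
#: never override the recursion.
REPORTING_DEGREE_TABLE: dict[str, float] = {
    "mz_twin": 1.0,
    "1st": 0.5,
    "2nd": 0.25,
    "3rd": 0.0078,
    "4th": 0.0020,
    "5th": 0.0005,
    "6th": 0.0001,
}

_MISSING = {"0", "", ".", "NA"}


@dataclass(frozen=True)
class Individual:
    iid: str
    family: str
    father: str | None
    mother: str | None
    sex: str  # "male" | "female" | "unknown"
    twin_group: str | None = None  # monozygotic-twin group label


@dataclass
class Pedigree:
    """Directed parentage graph over individuals.

    Invariants (enforced on construction): every named parent exists, each
    individual has zero or two recorded parents, and parentage is acyclic.
    """

    individuals: list[Individual]

    _index: dict[str, Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for ind in self.individuals:
            if ind.iid in self._index:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self._index[ind.iid] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals:
            n_parents = sum(p is not None for p in (ind.father, ind.mother))
            if n_parents == 1:
                raise PedigreeError(
                    f"individual {ind.iid!r} has exactly one recorded parent; "
                    "pedigrees must record both parents or neither"
                )
            for role, pid in (("father", ind.father), ("mother", ind.mother)):
                if pid is not None and pid not in self._index:
                    raise PedigreeError(
                        f"{role} {pid!r} of individual {ind.iid!r} "
                        "is not in the pedigree"
                    )
        self.topological_order()  # raises on cycles

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __getitem__(self, iid: str) -> Individual:
        return self._index[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    @property
    def founders(self) -> list[str]:
        return [i.iid for i in self.individuals if i.father is None]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        ind = self._index[iid]
        return ind.father, ind.mother

    def topological_order(self) -> list[str]:
        """Order ids so every parent precedes its offspring (Kahn's algorithm).

        Raises PedigreeError listing a cycle if the parentage graph is cyclic.
        """
        n_unplaced_parents = {
            i.iid: sum(p is not None for p in (i.father, i.mother))
            for i in self.individuals
        }
        children: dict[str, list[str]] = {i.iid: [] for i in self.individuals}
        for ind in self.individuals:
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    children[pid].append(ind.iid)
        ready = [iid for iid, k in n_unplaced_parents.items() if k == 0]
        order: list[str] = []
        while ready:
            iid = ready.pop()
            order.append(iid)
            for child in children[iid]:
                n_unplaced_parents[child] -= 1
                if n_unplaced_parents[child] == 0:
                    ready.append(child)
        if len(order) < len(self.individuals):
            stuck = sorted(set(self._index) - set(order))
            cycle = _find_cycle(self, stuck)
            raise PedigreeError(
                "cyclic parentage involving: " + " -> ".join(cycle)
            )
        return order

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": i.family,
                "iid": i.iid,
                "father": i.father or "0",
                "mother": i.mother or "0",
                "sex": {"male": "1", "female": "2"}.get(i.sex, "0"),
                "twin_group": i.twin_group or "0",
            }
            for i in self.individuals
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        """Write PED-style whitespace-delimited file (0 = missing)."""
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)


def _find_cycle(ped: Pedigree, stuck: list[str]) -> list[str]:
    """Walk parent links from a stuck node until a repeat appears."""
    seen: list[str] = []
    cur = stuck[0]
    while cur not in seen:
        seen.append(cur)
        f, m = ped.parents(cur)
        cur = f if f in stuck else m  # some parent must also be stuck
    return seen[seen.index(cur):] + [cur]


def _parse_sex(token: str) -> str:
    t = token.strip().upper()
    if t in {"1", "M", "MALE"}:
        return "male"
    if t in {"2", "F", "FEMALE"}:
        return "female"
    return "unknown"


def read_pedigree(path) -> Pedigree:
    """Read a PED-style whitespace-delimited pedigree file.

    Columns: family, individual, father, mother, sex; "0" marks a missing
    parent. An optional sixth column labels monozygotic-twin groups
    ("0" = none). Founders are individuals with both parents missing.
    """
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >=5 columns "
                    f"(family iid father mother sex), got {len(parts)}"
                )
            fam, iid, fa, mo, sex = parts[:5]
            twin = parts[5] if len(parts) > 5 else "0"
            individuals.append(
                Individual(
                    iid=iid,
                    family=fam,
                    father=None if fa in _MISSING else fa,
                    mother=None if mo in _MISSING else mo,
                    sex=_parse_sex(sex),
                    twin_group=None if twin in _MISSING else twin,
                )
            )
    return Pedigree(individuals)


@dataclass
class RelationshipMatrix:
    """Pairwise additive genetic relationship matrix.

    ``A[i,j]`` is the expected additive genetic covariance between
    individuals ``ids[i]`` and ``ids[j]`` in units of sigma_g^2 (twice the
    kinship coefficient). ``degree_table`` carries the conventional
    reporting coefficients per relationship degree.
    """

    ids: list[str]
    A: np.ndarray
    degree_table: dict[str, float] = field(
        default_factory=lambda: dict(REPORTING_DEGREE_TABLE)
    )

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError(f"A has shape {self.A.shape}, expected ({n},{n})")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric")

    def coefficient(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.A[i, j])

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return RelationshipMatrix(
            ids=list(ids), A=self.A[np.ix_(idx, idx)],
            degree_table=dict(self.degree_table),
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.A)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Compute A by the standard tabular recursion.

    Individuals are processed parents-first; for j processed before i:

        A[i,i] = 1 + 0.5 * A[father(i), mother(i)]   (1 for founders)
        A[i,j] = 0.5 * (A[j, father(i)] + A[j, mother(i)])  (0 for founders)

    Founders are assumed non-inbred and mutually unrelated. Members of a
    monozygotic-twin group (same ``twin_group`` label) are genetically
    identical: their pairwise coefficient is forced to 1. Their rows toward
    third parties already coincide because co-twins share both parents.
    """
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, iid in enumerate(order):
        fa, mo = ped.parents(iid)
        if fa is None:
            A[i, i] = 1.0
        else:
            f, m = pos[fa], pos[mo]
            A[i, i] = 1.0 + 0.5 * A[f, m]
            for j in range(i):
                A[i, j] = A[j, i] = 0.5 * (A[j, f] + A[j, m])

    twin_groups: dict[str, list[int]] = {}
    for iid in order:
        g = ped[iid].twin_group
        if g is not None:
            twin_groups.setdefault(g, []).append(pos[iid])
    for members in twin_groups.values():
        for a in members:
            for b in members:
                if a != b:
                    A[a, b] = 1.0

    # report in the pedigree's own order
    rm = RelationshipMatrix(ids=order, A=A)
    return rm.subset(ped.ids)


def pair_degree_census(
    rel: RelationshipMatrix,
    bins: dict[str, float] | None = None,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Count individual pairs per relationship-degree bin.

    Each unordered pair is assigned the degree label whose expected
    coefficient matches its A entry within ``atol``; zero coefficients are
    reported as ``unrelated`` and unmatched coefficients (e.g. from
    intermarriage) as ``other`` — never dropped silently.
    """
    if bins is None:
        bins = DEGREE_BINS
    labels = list(bins) + ["unrelated", "other"]
    counts = {lab: 0 for lab in labels}
    n = len(rel.ids)
    for i in range(n):
        for j in range(i + 1, n):
            a = rel.A[i, j]
            if abs(a) <= atol:
                counts["unrelated"] += 1
                continue
            for lab, coef in bins.items():
                if abs(a - coef) <= atol:
                    counts[lab] += 1
                    break
            else:
                counts["other"] += 1
    out = pd.DataFrame(
        {"degree": labels, "pairs": [counts[lab] for lab in labels]}
    )
    return out[out["pairs"] > 0].reset_index(drop=True) if n else out.iloc[:0]
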