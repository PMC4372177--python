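"""Pedigrees and kinship coefficients.

The random-effect covariance of the association models is ``2 * Phi * sigma_g^2``
where ``Phi`` is the matrix of pairwise kinship coefficients ``phi_ij``: the
probability that one allele drawn at random from individual *i* and one from *j*
are identical by descent. ``2 * phi_ij`` is then the expected proportion of
alleles the pair shares IBD (1/2 for parent-offspring or full siblings, 1/4 for
avuncular pairs, 1/8 for first cousins, and so on down the classic table of
relationship classes).

Kinship is computed by the standard recursion over the pedigree graph:

    phi(i, i) = 1/2 + 1/2 * phi(father(i), mother(i))
    phi(i, j) = 1/2 * (phi(father(i), j) + phi(mother(i), j))

with the second rule applied to whichever member of the pair appears in a later
generation, and founders pairwise unrelated. Inbred matings are handled by the
recursion (``phi_ii`` may exceed 1/2) although the bundled simulator never
produces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "kinship",
    "kinship_matrix",
]

MISSING = "0"

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent, bad id)."""


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "female" | "male" | "unknown"
    family_id: str

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated, acyclic collection of :class:`Individual` records.

    A parent referenced but not listed is treated as an unobserved founder
    only when exactly one parent is missing (the half-relationship encoding);
    a named parent id that does not resolve to a member raises
    :class:`PedigreeError`.
    """

    def __init__(self, members: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self._members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._members:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown parent {pid!r}"
                    )
        # cycle check: DFS over parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        color = {iid: WHITE for iid in self._members}

        def visit(iid: str, stack: list[str]) -> None:
            color[iid] = GREY
            stack.append(iid)
            ind = self._members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                if color[pid] == GREY:
                    cyc = stack[stack.index(pid):] + [pid]
                    raise PedigreeError(
                        "pedigree cycle involving " + " -> ".join(cyc)
                    )
                if color[pid] == WHITE:
                    visit(pid, stack)
            stack.pop()
            color[iid] = BLACK

        for iid in self._members:
            if color[iid] == WHITE:
                visit(iid, [])

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._members[iid]
        except KeyError:
            raise KeyError(f"individual {iid!r} not in pedigree") from None

    def __iter__(self):
        return iter(self._members.values())

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self._members.values() if m.is_founder]

    @property
    def families(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for m in self._members.values():
            fams.setdefault(m.family_id, []).append(m)
        return fams

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._members == other._members


@dataclass
class KinshipMatrix:
    """Pairwise kinship over an ordered sample set.

    ``phi`` holds the kinship coefficients; the association models use
    ``two_phi = 2 * phi``, whose diagonal is 1 for non-inbred individuals.
    """

    sample_ids: list[str]
    phi: np.ndarray

    @property
    def two_phi(self) -> np.ndarray:
        return 2.0 * self.phi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(sample_ids=[str(c) for c in df.columns], phi=df.to_numpy(float))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    """Read a PED-like file: FID IID FATHER MOTHER SEX, whitespace/tab split.

    "0" or an empty field marks a missing parent; sex codes are 1=male,
    2=female, 0=unknown.
    """
    members: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected 5 columns (FID IID FATHER MOTHER SEX), "
                    f"got {len(fields)}"
                )
            fid, iid, fa, mo, sex = fields[:5]
            members.append(
                Individual(
                    id=iid,
                    father_id=None if fa in (MISSING, "") else fa,
                    mother_id=None if mo in (MISSING, "") else mo,
                    sex=SEX_CODES.get(sex, "unknown"),
                    family_id=fid,
                )
            )
    return Pedigree(members)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.id,
                        ind.father_id or MISSING,
                        ind.mother_id or MISSING,
                        SEX_TO_CODE[ind.sex],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def _depths(ped: Pedigree) -> dict[str, int]:
    depth: dict[str, int] = {}

    def d(iid: str) -> int:
        if iid in depth:
            return depth[iid]
        ind = ped[iid]
        parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
        depth[iid] = 0 if not parents else 1 + max(d(p) for p in parents)
        return depth[iid]

    for iid in ped.ids:
        d(iid)
    return depth


def _kinship_fn(ped: Pedigree):
    depth = _depths(ped)

    @lru_cache(maxsize=None)
    def phi(i: str, j: str) -> float:
        if i == j:
            ind = ped[i]
            if ind.father_id is not None and ind.mother_id is not None:
                return 0.5 + 0.5 * phi(*sorted((ind.father_id, ind.mother_id)))
            return 0.5
        # recurse on the later-generation member
        a, b = (i, j) if depth[i] >= depth[j] else (j, i)
        ind = ped[a]
        if ind.is_founder:
            return 0.0
        total = 0.0
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                total += 0.5 * phi(*sorted((pid, b)))
        return total

    return phi


def kinship(ped: Pedigree, i: str, j: str) -> float:
    """Kinship coefficient ``phi_ij`` for two pedigree members."""
    for iid in (i, j):
        if iid not in ped:
            raise KeyError(f"individual {iid!r} not in pedigree")
    if ped[i].family_id != ped[j].family_id:
        return 0.0
    return _kinship_fn(ped)(*sorted((i, j)))


def kinship_matrix(ped: Pedigree, sample_ids: Sequence[str] | None = None) -> KinshipMatrix:
    """Kinship matrix over ``sample_ids`` (defaults to all members, file order).

    Members of different families have ``phi = 0``; duplicate ids are an error.
    """
    if sample_ids is None:
        sample_ids = ped.ids
    sample_ids = [str(s) for s in sample_ids]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in kinship_matrix request")
    for iid in sample_ids:
        if iid not in ped:
            raise KeyError(f"individual {iid!r} not in pedigree")
    phi_fn = _kinship_fn(ped)
    n = len(sample_ids)
    out = np.zeros((n, n))
    fam = {iid: ped[iid].family_id for iid in sample_ids}
    for a in range(n):
        for b in range(a, n):
            i, j = sample_ids[a], sample_ids[b]
            if fam[i] != fam[j]:
                continue
            out[a, b] = out[b, a] = phi_fn(*sorted((i, j)))
    return KinshipMatrix(sample_ids=list(sample_ids), phi=out)
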