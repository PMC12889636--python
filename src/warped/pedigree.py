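"""Pedigree data model, PED-style I/O, validation and patrilineal lineages.

A pedigree here is the relationship graph over individuals with recorded
sexes — the only "phenotype" used anywhere in this package.  No molecular
genotypes appear: the recorded sex of each individual is treated as a
perfect marker for the sex chromosomes, so a patrilineal (father-to-son)
line of males is a proxy for a single identical-by-descent Y chromosome.

Two validation modes exist.  ``strict`` enforces that every individual
referenced as a father is recorded male and every mother female.
``permissive`` waives that check: sex-permuted pedigrees (see
:mod:`warped.permutation`) keep the parent/child topology fixed while
shuffling sex labels, which can place a female label in a father role.
"""

from __future__ import annotations

import sys
from collections import deque
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_CODES = {
    "1": MALE, "m": MALE, "male": MALE,
    "2": FEMALE, "f": FEMALE, "female": FEMALE,
    "0": UNKNOWN, "u": UNKNOWN, "unknown": UNKNOWN,
}
_SEX_OUT = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
_MISSING = {"", "0"}


class PedigreeError(ValueError):
    """Base class for pedigree parse/validation failures."""


class PedigreeParseError(PedigreeError):
    pass


class PedigreeValidationError(PedigreeError):
    pass


@dataclass(frozen=True)
class Individual:
    """One pedigree member: an id, a recorded sex and optional parent links."""

    id: str
    sex: str = UNKNOWN
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeValidationError("individual id must be non-empty")
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise PedigreeValidationError(
                f"invalid sex {self.sex!r} for individual {self.id!r}"
            )


@dataclass(frozen=True)
class Lineage:
    """A patrilineal line: father→son chains rooted at a single founder male.

    ``n_transmissions`` counts every child (of either sex) whose father is a
    lineage member; these are the informative transmissions assayed by the
    transmission disequilibrium test.  Sex-unknown children count toward
    ``n_transmissions`` but toward neither sex tally.
    """

    founder_id: str
    member_ids: tuple[str, ...]
    transmitting_father_ids: frozenset[str]
    n_transmissions: int
    n_male: int
    n_female: int
    generations: int


class Pedigree:
    """Validated collection of :class:`Individual` plus graph indexes.

    Parameters
    ----------
    individuals
        The pedigree members; ids must be unique.
    mode
        ``"strict"`` (fathers male, mothers female) or ``"permissive"``.
    provenance
        Free-text label recording where the pedigree came from.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        mode: str = "strict",
        provenance: str = "",
        _validate: bool = True,
    ) -> None:
        if mode not in ("strict", "permissive"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.provenance = provenance
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeParseError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        # children indexed by the parental role, not the parent's sex label
        self._children_of_father: dict[str, list[str]] = {}
        self._children_of_mother: dict[str, list[str]] = {}
        for ind in self._members.values():
            if ind.father_id is not None:
                self._children_of_father.setdefault(ind.father_id, []).append(ind.id)
            if ind.mother_id is not None:
                self._children_of_mother.setdefault(ind.mother_id, []).append(ind.id)
        if _validate:
            self._validate()
        self._depths: Optional[dict[str, int]] = None

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __getitem__(self, individual_id: str) -> Individual:
        return self._members[individual_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._members == other._members

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def children_of(self, father_id: str) -> list[str]:
        """Ids of children listing ``father_id`` in the father role."""
        return list(self._children_of_father.get(father_id, ()))

    def maternal_children_of(self, mother_id: str) -> list[str]:
        return list(self._children_of_mother.get(mother_id, ()))

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for ind in self._members.values():
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                parent = self._members.get(pid)
                if parent is None:
                    raise PedigreeParseError(
                        f"individual {ind.id!r} references unknown {role} {pid!r}"
                    )
                if self.mode == "strict":
                    want = MALE if role == "father" else FEMALE
                    if parent.sex != want:
                        raise PedigreeValidationError(
                            f"{role} {pid!r} of {ind.id!r} is recorded "
                            f"{parent.sex}, expected {want} (strict mode)"
                        )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative three-colour DFS over parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        colour = dict.fromkeys(self._members, WHITE)
        for start in self._members:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, bool]] = [(start, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    colour[node] = BLACK
                    continue
                if colour[node] == BLACK:
                    continue
                if colour[node] == GREY:
                    raise PedigreeValidationError(
                        f"cyclic ancestry involving individual {node!r}"
                    )
                colour[node] = GREY
                stack.append((node, True))
                ind = self._members[node]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is not None and colour[pid] != BLACK:
                        if colour[pid] == GREY:
                            raise PedigreeValidationError(
                                f"cyclic ancestry involving individual {pid!r}"
                            )
                        stack.append((pid, False))

    # -- derived quantities -------------------------------------------------

    def founders(self) -> set[str]:
        """Ids with neither a recorded father nor a recorded mother."""
        return {
            i.id
            for i in self._members.values()
            if i.father_id is None and i.mother_id is None
        }

    def patriline_roots(self) -> set[str]:
        """Ids lacking only a recorded father (candidate patriline roots)."""
        return {i.id for i in self._members.values() if i.father_id is None}

    def generation_depths(self) -> dict[str, int]:
        """Longest ancestor-chain length per individual (founders at 0)."""
        if self._depths is not None:
            return self._depths
        depths: dict[str, int] = {}

        def depth(node: str) -> int:
            # iterative to survive very deep pedigrees
            stack = [node]
            while stack:
                n = stack[-1]
                if n in depths:
                    stack.pop()
                    continue
                ind = self._members[n]
                parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
                pending = [p for p in parents if p not in depths]
                if pending:
                    stack.extend(pending)
                    continue
                depths[n] = 1 + max((depths[p] for p in parents), default=-1)
                stack.pop()
            return depths[node]

        for i in self._members:
            depth(i)
        self._depths = depths
        return depths

    def with_sexes(self, sexes: dict[str, str], provenance: str = "") -> "Pedigree":
        """Copy of this pedigree with reassigned sexes, in permissive mode.

        Topology (parent edges) is preserved by construction, so validation
        is skipped; used by the sex-permutation null.
        """
        new = [
            replace(ind, sex=sexes.get(ind.id, ind.sex))
            for ind in self._members.values()
        ]
        return Pedigree(new, mode="permissive", provenance=provenance, _validate=False)

    # -- graph queries ------------------------------------------------------

    def neighbors(self, individual_id: str) -> list[str]:
        """Parents and children of an individual (undirected adjacency)."""
        ind = self._members[individual_id]
        out = [p for p in (ind.father_id, ind.mother_id) if p is not None]
        out.extend(self._children_of_father.get(individual_id, ()))
        out.extend(self._children_of_mother.get(individual_id, ()))
        return out


def undirected_distance(
    ped: Pedigree, a: str, b: str, max_radius: int
) -> Optional[int]:
    """Shortest undirected path length between ``a`` and ``b``.

    Uses only parent-child edges.  Returns ``None`` ("beyond") when the
    distance exceeds ``max_radius``.  Full siblings and half siblings are
    both at distance 2 (edges are counted, not shared parents).
    """
    for x in (a, b):
        if x not in ped:
            raise KeyError(f"unknown individual id {x!r}")
    if max_radius < 0:
        raise ValueError("max_radius must be >= 0")
    if a == b:
        return 0
    seen = {a}
    frontier = [a]
    for dist in range(1, max_radius + 1):
        nxt: list[str] = []
        for node in frontier:
            for nb in ped.neighbors(node):
                if nb == b:
                    return dist
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
        if not frontier:
            break
    return None


def within_radius(ped: Pedigree, start: str, max_radius: int) -> set[str]:
    """All ids within ``max_radius`` undirected edges of ``start`` (excl.)."""
    seen = {start}
    frontier = [start]
    out: set[str] = set()
    for _ in range(max_radius):
        nxt: list[str] = []
        for node in frontier:
            for nb in ped.neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
                    out.add(nb)
        frontier = nxt
        if not frontier:
            break
    return out


def _lineage_eligible(ped: Pedigree, ind: Individual) -> bool:
    # Lineage membership follows the father ROLE so that sex permutation
    # keeps lineage topology fixed: a child stays in the patriline if male
    # or if it itself occupies a father role.  On strict pedigrees every
    # father is male, so this reduces to plain father→son chains.
    return ind.sex == MALE or ind.id in ped._children_of_father


def patrilineal_lineages(ped: Pedigree) -> list[Lineage]:
    """One :class:`Lineage` per patriline root, in sorted root order.

    A root is an individual without a recorded father that is male or
    occupies a father role.  Members are the root plus everything reachable
    through father→son edges (father→father-role edges in permissive
    pedigrees).  Lineages are disjoint over members.
    """
    depths = ped.generation_depths()
    lineages = []
    roots = sorted(
        i.id
        for i in ped
        if i.father_id is None and _lineage_eligible(ped, i)
    )
    for root in roots:
        members: list[str] = []
        queue = deque([root])
        while queue:
            node = queue.popleft()
            members.append(node)
            for child_id in sorted(ped._children_of_father.get(node, ())):
                if _lineage_eligible(ped, ped[child_id]):
                    queue.append(child_id)
        n_trans = n_male = n_female = 0
        fathers = []
        for m in members:
            kids = ped._children_of_father.get(m, ())
            if kids:
                fathers.append(m)
            for k in kids:
                n_trans += 1
                sex = ped[k].sex
                if sex == MALE:
                    n_male += 1
                elif sex == FEMALE:
                    n_female += 1
        gens = max(depths[m] for m in members) - depths[root] + 1
        lineages.append(
            Lineage(
                founder_id=root,
                member_ids=tuple(members),
                transmitting_father_ids=frozenset(fathers),
                n_transmissions=n_trans,
                n_male=n_male,
                n_female=n_female,
                generations=gens,
            )
        )
    return lineages


def informative_transmissions(
    ped: Pedigree, lineage: Lineage
) -> tuple[int, int, int, frozenset[str]]:
    """Recount ``(n_transmissions, n_male, n_female, transmitting_fathers)``.

    Counts every child whose father is a lineage member; sex-unknown
    children enter the total but neither sex tally.
    """
    n = n_m = n_f = 0
    fathers = set()
    for member in lineage.member_ids:
        kids = ped.children_of(member)
        if kids:
            fathers.add(member)
        for k in kids:
            n += 1
            sex = ped[k].sex
            if sex == MALE:
                n_m += 1
            elif sex == FEMALE:
                n_f += 1
    return n, n_m, n_f, frozenset(fathers)


# -- I/O --------------------------------------------------------------------


def read_pedigree(
    source: IO[str], mode: str = "strict", provenance: str = ""
) -> Pedigree:
    """Parse a PED-style table: ``id father mother sex``, tab or whitespace
    separated; ``0`` or empty denotes a missing parent; sex codes 1/M/male,
    2/F/female, 0/U/unknown; ``#`` lines are comments."""
    individuals = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise PedigreeParseError(
                f"line {lineno}: expected 4 columns (id father mother sex), "
                f"got {len(fields)}"
            )
        iid, father, mother, sex_code = (f.strip() for f in fields[:4])
        sex = _SEX_CODES.get(sex_code.lower())
        if sex is None:
            raise PedigreeParseError(
                f"line {lineno}: unrecognized sex code {sex_code!r}"
            )
        individuals.append(
            Individual(
                id=iid,
                sex=sex,
                father_id=None if father in _MISSING else father,
                mother_id=None if mother in _MISSING else mother,
            )
        )
    return Pedigree(individuals, mode=mode, provenance=provenance)


def write_pedigree(ped: Pedigree, sink: IO[str] = sys.stdout) -> None:
    """Write the canonical PED-style table (rows sorted by id)."""
    sink.write("#id\tfather\tmother\tsex\n")
    for iid in sorted(ped.ids):
        ind = ped[iid]
        sink.write(
            "\t".join(
                (
                    ind.id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    _SEX_OUT[ind.sex],
                )
            )
            + "\n"
        )
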