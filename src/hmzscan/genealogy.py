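"""Population genealogy: meiotic distance and carrier-couple discovery.

The genealogy is a directed acyclic graph of parent -> child edges with
vital dates. Meiotic distance between two individuals is the minimum,
over their common ancestors c, of the number of meioses from each up to
c (parent-child = 1, full siblings = 2, first cousins = 4). Paths run
strictly upward, so spouses who share only a child have no meiotic
distance.

Carrier couples — a male and a female, both heterozygous for the same
variant, linked by one or more shared offspring — are the key unit for
recessive-lethality follow-up: each of their conceptions has a 25%
chance of being homozygous.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

MALE, FEMALE, UNKNOWN = "male", "female", "unknown"


@dataclass
class Person:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    birth_year: int | None = None
    death_year: int | None = None
    alive: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def death_age(self) -> int | None:
        if self.birth_year is None or self.death_year is None:
            return None
        return self.death_year - self.birth_year


class Genealogy:
    """Validated pedigree with ancestor queries.

    Construct via :func:`load_genealogy` (which validates) or directly
    from a dict of Person when the invariants are known to hold.
    """

    def __init__(self, individuals: dict[str, Person], current_year: int | None = None):
        self.individuals = individuals
        self.current_year = current_year
        self._children: dict[tuple[str, str], list[str]] = {}
        for p in individuals.values():
            if p.father_id is not None and p.mother_id is not None:
                self._children.setdefault((p.father_id, p.mother_id), []).append(p.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    @property
    def founders(self) -> list[str]:
        return [p.id for p in self.individuals.values() if p.is_founder]

    def parents(self, ind_id: str) -> list[str]:
        p = self.individuals[ind_id]
        return [x for x in (p.father_id, p.mother_id) if x is not None]

    def shared_offspring(self, father_id: str, mother_id: str) -> list[str]:
        return list(self._children.get((father_id, mother_id), []))

    def couples_with_offspring(self) -> list[tuple[str, str]]:
        return sorted(self._children)

    def ancestor_depths(self, ind_id: str) -> dict[str, int]:
        """Minimum meiosis count from ind_id up to each ancestor (self = 0)."""
        if ind_id not in self.individuals:
            raise KeyError(f"unknown individual: {ind_id}")
        depths = {ind_id: 0}
        queue = deque([ind_id])
        while queue:
            cur = queue.popleft()
            d = depths[cur] + 1
            for par in self.parents(cur):
                if par not in depths or d < depths[par]:
                    depths[par] = d
                    queue.append(par)
        return depths

    def generation_levels(self) -> list[list[str]]:
        """Individuals grouped by pedigree depth (founders first).

        Level of a non-founder is 1 + max(parent levels); every parent
        therefore appears in an earlier level than its children.
        """
        children_of: dict[str, list[str]] = {}
        pending: dict[str, int] = {}
        level: dict[str, int] = {}
        queue: deque[str] = deque()
        for p in self.individuals.values():
            pars = self.parents(p.id)
            pending[p.id] = len(pars)
            if not pars:
                level[p.id] = 0
                queue.append(p.id)
            for par in pars:
                children_of.setdefault(par, []).append(p.id)
        while queue:
            cur = queue.popleft()
            for child in children_of.get(cur, []):
                level[child] = max(level.get(child, 0), level[cur] + 1)
                pending[child] -= 1
                if pending[child] == 0:
                    queue.append(child)
        if len(level) != len(self.individuals):
            raise ValueError("pedigree contains a cycle")
        out: list[list[str]] = [[] for _ in range(max(level.values(), default=0) + 1)]
        for ind in self.individuals:  # preserve insertion order within levels
            out[level[ind]].append(ind)
        return out

    def _digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for p in self.individuals.values():
            for par in self.parents(p.id):
                g.add_edge(par, p.id)
        return g


def load_genealogy(
    records: Iterable[Person | dict], current_year: int | None = None
) -> Genealogy:
    """Build and validate a Genealogy from person records.

    Dangling parent references are materialised as founders (with a
    warning); cycles and parent-sex inconsistencies raise ValueError.
    """
    individuals: dict[str, Person] = {}
    for rec in records:
        p = rec if isinstance(rec, Person) else Person(**rec)
        if p.id in individuals:
            raise ValueError(f"duplicate individual id: {p.id}")
        individuals[p.id] = p

    # materialise dangling parents as founders
    for p in list(individuals.values()):
        for par_id, sex in ((p.father_id, MALE), (p.mother_id, FEMALE)):
            if par_id is not None and par_id not in individuals:
                logger.warning(
                    "parent %s of %s not in pedigree; added as founder", par_id, p.id
                )
                individuals[par_id] = Person(id=par_id, sex=sex, alive=False)

    # sex consistency: infer unknown parental sex, reject contradictions
    for p in individuals.values():
        if p.father_id is not None:
            f = individuals[p.father_id]
            if f.sex == FEMALE:
                raise ValueError(
                    f"{f.id} listed as father of {p.id} but recorded female"
                )
            if f.sex == UNKNOWN:
                f.sex = MALE
        if p.mother_id is not None:
            m = individuals[p.mother_id]
            if m.sex == MALE:
                raise ValueError(
                    f"{m.id} listed as mother of {p.id} but recorded male"
                )
            if m.sex == UNKNOWN:
                m.sex = FEMALE
        if (
            p.birth_year is not None
            and p.death_year is not None
            and p.death_year < p.birth_year
        ):
            raise ValueError(f"{p.id}: death_year precedes birth_year")

    g = Genealogy(individuals, current_year=current_year)
    dg = g._digraph()
    if not nx.is_directed_acyclic_graph(dg):
        cycle = nx.find_cycle(dg)
        raise ValueError(f"pedigree contains a cycle through {cycle[0][0]}")
    return g


def meiotic_distance(g: Genealogy, a: str, b: str) -> int | None:
    """Minimum meioses linking a and b through a common ancestor.

    None when no common ancestor exists. Paths are strictly upward from
    each individual (no up-down-up mixing).
    """
    if a == b:
        raise ValueError("meiotic distance requires two distinct individuals")
    da = g.ancestor_depths(a)
    db = g.ancestor_depths(b)
    common = da.keys() & db.keys()
    if not common:
        return None
    return min(da[c] + db[c] for c in common)


@dataclass(frozen=True)
class OffspringFlag:
    offspring_id: str
    death_age: int | None  # None if alive or vital dates missing
    early_death: bool | None  # None = undetermined (deceased, dates missing)


@dataclass(frozen=True)
class CarrierCouple:
    """A male-female pair, both carriers, linked by shared offspring."""

    father_id: str
    mother_id: str
    shared_offspring: tuple[str, ...]
    offspring_flags: tuple[OffspringFlag, ...]

    @property
    def n_offspring(self) -> int:
        return len(self.shared_offspring)

    @property
    def expected_hmz_offspring(self) -> float:
        """Expected homozygotes among offspring: each conception has a 1/4 risk."""
        return 0.25 * self.n_offspring

    @property
    def prob_at_least_one_hmz(self) -> float:
        return 1.0 - 0.75**self.n_offspring


def _offspring_flag(p: Person, age_threshold: int) -> OffspringFlag:
    if p.alive and p.death_year is None:
        return OffspringFlag(p.id, None, False)
    age = p.death_age
    if age is None:
        return OffspringFlag(p.id, None, None)  # deceased, dates missing
    return OffspringFlag(p.id, age, age < age_threshold)


def find_carrier_couples(
    g: Genealogy, carriers: set[str], age_threshold: int = 8
) -> list[CarrierCouple]:
    """All male-female pairs, both in ``carriers``, sharing >= 1 offspring.

    Offspring early-death flags use a strict ``death age < age_threshold``
    comparison (default 8 years). Output ordered by (father_id, mother_id).
    Individuals of unknown sex cannot form couples.
    """
    couples: list[CarrierCouple] = []
    for father_id, mother_id in g.couples_with_offspring():
        if father_id not in carriers or mother_id not in carriers:
            continue
        if father_id not in g or mother_id not in g:
            continue
        if g.individuals[father_id].sex != MALE:
            continue
        if g.individuals[mother_id].sex != FEMALE:
            continue
        kids = sorted(
            g.shared_offspring(father_id, mother_id),
            key=lambda k: (
                g.individuals[k].birth_year
                if g.individuals[k].birth_year is not None
                else 0,
                k,
            ),
        )
        flags = tuple(_offspring_flag(g.individuals[k], age_threshold) for k in kids)
        couples.append(
            CarrierCouple(
                father_id=father_id,
                mother_id=mother_id,
                shared_offspring=tuple(kids),
                offspring_flags=flags,
            )
        )
    return couples


def flag_candidate_homozygotes(
    g: Genealogy, couples: Sequence[CarrierCouple], age_threshold: int = 8
) -> list[tuple[str, CarrierCouple, bool | None]]:
    """Flatten carrier-couple offspring with early-death flags.

    Offspring of carrier couples are the candidate homozygotes; those who
    died before ``age_threshold`` years are flagged (None when deceased
    with missing vital dates).
    """
    out: list[tuple[str, CarrierCouple, bool | None]] = []
    for couple in couples:
        for kid in couple.shared_offspring:
            flag = _offspring_flag(g.individuals[kid], age_threshold)
            out.append((kid, couple, flag.early_death))
    return out
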