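"""Seeded synthetic pedigrees with optional planted distorters.

The real study population (a restricted multigenerational genealogy) is
not distributable, so every fixture used elsewhere in this package is
generated here: forward-simulated multi-generation pedigrees with
ground-truth carrier labels, a deterministic reconstruction of the focal
male-biased family's printed transmission totals, and a fixed "null"
topology for calibration suites where only the sex labels are random.

The forward simulator mirrors the Warp genetic model: a carrier father's
children are of the favored sex with probability ``true_penetrance`` and
carrier status follows the chromosome of the chosen mode.  Family sizes
are Poisson (large-historical-family mean of 2.5 by default); spouses
marry in from outside the pedigree, so generated pedigrees are non-inbred
trees unless loops are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .bp import MODE_FEMALE_X, MODE_MALE_Y, _MODE_ALIASES
from .pedigree import FEMALE, MALE, Individual, Pedigree


@dataclass(frozen=True)
class PlantedDistorter:
    """A distorter planted in the father of one founder couple."""

    founder_index: int = 0
    mode: str = MODE_MALE_Y
    true_penetrance: float = 0.90
    true_de_novo_rate: float = 0.0

    def __post_init__(self) -> None:
        mode = _MODE_ALIASES.get(str(self.mode).lower())
        if mode is None:
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        if not (0.0 <= self.true_penetrance <= 1.0):
            raise ValueError("true_penetrance must be in [0, 1]")
        if not (0.0 <= self.true_de_novo_rate <= 1.0):
            raise ValueError("true_de_novo_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    n_founder_couples: int = 10
    n_generations: int = 4
    offspring_mean: float = 2.5
    mating_prob: float = 0.8
    planted_distorter: Optional[PlantedDistorter] = None
    base_male_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founder_couples < 1 or self.n_generations < 1:
            raise ValueError("counts must be >= 1")
        if self.offspring_mean < 0:
            raise ValueError("offspring_mean must be >= 0")
        for name in ("mating_prob", "base_male_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TruthLabels:
    carrier_ids: frozenset[str]


def generate_pedigree(config: SimConfig) -> tuple[Pedigree, TruthLabels]:
    """Forward-simulate one pedigree; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    plant = config.planted_distorter
    favored = MALE if (plant is None or plant.mode == MODE_MALE_Y) else FEMALE
    y_mode = plant is None or plant.mode == MODE_MALE_Y

    individuals: list[Individual] = []
    carriers: set[str] = set()
    # couples: (father_id, mother_id)
    couples: list[tuple[str, str]] = []
    for i in range(config.n_founder_couples):
        f, m = f"F{i}a", f"F{i}b"
        individuals.append(Individual(id=f, sex=MALE))
        individuals.append(Individual(id=m, sex=FEMALE))
        couples.append((f, m))
        if plant is not None and i == plant.founder_index:
            carriers.add(f)

    counter = 0
    for _gen in range(1, config.n_generations):
        next_couples: list[tuple[str, str]] = []
        for father, mother in couples:
            n_kids = int(rng.poisson(config.offspring_mean))
            f_carrier = father in carriers
            m_carrier = mother in carriers
            for _ in range(n_kids):
                counter += 1
                cid = f"I{counter}"
                p_fav = (
                    plant.true_penetrance
                    if (plant is not None and f_carrier)
                    else config.base_male_prob
                    if favored == MALE
                    else 1.0 - config.base_male_prob
                )
                sex = favored if rng.random() < p_fav else (
                    FEMALE if favored == MALE else MALE
                )
                individuals.append(
                    Individual(id=cid, sex=sex, father_id=father, mother_id=mother)
                )
                if plant is not None:
                    dn = plant.true_de_novo_rate
                    if y_mode:
                        q = (
                            0.0 if sex != MALE
                            else (1.0 - dn) if f_carrier else dn
                        )
                    else:
                        p_pat = (1.0 - dn) if (f_carrier and sex == FEMALE) else 0.0
                        p_mat = 0.5 * (1.0 - dn) if m_carrier else 0.0
                        q = 1.0 - (1.0 - p_pat) * (1.0 - p_mat) * (1.0 - dn)
                    if q > 0.0 and rng.random() < q:
                        carriers.add(cid)
                if rng.random() < config.mating_prob:
                    counter += 1
                    sid = f"S{counter}"
                    spouse_sex = FEMALE if sex == MALE else MALE
                    individuals.append(Individual(id=sid, sex=spouse_sex))
                    if sex == MALE:
                        next_couples.append((cid, sid))
                    else:
                        next_couples.append((sid, cid))
        couples = next_couples
    if not individuals:
        raise ValueError("configuration produced zero individuals")
    return (
        Pedigree(individuals, provenance=f"simulated(seed={config.seed})"),
        TruthLabels(carrier_ids=frozenset(carriers)),
    )


def null_dataset(config: SimConfig, n_datasets: int) -> Iterator[
    tuple[Pedigree, TruthLabels]
]:
    """Independent null replicates (seeds config.seed+1 .. +n_datasets)."""
    if config.planted_distorter is not None:
        raise ValueError("null_dataset requires a config with no distorter")
    for i in range(1, n_datasets + 1):
        yield generate_pedigree(replace(config, seed=config.seed + i))


# -- the focal family ------------------------------------------------------

# Sibship plan for the reconstruction of the focal family: father path ->
# (n_sons, n_daughters).  Paths are hierarchical ("P.s2.s1" = first son of
# the progenitor's second son).  The four printed sibships (progenitor: two
# sons; first son: 5 of 6 male; second son: a single son; that grandson:
# 8 of 11 male) are exact; the remaining sibships are padding chosen so the
# lineage totals 33 transmitting fathers, 89 transmissions, 60 male and 29
# female over seven generations, with no padding sibship more male-biased
# than the printed ones.  This is a totals-matching reconstruction — the
# true family's internal structure is unpublished.
_FOCAL_PLAN: dict[str, tuple[int, int]] = {
    "P": (2, 0),
    "P.s1": (5, 1),
    "P.s2": (1, 0),
    "P.s2.s1": (8, 3),
    # sons of P.s1
    "P.s1.s1": (2, 1), "P.s1.s2": (2, 1), "P.s1.s3": (2, 1),
    "P.s1.s4": (2, 1), "P.s1.s5": (2, 1),
    # sons of P.s2.s1
    "P.s2.s1.s1": (2, 1), "P.s2.s1.s2": (2, 1), "P.s2.s1.s3": (2, 1),
    "P.s2.s1.s4": (2, 1), "P.s2.s1.s5": (2, 1), "P.s2.s1.s6": (2, 1),
    "P.s2.s1.s7": (2, 1), "P.s2.s1.s8": (2, 1),
    # generation 5-6 padding, including the chain that reaches generation 7
    "P.s2.s1.s1.s1": (1, 1),
    "P.s2.s1.s1.s1.s1": (1, 1),
    "P.s1.s1.s1": (2, 1), "P.s1.s2.s1": (2, 1),
    "P.s1.s3.s1": (1, 1), "P.s1.s4.s1": (1, 1), "P.s1.s5.s1": (1, 1),
    "P.s2.s1.s2.s1": (1, 1), "P.s2.s1.s3.s1": (1, 1),
    "P.s2.s1.s4.s1": (1, 1), "P.s2.s1.s5.s1": (1, 1),
    "P.s2.s1.s6.s1": (1, 1),
    "P.s2.s1.s7.s1": (1, 0), "P.s2.s1.s8.s1": (1, 0),
    "P.s1.s1.s2": (1, 0), "P.s1.s2.s2": (1, 0),
}


def focal_family_fixture() -> Pedigree:
    """Deterministic reconstruction of the focal male-biased patriline.

    The returned pedigree holds one seven-generation patriline whose
    lineage totals are exactly 33 transmitting fathers and 89 informative
    transmissions (60 male, 29 female, 67.4% male); each father's wife is
    an in-marrying founder female.
    """
    members: dict[str, Individual] = {
        "P": Individual(id="P", sex=MALE)
    }
    for path in sorted(_FOCAL_PLAN, key=lambda p: (p.count("."), p)):
        n_sons, n_daughters = _FOCAL_PLAN[path]
        if path not in members:
            raise AssertionError(f"sibship plan lists unknown father {path!r}")
        wife = f"{path}.w"
        members[wife] = Individual(id=wife, sex=FEMALE)
        for j in range(1, n_sons + 1):
            sid = f"{path}.s{j}"
            members[sid] = Individual(
                id=sid, sex=MALE, father_id=path, mother_id=wife
            )
        for j in range(1, n_daughters + 1):
            did = f"{path}.d{j}"
            members[did] = Individual(
                id=did, sex=FEMALE, father_id=path, mother_id=wife
            )
    return Pedigree(members.values(), provenance="focal-family reconstruction")


# -- fixed null topology for calibration -----------------------------------


def fixed_null_topology(
    n_lineages: int = 500, n_fathers: int = 64, kids_per_father: int = 16
) -> Pedigree:
    """Deterministic forest of patrilines for null-calibration suites.

    Each lineage is a chain of ``n_fathers`` fathers in which every father
    has ``kids_per_father`` children, one of whom (except under the last
    father) is the next father in the chain.  All sexes start male; pair
    with :func:`randomize_sexes` to draw the iid fair-coin sex labels of a
    null dataset over this fixed topology.  Large per-lineage transmission
    counts (the default is 1024) keep the chi-squared p-value lattice fine
    enough for distribution-level checks.
    """
    individuals = []
    for li in range(n_lineages):
        prev = None
        for fj in range(n_fathers):
            fid = f"L{li}F{fj}"
            individuals.append(
                Individual(id=fid, sex=MALE, father_id=prev)
            )
            for k in range(kids_per_father - (1 if fj + 1 < n_fathers else 0)):
                cid = f"L{li}F{fj}c{k}"
                individuals.append(Individual(id=cid, sex=MALE, father_id=fid))
            prev = fid
    return Pedigree(individuals, provenance="fixed null topology")


def randomize_sexes(ped: Pedigree, seed: int, p_male: float = 0.5) -> Pedigree:
    """Assign every individual an iid coin-flip sex (permissive pedigree)."""
    rng = np.random.default_rng(seed)
    draws = rng.random(len(ped))
    sexes = {
        iid: (MALE if draws[k] < p_male else FEMALE)
        for k, iid in enumerate(ped.ids)
    }
    return ped.with_sexes(sexes, provenance=f"randomized sexes(seed={seed})")
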