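import numpy as np
import pytest

from warped import Individual, ModelParams, Pedigree


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture
def founder_sons_pedigree():
    """Founder father with four sons (the classic male-biased sibship)."""
    inds = [Individual("f", "male")] + [
        Individual(f"s{i}", "male", father_id="f") for i in range(4)
    ]
    return Pedigree(inds)


@pytest.fixture
def cousin_pedigree():
    """Hand-built 8-person pedigree: grandparents, two married sons, one
    child each — first cousins are at undirected distance 4."""
    return Pedigree(
        [
            Individual("g1", "male"),
            Individual("g2", "female"),
            Individual("a", "male", father_id="g1", mother_id="g2"),
            Individual("b", "male", father_id="g1", mother_id="g2"),
            Individual("wa", "female"),
            Individual("wb", "female"),
            Individual("ca", "male", father_id="a", mother_id="wa"),
            Individual("cb", "female", father_id="b", mother_id="wb"),
        ]
    )


@pytest.fixture
def toy_lineage_pedigree():
    """Male founder M1 with sons M2, M3 and daughter F1; M2 has son M4 and
    daughter F2 — the worked patriline example."""
    return Pedigree(
        [
            Individual("M1", "male"),
            Individual("M2", "male", father_id="M1"),
            Individual("M3", "male", father_id="M1"),
            Individual("F1", "female", father_id="M1"),
            Individual("M4", "male", father_id="M2"),
            Individual("F2", "female", father_id="M2"),
        ]
    )


def random_tree_pedigree(rng: np.random.Generator, n_target: int) -> Pedigree:
    """Random non-inbred pedigree of at most ``n_target`` individuals.

    Spouses marry in from outside, so the family factor graph is a tree
    (belief propagation is exact); sexes include occasional unknowns and
    parent links are occasionally missing.
    """
    inds = [Individual("f0", "male"), Individual("m0", "female")]
    couples = [("f0", "m0")]
    k = 0
    while len(inds) < n_target and couples:
        f, m = couples.pop(0)
        for _ in range(int(rng.integers(0, 4))):
            if len(inds) >= n_target:
                break
            k += 1
            sex = str(rng.choice(["male", "female", "unknown"], p=[0.45, 0.45, 0.1]))
            father = f if rng.random() < 0.9 else None
            mother = m if rng.random() < 0.9 else None
            cid = f"c{k}"
            inds.append(Individual(cid, sex, father, mother))
            if sex != "unknown" and rng.random() < 0.6 and len(inds) + 1 < n_target:
                k += 1
                spouse = f"s{k}"
                inds.append(
                    Individual(spouse, "female" if sex == "male" else "male")
                )
                couples.append((cid, spouse) if sex == "male" else (spouse, cid))
    return Pedigree(inds, mode="permissive")
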