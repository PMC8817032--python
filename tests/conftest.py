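import numpy as np
import pytest

from hmzscan.genealogy import Genealogy, Person, load_genealogy


@pytest.fixture
def cousin_pedigree() -> Genealogy:
    """Three generations: two siblings whose children are first cousins.

    gp_m x gp_f -> sib_m, sib_f; sib_m x wife -> cousin_a;
    sib_f x husband -> cousin_b.
    """
    rows = [
        Person("gp_m", sex="male", birth_year=1900),
        Person("gp_f", sex="female", birth_year=1902),
        Person("sib_m", "gp_m", "gp_f", "male", 1925),
        Person("sib_f", "gp_m", "gp_f", "female", 1927),
        Person("wife", sex="female", birth_year=1926),
        Person("husband", sex="male", birth_year=1924),
        Person("cousin_a", "sib_m", "wife", "male", 1950),
        Person("cousin_b", "husband", "sib_f", "female", 1952),
    ]
    return load_genealogy(rows)


@pytest.fixture
def carrier_couples_pedigree() -> tuple[Genealogy, set[str]]:
    """Three carrier couples with ten offspring, four dead before age 8
    (at ages 2, 7, 4 and 5), plus a fourth couple with a single carrier.

    Returns (genealogy, carrier set). Carrier couples: (f1, m1) with 4
    offspring, (f2, m2) with 3, (f3, m3) with 3.
    """
    def kid(i, father, mother, birth, death_age=None):
        death = None if death_age is None else birth + death_age
        return Person(f"o{i}", father, mother, "female" if i % 2 else "male",
                      birth, death, alive=death is None)

    rows = [
        Person("f1", sex="male", birth_year=1930),
        Person("m1", sex="female", birth_year=1932),
        Person("f2", sex="male", birth_year=1928),
        Person("m2", sex="female", birth_year=1930),
        Person("f3", sex="male", birth_year=1935),
        Person("m3", sex="female", birth_year=1936),
        Person("f4", sex="male", birth_year=1931),
        Person("m4", sex="female", birth_year=1933),
        kid(1, "f1", "m1", 1955, death_age=2),
        kid(2, "f1", "m1", 1957, death_age=7),
        kid(3, "f1", "m1", 1959),
        kid(4, "f1", "m1", 1961),
        kid(5, "f2", "m2", 1954, death_age=4),
        kid(6, "f2", "m2", 1956, death_age=5),
        kid(7, "f2", "m2", 1958),
        kid(8, "f3", "m3", 1960),
        kid(9, "f3", "m3", 1962),
        kid(10, "f3", "m3", 1964),
        # f4 is a carrier but m4 is not: never a carrier couple
        kid(11, "f4", "m4", 1957),
    ]
    carriers = {"f1", "m1", "f2", "m2", "f3", "m3", "f4"}
    return load_genealogy(rows), carriers


def random_pedigree(rng: np.random.Generator, n_max: int = 100) -> Genealogy:
    """Random valid pedigree for property tests: individuals added in
    order, each with probability ~0.7 given two random earlier parents
    of compatible sex (or founder status otherwise)."""
    persons: list[Person] = []
    males: list[str] = []
    females: list[str] = []
    n = int(rng.integers(2, n_max + 1))
    for i in range(n):
        pid = f"i{i:03d}"
        sex = "male" if rng.random() < 0.5 else "female"
        father = mother = None
        if males and females and rng.random() < 0.7:
            father = males[int(rng.integers(len(males)))]
            mother = females[int(rng.integers(len(females)))]
        persons.append(Person(pid, father, mother, sex, birth_year=1900 + i))
        (males if sex == "male" else females).append(pid)
    return load_genealogy(persons)
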