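"""Gene-drop synthesis of founder-population cohorts.

Builds a multi-generation pedigree, drops founder alleles down it under
Mendelian transmission, and applies recessive embryonic lethality: a
conception homozygous for a variant with lethality s is, with
probability s, converted to a miscarriage recorded against the mother
(the individual is never instantiated). Baseline miscarriages are added
so that each conception independently miscarries at the configured
background rate. Ascertainment then samples living adults into a
genotyped cohort, which is what depletes homozygotes for early-lethal
variants and creates the deficit signal the screen looks for.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genealogy import FEMALE, MALE, Genealogy, Person
from .screen import VariantSummary

EARLY_WEEK_CLASS = "<13"
LATE_WEEK_CLASS = ">=13"


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant: founder MAF and recessive lethality s.

    ``s`` is the probability that a homozygous conception ends as an
    (early) miscarriage. ``hom_survives_to_sampling`` models the
    distinct mechanism of live-born homozygotes dying before adulthood
    (stillbirth / childhood death); 1.0 disables it.
    """

    variant_id: str
    maf: float
    s: float = 0.0
    consequence: str = "missense"
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "G"
    hom_survives_to_sampling: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.variant_id}: founder MAF must be in [0, 0.5]")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"{self.variant_id}: lethality s must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic founder-population cohort.

    Defaults describe a reduced-scale founder population: stationary-ish
    growth (mean 2.4 offspring per couple), a 15% background miscarriage
    rate per conception (clinically reported rates are 12-24%), adult-only
    ascertainment at 18 years, and high simulated imputation info
    (uniform on [0.95, 1.0] — variants common enough for this screen
    impute well; lower the bounds to exercise the info filter).
    """

    n_founders: int = 1000
    n_generations: int = 3
    mean_offspring: float = 2.4
    variants: tuple[VariantSpec, ...] = ()
    baseline_miscarriage_rate: float = 0.15
    early_week_fraction: float = 0.8  # baseline miscarriages in class "<13"
    sampling_min_age: int = 18
    participation_rate: float = 0.7
    consanguinity_rate: float = 0.0
    consanguinity_max_distance: int = 6
    info_low: float = 0.95
    info_high: float = 1.0
    founder_birth_year: int = 1900
    mother_age_min: int = 20
    mother_age_max: int = 35  # exclusive
    lifespan_mean: float = 80.0
    lifespan_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders % 2:
            raise ValueError("n_founders must be even")
        if self.mean_offspring <= 0:
            raise ValueError("mean_offspring must be > 0")
        for p in (
            self.baseline_miscarriage_rate,
            self.early_week_fraction,
            self.participation_rate,
            self.consanguinity_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if isinstance(self.variants, list):
            object.__setattr__(self, "variants", tuple(self.variants))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        variants = []
        for i, v in enumerate(d.pop("variants", [])):
            if isinstance(v, dict):
                variants.append(VariantSpec(**v))
            else:  # (variant_id, maf, s) tuples
                vid, maf, s = v
                variants.append(VariantSpec(variant_id=vid, maf=maf, s=s, pos=i + 1))
        return cls(variants=tuple(variants), **d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def demo(cls, n_neutral: int = 199, seed: int = 0) -> "SimConfig":
        """A cohort of roughly 20,000 genotyped adults carrying one fully
        lethal variant at founder MAF 2% (expected homozygotes ~ 8) among
        matched neutral variants of the same founder MAF."""
        variants = [
            VariantSpec(variant_id="lethal_0001", maf=0.02, s=1.0, pos=1)
        ] + [
            VariantSpec(variant_id=f"neutral_{i:04d}", maf=0.02, s=0.0, pos=i + 2)
            for i in range(n_neutral)
        ]
        return cls(
            n_founders=12000,
            n_generations=2,
            mean_offspring=2.4,
            participation_rate=0.6,
            variants=tuple(variants),
            seed=seed,
        )


@dataclass
class SimOutput:
    """Gene-drop results, before or after ascertainment."""

    genealogy: Genealogy
    genotypes: pd.DataFrame  # live-born individuals x variants, values 0/1/2
    miscarriage_records: pd.DataFrame  # mother_id, birth_year, pregnancies, ...
    truth: pd.DataFrame  # variant_id, maf, s
    current_year: int
    cohort_ids: list[str] | None = None
    summaries: list[VariantSummary] | None = None

    @property
    def n_cohort(self) -> int:
        if self.cohort_ids is None:
            raise ValueError("cohort not ascertained yet")
        return len(self.cohort_ids)


def _ancestor_depths_from(anc: dict[str, dict[str, int]], ind: str) -> dict[str, int]:
    return anc[ind]


def _related(anc_a: dict[str, int], anc_b: dict[str, int], max_dist: int) -> bool:
    common = anc_a.keys() & anc_b.keys()
    return any(anc_a[c] + anc_b[c] <= max_dist for c in common)


def build_pedigree(config: SimConfig, rng: np.random.Generator) -> Genealogy:
    """Forward-build a pedigree: founders in generation 0, then random
    monogamous pairing within each generation (consanguineous with
    probability ``consanguinity_rate``, otherwise explicitly unrelated
    beyond ``consanguinity_max_distance`` meioses) and Poisson offspring
    counts per couple. Acyclic by construction."""
    ids: list[str] = []
    father: list[str | None] = []
    mother: list[str | None] = []
    sex: list[str] = []
    birth: list[int] = []
    # merged parental ancestor-depth maps, used for relatedness checks
    anc: dict[str, dict[str, int]] = {}

    def add(ind_id, f, m, sx, by):
        ids.append(ind_id)
        father.append(f)
        mother.append(m)
        sex.append(sx)
        birth.append(by)
        d = {ind_id: 0}
        for par in (f, m):
            if par is not None:
                for a, k in anc[par].items():
                    if a not in d or k + 1 < d[a]:
                        d[a] = k + 1
        anc[ind_id] = d

    half = config.n_founders // 2
    jitter = rng.integers(-3, 4, size=config.n_founders)
    for i in range(config.n_founders):
        add(
            f"G0-{i:06d}",
            None,
            None,
            MALE if i < half else FEMALE,
            config.founder_birth_year + int(jitter[i]),
        )

    gen_members = list(range(config.n_founders))
    for g in range(1, config.n_generations + 1):
        males = [i for i in gen_members if sex[i] == MALE]
        females = [i for i in gen_members if sex[i] == FEMALE]
        rng.shuffle(males)
        rng.shuffle(females)
        pairs: list[tuple[int, int]] = []
        free = list(females)
        for mi in males:
            if not free:
                break
            want_kin = rng.random() < config.consanguinity_rate
            chosen = None
            fallback = None
            for j, fi in enumerate(free):
                rel = _related(
                    anc[ids[mi]], anc[ids[fi]], config.consanguinity_max_distance
                )
                if want_kin and rel:
                    chosen = j
                    break
                if not want_kin and not rel:
                    chosen = j
                    break
                if want_kin and not rel and fallback is None:
                    fallback = j  # no kin available -> settle for unrelated
            if chosen is None:
                chosen = fallback
            if chosen is None:
                continue  # no acceptable mate; stays childless
            fi = free[chosen]
            free[chosen] = free[-1]  # O(1) swap-pop; order is already shuffled
            free.pop()
            pairs.append((mi, fi))
        if not pairs:
            raise RuntimeError(f"population extinct at generation {g}: no couples")
        counts = rng.poisson(config.mean_offspring, size=len(pairs))
        next_gen: list[int] = []
        child_no = 0
        for (mi, fi), c in zip(pairs, counts):
            if c == 0:
                continue
            ages = rng.integers(config.mother_age_min, config.mother_age_max, size=c)
            sexes = rng.integers(0, 2, size=c)
            for a, sx in zip(ages, sexes):
                idx = len(ids)
                add(
                    f"G{g}-{child_no:06d}",
                    ids[mi],
                    ids[fi],
                    MALE if sx == 0 else FEMALE,
                    birth[fi] + int(a),
                )
                child_no += 1
                next_gen.append(idx)
        if not next_gen:
            raise RuntimeError(f"population extinct at generation {g}: no offspring")
        gen_members = next_gen

    current_year = max(birth[i] for i in gen_members) + config.sampling_min_age
    lifespans = np.maximum(
        0, np.rint(rng.normal(config.lifespan_mean, config.lifespan_sd, size=len(ids)))
    ).astype(int)
    individuals: dict[str, Person] = {}
    for i, ind_id in enumerate(ids):
        death = birth[i] + int(lifespans[i])
        alive = death > current_year
        individuals[ind_id] = Person(
            id=ind_id,
            father_id=father[i],
            mother_id=mother[i],
            sex=sex[i],
            birth_year=birth[i],
            death_year=None if alive else death,
            alive=alive,
        )
    return Genealogy(individuals, current_year=current_year)


def gene_drop(
    g: Genealogy, config: SimConfig, rng: np.random.Generator
) -> SimOutput:
    """Drop founder alleles down the pedigree and apply lethality.

    Founder genotypes are Binomial(2, MAF) per variant; each conception
    receives one uniformly chosen allele per parent. A conception
    homozygous for a variant with lethality s miscarries with probability
    s (recorded to the mother; the individual and any pedigree
    descendants are never instantiated). Baseline miscarriages are added
    per mother so each conception independently miscarries at
    ``baseline_miscarriage_rate`` (Poisson thinning: extra miscarried
    conceptions ~ Poisson(k * b / (1 - b)) on top of k live conceptions).
    """
    levels = g.generation_levels()
    order = [ind for level in levels for ind in level]
    idx = {ind: i for i, ind in enumerate(order)}
    m_total = len(order)
    specs = config.variants
    n_var = len(specs)
    mafs = np.array([v.maf for v in specs])
    s_vec = np.array([v.s for v in specs])

    geno = np.zeros((m_total, n_var), dtype=np.int8)
    conceived = np.zeros(m_total, dtype=bool)  # conception actually occurred
    miscarried = np.zeros(m_total, dtype=bool)
    lethal_misc_by_mother = np.zeros(m_total, dtype=np.int64)
    conceptions_by_mother = np.zeros(m_total, dtype=np.int64)

    founders = levels[0] if levels else []
    f_idx = np.array([idx[i] for i in founders], dtype=np.intp)
    conceived[f_idx] = True
    if n_var:
        # founders are themselves survivors of the lethality process, so
        # their genotypes come from HWE proportions with the homozygote
        # class thinned by (1 - s): {(1-q)^2, 2q(1-q), q^2 (1-s)} renormalised
        p0 = (1.0 - mafs) ** 2
        p1 = 2.0 * mafs * (1.0 - mafs)
        p2 = mafs**2 * (1.0 - s_vec)
        tot = p0 + p1 + p2
        u = rng.random((len(founders), n_var))
        geno[f_idx, :] = (
            (u > p0 / tot).astype(np.int8) + (u > (p0 + p1) / tot).astype(np.int8)
        )

    for level in levels[1:]:
        c_idx = np.array([idx[i] for i in level], dtype=np.intp)
        fa = np.array([idx[g.individuals[i].father_id] for i in level], dtype=np.intp)
        mo = np.array([idx[g.individuals[i].mother_id] for i in level], dtype=np.intp)
        ok = (
            conceived[fa]
            & conceived[mo]
            & ~miscarried[fa]
            & ~miscarried[mo]
        )
        if n_var:
            gt = (
                rng.random((len(level), n_var)) < geno[fa, :] / 2.0
            ).astype(np.int8) + (
                rng.random((len(level), n_var)) < geno[mo, :] / 2.0
            ).astype(np.int8)
            geno[c_idx, :] = gt
            p_death = 1.0 - np.prod(1.0 - s_vec * (gt == 2), axis=1)
            death_draw = rng.random(len(level)) < p_death
        else:
            death_draw = np.zeros(len(level), dtype=bool)
        conceived[c_idx] = ok
        misc = ok & death_draw
        miscarried[c_idx] = misc
        np.add.at(conceptions_by_mother, mo[ok], 1)
        np.add.at(lethal_misc_by_mother, mo[misc], 1)

    live = conceived & ~miscarried

    # childhood death of live-born homozygotes (stillbirth / early death
    # mechanisms that remove homozygotes before adult ascertainment)
    for v, spec in enumerate(specs):
        if spec.hom_survives_to_sampling < 1.0:
            hom = live & (geno[:, v] == 2)
            dies = hom & (rng.random(m_total) > spec.hom_survives_to_sampling)
            for i in np.flatnonzero(dies):
                p = g.individuals[order[i]]
                p.alive = False
                p.death_year = (p.birth_year or 0) + int(rng.integers(0, 8))

    # baseline miscarriages via Poisson thinning
    b = config.baseline_miscarriage_rate
    mother_mask = conceptions_by_mother > 0
    mother_idx = np.flatnonzero(mother_mask)
    k = conceptions_by_mother[mother_idx]
    extras = (
        rng.poisson(k * b / (1.0 - b)) if b > 0 else np.zeros(len(k), dtype=np.int64)
    )
    extras_early = rng.binomial(extras, config.early_week_fraction)
    lethal = lethal_misc_by_mother[mother_idx]

    records = pd.DataFrame(
        {
            "mother_id": [order[i] for i in mother_idx],
            "birth_year": [g.individuals[order[i]].birth_year for i in mother_idx],
            "pregnancies": k + extras,
            "miscarriages": lethal + extras,
            "n_early": lethal + extras_early,  # lethal homozygotes miscarry early
            "n_late": extras - extras_early,
        }
    )

    live_ids = [order[i] for i in np.flatnonzero(live)]
    pruned = Genealogy(
        {i: g.individuals[i] for i in live_ids}, current_year=g.current_year
    )
    genotypes = pd.DataFrame(
        geno[live, :],
        index=pd.Index(live_ids, name="individual"),
        columns=[v.variant_id for v in specs],
    )
    truth = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in specs],
            "maf": mafs,
            "s": s_vec,
        }
    )
    return SimOutput(
        genealogy=pruned,
        genotypes=genotypes,
        miscarriage_records=records,
        truth=truth,
        current_year=g.current_year,
    )


def ascertain_cohort(
    out: SimOutput, config: SimConfig, rng: np.random.Generator
) -> SimOutput:
    """Sample living adults into the genotyped cohort and summarise.

    Cohort = alive individuals aged >= sampling_min_age, each included
    with ``participation_rate``. Per-variant genotype counts become
    VariantSummary records with simulated imputation info drawn uniformly
    from [info_low, info_high]."""
    cy = out.current_year
    eligible = [
        p.id
        for p in out.genealogy.individuals.values()
        if p.alive and p.birth_year is not None and cy - p.birth_year >= config.sampling_min_age
    ]
    take = rng.random(len(eligible)) < config.participation_rate
    cohort = [i for i, t in zip(eligible, take) if t]
    if not cohort:
        raise RuntimeError("ascertained cohort is empty")

    gmat = out.genotypes.loc[cohort].to_numpy()
    info = rng.uniform(config.info_low, config.info_high, size=len(config.variants))
    summaries = []
    for v, spec in enumerate(config.variants):
        col = gmat[:, v]
        summaries.append(
            VariantSummary(
                variant_id=spec.variant_id,
                chrom=spec.chrom,
                pos=spec.pos,
                ref=spec.ref,
                alt=spec.alt,
                n_hom_ref=int(np.sum(col == 0)),
                n_het=int(np.sum(col == 1)),
                n_hom_alt=int(np.sum(col == 2)),
                n_missing=0,
                imputation_info=float(info[v]),
                consequence=spec.consequence,
            )
        )
    return replace(out, cohort_ids=cohort, summaries=summaries)


def simulate(config: SimConfig, rng: np.random.Generator | None = None) -> SimOutput:
    """build_pedigree -> gene_drop -> ascertain_cohort, one seeded pass."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = build_pedigree(config, rng)
    out = gene_drop(g, config, rng)
    return ascertain_cohort(out, config, rng)
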