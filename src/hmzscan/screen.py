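"""Deficit-of-homozygosity screen under Hardy-Weinberg equilibrium.

Given per-variant cohort genotype summaries, the screen computes the
expected number of minor-allele homozygotes E = q**2 * N (optionally with
an inbreeding adjustment), compares it with the observed count O, and
flags variants with a *complete deficit*: zero observed homozygotes at a
minor allele frequency high enough that, rounded to the nearest integer
(half-up), at least ``min_expected`` homozygotes would be expected. An
exact lower-tail binomial p-value quantifies each deficit, with
Benjamini-Hochberg adjustment across the scanned set.

This is the screening strategy used to discover recessive-lethal and
severe early-onset recessive genotypes in large founder-population
cohorts, where ascertainment of living adults depletes homozygotes for
such variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

CONSEQUENCE_CLASSES = ("missense", "pLoF", "other")


def normalize_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix, case-insensitively ('chr2' -> '2')."""
    s = str(chrom).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def round_half_up(x: float) -> int:
    """Nearest-integer rounding with ties away from zero toward +inf."""
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class VariantSummary:
    """Per-variant cohort genotype summary.

    Genotype counts refer to diploid hard calls; ``maf`` may be supplied
    directly when counts are unavailable (e.g. published frequencies), in
    which case ``n_hom_alt`` is interpreted as the observed count of
    minor-allele homozygotes.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    n_hom_ref: int | None = None
    n_het: int | None = None
    n_hom_alt: int | None = None
    n_missing: int = 0
    maf: float | None = None
    imputation_info: float | None = None
    consequence: str = "missense"

    @property
    def has_counts(self) -> bool:
        return (
            self.n_hom_ref is not None
            and self.n_het is not None
            and self.n_hom_alt is not None
        )

    @property
    def n_genotyped(self) -> int | None:
        if not self.has_counts:
            return None
        return self.n_hom_ref + self.n_het + self.n_hom_alt


class MafResult(NamedTuple):
    maf: float
    minor_is_alt: bool


@dataclass(frozen=True)
class ScreenConfig:
    """Filters and conventions for the deficit screen.

    min_expected
        Minimum rounded expected homozygote count for a variant to be
        eligible for a complete-deficit call (default 3).
    info_min
        Imputation-information cutoff; variants must exceed it strictly.
        Variants with no info score (directly genotyped) always pass.
    autosomes_only
        Drop variants not on chromosomes 1-22 (sex chromosomes violate
        the diploid HWE expectation used here).
    maf_min
        Explicit MAF cutoff, or "auto" to derive the smallest MAF whose
        rounded expectation reaches ``min_expected``.
    consequence_filter
        Consequence classes retained by the scan.
    inbreeding_f
        Optional inbreeding coefficient F; the homozygote frequency
        becomes q**2 + F*q*(1-q). Plain HWE when 0.
    """

    min_expected: int = 3
    info_min: float = 0.9
    autosomes_only: bool = True
    maf_min: float | str = "auto"
    consequence_filter: frozenset[str] = frozenset({"missense"})
    inbreeding_f: float = 0.0

    def __post_init__(self) -> None:
        if self.min_expected < 1:
            raise ValueError("min_expected must be >= 1")
        if not 0.0 <= self.info_min <= 1.0:
            raise ValueError("info_min must be in [0, 1]")


@dataclass(frozen=True)
class DeficitRecord:
    """One scanned variant's expected-vs-observed homozygote comparison."""

    variant_id: str
    maf: float
    n_genotyped: int
    expected_hmz: float
    expected_rounded: int
    observed_hmz: int
    oe_ratio: float | None
    p_deficit: float
    q_value: float
    complete_deficit: bool


def compute_maf(summary: VariantSummary) -> MafResult:
    """Minor allele frequency from hard-call genotype counts.

    Returns the folded frequency min(f, 1-f) of the alt allele fraction f
    among non-missing genotypes, and whether the minor allele is alt
    (ties at 0.5 count alt as minor).
    """
    if not summary.has_counts:
        raise ValueError(f"{summary.variant_id}: genotype counts absent")
    n_called = summary.n_genotyped
    if n_called == 0:
        raise ValueError(
            f"{summary.variant_id}: all genotypes missing, MAF uncomputable"
        )
    f_alt = (summary.n_het + 2 * summary.n_hom_alt) / (2 * n_called)
    if f_alt <= 0.5:
        return MafResult(f_alt, True)
    return MafResult(1.0 - f_alt, False)


def expected_homozygotes(maf: float, n: int, inbreeding_f: float = 0.0) -> float:
    """Expected minor-allele homozygote count under HWE: E = q**2 * N.

    With a nonzero inbreeding coefficient F the homozygote frequency is
    q**2 + F*q*(1-q) (Wright's adjustment).
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    if n < 1:
        raise ValueError("n must be >= 1")
    p_hom = maf * maf + inbreeding_f * maf * (1.0 - maf)
    return p_hom * n


def maf_threshold(n: int, min_expected: int = 3) -> float:
    """Smallest MAF whose rounded expected homozygote count reaches min_expected.

    round-half-up(q**2 * n) >= m first holds when q**2 * n >= m - 0.5,
    i.e. q = sqrt((m - 0.5) / n).
    """
    if n < 1 or min_expected < 1:
        raise ValueError("n and min_expected must be >= 1")
    q = math.sqrt((min_expected - 0.5) / n)
    # guard the defining property against one-ulp rounding of the sqrt
    while round_half_up(q * q * n) < min_expected:
        q = math.nextafter(q, 1.0)
    return q


def deficit_pvalue(
    observed: int, maf: float, n: int, inbreeding_f: float = 0.0
) -> float:
    """Exact lower-tail binomial probability P(X <= observed), X ~ Bin(n, q**2).

    For observed = 0 this is (1 - q**2)**n, the probability of seeing no
    homozygotes at all under HWE.
    """
    if not 0 <= observed <= n:
        raise ValueError("observed must be in [0, n]")
    p_hom = maf * maf + inbreeding_f * maf * (1.0 - maf)
    return float(binom.cdf(observed, n, p_hom))


def scan(
    cohort: Sequence[VariantSummary],
    n: int,
    config: ScreenConfig | None = None,
) -> list[DeficitRecord]:
    """Run the deficit screen over a cohort of variant summaries.

    Variants failing the consequence, imputation-info, autosome, or MAF
    filters are dropped. Surviving variants get one DeficitRecord each;
    BH q-values are computed across the emitted records only. Output is
    sorted by variant_id, so the scan is invariant to input order.
    """
    config = config or ScreenConfig()
    rows: list[tuple[str, float, int, int]] = []  # (id, maf, observed, n_eff)
    for s in cohort:
        if s.consequence not in config.consequence_filter:
            continue
        if config.autosomes_only and normalize_chrom(s.chrom) not in AUTOSOMES:
            continue
        if s.imputation_info is not None and s.imputation_info <= config.info_min:
            continue
        if s.has_counts:
            res = compute_maf(s)
            q = res.maf
            observed = s.n_hom_alt if res.minor_is_alt else s.n_hom_ref
            n_eff = n - s.n_missing
        else:
            if s.maf is None:
                raise ValueError(
                    f"{s.variant_id}: neither genotype counts nor MAF supplied"
                )
            if s.n_hom_alt is None:
                raise ValueError(
                    f"{s.variant_id}: observed homozygote count (n_hom_alt) "
                    "required when counts absent"
                )
            q, observed, n_eff = s.maf, s.n_hom_alt, n
        cutoff = (
            maf_threshold(n_eff, config.min_expected)
            if config.maf_min == "auto"
            else float(config.maf_min)
        )
        if q < cutoff:
            continue
        rows.append((s.variant_id, q, observed, n_eff))

    if not rows:
        logger.warning("deficit scan: no variants survived the filters")
        return []

    rows.sort(key=lambda r: r[0])
    records: list[DeficitRecord] = []
    pvals: list[float] = []
    for vid, q, observed, n_eff in rows:
        e = expected_homozygotes(q, n_eff, config.inbreeding_f)
        e_round = round_half_up(e)
        p = deficit_pvalue(observed, q, n_eff, config.inbreeding_f)
        pvals.append(p)
        records.append(
            DeficitRecord(
                variant_id=vid,
                maf=q,
                n_genotyped=n_eff,
                expected_hmz=e,
                expected_rounded=e_round,
                observed_hmz=observed,
                oe_ratio=(observed / e) if e > 0 else None,
                p_deficit=p,
                q_value=float("nan"),  # filled below
                complete_deficit=(observed == 0 and e_round >= config.min_expected),
            )
        )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    records = [
        DeficitRecord(**{**r.__dict__, "q_value": float(qv)})
        for r, qv in zip(records, qvals)
    ]
    return records
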