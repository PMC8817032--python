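"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 TSV with a header row and '\n' line endings;
readers round-trip writers exactly. Genotypes can also come from a
minimal VCF (diploid GT fields only; './.' is missing; multi-allelic
records are split per alt allele before summarisation).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .enrichment import MotherRecord, percent_1dp
from .genealogy import FEMALE, MALE, UNKNOWN, CarrierCouple, Genealogy, Person, load_genealogy
from .screen import DeficitRecord, VariantSummary

logger = logging.getLogger(__name__)

VARIANT_TABLE_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt",
    "n_hom_ref", "n_het", "n_hom_alt", "n_missing",
    "imputation_info", "consequence",
]
PEDIGREE_COLUMNS = ["id", "father_id", "mother_id", "sex", "birth_year", "death_year", "alive"]

_SEX_CODE = {MALE: 1, FEMALE: 2, UNKNOWN: 0}
_SEX_DECODE = {1: MALE, 2: FEMALE, 0: UNKNOWN}


class InputFormatError(ValueError):
    """Malformed input table/row; the CLI maps this to exit code 2."""


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return int(float(v))


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


# ---------------------------------------------------------------- variants

def read_variant_table(path: str | Path) -> list[VariantSummary]:
    """Read a per-variant summary TSV.

    Counts are optional when a ``maf`` column is supplied (published
    frequencies); in that case ``n_hom_alt`` is the observed count of
    minor-allele homozygotes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("variant_id", "chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    has_counts_cols = all(c in df.columns for c in ("n_hom_ref", "n_het", "n_hom_alt"))
    if not has_counts_cols and "maf" not in df.columns:
        raise InputFormatError(
            f"{path}: need either genotype-count columns "
            "(n_hom_ref, n_het, n_hom_alt) or a maf column"
        )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                VariantSummary(
                    variant_id=str(d["variant_id"]),
                    chrom=str(d["chrom"]),
                    pos=int(d["pos"]),
                    ref=str(d["ref"]),
                    alt=str(d["alt"]),
                    n_hom_ref=_opt_int(d.get("n_hom_ref")),
                    n_het=_opt_int(d.get("n_het")),
                    n_hom_alt=_opt_int(d.get("n_hom_alt")),
                    n_missing=_opt_int(d.get("n_missing")) or 0,
                    maf=_opt_float(d.get("maf")),
                    imputation_info=_opt_float(d.get("imputation_info")),
                    consequence=str(d.get("consequence", "missense")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise InputFormatError(f"{path}:{i}: {exc}") from exc
    return out


def write_variant_table(summaries: Sequence[VariantSummary], path: str | Path) -> None:
    rows = []
    for s in summaries:
        rows.append(
            {
                "variant_id": s.variant_id, "chrom": s.chrom, "pos": s.pos,
                "ref": s.ref, "alt": s.alt,
                "n_hom_ref": s.n_hom_ref, "n_het": s.n_het, "n_hom_alt": s.n_hom_alt,
                "n_missing": s.n_missing, "maf": s.maf,
                "imputation_info": s.imputation_info, "consequence": s.consequence,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_vcf(path: str | Path, default_consequence: str = "missense"):
    """Summarise a minimal VCF (diploid GT only) into VariantSummary records.

    Returns (summaries, n_samples). Multi-allelic records are split per
    alt allele; any genotype containing a negative allele index counts
    as missing. Consequence class is taken from an INFO key CSQCLASS
    when present, else ``default_consequence``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    out: list[VariantSummary] = []
    for rec in vcf:
        genos = [g[:-1] for g in rec.genotypes]  # strip phased flag
        csq = rec.INFO.get("CSQCLASS") or default_consequence
        for k, alt in enumerate(rec.ALT, start=1):
            n_hom_ref = n_het = n_hom_alt = n_missing = 0
            for al in genos:
                if any(a < 0 for a in al) or len(al) != 2:
                    n_missing += 1
                    continue
                c = sum(1 for a in al if a == k)
                if c == 2:
                    n_hom_alt += 1
                elif c == 1:
                    n_het += 1
                else:
                    n_hom_ref += 1
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}:{alt}" if rec.ID else vid
            out.append(
                VariantSummary(
                    variant_id=vid,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    n_hom_ref=n_hom_ref,
                    n_het=n_het,
                    n_hom_alt=n_hom_alt,
                    n_missing=n_missing,
                    imputation_info=rec.INFO.get("INFO_SCORE"),
                    consequence=str(csq),
                )
            )
    return out, n_samples


def write_deficit_records(records: Sequence[DeficitRecord], path: str | Path) -> None:
    """Deterministic TSV of screen output; MAF rendered as percent (2 dp)."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "maf_pct": f"{100.0 * r.maf:.2f}",
                "n_genotyped": r.n_genotyped,
                "expected_hmz": f"{r.expected_hmz:.4f}",
                "expected_rounded": r.expected_rounded,
                "observed_hmz": r.observed_hmz,
                "oe_ratio": "" if r.oe_ratio is None else f"{r.oe_ratio:.4f}",
                "p_deficit": f"{r.p_deficit:.6g}",
                "q_value": f"{r.q_value:.6g}",
                "complete_deficit": int(r.complete_deficit),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------- pedigree

def read_pedigree(path: str | Path, current_year: int | None = None) -> Genealogy:
    """Extended PED-like TSV: id, father_id, mother_id, sex (1/2/0),
    birth_year, death_year, alive (0/1). '0' or empty = absent parent."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    persons = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            father = d["father_id"] if d["father_id"] not in (None, "", "0") and not pd.isna(d["father_id"]) else None
            mother = d["mother_id"] if d["mother_id"] not in (None, "", "0") and not pd.isna(d["mother_id"]) else None
            persons.append(
                Person(
                    id=str(d["id"]),
                    father_id=father,
                    mother_id=mother,
                    sex=_SEX_DECODE.get(_opt_int(d["sex"]) or 0, UNKNOWN),
                    birth_year=_opt_int(d["birth_year"]),
                    death_year=_opt_int(d["death_year"]),
                    alive=bool(_opt_int(d["alive"])),
                )
            )
        except (TypeError, ValueError) as exc:
            raise InputFormatError(f"{path}:{i}: {exc}") from exc
    return load_genealogy(persons, current_year=current_year)


def write_pedigree(g: Genealogy, path: str | Path) -> None:
    rows = []
    for p in g.individuals.values():
        rows.append(
            {
                "id": p.id,
                "father_id": p.father_id or "0",
                "mother_id": p.mother_id or "0",
                "sex": _SEX_CODE[p.sex],
                "birth_year": p.birth_year,
                "death_year": p.death_year,
                "alive": int(p.alive),
            }
        )
    df = pd.DataFrame(rows)
    for col in ("birth_year", "death_year"):
        df[col] = df[col].astype("Int64")  # avoid float-formatted years
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_carriers(path: str | Path) -> set[str]:
    """Plain-text carrier set, one individual id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_carriers(carriers: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(carriers):
            fh.write(f"{c}\n")


def write_couples(couples: Sequence[CarrierCouple], path: str | Path,
                  distances: dict[tuple[str, str], int | None] | None = None) -> None:
    rows = []
    for c in couples:
        dist = (distances or {}).get((c.father_id, c.mother_id))
        rows.append(
            {
                "father_id": c.father_id,
                "mother_id": c.mother_id,
                "n_offspring": c.n_offspring,
                "offspring_ids": ",".join(c.shared_offspring),
                "n_early_death": sum(1 for f in c.offspring_flags if f.early_death),
                "n_undetermined": sum(1 for f in c.offspring_flags if f.early_death is None),
                "expected_hmz_offspring": c.expected_hmz_offspring,
                "prob_at_least_one_hmz": f"{c.prob_at_least_one_hmz:.4f}",
                "meiotic_distance": "" if dist is None else dist,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "father_id", "mother_id", "n_offspring", "offspring_ids",
            "n_early_death", "n_undetermined", "expected_hmz_offspring",
            "prob_at_least_one_hmz", "meiotic_distance",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ------------------------------------------------------- mother records

def read_mother_records(path: str | Path) -> list[MotherRecord]:
    """TSV: mother_id, birth_year, pregnancies, miscarriages,
    early_miscarriage_reported (0/1/NA)[, carrier_couple (0/1)]."""
    df = pd.read_csv(path, sep="\t", dtype={"mother_id": str})
    if "mother_id" not in df.columns:
        raise InputFormatError(f"{path}: missing required column: mother_id")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        early = _opt_int(d.get("early_miscarriage_reported"))
        out.append(
            MotherRecord(
                mother_id=str(d["mother_id"]),
                birth_year=_opt_int(d.get("birth_year")),
                pregnancies=_opt_int(d.get("pregnancies")),
                miscarriages=_opt_int(d.get("miscarriages")),
                early_miscarriage_reported=None if early is None else bool(early),
                carrier_couple=bool(_opt_int(d.get("carrier_couple")) or 0),
            )
        )
    return out


def write_mother_records(records: Sequence[MotherRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "mother_id": r.mother_id,
                "birth_year": r.birth_year,
                "pregnancies": r.pregnancies,
                "miscarriages": r.miscarriages,
                "early_miscarriage_reported": (
                    "" if r.early_miscarriage_reported is None
                    else int(r.early_miscarriage_reported)
                ),
                "carrier_couple": int(r.carrier_couple),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ------------------------------------------------------------- manifest

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, inputs: Iterable[str | Path]) -> Path:
    """Provenance record: resolved config, input checksums, library version.

    Deliberately timestamp-free so reruns with the same seed are
    byte-identical.
    """
    out_dir = Path(out_dir)
    manifest = {
        "hmzscan_version": __version__,
        "config": config,
        "inputs": {
            str(p): sha256_of(p) for p in inputs if Path(p).is_file()
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
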