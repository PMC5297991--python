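"""Extended-family segregation, frequency classification and the worked
candidate-variant table.

After the cascade nominates candidates from a sequenced trio, the rest of
the family is genotyped (in practice by Sanger sequencing) and each
variant is cross-tabulated against phenotype.  Unaffected members with
documented normal urinalysis who nonetheless carry *all* of the family's
candidate variants are putative obligate carriers — the signature of an
autosomal-dominant variant with incomplete penetrance.  Validated
variants are classified against reference population databases (ExAC,
1000 Genomes) as private or rare, and the carrier frequency in an
independent case cohort is bounded.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import beta

from .pedigree import Pedigree, Phenotype

#: coding/noncoding classification of effect vocabulary terms
_CODING_EFFECTS = {"NON_SYNONYMOUS_CODING", "STOP_GAINED", "FRAME_SHIFT",
                   "SYNONYMOUS_CODING", "STOP_LOST", "START_LOST"}
_NONCODING_EFFECTS = {"UTR_3_PRIME", "UTR_5_PRIME", "DOWNSTREAM", "UPSTREAM",
                      "INTRON", "INTERGENIC"}

#: database tokens meaning "no such variant observed"
ABSENT = "Absent"
#: token for positions ExAC cannot call (outside its coding-centric capture)
NOT_CALLABLE = "NC"


class ClassificationError(ValueError):
    """Unknown effect term or unparseable database token."""


# ---------------------------------------------------------------------------
# Segregation in extended families
# ---------------------------------------------------------------------------

@dataclass
class SegregationResult:
    family_id: str
    variant: str
    #: carrier counts cross-tabulated by phenotype
    carriers: dict[Phenotype, int]
    noncarriers: dict[Phenotype, int]
    obligate_carrier_candidates: list[str]   # unaffected carriers
    consistent_with_status: bool

    @property
    def n_genotyped(self) -> int:
        return sum(self.carriers.values()) + sum(self.noncarriers.values())


def classify_segregation(
    ped: Pedigree,
    carrier_status: Mapping[str, bool | None],
    variant: str,
) -> SegregationResult:
    """Cross-tabulate carrier status by phenotype for one variant.

    ``carrier_status`` maps individual id to True/False (``None`` or a
    missing id = not genotyped).  Consistency requires every genotyped
    biopsy-proven affected to carry the variant.
    """
    if not any(v is not None for v in carrier_status.values()):
        raise KeyError(f"variant {variant!r}: no genotypes supplied")
    carriers = {p: 0 for p in Phenotype}
    noncarriers = {p: 0 for p in Phenotype}
    unaffected_carriers: list[str] = []
    consistent = True
    for m in ped:
        status = carrier_status.get(m.individual_id)
        if status is None:
            continue
        (carriers if status else noncarriers)[m.phenotype] += 1
        if status and m.phenotype is Phenotype.UNAFFECTED:
            unaffected_carriers.append(m.individual_id)
        if not status and m.phenotype is Phenotype.IGAN_AFFECTED:
            consistent = False
    return SegregationResult(
        family_id=ped.family_id,
        variant=variant,
        carriers=carriers,
        noncarriers=noncarriers,
        obligate_carrier_candidates=sorted(unaffected_carriers),
        consistent_with_status=consistent,
    )


def detect_obligate_carriers(results: Sequence[SegregationResult]) -> list[str]:
    """Unaffected members carrying *every* family candidate variant.

    Only the unaffected phenotype (documented normal urinalysis) counts;
    unknown-phenotype members can never be obligate carriers.
    """
    if not results:
        return []
    sets = [set(r.obligate_carrier_candidates) for r in results]
    common = set.intersection(*sets)
    return sorted(common)


# ---------------------------------------------------------------------------
# Database frequency and coding classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyClassification:
    exac_value: str
    kg_value: str
    klass: str                    # "private" | "rare_db_present"
    max_frequency: float | None   # largest observed database frequency


def _parse_db_token(token: str, allow_nc: bool) -> float | None:
    t = str(token).strip()
    if t == ABSENT or (allow_nc and t == NOT_CALLABLE):
        return None
    try:
        return float(t)
    except ValueError:
        raise ClassificationError(
            f"unparseable database frequency token {token!r}"
        ) from None


def classify_database_frequency(
    exac_value: str, kg_value: str
) -> FrequencyClassification:
    """Private iff unseen in both ExAC and 1000 Genomes.

    ExAC's "NC" (position outside its callable coding capture) counts as
    absent for privacy; a variant seen in either database at any
    frequency is rare-but-present, with the maximum frequency recorded.
    """
    exac = _parse_db_token(exac_value, allow_nc=True)
    kg = _parse_db_token(kg_value, allow_nc=False)
    freqs = [f for f in (exac, kg) if f is not None]
    if not freqs:
        return FrequencyClassification(
            str(exac_value), str(kg_value), "private", None
        )
    return FrequencyClassification(
        str(exac_value), str(kg_value), "rare_db_present", max(freqs)
    )


def classify_coding(effect: str) -> str:
    """Map an effect term to {"coding", "noncoding"}.

    Accepts amino-acid suffixes ("STOP_GAINED=R26*").  Unknown terms
    raise: no silent default.
    """
    term = str(effect).split("=")[0].strip()
    if term in _CODING_EFFECTS:
        return "coding"
    if term in _NONCODING_EFFECTS:
        return "noncoding"
    raise ClassificationError(f"unknown effect term {effect!r}")


# ---------------------------------------------------------------------------
# Cohort carrier frequency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarrierFrequency:
    carriers: int
    n_individuals: int
    point: float            # carriers / 2n (allele-frequency scale)
    naive_bound: float      # 1/(2n): smallest nonzero detectable frequency
    exact_upper_95: float   # one-sided exact binomial upper bound


def cohort_carrier_frequency(
    carriers: int, n_individuals: int, alpha: float = 0.05
) -> CarrierFrequency:
    """Allele-frequency estimate and bounds from a carrier screen.

    With zero carriers among ``n`` diploid individuals the point estimate
    is 0; the naive bound ``1/(2n)`` is the smallest frequency the screen
    could have detected, and the exact one-sided upper bound solves
    ``(1-q)^(2n) = alpha``, i.e. ``q = 1 - alpha^(1/(2n))``.  Nonzero
    counts use the exact (Clopper-Pearson) upper limit.
    """
    if n_individuals <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= carriers <= 2 * n_individuals:
        raise ValueError("carrier count out of range")
    two_n = 2 * n_individuals
    point = carriers / two_n
    if carriers == 0:
        upper = 1.0 - alpha ** (1.0 / two_n)
    elif carriers == two_n:
        upper = 1.0
    else:
        upper = float(beta.isf(alpha, carriers + 1, two_n - carriers))
    return CarrierFrequency(
        carriers, n_individuals, point, 1.0 / two_n, upper
    )


# ---------------------------------------------------------------------------
# Worked example: the packaged candidate-variant table
# ---------------------------------------------------------------------------

_TABLE3_COLUMNS = [
    "family", "gene", "chrom", "pos", "ref", "alt",
    "effect", "validation", "exac", "kg",
]


def load_table3(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged 33-row candidate-variant table (or a custom one)."""
    if path is None:
        ref = importlib.resources.files("famcoseg").joinpath("data/table3.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _TABLE3_COLUMNS:
        raise ValueError(
            f"candidate table schema mismatch: got columns {list(df.columns)}"
        )
    return df


def table3_statistics(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Summary counts over the candidate-variant table.

    Returns validated (confirmed by Sanger, with or without control
    detection), co-segregating (confirmed and absent in the control),
    detected-in-control, unique co-segregating genes, noncoding among the
    co-segregating set, and private among the validated set.
    """
    df = load_table3() if table is None else table
    if list(df.columns) != _TABLE3_COLUMNS:
        raise ValueError("candidate table schema mismatch")
    coseg = df[df["validation"] == "Yes"]
    in_control = df[df["validation"] == "Yes + Control"]
    validated = df[df["validation"].isin(["Yes", "Yes + Control"])]
    noncoding = sum(
        classify_coding(e) == "noncoding" for e in coseg["effect"]
    )
    private = sum(
        classify_database_frequency(e, k).klass == "private"
        for e, k in zip(validated["exac"], validated["kg"])
    )
    return {
        "validated": len(validated),
        "cosegregating": len(coseg),
        "detected_in_control": len(in_control),
        "unique_genes_cosegregating": coseg["gene"].nunique(),
        "noncoding_cosegregating": int(noncoding),
        "private_validated": int(private),
    }
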