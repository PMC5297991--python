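"""The variant filter funnel: dual-caller VCFs to candidate variants.

Order of gates: per-caller hard quality filter, population-MAF filter,
impact filter, linked-region intersection; then caller merge,
co-segregation against the sequenced trio, and CADD prioritization.
The four record-level filters commute — the final set is order-invariant —
but per-stage counts follow the order above.  Coordinates are 1-based
(VCF convention); linked regions are inclusive 1-based intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .npl import LinkedRegion

UG = "UG"
HC = "HC"

DEFAULT_HARD_FILTER = {"qual": 30.0, "mq": 40.0, "dp": 5, "fs": 60.0}
DEFAULT_MAF_THRESHOLD = 0.01
DEFAULT_CADD_THRESHOLD = 5.0

#: snpEff-style effect terms mapped to their impact class
EFFECT_IMPACT = {
    "STOP_GAINED": "HIGH",
    "FRAME_SHIFT": "HIGH",
    "NON_SYNONYMOUS_CODING": "MODERATE",
    "SYNONYMOUS_CODING": "LOW",
    "UTR_3_PRIME": "MODIFIER",
    "UTR_5_PRIME": "MODIFIER",
    "DOWNSTREAM": "MODIFIER",
    "UPSTREAM": "MODIFIER",
    "INTRON": "MODIFIER",
}


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call against a split biallelic alt."""

    dosage: int          # alt-allele copies: 0, 1, 2; -1 = missing
    depth: int = 0

    @property
    def state(self) -> str:
        return {0: "ref_hom", 1: "het", 2: "alt_hom"}.get(self.dosage, "missing")

    @property
    def carries_alt(self) -> bool:
        return self.dosage > 0


@dataclass
class VariantRecord:
    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    qual: float
    mq: float
    fs: float
    genotypes: dict[str, GenotypeCall]
    eur_maf: float | None = None
    effect: str | None = None
    impact: str | None = None
    cadd: float | None = None
    gene: str | None = None
    callers: frozenset[str] = frozenset({UG})
    discordant_callers: bool = False
    repeat_region: bool = False

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"{self.key}: alt equals ref")
        if not self.callers:
            raise ValueError(f"{self.key}: empty caller set")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CandidateVariant:
    record: VariantRecord
    family_id: str
    cosegregating: bool
    priority_rank: int | None = None
    include_listed: bool = False


# ---------------------------------------------------------------------------
# VCF reading (annotated, one file per caller)
# ---------------------------------------------------------------------------

#: INFO-field contract for annotated inputs
INFO_CONTRACT = {
    "EUR_MAF": "Float: 1000 Genomes European minor allele frequency",
    "EFF": "String: effect term (snpEff vocabulary)",
    "IMPACT": "String: HIGH/MODERATE/LOW/MODIFIER",
    "CADD": "Float: scaled C-score",
    "GENE": "String: gene symbol",
    "MQ": "Float: RMS mapping quality",
    "FS": "Float: Fisher strand bias, phred-scaled",
}


def read_annotated_vcf(
    path: str | Path,
    caller: str,
    contig_alias: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read an annotated VCF into records, splitting multi-allelic sites.

    Requires the GT FORMAT field; per-sample depth comes from FORMAT DP
    when present.  INFO keys follow :data:`INFO_CONTRACT`; missing
    annotation keys yield ``None`` fields (e.g. absent EUR_MAF means the
    variant is not in the reference panel).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF carries no sample genotypes (no GT)")
    alias = dict(contig_alias or {})
    records: list[VariantRecord] = []
    for v in vcf:
        chrom = alias.get(v.CHROM, v.CHROM)
        try:
            depths = v.format("DP")
        except KeyError:
            depths = None
        info = dict(v.INFO)
        genos = v.genotypes  # [[a1, a2, phased], ...]
        for ai, alt in enumerate(v.ALT, start=1):
            calls: dict[str, GenotypeCall] = {}
            for si, sample in enumerate(samples):
                alleles = genos[si][:-1]
                if any(a < 0 for a in alleles):
                    dosage = -1
                else:
                    dosage = sum(1 for a in alleles if a == ai)
                d = 0
                if depths is not None:
                    dv = depths[si]
                    d = int(dv[0] if np.ndim(dv) else dv)
                    if d < 0:
                        d = 0
                calls[sample] = GenotypeCall(dosage, d)
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                    mq=float(info.get("MQ", 0.0)),
                    fs=float(info.get("FS", 0.0)),
                    genotypes=calls,
                    eur_maf=(
                        float(info["EUR_MAF"]) if "EUR_MAF" in info else None
                    ),
                    effect=info.get("EFF"),
                    impact=info.get("IMPACT"),
                    cadd=float(info["CADD"]) if "CADD" in info else None,
                    gene=info.get("GENE"),
                    callers=frozenset({caller}),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Record-level filters
# ---------------------------------------------------------------------------

def hard_filter(
    rec: VariantRecord,
    thresholds: Mapping[str, float] | None = None,
    rescue_samples: Sequence[str] | None = None,
) -> tuple[bool, str | None]:
    """GATK-style hard filter; returns (passed, first failing criterion).

    Pass requires variant confidence >= qual, mapping quality >= mq,
    maximum carrier depth >= dp and strand bias FS < fs.  A site below
    the depth gate is rescued when the alt allele was called in every
    ``rescue_sample`` (the both-affecteds low-coverage rule).
    """
    t = dict(DEFAULT_HARD_FILTER)
    if thresholds:
        t.update(thresholds)
    if rec.qual < t["qual"]:
        return False, "confidence"
    if rec.mq < t["mq"]:
        return False, "mapping_quality"
    carriers = [g for g in rec.genotypes.values() if g.carries_alt]
    max_depth = max((g.depth for g in carriers), default=0)
    if max_depth < t["dp"]:
        rescued = bool(rescue_samples) and all(
            rec.genotypes.get(s, GenotypeCall(-1)).carries_alt
            for s in rescue_samples
        )
        if not rescued:
            return False, "depth"
    if rec.fs >= t["fs"]:
        return False, "strand_bias"
    return True, None


def maf_filter(rec: VariantRecord, threshold: float = DEFAULT_MAF_THRESHOLD) -> bool:
    """Keep unless the European population MAF is known and > threshold.

    An absent frequency means the variant is not in the reference panel
    and is treated as rare (private variants stay in play).
    """
    return rec.eur_maf is None or rec.eur_maf <= threshold


def impact_filter(rec: VariantRecord) -> bool:
    """Drop LOW-impact (synonymous) variants; everything else is kept.

    MODIFIER survives because regulatory (UTR/up/downstream/intronic)
    variants are first-class candidates here.  Missing impact is kept.
    """
    impact = rec.impact
    if impact is None and rec.effect is not None:
        impact = EFFECT_IMPACT.get(rec.effect.split("=")[0])
    return impact != "LOW"


def region_filter(
    records: Iterable[VariantRecord], regions: Sequence[LinkedRegion]
) -> list[VariantRecord]:
    """Keep records whose 1-based position falls inside any linked region."""
    return [
        r
        for r in records
        if any(reg.contains(r.chrom, r.pos) for reg in regions)
    ]


def merge_callers(
    ug_records: Sequence[VariantRecord],
    hc_records: Sequence[VariantRecord],
) -> list[VariantRecord]:
    """Union of the two call sets keyed by (chrom, pos, ref, alt).

    Shared keys merge with ``callers = {UG, HC}``; conflicting genotype
    claims keep the UG genotypes and set ``discordant_callers`` for the
    review list.
    """
    merged: dict[tuple, VariantRecord] = {}
    for r in ug_records:
        merged[r.key] = r
    for r in hc_records:
        if r.key not in merged:
            merged[r.key] = r
            continue
        prev = merged[r.key]
        discord = any(
            prev.genotypes[s].dosage != r.genotypes[s].dosage
            for s in prev.genotypes
            if s in r.genotypes
        )
        merged[r.key] = replace(
            prev,
            callers=prev.callers | r.callers,
            discordant_callers=discord,
        )
    return sorted(merged.values(), key=lambda r: (r.chrom, r.pos, r.ref, r.alt))


def cosegregation_filter(
    records: Iterable[VariantRecord],
    affected: tuple[str, str],
    control: str,
    family_id: str = "",
) -> list[CandidateVariant]:
    """Keep variants carried by both affecteds and absent in the control.

    A missing control genotype drops the variant: absence cannot be
    asserted from a no-call.  Missing affected genotypes drop it too.
    Low depth in the affecteds does not disqualify a variant called in
    both (the depth gate's rescue handles that upstream).
    """
    a1, a2 = affected
    out = []
    for r in records:
        g1 = r.genotypes.get(a1, GenotypeCall(-1))
        g2 = r.genotypes.get(a2, GenotypeCall(-1))
        gc = r.genotypes.get(control, GenotypeCall(-1))
        keep = g1.carries_alt and g2.carries_alt and gc.dosage == 0
        if keep:
            out.append(CandidateVariant(r, family_id, cosegregating=True))
    return out


def prioritize_cadd(
    candidates: Sequence[CandidateVariant],
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD,
    include_list: Sequence[str] | None = None,
) -> list[CandidateVariant]:
    """Rank candidates with CADD strictly above threshold, descending.

    ``include_list`` entries (gene symbols or "chrom:pos" strings) are
    appended after the score-selected block regardless of score — the
    supervised additions (e.g. expression-supported genes).  Ties break
    by genomic coordinate.
    """
    inc = set(include_list or ())

    def included(c: CandidateVariant) -> bool:
        r = c.record
        return bool(inc) and (
            (r.gene is not None and r.gene in inc)
            or f"{r.chrom}:{r.pos}" in inc
        )

    scored = [
        c
        for c in candidates
        if c.record.cadd is not None and c.record.cadd > cadd_threshold
    ]
    scored.sort(key=lambda c: (-c.record.cadd, c.record.chrom, c.record.pos))
    extra = [c for c in candidates if included(c) and c not in scored]
    extra.sort(key=lambda c: (c.record.chrom, c.record.pos))
    ranked = []
    for rank, c in enumerate(scored + extra, start=1):
        ranked.append(
            replace_candidate(c, priority_rank=rank, include_listed=included(c))
        )
    return ranked


def replace_candidate(c: CandidateVariant, **kw) -> CandidateVariant:
    return CandidateVariant(
        record=c.record,
        family_id=c.family_id,
        cosegregating=c.cosegregating,
        priority_rank=kw.get("priority_rank", c.priority_rank),
        include_listed=kw.get("include_listed", c.include_listed),
    )


# ---------------------------------------------------------------------------
# Funnel accounting
# ---------------------------------------------------------------------------

class FunnelIntegrityError(ValueError):
    """A funnel stage reported more variants than its predecessor."""


@dataclass
class FunnelReport:
    """Ordered per-stage variant counts, one stream per caller."""

    stages: list[tuple[str, dict[str, int]]]

    def __post_init__(self) -> None:
        streams: dict[str, int] = {}
        for name, counts in self.stages:
            for caller, n in counts.items():
                if caller in streams and n > streams[caller]:
                    raise FunnelIntegrityError(
                        f"stage {name!r}: count {n} for {caller} exceeds "
                        f"previous {streams[caller]}"
                    )
                streams[caller] = n

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"stages": [{"stage": s, "counts": c} for s, c in self.stages]},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def to_tsv(self, path: str | Path) -> None:
        callers = sorted({c for _, counts in self.stages for c in counts})
        lines = ["stage\t" + "\t".join(callers)]
        for name, counts in self.stages:
            lines.append(
                name + "\t" + "\t".join(str(counts.get(c, "")) for c in callers)
            )
        Path(path).write_text("\n".join(lines) + "\n")


def funnel_report(stage_counts: Sequence[tuple[str, dict[str, int]]]) -> FunnelReport:
    """Validate per-stage counts (monotone non-increasing) and wrap them."""
    return FunnelReport(list(stage_counts))


# ---------------------------------------------------------------------------
# Whole-cascade driver
# ---------------------------------------------------------------------------

def run_cascade(
    ug_records: Sequence[VariantRecord],
    hc_records: Sequence[VariantRecord],
    regions: Sequence[LinkedRegion],
    affected: tuple[str, str],
    control: str,
    family_id: str = "",
    hard_thresholds: Mapping[str, float] | None = None,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD,
    include_list: Sequence[str] | None = None,
) -> tuple[list[CandidateVariant], FunnelReport]:
    """Run the full funnel for one family's trio; return candidates + report."""
    stages: list[tuple[str, dict[str, int]]] = [
        ("raw", {UG: len(ug_records), HC: len(hc_records)})
    ]
    streams = {UG: list(ug_records), HC: list(hc_records)}
    for name, predicate in (
        ("quality", lambda r: hard_filter(r, hard_thresholds, affected)[0]),
        ("maf", lambda r: maf_filter(r, maf_threshold)),
        ("impact", impact_filter),
    ):
        streams = {c: [r for r in rs if predicate(r)] for c, rs in streams.items()}
        stages.append((name, {c: len(rs) for c, rs in streams.items()}))
    streams = {c: region_filter(rs, regions) for c, rs in streams.items()}
    stages.append(("linked_region", {c: len(rs) for c, rs in streams.items()}))

    merged = merge_callers(streams[UG], streams[HC])
    stages.append(("merged", {"union": len(merged)}))
    candidates = cosegregation_filter(merged, affected, control, family_id)
    stages.append(("cosegregation", {"union": len(candidates)}))
    ranked = prioritize_cadd(candidates, cadd_threshold, include_list)
    stages.append(("prioritized", {"union": len(ranked)}))
    return ranked, funnel_report(stages)
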