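"""Gene-dropping simulator for multiplex dominant-disease pedigrees.

Produces everything the pipeline consumes — pedigrees, a genome-wide
marker panel with a genetic map, phenotypes, and dual-caller annotated
variant sets — with a known truth table, so every stage is testable
without external data.  The emulated regime: multiplex families each
segregating one rare autosomal-dominant variant with incomplete
penetrance, a biallelic (or fully informative) marker map, rare exonic
background variants, two callers with imperfect sensitivity, genotype
error and missingness.

Founder haplotypes recombine through each meiosis with the Haldane map
function ``theta = (1 - exp(-2d/100)) / 2``; the genetic map is linear at
1 cM/Mb.  All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cascade import EFFECT_IMPACT, HC, UG, GenotypeCall, VariantRecord
from .hmm import haldane_theta
from .markers import MISSING, GenotypePanel, Marker, MarkerMap
from .pedigree import Individual, Pedigree, Phenotype, Sex


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PedigreeShape:
    """Three-generation family: a founding couple, their children (the
    eldest marries in a spouse), and grandchildren."""

    n_children: int = 2
    n_grandchildren: int = 2


@dataclass
class MarkerSpec:
    n_chromosomes: int = 2
    n_per_chrom: int = 11
    spacing_cm: float = 10.0
    #: fully informative markers give every founder haplotype its own
    #: allele; otherwise markers are biallelic with the given MAF range
    fully_informative: bool = True
    biallelic_maf: tuple[float, float] = (0.3, 0.5)


@dataclass
class CausalSpec:
    chrom: str = "1"
    region_bp: tuple[int, int] = (45_000_000, 55_000_000)
    f_carrier: float = 0.6          # penetrance: P(IgAN | carrier)
    p_ua_carrier: float = 0.5       # P(urinary abnormality | unaffected carrier)
    phenocopy: float = 0.001        # P(IgAN | non-carrier)
    missing_phenotype_rate: float = 0.0  # P(phenotype recorded unknown)
    cadd: float = 15.0


@dataclass
class BackgroundSpec:
    mean_count: float = 60.0        # Poisson mean per family genome
    private_fraction: float = 0.5   # absent from the reference panel
    common_fraction: float = 0.15   # MAF above the 1% filter line
    rare_maf_range: tuple[float, float] = (1e-5, 5e-3)
    common_maf_range: tuple[float, float] = (0.02, 0.3)
    cadd_scale: float = 4.0         # exponential scale of scaled C-scores
    effect_probs: dict = field(
        default_factory=lambda: {
            "NON_SYNONYMOUS_CODING": 0.25,
            "SYNONYMOUS_CODING": 0.20,
            "UTR_3_PRIME": 0.15,
            "DOWNSTREAM": 0.15,
            "INTRON": 0.13,
            "UTR_5_PRIME": 0.05,
            "UPSTREAM": 0.05,
            "STOP_GAINED": 0.01,
            "FRAME_SHIFT": 0.01,
        }
    )


@dataclass
class ErrorSpec:
    genotype_error: float = 0.002   # per-call allele-swap rate (markers)
    missingness: float = 0.01
    s_ug: float = 0.95              # caller sensitivities
    s_hc: float = 0.95
    depth_mean: float = 20.0        # negative-binomial-like read depth
    depth_dispersion: float = 5.0
    hard_fail_fraction: float = 0.02  # sites drawn into hard-filter failure

    def noiseless(self) -> "ErrorSpec":
        return ErrorSpec(0.0, 0.0, 1.0, 1.0, self.depth_mean,
                         self.depth_dispersion, 0.0)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 8
    shape: PedigreeShape = field(default_factory=PedigreeShape)
    markers: MarkerSpec = field(default_factory=MarkerSpec)
    causal: CausalSpec = field(default_factory=CausalSpec)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    errors: ErrorSpec = field(default_factory=ErrorSpec)

    def __post_init__(self) -> None:
        for p in (
            self.causal.f_carrier, self.causal.p_ua_carrier,
            self.causal.phenocopy, self.errors.genotype_error,
            self.errors.missingness,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for s in (self.errors.s_ug, self.errors.s_hc):
            if not 0.0 < s <= 1.0:
                raise ValueError("caller sensitivities must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig, family_index: int) -> Pedigree:
    """Deterministic three-generation family; phenotypes start unknown.

    Member ids are globally unique (``F<i>.<name>``) so panels and VCFs
    can pool families.
    """
    shape = config.shape
    if shape.n_children < 1 or shape.n_grandchildren < 0:
        raise ValueError("infeasible pedigree shape")
    fam = f"F{family_index}"
    p = lambda name: f"{fam}.{name}"
    members = [
        Individual(p("gp1"), fam, sex=Sex.MALE),
        Individual(p("gp2"), fam, sex=Sex.FEMALE),
    ]
    for c in range(1, shape.n_children + 1):
        members.append(
            Individual(
                p(f"c{c}"), fam, father_id=p("gp1"), mother_id=p("gp2"),
                sex=Sex.MALE if c == 1 else Sex.FEMALE,
            )
        )
    if shape.n_grandchildren:
        members.append(Individual(p("sp1"), fam, sex=Sex.FEMALE))
        for g in range(1, shape.n_grandchildren + 1):
            members.append(
                Individual(
                    p(f"g{g}"), fam, father_id=p("c1"), mother_id=p("sp1"),
                    sex=Sex.MALE if g % 2 else Sex.FEMALE,
                )
            )
    return Pedigree(fam, members)


def sib_pair_pedigree(family_index: int) -> Pedigree:
    """Nuclear family with two children (used by calibration studies)."""
    fam = f"F{family_index}"
    p = lambda name: f"{fam}.{name}"
    return Pedigree(
        fam,
        [
            Individual(p("fa"), fam, sex=Sex.MALE),
            Individual(p("mo"), fam, sex=Sex.FEMALE),
            Individual(p("s1"), fam, father_id=p("fa"), mother_id=p("mo")),
            Individual(p("s2"), fam, father_id=p("fa"), mother_id=p("mo")),
        ],
    )


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def meiosis_bits(cms: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete's transmission indicator along a chromosome.

    The first position picks a parental haplotype uniformly; between
    adjacent positions the indicator flips with the Haldane recombination
    fraction for the intervening distance.
    """
    n = len(cms)
    bits = np.empty(n, dtype=np.int8)
    bits[0] = rng.integers(2)
    if n > 1:
        thetas = haldane_theta(np.diff(cms))
        flips = rng.random(n - 1) < thetas
        bits[1:] = flips
        bits = np.bitwise_xor.accumulate(bits)
    return bits


def gene_drop(
    ped: Pedigree, cms: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, int]]:
    """Drop founder haplotypes through one chromosome.

    Returns ``origins`` of shape (n_members, n_positions, 2): the founder
    haplotype label (2*founder_index + hap) carried by each member at each
    position, paternal then maternal — the true inheritance record — plus
    the member-id -> row map.
    """
    members = ped.topological_members()
    row = {m.individual_id: i for i, m in enumerate(members)}
    founders = [m for m in members if m.is_founder]
    fpos = {m.individual_id: i for i, m in enumerate(founders)}
    n = len(cms)
    origins = np.zeros((len(members), n, 2), dtype=np.int16)
    for m in members:
        i = row[m.individual_id]
        if m.is_founder:
            fi = fpos[m.individual_id]
            origins[i, :, 0] = 2 * fi
            origins[i, :, 1] = 2 * fi + 1
        else:
            for j, parent in enumerate((m.father_id, m.mother_id)):
                bits = meiosis_bits(cms, rng)
                origins[i, :, j] = origins[
                    row[parent], np.arange(n), bits
                ]
    return origins, row


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    pedigree: Pedigree
    origins: dict[str, np.ndarray]       # chrom -> (n_members, n_pos, 2)
    row: dict[str, int]
    causal_pos: tuple[str, int]          # (chrom, bp)
    causal_carriers: dict[str, bool]     # dosage > 0 per member
    variant_dosage: pd.DataFrame         # rows: variants; cols: member ids


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    pedigrees: list[Pedigree]
    panel: GenotypePanel
    truth: pd.DataFrame                  # one row per injected variant
    families: dict[str, FamilyTruth]
    ug_records: dict[str, list[VariantRecord]]
    hc_records: dict[str, list[VariantRecord]]
    sequenced: dict[str, tuple[str, str]]  # two sequenced affecteds


def _marker_grid(spec: MarkerSpec) -> dict[str, np.ndarray]:
    return {
        str(c + 1): np.arange(spec.n_per_chrom) * spec.spacing_cm
        for c in range(spec.n_chromosomes)
    }


def _cm_to_bp(cm: float) -> int:
    return int(round(cm * 1e6)) + 1


def _build_map(
    spec: MarkerSpec, n_founder_haps: int, rng: np.random.Generator
) -> MarkerMap:
    markers = []
    for chrom, cms in _marker_grid(spec).items():
        for k, cm in enumerate(cms):
            if spec.fully_informative:
                freqs = np.full(n_founder_haps, 1.0 / n_founder_haps)
            else:
                maf = rng.uniform(*spec.biallelic_maf)
                freqs = np.array([1 - maf, maf])
            markers.append(
                Marker(f"M{chrom}_{k}", chrom, float(cm), _cm_to_bp(cm), freqs)
            )
    return MarkerMap(markers)


_REF_ALT = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full synthetic study; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    shape_probe = simulate_pedigree(config, 1)
    n_haps = 2 * len(shape_probe.founders)
    mmap = _build_map(config.markers, n_haps, rng)
    grid = _marker_grid(config.markers)
    span_bp = {
        c: (_cm_to_bp(cms[0]), _cm_to_bp(cms[-1])) for c, cms in grid.items()
    }

    # founder haplotype alleles at markers, per family, drawn once
    peds, families = [], {}
    panel_rows, panel_ids = [], []
    truth_rows = []
    ug_records: dict[str, list[VariantRecord]] = {}
    hc_records: dict[str, list[VariantRecord]] = {}
    sequenced: dict[str, tuple[str, str]] = {}
    err = config.errors
    bg = config.background
    effects = list(bg.effect_probs)
    eprobs = np.array([bg.effect_probs[e] for e in effects])
    eprobs = eprobs / eprobs.sum()

    for fi in range(1, config.n_families + 1):
        ped = simulate_pedigree(config, fi)
        peds.append(ped)
        fam = ped.family_id

        # variant positions for this family
        lo, hi = config.causal.region_bp
        causal_bp = int(rng.integers(lo, hi))
        n_bg = rng.poisson(bg.mean_count)
        bg_chroms = rng.choice(list(grid), size=n_bg)
        bg_bps = np.array(
            [rng.integers(span_bp[c][0], span_bp[c][1]) for c in bg_chroms],
            dtype=np.int64,
        )

        # drop founder haplotypes over markers plus variant positions
        origins: dict[str, np.ndarray] = {}
        pos_index: dict[str, dict[int, int]] = {}
        row: dict[str, int] = {}
        for chrom, cms in grid.items():
            extra_bp = [bg_bps[k] for k in range(n_bg) if bg_chroms[k] == chrom]
            if chrom == config.causal.chrom:
                extra_bp.append(causal_bp)
            extra_cm = [(b - 1) / 1e6 for b in extra_bp]
            all_cm = np.concatenate([cms, extra_cm])
            order = np.argsort(all_cm, kind="stable")
            ori, row = gene_drop(ped, all_cm[order], rng)
            inv = np.empty_like(order)
            inv[order] = np.arange(len(order))
            origins[chrom] = ori[:, inv, :]  # back in build order
            pos_index[chrom] = {
                bp: len(cms) + k for k, bp in enumerate(extra_bp)
            }

        # causal carriers: founder haplotype label 0 (gp1, paternal hap)
        cpos = pos_index[config.causal.chrom][causal_bp]
        c_ori = origins[config.causal.chrom][:, cpos, :]
        carrier = {
            iid: bool((c_ori[r] == 0).any()) for iid, r in row.items()
        }

        # phenotypes
        ped = assign_phenotypes(ped, carrier, config.causal, rng)
        peds[-1] = ped
        families[fam] = None  # placeholder until truth assembled

        # marker genotypes: founder allele draws + origins
        n_mark = len(mmap)
        geno = np.empty((len(ped), n_mark, 2), dtype=np.int16)
        mrow = {m.individual_id: i for i, m in enumerate(ped)}
        for j, marker in enumerate(mmap):
            midx = list(grid[marker.chrom]).index(marker.cm)
            ori = origins[marker.chrom][:, midx, :]
            if config.markers.fully_informative:
                hap_alleles = np.arange(n_haps)
            else:
                hap_alleles = rng.choice(
                    len(marker.allele_freqs), size=n_haps, p=marker.allele_freqs
                )
            for iid, r in row.items():
                geno[mrow[iid], j] = hap_alleles[ori[r]]
        # genotype error: resample one allele; missingness: drop the call
        if err.genotype_error > 0 and not config.markers.fully_informative:
            hit = rng.random(geno.shape[:2]) < err.genotype_error
            flip = rng.integers(0, 2, size=geno.shape[:2])
            g0 = geno.copy()
            for i, j in zip(*np.nonzero(hit)):
                geno[i, j, flip[i, j]] = 1 - g0[i, j, flip[i, j]]
        if err.missingness > 0:
            miss = rng.random(geno.shape[:2]) < err.missingness
            geno[miss] = MISSING
        panel_rows.append(geno)
        panel_ids.extend(m.individual_id for m in ped)

        # assemble the family variant table (truth dosages per member)
        var_rows = []
        dosages = {}
        members = [m.individual_id for m in ped]
        for k in range(n_bg + 1):
            is_causal = k == n_bg
            chrom = config.causal.chrom if is_causal else str(bg_chroms[k])
            bp = causal_bp if is_causal else int(bg_bps[k])
            hap = 0 if is_causal else int(rng.integers(n_haps))
            vpos = pos_index[chrom][bp]
            ori = origins[chrom][:, vpos, :]
            dose = {iid: int((ori[r] == hap).sum()) for iid, r in row.items()}
            if not any(dose.values()):
                continue  # allele drifted out of the family
            ref, alt = _REF_ALT[bp % len(_REF_ALT)]
            if is_causal:
                eur_maf, effect, cadd = None, "NON_SYNONYMOUS_CODING", config.causal.cadd
            else:
                u = rng.random()
                if u < bg.private_fraction:
                    eur_maf = None
                elif u < bg.private_fraction + bg.common_fraction:
                    eur_maf = float(rng.uniform(*bg.common_maf_range))
                else:
                    lo_m, hi_m = bg.rare_maf_range
                    eur_maf = float(
                        np.exp(rng.uniform(np.log(lo_m), np.log(hi_m)))
                    )
                effect = str(rng.choice(effects, p=eprobs))
                cadd = float(rng.exponential(bg.cadd_scale))
            var_rows.append(
                {
                    "family": fam, "chrom": chrom, "pos": bp, "ref": ref,
                    "alt": alt, "is_causal": is_causal, "eur_maf": eur_maf,
                    "effect": effect,
                    "impact": EFFECT_IMPACT.get(effect, "MODIFIER"),
                    "cadd": cadd, "gene": f"GENE{chrom}_{bp % 97}",
                }
            )
            dosages[(chrom, bp, ref, alt)] = dose
        fam_truth = pd.DataFrame(var_rows)
        truth_rows.append(fam_truth)
        families[fam] = FamilyTruth(
            pedigree=ped,
            origins=origins,
            row=row,
            causal_pos=(config.causal.chrom, causal_bp),
            causal_carriers=carrier,
            variant_dosage=pd.DataFrame(
                {str(k): v for k, v in dosages.items()}
            ).T.reindex(columns=members),
        )

        # sequenced affecteds: the two first-listed IgAN cases
        aff = ped.affected()
        if len(aff) >= 2:
            sequenced[fam] = (aff[0], aff[1])
        samples = members
        ug_records[fam], hc_records[fam] = emulate_callers(
            fam_truth, dosages, samples, err, rng
        )

    panel = GenotypePanel(panel_ids, mmap, np.concatenate(panel_rows))
    truth = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame()
    )
    return SimulatedStudy(
        config, peds, panel, truth, families, ug_records, hc_records, sequenced
    )


def assign_phenotypes(
    ped: Pedigree,
    carrier: dict[str, bool],
    causal: CausalSpec,
    rng: np.random.Generator,
) -> Pedigree:
    """Draw phenotypes from carrier status under incomplete penetrance."""
    members = []
    for m in ped:
        if rng.random() < causal.missing_phenotype_rate:
            members.append(replace(m, phenotype=Phenotype.UNKNOWN))
            continue
        if carrier[m.individual_id]:
            if rng.random() < causal.f_carrier:
                pheno = Phenotype.IGAN_AFFECTED
            elif rng.random() < causal.p_ua_carrier:
                pheno = Phenotype.URINARY_ABNORMALITY
            else:
                pheno = Phenotype.UNAFFECTED
        else:
            if rng.random() < causal.phenocopy:
                pheno = Phenotype.IGAN_AFFECTED
            else:
                pheno = Phenotype.UNAFFECTED
        members.append(replace(m, phenotype=pheno))
    return Pedigree(ped.family_id, members)


def emulate_callers(
    fam_truth: pd.DataFrame,
    dosages: dict[tuple, dict[str, int]],
    samples: Sequence[str],
    err: ErrorSpec,
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Two caller-tagged record lists with sensitivity, error and noise.

    Each true variant enters a caller's list independently with that
    caller's sensitivity; site QUAL/MQ/FS are pass-dominant draws with a
    configurable fraction pushed into hard-filter failure; per-sample
    depth is a negative-binomial-like integer draw.
    """
    ug, hc = [], []
    for _, v in fam_truth.iterrows():
        key = (v["chrom"], int(v["pos"]), v["ref"], v["alt"])
        dose = dosages[key]
        in_ug = rng.random() < err.s_ug
        in_hc = rng.random() < err.s_hc
        if not (in_ug or in_hc):
            continue
        fail = rng.random() < err.hard_fail_fraction
        qual = float(rng.uniform(5, 25)) if fail else float(rng.uniform(40, 900))
        mq = 60.0 if not fail else 35.0
        fs = float(rng.exponential(5.0))
        calls = {}
        for s in samples:
            d = int(
                rng.negative_binomial(
                    err.depth_dispersion,
                    err.depth_dispersion / (err.depth_dispersion + err.depth_mean),
                )
            )
            dos = dose.get(s, 0)
            if rng.random() < err.missingness:
                dos = -1
            elif rng.random() < err.genotype_error:
                dos = int(rng.integers(0, 3))
            calls[s] = GenotypeCall(dos, d)
        kwargs = dict(
            chrom=str(v["chrom"]), pos=int(v["pos"]), ref=v["ref"], alt=v["alt"],
            qual=qual, mq=mq, fs=fs,
            eur_maf=None if pd.isna(v["eur_maf"]) else float(v["eur_maf"]),
            effect=v["effect"], impact=v["impact"],
            cadd=float(v["cadd"]), gene=v["gene"],
        )
        if in_ug:
            ug.append(VariantRecord(genotypes=dict(calls),
                                    callers=frozenset({UG}), **kwargs))
        if in_hc:
            hc.append(VariantRecord(genotypes=dict(calls),
                                    callers=frozenset({HC}), **kwargs))
    return ug, hc


# ---------------------------------------------------------------------------
# Writers (round-trip through the pipeline's own readers)
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write PED/MAP/genotype-PED, dual VCFs, truth TSV and a regions BED."""
    from .markers import write_genotype_ped, write_map
    from .pedigree import write_ped

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "families.ped",
        "map": out / "markers.map",
        "genotypes": out / "genotypes.ped",
        "truth": out / "truth.tsv",
        "vcf_ug": out / "calls_UG.vcf",
        "vcf_hc": out / "calls_HC.vcf",
    }
    write_ped(study.pedigrees, paths["ped"])
    write_map(study.panel.map, paths["map"])
    write_genotype_ped(study.panel, study.pedigrees, paths["genotypes"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    for caller, path in ((UG, paths["vcf_ug"]), (HC, paths["vcf_hc"])):
        recs = study.ug_records if caller == UG else study.hc_records
        flat = [r for fam in sorted(recs) for r in recs[fam]]
        write_vcf(flat, path, seed=study.config.seed)
    return paths


def write_vcf(
    records: Sequence[VariantRecord], path: str | Path, seed: int | None = None
) -> None:
    """Minimal VCF 4.2 writer honouring the annotated-INFO contract."""
    samples = sorted({s for r in records for s in r.genotypes})
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=EUR_MAF,Number=1,Type=Float,Description="European MAF">',
        '##INFO=<ID=EFF,Number=1,Type=String,Description="Effect term">',
        '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Impact class">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="Scaled C-score">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand-bias phred">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    if seed is not None:
        header.insert(1, f"##famcoseg_seed={seed}")
    header += [
        "##contig=<ID=%s>" % c
        for c in sorted({r.chrom for r in records}, key=str)
    ]
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    lines = []
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        info = [f"MQ={r.mq:g}", f"FS={r.fs:g}"]
        if r.eur_maf is not None:
            info.append(f"EUR_MAF={r.eur_maf:.8g}")
        if r.effect is not None:
            info.append(f"EFF={r.effect}")
        if r.impact is not None:
            info.append(f"IMPACT={r.impact}")
        if r.cadd is not None:
            info.append(f"CADD={r.cadd:g}")
        if r.gene is not None:
            info.append(f"GENE={r.gene}")
        cols = [
            r.chrom, str(r.pos), ".", r.ref, r.alt, f"{r.qual:g}", ".",
            ";".join(info), "GT:DP",
        ]
        for s in samples:
            g = r.genotypes.get(s, GenotypeCall(-1))
            cols.append(f"{gt_str[g.dosage]}:{g.depth}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(header + lines) + "\n")
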