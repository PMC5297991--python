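"""Marker maps, genotype panels, linkage-format I/O and marker QC.

QC follows the usual array-genotyping gates for family data: individuals
are screened first (call-rate, Mendelian-error fraction), then markers
(founder Hardy-Weinberg exact test, minor allele frequency).  HWE is tested
on founders only, because relatedness inflates the test in family panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pedigree import Pedigree, PedigreeError

MISSING = -1  # allele code for a missing call


class QCError(ValueError):
    """Raised when quality control leaves nothing to analyse."""


@dataclass
class Marker:
    name: str
    chrom: str
    cm: float                      # genetic position, centimorgan
    bp: int                        # physical position, 1-based
    allele_freqs: np.ndarray       # founder allele frequencies, sum to 1
    alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if abs(self.allele_freqs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"marker {self.name}: allele frequencies sum to "
                f"{self.allele_freqs.sum()}, not 1"
            )
        if not self.alleles:
            self.alleles = [str(i + 1) for i in range(len(self.allele_freqs))]


@dataclass
class MarkerMap:
    """Ordered marker map; genetic positions nondecreasing per chromosome."""

    markers: list[Marker]

    def __post_init__(self) -> None:
        last: dict[str, float] = {}
        for m in self.markers:
            if m.chrom in last and m.cm < last[m.chrom]:
                raise ValueError(
                    f"marker {m.name}: genetic position decreases on "
                    f"chromosome {m.chrom}"
                )
            last[m.chrom] = m.cm

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, i):
        return self.markers[i]

    def chrom_indices(self, chrom: str) -> list[int]:
        return [i for i, m in enumerate(self.markers) if m.chrom == chrom]

    def subset(self, indices: Sequence[int]) -> "MarkerMap":
        return MarkerMap([self.markers[i] for i in indices])


@dataclass
class GenotypePanel:
    """Unordered genotype calls, shape (n_individuals, n_markers, 2).

    Allele codes index into each marker's allele set; ``MISSING`` (-1)
    marks a missing call (both slots missing together).
    """

    individuals: list[str]
    map: MarkerMap
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        n_ind, n_mark, two = self.genotypes.shape
        if n_ind != len(self.individuals) or n_mark != len(self.map) or two != 2:
            raise ValueError("genotype array shape inconsistent with panel")
        self._row = {iid: i for i, iid in enumerate(self.individuals)}

    def row(self, individual_id: str) -> int:
        try:
            return self._row[individual_id]
        except KeyError:
            raise KeyError(f"no genotypes for individual {individual_id!r}") from None

    def genotype(self, individual_id: str, marker_index: int) -> tuple[int, int]:
        g = self.genotypes[self.row(individual_id), marker_index]
        return int(g[0]), int(g[1])

    def subset_markers(self, indices: Sequence[int]) -> "GenotypePanel":
        idx = list(indices)
        return GenotypePanel(
            list(self.individuals), self.map.subset(idx),
            self.genotypes[:, idx, :].copy(),
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypePanel":
        rows = [self.row(i) for i in ids]
        return GenotypePanel(
            list(ids), self.map, self.genotypes[rows, :, :].copy()
        )


# ---------------------------------------------------------------------------
# Linkage-dialect I/O: MAP and genotype-bearing PED
# ---------------------------------------------------------------------------

def read_map(path: str | Path, default_freqs: Sequence[float] = (0.5, 0.5)) -> MarkerMap:
    """Read a 4-column MAP file: chrom, name, cM, bp.

    An optional 5th column carries comma-separated allele frequencies;
    absent, markers are assumed biallelic with ``default_freqs``.
    """
    markers: list[Marker] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (4, 5):
            raise ValueError(f"MAP line {lineno}: expected 4 or 5 columns")
        chrom, name, cm, bp = fields[:4]
        freqs = (
            [float(x) for x in fields[4].split(",")]
            if len(fields) == 5
            else list(default_freqs)
        )
        markers.append(Marker(name, chrom, float(cm), int(bp), np.array(freqs)))
    return MarkerMap(markers)


def write_map(mmap: MarkerMap, path: str | Path) -> None:
    lines = [
        "\t".join(
            [
                m.chrom,
                m.name,
                f"{m.cm:g}",
                str(m.bp),
                ",".join(f"{f:.10g}" for f in m.allele_freqs),
            ]
        )
        for m in mmap
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_ped(path: str | Path, mmap: MarkerMap) -> GenotypePanel:
    """Read the genotype columns of a linkage PED (6 + 2 per marker).

    Allele codes are 1-based in the file (0 = missing) and stored 0-based.
    """
    individuals: list[str] = []
    rows: list[np.ndarray] = []
    n_mark = len(mmap)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * n_mark:
            raise ValueError(
                f"PED line {lineno}: expected {6 + 2 * n_mark} columns for "
                f"{n_mark} markers, got {len(fields)}"
            )
        individuals.append(fields[1])
        codes = np.array(fields[6:], dtype=np.int32).reshape(n_mark, 2)
        geno = codes - 1  # 0 (missing) -> -1
        geno[(codes == 0).any(axis=1)] = MISSING
        rows.append(geno.astype(np.int16))
    return GenotypePanel(individuals, mmap, np.stack(rows))


def write_genotype_ped(
    panel: GenotypePanel,
    peds: Iterable[Pedigree],
    path: str | Path,
) -> None:
    """Write a genotype-bearing linkage PED for the given pedigrees."""
    from .pedigree import _CODE_FROM_PHENO, _CODE_FROM_SEX  # shared dialect

    lines = []
    for ped in peds:
        for m in ped:
            geno = panel.genotypes[panel.row(m.individual_id)]
            codes = (geno + 1).clip(min=0)  # MISSING -> 0
            flat = " ".join(str(c) for c in codes.reshape(-1))
            lines.append(
                " ".join(
                    [
                        ped.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _CODE_FROM_SEX[m.sex],
                        _CODE_FROM_PHENO[m.phenotype],
                        flat,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one biallelic marker.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed count (the Wigginton-Cutler-Abecasis convention).  Monomorphic
    markers return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    # P(het = h | allele counts) ∝ 2^h / ((rare-h)/2)! h! ((common-h)/2)!
    common = 2 * n - rare
    n_rr = (rare - hets) // 2
    n_cc = (common - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(n_rr + 1)
        - gammaln(hets + 1)
        - gammaln(n_cc + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_Aa][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def _gamete_set(geno: tuple[int, int]) -> set[int] | None:
    if geno[0] == MISSING or geno[1] == MISSING:
        return None  # missing: compatible with anything
    return {geno[0], geno[1]}


def mendelian_consistent(
    child: tuple[int, int],
    father: tuple[int, int],
    mother: tuple[int, int],
) -> bool:
    """True iff the child genotype can arise from one allele per parent.

    Missing genotypes are compatible with anything.
    """
    if _gamete_set(child) is None:
        return True
    f = _gamete_set(father)
    m = _gamete_set(mother)
    c1, c2 = child
    for pat, mat in ((c1, c2), (c2, c1)):
        ok_f = f is None or pat in f
        ok_m = m is None or mat in m
        if ok_f and ok_m:
            return True
    return False


def count_mendelian_errors(
    panel: GenotypePanel, peds: Iterable[Pedigree]
) -> dict[str, tuple[int, int]]:
    """Per-individual (errors, checked) over all child-father-mother trios.

    An inconsistent trio charges one error to each of its three members,
    mirroring how per-individual Mendelian-error fractions are screened.
    """
    counts: dict[str, tuple[int, int]] = {
        iid: (0, 0) for iid in panel.individuals
    }
    n_mark = len(panel.map)
    for ped in peds:
        for m in ped:
            if m.is_founder or m.individual_id not in panel._row:
                continue
            trio = [m.individual_id, m.father_id, m.mother_id]
            if any(t is None or t not in panel._row for t in trio):
                continue
            rows = [panel.row(t) for t in trio]
            for j in range(n_mark):
                g = [tuple(panel.genotypes[r, j]) for r in rows]
                if all(a == MISSING for gt in g for a in gt):
                    continue
                ok = mendelian_consistent(*g)
                for t in trio:
                    e, n = counts[t]
                    counts[t] = (e + (0 if ok else 1), n + 1)
    return counts


# ---------------------------------------------------------------------------
# LD pruning (composite-genotype r^2 on founders)
# ---------------------------------------------------------------------------

def _genotype_dosage(panel: GenotypePanel, rows: Sequence[int]) -> np.ndarray:
    """Allele-1 dosage matrix (individuals x markers), NaN where missing."""
    g = panel.genotypes[rows, :, :].astype(float)
    dosage = (g == 1).sum(axis=2).astype(float)
    dosage[(g == MISSING).any(axis=2)] = np.nan
    return dosage


def ld_prune(
    panel: GenotypePanel,
    founder_ids: Sequence[str],
    r2_threshold: float = 0.10,
    window: int = 50,
) -> tuple[GenotypePanel, list[int]]:
    """Greedy left-to-right LD pruning on founder genotype correlations.

    A marker is dropped when its squared genotype correlation with any
    *retained* marker within ``window`` positions (same chromosome)
    strictly exceeds ``r2_threshold``.  Deterministic given input order.
    Returns the pruned panel and the retained marker indices.
    """
    rows = [panel.row(i) for i in founder_ids]
    dosage = _genotype_dosage(panel, rows)
    kept: list[int] = []
    for j, marker in enumerate(panel.map):
        drop = False
        for k in reversed(kept):
            if panel.map[k].chrom != marker.chrom or j - k > window:
                break
            x, y = dosage[:, k], dosage[:, j]
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3:
                continue
            xv, yv = x[mask], y[mask]
            if xv.std() == 0 or yv.std() == 0:
                continue
            r = np.corrcoef(xv, yv)[0, 1]
            if r * r > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(j)
    return panel.subset_markers(kept), kept


# ---------------------------------------------------------------------------
# Combined marker / individual QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exclusion:
    kind: str        # "individual" or "marker"
    identifier: str
    reason: str      # "missingness" | "mendelian" | "hwe" | "maf"
    value: float


@dataclass
class QCReport:
    exclusions: list[Exclusion]

    @property
    def excluded_individuals(self) -> list[str]:
        return [e.identifier for e in self.exclusions if e.kind == "individual"]

    @property
    def excluded_markers(self) -> list[str]:
        return [e.identifier for e in self.exclusions if e.kind == "marker"]


DEFAULT_QC = {"ind_missing": 0.05, "ind_mendel": 0.05, "hwe_p": 1e-6, "maf": 0.05}


def qc_markers(
    panel: GenotypePanel,
    peds: Sequence[Pedigree],
    thresholds: dict | None = None,
) -> tuple[GenotypePanel, QCReport]:
    """Individual-first, then marker QC.

    Individuals with a missing-call fraction or Mendelian-error fraction
    strictly above their thresholds are removed; then markers failing the
    founder HWE exact test (p <= hwe_p) or with minor allele frequency
    <= maf are removed.  Raises :class:`QCError` if nothing survives.
    """
    t = dict(DEFAULT_QC)
    if thresholds:
        t.update(thresholds)
    exclusions: list[Exclusion] = []

    missing = (panel.genotypes == MISSING).any(axis=2).mean(axis=1)
    mend = count_mendelian_errors(panel, peds)
    keep_ids = []
    for i, iid in enumerate(panel.individuals):
        if missing[i] > t["ind_missing"]:
            exclusions.append(
                Exclusion("individual", iid, "missingness", float(missing[i]))
            )
            continue
        e, n = mend.get(iid, (0, 0))
        frac = e / n if n else 0.0
        if frac > t["ind_mendel"]:
            exclusions.append(Exclusion("individual", iid, "mendelian", frac))
            continue
        keep_ids.append(iid)
    if not keep_ids:
        raise QCError("nothing survives QC: all individuals excluded")
    panel = panel.subset_individuals(keep_ids)

    founder_ids = [
        m.individual_id
        for ped in peds
        for m in ped.founders
        if m.individual_id in panel._row
    ]
    f_rows = [panel.row(i) for i in founder_ids]
    keep_markers: list[int] = []
    for j, marker in enumerate(panel.map):
        g = panel.genotypes[f_rows, j, :]
        called = g[~(g == MISSING).any(axis=1)]
        if len(marker.allele_freqs) == 2 and len(called):
            ones = (called == 1).sum(axis=1)
            n_AA = int((ones == 0).sum())
            n_Aa = int((ones == 1).sum())
            n_aa = int((ones == 2).sum())
            p_hwe = hwe_exact_p(n_AA, n_Aa, n_aa)
            if p_hwe <= t["hwe_p"]:
                exclusions.append(Exclusion("marker", marker.name, "hwe", p_hwe))
                continue
            af1 = (2 * n_aa + n_Aa) / (2 * len(called))
            maf = min(af1, 1 - af1)
            if maf <= t["maf"]:
                exclusions.append(Exclusion("marker", marker.name, "maf", maf))
                continue
        keep_markers.append(j)
    if not keep_markers:
        raise QCError("nothing survives QC: all markers excluded")
    return panel.subset_markers(keep_markers), QCReport(exclusions)
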