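"""Nonparametric linkage scoring: S_all, per-family Z, Kong-Cox LOD.

The Whittemore-Halpern ``S_all`` statistic scores an inheritance vector by
the extent of simultaneous founder-allele sharing among affected members:

    S_all(v) = 2^(-a) * sum_h prod_i b_i(h)!

where ``a`` is the number of affecteds, ``h`` ranges over the ``2^a`` ways
of picking one of the two founder alleles from each affected, and
``b_i(h)`` counts how often founder allele ``i`` occurs in the pick.  Null
moments are obtained by exhaustive enumeration over the uniform vector
distribution, and the per-family standardized score is averaged over the
posterior.  Per-position family scores combine through the Kong-Cox linear
model, a one-parameter likelihood tilt ``L(delta) = prod_f (1 + delta Z_f)``
whose maximized log10 is the LOD, with the one-sided mixture null
``p = Pr(chi2_1 > 2 ln10 LOD) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .hmm import InheritanceDistribution, PedigreeHMM
from .pedigree import Pedigree


# ---------------------------------------------------------------------------
# S_all
# ---------------------------------------------------------------------------

def s_all_from_labels(labels: np.ndarray, affected_rows: Sequence[int]) -> np.ndarray:
    """Vectorized S_all over classes; ``labels`` is (C, N, 2)."""
    aff = list(affected_rows)
    a = len(aff)
    if a < 2:
        raise ValueError("S_all requires at least 2 affected members")
    L = labels[:, aff, :]  # (C, a, 2)
    C = L.shape[0]
    total = np.zeros(C)
    for h in range(1 << a):
        picks = np.array([(h >> i) & 1 for i in range(a)])
        chosen = L[:, np.arange(a), picks]  # (C, a)
        s = np.sort(chosen, axis=1)
        # prod of factorials of label multiplicities == prod of run positions
        run = np.ones((C, a))
        for j in range(1, a):
            same = s[:, j] == s[:, j - 1]
            run[:, j] = np.where(same, run[:, j - 1] + 1, 1.0)
        total += run.prod(axis=1)
    return total / (1 << a)


def s_all(
    vector_labels: np.ndarray | Sequence[Sequence[int]],
    affected_rows: Sequence[int],
) -> float:
    """S_all for a single inheritance vector's member labels (N, 2)."""
    arr = np.asarray(vector_labels)[None, :, :]
    return float(s_all_from_labels(arr, affected_rows)[0])


@dataclass
class SallScorer:
    """Null-standardized S_all scoring bound to one pedigree's HMM.

    ``affected`` are individual ids counted as affected (by default the
    biopsy-proven cases, per the affected-only strategy).  ``z_min`` is the
    minimum achievable standardized score, used to bound the Kong-Cox
    tilting parameter.
    """

    hmm: PedigreeHMM
    affected: Sequence[str]
    uninformative: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        rows = [self.hmm._midx[a] for a in self.affected]
        self._scores = s_all_from_labels(self.hmm.labels, rows)
        # uniform over full vectors == uniform over classes (equal sizes)
        self.mu = float(self._scores.mean())
        var = float(((self._scores - self.mu) ** 2).mean())
        if var <= 0.0:
            self.uninformative = True
            self.sigma = 0.0
            self.z_min = 0.0
            self._z = np.zeros_like(self._scores)
        else:
            self.sigma = var ** 0.5
            self._z = (self._scores - self.mu) / self.sigma
            self.z_min = float(self._z.min())

    def z(self, dist: InheritanceDistribution) -> np.ndarray:
        """Posterior-averaged standardized score at each position."""
        return dist.posterior @ self._z


def npl_z(
    dist: InheritanceDistribution, affected: Sequence[str]
) -> tuple[np.ndarray, SallScorer]:
    """Per-position Z for one family; Z = 0 with a flag if uninformative."""
    scorer = SallScorer(dist.hmm, affected)
    return scorer.z(dist), scorer


# ---------------------------------------------------------------------------
# Kong-Cox linear model
# ---------------------------------------------------------------------------

def kong_cox_lod(
    z_by_family: Sequence[float],
    z_min_by_family: Sequence[float] | None = None,
    delta_cap: float = 10.0,
) -> tuple[float, float, float]:
    """Maximize the Kong-Cox linear likelihood; return (delta, LOD, p).

    ``delta`` is constrained to keep the tilted sharing distribution valid:
    when the per-family minimum achievable Z is supplied, the bound is
    ``min_f -1/z_min_f``; otherwise it falls back to the largest delta
    keeping all observed factors positive, capped at ``delta_cap``.
    """
    z = np.asarray([zf for zf in z_by_family if np.isfinite(zf)], dtype=float)
    if z.size == 0:
        raise ValueError("kong_cox_lod needs at least one finite Z")
    if z_min_by_family is not None:
        mins = np.asarray(z_min_by_family, dtype=float)
        neg = mins[mins < 0]
        dmax = float((-1.0 / neg).min()) - 1e-9 if neg.size else delta_cap
    else:
        neg = z[z < 0]
        dmax = float((-1.0 / neg).min()) - 1e-9 if neg.size else delta_cap
    dmax = min(dmax, delta_cap)
    if dmax <= 0 or not np.any(z > 0):
        return 0.0, 0.0, 0.5

    def neg_log10_lik(d: float) -> float:
        terms = 1.0 + d * z
        if np.any(terms <= 0):
            return np.inf
        return -float(np.log10(terms).sum())

    res = minimize_scalar(
        neg_log10_lik, bounds=(0.0, dmax), method="bounded",
        options={"xatol": 1e-10},
    )
    lod = max(0.0, -res.fun)
    delta = float(res.x) if lod > 0 else 0.0
    if lod == 0.0:
        delta = 0.0
    return delta, float(lod), lod_to_p(lod)


def lod_to_p(lod: float) -> float:
    """One-sided mixture-null p-value for a Kong-Cox LOD score."""
    if lod < 0:
        raise ValueError("LOD must be nonnegative")
    if lod == 0.0:
        return 0.5
    return 0.5 * float(chi2.sf(2.0 * np.log(10.0) * lod, df=1))


def p_to_lod(p: float) -> float:
    """Inverse of :func:`lod_to_p` on p in (0, 0.5]."""
    if not 0.0 < p <= 0.5:
        raise ValueError("p must lie in (0, 0.5]")
    return float(chi2.isf(2.0 * p, df=1)) / (2.0 * np.log(10.0))


def lod_p_convert(value: float, direction: str) -> float:
    if direction == "lod_to_p":
        return lod_to_p(value)
    if direction == "p_to_lod":
        return p_to_lod(value)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Scan result and region calling
# ---------------------------------------------------------------------------

@dataclass
class NPLResult:
    """Per-position combined scan: family Z scores, delta, LOD, p."""

    table: pd.DataFrame  # chrom, cm, bp, Z_<fam>..., delta, lod, p
    family_ids: list[str]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LinkedRegion:
    chrom: str
    start: int                 # 1-based bp, inclusive
    end: int                   # 1-based bp, inclusive
    peak_lod: float
    peak_p: float
    contributing_families: tuple[str, ...]

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def combine_families(
    chrom: str,
    positions: Sequence[tuple[float, int]],      # (cM, bp) per position
    z_by_family: dict[str, np.ndarray],
    z_min_by_family: dict[str, float],
) -> NPLResult:
    """Kong-Cox combination of per-family Z tracks on one chromosome."""
    fams = sorted(z_by_family)
    n = len(positions)
    rows = []
    for i in range(n):
        zs = [float(z_by_family[f][i]) for f in fams]
        mins = [z_min_by_family[f] for f in fams]
        delta, lod, p = kong_cox_lod(zs, mins)
        cm, bp = positions[i]
        rows.append([chrom, cm, bp, *zs, delta, lod, p])
    cols = ["chrom", "cm", "bp", *[f"Z_{f}" for f in fams], "delta", "lod", "p"]
    return NPLResult(pd.DataFrame(rows, columns=cols), fams)


def call_linked_regions(
    scan: NPLResult, lod_threshold: float = 1.5
) -> list[LinkedRegion]:
    """Maximal runs of positions with LOD > threshold, per chromosome.

    Region bounds extend outward to the physical positions of the flanking
    sub-threshold markers (or the chromosome's first/last scanned marker),
    reported as an inclusive 1-based interval.  Ties in the peak go to the
    leftmost maximum.
    """
    regions: list[LinkedRegion] = []
    t = scan.table
    for chrom, sub in t.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        above = (sub["lod"] > lod_threshold).to_numpy()
        i = 0
        while i < len(sub):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and above[j + 1]:
                j += 1
            lo = int(sub.loc[max(i - 1, 0), "bp"])
            hi = int(sub.loc[min(j + 1, len(sub) - 1), "bp"])
            run = sub.loc[i:j]
            peak = run["lod"].idxmax()  # first occurrence on ties
            contrib = tuple(
                f for f in scan.family_ids if run.loc[peak, f"Z_{f}"] > 0
            )
            regions.append(
                LinkedRegion(
                    chrom=str(chrom),
                    start=lo,
                    end=hi,
                    peak_lod=float(run.loc[peak, "lod"]),
                    peak_p=float(run.loc[peak, "p"]),
                    contributing_families=contrib,
                )
            )
            i = j + 1
    return regions


def write_regions_bed(regions: Iterable[LinkedRegion], path: str | Path) -> None:
    """BED export: 0-based half-open (start-1, end) conversion from 1-based."""
    lines = [
        f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
        f"lod={r.peak_lod:.4g};p={r.peak_p:.4g}"
        for r in regions
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_regions_bed(path: str | Path) -> list[LinkedRegion]:
    regions = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith(("#", "track")):
            continue
        fields = raw.split("\t")
        chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
        lod = p = float("nan")
        if len(fields) > 3:
            for kv in fields[3].split(";"):
                if kv.startswith("lod="):
                    lod = float(kv[4:])
                elif kv.startswith("p="):
                    p = float(kv[2:])
        regions.append(LinkedRegion(chrom, start0 + 1, end, lod, p, ()))
    return regions


# ---------------------------------------------------------------------------
# Whole-scan driver
# ---------------------------------------------------------------------------

def npl_scan(
    peds: Sequence[Pedigree],
    panel,
    affected_by_family: dict[str, Sequence[str]] | None = None,
    bit_limit: int = 16,
) -> NPLResult:
    """Affected-only NPL scan across all chromosomes and families.

    Families with fewer than two typed affecteds, or uninformative for
    sharing, contribute Z = 0 at every position.
    """
    from .hmm import inheritance_distribution
    from .pedigree import Phenotype

    chroms = []
    for m in panel.map:
        if m.chrom not in chroms:
            chroms.append(m.chrom)
    frames = []
    fam_ids = [p.family_id for p in peds]
    for chrom in chroms:
        idx = panel.map.chrom_indices(chrom)
        positions = [(panel.map[j].cm, panel.map[j].bp) for j in idx]
        z_tracks: dict[str, np.ndarray] = {}
        z_mins: dict[str, float] = {}
        for ped in peds:
            if affected_by_family is not None:
                aff = list(affected_by_family.get(ped.family_id, ()))
            else:
                aff = ped.affected()
            aff = [a for a in aff if a in panel._row]
            if len(aff) < 2:
                z_tracks[ped.family_id] = np.zeros(len(idx))
                z_mins[ped.family_id] = 0.0
                continue
            dist = inheritance_distribution(ped, panel, chrom, bit_limit=bit_limit)
            z, scorer = npl_z(dist, aff)
            z_tracks[ped.family_id] = z
            z_mins[ped.family_id] = scorer.z_min
        frames.append(
            combine_families(chrom, positions, z_tracks, z_mins).table
        )
    table = pd.concat(frames, ignore_index=True)
    return NPLResult(table, sorted(fam_ids))
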