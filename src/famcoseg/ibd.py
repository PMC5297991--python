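"""Regional IBD sharing and intrafamilial discordant-control selection.

For each WES trio the pipeline needs an intrafamilial negative control:
the relative who, inside the linked region, shares the least genetic
material identical by descent with the two affected individuals — a
"genetically discordant" control whose genome mimics the affecteds'
except over the haplotypes of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import InheritanceDistribution
from .npl import LinkedRegion
from .pedigree import Pedigree, Phenotype, kinship_coefficient


@dataclass(frozen=True)
class RegionalIBD:
    pair: tuple[str, str]
    region: LinkedRegion | None
    mean_ibd_proportion: float   # in [0, 1]


def _ibd_proportion_track(
    dist: InheritanceDistribution, a: str, b: str
) -> np.ndarray:
    """Expected IBD allele-sharing proportion of (a, b) per position."""
    hmm = dist.hmm
    la = hmm.labels[:, hmm._midx[a], :]  # (C, 2)
    lb = hmm.labels[:, hmm._midx[b], :]
    # IBD allele count under each class: size of the multiset intersection
    # of the two ordered label pairs (0, 1 or 2 for non-inbred pedigrees)
    eq = la[:, :, None] == lb[:, None, :]       # (C, 2, 2)
    direct = eq[:, 0, 0] & eq[:, 1, 1]
    crossed = eq[:, 0, 1] & eq[:, 1, 0]
    two = direct | crossed
    one = eq.any(axis=(1, 2)) & ~two
    ibd_count = 2.0 * two + 1.0 * one
    return dist.posterior @ (ibd_count / 2.0)


def regional_ibd(
    dist: InheritanceDistribution,
    a: str,
    b: str,
    region: LinkedRegion | None = None,
    region_cms: tuple[float, float] | None = None,
) -> RegionalIBD:
    """Mean posterior IBD proportion for a pair over the region's grid.

    Positions are the distribution's evaluation grid restricted to
    ``region_cms`` (a genetic-coordinate window) when given; with a
    uniform posterior this equals twice the kinship coefficient for
    non-inbred pairs.
    """
    if a == b:
        raise ValueError("regional IBD needs two distinct individuals")
    track = _ibd_proportion_track(dist, a, b)
    mask = np.ones(len(track), dtype=bool)
    if region_cms is not None:
        lo, hi = region_cms
        mask = (dist.positions_cm >= lo) & (dist.positions_cm <= hi)
    if not mask.any():
        raise ValueError("region contains no evaluated positions")
    return RegionalIBD((a, b), region, float(track[mask].mean()))


def select_intrafamilial_control(
    ped: Pedigree,
    dist: InheritanceDistribution,
    affected_pair: tuple[str, str],
    candidates: list[str] | None = None,
    region: LinkedRegion | None = None,
    region_cms: tuple[float, float] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Pick the genetically discordant control for a sequenced trio.

    Candidates default to unaffected members with genotype data available
    to the HMM.  Each candidate is scored by the mean of its regional IBD
    with the two affecteds; the minimizer wins.  Ties break toward the
    closer relative (larger mean kinship with the affecteds), then the
    lexically smallest id, making selection deterministic.  Returns the
    chosen id and the full audit ranking.
    """
    a1, a2 = affected_pair
    if candidates is None:
        candidates = [
            m.individual_id
            for m in ped
            if m.phenotype is Phenotype.UNAFFECTED
            and m.individual_id not in affected_pair
        ]
    candidates = [c for c in candidates if c not in affected_pair]
    if not candidates:
        raise ValueError(
            f"family {ped.family_id}: no eligible control candidate"
        )
    rows = []
    for c in candidates:
        i1 = regional_ibd(dist, c, a1, region, region_cms).mean_ibd_proportion
        i2 = regional_ibd(dist, c, a2, region, region_cms).mean_ibd_proportion
        kin = 0.5 * (
            kinship_coefficient(ped, c, a1) + kinship_coefficient(ped, c, a2)
        )
        rows.append(
            {
                "candidate": c,
                "ibd_with_affected1": i1,
                "ibd_with_affected2": i2,
                "mean_ibd": 0.5 * (i1 + i2),
                "max_ibd": max(i1, i2),
                "mean_kinship": kin,
            }
        )
    ranking = pd.DataFrame(rows).sort_values(
        by=["mean_ibd", "mean_kinship", "candidate"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return str(ranking.loc[0, "candidate"]), ranking
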