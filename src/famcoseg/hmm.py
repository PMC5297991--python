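"""Exact multipoint inheritance-vector HMM (Lander-Green machinery).

State space and symmetry
------------------------
Each non-founder contributes two meiosis indicator bits (paternal and
maternal transmission), giving a full space of ``2^(2n)`` inheritance
vectors for ``n`` non-founders.  Swapping the two haplotypes of a founder
relabels vectors without changing any observable, so vectors are grouped
into equivalence classes by fixing one designated transmission bit per
founder to 0; with ``f`` founders (all having children) this leaves the
classical ``b = 2n - f`` bits.  Emissions and allele-sharing statistics are
class-invariant, so they are evaluated once per class representative, while
the forward-backward recursion runs in the full space where the Haldane
transition kernel factorizes bit by bit.

Transitions between adjacent positions at genetic distance ``d`` cM flip
every meiosis bit independently with probability
``theta = (1 - exp(-2 d / 100)) / 2`` (Haldane, no interference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .markers import MISSING, GenotypePanel, MarkerMap
from .pedigree import Pedigree


class FeasibilityError(ValueError):
    """Pedigree exceeds the configured inheritance-vector bit limit."""


class MendelianImpossibilityError(ValueError):
    """Observed genotypes have zero likelihood under every vector."""


def haldane_theta(d_cm: float) -> float:
    """Recombination fraction for a genetic distance in centimorgan."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


@dataclass
class InheritanceDistribution:
    """Posterior over inheritance-vector classes per evaluation position."""

    ped: Pedigree
    positions_cm: np.ndarray          # evaluation grid, one chromosome
    chrom: str
    posterior: np.ndarray             # (n_positions, n_classes), rows sum to 1
    hmm: "PedigreeHMM"

    def __post_init__(self) -> None:
        sums = self.posterior.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posterior rows must each sum to 1")


class PedigreeHMM:
    """Per-pedigree machinery reusable across markers and replicates.

    Precomputes the meiosis-bit layout, founder flip masks, the
    full-vector -> class index map, and per-class founder-allele labels
    for every member.
    """

    def __init__(self, ped: Pedigree, bit_limit: int = 16):
        from .pedigree import bit_complexity

        self.ped = ped
        b = bit_complexity(ped)
        if b > bit_limit:
            raise FeasibilityError(
                f"family {ped.family_id}: bit complexity {b} exceeds limit "
                f"{bit_limit}; split the pedigree or raise the limit"
            )
        self.bits = b
        members = ped.topological_members()
        self.member_ids = [m.individual_id for m in members]
        self._midx = {iid: i for i, iid in enumerate(self.member_ids)}
        founders = [m for m in members if m.is_founder]
        nonfounders = [m for m in members if not m.is_founder]
        self.n_founders = len(founders)
        self.b_full = 2 * len(nonfounders)

        # meiosis bit 2k is the paternal, 2k+1 the maternal transmission of
        # nonfounder k (topological order)
        founder_pos = {m.individual_id: i for i, m in enumerate(founders)}
        flip_masks = [0] * len(founders)
        designated = [None] * len(founders)
        for k, m in enumerate(nonfounders):
            for j, parent in enumerate((m.father_id, m.mother_id)):
                bit = 2 * k + j
                if parent in founder_pos:
                    fi = founder_pos[parent]
                    flip_masks[fi] |= 1 << bit
                    if designated[fi] is None:
                        designated[fi] = bit
        self._founder_pos = founder_pos
        self._nonfounders = nonfounders
        self._founders = founders

        v = np.arange(1 << self.b_full, dtype=np.int64)
        for fi in range(len(founders)):
            d = designated[fi]
            if d is None:
                continue  # childless founder: no symmetry to fix
            hit = (v >> d) & 1 == 1
            v = np.where(hit, v ^ flip_masks[fi], v)
        canon = np.unique(v)
        self.n_classes = len(canon)
        self.class_of = np.searchsorted(canon, v).astype(np.int32)
        self.class_size = (1 << self.b_full) // self.n_classes

        # founder-allele labels per class: labels[c, i, :] are the ordered
        # (paternal, maternal) founder-haplotype labels of member i
        bits = ((canon[:, None] >> np.arange(self.b_full)) & 1).astype(np.int8)
        C = self.n_classes
        labels = np.zeros((C, len(members), 2), dtype=np.int16)
        for i, m in enumerate(members):
            if m.is_founder:
                fi = founder_pos[m.individual_id]
                labels[:, i, 0] = 2 * fi
                labels[:, i, 1] = 2 * fi + 1
        for k, m in enumerate(nonfounders):
            i = self._midx[m.individual_id]
            for j, parent in enumerate((m.father_id, m.mother_id)):
                pi = self._midx[parent]
                choice = bits[:, 2 * k + j].astype(np.int64)
                labels[:, i, j] = labels[np.arange(C), pi, choice]
        self.labels = labels
        self.n_labels = 2 * len(founders)

    # -- emissions ----------------------------------------------------------

    def emission(
        self,
        genotypes: Mapping[str, tuple[int, int] | None],
        allele_freqs: np.ndarray,
    ) -> np.ndarray:
        """P(observed genotypes | class) for one marker, per class.

        Sums founder-allele assignments weighted by population allele
        frequencies, eliminating over the founder-allele graph: each typed
        member constrains its two labels to carry its unordered genotype.
        """
        typed: list[tuple[int, int, int, int]] = []  # (member, a, b) by index
        for iid, g in genotypes.items():
            if g is None:
                continue
            a, b = g
            if a == MISSING or b == MISSING:
                continue
            typed.append((self._midx[iid], min(a, b), max(a, b)))
        C = self.n_classes
        if not typed:
            return np.ones(C)
        freqs = np.asarray(allele_freqs, dtype=float)
        typed_rows = {t[0] for t in typed}
        founder_rows = {self._midx[m.individual_id] for m in self._founders}
        if founder_rows and founder_rows <= typed_rows:
            return self._emission_founders_typed(typed, freqs)
        out = np.empty(C)
        for c in range(C):
            out[c] = self._emission_one(self.labels[c], typed, freqs)
        return out

    def _emission_founders_typed(self, typed, freqs) -> np.ndarray:
        """Vectorized emission when every founder genotype is observed.

        The founder-allele assignment is then pinned up to founder phase:
        enumerate the phase of each heterozygous founder, weight by the
        (phase-independent) product of founder allele frequencies, and
        check each typed non-founder against its per-class labels.
        """
        geno = {i: (a, b) for i, a, b in typed}
        weight = 1.0
        het_founders: list[tuple[int, int, int]] = []  # (founder_idx, a, b)
        base = np.empty(self.n_labels, dtype=np.int64)
        for m in self._founders:
            fi = self._founder_pos[m.individual_id]
            a, b = geno[self._midx[m.individual_id]]
            weight *= freqs[a] * freqs[b]
            base[2 * fi], base[2 * fi + 1] = a, b
            if a != b:
                het_founders.append((fi, a, b))
        nonf_typed = [
            (i, a, b) for i, a, b in typed
            if i not in {self._midx[m.individual_id] for m in self._founders}
        ]
        C = self.n_classes
        count = np.zeros(C)
        for phase in range(1 << len(het_founders)):
            hap = base.copy()
            for k, (fi, a, b) in enumerate(het_founders):
                if (phase >> k) & 1:
                    hap[2 * fi], hap[2 * fi + 1] = b, a
            ok = np.ones(C, dtype=bool)
            for i, a, b in nonf_typed:
                x = hap[self.labels[:, i, 0]]
                y = hap[self.labels[:, i, 1]]
                ok &= ((x == a) & (y == b)) | ((x == b) & (y == a))
                if not ok.any():
                    break
            count += ok
        return weight * count

    def _emission_one(self, labels, typed, freqs) -> float:
        # unary allele sets per label, plus pairwise het constraints
        allowed: dict[int, set[int]] = {}
        pairs: list[tuple[int, int, int, int]] = []
        for i, a, b in typed:
            l1, l2 = int(labels[i, 0]), int(labels[i, 1])
            gset = {a, b}
            for l in (l1, l2):
                allowed[l] = allowed.get(l, set(range(len(freqs)))) & gset
            if a != b:
                if l1 == l2:
                    return 0.0  # autozygous label cannot be heterozygous
                pairs.append((l1, l2, a, b))
            else:
                allowed[l1] = allowed.get(l1, set()) & {a}
                allowed[l2] = allowed.get(l2, set()) & {a}
        if any(not s for s in allowed.values()):
            return 0.0
        order = sorted(allowed)
        pos = {l: i for i, l in enumerate(order)}
        by_later: list[list[tuple[int, int, int]]] = [[] for _ in order]
        for l1, l2, a, b in pairs:
            i1, i2 = pos[l1], pos[l2]
            later, earlier = max(i1, i2), min(i1, i2)
            by_later[later].append((earlier, a, b))
        assign = [0] * len(order)

        def rec(i: int) -> float:
            if i == len(order):
                return 1.0
            total = 0.0
            for allele in allowed[order[i]]:
                ok = True
                for earlier, a, b in by_later[i]:
                    pair = {assign[earlier], allele} if earlier < i else None
                    if pair is not None and pair != {a, b}:
                        ok = False
                        break
                if not ok:
                    continue
                assign[i] = allele
                total += freqs[allele] * rec(i + 1)
            return total

        # same-label pair constraints with earlier == i never occur because
        # later > earlier by construction; l1 == l2 handled above
        return rec(0)

    # -- transitions --------------------------------------------------------

    def transmit(self, p: np.ndarray, theta: float) -> np.ndarray:
        """Apply the Haldane transition kernel over one interval.

        The kernel factorizes over meiosis bits: each flips independently
        with probability ``theta``.
        """
        if theta <= 0.0:
            return p
        q = p
        for bit in range(self.b_full):
            r = q.reshape(1 << (self.b_full - bit - 1), 2, 1 << bit)
            q = ((1 - theta) * r + theta * r[:, ::-1, :]).reshape(-1)
        return q

    def _expand(self, e_class: np.ndarray) -> np.ndarray:
        return e_class[self.class_of]

    def _collapse(self, p_full: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_classes)
        np.add.at(out, self.class_of, p_full)
        return out

    # -- multipoint posterior ------------------------------------------------

    def posterior(
        self,
        marker_cms: Sequence[float],
        emissions: Sequence[np.ndarray],
        eval_cms: Sequence[float] | None = None,
        chrom: str = "1",
    ) -> InheritanceDistribution:
        """Forward-backward posterior over classes at the evaluation grid.

        ``emissions`` holds one per-class emission vector per marker (as
        returned by :meth:`emission`); off-marker evaluation positions get
        unit emissions.
        """
        marker_cms = list(marker_cms)
        if sorted(marker_cms) != marker_cms:
            raise ValueError("marker positions must be sorted")
        if eval_cms is None:
            eval_cms = list(marker_cms)
        grid: list[tuple[float, int | None]] = [
            (cm, j) for j, cm in enumerate(marker_cms)
        ]
        known = set(marker_cms)
        grid += [(cm, None) for cm in eval_cms if cm not in known]
        grid.sort(key=lambda t: t[0])

        V = 1 << self.b_full
        uniform = np.full(V, 1.0 / V)
        n = len(grid)
        fwd = np.empty((n, V))
        cur = uniform.copy()
        for i, (cm, j) in enumerate(grid):
            if i > 0:
                cur = self.transmit(cur, haldane_theta(cm - grid[i - 1][0]))
            if j is not None:
                cur = cur * self._expand(emissions[j])
                tot = cur.sum()
                if tot <= 0.0:
                    raise MendelianImpossibilityError(
                        f"family {self.ped.family_id}: genotypes at marker "
                        f"index {j} ({chrom}:{cm} cM) are impossible under "
                        "every inheritance vector"
                    )
                cur = cur / tot
            fwd[i] = cur
        bwd = np.empty((n, V))
        cur = np.ones(V)
        for i in range(n - 1, -1, -1):
            cm, j = grid[i]
            if i < n - 1:
                cur = self.transmit(cur, haldane_theta(grid[i + 1][0] - cm))
            bwd[i] = cur
            if j is not None:
                cur = cur * self._expand(emissions[j])
                tot = cur.sum()
                if tot > 0:
                    cur = cur / tot

        want = sorted(set(eval_cms))
        rows = []
        grid_pos = [cm for cm, _ in grid]
        for cm in want:
            i = grid_pos.index(cm)
            post = fwd[i] * bwd[i]
            post /= post.sum()
            rows.append(self._collapse(post))
        return InheritanceDistribution(
            self.ped, np.array(want), chrom, np.vstack(rows), self
        )

    def panel_emissions(
        self, panel: GenotypePanel, marker_indices: Sequence[int]
    ) -> list[np.ndarray]:
        """Emission vectors for this family's typed members at each marker."""
        ems = []
        for j in marker_indices:
            genos: dict[str, tuple[int, int]] = {}
            for iid in self.member_ids:
                if iid in panel._row:
                    genos[iid] = panel.genotype(iid, j)
            ems.append(self.emission(genos, panel.map[j].allele_freqs))
        return ems


def inheritance_distribution(
    ped: Pedigree,
    panel: GenotypePanel,
    chrom: str,
    eval_cms: Sequence[float] | None = None,
    bit_limit: int = 16,
) -> InheritanceDistribution:
    """Posterior inheritance-vector distribution for one chromosome.

    Convenience wrapper building a :class:`PedigreeHMM`, computing marker
    emissions from the panel and running the forward-backward pass.  With
    every genotype missing the posterior is uniform at every position.
    """
    hmm = PedigreeHMM(ped, bit_limit=bit_limit)
    idx = panel.map.chrom_indices(chrom)
    cms = [panel.map[j].cm for j in idx]
    ems = hmm.panel_emissions(panel, idx)
    return hmm.posterior(cms, ems, eval_cms=eval_cms, chrom=chrom)
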