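"""Pedigree data model, six-column PED I/O, validation and relationship math.

Phenotype dialect
-----------------
Standard six-column PED encodes phenotype as ``1`` = unaffected, ``2`` =
affected, ``0``/``-9`` = unknown.  Familial IgA nephropathy studies track a
third observed state — persistent urinary abnormalities (microscopic
haematuria and/or proteinuria) without a biopsy-proven diagnosis — so this
package reserves code ``3`` for it.  Individuals with only intermittent
findings are coded unknown.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(Enum):
    UNAFFECTED = "unaffected"
    IGAN_AFFECTED = "igan_affected"
    URINARY_ABNORMALITY = "urinary_abnormality"
    UNKNOWN = "unknown"


_SEX_FROM_CODE = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_CODE_FROM_SEX = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_FROM_CODE = {
    "1": Phenotype.UNAFFECTED,
    "2": Phenotype.IGAN_AFFECTED,
    "3": Phenotype.URINARY_ABNORMALITY,
    "0": Phenotype.UNKNOWN,
    "-9": Phenotype.UNKNOWN,
}
_CODE_FROM_PHENO = {
    Phenotype.UNAFFECTED: "1",
    Phenotype.IGAN_AFFECTED: "2",
    Phenotype.URINARY_ABNORMALITY: "3",
    Phenotype.UNKNOWN: "0",
}


class PedigreeError(ValueError):
    """Structural problem in a pedigree or PED file."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN
    synthetic: bool = False  # completion spouse added for a half-founder

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: an ordered collection of :class:`Individual`.

    Members are kept in insertion order; parents need not precede children
    in the input, but :meth:`topological_members` yields founders first.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {m.individual_id: m for m in self.members}
        if len(self._index) != len(self.members):
            raise PedigreeError(
                f"family {self.family_id}: duplicate individual ids"
            )

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def member(self, individual_id: str) -> Individual:
        try:
            return self._index[individual_id]
        except KeyError:
            raise PedigreeError(
                f"family {self.family_id}: unknown individual {individual_id!r}"
            ) from None

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def affected(
        self,
        codes: Iterable[Phenotype] = (Phenotype.IGAN_AFFECTED,),
    ) -> list[str]:
        """Ids counting as affected; biopsy-proven cases only by default."""
        codeset = set(codes)
        return [m.individual_id for m in self.members if m.phenotype in codeset]

    def topological_members(self) -> list[Individual]:
        """Members ordered so every parent precedes its children."""
        order: list[Individual] = []
        placed: set[str] = set()
        pending = list(self.members)
        while pending:
            progressed = False
            remaining = []
            for m in pending:
                ready = all(
                    p is None or p in placed
                    for p in (m.father_id, m.mother_id)
                )
                if ready:
                    order.append(m)
                    placed.add(m.individual_id)
                    progressed = True
                else:
                    remaining.append(m)
            if not progressed:
                raise PedigreeError(
                    f"family {self.family_id}: pedigree graph contains a cycle"
                )
            pending = remaining
        return order


# ---------------------------------------------------------------------------
# PED I/O (six-column whitespace dialect)
# ---------------------------------------------------------------------------

def _parse_ped_row(line: str, lineno: int) -> Individual:
    fields = line.split()
    if len(fields) != 6:
        raise PedigreeError(
            f"PED line {lineno}: expected 6 whitespace-delimited columns, "
            f"got {len(fields)}"
        )
    fam, iid, fid, mid, sex_code, pheno_code = fields
    if sex_code not in _SEX_FROM_CODE:
        raise PedigreeError(f"PED line {lineno}: bad sex code {sex_code!r}")
    if pheno_code not in _PHENO_FROM_CODE:
        raise PedigreeError(
            f"PED line {lineno}: bad phenotype code {pheno_code!r}"
        )
    return Individual(
        individual_id=iid,
        family_id=fam,
        father_id=None if fid == "0" else fid,
        mother_id=None if mid == "0" else mid,
        sex=_SEX_FROM_CODE[sex_code],
        phenotype=_PHENO_FROM_CODE[pheno_code],
    )


def read_ped(path: str | Path | io.TextIOBase) -> list[Pedigree]:
    """Read a six-column PED file into one :class:`Pedigree` per family.

    Raises :class:`PedigreeError` naming the offending line on malformed
    rows, and a structure error for dangling parent references.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
    else:
        lines = Path(path).read_text().splitlines()
    by_family: dict[str, list[Individual]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        ind = _parse_ped_row(line, lineno)
        by_family.setdefault(ind.family_id, []).append(ind)
    peds = [Pedigree(fam, members) for fam, members in by_family.items()]
    for ped in peds:
        for m in ped:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ped:
                    raise PedigreeError(
                        f"family {ped.family_id}: individual "
                        f"{m.individual_id} references parent {pid!r} "
                        "not present in the family"
                    )
    return peds


def write_ped(peds: Iterable[Pedigree], path: str | Path | io.TextIOBase) -> None:
    """Write pedigrees in the same six-column dialect ``read_ped`` accepts."""
    rows = []
    for ped in peds:
        for m in ped:
            rows.append(
                "\t".join(
                    [
                        ped.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _CODE_FROM_SEX[m.sex],
                        _CODE_FROM_PHENO[m.phenotype],
                    ]
                )
            )
    text = "\n".join(rows) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    kind: str  # "sex" | "cycle" | "missing_member" | "half_founder" | ...
    individual_id: str | None
    message: str


def validate_pedigree(ped: Pedigree) -> list[Violation]:
    """Return all structural violations; an empty list means valid.

    Checks parental sexes, dangling parent references, half-founders
    (exactly one parent known), acyclicity, and presence of a founder.
    Reports rather than raises.
    """
    report: list[Violation] = []
    for m in ped:
        if (m.father_id is None) != (m.mother_id is None):
            report.append(
                Violation(
                    "half_founder",
                    m.individual_id,
                    f"{m.individual_id} has exactly one known parent; "
                    "complete with a synthetic spouse "
                    "(complete_half_founders)",
                )
            )
        for pid, want_sex, role in (
            (m.father_id, Sex.MALE, "father"),
            (m.mother_id, Sex.FEMALE, "mother"),
        ):
            if pid is None:
                continue
            if pid not in ped:
                report.append(
                    Violation(
                        "missing_member",
                        m.individual_id,
                        f"{role} {pid!r} of {m.individual_id} not in family",
                    )
                )
                continue
            parent = ped.member(pid)
            if parent.sex not in (want_sex, Sex.UNKNOWN):
                report.append(
                    Violation(
                        "sex",
                        pid,
                        f"{role} {pid} of {m.individual_id} has sex "
                        f"{parent.sex.value}",
                    )
                )
    # cycle detection: DFS on the child -> parent graph
    state: dict[str, int] = {}

    def visit(iid: str) -> bool:
        if state.get(iid) == 1:
            return True
        if state.get(iid) == 2:
            return False
        state[iid] = 1
        m = ped._index.get(iid)
        found = False
        if m is not None:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid in ped and visit(pid):
                    found = True
        state[iid] = 2
        return found

    for m in ped:
        if m.individual_id not in state and visit(m.individual_id):
            report.append(
                Violation(
                    "cycle",
                    m.individual_id,
                    f"{m.individual_id} is its own ancestor",
                )
            )
    if not any(m.is_founder for m in ped):
        report.append(
            Violation("no_founder", None, "pedigree has no founder")
        )
    return report


def complete_half_founders(ped: Pedigree) -> Pedigree:
    """Return a pedigree where every half-founder gains a synthetic spouse.

    The added founders are flagged ``synthetic=True`` and named
    ``_spouse_<child id>``; a common linkage-format convention.
    """
    members = list(ped.members)
    extra: list[Individual] = []
    for i, m in enumerate(members):
        if (m.father_id is None) != (m.mother_id is None):
            sid = f"_spouse_{m.individual_id}"
            missing_father = m.father_id is None
            extra.append(
                Individual(
                    individual_id=sid,
                    family_id=ped.family_id,
                    sex=Sex.MALE if missing_father else Sex.FEMALE,
                    synthetic=True,
                )
            )
            members[i] = Individual(
                individual_id=m.individual_id,
                family_id=m.family_id,
                father_id=sid if missing_father else m.father_id,
                mother_id=m.mother_id if missing_father else sid,
                sex=m.sex,
                phenotype=m.phenotype,
            )
    return Pedigree(ped.family_id, extra + members)


# ---------------------------------------------------------------------------
# Relationship coefficients and complexity
# ---------------------------------------------------------------------------

def kinship_coefficient(ped: Pedigree, a: str, b: str) -> float:
    """Recursive kinship coefficient phi(a, b).

    phi is the probability that one allele drawn at random from ``a`` and
    one from ``b`` at an autosomal locus are identical by descent.  For
    non-inbred pairs the expected genome-wide IBD proportion is ``2 * phi``.
    """
    ped.member(a), ped.member(b)  # raise on unknown ids
    order = {
        m.individual_id: i for i, m in enumerate(ped.topological_members())
    }
    cache: dict[tuple[str, str], Fraction] = {}

    def phi(x: str, y: str) -> Fraction:
        if order[x] < order[y]:
            x, y = y, x  # x is always the later-born (deeper) of the pair
        key = (x, y)
        if key in cache:
            return cache[key]
        mx = ped.member(x)
        if x == y:
            if mx.is_founder:
                val = Fraction(1, 2)
            else:
                val = Fraction(1, 2) + Fraction(1, 2) * phi(
                    mx.father_id, mx.mother_id
                )
        elif mx.is_founder:
            # both founders (y is no deeper than x): unrelated by convention
            val = Fraction(0)
        else:
            val = Fraction(1, 2) * (phi(mx.father_id, y) + phi(mx.mother_id, y))
        cache[key] = val
        return val

    return float(phi(a, b))


def bit_complexity(ped: Pedigree) -> int:
    """Lander-Green inheritance-vector bit count: 2*nonfounders - founders.

    Governs the 2^b state space of the exact multipoint HMM; additive over
    disjoint nuclear components.
    """
    n_non = len(ped.nonfounders)
    n_fou = len(ped.founders)
    return 2 * n_non - n_fou
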