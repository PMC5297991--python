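import numpy as np
import pytest

from famcoseg.pedigree import Individual, Pedigree, Phenotype, Sex


def make_trio(fam: str = "T1") -> Pedigree:
    return Pedigree(
        fam,
        [
            Individual("fa", fam, sex=Sex.MALE),
            Individual("mo", fam, sex=Sex.FEMALE),
            Individual(
                "ch", fam, father_id="fa", mother_id="mo",
                phenotype=Phenotype.IGAN_AFFECTED,
            ),
        ],
    )


def make_sib_pair(fam: str = "S1", affected: bool = True) -> Pedigree:
    pheno = Phenotype.IGAN_AFFECTED if affected else Phenotype.UNAFFECTED
    return Pedigree(
        fam,
        [
            Individual("fa", fam, sex=Sex.MALE),
            Individual("mo", fam, sex=Sex.FEMALE),
            Individual("s1", fam, father_id="fa", mother_id="mo", phenotype=pheno),
            Individual("s2", fam, father_id="fa", mother_id="mo", phenotype=pheno),
        ],
    )


def make_first_cousins(fam: str = "C1") -> Pedigree:
    """Two sibs marry in spouses; one child each: k1 and k2 are cousins."""
    return Pedigree(
        fam,
        [
            Individual("gp1", fam, sex=Sex.MALE),
            Individual("gp2", fam, sex=Sex.FEMALE),
            Individual("c1", fam, father_id="gp1", mother_id="gp2", sex=Sex.MALE),
            Individual("c2", fam, father_id="gp1", mother_id="gp2", sex=Sex.FEMALE),
            Individual("s1", fam, sex=Sex.FEMALE),
            Individual("s2", fam, sex=Sex.MALE),
            Individual("k1", fam, father_id="c1", mother_id="s1"),
            Individual("k2", fam, father_id="s2", mother_id="c2"),
        ],
    )


@pytest.fixture
def trio():
    return make_trio()


@pytest.fixture
def sib_pair():
    return make_sib_pair()


@pytest.fixture
def cousins():
    return make_first_cousins()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
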