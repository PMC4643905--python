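import pytest

from shotmapbench import CommunityProfile, Gene, ReferenceSet
from shotmapbench.synthetic import make_community, make_reference_set


def _codon_fill(n_nt: int) -> str:
    # stop-free filler ("GCA" = Ala repeats), trimmed to length
    return ("GCA" * (n_nt // 3 + 1))[:n_nt]


@pytest.fixture
def tiny_ref() -> ReferenceSet:
    """Two genomes, five genes, hand-checkable copy numbers.

    g1 carries F1 x2 and F2 x1; g2 carries F1 x1 and F3 x1.
    """
    g1 = _codon_fill(30) + "ATGAAAGTTCTTTGGTAA" + _codon_fill(30) + "ATGCATCATTGA" + _codon_fill(24)
    #                       ^ gene a: MKVLW (31..48)                ^ gene b: MHH (79..90)
    g2 = _codon_fill(15) + "ATGAAAGTTCTTTGGTAA" + _codon_fill(30)
    genes = [
        Gene("a", "g1", 31, 48, "+", "F1", protein="MKVLW"),
        Gene("b", "g1", 79, 90, "+", "F2", protein="MHH"),
        Gene("c", "g1", 100, 108, "+", "F1", protein="AAA"),
        Gene("d", "g2", 16, 33, "+", "F1", protein="MKVLW"),
        Gene("e", "g2", 40, 48, "+", "F3", protein="AAA"),
    ]
    taxonomy = {
        "g1": ("s1", "Escherichia coli", "Escherichia", "Enterobacteriaceae",
               "Enterobacterales", "Gammaproteobacteria", "Proteobacteria"),
        "g2": ("s2", "Salmonella enterica", "Salmonella", "Enterobacteriaceae",
               "Enterobacterales", "Gammaproteobacteria", "Proteobacteria"),
    }
    return ReferenceSet({"g1": g1, "g2": g2}, genes, taxonomy)


@pytest.fixture(scope="session")
def synth_ref() -> ReferenceSet:
    """The standard 10-genome / ~50-genes-per-genome benchmark reference."""
    return make_reference_set(seed=11)


@pytest.fixture(scope="session")
def synth_community(synth_ref) -> CommunityProfile:
    return make_community(sorted(synth_ref.genomes), seed=12)
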