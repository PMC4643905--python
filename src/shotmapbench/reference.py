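"""Annotated reference genomes, mock communities and family abundance profiles.

A :class:`ReferenceSet` holds the genomes, their protein-coding genes (each
assigned to a protein family) and a seven-rank taxonomy.  It plays two roles:
it is the ground truth that mock communities and simulated reads are built
from, and it is the search database that translated reads are classified
against.

A mock community is a :class:`CommunityProfile` mapping genome ids to
coverages ``A_j``.  The expected relative abundance of protein family *i* in a
community is obtained by weighting the per-genome copy number ``C_ij`` by the
genome coverage::

    A_i = sum_j C_ij * A_j          R_i = A_i / sum_i A_i

so that the ``R_i`` sum to one.  Copy numbers are always counted from the gene
records, never supplied directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "ReferenceSet",
    "CommunityProfile",
    "AbundanceProfile",
    "load_reference_set",
    "load_community_profile",
    "expected_family_abundance",
    "relative_normalize",
    "read_profile_tsv",
    "write_profile_tsv",
]

TAXONOMIC_RANKS = ("strain", "species", "genus", "family", "order", "class", "phylum")

NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene on a reference genome.

    Coordinates are 1-based inclusive nucleotide positions (GFF convention).
    ``length_aa`` is the protein length in amino acids; when no protein string
    is supplied it defaults to ``floor(span / 3)``.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    family_id: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.family_id:
            raise ValueError(f"gene {self.gene_id}: empty family_id")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def length_aa(self) -> int:
        if self.protein:
            return len(self.protein)
        return self.length_nt // 3


class ReferenceSet:
    """Genomes, genes and taxonomy backing simulation truth and classification.

    Parameters
    ----------
    genomes
        Mapping genome_id -> uppercase nucleotide sequence.
    genes
        Gene records; every gene's genome must exist and its coordinates must
        lie within the genome.
    taxonomy
        Mapping genome_id -> 7-tuple lineage ordered
        (strain, species, genus, family, order, class, phylum).  Optional for
        workflows that never perform clade exclusion.
    """

    def __init__(
        self,
        genomes: Mapping[str, str],
        genes: Iterable[Gene],
        taxonomy: Mapping[str, tuple] | None = None,
    ) -> None:
        self.genomes: dict[str, str] = {g: str(s).upper() for g, s in genomes.items()}
        self.genes: list[Gene] = list(genes)
        self.taxonomy: dict[str, tuple] = {}
        for genome_id, lineage in (taxonomy or {}).items():
            lineage = tuple(str(x) for x in lineage)
            if len(lineage) != len(TAXONOMIC_RANKS) or any(not x for x in lineage):
                raise ValueError(
                    f"taxonomy for {genome_id!r} must have exactly "
                    f"{len(TAXONOMIC_RANKS)} non-empty ranks, got {lineage!r}"
                )
            self.taxonomy[genome_id] = lineage

        self.genes_by_id: dict[str, Gene] = {}
        for gene in self.genes:
            if gene.genome_id not in self.genomes:
                raise ValueError(
                    f"gene {gene.gene_id} references absent genome {gene.genome_id!r}"
                )
            if gene.end > len(self.genomes[gene.genome_id]):
                raise ValueError(
                    f"gene {gene.gene_id} extends past the end of {gene.genome_id}"
                )
            if gene.gene_id in self.genes_by_id:
                raise ValueError(f"duplicate gene id {gene.gene_id!r}")
            self.genes_by_id[gene.gene_id] = gene

    @property
    def family_ids(self) -> set[str]:
        return {g.family_id for g in self.genes}

    def genes_of_genome(self, genome_id: str) -> list[Gene]:
        return [g for g in self.genes if g.genome_id == genome_id]

    def copy_numbers(self, genome_id: str) -> Counter:
        """Family copy numbers C_ij of one genome, counted from gene records."""
        return Counter(g.family_id for g in self.genes if g.genome_id == genome_id)

    def coding_sequence(self, gene: Gene) -> str:
        seq = self.genomes[gene.genome_id][gene.start - 1 : gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def gene_protein(self, gene: Gene) -> str:
        """The gene's protein, translating the coding span when absent."""
        if gene.protein:
            return gene.protein
        cds = self.coding_sequence(gene)
        cds = cds[: len(cds) - len(cds) % 3]
        return str(Seq(cds).translate()).rstrip("*")

    def lineage_taxon(self, genome_id: str, rank: str) -> str:
        try:
            idx = TAXONOMIC_RANKS.index(rank)
        except ValueError:
            raise ValueError(f"unknown taxonomic rank {rank!r}") from None
        if genome_id not in self.taxonomy:
            raise KeyError(f"no taxonomy for genome {genome_id!r}")
        return self.taxonomy[genome_id][idx]


@dataclass(frozen=True)
class CommunityProfile:
    """Genome coverages A_j defining a mock community."""

    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = list(self.abundances.values())
        if not vals or not any(v > 0 for v in vals):
            raise ValueError("community must have at least one positive coverage")
        for genome_id, v in self.abundances.items():
            if not (v >= 0) or v != v or v == float("inf"):
                raise ValueError(f"coverage for {genome_id!r} must be finite and >= 0")

    @property
    def total(self) -> float:
        return float(sum(self.abundances.values()))


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-family abundances with provenance.

    ``flavor`` records how the values arose: ``expected`` (from known copy
    numbers and coverages), ``count`` (gene-length-normalized hit counting) or
    ``coverage`` (aligned-residue based).  ``normalized`` profiles sum to one.
    """

    values: Mapping[str, float]
    flavor: str = "expected"
    normalized: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.flavor not in ("expected", "count", "coverage"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("abundances must be non-negative")
        if self.normalized:
            total = sum(self.values.values())
            if abs(total - 1.0) > NORMALIZATION_TOL:
                raise ValueError(f"profile marked normalized but sums to {total}")

    def __getitem__(self, family_id: str) -> float:
        return self.values[family_id]

    def __len__(self) -> int:
        return len(self.values)


def relative_normalize(profile: AbundanceProfile) -> AbundanceProfile:
    """Scale a profile so its values sum to one; idempotent."""
    total = float(sum(profile.values.values()))
    if total <= 0:
        raise ValueError("cannot normalize an empty or all-zero profile")
    values = {k: v / total for k, v in profile.values.items()}
    prov = profile.provenance
    if not profile.normalized:
        prov = (prov + "; " if prov else "") + "relative_normalize"
    return replace(profile, values=values, normalized=True, provenance=prov)


def expected_family_abundance(
    community: CommunityProfile, ref: ReferenceSet
) -> AbundanceProfile:
    """Expected relative family abundances R_i of a mock community.

    A_i = sum_j C_ij * A_j over genomes with positive coverage, then
    normalized to sum to one.  Families absent from every covered genome are
    omitted rather than reported as zero.
    """
    totals: Counter = Counter()
    for genome_id, coverage in community.abundances.items():
        if genome_id not in ref.genomes:
            raise KeyError(f"community genome {genome_id!r} absent from reference set")
        if coverage <= 0:
            continue
        for family_id, copies in ref.copy_numbers(genome_id).items():
            totals[family_id] += copies * coverage
    profile = AbundanceProfile(
        dict(totals), flavor="expected", provenance="expected_family_abundance"
    )
    return relative_normalize(profile)


# ---------------------------------------------------------------------------
# IO


def load_reference_set(
    genomes_path, genes_path, taxonomy_path=None
) -> ReferenceSet:
    """Load a reference set from FASTA genomes plus gene and taxonomy tables.

    The gene table is a TSV with header
    ``gene_id genome_id start end strand family_id protein``; the protein
    column may be empty, in which case the protein is obtained by translating
    the coding span.  The taxonomy table is a TSV with header
    ``genome_id strain species genus family order class phylum``.
    """
    genomes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genomes_path), "fasta")}

    table = pd.read_csv(genes_path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_id", "genome_id", "start", "end", "strand", "family_id"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    genes = [
        Gene(
            gene_id=row.gene_id,
            genome_id=row.genome_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            family_id=row.family_id,
            protein=getattr(row, "protein", "") or "",
        )
        for row in table.itertuples(index=False)
    ]

    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
        bad = [c for c in ("genome_id", *TAXONOMIC_RANKS) if c not in tax.columns]
        if bad:
            raise ValueError(f"taxonomy table missing columns: {bad}")
        # positional access: 'class' is a keyword and breaks attribute lookup
        ordered = tax[["genome_id", *TAXONOMIC_RANKS]].to_numpy()
        taxonomy = {row[0]: tuple(row[1:]) for row in ordered}

    ref = ReferenceSet(genomes, genes, taxonomy)
    # materialize proteins for genes that lack one so length_aa is stable
    ref.genes = [
        g if g.protein else replace(g, protein=ref.gene_protein(g)) for g in ref.genes
    ]
    ref.genes_by_id = {g.gene_id: g for g in ref.genes}
    return ref


def load_community_profile(path) -> CommunityProfile:
    """Read a ``genome_id <tab> coverage`` table."""
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(table.columns)
    return CommunityProfile(dict(zip(table[cols[0]], table[cols[1]].astype(float))))


def read_profile_tsv(path, flavor: str = "expected") -> AbundanceProfile:
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(table.columns)
    values = dict(zip(table[cols[0]], table[cols[1]].astype(float)))
    total = sum(values.values())
    return AbundanceProfile(
        values, flavor=flavor, normalized=abs(total - 1.0) <= NORMALIZATION_TOL
    )


def write_profile_tsv(profile: AbundanceProfile, path) -> None:
    frame = pd.DataFrame(
        sorted(profile.values.items()), columns=["family_id", "abundance"]
    )
    frame.to_csv(path, sep="\t", index=False)
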