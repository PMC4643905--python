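"""Synthetic reference sets, communities and sample matrices.

Generates all benchmark inputs programmatically: toy bacterial-like genomes
with planted protein-coding genes grouped into protein families, a
seven-rank taxonomy, community coverage vectors, and cross-sample abundance
matrices with optional planted group effects.  Because genes, copy numbers
and coverages are known exactly, every downstream estimate can be compared
with its expectation.

What the generator emulates: gene-dense genomes (short intergenic spacers),
protein families whose members diverge by a few percent amino-acid identity
across genomes, multi-copy families, and log-normally distributed genome
coverages.  What it does not emulate: real codon usage, repeats, mobile
elements, overlapping genes, GC bias, or phylogenetically structured
sequence divergence — so benchmark results quantify the pipeline's
statistical behaviour, not database completeness effects on real data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .reference import Gene, CommunityProfile, ReferenceSet, TAXONOMIC_RANKS
from .compare import SampleMatrix

__all__ = [
    "make_reference_set",
    "make_community",
    "make_sample_matrix",
    "make_pathway_map",
    "write_reference_files",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_table.stop_codons)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _diverge_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute a fraction of residues, modelling within-family divergence."""
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < divergence)[0]
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _lineages(n_genomes: int) -> dict[str, tuple]:
    """A small nested taxonomy: successive ranks merge genomes pairwise."""
    lineages = {}
    for i in range(n_genomes):
        lineage = [f"strain{i}"]
        for level, rank in enumerate(TAXONOMIC_RANKS[1:], start=1):
            lineage.append(f"{rank}{i // (2**level)}")
        lineages[f"g{i}"] = tuple(lineage)
    return lineages


def make_reference_set(
    n_genomes: int = 10,
    genes_per_genome: int = 50,
    n_families: int = 120,
    min_gene_len_aa: int = 100,
    max_gene_len_aa: int = 200,
    min_spacer_nt: int = 20,
    max_spacer_nt: int = 50,
    family_divergence: float = 0.05,
    seed: int = 0,
) -> ReferenceSet:
    """Build a toy annotated reference set with planted families.

    Each genome carries ``genes_per_genome`` genes drawn (with repetition,
    so multi-copy families arise) from a pool of ``n_families`` ancestral
    proteins of 100-200 aa; each planted copy diverges from its ancestor by
    ``family_divergence`` expected amino-acid substitutions per site.  Genes
    alternate with short random spacers and land on random strands, giving a
    gene-dense bacterial-like layout.  Fully deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ancestors = [
        _random_protein(int(rng.integers(min_gene_len_aa, max_gene_len_aa + 1)), rng)
        for _ in range(n_families)
    ]

    genomes: dict[str, str] = {}
    genes: list[Gene] = []
    for gi in range(n_genomes):
        genome_id = f"g{gi}"
        parts = []
        position = 0
        for slot in range(genes_per_genome):
            spacer = _random_dna(int(rng.integers(min_spacer_nt, max_spacer_nt + 1)), rng)
            parts.append(spacer)
            position += len(spacer)
            fam = int(rng.integers(n_families))
            protein = _diverge_protein(ancestors[fam], family_divergence, rng)
            cds = _reverse_translate(protein, rng)
            strand = "+" if rng.integers(2) else "-"
            placed = cds if strand == "+" else str(Seq(cds).reverse_complement())
            genes.append(
                Gene(
                    gene_id=f"{genome_id}_gene{slot}",
                    genome_id=genome_id,
                    start=position + 1,
                    end=position + len(placed),
                    strand=strand,
                    family_id=f"F{fam}",
                    protein=protein,
                )
            )
            parts.append(placed)
            position += len(placed)
        parts.append(_random_dna(int(rng.integers(min_spacer_nt, max_spacer_nt + 1)), rng))
        genomes[genome_id] = "".join(parts)

    return ReferenceSet(genomes, genes, _lineages(n_genomes))


def make_community(
    genome_ids,
    seed: int = 0,
    distribution: str = "lognormal",
    sigma: float = 1.0,
) -> CommunityProfile:
    """Random community coverages: log-normal (default) or uniform."""
    rng = np.random.default_rng(seed)
    ids = list(genome_ids)
    if distribution == "lognormal":
        cov = rng.lognormal(mean=0.0, sigma=sigma, size=len(ids))
    elif distribution == "uniform":
        cov = rng.uniform(0.5, 2.0, size=len(ids))
    else:
        raise ValueError(f"unknown coverage distribution {distribution!r}")
    return CommunityProfile(dict(zip(ids, cov.tolist())))


def make_sample_matrix(
    n_families: int = 50,
    n_samples: int = 20,
    n_groups: int = 2,
    n_affected: int = 0,
    effect_size: float = 2.0,
    seed: int = 0,
) -> SampleMatrix:
    """A families x samples matrix with log-normal abundances.

    The first ``n_affected`` families have their abundance multiplied by
    ``effect_size`` in the last group, planting a known differential signal;
    with ``n_affected=0`` the matrix is an exchangeable null.  Metadata gets
    a categorical ``group`` column and a continuous ``depth`` covariate.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=0.5, size=(n_families, n_samples))
    groups = np.array([f"grp{i % n_groups}" for i in range(n_samples)])
    affected_mask = groups == f"grp{n_groups - 1}"
    base[:n_affected, affected_mask] *= effect_size
    samples = [f"s{i}" for i in range(n_samples)]
    values = pd.DataFrame(
        base, index=[f"F{i}" for i in range(n_families)], columns=samples
    )
    meta = pd.DataFrame(
        {"group": groups, "depth": rng.uniform(1e6, 5e6, size=n_samples)},
        index=samples,
    )
    return SampleMatrix(values, meta)


def make_pathway_map(
    family_ids,
    n_pathways: int = 8,
    seed: int = 0,
    mean_size: int = 10,
) -> dict[str, set[str]]:
    """Random pathway membership: each pathway draws ~mean_size families."""
    rng = np.random.default_rng(seed)
    families = sorted(family_ids)
    out = {}
    for i in range(n_pathways):
        size = max(2, int(rng.poisson(mean_size)))
        size = min(size, len(families))
        members = rng.choice(len(families), size=size, replace=False)
        out[f"path{i}"] = {families[j] for j in members}
    return out


def write_reference_files(ref: ReferenceSet, community: CommunityProfile, outdir) -> dict:
    """Write a reference set and community as the on-disk input formats.

    Produces genomes.fasta, genes.tsv, taxonomy.tsv and community.tsv under
    ``outdir`` and returns the path mapping — handy for CLI round-trips.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fasta",
        "genes": outdir / "genes.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "community": outdir / "community.tsv",
    }
    with open(paths["genomes"], "w") as fh:
        for gid, seq in ref.genomes.items():
            fh.write(f">{gid}\n{seq}\n")
    pd.DataFrame(
        [
            (g.gene_id, g.genome_id, g.start, g.end, g.strand, g.family_id, g.protein)
            for g in ref.genes
        ],
        columns=["gene_id", "genome_id", "start", "end", "strand", "family_id", "protein"],
    ).to_csv(paths["genes"], sep="\t", index=False)
    pd.DataFrame(
        [(gid, *lineage) for gid, lineage in ref.taxonomy.items()],
        columns=["genome_id", *TAXONOMIC_RANKS],
    ).to_csv(paths["taxonomy"], sep="\t", index=False)
    pd.DataFrame(
        sorted(community.abundances.items()), columns=["genome_id", "coverage"]
    ).to_csv(paths["community"], sep="\t", index=False)
    return paths
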