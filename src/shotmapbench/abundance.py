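"""Gene-length-normalized protein-family abundance estimation.

Two flavors, both normalized by the winning hit's own target gene length
L_k (in amino acids) and then scaled to sum to one:

* count-based:    A_i = sum_k 1 / L_k        (one unit per classified hit)
* coverage-based: A_i = sum_k X_k / L_k      (X_k = aligned target residues)

Coverage-based abundance credits partial alignments, which matters for long
reads hanging off the 5' or 3' ends of genes.  Unclassified reads contribute
nothing; report them via :func:`classification_rate`.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from .classify import Classification
from .reference import AbundanceProfile, ReferenceSet, relative_normalize

__all__ = [
    "count_abundance",
    "coverage_abundance",
    "ags_normalize",
    "classification_rate",
]


def _gene_length_aa(ref: ReferenceSet, gene_id: str) -> int:
    gene = ref.genes_by_id.get(gene_id)
    if gene is None:
        raise KeyError(f"winning hit's target gene {gene_id!r} not in reference set")
    length = gene.length_aa
    if length <= 0:
        raise ValueError(f"gene {gene_id} has non-positive length")
    return length


def count_abundance(
    classifications: Iterable[Classification], ref: ReferenceSet
) -> AbundanceProfile:
    """Count-based family abundance: each hit contributes 1/L_k."""
    raw: dict[str, float] = defaultdict(float)
    n = 0
    for c in classifications:
        raw[c.family_id] += 1.0 / _gene_length_aa(ref, c.winning_hit.target_gene)
        n += 1
    if n == 0:
        raise ValueError("no classifications to build an abundance profile from")
    return relative_normalize(
        AbundanceProfile(dict(raw), flavor="count", provenance="count_abundance")
    )


def coverage_abundance(
    classifications: Iterable[Classification], ref: ReferenceSet
) -> AbundanceProfile:
    """Coverage-based family abundance: each hit contributes X_k/L_k."""
    raw: dict[str, float] = defaultdict(float)
    n = 0
    for c in classifications:
        length = _gene_length_aa(ref, c.winning_hit.target_gene)
        raw[c.family_id] += c.winning_hit.aligned_target_residues / length
        n += 1
    if n == 0:
        raise ValueError("no classifications to build an abundance profile from")
    return relative_normalize(
        AbundanceProfile(dict(raw), flavor="coverage", provenance="coverage_abundance")
    )


def ags_normalize(
    raw_values: Mapping[str, float], ags_bp: float, library_reads: int | None = None
) -> dict[str, float]:
    """Divide unnormalized abundances by the average genome size in Mb.

    Corrects cross-sample comparisons of non-relative abundances for
    variation in community genome size (a sample of big genomes yields fewer
    gene copies per read).  Within-sample *relative* profiles are unchanged
    by this scalar, so apply it before, not after, relative normalization.
    ``library_reads`` is accepted for per-library bookkeeping but does not
    enter the scaling.
    """
    if ags_bp <= 0:
        raise ValueError("average genome size must be positive")
    scale = ags_bp / 1e6
    return {k: v / scale for k, v in raw_values.items()}


def classification_rate(
    classifications: Iterable[Classification], n_reads: int
) -> float:
    """Fraction of reads with at least one classification."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    reads = {c.read_id for c in classifications}
    return len(reads) / n_reads
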