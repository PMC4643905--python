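"""Built-in translated protein search: Smith-Waterman with bit scores.

A small self-contained stand-in for an external translated search tool so
that the whole benchmark can run without third-party binaries.  Each query
peptide is locally aligned (BLOSUM62, affine gaps 11/1) against candidate
reference proteins and the raw score S is converted to bits with the
Karlin-Altschul transform::

    S' = (lambda * S - ln K) / ln 2
    E  = db_residues * query_len * 2 ** (-S')

using fixed published gapped-BLOSUM62 constants (lambda=0.267, K=0.041).
The constants only need to be internally consistent: thresholds in this
package are swept or calibrated against this aligner, never transplanted
from another tool.

By default an exact-match k-mer prefilter (k=5) restricts the all-vs-all
scan to target proteins sharing at least one k-mer with the query; pairs
without a shared k-mer essentially never reach useful scores, and
``seed_k=None`` recovers the exhaustive scan.
"""

from __future__ import annotations

import math
import numpy as np
from collections import defaultdict
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .classify import AlignmentHit
from .orfs import OrfRecord
from .reference import ReferenceSet

__all__ = ["AlignerParams", "naive_translated_align", "raw_score_to_bits"]


@dataclass(frozen=True)
class AlignerParams:
    """Scoring parameters of the built-in translated aligner."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    db_residues: int = 0  # 0: use the total reference protein length

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


def raw_score_to_bits(raw: float, params: AlignerParams) -> float:
    return (params.karlin_lambda * raw - math.log(params.karlin_k)) / math.log(2.0)


def _make_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -(params.gap_open)
    aligner.extend_gap_score = -(params.gap_extend)
    return aligner


def _seed_index(proteins: list[str], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = defaultdict(set)
    for t, protein in enumerate(proteins):
        for i in range(len(protein) - k + 1):
            index[protein[i : i + k]].add(t)
    return index


def naive_translated_align(
    orfs: list[OrfRecord],
    ref: ReferenceSet,
    params: AlignerParams | None = None,
    seed_k: int | None = 5,
    min_bits: float | None = None,
) -> list[AlignmentHit]:
    """Align every query peptide against the reference proteins.

    Emits the best local alignment per (query, target) pair; alignments with
    raw score <= 0 are suppressed, as are (optionally) hits below
    ``min_bits``.  ``seed_k`` enables the shared-k-mer prefilter; pass None
    for the exhaustive all-pairs scan.
    """
    params = params or AlignerParams()
    if not ref.genes:
        raise ValueError("reference set has no genes to align against")
    for orf in orfs:
        if "*" in orf.peptide:
            raise ValueError(f"ORF {orf.orf_id} contains a stop symbol")

    genes = ref.genes
    proteins = [ref.gene_protein(g) for g in genes]
    db_residues = params.db_residues or sum(len(p) for p in proteins)
    aligner = _make_aligner(params)
    index = _seed_index(proteins, seed_k) if seed_k else None

    hits: list[AlignmentHit] = []
    for orf in orfs:
        peptide = orf.peptide
        if index is None:
            candidates = range(len(genes))
        else:
            cand: set[int] = set()
            for i in range(len(peptide) - seed_k + 1):
                cand |= index.get(peptide[i : i + seed_k], _EMPTY)
            candidates = sorted(cand)
        for t in candidates:
            raw = aligner.score(peptide, proteins[t])
            if raw <= 0:
                continue
            bits = raw_score_to_bits(raw, params)
            if min_bits is not None and bits < min_bits:
                continue
            alignment = aligner.align(peptide, proteins[t])[0]
            coords = alignment.coordinates  # row 0: query, row 1: target
            q0, q1 = int(coords[0, 0]), int(coords[0, -1])
            sstart = int(coords[1, 0]) + 1
            send = int(coords[1, -1])
            aln_len = max(q1 - q0, send - sstart + 1)
            matches = 0
            for b in range(coords.shape[1] - 1):
                qa, qb = int(coords[0, b]), int(coords[0, b + 1])
                ta, tb = int(coords[1, b]), int(coords[1, b + 1])
                if qb - qa == tb - ta and qb > qa:  # match/mismatch block
                    qseg = np.frombuffer(peptide[qa:qb].encode(), dtype=np.uint8)
                    tseg = np.frombuffer(proteins[t][ta:tb].encode(), dtype=np.uint8)
                    matches += int((qseg == tseg).sum())
            identity = 100.0 * matches / aln_len if aln_len else 0.0
            hits.append(
                AlignmentHit(
                    query_id=orf.orf_id,
                    read_id=orf.read_id,
                    target_gene=genes[t].gene_id,
                    target_genome=genes[t].genome_id,
                    family_id=genes[t].family_id,
                    bit_score=bits,
                    e_value=db_residues * len(peptide) * 2.0 ** (-bits),
                    aln_len=aln_len,
                    target_span=(sstart, send),
                    identity_pct=identity,
                )
            )
    return hits


_EMPTY: frozenset = frozenset()
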