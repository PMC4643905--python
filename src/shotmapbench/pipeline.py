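"""End-to-end convenience wrappers over the annotation benchmark stages."""

from __future__ import annotations

from dataclasses import dataclass

from .abundance import classification_rate, count_abundance, coverage_abundance
from .align import AlignerParams, naive_translated_align
from .classify import Classification, classify_hits, default_bitscore_threshold
from .evaluation import l1_error
from .orfs import DEFAULT_MIN_ORF_LEN, predict_orfs
from .reference import (
    AbundanceProfile,
    CommunityProfile,
    ReferenceSet,
    expected_family_abundance,
)
from .simulate import ErrorModel, Read, simulate_reads

__all__ = ["AnnotationResult", "annotate_reads", "run_benchmark"]


@dataclass
class AnnotationResult:
    """Everything the annotation stages produce for one read library."""

    reads: list[Read]
    hits: list
    classifications: list[Classification]
    profile: AbundanceProfile
    classification_rate: float


def annotate_reads(
    reads: list[Read],
    ref: ReferenceSet,
    mode: str = "per_read",
    metric: str = "count",
    min_bits: float | None = None,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
    params: AlignerParams | None = None,
    seed_k: int | None = 5,
) -> AnnotationResult:
    """Translate, align, classify and profile one read library.

    ``min_bits`` defaults to the read-length-dependent threshold computed
    from the first read's length.
    """
    if not reads:
        raise ValueError("no reads to annotate")
    if min_bits is None:
        min_bits = default_bitscore_threshold(len(reads[0].seq))
    orfs = predict_orfs(reads, min_len=min_orf_len)
    # emit nothing below half the classification threshold: such hits can
    # never classify at min_bits and only cost memory
    hits = naive_translated_align(
        orfs, ref, params=params, seed_k=seed_k, min_bits=min_bits / 2.0
    )
    classifications = classify_hits(hits, mode=mode, min_bits=min_bits)
    builder = count_abundance if metric == "count" else coverage_abundance
    profile = builder(classifications, ref) if classifications else None
    return AnnotationResult(
        reads=reads,
        hits=hits,
        classifications=classifications,
        profile=profile,
        classification_rate=classification_rate(classifications, len(reads)),
    )


def run_benchmark(
    ref: ReferenceSet,
    community: CommunityProfile,
    n_reads: int,
    read_length: int,
    model: ErrorModel | None = None,
    seed: int = 0,
    mode: str = "per_read",
    metric: str = "count",
    min_bits: float | None = None,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
) -> tuple[AnnotationResult, float]:
    """Simulate a library from a mock community, annotate it, and score it.

    Returns the annotation result together with the L1 error between the
    estimated profile and the community's expected profile.
    """
    reads = simulate_reads(ref, community, n_reads, read_length, model=model, seed=seed)
    result = annotate_reads(
        reads, ref, mode=mode, metric=metric, min_bits=min_bits, min_orf_len=min_orf_len
    )
    expected = expected_family_abundance(community, ref)
    err = 1.0 if result.profile is None else l1_error(expected, result.profile)
    return result, err
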