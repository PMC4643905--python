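"""Annotation accuracy and functional-diversity evaluation.

The central accuracy metric is the L1 relative-abundance error between an
expected profile R and an estimated profile R-hat::

    D = 1/2 * sum_i | R_i - Rhat_i |

bounded on [0, 1]: zero for identical profiles and one for disjoint
supports.  On normalized profiles this is algebraically identical to the
Bray-Curtis dissimilarity, which is also provided (and asserted equal in the
test suite).

The module also provides the depth-dependence machinery: read-level
rarefaction (without replacement), Poisson/bootstrap coefficient-of-variation
estimates per family, a closed-form sequencing-depth calculator, alpha
diversity (richness, Shannon entropy in nats, Good's coverage) and empirical
false-positive rates for shuffled-read negatives.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import count_abundance, coverage_abundance
from .classify import AlignmentHit, Classification, classify_hits
from .reference import AbundanceProfile, ReferenceSet

__all__ = [
    "SweepResult",
    "l1_error",
    "bray_curtis",
    "threshold_sweep",
    "rarefy_classifications",
    "bootstrap_family_cv",
    "reads_for_target_cv",
    "alpha_diversity",
    "empirical_fpr",
]


def _require_normalized(profile: AbundanceProfile, name: str) -> None:
    if not profile.normalized:
        raise ValueError(f"{name} profile must be normalized (sum to 1)")


def l1_error(expected: AbundanceProfile, estimated: AbundanceProfile) -> float:
    """L1 relative-abundance error D = 1/2 sum |R_i - Rhat_i| in [0, 1]."""
    _require_normalized(expected, "expected")
    _require_normalized(estimated, "estimated")
    families = set(expected.values) | set(estimated.values)
    return 0.5 * sum(
        abs(expected.values.get(f, 0.0) - estimated.values.get(f, 0.0))
        for f in families
    )


def bray_curtis(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """Bray-Curtis dissimilarity sum|p-q| / sum(p+q); equals L1 error here."""
    _require_normalized(p, "first")
    _require_normalized(q, "second")
    families = set(p.values) | set(q.values)
    num = sum(abs(p.values.get(f, 0.0) - q.values.get(f, 0.0)) for f in families)
    den = sum(p.values.get(f, 0.0) + q.values.get(f, 0.0) for f in families)
    return num / den


@dataclass(frozen=True)
class SweepResult:
    """L1 error across a grid of bit-score thresholds.

    ``within1pct_band`` is the (lowest, highest) threshold whose error is
    within 1% of the optimum — wide bands mean threshold choice is forgiving.
    """

    thresholds: tuple[float, ...]
    errors: tuple[float, ...]
    optimum_bits: float
    within1pct_band: tuple[float, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold_bits": self.thresholds, "l1_error": self.errors})


def threshold_sweep(
    hits: list[AlignmentHit],
    expected: AbundanceProfile,
    ref: ReferenceSet,
    grid: Sequence[float],
    mode: str = "per_read",
    metric: str = "count",
) -> SweepResult:
    """Classify, profile and score the L1 error at each threshold in ``grid``.

    Thresholds at which nothing classifies score the maximum error of 1.
    """
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    grid = sorted(float(t) for t in grid)
    builder = count_abundance if metric == "count" else coverage_abundance
    errors = []
    for t in grid:
        classifications = classify_hits(hits, mode=mode, min_bits=t)
        if not classifications:
            errors.append(1.0)
            continue
        errors.append(l1_error(expected, builder(classifications, ref)))
    best = int(np.argmin(errors))
    tol = 1.01 * errors[best]
    in_band = [t for t, e in zip(grid, errors) if e <= tol]
    return SweepResult(
        thresholds=tuple(grid),
        errors=tuple(errors),
        optimum_bits=grid[best],
        within1pct_band=(min(in_band), max(in_band)),
    )


def rarefy_classifications(
    classifications: list[Classification],
    depth: int,
    replicates: int = 1,
    seed: int = 0,
    with_replacement: bool = False,
    ref: ReferenceSet | None = None,
    metric: str = "count",
    read_ids: Sequence[str] | None = None,
) -> list[AbundanceProfile]:
    """Subsample *reads* and rebuild an abundance profile per replicate.

    Sampling is over distinct source reads (a read keeps all of its
    classifications when drawn), without replacement for rarefaction or with
    replacement for bootstrapping.  ``read_ids`` is the universe sampled
    from — pass the whole library's ids so that depth counts sequenced
    reads; by default only classified reads are sampled.  Deterministic
    given ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if ref is None:
        raise ValueError("a reference set is required to rebuild profiles")
    by_read: dict[str, list[Classification]] = defaultdict(list)
    for c in classifications:
        by_read[c.read_id].append(c)
    read_ids = sorted(by_read) if read_ids is None else sorted(read_ids)
    if not with_replacement and depth > len(read_ids):
        raise ValueError(
            f"depth {depth} exceeds the {len(read_ids)} available classified reads"
        )
    rng = np.random.default_rng(seed)
    builder = count_abundance if metric == "count" else coverage_abundance
    profiles = []
    for _ in range(replicates):
        chosen = rng.choice(len(read_ids), size=depth, replace=with_replacement)
        subset: list[Classification] = []
        for idx in chosen:
            subset.extend(by_read.get(read_ids[idx], ()))
        profiles.append(builder(subset, ref))
    return profiles


def bootstrap_family_cv(
    classified_counts: Mapping[str, float],
    depths: Sequence[float] | None = None,
    replicates: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Coefficient of variation of per-family counts under Poisson resampling.

    In the absence of biological variation a family's classified-read count
    is Poisson distributed (variance equal to the mean), so its CV falls as
    1/sqrt(mean).  ``depths`` optionally rescales each family's expected
    count proportionally (depth acts as a multiplier on the given counts,
    with depth 1 meaning the counts as supplied); the result is a family x
    depth table of sd/mean ratios, NaN where the mean resample is zero.
    """
    if replicates < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    depths = [1.0] if depths is None else list(depths)
    rng = np.random.default_rng(seed)
    rows = {}
    for family, expected in sorted(classified_counts.items()):
        row = {}
        for depth in depths:
            mean_count = expected * depth
            if mean_count <= 0:
                row[depth] = np.nan
                continue
            draws = rng.poisson(mean_count, size=replicates)
            m = draws.mean()
            row[depth] = draws.std(ddof=1) / m if m > 0 else np.nan
        rows[family] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def reads_for_target_cv(cv_target: float, gene_len_bp: float, ags_bp: float) -> int:
    """Library size needed for a family-count CV at or below ``cv_target``.

    A single-copy gene of length ``gene_len_bp`` in a community of average
    genome size ``ags_bp`` receives a fraction gene_len/AGS of the reads, and
    a Poisson count m has CV 1/sqrt(m); so CV <= target requires
    m = 1/target^2 classified reads and hence
    N = ceil((1/target^2) * AGS/gene_len) total reads.  The canonical example:
    a 1 kb gene at AGS 3 Mb needs 100 classified reads and thus ~300,000
    single-end reads for CV <= 0.10.
    """
    if cv_target <= 0 or cv_target > 1:
        raise ValueError("cv_target must be in (0, 1]")
    if gene_len_bp <= 0 or ags_bp <= 0:
        raise ValueError("lengths must be positive")
    return math.ceil((1.0 / cv_target**2) * ags_bp / gene_len_bp)


def alpha_diversity(counts: Mapping[str, int]) -> tuple[int, float, float]:
    """(richness, Shannon entropy in nats, Good's coverage) of family counts.

    Richness counts families with positive counts; Shannon is
    H = -sum p_i ln p_i over positive proportions; Good's coverage is
    1 - F1/N with F1 the number of singleton families and N the total count.
    """
    positive = {f: int(c) for f, c in counts.items() if c > 0}
    if not positive:
        raise ValueError("alpha diversity of an all-zero count vector is undefined")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    n = sum(positive.values())
    props = np.array(list(positive.values()), dtype=float) / n
    shannon = float(-(props * np.log(props)).sum())
    singletons = sum(1 for c in positive.values() if c == 1)
    return len(positive), shannon, 1.0 - singletons / n


def empirical_fpr(
    shuffled_hits: list[AlignmentHit],
    grid: Sequence[float],
    n_reads: int,
    mode: str = "per_read",
) -> pd.Series:
    """Fraction of shuffled (synthetic-negative) reads classified per threshold."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rates = {}
    for t in sorted(float(x) for x in grid):
        classified = classify_hits(shuffled_hits, mode=mode, min_bits=t)
        rates[t] = len({c.read_id for c in classified}) / n_reads
    return pd.Series(rates, name="fpr").sort_index()
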