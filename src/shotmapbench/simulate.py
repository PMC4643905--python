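"""Truth-labelled shotgun read simulation from mock communities.

Reads are allocated to genomes in proportion to the community coverages
``A_j`` (multinomial allocation), start positions are uniform over valid
positions and strands are uniform.  Sequencing error is applied per read by a
position-dependent :class:`ErrorModel`; given an error the event is a
substitution with probability 4/5 and an insertion or deletion with
probability 1/10 each (a 4:1 substitution:indel ratio, approximately matching
raw Illumina error profiles).

Error models
------------
``error_free``
    No errors.
``uniform``
    Constant per-base error probability (``rate``; the benchmark default is
    1%).
``linear``
    Per-base probability interpolating linearly from ``rate_start`` at the
    first base to ``rate_end`` at the last (Sanger-style; 1% -> 2% default).
``poly4``
    Illumina-style fourth-degree polynomial ``p(i) = (a + b * i^4) / 100``
    with defaults a=3e-3, b=3.3e-8.  NOTE: the parameters follow Grinder's
    percent convention — the polynomial is evaluated in percent and divided
    by 100, giving ~3.3% at position 101 rather than an impossible >1
    probability.
``homopolymer``
    454-style model: each homopolymer run of length n is resampled from
    Normal(n, 0.03 + 0.15 * n), rounded and clamped at zero.  A deliberately
    simple approximation of published 454 length-error behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import CommunityProfile, ReferenceSet

__all__ = [
    "Read",
    "ErrorModel",
    "simulate_reads",
    "mutate_sequence",
    "shuffle_reads",
    "write_reads_fasta",
    "write_reads_fastq",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ERROR_MODEL_KINDS = ("error_free", "uniform", "linear", "poly4", "homopolymer")

SUBSTITUTION_PROB = 0.8  # 4:1 substitution:indel ratio
INSERTION_PROB = 0.1
DELETION_PROB = 0.1


@dataclass(frozen=True)
class Read:
    """A simulated shotgun read with its provenance.

    ``truth_start`` is the 1-based leftmost position of the sampled fragment
    on the source genome's forward strand; truth fields are empty strings /
    zero for reads whose provenance has been deliberately destroyed
    (see :func:`shuffle_reads`).
    """

    read_id: str
    seq: str
    truth_genome: str = ""
    truth_start: int = 0
    truth_strand: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ErrorModel:
    kind: str = "uniform"
    rate: float = 0.01
    rate_start: float = 0.01
    rate_end: float = 0.02
    poly4_a: float = 3e-3
    poly4_b: float = 3.3e-8
    poly4_max_len: int = 150  # longest read the polynomial stays a probability for
    sub_prob: float = SUBSTITUTION_PROB
    ins_prob: float = INSERTION_PROB
    del_prob: float = DELETION_PROB

    def __post_init__(self) -> None:
        if self.kind not in _ERROR_MODEL_KINDS:
            raise ValueError(f"unknown error model {self.kind!r}")
        if abs(self.sub_prob + self.ins_prob + self.del_prob - 1.0) > 1e-12:
            raise ValueError("substitution/insertion/deletion probabilities must sum to 1")
        for p in self.error_probabilities(self.poly4_max_len if self.kind == "poly4" else 2):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"error model yields probability {p} outside [0, 1]")

    def error_probabilities(self, length: int) -> np.ndarray:
        """Per-position error probabilities p(i) for a read of given length."""
        if self.kind in ("error_free", "homopolymer"):
            return np.zeros(length)
        if self.kind == "uniform":
            return np.full(length, self.rate)
        if self.kind == "linear":
            if length == 1:
                return np.array([self.rate_start])
            return np.linspace(self.rate_start, self.rate_end, length)
        # poly4: percent convention, position index is 1-based
        i = np.arange(1, length + 1, dtype=float)
        probs = (self.poly4_a + self.poly4_b * i**4) / 100.0
        if probs.size and probs[-1] > 1.0:
            raise ValueError(
                f"poly4 error probability exceeds 1 at position {length}; "
                "the polynomial is only valid for shorter reads"
            )
        return probs

    @classmethod
    def from_string(cls, text: str) -> "ErrorModel":
        """Parse CLI-style specs such as ``uniform:0.01`` or ``linear:0.01:0.02``."""
        parts = text.split(":")
        kind = parts[0]
        args = [float(x) for x in parts[1:]]
        if kind == "uniform" and args:
            return cls(kind="uniform", rate=args[0])
        if kind == "linear" and len(args) == 2:
            return cls(kind="linear", rate_start=args[0], rate_end=args[1])
        if kind == "poly4" and len(args) == 2:
            return cls(kind="poly4", poly4_a=args[0], poly4_b=args[1])
        if not args:
            return cls(kind=kind)
        raise ValueError(f"cannot parse error model spec {text!r}")


_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i


def _mutate_array(seq: np.ndarray, probs: np.ndarray, rng: np.random.Generator,
                  model: ErrorModel) -> np.ndarray:
    """Apply substitution/indel errors to a uint8 base array."""
    hit = np.nonzero(rng.random(seq.size) < probs)[0]
    if hit.size == 0:
        return seq
    kinds = rng.random(hit.size)
    offsets = rng.integers(1, 4, size=hit.size)  # offset to a different base
    pieces: list[np.ndarray] = []
    prev = 0
    for pos, k, off in zip(hit, kinds, offsets):
        pieces.append(seq[prev:pos])
        base = seq[pos]
        if k < model.sub_prob:
            idx = _BASE_INDEX[base]
            if idx < 0:  # N or other ambiguity: leave untouched
                pieces.append(seq[pos : pos + 1])
            else:
                pieces.append(_BASES[(idx + off) % 4 : (idx + off) % 4 + 1])
        elif k < model.sub_prob + model.ins_prob:
            j = int(rng.integers(0, 4))
            pieces.append(seq[pos : pos + 1])
            pieces.append(_BASES[j : j + 1])
        # deletion: emit nothing
        prev = pos + 1
    pieces.append(seq[prev:])
    return np.concatenate(pieces)


def _homopolymer_mutate(seq: str, rng: np.random.Generator) -> str:
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        n = j - i
        new_n = int(round(rng.normal(n, 0.03 + 0.15 * n)))
        out.append(seq[i] * max(new_n, 0))
        i = j
    return "".join(out)


def mutate_sequence(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply a sequencing-error model to one read sequence."""
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if model.kind == "error_free":
        return seq
    if model.kind == "homopolymer":
        return _homopolymer_mutate(seq, rng)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    probs = model.error_probabilities(len(seq))
    return _mutate_array(arr, probs, rng, model).tobytes().decode()


def simulate_reads(
    ref: ReferenceSet,
    community: CommunityProfile,
    n_reads: int,
    read_length: int,
    model: ErrorModel | None = None,
    seed: int = 0,
    weight_by_length: bool = False,
) -> list[Read]:
    """Simulate a truth-labelled shotgun library from a mock community.

    Reads per genome are multinomially allocated in proportion to ``A_j``
    (read literally as genome relative abundance).  With
    ``weight_by_length=True`` allocation is instead proportional to
    ``A_j * genome_length``, which realizes per-base coverage proportional to
    ``A_j``.  Deterministic given ``seed``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if read_length < 25:
        raise ValueError("read_length must be >= 25")
    model = model or ErrorModel(kind="error_free")
    rng = np.random.default_rng(seed)

    genome_ids = sorted(g for g, a in community.abundances.items() if a > 0)
    weights = []
    for gid in genome_ids:
        if gid not in ref.genomes:
            raise KeyError(f"community genome {gid!r} absent from reference set")
        if len(ref.genomes[gid]) < read_length:
            raise ValueError(
                f"genome {gid} ({len(ref.genomes[gid])} nt) shorter than read length"
            )
        w = community.abundances[gid]
        if weight_by_length:
            w *= len(ref.genomes[gid])
        weights.append(w)
    probs = np.asarray(weights) / sum(weights)
    counts = rng.multinomial(n_reads, probs)

    reads: list[Read] = []
    ordinal = 0
    for gid, count in zip(genome_ids, counts):
        genome = ref.genomes[gid]
        starts = rng.integers(1, len(genome) - read_length + 2, size=count)
        strands = rng.integers(0, 2, size=count)
        for start, fwd in zip(starts, strands):
            frag = genome[start - 1 : start - 1 + read_length]
            strand = "+" if fwd else "-"
            if strand == "-":
                frag = frag.translate(_RC)[::-1]
            seq = mutate_sequence(frag, model, rng)
            reads.append(
                Read(
                    read_id=f"read{ordinal}",
                    seq=seq,
                    truth_genome=gid,
                    truth_start=int(start),
                    truth_strand=strand,
                )
            )
            ordinal += 1
    return reads


_RC = str.maketrans("ACGTN", "TGCAN")


def shuffle_reads(reads: list[Read], seed: int = 0) -> list[Read]:
    """Randomly permute each read's bases, producing synthetic negatives.

    Length and base composition are preserved; truth fields are cleared
    because the shuffled sequence no longer derives from any genome.
    """
    if not reads:
        raise ValueError("no reads to shuffle")
    rng = np.random.default_rng(seed)
    out = []
    for read in reads:
        arr = np.frombuffer(read.seq.encode(), dtype=np.uint8).copy()
        rng.shuffle(arr)
        out.append(Read(read_id=read.read_id, seq=arr.tobytes().decode()))
    return out


def write_reads_fasta(reads: list[Read], path) -> None:
    """Write reads as FASTA, encoding truth in the header as id|genome|start|strand."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}|{r.truth_genome}|{r.truth_start}|{r.truth_strand}\n")
            fh.write(r.seq + "\n")


def write_reads_fastq(reads: list[Read], path, quality: int = 30) -> None:
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qchar * len(r.seq)}\n")


def write_truth_tsv(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttruth_genome\ttruth_start\ttruth_strand\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.truth_genome}\t{r.truth_start}\t{r.truth_strand}\n")
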