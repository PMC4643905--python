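"""Six-frame translation of reads and ORF extraction.

A read is translated in all six reading frames (three forward, three on the
reverse complement) with the standard genetic code, each frame is split on
stop codons into maximal stop-free peptides, and peptides shorter than a
length cutoff are discarded as likely spurious.  An ORF here is any maximal
stop-free run — reads are genome fragments, so ORFs are not required to start
with Met.  The default cutoff of 15 aa matches the short-ORF filter used for
real 454 metagenome annotation.

Output of external gene finders (e.g. Prodigal) can be imported instead of
the naive translation via :func:`import_external_orfs`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

from .simulate import Read

__all__ = [
    "OrfRecord",
    "FRAMES",
    "DEFAULT_MIN_ORF_LEN",
    "six_frame_translate",
    "split_and_filter_orfs",
    "predict_orfs",
    "import_external_orfs",
    "write_peptides_fasta",
    "read_id_of_orf",
]

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")
DEFAULT_MIN_ORF_LEN = 15

_ORF_ID_RE = re.compile(r"^(?P<read>.+)_f(?P<frame>[+-][123]|ext)_(?P<index>\d+)$")


@dataclass(frozen=True)
class OrfRecord:
    """A candidate peptide from one read.

    ``aa_start`` is the 1-based position of the peptide within its frame's
    full translation (1 for external predictions).
    """

    orf_id: str
    read_id: str
    frame: str
    aa_start: int
    peptide: str

    def __post_init__(self) -> None:
        if not self.peptide or "*" in self.peptide:
            raise ValueError(f"ORF {self.orf_id}: peptide must be non-empty and stop-free")


def six_frame_translate(read: Read | str) -> dict[str, str]:
    """Translate a read in all six frames, with ``*`` marking stops.

    Frames +1..+3 translate the read at offsets 0..2; -1..-3 translate the
    reverse complement at offsets 0..2.  Codons containing ambiguity codes
    translate to ``X``; trailing 1-2 nt that do not fill a codon are dropped.
    Reads shorter than 3 nt yield no frames (with a warning).
    """
    seq = read.seq if isinstance(read, Read) else read
    seq = seq.upper()
    if len(seq) < 3:
        warnings.warn(f"read of length {len(seq)} is too short to translate")
        return {}
    forward = Seq(seq)
    reverse = forward.reverse_complement()
    out: dict[str, str] = {}
    for offset in range(3):
        for strand, template in (("+", forward), ("-", reverse)):
            sub = template[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) == 0:
                continue
            out[f"{strand}{offset + 1}"] = str(sub.translate(table=1))
    return out


def split_and_filter_orfs(
    frames: dict[str, str],
    min_len: int = DEFAULT_MIN_ORF_LEN,
    read_id: str = "read",
) -> list[OrfRecord]:
    """Split translated frames on stops and drop short peptides.

    Each frame is split on ``*`` into maximal stop-free substrings; peptides
    of length strictly less than ``min_len`` are discarded.  Survivors get
    deterministic ids ``{read_id}_f{frame}_{index}`` with the index counting
    surviving peptides within the frame from zero.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    records = []
    for frame in FRAMES:
        translation = frames.get(frame)
        if not translation:
            continue
        index = 0
        position = 1  # 1-based aa position within the frame translation
        for piece in translation.split("*"):
            if len(piece) >= min_len:
                records.append(
                    OrfRecord(
                        orf_id=f"{read_id}_f{frame}_{index}",
                        read_id=read_id,
                        frame=frame,
                        aa_start=position,
                        peptide=piece,
                    )
                )
                index += 1
            position += len(piece) + 1
    return records


def predict_orfs(
    reads: list[Read], min_len: int = DEFAULT_MIN_ORF_LEN
) -> list[OrfRecord]:
    """Six-frame translate and filter every read in a library."""
    out: list[OrfRecord] = []
    for read in reads:
        out.extend(split_and_filter_orfs(six_frame_translate(read), min_len, read.read_id))
    return out


_PRODIGAL_RE = re.compile(r"^(?P<read>.+)_\d+$")


def import_external_orfs(fasta_path, read_id_rule=None) -> list[OrfRecord]:
    """Import amino-acid predictions from an external gene finder.

    ``read_id_rule`` maps a FASTA header token to the originating read id.
    It may be a compiled regex with a ``read`` group or a callable; the
    default handles Prodigal-style ids of the form ``{read_id}_{n}``.
    Terminal stop symbols are stripped; internal stops are rejected because a
    gene finder should never emit them.
    """
    if read_id_rule is None:
        read_id_rule = _PRODIGAL_RE
    offenders = []
    records = []
    for i, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        if callable(read_id_rule):
            read_id = read_id_rule(rec.id)
        else:
            m = read_id_rule.match(rec.id)
            read_id = m.group("read") if m else None
        if not read_id:
            offenders.append(rec.id)
            continue
        peptide = str(rec.seq).strip("*")
        if "*" in peptide:
            raise ValueError(f"imported ORF {rec.id} contains an internal stop")
        records.append(
            OrfRecord(
                orf_id=f"{read_id}_fext_{i}",
                read_id=read_id,
                frame="external",
                aa_start=1,
                peptide=peptide,
            )
        )
    if offenders:
        raise ValueError(f"headers not matching the read-id rule: {offenders}")
    return records


def write_peptides_fasta(orfs: list[OrfRecord], path) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.orf_id}\n{orf.peptide}\n")


def read_id_of_orf(orf_id: str) -> str:
    """Recover the read id from a deterministic ORF id by stripping the frame suffix."""
    m = _ORF_ID_RE.match(orf_id)
    if m:
        return m.group("read")
    return orf_id
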