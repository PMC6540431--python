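"""Six-frame translation, ORF enumeration and completeness classification.

Coordinate convention (used everywhere in the package): ORF intervals are
0-based half-open **on the forward strand**, with the frame sign carrying
the strand. For ORFs that end in a stop codon the interval includes the
stop codon, so ``len(peptide) * 3 == interval_length - 3`` in that case and
``len(peptide) * 3 == interval_length`` otherwise.

Completeness classes:

* ``complete`` — starts with an in-frame ATG and ends at an in-frame stop;
* ``partial5`` — runs from the transcript edge to an in-frame stop with no
  upstream in-frame stop and no ATG before its first codon (missing start);
* ``partial3`` — starts at an ATG and runs off the transcript edge
  (missing stop);
* ``internal`` — anchored at neither end.

The standard genetic code is used; ATG is the sole start codon. Codons
containing N translate to ``'X'`` and never count as start or stop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

from Bio.Data.CodonTable import standard_dna_table

if TYPE_CHECKING:  # pragma: no cover
    from .homology_search import HomologyHit

__all__ = [
    "OrfCall",
    "six_frame_translate",
    "find_orfs",
    "classify_against_hit",
    "translate",
    "reverse_complement",
    "frame_peptides",
]

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = (1, 2, 3, -1, -2, -3)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string codon by codon; trailing 1-2 nt ignored."""
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def six_frame_translate(sequence: str) -> dict[int, str]:
    """Translate all six frames; stops appear as ``'*'``.

    Frames +1..+3 start at offsets 0..2 of the forward strand; frames
    -1..-3 start at offsets 0..2 of the reverse complement.
    """
    sequence = sequence.upper()
    rc = reverse_complement(sequence)
    return {
        1: translate(sequence),
        2: translate(sequence[1:]),
        3: translate(sequence[2:]),
        -1: translate(rc),
        -2: translate(rc[1:]),
        -3: translate(rc[2:]),
    }


def frame_peptides(sequence: str) -> dict[int, str]:
    """Alias of :func:`six_frame_translate` used by the search stage."""
    return six_frame_translate(sequence)


@dataclass(frozen=True)
class OrfCall:
    """A predicted open reading frame on a transcript."""

    transcript_id: str
    frame: int
    nt_interval: tuple[int, int]
    peptide: str
    completeness: str

    @property
    def length_aa(self) -> int:
        return len(self.peptide)

    @property
    def has_stop(self) -> bool:
        return self.completeness in ("complete", "partial5")

    @property
    def has_start(self) -> bool:
        return self.completeness in ("complete", "partial3")


def _forward_interval(frame: int, seq_len: int, codon_start: int, codon_end: int) -> tuple[int, int]:
    """Map [codon_start, codon_end) in frame-local codons to forward-strand nt."""
    offset = abs(frame) - 1
    start = offset + 3 * codon_start
    end = offset + 3 * codon_end
    if frame > 0:
        return start, end
    # frame-local coordinates run along the reverse complement
    return seq_len - end, seq_len - start


def find_orfs(transcript, min_len_aa: int = 1) -> list[OrfCall]:
    """Enumerate ORFs in all six frames and classify their completeness.

    Each maximal stop-to-stop segment of a frame contributes at most one
    call; the list is sorted by peptide length, longest first (ties broken
    by frame then interval for determinism).
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    tid = getattr(transcript, "transcript_id", "")
    seq = (transcript.sequence if hasattr(transcript, "sequence") else str(transcript)).upper()
    calls: list[OrfCall] = []
    frames = six_frame_translate(seq)
    for frame, pep in frames.items():
        n = len(pep)
        seg_start = 0
        i = 0
        while seg_start < n:
            stop_idx = pep.find("*", seg_start)
            if stop_idx == -1:
                seg_end, terminated = n, False
            else:
                seg_end, terminated = stop_idx, True
            call = _classify_segment(
                tid, frame, seq, pep, seg_start, seg_end, terminated, min_len_aa
            )
            if call is not None:
                calls.append(call)
            seg_start = seg_end + 1
            i += 1
            if stop_idx == -1:
                break
    calls.sort(key=lambda c: (-c.length_aa, -c.frame, c.nt_interval))
    return calls


def _classify_segment(
    tid: str,
    frame: int,
    seq: str,
    pep: str,
    seg_start: int,
    seg_end: int,
    terminated: bool,
    min_len_aa: int,
) -> OrfCall | None:
    seg = pep[seg_start:seg_end]
    if not seg:
        return None
    m_idx = seg.find("M")
    first_segment = seg_start == 0
    if terminated:
        if m_idx != -1:
            codon_a, codon_b = seg_start + m_idx, seg_end
            peptide = seg[m_idx:]
            completeness = "complete"
        elif first_segment:
            codon_a, codon_b = seg_start, seg_end
            peptide = seg
            completeness = "partial5"
        else:
            # stop-terminated but unanchored: the stop is not part of the call
            peptide = seg
            interval = _forward_interval(frame, len(seq), seg_start, seg_end)
            if len(peptide) < min_len_aa:
                return None
            return OrfCall(tid, frame, interval, peptide, "internal")
        interval = _forward_interval(frame, len(seq), codon_a, codon_b + 1)  # + stop codon
    else:
        if m_idx != -1:
            codon_a, codon_b = seg_start + m_idx, seg_end
            peptide = seg[m_idx:]
            completeness = "partial3"
        else:
            codon_a, codon_b = seg_start, seg_end
            peptide = seg
            completeness = "internal"
        interval = _forward_interval(frame, len(seq), codon_a, codon_b)
    if len(peptide) < min_len_aa:
        return None
    return OrfCall(tid, frame, interval, peptide, completeness)


def classify_against_hit(
    orf: OrfCall, hit: "HomologyHit", query_len: int, transcript_len: int, *, margin: int = 3
) -> OrfCall:
    """Refine an ORF's completeness class using homology evidence.

    The start codon is judged internal — downgrading ``complete`` ->
    ``partial5`` and ``partial3`` -> ``internal`` even though an ATG
    exists — in either of two situations:

    * the alignment extends more than ``margin`` codons upstream of the
      ORF's start codon (homologous coding sequence before the ATG), or
    * the alignment misses more than ``margin`` residues of the query
      N-terminus while running into the subject's edge (the transcript is
      5'-truncated and cannot contain the true start).
    """
    if hit.transcript_id != orf.transcript_id or hit.frame != orf.frame:
        raise ValueError("hit and ORF must be on the same transcript and frame")
    has_start, has_stop = orf.has_start, orf.has_stop
    orf_codon_start, _ = frame_codon_span(orf, transcript_len)
    upstream_homology = orf_codon_start - hit.subject_interval[0] > margin
    edge_truncated = hit.query_interval[0] > margin and hit.subject_interval[0] <= margin
    if has_start and (upstream_homology or edge_truncated):
        has_start = False
    if has_start and has_stop:
        completeness = "complete"
    elif has_stop:
        completeness = "partial5"
    elif has_start:
        completeness = "partial3"
    else:
        completeness = "internal"
    return replace(orf, completeness=completeness)


def frame_codon_span(orf: OrfCall, transcript_len: int) -> tuple[int, int]:
    """The ORF's [start, end) span in frame-local codon coordinates.

    Frame-local coordinates index codons of the translated frame (the
    coordinate system of a homology hit's subject interval).
    """
    start, end = orf.nt_interval
    offset = abs(orf.frame) - 1
    length_codons = len(orf.peptide) + (1 if orf.has_stop else 0)
    if orf.frame > 0:
        codon_start = (start - offset) // 3
    else:
        # local coordinates run along the reverse complement
        codon_start = (transcript_len - end - offset) // 3
    return codon_start, codon_start + length_codons


def has_internal_stop(frame_peptide: str, span: tuple[int, int]) -> bool:
    """True if the frame translation contains '*' within [span)."""
    a, b = max(span[0], 0), min(span[1], len(frame_peptide))
    return "*" in frame_peptide[a:b]
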