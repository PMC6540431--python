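"""Greedy identity clustering of transcripts, longest representative kept.

Identity between two nucleotide sequences is the number of identity
columns in an optimal global alignment under unit match scoring, divided
by the length of the shorter sequence. Clustering is a single greedy
longest-first pass: each sequence joins the first existing representative
it matches at or above the threshold, otherwise it founds a new cluster —
so the longest member of every cluster is automatically its
representative. Comparison is forward-strand only.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _align
from .io_formats import TranscriptRecord

__all__ = ["ClusterResult", "pairwise_identity", "collapse"]


@dataclass(frozen=True)
class ClusterResult:
    representatives: list[TranscriptRecord]
    membership: dict[str, str]  # transcript_id -> representative_id
    identity_threshold: float
    word_size: int


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identity columns over the shorter sequence length."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    matches = _align.global_match_count(_align.encode_nt(a.upper()), _align.encode_nt(b.upper()))
    return matches / min(len(a), len(b))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def collapse(
    transcripts: list[TranscriptRecord],
    threshold: float = 0.98,
    word_size: int = 8,
    use_prefilter: bool = True,
) -> ClusterResult:
    """Collapse near-identical transcripts, retaining the longest of each
    cluster.

    The word-size k-mer prefilter only skips candidate pairs that share no
    k-mer at all; at the default threshold such pairs cannot reach it at
    desk scale, so the prefilter introduces no false negatives there.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(transcripts, key=lambda t: (-len(t.sequence), t.transcript_id))
    reps: list[TranscriptRecord] = []
    rep_kmers: list[set[str]] = []
    membership: dict[str, str] = {}
    for rec in order:
        kset = _kmer_set(rec.sequence, word_size) if use_prefilter else set()
        assigned = False
        for rep, rk in zip(reps, rep_kmers):
            if use_prefilter and kset.isdisjoint(rk):
                continue
            if pairwise_identity(rec.sequence, rep.sequence) >= threshold:
                membership[rec.transcript_id] = rep.transcript_id
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            rep_kmers.append(kset)
            membership[rec.transcript_id] = rec.transcript_id
    return ClusterResult(reps, membership, threshold, word_size)
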