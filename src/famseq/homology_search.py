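"""Translated homology search: protein queries against six-frame
translations of a transcript set.

Alignment is a full Smith-Waterman under affine gaps (no heuristic
seeding beyond an optional k-mer prefilter that can only skip subjects
sharing no 4-mer with the query). Significance uses the Karlin-Altschul
formula ``E = K * m * n * exp(-lambda * S)`` with published gapped
BLOSUM62/11/1 constants; the database length ``n`` is the total number of
translated residues across all six frames of all transcripts, without
effective-length corrections, so E-values are conservative and comparable
only within this implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _align
from .io_formats import TranscriptRecord
from .orf_translate import six_frame_translate

__all__ = [
    "HomologyHit",
    "SearchConfig",
    "smith_waterman",
    "AlignmentResult",
    "evalue_of",
    "search",
    "top_hit_transcript",
]


@dataclass(frozen=True)
class SearchConfig:
    """Scoring and reporting parameters for the translated search."""

    matrix: np.ndarray = field(default_factory=lambda: _align.BLOSUM62, repr=False)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267  # gapped BLOSUM62/11/1
    k: float = 0.041
    e_max: float = 1e-5
    max_hits_per_query: int = 50
    prefilter_kmer: int = 4
    use_prefilter: bool = True

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a query/subject peptide pair."""

    score: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@dataclass(frozen=True)
class HomologyHit:
    """A significant local alignment between a family query protein and a
    translated transcript region. Intervals are 0-based half-open amino-acid
    coordinates: the query interval on the query peptide, the subject
    interval on the frame-local translation of the transcript."""

    query_id: str
    transcript_id: str
    gene_id: str
    frame: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    raw_score: int
    bit_score: float
    evalue: float
    pct_identity: float
    contains_internal_stop: bool


def smith_waterman(query_aa: str, subject_aa: str, config: SearchConfig | None = None) -> AlignmentResult:
    """Optimal local alignment of two peptides under affine gaps.

    Characters outside the substitution-matrix alphabet are treated as X.
    Among equal-scoring alignments the one ending earliest in the subject,
    then earliest in the query, is reported; the traceback prefers matches
    over gaps. An empty alignment (score 0) is returned when no positive-
    scoring pair exists.
    """
    if not query_aa or not subject_aa:
        raise ValueError("smith_waterman requires non-empty peptides")
    config = config or SearchConfig()
    q = _align.encode_aa(query_aa.upper())
    s = _align.encode_aa(subject_aa.upper())
    score, end_i, end_j = _align.sw_affine(q, s, config.matrix, config.gap_open, config.gap_extend)
    if score <= 0:
        return AlignmentResult(0, (0, 0), (0, 0), 0, 0)
    q0, s0, matches, columns = _align.sw_affine_traceback(
        q, s, config.matrix, config.gap_open, config.gap_extend, end_i, end_j
    )
    return AlignmentResult(int(score), (int(q0), int(end_i)), (int(s0), int(end_j)), int(matches), int(columns))


def evalue_of(raw_score: float, query_len: int, database_len_aa: int, config: SearchConfig | None = None) -> float:
    """Karlin-Altschul expect value for a raw alignment score."""
    if query_len <= 0 or database_len_aa <= 0:
        raise ValueError("lengths must be positive")
    config = config or SearchConfig()
    kmn = config.k * query_len * database_len_aa
    if raw_score <= 0:
        return kmn
    return kmn * math.exp(-config.lam * raw_score)


def bit_score_of(raw_score: float, config: SearchConfig | None = None) -> float:
    config = config or SearchConfig()
    return (config.lam * raw_score - math.log(config.k)) / math.log(2)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class TranslatedDatabase:
    """Six-frame translations of a transcript set, built once per search."""

    def __init__(self, transcripts: Sequence[TranscriptRecord]):
        if not transcripts:
            raise ValueError("empty transcript set")
        self.transcripts = list(transcripts)
        self.frames: dict[str, dict[int, str]] = {
            t.transcript_id: six_frame_translate(t.sequence) for t in self.transcripts
        }
        self.gene_of: dict[str, str] = {
            t.transcript_id: (t.gene_id or t.transcript_id) for t in self.transcripts
        }
        self.total_residues: int = sum(
            len(pep) for frames in self.frames.values() for pep in frames.values()
        )
        self._kmer_cache: dict[tuple[str, int, int], set[str]] = {}

    def frame_kmers(self, transcript_id: str, frame: int, k: int) -> set[str]:
        key = (transcript_id, frame, k)
        got = self._kmer_cache.get(key)
        if got is None:
            got = _kmers(self.frames[transcript_id][frame], k)
            self._kmer_cache[key] = got
        return got


def search(
    queries: Mapping[str, str],
    transcripts: Sequence[TranscriptRecord] | TranslatedDatabase,
    config: SearchConfig | None = None,
) -> list[HomologyHit]:
    """Align every query against all six frames of every transcript.

    Hits with ``evalue <= config.e_max`` are kept, sorted by ascending
    E-value then descending raw score (ties broken by query, transcript,
    frame for determinism), and truncated to ``max_hits_per_query``.
    """
    if not queries:
        raise ValueError("empty query set")
    config = config or SearchConfig()
    db = transcripts if isinstance(transcripts, TranslatedDatabase) else TranslatedDatabase(list(transcripts))
    hits: list[HomologyHit] = []
    for query_id, query_aa in queries.items():
        q_kmers = _kmers(query_aa, config.prefilter_kmer) if config.use_prefilter else None
        per_query: list[HomologyHit] = []
        for rec in db.transcripts:
            for frame, pep in db.frames[rec.transcript_id].items():
                if not pep:
                    continue
                if q_kmers is not None and len(pep) >= config.prefilter_kmer:
                    if q_kmers.isdisjoint(db.frame_kmers(rec.transcript_id, frame, config.prefilter_kmer)):
                        continue
                aln = smith_waterman(query_aa, pep, config)
                if aln.score <= 0:
                    continue
                ev = evalue_of(aln.score, len(query_aa), db.total_residues, config)
                if ev > config.e_max:
                    continue
                per_query.append(
                    HomologyHit(
                        query_id=query_id,
                        transcript_id=rec.transcript_id,
                        gene_id=db.gene_of[rec.transcript_id],
                        frame=frame,
                        query_interval=aln.query_interval,
                        subject_interval=aln.subject_interval,
                        raw_score=aln.score,
                        bit_score=bit_score_of(aln.score, config),
                        evalue=ev,
                        pct_identity=aln.identity,
                        contains_internal_stop=_projected_internal_stop(
                            pep, aln, len(query_aa)
                        ),
                    )
                )
        per_query.sort(key=lambda h: (h.evalue, -h.raw_score, h.transcript_id, h.frame))
        hits.extend(per_query[: config.max_hits_per_query])
    return hits


def _projected_internal_stop(frame_peptide: str, aln: AlignmentResult, query_len: int) -> bool:
    """Whether the full-query projection of the alignment crosses a stop.

    The aligned subject interval is extended by the unaligned query
    overhangs on both sides (clipped to the frame); a ``'*'`` inside that
    span marks the hit as bracketed/interrupted by in-frame stops.
    """
    q0, q1 = aln.query_interval
    s0, s1 = aln.subject_interval
    lo = max(0, s0 - q0)
    hi = min(len(frame_peptide), s1 + (query_len - q1))
    return "*" in frame_peptide[lo:hi]


class NoHit:
    """Sentinel distinguishing 'searched, nothing found' from an error."""

    def __bool__(self) -> bool:  # pragma: no cover - trivial
        return False

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NoHit()"


NO_HIT = NoHit()


def top_hit_transcript(query_id: str, hits: Iterable[HomologyHit]) -> str | NoHit:
    """Gene id of the best hit for a query, or :data:`NO_HIT`.

    Best = lowest E-value; ties broken by higher identity, then
    lexicographic transcript id.
    """
    candidates = [h for h in hits if h.query_id == query_id]
    if not candidates:
        return NO_HIT
    best = min(candidates, key=lambda h: (h.evalue, -h.pct_identity, h.transcript_id))
    return best.gene_id
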