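"""Pair-level read filtering: adaptor, N-content and base-quality criteria.

A pair is removed when either mate fails any criterion; removal counts are
attributed to the first failing criterion in the fixed order
adaptor -> N fraction -> low quality, so the report is exhaustive and
mutually exclusive. All thresholds are strict ("greater than"): a mate
with exactly 5% N or exactly 50% sub-threshold bases is kept.

Adaptor detection, in place of the original vendor software, is a
documented reproducible rule: a mate fails if it contains an exact match
of at least ``min_adaptor_match`` consecutive nucleotides of any
configured adaptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import ReadPair, phred_scores

__all__ = ["QcPolicy", "QcReport", "filter_pairs"]


@dataclass(frozen=True)
class QcPolicy:
    adaptor_sequences: tuple[str, ...] = ()
    max_n_fraction: float = 0.05
    max_lowq_fraction: float = 0.50
    q_threshold: int = 10
    min_adaptor_match: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.max_n_fraction <= 1 or not 0 <= self.max_lowq_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if self.q_threshold < 0:
            raise ValueError("q_threshold must be >= 0")
        object.__setattr__(
            self, "adaptor_sequences", tuple(a.upper() for a in self.adaptor_sequences)
        )


@dataclass
class QcReport:
    n_input: int = 0
    n_kept: int = 0
    removed_adaptor: int = 0
    removed_n: int = 0
    removed_quality: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _adaptor_words(policy: QcPolicy) -> list[str]:
    words: list[str] = []
    k = policy.min_adaptor_match
    for adaptor in policy.adaptor_sequences:
        if len(adaptor) < k:
            continue
        words.extend(adaptor[i : i + k] for i in range(len(adaptor) - k + 1))
    return sorted(set(words))


def _mate_fails_adaptor(seq: str, words: Sequence[str]) -> bool:
    return any(w in seq for w in words)


def _mate_fails_n(seq: str, policy: QcPolicy) -> bool:
    return seq.count("N") / len(seq) > policy.max_n_fraction


def _mate_fails_quality(qual: str, policy: QcPolicy) -> bool:
    scores = phred_scores(qual)
    low = sum(1 for s in scores if s < policy.q_threshold)
    return low / len(scores) > policy.max_lowq_fraction


def filter_pairs(
    pairs: Iterable[ReadPair], policy: QcPolicy
) -> tuple[list[ReadPair], QcReport]:
    """Apply the three removal criteria at pair level.

    Both mates of a failing pair are dropped, keeping the output files
    synchronized. Filtering is idempotent: a second pass over the kept
    pairs removes nothing.
    """
    words = _adaptor_words(policy)
    kept: list[ReadPair] = []
    report = QcReport()
    for pair in pairs:
        report.n_input += 1
        mates = ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2))
        if words and any(_mate_fails_adaptor(seq, words) for seq, _ in mates):
            report.removed_adaptor += 1
        elif any(_mate_fails_n(seq, policy) for seq, _ in mates):
            report.removed_n += 1
        elif any(_mate_fails_quality(qual, policy) for _, qual in mates):
            report.removed_quality += 1
        else:
            kept.append(pair)
            report.n_kept += 1
    return kept, report
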