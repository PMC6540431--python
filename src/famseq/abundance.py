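"""Fragment assignment, EM abundance estimation, FPKM and heat-map
matrices.

Read mapping is replaced by a k-mer pseudo-alignment: a transcript is
compatible with a fragment iff each mate's k-mer set (in its better of
forward / reverse-complement orientation) achieves at least the
containment threshold in the transcript's k-mer set. Multi-mapping
fragments are resolved with the standard length-normalized multinomial
EM; FPKM uses the closed form
``count / ((efflen / 1e3) * (total_mapped / 1e6))`` with effective length
``max(L - mean_fragment_length + 1, 1)``.

Heat-map matrices follow the published convention: values are
``log2(FPKM + 1)``; each sample gets its own color breakpoints
(min = 1, midpoint = the sample's 75th percentile with linear
interpolation between order statistics, max = the sample maximum).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ReadPair, TranscriptRecord
from .orf_translate import reverse_complement

__all__ = [
    "CompatibilityTable",
    "ExpressionMatrix",
    "build_compatibility",
    "em_expected_counts",
    "fpkm",
    "gene_level",
    "heatmap_matrix",
    "family_share",
]


@dataclass
class CompatibilityTable:
    transcript_ids: list[str]
    effective_length: dict[str, float]
    # compatibility class (frozenset of transcript ids) -> fragment count
    class_counts: dict[frozenset, int]
    n_fragments: int
    n_unmapped: int

    @property
    def n_mapped(self) -> int:
        return self.n_fragments - self.n_unmapped


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_compatibility(
    reads: list[ReadPair],
    transcripts: list[TranscriptRecord],
    k: int = 25,
    containment: float = 0.8,
    fragment_mean: float | None = None,
) -> CompatibilityTable:
    """Pseudo-align paired fragments against a transcript set.

    ``fragment_mean`` (for the effective length) defaults to twice the
    first pair's mate length, a crude insert-size stand-in that callers
    with simulation truth should override.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if reads and k > min(len(reads[0].seq1), len(reads[0].seq2)):
        raise ValueError("k must not exceed the read length")
    if fragment_mean is None:
        fragment_mean = 2.0 * len(reads[0].seq1) if reads else 1.0
    tids = [t.transcript_id for t in transcripts]
    efflen = {
        t.transcript_id: max(len(t.sequence) - fragment_mean + 1, 1.0) for t in transcripts
    }
    index: dict[str, list[int]] = {}
    for idx, t in enumerate(transcripts):
        for kmer in _kmer_set(t.sequence, k):
            index.setdefault(kmer, []).append(idx)

    class_counts: Counter = Counter()
    n_unmapped = 0
    for pair in reads:
        c1 = _compatible_set(pair.seq1, index, len(transcripts), k, containment)
        c2 = _compatible_set(pair.seq2, index, len(transcripts), k, containment)
        compat = c1 & c2
        if not compat:
            n_unmapped += 1
            continue
        class_counts[frozenset(tids[i] for i in compat)] += 1
    return CompatibilityTable(tids, efflen, dict(class_counts), len(reads), n_unmapped)


def _compatible_set(
    seq: str, index: dict[str, list[int]], n_transcripts: int, k: int, containment: float
) -> set[int]:
    best: set[int] = set()
    for oriented in (seq, reverse_complement(seq)):
        kmers = [oriented[i : i + k] for i in range(len(oriented) - k + 1)]
        if not kmers:
            continue
        hits: Counter = Counter()
        for kmer in kmers:
            for idx in index.get(kmer, ()):
                hits[idx] += 1
        need = containment * len(kmers)
        best |= {idx for idx, n in hits.items() if n >= need}
    return best


def em_expected_counts(
    table: CompatibilityTable, max_iter: int = 1000, tol: float = 1e-8
) -> tuple[dict[str, float], list[float]]:
    """EM assignment of multi-mapping fragments to transcripts.

    E-step: each fragment splits over its compatible transcripts
    proportionally to ``theta_t / efflen_t``; M-step: ``theta`` is
    renormalized from the expected counts. Iterates until the max
    absolute change in theta falls below ``tol``. Returns the expected
    counts and the per-iteration observed-data log-likelihoods.

    Expected counts sum to the number of mapped fragments at every
    iteration; the log-likelihood is non-decreasing.
    """
    if table.n_fragments == 0:
        raise ValueError("empty compatibility table")
    tids = table.transcript_ids
    if table.n_mapped == 0:
        warnings.warn("all fragments unmapped; returning zero counts")
        return {t: 0.0 for t in tids}, []
    idx_of = {t: i for i, t in enumerate(tids)}
    efflen = np.array([table.effective_length[t] for t in tids])
    classes = [
        (np.fromiter((idx_of[t] for t in cls), dtype=np.int64), n)
        for cls, n in sorted(
            table.class_counts.items(), key=lambda kv: sorted(kv[0])
        )
    ]
    n_mapped = table.n_mapped
    theta = np.full(len(tids), 1.0 / len(tids))
    loglik: list[float] = []
    for _ in range(max_iter):
        counts = np.zeros(len(tids))
        ll = 0.0
        for members, n in classes:
            w = theta[members] / efflen[members]
            z = w.sum()
            counts[members] += n * (w / z)
            ll += n * np.log(z)
        loglik.append(float(ll))
        new_theta = counts / n_mapped
        delta = float(np.max(np.abs(new_theta - theta)))
        theta = new_theta
        if delta < tol:
            break
    counts = theta * n_mapped
    return {t: float(c) for t, c in zip(tids, counts)}, loglik


def fpkm(expected_count: float, effective_length_nt: float, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of effective length per million mapped."""
    if effective_length_nt < 1:
        raise ValueError("effective_length_nt must be >= 1")
    if total_mapped_fragments < 1:
        raise ValueError("total_mapped_fragments must be >= 1")
    return expected_count / ((effective_length_nt / 1e3) * (total_mapped_fragments / 1e6))


def gene_level(
    transcript_counts: dict[str, float],
    effective_length: dict[str, float],
    genes_trans_map: dict[str, str],
    total_mapped_fragments: int,
) -> dict[str, float]:
    """Aggregate transcript counts to gene FPKM.

    Gene expected count is the sum over member transcripts; gene
    effective length is the count-weighted mean of member effective
    lengths (unweighted mean when the gene has zero counts).
    """
    gene_counts: dict[str, float] = {}
    gene_lens: dict[str, list[tuple[float, float]]] = {}
    for tid, count in transcript_counts.items():
        gene = genes_trans_map.get(tid)
        if gene is None:
            if count > 0:
                raise ValueError(f"transcript {tid!r} with nonzero count is not in the gene map")
            continue
        gene_counts[gene] = gene_counts.get(gene, 0.0) + count
        gene_lens.setdefault(gene, []).append((count, effective_length[tid]))
    out: dict[str, float] = {}
    for gene, pairs in gene_lens.items():
        total_count = gene_counts[gene]
        if total_count > 0:
            efflen = sum(c * l for c, l in pairs) / total_count
        else:
            efflen = sum(l for _, l in pairs) / len(pairs)
        out[gene] = fpkm(total_count, max(efflen, 1.0), total_mapped_fragments)
    return out


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM plus the heat-map transform and breakpoints."""

    fpkm: pd.DataFrame
    transformed: pd.DataFrame = field(init=False)
    breakpoints: dict[str, tuple[float, float, float]] = field(init=False)
    degenerate_samples: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.transformed = np.log2(self.fpkm + 1.0)
        self.breakpoints = {}
        self.degenerate_samples = []
        for sample in self.transformed.columns:
            col = self.transformed[sample].to_numpy(dtype=float)
            mid = float(np.percentile(col, 75))  # linear interpolation
            hi = float(col.max())
            self.breakpoints[sample] = (1.0, mid, hi)
            if hi <= 0:
                self.degenerate_samples.append(sample)


def heatmap_matrix(gene_fpkm: pd.DataFrame) -> ExpressionMatrix:
    """Build the per-sample-scaled heat-map matrix from gene FPKM values."""
    return ExpressionMatrix(gene_fpkm.astype(float))


def family_share(
    gene_fpkm: pd.DataFrame, family_of_gene: dict[str, str]
) -> pd.DataFrame:
    """Per-family percent of summed FPKM, per sample.

    Families must partition the annotated genes; shares sum to 100 per
    sample. A sample with zero total FPKM yields NaN shares (flagged via
    the result itself).
    """
    missing = set(gene_fpkm.index) - set(family_of_gene)
    if missing:
        raise ValueError(f"genes without family assignment: {sorted(missing)[:5]}")
    fam = pd.Series({g: family_of_gene[g] for g in gene_fpkm.index})
    sums = gene_fpkm.groupby(fam).sum()
    totals = gene_fpkm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = sums.div(totals, axis=1) * 100.0
    return shares
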