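"""Ground-truthed synthetic transcriptomes and read sets.

Builds small transcriptomes with planted gene-family members at
controlled amino-acid divergence, complete and truncated ORFs, UTRs,
near-duplicate isoforms and unrelated decoys, plus paired-end reads drawn
from a per-transcript abundance vector with optional adaptor, N-content
and low-quality contamination. Everything is deterministic under a seed.

Family members are generated by mutating a common ancestor peptide with
substitutions only (no indels), so members of a family share a length and
their ungapped stacking is a true multiple alignment; coding sequences
are reverse-translated with uniform synonymous codon choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

from .io_formats import ReadPair, TranscriptRecord
from .orf_translate import reverse_complement, translate

__all__ = [
    "FamilySpec",
    "PlantEntry",
    "PlantingTruth",
    "ReadTruth",
    "make_family_reference",
    "mutate_peptide",
    "reverse_translate",
    "plant_transcriptome",
    "simulate_reads",
    "DEFAULT_ADAPTOR",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_ADAPTOR = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

# aa -> list of synonymous codons (standard code)
SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    SYNONYMOUS.setdefault(_aa, []).append(_codon)
for _aa in SYNONYMOUS:
    SYNONYMOUS[_aa].sort()
STOP_CODONS = sorted(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one planted gene family."""

    family_id: str
    n_members: int
    mean_orf_len_aa: int
    aa_divergence: float
    seed: int = 0
    len_sd_aa: float | None = None  # defaults to 3% of the mean

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0 <= self.aa_divergence < 1:
            raise ValueError("aa_divergence must be in [0, 1)")
        if self.mean_orf_len_aa < 30:
            raise ValueError("mean_orf_len_aa must be >= 30")


@dataclass(frozen=True)
class PlantEntry:
    family_id: str
    member_id: str
    completeness_class: str  # complete | partial5 | partial3 | internal | decoy
    planted_orf_coords: tuple[int, int]  # 0-based half-open, forward strand
    strand: str
    peptide: str  # planted (possibly truncated) peptide, empty for decoys


@dataclass
class PlantingTruth:
    """transcript_id -> what was planted there."""

    entries: dict[str, PlantEntry] = field(default_factory=dict)

    def __getitem__(self, tid: str) -> PlantEntry:
        return self.entries[tid]

    def non_decoys(self) -> dict[str, PlantEntry]:
        return {t: e for t, e in self.entries.items() if e.completeness_class != "decoy"}


@dataclass
class ReadTruth:
    """True provenance of a simulated read set."""

    theta: np.ndarray
    transcript_ids: list[str]
    counts: dict[str, int]
    sources: list[str]  # source transcript per fragment, in emission order

    def __post_init__(self) -> None:
        if abs(float(self.theta.sum()) - 1.0) > 1e-9:
            raise ValueError("theta must sum to 1")


def _divergence_to_rate(d: float) -> float:
    """Per-lineage substitution rate giving expected pairwise divergence d.

    Two members mutate independently from the ancestor at rate r to a
    uniformly chosen different residue; solving
    d = 2*r - (20/19)*r**2 for r.
    """
    if d == 0:
        return 0.0
    a = 20.0 / 19.0
    return (1.0 - math.sqrt(1.0 - a * d)) / a


def mutate_peptide(pep: str, rate: float, rng: np.random.Generator, keep_first: bool = True) -> str:
    """Substitute each site with probability ``rate`` (uniform different aa)."""
    out = list(pep)
    start = 1 if keep_first else 0
    for i in range(start, len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_family_reference(spec: FamilySpec) -> tuple[dict[str, str], dict[tuple[str, str], float]]:
    """Generate a family's member peptides plus a pairwise-identity report.

    Returns ``({member_id: peptide}, {(id_a, id_b): identity})``. Every
    peptide begins with M and all members share the (randomly drawn)
    family length, so identities are plain per-site agreement fractions.
    """
    rng = np.random.default_rng(spec.seed)
    sd = spec.len_sd_aa if spec.len_sd_aa is not None else 0.03 * spec.mean_orf_len_aa
    length = max(30, int(round(rng.normal(spec.mean_orf_len_aa, sd))))
    ancestor = "M" + "".join(
        AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for _ in range(length - 1)
    )
    rate = _divergence_to_rate(spec.aa_divergence)
    members = {
        f"{spec.family_id}{i + 1}": mutate_peptide(ancestor, rate, rng)
        for i in range(spec.n_members)
    }
    ids = list(members)
    report = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            same = sum(x == y for x, y in zip(members[a], members[b]))
            report[(a, b)] = same / length
    return members, report


def reverse_translate(pep: str, rng: np.random.Generator, with_stop: bool = True) -> str:
    """Back-translate a peptide with uniform synonymous codon choice."""
    codons = [SYNONYMOUS[aa][rng.integers(len(SYNONYMOUS[aa]))] for aa in pep]
    if with_stop:
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def _random_nt(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)]) if n else ""


def _gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.5


def plant_transcriptome(
    families: list[FamilySpec],
    completeness_mix: dict[str, float] | None = None,
    utr_len_range: tuple[int, int] = (20, 150),
    n_decoys: int = 0,
    near_duplicate_rate: float = 0.0,
    seed: int = 0,
    members_override: dict[str, dict[str, str]] | None = None,
) -> tuple[list[TranscriptRecord], PlantingTruth]:
    """Plant family members into a synthetic transcriptome.

    Each member is reverse-translated, wrapped in UTRs and truncated
    according to its sampled completeness class; near-duplicates copy a
    planted transcript with <= 2% substitutions (and at most a slight 3'
    trim) and share its gene id; decoys are random sequence with GC
    matched to the planted transcripts within 5%.

    ``members_override`` replaces the generated peptides of selected
    families (``{family_id: {member_id: peptide}}``) — used to build
    hand-constructed scenarios such as stepping-stone chains.
    """
    mix = completeness_mix or {"complete": 1.0}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("completeness_mix must sum to 1")
    bad_classes = set(mix) - {"complete", "partial5", "partial3", "internal"}
    if bad_classes:
        raise ValueError(f"unknown completeness classes: {sorted(bad_classes)}")
    if utr_len_range[0] < 0 or utr_len_range[1] < utr_len_range[0]:
        raise ValueError("utr_len_range must be a non-negative, ordered range")
    if not 0 <= near_duplicate_rate <= 1:
        raise ValueError("near_duplicate_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes])

    records: list[TranscriptRecord] = []
    truth = PlantingTruth()
    for fam in families:
        if members_override and fam.family_id in members_override:
            members = members_override[fam.family_id]
        else:
            members, _ = make_family_reference(fam)
        for member_id, pep in members.items():
            cls = classes[rng.choice(len(classes), p=probs)]
            rec, entry = _build_plant(fam.family_id, member_id, pep, cls, utr_len_range, rng)
            records.append(rec)
            truth.entries[rec.transcript_id] = entry

    # near-duplicate isoforms of planted transcripts
    planted = list(records)
    for rec in planted:
        if rng.random() < near_duplicate_rate:
            dup, entry = _make_near_duplicate(rec, truth.entries[rec.transcript_id], rng)
            records.append(dup)
            truth.entries[dup.transcript_id] = entry

    # decoys with matched GC and lengths
    if records:
        gc = _gc_content("".join(r.sequence for r in records))
        lengths = [len(r.sequence) for r in records]
    else:
        gc, lengths = 0.5, [500]
    for i in range(n_decoys):
        n = int(rng.integers(min(lengths), max(lengths) + 1))
        gc_i = float(np.clip(gc + rng.uniform(-0.05, 0.05), 0.05, 0.95))
        tid = f"decoy{i + 1:03d}"
        records.append(TranscriptRecord(tid, _random_nt(n, rng, gc_i), gene_id=tid))
        truth.entries[tid] = PlantEntry("", "", "decoy", (0, 0), "+", "")
    return records, truth


def _build_plant(
    family_id: str,
    member_id: str,
    pep: str,
    cls: str,
    utr_len_range: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[TranscriptRecord, PlantEntry]:
    cds = reverse_translate(pep, rng, with_stop=True)  # includes stop codon
    naa = len(pep)
    lo, hi = utr_len_range
    utr5 = _random_nt(int(rng.integers(lo, hi + 1)), rng)
    if len(utr5) >= 3:
        # in-frame stop immediately upstream of the ORF so UTR ATGs cannot
        # extend the planted reading frame
        utr5 = utr5[:-3] + STOP_CODONS[rng.integers(len(STOP_CODONS))]
    utr3 = _random_nt(int(rng.integers(lo, hi + 1)), rng)
    if cls == "complete":
        seq = utr5 + cds + utr3
        coords = (len(utr5), len(utr5) + len(cds))
        planted_pep = pep
    elif cls == "partial5":
        k = _cut_codons(naa, rng)
        seq = cds[3 * k :] + utr3  # starts in-frame at the transcript edge
        coords = (0, len(cds) - 3 * k)
        planted_pep = pep[k:]
    elif cls == "partial3":
        k = _cut_codons(naa, rng)
        body = cds[: 3 * (naa - k)]  # stop and last k codons lost
        seq = utr5 + body
        coords = (len(utr5), len(utr5) + len(body))
        planted_pep = pep[: naa - k]
    elif cls == "internal":
        a = _cut_codons(naa, rng)
        b = _cut_codons(naa, rng)
        body = cds[3 * a : 3 * (naa - b)]
        seq = body
        coords = (0, len(body))
        planted_pep = pep[a : naa - b]
    else:  # pragma: no cover - guarded upstream
        raise ValueError(cls)
    tid = f"t_{family_id}_{member_id}"
    gene = f"g_{family_id}_{member_id}"
    return TranscriptRecord(tid, seq, gene_id=gene), PlantEntry(
        family_id, member_id, cls, coords, "+", planted_pep
    )


def _cut_codons(naa: int, rng: np.random.Generator) -> int:
    """Codons removed by a truncation: 5-25% of the ORF, at least one."""
    return max(1, int(round(naa * rng.uniform(0.05, 0.25))))


def _make_near_duplicate(
    rec: TranscriptRecord, entry: PlantEntry, rng: np.random.Generator
) -> tuple[TranscriptRecord, PlantEntry]:
    seq = rec.sequence
    # trim at most 1% from the 3' end, never into the planted ORF
    max_trim = min(len(seq) // 100, len(seq) - entry.planted_orf_coords[1])
    trim = int(rng.integers(0, max_trim + 1)) if max_trim > 0 else 0
    seq = seq[: len(seq) - trim] if trim else seq
    n_edits = int(rng.integers(0, len(seq) // 100 + 1))  # <= 1% substitutions
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_edits, replace=False):
        choices = [c for c in "ACGT" if c != out[pos]]
        out[pos] = choices[rng.integers(3)]
    dup_id = rec.transcript_id + "_dup"
    return TranscriptRecord(dup_id, "".join(out), gene_id=rec.gene_id), PlantEntry(
        entry.family_id, entry.member_id, entry.completeness_class,
        entry.planted_orf_coords, entry.strand, entry.peptide,
    )


def simulate_reads(
    transcripts: list[TranscriptRecord],
    theta: np.ndarray,
    n_fragments: int,
    read_len: int = 90,
    insert_mean: int = 200,
    insert_sd: int = 20,
    error_rate: float = 0.0,
    adaptor_rate: float = 0.0,
    nfrac_rate: float = 0.0,
    lowq_rate: float = 0.0,
    adaptor: str = DEFAULT_ADAPTOR,
    seed: int = 0,
) -> tuple[list[ReadPair], ReadTruth]:
    """Draw paired fragments from an abundance vector.

    Fragments are assigned to transcripts multinomially with probability
    proportional to ``theta * effective_length``; mate 1 reads the 5' end
    of the fragment, mate 2 the reverse complement of its 3' end.
    Contamination knobs independently mark fragments to receive an adaptor
    prefix, > 5% N bases, or > 50% of bases below Q10 (on one random mate).
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    theta = np.asarray(theta, dtype=float)
    if len(theta) != len(transcripts):
        raise ValueError("theta length must match transcript count")
    if abs(theta.sum() - 1.0) > 1e-9 or (theta < 0).any():
        raise ValueError("theta must be a simplex over the transcripts")
    shortest = min(len(t.sequence) for t in transcripts)
    if read_len >= shortest:
        raise ValueError("read_len must be shorter than the shortest transcript")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(t.sequence) for t in transcripts])
    efflen = np.maximum(lengths - insert_mean + 1, 1)
    weights = theta * efflen
    total = weights.sum()
    if total <= 0:
        raise ValueError("theta puts no mass on any transcript")
    counts_vec = rng.multinomial(n_fragments, weights / total)

    pairs: list[ReadPair] = []
    sources: list[str] = []
    base_qual = chr(33 + 40) * read_len
    frag_no = 0
    for t_idx, count in enumerate(counts_vec):
        seq = transcripts[t_idx].sequence
        tid = transcripts[t_idx].transcript_id
        L = len(seq)
        for _ in range(count):
            insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)), read_len, L))
            start = int(rng.integers(0, L - insert + 1))
            frag = seq[start : start + insert]
            s1 = frag[:read_len]
            s2 = reverse_complement(frag)[:read_len]
            if error_rate > 0:
                s1 = _add_errors(s1, error_rate, rng)
                s2 = _add_errors(s2, error_rate, rng)
            q1 = q2 = base_qual
            if rng.random() < adaptor_rate:
                if rng.random() < 0.5:
                    s1 = (adaptor + s1)[:read_len]
                else:
                    s2 = (adaptor + s2)[:read_len]
            if rng.random() < nfrac_rate:
                n_n = int(math.ceil(0.08 * read_len))  # safely above the 5% bar
                pos = rng.choice(read_len, size=n_n, replace=False)
                target = list(s1) if rng.random() < 0.5 else None
                if target is not None:
                    for p in pos:
                        target[p] = "N"
                    s1 = "".join(target)
                else:
                    target = list(s2)
                    for p in pos:
                        target[p] = "N"
                    s2 = "".join(target)
            if rng.random() < lowq_rate:
                n_lq = int(math.ceil(0.6 * read_len))  # safely above the 50% bar
                pos = set(rng.choice(read_len, size=n_lq, replace=False).tolist())
                lowq = "".join(
                    chr(33 + 2) if i in pos else c for i, c in enumerate(base_qual)
                )
                if rng.random() < 0.5:
                    q1 = lowq
                else:
                    q2 = lowq
            frag_no += 1
            pairs.append(ReadPair(f"frag{frag_no:07d}", s1, q1, s2, q2))
            sources.append(tid)
    counts = {t.transcript_id: 0 for t in transcripts}
    for t_idx, count in enumerate(counts_vec):
        counts[transcripts[t_idx].transcript_id] = int(count)
    truth = ReadTruth(theta, [t.transcript_id for t in transcripts], counts, sources)
    return pairs, truth


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    out = list(read)
    for pos in rng.choice(len(read), size=n_err, replace=False):
        if out[pos] == "N":
            continue
        choices = [c for c in "ACGT" if c != out[pos]]
        out[pos] = choices[rng.integers(3)]
    return "".join(out)


def genes_trans_map_of(records: list[TranscriptRecord]) -> dict[str, str]:
    """``{transcript_id: gene_id}`` for a planted transcript set."""
    return {r.transcript_id: (r.gene_id or r.transcript_id) for r in records}
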