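"""Iterative gene-family annotation over a collapsed transcriptome.

Round 0 matches previously annotated (known) reference proteins to their
top-hit gene clusters. Each later round examines homology hits that do
not correlate to an already-annotated gene: candidates whose best ORF
exceeds half the family's average complete-ORF length (strictly) and that
are not interrupted by in-frame stops become novel records and their
peptides join the query set; the procedure stops at a fixpoint (a round
that adds nothing) or at ``max_rounds``.

Family length policies default to the averages used for the chemosensory
families (OR 406, GR 447, IR 676, OBP 178, CSP 132, CXE 563, CYP 510 aa);
arbitrary user-defined families are accepted with explicit averages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .homology_search import (
    NO_HIT,
    HomologyHit,
    SearchConfig,
    TranslatedDatabase,
    search,
    top_hit_transcript,
)
from .io_formats import TranscriptRecord
from .orf_translate import OrfCall, classify_against_hit, find_orfs, frame_codon_span

__all__ = [
    "DEFAULT_FAMILY_AVG_ORF_AA",
    "FamilyPolicy",
    "AnnotationRecord",
    "length_filter",
    "match_known",
    "iterate_annotation",
    "propose_collapses",
    "assign_names",
]

DEFAULT_FAMILY_AVG_ORF_AA: dict[str, int] = {
    "OR": 406,
    "GR": 447,
    "IR": 676,
    "OBP": 178,
    "CSP": 132,
    "CXE": 563,
    "CYP": 510,
}


@dataclass(frozen=True)
class FamilyPolicy:
    """Per-family acceptance policy for novel candidates."""

    family_id: str
    avg_complete_orf_len_aa: int = 0  # 0 -> look up the family default
    min_fraction: float = 0.5
    known_identity_floor: float = 0.98

    def __post_init__(self) -> None:
        if self.avg_complete_orf_len_aa == 0:
            if self.family_id not in DEFAULT_FAMILY_AVG_ORF_AA:
                raise ValueError(
                    f"no default average ORF length for family {self.family_id!r}"
                )
            object.__setattr__(
                self, "avg_complete_orf_len_aa", DEFAULT_FAMILY_AVG_ORF_AA[self.family_id]
            )
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.avg_complete_orf_len_aa <= 0:
            raise ValueError("avg_complete_orf_len_aa must be positive")


@dataclass(frozen=True)
class AnnotationRecord:
    name: str
    family_id: str
    gene_id: str
    transcript_id: str
    best_orf: OrfCall | None
    status: str  # known | novel | flagged_pseudogenized | collapsed_alias | not_found
    discovered_in_iteration: int
    evidence: HomologyHit | None


def length_filter(candidate: OrfCall, policy: FamilyPolicy) -> bool:
    """Strict cutoff: pass iff length > min_fraction * family average."""
    return candidate.length_aa > policy.min_fraction * policy.avg_complete_orf_len_aa


def _best_orf_for_hit(
    transcript: TranscriptRecord, hit: HomologyHit, query_len: int, min_len_aa: int = 10
) -> OrfCall | None:
    """The ORF on the hit's frame that best overlaps its subject interval,
    with completeness refined against the alignment."""
    best: OrfCall | None = None
    best_key: tuple[int, int] | None = None
    for orf in find_orfs(transcript, min_len_aa=min_len_aa):
        if orf.frame != hit.frame:
            continue
        span = frame_codon_span(orf, len(transcript.sequence))
        overlap = min(span[1], hit.subject_interval[1]) - max(span[0], hit.subject_interval[0])
        if overlap <= 0:
            continue
        key = (overlap, orf.length_aa)
        if best_key is None or key > best_key:
            best, best_key = orf, key
    if best is None:
        return None
    return classify_against_hit(best, hit, query_len, len(transcript.sequence))


class _Workspace:
    """Shared state across annotation rounds."""

    def __init__(
        self,
        transcripts: Sequence[TranscriptRecord],
        config: SearchConfig,
        min_len_aa: int,
    ):
        self.db = TranslatedDatabase(list(transcripts))
        self.by_id = {t.transcript_id: t for t in transcripts}
        self.config = config
        self.min_len_aa = min_len_aa
        self.hits: list[HomologyHit] = []
        self.query_family: dict[str, str] = {}
        self.query_len: dict[str, int] = {}

    def run_queries(self, queries: Mapping[str, str], family_of: Mapping[str, str]) -> None:
        if not queries:
            return
        self.hits.extend(search(queries, self.db, self.config))
        self.query_family.update(family_of)
        self.query_len.update({q: len(p) for q, p in queries.items()})


def match_known(
    known_refs: Mapping[str, Mapping[str, str]],
    transcripts: Sequence[TranscriptRecord],
    policies: Mapping[str, FamilyPolicy],
    config: SearchConfig | None = None,
    min_len_aa: int = 10,
) -> tuple[list[AnnotationRecord], list[str]]:
    """Round-0 matching of known reference proteins to gene clusters.

    Returns the records plus a list of collapse proposals (two known genes
    resolving to one gene cluster with overlapping hit spans are reported,
    never silently merged).
    """
    config = config or SearchConfig()
    ws = _Workspace(transcripts, config, min_len_aa)
    queries, family_of = _flatten_refs(known_refs)
    ws.run_queries(queries, family_of)
    records = _match_known_round(ws, known_refs, policies)
    proposals = _known_collapse_proposals(records)
    return records, proposals


def _flatten_refs(
    known_refs: Mapping[str, Mapping[str, str]]
) -> tuple[dict[str, str], dict[str, str]]:
    queries: dict[str, str] = {}
    family_of: dict[str, str] = {}
    for family, refs in known_refs.items():
        for name, pep in refs.items():
            if name in queries:
                raise ValueError(f"duplicate reference name {name!r}")
            queries[name] = pep
            family_of[name] = family
    return queries, family_of


def _match_known_round(
    ws: _Workspace,
    known_refs: Mapping[str, Mapping[str, str]],
    policies: Mapping[str, FamilyPolicy],
) -> list[AnnotationRecord]:
    records: list[AnnotationRecord] = []
    for family, refs in known_refs.items():
        policy = policies[family]
        for name in refs:
            gene = top_hit_transcript(name, ws.hits)
            if gene is NO_HIT:
                records.append(
                    AnnotationRecord(name, family, "", "", None, "not_found", 0, None)
                )
                continue
            best = min(
                (h for h in ws.hits if h.query_id == name),
                key=lambda h: (h.evalue, -h.pct_identity, h.transcript_id),
            )
            orf = _best_orf_for_hit(
                ws.by_id[best.transcript_id], best, ws.query_len[name], ws.min_len_aa
            )
            qualifying = orf is not None and length_filter(orf, policy)
            if best.contains_internal_stop and not qualifying:
                status = "flagged_pseudogenized"
            else:
                status = "known"
            records.append(
                AnnotationRecord(name, family, gene, best.transcript_id, orf, status, 0, best)
            )
    return records


def _known_collapse_proposals(records: Sequence[AnnotationRecord]) -> list[str]:
    proposals = []
    seen: dict[tuple[str, str], AnnotationRecord] = {}
    for rec in records:
        if not rec.gene_id:
            continue
        key = (rec.family_id, rec.gene_id)
        if key in seen:
            proposals.append(
                f"{rec.family_id}: {seen[key].name} and {rec.name} both resolve to "
                f"gene {rec.gene_id}"
            )
        else:
            seen[key] = rec
    return proposals


def iterate_annotation(
    transcripts: Sequence[TranscriptRecord],
    known_refs: Mapping[str, Mapping[str, str]],
    policies: Mapping[str, FamilyPolicy],
    config: SearchConfig | None = None,
    max_rounds: int = 10,
    min_len_aa: int = 10,
) -> tuple[list[AnnotationRecord], list[dict]]:
    """The full iterative annotation procedure.

    ``max_rounds`` counts novel-discovery rounds; ``max_rounds=1`` performs
    a single pass over the reference hits without re-searching with newly
    found members (iteration disabled).
    """
    config = config or SearchConfig()
    if not transcripts:
        return [], [{"round": 0, "n_new": 0, "n_queries": 0}]
    ws = _Workspace(transcripts, config, min_len_aa)
    queries, family_of = _flatten_refs(known_refs)
    ws.run_queries(queries, family_of)
    records = _match_known_round(ws, known_refs, policies)
    log: list[dict] = [
        {"round": 0, "n_new": len(records), "n_queries": len(queries)}
    ]
    annotated_genes: dict[str, set[str]] = {}
    names_in_use: dict[str, list[str]] = {}
    for rec in records:
        names_in_use.setdefault(rec.family_id, []).append(rec.name)
        if rec.gene_id:
            annotated_genes.setdefault(rec.family_id, set()).add(rec.gene_id)

    for round_no in range(1, max_rounds + 1):
        new_records = _novel_round(ws, policies, annotated_genes, round_no)
        named = []
        for family in sorted({r.family_id for r in new_records}):
            fam_new = [r for r in new_records if r.family_id == family]
            named.extend(
                assign_names(fam_new, family, names_in_use.get(family, []))
            )
        for rec in named:
            names_in_use.setdefault(rec.family_id, []).append(rec.name)
            annotated_genes.setdefault(rec.family_id, set()).add(rec.gene_id)
        records.extend(named)
        log.append(
            {"round": round_no, "n_new": len(named), "n_queries": len(ws.query_family)}
        )
        if not named:
            break
        if round_no == max_rounds:
            log.append({"round": round_no, "note": "max_rounds reached"})
            break
        # newly found members join the query set for the next round
        new_queries = {
            r.name: r.best_orf.peptide
            for r in named
            if r.status == "novel" and r.best_orf is not None
        }
        ws.run_queries(new_queries, {r.name: r.family_id for r in named if r.name in new_queries})
    return records, log


def _novel_round(
    ws: _Workspace,
    policies: Mapping[str, FamilyPolicy],
    annotated_genes: Mapping[str, set[str]],
    round_no: int,
) -> list[AnnotationRecord]:
    """Examine the cumulative hit table for unannotated gene clusters."""
    candidates: dict[tuple[str, str], HomologyHit] = {}
    for hit in ws.hits:
        family = ws.query_family[hit.query_id]
        if hit.gene_id in annotated_genes.get(family, set()):
            continue
        key = (family, hit.gene_id)
        prev = candidates.get(key)
        if prev is None or (hit.evalue, -hit.pct_identity) < (prev.evalue, -prev.pct_identity):
            candidates[key] = hit
    out: list[AnnotationRecord] = []
    for (family, gene_id), hit in sorted(
        candidates.items(), key=lambda kv: (kv[0][0], kv[1].evalue, kv[0][1])
    ):
        policy = policies[family]
        orf = _best_orf_for_hit(
            ws.by_id[hit.transcript_id], hit, ws.query_len[hit.query_id], ws.min_len_aa
        )
        qualifying = orf is not None and length_filter(orf, policy)
        if hit.contains_internal_stop and not qualifying:
            out.append(
                AnnotationRecord(
                    "", family, gene_id, hit.transcript_id, orf,
                    "flagged_pseudogenized", round_no, hit,
                )
            )
        elif qualifying:
            out.append(
                AnnotationRecord(
                    "", family, gene_id, hit.transcript_id, orf, "novel", round_no, hit
                )
            )
    return out


def propose_collapses(
    records: Sequence[AnnotationRecord],
    precedence: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[AnnotationRecord], list[str]]:
    """Merge same-family records resolving to one gene cluster.

    Records of one family whose evidence hits land on the same gene with
    mutually overlapping subject intervals are merged: the surviving name
    follows the user-configured precedence (first listed wins), falling
    back to lexicographic order; the others become ``collapsed_alias``.
    Disjoint spans (possible fusion transcripts) and cross-family
    proposals are reported, never auto-merged.
    """
    precedence = precedence or {}
    groups: dict[tuple[str, str], list[AnnotationRecord]] = {}
    passthrough: list[AnnotationRecord] = []
    for rec in records:
        if rec.gene_id and rec.status in ("known", "novel"):
            groups.setdefault((rec.family_id, rec.gene_id), []).append(rec)
        else:
            passthrough.append(rec)
    merged: list[AnnotationRecord] = []
    reports: list[str] = []
    for (family, gene_id), group in groups.items():
        if len(group) == 1:
            merged.append(group[0])
            continue
        overlapping, disjoint = _split_by_overlap(group)
        if disjoint:
            reports.append(
                f"warning: {family} records on gene {gene_id} have disjoint hit "
                f"spans ({', '.join(r.name for r in group)}); not collapsed"
            )
            merged.extend(group)
            continue
        order = list(precedence.get(family, []))

        def rank(rec: AnnotationRecord) -> tuple[int, str]:
            return (order.index(rec.name) if rec.name in order else len(order), rec.name)

        keeper = min(overlapping, key=rank)
        merged.append(keeper)
        for rec in overlapping:
            if rec is not keeper:
                merged.append(replace(rec, status="collapsed_alias"))
                reports.append(
                    f"{family}: {rec.name} collapsed into {keeper.name} (gene {gene_id})"
                )
    # cross-family co-location is only reported
    by_gene: dict[str, set[str]] = {}
    for rec in records:
        if rec.gene_id and rec.status in ("known", "novel"):
            by_gene.setdefault(rec.gene_id, set()).add(rec.family_id)
    for gene_id, fams in sorted(by_gene.items()):
        if len(fams) > 1:
            reports.append(
                f"warning: gene {gene_id} claimed by multiple families "
                f"({', '.join(sorted(fams))}); review required"
            )
    merged.extend(passthrough)
    return merged, reports


def _split_by_overlap(
    group: Sequence[AnnotationRecord],
) -> tuple[list[AnnotationRecord], bool]:
    """Check that every pair of records' hit spans mutually overlap."""
    spans = []
    for rec in group:
        hit = rec.evidence
        spans.append(hit.subject_interval if hit else (0, 0))
    disjoint = False
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            a, b = spans[i], spans[j]
            if min(a[1], b[1]) <= max(a[0], b[0]):
                disjoint = True
    return list(group), disjoint


def assign_names(
    novel_records: Sequence[AnnotationRecord],
    family: str,
    existing_names: Sequence[str],
) -> list[AnnotationRecord]:
    """Give unnamed records sequential names after the family inventory.

    The next free integer suffix continues the inventory (e.g. an
    inventory through 46 plus 14 novels yields 47..60); records are named
    in discovery order (iteration round, then E-value).
    """
    used: set[int] = set()
    for name in existing_names:
        if name.startswith(family):
            suffix = name[len(family):]
            if suffix.isdigit():
                used.add(int(suffix))
    next_no = max(used) + 1 if used else 1
    ordered = sorted(
        novel_records,
        key=lambda r: (
            r.discovered_in_iteration,
            r.evidence.evalue if r.evidence else 0.0,
            r.gene_id,
        ),
    )
    out: list[AnnotationRecord] = []
    taken = set(existing_names)
    for rec in ordered:
        if rec.name:
            if rec.name in taken:
                raise ValueError(f"name {rec.name!r} already in the {family} inventory")
            out.append(rec)
            taken.add(rec.name)
            continue
        while f"{family}{next_no}" in taken:
            next_no += 1
        name = f"{family}{next_no}"
        next_no += 1
        taken.add(name)
        out.append(replace(rec, name=name))
    return out
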