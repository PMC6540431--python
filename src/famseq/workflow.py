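"""Seed-pinned scenarios and end-to-end orchestration.

These helpers wire the synthetic generator to the annotation and
quantification stages: the default planted-family scenario used by the
recovery checks, the two-hop stepping-stone construction that requires
iterative searching, and a deterministic end-to-end run that writes the
annotation table, FPKM table and family tree to disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, phylo, redundancy, synthetic_data
from .family_annotation import (
    AnnotationRecord,
    FamilyPolicy,
    iterate_annotation,
    propose_collapses,
)
from .homology_search import SearchConfig
from .io_formats import TranscriptRecord, write_fasta
from .synthetic_data import FamilySpec, PlantingTruth, make_family_reference, mutate_peptide

__all__ = [
    "Scenario",
    "default_scenario",
    "stepping_stone_scenario",
    "recoverable_members",
    "annotated_members",
    "run_end_to_end",
]

DEFAULT_COMPLETENESS_MIX = {"complete": 0.8, "partial5": 0.1, "partial3": 0.1}


@dataclass
class Scenario:
    """A planted transcriptome bundled with everything annotation needs."""

    records: list[TranscriptRecord]
    truth: PlantingTruth
    known_refs: dict[str, dict[str, str]]
    policies: dict[str, FamilyPolicy]
    members: dict[str, dict[str, str]]  # family -> member -> peptide
    genes_trans_map: dict[str, str]


def default_scenario(
    seed: int = 0,
    n_members: int = 8,
    divergence: float = 0.3,
    n_decoys: int = 30,
    near_duplicate_rate: float = 0.05,
    n_known_per_family: int = 2,
    family_lengths: dict[str, int] | None = None,
) -> Scenario:
    """Four families at controlled divergence with partials, decoys and
    near-duplicate isoforms; the first few members per family serve as the
    previously annotated references."""
    lengths = family_lengths or {"OBP": 178, "CSP": 132, "OR": 406, "GR": 447}
    specs = [
        FamilySpec(fam, n_members, mean_len, divergence, seed=seed + i)
        for i, (fam, mean_len) in enumerate(sorted(lengths.items()))
    ]
    members = {spec.family_id: make_family_reference(spec)[0] for spec in specs}
    records, truth = synthetic_data.plant_transcriptome(
        specs,
        completeness_mix=DEFAULT_COMPLETENESS_MIX,
        n_decoys=n_decoys,
        near_duplicate_rate=near_duplicate_rate,
        seed=seed,
        members_override=members,
    )
    known_refs = {
        fam: dict(list(peps.items())[:n_known_per_family]) for fam, peps in members.items()
    }
    policies = {fam: FamilyPolicy(fam, lengths[fam]) for fam in lengths}
    return Scenario(
        records,
        truth,
        known_refs,
        policies,
        members,
        synthetic_data.genes_trans_map_of(records),
    )


def stepping_stone_scenario(seed: int = 0, mean_len: int = 120) -> Scenario:
    """A three-member chain R -> A -> B where B is reachable from the lone
    reference R only through the intermediate member A.

    Per-lineage substitution rates of 0.5 leave R and B ~25% identical —
    below detectability at the default E-value cutoff — while R-A and A-B
    stay ~50% identical and strongly detectable.
    """
    rng = np.random.default_rng(seed)
    length = mean_len
    ref = "M" + "".join(
        synthetic_data.AMINO_ACIDS[rng.integers(20)] for _ in range(length - 1)
    )
    a = mutate_peptide(ref, 0.5, rng)
    b = mutate_peptide(a, 0.5, rng)
    members = {"STP": {"STP1": ref, "STP2": a, "STP3": b}}
    spec = FamilySpec("STP", 3, mean_len, 0.0, seed=seed)
    records, truth = synthetic_data.plant_transcriptome(
        [spec],
        completeness_mix={"complete": 1.0},
        n_decoys=10,
        seed=seed,
        members_override=members,
    )
    return Scenario(
        records,
        truth,
        {"STP": {"STP1": ref}},
        {"STP": FamilyPolicy("STP", mean_len)},
        members,
        synthetic_data.genes_trans_map_of(records),
    )


def recoverable_members(
    scenario: Scenario,
) -> set[tuple[str, str]]:
    """(family, member) pairs whose planted ORF can pass the family length
    filter on at least one of their transcripts (known references are
    always recoverable via round-0 matching)."""
    out: set[tuple[str, str]] = set()
    for entry in scenario.truth.non_decoys().values():
        policy = scenario.policies[entry.family_id]
        known = entry.member_id in scenario.known_refs.get(entry.family_id, {})
        if known or len(entry.peptide) > policy.min_fraction * policy.avg_complete_orf_len_aa:
            out.add((entry.family_id, entry.member_id))
    return out


def annotated_members(
    scenario: Scenario, records: list[AnnotationRecord]
) -> set[tuple[str, str]]:
    """(family, member) pairs covered by a known/novel annotation record."""
    gene_to_members: dict[str, set[tuple[str, str]]] = {}
    for tid, entry in scenario.truth.non_decoys().items():
        gene = scenario.genes_trans_map[tid]
        gene_to_members.setdefault(gene, set()).add((entry.family_id, entry.member_id))
    out: set[tuple[str, str]] = set()
    for rec in records:
        if rec.status in ("known", "novel") and rec.gene_id:
            for fam, member in gene_to_members.get(rec.gene_id, set()):
                if fam == rec.family_id:
                    out.add((fam, member))
    return out


def decoy_annotations(scenario: Scenario, records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    decoy_genes = {
        scenario.genes_trans_map[tid]
        for tid, e in scenario.truth.entries.items()
        if e.completeness_class == "decoy"
    }
    return [r for r in records if r.gene_id in decoy_genes and r.status in ("known", "novel")]


def annotation_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "name": rec.name,
                "family": rec.family_id,
                "gene_id": rec.gene_id,
                "transcript_id": rec.transcript_id,
                "status": rec.status,
                "round": rec.discovered_in_iteration,
                "orf_length_aa": rec.best_orf.length_aa if rec.best_orf else 0,
                "completeness": rec.best_orf.completeness if rec.best_orf else "",
                "evalue": rec.evidence.evalue if rec.evidence else float("nan"),
                "identity": rec.evidence.pct_identity if rec.evidence else float("nan"),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(["family", "name", "status"]).reset_index(drop=True)


def run_end_to_end(seed: int, outdir: str | Path, *, small: bool = True) -> dict[str, Path]:
    """Simulate, collapse, annotate, quantify and build a tree; write the
    annotation TSV, FPKM TSV and Newick outputs. Deterministic per seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if small:
        scenario = default_scenario(
            seed=seed,
            n_members=4,
            n_decoys=10,
            family_lengths={"OBP": 178, "CSP": 132},
        )
    else:
        scenario = default_scenario(seed=seed)

    clusters = redundancy.collapse(scenario.records)
    reps = clusters.representatives
    records, _log = iterate_annotation(
        reps, scenario.known_refs, scenario.policies, SearchConfig()
    )
    records, _reports = propose_collapses(records)
    ann_path = outdir / "annotation.tsv"
    annotation_to_frame(records).to_csv(ann_path, sep="\t", index=False, float_format="%.6g")

    rng = np.random.default_rng(seed + 1)
    theta = rng.dirichlet(np.ones(len(reps)))
    read_len, insert_mean = 75, 180
    pairs, _read_truth = synthetic_data.simulate_reads(
        reps, theta, n_fragments=5000, read_len=read_len,
        insert_mean=insert_mean, insert_sd=15, error_rate=0.002, seed=seed + 2,
    )
    table = abundance.build_compatibility(pairs, reps, k=25, fragment_mean=insert_mean)
    counts, _ll = abundance.em_expected_counts(table)
    gene_fpkm = abundance.gene_level(
        counts, table.effective_length, scenario.genes_trans_map, table.n_mapped
    )
    fpkm_frame = pd.DataFrame({"sample1": pd.Series(gene_fpkm)}).sort_index()
    fpkm_path = outdir / "fpkm.tsv"
    fpkm_frame.to_csv(fpkm_path, sep="\t", float_format="%.6g")

    matrix = abundance.heatmap_matrix(fpkm_frame)
    (outdir / "breakpoints.json").write_text(
        json.dumps({s: list(bp) for s, bp in matrix.breakpoints.items()}, indent=2)
    )

    # family tree over the planted members of every family (true alignment:
    # members of a family share a length; pad families to a common width)
    seqs: dict[str, str] = {}
    width = max(len(p) for fam in scenario.members.values() for p in fam.values())
    for fam, peps in sorted(scenario.members.items()):
        for name, pep in peps.items():
            seqs[name] = pep + "-" * (width - len(pep))
    alignment = phylo.MultipleAlignment.from_dict(seqs)
    tree = phylo.bootstrap_support(alignment, n_replicates=50, seed=seed + 3)
    tree_path = outdir / "families.nwk"
    tree_path.write_text(tree.to_newick() + "\n")

    write_fasta(reps, outdir / "representatives.fasta")
    return {
        "annotation": ann_path,
        "fpkm": fpkm_path,
        "tree": tree_path,
        "breakpoints": outdir / "breakpoints.json",
        "representatives": outdir / "representatives.fasta",
    }
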