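from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famseq.abundance import (
    CompatibilityTable,
    build_compatibility,
    em_expected_counts,
    family_share,
    fpkm,
    gene_level,
    heatmap_matrix,
)
from famseq.io_formats import ReadPair, TranscriptRecord
from famseq.synthetic_data import simulate_reads

from _oracles import percentile_inc


def _random_records(rng, n, lo=600, hi=2000, prefix="t"):
    return [
        TranscriptRecord(f"{prefix}{i:02d}", "".join(rng.choice(list("ACGT"), int(rng.integers(lo, hi)))))
        for i in range(n)
    ]


class TestBuildCompatibility:
    def test_unique_source_unique_compatibility(self, rng):
        records = _random_records(rng, 3)
        pairs, truth = simulate_reads(records, np.array([1.0, 0, 0]), 200, read_len=80, seed=1)
        table = build_compatibility(pairs, records, fragment_mean=200)
        assert table.n_unmapped == 0
        assert set(table.class_counts) == {frozenset({"t00"})}

    def test_random_fragment_unmapped(self, rng):
        records = _random_records(rng, 2)
        alien = "".join(rng.choice(list("ACGT"), 80))
        pair = ReadPair("x", alien, "I" * 80, alien, "I" * 80)
        table = build_compatibility([pair], records, fragment_mean=200)
        assert table.n_unmapped == 1

    def test_near_identical_isoforms_shared(self, rng):
        base = "".join(rng.choice(list("ACGT"), 1200))
        iso = list(base)
        # a handful of substitutions: >99% identical; with k=25 a single
        # mismatch under a mate already erodes much of its k-mer containment
        for pos in rng.choice(1200, size=3, replace=False):
            iso[pos] = "A" if iso[pos] != "A" else "C"
        records = [TranscriptRecord("iso1", base), TranscriptRecord("iso2", "".join(iso))]
        pairs, _ = simulate_reads(records, np.array([0.5, 0.5]), 300, read_len=80, seed=2)
        table = build_compatibility(pairs, records, fragment_mean=200)
        both = table.class_counts.get(frozenset({"iso1", "iso2"}), 0)
        assert both / table.n_mapped > 0.5

    def test_substring_containment_oracle(self, rng):
        """Error-free fragments from distinct transcripts: compatibility
        equals the brute-force 'both mates are substrings' check."""
        records = _random_records(rng, 4)
        pairs, truth = simulate_reads(
            records, np.full(4, 0.25), 300, read_len=80, seed=3
        )
        table = build_compatibility(pairs, records, fragment_mean=200)
        from famseq.orf_translate import reverse_complement

        oracle = {}
        for pair in pairs:
            compat = frozenset(
                r.transcript_id
                for r in records
                if (pair.seq1 in r.sequence or reverse_complement(pair.seq1) in r.sequence)
                and (pair.seq2 in r.sequence or reverse_complement(pair.seq2) in r.sequence)
            )
            oracle[compat] = oracle.get(compat, 0) + 1
        assert table.class_counts == oracle

    def test_small_k_rejected(self, rng):
        records = _random_records(rng, 2)
        with pytest.raises(ValueError):
            build_compatibility([], records, k=4)


def _table(classes: dict[frozenset, int], efflens: dict[str, float]) -> CompatibilityTable:
    n = sum(classes.values())
    return CompatibilityTable(list(efflens), efflens, classes, n, 0)


class TestEm:
    def test_unique_mapping_counts_are_raw(self):
        table = _table(
            {frozenset({"a"}): 30, frozenset({"b"}): 70}, {"a": 500.0, "b": 1000.0}
        )
        counts, _ = em_expected_counts(table)
        assert counts == pytest.approx({"a": 30.0, "b": 70.0})

    def test_symmetric_sharing_splits_evenly(self):
        table = _table({frozenset({"a", "b"}): 100}, {"a": 800.0, "b": 800.0})
        counts, _ = em_expected_counts(table)
        assert counts["a"] == pytest.approx(50.0)
        assert counts["b"] == pytest.approx(50.0)

    def test_conservation_every_iteration(self):
        rng = np.random.default_rng(5)
        tids = [f"t{i}" for i in range(6)]
        classes = {}
        for _ in range(20):
            size = int(rng.integers(1, 4))
            cls = frozenset(rng.choice(tids, size=size, replace=False))
            classes[cls] = classes.get(cls, 0) + int(rng.integers(1, 50))
        efflens = {t: float(rng.integers(200, 2000)) for t in tids}
        table = _table(classes, efflens)
        # re-run EM manually to check conservation per iteration
        idx_of = {t: i for i, t in enumerate(tids)}
        efl = np.array([efflens[t] for t in tids])
        theta = np.full(len(tids), 1 / len(tids))
        n_mapped = table.n_mapped
        for _ in range(50):
            counts = np.zeros(len(tids))
            for cls, n in classes.items():
                members = np.array([idx_of[t] for t in cls])
                w = theta[members] / efl[members]
                counts[members] += n * w / w.sum()
            assert counts.sum() == pytest.approx(n_mapped)
            theta = counts / n_mapped
        final, _ = em_expected_counts(table)
        assert sum(final.values()) == pytest.approx(n_mapped)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(6)
        tids = [f"t{i}" for i in range(5)]
        classes = {
            frozenset({"t0", "t1"}): 40,
            frozenset({"t1", "t2", "t3"}): 30,
            frozenset({"t4"}): 30,
        }
        table = _table(classes, {t: float(rng.integers(300, 1500)) for t in tids})
        _, ll = em_expected_counts(table)
        assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))

    def test_parameter_recovery(self, rng):
        records = _random_records(rng, 20)
        theta = rng.dirichlet(np.ones(20))
        pairs, truth = simulate_reads(
            records, theta, 30_000, read_len=75, insert_mean=200,
            insert_sd=20, error_rate=0.002, seed=17,
        )
        table = build_compatibility(pairs, records, k=25, fragment_mean=200)
        counts, _ = em_expected_counts(table)
        efl = np.array([table.effective_length[r.transcript_id] for r in records])
        c = np.array([counts[r.transcript_id] for r in records])
        est = c / efl
        est /= est.sum()
        assert np.max(np.abs(est - theta)) <= 0.02

    def test_all_unmapped_warns_zero(self):
        table = CompatibilityTable(["a"], {"a": 100.0}, {}, 10, 10)
        with pytest.warns(UserWarning):
            counts, _ = em_expected_counts(table)
        assert counts == {"a": 0.0}


class TestFpkm:
    def test_closed_form(self):
        assert fpkm(10, 2000, 10**6) == pytest.approx(5.0)

    def test_zero_count(self):
        assert fpkm(0, 500, 1000) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fpkm(1, 500, 0)

    def test_matches_direct_formula(self, rng):
        for _ in range(50):
            c = float(rng.integers(0, 10**4))
            l = float(rng.integers(1, 10**4))
            t = int(rng.integers(1, 10**7))
            assert fpkm(c, l, t) == pytest.approx(c / ((l / 1e3) * (t / 1e6)))

    def test_scale_invariance(self, rng):
        # duplicating every fragment leaves FPKM unchanged
        c, l, t = 37.0, 812.0, 54_321
        assert fpkm(2 * c, l, 2 * t) == pytest.approx(fpkm(c, l, t))


class TestGeneLevel:
    def test_single_transcript_gene(self):
        out = gene_level({"t1": 10.0}, {"t1": 2000.0}, {"t1": "g1"}, 10**6)
        assert out["g1"] == pytest.approx(fpkm(10, 2000, 10**6))

    def test_weight_degeneracy(self):
        out = gene_level(
            {"t1": 10.0, "t2": 0.0}, {"t1": 1000.0, "t2": 4000.0},
            {"t1": "g1", "t2": "g1"}, 10**6,
        )
        assert out["g1"] == pytest.approx(fpkm(10, 1000, 10**6))

    def test_unmapped_transcript_with_counts_rejected(self):
        with pytest.raises(ValueError, match="t9"):
            gene_level({"t9": 5.0}, {"t9": 100.0}, {}, 1000)

    def test_weighted_formula_oracle(self, rng):
        counts = {f"t{i}": float(rng.integers(0, 100)) for i in range(9)}
        efflens = {f"t{i}": float(rng.integers(200, 3000)) for i in range(9)}
        gmap = {f"t{i}": f"g{i % 3}" for i in range(9)}
        total = 10**5
        out = gene_level(counts, efflens, gmap, total)
        for g in {"g0", "g1", "g2"}:
            members = [t for t, gg in gmap.items() if gg == g]
            csum = sum(counts[t] for t in members)
            if csum > 0:
                efl = sum(counts[t] * efflens[t] for t in members) / csum
            else:
                efl = sum(efflens[t] for t in members) / len(members)
            assert out[g] == pytest.approx(csum / ((efl / 1e3) * (total / 1e6)))


class TestHeatmap:
    def test_log_identities(self):
        frame = pd.DataFrame({"s": [0.0, 1.0, 7.0]}, index=["a", "b", "c"])
        matrix = heatmap_matrix(frame)
        assert list(matrix.transformed["s"]) == [0.0, 1.0, 3.0]

    def test_all_zero_sample_degenerate(self):
        frame = pd.DataFrame({"s": [0.0, 0.0]}, index=["a", "b"])
        matrix = heatmap_matrix(frame)
        assert matrix.breakpoints["s"] == (1.0, 0.0, 0.0)
        assert matrix.degenerate_samples == ["s"]

    def test_percentile_matches_sort_oracle(self, rng):
        values = rng.gamma(2.0, 50.0, size=100)
        frame = pd.DataFrame({"s": values}, index=[f"g{i}" for i in range(100)])
        matrix = heatmap_matrix(frame)
        transformed = list(np.log2(values + 1.0))
        assert matrix.breakpoints["s"][1] == pytest.approx(percentile_inc(transformed, 75))
        assert matrix.breakpoints["s"][2] == pytest.approx(max(transformed))
        assert matrix.breakpoints["s"][0] == 1.0

    def test_samples_have_independent_scales(self, rng):
        frame = pd.DataFrame(
            {"s1": rng.gamma(2, 10, 50), "s2": rng.gamma(2, 500, 50)},
            index=[f"g{i}" for i in range(50)],
        )
        matrix = heatmap_matrix(frame)
        assert matrix.breakpoints["s1"][2] != matrix.breakpoints["s2"][2]

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            heatmap_matrix(pd.DataFrame({"s": [-1.0]}, index=["a"]))


class TestFamilyShare:
    def test_single_family_is_100(self):
        frame = pd.DataFrame({"s": [2.0, 3.0]}, index=["g1", "g2"])
        shares = family_share(frame, {"g1": "F", "g2": "F"})
        assert shares.loc["F", "s"] == pytest.approx(100.0)

    def test_shares_sum_to_100(self, rng):
        frame = pd.DataFrame(
            {"s1": rng.gamma(2, 10, 12), "s2": rng.gamma(2, 10, 12)},
            index=[f"g{i}" for i in range(12)],
        )
        fam = {f"g{i}": f"F{i % 3}" for i in range(12)}
        shares = family_share(frame, fam)
        assert shares.sum(axis=0).to_numpy() == pytest.approx([100.0, 100.0])

    def test_planted_three_to_one_ratio(self, rng):
        records = _random_records(rng, 8)
        fam = {f"t{i:02d}": ("A" if i < 4 else "B") for i in range(8)}
        # family A carries 75% of the mass, family B 25%
        theta = np.array([0.1875] * 4 + [0.0625] * 4)
        pairs, _ = simulate_reads(records, theta, 20_000, read_len=75, seed=31)
        table = build_compatibility(pairs, records, fragment_mean=200)
        counts, _ = em_expected_counts(table)
        gmap = {t: t for t in fam}
        gene_fpkm = gene_level(counts, table.effective_length, gmap, table.n_mapped)
        frame = pd.DataFrame({"s": pd.Series(gene_fpkm)})
        shares = family_share(frame, fam)
        assert shares.loc["A", "s"] == pytest.approx(75.0, abs=4.0)
        assert shares.loc["B", "s"] == pytest.approx(25.0, abs=4.0)

    def test_missing_family_rejected(self):
        frame = pd.DataFrame({"s": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            family_share(frame, {})
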