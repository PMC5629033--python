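"""AP-MS scoring: NSAF, filter cascade, enrichment-index ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protpipe import (
    ApmsConfig,
    ProteinRecord,
    SpectralCountTable,
    ValidationError,
    compute_nsaf,
    filter_candidates,
    filter_localization,
    rank_by_enrichment_index,
    score_apms,
)
from protpipe.synthetic_data import SimulationConfig, simulate_apms


def brute_force_nsaf(rows: dict[str, tuple[int, int]]) -> dict[str, float]:
    """Independent NSAF oracle: (SpC/L) / sum(SpC/L) over bait-detected."""
    saf = {acc: spc / length for acc, (spc, length) in rows.items() if spc > 0}
    total = sum(saf.values())
    return {acc: v / total for acc, v in saf.items()}


def brute_force_filter(bait: int, control: int, uniq: int, cfg: ApmsConfig) -> bool:
    """Row-wise restatement of the evidence predicate."""
    if uniq < cfg.min_unique_peptides:
        return False
    if bait < cfg.min_spectra:
        return False
    if control == 0:
        return True
    return bait / control >= cfg.min_fold


class TestComputeNsaf:
    def test_single_protein_is_one(self):
        counts = SpectralCountTable.from_records([("P1", 10, 0, 2)])
        meta = [ProteinRecord("P1", "g", 500, "nuclear", 1.0)]
        assert compute_nsaf(counts, meta) == {"P1": pytest.approx(1.0)}

    def test_equal_length_normalized_counts_split_evenly(self):
        counts = SpectralCountTable.from_records([("P1", 10, 0, 2), ("P2", 20, 0, 2)])
        meta = [
            ProteinRecord("P1", "a", 100, "nuclear", 1.0),
            ProteinRecord("P2", "b", 200, "nuclear", 1.0),
        ]
        nsaf = compute_nsaf(counts, meta)
        assert nsaf["P1"] == pytest.approx(0.5)
        assert nsaf["P2"] == pytest.approx(0.5)

    def test_matches_brute_force_oracle_on_random_table(self):
        rng = np.random.default_rng(17)
        rows = {
            f"P{i:03d}": (int(rng.integers(0, 100)), int(rng.integers(100, 3000)))
            for i in range(50)
        }
        counts = SpectralCountTable.from_records(
            (acc, spc, 0, 2) for acc, (spc, _) in rows.items()
        )
        meta = [
            ProteinRecord(acc, "", length, "nuclear", 1.0)
            for acc, (_, length) in rows.items()
        ]
        nsaf = compute_nsaf(counts, meta)
        oracle = brute_force_nsaf(rows)
        assert set(nsaf) == set(oracle)
        for acc in oracle:
            assert nsaf[acc] == pytest.approx(oracle[acc], abs=1e-12)
        assert sum(nsaf.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_length_names_accession(self):
        counts = SpectralCountTable.from_records([("P1", 10, 0, 2)])
        with pytest.raises(ValidationError, match="P1"):
            compute_nsaf(counts, [])

    def test_scale_invariance_in_lengths(self):
        """Multiplying every length by a constant leaves NSAF unchanged."""
        rng = np.random.default_rng(3)
        spcs = rng.integers(1, 50, size=20)
        lengths = rng.integers(100, 1000, size=20)
        meta1 = [
            ProteinRecord(f"P{i}", "", int(l), "nuclear", 1.0)
            for i, l in enumerate(lengths)
        ]
        meta3 = [
            ProteinRecord(f"P{i}", "", int(l) * 3, "nuclear", 1.0)
            for i, l in enumerate(lengths)
        ]
        counts = SpectralCountTable.from_records(
            (f"P{i}", int(s), 0, 2) for i, s in enumerate(spcs)
        )
        a, b = compute_nsaf(counts, meta1), compute_nsaf(counts, meta3)
        for acc in a:
            assert a[acc] == pytest.approx(b[acc], rel=1e-12)


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "bait,control,uniq,expected",
        [
            (10, 0, 2, True),   # inclusive spectral-count floor
            (9, 0, 2, False),
            (40, 10, 2, True),  # inclusive 4-fold boundary
            (39, 10, 2, False),
            (10, 0, 1, False),  # unique-peptide floor
            (100, 30, 2, False),
            (120, 30, 2, True),
        ],
    )
    def test_threshold_boundaries(self, bait, control, uniq, expected):
        counts = SpectralCountTable.from_records([("P1", bait, control, uniq)])
        assert (("P1" in filter_candidates(counts, ApmsConfig())) is expected)

    def test_matches_predicate_oracle_on_boundary_grid(self):
        cfg = ApmsConfig()
        records = []
        expected = set()
        i = 0
        for bait in (0, 9, 10, 11, 39, 40, 41):
            for control in (0, 1, 2, 3, 10, 11):
                for uniq in (1, 2, 3):
                    acc = f"P{i:04d}"
                    i += 1
                    records.append((acc, bait, control, uniq))
                    if brute_force_filter(bait, control, uniq, cfg):
                        expected.add(acc)
        counts = SpectralCountTable.from_records(records)
        assert filter_candidates(counts, cfg) == expected

    @given(
        bait=st.integers(0, 200),
        control=st.integers(0, 60),
        uniq=st.integers(0, 6),
        bump_spectra=st.integers(0, 5),
        bump_fold=st.floats(0, 4),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_thresholds(self, bait, control, uniq, bump_spectra, bump_fold):
        """Raising min_spectra or min_fold never grows the retained set."""
        counts = SpectralCountTable.from_records([("P1", bait, control, uniq)])
        loose = filter_candidates(counts, ApmsConfig())
        tight = filter_candidates(
            counts,
            ApmsConfig(min_spectra=10 + bump_spectra, min_fold=4.0 + bump_fold),
        )
        assert tight <= loose


class TestFilterLocalization:
    def test_keeps_nuclear_and_unknown(self, small_counts, small_meta):
        out = filter_localization({"P0001", "P0002", "P0003"}, small_meta, ApmsConfig())
        assert out == {"P0001", "P0002"}

    def test_all_categories_allowed_is_identity(self, small_meta):
        cfg = ApmsConfig(allowed_localizations=frozenset({"nuclear", "unknown", "other"}))
        cands = {"P0001", "P0002", "P0003"}
        assert filter_localization(cands, small_meta, cfg) == cands

    def test_empty_candidates(self, small_meta):
        assert filter_localization(set(), small_meta, ApmsConfig()) == set()

    def test_missing_metadata_is_error(self, small_meta):
        with pytest.raises(ValidationError, match="P9999"):
            filter_localization({"P9999"}, small_meta, ApmsConfig())

    def test_order_independent_with_count_filter(self):
        """Localization and count filters commute (pure conjunction)."""
        cfg = ApmsConfig()
        counts, meta, _ = simulate_apms(SimulationConfig(seed=23))
        all_accs = set(counts.accessions)
        a = filter_localization(filter_candidates(counts, cfg), meta, cfg)
        b = filter_candidates(counts, cfg) & filter_localization(all_accs, meta, cfg)
        assert a == b


class TestRankByEnrichmentIndex:
    def _rank(self, candidates, nsaf, meta, counts, **kw):
        return rank_by_enrichment_index(candidates, nsaf, meta, counts, ApmsConfig(**kw))

    def test_lower_abundance_ranks_first_at_equal_nsaf(self):
        counts = SpectralCountTable.from_records([("P1", 10, 0, 2), ("P2", 10, 0, 2)])
        meta = [
            ProteinRecord("P1", "", 100, "nuclear", 10.0),
            ProteinRecord("P2", "", 100, "nuclear", 100.0),
        ]
        nsaf = {"P1": 0.1, "P2": 0.1}
        ranked = self._rank({"P1", "P2"}, nsaf, meta, counts)
        assert [c.accession for c in ranked] == ["P1", "P2"]
        assert ranked[0].enrichment_index == pytest.approx(0.01)
        assert ranked[1].enrichment_index == pytest.approx(0.001)
        assert [c.rank for c in ranked] == [1, 2]

    def test_top_k_larger_than_candidates_returns_all(self):
        counts, meta, _ = simulate_apms(SimulationConfig(seed=2))
        nsaf = compute_nsaf(counts, meta)
        cands = set(list(nsaf)[:30])
        ranked = self._rank(cands, nsaf, meta, counts, top_k=50)
        assert len(ranked) == 30

    def test_ties_broken_by_accession(self):
        counts = SpectralCountTable.from_records(
            [("B", 10, 0, 2), ("A", 10, 0, 2), ("C", 10, 0, 2)]
        )
        meta = [ProteinRecord(a, "", 100, "nuclear", 5.0) for a in "ABC"]
        nsaf = {a: 1 / 3 for a in "ABC"}
        ranked = self._rank(set("ABC"), nsaf, meta, counts, top_k=2)
        assert [c.accession for c in ranked] == ["A", "B"]

    def test_missing_abundance_imputes_min_and_flags(self):
        counts = SpectralCountTable.from_records([("P1", 10, 0, 2), ("P2", 10, 0, 2)])
        meta = [
            ProteinRecord("P1", "", 100, "nuclear", None),
            ProteinRecord("P2", "", 100, "nuclear", 7.0),
        ]
        nsaf = {"P1": 0.5, "P2": 0.5}
        ranked = self._rank({"P1", "P2"}, nsaf, meta, counts)
        by = {c.accession: c for c in ranked}
        assert by["P1"].abundance_imputed and not by["P2"].abundance_imputed
        assert by["P1"].enrichment_index == pytest.approx(0.5 / 7.0)

    def test_exclude_policy_drops_missing_abundance(self):
        counts = SpectralCountTable.from_records([("P1", 10, 0, 2), ("P2", 10, 0, 2)])
        meta = [
            ProteinRecord("P1", "", 100, "nuclear", None),
            ProteinRecord("P2", "", 100, "nuclear", 7.0),
        ]
        ranked = self._rank(
            {"P1", "P2"}, {"P1": 0.5, "P2": 0.5}, meta, counts,
            missing_abundance_policy="exclude",
        )
        assert [c.accession for c in ranked] == ["P2"]

    def test_no_positive_abundance_with_impute_is_error(self):
        counts = SpectralCountTable.from_records([("P1", 10, 0, 2)])
        meta = [ProteinRecord("P1", "", 100, "nuclear", None)]
        with pytest.raises(ValidationError, match="impute"):
            self._rank({"P1"}, {"P1": 1.0}, meta, counts)

    def test_unique_flag_and_fold(self, small_counts, small_meta):
        ranked = score_apms(small_counts, small_meta)
        by = {c.accession: c for c in ranked}
        assert by["P0001"].unique_flag and by["P0001"].fold_enrichment is None
        assert not by["P0002"].unique_flag
        assert by["P0002"].fold_enrichment == pytest.approx(4.0)


class TestPlantedRecovery:
    def test_false_discovery_decreases_with_enrichment_factor(self):
        """Among the top-50, the share of non-planted proteins shrinks as the
        planted enrichment factor grows."""
        fdp = {}
        for factor in (4.0, 16.0):
            vals = []
            for seed in range(10):
                cfg = SimulationConfig(enrichment_factor=factor, seed=seed)
                counts, meta, truth = simulate_apms(cfg)
                ranked = score_apms(counts, meta)
                if not ranked:
                    continue
                hits = sum(c.accession in truth.interactors for c in ranked)
                vals.append(1 - hits / len(ranked))
            fdp[factor] = np.mean(vals)
        assert fdp[16.0] <= fdp[4.0]
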