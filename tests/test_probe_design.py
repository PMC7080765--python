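import numpy as np
import pytest

from chipsmith.gene_catalog import CatalogEntry, GeneCategory, reverse_complement
from chipsmith.probe_design import (
    ProbeConfig,
    build_kmer_index,
    debracket,
    design_pipeline,
    extract_plex,
    interfering_filter,
    score_candidate,
)
from chipsmith.snp_catalog import SnpRecord


class TestInterferingFilter:
    def test_single_snp_survives(self):
        assert interfering_filter([100]) == [100]

    def test_window_boundary(self):
        assert interfering_filter([100, 110]) == []  # distance 10: both removed
        assert interfering_filter([100, 111]) == [100, 111]  # distance 11: both kept

    def test_duplicates_are_malformed(self):
        with pytest.raises(ValueError, match="duplicate"):
            interfering_filter([5, 5])

    def test_symmetry_of_removal(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            pos = sorted(rng.choice(500, size=rng.integers(2, 15), replace=False) + 1)
            keep = set(interfering_filter(pos))
            for p in pos:
                interferers = [q for q in pos if q != p and abs(q - p) <= 10]
                assert (p in keep) == (not interferers)
                for q in interferers:
                    assert q not in keep or p not in keep

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            pos = list(np.sort(rng.choice(1000, size=n, replace=False)) + 1)
            expected = [
                p for p in pos if all(abs(p - q) > 10 for q in pos if q != p)
            ]
            assert interfering_filter(pos) == expected


def make_entry(seq, gid="g", cat=GeneCategory.SCP):
    return CatalogEntry(gid, cat, seq, 0, 0, exons_local=[(1, len(seq))])


def balanced_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    while True:
        s = "".join(rng.choice(list("ACGT"), size=n))
        gc = (s.count("G") + s.count("C")) / n
        if 0.35 <= gc <= 0.65 and "AAAAAA" not in s and "TTTTTT" not in s \
                and "GGGGGG" not in s and "CCCCCC" not in s:
            return s


class TestExtractPlex:
    def test_plex_geometry_at_position_36(self):
        seq = balanced_seq(80)
        snp = SnpRecord("g", 36, seq[35], "G" if seq[35] != "G" else "C")
        plex = extract_plex(seq, snp)
        left = plex[: plex.index("[")]
        right = plex[plex.index("]") + 1 :]
        assert len(left) == 35 and len(right) == 36
        assert plex[35] == "[" and "/" in plex[36:40]

    def test_too_close_to_end_is_not_possible(self):
        seq = balanced_seq(80)
        assert extract_plex(seq, SnpRecord("g", 20, seq[19], "A")) is None
        assert extract_plex(seq, SnpRecord("g", 50, seq[49], "A")) is None  # needs 36 right

    def test_debracketed_plex_round_trips_to_source(self):
        seq = balanced_seq(120, seed=3)
        pos = 60
        snp = SnpRecord("g", pos, seq[pos - 1], "T" if seq[pos - 1] != "T" else "A")
        plex = extract_plex(seq, snp)
        assert debracket(plex, "ref") == seq[pos - 36 : pos + 36]


class TestScoreCandidate:
    def _clean_plex(self):
        seq = balanced_seq(72, seed=5)
        return seq[:35] + "[" + seq[35] + "/" + ("G" if seq[35] != "G" else "C") + "]" + seq[36:]

    def test_clean_plex_scores_one(self):
        score, status = score_candidate(self._clean_plex())
        assert score == 1.0 and status == "recommended"

    def test_homopolymer_penalty_lowers_score(self):
        seq = balanced_seq(72, seed=5)
        poly = "AAAAAA" + seq[6:]
        plex_clean = seq[:35] + "[A/G]" + seq[36:]
        plex_poly = poly[:35] + "[A/G]" + poly[36:]
        s_clean, _ = score_candidate(plex_clean)
        s_poly, _ = score_candidate(plex_poly)
        assert s_poly < s_clean

    def test_gc_penalty(self):
        plex = "A" * 20 + "CT" * 7 + "A[A/G]" + "ATCT" * 9  # low GC
        score, status = score_candidate(plex)
        assert score <= 0.5 and status == "not_recommended"

    def test_threshold_is_strict(self):
        # exactly one penalty -> score 0.50 -> not_recommended (strict > gate)
        seq = balanced_seq(72, seed=5)
        poly = seq[:20] + "AAAAAA" + seq[26:]
        gc = (poly.count("G") + poly.count("C")) / 72
        assert 0.30 <= gc <= 0.70
        plex = poly[:35] + f"[{poly[35]}/C]" + poly[36:]
        score, status = score_candidate(plex)
        assert score == 0.5 and status == "not_recommended"

    def test_shared_kmer_penalty_uses_catalog_index(self):
        seq = balanced_seq(100, seed=8)
        catalog = {
            "g1": make_entry(seq, "g1"),
            "g2": make_entry(seq[:50] + balanced_seq(50, seed=9), "g2"),
        }
        index = build_kmer_index(catalog)
        snp = SnpRecord("g1", 40, seq[39], "C" if seq[39] != "C" else "G")
        plex = extract_plex(seq, snp)
        shared, _ = score_candidate(plex, kmer_index=index, gene_id="g1")
        alone, _ = score_candidate(plex)
        assert shared < alone

    def test_wrong_length_plex_errors(self):
        with pytest.raises(ValueError):
            score_candidate("ACGT[A/G]ACGT")


class TestDesignPipeline:
    def test_hand_traced_toy_catalog(self):
        s1 = balanced_seq(200, seed=21)
        s2 = balanced_seq(200, seed=22)
        s3 = balanced_seq(200, seed=23)
        catalog = {
            "g1": make_entry(s1, "g1"),
            "g2": make_entry(s2, "g2"),
            "g3": make_entry(s3, "g3"),
        }
        def rec(g, p, seq):
            return SnpRecord(g, p, seq[p - 1], "A" if seq[p - 1] != "A" else "T")
        snps = [
            rec("g1", 50, s1), rec("g1", 58, s1),   # interfere (distance 8): both drop
            rec("g1", 120, s1),                     # survives
            rec("g2", 100, s2), rec("g2", 111, s2), # distance 11: both survive
            rec("g2", 190, s2),                     # survives filter, no right flank
            rec("g3", 36, s3),                      # survives, plex = bases 1..72
            rec("g3", 20, s3),                      # no left flank
        ]
        candidates, report = design_pipeline(catalog, snps, check_uniqueness=False)
        assert report.identified == 8
        assert report.interference_filtered == 6
        assert report.plex_extracted == 4
        statuses = {c.snp_id: c.status for c in candidates}
        assert statuses["g2_190"] == "not_possible"
        assert statuses["g3_20"] == "not_possible"
        g3 = next(c for c in candidates if c.snp_id == "g3_36")
        assert debracket(g3.plex) == s3[:72]
        assert g3.reverse_probe == reverse_complement(g3.forward_probe)

    def test_empty_snp_list(self):
        candidates, report = design_pipeline({}, [])
        assert candidates == [] and report.identified == 0

    def test_funnel_is_monotone(self, small_catalog):
        _, _, catalog = small_catalog
        rng = np.random.default_rng(4)
        snps = []
        for gid, e in catalog.items():
            for p in np.sort(rng.choice(e.length_bp, size=12, replace=False)) + 1:
                ref = e.sequence[p - 1]
                snps.append(SnpRecord(gid, int(p), ref, "A" if ref != "A" else "C"))
        _, report = design_pipeline(catalog, snps, check_uniqueness=False)
        assert (
            report.identified
            >= report.interference_filtered
            >= report.plex_extracted
            >= report.recommended
        )


def test_probe_config_validation():
    with pytest.raises(ValueError):
        ProbeConfig(snp_offset=73)
    with pytest.raises(ValueError):
        ProbeConfig(interference_window=-1)
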