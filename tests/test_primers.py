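import itertools
import re

import numpy as np
import pytest

from primereval.io import SequenceLibrary, SequenceRecord
from primereval.primers import (DEFAULT_PRIMERS, IUPAC_SETS, CoverageTable,
                                PrimerSpec, coverage, extract_amplicons,
                                iupac_match, read_primer_tsv,
                                reverse_complement, write_primer_tsv)


def expand(primer_seq):
    """Brute-force concrete expansion of a degenerate primer."""
    pools = [sorted(IUPAC_SETS[c]) for c in primer_seq]
    return ["".join(p) for p in itertools.product(*pools)]


def oracle_hits(primer, target, max_mm):
    """Independent matcher: IUPAC set containment per position."""
    out = []
    for seq, strand in ((primer.iupac_seq, "+"),
                        (reverse_complement(primer.iupac_seq), "-")):
        L = len(seq)
        for start in range(len(target) - L + 1):
            mm = sum(target[start + k] not in IUPAC_SETS[seq[k]]
                     for k in range(L))
            if mm <= max_mm:
                out.append((start, strand))
    return sorted(out)


class TestPrimerSpec:
    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            PrimerSpec("p", "ACXT", "forward")

    def test_lowercase_rejected(self):
        with pytest.raises(ValueError):
            PrimerSpec("p", "acgt", "forward")

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            PrimerSpec("p", "ACGT", "sideways")

    def test_default_set_is_five_loci_two_strands(self):
        assert len(DEFAULT_PRIMERS) == 10
        names = {p.name for p in DEFAULT_PRIMERS}
        assert names == {"338f", "338r", "518f", "518r", "799f", "799r",
                         "926f", "926r", "1062f", "1062r"}
        by_name = {p.name: p for p in DEFAULT_PRIMERS}
        for locus in ("338", "518", "799", "926", "1062"):
            f, r = by_name[locus + "f"], by_name[locus + "r"]
            assert reverse_complement(f.iupac_seq) == r.iupac_seq


class TestIupacMatch:
    def test_exact_substring(self):
        hits = iupac_match(PrimerSpec("p", "ACGT", "forward"), "TTACGTTT")
        assert (2, "+") in hits

    def test_799f_degenerate_match(self):
        primer = next(p for p in DEFAULT_PRIMERS if p.name == "799f")
        target = "GG" + "AACCGGATTAGATACCCTG" + "AA"
        # M matches C, K matches T; verified against concrete expansion
        assert any(t == "AACCGGATTAGATACCCTG"
                   for t in expand(primer.iupac_seq))
        assert iupac_match(primer, target, 0) == [(2, "+")]

    def test_mismatch_budget(self):
        p = PrimerSpec("p", "ACGT", "forward")
        assert all(s != "+" or pos != 0
                   for pos, s in iupac_match(p, "ACGA", 0))
        assert (0, "+") in iupac_match(p, "ACGA", 1)

    def test_gapped_sequence_rejected(self):
        with pytest.raises(ValueError):
            iupac_match(PrimerSpec("p", "ACGT", "forward"), "AC-GT")

    def test_max_mismatches_bounds(self):
        p = PrimerSpec("p", "ACGT", "forward")
        with pytest.raises(ValueError):
            iupac_match(p, "ACGT", 4)

    def test_target_n_counts_as_mismatch(self):
        p = PrimerSpec("p", "ACGT", "forward")
        assert iupac_match(p, "ACGN", 0) == []
        assert (0, "+") in iupac_match(p, "ACGN", 1)
        # even a primer N does not match a target N
        pn = PrimerSpec("p", "ACGN", "forward")
        assert iupac_match(pn, "ACGN", 0) == []

    def test_matches_oracle_on_random_cases(self):
        rng = np.random.default_rng(0)
        codes = list(IUPAC_SETS)
        for _ in range(150):
            plen = int(rng.integers(2, 7))
            primer = PrimerSpec(
                "p", "".join(rng.choice(codes, plen)), "forward")
            target = "".join(rng.choice(list("ACGT"), 12))
            for mm in (0, 1):
                if mm >= plen:
                    continue
                assert iupac_match(primer, target, mm) == \
                    oracle_hits(primer, target, mm)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50)        :
            primer = PrimerSpec(
                "p", "".join(rng.choice(list(IUPAC_SETS), 5)), "forward")
            target = "".join(rng.choice(list("ACGT"), 15))
            rc_primer = PrimerSpec("rc", reverse_complement(primer.iupac_seq),
                                   "forward")
            fwd = iupac_match(primer, target, 0)
            swapped = [(pos, "-" if s == "+" else "+")
                       for pos, s in iupac_match(rc_primer, target, 0)]
            assert sorted(fwd) == sorted(swapped)


class TestCoverage:
    def _lib(self, seqs, tax=None):
        return SequenceLibrary([
            SequenceRecord(f"s{i}", s, tax[i] if tax else None)
            for i, s in enumerate(seqs)])

    def test_three_of_four(self):
        site = "ACGTACGT"
        lib = self._lib([site + "AAAA", "AAAA" + site, site + "TTTT",
                         "GGGGGGGGGGGG"])
        primer = PrimerSpec("p", site, "forward")
        table = coverage([primer], lib)
        assert table.pct("p") == 75.0
        row = table.frame.iloc[0]
        assert row.noncoverage_pct == 25.0
        assert row.covered == 3 and row.total == 4

    def test_simulated_default_full_coverage(self, sim50):
        _, _, lib = sim50
        table = coverage(DEFAULT_PRIMERS, lib)
        for primer in DEFAULT_PRIMERS:
            assert table.pct(primer.name) == 100.0

    def test_coverage_plus_noncoverage_is_100(self, sim50):
        _, _, lib = sim50
        table = coverage(DEFAULT_PRIMERS[:2], lib)
        total = table.frame.coverage_pct + table.frame.noncoverage_pct
        assert np.allclose(total, 100.0, atol=1e-9)

    def test_regex_expansion_oracle(self):
        # strand-aware regex oracle over a small simulated library
        from primereval.simulate import SimulationConfig, simulate_library
        _, lib = simulate_library(SimulationConfig(n_taxa=30, seed=9))
        for primer in DEFAULT_PRIMERS:
            variants = expand(primer.iupac_seq) + \
                expand(reverse_complement(primer.iupac_seq))
            pattern = re.compile("|".join(
                f"(?={re.escape(v)})" for v in variants))
            table = coverage([primer], lib)
            expected = sum(bool(pattern.search(r.ungapped)) for r in lib)
            assert table.frame.iloc[0].covered == expected

    def test_group_rank(self):
        tax_a = [("domain", "Bacteria"), ("phylum", "A")]
        tax_b = [("domain", "Bacteria"), ("phylum", "B")]
        lib = self._lib(["ACGTAAAA", "ACGTTTTT", "GGGGCCCC"],
                        {0: tax_a, 1: tax_b, 2: tax_b})
        table = coverage([PrimerSpec("p", "ACGT", "forward")], lib,
                         group_rank="phylum")
        frame = table.frame.set_index("group")
        assert frame.loc["A"].coverage_pct == 100.0
        assert frame.loc["B"].coverage_pct == 50.0

    def test_unknown_rank(self, tiny_library):
        with pytest.raises(ValueError):
            coverage([PrimerSpec("p", "ACGT", "forward")], tiny_library,
                     group_rank="tribe")


class TestExtractAmplicons:
    def test_forward_window_arithmetic(self, sim50):
        _, _, lib = sim50
        primer = next(p for p in DEFAULT_PRIMERS if p.name == "799f")
        sr = extract_amplicons(lib, primer, read_length=280)
        for rec in sr:
            assert len(rec.ungapped) == 280 - len(primer)  # 261

    def test_reverse_window_arithmetic(self, sim50):
        _, _, lib = sim50
        primer = next(p for p in DEFAULT_PRIMERS if p.name == "338r")
        sr = extract_amplicons(lib, primer, read_length=280)
        for rec in sr:
            assert len(rec.ungapped) == 280 - len(primer)  # 262

    def test_reverse_read_is_upstream_in_reference_orientation(self):
        # reverse-primer site at ungapped [482, 500): retained [220, 482)
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), 600))
        site = "ACGTACGTACGTACGTAC"  # 18 nt, forward-orientation site
        seq = base[:482] + site + base[500:]
        primer = PrimerSpec("r", reverse_complement(site), "reverse")
        lib = SequenceLibrary([SequenceRecord("s", seq)])
        sr = extract_amplicons(lib, primer, read_length=280,
                               anchor_mismatches=0)
        assert sr["s"].ungapped == seq[220:482]
        assert len(sr["s"].ungapped) == 262

    def test_read_length_must_exceed_primer(self, tiny_library):
        primer = PrimerSpec("p", "ACGT", "forward")
        with pytest.raises(ValueError):
            extract_amplicons(tiny_library, primer, read_length=4)

    def test_missing_excluded_by_default(self):
        lib = SequenceLibrary([
            SequenceRecord("hit", "AAAAACGTACGTCCCCTTTTGGGG"),
            SequenceRecord("miss", "GGGGGGGGGGGGGGGGGGGGGGGG")])
        primer = PrimerSpec("p", "ACGTACGT", "forward")
        sr = extract_amplicons(lib, primer, read_length=16,
                               anchor_mismatches=0)
        assert sr.ids == ["hit"]

    def test_majority_column_fallback(self):
        lib = SequenceLibrary([
            SequenceRecord("a", "AAAAACGTACGTCCCCTTTTGGGG"),
            SequenceRecord("b", "TTTTACGTACGTCCCCTTTTGGGG"),
            SequenceRecord("miss", "GGGGGGGGGGGGGGGGGGGGGGGG")])
        primer = PrimerSpec("p", "ACGTACGT", "forward")
        sr = extract_amplicons(lib, primer, read_length=16,
                               anchor_mismatches=0,
                               on_missing="majority-column")
        assert set(sr.ids) == {"a", "b", "miss"}

    def test_alignment_consistency_with_gaps(self):
        # same ungapped content, different gap placement: extraction must
        # produce one consistent column space
        lib = SequenceLibrary([
            SequenceRecord("a", "AA--AAACGTACGTCCCCTTTTGG"),
            SequenceRecord("b", "AAAAACG--TACGTCCCCTTTTGG")])
        primer = PrimerSpec("p", "ACGTACGT", "forward")
        sr = extract_amplicons(lib, primer, read_length=14,
                               anchor_mismatches=0)
        assert len({len(r.aligned_seq) for r in sr}) == 1
        for rec in sr:
            assert len(rec.ungapped) == 6


class TestPrimerTsv:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "primers.tsv"
        write_primer_tsv(DEFAULT_PRIMERS, path)
        back = read_primer_tsv(path)
        assert [p.name for p in back] == [p.name for p in DEFAULT_PRIMERS]
        assert all(a.iupac_seq == b.iupac_seq
                   for a, b in zip(back, DEFAULT_PRIMERS))

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("p\tACGT\tforward\np\tACGT\treverse\n")
        with pytest.raises(ValueError):
            read_primer_tsv(path)
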