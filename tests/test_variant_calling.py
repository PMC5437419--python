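"""Tests for pileups, variant calling, diversity and spacer phasing."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from hor5s._seq import random_dna
from hor5s.errors import EmptyInput, InsufficientData, InvalidArgument
from hor5s.read_mapping import ReadPlacement
from hor5s.variant_calling import (
    PileupTable,
    VariantThresholds,
    call_variants,
    find_motif,
    nucleotide_diversity,
    phase_units,
    pileup_columns,
    snp_density,
)

from oracles import pi_all_pairs


def placement(ref, start, length, alt=None, rid="r"):
    """A perfect placement of ref[start:start+length], optionally with one
    substituted base given as (offset_in_read, base)."""
    seq = list((ref * 2)[start:start + length])
    if alt is not None:
        off, base = alt
        seq[off] = base
    return ReadPlacement(
        read_id=rid,
        ref_interval=(start, start + length),
        pos_mod=start % len(ref),
        strand="+",
        aligned_fraction=1.0,
        similarity=1.0,
        cigar=f"{length}=",
        score=length,
        read_seq="".join(seq),
    )


class TestPileup:
    def test_single_perfect_placement(self, ref):
        mono = ref.monomer
        table = pileup_columns([placement(mono, 10, 50)], mono)
        for i in range(10, 60):
            base = mono[i]
            assert table.base_counts[i, "ACGT".find(base)] == 1
            assert table.coverage[i] == 1
        assert table.coverage[9] == 0 and table.coverage[60] == 0

    def test_coverage_counts_spanning_placements(self, ref):
        mono = ref.monomer
        pls = [placement(mono, s, 100, rid=f"r{s}") for s in (0, 25, 50, 150)]
        table = pileup_columns(pls, mono)
        for pos in range(len(mono)):
            expected = sum(1 for s in (0, 25, 50, 150)
                           if s <= pos < s + 100 or s <= pos + len(mono) < s + 100)
            assert table.coverage[pos] == expected, pos

    def test_junction_spanning_placement_folds(self, ref):
        mono = ref.monomer
        L = len(mono)
        table = pileup_columns([placement(mono, L - 40, 100)], mono)
        assert table.coverage[L - 1] == 1
        assert table.coverage[0] == 1
        assert table.coverage[59] == 1
        assert table.coverage[60] == 0

    def test_planted_alt_frequency_within_binomial_bound(self, ref, rng):
        from scipy import stats
        mono = ref.monomer
        pos, alt_p = 30, 0.10
        pls = []
        for i in range(1000):
            has_alt = rng.random() < alt_p
            alt_base = "A" if mono[pos] != "A" else "G"
            pls.append(placement(mono, 0, 120,
                                 alt=(pos, alt_base) if has_alt else None,
                                 rid=f"r{i}"))
        table = pileup_columns(pls, mono)
        alt_count = table.base_counts[pos, "ACGT".find("A" if mono[pos] != "A" else "G")]
        lo = stats.binom.ppf(0.005, 1000, alt_p)
        hi = stats.binom.ppf(0.995, 1000, alt_p)
        assert lo <= alt_count <= hi


class TestCallVariants:
    def _table(self, ref, cov, alt_count, pos=30):
        alt_base = "A" if ref[pos] != "A" else "G"
        pls = [placement(ref, 0, len(ref),
                         alt=(pos, alt_base) if i < alt_count else None,
                         rid=f"r{i}") for i in range(cov)]
        return pileup_columns(pls, ref), alt_base

    def test_coverage_boundary(self, ref):
        table, _ = self._table(ref.monomer, 299, 200)
        assert call_variants(table) == []

    def test_all_thresholds_met_at_boundary(self, ref):
        table, alt = self._table(ref.monomer, 1000, 50)
        calls = call_variants(table)
        assert len(calls) == 1
        c = calls[0]
        assert (c.position, c.alt_allele, c.count, c.coverage) == (30, alt, 50, 1000)
        assert c.frequency == pytest.approx(0.05)

    def test_count_threshold(self, ref):
        table, _ = self._table(ref.monomer, 490, 49)
        assert call_variants(table) == []

    def test_region_labels(self, ref):
        table, _ = self._table(ref.monomer, 1000, 100, pos=30)
        calls = call_variants(table, annotation=ref.annotation)
        assert calls[0].region_label == "genic"
        table, _ = self._table(ref.monomer, 1000, 100, pos=150)
        calls = call_variants(table, annotation=ref.annotation)
        assert calls[0].region_label == "spacer"

    def test_adjacent_phased_snvs_merge_to_mnp(self, ref):
        mono = ref.monomer
        pls = []
        for i in range(1000):
            if i < 170:  # 17% carry both alternative alleles together
                seq = list(mono[:120])
                seq[40] = "A" if mono[40] != "A" else "G"
                seq[41] = "A" if mono[41] != "A" else "G"
                pls.append(ReadPlacement(f"r{i}", (0, 120), 0, "+", 1.0, 1.0,
                                         "120=", 120, "".join(seq)))
            else:
                pls.append(placement(mono, 0, 120, rid=f"r{i}"))
        calls = call_variants(pileup_columns(pls, mono))
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "MNP"
        assert c.position == 40
        assert len(c.ref_allele) == len(c.alt_allele) == 2
        assert c.frequency == pytest.approx(0.17)

    def test_unphased_adjacent_snvs_stay_separate(self, ref):
        mono = ref.monomer
        pls = []
        for i in range(1000):
            if i < 100:
                pls.append(placement(mono, 0, 120,
                                     alt=(40, "A" if mono[40] != "A" else "G"),
                                     rid=f"r{i}"))
            elif i < 200:
                pls.append(placement(mono, 0, 120,
                                     alt=(41, "A" if mono[41] != "A" else "G"),
                                     rid=f"r{i}"))
            else:
                pls.append(placement(mono, 0, 120, rid=f"r{i}"))
        calls = call_variants(pileup_columns(pls, mono))
        assert len(calls) == 2
        assert all(c.kind == "SNV" for c in calls)


@given(
    cov=st.integers(min_value=300, max_value=600),
    alt=st.integers(min_value=0, max_value=300),
    bump=st.sampled_from(["min_coverage", "min_count", "min_frequency"]),
)
def test_threshold_monotonicity(cov, alt, bump):
    """Raising any threshold never increases the number of calls."""
    from hor5s.repeat_model import default_reference
    mono = default_reference().monomer
    alt = min(alt, cov)
    alt_base = "A" if mono[30] != "A" else "G"
    pls = [placement(mono, 0, 120, alt=(30, alt_base) if i < alt else None,
                     rid=f"r{i}") for i in range(cov)]
    table = pileup_columns(pls, mono)
    base = VariantThresholds()
    n0 = len(call_variants(table, base))
    kwargs = {"min_coverage": base.min_coverage, "min_count": base.min_count,
              "min_frequency": base.min_frequency}
    kwargs[bump] = {"min_coverage": 400, "min_count": 80, "min_frequency": 0.2}[bump]
    n1 = len(call_variants(table, VariantThresholds(**kwargs)))
    assert n1 <= n0


class TestSnpDensity:
    def test_published_genic_density(self, ref):
        from hor5s.variant_calling import VariantCall
        calls = [VariantCall(p, "A", "G", "SNV", 60, 1000, 0.06) for p in (10, 50, 100)]
        assert snp_density(calls, (0, 120)) == 2.5

    def test_zero_and_dense_cases(self):
        from hor5s.variant_calling import VariantCall
        assert snp_density([], (0, 100)) == 0.0
        calls = [VariantCall(p, "A", "G", "SNV", 60, 1000, 0.06) for p in range(13)]
        assert snp_density(calls, (0, 100)) == 13.0

    def test_zero_length_region_rejected(self):
        with pytest.raises(ZeroDivisionError):
            snp_density([], (5, 5))


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        assert nucleotide_diversity(["ACGT" * 10] * 5).pi == 0.0

    def test_single_difference_closed_form(self):
        a = "A" * 70
        b = "A" * 35 + "C" + "A" * 34
        assert nucleotide_diversity([a, b]).pi == pytest.approx(1 / 70)

    def test_two_haplotype_mixture_matches_oracle(self, rng):
        h1 = random_dna(rng, 70)
        h2 = list(h1)
        for p in (5, 20, 40, 60):
            h2[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[h2[p]]
        h2 = "".join(h2)
        n1 = 415  # 83 % / 17 % haplotype mixture
        seqs = [h1] * n1 + [h2] * (500 - n1)
        pi = nucleotide_diversity(seqs).pi
        expected = 2 * (n1 / 500) * (1 - n1 / 500) * (4 / 70) * (500 / 499)
        assert pi == pytest.approx(expected, rel=1e-9)
        sample = seqs[::16]
        assert nucleotide_diversity(sample).pi == pytest.approx(
            pi_all_pairs(sample), abs=1e-12)

    def test_gap_columns_pairwise_deleted(self):
        a = "ACGTACGTAC"
        b = "ACG-ACGTAC"
        c = "ACGAACGTAC"
        res = nucleotide_diversity([a, b, c])
        # pair (a,b): 9 comparable, 0 diffs; (a,c): 10 comp, 1 diff; (b,c): 9, 0
        assert res.pi == pytest.approx((0 + 1 / 10 + 0) / 3, abs=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientData):
            nucleotide_diversity(["ACGT"])

    def test_oracle_agreement_on_random_inputs(self, rng):
        for trial in range(5):
            n = int(rng.integers(2, 50))
            seqs = [random_dna(rng, 40) for _ in range(n)]
            assert nucleotide_diversity(seqs).pi == pytest.approx(
                pi_all_pairs(seqs), abs=1e-12)


class TestFindMotif:
    def test_exact_occurrence(self, ref):
        q = ref.motif_queries["T"]
        read = "ACGT" * 5 + q + "TGCA" * 5
        hits = find_motif(read, q)
        assert any(h.position == 20 and h.matches == 10 and h.strand == "+" for h in hits)

    def test_single_mismatch_tolerated_two_rejected(self, ref):
        q = ref.motif_queries["T"]
        one = q[:4] + ("A" if q[4] != "A" else "C") + q[5:]
        two = list(one)
        two[8] = "A" if one[8] != "A" else "C"
        pad = "GGCC" * 8
        assert any(h.matches == 9 for h in find_motif(pad + one + pad, q))
        assert find_motif(pad + "".join(two) + pad, q) == []

    def test_reverse_strand_hit(self, ref):
        from hor5s._seq import revcomp
        q = ref.motif_queries["T"]
        read = "ACGT" * 5 + revcomp(q) + "TGCA" * 5
        hits = find_motif(read, q)
        assert any(h.strand == "-" and h.matches == 10 for h in hits)

    def test_query_length_enforced(self):
        with pytest.raises(InvalidArgument):
            find_motif("ACGTACGT", "ACGT")


class TestPhaseUnits:
    def test_all_a_array(self, ref, library):
        from hor5s.hor_analysis import find_gene_copies
        from hor5s.synthetic_data import ArraySpec, BlockSpec, build_array
        spec = ArraySpec((BlockSpec("tandem", n_units=21, unit_mixture={"S_A": 1.0}),))
        seq, _ = build_array(spec, library, 0)
        hits = find_gene_copies(seq, ref.genic_consensus)
        comp = phase_units(seq, hits, ref.motif_queries)
        assert comp.n_complete_units == 20
        assert comp.counts == {"T": 0, "A": 20, "other": 0}

    def test_ambiguous_unit_is_other(self, ref, library):
        # engineer a spacer carrying both query motifs
        from hor5s.hor_analysis import find_gene_copies
        from hor5s.repeat_model import DEFAULT_GENIC
        t = library["S_T"]
        sp = t.spacer[:60] + ref.motif_queries["A"] + t.spacer[70:]
        unit = DEFAULT_GENIC + sp
        seq = unit * 3
        hits = find_gene_copies(seq, ref.genic_consensus)
        comp = phase_units(seq, hits, ref.motif_queries)
        assert comp.counts["other"] == comp.n_complete_units

    def test_no_hits_rejected(self, ref):
        with pytest.raises(EmptyInput):
            phase_units("ACGT" * 100, [], ref.motif_queries)
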