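"""Nonsense synthesis: cropping, three-frame candidates, exact-match masking
and segment extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nonsenseq.genome_io import ProteinSequence, SourceClass, translate
from nonsenseq.nonsense_synthesis import (
    CandidateTranslation,
    crop_gene,
    extract_nonsense_segments,
    mask_true_matches,
    synthesize_candidates,
    synthesize_gene_nonsense,
)

from conftest import make_gene, random_nt, random_protein


def brute_force_mask(candidate: str, true_protein: str, min_match: int) -> np.ndarray:
    """O(n*m*k) scan over every candidate/protein offset pair."""
    mask = np.zeros(len(candidate), dtype=bool)
    for i in range(len(candidate) - min_match + 1):
        for j in range(len(true_protein) - min_match + 1):
            k = 0
            while (i + k < len(candidate) and j + k < len(true_protein)
                   and candidate[i + k] == true_protein[j + k]):
                k += 1
            if k >= min_match:
                mask[i : i + k] = True
    return mask


class TestCropGene:
    def test_long_intron_keeps_120_from_each_side(self):
        rng = np.random.default_rng(0)
        gene = make_gene(
            [random_nt(rng, 60), random_nt(rng, 60)], introns=[random_nt(rng, 300)]
        )
        cropped = crop_gene(gene)
        assert len(cropped.sequence) == 60 + 240 + 60
        assert int(np.count_nonzero(~cropped.nt_origin)) == 240

    def test_single_exon_no_utr_returned_unchanged(self):
        rng = np.random.default_rng(1)
        gene = make_gene([random_nt(rng, 90)])
        cropped = crop_gene(gene)
        assert cropped.sequence == gene.sequence
        assert cropped.nt_origin.all()

    def test_noncoding_border_distance_bounded_by_flank(self, small_sim):
        for gene in small_sim.genes[:10]:
            cropped = crop_gene(gene)
            noncoding = ~cropped.nt_origin
            assert (cropped.nt_border_distance[noncoding] <= 120).all()

    def test_exonic_distance_is_min_over_both_boundaries(self):
        rng = np.random.default_rng(2)
        # exon of 120 nt flanked by UTRs: interior position measures to nearer edge
        gene = make_gene(
            [random_nt(rng, 120)], utr5=random_nt(rng, 30), utr3=random_nt(rng, 30)
        )
        cropped = crop_gene(gene)
        exon_pos = np.flatnonzero(cropped.nt_origin)
        p = exon_pos[7]  # 8th exonic nucleotide: 8 from 5' border, 113 from 3'
        assert cropped.nt_border_distance[p] == 8
        assert cropped.nt_border_distance[exon_pos[-1]] == 1

    def test_increasing_flank_never_shortens_sequence(self, small_sim):
        gene = small_sim.genes[0]
        lengths = [len(crop_gene(gene, f).sequence) for f in (0, 60, 120, 10_000)]
        assert lengths == sorted(lengths)


class TestMaskTrueMatches:
    def test_verbatim_block_of_12_is_masked(self):
        rng = np.random.default_rng(3)
        true = random_protein(rng, 80)
        block = true[20:32]
        cand = random_protein(rng, 40) + block + random_protein(rng, 40)
        mask = mask_true_matches(cand, true)
        assert mask[40:52].all()
        assert not mask[:38].any() and not mask[54:].any()

    def test_nine_residue_block_is_below_threshold(self):
        rng = np.random.default_rng(4)
        true = random_protein(rng, 80)
        cand = random_protein(rng, 30) + true[10:19] + random_protein(rng, 30)
        assert not mask_true_matches(cand, true, min_match=10).any()

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(5)
        # low-complexity alphabet so shared substrings actually occur
        aa = list("ACDE")
        for _ in range(5):
            cand = "".join(rng.choice(aa, size=200))
            true = "".join(rng.choice(aa, size=200))
            got = mask_true_matches(cand, true, min_match=5)
            expected = brute_force_mask(cand, true, 5)
            assert np.array_equal(got, expected)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_bruteforce_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        cand = "".join(rng.choice(list("AC"), size=60))
        true = "".join(rng.choice(list("AC"), size=60))
        assert np.array_equal(
            mask_true_matches(cand, true, min_match=6),
            brute_force_mask(cand, true, 6),
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mask_true_matches("", "MAK")


class TestSynthesizeCandidates:
    def test_exactly_three_candidates_per_gene(self, small_sim):
        from nonsenseq.genome_io import compile_representative_protein

        for gene in small_sim.genes[:5]:
            prot = compile_representative_protein(gene)
            cands = synthesize_candidates(crop_gene(gene), prot)
            assert [c.frame for c in cands] == [0, 1, 2]

    def test_frame0_of_intronless_gene_is_fully_masked(self):
        rng = np.random.default_rng(6)
        protein = random_protein(rng, 40)
        from nonsenseq.synthetic_genome import _reverse_translate

        gene = make_gene([_reverse_translate(protein, rng)])
        prot = ProteinSequence("toy", protein, SourceClass.TRUE_NP)
        cands = synthesize_candidates(crop_gene(gene), prot)
        assert cands[0].residues == protein
        assert cands[0].matched_mask.all()

    def test_origin_follows_codon_central_nucleotide(self):
        # 1-nt exon/intron offset: codon spanning the boundary with an
        # intronic central nucleotide must be labeled noncoding
        exon1 = "ATGGCCA"        # 7 nt: codon 3 = "A" + first 2 intron nt
        intron = "GTTTTTTTAG"    # 10 nt
        exon2 = "AAGGGCC"
        gene = make_gene([exon1, exon2], introns=[intron])
        cropped = crop_gene(gene)
        prot = ProteinSequence("toy", "MMMMMMMMMMMM", SourceClass.TRUE_NP)
        cand = synthesize_candidates(cropped, prot)[0]
        # codon index 2 covers positions 6,7,8 -> central nt 7 is intronic
        assert cand.res_origin[0] and cand.res_origin[1]
        assert not cand.res_origin[2]

    def test_coding_residue_count_matches_recount(self, small_sim):
        from nonsenseq.genome_io import _CODON_TABLE, compile_representative_protein

        gene = small_sim.genes[1]
        prot = compile_representative_protein(gene)
        cropped = crop_gene(gene)
        for cand in synthesize_candidates(cropped, prot):
            n = 0
            for i in range(cand.frame, len(cropped.sequence) - 2, 3):
                codon = cropped.sequence[i : i + 3]
                if "N" in codon or _CODON_TABLE[codon] == "*":
                    continue
                if cropped.nt_origin[i + 1]:
                    n += 1
            assert int(np.count_nonzero(cand.res_origin)) == n


class TestExtractSegments:
    def _candidate(self, mask):
        mask = np.asarray(mask, dtype=bool)
        n = len(mask)
        return CandidateTranslation(
            "toy", 0, "A" * n, np.ones(n, dtype=bool), np.ones(n, dtype=np.int64), mask
        )

    def test_run_extraction_with_length_filter(self):
        mask = [False] * 30 + [True] * 12 + [False] * 5
        segs = extract_nonsense_segments(self._candidate(mask), min_segment_length=30)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 30)

    def test_fully_matched_candidate_yields_nothing(self):
        assert extract_nonsense_segments(self._candidate([True] * 50)) == []

    def test_no_segment_residue_shares_long_substring_with_truth(self, small_sim):
        from nonsenseq.genome_io import compile_representative_protein
        from nonsenseq.nonsense_synthesis import mask_true_matches as mtm

        for gene in small_sim.genes[:5]:
            prot = compile_representative_protein(gene)
            for seg in synthesize_gene_nonsense(gene, prot):
                assert not mtm(
                    seg.residues, prot.residues, min_match=10
                ).any() or len(seg.residues) < 10

    def test_increasing_min_match_never_decreases_nonsense_residues(self, small_sim):
        from nonsenseq.genome_io import compile_representative_protein

        gene = small_sim.genes[2]
        prot = compile_representative_protein(gene)
        totals = []
        for mm in (8, 10, 14, 20):
            segs = synthesize_gene_nonsense(gene, prot, min_match=mm,
                                            min_segment_length=1)
            totals.append(sum(len(s.residues) for s in segs))
        assert totals == sorted(totals)
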