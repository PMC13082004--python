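import numpy as np
import pytest

from pvep.haplotypes import (
    DELETED,
    FocalVariant,
    Incompatible,
    build_protein_haplotypes,
    extract_window,
    inject_missense,
    inject_variant,
    map_residue_index,
)
from pvep.synthetic import (
    PhasedCohort,
    ReferenceAssembly,
    Transcript,
    VariantRecord,
    revcomp,
)

from conftest import length_shift_before, sample_ploid_variants, splice_apply, \
    translate_oracle

UP, DOWN = 10, 40  # flanks around the toy CDS

TOY_CODONS = (["ATG"] + ["AAA"] * 9 + ["TAC"] + ["CCC"] * 9 + ["GGT"] * 9
              + ["TAA"])
TOY_CDS = "".join(TOY_CODONS)  # 30 codons, 29-residue protein
TOY_PROTEIN = "M" + "K" * 9 + "Y" + "P" * 9 + "G" * 9


def toy_reference(strand="+"):
    body = TOY_CDS if strand == "+" else revcomp(TOY_CDS)
    seq = "T" * UP + body + "C" * DOWN
    tx = Transcript(id="t1", contig="c", strand=strand,
                    exons=((UP, UP + len(TOY_CDS)),),
                    cds_start=UP, cds_end=UP + len(TOY_CDS))
    return ReferenceAssembly(contigs={"c": seq}, transcripts=[tx])


def make_cohort(samples, records):
    """records: list of (pos, ref, alt, info, gts-per-sample)."""
    recs = [
        VariantRecord(contig="c", pos=pos, ref=ref, alt=alt, info_score=info,
                      genotypes=np.array(gts, dtype=np.int8))
        for pos, ref, alt, info, gts in sorted(records)
    ]
    return PhasedCohort(samples=samples, records=recs)


class TestExtractWindow:
    def test_no_variants_equals_reference(self, reference, cohort):
        contig = "chr1"
        seq = reference.contigs[contig]
        # pick a sample/region with no variants nearby
        w = extract_window(
            make_cohort([("S0", "EUR")], []), ReferenceAssembly(
                contigs={"c": "ACGT" * 1000}, transcripts=[]),
            "S0", 0, "c", 2000, 400)
        assert w.seq == ("ACGT" * 1000)[1800:2200]
        assert w.pad_left == w.pad_right == 0

    def test_het_snv_phased(self):
        ref = ReferenceAssembly(contigs={"c": "A" * 500}, transcripts=[])
        cohort = make_cohort([("S0", "EUR")],
                             [(250, "A", "G", 0.99, [[0, 1]])])
        w0 = extract_window(cohort, ref, "S0", 0, "c", 250, 101)
        w1 = extract_window(cohort, ref, "S0", 1, "c", 250, 101)
        assert w0.seq == "A" * 101
        diffs = [i for i, (a, b) in enumerate(zip(w0.seq, w1.seq)) if a != b]
        assert diffs == [50] and w1.seq[50] == "G"

    def test_info_filter_applied(self):
        ref = ReferenceAssembly(contigs={"c": "A" * 500}, transcripts=[])
        cohort = make_cohort([("S0", "EUR")],
                             [(250, "A", "G", 0.85, [[1, 1]])])
        w = extract_window(cohort, ref, "S0", 0, "c", 250, 101)
        assert w.seq == "A" * 101  # INFO 0.85 < 0.9 dropped

    def test_deletion_shifts_offsets(self):
        base = "ACGTTGCA" * 100
        ref = ReferenceAssembly(contigs={"c": base}, transcripts=[])
        pos = 300
        rec = (pos, base[pos : pos + 3], base[pos], 0.99, [[1, 1]])
        cohort = make_cohort([("S0", "EUR")], [rec])
        center, size = 400, 201
        w = extract_window(cohort, ref, "S0", 0, "c", center, size)
        # oracle: rebuild the full haplotype naively, then slice
        full = splice_apply(base, [(pos, base[pos : pos + 3], base[pos])])
        s, e = center - size // 2, center - size // 2 + size
        variants = [(pos, base[pos : pos + 3], base[pos])]
        assert w.seq == full[s + length_shift_before(variants, s):
                             e + length_shift_before(variants, e)]
        # downstream reference coords shift by -2 in window coordinates
        for p in (pos + 10, pos + 50, center):
            assert w.map_position(p) == (p - s) - 2
        for p in (s, pos):  # anchor base itself is unshifted
            assert w.map_position(p) == p - s
        assert w.map_position(pos + 1) is DELETED

    def test_edge_padding(self):
        ref = ReferenceAssembly(contigs={"c": "ACGT" * 50}, transcripts=[])
        w = extract_window(make_cohort([("S0", "EUR")], []), ref,
                           "S0", 0, "c", 5, 101)
        assert len(w.seq) == 101
        assert w.pad_left == 45
        assert w.seq.startswith("N" * 45)
        assert w.seq[45:] == ("ACGT" * 50)[:56]

    def test_unknown_sample_and_contig(self, reference, cohort):
        with pytest.raises(KeyError):
            extract_window(cohort, reference, "NOPE", 0, "chr1", 1000, 101)
        with pytest.raises(KeyError):
            extract_window(cohort, reference, cohort.sample_ids[0], 0,
                           "chrZ", 1000, 101)

    def test_missing_genotype_rejected_unless_imputed(self):
        ref = ReferenceAssembly(contigs={"c": "A" * 500}, transcripts=[])
        cohort = make_cohort([("S0", "EUR")],
                             [(250, "A", "G", 0.99, [[-1, -1]])])
        with pytest.raises(ValueError, match="missing genotype"):
            extract_window(cohort, ref, "S0", 0, "c", 250, 101)
        w = extract_window(cohort, ref, "S0", 0, "c", 250, 101,
                           impute_ref=True)
        assert w.seq == "A" * 101

    def test_window_equals_whole_contig_slice(self, reference, snv_cohort):
        rng = np.random.default_rng(42)
        contig = "chr1"
        base = reference.contigs[contig]
        for _ in range(40):
            s_idx = int(rng.integers(len(snv_cohort.samples)))
            ploid = int(rng.integers(2))
            center = int(rng.integers(600, len(base) - 600))
            sample = snv_cohort.sample_ids[s_idx]
            w = extract_window(snv_cohort, reference, sample, ploid, contig,
                               center, 401)
            variants = sample_ploid_variants(snv_cohort, s_idx, ploid, contig)
            full = splice_apply(base, variants)
            s = center - 200
            assert w.seq == full[s + length_shift_before(variants, s):
                                 s + 401 + length_shift_before(variants, s + 401)]


class TestInjectVariant:
    def _window(self, seq, records=(), center=250, size=101):
        ref = ReferenceAssembly(contigs={"c": seq}, transcripts=[])
        cohort = make_cohort([("S0", "EUR")], list(records))
        return extract_window(cohort, ref, "S0", 0, "c", center, size)

    def test_clean_substitution(self):
        w = self._window("A" * 500)
        focal = FocalVariant(id="f", variant_class="splice", contig="c",
                             pos=250, ref="A", alt="T")
        mut = inject_variant(w, focal)
        assert isinstance(mut, str)
        diffs = [i for i, (a, b) in enumerate(zip(w.seq, mut)) if a != b]
        assert diffs == [50] and mut[50] == "T"

    def test_background_collision_incompatible(self):
        w = self._window("A" * 500, [(250, "A", "G", 0.99, [[1, 1]])])
        focal = FocalVariant(id="f", variant_class="splice", contig="c",
                             pos=250, ref="A", alt="T")
        out = inject_variant(w, focal)
        assert isinstance(out, Incompatible)
        assert out.reason == "background_allele_at_focal_site"

    def test_focal_site_deleted_incompatible(self):
        base = "ACGTTGCA" * 100
        w = self._window(base, [(248, base[248:252], base[248], 0.99, [[1, 1]])])
        focal = FocalVariant(id="f", variant_class="splice", contig="c",
                             pos=250, ref=base[250], alt="A" if base[250] != "A" else "T")
        out = inject_variant(w, focal)
        assert isinstance(out, Incompatible)
        assert out.reason == "site_deleted_by_background_indel"

    def test_downstream_of_insertion_lands_shifted(self):
        base = "ACGTTGCA" * 100
        ins = (230, base[230], base[230] + "GGG", 0.99, [[1, 1]])
        w = self._window(base, [ins])
        focal = FocalVariant(id="f", variant_class="splice", contig="c",
                             pos=260, ref=base[260],
                             alt="A" if base[260] != "A" else "T")
        mut = inject_variant(w, focal)
        # oracle: inject into the naively rebuilt haplotype
        full = splice_apply(base, [(230, base[230], base[230] + "GGG")])
        s = 250 - 50
        expected_wt = full[s : s + 101 + 3]
        assert w.seq == expected_wt
        idx = (260 - s) + 3  # +3 from the upstream insertion
        assert mut[idx] == focal.alt
        assert w.seq[idx] == focal.ref

    def test_position_outside_window_raises(self):
        w = self._window("A" * 500)
        focal = FocalVariant(id="f", variant_class="splice", contig="c",
                             pos=400, ref="A", alt="T")
        with pytest.raises(ValueError, match="outside"):
            inject_variant(w, focal)


class TestProteinHaplotypes:
    def test_zero_coding_variants_single_reference_haplotype(self):
        ref = toy_reference()
        cohort = make_cohort([("S0", "AFR"), ("S1", "EUR")], [])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        assert len(haps) == 1
        assert haps[0].sequence == TOY_PROTEIN
        assert haps[0].is_reference
        assert haps[0].frequencies == {"AFR": 1.0, "EUR": 1.0}

    def test_synonymous_collapses(self):
        ref = toy_reference()
        # codon 1 is AAA(K); third base at CDS nt 5 -> genomic UP+5; A->G => AAG(K)
        cohort = make_cohort([("S0", "EUR")],
                             [(UP + 5, "A", "G", 0.99, [[0, 1]])])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        assert len(haps) == 1
        assert haps[0].sequence == TOY_PROTEIN

    def test_shared_missense_frequencies(self):
        ref = toy_reference()
        # codon 11 CCC(P) -> ACC(T): genomic UP + 33
        rec = (UP + 33, "C", "A", 0.99, [[0, 1], [0, 0]])
        cohort = make_cohort([("S0", "EUR"), ("S1", "EUR")], [rec])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        assert len(haps) == 2
        by_ref = {h.is_reference: h for h in haps}
        # direct chromosome count: 3 of 4 reference, 1 of 4 carrier
        assert by_ref[True].frequencies["EUR"] == pytest.approx(0.75)
        assert by_ref[False].frequencies["EUR"] == pytest.approx(0.25)
        assert by_ref[False].sequence[11] == "T"

    def test_premature_stop_flagged(self):
        ref = toy_reference()
        # codon 10 TAC(Y) -> TAA(stop): third base genomic UP + 32
        cohort = make_cohort([("S0", "EUR")],
                             [(UP + 32, "C", "A", 0.99, [[0, 1]])])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        trunc = [h for h in haps if h.truncated]
        assert len(trunc) == 1
        assert trunc[0].sequence == TOY_PROTEIN[:10]

    def test_minus_strand_reconstruction(self):
        ref = toy_reference("-")
        assert ref.protein_sequence(ref.transcripts[0]) == TOY_PROTEIN
        # genomic SNV; expected protein via independent revcomp+translate
        pos = UP + 7
        base = ref.contigs["c"]
        alt = "G" if base[pos] != "G" else "T"
        cohort = make_cohort([("S0", "EUR")],
                             [(pos, base[pos], alt, 0.99, [[0, 1]])])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        mutated = splice_apply(base, [(pos, base[pos], alt)])
        expected = translate_oracle(revcomp(mutated[UP : UP + len(TOY_CDS)]))
        expected = expected.split("*")[0]
        assert any(h.sequence == expected for h in haps)

    def test_frequencies_sum_to_one_per_group(self, reference, cohort):
        for tx in reference.transcripts:
            haps = build_protein_haplotypes(cohort, reference, tx)
            groups = haps[0].frequencies.keys()
            for g in groups:
                total = sum(h.frequencies[g] for h in haps)
                assert total == pytest.approx(1.0)

    def test_round_trip_variants_reproduce_sequence(self, reference, cohort):
        """Applying a haplotype's variant list to the reference CDS and
        translating reproduces its stored sequence (independent oracle)."""
        by_id = {r.id: r for r in cohort.records}
        for tx in reference.transcripts:
            (s, e) = tx.exons[0][0], tx.exons[-1][1]
            for hap in build_protein_haplotypes(cohort, reference, tx):
                variants = [(by_id[v].pos, by_id[v].ref, by_id[v].alt)
                            for v in hap.variants]
                # restrict oracle to variants strictly inside one exon
                if any(not any(es < p and p + len(r) < ee
                               for es, ee in tx.exons)
                       for p, r, a in variants):
                    continue
                full = splice_apply(reference.contigs[tx.contig], variants)
                exon_seqs = []
                for es, ee in tx.exons:
                    shift_s = length_shift_before(variants, es)
                    shift_e = length_shift_before(variants, ee)
                    exon_seqs.append(full[es + shift_s : ee + shift_e])
                cds = "".join(exon_seqs)
                if tx.strand == "-":
                    cds = revcomp(cds)
                aa = translate_oracle(cds).split("*")[0]
                assert aa == hap.sequence


class TestResidueMap:
    def test_identity_without_indels(self):
        ref = toy_reference()
        cohort = make_cohort([("S0", "EUR")], [])
        hap = build_protein_haplotypes(cohort, ref, ref.transcripts[0])[0]
        for k in range(len(TOY_PROTEIN)):
            assert map_residue_index(hap, k) == k

    def _insertion_hap(self):
        ref = toy_reference()
        # 6-nt (2-residue) insertion anchored at the last base of codon 10
        pos = UP + 32  # third base of codon index 10
        base = ref.contigs["c"]
        rec = (pos, base[pos], base[pos] + "GCTGCT", 0.99, [[0, 1]])
        cohort = make_cohort([("S0", "EUR")], [rec])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        return next(h for h in haps if not h.is_reference)

    def test_insertion_shifts_downstream(self):
        hap = self._insertion_hap()
        assert len(hap.sequence) == len(TOY_PROTEIN) + 2
        # hand-counted: residues 0..10 unshifted, then +2
        assert map_residue_index(hap, 10) == 10
        assert map_residue_index(hap, 11) == 13
        assert map_residue_index(hap, 20) == 22

    def test_deletion_spanning_residue(self):
        ref = toy_reference()
        # delete codon 12 entirely (in-frame): anchor at last base of codon 11
        pos = UP + 35
        base = ref.contigs["c"]
        rec = (pos, base[pos : pos + 4], base[pos], 0.99, [[0, 1]])
        cohort = make_cohort([("S0", "EUR")], [rec])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        hap = next(h for h in haps if not h.is_reference)
        assert map_residue_index(hap, 12) is DELETED
        assert map_residue_index(hap, 13) == 12
        assert map_residue_index(hap, 5) == 5

    def test_out_of_range(self):
        ref = toy_reference()
        hap = build_protein_haplotypes(
            make_cohort([("S0", "EUR")], []), ref, ref.transcripts[0])[0]
        with pytest.raises(IndexError):
            map_residue_index(hap, 1000)


class TestInjectMissense:
    def _focal(self, residue, wt, mt):
        return FocalVariant(id="m", variant_class="missense",
                            transcript_id="t1", residue=residue,
                            wt_aa=wt, mt_aa=mt)

    def test_reference_haplotype_substitution(self):
        ref = toy_reference()
        hap = build_protein_haplotypes(
            make_cohort([("S0", "EUR")], []), ref, ref.transcripts[0])[0]
        out = inject_missense(hap, self._focal(11, "P", "L"))
        assert out == TOY_PROTEIN[:11] + "L" + TOY_PROTEIN[12:]

    def test_background_aa_mismatch_incompatible(self):
        ref = toy_reference()
        rec = (UP + 33, "C", "A", 0.99, [[0, 1]])  # P11 -> T11
        cohort = make_cohort([("S0", "EUR")], [rec])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        carrier = next(h for h in haps if not h.is_reference)
        out = inject_missense(carrier, self._focal(11, "P", "L"))
        assert isinstance(out, Incompatible)
        assert out.reason == "background_amino_acid_at_focal_site"

    def test_shifted_injection_after_deletion(self):
        ref = toy_reference()
        pos = UP + 35  # remove codon 12
        base = ref.contigs["c"]
        rec = (pos, base[pos : pos + 4], base[pos], 0.99, [[0, 1]])
        cohort = make_cohort([("S0", "EUR")], [rec])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        hap = next(h for h in haps if not h.is_reference)
        focal = self._focal(15, "P", "W")
        out = inject_missense(hap, focal)
        idx = map_residue_index(hap, 15)  # re-derive via the residue map
        assert out[idx] == "W"
        assert out[:idx] == hap.sequence[:idx]

    def test_deleted_residue_incompatible(self):
        ref = toy_reference()
        pos = UP + 35
        base = ref.contigs["c"]
        rec = (pos, base[pos : pos + 4], base[pos], 0.99, [[0, 1]])
        cohort = make_cohort([("S0", "EUR")], [rec])
        haps = build_protein_haplotypes(cohort, ref, ref.transcripts[0])
        hap = next(h for h in haps if not h.is_reference)
        out = inject_missense(hap, self._focal(12, "P", "L"))
        assert isinstance(out, Incompatible)

    def test_transcript_mismatch_raises(self):
        ref = toy_reference()
        hap = build_protein_haplotypes(
            make_cohort([("S0", "EUR")], []), ref, ref.transcripts[0])[0]
        focal = FocalVariant(id="m", variant_class="missense",
                             transcript_id="other", residue=1, wt_aa="K",
                             mt_aa="R")
        with pytest.raises(ValueError, match="transcript"):
            inject_missense(hap, focal)


class TestFocalVariantValidation:
    def test_missense_requires_protein_locus(self):
        with pytest.raises(ValueError, match="protein locus"):
            FocalVariant(id="x", variant_class="missense")

    def test_wt_equals_mt_rejected(self):
        with pytest.raises(ValueError):
            FocalVariant(id="x", variant_class="missense", transcript_id="t",
                         residue=1, wt_aa="A", mt_aa="A")

    def test_genomic_class_requires_locus(self):
        with pytest.raises(ValueError, match="genomic locus"):
            FocalVariant(id="x", variant_class="splice")

    def test_unknown_class(self):
        with pytest.raises(ValueError, match="class"):
            FocalVariant(id="x", variant_class="nonsense", contig="c", pos=1,
                         ref="A", alt="T")
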