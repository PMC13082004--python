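import pytest

from pvep.synthetic import (
    generate_focal_variants,
    generate_phased_cohort,
    generate_reference,
)


@pytest.fixture(scope="session")
def reference():
    return generate_reference(seed=1, n_contigs=1, contig_length=50_000,
                              n_transcripts=2)


@pytest.fixture(scope="session")
def cohort(reference):
    return generate_phased_cohort(reference, n_samples=20, seed=7,
                                  target_density=2e-3)


@pytest.fixture(scope="session")
def snv_cohort(reference):
    """Denser SNV-only cohort (no indels): equal-length haplotypes."""
    return generate_phased_cohort(reference, n_samples=30, seed=9,
                                  target_density=8e-3, indel_fraction=0.0)


@pytest.fixture(scope="session")
def focal_variants(reference):
    return generate_focal_variants(reference, seed=3, n_missense=3,
                                   n_splice=3, n_utr=3)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately different algorithms from the package)


def splice_apply(seq: str, variants) -> str:
    """Whole-sequence personalization oracle: string splicing, applied in
    descending position order."""
    for pos, ref, alt in sorted(variants, key=lambda v: -v[0]):
        assert seq[pos : pos + len(ref)] == ref
        seq = seq[:pos] + alt + seq[pos + len(ref):]
    return seq


def length_shift_before(variants, boundary: int) -> int:
    """Net length change contributed by variants lying entirely before a
    boundary (no ref span may cross it)."""
    shift = 0
    for pos, ref, alt in variants:
        assert not (pos < boundary < pos + len(ref)), "span crosses boundary"
        if pos + len(ref) <= boundary:
            shift += len(alt) - len(ref)
    return shift


def translate_oracle(cds: str) -> str:
    """Independent translation via Biopython."""
    from Bio.Seq import Seq

    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


def sample_ploid_variants(cohort, sample_idx: int, ploid: int, contig: str,
                          info_min: float = 0.9):
    """All INFO-passing (pos, ref, alt) triples carried by one chromosome."""
    return [
        (r.pos, r.ref, r.alt)
        for r in cohort.records
        if r.contig == contig and r.info_score >= info_min
        and r.genotypes[sample_idx, ploid] == 1
    ]
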