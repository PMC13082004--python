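"""Haplotype engine: personalized DNA windows and protein haplotypes from
phased cohorts, with indel-aware coordinate bookkeeping, plus focal-variant
injection into arbitrary personalized backgrounds.

Coordinates are 0-based half-open internally; VCF I/O converts from
1-based.  Injection collisions (a background variant occupying the focal
site) yield :class:`Incompatible` values, never exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pvep.synthetic import (
    PhasedCohort,
    ReferenceAssembly,
    Transcript,
    VariantRecord,
    revcomp,
    translate,
)

#: INFO-score quality filter applied to background variants throughout.
INFO_MIN = 0.9

CLINICAL_LABELS = ("benign", "likely_benign", "vus", "likely_pathogenic",
                   "pathogenic")
VARIANT_CLASSES = ("missense", "splice", "utr")


class _Deleted:
    """Sentinel: a queried reference position removed by a background indel."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "DELETED"

    def __bool__(self) -> bool:
        return False


DELETED = _Deleted()


@dataclass(frozen=True)
class Incompatible:
    """A focal variant that cannot be injected into this background."""

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass(frozen=True)
class FocalVariant:
    id: str
    variant_class: str  # missense | splice | utr
    clinical_label: str = "vus"
    # genomic locus (splice / utr classes)
    contig: str | None = None
    pos: int | None = None  # 0-based
    ref: str | None = None
    alt: str | None = None
    # protein locus (missense class)
    transcript_id: str | None = None
    residue: int | None = None  # 0-based reference residue index
    wt_aa: str | None = None
    mt_aa: str | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.clinical_label not in CLINICAL_LABELS:
            raise ValueError(f"unknown clinical label {self.clinical_label!r}")
        if self.variant_class == "missense":
            if None in (self.transcript_id, self.residue, self.wt_aa, self.mt_aa):
                raise ValueError(f"{self.id}: missense variant needs a protein locus")
            if self.wt_aa == self.mt_aa:
                raise ValueError(f"{self.id}: wt and mt amino acids are equal")
        else:
            if None in (self.contig, self.pos, self.ref, self.alt):
                raise ValueError(
                    f"{self.id}: {self.variant_class} variant needs a genomic locus"
                )
            if self.ref == self.alt:
                raise ValueError(f"{self.id}: ref and alt alleles are equal")


# ---------------------------------------------------------------------------
# Sequence personalization primitives


def _classify(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "sub"
    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
        return "ins"
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
        return "del"
    raise ValueError(f"unsupported complex allele {ref}>{alt}; pre-normalize inputs")


def _window_bases(seq: str, variants: list[tuple[int, str, str]],
                  start: int, end: int) -> list[str]:
    """Per reference position in [start, end): its personalized replacement.

    Substitutions replace in place; an insertion's extra bases are
    attributed to the anchor position; deleted positions become "".
    Variants only partially overlapping the window are clipped, so this
    agrees position-by-position with whole-contig personalization.
    """
    bases = list(seq[start:end])

    def setb(p: int, value: str) -> None:
        if start <= p < end:
            bases[p - start] = value

    for pos, ref, alt in variants:
        kind = _classify(ref, alt)
        if kind == "sub":
            for k in range(len(ref)):
                setb(pos + k, alt[k])
        elif kind == "ins":
            setb(pos, alt)
        else:  # del
            setb(pos, alt)
            for k in range(1, len(ref)):
                setb(pos + k, "")
    return bases


def _bases_to_seq_and_map(bases: list[str]) -> tuple[str, np.ndarray]:
    """Concatenate per-position bases; map[i] = output index of the
    reference-aligned (first) char of position i, or -1 if deleted."""
    offsets = np.full(len(bases), -1, dtype=np.int64)
    cursor = 0
    for i, b in enumerate(bases):
        if b:
            offsets[i] = cursor
            cursor += len(b)
    return "".join(bases), offsets


def ploid_variants(cohort: PhasedCohort, sample_idx: int, ploid: int,
                   contig: str, start: int, end: int,
                   info_min: float = INFO_MIN,
                   impute_ref: bool = False) -> list[VariantRecord]:
    """INFO-passing phased variants carried by one chromosome that overlap
    [start, end)."""
    out = []
    for rec in cohort.records:
        if rec.contig != contig:
            continue
        s, e = rec.ref_span()
        if e <= start or s >= end:
            continue
        gt = int(rec.genotypes[sample_idx, ploid])
        if gt < 0:
            if impute_ref:
                continue
            raise ValueError(
                f"missing genotype for sample index {sample_idx} at {rec.id}; "
                f"pass impute_ref=True to treat as reference"
            )
        if gt == 1 and rec.info_score >= info_min:
            out.append(rec)
    return out


@dataclass
class PersonalizedWindow:
    sample: str
    ploid: int
    contig: str
    start: int  # requested interval, 0-based half-open (may exceed contig)
    end: int
    seq: str  # personalized sequence, N-padded at contig edges
    offsets: np.ndarray  # ref pos (start..end) -> index into seq, -1 deleted
    pad_left: int
    pad_right: int
    applied_variants: tuple[str, ...] = ()

    def map_position(self, ref_pos: int):
        """Window coordinate of a reference position, or DELETED."""
        if not (self.start <= ref_pos < self.end):
            raise IndexError(f"position {ref_pos} outside window "
                             f"[{self.start},{self.end})")
        off = int(self.offsets[ref_pos - self.start])
        return DELETED if off < 0 else off


def extract_window(
    cohort: PhasedCohort,
    reference: ReferenceAssembly,
    sample: str,
    ploid: int,
    contig: str,
    center: int,
    window_size: int,
    info_min: float = INFO_MIN,
    impute_ref: bool = False,
) -> PersonalizedWindow:
    """Personalized genomic window centered on ``center`` for one chromosome.

    Applies every INFO-passing phased alt allele of the given ploid whose
    reference span overlaps the window; indels change the sequence length
    and shift downstream offsets.  Windows truncated at contig edges are
    padded with N (padding lengths recorded).
    """
    if ploid not in (0, 1):
        raise ValueError("ploid must be 0 or 1")
    if contig not in reference.contigs:
        raise KeyError(f"unknown contig {contig!r}")
    sample_idx = cohort.sample_index(sample)
    seq = reference.contigs[contig]
    start = center - window_size // 2
    end = start + window_size
    cs, ce = max(start, 0), min(end, len(seq))
    pad_left, pad_right = cs - start, end - ce
    records = ploid_variants(cohort, sample_idx, ploid, contig, cs, ce,
                             info_min=info_min, impute_ref=impute_ref)
    bases = _window_bases(seq, [(r.pos, r.ref, r.alt) for r in records], cs, ce)
    body, offsets = _bases_to_seq_and_map(bases)
    offsets = np.where(offsets >= 0, offsets + pad_left, -1)
    full_offsets = np.full(end - start, -1, dtype=np.int64)
    full_offsets[cs - start : ce - start] = offsets
    return PersonalizedWindow(
        sample=sample, ploid=ploid, contig=contig, start=start, end=end,
        seq="N" * pad_left + body + "N" * pad_right,
        offsets=full_offsets, pad_left=pad_left, pad_right=pad_right,
        applied_variants=tuple(r.id for r in records),
    )


def inject_variant(window: PersonalizedWindow, focal: FocalVariant):
    """Inject a genomic focal variant into a personalized window.

    Returns the mutated sequence, or :class:`Incompatible` when the
    personalized bases at the mapped position no longer equal the focal ref
    allele (a background variant occupies or deleted the site).  Only
    length-preserving alleles are supported for focal injection.
    """
    if focal.variant_class == "missense":
        raise ValueError("missense focal variants are injected at the protein level")
    if len(focal.ref) != len(focal.alt):
        raise ValueError(f"{focal.id}: focal indel injection is not supported")
    if focal.contig != window.contig:
        raise ValueError(f"{focal.id}: contig mismatch with window")
    if not (window.start <= focal.pos and
            focal.pos + len(focal.ref) <= window.end):
        raise ValueError(f"{focal.id}: position outside window")
    mapped = []
    for k in range(len(focal.ref)):
        off = window.map_position(focal.pos + k)
        if off is DELETED:
            return Incompatible("site_deleted_by_background_indel")
        mapped.append(off)
    if any(mapped[k + 1] != mapped[k] + 1 for k in range(len(mapped) - 1)):
        return Incompatible("background_insertion_within_focal_span")
    observed = "".join(window.seq[m] for m in mapped)
    if observed != focal.ref:
        return Incompatible("background_allele_at_focal_site")
    chars = list(window.seq)
    for k, m in enumerate(mapped):
        chars[m] = focal.alt[k]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Protein haplotypes


@dataclass
class ProteinHaplotype:
    id: str
    transcript_id: str
    sequence: str  # amino acids, truncated at the first stop if premature
    residue_map: np.ndarray  # ref residue index -> haplotype index, -1 deleted
    variants: tuple[str, ...]  # applied background variant ids
    frequencies: dict[str, float]  # superpopulation -> chromosome frequency
    n_chromosomes: int = 0
    truncated: bool = False  # premature stop or lost stop codon

    @property
    def is_reference(self) -> bool:
        return not self.variants


def _personalized_cds(reference: ReferenceAssembly, transcript: Transcript,
                      variants: list[VariantRecord]) -> tuple[str, np.ndarray]:
    """Apply variants to the spliced CDS; return (haplotype CDS on the
    transcript strand, per-reference-CDS-nt aligned index into it, -1 if
    deleted)."""
    seq = reference.contigs[transcript.contig]
    triples = [(r.pos, r.ref, r.alt) for r in variants]
    groups: list[str] = []
    for s, e in transcript.exons:
        groups.extend(_window_bases(seq, triples, s, e))
    concat = "".join(groups)
    n = len(groups)
    starts = np.full(n, -1, dtype=np.int64)
    cursor = 0
    for i, g in enumerate(groups):
        if g:
            starts[i] = cursor
            cursor += len(g)
    if transcript.strand == "+":
        return concat, starts
    # minus strand: reverse-complement; the reference-aligned char of a
    # multi-base group is its first char in genomic orientation, hence the
    # last char of the group after reverse-complementing.
    m = len(concat)
    aligned = np.full(n, -1, dtype=np.int64)
    for i, g in enumerate(groups):
        if g:
            aligned[n - 1 - i] = m - 1 - starts[i]
    return revcomp(concat), aligned


def _translate_flagged(cds: str) -> tuple[str, bool]:
    aa = translate(cds)
    stop = aa.find("*")
    if stop == -1:
        return aa, True  # stop codon lost
    return aa[:stop], stop < len(aa) - 1 or len(cds) % 3 != 0


def _residue_map(aligned_nt: np.ndarray, n_ref_residues: int,
                 hap_protein_len: int) -> np.ndarray:
    """Codon-level residue map from the per-nucleotide aligned-index map.

    A reference residue maps iff its three codon nucleotides survive,
    remain consecutive, and land in frame in the haplotype CDS."""
    rmap = np.full(n_ref_residues, -1, dtype=np.int64)
    for r in range(n_ref_residues):
        base = 3 * r
        if base + 2 >= len(aligned_nt):
            break
        q = aligned_nt[base : base + 3]
        if (q >= 0).all() and q[1] == q[0] + 1 and q[2] == q[0] + 2 and q[0] % 3 == 0:
            idx = int(q[0]) // 3
            if idx < hap_protein_len:
                rmap[r] = idx
    return rmap


def build_protein_haplotypes(
    cohort: PhasedCohort,
    reference: ReferenceAssembly,
    transcript: Transcript,
    info_min: float = INFO_MIN,
    impute_ref: bool = False,
) -> list[ProteinHaplotype]:
    """Reconstruct unique protein haplotypes for a transcript.

    Every sample x ploid chromosome gets its coding INFO-passing variants
    applied to the CDS on the transcript strand and translated; identical
    amino-acid sequences are deduplicated (synonymous changes collapse).
    Per-superpopulation frequency = carrying chromosomes / (2 * group size).
    Haplotypes with premature (or lost) stop codons are retained but
    flagged ``truncated``.
    """
    n_ref_res = len(reference.protein_sequence(transcript))
    group_sizes = cohort.group_sizes()
    seen: dict[str, ProteinHaplotype] = {}
    counts: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for s_idx, (sample, group) in enumerate(cohort.samples):
        for ploid in (0, 1):
            recs = [
                r for r in ploid_variants(
                    cohort, s_idx, ploid, transcript.contig,
                    transcript.cds_start, transcript.cds_end,
                    info_min=info_min, impute_ref=impute_ref,
                )
                if any(r.ref_span()[1] > s and r.ref_span()[0] < e
                       for s, e in transcript.exons)
            ]
            cds, aligned = _personalized_cds(reference, transcript, recs)
            protein, truncated = _translate_flagged(cds)
            key = protein
            if key not in seen:
                hap = ProteinHaplotype(
                    id=f"{transcript.id}_hap{len(seen)}",
                    transcript_id=transcript.id,
                    sequence=protein,
                    residue_map=_residue_map(aligned, n_ref_res, len(protein)),
                    variants=tuple(r.id for r in recs),
                    frequencies={},
                    truncated=truncated,
                )
                seen[key] = hap
                counts[key] = {}
                order.append(key)
            counts[key][group] = counts[key].get(group, 0) + 1
    haplotypes = []
    for key in order:
        hap = seen[key]
        hap.n_chromosomes = sum(counts[key].values())
        hap.frequencies = {
            g: counts[key].get(g, 0) / (2 * size)
            for g, size in sorted(group_sizes.items())
        }
        haplotypes.append(hap)
    return haplotypes


def map_residue_index(haplotype: ProteinHaplotype, reference_residue_index: int):
    """Haplotype residue index for a reference residue, or DELETED."""
    rmap = haplotype.residue_map
    if not (0 <= reference_residue_index < len(rmap)):
        raise IndexError(
            f"residue {reference_residue_index} outside reference protein "
            f"of length {len(rmap)}"
        )
    idx = int(rmap[reference_residue_index])
    return DELETED if idx < 0 else idx


def inject_missense(haplotype: ProteinHaplotype, focal: FocalVariant):
    """Substitute the focal mt amino acid into a compatible haplotype.

    Compatible iff the mapped residue exists and the haplotype carries the
    focal wt amino acid there; otherwise returns :class:`Incompatible`.
    """
    if focal.variant_class != "missense":
        raise ValueError(f"{focal.id} is not a missense variant")
    if focal.transcript_id != haplotype.transcript_id:
        raise ValueError(f"{focal.id}: transcript mismatch "
                         f"({focal.transcript_id} vs {haplotype.transcript_id})")
    idx = map_residue_index(haplotype, focal.residue)
    if idx is DELETED:
        return Incompatible("residue_deleted_by_background_indel")
    if haplotype.sequence[idx] != focal.wt_aa:
        return Incompatible("background_amino_acid_at_focal_site")
    return haplotype.sequence[:idx] + focal.mt_aa + haplotype.sequence[idx + 1 :]
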