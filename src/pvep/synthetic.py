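"""Self-contained synthetic fixtures: reference assemblies with coding
transcripts, phased diploid cohorts with superpopulation labels, focal
variants of three classes, planted additive + epistatic ground truth for
toy scorers, and toy residue distance maps.

Everything here is deterministic given its seed: generators are pure
functions of (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")

#: 20 canonical amino acids in alphabetical one-letter order; the fixed
#: alphabet used by protein scorer adapters.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS; '*' marks stops, 'X' marks incomplete/ambiguous codons."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aas.append(_CODON_TABLE.get(cds[i : i + 3], "X"))
    return "".join(aas)


class SizingError(ValueError):
    """Requested transcript geometry does not fit the contig."""


@dataclass(frozen=True)
class Transcript:
    id: str
    contig: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted, disjoint
    cds_start: int  # genomic coordinate of CDS start (0-based)
    cds_end: int  # genomic, half-open

    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class ReferenceAssembly:
    contigs: dict[str, str]
    transcripts: list[Transcript]

    def cds_sequence(self, transcript: Transcript) -> str:
        """Spliced CDS on the transcript strand (includes the stop codon)."""
        seq = self.contigs[transcript.contig]
        spliced = "".join(seq[s:e] for s, e in transcript.exons)
        return revcomp(spliced) if transcript.strand == "-" else spliced

    def protein_sequence(self, transcript: Transcript) -> str:
        aa = translate(self.cds_sequence(transcript))
        return aa[:-1] if aa.endswith("*") else aa

    def validate(self) -> None:
        for t in self.transcripts:
            if t.contig not in self.contigs:
                raise ValueError(f"transcript {t.id}: unknown contig {t.contig}")
            length = len(self.contigs[t.contig])
            prev_end = -1
            for s, e in t.exons:
                if not (0 <= s < e <= length):
                    raise ValueError(f"transcript {t.id}: exon ({s},{e}) out of bounds")
                if s < prev_end:
                    raise ValueError(f"transcript {t.id}: exons overlap or unsorted")
                prev_end = e
            if t.exon_length() % 3 != 0:
                raise ValueError(f"transcript {t.id}: CDS length not divisible by 3")
            aa = translate(self.cds_sequence(t))
            if "*" in aa[:-1]:
                raise ValueError(f"transcript {t.id}: internal stop codon")


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    pos: int  # 0-based position of the first ref base
    ref: str
    alt: str
    info_score: float
    genotypes: np.ndarray = field(compare=False)  # (n_samples, 2) int8, phased

    @property
    def id(self) -> str:
        # 1-based in the id, matching VCF output
        return f"{self.contig}:{self.pos + 1}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def ref_span(self) -> tuple[int, int]:
        return self.pos, self.pos + len(self.ref)


@dataclass
class PhasedCohort:
    samples: list[tuple[str, str]]  # (sample id, superpopulation label)
    records: list[VariantRecord]

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def superpopulations(self) -> list[str]:
        return [g for _, g in self.samples]

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for _, g in self.samples:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def validate(self, reference: ReferenceAssembly) -> None:
        for rec in self.records:
            seq = reference.contigs[rec.contig]
            if seq[rec.pos : rec.pos + len(rec.ref)] != rec.ref:
                raise ValueError(f"record {rec.id}: ref allele mismatch")
            if rec.genotypes.shape != (len(self.samples), 2):
                raise ValueError(f"record {rec.id}: ploidy != 2")
            if rec.ref == rec.alt:
                raise ValueError(f"record {rec.id}: ref == alt")
        by_contig: dict[str, list[int]] = {}
        for rec in self.records:
            by_contig.setdefault(rec.contig, []).append(rec.pos)
        for contig, positions in by_contig.items():
            if positions != sorted(positions):
                raise ValueError(f"contig {contig}: records unsorted")


@dataclass
class EpistasisGroundTruth:
    """Planted effect sizes backing the epistatic toy scorer.

    Additive background effects cancel in WT-vs-MUT deltas; they exist so
    the raw sequence score is background-dependent.  Clinical effects and
    interaction terms are what the pVEP delta is expected to recover.
    """

    additive: dict[str, float]  # background variant id -> effect
    clinical: dict[str, float]  # focal variant id -> effect
    interactions: dict[tuple[str, str], float]  # (background, clinical) -> effect
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for b, c in self.interactions:
            if b not in self.additive or c not in self.clinical:
                raise ValueError(f"interaction ({b},{c}) references unknown id")

    @property
    def background_ids(self) -> list[str]:
        return list(self.additive)

    @property
    def clinical_ids(self) -> list[str]:
        return list(self.clinical)

    def raw_score(self, background_present: dict[str, bool],
                  clinical_present: dict[str, bool]) -> float:
        """Noise-free sequence-level score: additive + clinical + interactions."""
        s = sum(e for b, e in self.additive.items() if background_present.get(b))
        s += sum(e for c, e in self.clinical.items() if clinical_present.get(c))
        s += sum(
            e for (b, c), e in self.interactions.items()
            if background_present.get(b) and clinical_present.get(c)
        )
        return s

    def delta_matrix(self, X: np.ndarray, background_ids: list[str],
                     clinical_ids: list[str]) -> np.ndarray:
        """Expected pVEP delta for each (haplotype row of X, clinical id).

        Y[h, j] = clinical_j + sum_i interaction(i, j) * X[h, i].
        """
        X = np.asarray(X, dtype=float)
        n_b = len(background_ids)
        if X.shape[1] != n_b:
            raise ValueError("X columns must match background_ids")
        b_index = {b: i for i, b in enumerate(background_ids)}
        c_index = {c: j for j, c in enumerate(clinical_ids)}
        gamma = np.zeros((n_b, len(clinical_ids)))
        for (b, c), e in self.interactions.items():
            if b in b_index and c in c_index:
                gamma[b_index[b], c_index[c]] = e
        base = np.array([self.clinical[c] for c in clinical_ids])
        return base[None, :] + X @ gamma

    def score_matrix(self, X: np.ndarray, background_ids: list[str],
                     clinical_ids: list[str],
                     rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-haplotype raw scores with every clinical variant injected:
        delta terms plus the additive background contribution (which is
        shared across targets and does not cancel in raw scores), plus
        Gaussian noise at ``noise_sd`` when an rng is supplied."""
        X = np.asarray(X, dtype=float)
        a = np.array([self.additive[b] for b in background_ids])
        Y = self.delta_matrix(X, background_ids, clinical_ids)
        Y = Y + (X @ a)[:, None]
        if rng is not None and self.noise_sd > 0:
            Y = Y + rng.normal(0.0, self.noise_sd, size=Y.shape)
        return Y

    def to_json(self) -> str:
        payload = {
            "additive": self.additive,
            "clinical": self.clinical,
            "interactions": [
                {"background": b, "clinical": c, "effect": e}
                for (b, c), e in self.interactions.items()
            ],
            "noise_sd": self.noise_sd,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EpistasisGroundTruth":
        payload = json.loads(text)
        return cls(
            additive=payload["additive"],
            clinical=payload["clinical"],
            interactions={
                (d["background"], d["clinical"]): d["effect"]
                for d in payload["interactions"]
            },
            noise_sd=payload["noise_sd"],
        )


# ---------------------------------------------------------------------------
# Reference generation


def _random_cds(rng: np.random.Generator, n_residues: int) -> str:
    codons = ["ATG"]
    codons += list(rng.choice(_SENSE_CODONS, size=n_residues - 1))
    codons.append(str(rng.choice(STOP_CODONS)))
    return "".join(codons)


def generate_reference(
    seed: int,
    n_contigs: int = 1,
    contig_length: int = 50_000,
    n_transcripts: int = 2,
    protein_length_range: tuple[int, int] = (80, 160),
    exons_range: tuple[int, int] = (1, 3),
    intron_length_range: tuple[int, int] = (60, 200),
    intergenic_gap: int = 400,
) -> ReferenceAssembly:
    """Generate a random assembly with valid, non-overlapping coding transcripts.

    Transcripts are laid out left-to-right per contig (round-robin across
    contigs); raises :class:`SizingError` if they cannot fit.
    """
    if contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    if n_transcripts < 0:
        raise ValueError("n_transcripts must be >= 0")
    rng = np.random.default_rng(seed)
    contig_names = [f"chr{i + 1}" for i in range(n_contigs)]
    contigs = {
        name: "".join(rng.choice(NUCLEOTIDES, size=contig_length))
        for name in contig_names
    }
    cursors = {name: intergenic_gap for name in contig_names}
    transcripts: list[Transcript] = []
    for t_idx in range(n_transcripts):
        contig = contig_names[t_idx % n_contigs]
        n_res = int(rng.integers(protein_length_range[0], protein_length_range[1] + 1))
        cds = _random_cds(rng, n_res)
        n_exons = int(rng.integers(exons_range[0], exons_range[1] + 1))
        n_exons = min(n_exons, len(cds) // 30 or 1)
        # split the CDS into n_exons chunks of >= 20 nt
        cuts = sorted(rng.choice(np.arange(20, len(cds) - 20), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        bounds = [0, *cuts, len(cds)]
        chunk_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = cds if strand == "+" else revcomp(cds)
        # chunk lengths along the genome follow genomic orientation
        glens = chunk_lens if strand == "+" else chunk_lens[::-1]
        introns = [int(rng.integers(*intron_length_range)) for _ in range(n_exons - 1)]
        span = sum(glens) + sum(introns)
        start = cursors[contig]
        if start + span + intergenic_gap > contig_length:
            raise SizingError(
                f"transcript {t_idx} (span {span} nt) does not fit in contig "
                f"{contig} of length {contig_length}; reduce n_transcripts or "
                f"increase contig_length"
            )
        exons = []
        pos = start
        offset = 0
        seq = contigs[contig]
        for k, glen in enumerate(glens):
            exons.append((pos, pos + glen))
            seq = seq[:pos] + genomic[offset : offset + glen] + seq[pos + glen :]
            offset += glen
            pos += glen
            if k < n_exons - 1:
                pos += introns[k]
        contigs[contig] = seq
        cursors[contig] = pos + intergenic_gap
        transcripts.append(
            Transcript(
                id=f"tx{t_idx + 1}",
                contig=contig,
                strand=strand,
                exons=tuple(exons),
                cds_start=exons[0][0],
                cds_end=exons[-1][1],
            )
        )
    assembly = ReferenceAssembly(contigs=contigs, transcripts=transcripts)
    assembly.validate()
    return assembly


# ---------------------------------------------------------------------------
# Cohort generation


def _assign_superpops(n_samples: int, proportions: dict[str, float]) -> list[str]:
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"superpopulation proportions sum to {total}, not 1")
    groups = sorted(proportions)
    raw = {g: proportions[g] * n_samples for g in groups}
    counts = {g: int(np.floor(raw[g])) for g in groups}
    remainder = n_samples - sum(counts.values())
    # largest fractional part first; ties broken by group name for determinism
    order = sorted(groups, key=lambda g: (-(raw[g] - counts[g]), g))
    for g in order[:remainder]:
        counts[g] += 1
    labels: list[str] = []
    for g in groups:
        labels.extend([g] * counts[g])
    return labels


DEFAULT_SUPERPOPS = {"AFR": 0.3, "AMR": 0.15, "EAS": 0.2, "EUR": 0.25, "SAS": 0.1}

#: Beta allele-frequency spectrum, skewed toward rare variants.
AF_BETA_PARAMS = (0.3, 3.0)


def generate_phased_cohort(
    reference: ReferenceAssembly,
    n_samples: int,
    superpop_proportions: dict[str, float] | None = None,
    target_density: float = 1e-3,
    seed: int = 0,
    indel_fraction: float = 0.1,
    max_indel_length: int = 3,
    info_range: tuple[float, float] = (0.5, 1.0),
) -> PhasedCohort:
    """Simulate a phased diploid cohort against ``reference``.

    Variant counts per contig are Poisson(target_density * length); allele
    frequencies follow Beta(0.3, 3) truncated to (0, 1); genotypes are
    independent Bernoulli draws per chromosome (no linkage).  INFO scores
    are emitted in ``info_range`` skewed toward the upper bound
    (hi - (hi-lo) * Beta(1,4), ~59% passing the 0.9 filter by default) so
    the downstream INFO >= 0.9 quality filter drops a known fraction.
    """
    if superpop_proportions is None:
        superpop_proportions = dict(DEFAULT_SUPERPOPS)
    if not (0 <= target_density <= 0.05):
        raise ValueError("target_density must be in [0, 0.05] variants per bp")
    labels = _assign_superpops(n_samples, superpop_proportions)
    samples = [(f"S{i:04d}", labels[i]) for i in range(n_samples)]
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    min_gap = max_indel_length + 2  # keep ref spans disjoint
    for contig in sorted(reference.contigs):
        seq = reference.contigs[contig]
        length = len(seq)
        n_var = int(rng.poisson(target_density * length))
        if n_var == 0:
            continue
        candidates = np.sort(
            rng.choice(np.arange(5, length - max_indel_length - 2),
                       size=min(n_var, length // min_gap), replace=False)
        )
        # drop the rare positions violating the indel-span spacing gap
        positions: list[int] = []
        last = -min_gap
        for p in candidates:
            if p - last >= min_gap:
                positions.append(int(p))
                last = int(p)
        for pos in positions:
            ref_base = seq[pos]
            if ref_base == "N":
                continue
            u = rng.random()
            if u < indel_fraction / 2:  # deletion
                k = int(rng.integers(1, max_indel_length + 1))
                ref, alt = seq[pos : pos + 1 + k], ref_base
            elif u < indel_fraction:  # insertion
                k = int(rng.integers(1, max_indel_length + 1))
                ref = ref_base
                alt = ref_base + "".join(rng.choice(NUCLEOTIDES, size=k))
            else:  # SNV
                ref = ref_base
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            if ref == alt:
                continue
            af = 0.0
            while not (0.0 < af < 1.0):
                af = float(rng.beta(*AF_BETA_PARAMS))
            gts = (rng.random((n_samples, 2)) < af).astype(np.int8)
            lo, hi = info_range
            info = float(hi - (hi - lo) * rng.beta(1.0, 4.0))
            records.append(
                VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                              info_score=info, genotypes=gts)
            )
    cohort = PhasedCohort(samples=samples, records=records)
    cohort.validate(reference)
    return cohort


# ---------------------------------------------------------------------------
# Planted epistasis


def carrier_counts(cohort: PhasedCohort, record: VariantRecord) -> int:
    return int(record.genotypes.sum())


def plant_epistasis(
    cohort: PhasedCohort,
    n_background: int,
    n_clinical: int,
    n_interactions: int,
    effect_scales: tuple[float, float] = (1.0, 0.5),
    noise_sd: float = 0.0,
    seed: int = 0,
    min_carrier_chromosomes: int = 0,
) -> EpistasisGroundTruth:
    """Plant additive + pairwise-epistatic ground truth on cohort variants.

    Background ids are drawn from the cohort's variant records (optionally
    only those with at least ``min_carrier_chromosomes`` carriers and as
    many non-carriers, so planted pairs are statistically testable);
    clinical ids are synthetic focal identifiers ``clin000``...
    """
    if n_interactions > n_background * n_clinical:
        raise ValueError(
            f"cannot plant {n_interactions} interactions among "
            f"{n_background}x{n_clinical} pairs"
        )
    rng = np.random.default_rng(seed)
    n_chrom = 2 * len(cohort.samples)
    eligible = [
        r.id for r in cohort.records
        if min_carrier_chromosomes
        <= carrier_counts(cohort, r)
        <= n_chrom - min_carrier_chromosomes
    ]
    if len(eligible) < n_background:
        raise ValueError(
            f"only {len(eligible)} eligible background variants, "
            f"need {n_background}"
        )
    background_ids = [str(b) for b in rng.choice(eligible, size=n_background,
                                                 replace=False)]
    clinical_ids = [f"clin{j:03d}" for j in range(n_clinical)]
    add_scale, int_scale = effect_scales
    additive = {
        b: float(rng.normal(0.0, add_scale)) for b in background_ids
    }
    clinical = {
        c: float(-np.abs(rng.normal(1.0, add_scale))) for c in clinical_ids
    }
    pair_idx = rng.choice(n_background * n_clinical, size=n_interactions,
                          replace=False)
    interactions: dict[tuple[str, str], float] = {}
    for k in pair_idx:
        b = background_ids[int(k) // n_clinical]
        c = clinical_ids[int(k) % n_clinical]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        interactions[(b, c)] = float(sign * int_scale * rng.uniform(0.8, 1.2))
    return EpistasisGroundTruth(
        additive=additive, clinical=clinical, interactions=interactions,
        noise_sd=noise_sd,
    )


def presence_matrix(cohort: PhasedCohort, variant_ids: list[str],
                    info_min: float = 0.0) -> np.ndarray:
    """Binary (chromosome x variant) presence matrix, rows ordered
    (sample0/ploid0, sample0/ploid1, sample1/ploid0, ...)."""
    by_id = {r.id: r for r in cohort.records}
    cols = []
    for vid in variant_ids:
        if vid not in by_id:
            raise KeyError(f"unknown variant id {vid!r}")
        rec = by_id[vid]
        col = rec.genotypes.reshape(-1)
        if rec.info_score < info_min:
            col = np.zeros_like(col)
        cols.append(col)
    if not cols:
        return np.zeros((2 * len(cohort.samples), 0), dtype=np.int8)
    return np.stack(cols, axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# Focal variants


def generate_focal_variants(
    reference: ReferenceAssembly,
    seed: int,
    n_missense: int = 5,
    n_splice: int = 5,
    n_utr: int = 5,
) -> list:
    """Toy focal-variant table spanning all three classes.

    Missense variants are residue substitutions on random transcripts;
    splice variants are SNVs near exon boundaries; UTR variants are SNVs in
    intergenic/flanking sequence near transcripts.  Clinical labels cycle
    through the five-level ClinVar-style scale.
    """
    from pvep.haplotypes import FocalVariant  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    labels = ["benign", "likely_benign", "vus", "likely_pathogenic", "pathogenic"]
    focals: list[FocalVariant] = []
    if (n_missense or n_splice) and not reference.transcripts:
        raise ValueError("reference has no transcripts for coding focal variants")
    for i in range(n_missense):
        tx = reference.transcripts[int(rng.integers(len(reference.transcripts)))]
        protein = reference.protein_sequence(tx)
        residue = int(rng.integers(1, len(protein)))  # skip the start Met
        wt = protein[residue]
        mt = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
        focals.append(FocalVariant(
            id=f"mis{i:03d}", variant_class="missense",
            transcript_id=tx.id, residue=residue, wt_aa=wt, mt_aa=mt,
            clinical_label=labels[i % len(labels)],
        ))
    for i in range(n_splice):
        tx = reference.transcripts[int(rng.integers(len(reference.transcripts)))]
        s, e = tx.exons[int(rng.integers(len(tx.exons)))]
        boundary = s if rng.random() < 0.5 else e
        pos = int(np.clip(boundary + int(rng.integers(-10, 11)), 1,
                          len(reference.contigs[tx.contig]) - 2))
        ref = reference.contigs[tx.contig][pos]
        if ref == "N":
            ref = reference.contigs[tx.contig][pos - 1]
            pos -= 1
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        focals.append(FocalVariant(
            id=f"spl{i:03d}", variant_class="splice",
            contig=tx.contig, pos=pos, ref=ref, alt=alt,
            clinical_label=labels[i % len(labels)],
        ))
    contigs = sorted(reference.contigs)
    for i in range(n_utr):
        contig = contigs[int(rng.integers(len(contigs)))]
        seq = reference.contigs[contig]
        covered = [(t.cds_start, t.cds_end) for t in reference.transcripts
                   if t.contig == contig]
        pos = None
        for _ in range(1000):
            cand = int(rng.integers(100, len(seq) - 100))
            if all(not (s <= cand < e) for s, e in covered):
                pos = cand
                break
        if pos is None:
            raise ValueError("could not place a non-coding focal variant")
        ref = seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        focals.append(FocalVariant(
            id=f"utr{i:03d}", variant_class="utr",
            contig=contig, pos=pos, ref=ref, alt=alt,
            clinical_label=labels[i % len(labels)],
        ))
    return focals


# ---------------------------------------------------------------------------
# Toy distance maps


def generate_toy_distance_map(
    n_residues: int,
    n_contact_clusters: int = 2,
    seed: int = 0,
    cluster_size: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric chain-like residue distance map (Angstrom) + confidences.

    Baseline distance grows linearly with sequence separation (adjacent
    residues sit under the 8 A contact threshold, |i-j| >= 2 sits above
    it); each contact cluster pulls a small off-diagonal block into contact
    range.  Returns (distance_map, plddt-like confidence in [0, 100]).
    """
    if n_residues < 10:
        raise ValueError("n_residues must be >= 10")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_residues)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    jitter = rng.uniform(-0.4, 0.4, size=(n_residues, n_residues))
    jitter = (jitter + jitter.T) / 2
    dist = 5.0 * sep + jitter
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    for _ in range(n_contact_clusters):
        i0 = int(rng.integers(0, n_residues - cluster_size))
        j0 = int(rng.integers(0, n_residues - cluster_size))
        if abs(i0 - j0) < cluster_size + 2:
            j0 = (j0 + cluster_size + 4) % (n_residues - cluster_size)
        block = rng.uniform(4.0, 7.5, size=(cluster_size, cluster_size))
        for a in range(cluster_size):
            for b in range(cluster_size):
                i, j = i0 + a, j0 + b
                if i == j:
                    continue
                dist[i, j] = block[a, b]
                dist[j, i] = block[a, b]
    confidence = rng.uniform(50.0, 100.0, size=n_residues)
    return dist, confidence
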