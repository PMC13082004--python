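"""Scorer-adapter contract, delta-score metrics, deterministic toy scorers,
and the main personalized-VEP loop.

Three scoring modes are supported behind one adapter interface:

* ``protein`` — sequence (+ optional masked position) -> per-position
  log-probabilities over the 20 amino acids;
* ``splice`` — nucleotide sequence -> per-position acceptor/donor
  probabilities in [0, 1];
* ``coverage`` — nucleotide sequence -> per-position, per-track
  non-negative coverage.

VEP scores are deltas between a personalized background sequence with and
without the focal variant; negative protein deltas mean less fit (more
pathogenic).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from pvep.haplotypes import (
    FocalVariant,
    Incompatible,
    build_protein_haplotypes,
    extract_window,
    inject_missense,
    inject_variant,
)
from pvep.synthetic import (
    AMINO_ACIDS,
    EpistasisGroundTruth,
    PhasedCohort,
    ReferenceAssembly,
)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

PROTEIN_STRATEGIES = ("masked_marginals", "wt_marginals", "pseudo_ppl")

#: Fixed channel order; also the argmax tie-break order for effect classes.
EFFECT_CLASSES = ("acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss")

SPLICE_METRICS = (*EFFECT_CLASSES, "vep", "class_code")
COVERAGE_METRICS = ("covr",)


class ScorerAdapter:
    """Base scorer adapter.  Subclasses implement the method(s) matching
    their ``mode`` and must be deterministic given identical input."""

    mode: str = ""
    name: str = "adapter"
    #: minimum input length the scorer needs; None = unconstrained
    context_length: int | None = None
    n_tracks: int = 1

    def protein_logprobs(self, seq: str, masked_pos: int | None = None) -> np.ndarray:
        raise NotImplementedError

    def splice_probs(self, seq: str) -> np.ndarray:
        raise NotImplementedError

    def coverage(self, seq: str) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Delta-score metrics


def _check_protein_pair(adapter: ScorerAdapter, seq_wt: str, seq_mut: str) -> list[int]:
    if adapter.mode != "protein":
        raise ValueError(f"adapter mode {adapter.mode!r} is not 'protein'")
    if len(seq_wt) != len(seq_mut):
        raise ValueError(
            "wt/mut length mismatch: protein deltas are defined for "
            "substitution-only pairs (indel-bearing pairs are rejected)"
        )
    return [i for i, (a, b) in enumerate(zip(seq_wt, seq_mut)) if a != b]


def protein_delta(adapter: ScorerAdapter, seq_wt: str, seq_mut: str,
                  strategy: str = "masked_marginals") -> float:
    """Delta log-likelihood between mutant and wild-type protein sequences.

    * ``masked_marginals`` — sum over differing positions i of
      logp(mt_i | wt masked at i) - logp(wt_i | same pass);
    * ``wt_marginals`` — same sums from a single unmasked WT forward pass;
    * ``pseudo_ppl`` — full pseudo-log-likelihood of mut minus wt, each
      position scored with its own sequence masked at that position.

    Negative values indicate a less fit (more pathogenic) mutant.
    """
    if strategy not in PROTEIN_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    diffs = _check_protein_pair(adapter, seq_wt, seq_mut)
    if not diffs:
        return 0.0
    if strategy == "masked_marginals":
        total = 0.0
        for i in diffs:
            lp = adapter.protein_logprobs(seq_wt, masked_pos=i)
            total += lp[i, AA_INDEX[seq_mut[i]]] - lp[i, AA_INDEX[seq_wt[i]]]
        return float(total)
    if strategy == "wt_marginals":
        lp = adapter.protein_logprobs(seq_wt)
        return float(sum(
            lp[i, AA_INDEX[seq_mut[i]]] - lp[i, AA_INDEX[seq_wt[i]]]
            for i in diffs
        ))
    # pseudo_ppl
    def pll(seq: str) -> float:
        total = 0.0
        for j in range(len(seq)):
            lp = adapter.protein_logprobs(seq, masked_pos=j)
            total += lp[j, AA_INDEX[seq[j]]]
        return total

    return float(pll(seq_mut) - pll(seq_wt))


@dataclass(frozen=True)
class SpliceDelta:
    acceptor_gain: float
    acceptor_loss: float
    donor_gain: float
    donor_loss: float
    vep: float
    effect_class: str

    @property
    def class_code(self) -> int:
        return EFFECT_CLASSES.index(self.effect_class)

    def as_dict(self) -> dict[str, float]:
        return {
            "acceptor_gain": self.acceptor_gain,
            "acceptor_loss": self.acceptor_loss,
            "donor_gain": self.donor_gain,
            "donor_loss": self.donor_loss,
            "vep": self.vep,
            "class_code": float(self.class_code),
        }


def splice_delta(adapter: ScorerAdapter, seq_wt: str, seq_mut: str,
                 scoring_window: int = 101) -> SpliceDelta:
    """Four splice delta scores over a centered scoring window.

    Gains are the windowed max of (P_mut - P_wt), losses of (P_wt - P_mut),
    per channel, each clipped at >= 0.  The VEP score is the max of the
    four; the effect class is the argmax channel (ties broken in fixed
    channel order).
    """
    if adapter.mode != "splice":
        raise ValueError(f"adapter mode {adapter.mode!r} is not 'splice'")
    if scoring_window % 2 == 0:
        raise ValueError("scoring_window must be odd (centered window)")
    if len(seq_wt) != len(seq_mut):
        raise ValueError("wt/mut length mismatch (SNV focal expected)")
    if len(seq_wt) < scoring_window:
        raise ValueError("sequence shorter than the scoring window")
    p_wt = np.asarray(adapter.splice_probs(seq_wt), dtype=float)
    p_mut = np.asarray(adapter.splice_probs(seq_mut), dtype=float)
    center = len(seq_wt) // 2
    half = scoring_window // 2
    win = slice(center - half, center + half + 1)
    d = p_mut[win] - p_wt[win]
    deltas = {
        "acceptor_gain": max(float(d[:, 0].max()), 0.0),
        "acceptor_loss": max(float(-d[:, 0].min()), 0.0),
        "donor_gain": max(float(d[:, 1].max()), 0.0),
        "donor_loss": max(float(-d[:, 1].min()), 0.0),
    }
    effect_class = max(EFFECT_CLASSES, key=lambda c: (deltas[c], -EFFECT_CLASSES.index(c)))
    return SpliceDelta(**deltas, vep=deltas[effect_class], effect_class=effect_class)


def covr(coverage_mut: np.ndarray, coverage_wt: np.ndarray,
         epsilon: float = 1e-6, absolute: bool = False) -> float:
    """Coverage-ratio score: the maximum (signed) log2 fold-change in
    predicted coverage over all positions and tracks, with pseudocount
    ``epsilon``.  ``absolute=True`` maximizes |log2 fold-change| instead.
    """
    mut = np.asarray(coverage_mut, dtype=float)
    wt = np.asarray(coverage_wt, dtype=float)
    if mut.shape != wt.shape:
        raise ValueError("coverage arrays must have identical shapes")
    if (mut < 0).any() or (wt < 0).any():
        raise ValueError("coverage values must be non-negative")
    ratios = np.log2((mut + epsilon) / (wt + epsilon))
    if absolute:
        flat = ratios.ravel()
        return float(flat[np.argmax(np.abs(flat))])
    return float(ratios.max())


# ---------------------------------------------------------------------------
# Toy scorer adapters


class PssmProteinAdapter(ScorerAdapter):
    """Position-additive protein scorer backed by a (length x 20)
    log-probability table; the sequence content never enters, so scores are
    background-independent by construction."""

    mode = "protein"
    name = "pssm"

    def __init__(self, logprob_table: np.ndarray):
        table = np.asarray(logprob_table, dtype=float)
        if table.ndim != 2 or table.shape[1] != len(AMINO_ACIDS):
            raise ValueError("logprob table must be (length, 20)")
        # normalize each position so logsumexp == 0
        self.table = table - logsumexp(table, axis=1, keepdims=True)

    @classmethod
    def from_random(cls, seed: int, length: int, scale: float = 2.0
                    ) -> "PssmProteinAdapter":
        rng = np.random.default_rng(seed)
        return cls(rng.normal(0.0, scale, size=(length, len(AMINO_ACIDS))))

    def protein_logprobs(self, seq: str, masked_pos: int | None = None) -> np.ndarray:
        if len(seq) > len(self.table):
            raise ValueError(
                f"sequence length {len(seq)} exceeds PSSM length {len(self.table)}"
            )
        return self.table[: len(seq)]


class EpistaticProteinAdapter(ScorerAdapter):
    """Protein scorer realizing an :class:`EpistasisGroundTruth` through
    haplotype-conditional log-probabilities.

    The raw sequence score sums planted additive background effects,
    clinical effects, and background x clinical interactions, with
    presence read off the sequence via residue catalogs.  Masked
    log-probabilities at a position are the softmax of raw scores over the
    20 possible residues there, so masked-marginal deltas reproduce the
    planted clinical + interaction sums exactly at noise_sd = 0.
    """

    mode = "protein"
    name = "epistatic"

    def __init__(
        self,
        truth: EpistasisGroundTruth,
        reference_protein: str,
        background_catalog: dict[str, tuple[int, str]],
        clinical_catalog: dict[str, tuple[int, str, str]],
        seed: int = 0,
    ):
        self.truth = truth
        self.reference_protein = reference_protein
        self.background_catalog = dict(background_catalog)
        self.clinical_catalog = dict(clinical_catalog)
        self.seed = seed
        positions = [r for r, _ in background_catalog.values()]
        positions += [r for r, _, _ in clinical_catalog.values()]
        if len(set(positions)) != len(positions):
            raise ValueError("catalog residue positions must be distinct")

    def _presence(self, seq: str) -> tuple[dict[str, bool], dict[str, bool]]:
        bg = {
            b: (r < len(seq) and seq[r] == alt)
            for b, (r, alt) in self.background_catalog.items()
        }
        cl = {
            c: (r < len(seq) and seq[r] == mt)
            for c, (r, _wt, mt) in self.clinical_catalog.items()
        }
        return bg, cl

    def raw_score(self, seq: str) -> float:
        bg, cl = self._presence(seq)
        score = self.truth.raw_score(bg, cl)
        if self.truth.noise_sd > 0:
            h = zlib.crc32(seq.encode()) ^ (self.seed & 0xFFFFFFFF)
            score += float(
                np.random.default_rng(h).normal(0.0, self.truth.noise_sd)
            )
        return score

    def protein_logprobs(self, seq: str, masked_pos: int | None = None) -> np.ndarray:
        rows = range(len(seq)) if masked_pos is None else [masked_pos]
        out = np.full((len(seq), len(AMINO_ACIDS)), -np.log(len(AMINO_ACIDS)))
        for p in rows:
            u = np.array([
                self.raw_score(seq[:p] + a + seq[p + 1 :]) for a in AMINO_ACIDS
            ])
            out[p] = u - logsumexp(u)
        return out


class MotifSpliceAdapter(ScorerAdapter):
    """Dinucleotide-motif splice scorer: AG immediately upstream drives the
    acceptor channel, GT immediately downstream the donor channel, mapped
    through a logistic squashing.  Destroying an AG collapses the acceptor
    probability, enabling compensatory-variant scenarios at toy scale."""

    mode = "splice"
    name = "motif_splice"

    def __init__(self, weight: float = 12.0, bias: float = -6.0):
        self.weight = weight
        self.bias = bias

    def splice_probs(self, seq: str) -> np.ndarray:
        n = len(seq)
        acc = np.zeros(n)
        don = np.zeros(n)
        for p in range(n):
            acc[p] = 1.0 if p >= 2 and seq[p - 2 : p] == "AG" else 0.0
            don[p] = 1.0 if p + 3 <= n and seq[p + 1 : p + 3] == "GT" else 0.0
        probs = expit(self.weight * np.stack([acc, don], axis=1) + self.bias)
        return probs


class TabulatedCoverageAdapter(ScorerAdapter):
    """Motif-driven coverage scorer: baseline coverage plus an amplitude
    bump wherever the motif occurs, per track (track t uses the motif
    shifted by t positions so tracks differ)."""

    mode = "coverage"
    name = "motif_coverage"

    def __init__(self, motif: str = "TATA", amplitude: float = 3.0,
                 baseline: float = 1.0, n_tracks: int = 1, halo: int = 5):
        self.motif = motif
        self.amplitude = amplitude
        self.baseline = baseline
        self.n_tracks = n_tracks
        self.halo = halo

    def coverage(self, seq: str) -> np.ndarray:
        n = len(seq)
        cov = np.full((n, self.n_tracks), self.baseline, dtype=float)
        m = len(self.motif)
        for p in range(n - m + 1):
            if seq[p : p + m] == self.motif:
                lo, hi = max(0, p - self.halo), min(n, p + m + self.halo)
                cov[lo:hi] += self.amplitude
        return cov


def make_toy_scorer(kind: str, **config) -> ScorerAdapter:
    """Dispatch toy scorer construction by family name."""
    if kind == "pssm":
        if "table" in config:
            return PssmProteinAdapter(config["table"])
        return PssmProteinAdapter.from_random(
            seed=config.get("seed", 0), length=config["length"],
            scale=config.get("scale", 2.0),
        )
    if kind == "epistatic":
        return EpistaticProteinAdapter(
            truth=config["truth"],
            reference_protein=config["reference_protein"],
            background_catalog=config["background_catalog"],
            clinical_catalog=config["clinical_catalog"],
            seed=config.get("seed", 0),
        )
    if kind == "motif_splice":
        return MotifSpliceAdapter(
            weight=config.get("weight", 12.0), bias=config.get("bias", -6.0)
        )
    if kind == "motif_coverage":
        return TabulatedCoverageAdapter(
            motif=config.get("motif", "TATA"),
            amplitude=config.get("amplitude", 3.0),
            baseline=config.get("baseline", 1.0),
            n_tracks=config.get("n_tracks", 1),
        )
    raise ValueError(f"unknown toy scorer kind {kind!r}")


# ---------------------------------------------------------------------------
# Result store and the main loop


@dataclass
class MetricConfig:
    splice_window_size: int = 10_101
    splice_scoring_window: int = 101
    coverage_window_size: int = 524_288
    protein_strategies: tuple[str, ...] = ("masked_marginals",)
    info_min: float = 0.9
    include_truncated: bool = False
    model_name: str = "toy"
    seed: int = 0

    def window_for_class(self, variant_class: str) -> int:
        return (self.splice_window_size if variant_class == "splice"
                else self.coverage_window_size)


ALL_DNA_METRICS = tuple(dict.fromkeys(SPLICE_METRICS + COVERAGE_METRICS))


@dataclass
class DnaContigStore:
    contig: str
    focal_ids: list[str]
    focal_classes: list[str]
    focal_labels: list[str]
    samples: list[str]
    metrics: list[str]
    values: np.ndarray  # (site, sample, ploid=2, metric), NaN = missing

    def metric_slice(self, focal_id: str, metric: str) -> np.ndarray:
        i = self.focal_ids.index(focal_id)
        j = self.metrics.index(metric)
        return self.values[i, :, :, j]


@dataclass
class PvepStore:
    dna: dict[str, DnaContigStore] = field(default_factory=dict)
    protein: pd.DataFrame = field(default_factory=pd.DataFrame)
    incompatibilities: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)

    def dna_scores(self, focal: FocalVariant, metric: str = "vep") -> np.ndarray:
        """Flat vector of non-missing per-chromosome scores for one focal."""
        store = self.dna[focal.contig]
        values = store.metric_slice(focal.id, metric).reshape(-1)
        return values[~np.isnan(values)]

    def protein_scores(self, focal_id: str, strategy: str = "masked_marginals",
                       weighted_by_chromosomes: bool = True) -> np.ndarray:
        """Per-chromosome protein scores for one focal variant (each unique
        haplotype repeated by its chromosome count when weighted)."""
        df = self.protein
        if df.empty:
            return np.array([])
        sel = df[(df.focal_id == focal_id) & (df.strategy == strategy)
                 & df.compatible]
        if weighted_by_chromosomes:
            return np.repeat(sel.score.to_numpy(float),
                             sel.n_chromosomes.to_numpy(int))
        return sel.score.to_numpy(float)

    def n_scored(self) -> dict[str, int]:
        dna_scored = 0
        for s in self.dna.values():
            for i, vclass in enumerate(s.focal_classes):
                metric = "vep" if vclass == "splice" else "covr"
                k = s.metrics.index(metric)
                dna_scored += int((~np.isnan(s.values[i, :, :, k])).sum())
        protein_scored = int(self.protein.compatible.sum()) if not self.protein.empty else 0
        return {"dna": dna_scored, "protein": protein_scored}


def run_pvep(
    focal_variants: list[FocalVariant],
    cohort: PhasedCohort,
    reference: ReferenceAssembly,
    adapters: dict[str, ScorerAdapter],
    config: MetricConfig | None = None,
) -> PvepStore:
    """Main pVEP loop.

    For every (focal, sample, ploid): the WT sequence is the personalized
    background, the MUT sequence adds the focal variant, both are scored,
    and the delta is stored per metric.  Incompatible (focal, haplotype)
    pairs are stored as missing with a logged reason; both haploid copies
    of each diploid individual are scored independently.
    """
    config = config or MetricConfig()
    for vclass in {f.variant_class for f in focal_variants}:
        mode = {"missense": "protein", "splice": "splice", "utr": "coverage"}[vclass]
        if mode not in adapters:
            raise ValueError(f"no adapter configured for mode {mode!r}")
        adapter = adapters[mode]
        if adapter.mode != mode:
            raise ValueError(f"adapter for {mode!r} has mode {adapter.mode!r}")
        if mode == "splice" and adapter.context_length is not None:
            if adapter.context_length > config.splice_window_size:
                raise ValueError(
                    "adapter context exceeds the configured splice window"
                )
    incompat_rows: list[dict] = []

    # ---- DNA side -------------------------------------------------------
    dna_stores: dict[str, DnaContigStore] = {}
    dna_focals = [f for f in focal_variants if f.variant_class in ("splice", "utr")]
    by_contig: dict[str, list[FocalVariant]] = {}
    for f in dna_focals:
        by_contig.setdefault(f.contig, []).append(f)
    metrics = list(ALL_DNA_METRICS)
    for contig, focals in sorted(by_contig.items()):
        n_sites, n_samples = len(focals), len(cohort.samples)
        values = np.full((n_sites, n_samples, 2, len(metrics)), np.nan)
        for i, focal in enumerate(focals):
            window_size = config.window_for_class(focal.variant_class)
            adapter = adapters["splice" if focal.variant_class == "splice"
                               else "coverage"]
            for j, (sample, _group) in enumerate(cohort.samples):
                for ploid in (0, 1):
                    window = extract_window(
                        cohort, reference, sample, ploid, contig,
                        center=focal.pos, window_size=window_size,
                        info_min=config.info_min,
                    )
                    mut = inject_variant(window, focal)
                    if isinstance(mut, Incompatible):
                        incompat_rows.append({
                            "focal_id": focal.id, "sample": sample,
                            "ploid": ploid, "reason": mut.reason,
                        })
                        continue
                    if focal.variant_class == "splice":
                        sd = splice_delta(adapter, window.seq, mut,
                                          config.splice_scoring_window)
                        for name, val in sd.as_dict().items():
                            values[i, j, ploid, metrics.index(name)] = val
                    else:
                        c = covr(adapter.coverage(mut), adapter.coverage(window.seq))
                        values[i, j, ploid, metrics.index("covr")] = c
        dna_stores[contig] = DnaContigStore(
            contig=contig,
            focal_ids=[f.id for f in focals],
            focal_classes=[f.variant_class for f in focals],
            focal_labels=[f.clinical_label for f in focals],
            samples=cohort.sample_ids,
            metrics=metrics,
            values=values,
        )

    # ---- protein side ---------------------------------------------------
    protein_rows: list[dict] = []
    missense = [f for f in focal_variants if f.variant_class == "missense"]
    hap_cache: dict[str, list] = {}
    tx_by_id = {t.id: t for t in reference.transcripts}
    for focal in missense:
        if focal.transcript_id not in tx_by_id:
            raise KeyError(f"{focal.id}: unknown transcript {focal.transcript_id}")
        if focal.transcript_id not in hap_cache:
            hap_cache[focal.transcript_id] = build_protein_haplotypes(
                cohort, reference, tx_by_id[focal.transcript_id],
                info_min=config.info_min,
            )
        adapter = adapters["protein"]
        for hap in hap_cache[focal.transcript_id]:
            if hap.truncated and not config.include_truncated:
                incompat_rows.append({
                    "focal_id": focal.id, "sample": hap.id, "ploid": -1,
                    "reason": "truncated_haplotype_filtered",
                })
                continue
            mut = inject_missense(hap, focal)
            if isinstance(mut, Incompatible):
                incompat_rows.append({
                    "focal_id": focal.id, "sample": hap.id, "ploid": -1,
                    "reason": mut.reason,
                })
                for strategy in config.protein_strategies:
                    protein_rows.append({
                        "model": config.model_name,
                        "transcript": focal.transcript_id,
                        "haplotype": hap.id, "strategy": strategy,
                        "focal_id": focal.id,
                        "clinical_label": focal.clinical_label,
                        "score": np.nan, "n_chromosomes": hap.n_chromosomes,
                        "compatible": False, "reason": mut.reason,
                    })
                continue
            for strategy in config.protein_strategies:
                score = protein_delta(adapter, hap.sequence, mut, strategy)
                protein_rows.append({
                    "model": config.model_name,
                    "transcript": focal.transcript_id,
                    "haplotype": hap.id, "strategy": strategy,
                    "focal_id": focal.id,
                    "clinical_label": focal.clinical_label,
                    "score": score, "n_chromosomes": hap.n_chromosomes,
                    "compatible": True, "reason": "",
                })

    provenance = {
        "adapters": {mode: a.name for mode, a in adapters.items()},
        "model": config.model_name,
        "seed": config.seed,
        "windows": {
            "splice": config.splice_window_size,
            "splice_scoring": config.splice_scoring_window,
            "coverage": config.coverage_window_size,
        },
        "info_min": config.info_min,
        "n_focal": len(focal_variants),
        "n_samples": len(cohort.samples),
        "strategies": list(config.protein_strategies),
    }
    return PvepStore(
        dna=dna_stores,
        protein=pd.DataFrame(
            protein_rows,
            columns=["model", "transcript", "haplotype", "strategy", "focal_id",
                     "clinical_label", "score", "n_chromosomes", "compatible",
                     "reason"],
        ),
        incompatibilities=pd.DataFrame(
            incompat_rows, columns=["focal_id", "sample", "ploid", "reason"]
        ),
        provenance=provenance,
    )
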