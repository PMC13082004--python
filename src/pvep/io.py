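"""File contracts: FASTA / GFF3 / VCF round trips for the synthetic
fixtures, the chunked DNA score store (zarr, with a plain-TSV export),
protein score tables in the nested parquet layout, run configuration and
provenance.

All writers are deterministic: identical inputs produce byte-identical
files (no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pvep.haplotypes import FocalVariant, ProteinHaplotype
from pvep.scoring import DnaContigStore, PvepStore
from pvep.synthetic import (
    EpistasisGroundTruth,
    PhasedCohort,
    ReferenceAssembly,
    Transcript,
    VariantRecord,
)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(reference: ReferenceAssembly, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(reference.contigs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(reference: ReferenceAssembly, path) -> None:
    lines = ["##gff-version 3"]
    for name, seq in sorted(reference.contigs.items()):
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for t in reference.transcripts:
        span = (t.exons[0][0] + 1, t.exons[-1][1])
        lines.append("\t".join([
            t.contig, "pvep", "mRNA", str(span[0]), str(span[1]), ".",
            t.strand, ".", f"ID={t.id}",
        ]))
        for k, (s, e) in enumerate(t.exons):
            lines.append("\t".join([
                t.contig, "pvep", "exon", str(s + 1), str(e), ".",
                t.strand, ".", f"ID={t.id}.exon{k};Parent={t.id}",
            ]))
        lines.append("\t".join([
            t.contig, "pvep", "CDS", str(t.cds_start + 1), str(t.cds_end), ".",
            t.strand, "0", f"ID={t.id}.cds;Parent={t.id}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[Transcript]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", keep_order=True)
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        cds_start = min(s for s, _ in cds)
        cds_end = max(e for _, e in cds)
        transcripts.append(Transcript(
            id=mrna.id, contig=mrna.seqid, strand=mrna.strand,
            exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
        ))
    return transcripts


def read_reference(fasta_path, gff3_path) -> ReferenceAssembly:
    return ReferenceAssembly(
        contigs=read_fasta(fasta_path), transcripts=read_gff3(gff3_path)
    )


# ---------------------------------------------------------------------------
# VCF (phased GT + INFO score); superpopulation labels in a TSV sidecar


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pvep-synthetic
##INFO=<ID=IS,Number=1,Type=Float,Description="Imputation INFO score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">
"""


def write_vcf(cohort: PhasedCohort, reference: ReferenceAssembly, path) -> None:
    lines = [_VCF_HEADER.rstrip("\n")]
    for name, seq in sorted(reference.contigs.items()):
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                   "INFO", "FORMAT", *cohort.sample_ids]
    lines.append("\t".join(header_cols))
    for rec in cohort.records:
        gts = "\t".join(f"{a}|{b}" for a, b in rec.genotypes)
        lines.append("\t".join([
            rec.contig, str(rec.pos + 1), rec.id, rec.ref, rec.alt, ".",
            "PASS", f"IS={rec.info_score:.6f}", "GT", gts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_samples_tsv(cohort: PhasedCohort, path) -> None:
    pd.DataFrame(cohort.samples, columns=["sample", "superpopulation"]) \
        .to_csv(path, sep="\t", index=False)


def read_vcf(vcf_path, samples_tsv_path) -> PhasedCohort:
    from cyvcf2 import VCF

    labels = pd.read_csv(samples_tsv_path, sep="\t")
    label_map = dict(zip(labels["sample"], labels["superpopulation"]))
    vcf = VCF(str(vcf_path))
    samples = [(s, label_map[s]) for s in vcf.samples]
    records = []
    for v in vcf:
        gts = np.array([[g[0], g[1]] for g in v.genotypes], dtype=np.int8)
        records.append(VariantRecord(
            contig=v.CHROM, pos=v.POS - 1, ref=v.REF, alt=v.ALT[0],
            info_score=float(v.INFO.get("IS", 1.0)), genotypes=gts,
        ))
    return PhasedCohort(samples=samples, records=records)


# ---------------------------------------------------------------------------
# Focal variants, ground truth, distance maps


def write_focal_tsv(focals: list[FocalVariant], path,
                    allele_frequencies: dict[str, float] | None = None) -> None:
    rows = []
    for f in focals:
        rows.append({
            "id": f.id, "class": f.variant_class, "label": f.clinical_label,
            "contig": f.contig or "", "pos": "" if f.pos is None else f.pos + 1,
            "ref": f.ref or "", "alt": f.alt or "",
            "transcript": f.transcript_id or "",
            "residue": "" if f.residue is None else f.residue + 1,
            "wt_aa": f.wt_aa or "", "mt_aa": f.mt_aa or "",
            "af": "" if not allele_frequencies
                 else f"{allele_frequencies.get(f.id, float('nan')):.6g}",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_focal_tsv(path) -> tuple[list[FocalVariant], dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    focals, afs = [], {}
    for _, row in df.iterrows():
        kwargs = dict(id=row["id"], variant_class=row["class"],
                      clinical_label=row["label"])
        if row["class"] == "missense":
            kwargs.update(transcript_id=row["transcript"],
                          residue=int(row["residue"]) - 1,
                          wt_aa=row["wt_aa"], mt_aa=row["mt_aa"])
        else:
            kwargs.update(contig=row["contig"], pos=int(row["pos"]) - 1,
                          ref=row["ref"], alt=row["alt"])
        focals.append(FocalVariant(**kwargs))
        if row.get("af", ""):
            afs[row["id"]] = float(row["af"])
    return focals, afs


def write_ground_truth(truth: EpistasisGroundTruth, path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def read_ground_truth(path) -> EpistasisGroundTruth:
    return EpistasisGroundTruth.from_json(Path(path).read_text())


def write_distance_map(distance_map: np.ndarray, confidence: np.ndarray,
                       map_path, confidence_path) -> None:
    np.savetxt(map_path, distance_map, fmt="%.4f", delimiter="\t")
    np.savetxt(confidence_path, confidence, fmt="%.4f", delimiter="\t")


def read_distance_map(map_path, confidence_path) -> tuple[np.ndarray, np.ndarray]:
    return (np.loadtxt(map_path, delimiter="\t"),
            np.loadtxt(confidence_path, delimiter="\t"))


# ---------------------------------------------------------------------------
# Haplotype tables


def write_haplotype_tsv(haplotypes: list[ProteinHaplotype], path) -> None:
    rows = []
    for h in haplotypes:
        rows.append({
            "id": h.id, "transcript": h.transcript_id, "sequence": h.sequence,
            "variants": ";".join(h.variants),
            "residue_map": ";".join(map(str, h.residue_map.tolist())),
            "n_chromosomes": h.n_chromosomes,
            "truncated": h.truncated,
            "frequencies": json.dumps(h.frequencies, sort_keys=True),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path) -> list[ProteinHaplotype]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    haps = []
    for _, row in df.iterrows():
        haps.append(ProteinHaplotype(
            id=row["id"], transcript_id=row["transcript"],
            sequence=row["sequence"],
            residue_map=np.array(
                [int(x) for x in row["residue_map"].split(";")]
                if row["residue_map"] else [], dtype=np.int64),
            variants=tuple(v for v in row["variants"].split(";") if v),
            frequencies=json.loads(row["frequencies"]),
            n_chromosomes=int(row["n_chromosomes"]),
            truncated=row["truncated"] in ("True", "true", "1"),
        ))
    return haps


# ---------------------------------------------------------------------------
# PvepStore persistence


STORE_SCHEMA_VERSION = 1


def write_store(store: PvepStore, root, cohort_name: str = "cohort",
                variant_source: str = "focal") -> None:
    """Persist a PvepStore: one zarr store per contig (site x sample x
    ploid x metric), protein parquet tables in the nested layout, plus
    plain-TSV exports and provenance/incompatibility sidecars."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    dna_rows = []
    for contig, cs in sorted(store.dna.items()):
        # axis labels go into attrs: string coords have no stable zarr v3 spec
        ds = xr.Dataset(
            {"values": (("site", "sample", "ploid", "metric"), cs.values)},
            attrs={
                "contig": contig,
                "sites": json.dumps(cs.focal_ids),
                "samples": json.dumps(cs.samples),
                "metrics": json.dumps(cs.metrics),
                "classes": json.dumps(cs.focal_classes),
                "labels": json.dumps(cs.focal_labels),
                "schema_version": STORE_SCHEMA_VERSION,
            },
        )
        ds.to_zarr(root / f"{contig}.zarr", mode="w", consolidated=False)
        for i, fid in enumerate(cs.focal_ids):
            for j, sample in enumerate(cs.samples):
                for ploid in (0, 1):
                    for k, metric in enumerate(cs.metrics):
                        v = cs.values[i, j, ploid, k]
                        if not np.isnan(v):
                            dna_rows.append((contig, fid, cs.focal_classes[i],
                                             cs.focal_labels[i], sample, ploid,
                                             metric, v))
    pd.DataFrame(dna_rows, columns=[
        "contig", "focal_id", "class", "label", "sample", "ploid", "metric",
        "value",
    ]).to_csv(root / "dna_scores.tsv", sep="\t", index=False)

    # protein tables: {cohort}/vep/{model}/{protein}/{haplotype}/{variant_source}/{strategy}
    if not store.protein.empty:
        for (model, protein, hap, strategy), sub in store.protein.groupby(
                ["model", "transcript", "haplotype", "strategy"], sort=True):
            out = (root / cohort_name / "vep" / model / protein / hap
                   / variant_source)
            out.mkdir(parents=True, exist_ok=True)
            fname = strategy.replace("_", "-") + ".parquet"
            sub.reset_index(drop=True).to_parquet(out / fname, index=False)
    store.protein.to_csv(root / "protein_scores.tsv", sep="\t", index=False)
    store.incompatibilities.to_csv(root / "incompatibilities.tsv", sep="\t",
                                   index=False)
    provenance = dict(store.provenance)
    provenance["schema_version"] = STORE_SCHEMA_VERSION
    (root / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n")


def read_store(root) -> PvepStore:
    root = Path(root)
    provenance = json.loads((root / "provenance.json").read_text())
    version = provenance.pop("schema_version", None)
    if version != STORE_SCHEMA_VERSION:
        raise ValueError(
            f"store schema version {version} != {STORE_SCHEMA_VERSION}; "
            f"refusing to reinterpret"
        )
    dna = {}
    for zpath in sorted(root.glob("*.zarr")):
        ds = xr.open_zarr(zpath, consolidated=False)
        contig = ds.attrs["contig"]
        dna[contig] = DnaContigStore(
            contig=contig,
            focal_ids=json.loads(ds.attrs["sites"]),
            focal_classes=json.loads(ds.attrs["classes"]),
            focal_labels=json.loads(ds.attrs["labels"]),
            samples=json.loads(ds.attrs["samples"]),
            metrics=json.loads(ds.attrs["metrics"]),
            values=ds["values"].values,
        )
        ds.close()
    protein_path = root / "protein_scores.tsv"
    protein = (pd.read_csv(protein_path, sep="\t")
               if protein_path.exists() and protein_path.stat().st_size > 1
               else pd.DataFrame())
    if not protein.empty:
        protein["reason"] = protein["reason"].fillna("")
    incompat = pd.read_csv(root / "incompatibilities.tsv", sep="\t")
    return PvepStore(dna=dna, protein=protein, incompatibilities=incompat,
                     provenance=provenance)


# ---------------------------------------------------------------------------
# Run configuration and provenance


@dataclass
class RunConfig:
    seed: int = 1
    n_samples: int = 30
    n_contigs: int = 1
    contig_length: int = 60_000
    n_transcripts: int = 3
    target_density: float = 1.2e-2
    indel_fraction: float = 0.1
    n_missense: int = 4
    n_splice: int = 4
    n_utr: int = 4
    # toy-scale windows; the published pipelines use 10101 / 524288
    splice_window: int = 2001
    splice_scoring_window: int = 101
    coverage_window: int = 4001
    protein_strategies: tuple = ("masked_marginals",)
    ridge_alpha: float = 1.0
    ridge_seed: int = 42
    info_min: float = 0.9
    contact_threshold: float = 8.0
    interaction_min_n: int = 10
    fdr_alpha: float = 0.05
    weight_floor: float = 0.01
    adapters: dict = field(default_factory=lambda: {
        "protein": "pssm", "splice": "motif_splice", "coverage": "motif_coverage",
    })
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0 <= self.info_min <= 1):
            raise ValueError("info_min must lie in [0, 1]")
        if self.contact_threshold <= 0:
            raise ValueError("contact_threshold must be positive")
        if self.splice_scoring_window % 2 == 0:
            raise ValueError("splice_scoring_window must be odd")
        self.protein_strategies = tuple(self.protein_strategies)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protein_strategies"] = list(self.protein_strategies)
        return d

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    import pvep

    payload = {
        "stage": stage,
        "config_digest": config.digest(),
        "seed": config.seed,
        "pvep_version": pvep.__version__,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
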