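"""Readers, writers, and validated record types for the pipeline's file formats.

All coordinates in files are 1-based inclusive (VCF / Bismark-coverage
convention); internal slicing is 0-based half-open.  Downstream modules
consume only the in-memory types defined here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from ._seq import BASES

log = logging.getLogger(__name__)

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id"]
METHYLATION_COLUMNS = ["chrom", "pos", "strand", "meth_reads", "total_reads"]
PREDICTION_COLUMNS = [
    "gene",
    "mutation_key",
    "mutagene_pancancer",
    "mutagene_cohort",
    "chasm_score",
    "recurrence",
]

MUTAGENE_LABELS = {"driver", "potential driver", "passenger", "neutral", "NA"}


class FormatError(ValueError):
    """Raised when a whole file cannot be interpreted."""


@dataclass(frozen=True)
class MutationRecord:
    """A single-nucleotide somatic substitution at a 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"alleles must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class MethylationRecord:
    """Bisulfite read counts at a strand-aware cytosine position."""

    chrom: str
    pos: int
    strand: str
    meth_reads: int
    total_reads: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.total_reads < 1:
            raise ValueError("total_reads must be positive")
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError(
                f"meth_reads {self.meth_reads} outside [0, {self.total_reads}]"
            )


@dataclass(frozen=True)
class PredictionRecord:
    """Merged driver-prediction row for one recurrent mutation.

    ``chasm_score`` is None when CHASMplus emitted no prediction
    (nonsense/silent mutations).
    """

    gene: str
    mutation_key: str
    mutagene_pancancer: str
    mutagene_cohort: str
    chasm_score: float | None
    recurrence: int

    def __post_init__(self):
        for lab in (self.mutagene_pancancer, self.mutagene_cohort):
            if lab not in MUTAGENE_LABELS:
                raise ValueError(f"unknown MutaGene label {lab!r}")
        if self.chasm_score is not None and not 0.0 <= self.chasm_score <= 1.0:
            raise ValueError(f"chasm_score outside [0,1]: {self.chasm_score}")
        if self.recurrence < 1:
            raise ValueError("recurrence must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants; defaults follow the study design.

    flank_collect: half-width of the window used to tally nucleotide
        frequencies (positions -5..+5).
    flank_score: half-width of the scoring span (positions -3..+3).
    neighborhood_halfwidth: half-width of the mutation neighborhood
        (121-bp window).
    mc_samples: resamples for the one-tailed Monte-Carlo test.
    shuffle_reps: replicates for the shuffled-matrix control.
    min_reads: minimum bisulfite read depth for a CpG to enter analyses
        ("more than nine reads" == at least 10).
    thresholds: methylation-ratio thresholds, in percent.
    alpha: significance level of the joint t + MC rule.
    """

    flank_collect: int = 5
    flank_score: int = 3
    neighborhood_halfwidth: int = 60
    mc_samples: int = 10_000
    shuffle_reps: int = 1_000
    min_reads: int = 10
    thresholds: tuple[int, ...] = (25, 75)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.flank_score > self.flank_collect:
            raise ValueError("flank_score must not exceed flank_collect")
        if self.neighborhood_halfwidth <= self.flank_collect:
            raise ValueError("neighborhood_halfwidth must exceed flank_collect")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if any(not 0 < t < 100 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "thresholds" in data:
            data["thresholds"] = tuple(data["thresholds"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["thresholds"] = list(data["thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA reference into {contig: uppercase sequence}.

    Ambiguous IUPAC bases are preserved; contigs containing them are
    reported with a warning.  Duplicate contig names are rejected.
    """
    contigs: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no sequences found in {path}")
    for rec in records:
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for contig {rec.id!r}")
        contigs[rec.id] = seq
        ambiguous = sum(b not in BASES for b in seq)
        if ambiguous:
            log.warning("contig %s contains %d non-ACGT bases", rec.id, ambiguous)
    return contigs


def write_fasta(contigs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular readers: shared row-validation pattern


def _read_table(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def _collect_rows(df, builder):
    """Run ``builder`` per row; return (records, rejections).

    rejections is a list of (1-based data row number, reason).
    """
    records, rejections = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(builder(row))
        except (ValueError, TypeError) as exc:
            rejections.append((i, str(exc)))
    for rownum, reason in rejections:
        log.warning("row %d rejected: %s", rownum, reason)
    return records, rejections


def parse_mutation_rows(df: pd.DataFrame):
    def build(row):
        return MutationRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            sample_id=str(row.sample_id),
        )

    return _collect_rows(df, build)


def read_mutations(path) -> list[MutationRecord]:
    """Read a MAF-like mutation TSV; invalid rows are logged and dropped."""
    df = _read_table(path, MUTATION_COLUMNS)
    records, _ = parse_mutation_rows(df)
    return records


def read_mutations_vcf(path) -> list[MutationRecord]:
    """Thin VCF adapter: SNVs only, first ALT, sample_id from the file
    name.  Non-SNV records are skipped with a log message."""
    from cyvcf2 import VCF

    records = []
    sample = Path(path).stem
    for v in VCF(str(path)):
        alt = v.ALT[0] if v.ALT else ""
        if len(v.REF) != 1 or len(alt) != 1:
            log.info("skipping non-SNV record at %s:%s", v.CHROM, v.POS)
            continue
        try:
            records.append(MutationRecord(v.CHROM, v.POS, v.REF, alt, sample))
        except ValueError as exc:
            log.warning("VCF record at %s:%s rejected: %s", v.CHROM, v.POS, exc)
    return records


def parse_methylation_rows(df: pd.DataFrame):
    def build(row):
        return MethylationRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            strand=str(row.strand),
            meth_reads=int(row.meth_reads),
            total_reads=int(row.total_reads),
        )

    return _collect_rows(df, build)


def read_methylation(path) -> list[MethylationRecord]:
    """Read Bismark-coverage-like methylation counts.

    No read-depth filter is applied here; filtering is an explicit
    pipeline step (`methylation_pipeline.filter_and_ratio`).
    """
    df = _read_table(path, METHYLATION_COLUMNS)
    records, _ = parse_methylation_rows(df)
    return records


def read_predictions(path) -> list[PredictionRecord]:
    df = _read_table(path, PREDICTION_COLUMNS)

    def build(row):
        raw = str(row.chasm_score)
        score = None if raw in {"NA", "nan", ""} else float(raw)
        return PredictionRecord(
            gene=str(row.gene),
            mutation_key=str(row.mutation_key),
            mutagene_pancancer=str(row.mutagene_pancancer),
            mutagene_cohort=str(row.mutagene_cohort),
            chasm_score=score,
            recurrence=int(row.recurrence),
        )

    records, _ = _collect_rows(df, build)
    return records


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples FPKM matrix (first column = gene id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse expression table {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"empty expression table {path}")
    return df


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records], columns=MUTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_methylation(records: Iterable[MethylationRecord], path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=METHYLATION_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def write_predictions(records: Iterable[PredictionRecord], path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["chasm_score"] = "NA" if r.chasm_score is None else repr(r.chasm_score)
        rows.append(d)
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# provenance


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_record(config: RunConfig, inputs: Mapping[str, str]) -> dict:
    """JSON-serializable record of a run: config, seed, input digests."""
    cfg = dataclasses.asdict(config)
    cfg["thresholds"] = list(cfg["thresholds"])
    return {
        "config": cfg,
        "seed": config.seed,
        "inputs": {name: file_digest(p) for name, p in inputs.items()},
    }


def write_provenance(record: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
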