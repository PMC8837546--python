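"""Readers, writers and run configuration.

File conventions: catalogs travel as VCF 4.2 (divergent candidates as
two-ALT records), copy-number segments and het-SNP counts as TSV, positional
resources as BED (0-based half-open, converted to 1-based inclusive
internally), phased evidence as TSV, and calls as TSV with the full filter
trail. Every writer embeds the configuration fingerprint for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
import yaml

from .phasing import PhasedPairEvidence
from .spectra import (
    CHANNEL_LABELS,
    ContextGenome,
    MutationRecord,
    TrinucleotideSpectrum,
)
from .vaf import (
    CopyNumberSegment,
    HetSNPObservation,
    PurityPloidy,
    SampleCallResult,
)


@dataclass
class RunConfig:
    """Pipeline thresholds and run parameters, serialised into every output."""

    seed: int = 0
    replicates: int = 1000
    q_threshold: float = 0.1
    guard_snp_p: float = 0.001
    guard_fisher_p: float = 0.01
    phasing_min_fraction: float = 0.1
    omega_bounds: Tuple[float, float] = (50.0, 1000.0)
    min_cosine: float = 0.9
    pool_factor: float = 0.5
    burden_cv: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q threshold must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")
        if self.omega_bounds[0] <= 0 or self.omega_bounds[0] >= self.omega_bounds[1]:
            raise ValueError("invalid omega bounds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "omega_bounds" in data:
            data["omega_bounds"] = tuple(data["omega_bounds"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["omega_bounds"] = list(data["omega_bounds"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def fingerprint(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# VCF catalogs

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DRIVER,Number=0,Type=Flag,Description="Annotated driver mutation">
##INFO=<ID=VTYPE,Number=1,Type=String,Description="snv or indel">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def read_catalog_vcf(path: str | Path, sample_id: str = "") -> List[MutationRecord]:
    """Load a somatic catalog from VCF 4.2, keeping record order.

    Two-ALT records become divergent candidates; records with a non-PASS
    FILTER are loaded with ``passed=False`` rather than dropped.
    """
    records: List[MutationRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - depends on pysam message
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    with vcf:
        for lineno, rec in enumerate(vcf, start=1):
            try:
                alts = tuple(rec.alts or ())
                vtype = rec.info.get("VTYPE", None)
                if vtype is None:
                    is_indel = len(rec.ref) != 1 or any(
                        len(a) != 1 for a in alts
                    )
                    vtype = "indel" if is_indel else "snv"
                passed = (not rec.filter.keys()) or ("PASS" in rec.filter.keys())
                records.append(
                    MutationRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=alts,
                        vtype=str(vtype),
                        is_driver="DRIVER" in rec.info,
                        sample_id=sample_id,
                        passed=passed,
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"malformed VCF record at {path} line ~{lineno}: {exc}"
                ) from exc
    return records


def write_catalog_vcf(
    records: Sequence[MutationRecord],
    path: str | Path,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write a catalog as plain-text VCF 4.2."""
    lines = [VCF_HEADER.rstrip("\n")]
    if contig_lengths:
        contig_lines = [
            f"##contig=<ID={c},length={l}>" for c, l in contig_lengths.items()
        ]
        header_lines = lines[0].split("\n")
        lines[0] = "\n".join(header_lines[:-1] + contig_lines + header_lines[-1:])
    for rec in records:
        info = [f"VTYPE={rec.vtype}"]
        if rec.is_driver:
            info.append("DRIVER")
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),
                    ".",
                    rec.ref,
                    ",".join(rec.alts),
                    ".",
                    "PASS" if rec.passed else "FAIL",
                    ";".join(info),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / intervals

def read_bed(path: str | Path) -> Dict[str, List[Tuple[int, int]]]:
    """Read BED intervals (0-based half-open), keyed by chromosome."""
    intervals: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"empty BED interval {chrom}:{start}-{end}")
            intervals.setdefault(chrom, []).append((start, end))
    return {c: sorted(v) for c, v in intervals.items()}


def write_bed(intervals: Dict[str, List[Tuple[int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def bed_to_internal(
    intervals: Dict[str, List[Tuple[int, int]]]
) -> Dict[str, List[Tuple[int, int]]]:
    """0-based half-open -> 1-based inclusive."""
    return {
        c: [(s + 1, e) for s, e in ivs] for c, ivs in intervals.items()
    }


def internal_to_bed(
    intervals: Dict[str, List[Tuple[int, int]]]
) -> Dict[str, List[Tuple[int, int]]]:
    """1-based inclusive -> 0-based half-open."""
    return {
        c: [(s - 1, e) for s, e in ivs] for c, ivs in intervals.items()
    }


def bed_positions(intervals: Dict[str, List[Tuple[int, int]]]) -> Dict[str, frozenset]:
    """Expand single-base BED intervals to 1-based position sets."""
    return {
        c: frozenset(p for s, e in ivs for p in range(s + 1, e + 1))
        for c, ivs in intervals.items()
    }


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(genome: ContextGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(
    path: str | Path,
    callable_intervals: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> ContextGenome:
    """Load an (indexed) reference; callable defaults to whole chromosomes."""
    import pyfaidx

    fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    sequences = {name: str(fasta[name][:]) for name in fasta.keys()}
    fasta.close()
    if callable_intervals is None:
        callable_intervals = {c: [(0, len(s))] for c, s in sequences.items()}
    return ContextGenome(sequences, callable_intervals)


# ---------------------------------------------------------------------------
# Tabular inputs

SEGMENT_COLUMNS = ["chrom", "start", "end", "major", "minor", "baf_seg", "logr_seg"]


def read_segments_tsv(path: str | Path) -> List[CopyNumberSegment]:
    """Read copy-number segments; overlapping segments are rejected."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment TSV missing columns: {sorted(missing)}")
    segments = [
        CopyNumberSegment(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            major=int(r.major),
            minor=int(r.minor),
            baf_seg=float(r.baf_seg),
            logr_seg=float(r.logr_seg),
        )
        for r in df.itertuples()
    ]
    by_chrom: Dict[str, List[CopyNumberSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
    return segments


def write_segments_tsv(
    segments: Sequence[CopyNumberSegment], path: str | Path,
    config: Optional[RunConfig] = None,
) -> None:
    df = pd.DataFrame(
        [
            {c: getattr(s, c) for c in SEGMENT_COLUMNS}
            for s in segments
        ]
    )
    _write_tsv(df, path, config)


def read_het_snps_tsv(path: str | Path) -> List[HetSNPObservation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        HetSNPObservation(
            chrom=str(r.chrom),
            pos=int(r.pos),
            major_count=int(r.major_count),
            minor_count=int(r.minor_count),
            logr=float(r.logr) if "logr" in df.columns else None,
        )
        for r in df.itertuples()
    ]


def write_het_snps_tsv(
    snps: Sequence[HetSNPObservation], path: str | Path,
    config: Optional[RunConfig] = None,
) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "major_count": s.major_count,
                "minor_count": s.minor_count,
                "logr": s.logr,
            }
            for s in snps
        ]
    )
    _write_tsv(df, path, config)


EVIDENCE_COLUMNS = [
    "sample", "snp_chrom", "snp_pos", "snv_pos", "n_rr", "n_ra", "n_ar", "n_aa",
]


def read_evidence_tsv(path: str | Path) -> List[PhasedPairEvidence]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence TSV missing columns: {sorted(missing)}")
    return [
        PhasedPairEvidence(
            snp_chrom=str(r.snp_chrom),
            snp_pos=int(r.snp_pos),
            snv_pos=int(r.snv_pos),
            n_rr=int(r.n_rr),
            n_ra=int(r.n_ra),
            n_ar=int(r.n_ar),
            n_aa=int(r.n_aa),
            sample_id=str(r.sample),
        )
        for r in df.itertuples()
    ]


def write_evidence_tsv(
    evidence: Sequence[PhasedPairEvidence], path: str | Path,
    config: Optional[RunConfig] = None,
) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": e.sample_id,
                "snp_chrom": e.snp_chrom,
                "snp_pos": e.snp_pos,
                "snv_pos": e.snv_pos,
                "n_rr": e.n_rr,
                "n_ra": e.n_ra,
                "n_ar": e.n_ar,
                "n_aa": e.n_aa,
            }
            for e in evidence
        ],
        columns=EVIDENCE_COLUMNS,
    )
    _write_tsv(df, path, config)


def write_spectrum_tsv(
    spectrum: TrinucleotideSpectrum, path: str | Path
) -> None:
    """Serialise a spectrum as 96 labelled rows in frozen channel order."""
    df = pd.DataFrame({"channel": CHANNEL_LABELS, "count": spectrum.counts})
    df.to_csv(path, sep="\t", index=False)


def read_spectrum_tsv(path: str | Path) -> TrinucleotideSpectrum:
    df = pd.read_csv(path, sep="\t")
    if list(df["channel"]) != list(CHANNEL_LABELS):
        raise ValueError("spectrum TSV channels out of order or incomplete")
    return TrinucleotideSpectrum(df["count"].to_numpy(dtype=float))


CALL_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "alt_count", "total",
    "p", "q", "powered", "verdict", "trail", "flags",
]


def write_calls(
    result: SampleCallResult, path: str | Path,
    config: Optional[RunConfig] = None,
) -> None:
    """Write per-SNV verdicts with their complete filter trail."""
    rows = []
    for call in result.calls:
        rows.append(
            {
                "sample": result.sample_id,
                "chrom": call.snv.chrom,
                "pos": call.snv.pos,
                "ref": call.snv.ref,
                "alt": call.snv.alt,
                "alt_count": call.snv.alt_count,
                "total": call.snv.total,
                "p": call.p,
                "q": call.q,
                "powered": call.powered,
                "verdict": call.verdict,
                "trail": "|".join(call.trail),
                "flags": "|".join(call.flags),
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=CALL_COLUMNS), path, config)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _write_tsv(
    df: pd.DataFrame, path: str | Path, config: Optional[RunConfig]
) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_fingerprint={config.fingerprint()} "
                     f"seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_purity_ploidy_tsv(
    entries: Dict[str, PurityPloidy], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {"sample": s, "rho": pp.rho, "psi_t": pp.psi_t}
            for s, pp in entries.items()
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_purity_ploidy_tsv(path: str | Path) -> Dict[str, PurityPloidy]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r.sample): PurityPloidy(rho=float(r.rho), psi_t=float(r.psi_t))
        for r in df.itertuples()
    }
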