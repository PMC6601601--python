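"""Probe-based diploid genotype calling from amplicon FASTQ.

The calling workflow mirrors the standard amplicon-seq path: trim the 3'
sequencing adapter, drop short/low-quality reads (mean Phred > 20, length
>= 100 by default), assign each surviving read an allele per SNP by exact
virtual-probe matching (forward and reverse complement), and call the
diploid genotype from the alt-allele read fraction with a depth gate and a
heterozygote band (default 0.2-0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .design import AmpliconDesign, SnpDef, reverse_complement
from .simulate import read_fastq

__all__ = [
    "ReadRecord",
    "AlleleCounts",
    "GenotypeCall",
    "CallParams",
    "QcSummary",
    "ProbeMatch",
    "trim_adapter",
    "filter_read",
    "match_probe",
    "count_alleles",
    "call_genotype",
    "genotype_reads",
    "genotype_sample",
    "write_genotype_table",
    "read_genotype_table",
    "write_vcf",
]

MIN_ADAPTER_PREFIX = 8


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: seq/qual length mismatch")

    @classmethod
    def from_fastq(cls, rid: str, seq: str, qual_str: str) -> "ReadRecord":
        return cls(rid, seq, tuple(ord(c) - 33 for c in qual_str))

    @property
    def mean_q(self) -> float:
        return float(np.mean(self.qual)) if self.qual else 0.0


class ProbeMatch(Enum):
    REF = "ref"
    ALT = "alt"
    NONE = "none"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class AlleleCounts:
    snp_id: str
    n_ref: int = 0
    n_alt: int = 0
    n_unassigned: int = 0

    @property
    def depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def alt_fraction(self) -> float | None:
        return self.n_alt / self.depth if self.depth else None


class Call(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class GenotypeCall:
    snp_id: str
    call: Call
    alt_fraction: float | None
    depth: int

    def genotype_string(self, snp: SnpDef) -> str:
        return {
            Call.HOM_REF: f"{snp.allele_ref}/{snp.allele_ref}",
            Call.HET: f"{snp.allele_ref}/{snp.allele_alt}",
            Call.HOM_ALT: f"{snp.allele_alt}/{snp.allele_alt}",
            Call.NO_CALL: "./.",
        }[self.call]


@dataclass(frozen=True)
class CallParams:
    """Filtering and ratio-calling thresholds."""

    min_mean_q: float = 20.0
    min_len: int = 100
    min_depth: int = 50
    het_low: float = 0.2
    het_high: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.het_low < self.het_high < 1:
            raise ValueError("need 0 < het_low < het_high < 1")


@dataclass
class QcSummary:
    """Per-sample read accounting; reads_in == reads_kept + reads_dropped."""

    reads_in: int = 0
    reads_kept: int = 0
    reads_dropped: int = 0
    assigned: dict[str, int] = field(default_factory=dict)


def trim_adapter(read: ReadRecord, adapter: str) -> ReadRecord:
    """Truncate a read before its 3' adapter, if present.

    The full adapter anywhere in the read, or a prefix of it (>= 8 bp)
    flush with the read's 3' end, triggers truncation; qualities are cut in
    lockstep.  Reads without adapter are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    pos = read.seq.find(adapter)
    if pos < 0:
        # partial read-through: adapter prefix at the very 3' end
        max_partial = min(len(adapter) - 1, len(read.seq))
        for k in range(max_partial, MIN_ADAPTER_PREFIX - 1, -1):
            if read.seq.endswith(adapter[:k]):
                pos = len(read.seq) - k
                break
    if pos < 0:
        return read
    return ReadRecord(read.read_id, read.seq[:pos], read.qual[:pos])


def filter_read(
    read: ReadRecord, min_mean_q: float = 20.0, min_len: int = 100
) -> bool:
    """Keep a read iff mean Phred quality strictly exceeds ``min_mean_q``
    and length is at least ``min_len``."""
    return len(read.seq) >= min_len and read.mean_q > min_mean_q


def _min_mismatches(hay: str, needle: str, cap: int) -> int:
    """Smallest Hamming distance of ``needle`` over all windows of ``hay``
    (early exit above ``cap``; returns cap+1 if nothing is closer)."""
    best = cap + 1
    L = len(needle)
    for i in range(len(hay) - L + 1):
        mm = 0
        for a, b in zip(hay[i : i + L], needle):
            if a != b:
                mm += 1
                if mm >= best:
                    break
        best = min(best, mm)
        if best == 0:
            return 0
    return best


def match_probe(
    read_seq: str,
    snp: SnpDef,
    _rc: str | None = None,
    max_mismatches: int = 0,
) -> ProbeMatch:
    """Assign a read an allele by probe search on both strands.

    Default is exact substring matching; a hit of either probe counts and
    hits of both make the read ambiguous.  With ``max_mismatches`` > 0 the
    probes compete on Hamming distance: the strictly closer probe wins if
    it is within tolerance (the two probes differ only at the SNP base, so
    plain fuzzy containment would always hit both).
    """
    rc = reverse_complement(read_seq) if _rc is None else _rc
    if max_mismatches == 0:
        hit_ref = snp.probe_ref in read_seq or snp.probe_ref in rc
        hit_alt = snp.probe_alt in read_seq or snp.probe_alt in rc
        if hit_ref and hit_alt:
            return ProbeMatch.AMBIGUOUS
        if hit_ref:
            return ProbeMatch.REF
        if hit_alt:
            return ProbeMatch.ALT
        return ProbeMatch.NONE
    mm_ref = min(
        _min_mismatches(read_seq, snp.probe_ref, max_mismatches),
        _min_mismatches(rc, snp.probe_ref, max_mismatches),
    )
    mm_alt = min(
        _min_mismatches(read_seq, snp.probe_alt, max_mismatches),
        _min_mismatches(rc, snp.probe_alt, max_mismatches),
    )
    if mm_ref > max_mismatches and mm_alt > max_mismatches:
        return ProbeMatch.NONE
    if mm_ref == mm_alt:
        return ProbeMatch.AMBIGUOUS
    return ProbeMatch.REF if mm_ref < mm_alt else ProbeMatch.ALT


def count_alleles(reads, design: AmpliconDesign) -> dict[str, AlleleCounts]:
    """Tally probe matches per SNP over (already trimmed/filtered) reads.

    ``reads`` may be ``ReadRecord`` objects or bare sequences; each read
    contributes at most once per SNP.
    """
    n_ref = {s.snp_id: 0 for s in design.snps}
    n_alt = dict(n_ref)
    n_un = dict(n_ref)
    for read in reads:
        seq = read.seq if isinstance(read, ReadRecord) else read
        rc = reverse_complement(seq)
        for snp in design.snps:
            m = match_probe(seq, snp, rc)
            if m is ProbeMatch.REF:
                n_ref[snp.snp_id] += 1
            elif m is ProbeMatch.ALT:
                n_alt[snp.snp_id] += 1
            else:
                n_un[snp.snp_id] += 1
    return {
        sid: AlleleCounts(sid, n_ref[sid], n_alt[sid], n_un[sid])
        for sid in n_ref
    }


def call_genotype(
    counts: AlleleCounts,
    min_depth: int = 50,
    het_low: float = 0.2,
    het_high: float = 0.8,
) -> GenotypeCall:
    """Ratio-threshold diploid call from allele read counts.

    Below ``min_depth`` informative reads the sample is a no-call; otherwise
    the alt-read fraction is thresholded: < het_low hom_ref, > het_high
    hom_alt, else het.
    """
    if not 0 < het_low < het_high < 1:
        raise ValueError("need 0 < het_low < het_high < 1")
    depth = counts.depth
    frac = counts.alt_fraction
    if depth < min_depth:
        return GenotypeCall(counts.snp_id, Call.NO_CALL, frac, depth)
    assert frac is not None
    if frac < het_low:
        call = Call.HOM_REF
    elif frac > het_high:
        call = Call.HOM_ALT
    else:
        call = Call.HET
    return GenotypeCall(counts.snp_id, call, frac, depth)


def genotype_reads(
    raw_reads,
    design: AmpliconDesign,
    params: CallParams | None = None,
) -> tuple[dict[str, GenotypeCall], QcSummary]:
    """Trim, filter, count and call over an in-memory read collection.

    ``raw_reads`` are ``(read_id, seq, qual_string)`` tuples (as produced by
    the simulator or the FASTQ reader) or ``ReadRecord`` objects.
    """
    params = params or CallParams()
    qc = QcSummary()
    kept: list[ReadRecord] = []
    for item in raw_reads:
        read = item if isinstance(item, ReadRecord) else ReadRecord.from_fastq(*item)
        qc.reads_in += 1
        read = trim_adapter(read, design.adapter)
        if filter_read(read, params.min_mean_q, params.min_len):
            kept.append(read)
            qc.reads_kept += 1
        else:
            qc.reads_dropped += 1
    counts = count_alleles(kept, design)
    qc.assigned = {sid: c.depth for sid, c in counts.items()}
    calls = {
        sid: call_genotype(c, params.min_depth, params.het_low, params.het_high)
        for sid, c in counts.items()
    }
    return calls, qc


def genotype_sample(
    fastq_path,
    design: AmpliconDesign,
    params: CallParams | None = None,
) -> tuple[dict[str, GenotypeCall], QcSummary]:
    """Genotype one sample from its FASTQ file (optionally gzipped)."""
    try:
        raw = read_fastq(fastq_path)
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {fastq_path}: {exc}") from exc
    return genotype_reads(raw, design, params)


# ---------------------------------------------------------------------------
# Output tables

def calls_to_frame(
    calls_per_sample: dict[str, dict[str, GenotypeCall]],
    design: AmpliconDesign,
) -> pd.DataFrame:
    """Long-to-wide genotype table: one row per sample."""
    rows = []
    for sample_id, calls in calls_per_sample.items():
        row: dict[str, object] = {"sample_id": sample_id}
        for snp in design.snps:
            call = calls[snp.snp_id]
            row[f"genotype_{snp.snp_id}"] = call.genotype_string(snp)
            row[f"depth_{snp.snp_id}"] = call.depth
            row[f"alt_fraction_{snp.snp_id}"] = (
                round(call.alt_fraction, 6) if call.alt_fraction is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_genotype_table(
    calls_per_sample: dict[str, dict[str, GenotypeCall]],
    design: AmpliconDesign,
    path,
) -> None:
    calls_to_frame(calls_per_sample, design).to_csv(path, sep="\t", index=False)


def read_genotype_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


_GT_CODE = {
    Call.HOM_REF: "0/0",
    Call.HET: "0/1",
    Call.HOM_ALT: "1/1",
    Call.NO_CALL: "./.",
}


def write_vcf(
    calls_per_sample: dict[str, dict[str, GenotypeCall]],
    design: AmpliconDesign,
    path,
    chrom: str = "amplicon",
    pos_offset: int = 0,
) -> None:
    """Write calls as a minimal VCF v4.2 (one record per SNP, GT:DP fields).

    ``pos_offset`` shifts amplicon offsets to reference coordinates
    (POS = offset + pos_offset + 1, 1-based).
    """
    samples = list(calls_per_sample)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(design.amplicon_seq) + pos_offset}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Informative read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for snp in design.snps:
            fields = [
                chrom,
                str(snp.offset + pos_offset + 1),
                snp.snp_id,
                snp.allele_ref,
                snp.allele_alt,
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for sample in samples:
                call = calls_per_sample[sample][snp.snp_id]
                fields.append(f"{_GT_CODE[call.call]}:{call.depth}")
            fh.write("\t".join(fields) + "\n")
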