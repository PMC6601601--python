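"""Amplicon design: the target region, its SNPs and the virtual probes.

The design describes one sequenced PCR product spanning two biallelic SNPs.
Each SNP carries a pair of short "virtual probe" sequences, identical except
at the SNP base, that are matched exactly against reads to assign each read
an allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP inside the amplicon.

    ``offset`` is the 0-based position of the SNP base in the amplicon;
    ``probe_ref``/``probe_alt`` are the two virtual probes, which must differ
    at exactly one position (the SNP base).
    """

    snp_id: str
    allele_ref: str
    allele_alt: str
    offset: int
    probe_ref: str
    probe_alt: str

    def __post_init__(self) -> None:
        if len(self.allele_ref) != 1 or len(self.allele_alt) != 1:
            raise ValueError(f"{self.snp_id}: alleles must be single bases")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if len(self.probe_ref) != len(self.probe_alt):
            raise ValueError(f"{self.snp_id}: probes must have equal length")
        diffs = sum(a != b for a, b in zip(self.probe_ref, self.probe_alt))
        if diffs != 1:
            raise ValueError(
                f"{self.snp_id}: probes differ at {diffs} positions, expected 1"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_ref, self.allele_alt)


@dataclass(frozen=True)
class AmpliconDesign:
    """One amplicon, its adapter and the SNPs it covers."""

    amplicon_seq: str
    adapter: str
    snps: tuple[SnpDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = set(self.amplicon_seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in amplicon: {sorted(bad)}")
        for snp in self.snps:
            if not 0 <= snp.offset < len(self.amplicon_seq):
                raise ValueError(f"{snp.snp_id}: offset outside amplicon")
            if self.amplicon_seq[snp.offset] != snp.allele_ref:
                raise ValueError(
                    f"{snp.snp_id}: amplicon base at offset {snp.offset} is "
                    f"{self.amplicon_seq[snp.offset]}, expected ref allele "
                    f"{snp.allele_ref}"
                )

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.snp_id for s in self.snps)

    def haplotype_seq(self, alleles: tuple[str, ...]) -> str:
        """Amplicon sequence carrying the given allele at each SNP."""
        if len(alleles) != len(self.snps):
            raise ValueError("one allele per SNP required")
        seq = list(self.amplicon_seq)
        for snp, allele in zip(self.snps, alleles):
            if allele not in snp.alleles:
                raise ValueError(f"{snp.snp_id}: allele {allele!r} not in design")
            seq[snp.offset] = allele
        return "".join(seq)


# Synthetic 119 bp amplicon mimicking the ESR1 intron-1 design: two SNPs,
# PvuII-like T/C and XbaI-like A/G, 46 bp apart, with 15 bp virtual probes
# centred on each SNP base.  The real study's primer/probe sequences live in
# its supplement; these defaults carry the same geometry on a synthetic
# backbone and are meant to be overridden by a design config for real data.
DEFAULT_AMPLICON_SEQ = (
    "GTCCATGGGTACACCTGTATTTGTTCGGCTACAGTCTGGGAGGCCCAAGCCATTGGGATA"
    "GGAGCTGATGAATTGTAGCGTCACACCAACCCTCGCCACGAAAGGCATCTTACAGGACA"
)

# Nextera transposase sequence, the usual Illumina adapter read-through.
DEFAULT_ADAPTER = "CTGTCTCTTATACACATCT"

DEFAULT_DESIGN = AmpliconDesign(
    amplicon_seq=DEFAULT_AMPLICON_SEQ,
    adapter=DEFAULT_ADAPTER,
    snps=(
        SnpDef(
            snp_id="rs2234693",
            allele_ref="T",
            allele_alt="C",
            offset=36,
            probe_ref="TACAGTCTGGGAGGC",
            probe_alt="TACAGTCCGGGAGGC",
        ),
        SnpDef(
            snp_id="rs9340799",
            allele_ref="A",
            allele_alt="G",
            offset=82,
            probe_ref="TAGCGTCACACCAAC",
            probe_alt="TAGCGTCGCACCAAC",
        ),
    ),
)


def design_to_dict(design: AmpliconDesign) -> dict:
    return {
        "amplicon_seq": design.amplicon_seq,
        "adapter": design.adapter,
        "snps": [
            {
                "snp_id": s.snp_id,
                "allele_ref": s.allele_ref,
                "allele_alt": s.allele_alt,
                "offset": s.offset,
                "probe_ref": s.probe_ref,
                "probe_alt": s.probe_alt,
            }
            for s in design.snps
        ],
    }


def design_from_dict(d: dict) -> AmpliconDesign:
    return AmpliconDesign(
        amplicon_seq=d["amplicon_seq"],
        adapter=d["adapter"],
        snps=tuple(SnpDef(**s) for s in d["snps"]),
    )


def load_design(path) -> AmpliconDesign:
    """Read an amplicon design from a YAML config file."""
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def save_design(design: AmpliconDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)
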