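"""File-format boundaries: FASTA/FASTQ/VCF/SAM/BED/TSV readers and writers.

This is the only module where 0-based internal coordinates meet the 1-based
conventions of VCF and SAM.
"""

from __future__ import annotations

import pandas as pd
import pysam

from .core import Alignment, cigar_from_string, cigar_to_string
from .fixtures import SimRead, TruthTable
from .scan import BiasRegion
from .variants import PhasedVariant


def write_fasta(path: str, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif name is not None:
                out[name].append(line)
    return {k: "".join(v) for k, v in out.items()}


def write_fastq_pair(prefix: str, reads: list[SimRead]) -> tuple[str, str]:
    """Write mate-split FASTQ files ``{prefix}_1.fastq`` / ``{prefix}_2.fastq``."""
    paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq")
    handles = {1: open(paths[0], "w"), 2: open(paths[1], "w")}
    try:
        for rd in reads:
            fh = handles.get(rd.mate, handles[1])
            fh.write(f"@{rd.read_id}\n{rd.seq_sequencer}\n+\n{'I' * len(rd.seq_sequencer)}\n")
    finally:
        for fh in handles.values():
            fh.close()
    return paths


def write_vcf(
    path: str,
    variants: list[PhasedVariant],
    contigs: dict[str, int],
    sample: str = "donor",
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            sep = "|" if v.phased else "/"
            gt = sep.join(str(a) for a in v.genotype)
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter_status}\t.\tGT\t{gt}\n"
            )


def write_truth_tsv(path: str, truth: TruthTable) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> TruthTable:
    return TruthTable.from_frame(pd.read_csv(path, sep="\t"))


_FLAG_PAIRED = 0x1
_FLAG_REVERSE = 0x10
_FLAG_MATE1 = 0x40
_FLAG_MATE2 = 0x80


def write_sam(path: str, alignments: list[Alignment], contigs: dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        tids = {n: i for i, n in enumerate(contigs)}
        for a in sorted(alignments, key=lambda x: (x.chrom, x.pos)):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            flag = 0
            if a.mate:
                flag |= _FLAG_PAIRED | (_FLAG_MATE1 if a.mate == 1 else _FLAG_MATE2)
            if a.is_reverse:
                flag |= _FLAG_REVERSE
            seg.flag = flag
            seg.reference_id = tids[a.chrom]
            seg.reference_start = a.pos
            seg.mapping_quality = a.mapq
            seg.cigarstring = cigar_to_string(a.cigar)
            seg.query_sequence = a.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(a.seq))
            out.write(seg)


def read_alignments(path: str, region: str | None = None) -> list[Alignment]:
    """Load SAM/BAM records as internal alignments (mapped, primary only)."""
    mode = "rb" if path.endswith(".bam") else "r"
    out: list[Alignment] = []
    with pysam.AlignmentFile(path, mode) as fh:
        try:
            it = fh.fetch(region=region) if region else fh.fetch(until_eof=True)
        except ValueError:
            it = fh
        for seg in it:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            mate = 0
            if seg.is_paired:
                mate = 1 if seg.is_read1 else 2
            out.append(
                Alignment(
                    read_id=seg.query_name,
                    mate=mate,
                    chrom=seg.reference_name,
                    pos=seg.reference_start,
                    cigar=cigar_from_string(seg.cigarstring),
                    seq=seg.query_sequence or "",
                    mapq=seg.mapping_quality,
                    is_reverse=seg.is_reverse,
                )
            )
    return out


def write_regions_bed(path: str, regions: list[BiasRegion], label: str | None = None) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda x: (x.chrom, x.start)):
            if label and r.label != label:
                continue
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{r.peak_score:.4g}\n")


def read_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append({"chrom": f[0], "start": int(f[1]), "end": int(f[2])})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
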