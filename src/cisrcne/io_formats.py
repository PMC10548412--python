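"""Readers/writers for the standard formats the pipeline touches.

Every coordinate held in memory is 0-based, half-open, on the forward
strand of its species; conversions to the conventions of each file format
(1-based closed GFF3, reverse-strand-relative MAF starts, ...) happen only
at the format boundary.  BED, bedGraph and VCF positions follow their own
standards on disk and are converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.AlignIO.MafIO import MafWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "MafRow",
    "AlignmentBlock",
    "GeneModel",
    "SignalTrack",
    "DERecord",
    "MafFormatError",
    "Gff3FormatError",
    "read_maf",
    "write_maf",
    "read_gff3",
    "read_vcf_positions",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_de_table",
    "write_de_table",
]


class MafFormatError(ValueError):
    """Raised for a malformed MAF record; carries the offending line number."""


class Gff3FormatError(ValueError):
    """Raised when a GFF3 gene model violates its own structure."""


# ---------------------------------------------------------------------------
# core interval / gene / alignment containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on the forward strand of ``chrom``.

    ``strand`` records the orientation of the feature the interval came
    from; the coordinates themselves are always forward-strand.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class MafRow:
    """One species row of an alignment block.

    ``interval`` is the forward-strand interval covered by the row's
    non-gap characters; ``strand`` is the alignment orientation; ``text``
    is the gapped sequence as it appears in the block; ``src_size`` the
    length of the source chromosome (needed to restore MAF minus-strand
    coordinates on write).
    """

    interval: GenomicInterval
    strand: str
    text: str
    src_size: int

    def __post_init__(self) -> None:
        ungapped = len(self.text) - self.text.count("-")
        if ungapped != self.interval.length:
            raise MafFormatError(
                f"row {self.interval.chrom}: {ungapped} non-gap chars but "
                f"interval length {self.interval.length}"
            )


@dataclass
class AlignmentBlock:
    """A reference-anchored multiple-alignment block.

    The reference row is always present and on the + strand.  A block
    whose ``rows`` cover every clade species ("complete profile") can act
    as a multiple-alignment anchor for collinearity detection.
    """

    ref_species: str
    rows: dict[str, MafRow]
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_species not in self.rows:
            raise MafFormatError(f"reference row {self.ref_species!r} missing")
        if self.rows[self.ref_species].strand != "+":
            raise MafFormatError("reference row must be on the + strand")
        widths = {len(r.text) for r in self.rows.values()}
        if len(widths) != 1:
            raise MafFormatError(f"rows disagree on width: {sorted(widths)}")

    @property
    def ref_interval(self) -> GenomicInterval:
        return self.rows[self.ref_species].interval

    @property
    def width(self) -> int:
        return len(self.rows[self.ref_species].text)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.rows)

    def is_complete(self, clade: set[str] | frozenset[str]) -> bool:
        return set(clade) <= set(self.rows)

    def ref_columns(self) -> np.ndarray:
        """Reference positions of each column; -1 where the reference is gapped."""
        text = self.rows[self.ref_species].text
        out = np.full(len(text), -1, dtype=np.int64)
        pos = self.ref_interval.start
        for i, c in enumerate(text):
            if c != "-":
                out[i] = pos
                pos += 1
        return out

    def column(self, i: int) -> dict[str, str]:
        """Bases of column ``i`` per species ('-' for a gap)."""
        return {sp: row.text[i] for sp, row in self.rows.items()}


@dataclass
class GeneModel:
    """A protein-coding gene: body, CDS, UTRs, and derived introns."""

    gene_id: str
    interval: GenomicInterval
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for iv in self.cds:
            if not self.interval.contains(iv):
                raise Gff3FormatError(
                    f"gene {self.gene_id}: CDS {iv} outside gene body {self.interval}"
                )
        for a, b in zip(self.cds, self.cds[1:]):
            if b.start < a.end:
                raise Gff3FormatError(
                    f"gene {self.gene_id}: overlapping CDS intervals {a} / {b}"
                )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def exonic(self) -> list[GenomicInterval]:
        """Sorted union of CDS and UTR intervals."""
        ivs = sorted(
            self.cds + self.utr5 + self.utr3, key=lambda iv: (iv.start, iv.end)
        )
        merged: list[GenomicInterval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end:
                last = merged[-1]
                if iv.end > last.end:
                    merged[-1] = GenomicInterval(
                        last.chrom, last.start, iv.end, last.strand
                    )
            else:
                merged.append(iv)
        return merged

    @property
    def introns(self) -> list[GenomicInterval]:
        ex = self.exonic
        return [
            GenomicInterval(a.chrom, a.end, b.start, self.strand)
            for a, b in zip(ex, ex[1:])
            if b.start > a.end
        ]

    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)


class SignalTrack:
    """Sparse per-base signal on the reference (bedGraph semantics).

    Positions not covered by any record have value 0.
    """

    def __init__(self, records: pd.DataFrame | None = None):
        # records: columns chrom, start, end, value
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if records is not None and len(records):
            for chrom, sub in records.groupby("chrom", sort=True):
                sub = sub.sort_values("start")
                self._by_chrom[str(chrom)] = (
                    sub["start"].to_numpy(np.int64),
                    sub["end"].to_numpy(np.int64),
                    sub["value"].to_numpy(float),
                )

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense signal over [start, end); 0 where uncovered."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._by_chrom:
            return out
        starts, ends, vals = self._by_chrom[chrom]
        # starts are sorted; ends need not be (nested records overwrite
        # earlier ones, letting a broad baseline underlie narrow features)
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[:hi], ends[:hi], vals[:hi]):
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start : b - start] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, s, e, v)
            for chrom, (ss, ee, vv) in sorted(self._by_chrom.items())
            for s, e, v in zip(ss, ee, vv)
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression call between two conditions."""

    gene_id: str
    logfc: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR must be in [0,1], got {self.fdr}")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def _split_src(src: str) -> tuple[str, str]:
    """MAF ``src`` convention is species.chromosome (split at first dot)."""
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, src


def _prevalidate_maf(path: str) -> None:
    """Line-numbered structural checks Biopython does not perform."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("s"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise MafFormatError(
                    f"{path}:{lineno}: s-line has {len(fields)} fields, expected 7"
                )
            _, _, start, size, strand, src_size, text = fields
            try:
                start_i, size_i, src_i = int(start), int(size), int(src_size)
            except ValueError as exc:
                raise MafFormatError(
                    f"{path}:{lineno}: non-numeric coordinate field"
                ) from exc
            if strand not in "+-":
                raise MafFormatError(f"{path}:{lineno}: bad strand {strand!r}")
            ungapped = len(text) - text.count("-")
            if ungapped != size_i:
                raise MafFormatError(
                    f"{path}:{lineno}: declared size {size_i} but "
                    f"{ungapped} non-gap characters"
                )
            if start_i + size_i > src_i:
                raise MafFormatError(
                    f"{path}:{lineno}: start+size exceeds srcSize"
                )


def read_maf(path: str, ref_species: str) -> list[AlignmentBlock]:
    """Read a MAF file into reference-sorted :class:`AlignmentBlock` objects.

    Blocks lacking a row for ``ref_species`` are skipped (counted in a
    warning); minus-strand row coordinates are converted to forward-strand
    intervals.  Raises :class:`MafFormatError` with a line number for
    malformed s-lines.
    """
    _prevalidate_maf(path)
    blocks: list[AlignmentBlock] = []
    skipped = 0
    for aln in AlignIO.parse(path, "maf"):
        rows: dict[str, MafRow] = {}
        score = float(aln.annotations.get("score", 0.0)) if hasattr(aln, "annotations") else 0.0
        for rec in aln:
            sp, chrom = _split_src(rec.id)
            ann = rec.annotations
            start, size = int(ann["start"]), int(ann["size"])
            src_size = int(ann["srcSize"])
            strand = "+" if int(ann["strand"]) == 1 else "-"
            if strand == "-":  # MAF minus-strand starts count from the 3' end
                fwd_start = src_size - (start + size)
            else:
                fwd_start = start
            rows[sp] = MafRow(
                interval=GenomicInterval(chrom, fwd_start, fwd_start + size, strand),
                strand=strand,
                text=str(rec.seq).upper(),
                src_size=src_size,
            )
        if ref_species not in rows:
            skipped += 1
            continue
        blocks.append(AlignmentBlock(ref_species=ref_species, rows=rows, score=score))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} block(s) without a reference row")
    blocks.sort(key=lambda b: (b.ref_interval.chrom, b.ref_interval.start))
    return blocks


def write_maf(blocks: list[AlignmentBlock], path: str) -> None:
    """Write blocks back to MAF, restoring minus-strand start conventions."""
    with open(path, "w") as fh:
        writer = MafWriter(fh)
        writer.write_header()
        for block in blocks:
            records = []
            order = [block.ref_species] + sorted(
                sp for sp in block.rows if sp != block.ref_species
            )
            for sp in order:
                row = block.rows[sp]
                iv = row.interval
                if row.strand == "-":
                    start = row.src_size - iv.end
                else:
                    start = iv.start
                rec = SeqRecord(Seq(row.text), id=f"{sp}.{iv.chrom}")
                rec.annotations = {
                    "start": start,
                    "size": iv.length,
                    "strand": 1 if row.strand == "+" else -1,
                    "srcSize": row.src_size,
                }
                records.append(rec)
            aln = MultipleSeqAlignment(records)
            aln.annotations = {"score": block.score}
            writer.write_alignment(aln)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_gff3_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed) into 0-based half-open form.

    One :class:`GeneModel` per gene; when a gene has several mRNAs the one
    with the longest summed CDS wins.  A gene whose CDS falls outside its
    body raises :class:`Gff3FormatError`.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_parts: dict[str, dict[str, list[GenomicInterval]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise Gff3FormatError(f"{path}: expected 9 columns, got {len(f)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            a = _parse_gff3_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise Gff3FormatError(f"{path}: gene feature without ID")
                genes[gid] = {"interval": iv}
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if mid is None or parent is None:
                    raise Gff3FormatError(f"{path}: mRNA without ID/Parent")
                mrna_parent[mid] = parent
                mrna_parts[mid] = {"CDS": [], "five_prime_UTR": [], "three_prime_UTR": []}
            elif ftype in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = a.get("Parent")
                if parent in mrna_parts:
                    mrna_parts[parent][ftype].append(iv)

    models: list[GeneModel] = []
    for gid, info in genes.items():
        mids = [m for m, p in mrna_parent.items() if p == gid]
        if not mids:
            models.append(GeneModel(gene_id=gid, interval=info["interval"]))
            continue
        best = max(mids, key=lambda m: sum(iv.length for iv in mrna_parts[m]["CDS"]))
        parts = mrna_parts[best]
        models.append(
            GeneModel(
                gene_id=gid,
                interval=info["interval"],
                cds=parts["CDS"],
                utr5=parts["five_prime_UTR"],
                utr3=parts["three_prime_UTR"],
            )
        )
    models.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return models


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Write gene models as GFF3 with gene/mRNA/CDS/UTR features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tcisrcne\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.1"
            fh.write(
                f"{iv.chrom}\tcisrcne\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for ftype, parts in (
                ("five_prime_UTR", g.utr5),
                ("CDS", g.cds),
                ("three_prime_UTR", g.utr3),
            ):
                for p in sorted(parts, key=lambda x: x.start):
                    fh.write(
                        f"{p.chrom}\tcisrcne\t{ftype}\t{p.start + 1}\t{p.end}\t.\t"
                        f"{iv.strand}\t.\tParent={mid}\n"
                    )


# ---------------------------------------------------------------------------
# VCF / FASTA / BED / bedGraph / DE table
# ---------------------------------------------------------------------------


def read_vcf_positions(path: str) -> set[tuple[str, int]]:
    """Biallelic SNP sites from a VCF as 0-based (chrom, pos), deduplicated."""
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: fewer than 5 VCF columns")
            chrom, pos, _id, ref, alt = f[:5]
            try:
                pos1 = int(pos)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric POS {pos!r}") from exc
            if len(ref) != 1 or ref not in "ACGTacgt":
                continue
            alts = alt.split(",")
            if len(alts) != 1 or len(alts[0]) != 1 or alts[0] not in "ACGTacgt":
                continue
            sites.add((chrom, pos1 - 1))
    return sites


def write_vcf(sites: list[tuple[str, int, str, str]], path: str) -> None:
    """Write (chrom, pos0, ref, alt) SNPs as a minimal VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in sorted(sites):
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        path,
        "fasta",
    )


def write_bed(
    entries: list[tuple[GenomicInterval, str, float]], path: str
) -> None:
    """BED6: (interval, name, score) rows; score carries the element score."""
    with open(path, "w") as fh:
        for iv, name, score in entries:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_bed(path: str) -> list[tuple[GenomicInterval, str, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 else 0.0
            strand = f[5] if len(f) > 5 else "+"
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


def read_bedgraph(path: str) -> SignalTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    return SignalTrack(df)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_de_table(path: str) -> dict[str, DERecord]:
    """TSV with columns gene_id, logFC, FDR -> records keyed by gene."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "logFC", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    return {
        str(r.gene_id): DERecord(str(r.gene_id), float(r.logFC), float(r.FDR))
        for r in df.itertuples()
    }


def write_de_table(records: list[DERecord], path: str) -> None:
    pd.DataFrame(
        [(r.gene_id, r.logfc, r.fdr) for r in records],
        columns=["gene_id", "logFC", "FDR"],
    ).to_csv(path, sep="\t", index=False)
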