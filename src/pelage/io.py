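"""Readers and writers for every on-disk format the pipeline touches.

One in-memory representation per artefact, strict validation on read
(readers reject rather than repair, and error messages carry the file
position).  Coordinates are 1-based inclusive everywhere, in memory and on
disk, matching the VCF/GFF3 convention.  All text formats are accepted
plain or gzip-compressed.

Formats owned by this module:

* genotype matrix — tab-delimited, one marker per row
  (``chrom  pos  id  <call per sample>``; calls are alternate-allele
  dosages ``0/1/2`` with ``.`` for missing),
* multi-sample variants — VCF 4.2 via :mod:`pysam`,
* reference sequence — FASTA via Biopython,
* transcript models — GFF3 (read via :mod:`gffutils`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pelage._util import FormatError, openf

MISSING: int = -1
_VALID_CALLS = {"0": 0, "1": 1, "2": 2, ".": MISSING}
_BASES = set("ACGT")


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a set of samples over an ordered marker map.

    ``calls`` holds alternate-allele dosage per (marker, sample) as int8:
    0, 1, 2 or :data:`MISSING` (-1).  Markers are sorted by (chromosome,
    position) with positions strictly increasing within a chromosome.
    """

    samples: list[str]
    markers: pd.DataFrame  # columns: id, chrom, pos
    calls: np.ndarray

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        required = ["id", "chrom", "pos"]
        if list(self.markers.columns[:3]) != required:
            raise ValueError(f"marker table must have columns {required}")
        if self.markers["id"].duplicated().any():
            dup = self.markers["id"][self.markers["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (self.markers["pos"] < 1).any():
            raise ValueError("marker positions are 1-based; position < 1 found")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1, 2 or missing (-1)")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def write(self, path) -> None:
        with openf(path, "wt") as fh:
            fh.write("chrom\tpos\tid\t" + "\t".join(self.samples) + "\n")
            sym = {0: "0", 1: "1", 2: "2", MISSING: "."}
            chroms = self.markers["chrom"].to_numpy()
            poss = self.markers["pos"].to_numpy()
            ids = self.markers["id"].to_numpy()
            for i in range(self.n_markers):
                row = "\t".join(sym[int(c)] for c in self.calls[i])
                fh.write(f"{chroms[i]}\t{poss[i]}\t{ids[i]}\t{row}\n")


def read_genotype_matrix(path) -> GenotypeMatrix:
    """Read the tab-delimited genotype-matrix dialect documented above.

    Rejects malformed rows, non-monotone positions, duplicate marker ids
    and unknown call symbols, naming the offending line.
    """
    path = Path(path)
    with openf(path, "rt") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(path, 1, "empty file")
        cols = header.split("\t")
        if cols[:3] != ["chrom", "pos", "id"]:
            raise FormatError(path, 1, "header must start with chrom<TAB>pos<TAB>id")
        samples = cols[3:]
        if not samples:
            raise FormatError(path, 1, "no sample columns")
        ids, chroms, poss, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise FormatError(path, lineno, f"expected {len(cols)} fields, got {len(parts)}")
            chrom, pos_s, mid = parts[0], parts[1], parts[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(path, lineno, f"non-integer position {pos_s!r}") from None
            if pos < 1:
                raise FormatError(path, lineno, "positions are 1-based; got position < 1")
            try:
                row = [_VALID_CALLS[c] for c in parts[3:]]
            except KeyError as exc:
                raise FormatError(path, lineno, f"unknown call symbol {exc.args[0]!r}") from None
            chroms.append(chrom)
            poss.append(pos)
            ids.append(mid)
            rows.append(row)
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    # sort by (chromosome in file order, position); validation of monotonicity
    # happens in the constructor after sorting.
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
    order = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].map(chrom_order).to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)
    calls = np.asarray(rows, dtype=np.int8)[order] if rows else np.empty((0, len(samples)), np.int8)
    try:
        return GenotypeMatrix(samples=samples, markers=markers, calls=calls)
    except ValueError as exc:
        raise FormatError(path, None, str(exc)) from None


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------

Genotype = tuple[int, int] | None


@dataclass(frozen=True)
class Variant:
    """One VCF record with per-sample unphased genotypes.

    ``genotypes`` maps sample id to an allele-index pair (0 = REF,
    1.. = ALT index + 1) or ``None`` for a missing call.  Phase separators
    are accepted on input and discarded; the analysis never uses phase.
    Multi-allelic records are kept intact.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    vid: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if not self.ref or set(self.ref) - _BASES:
            raise ValueError(f"bad reference allele {self.ref!r}")
        for a in self.alts:
            if not a or set(a) - _BASES:
                raise ValueError(f"bad alternate allele {a!r}")

    @property
    def end(self) -> int:
        """Last reference base covered (1-based inclusive)."""
        return self.pos + len(self.ref) - 1

    def alleles_of(self, sample: str) -> set[int]:
        gt = self.genotypes.get(sample)
        return set() if gt is None else set(gt)

    def hom_alt_index(self, sample: str) -> int | None:
        """ALT allele index (1-based) if the sample is homozygous non-reference."""
        gt = self.genotypes.get(sample)
        if gt is not None and gt[0] == gt[1] and gt[0] > 0:
            return gt[0]
        return None


def read_variants(path, sample_subset: Sequence[str] | None = None) -> Iterator[Variant]:
    """Stream :class:`Variant` records from a VCF 4.2 file in file order."""
    with pysam.VariantFile(str(path)) as vf:
        file_samples = list(vf.header.samples)
        if sample_subset is not None:
            unknown = set(sample_subset) - set(file_samples)
            if unknown:
                raise KeyError(f"samples not in VCF: {sorted(unknown)}")
            keep = list(sample_subset)
        else:
            keep = file_samples
        for rec in vf:
            genos: dict[str, Genotype] = {}
            for s in keep:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    genos[s] = None
                else:
                    genos[s] = (int(gt[0]), int(gt[1]))
            yield Variant(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts or ()),
                genotypes=genos,
                vid=rec.id,
            )


def write_vcf(path, variants: Iterable[Variant], samples: Sequence[str],
              contigs: dict[str, int]) -> None:
    """Write records as VCF 4.2 (plain text, or bgzip if path ends in .gz)."""
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    mode = "wz" if str(path).endswith(".gz") else "w"
    with pysam.VariantFile(str(path), mode, header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, *v.alts),
                id=v.vid,
            )
            for s in samples:
                gt = v.genotypes.get(s)
                rec.samples[s]["GT"] = (None, None) if gt is None else tuple(gt)
                rec.samples[s].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# Transcript models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on a reference chromosome.

    Exons are genomic-ascending 1-based inclusive intervals regardless of
    strand; ``strand`` says how to read them.  The CDS is the genomic
    interval [cds_start, cds_end]; its coding bases are the exonic bases
    inside that interval.  A *complete* model must have CDS length
    divisible by three.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    complete: bool = True

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s < 1 or e < s:
                raise ValueError(f"bad exon interval ({s}, {e})")
            if s <= prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            prev_end = e
        if not self.exons:
            raise ValueError("transcript has no exons")
        if self.cds_start > self.cds_end:
            raise ValueError("CDS start > end")
        if not (self._is_exonic(self.cds_start) and self._is_exonic(self.cds_end)):
            raise ValueError("CDS boundaries must fall inside exons")
        if self.complete and self.cds_len % 3 != 0:
            raise ValueError(f"CDS length {self.cds_len} not a multiple of 3")

    def _is_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def cds_blocks(self) -> list[tuple[int, int]]:
        """Coding sub-intervals of the exons, genomic ascending."""
        blocks = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                blocks.append((lo, hi))
        return blocks

    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_blocks())


def read_transcripts(path) -> list[TranscriptModel]:
    """Parse transcript models from GFF3 (exon + CDS features per transcript)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for feat_type in ("mRNA", "transcript"):
        for tx in db.features_of_type(feat_type):
            exons = sorted((f.start, f.end) for f in db.children(tx, featuretype="exon"))
            cds = sorted((f.start, f.end) for f in db.children(tx, featuretype="CDS"))
            if not cds:
                continue
            model = TranscriptModel(
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds_start=cds[0][0],
                cds_end=cds[-1][1],
            )
            # every CDS base must be exonic in the declared exon set
            covered = model.cds_blocks()
            if covered != cds:
                raise ValueError(
                    f"{tx.id}: CDS features not contained in exons (CDS {cds} vs exonic {covered})"
                )
            models.append(model)
    return models


def _cds_phases(model: TranscriptModel) -> list[int]:
    """GFF3 phase column for each CDS block, in genomic-ascending order."""
    blocks = model.cds_blocks()
    order = blocks if model.strand == "+" else list(reversed(blocks))
    phases, cum = {}, 0
    for s, e in order:
        phases[(s, e)] = (3 - cum % 3) % 3
        cum += e - s + 1
    return [phases[b] for b in blocks]


def write_gff3(path, models: Sequence[TranscriptModel], source: str = "pelage") -> None:
    with openf(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gid = f"gene:{m.transcript_id}"
            fh.write("\t".join([
                m.chrom, source, "gene", str(m.tx_start), str(m.tx_end),
                ".", m.strand, ".", f"ID={gid}",
            ]) + "\n")
            fh.write("\t".join([
                m.chrom, source, "mRNA", str(m.tx_start), str(m.tx_end),
                ".", m.strand, ".", f"ID={m.transcript_id};Parent={gid}",
            ]) + "\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write("\t".join([
                    m.chrom, source, "exon", str(s), str(e), ".", m.strand, ".",
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}",
                ]) + "\n")
            for (s, e), phase in zip(m.cds_blocks(), _cds_phases(m)):
                fh.write("\t".join([
                    m.chrom, source, "CDS", str(s), str(e), ".", m.strand, str(phase),
                    f"ID={m.transcript_id}.cds;Parent={m.transcript_id}",
                ]) + "\n")


# ---------------------------------------------------------------------------
# Reference bundle
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    """Per-chromosome sequence plus the transcript models annotated on it."""

    sequences: dict[str, str]
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self):
        for m in self.transcripts:
            if m.chrom not in self.sequences:
                raise ValueError(f"{m.transcript_id}: chromosome {m.chrom!r} not in reference")
            if m.tx_end > len(self.sequences[m.chrom]):
                raise ValueError(f"{m.transcript_id}: coordinates exceed chromosome length")

    def write(self, fasta_path, gff3_path=None, line_width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        with openf(fasta_path, "wt") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(records)
        if gff3_path is not None:
            write_gff3(gff3_path, self.transcripts)

    @classmethod
    def read(cls, fasta_path, gff3_path=None) -> "ReferenceBundle":
        with openf(fasta_path, "rt") as fh:
            sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
        transcripts = read_transcripts(gff3_path) if gff3_path is not None else []
        return cls(sequences=sequences, transcripts=transcripts)


def extract_cds(model: TranscriptModel, reference: ReferenceBundle) -> str:
    """Concatenated coding sequence in transcription order.

    Minus-strand models return the reverse complement of the ascending
    exon concatenation.
    """
    seq = reference.sequences.get(model.chrom)
    if seq is None:
        raise ValueError(f"chromosome {model.chrom!r} not in reference")
    if model.tx_end > len(seq):
        raise ValueError(f"{model.transcript_id}: coordinates out of bounds")
    parts = [seq[s - 1:e] for s, e in model.cds_blocks()]
    cds = "".join(parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    if model.complete and len(cds) % 3 != 0:
        raise ValueError("extracted CDS length not a multiple of 3")
    return cds
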