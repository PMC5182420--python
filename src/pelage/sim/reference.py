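"""Synthetic reference sequences and transcript models with known truth.

The main transcript is engineered so that deleting four bases (``TTAG``)
immediately after the first base of a chosen codon produces a frameshift
with a fully predetermined protein consequence: the wild-type codon is Val
(GTT), the first mutant residue is Gly, and the shifted reading frame
reaches its first stop at a chosen offset.  With the defaults (471 codons,
site at codon 96, Ter offset 50) the planted consequence is
``Val96GlyfsTer50`` and the site falls inside exon 4 of an 18-exon model.

Both reading frames are controlled during construction: the wild-type CDS
translates without internal stops, and the shifted frame downstream of the
deletion is stop-free until the engineered terminator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from pelage._util import rng_from
from pelage.io import ReferenceBundle, TranscriptModel
from pelage.sim.genedrop import SimulationConfig

STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
]


@dataclass(frozen=True)
class FrameshiftSite:
    """Engineered deletion site: ``deleted`` bases removed after the first
    base of ``codon``, shifting the frame to a stop at ``ter_offset``
    (HGVS counting: the first changed residue is 1)."""

    codon: int = 96
    deleted: str = "TTAG"
    ter_offset: int = 50
    ref_residue: str = "Val"
    alt_residue: str = "Gly"

    @property
    def hgvs_p(self) -> str:
        return f"{self.ref_residue}{self.codon}{self.alt_residue}fsTer{self.ter_offset}"


@dataclass
class TranscriptSpec:
    """Blueprint for one synthetic transcript."""

    transcript_id: str
    chrom: str
    strand: str = "+"
    tx_start: int = 1_000_000
    n_exons: int = 18
    cds_codons: int = 471  # includes the terminal stop codon
    utr5: int = 120
    utr3: int = 200
    intron_len: int = 400
    site: FrameshiftSite | None = None
    exon_cds_lengths: list[int] | None = None  # explicit split of the CDS over exons

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.n_exons < 1 or self.cds_codons < 3:
            raise ValueError("need at least one exon and three codons")
        if self.exon_cds_lengths is not None:
            if len(self.exon_cds_lengths) != self.n_exons:
                raise ValueError("exon_cds_lengths must have n_exons entries")
            if sum(self.exon_cds_lengths) % 3 != 0:
                raise ValueError("total CDS length not a multiple of 3")
            if sum(self.exon_cds_lengths) != 3 * self.cds_codons:
                raise ValueError("exon_cds_lengths inconsistent with cds_codons")

    @property
    def cds_len(self) -> int:
        return 3 * self.cds_codons

    def cds_chunks(self) -> list[int]:
        if self.exon_cds_lengths is not None:
            return list(self.exon_cds_lengths)
        base, rem = divmod(self.cds_len, self.n_exons)
        return [base + (1 if i < rem else 0) for i in range(self.n_exons)]


def _rel_layout(spec: TranscriptSpec) -> tuple[list[tuple[int, int]], int, int]:
    """Exon intervals, CDS start/end — all relative 1-based coordinates."""
    chunks = spec.cds_chunks()
    exons = []
    cur = 1
    for i, chunk in enumerate(chunks):
        length = chunk + (spec.utr5 if i == 0 else 0) + (spec.utr3 if i == len(chunks) - 1 else 0)
        exons.append((cur, cur + length - 1))
        cur += length + spec.intron_len
    cds_start = exons[0][0] + spec.utr5
    cds_end = exons[-1][1] - spec.utr3
    return exons, cds_start, cds_end


def _rel_cds_to_rel_genomic(spec: TranscriptSpec, cds_pos: int) -> int:
    """Relative genomic coordinate of a 1-based CDS position (ascending order)."""
    exons, cds_start, cds_end = _rel_layout(spec)
    remaining = cds_pos
    for s, e in exons:
        lo, hi = max(s, cds_start), min(e, cds_end)
        if lo > hi:
            continue
        n = hi - lo + 1
        if remaining <= n:
            return lo + remaining - 1
        remaining -= n
    raise ValueError(f"CDS position {cds_pos} beyond CDS length")


def _fill_codon(cds: list, start0: int, rng) -> None:
    """Fill unset bases of the wild-type codon at 0-based ``start0`` so it is non-stop."""
    for _ in range(200):
        trial = list(cds[start0:start0 + 3])
        for k in range(3):
            if trial[k] is None:
                trial[k] = "ACGT"[rng.integers(4)]
        if "".join(trial) not in STOP_CODONS:
            cds[start0:start0 + 3] = trial
            return
    raise RuntimeError("could not fill codon without creating a stop")


def _engineer_cds(spec: TranscriptSpec, rng: np.random.Generator) -> str:
    """Build the CDS string; honours the frameshift site when present."""
    n = spec.cds_len
    cds: list = [None] * n
    cds[0:3] = list("ATG")
    cds[n - 3:n] = list("TAA")

    site = spec.site
    if site is not None:
        c, t = site.codon, site.ter_offset
        if site.deleted != "TTAG" or site.ref_residue != "Val" or site.alt_residue != "Gly":
            raise ValueError("engineered sites currently support the TTAG/Val->Gly geometry")
        if not (2 <= c and 3 * c + 3 * (t - 1) + 4 <= n - 3):
            raise ValueError("frameshift site does not fit inside the CDS")
        # wild-type: codon c = GTT (Val), codon c+1 = AGG; deleting TTAG after
        # the G leaves mutant codon c = G + GA = Gly.
        anchor0 = 3 * c - 3  # 0-based index of codon c's first base
        cds[anchor0:anchor0 + 6] = list("GTTAGG")
        cds[anchor0 + 6] = "A"
        # mutant-frame codons c+1 .. c+t-2 must be non-stop; mutant codon
        # c+j occupies wild-type 0-based [anchor0+4+3j, anchor0+6+3j)
        for j in range(1, t - 1):
            p = anchor0 + 4 + 3 * j
            for _ in range(200):
                trial = _NONSTOP[rng.integers(len(_NONSTOP))]
                cds[p:p + 3] = list(trial)
                # wild-type codons fully determined by this chunk must be non-stop
                ok = True
                for w0 in range(p - p % 3, p + 3, 3):
                    codon = cds[w0:w0 + 3]
                    if None not in codon and "".join(codon) in STOP_CODONS:
                        ok = False
                        break
                if ok:
                    break
                cds[p:p + 3] = [None] * 3
            else:
                raise RuntimeError("frameshift-site engineering failed")
        # the engineered terminator of the shifted frame
        p = anchor0 + 4 + 3 * (t - 1)
        cds[p:p + 3] = list("TAA")

    for w0 in range(0, n, 3):
        if None in cds[w0:w0 + 3]:
            _fill_codon(cds, w0, rng)

    out = "".join(cds)
    protein = str(Seq(out).translate())
    if "*" in protein[:-1] or not protein.endswith("*"):
        raise RuntimeError("engineered CDS has an internal stop")
    if site is not None:
        mutant = out[:3 * site.codon - 2] + out[3 * site.codon + 2:]
        mprot = str(Seq(mutant[:len(mutant) - len(mutant) % 3]).translate())
        first = site.codon - 1
        assert protein[first] == "V" and mprot[first] == "G"
        assert mprot.find("*", first) - first + 1 == site.ter_offset
    return out


def default_transcript_specs(config: SimulationConfig) -> list[TranscriptSpec]:
    """The demo transcript set: the engineered kinase-like gene anchored at
    the causal locus, plus a small decoy transcript on another chromosome."""
    main = TranscriptSpec(transcript_id="TX_SGK3LIKE", chrom=config.causal_chrom,
                          site=FrameshiftSite())
    # shift the transcript so the deletion anchor (first base of the site
    # codon) sits exactly at the configured causal position
    rel_anchor = _rel_cds_to_rel_genomic(main, 3 * main.site.codon - 2)
    main.tx_start = config.causal_pos - (rel_anchor - 1)
    if main.tx_start < 1:
        raise ValueError("causal position too close to the chromosome start")
    others = [c for c in config.chromosomes if c != config.causal_chrom]
    specs = [main]
    if others:
        specs.append(TranscriptSpec(
            transcript_id="TX_DECOY", chrom=others[0], strand="+",
            tx_start=min(6_000_000, config.chromosomes[others[0]] // 2),
            n_exons=4, cds_codons=120, utr5=80, utr3=80, intron_len=300,
        ))
    return specs


def _random_sequence(length: int, rng: np.random.Generator) -> bytearray:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(lut[rng.integers(0, 4, size=length, dtype=np.int64)].tobytes())


def make_reference_bundle(config: SimulationConfig,
                          transcript_specs: list[TranscriptSpec] | None = None,
                          seed: int = 0) -> ReferenceBundle:
    """Random reference chromosomes carrying the specified transcripts.

    Deterministic for a fixed seed (byte-identical FASTA on re-run).  The
    wild-type CDS of every transcript translates without internal stops.
    """
    if transcript_specs is None:
        transcript_specs = default_transcript_specs(config)
    rng = rng_from(seed, 202)
    raw = {chrom: _random_sequence(length, rng)
           for chrom, length in config.chromosomes.items()}

    models = []
    for spec in transcript_specs:
        if spec.chrom not in raw:
            raise ValueError(f"{spec.transcript_id}: chromosome {spec.chrom!r} not declared")
        exons_rel, cds_s_rel, cds_e_rel = _rel_layout(spec)
        off = spec.tx_start - 1
        exons = [(s + off, e + off) for s, e in exons_rel]
        if exons[0][0] < 1 or exons[-1][1] > len(raw[spec.chrom]):
            raise ValueError(f"{spec.transcript_id}: transcript exceeds chromosome bounds")
        model = TranscriptModel(
            transcript_id=spec.transcript_id, chrom=spec.chrom, strand=spec.strand,
            exons=exons, cds_start=cds_s_rel + off, cds_end=cds_e_rel + off,
        )
        cds = _engineer_cds(spec, rng)
        placed = cds if spec.strand == "+" else str(Seq(cds).reverse_complement())
        seq = raw[spec.chrom]
        cursor = 0
        for s, e in model.cds_blocks():
            n = e - s + 1
            seq[s - 1:e] = placed[cursor:cursor + n].encode()
            cursor += n
        models.append(model)

    sequences = {chrom: buf.decode() for chrom, buf in raw.items()}
    return ReferenceBundle(sequences=sequences, transcripts=models)


@dataclass(frozen=True)
class PlantedSite:
    """Genomic description of the engineered deletion, VCF left-anchored."""

    chrom: str
    pos: int          # anchor position
    ref: str          # anchor base + deleted bases
    alt: str          # anchor base
    transcript_id: str
    codon: int
    hgvs_p: str
    ter_offset: int


def planted_site(bundle: ReferenceBundle, spec: TranscriptSpec) -> PlantedSite:
    """Locate the engineered frameshift site of ``spec`` on the genome."""
    if spec.site is None:
        raise ValueError(f"{spec.transcript_id} has no engineered site")
    model = next(m for m in bundle.transcripts if m.transcript_id == spec.transcript_id)
    seq = bundle.sequences[model.chrom]
    c = spec.site.codon
    k = len(spec.site.deleted)
    # deleted CDS positions are 3c-1 .. 3c-2+k (just after the codon's first base)
    cds_positions = list(range(3 * c - 1, 3 * c - 1 + k))
    off = spec.tx_start - 1
    Lc = spec.cds_len
    if spec.strand == "+":
        genomic = [_rel_cds_to_rel_genomic(spec, p) + off for p in cds_positions]
        anchor = _rel_cds_to_rel_genomic(spec, 3 * c - 2) + off
        if genomic != list(range(anchor + 1, anchor + 1 + k)):
            raise ValueError("engineered site spans an exon boundary")
    else:
        # minus strand: CDS position p sits at the (Lc - p + 1)-th coding
        # base in genomic-ascending order; the VCF anchor is the base
        # genomically left of the deleted block
        genomic = sorted(_rel_cds_to_rel_genomic(spec, Lc - p + 1) + off
                         for p in cds_positions)
        if genomic != list(range(genomic[0], genomic[0] + k)):
            raise ValueError("engineered site spans an exon boundary")
        anchor = genomic[0] - 1
    ref = seq[anchor - 1:anchor + k]
    alt = seq[anchor - 1]
    return PlantedSite(
        chrom=model.chrom, pos=anchor, ref=ref, alt=alt,
        transcript_id=model.transcript_id, codon=c,
        hgvs_p=spec.site.hgvs_p, ter_offset=spec.site.ter_offset,
    )
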