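"""Coding-consequence annotation: project variants onto transcript models.

A variant is classified against one transcript at a time.  Coding indels
are left-aligned first (the VCF anchor base is excluded from the affected
interval, so a "5-base REF / 1-base ALT" record is the same event as
"removes four bases"); the mutant CDS is then rebuilt by editing the
spliced coding sequence and translated.

Frameshift arithmetic follows HGVS ``fs`` rules: the first affected
residue is the first codon whose *encoded residue* differs between
wild-type and mutant translation (not merely the first codon overlapping
the indel — the shifted frame can initially reproduce wild-type
residues), and ``TerN`` counts the new-frame stop codon with that residue
as 1, so the mutant stop sits at protein position first_affected + N - 1.

Indels straddling a CDS/exon boundary are not given protein arithmetic:
they come back as class ``splice_region`` with a ``splice_region_unsupported``
flag (splice modelling is out of scope).  The standard nuclear codon
table is used throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from pelage.io import ReferenceBundle, TranscriptModel, Variant

CLASSES = (
    "synonymous", "missense", "inframe_insertion", "inframe_deletion",
    "frameshift", "stop_gained", "stop_lost", "start_lost",
    "noncoding", "intronic", "intergenic", "splice_region",
)


@dataclass
class Consequence:
    transcript_id: str | None
    kind: str
    protein_pos: int | None = None       # first affected residue, 1-based
    ref_residue: str | None = None       # one-letter code ('*' for stop)
    alt_residue: str | None = None
    novel_peptide_length: int | None = None  # novel residues before the new stop
    ter_position_mutant: int | None = None   # stop residue index in the mutant protein
    hgvs_p: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in CLASSES:
            raise ValueError(f"unknown consequence class {self.kind!r}")

    @property
    def ter_offset(self) -> int | None:
        """HGVS TerN value: stop position in the new frame, first changed residue = 1."""
        if self.ter_position_mutant is None or self.protein_pos is None:
            return None
        return self.ter_position_mutant - self.protein_pos + 1


# ---------------------------------------------------------------------------
# Interval arithmetic and coordinate mapping
# ---------------------------------------------------------------------------

def interval_length(start: int, end: int) -> int:
    """Inclusive bp length of a 1-based interval: end - start + 1."""
    if start > end:
        raise ValueError(f"interval start {start} > end {end}")
    return end - start + 1


def genomic_to_cds(model: TranscriptModel, pos: int) -> int | None:
    """1-based CDS coordinate of a genomic position, or None if not coding."""
    blocks = model.cds_blocks()
    if model.strand == "+":
        off = 0
        for s, e in blocks:
            if s <= pos <= e:
                return off + pos - s + 1
            off += e - s + 1
    else:
        off = 0
        for s, e in reversed(blocks):
            if s <= pos <= e:
                return off + e - pos + 1
            off += e - s + 1
    return None


def cds_to_genomic(model: TranscriptModel, cds_pos: int) -> int:
    """Genomic position of a 1-based CDS coordinate."""
    blocks = model.cds_blocks()
    order = blocks if model.strand == "+" else list(reversed(blocks))
    remaining = cds_pos
    for s, e in order:
        n = e - s + 1
        if remaining <= n:
            return s + remaining - 1 if model.strand == "+" else e - remaining + 1
        remaining -= n
    raise ValueError(f"CDS position {cds_pos} beyond CDS of {model.transcript_id}")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def left_align(pos: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Normalise a variant to its left-most minimal representation.

    Standard VCF normalisation: trim shared trailing bases (extending to
    the left with the reference when an allele would empty), then trim
    shared leading bases down to the anchored form.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos == 1:
                return pos, ref, alt  # cannot extend past the chromosome start
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                b = seq[pos - 2].upper()
                ref, alt, pos = b + ref, b + alt, pos - 1
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        else:
            return pos, ref, alt


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _footprint(pos: int, ref: str, alt: str) -> tuple[int, int, str, bool]:
    """(genomic start, genomic end, replacement, is_insertion) of the edited
    bases, with the indel anchor base excluded."""
    if len(ref) == len(alt):                     # SNV / MNV
        return pos, pos + len(ref) - 1, alt, False
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt[0]:   # pure deletion
        return pos + 1, pos + len(ref) - 1, "", False
    if len(ref) == 1 and len(alt) > 1 and ref[0] == alt[0]:   # pure insertion
        return pos + 1, pos, alt[1:], True
    # complex substitution: replace the whole REF (no shared anchor)
    return pos, pos + len(ref) - 1, alt, False


def _locate(model: TranscriptModel, gs: int, ge: int, insertion: bool) -> str:
    """Coarse location of the footprint relative to the transcript."""
    if insertion:
        # an insertion sits between gs-1 and gs; it is coding when both
        # flanking bases are coding and adjacent in the CDS
        left, right = genomic_to_cds(model, gs - 1), genomic_to_cds(model, gs)
        if left is not None and right is not None and abs(left - right) == 1:
            return "cds"
        if ge < model.tx_start or gs > model.tx_end:
            return "intergenic"
        if left is not None or right is not None:
            return "splice_region"
        if any(s <= gs - 1 <= e or s <= gs <= e for s, e in model.exons):
            return "noncoding"
        return "intronic"
    if ge < model.tx_start or gs > model.tx_end:
        return "intergenic"
    coding = [genomic_to_cds(model, p) for p in range(gs, ge + 1)]
    if all(c is not None for c in coding):
        cs = sorted(coding)
        if cs == list(range(cs[0], cs[0] + len(cs))):
            return "cds"
        return "splice_region"  # coding but discontiguous (spans an intron)
    if any(c is not None for c in coding):
        return "splice_region"
    exonic = [any(s <= p <= e for s, e in model.exons) for p in range(gs, ge + 1)]
    if all(exonic):
        return "noncoding"
    if not any(exonic):
        return "intronic"
    return "noncoding"  # UTR exon edge


def _first_difference(wt: str, mut: str) -> int | None:
    n = min(len(wt), len(mut))
    for i in range(n):
        if wt[i] != mut[i]:
            return i
    if len(wt) != len(mut):
        return n
    return None


def annotate(variant: Variant, model: TranscriptModel, reference: ReferenceBundle,
             alt_index: int = 0) -> Consequence:
    """Classify one alternate allele of ``variant`` against ``model``.

    The variant is left-aligned against the reference before projection.
    For coding indels the mutant CDS is rebuilt and translated; class and
    protein fields follow from comparing the two translations.
    """
    if variant.chrom != model.chrom:
        raise ValueError(
            f"variant on {variant.chrom} cannot be annotated against "
            f"{model.transcript_id} on {model.chrom}"
        )
    seq = reference.sequences[model.chrom]
    pos, ref, alt = left_align(variant.pos, variant.ref, variant.alts[alt_index], seq)
    if seq[pos - 1:pos - 1 + len(ref)].upper() != ref:
        raise ValueError(f"REF allele mismatch at {variant.chrom}:{pos}")

    gs, ge, replacement, insertion = _footprint(pos, ref, alt)
    where = _locate(model, gs, ge, insertion)
    tid = model.transcript_id
    if where == "intergenic":
        return Consequence(tid, "intergenic")
    if where == "intronic":
        return Consequence(tid, "intronic")
    if where == "noncoding":
        return Consequence(tid, "noncoding")
    if where == "splice_region":
        return Consequence(tid, "splice_region", flags=["splice_region_unsupported"])

    wt_cds = _extract_cds_cached(model, reference)
    mut_cds = _edit_cds(wt_cds, model, gs, ge, replacement, insertion)

    wt_prot = str(Seq(wt_cds).translate())
    mut_prot = str(Seq(mut_cds[:len(mut_cds) - len(mut_cds) % 3]).translate())
    net = len(mut_cds) - len(wt_cds)

    if net % 3 != 0:
        cons = _frameshift_fields(tid, wt_prot, mut_prot)
    elif net == 0:
        cons = _substitution_fields(tid, wt_prot, mut_prot)
    else:
        kind = "inframe_deletion" if net < 0 else "inframe_insertion"
        i = _first_difference(wt_prot, mut_prot)
        if i is None:
            i = len(wt_prot) - 1
        cons = Consequence(
            tid, kind, protein_pos=i + 1,
            ref_residue=wt_prot[i] if i < len(wt_prot) else None,
            alt_residue=mut_prot[i] if i < len(mut_prot) else None,
        )
    cons.hgvs_p = hgvs_protein(cons)
    return cons


_CDS_CACHE: dict[int, tuple[object, str]] = {}


def _extract_cds_cached(model: TranscriptModel, reference: ReferenceBundle) -> str:
    from pelage.io import extract_cds

    key = id(model)
    hit = _CDS_CACHE.get(key)
    if hit is not None and hit[0] is model:
        return hit[1]
    cds = extract_cds(model, reference)
    _CDS_CACHE[key] = (model, cds)
    if len(_CDS_CACHE) > 64:
        _CDS_CACHE.pop(next(iter(_CDS_CACHE)))
    return cds


def _edit_cds(cds: str, model: TranscriptModel, gs: int, ge: int,
              replacement: str, insertion: bool) -> str:
    """Apply the genomic edit to the spliced CDS (strand-aware)."""
    if insertion:
        left = genomic_to_cds(model, gs - 1)
        right = genomic_to_cds(model, gs)
        cut = min(left, right)  # insert between CDS positions cut and cut+1
        ins = replacement if model.strand == "+" else str(Seq(replacement).reverse_complement())
        return cds[:cut] + ins + cds[cut:]
    c1 = genomic_to_cds(model, gs)
    c2 = genomic_to_cds(model, ge)
    lo, hi = min(c1, c2), max(c1, c2)
    rep = replacement if model.strand == "+" else str(Seq(replacement).reverse_complement())
    return cds[:lo - 1] + rep + cds[hi:]


def _substitution_fields(tid: str, wt: str, mut: str) -> Consequence:
    i = _first_difference(wt, mut)
    if i is None:
        return Consequence(tid, "synonymous", protein_pos=None)
    ref_res, alt_res = wt[i], mut[i]
    if i == 0 and ref_res == "M":
        kind = "start_lost"
    elif alt_res == "*":
        kind = "stop_gained"
    elif ref_res == "*":
        kind = "stop_lost"
    else:
        kind = "missense"
    return Consequence(tid, kind, protein_pos=i + 1, ref_residue=ref_res, alt_residue=alt_res)


def _frameshift_fields(tid: str, wt: str, mut: str) -> Consequence:
    i = _first_difference(wt, mut)
    if i is None:
        # frame restored with no residue change before the wild-type stop
        return Consequence(tid, "synonymous", protein_pos=None)
    ref_res = wt[i] if i < len(wt) else "*"
    alt_res = mut[i] if i < len(mut) else "*"
    stop = mut.find("*", i)
    if stop >= 0:
        return Consequence(
            tid, "frameshift", protein_pos=i + 1, ref_residue=ref_res,
            alt_residue=alt_res, novel_peptide_length=stop - i,
            ter_position_mutant=stop + 1,
        )
    return Consequence(
        tid, "frameshift", protein_pos=i + 1, ref_residue=ref_res,
        alt_residue=alt_res, novel_peptide_length=len(mut) - i,
        ter_position_mutant=None,
    )


# ---------------------------------------------------------------------------
# HGVS p. strings
# ---------------------------------------------------------------------------

def _aa3(one: str) -> str:
    return "Ter" if one == "*" else seq3(one)


def hgvs_protein(consequence: Consequence) -> str:
    """HGVS-style protein notation for an annotated consequence.

    Frameshifts render as ``RefPosAltfsTerN`` (``fsTer?`` when no stop is
    reached before the transcript end); a frameshift whose first changed
    residue is itself a stop collapses to the nonsense form ``RefPosTer``.
    """
    c = consequence
    if c.kind == "synonymous":
        if c.protein_pos is None:
            return "p.="
        return f"{_aa3(c.ref_residue)}{c.protein_pos}="
    if c.kind in ("intergenic", "intronic", "noncoding", "splice_region"):
        return "p.?"
    if c.protein_pos is None or c.ref_residue is None:
        raise ValueError(f"protein fields missing for class {c.kind}")
    if c.kind == "missense":
        return f"{_aa3(c.ref_residue)}{c.protein_pos}{_aa3(c.alt_residue)}"
    if c.kind == "stop_gained":
        return f"{_aa3(c.ref_residue)}{c.protein_pos}Ter"
    if c.kind == "stop_lost":
        return f"Ter{c.protein_pos}{_aa3(c.alt_residue)}ext?"
    if c.kind == "start_lost":
        return "Met1?"
    if c.kind == "frameshift":
        if c.alt_residue == "*":
            return f"{_aa3(c.ref_residue)}{c.protein_pos}Ter"
        if c.ter_position_mutant is None:
            return f"{_aa3(c.ref_residue)}{c.protein_pos}{_aa3(c.alt_residue)}fsTer?"
        return (f"{_aa3(c.ref_residue)}{c.protein_pos}{_aa3(c.alt_residue)}"
                f"fsTer{c.ter_offset}")
    if c.kind == "inframe_deletion":
        return f"{_aa3(c.ref_residue)}{c.protein_pos}del"
    if c.kind == "inframe_insertion":
        return f"{_aa3(c.ref_residue)}{c.protein_pos}ins"
    raise ValueError(f"no HGVS form for class {c.kind}")


_FS_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})fsTer(\d+|\?)$")
_MIS_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
_SYN_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)=$")

_THREE_TO_ONE = {
    seq3(a): a for a in "ACDEFGHIKLMNPQRSTVWY"
}
_THREE_TO_ONE["Ter"] = "*"


def parse_hgvs_p(text: str) -> dict:
    """Parse the frameshift/missense/synonymous forms back to their fields."""
    m = _FS_RE.match(text)
    if m:
        ref3, pos, alt3, ter = m.groups()
        return {
            "kind": "frameshift",
            "protein_pos": int(pos),
            "ref_residue": _THREE_TO_ONE[ref3],
            "alt_residue": _THREE_TO_ONE[alt3],
            "ter_offset": None if ter == "?" else int(ter),
        }
    m = _MIS_RE.match(text)
    if m:
        ref3, pos, alt3 = m.groups()
        kind = "stop_gained" if alt3 == "Ter" else "missense"
        return {"kind": kind, "protein_pos": int(pos),
                "ref_residue": _THREE_TO_ONE[ref3], "alt_residue": _THREE_TO_ONE[alt3]}
    m = _SYN_RE.match(text)
    if m:
        ref3, pos = m.groups()
        return {"kind": "synonymous", "protein_pos": int(pos),
                "ref_residue": _THREE_TO_ONE[ref3]}
    raise ValueError(f"unparseable HGVS p. string {text!r}")


# ---------------------------------------------------------------------------
# Domain overlap
# ---------------------------------------------------------------------------

def domain_overlap(consequence: Consequence,
                   domains: list[tuple[str, int, int]]) -> list[tuple[str, str]]:
    """Fate of protein domains under a truncating consequence.

    Domains entirely at or after the first affected residue are lost,
    domains spanning it are truncated, domains entirely before it are
    intact.  For non-truncating consequences every domain is intact.
    """
    pos = consequence.protein_pos
    truncating = consequence.kind in ("frameshift", "stop_gained")
    out = []
    for name, start, end in domains:
        if start > end or start < 1:
            raise ValueError(f"bad domain interval {name}: ({start}, {end})")
        if not truncating or pos is None or end < pos:
            out.append((name, "intact"))
        elif start >= pos:
            out.append((name, "lost"))
        else:
            out.append((name, "truncated"))
    return out
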