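"""Multi-sample variant fixtures: one case genome against a control panel.

Emulates the sequencing stage of a recessive-trait study: the sequenced
case is homozygous for a planted private frameshift deletion inside the
mapped region, the control panel never carries its alternate allele, and a
configurable mix of background variants is shared with the panel or
private to the case.  The truth of every record is retained so downstream
filters can be checked record by record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from pelage._util import rng_from
from pelage.io import ReferenceBundle, TranscriptModel, Variant, extract_cds, write_vcf
from pelage.sim.reference import PlantedSite, TranscriptSpec, planted_site

_BASES = "ACGT"

# truth categories
PLANTED = "planted_frameshift"
SHARED = "shared_background"
PRIVATE_BG = "private_background"
PRIVATE_SYN = "private_synonymous"
PRIVATE_INTRONIC = "private_intronic"
PRIVATE_MISSENSE_DECOY = "private_missense_decoy"
PANEL_ONLY = "panel_only"


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    hgvs_p: str


@dataclass
class VariantFixture:
    """A generated variant study with per-record ground truth."""

    variants: list[Variant]
    case_id: str
    panel_ids: list[str]
    truth: dict[tuple[str, int], str]  # (chrom, pos) -> category
    planted: PlantedVariant | None = None

    @property
    def samples(self) -> list[str]:
        return [self.case_id] + self.panel_ids

    def write(self, path, contigs: dict[str, int]) -> None:
        write_vcf(path, self.variants, self.samples, contigs)


def _other_base(base: str, rng) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(3))]


def _genic_mask(models: list[TranscriptModel], chrom: str, pos: int) -> bool:
    return any(m.chrom == chrom and m.tx_start <= pos <= m.tx_end for m in models)


_SYN_THIRD = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}  # 4-fold degenerate prefixes


def _synonymous_snv(model: TranscriptModel, bundle: ReferenceBundle, rng) -> Variant | None:
    """A third-position SNV in a four-fold degenerate codon of the model."""
    from pelage.consequence import cds_to_genomic

    cds = extract_cds(model, bundle)
    codons = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
    candidates = [i for i, cod in enumerate(codons) if cod[:2] in _SYN_THIRD]
    if not candidates:
        return None
    i = candidates[int(rng.integers(len(candidates)))]
    cds_pos = 3 * i + 3
    gpos = cds_to_genomic(model, cds_pos)
    seq = bundle.sequences[model.chrom]
    ref = seq[gpos - 1]
    new_cds_base = _other_base(cds[cds_pos - 1], rng)
    alt = new_cds_base if model.strand == "+" else str(Seq(new_cds_base).complement())
    return Variant(chrom=model.chrom, pos=gpos, ref=ref, alts=(alt,))


def _missense_snv(model: TranscriptModel, bundle: ReferenceBundle, rng) -> Variant:
    """A first-position SNV; almost always changes the residue (retry until it does)."""
    from pelage.consequence import annotate, cds_to_genomic

    seq = bundle.sequences[model.chrom]
    for _ in range(100):
        codon_i = int(rng.integers(1, model.cds_len // 3 - 1))
        cds_pos = 3 * codon_i + 1
        gpos = cds_to_genomic(model, cds_pos)
        ref = seq[gpos - 1]
        alt = _other_base(ref, rng)
        var = Variant(chrom=model.chrom, pos=gpos, ref=ref, alts=(alt,))
        if annotate(var, model, bundle).kind == "missense":
            return var
    raise RuntimeError("could not place a missense decoy")


def _intronic_snv(model: TranscriptModel, bundle: ReferenceBundle, rng) -> Variant:
    s, e = model.exons[0][1] + 5, model.exons[1][0] - 5
    gpos = int(rng.integers(s, e + 1))
    ref = bundle.sequences[model.chrom][gpos - 1]
    return Variant(chrom=model.chrom, pos=gpos, ref=ref, alts=(_other_base(ref, rng),))


def plant_private_frameshift(
    reference: ReferenceBundle,
    panel_size: int = 89,
    deletion_length: int = 4,
    seed: int = 0,
    case_id: str = "CASE",
    site_spec: TranscriptSpec | None = None,
    n_background: int = 360,
    share_rate: float = 0.8,
    panel_missing_rate: float = 0.01,
    include_planted: bool = True,
    include_decoys: bool = True,
) -> VariantFixture:
    """Emit a case-versus-panel variant set with a planted private deletion.

    The case is homozygous for the planted frameshift; no panel sample
    carries its alternate allele.  ``share_rate`` of the background
    variants are carried by at least one panel sample; the rest are
    private homozygotes in the case (intergenic unless decoys place them
    in transcripts).  A ``panel_size`` of 89 reproduces the contrast-panel
    size of the motivating study design.
    """
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    rng = rng_from(seed, 303)
    panel_ids = [f"PANEL_{i:03d}" for i in range(1, panel_size + 1)]
    models = reference.transcripts
    variants: list[Variant] = []
    truth: dict[tuple[str, int], str] = {}
    used: set[tuple[str, int]] = set()

    def case_and_panel(category: str, case_gt, carriers: int) -> dict:
        genos = {case_id: case_gt}
        carrier_ids = (list(rng.choice(panel_ids, size=min(carriers, panel_size),
                                       replace=False)) if carriers else [])
        for s in panel_ids:
            if s in carrier_ids:
                genos[s] = (0, 1) if rng.random() < 0.7 else (1, 1)
            elif rng.random() < panel_missing_rate:
                genos[s] = None
            else:
                genos[s] = (0, 0)
        return genos

    planted: PlantedVariant | None = None
    if include_planted:
        if site_spec is not None and site_spec.site is not None and deletion_length == len(site_spec.site.deleted):
            site = planted_site(reference, site_spec)
            hgvs = site.hgvs_p
            chrom, pos, ref, alt = site.chrom, site.pos, site.ref, site.alt
            tx_id = site.transcript_id
        else:
            chrom, pos, ref, alt, tx_id, hgvs = _generic_deletion(
                reference, deletion_length, rng)
        genos = case_and_panel(PLANTED, (1, 1), carriers=0)
        variants.append(Variant(chrom=chrom, pos=pos, ref=ref, alts=(alt,), genotypes=genos))
        truth[(chrom, pos)] = PLANTED
        used.add((chrom, pos))
        planted = PlantedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                 transcript_id=tx_id, hgvs_p=hgvs)

    if include_decoys and models:
        main = models[0]
        for make, category in ((_synonymous_snv, PRIVATE_SYN),
                               (_intronic_snv, PRIVATE_INTRONIC)):
            var = make(main, reference, rng)
            if var is None or (var.chrom, var.pos) in used:
                continue
            genos = case_and_panel(category, (1, 1), carriers=0)
            variants.append(Variant(chrom=var.chrom, pos=var.pos, ref=var.ref,
                                    alts=var.alts, genotypes=genos))
            truth[(var.chrom, var.pos)] = category
            used.add((var.chrom, var.pos))
        if len(models) > 1:
            var = _missense_snv(models[1], reference, rng)
            if (var.chrom, var.pos) not in used:
                genos = case_and_panel(PRIVATE_MISSENSE_DECOY, (1, 1), carriers=0)
                variants.append(Variant(chrom=var.chrom, pos=var.pos, ref=var.ref,
                                        alts=var.alts, genotypes=genos))
                truth[(var.chrom, var.pos)] = PRIVATE_MISSENSE_DECOY
                used.add((var.chrom, var.pos))

    chroms = list(reference.sequences)
    for _ in range(n_background):
        for _try in range(50):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, len(reference.sequences[chrom]) + 1))
            if (chrom, pos) not in used and not _genic_mask(models, chrom, pos):
                break
        else:
            continue
        used.add((chrom, pos))
        ref = reference.sequences[chrom][pos - 1]
        if ref not in _BASES:
            continue
        alt = _other_base(ref, rng)
        r = rng.random()
        if r < share_rate:
            category = SHARED
            case_gt = [(0, 0), (0, 1), (1, 1)][int(rng.integers(3))]
            genos = case_and_panel(category, case_gt, carriers=1 + int(rng.poisson(3)))
        elif r < share_rate + (1 - share_rate) * 0.8:
            category = PRIVATE_BG
            genos = case_and_panel(category, (1, 1), carriers=0)
        else:
            category = PANEL_ONLY
            genos = case_and_panel(category, (0, 0), carriers=1 + int(rng.poisson(2)))
        variants.append(Variant(chrom=chrom, pos=pos, ref=ref, alts=(alt,), genotypes=genos))
        truth[(chrom, pos)] = category

    order = {c: i for i, c in enumerate(chroms)}
    variants.sort(key=lambda v: (order[v.chrom], v.pos))
    return VariantFixture(variants=variants, case_id=case_id, panel_ids=panel_ids,
                          truth=truth, planted=planted)


def _generic_deletion(reference: ReferenceBundle, deletion_length: int, rng):
    """Place a deletion of arbitrary length inside a CDS exon; truth via translation."""
    from pelage.consequence import annotate, hgvs_protein

    if not reference.transcripts:
        raise ValueError("reference has no transcripts; deletion must lie in a CDS exon")
    model = reference.transcripts[0]
    seq = reference.sequences[model.chrom]
    blocks = model.cds_blocks()
    for _ in range(200):
        s, e = blocks[int(rng.integers(len(blocks)))]
        if e - s + 1 < deletion_length + 2:
            continue
        anchor = int(rng.integers(s, e - deletion_length))
        if anchor <= model.cds_start:  # keep the start codon intact
            continue
        ref = seq[anchor - 1:anchor + deletion_length]
        alt = seq[anchor - 1]
        var = Variant(chrom=model.chrom, pos=anchor, ref=ref, alts=(alt,))
        cons = annotate(var, model, reference)
        if cons.kind in ("frameshift", "inframe_deletion"):
            return model.chrom, anchor, ref, alt, model.transcript_id, hgvs_protein(cons)
    raise ValueError(f"no CDS exon can host a {deletion_length} bp deletion")
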