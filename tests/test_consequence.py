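"""Consequence annotation against the genome-rebuild translation oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import toy_bundle
from oracles import random_coding_variant, rebuild_and_translate
from pelage.consequence import (
    Consequence,
    annotate,
    cds_to_genomic,
    domain_overlap,
    hgvs_protein,
    interval_length,
    left_align,
    parse_hgvs_p,
)
from pelage.io import Variant


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("start,end,length", [
    (16366702, 16366705, 4),         # the deleted TTAG
    (15973319, 20794824, 4_821_506),  # the mapped region, > 4.8 Mb
    (7, 7, 1),
])
def test_interval_length_inclusive(start, end, length):
    assert interval_length(start, end) == length


def test_interval_length_rejects_reversed():
    with pytest.raises(ValueError):
        interval_length(10, 9)


# ---------------------------------------------------------------------------
# Classification examples
# ---------------------------------------------------------------------------

def _snv_at_cds(bundle, model, cds_pos, new_base):
    from Bio.Seq import Seq

    g = cds_to_genomic(model, cds_pos)
    seq = bundle.sequences[model.chrom]
    alt = new_base if model.strand == "+" else str(Seq(new_base).complement())
    return Variant(model.chrom, g, seq[g - 1], (alt,))


def test_four_base_deletion_is_frameshift():
    bundle, model = toy_bundle(seed=11)
    g = cds_to_genomic(model, 16)
    seq = bundle.sequences[model.chrom]
    v = Variant(model.chrom, g, seq[g - 1:g + 4], (seq[g - 1],))
    assert annotate(v, model, bundle).kind == "frameshift"


def test_three_base_deletion_is_inframe():
    bundle, model = toy_bundle(seed=11)
    g = cds_to_genomic(model, 16)
    seq = bundle.sequences[model.chrom]
    v = Variant(model.chrom, g, seq[g - 1:g + 3], (seq[g - 1],))
    cons = annotate(v, model, bundle)
    assert cons.kind == "inframe_deletion"


def test_synonymous_and_missense_snvs():
    from Bio.Seq import Seq

    bundle, model = toy_bundle(seed=12, cds_codons=120)
    from pelage.io import extract_cds

    cds = extract_cds(model, bundle)
    # find a four-fold degenerate codon and change its third base
    four_fold = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
    idx = next(i for i in range(1, len(cds) // 3 - 1) if cds[3 * i:3 * i + 2] in four_fold)
    old = cds[3 * idx + 2]
    new = next(b for b in "ACGT" if b != old)
    v = _snv_at_cds(bundle, model, 3 * idx + 3, new)
    assert annotate(v, model, bundle).kind == "synonymous"
    # a CTx -> GTx first-position change is always Leu -> Val
    idx2 = next(i for i in range(1, len(cds) // 3 - 1) if cds[3 * i:3 * i + 2] == "CT")
    v2 = _snv_at_cds(bundle, model, 3 * idx2 + 1, "G")
    cons = annotate(v2, model, bundle)
    assert cons.kind == "missense"
    assert cons.hgvs_p == f"Leu{idx2 + 1}Val"


def test_intronic_noncoding_intergenic_locations():
    bundle, model = toy_bundle(seed=13)
    seq = bundle.sequences[model.chrom]
    intron_pos = model.exons[0][1] + 10
    v = Variant(model.chrom, intron_pos, seq[intron_pos - 1], ("A" if seq[intron_pos - 1] != "A" else "C",))
    assert annotate(v, model, bundle).kind == "intronic"
    utr_pos = model.exons[0][0] + 3  # inside the 5' UTR
    v = Variant(model.chrom, utr_pos, seq[utr_pos - 1], ("A" if seq[utr_pos - 1] != "A" else "C",))
    assert annotate(v, model, bundle).kind == "noncoding"
    v = Variant(model.chrom, 10, seq[9], ("A" if seq[9] != "A" else "C",))
    assert annotate(v, model, bundle).kind == "intergenic"


def test_exon_boundary_indel_flagged_not_project():
    bundle, model = toy_bundle(seed=14)
    seq = bundle.sequences[model.chrom]
    # deletion spanning the end of exon 2 into the intron
    end = model.exons[1][1]
    v = Variant(model.chrom, end - 2, seq[end - 3:end + 3], (seq[end - 3],))
    cons = annotate(v, model, bundle)
    assert cons.kind == "splice_region"
    assert "splice_region_unsupported" in cons.flags
    assert cons.protein_pos is None


def test_chromosome_mismatch_fails():
    bundle, model = toy_bundle(seed=15)
    v = Variant("elsewhere", 100, "A", ("T",))
    with pytest.raises(ValueError, match="annotated against"):
        annotate(v, model, bundle)


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------

def run_oracle_comparison(n_cases: int, seed: int) -> int:
    """Compare annotate with the genome-rebuild oracle on random variants."""
    rng = np.random.default_rng(seed)
    checked = 0
    while checked < n_cases:
        strand = "+" if rng.random() < 0.5 else "-"
        bundle, model = toy_bundle(seed=int(rng.integers(1 << 30)), strand=strand,
                                   cds_codons=int(rng.integers(25, 60)),
                                   n_exons=int(rng.integers(1, 5)))
        for _ in range(12):
            var = random_coding_variant(model, bundle, rng)
            if var is None:
                continue
            want = rebuild_and_translate(var, model, bundle)
            if want is None:
                continue
            cons = annotate(var, model, bundle)
            got = {
                "kind": cons.kind,
                "protein_pos": cons.protein_pos,
                "novel_peptide_length": cons.novel_peptide_length,
                "ter_position_mutant": cons.ter_position_mutant,
            }
            assert got == want, (var, got, want)
            # frameshift strings must parse back to their own fields
            if cons.kind == "frameshift" and cons.alt_residue != "*":
                fields = parse_hgvs_p(cons.hgvs_p)
                assert fields["protein_pos"] == cons.protein_pos
                assert fields["ter_offset"] == cons.ter_offset
            checked += 1
            if checked >= n_cases:
                break
    return checked


def test_annotate_matches_rebuild_oracle_sample():
    assert run_oracle_comparison(120, seed=77) == 120


def test_strand_symmetry():
    """The same CDS edit gives identical consequences on either strand."""
    rng = np.random.default_rng(55)
    plus_b, plus_m = toy_bundle(seed=21, strand="+", cds_codons=40)
    minus_b, minus_m = toy_bundle(seed=21, strand="-", cds_codons=40)
    from pelage.io import extract_cds

    assert extract_cds(plus_m, plus_b) == extract_cds(minus_m, minus_b)
    for cds_pos in (10, 33, 61, 100):
        for new in "ACGT":
            vp = _snv_at_cds(plus_b, plus_m, cds_pos, new)
            vm = _snv_at_cds(minus_b, minus_m, cds_pos, new)
            cp = annotate(vp, plus_m, plus_b)
            cm = annotate(vm, minus_m, minus_b)
            assert (cp.kind, cp.protein_pos, cp.ref_residue, cp.alt_residue) == \
                (cm.kind, cm.protein_pos, cm.ref_residue, cm.alt_residue)


@given(data=st.data())
def test_left_align_preserves_the_edit_and_is_idempotent(data):
    """Normalisation changes the representation, never the mutated sequence."""
    seq = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=80))
    pos = data.draw(st.integers(min_value=3, max_value=len(seq) - 8))
    if data.draw(st.booleans()):
        k = data.draw(st.integers(min_value=1, max_value=5))
        ref, alt = seq[pos - 1:pos + k], seq[pos - 1]
    else:
        ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=5))
        ref, alt = seq[pos - 1], seq[pos - 1] + ins

    def apply(p, r, a):
        assert seq[p - 1:p - 1 + len(r)] == r
        return seq[:p - 1] + a + seq[p - 1 + len(r):]

    p2, r2, a2 = left_align(pos, ref, alt, seq)
    assert apply(p2, r2, a2) == apply(pos, ref, alt)
    assert left_align(p2, r2, a2, seq) == (p2, r2, a2)


def test_left_alignment_of_homopolymer_deletion():
    seq = "GGGAAAATTTT"
    pos, ref, alt = left_align(7, "AT", "A", seq)  # delete one T of the run
    assert (pos, ref, alt) == (7, "AT", "A")
    pos, ref, alt = left_align(5, "AA", "A", seq)  # delete one A, shifts left
    assert (pos, ref, alt) == (3, "GA", "G")


# ---------------------------------------------------------------------------
# HGVS strings
# ---------------------------------------------------------------------------

def test_engineered_frameshift_hgvs():
    """The planted deletion annotates as Val96GlyfsTer50, and the mutant
    stop falls at residue 96 + 50 - 1 = 145."""
    from pelage.sim.genedrop import SimulationConfig
    from pelage.sim.reference import default_transcript_specs, make_reference_bundle, planted_site

    config = SimulationConfig(seed=6)
    specs = default_transcript_specs(config)
    bundle = make_reference_bundle(config, specs, seed=6)
    site = planted_site(bundle, specs[0])
    v = Variant(site.chrom, site.pos, site.ref, (site.alt,))
    cons = annotate(v, bundle.transcripts[0], bundle)
    assert cons.kind == "frameshift"
    assert cons.hgvs_p == "Val96GlyfsTer50"
    assert cons.protein_pos == 96
    assert cons.ter_position_mutant == 145 == cons.protein_pos + cons.ter_offset - 1
    assert cons.novel_peptide_length == 49


def test_missense_format():
    cons = Consequence("T", "missense", protein_pos=10, ref_residue="A", alt_residue="T")
    assert hgvs_protein(cons) == "Ala10Thr"


def test_synonymous_format():
    cons = Consequence("T", "synonymous", protein_pos=7, ref_residue="G")
    assert hgvs_protein(cons) == "Gly7="


def test_frameshift_without_downstream_stop_uses_question_mark():
    cons = Consequence("T", "frameshift", protein_pos=5, ref_residue="L",
                       alt_residue="P", novel_peptide_length=12,
                       ter_position_mutant=None)
    assert hgvs_protein(cons) == "Leu5ProfsTer?"


def test_hgvs_requires_fields():
    with pytest.raises(ValueError, match="missing"):
        hgvs_protein(Consequence("T", "missense"))


def test_parse_rejects_garbage():
    with pytest.raises(ValueError):
        parse_hgvs_p("not-hgvs")


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------

def test_domain_fates_for_truncation_at_96():
    cons = Consequence("T", "frameshift", protein_pos=96, ref_residue="V",
                       alt_residue="G", novel_peptide_length=49,
                       ter_position_mutant=145)
    fates = dict(domain_overlap(cons, [("kinase", 100, 300),
                                       ("px", 10, 50),
                                       ("linker", 90, 120)]))
    assert fates == {"kinase": "lost", "px": "intact", "linker": "truncated"}


def test_domains_intact_under_missense():
    cons = Consequence("T", "missense", protein_pos=96, ref_residue="V", alt_residue="G")
    assert domain_overlap(cons, [("kinase", 100, 300)]) == [("kinase", "intact")]


def test_bad_domain_interval_rejected():
    cons = Consequence("T", "frameshift", protein_pos=5, ref_residue="V", alt_residue="G")
    with pytest.raises(ValueError):
        domain_overlap(cons, [("d", 10, 5)])
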