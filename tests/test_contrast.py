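"""Private-variant contrast: absence semantics, region intersection, reports."""

import numpy as np
import pytest

from pelage.contrast import CandidateSet, ContrastParams, contrast, contrast_report, intersect_region
from pelage.io import Variant


def _var(pos, case_gt, panel_gts, ref="A", alts=("T",), chrom="chr1"):
    genos = {"CASE": case_gt}
    genos.update({f"P{i}": g for i, g in enumerate(panel_gts)})
    return Variant(chrom, pos, ref, alts, genos)


PANEL = [f"P{i}" for i in range(5)]


def test_private_homozygote_retained():
    cs = contrast([_var(10, (1, 1), [(0, 0)] * 5)], "CASE", PANEL)
    assert len(cs) == 1
    assert cs.stage_counts == {"input": 1, "case_called": 1,
                               "case_homozygous_alt": 1, "private": 1}


def test_panel_heterozygote_removes_in_allele_mode_but_not_genotype_mode():
    v = _var(10, (1, 1), [(0, 1), (0, 0), (0, 0), (0, 0), (0, 0)])
    assert len(contrast([v], "CASE", PANEL, ContrastParams(mode="allele_absent"))) == 0
    assert len(contrast([v], "CASE", PANEL, ContrastParams(mode="genotype_absent"))) == 1


def test_case_heterozygote_removed_by_homozygosity_requirement():
    v = _var(10, (0, 1), [(0, 0)] * 5)
    assert len(contrast([v], "CASE", PANEL)) == 0


def test_case_reference_homozygote_never_candidate():
    v = _var(10, (0, 0), [(1, 1)] * 5)
    params = ContrastParams(require_case_homozygous_alt=False)
    assert len(contrast([v], "CASE", PANEL, params)) == 0


def test_panel_missing_policies():
    v = _var(10, (1, 1), [None, (0, 0), (0, 0), (0, 0), (0, 0)])
    assert len(contrast([v], "CASE", PANEL)) == 1, "missing counts as absent by default"
    strict = ContrastParams(treat_panel_missing_as="unknown-excludes")
    assert len(contrast([v], "CASE", PANEL, strict)) == 0


def test_multiallelic_tested_per_case_allele():
    # case homozygous for ALT2; panel carries only ALT1
    v = _var(10, (2, 2), [(0, 1), (1, 1), (0, 0), (0, 0), (0, 0)], alts=("T", "G"))
    assert len(contrast([v], "CASE", PANEL)) == 1
    # but a panel carrier of ALT2 kills it
    v2 = _var(10, (2, 2), [(0, 2), (0, 0), (0, 0), (0, 0), (0, 0)], alts=("T", "G"))
    assert len(contrast([v2], "CASE", PANEL)) == 0


def test_case_sample_missing_from_records_fails():
    v = Variant("chr1", 10, "A", ("T",), {"P0": (0, 0)})
    with pytest.raises(KeyError, match="CASE"):
        contrast([v], "CASE", ["P0"])


def test_case_in_panel_rejected():
    with pytest.raises(ValueError, match="panel"):
        contrast([], "CASE", ["CASE"])


@pytest.mark.parametrize("trial", range(20))
def test_genotype_mode_retains_superset_of_allele_mode(trial):
    rng = np.random.default_rng(300 + trial)
    variants = []
    for pos in range(10, 200, 7):
        gts = []
        for _ in range(6):
            r = rng.random()
            gts.append(None if r < 0.1 else
                       (int(rng.integers(2)), int(rng.integers(2))))
        variants.append(_var(pos, gts[0] or (1, 1), gts[1:]))
    allele = contrast(variants, "CASE", PANEL, ContrastParams(mode="allele_absent"))
    geno = contrast(variants, "CASE", PANEL, ContrastParams(mode="genotype_absent"))
    allele_pos = {c.variant.pos for c in allele.candidates}
    geno_pos = {c.variant.pos for c in geno.candidates}
    assert allele_pos <= geno_pos


def test_contrast_is_idempotent():
    rng = np.random.default_rng(9)
    variants = [_var(p, (1, 1), [(0, 0) if rng.random() < 0.7 else (0, 1)
                                 for _ in range(5)])
                for p in range(10, 100, 3)]
    once = contrast(variants, "CASE", PANEL)
    twice = contrast([c.variant for c in once.candidates], "CASE", PANEL)
    assert {c.variant.pos for c in twice.candidates} == \
        {c.variant.pos for c in once.candidates}


# ---------------------------------------------------------------------------
# Region intersection
# ---------------------------------------------------------------------------

def _candidate_set(positions, chrom="chr29"):
    variants = [_var(p, (1, 1), [(0, 0)] * 5, chrom=chrom) for p in positions]
    return contrast(variants, "CASE", PANEL)


def test_intersect_keeps_study_deletion_coordinate():
    cs = _candidate_set([16366702, 14000000, 21000000])
    out = intersect_region(cs, ("chr29", 15973319, 20794824))
    assert [c.variant.pos for c in out.candidates] == [16366702]
    assert out.stage_counts["in_region"] == 1


def test_intersect_boundaries_inclusive():
    cs = _candidate_set([15973319, 20794824, 20794825])
    out = intersect_region(cs, ("chr29", 15973319, 20794824))
    assert [c.variant.pos for c in out.candidates] == [15973319, 20794824]


def test_intersect_empty_set():
    out = intersect_region(CandidateSet([], {"input": 0}), ("chr1", 1, 10))
    assert len(out) == 0 and out.stage_counts["in_region"] == 0


def test_stage_counts_non_increasing():
    cs = _candidate_set([1, 2, 3, 4])
    out = intersect_region(cs, ("chr29", 2, 3))
    chain = [out.stage_counts[k] for k in
             ("input", "case_called", "case_homozygous_alt", "private", "in_region")]
    assert all(a >= b for a, b in zip(chain, chain[1:]))


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def test_report_counts_partition_protein_altering():
    from pelage.consequence import Consequence

    cs = _candidate_set([10, 20, 30])
    kinds = ["missense", "frameshift", "synonymous"]
    for cand, kind in zip(cs.candidates, kinds):
        cand.consequence = Consequence("T", kind, protein_pos=5,
                                       ref_residue="A", alt_residue="V")
    frame = contrast_report(cs)
    assert frame.attrs["total"] == 3
    assert frame.attrs["protein_altering_total"] == 2
    counts = dict(zip(frame["consequence"], frame["count"]))
    assert counts["missense"] == 1 and counts["frameshift"] == 1


def test_report_all_zero_when_empty():
    frame = contrast_report(CandidateSet([], {}))
    assert (frame["count"] == 0).all()
    assert frame.attrs["total"] == 0


# ---------------------------------------------------------------------------
# Against simulation truth
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_planted_variant_survives_and_shared_variants_die(seed):
    from pelage.sim.genedrop import SimulationConfig
    from pelage.sim.reference import default_transcript_specs, make_reference_bundle
    from pelage.sim.variants import PLANTED, SHARED, plant_private_frameshift

    config = SimulationConfig(seed=seed)
    specs = default_transcript_specs(config)
    bundle = make_reference_bundle(config, specs, seed=seed)
    fx = plant_private_frameshift(bundle, panel_size=12, seed=seed,
                                  site_spec=specs[0])
    out = contrast(fx.variants, fx.case_id, fx.panel_ids)
    kept = {(c.variant.chrom, c.variant.pos) for c in out.candidates}
    planted_key = (fx.planted.chrom, fx.planted.pos)
    assert planted_key in kept
    shared = {k for k, cat in fx.truth.items() if cat == SHARED}
    assert not (kept & shared), "allele-shared variants must never survive"


def test_full_sharing_and_no_plant_leaves_zero_candidates():
    from pelage.sim.genedrop import SimulationConfig
    from pelage.sim.reference import default_transcript_specs, make_reference_bundle
    from pelage.sim.variants import plant_private_frameshift

    config = SimulationConfig(seed=3)
    specs = default_transcript_specs(config)
    bundle = make_reference_bundle(config, specs, seed=3)
    fx = plant_private_frameshift(bundle, panel_size=6, seed=3, share_rate=1.0,
                                  include_planted=False, include_decoys=False,
                                  panel_missing_rate=0.0)
    out = contrast(fx.variants, fx.case_id, fx.panel_ids)
    assert len(out) == 0
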