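"""Homozygosity profile and run extraction, checked against brute force."""

import numpy as np
import pytest

from conftest import make_matrix
from oracles import brute_force_runs, random_matrix
from pelage.io import MISSING
from pelage.roh import ScanParams, case_heterozygosity, find_runs, he_profile_plot, rank_report


def _runs_as_tuples(runs):
    return {(r.chrom, r.first_index, r.last_index, r.snp_count) for r in runs}


# ---------------------------------------------------------------------------
# He profile
# ---------------------------------------------------------------------------

def test_he_all_homozygous_is_zero():
    m = make_matrix([("chr29", 10)], [[0, 2, 0, 2, 2, 0, 0, 2, 2, 0, 0]])
    prof = case_heterozygosity(m, m.samples)
    assert prof.he[0] == 0.0


def test_he_one_het_of_ten_called():
    calls = [[1] + [0] * 9 + [MISSING]]
    m = make_matrix([("chr1", 10)], calls)
    prof = case_heterozygosity(m, m.samples)
    assert prof.he[0] == pytest.approx(0.1)
    assert prof.n_called[0] == 10 and prof.n_missing[0] == 1


def test_he_all_heterozygous_is_one():
    m = make_matrix([("chr1", 10)], [[1, 1, 1, 1]])
    prof = case_heterozygosity(m, m.samples)
    assert prof.he[0] == 1.0


def test_empty_case_set_fails():
    m = make_matrix([("chr1", 10)], [[0, 0]])
    with pytest.raises(ValueError, match="empty"):
        case_heterozygosity(m, [])


def test_he_restricted_to_case_subset():
    m = make_matrix([("chr1", 10)], [[1, 1, 0, 0]], samples=list("ABCD"))
    prof = case_heterozygosity(m, ["C", "D"])
    assert prof.he[0] == 0.0
    assert prof.n_cases == 2


# ---------------------------------------------------------------------------
# Run extraction
# ---------------------------------------------------------------------------

def test_he_vector_splits_into_two_runs():
    """He 0,0,0,x,0,0 with min 2 -> runs of 3 and 2 markers."""
    rows = [[0] * 4, [0] * 4, [2] * 4, [1, 0, 0, 0], [2] * 4, [0] * 4]
    m = make_matrix([("chr1", p) for p in (10, 20, 30, 40, 50, 60)], rows)
    prof = case_heterozygosity(m, m.samples)
    runs = find_runs(prof, m, ScanParams(min_run_snps=2))
    assert [(r.snp_count, r.start_pos, r.end_pos) for r in runs] == [(3, 10, 30), (2, 50, 60)]


def test_mapped_region_span_uses_inclusive_convention():
    """A run bounded by the study's chr29 coordinates spans > 4.8 Mb."""
    pos = [15973319, 16500000, 18000000, 20794824]
    m = make_matrix([("chr29", p) for p in pos], [[0] * 6] * 4)
    prof = case_heterozygosity(m, m.samples)
    runs = find_runs(prof, m, ScanParams(min_run_snps=2))
    assert runs[0].span_bp == 4_821_506
    assert runs[0].span_bp > 4_800_000


def test_runs_never_cross_chromosomes():
    rows = [[0] * 3] * 4
    m = make_matrix([("chr1", 10), ("chr1", 20), ("chr2", 10), ("chr2", 20)], rows)
    prof = case_heterozygosity(m, m.samples)
    runs = find_runs(prof, m, ScanParams(min_run_snps=1))
    assert {(r.chrom, r.snp_count) for r in runs} == {("chr1", 2), ("chr2", 2)}


def test_missing_heavy_marker_is_transparent_not_breaking():
    """A marker failing QC drops out of the scan instead of splitting the run."""
    rows = [[0, 0], [MISSING, 0], [2, 2], [0, 2]]
    m = make_matrix([("chr1", p) for p in (10, 20, 30, 40)], rows)
    prof = case_heterozygosity(m, m.samples)
    runs = find_runs(prof, m, ScanParams(min_run_snps=3))
    assert len(runs) == 1
    assert (runs[0].first_index, runs[0].last_index, runs[0].snp_count) == (0, 3, 3)
    # relaxing min_called makes the marker eligible again and it qualifies
    runs2 = find_runs(prof, m, ScanParams(min_run_snps=4, min_called=1))
    assert runs2[0].snp_count == 4


def test_shared_allele_mode_is_stricter():
    rows = [[0, 0], [0, 2], [0, 0]]  # middle marker: homozygous but discordant
    m = make_matrix([("chr1", p) for p in (10, 20, 30)], rows)
    prof = case_heterozygosity(m, m.samples)
    loose = find_runs(prof, m, ScanParams(min_run_snps=1))
    strict = find_runs(prof, m, ScanParams(min_run_snps=1, require_shared_allele=True),
                       case_ids=m.samples)
    assert max(r.snp_count for r in loose) == 3
    assert max(r.snp_count for r in strict) == 1


def test_tie_break_prefers_longer_span():
    rows = [[0]] * 2 + [[1]] + [[0]] * 2
    m = make_matrix([("chr1", p) for p in (10, 5000, 6000, 7000, 7010)], rows)
    prof = case_heterozygosity(m, m.samples)
    runs = find_runs(prof, m, ScanParams(min_run_snps=2))
    assert runs[0].span_bp == 4991 and runs[1].span_bp == 11


def test_rank_report_single_run(small_study):
    ped, config, matrix, truth = small_study
    cases = [i.id for i in ped.affecteds()][:11]
    prof = case_heterozygosity(matrix, cases)
    runs = find_runs(prof, matrix, ScanParams(), case_ids=cases)
    report = rank_report(runs, top_k=5)
    assert report.iloc[0]["rank"] == 1
    assert report.iloc[0]["snp_count"] == runs[0].snp_count


def test_sample_order_permutation_invariance():
    rng = np.random.default_rng(5)
    matrix, samples = random_matrix(rng)
    prof = case_heterozygosity(matrix, samples)
    runs = _runs_as_tuples(find_runs(prof, matrix, ScanParams(min_run_snps=2)))
    shuffled = list(samples)
    rng.shuffle(shuffled)
    prof2 = case_heterozygosity(matrix, shuffled)
    runs2 = _runs_as_tuples(find_runs(prof2, matrix, ScanParams(min_run_snps=2)))
    assert runs == runs2


@pytest.mark.parametrize("trial", range(40))
def test_find_runs_matches_brute_force(trial):
    rng = np.random.default_rng(1000 + trial)
    matrix, samples = random_matrix(rng, n_chrom=int(rng.integers(1, 4)),
                                    max_markers=80)
    min_run = int(rng.integers(1, 5))
    min_called = None if rng.random() < 0.5 else int(rng.integers(1, len(samples)))
    shared = bool(rng.random() < 0.3)
    params = ScanParams(min_run_snps=min_run, min_called=min_called,
                        require_shared_allele=shared)
    prof = case_heterozygosity(matrix, samples)
    got = _runs_as_tuples(find_runs(prof, matrix, params, case_ids=samples))
    want = brute_force_runs(matrix, samples, min_run_snps=min_run,
                            min_called=min_called, require_shared_allele=shared)
    assert got == want


@pytest.mark.parametrize("trial", range(15))
def test_adding_a_het_call_never_lengthens_runs(trial):
    """Monotonicity: a new heterozygote can only split or shrink runs."""
    rng = np.random.default_rng(2000 + trial)
    matrix, samples = random_matrix(rng, n_chrom=1, max_markers=60,
                                    het_rate=0.1, missing_rate=0.0)
    params = ScanParams(min_run_snps=1)
    prof = case_heterozygosity(matrix, samples)
    before = find_runs(prof, matrix, params)
    if not before:
        return
    target = before[0]
    i = int(rng.integers(target.first_index, target.last_index + 1))
    calls = matrix.calls.copy()
    calls[i, int(rng.integers(len(samples)))] = 1
    import pelage.io as pio
    matrix2 = pio.GenotypeMatrix(samples=matrix.samples, markers=matrix.markers,
                                 calls=calls)
    after = find_runs(case_heterozygosity(matrix2, samples), matrix2, params)
    max_before = max(r.snp_count for r in before)
    assert all(r.snp_count <= max_before for r in after)
    intervals_before = [(r.chrom, r.first_index, r.last_index) for r in before]
    for r in after:
        assert any(c == r.chrom and f <= r.first_index and r.last_index <= l
                   for c, f, l in intervals_before), "new runs must nest in old runs"


def test_he_profile_plot_files(tmp_path, small_study):
    ped, config, matrix, truth = small_study
    cases = [i.id for i in ped.affecteds()][:11]
    prof = case_heterozygosity(matrix, cases)
    others = [i.id for i in ped.individuals if i.phenotype != "affected"][:20]
    panel_prof = case_heterozygosity(matrix, others)
    out = tmp_path / "he.png"
    he_profile_plot(prof, out, highlight=("chr1", 5_000_000, 7_000_000),
                    panel_profile=panel_prof)
    assert out.stat().st_size > 0
    out2 = tmp_path / "he_plain.png"
    he_profile_plot(prof, out2)
    assert out2.stat().st_size > 0
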