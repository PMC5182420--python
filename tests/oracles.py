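"""Independent oracles used by the test suite.

These deliberately re-derive results by a different route than the
library: the run-finder oracle enumerates every marker interval
quadratically, and the consequence oracle edits the *genome*, shifts the
transcript coordinates and re-extracts the CDS, instead of editing the
spliced CDS directly.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from pelage.consequence import cds_to_genomic, left_align
from pelage.io import MISSING, GenotypeMatrix, ReferenceBundle, TranscriptModel, Variant, extract_cds


# ---------------------------------------------------------------------------
# Quadratic run enumeration
# ---------------------------------------------------------------------------

def brute_force_runs(matrix: GenotypeMatrix, case_ids, min_run_snps=1,
                     min_called=None, require_shared_allele=False):
    """All maximal qualifying intervals, by exhaustive (a, b) enumeration.

    Returns a set of (chrom, first_marker_index, last_marker_index, count).
    """
    calls = matrix.calls[:, matrix.sample_index(list(case_ids))]
    n_cases = calls.shape[1]
    mc = n_cases if min_called is None else min_called
    elig, qual = [], []
    for i in range(matrix.n_markers):
        called = [int(c) for c in calls[i] if c != MISSING]
        e = len(called) >= max(mc, 1)
        q = e and all(c != 1 for c in called)
        if q and require_shared_allele:
            q = len(set(called)) <= 1
        elig.append(e)
        qual.append(q)
    chroms = matrix.markers["chrom"].tolist()
    out = set()
    for chrom in dict.fromkeys(chroms):
        idx = [i for i in range(len(chroms)) if chroms[i] == chrom and elig[i]]
        q = [qual[i] for i in idx]
        n = len(idx)
        pref = [0]
        for x in q:
            pref.append(pref[-1] + int(x))
        for a in range(n):
            for b in range(a, n):
                full = pref[b + 1] - pref[a] == b - a + 1
                if not full:
                    continue
                maximal = (a == 0 or not q[a - 1]) and (b == n - 1 or not q[b + 1])
                if maximal and b - a + 1 >= min_run_snps:
                    out.add((chrom, idx[a], idx[b], b - a + 1))
    return out


def random_matrix(rng, n_chrom=2, max_markers=100, n_samples=8,
                  het_rate=0.25, missing_rate=0.1) -> tuple[GenotypeMatrix, list[str]]:
    """A random dosage matrix with plenty of qualifying stretches."""
    import pandas as pd

    samples = [f"S{i}" for i in range(n_samples)]
    rows, calls = [], []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        m = int(rng.integers(5, max_markers + 1))
        pos = np.sort(rng.choice(10_000_000, size=m, replace=False)) + 1
        for k, p in enumerate(pos):
            rows.append((f"{chrom}_{k}", chrom, int(p)))
            r = rng.random(n_samples)
            row = np.where(r < het_rate, 1,
                           np.where(rng.random(n_samples) < 0.5, 0, 2)).astype(np.int8)
            row[rng.random(n_samples) < missing_rate] = MISSING
            calls.append(row)
    markers = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    return GenotypeMatrix(samples=samples, markers=markers,
                          calls=np.array(calls, dtype=np.int8)), samples


# ---------------------------------------------------------------------------
# Genome-rebuild consequence oracle
# ---------------------------------------------------------------------------

def _shifted_model(model: TranscriptModel, pos: int, ref: str, alt: str) -> TranscriptModel | None:
    """Transcript model in mutant-genome coordinates.

    Only valid when the edit is strictly inside one exon (no boundary
    coordinates fall inside the edited/deleted interval); returns None
    otherwise.
    """
    net = len(alt) - len(ref)

    def remap(g: int) -> int | None:
        if net == 0 or g <= pos:
            return g
        if len(ref) > len(alt):  # deletion: ref[1:] removed
            if g >= pos + len(ref):
                return g + net
            if g > pos + len(alt) - 1:
                return None  # inside the deleted bases
            return g
        return g + net  # insertion after pos

    coords = [model.cds_start, model.cds_end]
    new_exons = []
    for s, e in model.exons:
        s2, e2 = remap(s), remap(e)
        if s2 is None or e2 is None:
            return None
        new_exons.append((s2, e2))
    c1, c2 = remap(coords[0]), remap(coords[1])
    if c1 is None or c2 is None:
        return None
    return TranscriptModel(
        transcript_id=model.transcript_id, chrom=model.chrom, strand=model.strand,
        exons=new_exons, cds_start=c1, cds_end=c2, complete=False,
    )


def _classify(wt_prot: str, mut_prot: str, net: int) -> dict:
    """Oracle-local classification from the two translations."""
    n = min(len(wt_prot), len(mut_prot))
    i = next((k for k in range(n) if wt_prot[k] != mut_prot[k]), None)
    if i is None and len(wt_prot) != len(mut_prot):
        i = n
    if net % 3 != 0:
        if i is None:
            return {"kind": "synonymous", "protein_pos": None,
                    "novel_peptide_length": None, "ter_position_mutant": None}
        stop = mut_prot.find("*", i)
        return {
            "kind": "frameshift",
            "protein_pos": i + 1,
            "novel_peptide_length": (stop - i) if stop >= 0 else len(mut_prot) - i,
            "ter_position_mutant": (stop + 1) if stop >= 0 else None,
        }
    if net != 0:
        kind = "inframe_deletion" if net < 0 else "inframe_insertion"
        pos = (i + 1) if i is not None else len(wt_prot)
        return {"kind": kind, "protein_pos": pos,
                "novel_peptide_length": None, "ter_position_mutant": None}
    if i is None:
        return {"kind": "synonymous", "protein_pos": None,
                "novel_peptide_length": None, "ter_position_mutant": None}
    if i == 0 and wt_prot[0] == "M":
        kind = "start_lost"
    elif mut_prot[i] == "*":
        kind = "stop_gained"
    elif wt_prot[i] == "*":
        kind = "stop_lost"
    else:
        kind = "missense"
    return {"kind": kind, "protein_pos": i + 1,
            "novel_peptide_length": None, "ter_position_mutant": None}


def rebuild_and_translate(variant: Variant, model: TranscriptModel,
                          reference: ReferenceBundle) -> dict | None:
    """Full mutant-genome oracle; None when the edit touches a boundary."""
    seq = reference.sequences[model.chrom]
    pos, ref, alt = left_align(variant.pos, variant.ref, variant.alts[0], seq)
    mut_seq = seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]
    model2 = _shifted_model(model, pos, ref, alt)
    if model2 is None:
        return None
    wt_cds = extract_cds(model, reference)
    mut_bundle = ReferenceBundle(sequences={model.chrom: mut_seq}, transcripts=[])
    mut_cds = extract_cds(model2, mut_bundle)
    wt_prot = str(Seq(wt_cds).translate())
    usable = len(mut_cds) - len(mut_cds) % 3
    mut_prot = str(Seq(mut_cds[:usable]).translate())
    return _classify(wt_prot, mut_prot, len(mut_cds) - len(wt_cds))


def random_coding_variant(model: TranscriptModel, reference: ReferenceBundle, rng):
    """A random SNV/deletion/insertion whose (normalised) footprint lies
    strictly inside one CDS exon; returns None for an unusable draw."""
    seq = reference.sequences[model.chrom]
    kind = ("snv", "del", "ins")[int(rng.integers(3))]
    cds_len = model.cds_len
    p = int(rng.integers(4, cds_len - 12))
    g = cds_to_genomic(model, p)
    block = next(((s, e) for s, e in model.cds_blocks() if s <= g <= e), None)
    if block is None:
        return None
    s, e = block
    if kind == "snv":
        ref = seq[g - 1]
        alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
        var = Variant(chrom=model.chrom, pos=g, ref=ref, alts=(alt,))
    elif kind == "del":
        k = int(rng.integers(1, 7))
        if g + k > e:
            return None
        var = Variant(chrom=model.chrom, pos=g, ref=seq[g - 1:g + k], alts=(seq[g - 1],))
    else:
        k = int(rng.integers(1, 7))
        ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=k))
        var = Variant(chrom=model.chrom, pos=g, ref=seq[g - 1], alts=(seq[g - 1] + ins,))
    # reject draws whose normalised footprint escapes the exon interior
    npos, nref, nalt = left_align(var.pos, var.ref, var.alts[0], seq)
    lo = npos if len(nref) == len(nalt) else npos + 1
    hi = npos + len(nref) - 1
    if len(nref) == 1 and len(nalt) > 1:
        hi = npos + 1  # insertion needs both flanks inside the block
    if not (s < lo and hi < e):
        return None
    return var
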