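"""Private-variant contrast: case genotypes absent from a control panel.

Reproduces the genotype-contrast step of a recessive-trait study: keep
records at which the sequenced case is homozygous for an alternate allele
and that allele (or genotype, depending on mode) is absent from every
panel genome, then intersect the survivors with the mapped region.

Two absence semantics are exposed because the phrase "genotypes not found
in N other samples" is ambiguous:

* ``allele_absent`` (default, stricter): no panel sample carries the
  case's homozygous alternate allele at all — a panel heterozygote kills
  the record.
* ``genotype_absent``: no panel sample has the same homozygous genotype —
  panel heterozygotes are tolerated (the behaviour of genotype-level
  contrast tools).

Panel missing genotypes count as "not carrying" by default
(``treat_panel_missing_as='absent'``); ``'unknown-excludes'`` drops any
record with panel missingness instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

from pelage.io import Variant

PROTEIN_ALTERING = frozenset({
    "missense", "inframe_insertion", "inframe_deletion", "frameshift",
    "stop_gained", "stop_lost", "start_lost",
})


@dataclass
class ContrastParams:
    mode: str = "allele_absent"  # or "genotype_absent"
    require_case_homozygous_alt: bool = True
    treat_panel_missing_as: str = "absent"  # or "unknown-excludes"
    region: tuple[str, int, int] | None = None

    def __post_init__(self):
        if self.mode not in ("allele_absent", "genotype_absent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.treat_panel_missing_as not in ("absent", "unknown-excludes"):
            raise ValueError(f"unknown missing policy {self.treat_panel_missing_as!r}")
        if self.region is not None and self.region[1] > self.region[2]:
            raise ValueError("region start must be <= end")


@dataclass
class Candidate:
    variant: Variant
    case_alt_index: int            # 1-based ALT index the case is homozygous for
    consequence: object | None = None  # filled by the annotation stage
    flags: list[str] = field(default_factory=list)


@dataclass
class CandidateSet:
    """Retained records plus per-stage counts (non-increasing along the chain)."""

    candidates: list[Candidate]
    stage_counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.candidates)


def contrast(variants: Iterable[Variant], case_id: str, panel_ids,
             params: ContrastParams | None = None) -> CandidateSet:
    """Filter a variant stream for case-homozygous genotypes absent from the panel."""
    params = params or ContrastParams()
    panel_ids = list(panel_ids)
    if case_id in panel_ids:
        raise ValueError("case sample must not appear in the panel")
    n_total = n_case_called = n_hom = 0
    kept: list[Candidate] = []
    for v in variants:
        n_total += 1
        if case_id not in v.genotypes:
            raise KeyError(f"case sample {case_id!r} missing from variant records")
        gt = v.genotypes[case_id]
        if gt is None:
            continue
        n_case_called += 1
        alt = v.hom_alt_index(case_id)
        if params.require_case_homozygous_alt:
            if alt is None:
                continue
        elif alt is None:
            # without the homozygosity requirement any non-reference genotype
            # is eligible; test each carried alternate allele
            alt = next((a for a in sorted(v.alleles_of(case_id)) if a > 0), None)
            if alt is None:
                continue
        n_hom += 1
        if _absent_from_panel(v, alt, panel_ids, params):
            kept.append(Candidate(variant=v, case_alt_index=alt))
    counts = {
        "input": n_total,
        "case_called": n_case_called,
        "case_homozygous_alt": n_hom,
        "private": len(kept),
    }
    return CandidateSet(candidates=kept, stage_counts=counts)


def _absent_from_panel(v: Variant, alt: int, panel_ids, params: ContrastParams) -> bool:
    for s in panel_ids:
        if s not in v.genotypes:
            continue
        gt = v.genotypes[s]
        if gt is None:
            if params.treat_panel_missing_as == "unknown-excludes":
                return False
            continue
        if params.mode == "allele_absent":
            if alt in gt:
                return False
        else:  # genotype_absent
            if gt == (alt, alt):
                return False
    return True


def intersect_region(candidates: CandidateSet, region: tuple[str, int, int]) -> CandidateSet:
    """Retain candidates anchored inside [start, end] (1-based inclusive).

    Indels qualify when their left-anchored start position lies in the
    region, matching how a region filter sees a VCF record.
    """
    chrom, start, end = region
    if start > end:
        raise ValueError("region start must be <= end")
    kept = [c for c in candidates.candidates
            if c.variant.chrom == chrom and start <= c.variant.pos <= end]
    counts = dict(candidates.stage_counts)
    counts["in_region"] = len(kept)
    return CandidateSet(candidates=kept, stage_counts=counts)


def contrast_report(candidates: CandidateSet) -> pd.DataFrame:
    """Counts by consequence class for annotated candidates, plus totals.

    Mirrors the staged summary of a discovery report ("N private, of which
    M protein-altering: ...").  Rows are deterministic: every known class
    appears, in a fixed order, with zero counts where empty.
    """
    classes = [
        "missense", "inframe_insertion", "inframe_deletion", "frameshift",
        "stop_gained", "stop_lost", "start_lost", "synonymous", "splice_region",
        "noncoding", "intronic", "intergenic",
    ]
    counts = {k: 0 for k in classes}
    for c in candidates.candidates:
        kind = getattr(c.consequence, "kind", None) or "intergenic"
        counts[kind] = counts.get(kind, 0) + 1
    rows = [(k, counts[k], k in PROTEIN_ALTERING) for k in classes]
    frame = pd.DataFrame(rows, columns=["consequence", "count", "protein_altering"])
    total_pa = int(frame.loc[frame["protein_altering"], "count"].sum())
    frame.attrs["total"] = len(candidates.candidates)
    frame.attrs["protein_altering_total"] = total_pa
    return frame
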