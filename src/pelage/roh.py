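"""Case-group homozygosity profile and runs of homozygosity.

The mapping statistic is *observed* heterozygosity within the case group:
for each marker, He = (heterozygous calls) / (called cases).  This is the
per-genotype criterion used when mapping a fully penetrant recessive trait
in a set of affecteds — a qualifying marker has He = 0, i.e. every called
case is homozygous — and is deliberately not the allele-frequency
("expected") heterozygosity that shares the same symbol.

Markers at which fewer than ``min_called`` cases are called are treated as
failing chip QC: they are removed from the scan entirely (they neither
qualify nor interrupt a run), mirroring how an "informative SNP" set is
defined before a run analysis.  Runs never cross a chromosome boundary and
are ranked by SNP count, ties broken by bp span then genomic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pelage.io import MISSING, GenotypeMatrix


@dataclass
class ScanParams:
    min_run_snps: int = 20
    min_called: int | None = None  # None: every case must be called (strict)
    require_shared_allele: bool = False

    def __post_init__(self):
        if self.min_run_snps < 1:
            raise ValueError("min_run_snps must be >= 1")


@dataclass
class HeProfile:
    """Per-marker observed heterozygosity within the case group."""

    markers: pd.DataFrame  # id, chrom, pos — aligned to the source matrix
    he: np.ndarray         # fraction of called cases that are heterozygous; NaN if none called
    n_called: np.ndarray
    n_missing: np.ndarray
    n_cases: int

    def __post_init__(self):
        n = len(self.markers)
        for arr in (self.he, self.n_called, self.n_missing):
            if len(arr) != n:
                raise ValueError("profile arrays must align to the marker table")
        if np.any(self.n_called + self.n_missing != self.n_cases):
            raise ValueError("called + missing must equal the case count")
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.he) | ((self.he >= 0) & (self.he <= 1))
        if not ok.all():
            raise ValueError("He must lie in [0, 1]")

    def frame(self) -> pd.DataFrame:
        out = self.markers.copy()
        out["he"] = self.he
        out["n_called"] = self.n_called
        out["n_missing"] = self.n_missing
        return out


@dataclass(frozen=True)
class HomozygosityRun:
    """A maximal stretch of contiguous qualifying markers on one chromosome."""

    chrom: str
    first_index: int   # row index into the source matrix marker table
    last_index: int
    start_pos: int
    end_pos: int
    snp_count: int

    @property
    def span_bp(self) -> int:
        """Inclusive bp length, end - start + 1."""
        return self.end_pos - self.start_pos + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_pos <= pos <= self.end_pos


def case_heterozygosity(matrix: GenotypeMatrix, case_ids) -> HeProfile:
    """Observed heterozygosity of the case group at every marker."""
    case_ids = list(case_ids)
    if not case_ids:
        raise ValueError("case set is empty")
    cols = matrix.sample_index(case_ids)
    calls = matrix.calls[:, cols]
    called = calls != MISSING
    n_called = called.sum(axis=1)
    n_het = (calls == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        he = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    return HeProfile(
        markers=matrix.markers,
        he=he,
        n_called=n_called.astype(int),
        n_missing=(len(case_ids) - n_called).astype(int),
        n_cases=len(case_ids),
    )


def _qualifying_and_eligible(profile: HeProfile, matrix: GenotypeMatrix,
                             case_ids, params: ScanParams):
    """Boolean marker masks: eligible (passes QC) and qualifying (He = 0 etc.)."""
    if len(profile.markers) != matrix.n_markers:
        raise ValueError("profile is not aligned to the matrix markers")
    min_called = params.min_called if params.min_called is not None else profile.n_cases
    eligible = profile.n_called >= max(min_called, 1)
    qual = eligible & (profile.he == 0)
    if params.require_shared_allele:
        cols = matrix.sample_index(list(case_ids))
        calls = matrix.calls[:, cols]
        called = calls != MISSING
        masked = np.where(called, calls, np.int8(-9))
        any0 = (masked == 0).any(axis=1)
        any2 = (masked == 2).any(axis=1)
        qual &= ~(any0 & any2)
    return eligible, qual


def find_runs(profile: HeProfile, matrix: GenotypeMatrix, params: ScanParams,
              case_ids=None) -> list[HomozygosityRun]:
    """Maximal runs of consecutive eligible He = 0 markers, ranked.

    ``case_ids`` is only needed when ``params.require_shared_allele`` is
    set (the shared-allele check needs the raw calls).  The returned list
    is sorted by snp_count descending, then span_bp descending, then
    genomic order; runs on a chromosome are disjoint and never cross a
    chromosome boundary.
    """
    if params.require_shared_allele and case_ids is None:
        raise ValueError("case_ids required when require_shared_allele is set")
    eligible, qual = _qualifying_and_eligible(profile, matrix, case_ids or [], params)
    chroms = profile.markers["chrom"].to_numpy()
    poss = profile.markers["pos"].to_numpy()
    runs: list[HomozygosityRun] = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero((chroms == chrom) & eligible)
        if idx.size == 0:
            continue
        q = qual[idx]
        # boundaries of maximal True stretches over the eligible subsequence
        padded = np.concatenate(([False], q, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        for s, e in zip(starts, ends):
            count = e - s + 1
            if count < params.min_run_snps:
                continue
            fi, li = int(idx[s]), int(idx[e])
            runs.append(HomozygosityRun(
                chrom=str(chrom), first_index=fi, last_index=li,
                start_pos=int(poss[fi]), end_pos=int(poss[li]), snp_count=count,
            ))
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
    runs.sort(key=lambda r: (-r.snp_count, -r.span_bp, chrom_order[r.chrom], r.start_pos))
    return runs


def rank_report(runs: list[HomozygosityRun], top_k: int = 10) -> pd.DataFrame:
    """Deterministic ranked table of the top runs.

    span_bp uses the inclusive convention (last - first + 1), recorded in
    the column name.
    """
    rows = [
        (rank, r.chrom, r.start_pos, r.end_pos, r.snp_count, r.span_bp)
        for rank, r in enumerate(runs[:top_k], start=1)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "chrom", "start", "end", "snp_count", "span_bp_inclusive"]
    )


def he_profile_plot(profile: HeProfile, path, highlight: tuple[str, int, int] | None = None,
                    panel_profile: HeProfile | None = None) -> None:
    """Per-chromosome He-vs-position plot, optionally with a highlighted
    candidate region (dotted boundaries) and a second overlaid series
    (e.g. a breed panel) for contrast."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(profile.markers["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.2 * len(chroms)),
                             squeeze=False, sharey=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        sel = profile.markers["chrom"] == chrom
        pos = profile.markers.loc[sel, "pos"] / 1e6
        ax.plot(pos, profile.he[sel.to_numpy()], ".", ms=2, color="tab:blue", label="cases")
        if panel_profile is not None:
            psel = panel_profile.markers["chrom"] == chrom
            ax.plot(panel_profile.markers.loc[psel, "pos"] / 1e6,
                    panel_profile.he[psel.to_numpy()], ".", ms=2, color="tab:red",
                    alpha=0.5, label="panel")
        if highlight is not None and highlight[0] == chrom:
            for x in (highlight[1], highlight[2]):
                ax.axvline(x / 1e6, ls=":", color="k")
        ax.set_ylabel("He")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    if panel_profile is not None:
        axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
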