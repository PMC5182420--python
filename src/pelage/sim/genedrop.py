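"""Gene drop: founder haplotypes transmitted down a pedigree with recombination.

Founders receive labelled haplotypes; each meiosis recombines under the
Haldane model (crossover count Poisson with mean equal to the map length
in Morgans, positions uniform, no interference) with a uniform
marker-to-genetic map at a configurable cM/Mb.  Chip-like biallelic
genotypes are read off the transmitted haplotype mosaics, and the full
ancestry of every homologue is returned as a truth record.

Transmission at the causal locus is constrained to match the causal-allele
dosage recorded on the pedigree (the pedigree builder samples Mendelian
transmissions; the gene drop realises them as haplotype ancestry).  The
constraint is imposed by flipping the gamete's starting homologue when
needed, which leaves the crossover process unbiased because the starting
homologue is an independent fair coin.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pelage._util import openf, rng_from
from pelage.io import MISSING, GenotypeMatrix
from pelage.sim.pedigree import Individual, Pedigree

Segment = tuple[int, int, str]  # start, end (1-based inclusive), founder-haplotype label


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic chip experiment.

    Defaults are a scaled-down chip study: three 12 Mb autosomes with 480
    markers each (about one marker per 25 kb, the density of a
    high-density canine array relative to segment sizes), 1 cM/Mb, fully
    distinct founder haplotypes and 0.2% missing calls (post-QC chip-like).
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12_000_000, "chr2": 12_000_000, "chr3": 12_000_000}
    )
    n_markers: int = 480  # per chromosome
    marker_spacing: str = "uniform"  # or "even"
    causal_chrom: str = "chr1"
    causal_pos: int = 6_000_000
    founder_haplotype_diversity: int | None = None  # None: every founder homologue distinct
    cm_per_mb: float = 1.0
    missing_rate: float = 0.002
    allele_freq_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self):
        if self.causal_chrom not in self.chromosomes:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} not declared")
        if not (1 <= self.causal_pos <= self.chromosomes[self.causal_chrom]):
            raise ValueError("causal position outside its chromosome")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing rate must lie in [0, 1]")
        if self.marker_spacing not in ("uniform", "even"):
            raise ValueError("marker_spacing must be 'uniform' or 'even'")
        if self.n_markers < 1:
            raise ValueError("need at least one marker per chromosome")

    def morgans(self, chrom: str) -> float:
        return self.chromosomes[chrom] / 1e6 * self.cm_per_mb / 100.0


@dataclass
class TruthRecord:
    """Ground truth of one gene drop.

    ``segments[(individual, homologue)][chrom]`` is the list of inherited
    segments tiling that chromosome copy; homologue 0 is paternal.
    """

    segments: dict[tuple[str, int], dict[str, list[Segment]]]
    causal_dosage: dict[str, int]
    causal_chrom: str
    causal_pos: int
    planted_variant: object | None = None

    def segments_frame(self) -> pd.DataFrame:
        rows = []
        for (iid, hom), per_chrom in self.segments.items():
            for chrom, segs in per_chrom.items():
                for s, e, lab in segs:
                    rows.append((iid, hom, chrom, s, e, lab))
        return pd.DataFrame(rows, columns=["individual", "homologue", "chrom",
                                           "start", "end", "founder_haplotype"])

    def haplotype_at(self, iid: str, hom: int, chrom: str, pos: int) -> str:
        for s, e, lab in self.segments[(iid, hom)][chrom]:
            if s <= pos <= e:
                return lab
        raise KeyError(f"position {chrom}:{pos} not covered for {iid}/{hom}")

    def is_autozygous_at(self, iid: str, chrom: str, pos: int) -> bool:
        return (self.haplotype_at(iid, 0, chrom, pos)
                == self.haplotype_at(iid, 1, chrom, pos))

    def write(self, path) -> None:
        """Write the segment table as the documented tab-delimited sidecar."""
        frame = self.segments_frame()
        with openf(path, "wt") as fh:
            fh.write(f"#causal\t{self.causal_chrom}\t{self.causal_pos}\n")
            for iid, d in self.causal_dosage.items():
                fh.write(f"#dosage\t{iid}\t{d}\n")
            frame.to_csv(fh, sep="\t", index=False)


def _marker_positions(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for chrom, length in config.chromosomes.items():
        m = config.n_markers
        if config.marker_spacing == "even":
            pos = np.linspace(1, length, m, dtype=np.int64)
        else:
            pos = np.sort(rng.choice(length, size=m, replace=False)) + 1
        out[chrom] = np.unique(pos)
    return out


def _meiosis(parent: Individual,
             parent_segments: dict[int, dict[str, list[Segment]]],
             transmit_causal: bool,
             config: SimulationConfig,
             rng: np.random.Generator) -> dict[str, list[Segment]]:
    """One gamete: recombine the parent's two homologues per Haldane."""
    gamete: dict[str, list[Segment]] = {}
    for chrom, length in config.chromosomes.items():
        n_x = rng.poisson(config.morgans(chrom))
        xs = sorted(set(int(x) for x in rng.integers(1, length, size=n_x)))
        h0 = int(rng.integers(2))
        if chrom == config.causal_chrom and parent.causal_dosage == 1:
            carrier_h = parent.causal_homologues()[0]
            want = carrier_h if transmit_causal else 1 - carrier_h
            h_at = (h0 + bisect.bisect_left(xs, config.causal_pos)) % 2
            if h_at != want:
                h0 = 1 - h0
        elif parent.causal_dosage == 0 and transmit_causal:
            raise ValueError(f"{parent.id}: cannot transmit an allele it does not carry")
        # assemble gamete segments by walking the crossover intervals
        bounds = [1] + [x + 1 for x in xs] + [length + 1]
        segs: list[Segment] = []
        h = h0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if lo < hi:
                for s, e, lab in parent_segments[h][chrom]:
                    os, oe = max(s, lo), min(e, hi - 1)
                    if os <= oe:
                        if segs and segs[-1][2] == lab and segs[-1][1] == os - 1:
                            segs[-1] = (segs[-1][0], oe, lab)
                        else:
                            segs.append((os, oe, lab))
            h = 1 - h
        gamete[chrom] = segs
    return gamete


def gene_drop(pedigree: Pedigree, config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Drop founder haplotypes down the pedigree and read off chip genotypes.

    Returns the dosage matrix over all pedigree members (columns in
    pedigree order) and the truth record.  Deterministic given
    (pedigree, config): the same seed yields identical output.
    """
    rng = rng_from(config.seed, 101)
    positions = _marker_positions(config, rng)

    founders = pedigree.founders()
    labels = [f"{f.id}.{tag}" for f in founders for tag in ("a", "b")]
    n_pool = config.founder_haplotype_diversity or len(labels)
    if n_pool < 1:
        raise ValueError("founder haplotype diversity must be >= 1")
    if n_pool >= len(labels):
        label_row = {lab: i for i, lab in enumerate(labels)}
        n_pool = len(labels)
    else:
        label_row = {lab: int(rng.integers(n_pool)) for lab in labels}

    lo, hi = config.allele_freq_range
    pool = {}
    for chrom, pos in positions.items():
        freqs = rng.uniform(lo, hi, size=len(pos))
        pool[chrom] = (rng.random((n_pool, len(pos))) < freqs).astype(np.int8)

    segments: dict[tuple[str, int], dict[str, list[Segment]]] = {}
    for ind in pedigree.individuals:
        if ind.founder:
            for hom, tag in enumerate(("a", "b")):
                segments[(ind.id, hom)] = {
                    chrom: [(1, length, f"{ind.id}.{tag}")]
                    for chrom, length in config.chromosomes.items()
                }
        else:
            sire, dam = pedigree[ind.sire], pedigree[ind.dam]
            segments[(ind.id, 0)] = _meiosis(
                sire, {0: segments[(sire.id, 0)], 1: segments[(sire.id, 1)]},
                ind.causal_from_sire, config, rng)
            segments[(ind.id, 1)] = _meiosis(
                dam, {0: segments[(dam.id, 0)], 1: segments[(dam.id, 1)]},
                ind.causal_from_dam, config, rng)

    # read genotypes off the haplotype mosaics
    chroms = list(config.chromosomes)
    n_total = sum(len(positions[c]) for c in chroms)
    samples = [ind.id for ind in pedigree.individuals]
    calls = np.zeros((n_total, len(samples)), dtype=np.int8)
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += len(positions[c])

    for j, ind in enumerate(pedigree.individuals):
        for hom in (0, 1):
            for chrom in chroms:
                pos = positions[chrom]
                base = offsets[chrom]
                for s, e, lab in segments[(ind.id, hom)][chrom]:
                    i0 = np.searchsorted(pos, s, side="left")
                    i1 = np.searchsorted(pos, e, side="right")
                    if i1 > i0:
                        calls[base + i0:base + i1, j] += pool[chrom][label_row[lab], i0:i1]

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    marker_rows = []
    for chrom in chroms:
        for p in positions[chrom]:
            marker_rows.append((f"{chrom}_{int(p):08d}", chrom, int(p)))
    markers = pd.DataFrame(marker_rows, columns=["id", "chrom", "pos"])

    matrix = GenotypeMatrix(samples=samples, markers=markers, calls=calls)
    truth = TruthRecord(
        segments=segments,
        causal_dosage={ind.id: ind.causal_dosage for ind in pedigree.individuals},
        causal_chrom=config.causal_chrom,
        causal_pos=config.causal_pos,
    )
    return matrix, truth
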