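"""Breed-history-like pedigrees with a single founder carrier.

The builder emulates how a recessive trait is captured in a young breed:
one founder carries the causal allele, her descendants are line-bred
(backcrossed to relatives) with occasional outcrosses to unrelated coated
founders, and a few popular sires are reused across many matings.  Mate
selection favours affected and carrier animals, an idealisation of a
breeder selecting for the trait (real breeders infer carrier status from
test matings; here the simulator reads it from the truth).

The causal locus is transmitted during construction, so carrier status,
phenotype (fully penetrant recessive) and, later, the gene drop are all
mutually consistent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from pelage._util import FormatError, openf, rng_from

PHENOTYPES = ("affected", "unaffected", "unknown")


@dataclass
class Individual:
    id: str
    sire: str | None
    dam: str | None
    sex: str  # 'M' or 'F'
    phenotype: str
    founder: bool = False
    # causal-locus truth; homologue 0 is paternal (founders: the ".a" homologue)
    causal_dosage: int = 0
    causal_from_sire: bool = False
    causal_from_dam: bool = False

    def causal_homologues(self) -> tuple[int, ...]:
        """Homologue indices carrying the causal allele (0 paternal, 1 maternal)."""
        if self.founder:
            return (0,) if self.causal_dosage == 1 else ((0, 1) if self.causal_dosage == 2 else ())
        out = []
        if self.causal_from_sire:
            out.append(0)
        if self.causal_from_dam:
            out.append(1)
        return tuple(out)


@dataclass
class Pedigree:
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"{ind.id}: parent {parent!r} not listed before child"
                    )
            if ind.founder and (ind.sire is not None or ind.dam is not None):
                raise ValueError(f"{ind.id}: founders must have no parents")
            if not ind.founder and (ind.sire is None or ind.dam is None):
                raise ValueError(f"{ind.id}: non-founder must have both parents")
            if ind.sex not in ("M", "F"):
                raise ValueError(f"{ind.id}: sex must be M or F")
            if ind.phenotype not in PHENOTYPES:
                raise ValueError(f"{ind.id}: bad phenotype {ind.phenotype!r}")
            seen[ind.id] = ind
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.founder]

    def affecteds(self) -> list[Individual]:
        return [i for i in self.individuals if i.phenotype == "affected"]

    def matings(self) -> dict[tuple[str, str], list[Individual]]:
        """Children grouped by (sire, dam) pair."""
        out: dict[tuple[str, str], list[Individual]] = {}
        for ind in self.individuals:
            if not ind.founder:
                out.setdefault((ind.sire, ind.dam), []).append(ind)
        return out


def write_pedigree(pedigree: Pedigree, path) -> None:
    """Write the 5-column dialect: id, sire, dam, sex, phenotype (0 = no parent)."""
    with openf(path, "wt") as fh:
        fh.write("id\tsire\tdam\tsex\tphenotype\n")
        for ind in pedigree.individuals:
            fh.write(
                f"{ind.id}\t{ind.sire or 0}\t{ind.dam or 0}\t{ind.sex}\t{ind.phenotype}\n"
            )


def read_pedigree(path) -> Pedigree:
    """Read the 5-column dialect written by :func:`write_pedigree`.

    Causal-locus truth fields are not part of the file format; the
    individuals come back with dosage 0 and phenotype as recorded.
    """
    path = Path(path)
    inds = []
    with openf(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "sire", "dam", "sex", "phenotype"]:
            raise FormatError(path, 1, "bad pedigree header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise FormatError(path, lineno, f"expected 5 fields, got {len(parts)}")
            iid, sire, dam, sex, pheno = parts
            sire_id = None if sire == "0" else sire
            dam_id = None if dam == "0" else dam
            inds.append(Individual(
                id=iid, sire=sire_id, dam=dam_id, sex=sex, phenotype=pheno,
                founder=sire_id is None and dam_id is None,
            ))
    try:
        return Pedigree(inds)
    except ValueError as exc:
        raise FormatError(path, None, str(exc)) from None


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

def _transmit(parent: Individual, rng: np.random.Generator) -> bool:
    if parent.causal_dosage == 2:
        return True
    if parent.causal_dosage == 1:
        return bool(rng.random() < 0.5)
    return False


def _make_child(iid: str, sire: Individual, dam: Individual,
                rng: np.random.Generator) -> Individual:
    from_sire = _transmit(sire, rng)
    from_dam = _transmit(dam, rng)
    dosage = int(from_sire) + int(from_dam)
    return Individual(
        id=iid,
        sire=sire.id,
        dam=dam.id,
        sex="M" if rng.random() < 0.5 else "F",
        phenotype="affected" if dosage == 2 else "unaffected",
        causal_dosage=dosage,
        causal_from_sire=from_sire,
        causal_from_dam=from_dam,
    )


def _mate_score(ind: Individual) -> tuple:
    # affected first, then carriers; stable tiebreak on id
    return (ind.phenotype != "affected", -ind.causal_dosage, ind.id)


def _attempt(n_generations, backcross_rate, popular_sire_rate, litter_size,
             matings_per_generation, rng) -> Pedigree | None:
    inds: list[Individual] = []
    counter = itertools.count(1)

    def add(ind):
        inds.append(ind)
        return ind

    founder_dam = add(Individual("FND1", None, None, "F", "unaffected",
                                 founder=True, causal_dosage=1))
    founder_sire = add(Individual("FND2", None, None, "M", "unaffected", founder=True))

    generations: dict[int, list[Individual]] = {0: [founder_dam, founder_sire]}
    n_out = itertools.count(1)

    # generation 1: the founder carrier's litter
    litter = max(3, int(rng.poisson(litter_size)))
    generations[1] = [
        add(_make_child(f"G1_{next(counter)}", founder_sire, founder_dam, rng))
        for _ in range(litter)
    ]

    for g in range(2, n_generations + 1):
        prev = generations[g - 1] + generations.get(g - 2, [])
        dams = sorted([i for i in prev if i.sex == "F" and not i.founder], key=_mate_score)
        if not dams:
            return None  # all-male generation; caller retries with a fresh stream
        males = sorted(
            [i for i in inds if i.sex == "M" and not i.founder], key=_mate_score
        )
        popular = males[0] if males else None
        generations[g] = []
        for m in range(matings_per_generation):
            dam = dams[m % len(dams)]
            if popular is not None and rng.random() < popular_sire_rate:
                sire = popular
            elif males and rng.random() < backcross_rate:
                sire = males[int(rng.integers(len(males)))]
            else:
                sire = add(Individual(f"OUT{next(n_out)}", None, None, "M",
                                      "unaffected", founder=True))
            litter = max(1, int(rng.poisson(litter_size)))
            for _ in range(litter):
                generations[g].append(
                    add(_make_child(f"G{g}_{next(counter)}", sire, dam, rng))
                )
    return Pedigree(inds)


def build_aht_like_pedigree(
    n_generations: int = 6,
    backcross_rate: float = 0.75,
    popular_sire_rate: float = 0.25,
    litter_size: int = 5,
    matings_per_generation: int = 4,
    min_affected: int = 1,
    seed: int = 0,
    max_attempts: int = 60,
) -> Pedigree:
    """Build a pedigree with one founder carrier and ≥ ``min_affected`` affecteds.

    ``backcross_rate`` is the probability that a mating uses a male from
    within the pedigree rather than a fresh outcross founder;
    ``popular_sire_rate`` is the probability that the generation's
    preferred stud is reused.  Construction is rejection-sampled: a draw
    producing fewer than ``min_affected`` affected individuals is retried
    with a fresh substream of the same seed (bounded attempts).
    """
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2")
    if litter_size < 1 or matings_per_generation < 1:
        raise ValueError("impossible constraints: litters and matings must be >= 1")
    if not (0 <= backcross_rate <= 1 and 0 <= popular_sire_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    for attempt in range(max_attempts):
        rng = rng_from(seed, 11, attempt)
        ped = _attempt(n_generations, backcross_rate, popular_sire_rate,
                       litter_size, matings_per_generation, rng)
        if ped is not None and len(ped.affecteds()) >= min_affected:
            return ped
    raise RuntimeError(
        f"no pedigree with >= {min_affected} affected individuals in "
        f"{max_attempts} attempts; constraints may be unsatisfiable"
    )
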