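"""Deterministic genotype-to-pelage rules for the five major coat genes.

The five loci and their alleles:

* **RSPO2** — ``ancestral`` / ``insertion``; one insertion allele is enough
  for furnishings (dominant).
* **FGF5** — ``short`` / ``long``; long coat requires two ``long`` alleles
  (recessive at the two-allele level, the breed-typical configuration).
* **KRT71** — ``straight`` / ``curl``; one ``curl`` allele curls the coat,
  but only a long coat can curl — on a short coat the fur is simply not
  long enough, so curl is masked.
* **FOXI3** — ``wildtype`` / ``dup`` (the 7 bp duplication).  Semi-dominant
  ectodermal-dysplasia hairlessness: heterozygotes are hairless,
  homozygous duplication is embryonic lethal.
* **SGK3** — ``wildtype`` / ``del`` (the 4 bp frameshift deletion).  Fully
  recessive hairlessness: two copies lose the coat, and the homozygote is
  viable.

Rules are applied in priority order (lethality, then the two hairless
modes, then coat texture), so every genotype maps to exactly one
phenotype.  Dominance per locus is configurable for the two texture loci
where breed surveys, not crosses, fix the default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

ALLELES = {
    "rspo2": ("ancestral", "insertion"),
    "fgf5": ("short", "long"),
    "krt71": ("straight", "curl"),
    "foxi3": ("wildtype", "dup"),
    "sgk3": ("wildtype", "del"),
}

MASKED = "masked"
UNKNOWN = "unknown"

# number of derived alleles required for the derived phenotype at the
# texture loci (1 = dominant, 2 = recessive)
DEFAULT_DOMINANCE = {"rspo2": 1, "fgf5": 2, "krt71": 1}


@dataclass(frozen=True)
class CoatGenotype:
    """Diploid allele pair per locus; a locus may be None (unknown)."""

    rspo2: tuple[str, str] | None = ("ancestral", "ancestral")
    fgf5: tuple[str, str] | None = ("short", "short")
    krt71: tuple[str, str] | None = ("straight", "straight")
    foxi3: tuple[str, str] | None = ("wildtype", "wildtype")
    sgk3: tuple[str, str] | None = ("wildtype", "wildtype")

    def __post_init__(self):
        for locus, valid in ALLELES.items():
            pair = getattr(self, locus)
            if pair is None:
                continue
            if len(pair) != 2 or any(a not in valid for a in pair):
                raise ValueError(f"{locus}: bad allele pair {pair!r} (valid: {valid})")

    def dose(self, locus: str) -> int | None:
        """Count of the derived allele at ``locus`` (None when unknown)."""
        pair = getattr(self, locus)
        if pair is None:
            return None
        derived = ALLELES[locus][1]
        return sum(a == derived for a in pair)


@dataclass(frozen=True)
class CoatPhenotype:
    viability: str          # viable | embryonic_lethal
    hairless: str           # none | CED_hairless | recessive_hairless
    furnishings: object     # bool | MASKED | UNKNOWN
    length: str             # short | long | MASKED | UNKNOWN
    curl: str               # straight | curly | MASKED | UNKNOWN

    def __post_init__(self):
        if self.viability == "embryonic_lethal":
            if not (self.hairless == MASKED and self.furnishings == MASKED
                    and self.length == MASKED and self.curl == MASKED):
                raise ValueError("embryonic lethality masks all other fields")
        if self.hairless in ("CED_hairless", "recessive_hairless"):
            if self.length != MASKED or self.curl != MASKED:
                raise ValueError("hairlessness masks length and curl")


def predict_coat(genotype: CoatGenotype,
                 dominance: dict[str, int] | None = None) -> CoatPhenotype:
    """Apply the rule table to one genotype.

    Priority: FOXI3 dup/dup lethal → FOXI3 het CED hairless → SGK3 del/del
    recessive hairless → texture (furnishings dominant, long recessive,
    curl dominant but masked on short coats).  Invariant to allele order
    within each locus.
    """
    dom = dict(DEFAULT_DOMINANCE)
    if dominance:
        dom.update(dominance)

    foxi3 = genotype.dose("foxi3")
    sgk3 = genotype.dose("sgk3")

    if foxi3 == 2:
        return CoatPhenotype("embryonic_lethal", MASKED, MASKED, MASKED, MASKED)

    def furnishings():
        d = genotype.dose("rspo2")
        if d is None:
            return UNKNOWN
        return d >= dom["rspo2"]

    if foxi3 == 1:
        return CoatPhenotype("viable", "CED_hairless", furnishings(), MASKED, MASKED)
    if foxi3 is None:
        return CoatPhenotype("viable", UNKNOWN, furnishings(), UNKNOWN, UNKNOWN)
    if sgk3 == 2:
        return CoatPhenotype("viable", "recessive_hairless", furnishings(), MASKED, MASKED)
    if sgk3 is None:
        return CoatPhenotype("viable", UNKNOWN, furnishings(), UNKNOWN, UNKNOWN)

    fgf5 = genotype.dose("fgf5")
    if fgf5 is None:
        length = UNKNOWN
    else:
        length = "long" if fgf5 >= dom["fgf5"] else "short"
    if length == "short":
        curl = MASKED  # fur too short to curl, whatever KRT71 says
    elif length == UNKNOWN:
        curl = UNKNOWN
    else:
        k = genotype.dose("krt71")
        curl = UNKNOWN if k is None else ("curly" if k >= dom["krt71"] else "straight")
    return CoatPhenotype("viable", "none", furnishings(), length, curl)


def enumerate_phenotype_table(dominance: dict[str, int] | None = None) -> pd.DataFrame:
    """All 3^5 unordered diploid genotype combinations with their phenotypes."""
    per_locus = {}
    for locus, (anc, der) in ALLELES.items():
        per_locus[locus] = [(anc, anc), (anc, der), (der, der)]
    rows = []
    for combo in itertools.product(*(per_locus[l] for l in ALLELES)):
        genotype = CoatGenotype(**dict(zip(ALLELES, combo)))
        ph = predict_coat(genotype, dominance)
        rows.append({
            **{locus: "/".join(pair) for locus, pair in zip(ALLELES, combo)},
            "viability": ph.viability,
            "hairless": ph.hairless,
            "furnishings": ph.furnishings,
            "length": ph.length,
            "curl": ph.curl,
        })
    return pd.DataFrame(rows)


def read_coat_calls(path) -> list[CoatGenotype]:
    """Read a tab-delimited locus-call table: sample then one ``a/b`` pair
    per locus column (``.`` for unknown)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in frame.iterrows():
        kwargs = {}
        for locus in ALLELES:
            val = row.get(locus)
            if val is None or pd.isna(val) or val == ".":
                kwargs[locus] = None
            else:
                pair = tuple(val.split("/"))
                kwargs[locus] = pair
        out.append(CoatGenotype(**kwargs))
    return out
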