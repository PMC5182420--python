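"""Shared fixtures: tiny genotype matrices, toy references, one demo study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pelage.io import MISSING, GenotypeMatrix
from pelage.sim.genedrop import SimulationConfig
from pelage.sim.reference import TranscriptSpec, make_reference_bundle

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(chrom_pos: list[tuple[str, int]], calls: list[list[int]],
                samples: list[str] | None = None) -> GenotypeMatrix:
    """Hand-build a matrix from (chrom, pos) rows and dosage rows."""
    samples = samples or [f"S{i}" for i in range(len(calls[0]))]
    markers = pd.DataFrame(
        [(f"m{i}", c, p) for i, (c, p) in enumerate(chrom_pos)],
        columns=["id", "chrom", "pos"],
    )
    return GenotypeMatrix(samples=samples, markers=markers,
                          calls=np.array(calls, dtype=np.int8))


def toy_bundle(seed: int = 0, strand: str = "+", cds_codons: int = 40,
               n_exons: int = 3):
    """A small single-transcript reference for annotation tests."""
    config = SimulationConfig(
        chromosomes={"toy": 6000}, n_markers=4, causal_chrom="toy",
        causal_pos=3000, seed=seed,
    )
    spec = TranscriptSpec(
        transcript_id="TOY", chrom="toy", strand=strand, tx_start=200,
        n_exons=n_exons, cds_codons=cds_codons, utr5=30, utr3=30, intron_len=80,
    )
    bundle = make_reference_bundle(config, [spec], seed=seed)
    return bundle, bundle.transcripts[0]


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """One full synthetic study plus its pipeline report (built once)."""
    from pelage.pipeline import make_demo, run_pipeline

    out = tmp_path_factory.mktemp("demo")
    config = make_demo(seed=1, out_dir=out)
    report = run_pipeline(config)
    return config, report


@pytest.fixture(scope="session")
def small_study():
    """Pedigree + gene drop at default study conditions (built once)."""
    from pelage.sim.genedrop import gene_drop
    from pelage.sim.pedigree import build_aht_like_pedigree

    ped = build_aht_like_pedigree(seed=7, min_affected=8)
    config = SimulationConfig(seed=7)
    matrix, truth = gene_drop(ped, config)
    return ped, config, matrix, truth
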