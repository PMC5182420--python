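"""End-to-end orchestration: scan → contrast → intersect → annotate → report.

The pipeline mirrors the discovery chain of a recessive-trait study: the
case group's homozygosity scan picks the rank-1 run, the sequenced case is
contrasted against the control panel, survivors are intersected with the
rank-1 region, and protein-altering candidates are reported with HGVS
protein strings.  Everything is driven by one YAML config; the report body
is deterministic given the inputs (no timestamps inside it) and carries
input checksums so any number in it can be re-derived.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

import pelage
from pelage.consequence import annotate, hgvs_protein
from pelage.contrast import PROTEIN_ALTERING, CandidateSet, ContrastParams, contrast, contrast_report, intersect_region
from pelage.io import ReferenceBundle, read_genotype_matrix, read_variants
from pelage.roh import ScanParams, case_heterozygosity, find_runs, rank_report

log = logging.getLogger("pelage.pipeline")


@dataclass
class PipelineConfig:
    genotype_matrix: str
    case_ids_file: str
    vcf: str
    case_sample: str
    panel_samples_file: str
    reference_fasta: str
    transcripts_gff3: str
    out_dir: str
    domains_file: str | None = None
    scan: ScanParams = field(default_factory=ScanParams)
    contrast: ContrastParams = field(default_factory=ContrastParams)
    top_k_regions: int = 1
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scan = ScanParams(**raw.pop("scan", {}))
        cp = raw.pop("contrast", {})
        if "region" in cp and cp["region"] is not None:
            cp["region"] = tuple(cp["region"])
        params = ContrastParams(**cp)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(scan=scan, contrast=params, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class CandidateReport:
    status: str                      # "ok" or "no mappable region"
    region: tuple[str, int, int] | None
    ranked_runs: list[dict]
    stage_counts: dict[str, int]
    final_candidates: list[dict]
    consequence_counts: dict[str, int]
    provenance: dict

    def body(self) -> dict:
        return {
            "status": self.status,
            "region": list(self.region) if self.region else None,
            "ranked_runs": self.ranked_runs,
            "stage_counts": self.stage_counts,
            "consequence_counts": self.consequence_counts,
            "final_candidates": self.final_candidates,
            "provenance": self.provenance,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.body(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_pipeline(config: PipelineConfig) -> CandidateReport:
    """Execute the full chain and return (and write) the candidate report."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    provenance = {
        "pelage_version": pelage.__version__,
        "config_hash": config.config_hash(),
        "input_checksums": {
            "genotype_matrix": _sha256(config.genotype_matrix),
            "vcf": _sha256(config.vcf),
            "reference_fasta": _sha256(config.reference_fasta),
            "transcripts_gff3": _sha256(config.transcripts_gff3),
        },
    }

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("scan")
        matrix = read_genotype_matrix(config.genotype_matrix)
        case_ids = _read_id_list(config.case_ids_file)
        profile = case_heterozygosity(matrix, case_ids)
        runs = find_runs(profile, matrix, config.scan, case_ids=case_ids)
        ranked = rank_report(runs, top_k=max(config.top_k_regions, 10))
        ranked.to_csv(out_dir / "runs.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"scan stage failed: {exc}") from exc

    ranked_rows = ranked.to_dict(orient="records")
    if not runs:
        report = CandidateReport(
            status="no mappable region", region=None, ranked_runs=[],
            stage_counts={}, final_candidates=[], consequence_counts={},
            provenance=provenance,
        )
        report.write(out_dir / "report.json")
        return report
    top = runs[0]
    region = (top.chrom, top.start_pos, top.end_pos)

    try:
        stage("contrast")
        panel_ids = _read_id_list(config.panel_samples_file)
        variants = read_variants(config.vcf, [config.case_sample] + panel_ids)
        candidates = contrast(variants, config.case_sample, panel_ids, config.contrast)
        stage("intersect")
        regional = intersect_region(candidates, region)
    except Exception as exc:
        raise RuntimeError(f"contrast stage failed: {exc}") from exc

    try:
        stage("annotate")
        reference = ReferenceBundle.read(config.reference_fasta, config.transcripts_gff3)
        domains = _read_domains(config.domains_file) if config.domains_file else []
        final = []
        for cand in regional.candidates:
            cons = _annotate_best(cand, reference)
            cand.consequence = cons
            if cons is not None and cons.kind in PROTEIN_ALTERING:
                entry = {
                    "chrom": cand.variant.chrom,
                    "pos": cand.variant.pos,
                    "ref": cand.variant.ref,
                    "alt": cand.variant.alts[cand.case_alt_index - 1],
                    "transcript": cons.transcript_id,
                    "consequence": cons.kind,
                    "hgvs_p": cons.hgvs_p,
                }
                if domains and cons.protein_pos is not None:
                    from pelage.consequence import domain_overlap
                    entry["domains"] = [
                        {"name": n, "fate": fate}
                        for n, fate in domain_overlap(cons, domains)
                    ]
                final.append(entry)
    except Exception as exc:
        raise RuntimeError(f"annotate stage failed: {exc}") from exc

    table = contrast_report(regional)
    counts = dict(regional.stage_counts)
    counts["protein_altering_in_region"] = len(final)
    report = CandidateReport(
        status="ok", region=region, ranked_runs=ranked_rows,
        stage_counts=counts, final_candidates=final,
        consequence_counts={row["consequence"]: int(row["count"])
                            for _, row in table.iterrows() if row["count"]},
        provenance=provenance,
    )
    report.write(out_dir / "report.json")
    return report


def _annotate_best(cand, reference: ReferenceBundle):
    """Annotate against every overlapping transcript; report the most severe."""
    severity = {k: i for i, k in enumerate([
        "frameshift", "stop_gained", "start_lost", "stop_lost", "missense",
        "inframe_deletion", "inframe_insertion", "splice_region", "synonymous",
        "noncoding", "intronic", "intergenic",
    ])}
    v = cand.variant
    best = None
    for model in reference.transcripts:
        if model.chrom != v.chrom:
            continue
        cons = annotate(v, model, reference, alt_index=cand.case_alt_index - 1)
        if best is None or severity[cons.kind] < severity[best.kind]:
            best = cons
    return best


def _read_domains(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            name, start, end = line.rstrip("\n").split("\t")
            out.append((name, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# Demo fixture
# ---------------------------------------------------------------------------

def make_demo(seed: int = 1, out_dir=None, panel_size: int = 20,
              min_affected: int = 8) -> PipelineConfig:
    """Generate a complete small synthetic study runnable by run_pipeline.

    Writes pedigree, chip matrix, case list, reference FASTA + GFF3,
    multi-sample VCF, domain table, truth sidecars and a pipeline config
    into ``out_dir`` (a ``demo`` directory beside the cwd by default) and
    returns the loaded config.  Deterministic for a fixed seed.
    """
    import tempfile

    from pelage.sim.genedrop import SimulationConfig, gene_drop
    from pelage.sim.pedigree import build_aht_like_pedigree, write_pedigree
    from pelage.sim.reference import default_transcript_specs, make_reference_bundle
    from pelage.sim.variants import plant_private_frameshift

    out = Path(out_dir) if out_dir is not None else Path(tempfile.mkdtemp(prefix="pelage_demo_"))
    out.mkdir(parents=True, exist_ok=True)

    ped = build_aht_like_pedigree(seed=seed, min_affected=min_affected)
    sim_config = SimulationConfig(seed=seed)
    matrix, truth = gene_drop(ped, sim_config)
    specs = default_transcript_specs(sim_config)
    bundle = make_reference_bundle(sim_config, specs, seed=seed)
    affecteds = [i.id for i in ped.affecteds()][:11]
    case_sample = affecteds[-1]
    fixture = plant_private_frameshift(
        bundle, panel_size=panel_size, seed=seed, case_id=case_sample,
        site_spec=specs[0],
    )
    truth.planted_variant = fixture.planted

    write_pedigree(ped, out / "pedigree.tsv")
    matrix.write(out / "genotypes.tsv")
    (out / "cases.txt").write_text("".join(s + "\n" for s in affecteds))
    (out / "panel.txt").write_text("".join(s + "\n" for s in fixture.panel_ids))
    bundle.write(out / "reference.fa", out / "transcripts.gff3")
    fixture.write(out / "variants.vcf",
                  contigs={c: len(s) for c, s in bundle.sequences.items()})
    truth.write(out / "truth_segments.tsv")
    with open(out / "truth_variants.tsv", "w") as fh:
        fh.write("chrom\tpos\tcategory\n")
        for (chrom, pos), category in sorted(fixture.truth.items()):
            fh.write(f"{chrom}\t{pos}\t{category}\n")
    with open(out / "domains.tsv", "w") as fh:
        fh.write("name\tstart\tend\n")
        fh.write("STKc_kinase\t100\t360\n")
        fh.write("PX_domain\t10\t90\n")

    config = PipelineConfig(
        genotype_matrix=str(out / "genotypes.tsv"),
        case_ids_file=str(out / "cases.txt"),
        vcf=str(out / "variants.vcf"),
        case_sample=case_sample,
        panel_samples_file=str(out / "panel.txt"),
        reference_fasta=str(out / "reference.fa"),
        transcripts_gff3=str(out / "transcripts.gff3"),
        domains_file=str(out / "domains.tsv"),
        out_dir=str(out / "results"),
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
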