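"""End-to-end candidate funnel.

Orchestrates the staged filter sequence over a cohort:

1. all normalized variants;
2. variants in annotated 3'UTRs;
3. variants whose footprint overlaps a canonical seed-pairing site of a
   hypothesized miRNA-transcript pair (gains optionally included);
4. pairs whose miRNA is detected in the population of interest;
5. candidates, after optional rarity/status filters.

Stage membership is tracked as sets, so monotonicity is a structural
property of the run, not just of the printed counts.  The final manual
step of the emulated study — picking phenotype-consistent candidates by
expert review — is deliberately not automated; phenotype columns pass
through for human review.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import expression_filter as ef
from . import reference_model as rm
from . import seed_sites as ss
from . import variant_ingest as vi
from .disruption import call_disruption, sense_edit, variant_overlaps_site

logger = logging.getLogger(__name__)

STAGES = (
    "total_variants",
    "utr3_variants",
    "seed_site_overlap",
    "expressed_mirna",
    "candidates",
)


@dataclass
class PipelineConfig:
    """Paths and parameters of one run.  All paths must exist at run time."""

    genome: Path
    transcripts: Path
    vcf: Path
    mirnas: Path
    pairs: Path
    expression: Path
    groups: Optional[Path] = None
    transcripts_dialect: str = "transcript_table"
    rare_threshold: float = 0.01
    fc_cutoff: float = 1.0
    normalization: str = "left_align"
    expressed_population: Optional[str] = None
    include_gains: bool = False
    require_rare: bool = False
    upstream_bp: int = 2000
    strip_versions: bool = True
    join_failure_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome", "transcripts", "vcf", "mirnas", "pairs", "expression", "groups"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        if not 0 <= self.rare_threshold <= 1:
            raise ValueError("rare_threshold outside [0, 1]")
        if self.fc_cutoff <= 0:
            raise ValueError("fc_cutoff must be positive")
        if self.normalization not in {"left_align", "paper_1bp"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not 0 <= self.join_failure_tolerance <= 1:
            raise ValueError("join_failure_tolerance outside [0, 1]")

    def validate_paths(self) -> None:
        for name in ("genome", "transcripts", "vcf", "mirnas", "pairs", "expression", "groups"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        for key in ("genome", "transcripts", "vcf", "mirnas", "pairs", "expression", "groups"):
            if raw.get(key):
                raw[key] = str((base / raw[key]).resolve())
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, Path):
                out[key] = str(value)
        return out


@dataclass
class FunnelReport:
    """Ordered stage records; counts are nonincreasing along the funnel."""

    stages: list[dict] = field(default_factory=list)

    def add(self, label: str, variant_keys: set, pair_items: Optional[set] = None) -> None:
        self.stages.append(
            {
                "stage": label,
                "n_variants": len(variant_keys),
                "n_pairs": len(pair_items) if pair_items is not None else None,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stages, columns=["stage", "n_variants", "n_pairs"])
        df["n_pairs"] = df["n_pairs"].astype("Int64")
        return df

    def counts(self) -> dict[str, int]:
        return {s["stage"]: s["n_variants"] for s in self.stages}


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    funnel: FunnelReport
    calls: pd.DataFrame
    annotated: pd.DataFrame
    stage_sets: dict[str, set]
    manifest: dict


def _read_groups(path: Optional[Path]) -> Optional[dict[str, str]]:
    if path is None:
        return None
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"sample", "sample_id"}:
                continue
            groups[fields[0]] = fields[1]
    return groups


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full funnel; deterministic given the inputs."""
    t0 = time.monotonic()
    config.validate_paths()

    genome = rm.load_genome(config.genome)
    transcripts = rm.load_transcripts(
        config.transcripts, dialect=config.transcripts_dialect,
        strip_versions=config.strip_versions,
    )
    mirnas = ss.load_mirnas(config.mirnas)
    pairs = ss.load_pairs(config.pairs)
    expression = ef.read_expression_table(config.expression)
    groups = _read_groups(config.groups)
    population = config.expressed_population or expression.populations[0]
    logger.info("loaded %d transcripts, %d miRNAs, %d pairs", len(transcripts), len(mirnas), len(pairs))

    raw_variants, counts = vi.read_vcf(config.vcf, sample_groups=groups, genome=genome)

    # normalize; deduplicate identical normalized events
    normalized: list[vi.Variant] = []
    seen: set = set()
    for v in raw_variants:
        for nv in vi.normalize_variant(v, genome, mode=config.normalization):
            if nv.key not in seen:
                seen.add(nv.key)
                normalized.append(nv)

    annotated = [
        vi.annotate_region(
            v, transcripts, upstream_bp=config.upstream_bp, rare_threshold=config.rare_threshold
        )
        for v in normalized
    ]
    by_key = {av.variant.key: av for av in annotated}

    funnel = FunnelReport()
    stage_sets: dict[str, set] = {}
    stage_sets["total_variants"] = set(by_key)
    funnel.add("total_variants", stage_sets["total_variants"])

    utr3 = {k for k, av in by_key.items() if av.region == "UTR3"}
    stage_sets["utr3_variants"] = utr3
    funnel.add("utr3_variants", utr3)

    # localize sites for the pair hypotheses
    needed_tx = rm.transcripts_by_id(transcripts)
    utr_records = {}
    for tid, tx in needed_tx.items():
        try:
            utr_records[tid] = rm.extract_utr3(tx, genome)
        except (ValueError, KeyError, IndexError) as exc:
            logger.warning("no 3'UTR extracted for %s: %s", tid, exc)
    site_map = ss.localize_pair_sites(pairs, utr_records, mirnas)
    if pairs:
        failure_rate = len(site_map.unresolved) / len(pairs)
        if failure_rate > config.join_failure_tolerance:
            raise ValueError(
                f"{len(site_map.unresolved)}/{len(pairs)} pair hypotheses failed to join "
                f"(tolerance {config.join_failure_tolerance})"
            )

    # stage: variants overlapping a canonical seed-pairing site of a pair
    overlap_items: set[tuple] = set()  # (variant key, mirna, transcript)
    for key in utr3:
        av = by_key[key]
        for hit in av.utr3_hits():
            tid = hit.transcript_id
            rec = utr_records.get(tid)
            if rec is None:
                continue
            for (mirna_name, pair_tid), sites in site_map.sites.items():
                if pair_tid != tid:
                    continue
                try:
                    edit = sense_edit(rec, av.variant)
                except ValueError:
                    continue
                hit_any = any(
                    variant_overlaps_site(
                        edit.start,
                        max(len(edit.ref), 1),
                        site,
                        insertion=edit.insertion,
                    )
                    for site in sites
                )
                if hit_any:
                    overlap_items.add((key, mirna_name, tid))
                elif config.include_gains:
                    call = call_disruption(rec, av.variant, mirnas[mirna_name])
                    if call.status == "GAINED":
                        overlap_items.add((key, mirna_name, tid))
    stage_sets["seed_site_overlap"] = {k for k, _, _ in overlap_items}
    funnel.add("seed_site_overlap", stage_sets["seed_site_overlap"], overlap_items)

    expressed = ef.expressed_mirnas(expression, population)
    expressed_items = {item for item in overlap_items if item[1] in expressed}
    stage_sets["expressed_mirna"] = {k for k, _, _ in expressed_items}
    funnel.add("expressed_mirna", stage_sets["expressed_mirna"], expressed_items)

    # disruption calls for surviving (variant, miRNA, transcript) triples
    call_rows = []
    candidate_items = set()
    for key, mirna_name, tid in sorted(expressed_items):
        av = by_key[key]
        rec = utr_records[tid]
        call = call_disruption(rec, av.variant, mirnas[mirna_name])
        keep = call.status in {"LOST", "RETAINED"} or (
            config.include_gains and call.status == "GAINED"
        )
        if keep and config.require_rare and av.rarity != "rare":
            keep = False
        if keep and call.status != "NONE":
            candidate_items.add((key, mirna_name, tid))
        call_rows.append(
            {
                "variant": av.label,
                "chrom": av.variant.chrom,
                "pos": av.variant.pos,
                "ref": av.variant.ref,
                "alt": av.variant.alt,
                "gene": av.gene_symbol or "",
                "transcript": tid,
                "mirna": mirna_name,
                "status": call.status,
                "ref_site_offsets": ",".join(str(s.start_offset) for s in call.ref_sites),
                "alt_site_offsets": ",".join(str(s.start_offset) for s in call.alt_sites),
            }
        )
    stage_sets["candidates"] = {k for k, _, _ in candidate_items}
    funnel.add("candidates", stage_sets["candidates"], candidate_items)

    # monotonicity is structural: each stage set is contained in the previous
    for prev, nxt in zip(STAGES, STAGES[1:]):
        if not stage_sets[nxt] <= stage_sets[prev]:
            raise AssertionError(f"funnel stage {nxt} is not a subset of {prev}")

    candidate_rows = []
    for key, mirna_name, tid in sorted(candidate_items):
        av = by_key[key]
        rec = utr_records[tid]
        call = call_disruption(rec, av.variant, mirnas[mirna_name])
        candidate_rows.append(
            {
                "gene": av.gene_symbol or "",
                "transcript": tid,
                "cstar_label": av.cstar_label or "",
                "variant": str(av.variant),
                "mirna": mirna_name,
                "status": call.status,
                "maf": av.maf,
                "rarity": av.rarity or "",
                "n_case": counts.n_carriers(key, "case"),
                "n_control": counts.n_carriers(key, "control"),
                "phenotype": "",
            }
        )
    candidates = pd.DataFrame(
        candidate_rows,
        columns=[
            "gene", "transcript", "cstar_label", "variant", "mirna", "status",
            "maf", "rarity", "n_case", "n_control", "phenotype",
        ],
    ).sort_values(["gene", "cstar_label", "mirna"], kind="mergesort").reset_index(drop=True)

    annotated_rows = [
        {
            "chrom": av.variant.chrom,
            "pos": av.variant.pos,
            "ref": av.variant.ref,
            "alt": av.variant.alt,
            "gene": av.gene_symbol or "",
            "transcript": av.transcript_id or "",
            "region": av.region,
            "cstar_label": av.cstar_label or "",
            "maf": av.maf,
            "rarity": av.rarity or "",
            "n_case": counts.n_carriers(av.variant.key, "case"),
            "n_control": counts.n_carriers(av.variant.key, "control"),
        }
        for av in sorted(annotated, key=lambda a: (a.variant.chrom, a.variant.pos, a.variant.alt))
    ]
    annotated_df = pd.DataFrame(
        annotated_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "transcript", "region",
            "cstar_label", "maf", "rarity", "n_case", "n_control",
        ],
    )
    calls_df = pd.DataFrame(
        call_rows,
        columns=[
            "variant", "chrom", "pos", "ref", "alt", "gene", "transcript",
            "mirna", "status", "ref_site_offsets", "alt_site_offsets",
        ],
    ).sort_values(["gene", "variant", "mirna"], kind="mergesort").reset_index(drop=True)

    manifest = {
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in config.to_dict().items()
            if name in {"genome", "transcripts", "vcf", "mirnas", "pairs", "expression", "groups"}
            and p is not None
        },
        "expressed_population": population,
        "n_pairs": len(pairs),
        "n_unresolved_pairs": len(site_map.unresolved),
        "n_zero_site_pairs": len(site_map.zero_site_pairs),
        "stage_counts": funnel.counts(),
        "stage_pair_counts": {
            "seed_site_overlap": len(overlap_items),
            "expressed_mirna": len(expressed_items),
            "candidates": len(candidate_items),
        },
        "elapsed_seconds": round(time.monotonic() - t0, 3),
    }
    logger.info("funnel: %s", manifest["stage_counts"])
    return PipelineResult(
        candidates=candidates,
        funnel=funnel,
        calls=calls_df,
        annotated=annotated_df,
        stage_sets=stage_sets,
        manifest=manifest,
    )


def write_reports(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write candidates/funnel/calls/annotated TSVs plus a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": outdir / "candidates.tsv",
        "funnel": outdir / "funnel.tsv",
        "calls": outdir / "disruption_calls.tsv",
        "annotated": outdir / "annotated_variants.tsv",
        "manifest": outdir / "manifest.json",
    }
    result.candidates.to_csv(paths["candidates"], sep="\t", index=False)
    result.funnel.to_frame().to_csv(paths["funnel"], sep="\t", index=False)
    result.calls.to_csv(paths["calls"], sep="\t", index=False)
    result.annotated.to_csv(paths["annotated"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
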