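"""Pipeline orchestration and presence/absence matrix building."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from riboreg import __version__
from riboreg.aptamer_search import (
    AptamerHit,
    MotifConfig,
    build_profile,
    default_threshold,
    hits_to_bed,
    hits_to_tsv,
    scan_all,
)
from riboreg.context_mapper import ContextClass, GenomicContext, contexts_to_tsv, locate_all
from riboreg.genome_io import GeneModel, GenomeRecord, read_fasta, read_gff3
from riboreg.regulation_classifier import (
    ClassifierParams,
    RegulationCall,
    calls_to_tsv,
    classify_all,
)

log = logging.getLogger(__name__)

# cell encoding for the presence/absence matrix
RS_AND_GENE = 2
GENE_ONLY = 1
ABSENT = 0


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable surfaced by config file and CLI flags."""

    pseudocount: float = 1.0
    gap_open: float = -4.0
    gap_extend: float = -2.0
    threshold_bits: float | None = None
    threshold_fraction: float = 0.6
    p1_len: int = 9
    gg_separation: int = 18
    gg_proximal_window: int = 4
    classifier: ClassifierParams = ClassifierParams()

    def motif_config(self) -> MotifConfig:
        return MotifConfig(self.gg_separation, self.gg_proximal_window)


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a key=value config file ('#' comments, blank lines ignored)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected key=value): {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def params_from_mapping(mapping: Mapping[str, str]) -> PipelineParams:
    pp_fields = {f.name: f.type for f in fields(PipelineParams) if f.name != "classifier"}
    cl_fields = {f.name for f in fields(ClassifierParams)}
    pp_kwargs: dict = {}
    cl_kwargs: dict = {}
    for key, value in mapping.items():
        if key in cl_fields:
            cl_kwargs[key] = _coerce(value)
        elif key in pp_fields:
            pp_kwargs[key] = _coerce(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return PipelineParams(classifier=ClassifierParams(**cl_kwargs), **pp_kwargs)


def _coerce(value: str):
    low = value.lower()
    if low in {"true", "false"}:
        return low == "true"
    if low in {"none", "null", "."}:
        return None
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        return value


@dataclass
class PipelineResult:
    hits: list[AptamerHit]
    contexts: list[GenomicContext]
    calls: list[RegulationCall]
    threshold_bits: float


def run_pipeline(
    genome_path: str | Path,
    seed_alignment_path: str | Path,
    gff_path: str | Path | None,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    category_map: Mapping[str, str] | None = None,
    species_map: Mapping[str, str] | None = None,
) -> PipelineResult:
    """scan -> locate -> classify, writing all result tables to ``out_dir``.

    Raises ``FileNotFoundError``/format errors for the CLI to translate into
    exit code 2.  Output is a pure function of (inputs, params).
    """
    params = params or PipelineParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genomes = read_fasta(genome_path)
    if all(g.length == 0 for g in genomes):
        raise ValueError("empty genome")
    seed = read_fasta(seed_alignment_path)
    profile = build_profile(
        [r.sequence for r in seed], pseudocount=params.pseudocount,
        gap_open=params.gap_open, gap_extend=params.gap_extend,
    )
    threshold = (
        params.threshold_bits
        if params.threshold_bits is not None
        else default_threshold(profile, params.threshold_fraction)
    )
    genes: list[GeneModel] = read_gff3(gff_path, genomes) if gff_path else []

    hits = scan_all(profile, genomes, threshold_bits=threshold, p1_len=params.p1_len)
    contexts = locate_all(hits, genes)
    classifiable = [
        (h, c) for h, c in zip(hits, contexts) if c.gene_id is not None
    ]
    calls = classify_all(
        [h for h, _ in classifiable], [c for _, c in classifiable],
        genes, genomes, params.classifier,
    )

    (out / "hits.tsv").write_text(hits_to_tsv(hits, params.motif_config()))
    (out / "hits.bed").write_text(hits_to_bed(hits))
    (out / "contexts.tsv").write_text(contexts_to_tsv(contexts))
    (out / "calls.tsv").write_text(calls_to_tsv(calls))
    if category_map is not None and species_map is not None:
        matrix = build_matrix(calls, contexts, genes, category_map, species_map)
        (out / "matrix.tsv").write_text(matrix_to_tsv(matrix))
    log_lines = [
        f"riboreg version: {__version__}",
        f"genome: {genome_path}",
        f"seed alignment: {seed_alignment_path}",
        f"gff: {gff_path}",
        f"profile length: {profile.length}",
        f"threshold_bits: {threshold:.4f}",
        f"params: {params}",
        f"n_hits: {len(hits)}; n_calls: {len(calls)}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(hits, contexts, calls, threshold)


# ---------------------------------------------------------------------------
# Presence/absence matrix


@dataclass
class PresenceAbsenceMatrix:
    rows: list[str]  # species
    columns: list[str]  # gene categories
    cells: dict[tuple[str, str], int]  # (species, category) -> state


def build_matrix(
    calls: Sequence[RegulationCall],
    contexts: Sequence[GenomicContext],
    genes: Sequence[GeneModel],
    category_map: Mapping[str, str],
    species_map: Mapping[str, str],
) -> PresenceAbsenceMatrix:
    """Species x category matrix of riboswitch/gene presence states.

    ``category_map`` maps gene_id -> category; ``species_map`` maps
    seq_id -> species.  A cell is RS_AND_GENE when >=1 call or located
    (non-intergenic) hit lands on a gene of that category, GENE_ONLY when the
    category's gene exists without a hit, else ABSENT.  Row/column order
    follows first appearance in the input maps.
    """
    species_order = list(dict.fromkeys(species_map.values()))
    category_order = list(dict.fromkeys(category_map.values()))

    gene_species: dict[str, str] = {}
    for g in genes:
        sp = species_map.get(g.seq_id)
        if sp is not None:
            gene_species[g.gene_id] = sp
        if g.gene_id not in category_map:
            log.warning("gene %s has no category; left out of the matrix", g.gene_id)

    hit_genes = {c.gene_id for c in contexts if c.gene_id is not None}
    hit_genes |= {c.gene_id for c in calls if c.gene_id is not None}

    cells: dict[tuple[str, str], int] = {
        (sp, cat): ABSENT for sp in species_order for cat in category_order
    }
    for g in genes:
        cat = category_map.get(g.gene_id)
        sp = gene_species.get(g.gene_id)
        if cat is None or sp is None:
            continue
        state = RS_AND_GENE if g.gene_id in hit_genes else GENE_ONLY
        cells[(sp, cat)] = max(cells[(sp, cat)], state)
    for sp in species_order:
        if not any(gene_species.get(g.gene_id) == sp for g in genes):
            log.warning("species %s has zero genes; row is all ABSENT", sp)
    return PresenceAbsenceMatrix(species_order, category_order, cells)


def matrix_to_tsv(matrix: PresenceAbsenceMatrix) -> str:
    lines = ["\t".join(["species"] + matrix.columns)]
    for sp in matrix.rows:
        lines.append(
            "\t".join([sp] + [str(matrix.cells[(sp, cat)]) for cat in matrix.columns])
        )
    return "\n".join(lines) + "\n"


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """TSV of (key, value) pairs; order-preserving; header optional."""
    out: dict[str, str] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines()):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {i + 1} is not two-column TSV")
        if i == 0 and parts[0].lower() in {"gene_id", "seq_id", "key"}:
            continue
        out[parts[0]] = parts[1]
    return out
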