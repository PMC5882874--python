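"""Tabular filter rules for transporter annotation and marker selection.

The homology searches themselves (BLASTP/Pfam/TMHMM) are not executed; their
evidence arrives as table columns.  The decision rules are:

- transporter candidates: E-value <= 1e-5 AND similarity >= 50% AND coverage
  >= 30%, plus a transporter domain and >= ``min_tm`` transmembrane helices;
- single-copy markers: exactly one hit per genome with E-value <= 1e-5 and
  coverage strictly > 50% in *every* genome.

Comparison strictness follows the printed operators (>=30 vs >50).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class HomologyRecord:
    query_id: str
    subject_id: str
    evalue: float
    similarity_pct: float
    coverage_pct: float
    has_transporter_domain: bool
    n_tm_helices: int

    def __post_init__(self) -> None:
        for name, v in (("similarity_pct", self.similarity_pct), ("coverage_pct", self.coverage_pct)):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] for query {self.query_id}")
        if self.evalue < 0:
            raise ValueError(f"negative E-value for query {self.query_id}")
        if self.n_tm_helices < 0:
            raise ValueError(f"negative n_tm_helices for query {self.query_id}")


@dataclass(frozen=True)
class MarkerRecord:
    protein_id: str
    genome_id: str
    n_hits: int
    best_evalue: float
    best_coverage_pct: float


@dataclass(frozen=True)
class TransporterFilterParams:
    max_evalue: float = 1e-5
    min_similarity_pct: float = 50.0
    min_coverage_pct: float = 30.0
    min_tm: int = 1


def record_passes_transporter_filter(
    rec: HomologyRecord, params: TransporterFilterParams | None = None
) -> bool:
    p = params or TransporterFilterParams()
    return (
        rec.evalue <= p.max_evalue
        and rec.similarity_pct >= p.min_similarity_pct
        and rec.coverage_pct >= p.min_coverage_pct
        and rec.has_transporter_domain
        and rec.n_tm_helices >= p.min_tm
    )


def filter_transporter_candidates(
    records: Iterable[HomologyRecord], params: TransporterFilterParams | None = None
) -> list[str]:
    """Sorted unique query ids with at least one record passing all rules."""
    p = params or TransporterFilterParams()
    return sorted({r.query_id for r in records if record_passes_transporter_filter(r, p)})


@dataclass(frozen=True)
class MarkerFilterParams:
    max_evalue: float = 1e-5
    min_coverage_pct: float = 50.0  # strict >


def select_single_copy_markers(
    records: Iterable[MarkerRecord],
    genomes: Sequence[str],
    params: MarkerFilterParams | None = None,
) -> list[str]:
    """Protein ids that are single-copy, significant and well-covered in
    *every* listed genome.  A (protein, genome) pair missing from the table
    raises ``KeyError`` naming the genome."""
    p = params or MarkerFilterParams()
    table: dict[str, dict[str, MarkerRecord]] = {}
    for r in records:
        table.setdefault(r.protein_id, {})[r.genome_id] = r
    selected = []
    for protein in sorted(table):
        ok = True
        for genome in genomes:
            rec = table[protein].get(genome)
            if rec is None:
                raise KeyError(
                    f"genome {genome!r} missing from marker table for protein {protein!r}"
                )
            if not (
                rec.n_hits == 1
                and rec.best_evalue <= p.max_evalue
                and rec.best_coverage_pct > p.min_coverage_pct
            ):
                ok = False
                break
        if ok:
            selected.append(protein)
    return selected


# ---------------------------------------------------------------------------
# TSV I/O

_HOMOLOGY_COLUMNS = (
    "query_id", "subject_id", "evalue", "similarity_pct", "coverage_pct",
    "has_transporter_domain", "n_tm_helices",
)
_MARKER_COLUMNS = ("protein_id", "genome_id", "n_hits", "best_evalue", "best_coverage_pct")

_TRUE = {"1", "true", "t", "yes"}


def read_homology_tsv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[HomologyRecord]:
    """Read a homology evidence table.

    ``column_map`` maps the canonical field names to the file's column names
    (e.g. for outfmt-6-like headers).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _HOMOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"homology table {path} missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        flag = row.has_transporter_domain
        if not isinstance(flag, (bool,)):
            flag = str(flag).strip().lower() in _TRUE
        records.append(
            HomologyRecord(
                query_id=str(row.query_id),
                subject_id=str(row.subject_id),
                evalue=float(row.evalue),
                similarity_pct=float(row.similarity_pct),
                coverage_pct=float(row.coverage_pct),
                has_transporter_domain=bool(flag),
                n_tm_helices=int(row.n_tm_helices),
            )
        )
    return records


def write_homology_tsv(records: Iterable[HomologyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "subject_id": r.subject_id,
                "evalue": r.evalue,
                "similarity_pct": r.similarity_pct,
                "coverage_pct": r.coverage_pct,
                "has_transporter_domain": int(r.has_transporter_domain),
                "n_tm_helices": r.n_tm_helices,
            }
            for r in records
        ],
        columns=list(_HOMOLOGY_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_marker_tsv(path: str | Path) -> list[MarkerRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table {path} missing columns: {missing}")
    return [
        MarkerRecord(
            protein_id=str(r.protein_id),
            genome_id=str(r.genome_id),
            n_hits=int(r.n_hits),
            best_evalue=float(r.best_evalue),
            best_coverage_pct=float(r.best_coverage_pct),
        )
        for r in df.itertuples(index=False)
    ]
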