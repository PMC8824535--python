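"""Category-specific gene lists from flat annotation tables.

Three independent filters build the gene sets used to score miRNA target
counts:

* **process** sets — keyword screening of GO-style term names (a gene joins a
  category when any of the category's keywords occurs in the name of any term
  annotating it);
* a **disease** set — genes with sufficient disease-association evidence
  (publication count or variant count at or above a threshold);
* a **tissue** set — genes expressed with sufficient confidence in any tissue
  on a cardiac-centric whitelist.

All thresholds use inclusive (``>=``) semantics and are configurable through
:class:`GeneSetConfig`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GoAnnotationRecord",
    "DiseaseGeneRecord",
    "TissueExpressionRecord",
    "GeneSet",
    "GeneSetConfig",
    "DEFAULT_CATEGORY_KEYWORDS",
    "DEFAULT_TISSUE_WHITELIST",
    "screen_go_annotations",
    "filter_disease_genes",
    "select_tissue_genes",
    "read_go_annotations",
    "read_disease_records",
    "read_tissue_records",
    "load_gene_set_config",
]

#: Cardiovascular process categories with their default screening keywords.
#: Keywords default to the category names themselves and are user-overridable.
DEFAULT_CATEGORY_KEYWORDS: dict[str, list[str]] = {
    "angiogenesis": ["angiogenesis"],
    "cardiac_muscle_functions": ["cardiac muscle"],
    "coagulation": ["coagulation"],
    "fibrosis": ["fibrosis"],
    "hemopoiesis": ["hemopoiesis", "haemopoiesis", "hematopoiesis"],
    "inflammation": ["inflammation", "inflammatory"],
    "muscle_hypertrophy": ["muscle hypertrophy"],
    "platelet_activity": ["platelet"],
}

#: The 14 cardiac tissues/cell types accepted by the tissue filter.
DEFAULT_TISSUE_WHITELIST: list[str] = [
    "Atrium",
    "Capillary pericyte",
    "Cardiac muscle",
    "Cardiac Purkinje_cell",
    "Cardiac Purkinje fiber",
    "Cardiofibroblast",
    "Cardiomyoblast",
    "Cardiovascular system",
    "Heart endothelial cell",
    "Heart",
    "Heart ventricle",
    "Left atrium",
    "Left ventricle",
    "Pericyte",
]


def _norm_gene(gene: str) -> str:
    return str(gene).strip().upper()


@dataclass(frozen=True)
class GoAnnotationRecord:
    """One GO-style annotation: a term id, its free-text name, one gene."""

    term_id: str
    term_name: str
    gene: str

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        object.__setattr__(self, "gene", _norm_gene(self.gene))


@dataclass(frozen=True)
class DiseaseGeneRecord:
    """Per-gene disease-association evidence counts."""

    gene: str
    n_publications: int
    n_variants: int

    def __post_init__(self) -> None:
        if self.n_publications < 0 or self.n_variants < 0:
            raise ValueError(
                f"negative evidence count for {self.gene!r}: "
                f"publications={self.n_publications}, variants={self.n_variants}"
            )
        object.__setattr__(self, "gene", _norm_gene(self.gene))
        object.__setattr__(self, "n_publications", int(self.n_publications))
        object.__setattr__(self, "n_variants", int(self.n_variants))


@dataclass(frozen=True)
class TissueExpressionRecord:
    """Gene expression confidence (0-5 scale) in one tissue."""

    gene: str
    tissue: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 5.0:
            raise ValueError(
                f"confidence {self.confidence} for {self.gene!r} outside [0, 5]"
            )
        object.__setattr__(self, "gene", _norm_gene(self.gene))


@dataclass
class GeneSet:
    """Named collection of gene symbols with a category kind."""

    label: str
    kind: str  # process | disease | tissue
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("GeneSet label must be non-empty")
        if self.kind not in {"process", "disease", "tissue"}:
            raise ValueError(f"unknown gene-set kind {self.kind!r}")
        self.genes = {_norm_gene(g) for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetConfig:
    """Thresholds, keywords and tissue whitelist for the three filters."""

    keyword_map: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CATEGORY_KEYWORDS.items()}
    )
    disease_min_publications: int = 5
    disease_min_variants: int = 3
    tissue_whitelist: list[str] = field(
        default_factory=lambda: list(DEFAULT_TISSUE_WHITELIST)
    )
    tissue_min_confidence: float = 1.0
    whole_word: bool = False  # keyword matching mode; default substring

    def __post_init__(self) -> None:
        if self.disease_min_publications < 0 or self.disease_min_variants < 0:
            raise ValueError("disease thresholds must be >= 0")
        if self.tissue_min_confidence < 0:
            raise ValueError("tissue_min_confidence must be >= 0")
        if not self.tissue_whitelist:
            raise ValueError("tissue_whitelist must be non-empty")


def _keyword_matches(keyword: str, text: str, whole_word: bool) -> bool:
    if whole_word:
        return re.search(rf"\b{re.escape(keyword.lower())}\b", text.lower()) is not None
    return keyword.lower() in text.lower()


def screen_go_annotations(
    records: list[GoAnnotationRecord], config: GeneSetConfig
) -> dict[str, GeneSet]:
    """Assign genes to process categories by keyword screening of term names.

    A gene enters a category iff at least one of the category's keywords
    occurs (case-insensitive substring, or whole-word when configured) in the
    ``term_name`` of at least one of the gene's annotations.
    """
    if not records:
        raise ValueError("no annotations")
    if not any(config.keyword_map.values()):
        logger.warning("all categories have empty keyword lists")
    out: dict[str, GeneSet] = {}
    for category, keywords in config.keyword_map.items():
        if not keywords:
            logger.warning("category %r has no keywords; returning empty set", category)
            out[category] = GeneSet(label=category, kind="process", genes=set())
            continue
        genes = {
            rec.gene
            for rec in records
            if any(_keyword_matches(kw, rec.term_name, config.whole_word) for kw in keywords)
        }
        out[category] = GeneSet(label=category, kind="process", genes=genes)
    return out


def filter_disease_genes(
    records: list[DiseaseGeneRecord], config: GeneSetConfig
) -> GeneSet:
    """Retain genes with >= ``disease_min_publications`` publications OR
    >= ``disease_min_variants`` disease-associated variants."""
    genes = {
        rec.gene
        for rec in records
        if rec.n_publications >= config.disease_min_publications
        or rec.n_variants >= config.disease_min_variants
    }
    return GeneSet(label="CVD", kind="disease", genes=genes)


def select_tissue_genes(
    records: list[TissueExpressionRecord], config: GeneSetConfig
) -> GeneSet:
    """Retain genes expressed with confidence >= threshold in a whitelisted
    tissue.  Unknown tissue names are silently ignored."""
    whitelist = set(config.tissue_whitelist)
    genes = {
        rec.gene
        for rec in records
        if rec.tissue in whitelist and rec.confidence >= config.tissue_min_confidence
    }
    return GeneSet(label="cardiac_tissue", kind="tissue", genes=genes)


# ---------------------------------------------------------------------------
# Flat-file ingest


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_go_annotations(path) -> list[GoAnnotationRecord]:
    df = _read_table(path, ("term_id", "term_name", "gene"))
    df = df.drop_duplicates(subset=["term_id", "gene"])
    return [
        GoAnnotationRecord(r.term_id, r.term_name, r.gene)
        for r in df.itertuples(index=False)
    ]


def read_disease_records(path) -> list[DiseaseGeneRecord]:
    df = _read_table(path, ("gene", "n_publications", "n_variants"))
    records: list[DiseaseGeneRecord] = []
    n_dropped = 0
    for r in df.itertuples(index=False):
        if pd.isna(r.n_publications) or pd.isna(r.n_variants):
            n_dropped += 1
            continue
        records.append(
            DiseaseGeneRecord(r.gene, int(r.n_publications), int(r.n_variants))
        )
    if n_dropped:
        logger.warning("dropped %d disease records with missing counts", n_dropped)
    return records


def read_tissue_records(path) -> list[TissueExpressionRecord]:
    df = _read_table(path, ("gene", "tissue", "confidence"))
    return [
        TissueExpressionRecord(r.gene, r.tissue, float(r.confidence))
        for r in df.itertuples(index=False)
    ]


def load_gene_set_config(path) -> GeneSetConfig:
    """Load a :class:`GeneSetConfig` from a YAML mapping; absent keys keep
    their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return GeneSetConfig(**raw)
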