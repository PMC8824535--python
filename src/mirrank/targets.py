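"""Multi-database miRNA target prediction filtering and aggregation.

Predictions arrive as one row per (miRNA, gene, database) with a
database-native score.  The pipeline:

1. expands stem-loop miRNA identifiers into the stem-loop plus both mature
   arms (``-3p``/``-5p``), since target predictions are arm-specific;
2. keeps only the top fraction (default top decile) of predictions, ranked
   best-first within each database according to that database's score
   orientation;
3. aggregates surviving predictions into one target set per queried miRNA,
   with per-gene *support* = the number of distinct databases predicting the
   interaction, merging arm-expanded variants back under the queried
   stem-loop id.
"""

from __future__ import annotations

import json
import math
import re
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MirnaId",
    "PredictedInteraction",
    "TargetSet",
    "TargetFilterConfig",
    "expand_mirna_identifiers",
    "filter_top_fraction",
    "aggregate_target_sets",
    "read_interactions",
    "write_target_sets",
]

_MIRNA_RE = re.compile(r"^[A-Za-z]{3}-(miR|mir|let)-[A-Za-z0-9.\-]+$")
_ARM_RE = re.compile(r"-(3p|5p)$")


@dataclass(frozen=True, order=True)
class MirnaId:
    """miRBase-style identifier, e.g. ``hsa-miR-126`` (stem-loop) or
    ``hsa-miR-1-3p`` (mature).  ``arm`` is derived from the name suffix."""

    name: str

    def __post_init__(self) -> None:
        if not _MIRNA_RE.match(self.name):
            raise ValueError(f"malformed miRNA identifier: {self.name!r}")

    @property
    def arm(self) -> str:
        m = _ARM_RE.search(self.name)
        return f"-{m.group(1)}" if m else "none"

    @property
    def stem(self) -> str:
        """Name with any mature-arm suffix removed."""
        return _ARM_RE.sub("", self.name)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class PredictedInteraction:
    """One miRNA->gene prediction from one database, native score scale.

    ``better`` states the database's score orientation: ``"higher"`` when
    larger scores are stronger predictions, ``"lower"`` otherwise.
    """

    mirna: MirnaId
    gene: str
    database: str
    score: float
    better: str = "higher"

    def __post_init__(self) -> None:
        if self.better not in {"higher", "lower"}:
            raise ValueError(f"unknown score orientation {self.better!r}")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.mirna.name}->{self.gene}")
        object.__setattr__(self, "gene", str(self.gene).strip().upper())


@dataclass
class TargetSet:
    """Aggregated targets of one (queried) miRNA.

    ``targets`` maps gene -> support (distinct databases predicting it);
    ``arm_provenance`` maps gene -> set of arm-level miRNA names that
    contributed the prediction.
    """

    mirna: MirnaId
    targets: dict[str, int] = field(default_factory=dict)
    arm_provenance: dict[str, set[str]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return set(self.targets)


@dataclass
class TargetFilterConfig:
    top_fraction: float = 0.10
    per_database: bool = True
    min_support: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


def expand_mirna_identifiers(ids: list[MirnaId]) -> list[MirnaId]:
    """Replace every stem-loop id by {itself, -3p, -5p}; mature ids pass
    through.  Order stable, duplicates removed."""
    out: list[MirnaId] = []
    seen: set[str] = set()
    for mid in ids:
        if mid.arm == "none":
            triple = [mid, MirnaId(mid.name + "-3p"), MirnaId(mid.name + "-5p")]
        else:
            triple = [mid]
        for m in triple:
            if m.name not in seen:
                seen.add(m.name)
                out.append(m)
    return out


def _retained_in_group(
    group: list[PredictedInteraction], fraction: float
) -> list[PredictedInteraction]:
    if not group:
        return []
    orientations = {i.better for i in group}
    if len(orientations) > 1:
        raise ValueError(
            f"database {group[0].database!r} mixes score orientations {orientations}"
        )
    higher = orientations.pop() == "higher"
    n_keep = math.ceil(fraction * len(group))
    ranked = sorted((i.score for i in group), reverse=higher)
    cut = ranked[n_keep - 1]
    # all records tied at the boundary score are retained
    if higher:
        return [i for i in group if i.score >= cut]
    return [i for i in group if i.score <= cut]


def filter_top_fraction(
    interactions: list[PredictedInteraction], config: TargetFilterConfig
) -> list[PredictedInteraction]:
    """Retain the best-scoring ``top_fraction`` of predictions.

    With ``per_database=True`` (default) the cut is taken within each
    database; otherwise over the pooled table (meaningful only when all
    sources share an orientation and scale).  Boundary ties are all kept, so
    the retained count is ``ceil(f*n)`` exactly when scores are distinct and
    never smaller.
    """
    if not interactions:
        return []
    if not config.per_database:
        return _retained_in_group(list(interactions), config.top_fraction)
    by_db: dict[str, list[PredictedInteraction]] = defaultdict(list)
    for i in interactions:
        by_db[i.database].append(i)
    out: list[PredictedInteraction] = []
    for db in by_db:
        out.extend(_retained_in_group(by_db[db], config.top_fraction))
    return out


def aggregate_target_sets(
    interactions: list[PredictedInteraction],
    config: TargetFilterConfig | None = None,
    query_ids: list[MirnaId] | None = None,
) -> list[TargetSet]:
    """Aggregate (already filtered) predictions into per-miRNA target sets.

    Support of a gene is the number of distinct databases predicting the
    (miRNA, gene) pair, counted across arm variants when those variants were
    expanded from a stem-loop query in ``query_ids``.  Genes with support
    below ``min_support`` are dropped.
    """
    config = config or TargetFilterConfig()
    # map each observed miRNA name to its reporting key (the queried id)
    stem_of_query = {}
    if query_ids:
        for q in query_ids:
            if q.arm == "none":
                stem_of_query[q.stem] = q

    def report_key(mid: MirnaId) -> MirnaId:
        if mid.arm != "none" and mid.stem in stem_of_query:
            return stem_of_query[mid.stem]
        return mid

    dbs: dict[MirnaId, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    arms: dict[MirnaId, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for i in interactions:
        key = report_key(i.mirna)
        dbs[key][i.gene].add(i.database)
        arms[key][i.gene].add(i.mirna.name)

    out: list[TargetSet] = []
    for key in sorted(dbs, key=lambda m: m.name):
        targets = {
            gene: len(sources)
            for gene, sources in dbs[key].items()
            if len(sources) >= config.min_support
        }
        provenance = {g: arms[key][g] for g in targets}
        out.append(TargetSet(mirna=key, targets=targets, arm_provenance=provenance))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_interactions(
    path, orientation: dict[str, str] | None = None
) -> list[PredictedInteraction]:
    """Read a prediction TSV with columns (mirna, gene, database, score).

    ``orientation`` maps database name -> "higher"|"lower"; unmapped
    databases default to "higher".
    """
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str, "database": str})
    missing = {"mirna", "gene", "database", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    orientation = orientation or {}
    return [
        PredictedInteraction(
            mirna=MirnaId(r.mirna),
            gene=r.gene,
            database=r.database,
            score=float(r.score),
            better=orientation.get(r.database, "higher"),
        )
        for r in df.itertuples(index=False)
    ]


def write_target_sets(target_sets: list[TargetSet], tsv_path, provenance_path=None):
    """Write aggregated targets as TSV (mirna, gene, support) plus an optional
    JSON sidecar with per-arm provenance."""
    rows = [
        {"mirna": ts.mirna.name, "gene": gene, "support": support}
        for ts in target_sets
        for gene, support in sorted(ts.targets.items())
    ]
    pd.DataFrame(rows, columns=["mirna", "gene", "support"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if provenance_path is not None:
        side = {
            ts.mirna.name: {g: sorted(v) for g, v in sorted(ts.arm_provenance.items())}
            for ts in target_sets
        }
        with open(provenance_path, "w") as fh:
            json.dump(side, fh, indent=1, sort_keys=True)
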