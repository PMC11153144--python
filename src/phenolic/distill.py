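"""Genome-level pathway distillation and sample-level expression rollups.

A genome *encodes* a transformation pathway when it carries annotations
satisfying strictly more than half of the pathway's steps (a step is
satisfied by any of its alternative families). An encoded pathway is
*expressed* in a sample when at least one of the genome's genes annotated to
any family of the pathway retains a positive count after the global count
filter. Expression summaries sum normalized expression (geTMM) over pathway
member genes per sample, average over replicates within each
(habitat, depth) group, and z-score each pathway across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotate import Annotation
from .db import Database, PathwayDef


@dataclass
class GenomeAnnotation:
    """All annotations for one genome, with its genus label."""

    genome_id: str
    genus: str
    gene_ids: set[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        stray = {a.gene_id for a in self.annotations} - self.gene_ids
        if stray:
            raise ValueError(
                f"genome {self.genome_id!r}: annotated genes not in gene set: "
                f"{sorted(stray)[:5]}"
            )

    @property
    def families_present(self) -> set[str]:
        return {a.family_id for a in self.annotations}

    def genes_for_families(self, family_ids: Iterable[str]) -> set[str]:
        wanted = set(family_ids)
        return {a.gene_id for a in self.annotations if a.family_id in wanted}


@dataclass(frozen=True)
class PathwayStatus:
    genome_id: str
    pathway_id: int
    completeness: float
    encoded: bool
    expressed_in: frozenset[str] = frozenset()


ENCODED_MIN_COMPLETENESS = 0.5  # strict: completeness must EXCEED this


def pathway_completeness(
    genome: GenomeAnnotation, pathway: PathwayDef
) -> tuple[float, bool]:
    """Fraction of pathway steps satisfied by the genome's annotations.

    Returns ``(completeness, encoded)`` where ``encoded`` uses the strict
    >50% rule: a genome with exactly half of the steps does not encode.
    """
    present = genome.families_present
    satisfied = sum(1 for step in pathway.steps if step & present)
    completeness = satisfied / len(pathway.steps)
    return completeness, completeness > ENCODED_MIN_COMPLETENESS


def pathway_expressed(
    genome: GenomeAnnotation,
    pathway: PathwayDef,
    filtered_counts: pd.DataFrame,
    sample_id: str,
) -> bool:
    """Whether the genome expresses the pathway in one sample.

    ``filtered_counts`` is the gene x sample matrix after the global count
    filter; expression requires the genome to encode the pathway AND at least
    one of its pathway-member genes to have a positive post-filter count.
    """
    if sample_id not in filtered_counts.columns:
        raise KeyError(f"sample {sample_id!r} absent from count matrix")
    _, encoded = pathway_completeness(genome, pathway)
    if not encoded:
        return False
    member_families = set().union(*pathway.steps)
    genes = genome.genes_for_families(member_families)
    genes &= set(filtered_counts.index)
    if not genes:
        return False
    return bool((filtered_counts.loc[sorted(genes), sample_id] > 0).any())


def distill_genomes(
    genomes: Iterable[GenomeAnnotation],
    db: Database,
    filtered_counts: pd.DataFrame | None = None,
) -> list[PathwayStatus]:
    """Full genome x pathway status sweep (completeness, encoded, expressed)."""
    statuses = []
    samples = list(filtered_counts.columns) if filtered_counts is not None else []
    for genome in genomes:
        for pid in sorted(db.pathways):
            pw = db.pathways[pid]
            completeness, encoded = pathway_completeness(genome, pw)
            expressed_in: set[str] = set()
            if encoded and filtered_counts is not None:
                member_families = set().union(*pw.steps)
                genes = genome.genes_for_families(member_families)
                genes &= set(filtered_counts.index)
                if genes:
                    sub = filtered_counts.loc[sorted(genes), samples]
                    expressed_in = {s for s in samples if (sub[s] > 0).any()}
            statuses.append(
                PathwayStatus(
                    genome.genome_id, pid, completeness, encoded,
                    frozenset(expressed_in),
                )
            )
    return statuses


def statuses_to_frame(statuses: Iterable[PathwayStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": s.genome_id,
                "pathway_id": s.pathway_id,
                "completeness": s.completeness,
                "encoded": s.encoded,
                "expressed_in": ";".join(sorted(s.expressed_in)),
            }
            for s in statuses
        ],
        columns=["genome_id", "pathway_id", "completeness", "encoded", "expressed_in"],
    )


# ---------------------------------------------------------------------------
# expression summaries

def summarize_pathway_expression(
    genomes: Iterable[GenomeAnnotation],
    db: Database,
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Pathway x (habitat, depth) z-scored expression table.

    For each pathway: sum geTMM over all genes annotated to any of the
    pathway's families per sample, average those sums over the replicates of
    each (habitat, depth) group, then z-score the pathway's group averages
    (mean 0, sd 1 across groups; a pathway flat across all groups gets
    z = 0 everywhere rather than NaN).

    ``metadata`` is indexed by sample id with at least ``habitat`` and
    ``depth`` columns; every group must contain at least one replicate.
    """
    meta = metadata.loc[list(normalized.columns)]
    groups = meta.groupby(["habitat", "depth"], sort=True).groups
    if any(len(idx) == 0 for idx in groups.values()):
        raise ValueError("expression group with zero replicates")

    gene_to_pathways: dict[str, set[int]] = {}
    for genome in genomes:
        for pid in sorted(db.pathways):
            members = set().union(*db.pathways[pid].steps)
            for g in genome.genes_for_families(members):
                gene_to_pathways.setdefault(g, set()).add(pid)

    rows = {}
    group_keys = sorted(groups)
    for pid in sorted(db.pathways):
        genes = sorted(
            g for g, ps in gene_to_pathways.items()
            if pid in ps and g in normalized.index
        )
        sums = (
            normalized.loc[genes].sum(axis=0)
            if genes
            else pd.Series(0.0, index=normalized.columns)
        )
        means = np.array(
            [sums[list(groups[key])].mean() for key in group_keys]
        )
        sd = means.std(ddof=0)
        z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
        rows[pid] = z
    out = pd.DataFrame.from_dict(rows, orient="index", columns=[
        f"{h}_{d}" for h, d in group_keys
    ])
    out.index.name = "pathway_id"
    return out


def expressed_by_habitat(
    statuses: Iterable[PathwayStatus], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Genome x habitat flag: expressed >=1 pathway in any sample of the habitat."""
    sample_habitat = metadata["habitat"].to_dict()
    habitats = sorted(set(sample_habitat.values()))
    flags: dict[str, dict[str, bool]] = {}
    for s in statuses:
        row = flags.setdefault(s.genome_id, {h: False for h in habitats})
        for sample in s.expressed_in:
            row[sample_habitat[sample]] = True
    out = pd.DataFrame.from_dict(flags, orient="index").reindex(
        columns=habitats
    ).fillna(False).sort_index()
    out.index.name = "genome_id"
    return out
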