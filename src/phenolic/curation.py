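"""Curation workflow turning seed/decoy sequence sets into a calibrated family.

The workflow mirrors how expert-curated annotation families are built:

1. biochemically characterized true members ("seeds") and related but
   functionally distinct sequences ("decoys") are searched against a large
   reference protein collection to recruit homologs (top-k per query);
2. all four sequence classes are aligned (externally — any aligner) and a
   phylogeny is inferred (externally — any tree tool producing Newick);
3. the tree is rerooted on the clade holding all decoy-class sequences, the
   clade holding all seeds is extracted, and its non-seed tips become the
   training set, leaving the seeds themselves as a hold-out;
4. a model built from the training set alone is scored against every class:
   the A score is the minimum held-out seed bitscore (precision), the B score
   the minimum in-clade homolog bitscore (recall), and both must clear the
   ceiling set by the best-scoring decoy-class sequence. When the homolog
   minimum does not clear the ceiling the family ships A-only.

Multiple-sequence alignment and tree inference are consumed through standard
formats (aligned FASTA, Newick), never reimplemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import pandas as pd
import pyhmmer

from .annotate import run_profile_search, run_similarity_search

SEED = "seed"
SEED_HOMOLOG = "seed_homolog"
DECOY = "decoy"
DECOY_HOMOLOG = "decoy_homolog"


class CurationError(ValueError):
    pass


class CladeSeparationError(CurationError):
    """Seeds and decoys are not separable on the tree (a decoy-class tip
    falls inside the seed MRCA after decoy-rooting)."""


@dataclass
class CurationInput:
    """Sequence classes feeding one family's calibration.

    ``decoy_homologs`` are reference hits recruited from decoy queries; they
    are treated as decoy-class everywhere (rooting and score ceilings), same
    as the original decoys.
    """

    family_id: str
    seed_sequences: dict[str, str]
    decoy_sequences: dict[str, str]
    reference_protein_db: dict[str, str] = field(default_factory=dict)
    decoy_homologs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seed_sequences:
            raise CurationError("at least one seed sequence required")
        if not self.decoy_sequences:
            raise CurationError("at least one decoy sequence required")
        overlap = set(self.seed_sequences) & set(self.decoy_sequences)
        if overlap:
            raise CurationError(
                f"seed and decoy ids overlap: {sorted(overlap)}"
            )


@dataclass
class CalibrationResult:
    family_id: str
    score_A: float
    score_B: float | None
    max_decoy_score: float
    per_sequence_scores: pd.DataFrame  # columns: id, class, bitscore
    failed: bool = False
    failure_reason: str | None = None


# ---------------------------------------------------------------------------
# homolog recruitment

def recruit_homologs(
    query_sequences: Mapping[str, str],
    reference_protein_db: Mapping[str, str],
    k: int = 200,
) -> dict[str, str]:
    """Union over queries of each query's top-k reference hits by bitscore.

    Ties at the k-th score are broken by reference id for determinism; the
    union is de-duplicated by id. ``k`` defaults to 200, the depth used when
    recruiting from a comprehensive reference collection.
    """
    if k < 1:
        raise CurationError("k must be >= 1")
    if not reference_protein_db:
        raise CurationError("reference protein database is empty")
    recruited: dict[str, str] = {}
    for qid in sorted(query_sequences):
        scored = _score_against_each(query_sequences[qid], reference_protein_db)
        scored.sort(key=lambda t: (-t[1], t[0]))
        for rid, _ in scored[:k]:
            recruited.setdefault(rid, reference_protein_db[rid])
    return recruited


def _score_against_each(
    query: str, references: Mapping[str, str]
) -> list[tuple[str, float]]:
    from .annotate import _make_aligner, raw_to_bits  # engine internals

    aligner = _make_aligner()
    allowed = set(str(aligner.substitution_matrix.alphabet))
    q = "".join(c if c in allowed else "X" for c in query.upper())
    out = []
    for rid in sorted(references):
        r = "".join(c if c in allowed else "X" for c in references[rid].upper())
        out.append((rid, raw_to_bits(aligner.score(q, r))))
    return out


# ---------------------------------------------------------------------------
# alignment trimming

def trim_alignment(
    msa: Sequence[tuple[str, str]], max_gap_fraction: float = 0.9
) -> list[tuple[str, str]]:
    """Drop alignment columns whose gap fraction exceeds ``max_gap_fraction``.

    ``msa`` is a list of (id, aligned sequence) pairs; gaps are ``-`` or
    ``.``. Row order is preserved. A fixed gap-fraction rule replaces
    adaptive gap-trimming heuristics so the trim is a documented, reproducible
    parameter.
    """
    if not msa:
        return []
    length = len(msa[0][1])
    for rid, row in msa:
        if len(row) != length:
            raise CurationError(f"ragged alignment: row {rid!r} length differs")
    n = len(msa)
    keep = []
    for col in range(length):
        gaps = sum(1 for _, row in msa if row[col] in "-.")
        if gaps / n <= max_gap_fraction:
            keep.append(col)
    return [(rid, "".join(row[c] for c in keep)) for rid, row in msa]


# ---------------------------------------------------------------------------
# clade extraction

def extract_training_clade(
    newick_tree: str | Path,
    seed_ids: set[str],
    decoy_ids: set[str],
) -> set[str]:
    """Extract the hold-out-safe training set from a family phylogeny.

    The tree is rerooted on the edge above the smallest clade containing all
    decoy-class tips and no seeds; the tips of the seed MRCA, minus the seeds
    themselves and minus any decoy-class tips, are returned. Raises
    :class:`CladeSeparationError` if no decoy clade excluding the seeds
    exists, or if a decoy-class tip falls inside the seed MRCA. An empty
    result (seeds monophyletic with no interleaved homologs) is legal and is
    reported with a warning.
    """
    tree = _read_tree(newick_tree)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = (set(seed_ids) | set(decoy_ids)) - labels
    if missing:
        raise CurationError(f"tips missing from tree: {sorted(missing)}")

    tree.encode_bipartitions()
    ns = tree.taxon_namespace
    decoy_mask = ns.taxa_bitmask(labels=sorted(decoy_ids))
    seed_mask = ns.taxa_bitmask(labels=sorted(seed_ids))
    full_mask = tree.seed_node.edge.bipartition.leafset_bitmask

    # the decoy clade: smallest edge-side containing all decoys and no seeds
    # (either orientation of the bipartition counts; rerooting at the edge is
    # the same operation regardless)
    best_edge = None
    best_size = None
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        side = edge.bipartition.leafset_bitmask
        for mask in (side, side ^ full_mask):
            if mask & decoy_mask == decoy_mask and mask & seed_mask == 0:
                size = bin(mask).count("1")
                if best_size is None or size < best_size:
                    best_edge, best_size = edge, size
    if best_edge is None:
        raise CladeSeparationError(
            "no clade contains all decoy-class tips without a seed; "
            "seeds and decoys are not separable on this tree"
        )
    tree.reroot_at_edge(best_edge, update_bipartitions=True)

    mrca = tree.mrca(taxa=[t for t in ns if t.label in seed_ids])
    clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    inside_decoys = clade_tips & set(decoy_ids)
    if inside_decoys:
        raise CladeSeparationError(
            f"decoy-class tips inside the seed clade: {sorted(inside_decoys)}"
        )
    training = clade_tips - set(seed_ids)
    if not training:
        warnings.warn(
            "seed clade contains no homologs: empty training set",
            stacklevel=2,
        )
    return training


def _read_tree(newick_tree: str | Path) -> dendropy.Tree:
    # preserve_underscores: unquoted labels with underscores are common in
    # sequence ids and must not be mangled into spaces
    if isinstance(newick_tree, Path) or (
        isinstance(newick_tree, str)
        and "(" not in newick_tree
        and Path(newick_tree).exists()
    ):
        return dendropy.Tree.get(
            path=str(newick_tree), schema="newick", preserve_underscores=True
        )
    return dendropy.Tree.get(
        data=str(newick_tree), schema="newick", preserve_underscores=True
    )


# ---------------------------------------------------------------------------
# model building and calibration

def build_profile_from_members(
    family_id: str, aligned_members: Sequence[tuple[str, str]]
) -> pyhmmer.plan7.HMM:
    """Build a profile HMM from an aligned training set (pyhmmer Builder)."""
    if not aligned_members:
        raise CurationError("cannot build a profile from zero sequences")
    alphabet = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=family_id.encode(),
        sequences=[
            pyhmmer.easel.TextSequence(name=rid.encode(), sequence=seq)
            for rid, seq in aligned_members
        ],
    )
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
    return hmm


def profile_engine(model: pyhmmer.plan7.HMM) -> Callable[[Mapping[str, str]], dict[str, float]]:
    """Engine closure scoring sequences against a profile HMM."""

    def engine(sequences: Mapping[str, str]) -> dict[str, float]:
        hits = run_profile_search(sequences, {"_model": model})
        return {h.gene_id: h.bitscore for h in hits}

    return engine


def similarity_engine(
    representatives: Mapping[str, str],
) -> Callable[[Mapping[str, str]], dict[str, float]]:
    """Engine closure scoring sequences against a representative set."""

    def engine(sequences: Mapping[str, str]) -> dict[str, float]:
        hits = run_similarity_search(sequences, {"_model": representatives})
        return {h.gene_id: h.bitscore for h in hits}

    return engine


def calibrate_thresholds(
    model,
    curation_input: CurationInput,
    training_clade_members: Mapping[str, str],
    search_engine: Callable[[Mapping[str, str]], dict[str, float]] | None = None,
) -> CalibrationResult:
    """Derive A/B thresholds by scoring every sequence class against the model.

    The model must have been built from ``training_clade_members`` only, so
    the seeds act as a genuine hold-out. Rules:

    * ``score_A`` = minimum bitscore over seed sequences; a seed with no
      reported hit, or any seed at or below the decoy ceiling, fails the
      calibration outright.
    * ``score_B`` = minimum bitscore over in-clade seed homologs, accepted
      only when strictly above the decoy ceiling and strictly below
      ``score_A``; otherwise the family ships A-only.
    * decoy ceiling = maximum bitscore over decoys and decoy homologs
      (0 when nothing in the decoy class is even reported).
    """
    if search_engine is None:
        if isinstance(model, pyhmmer.plan7.HMM):
            search_engine = profile_engine(model)
        else:
            search_engine = similarity_engine(model)

    rows: list[dict] = []

    def score_class(seqs: Mapping[str, str], cls: str) -> list[float]:
        scores = search_engine(seqs) if seqs else {}
        out = []
        for sid in sorted(seqs):
            s = scores.get(sid)
            rows.append(
                {"id": sid, "class": cls, "bitscore": float("nan") if s is None else s}
            )
            if s is not None:
                out.append(s)
        return out

    seed_scores = score_class(curation_input.seed_sequences, SEED)
    homolog_scores = score_class(dict(training_clade_members), SEED_HOMOLOG)
    decoy_scores = score_class(curation_input.decoy_sequences, DECOY)
    decoy_h_scores = score_class(curation_input.decoy_homologs, DECOY_HOMOLOG)

    table = pd.DataFrame(rows, columns=["id", "class", "bitscore"])
    decoy_ceiling = max(decoy_scores + decoy_h_scores, default=0.0)

    n_seeds = len(curation_input.seed_sequences)
    if len(seed_scores) < n_seeds:
        return CalibrationResult(
            curation_input.family_id, float("nan"), None, decoy_ceiling, table,
            failed=True, failure_reason="one or more seeds not recognized by the model",
        )
    score_A = min(seed_scores)
    if score_A <= decoy_ceiling:
        return CalibrationResult(
            curation_input.family_id, score_A, None, decoy_ceiling, table,
            failed=True,
            failure_reason=(
                f"minimum seed bitscore {score_A:.1f} does not exceed the "
                f"decoy ceiling {decoy_ceiling:.1f}"
            ),
        )
    score_B: float | None = None
    if homolog_scores:
        candidate = min(homolog_scores)
        if (
            len(homolog_scores) == len(training_clade_members)
            and candidate > decoy_ceiling
            and candidate < score_A
        ):
            score_B = candidate
    return CalibrationResult(
        curation_input.family_id, score_A, score_B, decoy_ceiling, table
    )
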