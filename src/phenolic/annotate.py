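"""Profile and similarity searches with two-tier (A/B) rank assignment.

Two search engines feed one ranking rule. Profile families are searched with
HMMER (via pyhmmer) against HMMER3 profiles; similarity families are searched
by local pairwise alignment (BLOSUM62, affine gaps) against each family's
representative sequences, keeping the best bitscore per (gene, family).

Ranking compares each hit's bitscore against the family's calibrated
thresholds, inclusively: ``bitscore >= score_A`` is rank A (high confidence);
otherwise ``score_B <= bitscore < score_A`` is rank B (high recall);
everything else is dropped. Inclusivity at A follows from A being defined as
the minimum bitscore over held-out seed sequences — the weakest seed itself
must annotate at rank A.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pyhmmer
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .db import Database

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1),
# used to express raw local-alignment scores in bits
_KA_LAMBDA = 0.267
_KA_K = 0.041
_LN2 = math.log(2.0)

#: raw hits below this many bits are not reported by the similarity engine;
#: ranking alone decides inclusion in Annotations above the floor
DEFAULT_REPORT_FLOOR_BITS = 25.0

RANK_A = "A"
RANK_B = "B"


@dataclass(frozen=True)
class RawHit:
    """One engine hit: a gene matched a family model with some bitscore."""

    gene_id: str
    family_id: str
    bitscore: float
    evalue: float | None = None
    query_span: tuple[int, int] | None = None  # 1-based inclusive on the protein


@dataclass(frozen=True)
class Annotation:
    gene_id: str
    family_id: str
    bitscore: float
    rank: str


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sequence input

def read_protein_fasta(source: str | Path | io.TextIOBase) -> dict[str, str]:
    """Read amino-acid FASTA into an ordered id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in records:
            raise AnnotationError(f"duplicate sequence id {rec.id!r} in FASTA")
        records[rec.id] = str(rec.seq).upper()
    return records


# ---------------------------------------------------------------------------
# profile search (HMMER)

def run_profile_search(
    proteins: Mapping[str, str] | str | Path,
    profile_models: Mapping[str, pyhmmer.plan7.HMM | str | Path],
) -> list[RawHit]:
    """Search every protein against every profile model.

    Parameters
    ----------
    proteins:
        id -> amino-acid sequence mapping, or a path to a protein FASTA.
    profile_models:
        family_id -> HMM mapping; values may be in-memory pyhmmer HMMs or
        paths to HMMER3 text files (first profile in the file is used).

    Returns one :class:`RawHit` per (gene, family) with a reported match;
    genes with no hit are simply absent.
    """
    if not isinstance(proteins, Mapping):
        proteins = read_protein_fasta(proteins)
    alphabet = pyhmmer.easel.Alphabet.amino()
    digital = [
        pyhmmer.easel.TextSequence(name=gid.encode(), sequence=seq).digitize(alphabet)
        for gid, seq in proteins.items()
    ]
    hits_out: list[RawHit] = []
    if not digital:
        return hits_out
    pipeline = pyhmmer.plan7.Pipeline(alphabet)
    for family_id in sorted(profile_models):
        hmm = _as_hmm(profile_models[family_id], family_id)
        pipeline.clear()
        top = pipeline.search_hmm(hmm, pyhmmer.easel.DigitalSequenceBlock(alphabet, digital))
        for hit in top:
            if not hit.reported:
                continue
            best_dom = hit.best_domain
            span = None
            if best_dom is not None:
                ali = best_dom.alignment
                span = (ali.target_from, ali.target_to)
            hits_out.append(
                RawHit(
                    gene_id=hit.name if isinstance(hit.name, str) else hit.name.decode(),
                    family_id=family_id,
                    bitscore=float(hit.score),
                    evalue=float(hit.evalue),
                    query_span=span,
                )
            )
    return hits_out


def _as_hmm(model, family_id: str) -> pyhmmer.plan7.HMM:
    if isinstance(model, pyhmmer.plan7.HMM):
        return model
    try:
        with pyhmmer.plan7.HMMFile(str(model)) as fh:
            return fh.read()
    except Exception as exc:  # corrupt or unreadable artifact
        raise AnnotationError(
            f"cannot load profile model for family {family_id!r}: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# similarity search (local pairwise alignment)

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def raw_to_bits(raw_score: float) -> float:
    """Karlin-Altschul conversion of a raw alignment score to bits."""
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / _LN2


def run_similarity_search(
    proteins: Mapping[str, str] | str | Path,
    family_sequence_sets: Mapping[str, Mapping[str, str]],
    report_floor_bits: float = DEFAULT_REPORT_FLOOR_BITS,
) -> list[RawHit]:
    """Best local-alignment bitscore of each gene against each family.

    Each family supplies a set of representative sequences; the hit recorded
    for a (gene, family) pair is the maximum bitscore over representatives.
    Hits below ``report_floor_bits`` are not reported.
    """
    if not isinstance(proteins, Mapping):
        proteins = read_protein_fasta(proteins)
    aligner = _make_aligner()
    allowed = set(str(aligner.substitution_matrix.alphabet))
    hits_out: list[RawHit] = []
    for family_id in sorted(family_sequence_sets):
        reps = family_sequence_sets[family_id]
        for gene_id, seq in proteins.items():
            qseq = "".join(c if c in allowed else "X" for c in seq)
            best_bits = -math.inf
            best_rep = None
            for rep_id in sorted(reps):
                rseq = "".join(c if c in allowed else "X" for c in reps[rep_id].upper())
                if not qseq or not rseq:
                    continue
                bits = raw_to_bits(aligner.score(qseq, rseq))
                if bits > best_bits:
                    best_bits = bits
                    best_rep = rseq
            if best_rep is None or best_bits < report_floor_bits:
                continue
            aln = aligner.align(qseq, best_rep)[0]
            blocks = aln.aligned[0]
            span = (int(blocks[0][0]) + 1, int(blocks[-1][1])) if len(blocks) else None
            hits_out.append(
                RawHit(
                    gene_id=gene_id,
                    family_id=family_id,
                    bitscore=best_bits,
                    evalue=None,
                    query_span=span,
                )
            )
    return hits_out


def self_alignment_bits(sequence: str) -> float:
    """Bitscore of a sequence aligned to itself (identity ceiling)."""
    aligner = _make_aligner()
    return raw_to_bits(aligner.score(sequence, sequence))


# ---------------------------------------------------------------------------
# ranking

def assign_ranks(raw_hits: Iterable[RawHit], db: Database) -> list[Annotation]:
    """Apply each family's A/B thresholds to its hits (inclusive comparisons).

    Multiple hits of one gene to one family are collapsed to the maximum
    bitscore before ranking. Hits below every threshold are dropped. Output
    order is deterministic (gene_id, family_id), independent of input order.
    """
    best: dict[tuple[str, str], float] = {}
    for hit in raw_hits:
        if hit.family_id not in db.families:
            raise AnnotationError(f"hit references unknown family {hit.family_id!r}")
        if not math.isfinite(hit.bitscore):
            raise AnnotationError(
                f"non-finite bitscore for gene {hit.gene_id!r} / family {hit.family_id!r}"
            )
        key = (hit.gene_id, hit.family_id)
        if key not in best or hit.bitscore > best[key]:
            best[key] = hit.bitscore
    annotations = []
    for (gene_id, family_id) in sorted(best):
        score = best[(gene_id, family_id)]
        fam = db.families[family_id]
        if score >= fam.score_A:
            rank = RANK_A
        elif fam.score_B is not None and score >= fam.score_B:
            rank = RANK_B
        else:
            continue
        annotations.append(Annotation(gene_id, family_id, score, rank))
    return annotations


def best_annotation_per_gene(
    annotations: Iterable[Annotation],
) -> dict[str, Annotation]:
    """Summarize to one annotation per gene.

    Preference order: rank A over rank B, then higher bitscore, then
    lexicographically smaller family_id. The long-form annotation list is the
    authoritative record; this summary is a convenience view.
    """
    best: dict[str, Annotation] = {}
    for ann in annotations:
        cur = best.get(ann.gene_id)
        if cur is None or _pref_key(ann) < _pref_key(cur):
            best[ann.gene_id] = ann
    return best


def _pref_key(ann: Annotation) -> tuple:
    return (0 if ann.rank == RANK_A else 1, -ann.bitscore, ann.family_id)


# ---------------------------------------------------------------------------
# tabular output

def annotations_to_frame(annotations: Sequence[Annotation]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "family_id": a.family_id,
                "bitscore": a.bitscore,
                "rank": a.rank,
            }
            for a in annotations
        ],
        columns=["gene_id", "family_id", "bitscore", "rank"],
    )
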