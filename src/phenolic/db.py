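"""Annotation database: gene families, substrate ontology, transformation pathways.

The database is the unit that makes polyphenol annotation portable: each
:class:`GeneFamily` carries its own two-tier bitscore thresholds (a
high-confidence "A" score and an optional high-recall "B" score) plus the
substrate-ontology terms it maps to, and each :class:`PathwayDef` aggregates
families into an ordered series of reaction steps labelled by oxygen
dependence and trophic level (polymeric polyphenol, monomeric polyphenol,
phenolic/benzoic acid).

On disk the database is three flat, diffable TSV tables (``families.tsv``,
``ontology.tsv``, ``pathways.tsv``) next to a ``models/`` directory of search
artifacts (HMMER3 text profiles or representative-sequence FASTA) keyed by
``model_ref``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

PROFILE_HMM = "profile_hmm"
SEQUENCE_SIMILARITY = "sequence_similarity"
SEARCH_METHODS = (PROFILE_HMM, SEQUENCE_SIMILARITY)

TROPHIC_LEVELS = ("polymer", "monomer", "phenolic_benzoic")
OXYGEN_CLASSES = ("oxic", "anoxic")

FAMILY_COLUMNS = [
    "family_id",
    "label",
    "search_method",
    "score_A",
    "score_B",
    "substrate_terms",
    "notes",
    "model_ref",
]
ONTOLOGY_COLUMNS = ["term_id", "name", "parent_term_id"]
PATHWAY_COLUMNS = ["pathway_id", "name", "trophic_level", "oxygen", "steps"]

STEP_SEP = ";"
ALT_SEP = "|"
TERM_SEP = ";"


class DatabaseError(ValueError):
    """Fatal structural problem with an annotation database."""


@dataclass(frozen=True)
class GeneFamily:
    """One searchable annotation unit with its calibrated thresholds.

    ``score_A`` is the precision threshold (lowest bitscore of a held-out
    characterized seed sequence); ``score_B``, when present, is the recall
    threshold, constrained above every decoy score during calibration.
    Families imported from databases that publish a single cutoff store it as
    ``score_A`` with ``score_B`` absent.
    """

    family_id: str
    label: str
    search_method: str
    score_A: float
    score_B: float | None = None
    substrate_terms: tuple[str, ...] = ()
    notes: str = ""
    model_ref: str = ""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    parent_term_id: str | None = None


@dataclass(frozen=True)
class PathwayDef:
    """An ordered chain of reaction steps, each satisfiable by alternatives.

    ``steps`` is a tuple of frozensets of family ids: a genome satisfies a
    step if it carries an annotation to any family in that step's set.
    """

    pathway_id: int
    name: str
    trophic_level: str
    oxygen: str
    steps: tuple[frozenset[str], ...]


@dataclass
class Database:
    families: dict[str, GeneFamily] = field(default_factory=dict)
    ontology: dict[str, OntologyTerm] = field(default_factory=dict)
    pathways: dict[int, PathwayDef] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Database):
            return NotImplemented
        return (
            self.families == other.families
            and self.ontology == other.ontology
            and self.pathways == other.pathways
        )


# ---------------------------------------------------------------------------
# validation

def validate_database(db: Database) -> list[str]:
    """Return all invariant violations, each naming the entity and the rule.

    An empty list means the database is internally consistent: thresholds
    ordered (0 < score_B < score_A), ontology parent links acyclic, and every
    cross-table reference resolving.
    """
    violations: list[str] = []
    for fid, fam in db.families.items():
        if fid != fam.family_id:
            violations.append(f"family {fid!r}: key does not match family_id")
        if fam.search_method not in SEARCH_METHODS:
            violations.append(
                f"family {fid!r}: unknown search_method {fam.search_method!r}"
            )
        if not (math.isfinite(fam.score_A) and fam.score_A > 0):
            violations.append(f"family {fid!r}: score_A must be finite and > 0")
        if fam.score_B is not None:
            if not math.isfinite(fam.score_B):
                violations.append(f"family {fid!r}: score_B must be finite")
            elif fam.score_B >= fam.score_A:
                violations.append(f"family {fid!r}: score_B must be < score_A")
        for term in fam.substrate_terms:
            if term not in db.ontology:
                violations.append(
                    f"family {fid!r}: unresolved substrate term {term!r}"
                )
    for tid, term in db.ontology.items():
        if term.parent_term_id is not None and term.parent_term_id not in db.ontology:
            violations.append(
                f"ontology term {tid!r}: unresolved parent {term.parent_term_id!r}"
            )
    violations.extend(_ontology_cycles(db.ontology))
    for pid, pw in db.pathways.items():
        if len(pw.steps) < 1:
            violations.append(f"pathway {pid}: must have at least one step")
        if pw.trophic_level not in TROPHIC_LEVELS:
            violations.append(
                f"pathway {pid}: unknown trophic_level {pw.trophic_level!r}"
            )
        if pw.oxygen not in OXYGEN_CLASSES:
            violations.append(f"pathway {pid}: unknown oxygen class {pw.oxygen!r}")
        for i, step in enumerate(pw.steps):
            if not step:
                violations.append(f"pathway {pid}: step {i + 1} is empty")
            for fid in step:
                if fid not in db.families:
                    violations.append(
                        f"pathway {pid}: step {i + 1} references unknown family {fid!r}"
                    )
    return violations


def _ontology_cycles(ontology: dict[str, OntologyTerm]) -> list[str]:
    violations = []
    # walk parent pointers from every term; a revisit closes a cycle, which is
    # reported once, attributed to its lexicographically smallest member
    for tid in ontology:
        path: list[str] = []
        index: dict[str, int] = {}
        cur: str | None = tid
        while cur is not None and cur in ontology:
            if cur in index:
                cycle = path[index[cur]:]
                if tid == min(cycle):
                    violations.append(
                        f"ontology term {tid!r}: cyclic parent chain "
                        f"({' -> '.join(cycle + [cur])})"
                    )
                break
            index[cur] = len(path)
            path.append(cur)
            cur = ontology[cur].parent_term_id
    return violations


# ---------------------------------------------------------------------------
# on-disk format

def _check_id(value: str, what: str) -> str:
    if "\t" in value or "\n" in value:
        raise DatabaseError(f"{what} {value!r} contains a tab or newline")
    return value


def write_database(db: Database, root_path: str | Path) -> None:
    """Write the three TSV tables with byte-stable, id-sorted row order."""
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    fam_rows = []
    for fid in sorted(db.families):
        fam = db.families[fid]
        _check_id(fam.family_id, "family_id")
        for t in fam.substrate_terms:
            _check_id(t, "substrate term")
        fam_rows.append(
            {
                "family_id": fam.family_id,
                "label": fam.label,
                "search_method": fam.search_method,
                "score_A": repr(fam.score_A),
                "score_B": "" if fam.score_B is None else repr(fam.score_B),
                "substrate_terms": TERM_SEP.join(fam.substrate_terms),
                "notes": fam.notes,
                "model_ref": fam.model_ref,
            }
        )
    ont_rows = []
    for tid in sorted(db.ontology):
        term = db.ontology[tid]
        _check_id(term.term_id, "term_id")
        ont_rows.append(
            {
                "term_id": term.term_id,
                "name": term.name,
                "parent_term_id": term.parent_term_id or "",
            }
        )
    pw_rows = []
    for pid in sorted(db.pathways):
        pw = db.pathways[pid]
        for step in pw.steps:
            for fid in step:
                _check_id(fid, "family_id")
        pw_rows.append(
            {
                "pathway_id": str(pw.pathway_id),
                "name": pw.name,
                "trophic_level": pw.trophic_level,
                "oxygen": pw.oxygen,
                "steps": STEP_SEP.join(
                    ALT_SEP.join(sorted(step)) for step in pw.steps
                ),
            }
        )
    _write_tsv(root / "families.tsv", FAMILY_COLUMNS, fam_rows)
    _write_tsv(root / "ontology.tsv", ONTOLOGY_COLUMNS, ont_rows)
    _write_tsv(root / "pathways.tsv", PATHWAY_COLUMNS, pw_rows)


def _write_tsv(path: Path, columns: list[str], rows: list[dict]) -> None:
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(row[c] for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_database(root_path: str | Path) -> Database:
    """Load and cross-validate the three TSV tables under ``root_path``.

    Raises :class:`DatabaseError` naming the missing table, or listing every
    referential-integrity violation at once.
    """
    root = Path(root_path)
    tables = {}
    for name in ("families", "ontology", "pathways"):
        path = root / f"{name}.tsv"
        if not path.exists():
            raise DatabaseError(f"missing database table: {name}.tsv")
        tables[name] = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False
        )
    db = Database()
    for _, row in tables["ontology"].iterrows():
        term = OntologyTerm(
            term_id=row["term_id"],
            name=row["name"],
            parent_term_id=row["parent_term_id"] or None,
        )
        db.ontology[term.term_id] = term
    for _, row in tables["families"].iterrows():
        fam = GeneFamily(
            family_id=row["family_id"],
            label=row["label"],
            search_method=row["search_method"],
            score_A=float(row["score_A"]),
            score_B=float(row["score_B"]) if row["score_B"] != "" else None,
            substrate_terms=tuple(
                t for t in row["substrate_terms"].split(TERM_SEP) if t
            ),
            notes=row["notes"],
            model_ref=row["model_ref"],
        )
        db.families[fam.family_id] = fam
    for _, row in tables["pathways"].iterrows():
        steps = tuple(
            frozenset(alt for alt in step.split(ALT_SEP) if alt)
            for step in row["steps"].split(STEP_SEP)
            if step
        )
        pw = PathwayDef(
            pathway_id=int(row["pathway_id"]),
            name=row["name"],
            trophic_level=row["trophic_level"],
            oxygen=row["oxygen"],
            steps=steps,
        )
        db.pathways[pw.pathway_id] = pw
    violations = validate_database(db)
    if violations:
        raise DatabaseError(
            "invalid database:\n" + "\n".join(f"  - {v}" for v in violations)
        )
    return db


def make_database(
    families: Iterable[GeneFamily],
    ontology: Iterable[OntologyTerm] = (),
    pathways: Iterable[PathwayDef] = (),
) -> Database:
    """Assemble and validate a :class:`Database` from component records."""
    db = Database(
        families={f.family_id: f for f in families},
        ontology={t.term_id: t for t in ontology},
        pathways={p.pathway_id: p for p in pathways},
    )
    violations = validate_database(db)
    if violations:
        raise DatabaseError(
            "invalid database:\n" + "\n".join(f"  - {v}" for v in violations)
        )
    return db
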