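"""Deterministic synthetic-data generators with planted ground truth.

Every analysis module in this package is testable offline against data whose
correct answer is known by construction:

* protein families built from a motif-plus-scaffold design, where seeds,
  seed homologs, decoys and decoy homologs diverge from family base
  sequences at controlled substitution rates — profile and similarity
  searches separate the classes with a margin that is *verified during
  generation* (generation fails loudly if seeds stop self-recognizing or a
  decoy breaches the margin);
* family phylogenies with a planted in-clade homolog set, for exercising
  decoy-rooted clade extraction;
* genome gene tables hitting exact pathway-completeness targets;
* negative-binomial count matrices over a 3 habitats x 3 depths x 3
  replicates layout with planted talented and dominant genera;
* FT-ICR-MS formula tables sampled inside (or outside) the refined Van
  Krevelen regions.

Every generator is a pure function of its spec and seed: the same inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import db as dbmod
from .annotate import Annotation, RANK_A
from .curation import build_profile_from_members, profile_engine, similarity_engine
from .db import Database, GeneFamily, OntologyTerm, PathwayDef, make_database
from .distill import GenomeAnnotation
from .vankrevelen import ClassBoundaries, DEFAULT_BOUNDARIES, NONE_CLASS, classify

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

HABITATS = ("palsa", "bog", "fen")
DEPTHS = ("surface", "middle", "deep")

#: which (habitat, depth) strata sit at or below the water table: the palsa
#: is elevated and dry, the bog is saturated below its surface, the fen is
#: inundated throughout
SATURATED_STRATA = frozenset(
    [("bog", "middle"), ("bog", "deep"), ("fen", "surface"), ("fen", "middle"), ("fen", "deep")]
)


class FixtureGenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# protein families

@dataclass(frozen=True)
class FamilyFixtureSpec:
    n_families: int = 2
    n_seeds: int = 4
    n_homologs: int = 8
    n_decoys: int = 4
    n_decoy_homologs: int = 4
    scaffold_len: int = 150
    motif_len: int = 40
    seed_divergence: float = 0.05
    homolog_divergence: float = 0.15
    decoy_divergence: float = 0.5
    min_margin_bits: float = 20.0  # required gap: min seed score - max decoy score


@dataclass
class ProteinFamilyFixture:
    family_id: str
    seeds: dict[str, str]
    homologs: dict[str, str]
    decoys: dict[str, str]
    decoy_homologs: dict[str, str]
    truth: pd.DataFrame  # id, class, profile_bits, similarity_bits
    profile_margin: float
    similarity_margin: float

    def all_sequences(self) -> dict[str, str]:
        return {**self.seeds, **self.homologs, **self.decoys, **self.decoy_homologs}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    chars[hit] = rng.choice(AMINO_ACIDS, size=int(hit.sum()))
    return "".join(chars)


def make_protein_families(
    spec: FamilyFixtureSpec, seed: int
) -> list[ProteinFamilyFixture]:
    """Generate motif-bearing families whose classes are score-separable.

    For each family, a base sequence (scaffold + functional motif) spawns
    seeds and homologs at low/medium substitution rates; decoys keep the
    scaffold at high divergence with the motif replaced, making them related
    but functionally distinct. A profile built from the homologs and a
    similarity search against them must both separate the minimum seed score
    from the maximum decoy-class score by ``min_margin_bits``.
    """
    rng = np.random.default_rng(seed)
    fixtures = []
    for fi in range(spec.n_families):
        fam = f"fam{fi:03d}"
        scaffold = _random_seq(rng, spec.scaffold_len)
        motif = _random_seq(rng, spec.motif_len)
        decoy_motif = _random_seq(rng, spec.motif_len)
        half = spec.scaffold_len // 2
        base = scaffold[:half] + motif + scaffold[half:]
        decoy_base = (
            _mutate(rng, scaffold[:half], spec.decoy_divergence)
            + decoy_motif
            + _mutate(rng, scaffold[half:], spec.decoy_divergence)
        )
        seeds = {
            f"{fam}_seed{i}": _mutate(rng, base, spec.seed_divergence)
            for i in range(spec.n_seeds)
        }
        homologs = {
            f"{fam}_hom{i}": _mutate(rng, base, spec.homolog_divergence)
            for i in range(spec.n_homologs)
        }
        decoys = {
            f"{fam}_dec{i}": _mutate(rng, decoy_base, spec.seed_divergence)
            for i in range(spec.n_decoys)
        }
        decoy_homologs = {
            f"{fam}_dech{i}": _mutate(rng, decoy_base, spec.homolog_divergence)
            for i in range(spec.n_decoy_homologs)
        }
        fixture = _verify_family(
            fam, seeds, homologs, decoys, decoy_homologs, spec.min_margin_bits
        )
        fixtures.append(fixture)
    return fixtures


def _verify_family(
    family_id, seeds, homologs, decoys, decoy_homologs, min_margin
) -> ProteinFamilyFixture:
    hmm = build_profile_from_members(
        family_id, sorted(homologs.items())
    )
    p_engine = profile_engine(hmm)
    s_engine = similarity_engine(homologs)
    classes = [
        ("seed", seeds),
        ("seed_homolog", homologs),
        ("decoy", decoys),
        ("decoy_homolog", decoy_homologs),
    ]
    rows = []
    for cls, seqs in classes:
        p_scores = p_engine(seqs)
        s_scores = s_engine(seqs)
        for sid in sorted(seqs):
            rows.append(
                {
                    "id": sid,
                    "class": cls,
                    "profile_bits": p_scores.get(sid, 0.0),
                    "similarity_bits": s_scores.get(sid, 0.0),
                }
            )
    truth = pd.DataFrame(rows)
    margins = {}
    for col in ("profile_bits", "similarity_bits"):
        seed_min = truth.loc[truth["class"] == "seed", col].min()
        decoy_max = truth.loc[
            truth["class"].isin(["decoy", "decoy_homolog"]), col
        ].max()
        margins[col] = float(seed_min - decoy_max)
        if margins[col] < min_margin:
            raise FixtureGenerationError(
                f"family {family_id}: {col} margin {margins[col]:.1f} bits "
                f"below required {min_margin:.1f}; divergence too high for "
                "seeds to self-recognize cleanly"
            )
    return ProteinFamilyFixture(
        family_id, seeds, homologs, decoys, decoy_homologs, truth,
        profile_margin=margins["profile_bits"],
        similarity_margin=margins["similarity_bits"],
    )


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in sequences:
            fh.write(f">{sid}\n{sequences[sid]}\n")


# ---------------------------------------------------------------------------
# family phylogenies with planted clade structure

def _random_subtree(rng: np.random.Generator, labels: list[str]) -> str:
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    left = list(labels[:k])
    right = list(labels[k:])
    return f"({_random_subtree(rng, left)},{_random_subtree(rng, right)})"


def make_clade_tree(
    seed: int,
    n_seeds: int = 3,
    n_inclade: int = 3,
    n_outclade: int = 2,
    n_decoys: int = 3,
) -> tuple[str, dict]:
    """Random tree with a planted seed clade, outside homologs and decoys.

    The seed MRCA (after decoy rooting) contains exactly the seeds plus the
    in-clade homologs; out-of-clade homologs branch between that clade and
    the decoy clade. Returns ``(newick, truth)`` where truth lists seed ids,
    decoy-class ids and the planted in-clade homolog set the extraction must
    recover.
    """
    if n_seeds < 2:
        raise ValueError("need >= 2 seeds to define a seed clade")
    rng = np.random.default_rng(seed)
    seeds = [f"s{i}" for i in range(n_seeds)]
    inclade = [f"h{i}" for i in range(n_inclade)]
    outclade = [f"o{i}" for i in range(n_outclade)]
    decoys = [f"d{i}" for i in range(n_decoys)]

    # each side of the seed-clade root must hold a seed so the MRCA of the
    # seeds is the whole clade
    k = int(rng.integers(1, n_seeds))
    left = seeds[:k] + [h for h in inclade if rng.random() < 0.5]
    right = seeds[k:] + [h for h in inclade if h not in left]
    rng.shuffle(left)
    rng.shuffle(right)
    seed_clade = f"({_random_subtree(rng, left)},{_random_subtree(rng, right)})"
    ingroup = seed_clade
    for o in outclade:  # grade outside homologs onto the path above the clade
        ingroup = f"({ingroup},{o})"
    decoy_clade = (
        _random_subtree(rng, list(decoys)) if n_decoys > 1 else decoys[0]
    )
    newick = f"({ingroup},{decoy_clade});"
    truth = {
        "seed_ids": set(seeds),
        "decoy_ids": set(decoys),
        "inclade_homologs": set(inclade),
        "outclade_homologs": set(outclade),
    }
    return newick, truth


# ---------------------------------------------------------------------------
# miniature annotation database

def make_fixture_db(
    n_pathways: int = 20,
    steps_per_pathway: int = 2,
    score_A: float = 200.0,
    score_B: float = 120.0,
) -> Database:
    """A miniature annotation database: one family per pathway step.

    Trophic levels are assigned in three contiguous blocks of pathways
    (polymer, monomer, phenolic/benzoic); oxygen classes alternate.
    """
    terms = [OntologyTerm("T:polyphenol", "polyphenol substrate", None)]
    families = []
    pathways = []
    third = -(-n_pathways // 3)
    for p in range(1, n_pathways + 1):
        trophic = dbmod.TROPHIC_LEVELS[min((p - 1) // third, 2)]
        steps = []
        for s in range(steps_per_pathway):
            fid = f"P{p:03d}S{s}"
            families.append(
                GeneFamily(
                    family_id=fid,
                    label=f"pathway {p} step {s + 1} enzyme",
                    search_method=dbmod.SEQUENCE_SIMILARITY,
                    score_A=score_A,
                    score_B=score_B,
                    substrate_terms=("T:polyphenol",),
                    model_ref=f"models/{fid}.faa",
                )
            )
            steps.append(frozenset([fid]))
        pathways.append(
            PathwayDef(
                pathway_id=p,
                name=f"transformation {p}",
                trophic_level=trophic,
                oxygen=dbmod.OXYGEN_CLASSES[p % 2],
                steps=tuple(steps),
            )
        )
    return make_database(families, terms, pathways)


# ---------------------------------------------------------------------------
# genomes with exact completeness targets

def make_genomes(
    db: Database,
    completeness_targets: dict[str, dict[int, float]],
    genus_map: dict[str, str] | None = None,
) -> list[GenomeAnnotation]:
    """Genomes whose annotations satisfy exactly the requested fractions.

    ``completeness_targets`` maps genome id -> {pathway id -> fraction}; a
    fraction that is not a multiple of 1/n_steps is rejected. Annotated
    genes are named ``<genome>|<family>`` and scored 10 bits above the
    family's A threshold.
    """
    genomes = []
    for genome_id in sorted(completeness_targets):
        gene_ids: set[str] = set()
        annotations: list[Annotation] = []
        for pid, frac in sorted(completeness_targets[genome_id].items()):
            pw = db.pathways[pid]
            n_steps = len(pw.steps)
            n_sat = frac * n_steps
            if abs(n_sat - round(n_sat)) > 1e-9:
                raise FixtureGenerationError(
                    f"completeness {frac} not representable on a "
                    f"{n_steps}-step pathway"
                )
            for step in pw.steps[: int(round(n_sat))]:
                fid = sorted(step)[0]
                gid = f"{genome_id}|{fid}"
                gene_ids.add(gid)
                annotations.append(
                    Annotation(gid, fid, db.families[fid].score_A + 10.0, RANK_A)
                )
        genus = (genus_map or {}).get(genome_id, genome_id)
        genomes.append(GenomeAnnotation(genome_id, genus, gene_ids, annotations))
    return genomes


# ---------------------------------------------------------------------------
# count matrices with planted talent/dominance

@dataclass(frozen=True)
class CountFixtureSpec:
    n_background_genera: int = 24
    background_pathways_per_genus: int = 6
    background_mean: float = 30.0
    talented_genus: str = "g_talented"
    talented_habitat: str = "bog"
    talented_n_pathways: int = 18
    talented_mean: float = 15.0
    dominant_genus: str = "g_dominant"
    dominant_trophic: str = "monomer"
    dominant_habitat: str = "fen"
    dominant_mean: float = 200.0
    nb_dispersion: float = 10.0
    replicates: int = 3
    n_pathways: int = 20
    steps_per_pathway: int = 2


@dataclass
class CountFixture:
    db: Database
    genomes: list[GenomeAnnotation]
    counts: pd.DataFrame
    gene_lengths: pd.Series
    metadata: pd.DataFrame
    truth: dict


def _nb(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def make_counts(spec: CountFixtureSpec, seed: int) -> CountFixture:
    """Count matrix over 3 habitats x 3 depths x replicates with planted truth.

    Background genera each encode a rotating set of pathways and express them
    everywhere at a modest mean, so no background genus approaches either
    metric threshold. The talented genus encodes and expresses
    ``talented_n_pathways`` pathways only in its habitat at a deliberately low
    per-gene mean (so it stays below the dominance threshold); the dominant
    genus expresses every pathway of one trophic level in one habitat at a
    high mean (far above the 10% share threshold, but across fewer pathways
    than the talent threshold).
    """
    rng = np.random.default_rng(seed)
    db = make_fixture_db(spec.n_pathways, spec.steps_per_pathway)
    trophic_of = {p: db.pathways[p].trophic_level for p in db.pathways}
    troph_pids = {
        t: sorted(p for p in db.pathways if trophic_of[p] == t)
        for t in dbmod.TROPHIC_LEVELS
    }

    targets: dict[str, dict[int, float]] = {}
    genus_map: dict[str, str] = {}
    for i in range(spec.n_background_genera):
        gname = f"g_bg{i:02d}"
        gid = f"mag_bg{i:02d}"
        # stride-7 assignment spreads each genus's pathways across the three
        # trophic blocks, so no background genus concentrates in one level
        pids = sorted(
            {
                (i + 7 * j) % spec.n_pathways + 1
                for j in range(spec.background_pathways_per_genus)
            }
        )
        targets[gid] = {p: 1.0 for p in pids}
        genus_map[gid] = gname
    tal_gid = "mag_talented"
    targets[tal_gid] = {p: 1.0 for p in range(1, spec.talented_n_pathways + 1)}
    genus_map[tal_gid] = spec.talented_genus
    dom_gid = "mag_dominant"
    targets[dom_gid] = {p: 1.0 for p in troph_pids[spec.dominant_trophic]}
    genus_map[dom_gid] = spec.dominant_genus
    genomes = make_genomes(db, targets, genus_map)

    samples = [
        f"{h}_{d}_r{r + 1}"
        for h in HABITATS
        for d in DEPTHS
        for r in range(spec.replicates)
    ]
    metadata = pd.DataFrame(
        [
            {
                "sample_id": f"{h}_{d}_r{r + 1}",
                "habitat": h,
                "depth": d,
                "saturation": "saturated" if (h, d) in SATURATED_STRATA else "unsaturated",
                "replicate": f"r{r + 1}",
            }
            for h in HABITATS
            for d in DEPTHS
            for r in range(spec.replicates)
        ]
    ).set_index("sample_id")

    gene_rows = []
    for genome in genomes:
        for gid in sorted(genome.gene_ids):
            gene_rows.append((gid, genome.genus))
    gene_ids = [g for g, _ in gene_rows]
    # typical microbial CDS lengths; a narrow band keeps RPK weighting from
    # dominating the planted expression structure
    lengths = pd.Series(
        rng.integers(800, 1200, size=len(gene_ids)), index=gene_ids, name="length_bp"
    )

    counts = np.zeros((len(gene_ids), len(samples)), dtype=int)
    habitat_of = metadata["habitat"].to_dict()
    for gi, (gid, genus) in enumerate(gene_rows):
        if genus == spec.talented_genus:
            means = [
                spec.talented_mean if habitat_of[s] == spec.talented_habitat else 0.0
                for s in samples
            ]
        elif genus == spec.dominant_genus:
            means = [
                spec.dominant_mean if habitat_of[s] == spec.dominant_habitat else 0.0
                for s in samples
            ]
        else:
            means = [spec.background_mean] * len(samples)
        counts[gi] = [
            _nb(rng, m, spec.nb_dispersion, 1)[0] for m in means
        ]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)

    truth = {
        "talented_genera": {spec.talented_genus},
        "dominant_genera": {spec.dominant_genus},
        "talented_habitat": spec.talented_habitat,
        "dominant_key": (spec.dominant_trophic, spec.dominant_habitat),
        "genus_of_genome": genus_map,
    }
    return CountFixture(db, genomes, counts_df, lengths, metadata, truth)


# ---------------------------------------------------------------------------
# molecular formulae

@dataclass(frozen=True)
class FormulaFixtureSpec:
    class_counts: dict = field(
        default_factory=lambda: {"lignin": 10, "HT": 10, "CT": 10, "none": 10}
    )
    samples: tuple[str, ...] = ("s1",)
    intensity_range: tuple[float, float] = (1e5, 1e7)
    c_range: tuple[int, int] = (12, 30)


def make_formulas(
    spec: FormulaFixtureSpec,
    seed: int,
    boundaries: ClassBoundaries = DEFAULT_BOUNDARIES,
) -> pd.DataFrame:
    """Formula table with rows planted inside (or outside) each region.

    Rejection-samples integer compositions until the realized O:C and H:C
    ratios fall strictly inside the requested region (or outside all three
    for the ``none`` class). Returns a peak-list-shaped table with a
    ``true_class`` truth column.
    """
    rng = np.random.default_rng(seed)
    regions = boundaries.regions()
    rows = []
    for sample in spec.samples:
        for cls, n in sorted(spec.class_counts.items()):
            if n < 0:
                raise ValueError("class counts must be >= 0")
            for i in range(n):
                c, h, o = _sample_formula(rng, cls, regions, boundaries, spec.c_range)
                rows.append(
                    {
                        "sample_id": sample,
                        "C": c,
                        "H": h,
                        "O": o,
                        "N": int(rng.integers(0, 3)),
                        "S": 0,
                        "P": 0,
                        "intensity": float(
                            rng.uniform(*spec.intensity_range)
                        ),
                        "true_class": cls,
                    }
                )
    return pd.DataFrame(rows)


def _sample_formula(rng, cls, regions, boundaries, c_range) -> tuple[int, int, int]:
    for _ in range(10000):
        c = int(rng.integers(c_range[0], c_range[1] + 1))
        if cls == NONE_CLASS:
            o = int(rng.integers(0, 2 * c + 1))
            h = int(rng.integers(1, 2 * c + 1))
        else:
            region = regions[cls]
            o = int(np.round(rng.uniform(*region.oc) * c))
            h = int(np.round(rng.uniform(*region.hc) * c))
        if h < 1 or o < 0:
            continue
        got = classify((c, h, o), boundaries)
        if got == cls:
            return c, h, o
    raise FixtureGenerationError(f"could not sample a formula of class {cls!r}")
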