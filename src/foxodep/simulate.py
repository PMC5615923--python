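"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a tissue-specific label-free proteomics
experiment contrasting four genotypes (wild type A, foxo-null B, insulin-
producing-cell ablated C, ablated foxo-null D) with six biological replicates
each, on the log2 intensity scale.  Proteins belong to one of four planted
classes:

* ``null`` — no response to ablation in either background;
* ``foxo_independent`` — identical response with and without foxo;
* ``foxo_dependent`` — response in the wild-type background that is reduced
  (by default abolished) in the foxo-null background;
* ``exaggerated`` — response that is *stronger* in the foxo-null background.

Missingness is missing-not-at-random: each value is censored with logistic
probability increasing as intensity falls, mimicking the low-abundance
left-censoring that downshifted-normal imputation presumes.

The generator also emits every auxiliary input the pipeline consumes: a
scale-free protein-protein interaction network with planted dense modules
populated preferentially by foxo-dependent proteins, a small ontology DAG
with one term matched to each module, and promoter sequences with planted
motif occurrences.  One bundle is one tissue; multi-tissue studies are
independent bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import expit

from .containers import GENOTYPES, IntensityMatrix
from .enrichment import MotifModel

CLASSES = ("null", "foxo_dependent", "foxo_independent", "exaggerated")

__all__ = [
    "SimConfig",
    "SyntheticBundle",
    "CLASSES",
    "generate_intensities",
    "apply_missingness",
    "generate_network",
    "generate_ontology",
    "generate_promoters",
    "default_foxo_motif",
    "make_bundle",
    "write_bundle",
]


@dataclass
class SimConfig:
    """Parameters of the intensity-matrix generator.

    ``effect_size`` is either a constant |delta log2| magnitude or a callable
    ``(rng, n) -> array`` drawing one magnitude per protein.  Signs are
    random.  ``dependent_db_ratio`` and ``exaggerated_db_ratio`` set the
    foxo-null-background response relative to the wild-type-background
    response for the two non-symmetric classes.
    """

    n_proteins: int = 2000
    n_replicates: int = 6
    genotypes: tuple[str, ...] = GENOTYPES
    tissue: str = "gut"
    baseline_mean_range: tuple[float, float] = (22.0, 38.0)
    residual_sd: float = 0.3
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.70,
            "foxo_dependent": 0.12,
            "foxo_independent": 0.12,
            "exaggerated": 0.06,
        }
    )
    effect_size: float | Callable[[np.random.Generator, int], np.ndarray] = 1.0
    dependent_db_ratio: float = 0.0
    exaggerated_db_ratio: float = 2.0
    mnar_midpoint: float = 21.5
    mnar_steepness: float = 0.8
    dropped_samples: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class_fractions must be nonnegative")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")
        if len(self.genotypes) != 4:
            raise ValueError("exactly four genotype labels required")

    def sample_names(self) -> list[str]:
        return [
            f"{self.tissue}_{g}{r + 1}"
            for g in self.genotypes
            for r in range(self.n_replicates)
        ]


def _class_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n proteins to the four classes."""
    raw = {c: fractions.get(c, 0.0) * n for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def generate_intensities(config: SimConfig) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Complete (no-missing) intensity matrix plus per-protein ground truth.

    Group means are baseline + planted effects (A and B share the baseline,
    C adds the wild-type-background effect, D the foxo-null-background
    effect); residuals are i.i.d. normal with sd ``config.residual_sd``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]

    counts = _class_counts(config.class_fractions, n)
    labels = np.array([c for c in CLASSES for _ in range(counts[c])])
    labels = labels[rng.permutation(n)]

    baseline = rng.uniform(*config.baseline_mean_range, size=n)
    if callable(config.effect_size):
        magnitude = np.asarray(config.effect_size(rng, n), dtype=float)
    else:
        magnitude = np.full(n, float(config.effect_size))
    signs = rng.choice([-1.0, 1.0], size=n)
    delta = magnitude * signs

    effect_ca = np.zeros(n)
    effect_db = np.zeros(n)
    is_dep = labels == "foxo_dependent"
    is_ind = labels == "foxo_independent"
    is_exa = labels == "exaggerated"
    effect_ca[is_dep | is_ind | is_exa] = delta[is_dep | is_ind | is_exa]
    effect_db[is_ind] = delta[is_ind]
    effect_db[is_dep] = config.dependent_db_ratio * delta[is_dep]
    effect_db[is_exa] = config.exaggerated_db_ratio * delta[is_exa]

    g_a, g_b, g_c, g_d = config.genotypes
    group_means = {
        g_a: baseline,
        g_b: baseline,
        g_c: baseline + effect_ca,
        g_d: baseline + effect_db,
    }
    reps = config.n_replicates
    values = np.empty((n, 4 * reps))
    for gi, g in enumerate(config.genotypes):
        block = group_means[g][:, None] + rng.normal(
            0.0, config.residual_sd, size=(n, reps)
        )
        values[:, gi * reps : (gi + 1) * reps] = block

    sample_ids = config.sample_names()
    samples = pd.DataFrame(
        {
            "genotype": [g for g in config.genotypes for _ in range(reps)],
            "tissue": config.tissue,
            "replicate": [r + 1 for _ in config.genotypes for r in range(reps)],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    vdf = pd.DataFrame(values, index=pd.Index(proteins, name="protein"), columns=sample_ids)
    if config.dropped_samples:
        missing = set(config.dropped_samples) - set(sample_ids)
        if missing:
            raise ValueError(f"dropped_samples not in design: {sorted(missing)}")
        keep = [s for s in sample_ids if s not in set(config.dropped_samples)]
        vdf = vdf[keep]
        samples = samples.loc[keep]

    ground_truth = pd.DataFrame(
        {
            "class": labels,
            "effect_CA": effect_ca,
            "effect_DB": effect_db,
            "module_id": -1,
            "annotated_terms": "",
            "motif_planted": False,
        },
        index=vdf.index,
    )
    return IntensityMatrix(values=vdf, samples=samples), ground_truth


def apply_missingness(
    matrix: IntensityMatrix, config: SimConfig, seed: int | None = None
) -> IntensityMatrix:
    """Censor values missing-not-at-random via a logistic in intensity.

    Each cell goes missing independently with probability
    ``logistic((mnar_midpoint - value) * mnar_steepness)``: low-abundance
    values are preferentially lost.  Steepness 0 gives a flat 50% rate;
    midpoint -> -inf gives no missingness.
    """
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
    vals = matrix.values.to_numpy()
    p_miss = expit((config.mnar_midpoint - vals) * config.mnar_steepness)
    drop = rng.uniform(size=vals.shape) < p_miss
    out = matrix.values.where(~drop)
    return IntensityMatrix(values=out, samples=matrix.samples.copy())


def generate_network(
    n_nodes: int,
    n_modules: int,
    module_size: int,
    attachment_edges: int = 3,
    seed: int = 0,
    nodes: Sequence[str] | None = None,
    preferred: Sequence[str] | None = None,
    within_module_prob: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Scale-free interaction network with planted dense modules.

    A preferential-attachment (Barabasi-Albert) backbone guarantees a
    connected, heavy-tailed graph; ``n_modules`` disjoint node sets of
    ``module_size`` are then densified (each within-module pair wired with
    probability ``within_module_prob``).  Module slots are filled from the
    ``preferred`` nodes first, emulating pathway-level coherence of the
    foxo-dependent response.  Edge confidences are uniform on [0, 1] for
    backbone edges and on [0.4, 1] for planted module edges, so filtering at
    the 0.4 confidence level keeps every planted edge.

    Returns an edge table (node_a, node_b, confidence) and the node -> module
    assignment (module ids 0..n_modules-1).
    """
    if module_size * n_modules > n_nodes:
        raise ValueError("modules cannot exceed the node set")
    if n_nodes <= attachment_edges:
        raise ValueError("n_nodes must exceed attachment_edges")
    if nodes is None:
        nodes = [f"P{i:05d}" for i in range(n_nodes)]
    if len(nodes) != n_nodes:
        raise ValueError("len(nodes) must equal n_nodes")

    rng = np.random.default_rng(seed)
    backbone = nx.barabasi_albert_graph(n_nodes, attachment_edges, seed=int(seed))
    relabel = dict(enumerate(nodes))
    backbone = nx.relabel_nodes(backbone, relabel)

    preferred = [p for p in (preferred or []) if p in set(nodes)]
    pool = list(rng.permutation(np.array(preferred, dtype=object))) + [
        n for n in rng.permutation(np.array(nodes, dtype=object)) if n not in set(preferred)
    ]
    module_of: dict[str, int] = {}
    planted_edges: set[tuple[str, str]] = set()
    for m in range(n_modules):
        members = pool[m * module_size : (m + 1) * module_size]
        for node in members:
            module_of[node] = m
        for i in range(module_size):
            for j in range(i + 1, module_size):
                if within_module_prob >= 1.0 or rng.uniform() < within_module_prob:
                    a, b = sorted((members[i], members[j]))
                    planted_edges.add((a, b))

    rows = []
    seen = set()
    for a, b in planted_edges:
        rows.append((a, b, float(rng.uniform(0.4, 1.0))))
        seen.add((a, b))
    for u, v in backbone.edges():
        a, b = sorted((u, v))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        rows.append((a, b, float(rng.uniform(0.0, 1.0))))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    edges = edges.sort_values(["node_a", "node_b"], kind="mergesort").reset_index(drop=True)
    return edges, module_of


def generate_ontology(
    n_terms: int,
    size_range: tuple[int, int] = (5, 30),
    dag_depth: int = 3,
    seed: int = 0,
    genes: Sequence[str] = (),
    module_genes: Mapping[int, Sequence[str]] | None = None,
) -> tuple[dict[str, list[str]], dict[str, list[str]], dict[int, str]]:
    """Random acyclic term DAG with gene annotations.

    ``n_terms`` terms are spread over depths 1..``dag_depth`` under a single
    root; each non-root term gets one parent from the level above (the root
    for depth 1, so ``dag_depth=1`` yields a flat ontology).  Direct gene
    sets are uniform samples with sizes in ``size_range``.  For each planted
    network module one extra term annotated exactly to the module's genes is
    added, so module recovery can be read out as term enrichment.

    Returns ``(term_parents, term_genes, module_term)`` dictionaries ready
    for :class:`~foxodep.enrichment.Ontology`.
    """
    if dag_depth < 1:
        raise ValueError("dag_depth must be >= 1")
    lo, hi = size_range
    if not 1 <= lo <= hi <= max(1, len(genes)):
        raise ValueError("size_range must fit within the gene universe")
    rng = np.random.default_rng(seed)
    genes = list(genes)

    root = "T0000"
    term_parents: dict[str, list[str]] = {root: []}
    term_genes: dict[str, list[str]] = {root: []}
    by_depth: dict[int, list[str]] = {0: [root]}
    for i in range(n_terms):
        term = f"T{i + 1:04d}"
        depth = 1 + i % dag_depth
        parent_pool = by_depth[depth - 1]
        parent = parent_pool[int(rng.integers(len(parent_pool)))]
        term_parents[term] = [parent]
        by_depth.setdefault(depth, []).append(term)
        size = int(rng.integers(lo, hi + 1))
        term_genes[term] = sorted(
            rng.choice(np.array(genes, dtype=object), size=size, replace=False)
        )
    module_term: dict[int, str] = {}
    for m in sorted(module_genes or {}):
        term = f"TM{m:03d}"
        term_parents[term] = [root]
        term_genes[term] = sorted(module_genes[m])
        module_term[m] = term
    return term_parents, term_genes, module_term


def generate_promoters(
    motif: MotifModel,
    genes: Sequence[str],
    planted_genes: Sequence[str],
    length: int = 1000,
    seed: int = 0,
) -> dict[str, str]:
    """I.i.d. background promoters with exact-consensus motif insertions.

    Each gene receives a ``length``-bp sequence drawn from the motif's
    background base frequencies; genes in ``planted_genes`` get one exact
    consensus occurrence at a uniform random position.
    """
    if motif.width >= length:
        raise ValueError("motif width must be smaller than promoter length")
    unknown = set(planted_genes) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene list: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    consensus = motif.consensus
    planted = set(planted_genes)
    promoters: dict[str, str] = {}
    for gene in genes:
        seq = rng.choice(bases, size=length, p=motif.background)
        if gene in planted:
            pos = int(rng.integers(0, length - motif.width + 1))
            seq[pos : pos + motif.width] = list(consensus)
        promoters[gene] = "".join(seq)
    return promoters


def default_foxo_motif() -> MotifModel:
    """A FoxO-like forkhead motif (consensus TTGTTTAC), near-deterministic."""
    consensus = "TTGTTTAC"
    idx = {b: i for i, b in enumerate("ACGT")}
    matrix = np.full((len(consensus), 4), 0.03)
    for row, base in enumerate(consensus):
        matrix[row, idx[base]] = 0.91
    return MotifModel(matrix=matrix, name="foxo_like")


# ---------------------------------------------------------------------------
# Bundle: everything the pipeline consumes, cross-referenced
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """All simulated inputs for one tissue, with ground truth."""

    config: SimConfig
    complete: IntensityMatrix
    observed: IntensityMatrix
    ground_truth: pd.DataFrame
    network_edges: pd.DataFrame
    module_of: dict[str, int]
    term_parents: dict[str, list[str]]
    term_genes: dict[str, list[str]]
    module_term: dict[int, str]
    promoters: dict[str, str]
    motif: MotifModel


def make_bundle(
    config: SimConfig | None = None,
    n_modules: int = 3,
    module_size: int = 12,
    attachment_edges: int = 3,
    within_module_prob: float = 1.0,
    n_terms: int = 40,
    term_size_range: tuple[int, int] = (5, 30),
    dag_depth: int = 3,
    plant_fraction: float = 0.5,
    background_plant_fraction: float = 0.05,
    promoter_length: int = 1000,
    motif: MotifModel | None = None,
) -> SyntheticBundle:
    """Generate a complete, internally consistent synthetic study.

    ``plant_fraction`` of foxo-dependent genes and
    ``background_plant_fraction`` of all other genes receive a planted motif
    occurrence in their promoter.
    """
    config = config or SimConfig()
    motif = motif or default_foxo_motif()

    complete, gt = generate_intensities(config)
    observed = apply_missingness(complete, config)
    proteins = list(complete.proteins)

    dependent = list(gt.index[gt["class"] == "foxo_dependent"])
    edges, module_of = generate_network(
        n_nodes=len(proteins),
        n_modules=n_modules,
        module_size=module_size,
        attachment_edges=attachment_edges,
        seed=config.seed + 7,
        nodes=proteins,
        preferred=dependent,
        within_module_prob=within_module_prob,
    )
    gt["module_id"] = [module_of.get(p, -1) for p in gt.index]

    module_genes = {}
    for node, m in module_of.items():
        module_genes.setdefault(m, []).append(node)
    term_parents, term_genes, module_term = generate_ontology(
        n_terms,
        size_range=term_size_range,
        dag_depth=dag_depth,
        seed=config.seed + 11,
        genes=proteins,
        module_genes=module_genes,
    )
    gene_terms: dict[str, list[str]] = {}
    for term, tg in term_genes.items():
        for g in tg:
            gene_terms.setdefault(g, []).append(term)
    gt["annotated_terms"] = [";".join(sorted(gene_terms.get(p, []))) for p in gt.index]

    rng = np.random.default_rng(config.seed + 13)
    others = [p for p in proteins if p not in set(dependent)]
    planted = sorted(
        list(rng.permutation(np.array(dependent, dtype=object))[: round(plant_fraction * len(dependent))])
        + list(
            rng.permutation(np.array(others, dtype=object))[
                : round(background_plant_fraction * len(others))
            ]
        )
    )
    promoters = generate_promoters(
        motif, proteins, planted, length=promoter_length, seed=config.seed + 17
    )
    gt["motif_planted"] = gt.index.isin(planted)

    return SyntheticBundle(
        config=config,
        complete=complete,
        observed=observed,
        ground_truth=gt,
        network_edges=edges,
        module_of=module_of,
        term_parents=term_parents,
        term_genes=term_genes,
        module_term=module_term,
        promoters=promoters,
        motif=motif,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize a bundle to the pipeline's plain-text interchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": outdir / "intensities.tsv",
        "samples": outdir / "samples.tsv",
        "complete": outdir / "intensities_complete.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "edges": outdir / "network_edges.tsv",
        "term_genes": outdir / "term_genes.tsv",
        "term_parents": outdir / "term_parents.tsv",
        "promoters": outdir / "promoters.fasta",
        "motif": outdir / "motif.meme",
        "config": outdir / "sim_config.yaml",
    }
    bundle.observed.to_tsv(paths["intensities"], paths["samples"])
    bundle.complete.values.to_csv(paths["complete"], sep="\t", index_label="protein")
    bundle.ground_truth.to_csv(paths["ground_truth"], sep="\t", index_label="protein")
    bundle.network_edges.to_csv(paths["edges"], sep="\t", index=False)
    pd.DataFrame(
        [(t, g) for t in sorted(bundle.term_genes) for g in bundle.term_genes[t]],
        columns=["term", "gene"],
    ).to_csv(paths["term_genes"], sep="\t", index=False)
    pd.DataFrame(
        [(t, p) for t in sorted(bundle.term_parents) for p in bundle.term_parents[t]],
        columns=["term", "parent"],
    ).to_csv(paths["term_parents"], sep="\t", index=False)
    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in sorted(bundle.promoters.items())
    ]
    SeqIO.write(records, str(paths["promoters"]), "fasta")
    bundle.motif.to_meme(paths["motif"])
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(bundle.config).items()
        if not callable(v)
    }
    cfg["class_fractions"] = dict(bundle.config.class_fractions)
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
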