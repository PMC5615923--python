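"""End-to-end orchestration: simulate -> preprocess -> model -> classify ->
propagate -> enrich, as a configured, logged, reproducible run.

Every stage writes plain-text TSV/JSON outputs into the run directory, and
the run ends with a ``manifest.json`` (seeds, config hash, row counts) and a
human-readable ``summary.txt``.  All randomness derives from the single run
seed, so repeated runs with the same configuration are byte-identical.

Stages can be skipped (``skip_stages``), in which case their outputs are
loaded from a previous run in the same directory — useful to re-run only the
downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import DependencyThreshold, IntensityMatrix
from .dependency import classify_dependency, equivalence_threshold
from .diffexp import run_contrasts
from .enrichment import (
    MotifModel,
    Ontology,
    direction_test,
    elim_fisher,
    motif_overlap_test,
    scan_promoters,
)
from .io import (
    read_edges,
    read_intensities,
    read_promoters,
    read_term_genes,
    read_term_parents,
)
from .netprop import (
    PropagationConfig,
    cluster_scores,
    combined_profile,
    linkage_newick,
    load_network,
    normalize_adjacency,
    propagate_scores,
)
from .preprocess import ImputationParams, filter_min_valid, impute_downshift
from .simulate import SimConfig, SyntheticBundle, make_bundle, write_bundle

logger = logging.getLogger("foxodep")

STAGES = ("simulate", "preprocess", "de", "classify", "propagate", "enrich")

CONTRAST_NAMES = ("CvsA", "DvsB", "interaction")


@dataclass
class PipelineConfig:
    """Every knob of a pipeline run; round-trips through YAML/JSON."""

    outdir: str = "foxodep_run"
    seed: int = 0
    tissue: str = "gut"
    fdr: float = 0.1
    enrichment_alpha: float = 0.05
    min_significant: int = 5
    n_clusters: int = 6
    equivalence_t: float | None = None  # manual override of the margin t
    motif_p_threshold: float = 1e-4
    sim: SimConfig = field(default_factory=SimConfig)
    imputation: ImputationParams = field(default_factory=ImputationParams)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    bundle: dict[str, Any] = field(default_factory=dict)  # make_bundle kwargs
    skip_stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.skip_stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        # one seed rules them all: stage seeds are fixed offsets of it
        self.sim.seed = self.seed
        self.sim.tissue = self.tissue
        self.imputation.seed = self.seed + 101

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and not isinstance(d["sim"], SimConfig):
            sim = dict(d["sim"])
            for key in ("genotypes", "dropped_samples"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "baseline_mean_range" in sim:
                sim["baseline_mean_range"] = tuple(sim["baseline_mean_range"])
            d["sim"] = SimConfig(**sim)
        if "imputation" in d and not isinstance(d["imputation"], ImputationParams):
            d["imputation"] = ImputationParams(**d["imputation"])
        if "propagation" in d and not isinstance(d["propagation"], PropagationConfig):
            d["propagation"] = PropagationConfig(**d["propagation"])
        if "skip_stages" in d:
            d["skip_stages"] = tuple(d["skip_stages"])
        if "bundle" in d and d["bundle"]:
            b = dict(d["bundle"])
            if "term_size_range" in b:
                b["term_size_range"] = tuple(b["term_size_range"])
            d["bundle"] = b
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, outdir: Path) -> SyntheticBundle:
    bundle = make_bundle(config.sim, **config.bundle)
    write_bundle(bundle, outdir / "simulated")
    return bundle


def _load_simulated(outdir: Path) -> dict[str, Any]:
    sim = outdir / "simulated"
    return {
        "observed": read_intensities(sim / "intensities.tsv", sim / "samples.tsv"),
        "edges": read_edges(sim / "network_edges.tsv"),
        "term_genes": read_term_genes(sim / "term_genes.tsv"),
        "term_parents": read_term_parents(sim / "term_parents.tsv"),
        "promoters": read_promoters(sim / "promoters.fasta"),
        "motif": MotifModel.from_meme(sim / "motif.meme"),
        "ground_truth": pd.read_csv(
            sim / "ground_truth.tsv", sep="\t", index_col="protein"
        ),
    }


def _stage_preprocess(config: PipelineConfig, observed: IntensityMatrix, outdir: Path) -> IntensityMatrix:
    filtered = filter_min_valid(observed, config.imputation.min_valid)
    imputed = impute_downshift(filtered, config.imputation)
    imputed.to_tsv(outdir / "preprocessed.tsv", outdir / "preprocessed_samples.tsv")
    imputed.imputed.to_csv(outdir / "imputed_mask.tsv", sep="\t", index_label="protein")
    return imputed


def _stage_de(config: PipelineConfig, matrix: IntensityMatrix, outdir: Path) -> dict[str, pd.DataFrame]:
    results = run_contrasts(matrix, fdr=config.fdr)
    for name, table in results.items():
        table.to_csv(outdir / f"de_{name}.tsv", sep="\t", index_label="protein")
    return results


def _load_de(outdir: Path) -> dict[str, pd.DataFrame]:
    return {
        name: pd.read_csv(outdir / f"de_{name}.tsv", sep="\t", index_col="protein")
        for name in CONTRAST_NAMES
    }


def _stage_classify(
    config: PipelineConfig, de: dict[str, pd.DataFrame], outdir: Path
) -> tuple[float | None, pd.DataFrame]:
    inter = de["interaction"]
    t_value: float | None
    if config.equivalence_t is not None:
        t_value = float(config.equivalence_t)
        provenance: list[str] = []
    else:
        try:
            thr = equivalence_threshold(inter, fdr=config.fdr, tissue=config.tissue)
            t_value, provenance = thr.t, thr.provenance
        except ValueError:
            logger.warning(
                "no significant interaction proteins and no manual t; "
                "equivalence rule disabled for this run"
            )
            t_value, provenance = None, []
    calls = classify_dependency(
        de["CvsA"], de["DvsB"], inter, t_value if t_value is not None else 0.0
    )
    calls.to_csv(outdir / "classification.tsv", sep="\t", index_label="protein")
    (outdir / "threshold.json").write_text(
        json.dumps(
            {"t": t_value, "tissue": config.tissue, "provenance": provenance},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return t_value, calls


def _load_classify(outdir: Path) -> tuple[float | None, pd.DataFrame]:
    calls = pd.read_csv(outdir / "classification.tsv", sep="\t", index_col="protein")
    t_value = json.loads((outdir / "threshold.json").read_text())["t"]
    return t_value, calls


def _stage_propagate(
    config: PipelineConfig,
    de: dict[str, pd.DataFrame],
    calls: pd.DataFrame,
    edges: pd.DataFrame,
    node_universe: Sequence[str],
    outdir: Path,
) -> pd.DataFrame:
    graph = load_network(edges, config.propagation.min_confidence, nodes=node_universe)
    W, nodes = normalize_adjacency(graph, weighted=config.propagation.weighted)
    pvals = de["CvsA"]["p"]
    dep_set = set(calls.index[calls["label"] == "foxo_dependent"])
    ind_set = set(calls.index[calls["label"] == "foxo_independent"])
    dep = propagate_scores(pvals, dep_set, W, nodes, config.propagation)
    ind = propagate_scores(pvals, ind_set, W, nodes, config.propagation)
    combined = combined_profile(dep, ind)
    profiles = np.column_stack([dep["corrected"], ind["corrected"]])
    clusters = cluster_scores(profiles, min(config.n_clusters, len(nodes)))
    table = pd.DataFrame(
        {
            "Y_dep": dep["Y"],
            "F_dep": dep["F"],
            "bias": dep["bias"],
            "corrected_dep": dep["corrected"],
            "Y_indep": ind["Y"],
            "F_indep": ind["F"],
            "corrected_indep": ind["corrected"],
            "combined": combined,
            "cluster": clusters,
        },
        index=pd.Index(nodes, name="node"),
    )
    table.to_csv(outdir / "propagation.tsv", sep="\t", index_label="node")
    (outdir / "dendrogram.newick").write_text(linkage_newick(profiles, nodes) + "\n")
    return table


def _load_propagate(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "propagation.tsv", sep="\t", index_col="node")


def _stage_enrich(
    config: PipelineConfig,
    de: dict[str, pd.DataFrame],
    calls: pd.DataFrame,
    prop: pd.DataFrame,
    term_parents: Mapping[str, list[str]],
    term_genes: Mapping[str, list[str]],
    promoters: Mapping[str, str],
    motif: MotifModel,
    outdir: Path,
) -> dict[str, Any]:
    ontology = Ontology(term_parents, term_genes)
    detected = list(calls.index)
    dep_set = sorted(calls.index[calls["label"] == "foxo_dependent"])

    stats: dict[str, Any] = {"n_dependent": len(dep_set)}

    # term enrichment of the dependent set against the detected background
    if dep_set:
        enr_dep = elim_fisher(
            ontology, dep_set, detected, config.enrichment_alpha, config.min_significant
        )
    else:
        enr_dep = pd.DataFrame()
    enr_dep.to_csv(outdir / "enrichment_dependent.tsv", sep="\t", index=False)

    # cluster with the strongest dependent-minus-independent signal,
    # enriched against all network nodes (the propagation universe)
    cluster_means = prop.groupby("cluster")["combined"].mean()
    dep_cluster = int(cluster_means.idxmax())
    cluster_genes = sorted(prop.index[prop["cluster"] == dep_cluster])
    enr_cluster = elim_fisher(
        ontology,
        cluster_genes,
        list(prop.index),
        config.enrichment_alpha,
        config.min_significant,
    )
    enr_cluster.to_csv(outdir / "enrichment_cluster.tsv", sep="\t", index=False)
    stats["dependent_cluster"] = dep_cluster
    stats["dependent_cluster_size"] = len(cluster_genes)

    # promoter motif scan over measured genes; overlap with the dependent set
    measured_promoters = {g: promoters[g] for g in detected if g in promoters}
    hits = scan_promoters(measured_promoters, motif, config.motif_p_threshold)
    hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    if dep_set:
        overlap = motif_overlap_test(hits["gene"].unique(), dep_set, detected)
        stats["motif_overlap"] = _plainify(overlap)

    # directional shift of the dependent set's fold changes
    if len(dep_set) >= 2:
        t_stat, p, degenerate = direction_test(
            de["CvsA"].loc[dep_set, "estimate"].to_numpy()
        )
        stats["direction_test"] = {"t": t_stat, "p": p, "degenerate": degenerate}

    (outdir / "enrichment_stats.json").write_text(
        json.dumps(_plainify(stats), indent=2, sort_keys=True) + "\n"
    )
    return {"dependent": enr_dep, "cluster": enr_cluster, "hits": hits, "stats": stats}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, until: str = "enrich") -> dict[str, Any]:
    """Execute the pipeline stages in order; returns the run manifest.

    Stages listed in ``config.skip_stages`` are not recomputed: their outputs
    are loaded from ``config.outdir`` (they must exist from a previous run).
    ``until`` stops the run after the named stage.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    last = STAGES.index(until)
    skip = set(config.skip_stages)

    manifest: dict[str, Any] = {
        "package": "foxodep",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            "simulate": config.seed,
            "missingness": config.seed + 1_000_003,
            "network": config.seed + 7,
            "ontology": config.seed + 11,
            "motif_planting": config.seed + 13,
            "promoters": config.seed + 17,
            "imputation": config.seed + 101,
        },
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "row_counts": {},
        "stages_run": [],
    }
    counts = manifest["row_counts"]

    def ran(stage: str, **rows: int) -> None:
        manifest["stages_run"].append(stage)
        counts.update(rows)
        logger.info("stage %s done", stage)

    current = "simulate"
    try:
        # simulate ---------------------------------------------------------
        if "simulate" in skip:
            sim = _load_simulated(outdir)
            observed = sim["observed"]
            edges, term_parents, term_genes = (
                sim["edges"],
                sim["term_parents"],
                sim["term_genes"],
            )
            promoters, motif = sim["promoters"], sim["motif"]
        else:
            bundle = _stage_simulate(config, outdir)
            observed = bundle.observed
            edges = bundle.network_edges
            term_parents, term_genes = bundle.term_parents, bundle.term_genes
            promoters, motif = bundle.promoters, bundle.motif
            ran("simulate", proteins=observed.n_proteins, network_edges=len(edges))
        if last == 0:
            return _finish(manifest, outdir)

        current = "preprocess"
        # preprocess ---------------------------------------------------------
        if "preprocess" in skip:
            matrix = read_intensities(
                outdir / "preprocessed.tsv", outdir / "preprocessed_samples.tsv"
            )
        else:
            matrix = _stage_preprocess(config, observed, outdir)
            ran("preprocess", preprocessed=matrix.n_proteins)
        if last == 1:
            return _finish(manifest, outdir)

        current = "de"
        # differential expression -------------------------------------------
        if "de" in skip:
            de = _load_de(outdir)
        else:
            de = _stage_de(config, matrix, outdir)
            ran("de", **{f"significant_{k}": int(v["significant"].sum()) for k, v in de.items()})
        if last == 2:
            return _finish(manifest, outdir)

        current = "classify"
        # classify -----------------------------------------------------------
        if "classify" in skip:
            t_value, calls = _load_classify(outdir)
        else:
            t_value, calls = _stage_classify(config, de, outdir)
            label_counts = calls["label"].value_counts()
            ran(
                "classify",
                foxo_dependent=int(label_counts.get("foxo_dependent", 0)),
                foxo_independent=int(label_counts.get("foxo_independent", 0)),
            )
        manifest["equivalence_t"] = t_value
        if last == 3:
            return _finish(manifest, outdir)

        current = "propagate"
        # propagate ----------------------------------------------------------
        if "propagate" in skip:
            prop = _load_propagate(outdir)
        else:
            prop = _stage_propagate(
                config, de, calls, edges, list(calls.index), outdir
            )
            ran("propagate", network_nodes=len(prop))
        if last == 4:
            return _finish(manifest, outdir)

        current = "enrich"
        # enrich -------------------------------------------------------------
        if "enrich" not in skip:
            enr = _stage_enrich(
                config, de, calls, prop, term_parents, term_genes, promoters, motif, outdir
            )
            ran(
                "enrich",
                enriched_terms_dependent=len(enr["dependent"]),
                motif_hits=len(enr["hits"]),
            )
            manifest["enrichment_stats"] = _plainify(enr["stats"])
            _write_summary(outdir, manifest, de, calls, prop, enr)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc
    return _finish(manifest, outdir)


def _finish(manifest: dict, outdir: Path) -> dict:
    (outdir / "manifest.json").write_text(
        json.dumps(_plainify(manifest), indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _write_summary(outdir, manifest, de, calls, prop, enr) -> None:
    lines = [f"foxodep run summary (seed {manifest['seed']})", ""]
    for name, table in de.items():
        lines.append(f"significant {name}: {int(table['significant'].sum())}")
    lines.append("")
    for label, count in calls["label"].value_counts().sort_index().items():
        lines.append(f"label {label}: {count}")
    lines.append(f"equivalence t: {manifest.get('equivalence_t')}")
    lines.append("")
    sizes = prop["cluster"].value_counts().sort_index()
    lines.append("cluster sizes: " + ", ".join(f"{c}:{n}" for c, n in sizes.items()))
    if not enr["cluster"].empty:
        top = enr["cluster"].head(3)["term"].tolist()
        lines.append("top cluster terms: " + ", ".join(top))
    if not enr["dependent"].empty:
        top = enr["dependent"].head(3)["term"].tolist()
        lines.append("top dependent-set terms: " + ", ".join(top))
    stats = enr["stats"]
    if "motif_overlap" in stats:
        mo = stats["motif_overlap"]
        lines.append(
            f"motif overlap: {mo['overlap']}/{mo['regulated']} regulated genes "
            f"with hits (fraction {mo['fraction']:.3f}, p {mo['pvalue']:.3g})"
        )
    if "direction_test" in stats:
        dt = stats["direction_test"]
        lines.append(f"direction test: t={dt['t']:.3f}, p={dt['p']:.3g}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


def validate_inputs(paths: Mapping[str, str | Path]) -> list[str]:
    """Schema and cross-reference checks for external input files.

    ``paths`` may contain any of: ``intensities`` + ``samples``, ``edges``,
    ``term_genes`` + ``term_parents``, ``promoters``, ``motif``.  Returns a
    list of human-readable issues; an empty list means the inputs are valid.
    """
    issues: list[str] = []

    if "intensities" in paths and "samples" in paths:
        try:
            values = pd.read_csv(paths["intensities"], sep="\t", index_col="protein")
            samples = pd.read_csv(paths["samples"], sep="\t", index_col="sample")
            dup = values.index[values.index.duplicated()].unique().tolist()
            if dup:
                issues.append(f"intensities: duplicate protein rows {dup[:5]}")
            for s in samples.index:
                if s not in values.columns:
                    issues.append(f"samples: sample {s!r} missing from intensity header")
            for s in values.columns:
                if s not in samples.index:
                    issues.append(f"intensities: column {s!r} missing from sample metadata")
            for col in ("genotype", "tissue", "replicate"):
                if col not in samples.columns:
                    issues.append(f"samples: missing column {col!r}")
            non_numeric = values.apply(
                lambda c: pd.to_numeric(c, errors="coerce").isna() & c.notna()
            )
            if non_numeric.any().any():
                bad = list(zip(*np.nonzero(non_numeric.to_numpy())))[:3]
                issues.append(f"intensities: non-numeric cells at (row, col) {bad}")
        except Exception as exc:  # malformed file
            issues.append(f"intensities/samples: {exc}")

    if "edges" in paths:
        try:
            edges = read_edges(paths["edges"])
            conf = pd.to_numeric(edges["confidence"], errors="coerce")
            if conf.isna().any() or (conf < 0).any() or (conf > 1).any():
                issues.append("edges: confidence values must be numeric in [0, 1]")
        except Exception as exc:
            issues.append(f"edges: {exc}")

    if "term_genes" in paths and "term_parents" in paths:
        try:
            tg = read_term_genes(paths["term_genes"])
            tp = read_term_parents(paths["term_parents"])
            Ontology(tp, tg)
        except Exception as exc:
            issues.append(f"ontology: {exc}")

    if "promoters" in paths:
        try:
            promoters = read_promoters(paths["promoters"])
            for gene, seq in promoters.items():
                if set(seq) - set("ACGTN"):
                    issues.append(f"promoters: {gene} contains non-ACGTN characters")
                    break
        except Exception as exc:
            issues.append(f"promoters: {exc}")

    if "motif" in paths:
        try:
            MotifModel.from_meme(paths["motif"])
        except Exception as exc:
            issues.append(f"motif: {exc}")

    return issues
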