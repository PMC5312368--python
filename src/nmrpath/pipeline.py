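"""End-to-end pipeline orchestration from a single seeded configuration.

``run_pipeline`` executes the full chain on either real inputs (spectra TSV,
assignment map, pathway XML directory) or a synthetic design block:
preprocessing (water-region exclusion, segment alignment, total-sum
normalization), SRV clustering, per-contrast chemometrics (PCA, PLS-DA with
permutation validation, OPLS-DA with differential-variable selection),
OR-STOCSY correlation extraction, perturbed-network reconstruction and
pathway-impact scoring. Contrasts are always stage versus control. All
artifacts are written under the output directory and summarized in a
machine-readable JSON report; a rerun with the same configuration and seed
is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chemometrics as chem
from . import network as net
from . import pathways as pw
from . import preprocess as pre
from . import srv as srvmod
from . import stocsy
from . import synthdata as syn
from .errors import ArgumentError, DesignError

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one of real inputs / synthetic)."""

    seed: int = 0
    outdir: str = "nmrpath_out"
    # real inputs
    spectra: str | None = None
    assignment: str | None = None
    kgml_dir: str | None = None
    # synthetic design block
    synthetic: dict | None = None
    # parameters (defaults follow the documented analysis conventions)
    exclusion: tuple[float, float] = (4.6, 5.7)
    normalization_total: float = 100.0
    align_max_shift: int = 5
    align_segments: list[tuple[float, float]] | None = None
    srv_singlet_size: float = 0.01
    srv_threshold: float = 0.8
    cv_folds: int = 7
    n_ortho: int = 1
    n_perm: int = 50
    correlation_threshold: float = 0.9
    impact_threshold: float = 0.3
    alpha_strong: float = 0.01
    alpha_weak: float = 0.05
    control_group: str = "CON"

    def __post_init__(self) -> None:
        real = all(x is not None for x in (self.spectra, self.assignment, self.kgml_dir))
        some_real = any(x is not None for x in (self.spectra, self.assignment, self.kgml_dir))
        if self.synthetic is not None and some_real:
            raise ArgumentError("config must provide real inputs or a synthetic block, not both")
        if self.synthetic is None and not real:
            raise ArgumentError(
                "config must provide either all real inputs (spectra, assignment, kgml_dir) "
                "or a synthetic block"
            )
        if not 0 < self.correlation_threshold <= 1:
            raise ArgumentError("correlation_threshold must lie in (0, 1]")
        if not 0 <= self.impact_threshold <= 1:
            raise ArgumentError("impact_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        inputs = doc.pop("inputs", {})
        params = doc.pop("params", {})
        merged = {**doc, **params}
        if inputs:
            merged["spectra"] = inputs.get("spectra")
            merged["assignment"] = inputs.get("assignment")
            merged["kgml_dir"] = inputs.get("kgml_dir")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(merged) - known
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "exclusion" in merged:
            merged["exclusion"] = tuple(merged["exclusion"])
        if merged.get("align_segments"):
            merged["align_segments"] = [tuple(s) for s in merged["align_segments"]]
        return cls(**merged)


def _synthetic_inputs(cfg: PipelineConfig, outdir: Path):
    block = dict(cfg.synthetic or {})
    n_met = int(block.get("n_metabolites", 30))
    resolution = float(block.get("resolution", syn.DEFAULT_RESOLUTION))
    group_sizes = dict(block.get("group_sizes", syn.STUDY_GROUP_SIZES))
    n_pathways = int(block.get("n_pathways", 5))
    # keep the line-to-bucket geometry of the default axis when coarsened
    halfwidth = float(
        block.get("halfwidth", syn.DEFAULT_HALFWIDTH * resolution / syn.DEFAULT_RESOLUTION)
    )
    library = syn.make_metabolite_library(
        n_met, seed=cfg.seed, max_peaks=2, disjoint=True, halfwidth=halfwidth
    )
    design = syn.default_design(seed=cfg.seed, library=library)
    design.group_sizes = group_sizes
    design.jitter_sd = float(
        block.get("jitter_sd", syn.DEFAULT_JITTER_SD * resolution / syn.DEFAULT_RESOLUTION)
    )
    truth = syn.simulate_concentrations(design, library)
    background = syn.make_metabolite_library(
        6, seed=cfg.seed + 1_000_003, max_peaks=2, halfwidth=0.004
    )
    matrix = syn.render_spectra(
        truth,
        library,
        design,
        resolution=resolution,
        background=background,
        background_scale=float(block.get("background_scale", 0.3)),
    )
    topos = syn.toy_pathways_for_library([s.name for s in library], n_pathways=n_pathways)
    kgml_dir = outdir / "kgml"
    syn.make_toy_kgml(topos, kgml_dir)
    pre.write_spectra(matrix, outdir / "spectra.tsv")
    pre.write_assignment_map(truth.assignment_map, outdir / "assignment.yaml")
    _write_truth(truth, outdir / "truth.json")
    return matrix, truth.assignment_map, kgml_dir


def _write_truth(truth: syn.SyntheticTruth, path: Path) -> None:
    doc = {
        "true_correlations": {
            f"{a}|{b}": r for (a, b), r in sorted(truth.true_correlations.items())
        },
        "true_differential": {m: d for m, d in sorted(truth.true_differential.items())},
        "perturbed_pathways": truth.perturbed_pathways,
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the JSON-serializable report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.synthetic is not None:
        matrix, amap, kgml_dir = _synthetic_inputs(cfg, outdir)
    else:
        matrix = pre.load_spectra(cfg.spectra)
        amap = pre.load_assignment_map(cfg.assignment)
        kgml_dir = Path(cfg.kgml_dir)

    # --- preprocess: exclude -> align -> normalize -------------------------
    matrix = pre.exclude_region(matrix, *cfg.exclusion)
    segments = cfg.align_segments or pre.tiled_segments(
        matrix.ppm, width=0.1, exclude=cfg.exclusion
    )
    matrix, shifts = pre.align_segments(matrix, segments, cfg.align_max_shift)
    matrix = pre.normalize_total_sum(matrix, cfg.normalization_total)
    pre.write_spectra(matrix, outdir / "preprocessed.tsv")

    # --- SRV ---------------------------------------------------------------
    params = srvmod.SrvParams(
        singlet_size=cfg.srv_singlet_size,
        resolution=matrix.resolution,
        landscape_threshold=cfg.srv_threshold,
    )
    landscape = srvmod.coupling_landscape(matrix)
    clusters = srvmod.build_clusters(landscape, params, matrix.ppm)
    cmatrix = srvmod.summarize_clusters(matrix, clusters)
    coverage = srvmod.coverage_fraction(matrix, clusters)
    clusters.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    cmatrix.to_frame().to_csv(outdir / "cluster_matrix.tsv", sep="\t")

    groups = list(dict.fromkeys(matrix.group_labels))
    if cfg.control_group not in groups:
        raise DesignError(f"control group '{cfg.control_group}' absent from data")
    stages = [g for g in groups if g != cfg.control_group]

    fragments = [net.parse_kgml(p) for p in sorted(Path(kgml_dir).glob("*.xml"))]
    biograph = net.build_biograph(fragments)

    labels = np.array(cmatrix.group_labels)
    report_stages: dict = {}
    for stage in stages:
        mask = np.isin(labels, [cfg.control_group, stage])
        X = cmatrix.values[mask]
        ylab = labels[mask]
        y = chem.encode_classes(ylab, control=cfg.control_group)
        Xs = chem.autoscale(X, columns=cmatrix.cluster_ids)
        n_comp = min(2, Xs.ns - 1, Xs.nv)
        pca_model = chem.pca(Xs, n_comp=n_comp, cv_folds=cfg.cv_folds, seed=cfg.seed)
        pls = chem.plsda(Xs, y, n_comp=n_comp, cv_folds=cfg.cv_folds, seed=cfg.seed)
        rpt = chem.permutation_test(
            Xs, y, n_perm=cfg.n_perm, seed=cfg.seed, n_comp=n_comp, cv_folds=cfg.cv_folds
        )
        opls = chem.oplsda(Xs, y, n_ortho=cfg.n_ortho)
        rule = chem.SignificanceRule(alpha_strong=cfg.alpha_strong, alpha_weak=cfg.alpha_weak)
        diff = chem.select_differential(opls, rule)
        assigned = stocsy.assign_clusters(clusters, amap)
        diff["metabolite"] = [assigned[i] for i in range(len(assigned))]
        diff.to_csv(outdir / f"differential_{stage}.tsv", sep="\t", index=False)

        filtered, _ = stocsy.orthogonal_filter(Xs, y, n_ortho=max(1, cfg.n_ortho))
        C = stocsy.correlation_matrix(filtered, variant="OR-STOCSY")
        edges = stocsy.classify_edges(
            stocsy.threshold_edges(C, cfg.correlation_threshold), clusters, amap
        )
        stocsy.edges_to_frame(edges, clusters).to_csv(
            outdir / f"edges_{stage}.tsv", sep="\t", index=False
        )
        pairs = stocsy.inter_metabolite_pairs(edges)

        met_dir: dict[str, str] = {}
        for _, row in diff.iterrows():
            met = row["metabolite"]
            if met is None:
                continue
            if row["label"] != "NS":
                met_dir[met] = row["direction"]
            met_dir.setdefault(met, "unchanged")
        stage_report: dict = {
            "n_samples": int(mask.sum()),
            "pca_r2x_cum": round(pca_model.r2x_cum, 4),
            "pls_r2y": round(pls.r2y, 4),
            "pls_q2": round(pls.q2, 4),
            "rpt_valid": rpt.valid,
            "opls_r2y": round(opls.r2y, 4),
            "n_differential": int((diff["label"] != "NS").sum()),
            "n_edges": len(edges),
            "n_edges_intra": sum(e.type == "intra" for e in edges),
            "n_edges_inter": sum(e.type == "inter" for e in edges),
            "n_inter_pairs": len(pairs),
        }
        if pairs:
            network = net.extract_subnetwork(biograph, pairs, directions=met_dir)
            net.write_outputs(network, outdir / "networks", f"network_{stage}")
            hit_mets = [
                n for n, role in network.roles.items() if role == "correlated-measured"
            ]
            table = pw.pathway_impact_table(
                biograph, hit_mets, impact_threshold=cfg.impact_threshold
            )
            table.to_csv(outdir / f"pathways_{stage}.tsv", sep="\t", index=False)
            sig = pw.significant_pathways(table, cfg.impact_threshold)
            stage_report.update(
                {
                    "network_counts": network.counts,
                    "n_significant_pathways": int(len(sig)),
                    "significant_pathways": sig["pathway_id"].tolist(),
                }
            )
        else:
            stage_report.update(
                {
                    "network_counts": None,
                    "n_significant_pathways": 0,
                    "significant_pathways": [],
                }
            )
        report_stages[stage] = stage_report

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "parameters": {
            "exclusion": list(cfg.exclusion),
            "normalization_total": cfg.normalization_total,
            "align_max_shift": cfg.align_max_shift,
            "srv_singlet_size": cfg.srv_singlet_size,
            "srv_threshold": cfg.srv_threshold,
            "cv_folds": cfg.cv_folds,
            "n_ortho": cfg.n_ortho,
            "n_perm": cfg.n_perm,
            "correlation_threshold": cfg.correlation_threshold,
            "impact_threshold": cfg.impact_threshold,
            "alpha_strong": cfg.alpha_strong,
            "alpha_weak": cfg.alpha_weak,
        },
        "n_samples": matrix.n_samples,
        "n_buckets": matrix.n_buckets,
        "n_clusters": len(clusters),
        "coverage_fraction": round(coverage, 6),
        "biograph_counts": biograph.counts,
        "stages": report_stages,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def make_fixtures(seed: int, outdir) -> dict:
    """Small deterministic spectra + pathway fixture set for tests/examples."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = syn.make_metabolite_library(8, seed=seed, max_peaks=2, disjoint=True)
    names = [s.name for s in library]
    design = syn.SimulationDesign(
        group_sizes={"CON": 10, "GC": 10},
        effect_matrix={names[0]: {"GC": 2.0}, names[1]: {"GC": 0.5}},
        latent_factors=[
            syn.LatentFactor(loadings={names[2]: 1.0, names[3]: 1.0}, sd=0.4),
            syn.LatentFactor(loadings={names[4]: 1.0, names[5]: -1.0}, sd=0.4),
        ],
        residual_sd=0.15,
        residual_sd_overrides={n: 0.04 for n in names[2:6]},
        noise_sd=0.005,
        jitter_sd=0.002,
        seed=seed,
    )
    truth = syn.simulate_concentrations(design, library)
    matrix = syn.render_spectra(truth, library, design, resolution=0.005)
    pre.write_spectra(matrix, outdir / "spectra.tsv")
    pre.write_assignment_map(truth.assignment_map, outdir / "assignment.yaml")
    _write_truth(truth, outdir / "truth.json")
    topos = syn.toy_pathways_for_library(names, n_pathways=3)
    syn.make_toy_kgml(topos, outdir / "kgml")
    return {
        "spectra": str(outdir / "spectra.tsv"),
        "assignment": str(outdir / "assignment.yaml"),
        "truth": str(outdir / "truth.json"),
        "kgml_dir": str(outdir / "kgml"),
        "n_planted_correlations": len(truth.true_correlations),
    }
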