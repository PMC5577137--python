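"""End-to-end orchestration of the subtype-discovery analysis.

Stage order follows the analysis narrative: preprocessing, SAM between ER+
and TNBC, hierarchical clustering and TN-like labelling, a second SAM
between ER-true and TN-like, the graphical-model stage, E-Flux FBA on the
bundled Warburg network, the compound covariate classifier with LOOCV and
permutation significance, survival evaluation, and the cohort table.  All
stage outputs are plain TSV/JSON, and a manifest records seeds, parameters
and per-stage shapes so any run can be reproduced or resumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import classify, cohort, diffexp, fba, network, preprocess, survival
from .synth import CohortSpec, SyntheticCohort, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("tnlike.pipeline")

# group-dependent metabolic programme used to drive the toy FBA stage:
# glycolysis/glutaminolysis/LDH genes are elevated in TN-like and TNBC
# tumours, the lumped oxidative step is low in every tumour (Warburg), and
# a constant highly expressed housekeeping gene (ACTB, on the ATP
# maintenance reaction) anchors each tumour's GPR maximum so that the
# per-tumour normalisation preserves between-group differences.
_GLYCO_GENES = ("SLC2A1", "SLC1A5", "HK1", "GAPDH", "PKM", "GLS", "GLUD1",
                "LDHA", "LDHB", "G6PD")
_OX_GENES = ("PDHA1", "SDHA", "NDUFA1")
_HOUSEKEEPING = ("ACTB",)


@dataclass
class PipelineConfig:
    """Validated stage toggles and parameters for one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0
    # preprocessing
    min_frac: float = 0.75
    min_peptides: int = 2
    impute_width: float = 0.3
    impute_shift: float = 1.8
    # differential expression
    sam_n_perm: int = 300
    sam_fdr: float = 0.05
    # network
    run_network: bool = True
    stepw_max_edges: int = 10
    stepw_max_features: int = 40     # stepwise stage only below this size
    node_max_size: int = 30
    # fba
    run_fba: bool = True
    metabolic_shift: float = 1.0
    # classifier
    run_classifier: bool = True
    ccp_alpha: float = 0.05
    ccp_n_perm: int = 0              # label permutations (0 = skip)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        cohort_doc = doc.pop("cohort", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        spec_known = set(CohortSpec.__dataclass_fields__)
        bad = set(cohort_doc) - spec_known
        if bad:
            raise ValueError(f"unknown cohort keys: {sorted(bad)}")
        if "n_per_group" in cohort_doc:
            cohort_doc["n_per_group"] = tuple(cohort_doc["n_per_group"])
        if "surv5" in cohort_doc:
            cohort_doc["surv5"] = tuple(cohort_doc["surv5"])
        spec = CohortSpec(**cohort_doc)
        cfg = cls(cohort=spec, **doc)
        spec.validate()
        return cfg


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run (mirrored on disk as TSV/JSON)."""

    config: PipelineConfig
    cohort_data: SyntheticCohort
    zscored: pd.DataFrame
    de_er_vs_tnbc: diffexp.DeResult
    subtype: pd.Series
    de_ertrue_vs_tnlike: diffexp.DeResult | None = None
    nodes: list | None = None
    node_pvalues: pd.DataFrame | None = None
    growth: fba.GrowthComparison | None = None
    cv_report: classify.CvReport | None = None
    km_5y: dict | None = None
    logrank_p: dict | None = None
    cox: pd.DataFrame | None = None
    cohort_table: cohort.CohortTable | None = None
    run_dir: Path | None = None


def _metabolic_abundance(
    labels: pd.Series, shift: float, seed: int
) -> pd.DataFrame:
    """Synthetic per-tumour abundances for the toy-network genes."""
    rng = np.random.default_rng(seed)
    genes = list(_GLYCO_GENES) + list(_OX_GENES) + list(_HOUSEKEEPING)
    base = pd.DataFrame(
        10.0 * np.exp(0.25 * rng.standard_normal((len(genes), len(labels)))),
        index=genes,
        columns=labels.index,
    )
    hot = labels.isin(["TN-like", "TNBC"]).to_numpy()
    base.loc[list(_GLYCO_GENES), hot] *= np.exp(shift)
    base.loc[list(_OX_GENES)] *= 0.1   # oxidative step low everywhere (Warburg)
    base.loc[list(_HOUSEKEEPING)] = 100.0   # constant normalisation ceiling
    return base


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic-cohort analysis; optionally write artifacts."""
    config.cohort.validate()
    run_dir = None
    if out_dir is not None:
        run_dir = Path(out_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tnlike_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": {},
    }
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest["config"] = json.loads(cfg_json)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

    # --- synthetic cohort -------------------------------------------------
    log.info("generating cohort (seed=%d)", config.cohort.seed)
    data = generate_cohort(config.cohort)
    ann = data.annotation
    manifest["stages"]["synth"] = {
        "n_samples": int(ann.shape[0]),
        "n_proteins": int(data.expression.data.shape[0]),
        "n_mirna": int(data.mirna.shape[0]),
    }

    # --- preprocessing ----------------------------------------------------
    er_status = ann["er_status"]
    mat = preprocess.filter_quantifiable(
        data.expression, er_status, min_frac=config.min_frac,
        min_peptides=config.min_peptides,
    )
    mat = preprocess.log2_transform(mat)
    mat = preprocess.impute_downshift(
        mat, config.impute_width, config.impute_shift, seed=config.seed
    )
    mat = preprocess.zscore_rows(mat)
    if ann["batch"].nunique() > 1:
        mat = preprocess.correct_batch(mat, ann["batch"])
    z = mat.data
    manifest["stages"]["preprocess"] = {"n_features": int(z.shape[0])}
    log.info("preprocessing: %d quantifiable proteins", z.shape[0])

    # --- SAM: ER+ vs TNBC, cluster, label TN-like -------------------------
    de1 = diffexp.sam_fdr(
        z, er_status, n_perm=config.sam_n_perm, fdr_cut=config.sam_fdr,
        seed=config.seed + 1,
    )
    selected = de1.selected
    if len(selected) < 2:
        raise RuntimeError("SAM selected fewer than 2 proteins; cannot cluster")
    _, clusters = diffexp.cluster_average_pearson(z.loc[selected])
    subtype = diffexp.label_tn_like(clusters, er_status)
    manifest["stages"]["diffexp"] = {
        "n_selected_er_vs_tnbc": int(len(selected)),
        "n_tn_like": int((subtype == "TN-like").sum()),
        "s0": de1.s0,
    }
    log.info("SAM ER+ vs TNBC: %d proteins; %d TN-like tumours",
             len(selected), (subtype == "TN-like").sum())

    # --- SAM: ER-true vs TN-like ------------------------------------------
    de2 = None
    er_pos = subtype[subtype != "TNBC"].index
    n_tnlike = (subtype == "TN-like").sum()
    if n_tnlike >= 2 and (subtype == "ER-true").sum() >= 2:
        de2 = diffexp.sam_fdr(
            z[er_pos], subtype[er_pos], n_perm=config.sam_n_perm,
            fdr_cut=config.sam_fdr, seed=config.seed + 2,
        )
        manifest["stages"]["diffexp"]["n_selected_ertrue_vs_tnlike"] = int(
            len(de2.selected)
        )

    # --- graphical model ---------------------------------------------------
    nodes = node_pvalues = None
    if config.run_network:
        feats = pd.Index(selected)
        if de2 is not None:
            feats = feats.union(de2.selected)
        mirna_z = preprocess.zscore_rows(data.mirna)
        net_matrix = pd.concat([z.loc[feats], mirna_z])
        kind = pd.Series("protein", index=net_matrix.index)
        kind.loc[data.mirna.index] = "mirna"
        graph = network.min_bic_forest(net_matrix)
        if net_matrix.shape[0] <= config.stepw_max_features and config.stepw_max_edges:
            graph = network.stepw_add(graph, net_matrix, config.stepw_max_edges)
        nodes = network.split_functional_nodes(graph, max_size=config.node_max_size)
        rows = []
        for nd in nodes:
            if all(kind.get(m) == "mirna" for m in nd.members):
                continue
            act = network.node_activity(nd, net_matrix, feature_kind=kind)
            row = {"node": nd.node_id, "size": len(nd.members)}
            if n_tnlike >= 3:
                _, row["p_ertrue_vs_tnlike"] = network.compare_activity(
                    act[er_pos], subtype[er_pos]
                )
            rows.append(row)
        node_pvalues = pd.DataFrame(rows).set_index("node") if rows else None
        manifest["stages"]["network"] = {
            "n_vertices": int(graph.graph.number_of_nodes()),
            "n_edges": int(graph.graph.number_of_edges()),
            "n_functional_nodes": len(nodes),
        }
        log.info("network: %d edges, %d functional nodes",
                 graph.graph.number_of_edges(), len(nodes))

    # --- E-Flux FBA on the toy Warburg network -----------------------------
    growth = None
    if config.run_fba:
        model = fba.load_toy_model("toy_warburg")
        abundance = _metabolic_abundance(
            subtype, config.metabolic_shift, config.seed + 3
        )
        growth = fba.growth_by_group(model, abundance, subtype,
                                     reference_group="ER-true")
        manifest["stages"]["fba"] = {
            "n_solved": int(len(growth.objectives)),
            "median_growth": {
                g: float(growth.objectives[growth.labels == g].median())
                for g in pd.unique(growth.labels)
            },
        }
    elif run_dir is not None:
        manifest["stages"]["fba"] = {"skipped": True}

    # --- classifier ---------------------------------------------------------
    cv_report = None
    if config.run_classifier and n_tnlike >= 3:
        sub_z = z[er_pos]
        cv_report = classify.loocv(sub_z, subtype[er_pos], alpha=config.ccp_alpha)
        if config.ccp_n_perm:
            cv_report = classify.permutation_significance(
                sub_z, subtype[er_pos], n_perm=config.ccp_n_perm,
                alpha=config.ccp_alpha, seed=config.seed + 4,
                observed_error=cv_report.loocv_error,
            )
        manifest["stages"]["classifier"] = {
            "loocv_error": cv_report.loocv_error,
            "permutation_p": cv_report.permutation_p,
        }
        log.info("classifier LOOCV error %.3f", cv_report.loocv_error)

    # --- survival -----------------------------------------------------------
    km_5y, logrank_p = {}, {}
    sdata_all = survival.SurvivalData(ann["dmfs_months"], ann["event"])
    for g in pd.unique(subtype):
        idx = subtype.index[subtype == g]
        curve = survival.km_estimate(
            survival.SurvivalData(
                ann.loc[idx, "dmfs_months"], ann.loc[idx, "event"]
            ),
            label=str(g),
        )
        km_5y[g] = survival.survival_at_5y(curve)
    if n_tnlike >= 2:
        _, logrank_p["ER-true_vs_TN-like"] = survival.logrank(
            survival.SurvivalData(
                ann.loc[er_pos, "dmfs_months"], ann.loc[er_pos, "event"]
            ),
            subtype[er_pos],
        )
    _, logrank_p["three_group"] = survival.logrank(sdata_all, subtype)
    cox = None
    if n_tnlike >= 2:
        cov = pd.DataFrame({"tn_like": (subtype[er_pos] == "TN-like").astype(float)})
        try:
            cox = survival.cox_fit(
                survival.SurvivalData(
                    ann.loc[er_pos, "dmfs_months"], ann.loc[er_pos, "event"], cov
                )
            )
        except Exception as exc:  # separation / too few events at small n
            log.warning("Cox fit skipped: %s", exc)
    manifest["stages"]["survival"] = {
        "km_5y": {k: float(v) for k, v in km_5y.items()},
        "logrank_p": {k: float(v) for k, v in logrank_p.items()},
    }

    # --- cohort table -------------------------------------------------------
    table_ann = ann.assign(subtype=subtype)
    cohort_table = cohort.summarize(
        table_ann, variables=["group", "batch", "event"], column="subtype"
    )

    result = PipelineResult(
        config=config,
        cohort_data=data,
        zscored=z,
        de_er_vs_tnbc=de1,
        subtype=subtype,
        de_ertrue_vs_tnlike=de2,
        nodes=nodes,
        node_pvalues=node_pvalues,
        growth=growth,
        cv_report=cv_report,
        km_5y=km_5y,
        logrank_p=logrank_p,
        cox=cox,
        cohort_table=cohort_table,
        run_dir=run_dir,
    )

    if run_dir is not None:
        _write_artifacts(result, manifest, run_dir)
    return result


def _write_artifacts(result: PipelineResult, manifest: dict, run_dir: Path) -> None:
    preprocess.write_matrix_tsv(result.zscored, run_dir / "expression_zscored.tsv")
    ann = result.cohort_data.annotation.assign(subtype=result.subtype)
    ann.to_csv(run_dir / "annotation.tsv", sep="\t")
    result.de_er_vs_tnbc.table.to_csv(run_dir / "sam_er_vs_tnbc.tsv", sep="\t")
    if result.de_ertrue_vs_tnlike is not None:
        result.de_ertrue_vs_tnlike.table.to_csv(
            run_dir / "sam_ertrue_vs_tnlike.tsv", sep="\t"
        )
    if result.node_pvalues is not None:
        result.node_pvalues.to_csv(run_dir / "functional_nodes.tsv", sep="\t")
    if result.growth is not None:
        result.growth.objectives.to_frame().assign(
            subtype=result.growth.labels
        ).to_csv(run_dir / "fba_growth.tsv", sep="\t")
    if result.cox is not None:
        result.cox.to_csv(run_dir / "cox.tsv", sep="\t")
    result.cohort_table.table.to_csv(run_dir / "cohort_table.tsv", sep="\t")
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
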