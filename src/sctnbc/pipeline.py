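"""Pipeline orchestration: staged runs driven by a YAML/dict config.

Stages (canonical order): ``simulate``, ``qc``, ``normalize``, ``celltype``,
``cnv``, ``cluster``, ``signature``, ``survive``.  Each stage writes TSV/JSON
outputs into the run directory and records parameters plus record counts in
``run_summary.json``.  Runs are deterministic given the config seed; derived
per-stage seeds are fixed offsets.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import celltype as ct
from . import clustering as cl
from . import cnv as cnvmod
from . import core_io as io
from . import qc as qcmod
from . import signatures as sig
from . import survival as surv
from . import synthetic as syn
from .types import SCTNBCError, ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "normalize", "celltype", "cnv", "cluster", "signature", "survive")

DEFAULT_PARAMS: dict = {
    "mad_k": 4.0,
    "cycling_mad_k": 2.0,
    "prevalence": 0.95,
    "expression_threshold": 0.1,
    "window": 100,
    "clip": 3.0,
    "min_mean": 0.1,
    "margin": 1.1,
    "majority": 0.7,
    "ruv_k": 1,
    "n_control_genes": 500,
    "count_mode": "mode_anchored",
    "size_factor_method": "median_ratio",
    "n_top": 100,
    "fdr": 0.05,
    "dc_percentile": 2.0,
    "carrier_percentile": 95.0,
    "survival_beta": 1.0,
    "survival_n_samples": 300,
    "survival_censor_rate": 0.3,
    "signature_size": 30,
}

# fixed per-stage seed offsets (design decision: one config seed, derived streams)
SEED_OFFSETS = {"simulate": 0, "cluster": 11, "survive": 13, "celltype": 17}


class PipelineError(SCTNBCError):
    pass


class Pipeline:
    """Holds run state, loads stage inputs lazily, writes stage outputs."""

    def __init__(self, config: dict, out_dir: str):
        self.config = dict(config)
        self.params = {**DEFAULT_PARAMS, **(config.get("params") or {})}
        self.seed = int(config.get("seed", 0))
        self.out_dir = out_dir
        os.makedirs(out_dir, exist_ok=True)
        self.state: dict = {}
        self.summary: dict = {"seed": self.seed, "params": self.params, "stages": {}}

    # ----------------------------------------------------------------- utils
    def _path(self, name: str) -> str:
        return os.path.join(self.out_dir, name)

    def _stage_seed(self, stage: str) -> int:
        return self.seed + SEED_OFFSETS.get(stage, 0)

    def _write_table(self, name: str, df: pd.DataFrame, index: bool = False) -> None:
        df.to_csv(self._path(name), sep="\t", index=index, float_format="%.10g")

    def _record(self, stage: str, **info) -> None:
        self.summary["stages"].setdefault(stage, {}).update(info)

    def _require(self, key: str, producer: str, loader=None):
        """Fetch a state item, loading it from the run directory if a prior
        standalone run produced it; otherwise fail naming the missing stage."""
        if key in self.state:
            return self.state[key]
        if loader is not None:
            try:
                value = loader()
            except (OSError, SCTNBCError):
                value = None
            if value is not None:
                self.state[key] = value
                return value
        raise PipelineError(
            f"missing input {key!r}: run stage {producer!r} first (no output in {self.out_dir})"
        )

    # ----------------------------------------------------------------- run
    def run(self, stages: list[str] | None = None) -> dict:
        requested = list(stages) if stages else list(STAGES)
        unknown = [s for s in requested if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        for stage in STAGES:
            if stage in requested:
                getattr(self, f"stage_{stage}")()
        with open(self._path("run_summary.json"), "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True, default=_json_default)
        return self.summary

    # ----------------------------------------------------------------- inputs
    def _load_inputs(self) -> None:
        """Read the raw inputs named in config['inputs'] into state."""
        inputs = self.config.get("inputs") or {}
        if "expression" in inputs and "expression" not in self.state:
            self.state["expression"] = io.read_expression(
                inputs["expression"],
                format=inputs.get("format", "tsv_dense"),
                unit=inputs.get("unit", "raw_tpm"),
                orientation=inputs.get("orientation", "cells_by_genes"),
            )
        if "cells" in inputs and "cells" not in self.state:
            self.state["cells"] = pd.read_csv(inputs["cells"], sep="\t")
        if "genes" in inputs and "genes" not in self.state:
            self.state["genes"] = io.read_gene_positions(inputs["genes"])
        if "normal_reference" in inputs and "normal_reference" not in self.state:
            self.state["normal_reference"] = io.read_expression(
                inputs["normal_reference"], unit="raw_tpm"
            )
        if "markers" in inputs and "marker_sets" not in self.state:
            self.state["marker_sets"] = {
                s.name: s.up_genes for s in io.read_gmt(inputs["markers"])
            }
        if "cycling" in inputs and "cycling_sets" not in self.state:
            sets = {s.name.lower(): s.up_genes for s in io.read_gmt(inputs["cycling"])}
            self.state["cycling_sets"] = sets
        if "segments" in inputs and "segments" not in self.state:
            self.state["segments"] = io.read_segments(inputs["segments"])
        if "cohort" in inputs and "cohort" not in self.state:
            cohort, bulk = io.read_survival_cohort(inputs["cohort"])
            self.state["cohort"], self.state["bulk"] = cohort, bulk
        if "signatures" in inputs and "signatures" not in self.state:
            self.state["signatures"] = io.read_gmt(inputs["signatures"])

    # ----------------------------------------------------------------- stages
    def stage_simulate(self) -> None:
        sim_cfg = self.config.get("simulate")
        if sim_cfg is None:
            raise PipelineError("stage 'simulate' requires a 'simulate' config section")
        cfg = _build_sim_config(sim_cfg, default_seed=self._stage_seed("simulate"))
        expr, cells, genes, truth = syn.generate_tumor_dataset(cfg)
        normal_ref = syn.generate_normal_reference(cfg, n_cells=int(sim_cfg.get("n_normal", 60)))
        self.state.update(
            expression=expr,
            cells=cells,
            genes=genes,
            truth=truth,
            normal_reference=normal_ref,
            marker_sets=truth.marker_sets,
            cycling_sets=truth.cycling_sets,
        )
        io.write_expression(self._path("expression.tsv"), expr)
        io.write_expression(self._path("normal_reference.tsv"), normal_ref)
        self._write_table("cells.tsv", cells)
        io.write_gene_positions(self._path("genes.tsv"), genes)
        self._write_table("truth_cells.tsv", truth.cells)
        with open(self._path("truth_sets.json"), "w") as fh:
            json.dump(
                {
                    "marker_sets": truth.marker_sets,
                    "cycling_sets": truth.cycling_sets,
                    "cnv_blocks": truth.cnv_blocks,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        io.write_gmt(
            self._path("markers.gmt"),
            [GeneSignature(t, g) for t, g in truth.marker_sets.items()],
        )
        self._record("simulate", n_cells=expr.n_cells, n_genes=expr.n_genes, seed=cfg.seed)

    def stage_qc(self) -> None:
        self._load_inputs()
        expr = self._require("expression", "simulate")
        cells = self._require("cells", "simulate")
        metrics = qcmod.compute_cell_qc_metrics(
            expr, threshold=self.params["expression_threshold"]
        )
        mad_res = qcmod.filter_cells_by_mad(metrics, k=self.params["mad_k"])
        expr_cells = expr.subset_cells(mad_res.kept_cells)
        patient = cells.set_index("cell_id")["patient_id"]
        kept_genes = qcmod.filter_genes_by_prevalence(
            expr_cells,
            patient.loc[expr_cells.cell_ids],
            threshold=self.params["expression_threshold"],
            prevalence=self.params["prevalence"],
        )
        filtered = expr_cells.subset_genes(kept_genes)
        self.state["qc_metrics"] = metrics
        self.state["qc_expression"] = filtered
        self._write_table("qc_metrics.tsv", metrics)
        with open(self._path("kept_cells.txt"), "w") as fh:
            fh.write("\n".join(mad_res.kept_cells) + "\n")
        with open(self._path("kept_genes.txt"), "w") as fh:
            fh.write("\n".join(kept_genes) + "\n")
        io.write_expression(self._path("qc_expression.tsv"), filtered)
        self._record(
            "qc",
            cells_in=expr.n_cells,
            cells_removed=len(mad_res.removed_cells),
            cells_out=filtered.n_cells,
            removed_per_metric=mad_res.removed_per_metric,
            genes_in=expr.n_genes,
            genes_out=filtered.n_genes,
        )

    def stage_normalize(self) -> None:
        self._load_inputs()
        expr = self._require(
            "qc_expression",
            "qc",
            loader=lambda: io.read_expression(self._path("qc_expression.tsv"), unit="raw_tpm"),
        )
        counts = qcmod.estimate_relative_counts(expr, mode=self.params["count_mode"])
        factors = qcmod.compute_size_factors(counts, method=self.params["size_factor_method"])
        positive = factors[factors > 0].index.tolist()
        counts_kept = counts.subset_cells(positive)
        normalized = qcmod.normalize_by_size_factors(counts_kept, factors)
        k = int(self.params["ruv_k"])
        if k > 0:
            controls = qcmod.least_variable_genes(
                normalized, n=int(self.params["n_control_genes"])
            )
            normalized = qcmod.remove_unwanted_variation(normalized, controls, k=k)
        self.state["size_factors"] = factors
        self.state["normalized"] = normalized
        self._write_table("size_factors.tsv", factors.reset_index())
        io.write_expression(self._path("normalized.tsv"), normalized)
        self._record(
            "normalize",
            cells_in=expr.n_cells,
            zero_factor_cells=int((factors == 0).sum()),
            cells_out=normalized.n_cells,
        )

    def stage_celltype(self) -> None:
        self._load_inputs()
        normalized = self._require(
            "normalized",
            "normalize",
            loader=lambda: io.read_expression(self._path("normalized.tsv"), unit="normalized_log"),
        )
        marker_sets = self._require("marker_sets", "simulate")
        coords = cl.embed_cells(normalized.values, seed=self._stage_seed("celltype"))
        clusters = cl.density_peak_cluster(coords, dc_percentile=self.params["dc_percentile"])
        types = ct.assign_cell_types(
            normalized,
            marker_sets,
            cluster_labels=clusters,
            margin=self.params["margin"],
            majority=self.params["majority"],
        )
        cycling_sets = self.state.get("cycling_sets")
        records = pd.DataFrame({"cell_id": normalized.cell_ids, "cell_type": types.to_numpy()})
        if cycling_sets:
            cyc = ct.classify_cycling(
                normalized,
                cycling_sets["g1s"],
                cycling_sets["g2m"],
                k=self.params["cycling_mad_k"],
            )
            records = records.merge(cyc, on="cell_id")
        cells = self.state.get("cells")
        if cells is not None:
            records = records.merge(
                cells[["cell_id", "patient_id"]], on="cell_id", how="left"
            )
        self.state["cell_records"] = records
        self._write_table("cell_records.tsv", records)
        counts = types.value_counts().to_dict()
        self._record("celltype", n_cells=len(records), type_counts=counts)

    def stage_cnv(self) -> None:
        self._load_inputs()
        inputs = self.config.get("inputs") or {}
        if "genes" not in self.state and "genes" not in inputs and "simulate" not in self.config:
            raise PipelineError("stage 'cnv' requires a gene-position table ('genes' input)")
        expr = self._require(
            "qc_expression",
            "qc",
            loader=lambda: io.read_expression(self._path("qc_expression.tsv"), unit="raw_tpm"),
        )
        genes = self._require("genes", "simulate")
        normal_ref = self._require("normal_reference", "simulate")
        records = self.state.get("cell_records")
        if records is None:
            records = _maybe_read_tsv(self._path("cell_records.tsv"))
        if records is not None and "cell_type" in records:
            epi = set(records.loc[records["cell_type"] == "epithelial", "cell_id"])
            keep = [c for c in expr.cell_ids if c in epi]
            if keep:
                expr = expr.subset_cells(keep)
        # half the normal cells define the subtraction baseline; the held-out
        # half provides the burden null
        n_ref = normal_ref.n_cells
        baseline = normal_ref.subset_cells(np.arange(n_ref // 2))
        heldout = normal_ref.subset_cells(np.arange(n_ref // 2, n_ref))
        centered = cnvmod.reference_normalize(expr, baseline)
        cnv = cnvmod.infer_cnv_profiles(
            centered,
            genes,
            window=int(self.params["window"]),
            clip=self.params["clip"],
            min_mean=self.params["min_mean"],
        )
        ref_centered = cnvmod.reference_normalize(heldout, baseline)
        ref_cnv = cnvmod.infer_cnv_profiles(
            centered=_restrict_scaled_mean(ref_centered, centered),
            gene_records=genes,
            window=int(self.params["window"]),
            clip=self.params["clip"],
            min_mean=self.params["min_mean"],
        )
        calls = cnvmod.call_cnv_subclones(
            cnv, ref_cnv, percentile=self.params["carrier_percentile"]
        )
        cormap = cnvmod.correlation_map(
            np.log2(expr.values + 1.0), cell_ids=expr.cell_ids
        )
        self.state["cnv"] = cnv
        self.state["subclones"] = calls
        cnv_df = pd.DataFrame(cnv.values, index=cnv.cell_ids, columns=cnv.gene_ids)
        cnv_df.index.name = "cell_id"
        self._write_table("cnv_matrix.tsv", cnv_df, index=True)
        self._write_table("subclones.tsv", calls.calls)
        self._write_table("correlation.tsv", cormap.matrix, index=True)
        self._record(
            "cnv",
            shared_genes=centered.n_shared_genes,
            cnv_genes=len(cnv.gene_ids),
            carriers=int(calls.calls["carrier"].sum()),
            n_subclones=calls.n_subclones,
        )

    def stage_cluster(self) -> None:
        self._load_inputs()
        normalized = self._require(
            "normalized",
            "normalize",
            loader=lambda: io.read_expression(self._path("normalized.tsv"), unit="normalized_log"),
        )
        records = self._require(
            "cell_records",
            "celltype",
            loader=lambda: _maybe_read_tsv(self._path("cell_records.tsv")),
        )
        epi_ids = records.loc[records["cell_type"] == "epithelial", "cell_id"].tolist()
        if len(epi_ids) < 10:
            raise PipelineError("fewer than 10 epithelial cells to cluster")
        epi = normalized.subset_cells(epi_ids)
        cells = self._require("cells", "simulate")
        patient = cells.set_index("cell_id")["patient_id"].loc[epi.cell_ids]
        residuals = cl.regress_out_patient(epi, patient)
        coords = cl.embed_cells(residuals, seed=self._stage_seed("cluster"))
        labels = cl.density_peak_cluster(coords, dc_percentile=self.params["dc_percentile"])
        out = pd.DataFrame(
            {
                "cell_id": epi.cell_ids,
                "epithelial_cluster": labels,
                "tsne1": coords[:, 0],
                "tsne2": coords[:, 1],
            }
        )
        self.state["epithelial_clusters"] = out
        self.state["epithelial_expression"] = epi
        self._write_table("clusters.tsv", out[["cell_id", "epithelial_cluster"]])
        self._write_table("embedding.tsv", out[["cell_id", "tsne1", "tsne2"]])
        sizes = out["epithelial_cluster"].value_counts().sort_index().to_dict()
        self._record("cluster", n_epithelial=len(out), cluster_sizes={int(k): int(v) for k, v in sizes.items()})

    def stage_signature(self) -> None:
        self._load_inputs()
        clusters = self._require(
            "epithelial_clusters",
            "cluster",
            loader=lambda: _maybe_read_tsv(self._path("clusters.tsv")),
        )
        normalized = self._require(
            "normalized",
            "normalize",
            loader=lambda: io.read_expression(self._path("normalized.tsv"), unit="normalized_log"),
        )
        epi = normalized.subset_cells(clusters["cell_id"].tolist())
        labels = clusters["epithelial_cluster"].to_numpy()
        target = int(pd.Series(labels).value_counts().index[0])  # largest cluster
        table = sig.derive_cluster_signature(
            epi,
            labels,
            target,
            n_top=int(self.params["n_top"]),
            fdr=self.params["fdr"],
        )
        self.state["cluster_signature"] = table
        self.state["target_cluster"] = target
        self._write_table("cluster_signature.tsv", table)
        result: dict = {"target_cluster": target, "n_signature_genes": len(table)}
        segments = self.state.get("segments")
        if segments is not None:
            genes = self._require("genes", "simulate")
            gain_genes = sig.genes_in_segments(segments, genes, call="gain")
            overlap, fold, p = sig.overrepresentation_test(
                table["gene_id"].tolist(),
                [g for g in gain_genes if g in set(epi.gene_ids)],
                epi.gene_ids,
            )
            result["wes_gain_overlap"] = {"overlap": overlap, "fold": fold, "p": p}
        ext = self.state.get("signatures")
        if ext:
            scores = sig.score_signatures(epi, ext)
            self._write_table("signature_scores.tsv", scores.reset_index())
            if scores.shape[1] >= 2:
                assigned = sig.assign_to_signature(scores)
                self._write_table(
                    "signature_assignments.tsv", assigned.rename("signature").reset_index()
                )
        with open(self._path("signature_summary.json"), "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True, default=_json_default)
        self._record("signature", **result)

    def stage_survive(self) -> None:
        self._load_inputs()
        if "cohort" in self.state:
            cohort, bulk = self.state["cohort"], self.state.get("bulk")
            sig_obj = _first_signature(self.state.get("signatures"))
            if sig_obj is None:
                sig_table = self._require(
                    "cluster_signature",
                    "signature",
                    loader=lambda: _maybe_read_tsv(self._path("cluster_signature.tsv")),
                )
                sig_obj = GeneSignature("cluster_signature", sig_table["gene_id"].tolist())
        else:
            sig_table = self._require(
                "cluster_signature",
                "signature",
                loader=lambda: _maybe_read_tsv(self._path("cluster_signature.tsv")),
            )
            n_genes = min(int(self.params["signature_size"]), len(sig_table))
            if n_genes == 0:
                raise PipelineError("empty cluster signature; cannot build survival cohort")
            sig_obj = GeneSignature("cluster_signature", sig_table["gene_id"].head(n_genes).tolist())
            cohort, bulk, _ = syn.generate_survival_cohort(
                n_samples=int(self.params["survival_n_samples"]),
                signature=sig_obj,
                beta=self.params["survival_beta"],
                censor_rate=self.params["survival_censor_rate"],
                seed=self._stage_seed("survive"),
            )
            io.write_survival_cohort(self._path("cohort.tsv"), cohort, bulk)
        if bulk is None:
            raise PipelineError("survival cohort has no expression columns to score")
        scores = surv.score_bulk_samples(bulk, sig_obj)
        quartiles = surv.stratify_by_quartiles(scores)
        km_tables = []
        for q in sorted(quartiles.unique()):
            m = quartiles == q
            km = surv.km_estimate(cohort.loc[m.to_numpy(), "time"], cohort.loc[m.to_numpy(), "event"])
            km["quartile"] = q
            km_tables.append(km)
        stat, df, p_logrank = surv.logrank_test(
            quartiles.to_numpy(), cohort["time"].to_numpy(), cohort["event"].to_numpy()
        )
        cox = surv.cox_univariate(
            scores.to_numpy(), cohort["time"].to_numpy(), cohort["event"].to_numpy()
        )
        self._write_table("km.tsv", pd.concat(km_tables, ignore_index=True))
        results = {
            "logrank": {"statistic": stat, "df": df, "p": p_logrank},
            "cox": {
                "coef": cox.coef,
                "hazard_ratio": cox.hazard_ratio,
                "se": cox.se,
                "p": cox.p,
            },
            "signature": sig_obj.name,
            "n_samples": len(cohort),
        }
        with open(self._path("survival_tests.json"), "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=_json_default)
        self.state["survival_results"] = results
        self._record("survive", **results)


def _restrict_scaled_mean(ref_centered, tumor_centered):
    """Give the reference run the tumor's gene filter, so both CNV matrices
    cover the same genes."""
    lookup = dict(zip(tumor_centered.gene_ids, tumor_centered.scaled_mean))
    ref_centered.scaled_mean = np.array([lookup.get(g, -np.inf) for g in ref_centered.gene_ids])
    return ref_centered


def _maybe_read_tsv(path: str) -> pd.DataFrame | None:
    if not os.path.exists(path):
        return None
    return pd.read_csv(path, sep="\t")


def _first_signature(signatures) -> GeneSignature | None:
    if signatures:
        return signatures[0]
    return None


def _build_sim_config(sim_cfg: dict, default_seed: int) -> syn.SimulationConfig:
    cfg = dict(sim_cfg)
    cfg.pop("n_normal", None)
    specs = [
        s if isinstance(s, syn.CNVSpec) else syn.CNVSpec(**s) for s in cfg.pop("cnv_specs", [])
    ]
    if "cell_type_fractions" in cfg:
        cfg["cell_type_fractions"] = dict(cfg["cell_type_fractions"])
    if "cycling_cell_types" in cfg:
        cfg["cycling_cell_types"] = tuple(cfg["cycling_cell_types"])
    cfg.setdefault("seed", default_seed)
    return syn.SimulationConfig(cnv_specs=specs, **cfg)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: dict, out_dir: str, stages: list[str] | None = None) -> dict:
    """Run the configured stages into ``out_dir`` and return the run summary."""
    return Pipeline(config, out_dir).run(stages)
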