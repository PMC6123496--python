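"""Synthetic tumor and survival-cohort generators with ground truth.

The expression model is log-normal with multiplicative effects: each cell's
raw value for gene g is ``exp(Normal(mu_g + effects, sigma))`` where effects
accumulate (in natural-log space) marker elevation for the cell's type,
cycling-program elevation for cycling cells, copy-number dosage for carrier
cells, and a per-patient batch offset.  Dosage is applied *before* the final
per-cell rescale to TPM, so a gain block slightly depresses all other genes —
the compositional artifact the CNV inference has to tolerate.  Dropout is
an independent Bernoulli zeroing by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SCTNBCError, ExpressionMatrix, GeneSignature, TPM_TOTAL, assign_order_index

LN2 = math.log(2.0)


@dataclass
class CNVSpec:
    """A contiguous gene-dosage block carried by part of one patient's cells."""

    patient: str
    carrier_fraction: float
    block_start: int  # 0-based order-index range, half-open
    block_end: int
    dosage: float
    block_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.carrier_fraction <= 1.0):
            raise SCTNBCError("carrier_fraction must lie in [0, 1]")
        if self.dosage <= 0:
            raise SCTNBCError("dosage multiplier must be > 0")
        if self.block_start >= self.block_end:
            raise SCTNBCError("empty CNV block")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tumor generator (see module docstring)."""

    n_patients: int = 4
    cells_per_patient: int = 80
    n_genes: int = 1000
    cell_type_fractions: dict[str, float] = field(
        default_factory=lambda: {"epithelial": 0.6, "t_cell": 0.2, "macrophage": 0.1, "stroma": 0.1}
    )
    marker_genes_per_type: int = 25
    marker_effect: float = 3.0  # log2 fold elevation on marker genes
    cycling_fraction: float = 0.2
    cycling_effect: float = 2.0  # log2 fold on cycling program genes
    cycling_genes_per_phase: int = 20
    cycling_cell_types: tuple[str, ...] = ("epithelial",)
    # shared epithelial subpopulation programs crossing patients (0 = none)
    n_epithelial_programs: int = 0
    program_genes_per_set: int = 30
    program_effect: float = 2.0  # log2 fold on a program's genes
    cnv_specs: list[CNVSpec] = field(default_factory=list)
    patient_batch_sd: float = 0.0  # sd of per-patient per-gene log offsets
    baseline_log_mean: float = 2.0  # natural-log scale
    baseline_log_mean_sd: float = 1.0  # spread of per-gene log means
    baseline_log_sd: float = 0.5  # per-cell log noise
    dropout_rate: float = 0.0
    n_chromosomes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cell_type_fractions.values())
        if any(f < 0 or f > 1 for f in self.cell_type_fractions.values()):
            raise SCTNBCError("cell type fractions must lie in [0, 1]")
        if total > 1.0 + 1e-9:
            raise SCTNBCError(f"cell type fractions sum to {total:.3f} > 1")
        for spec in self.cnv_specs:
            if spec.block_end > self.n_genes:
                raise SCTNBCError("CNV block range exceeds gene count")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise SCTNBCError("dropout_rate must lie in [0, 1)")
        needed = (
            len(self.cell_type_fractions) * self.marker_genes_per_type
            + 2 * self.cycling_genes_per_phase
            + self.n_epithelial_programs * self.program_genes_per_set
        )
        if needed > self.n_genes:
            raise SCTNBCError("not enough genes for the requested marker and cycling sets")


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside a synthetic dataset."""

    cells: pd.DataFrame  # cell_id, patient_id, cell_type, cycling, cnv_carrier, cnv_block
    marker_sets: dict[str, list[str]]
    cycling_sets: dict[str, list[str]]  # keys g1s, g2m
    cnv_blocks: dict[str, dict]  # block_id -> {genes, patient, dosage, carriers}
    program_sets: dict[str, list[str]] = field(default_factory=dict)
    beta: float | None = None
    scores: pd.DataFrame | None = None  # survival cohorts: per-sample latent score


def _gene_rng(seed: int) -> np.random.Generator:
    # gene-level parameters get their own stream so tumor and normal-reference
    # draws share the same panel
    return np.random.default_rng([seed, 101])


def _gene_panel(config: SimulationConfig):
    """Deterministic gene ids, genomic layout and per-gene log means."""
    rng = _gene_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    per_chrom = int(np.ceil(n / config.n_chromosomes))
    chroms, starts = [], []
    for i in range(n):
        chroms.append(f"chr{i // per_chrom + 1}")
        starts.append((i % per_chrom) * 1000 + 1)
    genes = pd.DataFrame({"gene_id": gene_ids, "chromosome": chroms, "start": starts})
    genes["end"] = genes["start"] + 999
    genes = assign_order_index(genes)
    log_means = rng.normal(config.baseline_log_mean, config.baseline_log_mean_sd, n)
    return genes, log_means


def _assigned_sets(config: SimulationConfig):
    """Carve marker and cycling gene sets out of the panel, spread across it."""
    n = config.n_genes
    types = list(config.cell_type_fractions)
    rng = np.random.default_rng([config.seed, 202])
    # avoid CNV blocks so marker signal does not collide with dosage signal
    blocked = np.zeros(n, dtype=bool)
    for spec in config.cnv_specs:
        blocked[spec.block_start : spec.block_end] = True
    free = np.flatnonzero(~blocked)
    needed = (
        len(types) * config.marker_genes_per_type
        + 2 * config.cycling_genes_per_phase
        + config.n_epithelial_programs * config.program_genes_per_set
    )
    if needed > free.size:
        raise SCTNBCError("not enough genes outside CNV blocks for marker/cycling sets")
    chosen = rng.choice(free, size=needed, replace=False)
    marker_sets: dict[str, list[int]] = {}
    pos = 0
    for t in types:
        marker_sets[t] = sorted(chosen[pos : pos + config.marker_genes_per_type].tolist())
        pos += config.marker_genes_per_type
    cycling_sets = {
        "g1s": sorted(chosen[pos : pos + config.cycling_genes_per_phase].tolist()),
        "g2m": sorted(
            chosen[pos + config.cycling_genes_per_phase : pos + 2 * config.cycling_genes_per_phase].tolist()
        ),
    }
    pos += 2 * config.cycling_genes_per_phase
    program_sets: dict[str, list[int]] = {}
    for p in range(config.n_epithelial_programs):
        program_sets[f"program_{p + 1}"] = sorted(
            chosen[pos : pos + config.program_genes_per_set].tolist()
        )
        pos += config.program_genes_per_set
    return marker_sets, cycling_sets, program_sets


def generate_tumor_dataset(config: SimulationConfig):
    """Generate (expression raw_tpm, cell table, gene table, truth).

    Deterministic given ``config.seed``.
    """
    genes, log_means = _gene_panel(config)
    marker_idx, cycling_idx, program_idx = _assigned_sets(config)
    rng = np.random.default_rng([config.seed, 303])
    n_genes = config.n_genes

    patients = [f"P{p + 1}" for p in range(config.n_patients)]
    batch = {
        p: rng.normal(0.0, config.patient_batch_sd, n_genes) if config.patient_batch_sd > 0
        else np.zeros(n_genes)
        for p in patients
    }

    types = list(config.cell_type_fractions)
    fracs = np.array([config.cell_type_fractions[t] for t in types], dtype=float)
    leftover = 1.0 - fracs.sum()
    pool = types + (["unassigned"] if leftover > 1e-9 else [])
    probs = np.append(fracs, leftover) if leftover > 1e-9 else fracs
    probs = probs / probs.sum()

    rows = []
    loc_rows = []
    cnv_flags: dict[str, list[str]] = {}
    cell_counter = 0
    for p in patients:
        n_cells = config.cells_per_patient
        cell_types = rng.choice(pool, size=n_cells, p=probs)
        cycling = np.zeros(n_cells, dtype=bool)
        eligible = np.isin(cell_types, config.cycling_cell_types)
        cycling[eligible] = rng.random(eligible.sum()) < config.cycling_fraction
        program_names = sorted(program_idx)
        programs = (
            rng.choice(program_names, size=n_cells) if program_names else np.array([""] * n_cells)
        )

        # carrier assignment per CNV spec for this patient
        carrier_of: list[list[CNVSpec]] = [[] for _ in range(n_cells)]
        for spec in config.cnv_specs:
            if spec.patient != p:
                continue
            eligible_idx = np.flatnonzero(cell_types == "epithelial")
            k = int(round(spec.carrier_fraction * eligible_idx.size))
            chosen = rng.choice(eligible_idx, size=k, replace=False) if k else np.array([], int)
            for i in chosen:
                carrier_of[i].append(spec)

        for i in range(n_cells):
            cid = f"C{cell_counter:05d}"
            cell_counter += 1
            loc = log_means + batch[p]
            t = cell_types[i]
            if t in marker_idx:
                loc[marker_idx[t]] += config.marker_effect * LN2
            if cycling[i]:
                loc[cycling_idx["g1s"]] += config.cycling_effect * LN2
                loc[cycling_idx["g2m"]] += config.cycling_effect * LN2
            program = programs[i] if t == "epithelial" else ""
            if program:
                loc[program_idx[program]] += config.program_effect * LN2
            block_ids = []
            for spec in carrier_of[i]:
                loc[spec.block_start : spec.block_end] += math.log(spec.dosage)
                bid = spec.block_id or f"{spec.patient}:{spec.block_start}-{spec.block_end}"
                block_ids.append(bid)
                cnv_flags.setdefault(bid, []).append(cid)
            loc_rows.append(loc)
            rows.append(
                {
                    "cell_id": cid,
                    "patient_id": p,
                    "sort_protocol": "cd45_depleted",
                    "cell_type": t,
                    "cycling": bool(cycling[i]),
                    "program": program,
                    "cnv_carrier": bool(block_ids),
                    "cnv_block": ";".join(block_ids) if block_ids else "",
                }
            )

    loc = np.vstack(loc_rows)
    values = np.exp(rng.normal(loc, config.baseline_log_sd))
    if config.dropout_rate > 0:
        keep = rng.random(values.shape) >= config.dropout_rate
        values = values * keep
    values = _rescale_tpm(values)

    truth_cells = pd.DataFrame(rows)
    cells = truth_cells[["cell_id", "patient_id", "sort_protocol"]].copy()
    gid = genes["gene_id"].to_numpy()
    truth = SyntheticTruth(
        cells=truth_cells,
        marker_sets={t: gid[idx].tolist() for t, idx in marker_idx.items()},
        cycling_sets={k: gid[idx].tolist() for k, idx in cycling_idx.items()},
        program_sets={k: gid[idx].tolist() for k, idx in program_idx.items()},
        cnv_blocks={
            (spec.block_id or f"{spec.patient}:{spec.block_start}-{spec.block_end}"): {
                "genes": gid[spec.block_start : spec.block_end].tolist(),
                "patient": spec.patient,
                "dosage": spec.dosage,
                "carriers": cnv_flags.get(
                    spec.block_id or f"{spec.patient}:{spec.block_start}-{spec.block_end}", []
                ),
            }
            for spec in config.cnv_specs
        },
    )
    expr = ExpressionMatrix(values, truth_cells["cell_id"].tolist(), gid.tolist(), "raw_tpm")
    return expr, cells, genes, truth


def _rescale_tpm(values: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True)
    scale = np.where(totals > 0, TPM_TOTAL / np.where(totals > 0, totals, 1.0), 0.0)
    return values * scale


def generate_normal_reference(
    config: SimulationConfig, n_cells: int = 240, seed: int | None = None, dropout: bool = True
) -> ExpressionMatrix:
    """Baseline epithelial cells on the shared gene panel: no CNV, batch,
    cycling or program effects.  Dropout (a technical artifact, not a
    malignant effect) is applied at the config rate unless disabled."""
    if n_cells < 2:
        raise SCTNBCError("need at least 2 reference cells")
    genes, log_means = _gene_panel(config)
    marker_idx, _, _ = _assigned_sets(config)
    loc = log_means.copy()
    if "epithelial" in marker_idx:
        loc[marker_idx["epithelial"]] += config.marker_effect * LN2
    rng = np.random.default_rng([seed if seed is not None else config.seed, 404])
    values = np.exp(rng.normal(loc[None, :], config.baseline_log_sd, (n_cells, config.n_genes)))
    if dropout and config.dropout_rate > 0:
        values = values * (rng.random(values.shape) >= config.dropout_rate)
    values = _rescale_tpm(values)
    ids = [f"N{i:05d}" for i in range(n_cells)]
    return ExpressionMatrix(values, ids, genes["gene_id"].tolist(), "raw_tpm")


def generate_survival_cohort(
    n_samples: int,
    signature: GeneSignature,
    beta: float,
    censor_rate: float = 0.3,
    seed: int = 0,
    n_noise_genes: int = 50,
    baseline_hazard: float = 0.02,
):
    """Simulate a bulk cohort whose hazard depends on a latent signature score.

    Per sample, a standard-normal score ``s`` shifts the signature's up genes
    by ``+s`` (down genes by ``-s``) on the log-expression scale; event times
    are exponential with hazard ``baseline_hazard * exp(beta * s)``; censoring
    is by an independent exponential clock calibrated so that, at ``beta = 0``,
    roughly ``censor_rate`` of samples are censored.

    Returns ``(cohort, bulk_expr, truth)``.
    """
    if n_samples < 8:
        raise SCTNBCError("need at least 8 samples (quartiles undefined below that)")
    if not math.isfinite(beta):
        raise SCTNBCError("beta must be finite")
    if not (0.0 <= censor_rate < 1.0):
        raise SCTNBCError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng([seed, 505])

    sig_genes = list(signature.up_genes) + list(signature.down_genes)
    gene_ids = sig_genes + [f"NOISE{i:04d}" for i in range(n_noise_genes)]
    n_genes = len(gene_ids)
    base = rng.normal(5.0, 1.0, n_genes)

    s = rng.standard_normal(n_samples)
    expr = rng.normal(base[None, :], 0.5, (n_samples, n_genes))
    n_up = len(signature.up_genes)
    expr[:, :n_up] += s[:, None]
    if signature.down_genes:
        expr[:, n_up : len(sig_genes)] -= s[:, None]

    hazard = baseline_hazard * np.exp(beta * s)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    samples = [f"S{i:04d}" for i in range(n_samples)]
    cohort = pd.DataFrame({"sample": samples, "time": time, "event": event})
    bulk = ExpressionMatrix(expr, samples, gene_ids, "normalized_log")
    truth = SyntheticTruth(
        cells=pd.DataFrame({"cell_id": samples}),
        marker_sets={},
        cycling_sets={},
        cnv_blocks={},
        beta=beta,
        scores=pd.DataFrame({"sample": samples, "score": s}),
    )
    return cohort, bulk, truth
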