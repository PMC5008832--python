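"""Synthetic cohorts, qPCR tables, networks and clinical tables with planted truth.

The meta-cohort generator emulates the structure of the three public
HGU133a Barrett's-esophagus series the funnel was designed for: one
progressor (P-BE) dataset of 8 samples and two non-progressor (nonP-BE)
datasets of 7 and 18 samples, log2 intensities drawn from a two-component
(unexpressed / expressed) normal mixture, additive per-dataset gene-wise
batch shifts, and a configurable set of planted progression genes that are
both mean-shifted and exclusively expressed in P-BE samples.  Every
generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from beprog.types import (
    ClinicalRecord,
    CtTable,
    ExpressionMatrix,
    FrozenReference,
    SampleInfo,
    ValidationError,
    WeightedNetwork,
)


@dataclass(frozen=True)
class DatasetSpec:
    dataset_id: str
    group: str
    n_samples: int


def default_datasets() -> list[DatasetSpec]:
    """The meta-cohort composition: 8 P-BE plus 7 and 18 nonP-BE samples."""
    return [
        DatasetSpec("DS1", "P-BE", 8),
        DatasetSpec("DS2", "nonP-BE", 7),
        DatasetSpec("DS3", "nonP-BE", 18),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic meta-cohort.

    Intensity units are log2 throughout.  The defaults place the expressed
    and unexpressed components at typical microarray magnitudes, far enough
    apart (mu_expr - mu_unexpr > 4 sigma) that barcode calls are essentially
    noiseless at the default cutoff.
    """

    n_genes: int = 2000
    datasets: list[DatasetSpec] = field(default_factory=default_datasets)
    frac_expressed_baseline: float = 0.35
    mu_unexpr: float = 4.0
    sigma_unexpr: float = 0.5
    mu_expr: float = 9.0
    sigma_expr: float = 1.0
    batch_shift_sd: float = 0.5
    z_cut: float = 5.0
    planted_de: list[tuple[int, float]] = field(default_factory=list)
    planted_exclusive: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not self.datasets:
            raise ValidationError("at least one dataset spec required")
        if not (0 < self.frac_expressed_baseline < 1):
            raise ValidationError("frac_expressed_baseline must lie in (0, 1)")
        if self.sigma_unexpr <= 0 or self.sigma_expr <= 0:
            raise ValidationError("scale parameters must be > 0")
        if self.batch_shift_sd < 0:
            raise ValidationError("batch_shift_sd must be >= 0")
        if self.mu_expr <= self.mu_unexpr:
            raise ValidationError("mu_expr must exceed mu_unexpr")
        for idx, effect in self.planted_de:
            if not (0 <= idx < self.n_genes):
                raise ValidationError(f"planted DE index {idx} out of range")
            if not np.isfinite(effect):
                raise ValidationError("planted effects must be finite")
        for idx in self.planted_exclusive:
            if not (0 <= idx < self.n_genes):
                raise ValidationError(f"planted exclusive index {idx} out of range")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class TruthSet:
    """What was planted: effects, exclusive genes, and the per-sample state table."""

    planted_de: dict[str, float]
    planted_exclusive: list[str]
    expressed_state: pd.DataFrame  # genes x samples, bool

    @property
    def planted_genes(self) -> set[str]:
        return set(self.planted_de) | set(self.planted_exclusive)


def generate_meta_cohort(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], FrozenReference, TruthSet]:
    """Simulate the multi-dataset cohort plus its frozen reference and truth.

    Per dataset, each (gene, sample) intensity is drawn from the unexpressed
    or expressed normal component according to the gene's baseline state
    (shared across samples, so baseline bimodality carries no group signal)
    or, for planted-exclusive genes, expressed only in P-BE samples.  Planted
    mean effects are added to P-BE samples; each dataset receives its own
    gene-wise batch shift.  The frozen reference is built from the generating
    parameters, not refit from the data.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = config.gene_ids()
    n = config.n_genes

    baseline_state = rng.random(n) < config.frac_expressed_baseline
    excl_idx = np.array(sorted(set(config.planted_exclusive)), dtype=int)
    if excl_idx.size:
        baseline_state[excl_idx] = False  # exclusive genes are off outside P-BE
    effects = np.zeros(n)
    for idx, effect in config.planted_de:
        effects[idx] += effect

    # gene-aligned sorted reference quantiles from the clean baseline mixture
    ref_noise = rng.normal(size=n)
    ref_values = np.where(
        baseline_state,
        config.mu_expr + config.sigma_expr * ref_noise,
        config.mu_unexpr + config.sigma_unexpr * ref_noise,
    )
    ref = FrozenReference(
        gene_ids=gene_ids,
        mu_unexpr=np.full(n, config.mu_unexpr),
        sigma_unexpr=np.full(n, config.sigma_unexpr),
        z_cut=config.z_cut,
        ref_quantiles=np.sort(ref_values),
    )

    matrices: list[ExpressionMatrix] = []
    state_cols: dict[str, np.ndarray] = {}
    for spec in config.datasets:
        batch = (
            rng.normal(0.0, config.batch_shift_sd, size=n)
            if config.batch_shift_sd > 0
            else np.zeros(n)
        )
        cols = {}
        samples = []
        for j in range(spec.n_samples):
            state = baseline_state.copy()
            if spec.group == "P-BE" and excl_idx.size:
                state[excl_idx] = True
            mu = np.where(state, config.mu_expr, config.mu_unexpr)
            sigma = np.where(state, config.sigma_expr, config.sigma_unexpr)
            vals = mu + sigma * rng.normal(size=n) + batch
            if spec.group == "P-BE":
                vals = vals + effects
            sid = f"{spec.dataset_id}_S{j + 1:02d}"
            cols[sid] = vals
            state_cols[sid] = state
            samples.append(
                SampleInfo(sample_id=sid, dataset_id=spec.dataset_id, group=spec.group)
            )
        values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
        matrices.append(ExpressionMatrix(values, samples))

    truth = TruthSet(
        planted_de={gene_ids[i]: e for i, e in config.planted_de},
        planted_exclusive=[gene_ids[i] for i in sorted(set(config.planted_exclusive))],
        expressed_state=pd.DataFrame(
            state_cols, index=pd.Index(gene_ids, name="gene_id")
        ),
    )
    return matrices, ref, truth


def generate_qpcr(
    n_per_group: int,
    effect_log2: float,
    sd_ct: float,
    seed: int,
    target_gene: str = "CYR61",
    calibrator_gene: str = "GAPDH",
    base_ct_target: float = 26.0,
    base_ct_calibrator: float = 20.0,
    loading_sd: float = 1.0,
) -> CtTable:
    """Simulate duplicate Ct measurements for a case/control qPCR experiment.

    A per-patient loading shift (RNA input variation) moves target and
    calibrator together — the variation the ddCt construction removes.  The
    target's Ct is lowered by ``effect_log2`` cycles in the P-BE group (one
    cycle earlier = twice the template); replicate noise has sd ``sd_ct``.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if sd_ct < 0:
        raise ValidationError("sd_ct must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, prefix in (("P-BE", "P"), ("nonP-BE", "N")):
        for i in range(n_per_group):
            patient = f"{prefix}{i + 1:02d}"
            loading = rng.normal(0.0, loading_sd)
            shift = -effect_log2 if group == "P-BE" else 0.0
            for gene, base, delta in (
                (target_gene, base_ct_target, shift),
                (calibrator_gene, base_ct_calibrator, 0.0),
            ):
                for rep in (1, 2):
                    ct = base + loading + delta + rng.normal(0.0, sd_ct)
                    rows.append(
                        {
                            "patient_id": patient,
                            "group": group,
                            "timepoint": "t0",
                            "gene_id": gene,
                            "replicate_index": rep,
                            "ct": ct,
                        }
                    )
    return CtTable(pd.DataFrame(rows), calibrator_gene=calibrator_gene)


def generate_clinical(
    n_p: int,
    n_np: int,
    seed: int,
    fup_range_p: tuple[int, int] = (1, 13),
    fup_range_np: tuple[int, int] = (3, 17),
) -> list[ClinicalRecord]:
    """Simulate a follow-up cohort with group-biased ordinal marker calls.

    Follow-up ranges default to those of the validation cohort (progressors
    1-13 years, non-progressors 3-17 years).  Progressors are biased toward
    High / strong-staining calls so that downstream contingency tests have
    signal to find.
    """
    if n_p < 1 or n_np < 1:
        raise ValidationError("need at least one patient per group")
    rng = np.random.default_rng(seed)
    records = []
    for group, count, fup_range in (
        ("P-BE", n_p, fup_range_p),
        ("nonP-BE", n_np, fup_range_np),
    ):
        progressed = group == "P-BE"
        p_high = 0.7 if progressed else 0.15
        cyr_levels = ["-", "+", "++", "+++"]
        taz_levels = ["-", "+", "++"]
        cyr_probs = [0.05, 0.15, 0.3, 0.5] if progressed else [0.2, 0.5, 0.25, 0.05]
        taz_probs = [0.1, 0.4, 0.5] if progressed else [0.5, 0.4, 0.1]
        for i in range(count):
            years = int(rng.integers(fup_range[0], fup_range[1] + 1))
            age_first = int(rng.integers(40, 71))
            qpcr = lambda: "High" if rng.random() < p_high else "Low"  # noqa: E731
            records.append(
                ClinicalRecord(
                    patient_id=f"{'P' if progressed else 'N'}{i + 1:02d}",
                    group=group,
                    age_first=age_first,
                    age_last=age_first + years,
                    years_fup=years,
                    qpcr_cyr61_t0=qpcr(),
                    qpcr_taz_t0=qpcr(),
                    ihc_cyr61_t0=str(rng.choice(cyr_levels, p=cyr_probs)),
                    ihc_taz_t0=str(rng.choice(taz_levels, p=taz_probs)),
                    qpcr_cyr61_t1=qpcr(),
                    qpcr_taz_t1=qpcr(),
                    ihc_cyr61_t1=str(rng.choice(cyr_levels, p=cyr_probs)),
                    ihc_taz_t1=str(rng.choice(taz_levels, p=taz_probs)),
                )
            )
    return records


def generate_network(
    n_nodes: int,
    edge_prob: float,
    seed: int,
    module_genes: list[str] | None = None,
    gene_ids: list[str] | None = None,
    module_weight: float = 1.0,
    background_weight: float = 1.0,
) -> WeightedNetwork:
    """Random background network with an optional planted module (clique).

    Useful for exercising guilt-by-association ranking: the planted clique's
    members are densely interconnected against an Erdos-Renyi background.
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        width = max(4, len(str(n_nodes - 1)))
        gene_ids = [f"G{i:0{width}d}" for i in range(n_nodes)]
    if len(gene_ids) != n_nodes:
        raise ValidationError("gene_ids length must equal n_nodes")
    module = set(module_genes or [])
    unknown = module - set(gene_ids)
    if unknown:
        raise ValidationError(f"module genes not among nodes: {sorted(unknown)}")
    edges: list[tuple[str, str, float]] = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            u, v = gene_ids[i], gene_ids[j]
            if u in module and v in module:
                edges.append((u, v, module_weight))
            elif rng.random() < edge_prob:
                edges.append((u, v, background_weight))
    return WeightedNetwork.from_edges(edges)
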