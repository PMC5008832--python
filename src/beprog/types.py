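"""Domain types for the discovery funnel and the validation arm.

Every type checks its invariants at construction and raises
:class:`ValidationError` (a ``ValueError``) on violation, so that malformed
objects never propagate into downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

GROUPS = ("P-BE", "nonP-BE", "EA")
TIMEPOINTS = ("t0", "t1")

# Ordinal immunostaining alphabets; TAZ tops out at "++" while CYR61
# reaches "+++" (three-level scores anchored differently per antibody).
IHC_CYR61_LEVELS = ("-", "+", "++", "+++")
IHC_TAZ_LEVELS = ("-", "+", "++")
QPCR_LEVELS = ("Low", "High")


class ValidationError(ValueError):
    """An object violated a domain invariant at construction."""


@dataclass(frozen=True)
class SampleInfo:
    """One profiled sample: which dataset it came from and its clinical group."""

    sample_id: str
    dataset_id: str
    group: str
    patient_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: group {self.group!r} not one of {GROUPS}"
            )
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint {self.timepoint!r} "
                f"not one of {TIMEPOINTS}"
            )


class ExpressionMatrix:
    """Dense genes x samples grid of log2 intensities joined to a manifest.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    samples
        Sample metadata, one entry per column, in column order.
    """

    def __init__(self, values: pd.DataFrame, samples: list[SampleInfo]) -> None:
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if len(samples) != values.shape[1]:
            raise ValidationError(
                f"{len(samples)} sample records for {values.shape[1]} columns"
            )
        ids = [s.sample_id for s in samples]
        if ids != list(values.columns):
            raise ValidationError("sample order does not match matrix columns")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in manifest")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        self.values = values.astype(float)
        self.samples = list(samples)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        """Group label per sample, indexed by sample id."""
        return pd.Series(
            {s.sample_id: s.group for s in self.samples}, name="group"
        ).loc[self.sample_ids]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        return ExpressionMatrix(
            self.values[[s.sample_id for s in samples]], samples
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


class FrozenReference:
    """Frozen per-gene unexpressed distribution plus platform reference quantiles.

    Drives both normalization (samples are quantile-mapped onto
    ``ref_quantiles``) and barcoding (a value is called expressed when it
    lies at least ``z_cut`` standard deviations above the gene's unexpressed
    location).
    """

    def __init__(
        self,
        gene_ids: list[str],
        mu_unexpr: np.ndarray,
        sigma_unexpr: np.ndarray,
        z_cut: float,
        ref_quantiles: np.ndarray,
    ) -> None:
        gene_index = pd.Index(gene_ids)
        if gene_index.has_duplicates:
            raise ValidationError("duplicate gene ids in reference")
        mu = np.asarray(mu_unexpr, dtype=float)
        sigma = np.asarray(sigma_unexpr, dtype=float)
        if mu.shape != (len(gene_index),) or sigma.shape != (len(gene_index),):
            raise ValidationError("mu/sigma length must match gene ids")
        if not np.all(sigma > 0):
            raise ValidationError("sigma_unexpr must be > 0 for every gene")
        if not np.isfinite(z_cut):
            raise ValidationError("z_cut must be finite")
        rq = np.asarray(ref_quantiles, dtype=float)
        if rq.ndim != 1 or rq.size == 0:
            raise ValidationError("ref_quantiles must be a non-empty vector")
        if np.any(np.diff(rq) < 0):
            raise ValidationError("ref_quantiles must be non-decreasing")
        self.gene_ids = gene_index
        self.mu_unexpr = pd.Series(mu, index=gene_index, name="mu_unexpr")
        self.sigma_unexpr = pd.Series(sigma, index=gene_index, name="sigma_unexpr")
        self.z_cut = float(z_cut)
        self.ref_quantiles = rq

    def covers(self, gene_ids) -> list[str]:
        """Return the genes NOT covered by this reference (empty if all are)."""
        return [g for g in gene_ids if g not in self.gene_ids]


@dataclass(frozen=True)
class EBayesParams:
    """Hyperparameters of the moderated-statistic fit.

    d0 is the prior degrees of freedom of the variance prior (may be
    ``inf``), s0_sq its location, and p_de the assumed prior fraction of
    differentially expressed genes entering the log-posterior-odds score.
    """

    d0: float
    s0_sq: float
    p_de: float = 0.01
    v0: float | None = None  # coefficient-variance prior for DE genes

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValidationError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValidationError("s0_sq must be > 0")
        if not (0 < self.p_de < 1):
            raise ValidationError("p_de must lie in (0, 1)")


class DEResult:
    """Per-gene differential expression table.

    Columns: ``log2fc`` (group-mean difference of log2 values),
    ``mean_expr``, ``t_mod`` (moderated t), ``df_total``, ``p``, ``p_adj``
    (Benjamini-Hochberg), ``lods`` (log posterior odds of differential
    expression, the selection score), ``zero_variance`` flag.
    """

    REQUIRED = ("log2fc", "mean_expr", "t_mod", "df_total", "p", "p_adj", "lods")

    def __init__(self, table: pd.DataFrame, params: EBayesParams) -> None:
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"DE table missing columns: {missing}")
        p = table["p"].to_numpy()
        p_adj = table["p_adj"].to_numpy()
        if np.any((p < 0) | (p > 1)) or np.any((p_adj < 0) | (p_adj > 1)):
            raise ValidationError("p and p_adj must lie in [0, 1]")
        if np.any(p_adj < p - 1e-12):
            raise ValidationError("p_adj must be >= p")
        if not np.all(np.isfinite(table["lods"].to_numpy())):
            raise ValidationError("lods must be finite (clip at the floor)")
        self.table = table
        self.params = params

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __repr__(self) -> str:
        return f"DEResult({len(self.table)} genes, d0={self.params.d0:.3g})"


@dataclass
class Barcode:
    """Per-dataset expressed-fraction table with its derived gene set."""

    dataset_id: str
    group: str
    freq: pd.Series
    gene_set: frozenset
    frac_rule: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group {self.group!r} not one of {GROUPS}")
        f = self.freq.to_numpy(dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValidationError("expressed fractions must lie in [0, 1]")
        if not self.gene_set <= set(self.freq.index):
            raise ValidationError("gene_set must be a subset of the gene ids")


@dataclass
class CandidateSet:
    """Ordered candidate genes with per-gene filter provenance."""

    genes: list[str]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("candidate genes must be unique")
        for g in self.genes:
            self.provenance.setdefault(g, ())

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member sets."""

    def __init__(self, sets: dict[str, set], descriptions: dict[str, str] | None = None):
        for name, members in sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        self.sets = dict(sets)
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation result."""

    set_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValidationError("overlap k cannot exceed min(n, K)")
        if not (0 < self.p <= 1):
            raise ValidationError("p must lie in (0, 1]")


class WeightedNetwork:
    """Undirected positively weighted gene network (no self-loops)."""

    def __init__(self, graph: nx.Graph) -> None:
        if any(u == v for u, v in graph.edges()):
            raise ValidationError("self-loops are not allowed")
        for u, v, w in graph.edges(data="weight"):
            if w is None or not w > 0:
                raise ValidationError(f"edge ({u}, {v}) must have positive weight")
        self.graph = graph

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str, float]]) -> "WeightedNetwork":
        """Build from an edge list; duplicate edges (either orientation) sum."""
        g = nx.Graph()
        for u, v, w in edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r} rejected")
            if not w > 0:
                raise ValidationError(f"non-positive weight on edge ({u}, {v})")
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=w)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


class CtTable:
    """Replicate qPCR quantification cycles with a designated calibrator gene.

    Rows: (patient_id, group, timepoint, gene_id, replicate_index, ct).
    """

    COLUMNS = ("patient_id", "group", "timepoint", "gene_id", "replicate_index", "ct")

    def __init__(self, rows: pd.DataFrame, calibrator_gene: str = "GAPDH") -> None:
        missing = [c for c in self.COLUMNS if c not in rows.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns: {missing}")
        ct = rows["ct"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ct)) or np.any(ct <= 0):
            raise ValidationError("ct values must be finite and > 0")
        bad = set(rows["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown groups in Ct table: {sorted(bad)}")
        self.rows = rows.reset_index(drop=True)
        self.calibrator_gene = calibrator_gene

    @property
    def target_genes(self) -> list[str]:
        return sorted(set(self.rows["gene_id"]) - {self.calibrator_gene})


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares dilution curve of Ct on log10(input mass)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError("a valid dilution series has negative slope")
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's follow-up and ordinal marker calls at both timepoints."""

    patient_id: str
    group: str
    age_first: int
    age_last: int
    years_fup: int
    qpcr_cyr61_t0: str
    qpcr_taz_t0: str
    ihc_cyr61_t0: str
    ihc_taz_t0: str
    qpcr_cyr61_t1: str
    qpcr_taz_t1: str
    ihc_cyr61_t1: str
    ihc_taz_t1: str

    def __post_init__(self) -> None:
        if self.group not in ("P-BE", "nonP-BE"):
            raise ValidationError(
                f"patient {self.patient_id!r}: group {self.group!r} "
                "must be P-BE or nonP-BE"
            )
        if self.years_fup < 0:
            raise ValidationError(f"patient {self.patient_id!r}: years_fup < 0")
        if self.age_last < self.age_first:
            raise ValidationError(
                f"patient {self.patient_id!r}: age_last < age_first"
            )
        for fld, alphabet in (
            ("qpcr_cyr61_t0", QPCR_LEVELS),
            ("qpcr_taz_t0", QPCR_LEVELS),
            ("qpcr_cyr61_t1", QPCR_LEVELS),
            ("qpcr_taz_t1", QPCR_LEVELS),
            ("ihc_cyr61_t0", IHC_CYR61_LEVELS),
            ("ihc_cyr61_t1", IHC_CYR61_LEVELS),
            ("ihc_taz_t0", IHC_TAZ_LEVELS),
            ("ihc_taz_t1", IHC_TAZ_LEVELS),
        ):
            token = getattr(self, fld)
            if token not in alphabet:
                raise ValidationError(
                    f"patient {self.patient_id!r}, column {fld!r}: "
                    f"token {token!r} outside alphabet {alphabet}"
                )


class ContingencyTable:
    """Group x ordinal-score count table for categorical testing."""

    def __init__(self, counts: pd.DataFrame) -> None:
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            arr = np.round(arr).astype(int)
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValidationError("need at least 2 rows and 2 columns")
        self.counts = pd.DataFrame(
            arr, index=counts.index, columns=counts.columns
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape
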