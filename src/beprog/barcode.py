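"""Expression-barcode binarization and the consistency/exclusivity funnel.

A gene is called expressed in a sample when its intensity lies at least
``z_cut`` standard deviations above the gene's frozen unexpressed location.
Dataset barcodes then keep only genes expressed consistently — in 100% of
progressor (P-BE) samples, or in at least 75% of non-progressor / carcinoma
samples — group barcodes intersect datasets, and the exclusivity step keeps
genes expressed in progressors but not in non-progressors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from beprog.types import (
    Barcode,
    CandidateSet,
    ExpressionMatrix,
    FrozenReference,
    ValidationError,
)

DEFAULT_FRAC_RULES = {"P-BE": 1.00, "nonP-BE": 0.75, "EA": 0.75}


def default_frac_rule(group: str) -> float:
    return DEFAULT_FRAC_RULES.get(group, 0.75)


def binarize(m: ExpressionMatrix, ref: FrozenReference) -> pd.DataFrame:
    """Binary expressed (1) / non-expressed (0) calls against frozen cutoffs.

    Call 1 iff (value - mu_unexpr_g) / sigma_unexpr_g >= z_cut (inclusive).
    """
    missing = ref.covers(m.gene_ids)
    if missing:
        raise ValidationError(
            f"{len(missing)} genes missing from reference (first: {missing[:5]})"
        )
    mu = ref.mu_unexpr.loc[m.gene_ids].to_numpy()[:, None]
    sigma = ref.sigma_unexpr.loc[m.gene_ids].to_numpy()[:, None]
    z = (m.values.to_numpy(dtype=float) - mu) / sigma
    calls = (z >= ref.z_cut).astype(np.int8)
    return pd.DataFrame(calls, index=m.values.index, columns=m.values.columns)


def dataset_barcode(
    calls: pd.DataFrame,
    dataset_id: str,
    group: str,
    frac_rule: float | None = None,
) -> Barcode:
    """One dataset's expressed-fraction table and its consistency gene set.

    A gene enters the set iff its expressed fraction >= frac_rule
    (inclusive); the rule defaults to 1.00 for P-BE and 0.75 otherwise.
    """
    if calls.shape[1] == 0:
        raise ValidationError(f"dataset {dataset_id!r} has no samples")
    if frac_rule is None:
        frac_rule = default_frac_rule(group)
    if not (0 <= frac_rule <= 1):
        raise ValidationError("frac_rule must lie in [0, 1]")
    freq = calls.mean(axis=1)
    gene_set = frozenset(freq.index[freq >= frac_rule])
    return Barcode(
        dataset_id=dataset_id,
        group=group,
        freq=freq,
        gene_set=gene_set,
        frac_rule=frac_rule,
    )


def group_barcode(barcodes: list[Barcode]) -> set:
    """Intersect the dataset gene sets of one clinical group."""
    if not barcodes:
        raise ValidationError("need at least one dataset barcode")
    groups = {b.group for b in barcodes}
    if len(groups) > 1:
        raise ValidationError(f"mixed groups in group barcode: {sorted(groups)}")
    result = set(barcodes[0].gene_set)
    for b in barcodes[1:]:
        result &= b.gene_set
    return result


def exclusive_genes(
    pbe: set, nonpbe: set, ea: set | None = None, subtract_ea: bool = False
) -> set:
    """Genes expressed in the P-BE barcode but absent from the nonP-BE one.

    The carcinoma (EA) barcode is computed and reported alongside but only
    subtracted when ``subtract_ea`` is set.
    """
    result = set(pbe) - set(nonpbe)
    if subtract_ea:
        if ea is None:
            raise ValidationError("subtract_ea requires an EA barcode set")
        result -= set(ea)
    return result


def intersect_candidates(de_genes: CandidateSet, exclusive: set) -> CandidateSet:
    """Restrict DE candidates to barcode-exclusive genes, preserving order."""
    kept = [g for g in de_genes.genes if g in exclusive]
    provenance = {
        g: tuple(de_genes.provenance.get(g, ())) + ("barcode-exclusive",)
        for g in kept
    }
    return CandidateSet(genes=kept, provenance=provenance)


def barcode_stage(
    matrices: list[ExpressionMatrix],
    ref: FrozenReference,
    frac_rules: dict[str, float] | None = None,
    subtract_ea: bool = False,
) -> tuple[dict[str, Barcode], dict[str, set], set]:
    """Run binarize -> dataset barcodes -> group barcodes -> exclusivity.

    Datasets are keyed by dataset_id; a dataset's group comes from its
    manifest (all samples of one input matrix must share dataset and group).
    Returns (dataset barcodes, group barcodes, exclusive gene set).
    """
    rules = dict(DEFAULT_FRAC_RULES)
    if frac_rules:
        rules.update(frac_rules)
    barcodes: dict[str, Barcode] = {}
    by_group: dict[str, list[Barcode]] = {}
    for m in matrices:
        datasets = {s.dataset_id for s in m.samples}
        groups = {s.group for s in m.samples}
        if len(datasets) != 1 or len(groups) != 1:
            raise ValidationError(
                "each barcode input matrix must hold one dataset of one group"
            )
        dataset_id, group = datasets.pop(), groups.pop()
        calls = binarize(m, ref)
        bc = dataset_barcode(calls, dataset_id, group, rules.get(group))
        barcodes[dataset_id] = bc
        by_group.setdefault(group, []).append(bc)
    group_sets = {g: group_barcode(bcs) for g, bcs in sorted(by_group.items())}
    pbe = group_sets.get("P-BE", set())
    nonpbe = group_sets.get("nonP-BE", set())
    ea = group_sets.get("EA")
    exclusive = exclusive_genes(pbe, nonpbe, ea=ea, subtract_ea=subtract_ea)
    return barcodes, group_sets, exclusive
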