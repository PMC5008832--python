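"""Frozen-quantile normalization and cross-dataset pooling.

Heterogeneous datasets become comparable by mapping every sample's values
onto a fixed vector of reference quantiles — normalization against
parameters frozen once, so a sample's normalized values never depend on
which other samples happen to be processed with it.  This is a gene-level
counterpart of frozen RMA: the probe-level effects of the original method
are out of scope because every downstream stage consumes gene-level values
and frozen cutoffs only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from beprog.types import ExpressionMatrix, FrozenReference, ValidationError


def _map_column(values: np.ndarray, ref_quantiles: np.ndarray) -> np.ndarray:
    """Quantile-map one sample onto the reference grid, averaging ties."""
    n = values.size
    m = ref_quantiles.size
    order = np.argsort(values, kind="stable")
    # reference quantile function evaluated at this sample's plotting positions
    probs = (np.arange(n) + 0.5) / n
    grid = (np.arange(m) + 0.5) / m
    mapped_sorted = np.interp(probs, grid, ref_quantiles)
    out = np.empty(n)
    out[order] = mapped_sorted
    # tied input values receive the mean of their assigned quantiles
    if np.unique(values).size != n:
        out = pd.Series(out).groupby(values).transform("mean").to_numpy()
    return out


def normalize_frozen(m: ExpressionMatrix, ref: FrozenReference) -> ExpressionMatrix:
    """Quantile-map each sample independently onto the frozen reference.

    Within-sample ranks are preserved exactly; the operation is idempotent.
    """
    missing = ref.covers(m.gene_ids)
    if missing:
        raise ValidationError(
            f"{len(missing)} genes missing from the frozen reference "
            f"(first few: {missing[:5]})"
        )
    arr = m.values.to_numpy(dtype=float)
    out = np.column_stack(
        [_map_column(arr[:, j], ref.ref_quantiles) for j in range(arr.shape[1])]
    )
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.samples)


def pool_datasets(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate normalized datasets over their common gene set.

    Genes are intersected and sorted lexicographically so the result does
    not depend on input gene order; sample metadata is carried through.
    """
    if not matrices:
        raise ValidationError("no matrices to pool")
    common: set = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValidationError("empty gene intersection across datasets")
    genes = sorted(common)
    values = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    samples = [s for m in matrices for s in m.samples]
    return ExpressionMatrix(values, samples)
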