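"""Readers and writers for the pipeline's external formats.

Formats: tab-separated expression matrices (first column the gene id, one
column per sample), CSV manifests / clinical tables / Ct tables, GMT gene-set
collections, and 3-column tab-separated weighted edge lists.  All writers can
prepend a commented provenance header (tool version, config hash, seed);
readers skip ``#`` comment lines.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from beprog.types import (
    ClinicalRecord,
    CtTable,
    ExpressionMatrix,
    FrozenReference,
    GeneSetCollection,
    SampleInfo,
    ValidationError,
    WeightedNetwork,
)

MANIFEST_COLUMNS = ("sample_id", "dataset_id", "group")
CLINICAL_COLUMNS = (
    "patient_id",
    "group",
    "age_first",
    "age_last",
    "years_fup",
    "qpcr_cyr61_t0",
    "qpcr_taz_t0",
    "ihc_cyr61_t0",
    "ihc_taz_t0",
    "qpcr_cyr61_t1",
    "qpcr_taz_t1",
    "ihc_cyr61_t1",
    "ihc_taz_t1",
)


def provenance_header(config_hash: str | None = None, seed: int | None = None) -> str:
    """Commented provenance lines recording tool version, config hash, seed."""
    from beprog import __version__

    lines = [f"# beprog {__version__}"]
    if config_hash is not None:
        lines.append(f"# config_hash {config_hash}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    return "\n".join(lines) + "\n"


def read_manifest(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            SampleInfo(
                sample_id=row["sample_id"],
                dataset_id=row["dataset_id"],
                group=row["group"],
                patient_id=_opt(row.get("patient_id")),
                timepoint=_opt(row.get("timepoint")),
            )
        )
    return samples


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    value = str(value)
    return value if value not in ("", "nan") else None


def read_expression(
    path: str | Path, manifest: str | Path | list[SampleInfo]
) -> ExpressionMatrix:
    """Read a TSV expression matrix and join it to its sample manifest.

    The first column holds gene ids; remaining columns are samples.  A gene
    id occurring twice is a hard error (probe-to-gene collapse must happen
    upstream, see :func:`collapse_duplicate_genes`); a matrix sample missing
    from the manifest is a hard error naming the sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene ids in {path}: {dups}")
    samples = manifest if isinstance(manifest, list) else read_manifest(manifest)
    by_id = {s.sample_id: s for s in samples}
    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise ValidationError(
            f"samples in matrix but not in manifest: {unknown}"
        )
    ordered = [by_id[c] for c in df.columns]
    return ExpressionMatrix(df, ordered)


def write_expression(
    m: ExpressionMatrix, path: str | Path, header: str | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df = m.values.copy()
        df.index.name = "gene_id"
        df.to_csv(fh, sep="\t", float_format="%.10g")


def write_manifest(samples: list[SampleInfo], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "dataset_id": s.dataset_id,
            "group": s.group,
            "patient_id": s.patient_id or "",
            "timepoint": s.timepoint or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a gene id, keeping the row of highest mean intensity.

    This is the conventional deterministic probe-to-gene collapse applied
    before the funnel operates on unique gene identifiers.
    """
    if not values.index.has_duplicates:
        return values
    means = values.mean(axis=1).to_numpy()
    df = values.copy()
    df["_mean"] = means
    df["_gene"] = df.index
    # stable sort keeps the first (highest-mean) row per gene
    df = df.sort_values("_mean", ascending=False, kind="stable")
    df = df[~df["_gene"].duplicated()]
    df = df.loc[sorted(df.index)]
    return df.drop(columns=["_mean", "_gene"])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, members."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = set(m for m in fields[2:] if m)
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_network(path: str | Path) -> WeightedNetwork:
    """Read a 3-column (nodeA, nodeB, weight) tab/whitespace edge list.

    Duplicate edges in either orientation have their weights summed;
    self-loops and non-positive weights are rejected.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            u, v, w_str = fields
            try:
                w = float(w_str)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: weight {w_str!r} is not a number"
                ) from exc
            if not w > 0:
                raise ValidationError(f"{path}:{lineno}: non-positive weight {w}")
            if u == v:
                raise ValidationError(f"{path}:{lineno}: self-loop on {u!r}")
            edges.append((u, v, w))
    return WeightedNetwork.from_edges(edges)


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.10g}\n")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical follow-up table (per-patient marker calls, both timepoints)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ClinicalRecord(
                    patient_id=row["patient_id"],
                    group=row["group"],
                    age_first=int(row["age_first"]),
                    age_last=int(row["age_last"]),
                    years_fup=int(row["years_fup"]),
                    qpcr_cyr61_t0=row["qpcr_cyr61_t0"],
                    qpcr_taz_t0=row["qpcr_taz_t0"],
                    ihc_cyr61_t0=row["ihc_cyr61_t0"],
                    ihc_taz_t0=row["ihc_taz_t0"],
                    qpcr_cyr61_t1=row["qpcr_cyr61_t1"],
                    qpcr_taz_t1=row["qpcr_taz_t1"],
                    ihc_cyr61_t1=row["ihc_cyr61_t1"],
                    ihc_taz_t1=row["ihc_taz_t1"],
                )
            )
        except (ValidationError, TypeError) as exc:
            raise ValidationError(f"{path}, row {i + 2}: {exc}") from exc
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = [{c: getattr(r, c) for c in CLINICAL_COLUMNS} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def clinical_fixture_path() -> Path:
    """Path of the packaged 19-patient validation-cohort table."""
    return Path(
        importlib.resources.files("beprog").joinpath("data/table2.csv")  # type: ignore[arg-type]
    )


def read_ct_table(path: str | Path, calibrator_gene: str = "GAPDH") -> CtTable:
    df = pd.read_csv(path, comment="#")
    return CtTable(df, calibrator_gene=calibrator_gene)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.rows.to_csv(path, index=False)


def write_frozen_reference(ref: FrozenReference, path: str | Path) -> None:
    """TSV of per-gene unexpressed location/scale plus the reference quantiles.

    The quantile column stores the sorted reference intensities row-aligned
    with the genes (one quantile per reference gene); the expression cutoff
    in sd units is carried in a comment line.
    """
    if len(ref.ref_quantiles) != len(ref.gene_ids):
        raise ValidationError(
            "reference quantile vector must be gene-aligned for TSV round-trip"
        )
    df = pd.DataFrame(
        {
            "gene_id": ref.gene_ids,
            "mu_unexpr": ref.mu_unexpr.to_numpy(),
            "sigma_unexpr": ref.sigma_unexpr.to_numpy(),
            "ref_quantile": ref.ref_quantiles,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# z_cut {ref.z_cut:.10g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_frozen_reference(path: str | Path) -> FrozenReference:
    z_cut = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# z_cut"):
                z_cut = float(line.split()[-1])
            if not line.startswith("#"):
                break
    if z_cut is None:
        raise ValidationError(f"{path}: missing '# z_cut' header line")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    return FrozenReference(
        gene_ids=list(df["gene_id"]),
        mu_unexpr=df["mu_unexpr"].to_numpy(),
        sigma_unexpr=df["sigma_unexpr"].to_numpy(),
        z_cut=z_cut,
        ref_quantiles=df["ref_quantile"].to_numpy(),
    )
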