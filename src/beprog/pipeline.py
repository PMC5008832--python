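"""End-to-end orchestration of the discovery funnel.

``run_funnel`` executes normalize -> pool -> moderated DE -> candidate
selection -> barcode binarization -> dataset/group barcodes -> exclusivity
-> candidate intersection (-> enrichment -> network expansion), writing
every intermediate as TSV plus a machine-readable funnel-count summary.
Inputs come either from a simulation section (synthetic cohort with planted
truth, so the summary can report recovery metrics) or from files on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from beprog import io
from beprog.barcode import barcode_stage, intersect_candidates
from beprog.diffexp import fit_moderated, select_candidates
from beprog.enrichment import expand_neighbors, hypergeom_enrich
from beprog.normalize import normalize_frozen, pool_datasets
from beprog.simulate import DatasetSpec, SimulationConfig, generate_meta_cohort
from beprog.types import CandidateSet, ExpressionMatrix, ValidationError

log = logging.getLogger("beprog")

STAGES = (
    "normalize",
    "pool",
    "diffexp",
    "select",
    "barcode",
    "intersect",
    "enrich",
    "network",
)


class StageError(RuntimeError):
    """A funnel stage failed; partial outputs are retained in the run dir."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def simulation_from_config(sim: dict, seed: int) -> SimulationConfig:
    """Build a cohort config from the `simulate:` section of a funnel config.

    Planted progression genes (both mean-shifted and P-BE-exclusive) are
    chosen by a dedicated random stream derived from the run seed.
    """
    sim = dict(sim)
    n_genes = int(sim.pop("n_genes", 2000))
    n_planted = int(sim.pop("n_planted", 0))
    effect = float(sim.pop("effect_log2", 2.0))
    datasets = sim.pop("datasets", None)
    if datasets is not None:
        datasets = [DatasetSpec(d["dataset_id"], d["group"], int(d["n_samples"])) for d in datasets]
    rng = np.random.default_rng([int(seed), 17])
    planted = sorted(rng.choice(n_genes, size=n_planted, replace=False).tolist())
    kwargs = dict(
        n_genes=n_genes,
        planted_de=[(i, effect) for i in planted],
        planted_exclusive=planted,
        seed=int(seed),
        **sim,
    )
    if datasets is not None:
        kwargs["datasets"] = datasets
    return SimulationConfig(**kwargs)


def _split_by_dataset(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Split matrices so each holds exactly one (dataset, group)."""
    out = []
    for m in matrices:
        keys = sorted({(s.dataset_id, s.group) for s in m.samples})
        if len(keys) == 1:
            out.append(m)
            continue
        for dataset_id, group in keys:
            ids = [
                s.sample_id
                for s in m.samples
                if (s.dataset_id, s.group) == (dataset_id, group)
            ]
            out.append(m.subset_samples(ids))
    return out


def run_funnel(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full funnel from a single structured config; returns run dir."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    chash = config_hash(cfg)
    run_dir = Path(out_dir or cfg.get("out", "funnel_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    header = io.provenance_header(config_hash=chash, seed=seed)
    log.info("funnel run %s (seed %d) -> %s", chash, seed, run_dir)

    summary: dict = {"config_hash": chash, "seed": seed, "stages": {}}

    def _write_summary() -> None:
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    def _write_genes(genes, name: str) -> None:
        with open(run_dir / name, "w") as fh:
            fh.write(header)
            for g in genes:
                fh.write(f"{g}\n")

    truth = None
    try:
        if "simulate" in cfg:
            sim_cfg = simulation_from_config(cfg["simulate"], seed)
            matrices, ref, truth = generate_meta_cohort(sim_cfg)
        else:
            inputs = cfg["inputs"]
            manifest = io.read_manifest(inputs["manifest"])
            matrices = [
                io.read_expression(p, manifest) for p in inputs["matrices"]
            ]
            ref = io.read_frozen_reference(inputs["reference"])
    except Exception as exc:  # noqa: BLE001
        _write_summary()
        raise StageError("inputs", exc) from exc

    dx = cfg.get("diffexp", {})
    bc_cfg = cfg.get("barcode", {})

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001
            _write_summary()
            raise StageError(name, exc) from exc
        summary["stages"][name] = "done"
        return result

    normalized = stage(
        "normalize", lambda: [normalize_frozen(m, ref) for m in matrices]
    )
    for m in normalized:
        ds = m.samples[0].dataset_id
        io.write_expression(m, run_dir / f"normalized_{ds}.tsv", header=header)

    pooled = stage("pool", lambda: pool_datasets(normalized))
    io.write_expression(pooled, run_dir / "pooled.tsv", header=header)
    io.write_manifest(pooled.samples, run_dir / "manifest.csv")
    summary["n_genes_in"] = pooled.n_genes
    summary["n_samples"] = pooled.n_samples

    de, params = stage(
        "diffexp",
        lambda: fit_moderated(
            pooled,
            group_a=dx.get("group_a", "P-BE"),
            group_b=dx.get("group_b", "nonP-BE"),
            p_de=float(dx.get("p_de", 0.01)),
        ),
    )
    with open(run_dir / "de.tsv", "w") as fh:
        fh.write(header)
        de.table.rename_axis("gene_id").to_csv(fh, sep="\t", float_format="%.6g")
    summary["ebayes"] = {"d0": params.d0, "s0_sq": params.s0_sq, "p_de": params.p_de}

    candidates = stage(
        "select",
        lambda: select_candidates(
            de,
            lods_min=float(dx.get("lods_min", 5.0)),
            abs_log2fc_min=float(dx.get("lfc_min", 0.58)),
            up_only=bool(dx.get("up_only", False)),
        ),
    )
    _write_genes(candidates.genes, "candidates_de.txt")
    summary["n_de"] = len(candidates)

    barcodes, group_sets, exclusive = stage(
        "barcode",
        lambda: barcode_stage(
            _split_by_dataset(normalized),
            ref,
            frac_rules=bc_cfg.get("rules"),
            subtract_ea=bool(bc_cfg.get("subtract_ea", False)),
        ),
    )
    freq = pd.DataFrame({ds: bc.freq for ds, bc in sorted(barcodes.items())})
    with open(run_dir / "barcode_freq.tsv", "w") as fh:
        fh.write(header)
        freq.rename_axis("gene_id").to_csv(fh, sep="\t", float_format="%.6g")
    for group, genes in group_sets.items():
        _write_genes(sorted(genes), f"barcode_group_{group}.txt")
    _write_genes(sorted(exclusive), "barcode_exclusive.txt")
    summary["n_exclusive"] = len(exclusive)

    final = stage("intersect", lambda: intersect_candidates(candidates, exclusive))
    _write_genes(final.genes, "candidates_final.txt")
    summary["n_final"] = len(final)

    if cfg.get("enrichment", {}).get("gmt") and len(final) > 0:
        sets = io.read_gmt(cfg["enrichment"]["gmt"])
        results = stage(
            "enrich",
            lambda: hypergeom_enrich(set(final.genes), sets, set(pooled.gene_ids)),
        )
        rows = pd.DataFrame([r.__dict__ for r in results])
        with open(run_dir / "enrichment.tsv", "w") as fh:
            fh.write(header)
            rows.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        summary["top_enriched"] = results[0].set_name if results else None

    net_cfg = cfg.get("network", {})
    if net_cfg.get("path") and len(final) > 0:
        net = io.read_network(net_cfg["path"])
        expanded = stage(
            "network",
            lambda: expand_neighbors(
                net,
                set(final.genes),
                k=int(net_cfg.get("k", 100)),
                lam=float(net_cfg.get("lambda", 1.0)),
            ),
        )
        _write_genes(sorted(expanded), "candidates_expanded.txt")
        summary["n_expanded"] = len(expanded)

    if truth is not None:
        planted = truth.planted_genes
        recovered = planted & set(final.genes)
        false_pos = set(final.genes) - planted
        summary["recovery"] = {
            "n_planted": len(planted),
            "n_recovered": len(recovered),
            "recovery_frac": len(recovered) / len(planted) if planted else None,
            "n_false_positives": len(false_pos),
        }
        _write_genes(sorted(planted), "truth_planted.txt")

    _write_summary()
    return run_dir


def report(run_dir: str | Path) -> str:
    """Human-readable markdown summary of a (possibly partial) funnel run."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise ValidationError(f"no summary.json in {run_dir}")
    with open(summary_path) as fh:
        summary = json.load(fh)
    lines = [
        f"# Funnel run {summary.get('config_hash', '?')}",
        "",
        f"Seed: {summary.get('seed')}",
        "",
        "## Stages",
    ]
    done = summary.get("stages", {})
    for stage_name in STAGES:
        mark = "done" if done.get(stage_name) == "done" else "MISSING"
        lines.append(f"- {stage_name}: {mark}")
    lines += ["", "## Funnel counts"]
    for key in ("n_genes_in", "n_samples", "n_de", "n_exclusive", "n_final", "n_expanded"):
        if key in summary:
            lines.append(f"- {key}: {summary[key]}")
    if "recovery" in summary:
        r = summary["recovery"]
        lines += [
            "",
            "## Planted-truth recovery",
            f"- planted: {r['n_planted']}",
            f"- recovered: {r['n_recovered']}"
            + (
                f" ({100 * r['recovery_frac']:.0f}%)"
                if r["recovery_frac"] is not None
                else ""
            ),
            f"- false positives: {r['n_false_positives']}",
        ]
    final_path = run_dir / "candidates_final.txt"
    if final_path.exists():
        genes = [
            line.strip()
            for line in final_path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        lines += ["", "## Top candidates", ", ".join(genes[:20]) or "(none)"]
    return "\n".join(lines) + "\n"


def funnel_counts(summary: dict) -> list[int]:
    """The monotone funnel: genes in -> DE -> exclusive-intersect -> final."""
    return [
        summary.get("n_genes_in", 0),
        summary.get("n_de", 0),
        summary.get("n_final", 0),
    ]
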