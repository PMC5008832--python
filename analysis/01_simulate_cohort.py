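"""Simulate the three-dataset discovery cohort with planted progression genes.

Emulates the structure of the public meta-cohort the funnel targets: one
progressor dataset of 8 samples plus non-progressor datasets of 7 and 18
samples, 2000 genes, with 20 planted progression genes that are both
mean-shifted (+2.0 log2) and exclusively expressed in progressor samples.
Writes the per-dataset matrices, manifest, frozen reference and truth under
results/01_cohort/.
"""

from pathlib import Path

import numpy as np

from beprog import io
from beprog.simulate import SimulationConfig, generate_meta_cohort

SEED = 1
OUT = Path("results/01_cohort")


def main() -> None:
    rng = np.random.default_rng([SEED, 17])
    planted = sorted(rng.choice(2000, size=20, replace=False).tolist())
    cfg = SimulationConfig(
        n_genes=2000,
        planted_de=[(i, 2.0) for i in planted],
        planted_exclusive=planted,
        seed=SEED,
    )
    matrices, ref, truth = generate_meta_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    samples = [s for m in matrices for s in m.samples]
    io.write_manifest(samples, OUT / "manifest.csv")
    for m in matrices:
        ds = m.samples[0].dataset_id
        io.write_expression(m, OUT / f"{ds}.tsv", header=io.provenance_header(seed=SEED))
    io.write_frozen_reference(ref, OUT / "reference.tsv")
    (OUT / "truth_planted.txt").write_text(
        "".join(f"{g}\n" for g in sorted(truth.planted_genes))
    )
    print(f"wrote {len(matrices)} datasets ({len(samples)} samples, 2000 genes)")
    print(f"planted {len(truth.planted_genes)} progression genes -> {OUT}")


if __name__ == "__main__":
    main()
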