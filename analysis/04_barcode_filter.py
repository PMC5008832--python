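"""Barcode binarization, consistency filtering, and candidate intersection.

Binarizes each normalized dataset against the frozen cutoffs, builds the
dataset barcodes (expressed in 100% of P-BE samples, >= 75% of nonP-BE
samples), intersects them into group barcodes, derives the P-BE-exclusive
gene set, and intersects it with the DE candidates.  Compares the final
candidate list with the planted truth.  Writes results/04_barcode/.
"""

from pathlib import Path

import pandas as pd

from beprog import io
from beprog.barcode import barcode_stage, intersect_candidates
from beprog.normalize import normalize_frozen
from beprog.types import CandidateSet

COHORT = Path("results/01_cohort")
DE = Path("results/03_de")
OUT = Path("results/04_barcode")


def main() -> None:
    manifest = io.read_manifest(COHORT / "manifest.csv")
    ref = io.read_frozen_reference(COHORT / "reference.tsv")
    normalized = [
        normalize_frozen(io.read_expression(p, manifest), ref)
        for p in sorted(COHORT.glob("DS*.tsv"))
    ]
    de_genes = (DE / "candidates_de.txt").read_text().split()
    candidates = CandidateSet(de_genes, {g: ("DE",) for g in de_genes})

    barcodes, group_sets, exclusive = barcode_stage(normalized, ref)
    final = intersect_candidates(candidates, exclusive)

    OUT.mkdir(parents=True, exist_ok=True)
    freq = pd.DataFrame({ds: bc.freq for ds, bc in sorted(barcodes.items())})
    freq.rename_axis("gene_id").to_csv(OUT / "barcode_freq.tsv", sep="\t")
    (OUT / "exclusive.txt").write_text("".join(f"{g}\n" for g in sorted(exclusive)))
    (OUT / "candidates_final.txt").write_text(
        "".join(f"{g}\n" for g in final.genes)
    )

    planted = set((COHORT / "truth_planted.txt").read_text().split())
    recovered = planted & set(final.genes)
    print(
        "funnel: "
        f"{len(de_genes)} DE -> {len(exclusive)} P-BE-exclusive -> "
        f"{len(final)} final candidates"
    )
    print(
        f"recovery vs planted truth: {len(recovered)}/{len(planted)} "
        f"({100 * len(recovered) / len(planted):.0f}%), "
        f"{len(set(final.genes) - planted)} false positives"
    )


if __name__ == "__main__":
    main()
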