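"""Clinical follow-up summaries and ordinal marker tests on the packaged cohort.

Summarizes follow-up years per group for the packaged 19-patient validation
table and tests the association between clinical group and the ordinal
immunostaining scores of both markers at both timepoints with Pearson's
chi-squared test.  Writes results/07_clinical/.
"""

from pathlib import Path

from beprog import io
from beprog.types import ContingencyTable
from beprog.validation import chi_squared, score_table, summarize_followup

OUT = Path("results/07_clinical")


def main() -> None:
    records = io.read_clinical(io.clinical_fixture_path())
    OUT.mkdir(parents=True, exist_ok=True)
    lines = []
    for group, s in summarize_followup(records).items():
        line = (
            f"{group}: n={s['n']}, mean follow-up {s['mean']} years, "
            f"range {s['min']}-{s['max']}"
        )
        print(line)
        lines.append(line)
    for marker in ("ihc_cyr61", "ihc_taz"):
        for tp in ("t0", "t1"):
            table = score_table(records, marker, tp)
            table.counts.to_csv(OUT / f"counts_{marker}_{tp}.tsv", sep="\t")
            nonzero = table.counts.loc[:, table.counts.sum(axis=0) > 0]
            if nonzero.shape[1] < 2:
                continue
            x2, df, p = chi_squared(ContingencyTable(nonzero))
            line = f"{marker} @ {tp}: X2={x2:.2f}, df={df}, p={p:.3g}"
            print(line)
            lines.append(line)
    (OUT / "summary.txt").write_text("".join(f"{s}\n" for s in lines))


if __name__ == "__main__":
    main()
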