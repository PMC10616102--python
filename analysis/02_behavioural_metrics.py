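"""Model-free behavioural indices of the simulated cohort.

Computes a-priori (round-1) trust, mean trust, reciprocity, the
retaliation marker and total winnings per session from
results/trials.csv and writes results/metrics.csv.
"""

import json
from pathlib import Path

from trustgame.dataio import read_trials
from trustgame.metrics import metrics_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trajs, errors = read_trials(OUT / "trials.csv")
    if len(errors):
        print(f"warning: {len(errors)} malformed rows skipped")
    table, meta = metrics_table(trajs)
    table.to_csv(OUT / "metrics.csv", index=False)
    (OUT / "metrics_meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    desc = table[["a_priori_trust", "mean_trust", "reciprocity",
                  "retaliation_index", "total_winnings"]].describe().loc[
        ["mean", "std", "min", "max"]]
    print(f"{len(table)} sessions -> {OUT / 'metrics.csv'}")
    print(desc.round(2).to_string())
    n_ret = table["retaliation_index"].notna().sum()
    print(f"{n_ret} sessions experienced at least one unfair repayment "
          "(retaliation index defined).")


if __name__ == "__main__":
    main()
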