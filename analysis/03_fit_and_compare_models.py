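"""Grid-search model fitting and M1-M5 comparison.

Fits the full interactive-POMDP model (M1) and its nested reductions
(M2: no irritability; M3: also fixed risk aversion/stochasticity;
M4: also no theory of mind; M5: random) to a subsample of simulated
sessions by exhaustive search over the desk-scale grid, and ranks the
variants by average Draper BIC.  Writes results/fits.csv and
results/model_comparison.csv.
"""

from pathlib import Path

from trustgame.dataio import read_trials
from trustgame.inference import compare_models, grid_size, reduced_grid

OUT = Path(__file__).resolve().parents[1] / "results"
N_SESSIONS = 12  # desk-scale subsample


def main() -> None:
    trajs, _ = read_trials(OUT / "trials.csv")
    subsample = trajs[:N_SESSIONS]
    grid = reduced_grid()
    print(f"fitting {len(subsample)} sessions on a {grid_size(grid)}-point "
          "grid (M1), nested reductions inherit the same axes...")
    summary, per_subject = compare_models(subsample, grid=grid)
    per_subject.to_csv(OUT / "fits.csv", index=False)
    summary.to_csv(OUT / "model_comparison.csv", index=False)
    print(summary.round(3).to_string(index=False))
    means = summary.set_index("model")
    winner = summary.iloc[0]["model"]
    print(f"lowest average Draper BIC: {winner}.")
    print(f"mean NLL ordering M1 <= M2: "
          f"{means.loc['M1', 'mean_nll']:.2f} <= "
          f"{means.loc['M2', 'mean_nll']:.2f} (nested grids).")
    print("Note: this demo cohort deliberately includes very stochastic "
          "agents (beta = 1/4); for them the likelihood gain of the full "
          "model cannot repay its 7-parameter penalty, so the random "
          "benchmark can rank highly on BIC.  Cohorts of low-stochasticity "
          "irritable agents are won by M1 (see the model-comparison check "
          "in the test suite).  M5's ceiling is 20*ln(5) = 32.19 when no "
          "investment is zero; forced zero-investment rounds lower it.")


if __name__ == "__main__":
    main()
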