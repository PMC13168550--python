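"""Headline accuracy and diagnosis rates from the scenario grid.

Reads results/grid/records.csv (produced by 03_run_scenario_grid.py) and
reports the quantities that summarize the study: the fraction of
full-occupancy datasets flagged as heterogeneous, goodness-of-fit failure
rates per model on full-length histories, and mean occupancy error (in
percentage points) per model and number of visits.  Writes
results/grid_headlines.csv and, when matplotlib is available, a mean-error
vs visits figure.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pd.read_csv(RESULTS / "grid" / "records.csv")
    n_visits = records["T"].max()
    full = records[records["T"] == n_visits]
    rows = []

    het = full[(full.psi == full.psi.max()) & (full.model == "basic")]
    rows.append({"quantity": "het_flag_rate_full_occupancy",
                 "value": het.het_flag.mean(), "n": len(het)})
    print(f"heterogeneity flagged in {100 * het.het_flag.mean():.0f}% of "
          f"full-occupancy datasets (n={len(het)})")

    for model in ("basic", "rn", "zibb"):
        sub = full[full.model == model]
        rows.append({"quantity": f"gof_fail_rate_{model}",
                     "value": sub.gof_flag.mean(), "n": len(sub)})
        print(f"{model} GOF failure rate at T={n_visits}: "
              f"{100 * sub.gof_flag.mean():.0f}%")

    for model in ("basic", "rn", "zibb"):
        for T in sorted(records["T"].unique()):
            sub = records[(records.model == model) & (records["T"] == T)]
            rows.append({"quantity": f"mean_error_{model}_T{T}",
                         "value": sub.error.mean(), "n": len(sub)})
    for model in ("basic", "rn", "zibb"):
        e2 = records[(records.model == model) & (records["T"] == 2)].error.mean()
        eN = records[(records.model == model)
                     & (records["T"] == n_visits)].error.mean()
        print(f"{model} mean error: {e2:+.1f} points at T=2, "
              f"{eN:+.1f} points at T={n_visits}")

    pd.DataFrame(rows).to_csv(RESULTS / "grid_headlines.csv", index=False)
    print(f"wrote {RESULTS / 'grid_headlines.csv'}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    for model in ("basic", "rn", "zibb"):
        sub = (records[records.model == model]
               .groupby("T").error.mean().sort_index())
        ax.plot(sub.index, sub.values, marker="o", label=model)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("visits per site (T)")
    ax.set_ylabel("mean occupancy error (percentage points)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "mean_error_by_visits.png", dpi=150)
    print(f"wrote {RESULTS / 'mean_error_by_visits.png'}")


if __name__ == "__main__":
    main()
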