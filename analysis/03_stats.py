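"""Replicate-level inference over the measured dataset.

Aggregates fields per biological replicate, joins the viability tables,
and runs the per-variable two-way ANOVA with gatekept Tukey comparisons,
t-tests against the untreated control, and the pooled Pearson correlation
matrix.  Writes results/stats/ and prints the significant main effects.
"""

import pathlib

import pandas as pd

from mitomorph.report import aggregate_replicates, run_stats
from mitomorph.viability import viability_table

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    metrics = pd.read_csv(ROOT / "metrics" / "field_metrics.csv").fillna({"qc_flag": ""})
    mtt = pd.read_csv(ROOT / "dataset" / "mtt_wells.csv")
    counts = pd.read_csv(ROOT / "dataset" / "cell_counts.csv")
    rep = aggregate_replicates(metrics).merge(
        viability_table(mtt, counts),
        on=["katp_level", "rotenone", "replicate"],
    )
    rep = rep.drop(columns=[c for c in ("branch_count", "junction_count", "rod_count",
                                        "mito_area_px", "er_area_px") if c in rep])
    res = run_stats(rep)
    res.save(ROOT / "stats")

    anova = res.anova[res.anova.source != "residual"]
    sig = anova[anova.p < res.alpha]
    print("significant ANOVA effects (alpha=0.05):")
    for _, row in sig.iterrows():
        print(f"  {row.variable:24s} {row.source:12s} F={row.F:8.2f} p={row.p:.2e}")
    print("\ngatekeeping:", res.decisions)
    strong = [
        (a, b, res.correlations.r.loc[a, b])
        for a, b in res.correlations.significant_pairs()
        if abs(res.correlations.r.loc[a, b]) >= 0.5
    ]
    print("\nstrong significant correlations (|r| >= 0.5):")
    for a, b, r in strong:
        print(f"  {a} ~ {b}: r={r:+.2f}")


if __name__ == "__main__":
    main()
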