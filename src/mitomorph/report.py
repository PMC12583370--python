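"""Replicate-level statistical report over the tidy measurement tables.

Joins morphology, calcium and viability records on (replicate, katp_level,
rotenone), averages fields to one value per biological replicate, and runs
the full inference battery per variable: two-way ANOVA (KATP x rotenone),
gatekept Tukey comparisons, Student's t of each treated condition against
the untreated control, and one pooled Pearson correlation matrix across
all replicate records.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import stats as st

__all__ = ["StatsReport", "aggregate_replicates", "run_stats"]

KEY_COLS = ["katp_level", "rotenone", "replicate"]


@dataclass
class StatsReport:
    """All inference outputs of one experiment.

    ``anova`` / ``tukey`` / ``ttests`` are long-format tables over the
    analysed variables; ``correlations`` is the Pearson matrix;
    ``decisions`` records the gatekeeping outcome per variable.
    """

    anova: pd.DataFrame
    tukey: pd.DataFrame
    ttests: pd.DataFrame
    correlations: st.CorrelationMatrix
    replicate_table: pd.DataFrame
    alpha: float = 0.05
    decisions: dict[str, str] = dc_field(default_factory=dict)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.anova.to_csv(out / "anova.csv", index=False)
        self.tukey.to_csv(out / "tukey.csv", index=False)
        self.ttests.to_csv(out / "ttests.csv", index=False)
        self.correlations.r.to_csv(out / "correlations_r.csv")
        self.correlations.p.to_csv(out / "correlations_p.csv")
        self.replicate_table.to_csv(out / "replicates.csv", index=False)


def aggregate_replicates(
    field_table: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Average per-field values to one row per biological replicate.

    Fields flagged by QC contribute only their defined values (NaNs are
    skipped by the mean); a replicate with no defined value stays NaN.
    """
    variables = variables or [
        c
        for c in field_table.columns
        if c not in KEY_COLS + ["field_id", "qc_flag", "background"]
        and pd.api.types.is_numeric_dtype(field_table[c])
    ]
    return (
        field_table.groupby(KEY_COLS, sort=False)[variables]
        .mean()
        .reset_index()
    )


def run_stats(
    replicate_table: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
    control_katp: str = "ctrl",
    control_rotenone: str = "veh",
) -> StatsReport:
    """Per-variable factorial inference over replicate-level records.

    Every variable gets a balanced two-way ANOVA (factor A = KATP level,
    factor B = rotenone) with gatekept Tukey post-hoc comparisons, plus
    Student's t of each non-control condition against the untreated
    control condition.  One pooled Pearson matrix covers all variables
    across all replicate records.
    """
    df = replicate_table
    variables = variables or [
        c
        for c in df.columns
        if c not in KEY_COLS and pd.api.types.is_numeric_dtype(df[c])
    ]
    anova_rows, tukey_frames, ttest_rows = [], [], []
    decisions: dict[str, str] = {}
    for var in variables:
        sub = df[KEY_COLS + [var]].dropna(subset=[var])
        try:
            tab = st.two_way_anova(
                sub[var].to_numpy(), sub["katp_level"].to_numpy(), sub["rotenone"].to_numpy()
            )
        except ValueError as exc:
            decisions[var] = f"anova_skipped: {exc}"
            continue
        frame = tab.to_frame()
        frame.insert(0, "variable", var)
        anova_rows.append(frame)

        posthoc = st.gatekept_posthoc(
            tab,
            sub.rename(columns={var: "value"}),
            alpha=alpha,
            a_col="katp_level",
            b_col="rotenone",
        )
        decisions[var] = ";".join(t.family for t in posthoc)
        for t in posthoc:
            tf = t.to_frame()
            if not tf.empty:
                tf.insert(0, "variable", var)
                tukey_frames.append(tf)

        ctrl_vals = sub[
            (sub["katp_level"] == control_katp)
            & (sub["rotenone"] == control_rotenone)
        ][var].to_numpy()
        if ctrl_vals.size >= 2:
            for (ka, rot), grp in sub.groupby(["katp_level", "rotenone"], sort=False):
                if (ka, rot) == (control_katp, control_rotenone):
                    continue
                vals = grp[var].to_numpy()
                if vals.size < 2:
                    continue
                t_stat, t_df, p = st.students_t(vals, ctrl_vals)
                ttest_rows.append(
                    {
                        "variable": var,
                        "group": f"{ka}:{rot}",
                        "control": f"{control_katp}:{control_rotenone}",
                        "t": t_stat,
                        "df": t_df,
                        "p": p,
                        "significant": p < alpha,
                    }
                )

    anova = (
        pd.concat(anova_rows, ignore_index=True)
        if anova_rows
        else pd.DataFrame(columns=["variable", "source", "sum_sq", "df", "mean_sq", "F", "p"])
    )
    tukey = (
        pd.concat(tukey_frames, ignore_index=True)
        if tukey_frames
        else pd.DataFrame(
            columns=["variable", "family", "group_1", "group_2", "mean_diff", "q", "p_adj", "significant"]
        )
    )
    ttests = pd.DataFrame(ttest_rows)
    corr = st.pearson_matrix(df[variables])
    return StatsReport(
        anova=anova,
        tukey=tukey,
        ttests=ttests,
        correlations=corr,
        replicate_table=df,
        alpha=alpha,
        decisions=decisions,
    )
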