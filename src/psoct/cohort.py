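"""Cohort-level statistics: descriptive tables and paired comparisons.

Scan-level mean birefringence values (3 repeats per subject, arm and
visit day) are averaged to subject level, summarized per arm/day
(quartiles, mean, SD, SEM), and compared within subject between day 29
and day 1 with a two-sided paired t-test:

    d_i = dn_i(day29) - dn_i(day1),
    t   = mean(d) / (sd(d) / sqrt(n)),      df = n - 1,
    CI  = mean(d) +- t_{0.975, n-1} * sd(d) / sqrt(n).

Repeats are averaged before testing to avoid pseudo-replication; no
multiple-testing adjustment is applied across arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["PairedResult", "validate_cohort_table", "subject_level",
           "descriptive_table", "paired_ttest", "paired_ttest_from_summary",
           "cohort_report"]

REQUIRED_COLUMNS = ["subject", "arm", "day", "repeat", "mean_dn"]
MAX_REPEATS = 3


@dataclass(frozen=True)
class PairedResult:
    """Within-subject day29 - day1 comparison for one treatment arm."""

    arm: str
    n: int
    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    t: float
    p: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("paired comparison requires n >= 2 subjects")
        if not (self.ci_low <= self.mean_diff <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean difference")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, repeat counts and finiteness."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if table.empty:
        raise ValueError("cohort table is empty")
    if not np.isfinite(table["mean_dn"]).all():
        raise ValueError("non-finite mean_dn in cohort table")
    counts = table.groupby(["subject", "arm", "day"]).size()
    if (counts > MAX_REPEATS).any():
        bad = counts[counts > MAX_REPEATS].index.tolist()
        raise ValueError(f"more than {MAX_REPEATS} repeats for {bad}")
    return table


def subject_level(table: pd.DataFrame) -> pd.DataFrame:
    """Average repeat-level mean_dn to one value per (subject, arm, day)."""
    validate_cohort_table(table)
    out = (table.groupby(["subject", "arm", "day"], as_index=False)["mean_dn"]
           .mean())
    return out


def descriptive_table(values: np.ndarray) -> dict[str, float]:
    """Quartiles (linear interpolation), mean, sample SD and SEM."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 1:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {
        "q25": float(q25), "median": float(med), "q75": float(q75),
        "mean": float(v.mean()), "sd": sd, "sem": sd / np.sqrt(v.size),
        "n": int(v.size),
    }


def paired_ttest(day1: np.ndarray, day29: np.ndarray, arm: str = "") -> PairedResult:
    """Two-sided paired t-test of day29 vs day1 values matched by subject."""
    a = np.asarray(day1, dtype=np.float64)
    b = np.asarray(day29, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("day1 and day29 must have matched lengths")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = b - a
    return paired_ttest_from_summary(float(d.mean()),
                                     float(d.std(ddof=1)), n, arm=arm)


def paired_ttest_from_summary(mean_diff: float, sd_diff: float, n: int,
                              arm: str = "") -> PairedResult:
    """Paired t-test from the summary statistics of the differences.

    Useful for recomputing a test from a printed mean/SD/n triple.  A zero
    SD with a zero mean yields t = 0, p = 1.
    """
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    sem = sd_diff / np.sqrt(n)
    df = n - 1
    if sem == 0:
        t = 0.0 if mean_diff == 0 else np.inf * np.sign(mean_diff)
    else:
        t = mean_diff / sem
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    tcrit = float(stats.t.ppf(0.975, df))
    return PairedResult(arm=arm, n=int(n), mean_diff=mean_diff, sd_diff=sd_diff,
                        ci_low=mean_diff - tcrit * sem,
                        ci_high=mean_diff + tcrit * sem,
                        t=float(t), p=p)


def cohort_report(table: pd.DataFrame, outdir: str | Path,
                  make_plot: bool = True) -> dict[str, PairedResult]:
    """Write descriptive and paired-comparison CSVs plus a change plot.

    Produces ``descriptives.csv`` (one row per arm/day with quartiles,
    mean, SD, SEM), ``paired_tests.csv`` (one row per arm) and
    ``subject_changes.png`` (per-subject day1 -> day29 lines per arm).
    Outputs are deterministic for a fixed input table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subj = subject_level(table)

    desc_rows = []
    for (arm, day), grp in sorted(subj.groupby(["arm", "day"])):
        row = {"arm": arm, "day": day}
        row.update(descriptive_table(grp["mean_dn"].to_numpy()))
        desc_rows.append(row)
    pd.DataFrame(desc_rows).to_csv(outdir / "descriptives.csv", index=False)

    results: dict[str, PairedResult] = {}
    test_rows = []
    for arm, grp in sorted(subj.groupby("arm")):
        wide = grp.pivot(index="subject", columns="day", values="mean_dn")
        if not {1, 29}.issubset(wide.columns):
            logger.warning("arm %s lacks both visit days; skipped", arm)
            continue
        paired = wide[[1, 29]].dropna()
        dropped = len(wide) - len(paired)
        if dropped:
            logger.info("arm %s: %d subject(s) missing a day excluded from pairing",
                        arm, dropped)
        res = paired_ttest(paired[1].to_numpy(), paired[29].to_numpy(), arm=arm)
        results[arm] = res
        test_rows.append({
            "arm": arm, "n": res.n, "mean_diff": res.mean_diff,
            "sd_diff": res.sd_diff, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "t": res.t, "p": res.p,
        })
    if not test_rows:
        raise ValueError("no arm had both visit days; cannot build report")
    pd.DataFrame(test_rows).to_csv(outdir / "paired_tests.csv", index=False)

    if make_plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        arms = sorted(results)
        fig, axes = plt.subplots(1, len(arms), figsize=(4 * len(arms), 4),
                                 squeeze=False, sharey=True)
        for ax, arm in zip(axes[0], arms):
            grp = subj[subj["arm"] == arm]
            wide = grp.pivot(index="subject", columns="day", values="mean_dn").dropna()
            for _, r in wide.iterrows():
                ax.plot([1, 29], [r[1] * 1e6, r[29] * 1e6], "o-", color="0.5",
                        alpha=0.6, markersize=3)
            ax.set_title(arm)
            ax.set_xticks([1, 29])
            ax.set_xlabel("visit day")
        axes[0][0].set_ylabel(r"mean dermal $\Delta n$ ($\times 10^{-6}$)")
        fig.tight_layout()
        fig.savefig(outdir / "subject_changes.png", dpi=120)
        plt.close(fig)
    return results
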