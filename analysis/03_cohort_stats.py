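#!/usr/bin/env python
"""Group statistics over the RT results: models 1-3, threshold, ROC/AUC.

Reads results/rt_results.csv (step 02) and reproduces the statistical
layer of the analysis: per-group summary rows (n, mean, SD, SE, 95% CI),
each positive (sub)group compared against the negative reference with
Welch t-tests and Bonferroni correction under three grouping models, the
negative threshold (upper CI bound of the negative group), and the ROC
curve with its Mann-Whitney AUC.

Writes per-model summary/comparison CSVs and roc_points.csv under results/.

Run:  python analysis/03_cohort_stats.py
"""

import json
from pathlib import Path
from types import SimpleNamespace

import pandas as pd

from ecgrt import negative_threshold, roc_auc, run_model
from ecgrt.io import read_rt_results

ROOT = Path(__file__).resolve().parents[1]


def main():
    df = read_rt_results(ROOT / "results" / "rt_results.csv")
    results = [SimpleNamespace(group=r.group, rt_pct=r.rt_index_pct)
               for r in df.itertuples(index=False)]

    report = {}
    for model in (1, 2, 3):
        mr = run_model(results, model)
        print(f"\nModel {model} (one-way ANOVA F={mr.anova_f:.2f}, "
              f"p={mr.anova_p:.2g}; Bonferroni x{len(mr.comparisons)})")
        rows = []
        for s in mr.summaries:
            rows.append({"group": s.group, "n": s.n,
                         "rt_index_pct": round(s.mean, 2),
                         "sd_pct": round(s.sd, 2),
                         "se_pct": round(s.se, 2),
                         "ci_upper_pct": round(s.ci_upper, 2),
                         "ci_lower_pct": round(s.ci_lower, 2)})
            print(f"  {s.group:9s} n={s.n:2d}  {s.mean:5.2f}% "
                  f"(SE {s.se:.2f}, CI {s.ci_lower:.2f}-{s.ci_upper:.2f})")
        pd.DataFrame(rows).to_csv(
            ROOT / "results" / f"model{model}_summary.csv", index=False)
        comp_rows = []
        for c in mr.comparisons:
            comp_rows.append({"group": c.group_a, "t": round(c.t_statistic, 3),
                              "df": round(c.df, 1), "p_raw": c.p_raw,
                              "p_bonferroni": c.p_adjusted,
                              "significant": c.significant})
            print(f"    {c.group_a:9s} vs negative: t={c.t_statistic:6.2f} "
                  f"p_adj={c.p_adjusted:.2g} "
                  f"{'*' if c.significant else 'ns'}")
        pd.DataFrame(comp_rows).to_csv(
            ROOT / "results" / f"model{model}_comparisons.csv", index=False)
        report[f"model{model}"] = {"anova_p": mr.anova_p,
                                   "comparisons": comp_rows}

    neg = df[df.group == "negative"].rt_index_pct.tolist()
    thr = negative_threshold(neg)
    scores = df.rt_index_pct.tolist()
    labels = (df.group != "negative").astype(int).tolist()
    roc = roc_auc(scores, labels)
    flagged = sum(s > thr for s, l in zip(scores, labels) if l == 1)
    n_pos = sum(labels)
    print(f"\nnegative threshold {thr:.2f}% "
          f"(flags {flagged}/{n_pos} positives)")
    print(f"AUC {roc.auc:.3f} (p={roc.p_value:.2g})")
    pd.DataFrame({"threshold": roc.thresholds,
                  "sensitivity": roc.sensitivity,
                  "specificity": roc.specificity}).to_csv(
        ROOT / "results" / "roc_points.csv", index=False, float_format="%.6g")
    report["negative_threshold_pct"] = round(thr, 2)
    report["auc"] = round(roc.auc, 3)
    report["auc_p"] = roc.p_value
    (ROOT / "results" / "stats_summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    print(f"wrote results/model*_summary.csv, model*_comparisons.csv, "
          f"roc_points.csv, stats_summary.json")


if __name__ == "__main__":
    main()
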