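#!/usr/bin/env python
"""Diagnostic prevalence with Wilson intervals, disorder co-occurrence and
comparator (PHQ-9 / GAD-7) cross-validation on the synthetic cohort, via the
full pipeline report.

Reads results/cohort.csv; writes the report files under results/report/.
"""

from pathlib import Path

from icdscreen import pipeline as pl

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = pl.read_cohort(OUT / "cohort.csv")
    rep = pl.run_full_analysis(df)
    files = pl.write_report(rep, OUT / "report")

    for label, key in (("depressive episode", "depressive_episode"),
                       ("generalized anxiety", "gad"),
                       ("either disorder", "either"),
                       ("both disorders", "both")):
        p = rep.prevalence[key]
        print(f"{label}: {100*p['proportion']:.1f}% "
              f"(95% CI {100*p['ci_low']:.1f}-{100*p['ci_high']:.1f}%), "
              f"{p['n_cases']}/{p['n_total']}")
    assoc = rep.associations
    if "idq_iaq" in assoc:
        a = assoc["idq_iaq"]
        print(f"depression x anxiety caseness: chi2({a['df']}) = {a['chi2']:.1f}, "
              f"p = {a['p']:.2g}; {a['pct_dep_also_anx']:.1f}% of depression "
              f"cases also anxiety cases")
    for which, comp in (("idq", "phq"), ("iaq", "gad")):
        a = assoc[f"{which}_{comp}"]
        print(f"{which.upper()} vs {comp.upper()}-cutoff: comparator caseness "
              f"{100*a['prevalence']:.1f}%, r = {a['pearson_r']:.2f}")
    print("wrote", ", ".join(str(f.relative_to(OUT.parent)) for f in files))


if __name__ == "__main__":
    main()
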