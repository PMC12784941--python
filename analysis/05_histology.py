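"""Histological quantification of the simulated terminal sections.

Derives nuclear-area classification thresholds from the curated training
sample, classifies detected nuclei, computes neuronal/glial densities
and corrected myelin OD (section-averaged), and tests group and lateral
differences with BH-FDR.
"""

from pathlib import Path

import pandas as pd

from corticothal import latstats, pipeline

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7
PAIRS = (("LNi", "LNc"), ("VPNi", "VPNc"), ("RSi", "RSc"))
METRICS = ("cd_ne", "cd_gl", "od")


def main():
    OUT.mkdir(exist_ok=True)
    cohort = pipeline.default_cohort(seed=SEED)
    thresholds = pipeline.derive_training_thresholds(cohort.config)
    print("classification thresholds (um^2): "
          f"neuronal [{thresholds.neuronal[0]:.1f}, {thresholds.neuronal[1]:.1f}], "
          f"glial [{thresholds.glial[0]:.1f}, {thresholds.glial[1]:.1f}]")

    histo = pipeline.process_cohort_histology(cohort, thresholds)
    histo.to_csv(OUT / "histology_roi_means.tsv", sep="\t", index=False)
    print(f"animals with histology: {histo['animal'].nunique()}")

    rows = []
    tbi = histo[histo["group"] == "TBI"]
    sham = histo[histo["group"] == "SHAM"]
    for metric in METRICS:
        for ipsi, contra in PAIRS:
            a = tbi[tbi["roi"] == ipsi].set_index("animal")[metric]
            b = tbi[tbi["roi"] == contra].set_index("animal")[metric]
            res = latstats.paired_ttest(a, b.reindex(a.index))
            rows.append({"comparison": f"TBI {ipsi} vs {contra} ({metric})",
                         "t": res.statistic, "p": res.p})
        for roi in ("LNi", "VPNi"):
            res = latstats.two_sample_ttest(
                tbi[tbi["roi"] == roi][metric], sham[sham["roi"] == roi][metric]
            )
            rows.append({"comparison": f"TBI vs SHAM in {roi} ({metric})",
                         "t": res.statistic, "p": res.p})
    tests = pd.DataFrame(rows)
    tests["q"] = latstats.bh_fdr(tests["p"].to_numpy())
    tests.to_csv(OUT / "histology_tests.tsv", sep="\t", index=False)

    for rec in tests.itertuples():
        flag = "*" if rec.q < 0.05 else " "
        print(f" {flag} {rec.comparison}: t={rec.t:.2f}, q={rec.q:.3g}")


if __name__ == "__main__":
    main()
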