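"""TSPO-PET uptake quantification of the simulated subacute scans.

Sums the 15-60 min frames, normalizes to rostro-thoracic uptake, drops
faulty injections, then tests ipsilateral-vs-contralateral thalamic
uptake (paired, within TBI) and TBI-vs-SHAM per ROI, BH-FDR corrected.
"""

from pathlib import Path

import pandas as pd

from corticothal import latstats, pipeline

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7
PAIRS = (("LNi", "LNc"), ("VPNi", "VPNc"))


def main():
    OUT.mkdir(exist_ok=True)
    cohort = pipeline.default_cohort(seed=SEED)
    pet = pipeline.process_cohort_pet(cohort)
    pet.to_csv(OUT / "pet_uptake.tsv", sep="\t", index=False)

    ok = pet[pet["injection_ok"]]
    n_bad = pet[~pet["injection_ok"]]["animal"].nunique()
    print(f"scanned: {pet['animal'].nunique()} animals; "
          f"faulty injections excluded: {n_bad}; analyzed: {ok['animal'].nunique()}")

    wide = ok.pivot_table(index=["animal", "group"], columns="roi",
                          values="u_feppa").reset_index()
    rows = []
    tbi = wide[wide["group"] == "TBI"]
    for ipsi, contra in PAIRS:
        res = latstats.paired_ttest(tbi[ipsi], tbi[contra], label=f"{ipsi} vs {contra}")
        rows.append({"comparison": f"TBI {ipsi} vs {contra} (paired)",
                     "t": res.statistic, "p": res.p})
    sham = wide[wide["group"] == "SHAM"]
    for roi in ("LNi", "LNc", "VPNi", "VPNc", "RS", "CG"):
        res = latstats.two_sample_ttest(tbi[roi], sham[roi], label=roi)
        rows.append({"comparison": f"TBI vs SHAM in {roi}",
                     "t": res.statistic, "p": res.p})
    tests = pd.DataFrame(rows)
    tests["q"] = latstats.bh_fdr(tests["p"].to_numpy())
    tests.to_csv(OUT / "pet_tests.tsv", sep="\t", index=False)

    for rec in tests.itertuples():
        flag = "*" if rec.q < 0.05 else " "
        print(f" {flag} {rec.comparison}: t={rec.t:.2f}, q={rec.q:.4g}")
    means = ok.groupby(["group", "roi"])["u_feppa"].mean().unstack()
    print("\nmean uptake (%/ml):")
    print(means.round(3).to_string())


if __name__ == "__main__":
    main()
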