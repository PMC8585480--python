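#!/usr/bin/env python
"""Risk-factor association and causal mediation for the identified CpGs.

Direction 1: joint lifestyle model per hit CpG (methylation as outcome),
then smoking -> CpG -> CHD mediation where the screen passes (p < 0.05).
Direction 2: quartile association of CpGs with cardiometabolic traits
(BP-medication offsets applied), then CpG -> trait -> CHD mediation.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import BUNDLE_DIR, RESULTS_DIR, SEED, STUDY, WORK_DIR  # noqa: E402

from ewasnet import io as enio  # noqa: E402
from ewasnet.mediation import (  # noqa: E402
    lifestyle_cpg_association,
    mediate,
    quartile_trait_association,
)
from ewasnet.simulate import (  # noqa: E402
    SBP_EXPOSURE_PROBE,
    SMOKING_MEDIATOR_PROBE,
    analytic_proportion_mediated,
)


def main() -> None:
    pheno = enio.read_phenotype(BUNDLE_DIR / "phenotype.csv")
    beta_df = enio.read_matrix(WORK_DIR / "beta.tsv", "beta")
    sub_pheno = pheno.subset(list(beta_df.columns))

    hit_probes = [SMOKING_MEDIATOR_PROBE, SBP_EXPOSURE_PROBE]
    hits = beta_df.loc[[p for p in hit_probes if p in beta_df.index]]

    # --- direction 1: lifestyle -> CpG -> CHD ---------------------------
    assoc = lifestyle_cpg_association(hits, sub_pheno)
    screen = assoc[assoc["p"] < 0.05]
    print("lifestyle-CpG screen (p < 0.05):")
    print(screen.to_string(index=False))

    med_rows = []
    for _, row in screen.iterrows():
        if row["factor"] != "smoking":
            continue
        r = mediate("lifestyle", "smoking", row["probe"], sub_pheno,
                    beta=beta_df, n_boot=0, seed=SEED)
        med_rows.append({
            "direction": "lifestyle", "exposure": "smoking",
            "mediator": row["probe"], "or_te": r.or_te, "or_nde": r.or_nde,
            "or_nie": r.or_nie,
            "proportion_mediated_pct": 100 * r.proportion_mediated,
            "p_mediation": r.p_nie,
        })
        true_pm = analytic_proportion_mediated(
            b1=STUDY.smoking_cpg_effect, t1=STUDY.smoking_chd_direct,
            t2=STUDY.cpg_chd_log_or,
            sigma2=STUDY.smoking_mediator_noise ** 2)
        print(f"smoking -> {row['probe']} -> CHD: proportion mediated "
              f"{100 * r.proportion_mediated:.1f}% "
              f"(generating-model truth {100 * true_pm:.1f}%; single-cohort "
              "estimates carry sampling error ~15-20 points and quantile "
              "normalization attenuates the mediator effect), "
              f"p = {r.p_nie:.3f}")

    # --- direction 2: CpG -> trait -> CHD -------------------------------
    quart_rows = []
    for probe in hits.index:
        for trait in ("sbp", "dbp", "tc", "glucose"):
            q = quartile_trait_association(beta_df.loc[probe], trait, sub_pheno)
            quart_rows.append({"probe": probe, "trait": trait, **q})
    quart = pd.DataFrame(quart_rows)
    print("\nquartile trait associations (Q4 vs Q1):")
    print(quart.to_string(index=False))

    for _, row in quart[quart["p_trend"] < 0.05].iterrows():
        r = mediate("trait", row["probe"], row["trait"], sub_pheno,
                    beta=beta_df, n_boot=0, seed=SEED)
        med_rows.append({
            "direction": "trait", "exposure": row["probe"],
            "mediator": row["trait"], "or_te": r.or_te, "or_nde": r.or_nde,
            "or_nie": r.or_nie,
            "proportion_mediated_pct": 100 * r.proportion_mediated,
            "p_mediation": r.p_nie,
        })
        print(f"{row['probe']} -> {row['trait']} -> CHD: proportion mediated "
              f"{100 * r.proportion_mediated:.1f}%, p = {r.p_nie:.3f}")

    RESULTS_DIR.mkdir(exist_ok=True)
    assoc.to_csv(RESULTS_DIR / "05_lifestyle_cpg.tsv", sep="\t", index=False,
                 float_format="%.4g")
    quart.to_csv(RESULTS_DIR / "05_quartile_traits.tsv", sep="\t", index=False,
                 float_format="%.4g")
    pd.DataFrame(med_rows).to_csv(RESULTS_DIR / "05_mediation.tsv", sep="\t",
                                  index=False, float_format="%.4g")
    print(f"\nmediation table -> {RESULTS_DIR / '05_mediation.tsv'}")


if __name__ == "__main__":
    main()
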