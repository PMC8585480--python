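#!/usr/bin/env python
"""Weighted co-methylation network over the top association CpGs.

Selects the top-K CpGs from the EWAS, removes clustering outliers, chooses
the soft power, builds TOM-based modules, tests module eigengenes against
case status (Bonferroni across modules), computes module-specific FDR for
significant modules, and runs the selection-bias permutation guard.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import BUNDLE_DIR, RESULTS_DIR, SEED, WORK_DIR  # noqa: E402

from ewasnet import io as enio  # noqa: E402
from ewasnet.datamodel import MethylationMatrix  # noqa: E402
from ewasnet.ewas import build_design, SurrogateVariableSet  # noqa: E402
from ewasnet.network import (  # noqa: E402
    build_modules,
    choose_soft_power,
    detect_sample_outliers,
    module_specific_fdr,
    module_trait_test,
    permutation_module_test,
    select_top_k,
)

K = 2000
PERMUTATIONS = 20


def main() -> None:
    pheno = enio.read_phenotype(BUNDLE_DIR / "phenotype.csv")
    beta_df = enio.read_matrix(WORK_DIR / "beta.tsv", "beta")
    res = pd.read_csv(WORK_DIR / "ewas.tsv", sep="\t")
    svs_df = pd.read_csv(WORK_DIR / "surrogate_variables.tsv", sep="\t",
                         index_col=0)

    top = select_top_k(res, min(K, len(res)))
    sub = beta_df.loc[top]
    outliers = detect_sample_outliers(sub)
    samples = [s for s in sub.columns if s not in set(outliers)]
    print(f"top {len(top)} CpGs; sample-clustering outliers removed: "
          f"{outliers or 'none'}")
    sub = sub[samples]
    sub_pheno = pheno.subset(samples)
    svs = SurrogateVariableSet(sv=svs_df.loc[samples])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = choose_soft_power(sub)
        mods = build_modules(sub, power, seed=SEED)
    sizes = {m: int((mods.labels == m).sum()) for m in mods.module_names}
    print(f"soft power {power}; modules: {sizes}")

    design = build_design(sub_pheno)
    n_mod = max(len(mods.module_names), 1)
    rows = []
    for m in mods.module_names:
        coef, p = module_trait_test(mods.eigengenes[m], design, svs)
        rows.append({"module": m, "n_probes": int((mods.labels == m).sum()),
                     "coef": coef, "p": p,
                     "bonferroni_significant": bool(p < 0.05 / n_mod)})
    trait = pd.DataFrame(rows)
    print(trait.to_string(index=False))

    RESULTS_DIR.mkdir(exist_ok=True)
    trait.to_csv(RESULTS_DIR / "04_module_trait.tsv", sep="\t", index=False,
                 float_format="%.4g")
    mods.labels.to_csv(WORK_DIR / "modules.tsv", sep="\t")

    fdr_frames = []
    for m in trait.loc[trait["bonferroni_significant"], "module"]:
        mf = module_specific_fdr(res, mods.probes_in(m)).reset_index()
        mf["module"] = m
        n_sig = int((mf["module_fdr"] < 0.01).sum())
        print(f"module {m}: {n_sig} CpGs at module-specific FDR < 0.01")
        fdr_frames.append(mf[mf["module_fdr"] < 0.01])
    if fdr_frames:
        pd.concat(fdr_frames).to_csv(RESULTS_DIR / "04_module_fdr_hits.tsv",
                                     sep="\t", index=False, float_format="%.4g")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        perm = permutation_module_test(
            MethylationMatrix(beta=beta_df[samples]), sub_pheno, svs,
            k=min(K, len(res)), B=PERMUTATIONS, seed=SEED, power=power)
    print(f"permutation guard (B={PERMUTATIONS}): observed min module p = "
          f"{perm.observed_min_p:.2e}, empirical p = {perm.empirical_p:.3f}")
    (RESULTS_DIR / "04_permutation.json").write_text(json.dumps({
        "B": PERMUTATIONS,
        "observed_min_p": perm.observed_min_p,
        "empirical_p": perm.empirical_p,
    }, indent=2))


if __name__ == "__main__":
    main()
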