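"""Rank the candidate cache-size models.

Builds the null + one- + two-covariate GLM set on the four principal
covariates (aspect, tree density, air temperature, soil temperature —
the variables the field analysis retained), ranks it by AICc, and adds
Akaike weights and 10,000-resample bootstrap selection frequencies.
"""

from pathlib import Path

import pandas as pd

from middencache import (
    DISPLAY_NAMES,
    PRINCIPAL_COVARIATES,
    ModelSpec,
    add_null_covariate,
    dataio,
    deviance_explained,
    fit_gaussian_glm,
    select_models,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20150824


def main() -> None:
    df = pd.read_csv(OUT / "analysis_table.csv")
    table = select_models(df, PRINCIPAL_COVARIATES, name_map=DISPLAY_NAMES,
                          bootstrap_reps=10000, seed=SEED)
    dataio.write_selection_table(table, OUT / "selection_table.csv")

    fr = table.to_frame()
    print(fr[["model_label", "k", "delta_aicc", "waicc", "pi"]]
          .round({"delta_aicc": 1, "waicc": 4, "pi": 3}).to_string(index=False))

    best = table.best
    fit = fit_gaussian_glm(ModelSpec(best.spec.label, best.spec.terms),
                           add_null_covariate(df, SEED))
    print(f"\nbest model: {best.spec.label}")
    print(f"  wAICc = {best.waicc:.4f}, pi = {best.pi:.3f} "
          f"(B = {table.bootstrap_reps}, redraws = {table.redraws})")
    print(f"  deviance explained = {100 * deviance_explained(fit):.1f}%")


if __name__ == "__main__":
    main()
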