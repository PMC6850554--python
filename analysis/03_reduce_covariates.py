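"""Thin the covariate set.

Runs the iterative PCA / correlation elimination over the 19 candidate
covariates (biotic and abiotic groups, then the pooled survivors) and
writes the elimination trace and the retained set.
"""

from pathlib import Path

import pandas as pd

from middencache import COVARIATE_GROUPS, iterative_reduce

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = pd.read_csv(OUT / "analysis_table.csv")
    cols = list(COVARIATE_GROUPS)
    trace = iterative_reduce(df[cols], COVARIATE_GROUPS)

    trace.to_frame().to_csv(OUT / "reduction_trace.csv", index=False)
    (OUT / "retained_covariates.txt").write_text("\n".join(trace.retained) + "\n")

    print(f"{len(cols)} candidate covariates -> {len(trace.retained)} retained "
          f"after {len(trace.rounds)} eliminations")
    for r in trace.rounds:
        print(f"  [{r.group:8s}] dropped {r.eliminated_variable:22s} "
              f"(r = {r.pearson_r:+.2f} with {r.partner_variable}, p = {r.p_value:.2g})")
    print("retained:", ", ".join(trace.retained))


if __name__ == "__main__":
    main()
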