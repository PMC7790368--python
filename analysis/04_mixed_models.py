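#!/usr/bin/env python
"""Report the mixed-effects model selection over the validated synergies.

Reads the pipeline's comparison tables and final-model reports (run
analysis/02 first) and checks whether the selected synergy is the one the
cohort generator actually linked to coordination variability (the
torso-bounce/push-off pattern).
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPELINE_DIR  # noqa: E402

from kinesynergy.simulate import bounce_direction  # noqa: E402


def main() -> None:
    with open(PIPELINE_DIR / "pm.json") as fh:
        pm = json.load(fh)
    with open(PIPELINE_DIR / "final_models.json") as fh:
        finals = json.load(fh)

    vecs = np.asarray(pm["eigenvectors"])
    align = np.abs(vecs @ bounce_direction())
    planted_k = int(np.argmax(align)) + 1
    print(
        f"planted DP-linked synergy: PM{planted_k} "
        f"(alignment with the push-off pattern: {align.max():.2f})"
    )
    for response, final in finals.items():
        comp = pd.read_csv(PIPELINE_DIR / f"comparison_{response}.csv")
        print(f"\n{response}: model comparison across synergies")
        print(
            comp[["model", "k", "df", "AIC", "BIC", "logLik", "singular"]]
            .round(2)
            .to_string(index=False)
        )
        hit = "matches" if final["k"] == planted_k else "does not match"
        print(
            f"best fit: PA{final['k']} (AIC {final['aic']:.1f}) -- {hit} the planted synergy"
        )
        beta_pa = final["beta"].get("pa")
        if beta_pa is not None:
            print(
                f"  fixed PA effect: beta = {beta_pa:.2f} (ICC {final['icc']:.2f}, "
                f"pseudo-R2 fixed {final['pseudo_r2_fixed']:.2f}, "
                f"LRT p = {final['p_pa_lrt']:.4g}, "
                f"Bonferroni-significant: {final['significant_bonferroni']})"
            )


if __name__ == "__main__":
    main()
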