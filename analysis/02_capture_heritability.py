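#!/usr/bin/env python
"""How much heritability do genotyped vs imputed panels capture?

Computes per-variant imputation r² and tagging ρ² on the calibrated panel,
then the expected proportion of heritability captured by the genotyped subset
(h²_G/h²) and by all imputed variants (h²_I/h²) across the alpha range — the
key result: imputation recovers far more rare-variant heritability than array
tagging, and both collapse as effects shift toward rare variants (alpha -> -1.5).
"""

from pathlib import Path

import numpy as np

from prscap import coverage, io, synthgeno

SEED = 7
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = synthgeno.default_panel(seed=SEED)
    panel, removed = coverage.maf_filter(panel, 1e-5)
    cap = coverage.build_capture_table(panel)
    RESULTS.mkdir(exist_ok=True)
    io.write_capture_table(cap, RESULTS / "capture_table.tsv")

    ut = ~cap.is_genotyped
    print(f"panel after MAF filter: {cap.m} variants ({removed} removed)")
    print(f"untyped variants: mean r²_imput={cap.r2_imput[ut].mean():.3f}, "
          f"mean ρ²={cap.rho2[ut].mean():.3f}, "
          f"cor(ρ², r²_imput)={np.corrcoef(cap.rho2[ut], cap.r2_imput[ut])[0, 1]:.2f}")

    grid = np.linspace(-1.5, 0.0, 31)
    curve = coverage.expected_capture_curve(cap, grid)
    mc = coverage.capture_proportion_curve(cap, [-1.5, -0.75, 0.0], n_rep=200, seed=SEED)
    curve.to_csv(RESULTS / "capture_curve.tsv", sep="\t", index=False)
    mc.to_csv(RESULTS / "capture_curve_mc.tsv", sep="\t", index=False)

    for _, row in curve.iloc[[0, 15, 30]].iterrows():
        print(f"alpha={row['alpha']:+.2f}: genotyped capture {row['prop_G']:.1%}, "
              f"imputed capture {row['prop_I']:.1%}")
    print(f"wrote capture table and curves to {RESULTS}")


if __name__ == "__main__":
    main()
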