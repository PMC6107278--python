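"""Probabilistic sensitivity analysis: CE plane and acceptability curve.

Draws 10,000 joint parameter samples (test price ~ Uniform(£50, £620)),
re-evaluates the full pipeline per draw, and writes the cost-effectiveness
plane and the CEAC over willingness-to-pay values up to £100,000/QALY.
"""

from pathlib import Path

import numpy as np

from cystotriage.parameters import build_base_case
from cystotriage.sensitivity import ceac, run_psa

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N = 10000


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = build_base_case()
    sample = run_psa(params, n=N, seed=SEED, price_range=(50.0, 620.0))

    plane = sample.outcomes.assign(
        delta_cost=lambda d: d.cost_alt - d.cost_ref,
        delta_qalys=lambda d: d.qalys_alt - d.qalys_ref)
    # thin the stored plane to keep the repository artefact small
    plane.iloc[::10].round(5).to_csv(OUT / "ce_plane.csv", index=False)

    grid = np.linspace(0.0, 100000.0, 101)
    curve = ceac(sample, grid)
    curve.to_frame().to_csv(OUT / "ceac.csv", index=False)

    p20 = float(ceac(sample, [20000.0]).p_triage[0])
    print(f"n = {N} draws (seed {SEED}, {sample.n_redrawn} redrawn)")
    print(f"P(triage cost-effective at £20,000/QALY) = {p20:.3f}")
    lo, hi = curve.p_triage.min(), curve.p_triage.max()
    print(f"CEAC range over £0-£100k: {lo:.3f}-{hi:.3f}")


if __name__ == "__main__":
    main()
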