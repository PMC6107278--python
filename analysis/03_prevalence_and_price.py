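"""Prevalence sensitivity and the two-way price x prevalence frontier.

Sweeps bladder-cancer prevalence to locate where the triage strategy stops
gaining QALYs over cystoscopy-for-all, computes the maximum cost-effective
test price at each prevalence (WTP £20,000/QALY), and sweeps the
per-cystoscopy utility factor.
"""

from pathlib import Path

import numpy as np

from cystotriage.parameters import build_base_case
from cystotriage.sensitivity import (cysto_disutility_sweep, prevalence_sweep,
                                     qaly_crossover, two_way_price_prevalence)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = build_base_case()

    sweep = prevalence_sweep(params, np.arange(0.0, 0.2001, 0.005))
    sweep.to_csv(OUT / "prevalence_sweep.csv", index=False)
    cross = qaly_crossover(sweep)
    print(f"Triage gains QALYs up to a prevalence of "
          f"{cross:.3f}" if cross else "No QALY crossover on [0, 0.20]")

    frontier = two_way_price_prevalence(params, np.arange(0.0, 0.1401, 0.005))
    frontier.to_csv(OUT / "price_prevalence_frontier.csv", index=False)
    eff = frontier[frontier.effective]
    print(f"Maximum cost-effective price while also QALY-effective "
          f"(prevalence {eff.prevalence.min():.2f}-{eff.prevalence.max():.2f}): "
          f"£{eff.threshold_price.max():.2f}")

    cysto = cysto_disutility_sweep(params, np.linspace(0.95, 1.0, 11))
    cysto.to_csv(OUT / "cysto_utility_sweep.csv", index=False)
    print("ΔQALY falls monotonically as cystoscopy becomes less burdensome:",
          bool(cysto.delta_qalys.is_monotonic_decreasing))


if __name__ == "__main__":
    main()
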