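"""Threshold-price analysis of the biomarker test.

Finds the highest test price at which the triage strategy remains
cost-effective at £20,000/QALY (closed form, verified by bisection) and
tabulates incremental NMB against price for the NMB-vs-price figure.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cystotriage.economics import evaluate_both, nmb
from cystotriage.parameters import build_base_case
from cystotriage.sensitivity import threshold_price, threshold_price_bisection

OUT = Path(__file__).resolve().parents[1] / "results"
WTP = 20000.0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = build_base_case()
    price, ok = threshold_price(params, WTP)
    check = threshold_price_bisection(params, WTP)
    assert abs(price - check) < 0.02, "closed form disagrees with bisection"

    import dataclasses
    rows = []
    for p in np.arange(0.0, 701.0, 50.0):
        ref, alt = evaluate_both(dataclasses.replace(params, dcrshp_price=p))
        rows.append({"price": p, "nmb_cystoscopy": nmb(ref, WTP),
                     "nmb_triage": nmb(alt, WTP)})
    pd.DataFrame(rows).to_csv(OUT / "nmb_vs_price.csv", index=False)

    print(f"Threshold price at WTP £{WTP:.0f}/QALY: £{price:.2f} "
          f"(bisection check £{check:.2f})")
    if not ok:
        print("  triage not cost-effective even for a free test")


if __name__ == "__main__":
    main()
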