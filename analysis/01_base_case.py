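"""Base-case cost-utility results for both testing strategies.

Evaluates the decision tree + 5-year Markov model at the pooled prevalence
(12.95%) with the biomarker test priced at £465.48, and writes the
incremental cost-effectiveness table to results/base_case.csv.
"""

from pathlib import Path

from cystotriage.economics import evaluate_both, icer, table_report
from cystotriage.parameters import build_base_case, catalogue_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = build_base_case()
    ref, alt = evaluate_both(params)
    report = table_report(ref, alt)
    report.to_csv(OUT / "base_case.csv", index=False)
    catalogue_frame(params).to_csv(OUT / "parameter_catalogue.csv", index=False)

    inc = icer(ref, alt)
    print(report.round(4).to_string(index=False))
    print(f"\nAt a test price of £{params.dcrshp_price:.2f} and prevalence "
          f"{params.prevalence:.4f}:")
    print(f"  triage vs cystoscopy: ΔC = £{inc.delta_cost:+.2f}, "
          f"ΔQALY = {inc.delta_qalys:+.5f}, ΔLY = {inc.delta_ly:+.5f} "
          f"({inc.dominance})")


if __name__ == "__main__":
    main()
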