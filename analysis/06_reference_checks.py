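"""Closure checks against the published per-site and register tables.

Everything independently derivable from print is recomputed by the
package: the per-site patient/event totals, the audit-funnel arithmetic
on the pooled failure rates, the event-count-weighted pooling of
per-site rates, and the 11-option register fragment. Writes
results/reference_checks.json.
"""

import argparse
import json
from pathlib import Path

from icpc_audit import correct_code_pct_from_step_rates, valid_pct_from_step_rates
from icpc_audit.refdata import d01_register, pooled_pct_from_site_rates, site_statistics

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    frame = site_statistics()

    totals = {
        "n_sites": len(frame),
        "patients": int(frame["patients"].sum()),
        "problem_events": int(frame["problem_events"].sum()),
    }
    funnel = {
        "pct_valid_from_pooled_rates": round(valid_pct_from_step_rates(6.2, 4.0, 53.8), 1),
        "pct_correct_code_from_pooled_rates": round(
            correct_code_pct_from_step_rates(6.2, 4.0), 1
        ),
    }
    pooled = {
        col.replace("pct_", "pooled_"): round(pooled_pct_from_site_rates(frame, col), 1)
        for col in ("pct_missing", "pct_code_mismatch", "pct_text_mismatch")
    }
    register = {"d01_option_count": d01_register().option_count("D01")}

    print(f"site totals: {totals['patients']} patients, "
          f"{totals['problem_events']} problem events across {totals['n_sites']} sites")
    print(f"funnel closure: {funnel['pct_valid_from_pooled_rates']}% fully conformant, "
          f"{funnel['pct_correct_code_from_pooled_rates']}% with a register-valid code")
    print(f"weighted pooling of per-site rates: missing {pooled['pooled_missing']}%, "
          f"code mismatch {pooled['pooled_code_mismatch']}%, "
          f"text mismatch {pooled['pooled_text_mismatch']}% "
          "(reconstructed from 1-decimal per-site rates)")
    print(f"register fragment: D01 has {register['d01_option_count']} text options")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "reference_checks.json").write_text(
        json.dumps({"totals": totals, "funnel": funnel,
                    "weighted_pooling": pooled, "register": register}, indent=2) + "\n"
    )
    print(f"outputs -> {out / 'reference_checks.json'}")


if __name__ == "__main__":
    main()
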