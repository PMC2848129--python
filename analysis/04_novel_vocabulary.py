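"""Characterize clinician-added ('new') diagnosis texts in the stream.

Novel texts are those absent from the register's full text set —
register-wide, so a text filed under the wrong code but registered
elsewhere counts as a text mismatch, not a novel diagnosis. Reports the
distinct novel texts with usage counts and buckets their reuse (used
once / 2-10 times / more than 10), which is heavily skewed toward
single use under Zipf-like reuse.
"""

import argparse
import json
from pathlib import Path

from icpc_audit import find_novel_diagnoses, load_events, load_register, usage_buckets

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    sim = ROOT / "results" / "synthetic"
    out = ROOT / "results" / "vocabulary"
    out.mkdir(parents=True, exist_ok=True)

    register = load_register(sim / "register.tsv")
    events = load_events(sim / "events.tsv").events
    report = find_novel_diagnoses(events, register)
    buckets = usage_buckets(report)

    with open(out / "novel_diagnoses.tsv", "w", encoding="utf-8") as fh:
        report.write_tsv(fh)
    (out / "usage_buckets.json").write_text(
        json.dumps({"n_novel_texts": report.n_novel_texts, "once": buckets.once,
                    "few_2_10": buckets.few, "many_gt_10": buckets.many}, indent=2) + "\n"
    )

    n_uses = sum(e.count for e in report.entries.values())
    print(f"{report.n_novel_texts} distinct novel texts covering {n_uses} events "
          f"({100 * n_uses / len(events):.1f}% of the stream)")
    print(f"reuse buckets: {buckets.once} used once, {buckets.few} used 2-10 times, "
          f"{buckets.many} used >10 times")
    top = max(report.entries.values(), key=lambda e: e.count, default=None)
    if top:
        print(f"most reused: {top.text!r} ({top.count} uses, {len(top.codes)} codes)")
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
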