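"""Per-phase appropriate/inappropriate coding in wildcard-defined areas.

Selects events for each shipped problem area (pneumonia/lower
respiratory, diabetes, tonsillitis, anaemia) by SQL-LIKE wildcard
patterns over the normalized diagnosis text, then tabulates — per study
phase — how many carry a code from the area's configured appropriate
set vs a register-valid code outside it, with across-site dispersion
(median, sample SD, mean, SE, range).

The synthetic texts are generated tokens, so on the simulated stream
the areas are exercised against a handful of planted area events.
"""

import argparse
from datetime import date
from pathlib import Path

import pandas as pd

from icpc_audit import ProblemEvent, area_phase_summary, load_events, load_register, match_area
from icpc_audit.refdata import default_problem_areas

ROOT = Path(__file__).resolve().parents[1]

# planted area events: realistic labels over both phases and three sites
PLANTED = [
    ("s1", date(1995, 3, 1), "R81", "Bakteriell pneumoni"),
    ("s1", date(1996, 7, 1), "R81", "Pneumoni"),
    ("s2", date(1997, 2, 1), "D01", "Pneumoni høyre side"),   # inappropriate
    ("s2", date(2003, 5, 1), "R81", "Mykoplasma pneumoni"),
    ("s3", date(2004, 9, 1), "", "Pneumoni kontroll"),              # missing code
    ("s1", date(1994, 1, 1), "T90", "Diabetes mellitus type 2"),
    ("s2", date(2005, 6, 1), "T90", "Diabetes kontroll"),
    ("s3", date(2006, 6, 1), "B80", "Diabetes og anemi"),           # inappropriate for diabetes
    ("s1", date(1998, 4, 1), "R76", "Akutt tonsillitt"),
    ("s2", date(2002, 8, 1), "R72", "Streptokokk tonsillitt"),
    ("s3", date(2001, 1, 1), "B80", "Jernmangelanemi"),
    ("s1", date(1993, 2, 1), "B82", "Alvorlig anemi"),
]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    sim = ROOT / "results" / "synthetic"
    out = ROOT / "results" / "areas"
    out.mkdir(parents=True, exist_ok=True)

    register = load_register(sim / "register.tsv")
    events = load_events(sim / "events.tsv").events
    events = events + [ProblemEvent(*row) for row in PLANTED]

    rows = []
    for area in default_problem_areas():
        selected = match_area(events, area)
        print(f"{area.name}: {len(selected)} events matched "
              f"{len(area.patterns)} pattern(s)")
        for phase, stats in sorted(
            area_phase_summary(selected, area, register).items(),
            key=lambda kv: kv[0].value,
        ):
            rows.append({
                "area": area.name, "phase": phase.value,
                "n_total": stats.n_total,
                "n_appropriate": stats.n_appropriate,
                "n_inappropriate": stats.n_inappropriate,
                "pct_appropriate": round(stats.pct_appropriate, 1),
                "pct_inappropriate": round(stats.pct_inappropriate, 1),
                "median_appropriate": stats.appropriate.median,
                "mean_appropriate": round(stats.appropriate.mean, 2),
                "range_appropriate": f"{stats.appropriate.range_lo}-{stats.appropriate.range_hi}",
                "n_sites": stats.n_sites,
            })
            print(f"  {phase.value}: {stats.n_appropriate} appropriate / "
                  f"{stats.n_inappropriate} inappropriate of {stats.n_total}")

    pd.DataFrame(rows).to_csv(out / "area_phase_stats.tsv", sep="\t", index=False)
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
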