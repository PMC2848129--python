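"""Published reference figures shipped with the package.

Two small tables from the 12-site Norwegian primary-care material are
bundled so the pipeline's arithmetic can be checked against print:
per-site collection periods, patient/event counts and audit failure
rates; and the 11 published diagnosis-text options for code D01. The
default problem-area definitions (editable JSON) live here too.

The full 1.5-million-event export was never deposited; these tables are
summary figures only, used to validate aggregation, never as audit
input.
"""

from __future__ import annotations

import io
from importlib import resources

import numpy as np
import pandas as pd

from .register import Register, parse_register
from .vocabulary import ProblemAreaDefinition, load_area_definitions

__all__ = [
    "d01_register",
    "default_problem_areas",
    "pooled_pct_from_site_rates",
    "site_statistics",
]


def _data_text(name: str) -> str:
    return resources.files("icpc_audit.data").joinpath(name).read_text(encoding="utf-8")


def site_statistics() -> pd.DataFrame:
    """Per-site reference table: dates, patients, events, failure rates."""
    return pd.read_csv(
        io.StringIO(_data_text("site_statistics.tsv")),
        sep="\t",
        comment="#",
        parse_dates=["first_event", "last_event"],
    )


def d01_register() -> Register:
    """The published 11-option register fragment for code D01."""
    return parse_register(io.StringIO(_data_text("d01_options.tsv")))


def default_problem_areas() -> list[ProblemAreaDefinition]:
    """Shipped wildcard definitions for the four studied problem areas."""
    return load_area_definitions(io.StringIO(_data_text("problem_areas.json")))


def pooled_pct_from_site_rates(
    frame: pd.DataFrame,
    rate_col: str,
    n_col: str = "problem_events",
) -> float:
    """Event-count-weighted pooled rate from per-site printed percentages.

    Per-site failure counts are reconstructed as ``round(pct/100 * n)``
    (half away from zero, since the printed rates are rounded values of
    integer counts) and pooled as ``100 * sum(counts) / sum(n)``.
    """
    counts = np.floor(frame[rate_col] / 100.0 * frame[n_col] + 0.5)
    return 100.0 * counts.sum() / frame[n_col].sum()
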