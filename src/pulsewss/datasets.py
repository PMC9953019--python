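"""Packaged result tables for the seven-aneurysm factorial study.

The package ships, as plain CSV, the printed summary tables of a
5 rheology x 3 inlet-profile factorial study on seven patient-specific
abdominal aortic aneurysms:

==========  ============================================================
table id    contents
==========  ============================================================
``T1``      per-case inlet radius, mean/peak Reynolds number, Womersley
            number
``T3``      grid-convergence triplet (coarse/medium/fine) for TAWSS,
            OSI and RRT, with the published convergence diagnostics
``T5``      flow asymmetry / dispersion percentages (``FA_pct``,
            ``FD_pct``)
``T6``      thrombus-prone area percentages (``TAWSS_pct``, ``OSI_pct``,
            ``RRT_pct``)
``T7``      area-averaged index values (``*_ave``)
``T8``      index maxima (``*_max``)
``T9``      index minima (``*_min``)
==========  ============================================================

``T5``-``T9`` are long-format tables with header
``case,rheology,inlet,variable,value`` and 105 records per response
variable (7 cases x 5 rheologies x 3 inlets).  Values are stored exactly
as printed (same decimal places).
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CASES", "RHEOLOGIES", "INLETS", "RESPONSE_VARIABLES",
    "fixture_path", "load_paper_table", "load_all_responses",
]

CASES = ("2B", "7A", "14B", "16A", "31A", "41B", "63A")
RHEOLOGIES = ("Cs", "CY", "HB", "N", "P")
INLETS = ("Parabolic", "Plug", "Womersley")

#: The fourteen response variables, keyed by the table that carries them.
RESPONSE_VARIABLES = {
    "T5": ("FA_pct", "FD_pct"),
    "T6": ("TAWSS_pct", "OSI_pct", "RRT_pct"),
    "T7": ("TAWSS_ave", "OSI_ave", "RRT_ave"),
    "T8": ("TAWSS_max", "OSI_max", "RRT_max"),
    "T9": ("TAWSS_min", "OSI_min", "RRT_min"),
}

_FILES = {
    "T1": "table1.csv",
    "T3": "table3.csv",
    "T5": "table5.csv",
    "T6": "table6.csv",
    "T7": "table7.csv",
    "T8": "table8.csv",
    "T9": "table9.csv",
}


def fixture_path(table_id: str) -> Path:
    """Filesystem path of a packaged table CSV."""
    try:
        fname = _FILES[table_id]
    except KeyError:
        raise ValueError(
            f"unknown table id {table_id!r}; choose from {sorted(_FILES)}"
        ) from None
    return Path(resources.files("pulsewss").joinpath("data", fname))


def load_paper_table(table_id: str) -> pd.DataFrame:
    """Load a packaged table.

    ``T5``-``T9`` come back in long format (``case, rheology, inlet,
    variable, value``); ``T1`` and ``T3`` keep their own constant-table
    schemas.
    """
    df = pd.read_csv(fixture_path(table_id))
    if table_id in RESPONSE_VARIABLES:
        expected = 105 * len(RESPONSE_VARIABLES[table_id])
        if len(df) != expected:  # pragma: no cover - packaging guard
            raise RuntimeError(
                f"{table_id}: expected {expected} records, found {len(df)}")
    return df


def load_all_responses() -> pd.DataFrame:
    """Concatenate ``T5``-``T9`` into one long table of all 14 responses."""
    return pd.concat(
        [load_paper_table(t) for t in RESPONSE_VARIABLES], ignore_index=True
    )
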