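"""Published reference scores shipped with the package.

The 148-nation analysis behind the published index is built from data-bank
extracts that are not redistributed here, but the printed index scores of
the 30 extreme nations — the 15 most and 15 least vulnerable, i.e. the
upper and lower tenth percentiles of the 148-nation cohort — are. Because
the cohort's most and least vulnerable nations are both in this subset, the
min-max anchors of the full cohort are recoverable from it, and the
additive vulnerability scores can be reproduced from the printed
sensitivity, exposure and adaptive-capacity values alone.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: size of the full cohort the fixture's ranks refer to
FULL_COHORT_N = 148


def extreme_nations_fixture() -> pd.DataFrame:
    """The 30 extreme nations' published ranks and rounded index scores.

    Indexed by nation_id; columns: ``name``, ``group`` ("most"/"least"),
    published rank/score pairs for overall vulnerability (``v_rank``/``v``),
    sensitivity (``s_rank``/``s``), exposure (``e_rank``/``e``), adaptive
    capacity (``ac_rank``/``ac``) and the climate-only and population-only
    scenario vulnerabilities (``v_cc*``, ``v_pg*``). Scores are printed to
    two decimals.
    """
    path = resources.files("herdvuln.data") / "index_scores_extremes.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype={"nation_id": str})
    return df.set_index("nation_id")


def extreme_nations_indices() -> pd.DataFrame:
    """The fixture's S, E, AC columns renamed for the model stage."""
    df = extreme_nations_fixture()
    return df[["s", "e", "ac"]].rename(columns={"s": "S", "e": "E", "ac": "AC"})
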