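"""Published bookkeeping of the trial's 23-target roster.

The trial identified 23 FDG targets across subjects; seven of them
(targets 2, 10, 11, 13, 20, 21 and 23) fell below the 1.728-mL
evaluability threshold and were excluded from the statistical analysis,
leaving 16 evaluable targets.  Target 2 measured only 0.1 mL.

Per-target volumes beyond these facts were not published, so the roster
returned here carries synthetic representative volumes: the published
content is the id list and each target's evaluability status, which is all
the bookkeeping utilities consume.
"""

from __future__ import annotations

import pandas as pd

from .quantify import is_evaluable

__all__ = [
    "N_TARGETS",
    "EXCLUDED_TARGET_IDS",
    "trial_target_roster",
    "count_evaluable",
]

#: Total targets identified across subjects.
N_TARGETS = 23
#: Targets excluded as smaller than 3x3x3 voxels (1.728 mL).
EXCLUDED_TARGET_IDS = frozenset({2, 10, 11, 13, 20, 21, 23})

# Representative (synthetic) volumes: 0.1 mL is the published size of
# target 2; other excluded targets get a sub-threshold placeholder and
# evaluable targets a supra-threshold placeholder.
_SUBTHRESHOLD_PLACEHOLDER_ML = 1.0
_EVALUABLE_PLACEHOLDER_ML = 5.0


def trial_target_roster() -> pd.DataFrame:
    """The 23-target roster with representative volumes.

    Columns: ``target_id``, ``volume_ml`` (synthetic except target 2),
    ``published_excluded`` (the published exclusion status).
    """
    rows = []
    for tid in range(1, N_TARGETS + 1):
        excluded = tid in EXCLUDED_TARGET_IDS
        if tid == 2:
            vol = 0.1
        elif excluded:
            vol = _SUBTHRESHOLD_PLACEHOLDER_ML
        else:
            vol = _EVALUABLE_PLACEHOLDER_ML
        rows.append(
            {"target_id": tid, "volume_ml": vol, "published_excluded": excluded}
        )
    return pd.DataFrame(rows)


def count_evaluable(roster: pd.DataFrame | None = None) -> int:
    """Number of roster targets passing the 1.728-mL evaluability filter."""
    if roster is None:
        roster = trial_target_roster()
    return int(roster["volume_ml"].map(is_evaluable).sum())
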